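"""Shared in-memory containers for assay count data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ASSAYS", "AssayCounts"]

#: the five assay quantities emitted by the study design:
#: labelled unspliced RNA (TT-seq), nuclear unspliced / nuclear spliced /
#: cytoplasmic spliced RNA (Frac-seq) and total RNA (conventional RNA-seq).
ASSAYS = (
    "TT_labelled_unspliced",
    "FRAC_nuclear_unspliced",
    "FRAC_nuclear_spliced",
    "FRAC_cytoplasmic_spliced",
    "TOTAL",
)


@dataclass
class AssayCounts:
    """Gene x sample count matrix for one assay quantity.

    Attributes
    ----------
    assay
        One of :data:`ASSAYS`.
    matrix
        DataFrame (genes as rows, samples as columns) of non-negative
        counts.  Counts are integers when sampled; the noiseless simulation
        mode emits expected counts as floats.
    samples
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``, aligned with the matrix columns.
    """

    assay: str
    matrix: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay label {self.assay!r}; expected one of {ASSAYS}")
        if self.matrix.columns.duplicated().any():
            dup = self.matrix.columns[self.matrix.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in {self.assay} matrix")
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in {self.assay} matrix")
        missing = set(self.matrix.columns) - set(self.samples.index)
        extra = set(self.samples.index) - set(self.matrix.columns)
        if missing or extra:
            raise ValueError(
                f"{self.assay}: sample ids in matrix but not sheet {sorted(missing)}; "
                f"in sheet but not matrix {sorted(extra)}"
            )
        self.samples = self.samples.loc[self.matrix.columns]
        vals = self.matrix.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"{self.assay}: matrix entries must be numeric")
        if (vals < 0).any():
            raise ValueError(f"{self.assay}: negative counts present")
        counts = self.samples["condition"].value_counts()
        if (counts < 1).any() or len(counts) == 0:
            raise ValueError(f"{self.assay}: every condition needs >= 1 replicate")
        self.matrix.index.name = "gene_id"

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    def columns_for(self, condition: str) -> pd.Index:
        return self.samples.index[self.samples["condition"] == condition]

    def require_integers(self) -> None:
        vals = self.matrix.to_numpy(float)
        if not np.allclose(vals, np.round(vals), atol=1e-8):
            raise ValueError(f"{self.assay}: non-integer count entries present")
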