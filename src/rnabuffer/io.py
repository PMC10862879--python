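"""Tab-delimited readers/writers for count matrices, sample sheets and
annotation tables.

All tables are plain TSV with headers; count matrices have genes as rows
with ``gene_id`` as the first column.  Writers use a fixed float format so
that identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ASSAYS, AssayCounts

__all__ = [
    "read_matrix",
    "read_sample_sheet",
    "read_annotation",
    "read_counts",
    "write_matrix",
    "write_table",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "replicate", "assay")
ANNOTATION_COLUMNS = (
    "premrna_length_kb",
    "n_exons",
    "intronless",
    "mitochondrial",
    "spikein",
    "target",
)
FLOAT_FORMAT = "%.10g"


def _check_exists(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return path


def read_matrix(path) -> pd.DataFrame:
    """Read a gene x sample TSV count matrix (first column ``gene_id``)."""
    path = _check_exists(path)
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {frame.columns[0]!r}")
    frame = frame.set_index("gene_id")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene_id {dup!r}")
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric entries in columns {non_numeric}")
    if (frame.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts present")
    return frame


def read_sample_sheet(path) -> pd.DataFrame:
    path = _check_exists(path)
    sheet = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet is missing columns {sorted(missing)}")
    unknown = set(sheet["assay"]) - set(ASSAYS)
    if unknown:
        raise ValueError(f"{path}: unknown assay labels {sorted(unknown)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicated sample_id {dup!r}")
    return sheet.set_index("sample_id")


def read_annotation(path, required=ANNOTATION_COLUMNS) -> pd.DataFrame:
    path = _check_exists(path)
    ann = pd.read_csv(path, sep="\t")
    if ann.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id'")
    ann = ann.set_index("gene_id")
    missing = set(required) - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation is missing columns {sorted(missing)}")
    for flag in ("intronless", "mitochondrial", "spikein", "target"):
        if flag in ann.columns:
            ann[flag] = ann[flag].astype(bool)
    return ann


def read_counts(
    directory, sample_sheet_path=None, require_integer: bool = False
) -> dict[str, AssayCounts]:
    """Read every assay matrix referenced by a sample sheet.

    Expects ``counts_<assay>.tsv`` files next to the sheet (default
    ``<directory>/sample_sheet.tsv``).  Sample ids present in the sheet but
    absent from the matrix (or vice versa) raise with the offending ids.
    Noiseless simulated fixtures contain expected counts as floats;
    ``require_integer`` enforces integer counts for real data.
    """
    directory = Path(directory)
    sheet = read_sample_sheet(sample_sheet_path or directory / "sample_sheet.tsv")
    out: dict[str, AssayCounts] = {}
    for assay in sheet["assay"].unique():
        matrix = read_matrix(directory / f"counts_{assay}.tsv")
        samples = sheet[sheet["assay"] == assay][["condition", "replicate"]]
        ac = AssayCounts(assay=assay, matrix=matrix, samples=samples)
        if require_integer:
            ac.require_integers()
        out[assay] = ac
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
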