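"""Scatter plots of the buffering panel.

One figure per compensatory axis: Dlog2(transcription) against
Dlog2(retention), Dlog2(stability) or Dlog2(N/C ratio), with significant
genes darkened, intronless genes outlined on the N/C panel, and an
optional colour overlay for total-RNA changes (up/down/ns).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["buffering_scatter", "write_buffering_plots"]

_AXES = {
    "retention": "Dlog2 nuclear retention",
    "cyto_stability": "Dlog2 cytoplasmic stability",
    "ncr": "Dlog2 N/C ratio",
}
_DE_COLORS = {"up": "#c0392b", "down": "#2471a3", "ns": "#b0b0b0"}


def buffering_scatter(
    fold_changes: pd.DataFrame,
    axis: str,
    annotation: pd.DataFrame | None = None,
    total_de: pd.DataFrame | None = None,
    ax=None,
):
    """Scatter of Dlog2 alpha vs one compensatory axis; returns the Axes."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    lfc = fold_changes.pivot(index="gene_id", columns="rate", values="log2fc")
    cls = fold_changes.pivot(index="gene_id", columns="rate", values="class")
    sub = lfc[["alpha", axis]].dropna()
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4.0))
    if total_de is not None:
        colors = total_de["class"].reindex(sub.index).fillna("ns").map(_DE_COLORS)
        ax.scatter(sub["alpha"], sub[axis], s=6, c=colors, linewidths=0)
    else:
        sig = cls["alpha"].reindex(sub.index).isin(["up", "down"])
        ax.scatter(sub.loc[~sig, "alpha"], sub.loc[~sig, axis], s=5,
                   c="#c9c9c9", linewidths=0)
        ax.scatter(sub.loc[sig, "alpha"], sub.loc[sig, axis], s=7,
                   c="#333333", linewidths=0)
    if axis == "ncr" and annotation is not None and "intronless" in annotation:
        il = annotation.index[annotation["intronless"].astype(bool)].intersection(sub.index)
        ax.scatter(sub.loc[il, "alpha"], sub.loc[il, "ncr"], s=14,
                   facecolors="none", edgecolors="black", linewidths=0.6)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel("Dlog2 transcription rate")
    ax.set_ylabel(_AXES[axis])
    return ax


def write_buffering_plots(
    fold_changes: pd.DataFrame,
    directory,
    annotation: pd.DataFrame | None = None,
    total_de: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the three panels as PNG files; returns the paths."""
    directory = Path(directory)
    paths = []
    for axis in _AXES:
        ax = buffering_scatter(fold_changes, axis, annotation, total_de)
        path = directory / f"scatter_alpha_vs_{axis}.png"
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        paths.append(path)
    return paths
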