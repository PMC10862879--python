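"""Quantifying gene-specific transcript buffering.

Buffering is the compensatory coupling between a gene's transcription
change and its nuclear retention / cytoplasmic stability changes that
keeps its RNA abundance stable.  This module measures it from the
rate-level fold changes: Pearson correlations between Dlog2(alpha) and the
compensatory axes, N/C-ratio behaviour (count-level and rate-level routes),
gene-architecture binning with Mann-Whitney tests, target-set enrichment,
and a per-gene buffering-efficiency classification against total-RNA
differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssayCounts
from .normalize import bh_adjust

__all__ = [
    "PearsonResult",
    "BufferingSummary",
    "pearson",
    "buffering_correlations",
    "ncr_fold_change_from_counts",
    "bin_comparison",
    "mann_whitney",
    "target_enrichment",
    "buffering_efficiency",
]

LENGTH_BIN_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf)
LENGTH_BIN_LABELS = ("<10", "10-20", "20-30", "30-40", "40-50", ">50")


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation with two-sided p (t-distribution, n-2 df).

    Pairs with a missing value are dropped (their number is reflected in
    ``n``).  Zero variance in either input leaves r undefined (NaN).
    """
    x = pd.Series(np.asarray(x, float))
    y = pd.Series(np.asarray(y, float))
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"pearson requires >= 3 complete pairs, got {n}")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return PearsonResult(np.nan, np.nan, n)
    r, p = stats.pearsonr(x, y)
    return PearsonResult(float(r), float(p), n)


@dataclass
class BufferingSummary:
    """Correlation panel of the buffering analysis.

    ``*_all`` correlations are over every analysed gene; ``*_sig`` over the
    genes with a significant transcription change (or significance on both
    axes, if requested); the NCR panel is reported for all genes and for
    intronless genes separately.
    """

    r_alpha_retention_all: float
    r_alpha_retention_sig: float
    r_alpha_stability_all: float
    r_alpha_stability_sig: float
    r_alpha_ncr_all: float
    r_alpha_ncr_intronless: float
    n_all: int
    n_sig: int
    n_intronless: int
    notes: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def _wide(fold_changes: pd.DataFrame, column: str) -> pd.DataFrame:
    return fold_changes.pivot(index="gene_id", columns="rate", values=column)


def buffering_correlations(
    fold_changes: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    require_both_axes: bool = False,
) -> BufferingSummary:
    """Pearson correlations of Dlog2(alpha) with the compensatory axes.

    ``fold_changes`` is the long table from
    :func:`rnabuffer.rates.rate_fold_changes`.  The significant subset is
    defined by the alpha-rate class (|log2fc| > threshold, p below
    threshold, as encoded in the table); with ``require_both_axes`` a gene
    must also be significant on the partner axis.
    """
    lfc = _wide(fold_changes, "log2fc")
    cls = _wide(fold_changes, "class")
    notes = []

    def corr(a: str, b: str, mask=None) -> tuple[float, int]:
        sub = lfc[[a, b]].dropna()
        if mask is not None:
            sub = sub.loc[sub.index.intersection(mask)]
        if len(sub) < 3:
            notes.append(f"<3 genes for corr({a},{b}); omitted")
            return np.nan, len(sub)
        res = pearson(sub[a], sub[b])
        return res.r, res.n

    sig_alpha = cls.index[cls["alpha"].isin(["up", "down"])]

    def sig_mask(partner: str) -> pd.Index:
        if not require_both_axes:
            return sig_alpha
        return sig_alpha.intersection(cls.index[cls[partner].isin(["up", "down"])])

    r_ret_all, n_all = corr("alpha", "retention")
    r_ret_sig, n_sig = corr("alpha", "retention", sig_mask("retention"))
    r_sta_all, _ = corr("alpha", "cyto_stability")
    r_sta_sig, _ = corr("alpha", "cyto_stability", sig_mask("cyto_stability"))
    r_ncr_all, _ = corr("alpha", "ncr")
    if annotation is not None and "intronless" in annotation:
        intronless = annotation.index[annotation["intronless"].astype(bool)]
        r_ncr_il, n_il = corr("alpha", "ncr", intronless)
    else:
        notes.append("no intronless annotation; intronless NCR correlation omitted")
        r_ncr_il, n_il = np.nan, 0

    return BufferingSummary(
        r_alpha_retention_all=r_ret_all,
        r_alpha_retention_sig=r_ret_sig,
        r_alpha_stability_all=r_sta_all,
        r_alpha_stability_sig=r_sta_sig,
        r_alpha_ncr_all=r_ncr_all,
        r_alpha_ncr_intronless=r_ncr_il,
        n_all=n_all,
        n_sig=len(sig_alpha),
        n_intronless=n_il,
        notes="; ".join(notes),
    )


def ncr_fold_change_from_counts(
    nuclear: AssayCounts,
    cytoplasmic: AssayCounts,
    factors_nuclear: pd.Series,
    factors_cytoplasmic: pd.Series,
    control: str = "control",
    treated: str = "treated",
    pseudo: float = 0.0,
) -> pd.Series:
    """Count-level Dlog2 of the nuclear/cytoplasmic ratio, treated vs control.

    Independent of the kinetic model: Dlog2 NCR =
    log2(N/C)_treated - log2(N/C)_control on replicate-averaged normalized
    spliced counts (plus an optional pseudo-level for zero-laden data).  On
    noiseless data this equals the rate-level (gamma - eta) fold change
    exactly.
    """
    genes = nuclear.matrix.index.intersection(cytoplasmic.matrix.index)

    def mean_norm(ac: AssayCounts, factors: pd.Series, condition: str) -> pd.Series:
        cols = ac.columns_for(condition)
        if len(cols) == 0:
            raise ValueError(f"condition {condition!r} missing from assay {ac.assay}")
        return (
            ac.matrix.loc[genes, cols].div(factors.loc[cols], axis=1).mean(axis=1)
            + pseudo
        )

    n_c = mean_norm(nuclear, factors_nuclear, control)
    n_t = mean_norm(nuclear, factors_nuclear, treated)
    c_c = mean_norm(cytoplasmic, factors_cytoplasmic, control)
    c_t = mean_norm(cytoplasmic, factors_cytoplasmic, treated)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(n_t / c_t) - np.log2(n_c / c_c)
    out = pd.Series(out, index=genes, name="delta_log2_ncr")
    return out.replace([np.inf, -np.inf], np.nan)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two samples.

    Exact null distribution when both groups have <= 8 observations and the
    pooled values are tie-free; otherwise the normal approximation with tie
    correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


_SCHEMES = ("premrna_length_kb", "exon_count", "intronless_vs_rest", "histone_class")


def bin_comparison(
    values: pd.Series,
    annotation: pd.DataFrame,
    scheme: str = "premrna_length_kb",
) -> pd.DataFrame:
    """Compare a per-gene statistic between gene-architecture bins.

    Bins follow the scheme: pre-mRNA length (<10, 10-20, ..., >50 kb; the
    <10 kb bin is the reference), exon count (1, 2, ..., 7, >=8; one exon
    is the reference), intronless vs intron-containing (the latter is the
    reference) or a user-supplied ``histone_class`` column (first class in
    sorted order is the reference).  Each bin is tested against the
    reference with a two-sided Mann-Whitney test; p-values are BH-adjusted
    across the bin comparisons.  Empty bins are skipped with a note.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    ann = annotation.reindex(values.index)
    values = values.dropna()
    ann = ann.reindex(values.index)

    if scheme == "premrna_length_kb":
        bins = pd.cut(
            ann["premrna_length_kb"], LENGTH_BIN_EDGES, labels=LENGTH_BIN_LABELS
        ).astype(object)
        order = list(LENGTH_BIN_LABELS)
    elif scheme == "exon_count":
        n_ex = ann["n_exons"].clip(upper=8)
        bins = n_ex.map(lambda k: ">=8" if k == 8 else str(int(k)))
        order = [str(i) for i in range(1, 8)] + [">=8"]
    elif scheme == "intronless_vs_rest":
        bins = np.where(ann["intronless"].astype(bool), "intronless", "intron-containing")
        bins = pd.Series(bins, index=values.index)
        order = ["intron-containing", "intronless"]
    else:
        bins = ann["histone_class"].astype(object)
        order = sorted(bins.dropna().unique())

    bins = pd.Series(bins, index=values.index)
    reference = order[0]
    ref_values = values[bins == reference]
    rows = []
    notes = []
    for label in order:
        sub = values[bins == label]
        row = {
            "bin": label,
            "n": len(sub),
            "median": float(sub.median()) if len(sub) else np.nan,
            "U": np.nan,
            "p": np.nan,
            "is_reference": label == reference,
        }
        if label != reference:
            if len(sub) == 0 or len(ref_values) == 0:
                notes.append(f"bin {label!r} empty; comparison skipped")
            else:
                row["U"], row["p"] = mann_whitney(sub, ref_values)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("bin")
    tested = out["p"].notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out.attrs["notes"] = notes
    out.attrs["scheme"] = scheme
    return out


def target_enrichment(
    deg_sets: dict[str, set],
    targets: set,
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each DEG set for the target flag.

    For each set, reports the Venn-style contingency counts, the sample
    odds ratio and the one-sided hypergeometric p of the overlap being at
    least as large as observed.  Empty sets get p = 1 and a flag.
    """
    universe = set(universe)
    targets = set(targets) & universe
    M, K = len(universe), len(targets)
    rows = []
    for name, genes in deg_sets.items():
        genes = set(genes) & universe
        n = len(genes)
        k = len(genes & targets)
        if n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        a, b = k, n - k
        c, d = K - k, M - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append(
            {
                "set": name,
                "n_set": n,
                "n_targets": K,
                "overlap": k,
                "expected_overlap": n * K / M if M else np.nan,
                "odds_ratio": odds,
                "p": p,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def buffering_efficiency(
    fold_changes: pd.DataFrame,
    total_de: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Classify genes by how completely buffering absorbed their
    transcription change.

    A gene whose transcription changed significantly (rate-level criteria,
    as encoded in ``fold_changes``'s alpha class) while its total RNA
    stayed non-significant (DEG criteria encoded in ``total_de``'s class)
    is ``buffered``; genes whose total RNA changed significantly are
    ``under_buffered_up`` / ``under_buffered_down``; everything else is
    ``unclassified``.  Genes missing either input are ``unclassified``.

    Returns per-gene labels and a summary stratified by target status with
    the median |Dlog2 alpha| of the buffered and under-buffered classes
    (buffering is expected to be most efficient for the largest
    transcription changes).
    """
    alpha = fold_changes[fold_changes["rate"] == "alpha"].set_index("gene_id")
    genes = alpha.index.union(total_de.index)
    alpha_cls = alpha["class"].reindex(genes)
    alpha_lfc = alpha["log2fc"].reindex(genes)
    total_cls = total_de["class"].reindex(genes)

    labels = pd.Series("unclassified", index=genes, name="efficiency")
    known = alpha_cls.notna() & total_cls.notna()
    labels[known & (total_cls == "up")] = "under_buffered_up"
    labels[known & (total_cls == "down")] = "under_buffered_down"
    labels[known & (total_cls == "ns") & alpha_cls.isin(["up", "down"])] = "buffered"

    abs_dalpha = alpha_lfc.abs()
    under = labels.isin(["under_buffered_up", "under_buffered_down"])
    strata = (
        annotation["target"].reindex(genes).fillna(False).astype(bool)
        if annotation is not None and "target" in annotation
        else pd.Series(False, index=genes)
    )
    rows = []
    for is_target, sub in labels.groupby(strata):
        rows.append(
            {
                "stratum": "target" if is_target else "non_target",
                "n_buffered": int((sub == "buffered").sum()),
                "n_under_buffered_up": int((sub == "under_buffered_up").sum()),
                "n_under_buffered_down": int((sub == "under_buffered_down").sum()),
                "n_unclassified": int((sub == "unclassified").sum()),
            }
        )
    summary = pd.DataFrame(rows).set_index("stratum")
    summary.attrs["median_abs_dalpha_buffered"] = float(
        abs_dalpha[labels == "buffered"].median()
    )
    summary.attrs["median_abs_dalpha_under_buffered"] = float(
        abs_dalpha[under].median()
    )
    return labels, summary
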