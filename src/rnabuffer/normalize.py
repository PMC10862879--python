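"""Library-size normalization and a simplified negative-binomial Wald test.

Size factors use the median-of-ratios method, optionally restricted to a
reference gene set (exogenous spike-ins for labelled-RNA libraries, where
the global amount of nascent RNA may itself change between conditions).
The differential test is a deliberately simple NB Wald test: per-gene
method-of-moments dispersions shrunk toward a local mean-dispersion trend,
delta-method standard errors on the log2 fold change, standard-normal
p-values, Benjamini-Hochberg adjustment.  It keeps the statistical contract
of the standard RNA-seq workflow (NB Wald + BH) in a form that is fully
transparent and testable; it does not attempt parity with DESeq2's
empirical-Bayes machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AssayCounts

__all__ = [
    "size_factors_median_of_ratios",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "classify_deg",
    "expression_filter",
]

LN2 = np.log(2.0)


def _matrix_of(counts) -> pd.DataFrame:
    return counts.matrix if isinstance(counts, AssayCounts) else counts


def size_factors_median_of_ratios(
    counts, reference_genes=None
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The pseudo-reference of each gene is the geometric mean of its counts
    across samples, over genes with all-positive counts (restricted to
    ``reference_genes`` when given, e.g. spike-in rows for TT-seq).  A
    sample's factor is the median of its count/reference ratios over those
    genes.
    """
    matrix = _matrix_of(counts)
    if matrix.shape[1] < 2:
        raise ValueError("size factors require at least two samples")
    if reference_genes is not None:
        reference_genes = pd.Index(reference_genes)
        missing = reference_genes.difference(matrix.index)
        if len(reference_genes) == 0:
            raise ValueError("empty reference gene set")
        if len(missing):
            raise ValueError(f"reference genes absent from matrix: {list(missing[:5])}")
        matrix = matrix.loc[reference_genes]
    vals = matrix.to_numpy(float)
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has all-positive counts; filter low-count genes or supply reference_genes"
        )
    sub = vals[positive]
    ref = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def estimate_dispersion(
    counts: AssayCounts,
    factors: pd.Series,
    n_neighbors: int = 50,
    shrink_weight: float = 0.5,
    trim: float = 0.05,
) -> pd.Series:
    """Per-gene NB dispersion phi (var = mu + phi mu^2), method of moments.

    Raw phi_g = max(0, (s2 - mu)/mu^2) pooled across conditions on
    normalized counts, then shrunk ``shrink_weight`` toward the trimmed
    mean dispersion of the ``n_neighbors`` genes closest in base mean --
    a light-weight stabilisation standing in for full empirical-Bayes
    shrinkage.
    """
    norm = counts.matrix.div(factors.loc[counts.matrix.columns], axis=1)
    num = pd.Series(0.0, index=norm.index)
    den = 0
    any_replicated = False
    for condition in counts.conditions:
        cols = counts.columns_for(condition)
        if len(cols) < 2:
            continue
        any_replicated = True
        sub = norm[cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = (s2 - mu) / (mu**2)
        phi_c = phi_c.replace([np.inf, -np.inf], np.nan).fillna(0.0)
        num += (len(cols) - 1) * phi_c
        den += len(cols) - 1
    if not any_replicated:
        raise ValueError(
            "no condition has >= 2 replicates; supply a dispersion via configuration"
        )
    raw = (num / den).clip(lower=0.0)

    # light trim only: the MoM sampling distribution is right-skewed, so
    # heavy trimming biases the local trend low (anti-conservative tests)
    base_mean = norm.mean(axis=1)
    order = base_mean.sort_values(kind="mergesort").index
    sorted_raw = raw.loc[order]
    local = (
        sorted_raw.rolling(window=n_neighbors, center=True, min_periods=1)
        .apply(lambda w: stats.trim_mean(w, trim), raw=True)
        .reindex(raw.index)
    )
    return (1 - shrink_weight) * raw + shrink_weight * local


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wald_test(
    counts: AssayCounts,
    factors: pd.Series,
    dispersions,
    control: str = "control",
    treated: str = "treated",
    pseudo: float = 0.5,
    shrink_prior_sd: float | None = None,
) -> pd.DataFrame:
    """NB Wald test of treated vs control on normalized counts.

    Per gene: condition means of normalized counts; log2fc =
    log2((mu_t + pseudo)/(mu_c + pseudo)); delta-method SE
    (1/ln2) * sqrt(sum_c (1/n_c)(1/mu_c + phi)); two-sided normal p;
    BH-adjusted p.  Genes with zero counts everywhere are excluded and
    reported in ``result.attrs['excluded_all_zero']``.  With
    ``shrink_prior_sd`` set, the reported log2fc is additionally shrunk
    toward 0 by a normal prior of that sd (p-values stay unshrunk).
    """
    norm = counts.matrix.div(factors.loc[counts.matrix.columns], axis=1)
    cols_c = counts.columns_for(control)
    cols_t = counts.columns_for(treated)
    if len(cols_c) == 0 or len(cols_t) == 0:
        raise ValueError(f"conditions {control!r} and {treated!r} must both be present")

    all_zero = (counts.matrix == 0).all(axis=1)
    excluded = list(norm.index[all_zero])
    norm = norm.loc[~all_zero]
    phi = (
        dispersions.loc[norm.index].to_numpy(float)
        if isinstance(dispersions, pd.Series)
        else np.full(len(norm), float(dispersions))
    )

    mu_c = norm[cols_c].mean(axis=1).to_numpy(float) + pseudo
    mu_t = norm[cols_t].mean(axis=1).to_numpy(float) + pseudo
    lfc = np.log2(mu_t / mu_c)
    se = (
        np.sqrt(
            (1.0 / mu_t + phi) / len(cols_t) + (1.0 / mu_c + phi) / len(cols_c)
        )
        / LN2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if shrink_prior_sd is not None:
        lfc = lfc * shrink_prior_sd**2 / (shrink_prior_sd**2 + se**2)
    result = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": lfc,
            "se": se,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=norm.index,
    )
    result.attrs["excluded_all_zero"] = excluded
    return result


def classify_deg(
    results: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Label each gene up / down / ns at the DEG thresholds.

    ``up`` requires log2fc > lfc_threshold and padj < alpha; ``down`` the
    mirror image.  Returns the labelled table and a tally dict.
    """
    out = results.copy()
    sig = out["padj"] < alpha
    out["class"] = np.where(
        sig & (out["log2fc"] > lfc_threshold),
        "up",
        np.where(sig & (out["log2fc"] < -lfc_threshold), "down", "ns"),
    )
    tally = {
        "n_up": int((out["class"] == "up").sum()),
        "n_down": int((out["class"] == "down").sum()),
        "n_ns": int((out["class"] == "ns").sum()),
    }
    return out, tally


def expression_filter(
    counts: AssayCounts,
    factors: pd.Series,
    annotation: pd.DataFrame,
    min_expr: float = 1.0,
) -> pd.Index:
    """Retain expressed, non-mitochondrial genes.

    Expression is a depth-scaled, length-normalized mean (normalized counts
    per kb per million normalized reads, an FPKM analogue); genes above
    ``min_expr`` with ``mitochondrial == False`` are kept.  Genes lacking a
    length are excluded with a warning.
    """
    import warnings

    norm = counts.matrix.div(factors.loc[counts.matrix.columns], axis=1)
    length = annotation["premrna_length_kb"].reindex(norm.index)
    no_length = length.isna() | (length <= 0)
    if no_length.any():
        warnings.warn(
            f"{int(no_length.sum())} genes lack a pre-mRNA length and were excluded",
            stacklevel=2,
        )
    per_million = norm.sum(axis=0) / 1e6
    expr = norm.div(per_million, axis=1).div(length, axis=0).mean(axis=1)
    mito = annotation["mitochondrial"].reindex(norm.index).fillna(False).astype(bool)
    keep = (expr > min_expr) & ~mito & ~no_length
    return norm.index[keep]
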