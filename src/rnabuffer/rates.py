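"""Gene-specific kinetic rates from normalized assay means, with error
propagation and between-condition fold changes.

At quasi-equilibrium the compartment levels satisfy u_N = alpha/beta,
s_N = alpha/eta, s_C = alpha/gamma, and the labelled signal after a short
pulse is proportional to alpha.  Replicate-averaged normalized counts
(U_lab, U_N, S_N, S_C) therefore yield, up to one unknown global scale per
rate type::

    alpha ~ U_lab      beta ~ U_lab / U_N
    eta   ~ U_lab / S_N    gamma ~ U_lab / S_C

Only between-condition ratios of these estimates are interpreted, so the
unknown scales cancel provided each assay is normalized consistently
across conditions (size factors computed jointly over both conditions'
samples; spike-in-anchored for the labelled assay).

Uncertainties are first-order delta-method standard errors on the log
scale; condition errors are treated as independent (independent cultures).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssayCounts
from .normalize import bh_adjust

__all__ = [
    "QUANTITY_BY_ASSAY",
    "RATE_QUANTITIES",
    "DERIVED_RATES",
    "average_normalized",
    "estimate_rates",
    "propagate_errors",
    "rate_fold_changes",
    "tally_rate_classes",
]

LN2 = np.log(2.0)

QUANTITY_BY_ASSAY = {
    "TT_labelled_unspliced": "U_lab",
    "FRAC_nuclear_unspliced": "U_N",
    "FRAC_nuclear_spliced": "S_N",
    "FRAC_cytoplasmic_spliced": "S_C",
}

#: numerator/denominator of each rate estimator
RATE_QUANTITIES = {
    "alpha": ("U_lab", None),
    "beta": ("U_lab", "U_N"),
    "eta": ("U_lab", "S_N"),
    "gamma": ("U_lab", "S_C"),
}

#: derived axes reported alongside the four rates: nuclear retention is the
#: inverse of export, cytoplasmic stability the inverse of degradation, and
#: the N/C ratio equals gamma/eta at steady state.
DERIVED_RATES = ("retention", "cyto_stability", "ncr")


def average_normalized(
    counts: dict[str, AssayCounts],
    factors: dict[str, pd.Series],
    condition: str,
    keep_genes=None,
) -> pd.DataFrame:
    """Replicate-averaged normalized counts per quantity for one condition.

    Returns a DataFrame with columns U_lab, U_N, S_N, S_C, their standard
    errors (sample sd / sqrt(n); NaN with a single replicate) and the
    replicate count.  Restricted to genes present in all four matrices
    (which drops spike-in rows, present only in the labelled matrices) and,
    when given, to ``keep_genes`` (e.g. the output of the expression
    filter).
    """
    frames = {}
    genes = None
    for assay, quantity in QUANTITY_BY_ASSAY.items():
        if assay not in counts:
            raise KeyError(f"assay {assay!r} missing from counts")
        ac = counts[assay]
        cols = ac.columns_for(condition)
        if len(cols) == 0:
            raise ValueError(f"condition {condition!r} absent from assay {assay}")
        norm = ac.matrix[cols].div(factors[assay].loc[cols], axis=1)
        mean = norm.mean(axis=1)
        if len(cols) >= 2:
            se = norm.std(axis=1, ddof=1) / np.sqrt(len(cols))
        else:
            se = pd.Series(np.nan, index=norm.index)
        frames[quantity] = mean
        frames["se_" + quantity] = se
        frames["n_" + quantity] = pd.Series(len(cols), index=norm.index)
        genes = norm.index if genes is None else genes.intersection(norm.index)
    out = pd.DataFrame({k: v.reindex(genes) for k, v in frames.items()})
    if keep_genes is not None:
        out = out.loc[out.index.intersection(pd.Index(keep_genes))]
    out.index.name = "gene_id"
    return out


def estimate_rates(
    means: pd.DataFrame, intronless: pd.Series | None = None
) -> pd.DataFrame:
    """Point estimates of alpha, beta, eta, gamma from assay means.

    Rates with a zero denominator are NaN with a reason recorded in
    ``result.attrs['missing_reasons']``.  Intronless genes have no defined
    splicing rate: beta is skipped for them while eta is still computed
    from S_N.
    """
    reasons: list[dict] = []
    intronless = (
        intronless.reindex(means.index).fillna(False).astype(bool)
        if intronless is not None
        else pd.Series(False, index=means.index)
    )
    out = pd.DataFrame(index=means.index)
    for rate, (num, den) in RATE_QUANTITIES.items():
        value = means[num].astype(float).copy()
        if den is not None:
            d = means[den].astype(float)
            bad = ~(d > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                value = value / d
            value[bad] = np.nan
            for g in means.index[bad]:
                reasons.append({"gene_id": g, "rate": rate, "reason": f"{den}=0"})
        if rate == "beta":
            value[intronless] = np.nan
            for g in means.index[intronless]:
                reasons.append({"gene_id": g, "rate": "beta", "reason": "intronless"})
        out[rate] = value
    out.attrs["missing_reasons"] = pd.DataFrame(
        reasons, columns=["gene_id", "rate", "reason"]
    )
    return out


def propagate_errors(means: pd.DataFrame) -> pd.DataFrame:
    """Delta-method SEs of the log2 rate estimates.

    For a ratio A/B with independent errors,
    se_ln = sqrt((se_A/A)^2 + (se_B/B)^2) and se_log2 = se_ln / ln 2; alpha
    uses the single-source case.  Genes with any relative input SE > 0.5
    are flagged ``low_confidence`` (first-order propagation unreliable)
    but still reported.
    """
    rel = {}
    for q in ("U_lab", "U_N", "S_N", "S_C"):
        with np.errstate(divide="ignore", invalid="ignore"):
            rel[q] = (means["se_" + q] / means[q]).astype(float)
    out = pd.DataFrame(index=means.index)
    low = pd.Series(False, index=means.index)
    for rate, (num, den) in RATE_QUANTITIES.items():
        var_ln = rel[num] ** 2
        used = [rel[num]]
        if den is not None:
            var_ln = var_ln + rel[den] ** 2
            used.append(rel[den])
        out["se_log2_" + rate] = np.sqrt(var_ln) / LN2
        for r in used:
            low = low | (r > 0.5)
    out["low_confidence"] = low
    return out


def rate_fold_changes(
    rates_ctl: pd.DataFrame,
    se_ctl: pd.DataFrame,
    rates_trt: pd.DataFrame,
    se_trt: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Per-gene log2 fold changes of each rate, treated vs control.

    Long-format result with one row per gene x rate, covering the four
    primary rates plus the derived axes: retention = -eta, cyto_stability =
    -gamma and ncr = gamma - eta (on the log2-fold-change scale; exact
    identities by construction).  SEs combine conditions in quadrature;
    p-values are two-sided z-tests; classification uses |log2fc| >
    ``lfc_threshold`` and raw p < ``p_threshold`` (BH-adjusted p instead
    when ``use_adjusted``).
    """
    genes = rates_ctl.index.intersection(rates_trt.index)
    blocks = []
    store: dict[str, pd.DataFrame] = {}
    for rate in ("alpha", "beta", "eta", "gamma"):
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(
                rates_trt[rate].reindex(genes) / rates_ctl[rate].reindex(genes)
            )
        se = np.sqrt(
            se_ctl["se_log2_" + rate].reindex(genes) ** 2
            + se_trt["se_log2_" + rate].reindex(genes) ** 2
        )
        store[rate] = pd.DataFrame({"log2fc": lfc, "se": se})
    # derived axes
    store["retention"] = pd.DataFrame(
        {"log2fc": -store["eta"]["log2fc"], "se": store["eta"]["se"]}
    )
    store["cyto_stability"] = pd.DataFrame(
        {"log2fc": -store["gamma"]["log2fc"], "se": store["gamma"]["se"]}
    )
    store["ncr"] = pd.DataFrame(
        {
            "log2fc": store["gamma"]["log2fc"] - store["eta"]["log2fc"],
            "se": np.sqrt(store["gamma"]["se"] ** 2 + store["eta"]["se"] ** 2),
        }
    )
    for rate, frame in store.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            z = frame["log2fc"] / frame["se"]
        p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=genes)
        p[frame["log2fc"].isna() | frame["se"].isna()] = np.nan
        padj = pd.Series(np.nan, index=genes)
        ok = p.notna()
        if ok.any():
            padj[ok] = bh_adjust(p[ok].to_numpy())
        crit_p = padj if use_adjusted else p
        cls = np.where(
            (crit_p < p_threshold) & (frame["log2fc"] > lfc_threshold),
            "up",
            np.where(
                (crit_p < p_threshold) & (frame["log2fc"] < -lfc_threshold),
                "down",
                "ns",
            ),
        )
        cls = np.where(frame["log2fc"].isna(), "missing", cls)
        blocks.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "rate": rate,
                    "log2fc": frame["log2fc"].to_numpy(),
                    "se": frame["se"].to_numpy(),
                    "p": p.to_numpy(),
                    "padj": padj.to_numpy(),
                    "class": cls,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def tally_rate_classes(fold_changes: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of up/down/ns calls per rate type."""
    rows = []
    for rate, sub in fold_changes.groupby("rate", sort=True):
        counted = sub[sub["class"] != "missing"]
        n = len(counted)
        n_up = int((counted["class"] == "up").sum())
        n_down = int((counted["class"] == "down").sum())
        rows.append(
            {
                "rate": rate,
                "n": n,
                "n_up": n_up,
                "n_down": n_down,
                "n_ns": n - n_up - n_down,
                "pct_up": 100.0 * n_up / n if n else 0.0,
                "pct_down": 100.0 * n_down / n if n else 0.0,
            }
        )
    columns = ["rate", "n", "n_up", "n_down", "n_ns", "pct_up", "pct_down"]
    return pd.DataFrame(rows, columns=columns).set_index("rate")
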