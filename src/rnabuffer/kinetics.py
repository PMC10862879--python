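"""Closed-form mathematics of the four-rate mRNA cascade.

The model tracks three compartments per gene: unspliced nuclear pre-mRNA
``u_N``, spliced nuclear mRNA ``s_N`` and spliced cytoplasmic mRNA ``s_C``.
Pre-mRNA is synthesised at a constant transcription rate ``alpha``
(molecules/h, arbitrary scale), spliced at rate ``beta`` (1/h), exported to
the cytoplasm at rate ``eta`` (1/h) and degraded in the cytoplasm at rate
``gamma`` (1/h)::

    du_N/dt = alpha - beta * u_N
    ds_N/dt = beta * u_N - eta * s_N
    ds_C/dt = eta * s_N - gamma * s_C

Nuclear degradation is omitted: export is assumed fast relative to nuclear
decay, so nuclear residence of spliced mRNA is governed by translocation.
All times are in hours; a 10-minute metabolic-labelling pulse is tau = 1/6 h.

Because the system is a linear cascade, trajectories are sums of
exponentials; the implementation switches to the confluent
(polynomial x exponential) branch when rates coincide within a relative
tolerance, so nearly-degenerate rate sets are handled without catastrophic
cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RATE_COLUMNS",
    "ABUNDANCE_COLUMNS",
    "DEGENERACY_RTOL",
    "PulseConfig",
    "RateSet",
    "steady_state",
    "solve_dynamics",
    "labeled_unspliced",
    "equilibration_time",
]

RATE_COLUMNS = ("alpha", "beta", "eta", "gamma")
SE_COLUMNS = ("se_log_alpha", "se_log_beta", "se_log_eta", "se_log_gamma")
ABUNDANCE_COLUMNS = ("u_N", "s_N", "s_C")

#: relative gap below which two kinetic rates are treated as coincident
DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class PulseConfig:
    """Metabolic-labelling pulse: duration tau (hours) and labelling efficiency.

    The default is the 10-minute 4sU pulse used for TT-seq, tau = 1/6 h,
    with unit efficiency (efficiency rescales the labelled signal linearly
    and cancels in fold changes).
    """

    duration: float = 1.0 / 6.0
    label_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration}")
        if not 0 < self.label_efficiency <= 1:
            raise ValueError(
                f"label_efficiency must be in (0, 1], got {self.label_efficiency}"
            )


class RateSet:
    """Per-gene kinetic rates (alpha, beta, eta, gamma), optionally with
    standard errors on the natural-log scale.

    Wraps a DataFrame indexed by gene id with columns ``alpha``, ``beta``,
    ``eta``, ``gamma`` and optional ``se_log_*`` columns.  ``beta = inf``
    encodes an intronless gene (splicing is instantaneous; no unspliced
    species exists).
    """

    def __init__(self, rates: pd.DataFrame):
        missing = [c for c in RATE_COLUMNS if c not in rates.columns]
        if missing:
            raise ValueError(f"RateSet table is missing columns {missing}")
        rates = rates.copy()
        rates.index.name = "gene_id"
        self._validate(rates)
        self.rates = rates

    @staticmethod
    def _validate(rates: pd.DataFrame) -> None:
        alpha = rates["alpha"].to_numpy(float)
        bad = ~(alpha >= 0)
        if bad.any():
            g = rates.index[bad][0]
            raise ValueError(f"alpha must be >= 0; offending gene {g!r}")
        for name in ("beta", "eta", "gamma"):
            vals = rates[name].to_numpy(float)
            bad = ~(vals > 0)
            if bad.any():
                g = rates.index[bad][0]
                raise ValueError(
                    f"rate {name!r} must be > 0 for every gene; offending gene {g!r}"
                )
        for name in SE_COLUMNS:
            if name in rates.columns:
                se = rates[name].to_numpy(float)
                ok = np.isnan(se) | (np.isfinite(se) & (se >= 0))
                if not ok.all():
                    g = rates.index[~ok][0]
                    raise ValueError(
                        f"{name} must be finite and >= 0 when present; offending gene {g!r}"
                    )

    @classmethod
    def from_arrays(cls, gene_ids, alpha, beta, eta, gamma, **se) -> "RateSet":
        frame = pd.DataFrame(
            {"alpha": alpha, "beta": beta, "eta": eta, "gamma": gamma, **se},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return cls(frame)

    def __len__(self) -> int:
        return len(self.rates)

    def __getitem__(self, column: str) -> pd.Series:
        return self.rates[column]

    @property
    def gene_ids(self) -> pd.Index:
        return self.rates.index


def steady_state(rates: RateSet) -> pd.DataFrame:
    """Steady-state abundances u_N = alpha/beta, s_N = alpha/eta, s_C = alpha/gamma.

    Intronless genes (beta = inf) have u_N = 0.  Returns a DataFrame indexed
    like the RateSet with columns ``u_N``, ``s_N``, ``s_C``.
    """
    r = rates.rates
    alpha = r["alpha"].to_numpy(float)
    out = pd.DataFrame(
        {
            "u_N": alpha / r["beta"].to_numpy(float),
            "s_N": alpha / r["eta"].to_numpy(float),
            "s_C": alpha / r["gamma"].to_numpy(float),
        },
        index=rates.gene_ids,
    )
    return out


def _rel_close(a, b, rtol=DEGENERACY_RTOL):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return np.abs(a - b) <= rtol * np.maximum(np.abs(a), np.abs(b))


def _conv2(a, b, t):
    """Convolution of exp(-a s) and exp(-b s) evaluated at t (elementwise).

    Equals (e^{-a t} - e^{-b t}) / (b - a), with the confluent limit
    t e^{-a t} when a and b coincide.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    t = np.asarray(t, float)
    close = _rel_close(a, b)
    m = 0.5 * (a + b)
    denom = np.where(close, 1.0, b - a)
    generic = (np.exp(-a * t) - np.exp(-b * t)) / denom
    confluent = t * np.exp(-m * t)
    return np.where(close, confluent, generic)


def _conv3_pair(p, q, t):
    # double node p, simple node q: [e^{-q t} - e^{-p t}(1 + (p - q) t)] / (p - q)^2
    d = p - q
    return (np.exp(-q * t) - np.exp(-p * t) * (1.0 + d * t)) / (d * d)


def _conv3(a, b, c, t):
    """Triple convolution of exponentials with rates a, b, c at time t.

    Symmetric in (a, b, c); handles coincident rates via confluent limits.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    t = np.asarray(t, float)
    ab = _rel_close(a, b)
    ac = _rel_close(a, c)
    bc = _rel_close(b, c)
    all_close = ab & ac & bc

    def safe(d, mask):
        return np.where(mask, 1.0, d)

    # generic branch (guard denominators where any pair coincides)
    any_close = ab | ac | bc
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = (
            np.exp(-a * t) / (safe(b - a, any_close) * safe(c - a, any_close))
            + np.exp(-b * t) / (safe(a - b, any_close) * safe(c - b, any_close))
            + np.exp(-c * t) / (safe(a - c, any_close) * safe(b - c, any_close))
        )
        m3 = (a + b + c) / 3.0
        triple = 0.5 * t * t * np.exp(-m3 * t)

        # pair branches (guard against the all-close case)
        pair_ab = _conv3_pair(np.where(all_close, 1.0, 0.5 * (a + b)),
                              np.where(all_close, 2.0, c), t)
        pair_ac = _conv3_pair(np.where(all_close, 1.0, 0.5 * (a + c)),
                              np.where(all_close, 2.0, b), t)
        pair_bc = _conv3_pair(np.where(all_close, 1.0, 0.5 * (b + c)),
                              np.where(all_close, 2.0, a), t)

    out = np.where(
        all_close,
        triple,
        np.where(
            ab,
            pair_ab,
            np.where(ac, pair_ac, np.where(bc, pair_bc, generic)),
        ),
    )
    return out


def _deviation(beta, eta, gamma, du0, ds0, dc0, t):
    """Deviation from steady state at time t for the linear cascade."""
    e_b = np.exp(-beta * t)
    e_e = np.exp(-eta * t)
    e_g = np.exp(-gamma * t)
    du = du0 * e_b
    ds = ds0 * e_e + beta * du0 * _conv2(beta, eta, t)
    dc = (
        dc0 * e_g
        + eta * ds0 * _conv2(eta, gamma, t)
        + eta * beta * du0 * _conv3(beta, eta, gamma, t)
    )
    return du, ds, dc


def solve_dynamics(
    rates: RateSet, initial: pd.DataFrame, times
) -> np.ndarray:
    """Exact trajectory of (u_N, s_N, s_C) from ``initial`` at the given times.

    Parameters
    ----------
    rates
        Kinetic rates (finite beta required; intronless genes have no
        unspliced dynamics to solve).
    initial
        DataFrame with columns ``u_N``, ``s_N``, ``s_C`` aligned to the
        RateSet's genes.
    times
        Non-negative, strictly increasing time points (hours).

    Returns
    -------
    ndarray of shape (len(times), n_genes, 3), compartments ordered
    (u_N, s_N, s_C).  Converges to :func:`steady_state` as t grows.
    """
    t = np.asarray(times, float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if (t < 0).any():
        raise ValueError("negative time points are not allowed")
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")

    r = rates.rates
    beta = r["beta"].to_numpy(float)
    if not np.isfinite(beta).all():
        g = rates.gene_ids[~np.isfinite(beta)][0]
        raise ValueError(
            f"solve_dynamics requires finite beta; gene {g!r} is intronless (beta=inf)"
        )
    eta = r["eta"].to_numpy(float)
    gamma = r["gamma"].to_numpy(float)

    ss = steady_state(rates)
    init = initial.reindex(rates.gene_ids)
    du0 = init["u_N"].to_numpy(float) - ss["u_N"].to_numpy(float)
    ds0 = init["s_N"].to_numpy(float) - ss["s_N"].to_numpy(float)
    dc0 = init["s_C"].to_numpy(float) - ss["s_C"].to_numpy(float)

    out = np.empty((len(t), len(rates), 3))
    for k, tk in enumerate(t):
        du, ds, dc = _deviation(beta, eta, gamma, du0, ds0, dc0, tk)
        out[k, :, 0] = ss["u_N"].to_numpy(float) + du
        out[k, :, 1] = ss["s_N"].to_numpy(float) + ds
        out[k, :, 2] = ss["s_C"].to_numpy(float) + dc
    return out


def labeled_unspliced(rates: RateSet, pulse: PulseConfig) -> pd.Series:
    """Expected labelled unspliced level after a pulse of length tau.

    Starting from zero labelled molecules, u_lab(tau) =
    efficiency * (alpha/beta) * (1 - e^{-beta tau}).  For a short pulse
    (beta*tau -> 0) this tends to efficiency * alpha * tau, i.e. the
    labelled signal becomes directly proportional to the transcription
    rate -- the linear readout used in rate inference.  Intronless genes
    (beta = inf) carry no unspliced species and return 0.
    """
    r = rates.rates
    alpha = r["alpha"].to_numpy(float)
    beta = r["beta"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        level = alpha / beta * -np.expm1(-beta * pulse.duration)
    level = np.where(np.isinf(beta), 0.0, level)
    return pd.Series(
        pulse.label_efficiency * level, index=rates.gene_ids, name="u_lab"
    )


def _max_relative_deviation(beta, eta, gamma, ss, du0, ds0, dc0, t):
    du, ds, dc = _deviation(beta, eta, gamma, du0, ds0, dc0, t)
    return np.max(
        np.abs(np.stack([du / ss[0], ds / ss[1], dc / ss[2]])), axis=0
    )


def equilibration_time(
    rates: RateSet,
    relative_tol: float,
    initial: pd.DataFrame | None = None,
    n_grid: int = 2048,
) -> pd.Series:
    """Time for all compartments to settle within ``relative_tol`` of steady state.

    Returns, per gene, the smallest t (hours) such that every compartment,
    started from ``initial`` (default: empty compartments, i.e. synthesis
    switched on at t=0; pass the old steady state to model a rate change),
    stays within ``relative_tol`` (relative) of the new steady state for all
    later times.  The search horizon scales with the slowest eigenvalue
    min(beta, eta, gamma); genes with alpha = 0 have no relative scale and
    return NaN.  Used to flag genes for which a fixed treatment duration
    (e.g. 24 h) is too short to reach quasi-equilibrium, given half-lives on
    the order of hours.
    """
    if not 0 < relative_tol < 1:
        raise ValueError("relative_tol must be in (0, 1)")
    r = rates.rates
    ss = steady_state(rates)
    if initial is None:
        initial = pd.DataFrame(0.0, index=rates.gene_ids, columns=list(ABUNDANCE_COLUMNS))
    init = initial.reindex(rates.gene_ids)

    times = np.empty(len(rates))
    for i, g in enumerate(rates.gene_ids):
        beta, eta, gamma = (float(r.loc[g, c]) for c in ("beta", "eta", "gamma"))
        alpha = float(r.loc[g, "alpha"])
        if alpha == 0:
            times[i] = np.nan
            continue
        ssg = ss.loc[g].to_numpy(float)
        du0 = float(init.loc[g, "u_N"]) - ssg[0]
        ds0 = float(init.loc[g, "s_N"]) - ssg[1]
        dc0 = float(init.loc[g, "s_C"]) - ssg[2]
        kmin = min(beta, eta, gamma)
        horizon = (np.log(1.0 / relative_tol) + 15.0) / kmin
        grid = np.linspace(0.0, horizon, n_grid)
        dev = _max_relative_deviation(beta, eta, gamma, ssg, du0, ds0, dc0, grid)
        above = np.nonzero(dev > relative_tol)[0]
        if len(above) == 0:
            times[i] = 0.0
            continue
        lo, hi = grid[above[-1]], grid[min(above[-1] + 1, n_grid - 1)]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _max_relative_deviation(beta, eta, gamma, ssg, du0, ds0, dc0, mid) > relative_tol:
                lo = mid
            else:
                hi = mid
        times[i] = hi
    return pd.Series(times, index=rates.gene_ids, name="equilibration_time_h")
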