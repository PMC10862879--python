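"""Synthetic TT-seq / Frac-seq / total RNA-seq data with known kinetics.

The generator draws gene-specific kinetic rates in a control condition,
perturbs transcription in a treated condition with a controllable
compensatory (buffering) coupling to nuclear export and cytoplasmic
degradation, and emits negative-binomial count matrices for the five assay
quantities of the study design, plus exogenous spike-in rows for the
labelled-RNA libraries.  Every downstream stage of the package can
therefore be exercised against known ground truth without any downloads.

Conventions
-----------
* Effect sizes (``effect_logmean``, ``effect_logsd``, ``response_logsd``)
  are on the log2 scale; rate hyper-parameters (``rate_logmean``,
  ``rate_logsd``) are natural-log-normal parameters.
* ``buffering_rho`` in [-1, 0] is the target correlation between the
  transcription change Dlog2(alpha) and the *retention* change
  -Dlog2(eta) (equivalently the cytoplasmic-stability change
  -Dlog2(gamma)).  rho = -1 is perfect buffering: nuclear and cytoplasmic
  abundances, and hence the N/C ratio, are unchanged by the perturbation.
* The compensatory response tracks Dlog2(alpha) itself, so a cohort whose
  transcription drops on average acquires, on average, increased retention
  and stability -- the sign structure the assays are meant to reveal.
* Intronless genes have no unspliced species (beta = inf, pre-mRNA flux
  goes straight to spliced nuclear mRNA) and an attenuated export response
  (``intronless_response_scale``), so under perfect buffering they still
  shift their N/C ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ASSAYS, AssayCounts
from .kinetics import PulseConfig, RateSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "sample_rates",
    "simulate_counts",
    "write_fixture",
]

CONDITIONS = ("control", "treated")

_DEFAULT_RATE_LOGMEAN = {
    "alpha": np.log(20.0),  # arbitrary molecule scale
    "beta": np.log(10.0),  # splicing half-life ~4 min
    "eta": np.log(1.5),  # export half-life ~30 min
    "gamma": np.log(np.log(2) / 9.0),  # cytoplasmic half-life ~9 h
}
_DEFAULT_RATE_LOGSD = {"alpha": 1.0, "beta": 0.5, "eta": 0.5, "gamma": 0.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment."""

    n_genes: int = 2000
    n_spikein: int = 100
    n_replicates: int = 3
    seed: int = 0
    depth_per_assay: float = 5e6
    dispersion: float = 0.05  # NB dispersion phi: var = mu + phi mu^2
    library_jitter_sd: float = 0.15  # log-normal sd of per-library depth
    rate_logmean: dict = field(default_factory=lambda: dict(_DEFAULT_RATE_LOGMEAN))
    rate_logsd: dict = field(default_factory=lambda: dict(_DEFAULT_RATE_LOGSD))
    perturbed_fraction: float = 0.3
    effect_logmean: float = -0.5  # mean Dlog2 alpha of perturbed genes
    effect_logsd: float = 1.5  # spread of Dlog2 alpha
    response_logsd: float = 1.5  # spread of the coupled eta/gamma responses
    buffering_rho: float = -0.8  # corr(Dlog2 alpha, Dlog2 retention)
    intronless_fraction: float = 0.05
    intronless_response_scale: float = 0.5
    mitochondrial_fraction: float = 0.005
    target_fraction: float = 0.2
    spikein_mass_fraction: float = 1.0 / 11.0  # spike:sample RNA in a 1:10 ratio
    contamination: float = 0.0  # cross-leakage between fractions
    pulse: PulseConfig = field(default_factory=PulseConfig)
    pulse_mode: str = "exact"  # "exact" | "linear" labelled-RNA readout

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_spikein, self.n_replicates) <= 0:
            raise ValueError("n_genes, n_spikein and n_replicates must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not -1.0 <= self.buffering_rho <= 0.0:
            raise ValueError("buffering_rho must lie in [-1, 0]")
        for name in (
            "perturbed_fraction",
            "intronless_fraction",
            "mitochondrial_fraction",
            "target_fraction",
            "contamination",
            "intronless_response_scale",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pulse_mode not in ("exact", "linear"):
            raise ValueError("pulse_mode must be 'exact' or 'linear'")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    annotation: pd.DataFrame  # per-gene architecture table (includes spike rows)
    rates_control: RateSet
    rates_treated: RateSet
    spike_abundance: pd.Series  # fixed labelled-RNA signal of spike-in rows
    seed: int

    @property
    def delta_log2(self) -> pd.DataFrame:
        """True Dlog2 of alpha, eta, gamma (treated vs control)."""
        ctl, trt = self.rates_control.rates, self.rates_treated.rates
        out = {}
        for rate in ("alpha", "eta", "gamma"):
            out[rate] = np.log2(trt[rate] / ctl[rate])
        return pd.DataFrame(out)


def sample_rates(config: SimulationConfig) -> SimulationTruth:
    """Draw ground-truth kinetic rates for both conditions.

    Control rates are log-normal.  A ``perturbed_fraction`` of genes
    (targets over-represented 3:1) receives Dlog2 alpha ~
    Normal(effect_logmean, effect_logsd); their export and degradation
    rates respond with correlation ``-buffering_rho`` to Dlog2 alpha
    (Gaussian coupling on the log2 scale), so that retention and stability
    changes anti-correlate with the transcription change.  Spike-in rows
    have a fixed abundance in both conditions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"gene_{i:05d}" for i in range(n)], name="gene_id")

    rates = {
        r: np.exp(rng.normal(config.rate_logmean[r], config.rate_logsd[r], n))
        for r in ("alpha", "beta", "eta", "gamma")
    }

    # gene architecture
    length_kb = np.exp(rng.normal(np.log(20.0), 0.9, n))
    n_exons = np.maximum(1, np.round(length_kb / 2.5 + rng.normal(0, 1.5, n))).astype(int)
    intronless = rng.random(n) < config.intronless_fraction
    n_exons[intronless] = 1
    length_kb[intronless] = np.minimum(length_kb[intronless], 5.0)  # intronless genes are short
    n_exons[~intronless] = np.maximum(2, n_exons[~intronless])
    rates["beta"][intronless] = np.inf
    mito = rng.random(n) < config.mitochondrial_fraction

    # perturbation of transcription with compensatory eta/gamma response
    n_pert = int(round(config.perturbed_fraction * n))
    # direct targets of the perturbed regulator, over-sampled among perturbed genes
    weights = np.ones(n)
    targets = rng.random(n) < config.target_fraction
    weights[targets] = 3.0
    perturbed_idx = rng.choice(n, size=n_pert, replace=False, p=weights / weights.sum())
    perturbed = np.zeros(n, bool)
    perturbed[perturbed_idx] = True

    d_alpha = np.zeros(n)
    d_eta = np.zeros(n)
    d_gamma = np.zeros(n)
    m, s = config.effect_logmean, config.effect_logsd
    sr = config.response_logsd
    rho = -config.buffering_rho  # corr(Dalpha, Deta) on the rate scale
    d_alpha[perturbed] = rng.normal(m, s, n_pert)
    coupled = rho * (sr / s) * d_alpha[perturbed]
    noise_sd = sr * np.sqrt(max(0.0, 1.0 - rho * rho))
    d_eta[perturbed] = coupled + noise_sd * rng.standard_normal(n_pert)
    d_gamma[perturbed] = coupled + noise_sd * rng.standard_normal(n_pert)
    # intronless genes compensate poorly through export
    d_eta[intronless] *= config.intronless_response_scale

    treated = {
        "alpha": rates["alpha"] * 2.0 ** d_alpha,
        "beta": rates["beta"].copy(),
        "eta": rates["eta"] * 2.0 ** d_eta,
        "gamma": rates["gamma"] * 2.0 ** d_gamma,
    }

    spikes = pd.Index(
        [f"spike_{i:04d}" for i in range(config.n_spikein)], name="gene_id"
    )
    spike_abundance = pd.Series(
        np.exp(rng.normal(0.0, 1.0, config.n_spikein)), index=spikes, name="abundance"
    )

    annotation = pd.DataFrame(
        {
            "premrna_length_kb": np.round(length_kb, 4),
            "n_exons": n_exons,
            "intronless": intronless,
            "mitochondrial": mito,
            "spikein": False,
            "target": targets,
            "perturbed": perturbed,
        },
        index=genes,
    )
    spike_ann = pd.DataFrame(
        {
            "premrna_length_kb": 1.0,
            "n_exons": 1,
            "intronless": True,
            "mitochondrial": False,
            "spikein": True,
            "target": False,
            "perturbed": False,
        },
        index=spikes,
    )
    annotation = pd.concat([annotation, spike_ann])

    return SimulationTruth(
        annotation=annotation,
        rates_control=RateSet.from_arrays(genes, **rates),
        rates_treated=RateSet.from_arrays(genes, **treated),
        spike_abundance=spike_abundance,
        seed=config.seed,
    )


def _labelled_signal(rates: RateSet, config: SimulationConfig) -> np.ndarray:
    """Expected labelled signal per gene after the pulse.

    ``linear`` mode uses the short-pulse first-order readout
    eff * alpha * tau (labelled RNA directly proportional to transcription
    rate).  ``exact`` mode accumulates labelled molecules over the pulse:
    through the unspliced pool for intron-containing genes, through the
    spliced nuclear pool for intronless ones.
    """
    r = rates.rates
    alpha = r["alpha"].to_numpy(float)
    tau = config.pulse.duration
    eff = config.pulse.label_efficiency
    if config.pulse_mode == "linear":
        return eff * alpha * tau
    beta = r["beta"].to_numpy(float)
    eta = r["eta"].to_numpy(float)
    k = np.where(np.isinf(beta), eta, beta)
    return eff * alpha / k * -np.expm1(-k * tau)


def _expected_abundances(rates: RateSet, config: SimulationConfig) -> pd.DataFrame:
    r = rates.rates
    alpha = r["alpha"].to_numpy(float)
    beta = r["beta"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        u_n = np.where(np.isinf(beta), 0.0, alpha / beta)
    s_n = alpha / r["eta"].to_numpy(float)
    s_c = alpha / r["gamma"].to_numpy(float)
    c = config.contamination
    u_n_obs = (1.0 - c) * u_n
    s_n_obs = (1.0 - c) * s_n + c * s_c
    s_c_obs = (1.0 - c) * s_c + c * s_n
    return pd.DataFrame(
        {
            "TT_labelled_unspliced": _labelled_signal(rates, config),
            "FRAC_nuclear_unspliced": u_n_obs,
            "FRAC_nuclear_spliced": s_n_obs,
            "FRAC_cytoplasmic_spliced": s_c_obs,
            "TOTAL": u_n + s_n + s_c,
        },
        index=rates.gene_ids,
    )


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, config: SimulationConfig):
    if np.nanmax(mu) > 1e15:
        raise OverflowError(
            "expected counts exceed 1e15; lower depth_per_assay or rate scales"
        )
    phi = config.dispersion
    if phi > 0:
        size = 1.0 / phi
        p = size / (size + mu)
        return rng.negative_binomial(size, p).astype(float)
    if config.library_jitter_sd > 0:
        return rng.poisson(mu).astype(float)
    return mu  # fully deterministic expectations


def simulate_counts(
    truth: SimulationTruth, config: SimulationConfig
) -> tuple[dict[str, AssayCounts], pd.DataFrame]:
    """Emit count matrices for the five assays plus a sample sheet.

    Per condition x replicate and assay, the expected count of a gene is a
    per-library scale times its expected abundance, with the scale set so
    each library totals ~``depth_per_assay`` (log-normal jitter of sd
    ``library_jitter_sd``).  Counts are NB(mu, phi); Poisson when phi = 0;
    exact expectations (floats) when phi = 0 and jitter is disabled.
    Spike-in rows appear only in the labelled (TT) matrices, at a fixed,
    condition-independent abundance comprising ``spikein_mass_fraction`` of
    the library.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    expected = {
        "control": _expected_abundances(truth.rates_control, config),
        "treated": _expected_abundances(truth.rates_treated, config),
    }
    # scale spikes to a fixed share of the control labelled library
    tt_total_ctl = expected["control"]["TT_labelled_unspliced"].sum()
    spike_scale = (
        config.spikein_mass_fraction
        / (1.0 - config.spikein_mass_fraction)
        * tt_total_ctl
        / truth.spike_abundance.sum()
    )
    spikes = truth.spike_abundance * spike_scale

    sheet_rows = []
    matrices: dict[str, list[pd.Series]] = {assay: [] for assay in ASSAYS}
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            for assay in ASSAYS:
                sample_id = f"{condition}_{assay}_rep{rep}"
                x = expected[condition][assay]
                if assay == "TT_labelled_unspliced":
                    x = pd.concat([x, spikes])
                depth = config.depth_per_assay
                if config.library_jitter_sd > 0:
                    depth *= np.exp(rng.normal(0.0, config.library_jitter_sd))
                mu = x.to_numpy(float) * (depth / x.sum())
                counts = _draw_counts(rng, mu, config)
                matrices[assay].append(pd.Series(counts, index=x.index, name=sample_id))
                sheet_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "replicate": rep,
                        "assay": assay,
                    }
                )
    sample_sheet = pd.DataFrame(sheet_rows).set_index("sample_id")

    out: dict[str, AssayCounts] = {}
    for assay in ASSAYS:
        matrix = pd.concat(matrices[assay], axis=1)
        samples = sample_sheet[sample_sheet["assay"] == assay][["condition", "replicate"]]
        out[assay] = AssayCounts(assay=assay, matrix=matrix, samples=samples)
    return out, sample_sheet.reset_index()


def write_fixture(
    truth: SimulationTruth,
    counts: dict[str, AssayCounts],
    sample_sheet: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write tab-delimited matrices, sample sheet, annotation and truth tables.

    The files round-trip losslessly through :func:`rnabuffer.io.read_counts`
    and friends.  Returns a name -> path mapping of everything written.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"fixture directory does not exist: {directory}")
    written: dict[str, Path] = {}
    from .io import write_matrix, write_table  # local import to avoid cycle

    for assay, ac in counts.items():
        path = directory / f"counts_{assay}.tsv"
        write_matrix(ac.matrix, path)
        written[assay] = path
    written["sample_sheet"] = directory / "sample_sheet.tsv"
    write_table(sample_sheet, written["sample_sheet"], index=False)
    written["annotation"] = directory / "annotation.tsv"
    write_table(truth.annotation, written["annotation"])
    rates = truth.rates_control.rates.join(
        truth.rates_treated.rates, lsuffix="_control", rsuffix="_treated"
    )
    written["truth_rates"] = directory / "truth_rates.tsv"
    write_table(rates, written["truth_rates"])
    return written


def noiseless_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """Convenience: a copy of ``config`` with all stochastic layers disabled
    (zero dispersion, no library jitter, linear pulse readout)."""
    base = config or SimulationConfig()
    return replace(
        base, dispersion=0.0, library_jitter_sd=0.0, pulse_mode="linear", **overrides
    )
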