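import numpy as np
import pandas as pd
import pytest

import rnabuffer as rb
from rnabuffer import normalize as norm
from rnabuffer import rates as rt


def random_rateset(rng, n, allow_degenerate=False):
    """Random valid rate sets spanning a few orders of magnitude."""
    alpha = np.exp(rng.normal(2.0, 1.0, n))
    beta = np.exp(rng.normal(1.5, 0.8, n))
    eta = np.exp(rng.normal(0.3, 0.8, n))
    gamma = np.exp(rng.normal(-2.0, 0.8, n))
    if allow_degenerate:
        pick = rng.random(n) < 0.2
        eta[pick] = beta[pick]
    return rb.RateSet.from_arrays(
        [f"g{i}" for i in range(n)], alpha, beta, eta, gamma
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Default-noise simulated experiment, small enough for fast tests."""
    config = rb.SimulationConfig(n_genes=300, n_spikein=40, seed=11)
    truth = rb.sample_rates(config)
    counts, sheet = rb.simulate_counts(truth, config)
    return config, truth, counts, sheet


@pytest.fixture(scope="session")
def noiseless_fixture():
    """phi=0, no jitter, linear pulse: expectations only."""
    config = rb.noiseless_config(rb.SimulationConfig(n_genes=300, n_spikein=40, seed=12))
    truth = rb.sample_rates(config)
    counts, sheet = rb.simulate_counts(truth, config)
    return config, truth, counts, sheet


def assay_factors(counts, annotation):
    spikes = annotation.index[annotation["spikein"]]
    out = {}
    for assay, ac in counts.items():
        ref = spikes.intersection(ac.matrix.index)
        out[assay] = norm.size_factors_median_of_ratios(
            ac, reference_genes=ref if len(ref) else None
        )
    return out


def infer_fold_changes(counts, annotation, **kwargs):
    """Normalization -> means -> rates -> fold changes, as the pipeline wires it."""
    factors = assay_factors(counts, annotation)
    per = {}
    for condition in ("control", "treated"):
        means = rt.average_normalized(counts, factors, condition)
        per[condition] = (
            means,
            rt.estimate_rates(means, intronless=annotation["intronless"]),
            rt.propagate_errors(means),
        )
    fc = rt.rate_fold_changes(
        per["control"][1], per["control"][2], per["treated"][1], per["treated"][2],
        **kwargs,
    )
    return factors, per, fc
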