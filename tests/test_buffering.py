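"""Buffering correlations, NCR, architecture bins, enrichment, efficiency."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import rnabuffer as rb
from rnabuffer import buffering as buf

from conftest import assay_factors, infer_fold_changes


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert buf.pearson(x, -x).r == pytest.approx(-1.0)

    def test_location_scale_invariance(self):
        x = np.random.default_rng(0).normal(size=50)
        assert buf.pearson(x, 2 * x + 3).r == pytest.approx(1.0)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        res = buf.pearson(x, y)
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        res = buf.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.r)

    def test_matches_two_pass_formula(self):
        # textbook two-pass oracle on random vectors
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(5, 60)
            x, y = rng.normal(size=(2, n))
            sx, sy = x - x.mean(), y - y.mean()
            oracle = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
            assert buf.pearson(x, y).r == pytest.approx(oracle, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps = [buf.pearson(rng.normal(size=30), rng.normal(size=30)).p for _ in range(400)]
        assert 0.01 < np.mean(np.array(ps) < 0.05) < 0.1


def mw_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all pooled arrangements (no ties)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.asarray(us)
    mean_u = n * m / 2
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)


class TestMannWhitney:
    def test_textbook_case(self):
        u, p = buf.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = buf.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for n, m in itertools.product(range(3, 7), repeat=2):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = vals[:n], vals[n:]
            _, p = buf.mann_whitney(x, y)
            assert p == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 200)
        y = rng.normal(3, 1, 200)
        _, p = buf.mann_whitney(x, y)
        assert p < 1e-10


def hypergeom_tail_oracle(k, M, K, n):
    """Sum of the hypergeometric pmf over the overlap tail >= k."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += (
            math.comb(K, j) * math.comb(M - K, n - j) / math.comb(M, n)
        )
    return total


class TestTargetEnrichment:
    def test_complete_overlap_small_universe(self):
        universe = {f"g{i}" for i in range(10)}
        setA = {f"g{i}" for i in range(5)}
        out = buf.target_enrichment({"A": setA}, setA, universe)
        assert out.loc["A", "p"] == pytest.approx(1 / 252)
        assert out.loc["A", "overlap"] == 5

    def test_disjoint_sets_not_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        out = buf.target_enrichment(
            {"A": {f"g{i}" for i in range(5)}}, {f"g{i}" for i in range(10, 15)}, universe
        )
        assert out.loc["A", "p"] == pytest.approx(1.0)

    def test_empty_set_flagged(self):
        universe = {f"g{i}" for i in range(10)}
        out = buf.target_enrichment({"A": set()}, {"g1"}, universe)
        assert out.loc["A", "p"] == 1.0 and bool(out.loc["A", "empty"])

    def test_matches_tail_summation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            M = int(rng.integers(8, 31))
            K = int(rng.integers(1, M))
            n = int(rng.integers(1, M))
            universe = [f"g{i}" for i in range(M)]
            targets = set(rng.choice(universe, K, replace=False))
            chosen = set(rng.choice(universe, n, replace=False))
            k = len(chosen & targets)
            out = buf.target_enrichment({"A": chosen}, targets, set(universe))
            assert out.loc["A", "p"] == pytest.approx(
                hypergeom_tail_oracle(k, M, K, n), rel=1e-10
            )


class TestNcrFromCounts:
    def test_no_change_gives_zero(self, noiseless_fixture):
        _, truth, counts, _ = noiseless_fixture
        factors = assay_factors(counts, truth.annotation)
        ncr = buf.ncr_fold_change_from_counts(
            counts["FRAC_nuclear_spliced"],
            counts["FRAC_cytoplasmic_spliced"],
            factors["FRAC_nuclear_spliced"],
            factors["FRAC_cytoplasmic_spliced"],
        )
        unpert = truth.annotation.index[
            ~truth.annotation["perturbed"] & ~truth.annotation["spikein"]
        ]
        assert ncr.reindex(unpert).abs().max() < 1e-9

    def test_doubled_nuclear_counts(self):
        from rnabuffer.containers import AssayCounts

        genes = ["g0", "g1"]
        def ac(vals_ctl, vals_trt):
            matrix = pd.DataFrame(
                {"c1": vals_ctl, "c2": vals_ctl, "t1": vals_trt, "t2": vals_trt},
                index=genes,
            )
            samples = pd.DataFrame(
                {"condition": ["control", "control", "treated", "treated"],
                 "replicate": [1, 2, 1, 2]},
                index=matrix.columns,
            )
            return AssayCounts("FRAC_nuclear_spliced", matrix, samples)

        nuc = ac([10.0, 20.0], [20.0, 40.0])
        cyt_m = ac([30.0, 50.0], [30.0, 50.0])
        cyt = AssayCounts("FRAC_cytoplasmic_spliced", cyt_m.matrix, cyt_m.samples)
        ones = pd.Series(1.0, index=nuc.matrix.columns)
        ncr = buf.ncr_fold_change_from_counts(nuc, cyt, ones, ones)
        assert np.allclose(ncr, 1.0)

    def test_rate_level_identity_and_perfect_buffering(self):
        cfg = rb.noiseless_config(
            rb.SimulationConfig(n_genes=300, n_spikein=30, seed=21, buffering_rho=-1.0)
        )
        truth = rb.sample_rates(cfg)
        counts, _ = rb.simulate_counts(truth, cfg)
        factors, _, fc = infer_fold_changes(counts, truth.annotation)
        ncr_rate = fc[fc["rate"] == "ncr"].set_index("gene_id")["log2fc"]
        ncr_cnt = buf.ncr_fold_change_from_counts(
            counts["FRAC_nuclear_spliced"],
            counts["FRAC_cytoplasmic_spliced"],
            factors["FRAC_nuclear_spliced"],
            factors["FRAC_cytoplasmic_spliced"],
        )
        diff = (ncr_rate - ncr_cnt.reindex(ncr_rate.index)).dropna()
        assert diff.abs().max() < 1e-6
        ann = truth.annotation
        pert = ann.index[ann["perturbed"] & ~ann["intronless"] & ~ann["spikein"]]
        assert ncr_cnt.reindex(pert).abs().max() < 0.01
        # intronless genes compensate export poorly: their NCR does shift
        il = ann.index[ann["perturbed"] & ann["intronless"] & ~ann["spikein"]]
        if len(il):
            assert ncr_cnt.reindex(il).abs().max() > 0.1


class TestBinComparison:
    def annotation(self, n, rng):
        return pd.DataFrame(
            {
                "premrna_length_kb": rng.uniform(1, 80, n),
                "n_exons": rng.integers(1, 12, n),
                "intronless": rng.random(n) < 0.1,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_identical_bins_not_significant(self):
        rng = np.random.default_rng(6)
        ann = self.annotation(600, rng)
        values = pd.Series(rng.normal(0, 1, 600), index=ann.index)
        out = buf.bin_comparison(values, ann, "premrna_length_kb")
        assert bool(out["is_reference"].loc["<10"])
        assert (out["p"].dropna() > 0.01).all()

    def test_shifted_bin_detected(self):
        rng = np.random.default_rng(7)
        ann = self.annotation(600, rng)
        values = pd.Series(rng.normal(0, 1, 600), index=ann.index)
        shifted = ann["premrna_length_kb"] > 50
        values[shifted] += 5.0
        out = buf.bin_comparison(values, ann, "premrna_length_kb")
        assert out.loc[">50", "padj"] < 1e-6
        assert out.loc["10-20", "padj"] > 0.01

    def test_intronless_scheme(self):
        rng = np.random.default_rng(8)
        ann = self.annotation(300, rng)
        values = pd.Series(rng.normal(0, 1, 300), index=ann.index)
        values[ann["intronless"]] += 2.0
        out = buf.bin_comparison(values, ann, "intronless_vs_rest")
        assert out.loc["intronless", "p"] < 1e-4

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            buf.bin_comparison(pd.Series(dtype=float), pd.DataFrame(), "nope")


class TestBufferingCorrelations:
    def test_perfect_buffering_machine_precision(self):
        cfg = rb.noiseless_config(
            rb.SimulationConfig(n_genes=400, n_spikein=30, seed=22, buffering_rho=-1.0)
        )
        truth = rb.sample_rates(cfg)
        counts, _ = rb.simulate_counts(truth, cfg)
        _, _, fc = infer_fold_changes(counts, truth.annotation)
        # restrict to perturbed intron-containing genes, where the coupling
        # is exactly deterministic
        ann = truth.annotation
        pert = ann.index[ann["perturbed"] & ~ann["intronless"] & ~ann["spikein"]]
        sub = fc[fc["gene_id"].isin(pert)]
        summary = buf.buffering_correlations(sub, ann)
        assert summary.r_alpha_retention_all == pytest.approx(-1.0, abs=1e-9)

    def test_uncoupled_generator_gives_no_correlation(self):
        cfg = rb.noiseless_config(
            rb.SimulationConfig(n_genes=5000, n_spikein=50, seed=23, buffering_rho=0.0)
        )
        truth = rb.sample_rates(cfg)
        counts, _ = rb.simulate_counts(truth, cfg)
        _, _, fc = infer_fold_changes(counts, truth.annotation)
        summary = buf.buffering_correlations(fc, truth.annotation)
        assert abs(summary.r_alpha_retention_all) < 0.05

    def test_sig_subset_and_notes(self, small_fixture):
        _, truth, counts, _ = small_fixture
        _, _, fc = infer_fold_changes(counts, truth.annotation)
        summary = buf.buffering_correlations(fc, truth.annotation)
        assert -1 <= summary.r_alpha_retention_sig <= 0
        assert summary.n_sig <= summary.n_all


class TestBufferingEfficiency:
    def make_inputs(self, alpha_cls, alpha_lfc, total_cls):
        fc = pd.DataFrame(
            {
                "gene_id": list(alpha_cls),
                "rate": "alpha",
                "log2fc": [alpha_lfc[g] for g in alpha_cls],
                "se": 0.1,
                "p": 0.001,
                "padj": 0.01,
                "class": [alpha_cls[g] for g in alpha_cls],
            }
        )
        total = pd.DataFrame(
            {"class": list(total_cls.values())}, index=list(total_cls)
        )
        return fc, total

    def test_definitions(self):
        fc, total = self.make_inputs(
            {"a": "down", "b": "ns", "c": "up", "d": "ns"},
            {"a": -2.0, "b": 0.1, "c": 1.5, "d": 0.0},
            {"a": "ns", "b": "up", "c": "down", "d": "ns"},
        )
        labels, summary = buf.buffering_efficiency(fc, total)
        assert labels["a"] == "buffered"  # alpha down 4-fold, total flat
        assert labels["b"] == "under_buffered_up"  # total up despite flat alpha
        assert labels["c"] == "under_buffered_down"
        assert labels["d"] == "unclassified"

    def test_missing_gene_unclassified(self):
        fc, total = self.make_inputs({"a": "down"}, {"a": -2.0}, {"b": "ns"})
        labels, _ = buf.buffering_efficiency(fc, total)
        assert labels["a"] == "unclassified" and labels["b"] == "unclassified"

    def test_buffered_genes_have_larger_transcription_changes(self):
        # construction: large-effect genes perfectly buffered, small-effect
        # genes leak into total RNA
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(200)]
        big = rng.random(200) < 0.5
        alpha_lfc = np.where(big, rng.normal(-3, 0.3, 200), rng.normal(-1.2, 0.2, 200))
        alpha_cls = {g: ("down" if alpha_lfc[i] < -1 else "ns") for i, g in enumerate(genes)}
        total_cls = {g: ("ns" if big[i] else "down") for i, g in enumerate(genes)}
        fc, total = self.make_inputs(alpha_cls, dict(zip(genes, alpha_lfc)), total_cls)
        labels, summary = buf.buffering_efficiency(fc, total)
        assert (
            summary.attrs["median_abs_dalpha_buffered"]
            > summary.attrs["median_abs_dalpha_under_buffered"]
        )

    def test_end_to_end_sign_structure(self, small_fixture):
        # the qualitative reproduction: transcription mostly down, retention
        # mostly up, negative coupling on both compensatory axes
        _, truth, counts, _ = small_fixture
        _, _, fc = infer_fold_changes(counts, truth.annotation)
        t = rb.tally_rate_classes(fc)
        assert t.loc["alpha", "n_down"] > t.loc["alpha", "n_up"]
        assert t.loc["retention", "n_up"] > t.loc["retention", "n_down"]
        summary = buf.buffering_correlations(fc, truth.annotation)
        assert summary.r_alpha_retention_all < 0
        assert summary.r_alpha_stability_all < 0
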