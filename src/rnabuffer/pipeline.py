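"""End-to-end driver: simulate (or read) counts, normalize, infer rates,
quantify buffering, and write a report directory.

Every run is driven by a single :class:`PipelineConfig` (optionally read
from YAML), writes every intermediate table as TSV plus a machine-readable
``summary.json``, and is fully deterministic for a given config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import buffering as buf
from . import io as rio
from . import normalize as norm
from . import rates as rt
from .containers import AssayCounts
from .simulate import SimulationConfig, sample_rates, simulate_counts

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("rnabuffer")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``input_dir`` (fixture directory with count matrices,
    sample sheet and annotation) or ``simulation`` (generator parameters)
    must be set.  Thresholds follow the two conventions of the analysis:
    DEG calls on counts use |log2fc| > ``deg_lfc`` with BH-adjusted
    p < ``deg_alpha``; rate-change calls use |log2fc| > ``rate_lfc`` with
    raw p < ``rate_p`` (BH-adjusted instead when ``rate_use_adjusted``).
    """

    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    output_dir: str = "rnabuffer_out"
    seed: int = 0
    control: str = "control"
    treated: str = "treated"
    deg_lfc: float = 1.0
    deg_alpha: float = 0.05
    rate_lfc: float = 1.0
    rate_p: float = 0.01
    rate_use_adjusted: bool = False
    expression_min: float = 1.0
    pseudo_level: float = 0.5
    spikein_anchor: bool = True  # anchor TT size factors on spike-in rows
    joint_factors: bool = True  # per assay, jointly across conditions
    require_both_axes: bool = False
    make_plots: bool = False  # write buffering scatter PNGs

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_dir or simulation must be configured"
            )
        for name in ("deg_lfc", "deg_alpha", "rate_lfc", "rate_p", "pseudo_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            pulse = sim.pop("pulse", None)
            if pulse is not None:
                from .kinetics import PulseConfig

                sim["pulse"] = PulseConfig(**pulse)
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    # no timestamps: identical runs must produce byte-identical logs
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _obtain_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        log.info("simulating counts (n_genes=%d, seed=%d)", sim.n_genes, sim.seed)
        truth = sample_rates(sim)
        counts, _sheet = simulate_counts(truth, sim)
        annotation = truth.annotation
        return counts, annotation, truth
    directory = Path(config.input_dir)
    annotation = rio.read_annotation(directory / "annotation.tsv")
    counts = rio.read_counts(directory)
    return counts, annotation, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report directory; returns its path.

    Stages: obtain counts -> size factors -> expression filter -> total-RNA
    differential expression -> replicate-averaged means per condition ->
    rate estimates with propagated errors -> rate fold changes and tallies
    -> buffering correlations, count-level NCR, architecture bins, target
    enrichment and efficiency labels -> summary.json + run.log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _run(config: PipelineConfig, outdir: Path) -> Path:
    summary: dict = {"seed": config.seed}
    attrition: dict = {}

    counts, annotation, truth = _stage("input")(_obtain_inputs)(config)
    required = set(rio.ANNOTATION_COLUMNS)
    missing = required - set(annotation.columns)
    if missing:  # validate before any computation starts
        raise ValueError(f"annotation is missing required columns {sorted(missing)}")
    spikes = annotation.index[annotation["spikein"]]
    genes_in = counts["TOTAL"].matrix.index
    attrition["n_input_genes"] = int(len(genes_in))

    @_stage("normalization")
    def _factors() -> dict[str, pd.Series]:
        out = {}
        for assay, ac in counts.items():
            ref = None
            if assay == "TT_labelled_unspliced" and config.spikein_anchor:
                ref = spikes.intersection(ac.matrix.index)
                if len(ref) == 0:
                    raise ValueError("spike-in anchoring requested but no spike rows found")
            out[assay] = norm.size_factors_median_of_ratios(ac, reference_genes=ref)
        return out

    factors = _factors()
    factor_table = pd.concat(factors.values()).rename("size_factor").to_frame()
    rio.write_table(factor_table, outdir / "size_factors.tsv")

    @_stage("expression_filter")
    def _filter() -> pd.Index:
        return norm.expression_filter(
            counts["TOTAL"], factors["TOTAL"], annotation, min_expr=config.expression_min
        )

    keep = _filter()
    attrition["n_expressed"] = int(len(keep))
    attrition["n_filtered_expression_or_mito"] = int(len(genes_in) - len(keep))
    log.info("expression filter kept %d of %d genes", len(keep), len(genes_in))

    @_stage("total_rna_de")
    def _total_de() -> tuple[pd.DataFrame, dict]:
        ac = counts["TOTAL"]
        sub = AssayCounts(
            assay="TOTAL",
            matrix=ac.matrix.loc[ac.matrix.index.intersection(keep)],
            samples=ac.samples,
        )
        disp = norm.estimate_dispersion(sub, factors["TOTAL"])
        de = norm.wald_test(
            sub,
            factors["TOTAL"],
            disp,
            control=config.control,
            treated=config.treated,
            pseudo=config.pseudo_level,
        )
        return norm.classify_deg(de, config.deg_lfc, config.deg_alpha)

    total_de, deg_tally = _total_de()
    rio.write_table(total_de, outdir / "de_TOTAL.tsv")
    summary["deg_total"] = deg_tally
    log.info("total-RNA DEGs: %(n_up)d up, %(n_down)d down", deg_tally)

    @_stage("rate_inference")
    def _rates():
        out = {}
        for condition in (config.control, config.treated):
            means = rt.average_normalized(counts, factors, condition, keep_genes=keep)
            rates = rt.estimate_rates(means, intronless=annotation["intronless"])
            ses = rt.propagate_errors(means)
            rio.write_table(means, outdir / f"mean_abundance_{condition}.tsv")
            rio.write_table(
                rates.join(ses), outdir / f"rates_{condition}.tsv"
            )
            out[condition] = (means, rates, ses)
        fc = rt.rate_fold_changes(
            out[config.control][1],
            out[config.control][2],
            out[config.treated][1],
            out[config.treated][2],
            lfc_threshold=config.rate_lfc,
            p_threshold=config.rate_p,
            use_adjusted=config.rate_use_adjusted,
        )
        return out, fc

    per_condition, fold_changes = _rates()
    rio.write_table(fold_changes, outdir / "rate_fold_changes.tsv", index=False)
    n_analysed = fold_changes[fold_changes["rate"] == "alpha"]["log2fc"].notna().sum()
    attrition["n_rate_analysed"] = int(n_analysed)
    attrition["n_rate_dropped"] = int(len(keep) - n_analysed)

    tallies = rt.tally_rate_classes(fold_changes)
    rio.write_table(tallies, outdir / "rate_tallies.tsv")
    summary["rate_tallies"] = {
        rate: {k: (int(v) if isinstance(v, (int, np.integer)) else float(v))
               for k, v in row.items()}
        for rate, row in tallies.to_dict("index").items()
    }
    log.info(
        "alpha tallies: %d up / %d down of %d",
        tallies.loc["alpha", "n_up"],
        tallies.loc["alpha", "n_down"],
        tallies.loc["alpha", "n"],
    )

    @_stage("buffering")
    def _buffering():
        corr = buf.buffering_correlations(
            fold_changes, annotation, require_both_axes=config.require_both_axes
        )
        ncr_counts = buf.ncr_fold_change_from_counts(
            counts["FRAC_nuclear_spliced"],
            counts["FRAC_cytoplasmic_spliced"],
            factors["FRAC_nuclear_spliced"],
            factors["FRAC_cytoplasmic_spliced"],
            control=config.control,
            treated=config.treated,
            pseudo=config.pseudo_level,
        ).reindex(keep)
        bins = {
            scheme: buf.bin_comparison(ncr_counts, annotation, scheme)
            for scheme in ("premrna_length_kb", "exon_count", "intronless_vs_rest")
        }
        deg_sets = {
            "total_up": set(total_de.index[total_de["class"] == "up"]),
            "total_down": set(total_de.index[total_de["class"] == "down"]),
        }
        enrichment = buf.target_enrichment(
            deg_sets,
            set(annotation.index[annotation["target"]]),
            set(total_de.index),
        )
        labels, eff_summary = buf.buffering_efficiency(
            fold_changes, total_de, annotation
        )
        return corr, ncr_counts, bins, enrichment, labels, eff_summary

    corr, ncr_counts, bins, enrichment, labels, eff_summary = _buffering()
    rio.write_table(ncr_counts.to_frame(), outdir / "ncr_fold_change_counts.tsv")
    for scheme, table in bins.items():
        rio.write_table(table, outdir / f"bins_{scheme}.tsv")
    rio.write_table(enrichment, outdir / "target_enrichment.tsv")
    rio.write_table(labels.to_frame(), outdir / "buffering_efficiency_labels.tsv")
    rio.write_table(eff_summary, outdir / "buffering_efficiency_summary.tsv")

    summary["buffering"] = {
        k: (v if isinstance(v, (str, int)) else (None if pd.isna(v) else float(v)))
        for k, v in corr.as_dict().items()
    }
    summary["buffering_efficiency"] = {
        "median_abs_dalpha_buffered": eff_summary.attrs["median_abs_dalpha_buffered"],
        "median_abs_dalpha_under_buffered": eff_summary.attrs[
            "median_abs_dalpha_under_buffered"
        ],
        "labels": {k: int(v) for k, v in labels.value_counts().items()},
    }
    summary["attrition"] = attrition
    log.info(
        "buffering correlations: retention all=%.3f sig=%.3f; stability all=%.3f",
        corr.r_alpha_retention_all,
        corr.r_alpha_retention_sig
        if corr.r_alpha_retention_sig == corr.r_alpha_retention_sig
        else float("nan"),
        corr.r_alpha_stability_all,
    )

    if truth is not None:
        true_d = truth.delta_log2
        est = fold_changes.pivot(index="gene_id", columns="rate", values="log2fc")
        recov = {}
        for rate in ("alpha", "eta", "gamma"):
            pair = pd.DataFrame(
                {"true": true_d[rate], "est": est[rate].reindex(true_d.index)}
            ).dropna()
            if len(pair) >= 3 and pair["true"].std() > 0:
                recov[rate] = float(np.corrcoef(pair["true"], pair["est"])[0, 1])
        summary["recovery_r_vs_truth"] = recov
        log.info("recovery r vs truth: %s", recov)

    if config.make_plots:
        from .plotting import write_buffering_plots

        write_buffering_plots(fold_changes, outdir, annotation, total_de)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report complete")
    return outdir
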