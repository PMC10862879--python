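# Methods

## Model

Each gene is modelled as a linear cascade of first-order steps:
transcription produces unspliced nuclear pre-mRNA u_N at constant rate α
(molecules/h, arbitrary scale); splicing converts it to spliced nuclear
mRNA s_N at rate β (1/h); export moves s_N to the cytoplasm at rate η
(1/h); cytoplasmic degradation removes s_C at rate γ (1/h). The rates are
*effective*: each lumps a multi-step biological process into a single
exponential stage. Two structural assumptions matter:

- **No nuclear decay.** Export is taken to be fast relative to nuclear
  degradation, so nuclear residence of spliced mRNA is governed entirely
  by translocation (retention ≡ 1/η). If nuclear decay were substantial,
  η would absorb it and "retention" would conflate residence with decay.
- **Quasi-equilibrium.** Rates are read off a single post-treatment time
  point assuming the system has reached the steady state of the new rates
  (u_N = α/β, s_N = α/η, s_C = α/γ). `equilibration_time` quantifies when
  this is safe: a gene with a ~9 h cytoplasmic half-life needs ≈40 h to
  settle within 5%, so for a 24 h treatment the slowest genes are only
  approximately equilibrated. This is a real, quantifiable bias of the
  design, not of the implementation.

Trajectories are computed in closed form (sums of exponentials via
divided differences of e^{−λt}); when two or three of (β, η, γ) coincide
within a relative gap of 1e−9 the confluent (polynomial × exponential)
branch is used, avoiding catastrophic cancellation. The closed form is
tested against a generic ODE integrator.

**Pulse readout.** The labelled unspliced signal after a pulse of length
τ is (α/β)(1 − e^{−βτ}) per unit labelling efficiency (`pulse_mode:
exact`), tending to α·τ for βτ → 0 (`linear`). Simulation defaults to
`exact`, inference to `linear` — the first-order approximation the
steady-state estimators rest on. Because β is gene-specific the
approximation distorts *levels* gene-specifically, but the distortion
cancels in between-condition fold changes as long as β itself does not
change. Time is in hours throughout; the default pulse is τ = 1/6 h
(a 10-minute 4sU pulse).

## Rate inference

From replicate-averaged normalized counts (U_lab, U_N, S_N, S_C):
α ≈ U_lab, β ≈ U_lab/U_N, η ≈ U_lab/S_N, γ ≈ U_lab/S_C, each up to one
unknown global scale per rate type. Consequences taken seriously:

- Only between-condition log2 fold changes are interpreted. Size factors
  are computed per assay *jointly over both conditions' samples*, so the
  per-assay scale is shared and cancels.
- Labelled (TT) libraries are normalized on spike-in rows only:
  median-of-ratios over the whole library would erase a genuine global
  shift in transcription.
- Intronless genes have no unspliced species: β is reported missing for
  them; η and γ are computed as usual.
- Standard errors: first-order delta method on the natural log,
  se_ln(A/B) = sqrt((se_A/A)² + (se_B/B)²), divided by ln 2 for the log2
  scale; condition errors combined in quadrature (independent cultures).
  Genes with any relative input SE above 0.5 are flagged low-confidence —
  first-order propagation is unreliable there (verified against a
  Monte-Carlo oracle: agreement within 5% holds for relative SEs ≤ 0.2).
- Significance of rate changes: two-sided z-test from the propagated SE,
  classified at |log2fc| > 1 with raw p < 0.01 (a configuration flag
  switches to BH-adjusted p). Derived axes are exact identities of the
  primary ones — retention = −η, stability = −γ, N/C ratio = γ − η on the
  log2-fold-change scale; the N/C SE treats the η and γ errors as
  independent, which is slightly conservative since both share U_lab
  (the count-level N/C route, which cancels U_lab entirely, is provided
  as an independent check and agrees exactly on noiseless data).

## Differential expression (total RNA)

A deliberately transparent stand-in for the standard RNA-seq workflow:
median-of-ratios size factors (pseudo-reference = geometric mean over
genes with all-positive counts; factors rescaled to geometric mean 1),
method-of-moments NB dispersion φ_g = max(0, (s² − μ)/μ²) pooled across
conditions and shrunk 50% toward the trimmed-mean dispersion of the 50
nearest genes by base mean, a Wald z-test on log2 of pseudo-count-guarded
condition means with SE (1/ln2)·sqrt(Σ_c (1/n_c)(1/μ_c + φ)), and BH
adjustment. DEGs: |log2fc| > 1, adjusted p < 0.05.

Numerical choices: pseudo-level ε = 0.5 normalized counts guards zeros
(configurable); the local dispersion trend uses a *light* trim (5%)
because the MoM sampling distribution at 2–3 replicates is strongly
right-skewed and heavier trimming biases the trend low, making the test
anti-conservative. Known limitation: with per-gene plug-in dispersions at
3 replicates the test is still mildly liberal (null type-I error ≈ 0.065
rather than 0.05); with the dispersion known it is calibrated (≈ 0.048).
Full empirical-Bayes dispersion shrinkage and outlier refitting are
intentionally out of scope.

The expression filter retains genes above a depth-scaled,
length-normalized expression of 1 (counts per kb per million normalized
reads, an FPKM analogue) and excludes mitochondrial genes.

## Synthetic data generator

The generator emulates the study design end to end: gene-specific control
rates are log-normal (splicing half-life minutes, export ~30 min,
cytoplasmic half-life centred on 9 h, transcription spanning ~2 orders of
magnitude); a fraction of genes (default 0.3) receives a transcription
change Δlog2 α ~ N(−0.5, 1.5) — mostly downward, with ~16% of all genes
beyond |log2FC| = 1, commensurate with an acute loss of a transcriptional
coactivator; export and degradation respond with correlation −ρ to Δα
(ρ = `buffering_rho` ∈ [−1, 0] is the target correlation between Δα and
the *retention* change −Δη). The response tracks Δα itself, so a cohort
whose transcription drops acquires, on average, longer nuclear residence
and higher stability. At ρ = −1 the coupling is deterministic and
identical for η and γ: nuclear and cytoplasmic levels and the N/C ratio
are exactly unchanged — perfect buffering. Intronless genes (default 5%,
short, one exon) have β = ∞, contribute no unspliced counts, and
compensate through export only half as well (`intronless_response_scale`),
so they shift their N/C ratio even under otherwise perfect buffering.
Putative direct targets of the perturbed factor (default 20% of genes)
are over-sampled 3:1 among perturbed genes, giving the expected target
enrichment among down-regulated genes.

Counts: five assays per condition × replicate (labelled unspliced,
nuclear unspliced, nuclear spliced, cytoplasmic spliced, total), expected
counts = per-library scale × abundance with each library totalling
~`depth_per_assay` (default 5e6) under log-normal depth jitter (sd 0.15),
drawn NB(μ, φ) with φ = 0.05 by default (variance μ + φμ²; Poisson at
φ = 0 with jitter; exact expectations when both noise layers are off —
the mode used for machine-precision identity checks). Spike-in rows
appear only in labelled libraries, at fixed abundance comprising 1/11 of
the library (a 1:10 spike:sample ratio). An optional `contamination`
parameter leaks a fraction of each fraction's signal into the other for
robustness tests; it is off by default.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: positional/isoform structure (counts are
gene-level draws around exact steady-state expectations), correlated
biological replicate effects beyond library depth, nuclear degradation,
transcriptional bursting, partial equilibration at 24 h (simulated
conditions are exactly at steady state), and any real spike-in
protocol variability.

## Problem sizes and determinism

Default analyses run at 2000 genes × 3 replicates; identity checks use
300–500 genes; calibration nulls 3000–5000 genes; the Monte-Carlo error
propagation oracle uses 1e5 draws × 100 cases. One seed drives every
random layer; identical configuration and seed reproduce every output
table byte for byte (fixed float formatting, no timestamps in logs).

Under the default conditions the recovery correlation between true and
estimated Δlog2 is ≈ 0.95 for α and ≈ 0.90–0.91 for η and γ among genes
with well-measured means — the binding constraint is counting noise at
φ = 0.05 with 3 replicates, which floors the fold-change SE near 0.37
(log2) for the ratio-based rates regardless of depth.

## Design choices where the design was open

- Which count class feeds U_lab (intronic only vs whole-gene labelled
  reads) is exposed via the simulation's pulse/readout configuration;
  inference consumes whatever the `TT_labelled_unspliced` matrix holds.
- Frac-seq size factors are computed per fraction (per assay), not
  jointly across fractions; a shared global scale would be erased in the
  N/C *difference* anyway.
- "Significant genes" in the correlation panel require significance on
  the transcription axis only (`require_both_axes` switches to both).
- Rate-change significance uses raw p < 0.01 by default; BH-adjusted
  gating is available (`rate_use_adjusted`).
- Per-quantity effective-length normalization is not applied: it cancels
  in fold changes, which are the only interpreted quantities.
- Histone-class binning is driven by a user-supplied `histone_class`
  annotation column; the package does not ship gene lists.
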