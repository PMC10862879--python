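# rnabuffer

Gene-specific rates of mRNA metabolism — and how completely cells *buffer*
changes in them — from metabolic-labelling (TT-seq-like) and
nuclear/cytoplasmic fractionation (Frac-seq-like) RNA-seq counts.

## The problem

Total RNA-seq measures steady-state abundance, which confounds synthesis
with export and degradation: a transcriptional activator can look like a
repressor if cells compensate for lost synthesis by retaining and
stabilising the remaining transcripts. Disentangling the two requires
assays that see the individual steps — a short 4sU pulse that labels
newly synthesised RNA (transcription readout) and sequencing of separated
nuclear and cytoplasmic fractions (where the molecules sit).

`rnabuffer` is for computational biologists who have (or want to simulate)
such data in two conditions and want per-gene answers: which rates changed,
by how much, with what confidence — and whether the changes in synthesis
were absorbed by compensatory changes in export and stability
("transcript buffering") or leaked into RNA abundance.

## The model

Each gene is a linear cascade with four first-order rates:

```
du_N/dt = α − β·u_N          (transcription α, splicing β)
ds_N/dt = β·u_N − η·s_N      (nuclear export η)
ds_C/dt = η·s_N − γ·s_C      (cytoplasmic degradation γ)
```

where u_N, s_N, s_C are unspliced nuclear, spliced nuclear and spliced
cytoplasmic mRNA. Nuclear degradation is neglected (export is assumed
faster). If the treatment is long relative to the RNA half-lives the cells
sit at the steady state

```
u_N = α/β,   s_N = α/η,   s_C = α/γ,
```

and a short labelling pulse of length τ gives a labelled unspliced signal
(α/β)(1 − e^(−βτ)) ≈ α·τ, directly proportional to transcription. Hence,
from replicate-averaged normalized counts U_lab, U_N, S_N, S_C, the rates
follow up to one global scale per rate type:

```
α ≈ U_lab,   β ≈ U_lab/U_N,   η ≈ U_lab/S_N,   γ ≈ U_lab/S_C,
```

with delta-method standard errors on the log scale. Only between-condition
ratios (log2 fold changes) are interpreted, so the unknown scales cancel;
labelled libraries are normalized on exogenous spike-ins so that global
shifts in transcription are not normalized away. Nuclear retention is
1/η, cytoplasmic stability 1/γ, and the N/C ratio s_N/s_C = γ/η.

Buffering is then quantified as the (negative) correlation between
Δlog2 α and the retention/stability fold changes, the flatness of
Δlog2 (N/C), and a per-gene efficiency label (transcription changed but
total RNA flat = buffered).

## Worked example

`examples/buffering_report.py` runs the full pipeline on the default
synthetic experiment (2000 genes, 3 replicates per condition, negative-
binomial noise, a perturbation that lowers transcription on average with
compensatory coupling ρ = −0.8) and prints:

```
correlations of Dlog2(transcription) with the compensatory axes:
  vs retention  (all genes):        r = -0.758
  vs retention  (significant only): r = -0.817
  vs stability  (all genes):        r = -0.792
  vs N/C ratio  (all genes):        r = 0.043

transcription calls: 228 down vs 71 up, of 1926 genes
retention calls:     207 up vs 81 down

buffering efficiency (rate change vs total-RNA change):
  median |Dlog2 alpha|, buffered genes:       1.71
  median |Dlog2 alpha|, under-buffered genes: 1.11
```

Read: transcription dropped for three times as many genes as it rose;
those genes retained their transcripts longer in the nucleus and
stabilised them in the cytoplasm (negative correlations), keeping the
N/C ratio flat; and the genes with the *largest* transcription changes
are the best buffered. The other examples (`steady_state_and_flux.py`,
`simulate_and_recover_rates.py`) walk the kinetic model and the
rate-recovery accuracy.

A thin CLI mirrors the stages: `rnabuffer simulate`, `normalize`,
`rates`, `buffering`, `run-all --config config.yaml`.

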