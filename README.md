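# tilechip

Tiling-array (ChIP-chip) analysis for regulatory genomics: probe-level
peak calling under the per-array neighborhood model, ranked feature
annotation, divergent-gene-pair and insulator/TAD-boundary overlap rules,
chromosome/size-preserving permutation enrichment, anchored signal
meta-profiles, RNA Pol II pausing classification, per-gene histone-mark
differential tests, motif scanning with exact p-values, pseudomedian
smoothing, and ΔΔCt quantification.

The package is aimed at epigenomics analysts who need the classic
ChIP-chip workflow — the kind used to map an insulator-associated
transcription factor against H3K27me3 Polycomb domains, H3K4me3,
divergently paired genes, and RNA Pol II pausing in *Drosophila* — as
reusable, tested code.  Every stage is exercisable end-to-end on
synthetic data with recorded ground truth (`tilechip.simulate`), so
correctness is established by oracles instead of by archival array data.

## The core statistics

**Peak calling.** Probe *i* (per-probe p-value *pᵢ*) is *significant* iff
some adjacent probe *j* within 1 kb satisfies (pᵢ + pⱼ)/2 < 0.05.  Peaks
are maximal runs of significant probes with consecutive significant
probes ≤ 300 bp apart and ≥ 4 significant probes.  Per-probe p-values
default to a robust empirical null: z = (x − median)/(1.4826·MAD)
genome-wide, p = 1 − Φ(z).

**Permutation enrichment.** Each query interval is re-placed uniformly on
its own chromosome (count, size, chromosome preserved), 1000 times; the
observed overlap (targets expanded ±500 bp) is scored as
z = (obs − mean)/sd against the permuted distribution, with
fold = obs/mean.

**Pol II pausing.** For genes ≥ 1 kb, the median signal over the paused
region [TSS−30, TSS+300] is compared between mutant and control:
category 1 = lower in mutant (reduced recruitment), category 2 = higher
(increased pausing); gene-body medians ([TSS+1000, TES]) accompany each
call, Mann-Whitney U over probes gives the region-level significance.

**Per-gene histone tests.** Welch's t (or Mann-Whitney) over probe values
in TSS-anchored intervals (H3K4me3: [TSS, +2000]; H3K27me3: [+200,
+2200]), Benjamini-Hochberg corrected; genes are classed as K27-depleted
only, K4-enriched only, both, or unchanged, and expression folds map to
moderate (2–5×), high (>5–10×), maximal (>10×).

**Motifs.** PWM log-odds in bits against the background's order-0
marginal, with p-values from the exact score distribution via dynamic
programming (1e-3 bit lattice); IUPAC consensus scans (e.g. YAACKG,
match probability 1/1024 under a uniform background) gate exact matches
at p < 0.001.

**Pseudomedian smoothing.** Span-3 Hodges-Lehmann: the median of all
Walsh averages (xᵢ + xⱼ)/2 over each 3-probe window.

See `docs/methods.md` for assumptions, parameter defaults, and design
choices.

## Worked example

The numbered drivers under `analysis/` run a complete synthetic study
(two 300 kb chromosomes, ~18,000 probes/track, 60 genes, 50 planted
binding sites, 10 half-depleted H3K27me3 domains).  From `analysis/`:

```
$ python 02_call_peaks.py
called 50 peaks against 50 planted sites
sensitivity 1.000, precision 1.000
wrote .../results/called_peaks.bed and .tsv sidecar

$ python 05_domain_profiles.py
in-domain signal: control 2.008 vs mutant 1.000 (t = 224.9, p = 0)

$ python 06_polii_classes.py
category 1: 35 genes, category 2: 25 genes, excluded: 0
agreement with planted regimes: 100%
paused region: 60/60 genes significant (Mann-Whitney, q < 0.05)
```

Reading these numbers: the neighborhood caller recovers every planted
SNR-4 site with no false calls on this realization; the pooled-probe
Welch test sees the planted 50% H3K27me3 depletion (control mean 2.0 →
mutant 1.0); and the paused-region median comparison assigns every gene
to its planted Pol II regime.  `01_simulate_study.py` writes the study's
annotation and truth files, `03`–`04` annotate peaks and run permutation
enrichment, `07`–`10` cover histone-mark classes, motif scans, smoothing,
and qPCR.  Tables land in `results/`, bulky wiggle exports in `scratch/`.

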