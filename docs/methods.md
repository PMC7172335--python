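# Methods

`tilechip` re-implements, as a tested pipeline, the analysis workflow of a
tiling-array (ChIP-chip) study of an insulator-associated transcription
factor in *Drosophila* wing discs: probe-level peak calling, ranked feature
annotation, divergent-gene-pair and boundary overlap rules, permutation
enrichment, anchored signal meta-profiles, RNA Pol II pausing
classification, per-gene histone-mark differential tests, motif scanning,
pseudomedian smoothing, and ddCt quantification.  Every stage runs on
synthetic data with recorded ground truth, so each guarantee is checked
against an oracle rather than against irreproducible archival arrays.

## Coordinates and probe model

Internal coordinates are 0-based half-open throughout; GFF (1-based
inclusive) and wiggle (1-based) are converted exactly once at the I/O
boundary.  A probe is identified by (chromosome, start); every distance
rule measures start-to-start, chosen once and used consistently because the
source protocol never states start vs. center.  Multi-replicate tracks
store replicates as samples; stages that need one value per probe per
condition take the per-probe mean across replicates.  The ChIP signal is
treated as an opaque real-valued log2 intensity — the pipeline does not
assume ratio vs. single-channel scaling.

## Peak calling (per-array neighborhood model)

The caller consumes per-probe p-values.  Probe *i* is significant iff some
adjacent probe *j* within `neighbor_max_gap` = 1000 bp satisfies
mean(p_i, p_j) < `probe_alpha` = 0.05 (strict, matching "less than"); this
is the weakest reading of the averaged-neighbor clause and is isolated
behind a single predicate.  Peaks are maximal runs of significant probes
with consecutive significant probes ≤ `peak_probe_gap` = 300 bp apart,
kept when the run holds ≥ `min_sig_probes` = 4.  The 1000 bp clause defines
neighborhood only; the 300 bp clause is the run rule.  A peak spans
[first significant probe start, last significant probe start + probe
length) — the protocol never defines peak edges, so the significant-probe
footprint is used.  A run's score is −log10 of the mean p over its
significant probes.

Because the p-value construction behind the original caller is not
published, `probe_significance` supplies a declared stand-in: a robust
one-sided upper-tail test against the array's own empirical null,
z = (x − median) / (1.4826·MAD) genome-wide per sample, p = 1 − Φ(z).
`call_peaks` accepts externally computed p-values, decoupling the two.
Ties at p = α are not significant; a zero-MAD array raises a
degenerate-null error rather than fabricating p-values.

## Annotation rules

Feature assignment tests, in fixed rank order, promoter > exon > intron >
intergenic, with ≥ 1 bp overlap as the universal predicate.  The promoter
is the 200 bp immediately upstream of the TSS, mirrored on the minus
strand.  "Within ± N bp" rules are implemented as symmetric expansion by N
followed by the overlap predicate.  Divergently paired genes (DPGs) are
(minus, plus) gene pairs whose bodies point away from the inter-TSS gap
with TSS distance ≤ 1000 bp; a gene may join several pairs, a gap of 0 is
allowed, and a configurable id list (e.g. histone clusters) is excluded.
A pair is *bound* when a peak overlaps the union of 500 bp downstream of
either TSS (in each gene's own direction) and the inter-TSS span.  Domain
or TAD boundaries count as bound within 5 kb.

## Permutation enrichment

Shuffles preserve interval count, length, and chromosome: each interval is
independently re-placed uniformly on its own chromosome (shuffled
intervals may overlap — the protocol has no exclusion clause).  The
observed overlap (each query interval counted at most once, targets
expanded by the slack, default 500 bp, applied to the target set only) is
compared to 1000 shuffles by z-test with the n−1 sd; the p-value is
two-sided by default (one-sided available).  A zero-spread null is flagged
degenerate and reported as NA, never as 0.  Fisher's exact test
(two-sided, minimum-likelihood enumeration via scipy) and the upper-tail
hypergeometric test cover the count-table comparisons; the hypergeometric
universe N is always an explicit argument because the published DPG
overlap test does not state it.

## Profiles and region tests

Anchored profiles place probe values at anchor-relative coordinates,
reflecting minus-strand anchors and domain end-boundaries so "downstream"
/ "into the domain" always points toward +x.  The per-entity statistic is
a centered sliding window (10 bp for domain profiles, 100 bp for Pol II
profiles) stepping 1 bp; empty windows contribute NaN and are ignored in
the cross-entity aggregate (no zero fill, which would create
probe-spacing artifacts).  Display smoothing is a 900 bp centered moving
average with shrinking edge windows.

The domain depletion test pools every probe value inside any (merged)
domain per condition and applies Welch's t-test — Welch wherever the
protocol prints "Student's t test", as the conservative unequal-variance
choice (pooled-variance available by flag).  Pol II classification
compares median mutant vs. control signal over the strand-oriented paused
region [TSS−30, TSS+300] for genes ≥ 1000 bp: lower in mutant → category
1, higher → category 2, exact tie or missing probes → excluded with a
reason; gene-body medians ([TSS+1000, TES]) are reported alongside, and
genes whose body would be empty are excluded from body-region tests.
Per-gene region tests (H3K4me3 over [TSS, TSS+2000], H3K27me3 over
[TSS+200, TSS+2200], Pol II paused/body) compare the two conditions'
probe values — probes, not replicate arrays, are the unit of replication,
as the pooled-probe wording of the domain test implies; the
replicate-level alternative would need more arrays than the protocol
used.  Mann-Whitney is exact for tie-free samples with min size ≤ 20 and
normal-approximated with tie correction otherwise; all-tied samples
return p = 1.  Benjamini-Hochberg q-values are computed over all tested
genes; q < 0.05 is significant.  Upregulation folds map to categories:
none < 2, moderate 2–5, high >5–10, maximal >10.

## Motif scanning

The Markov background is fitted by transition counting with pseudocount
0.1 per cell over the literal input text (reverse-complement augmentation
by flag).  "7 bp" background is read as order 7; the order is a config
field because fitting order 7 needs genome-scale input — synthetic runs
use orders 0–2, and either reading (order 6 or 7) is reachable.  PWM
scores are log2 odds against the background's order-0 marginal; p-values
come from the exact distribution of scores of random background words,
computed by dynamic programming on a lattice of 1e-3 bits.  The
position-independent order-0 null is what makes a single per-position
p-value well defined.  Zero PWM cells score −∞ and can never be hits;
their probability mass leaves the finite support of the null.  Consensus
scans (YAACKG, TTSSSSS) are exact IUPAC matches on both strands, gated by
the closed-form match probability (product of admitted-base marginals;
1/1024 for YAACKG under a uniform background, below the 0.001 threshold).
De novo discovery is out of scope: "overrepresented sequences" are
realized as scan-and-threshold against supplied matrices.

## Pseudomedian smoothing

Track export uses the one-sample Hodges-Lehmann pseudomedian with
span = 3 probes: per probe, the median of all Walsh averages
(x_i + x_j)/2, i ≤ j, over the centered window, shrunk at chromosome
ends.  The span counts probes, not bp, per the cited smoothing tool's
convention.  The original "Mohanan-modified" variant is not described in
any accessible source, so the classical estimator is used and the variant
name recorded here.

## ddCt quantification

Technical replicates are averaged first, then biological replicates,
exactly in that order; fold = 2^(−ddCt) with amplification efficiency
fixed at 2.  Reciprocal folds multiply to 1 exactly and folds are
invariant to any constant Ct shift.  Significance is a two-sided unpaired
t-test on per-biological-replicate folds.

## Synthetic data: what it emulates and what it does not

The generator builds a multi-chromosome genome with a regular probe grid
(default spacing 33 bp — the tiling design's median probe spacing — with
60-mer-style probes of length 50), Gaussian background noise, boxcar
factor peaks of height snr·σ, broad plateau domains multiplicatively
depleted in the mutant, per-gene Pol II tracks (paused spike over
[TSS−30, TSS+300], body plateau from TSS+1000) in two planted regimes
(regime 1: spike and body both scaled 0.5 in the mutant; regime 2: spike
×1.5, body ×0.5), divergent pairs with TSS gaps uniform on [50, 1000] bp,
and i.i.d. promoter sequences with planted exact-consensus motifs.  The
default planted-peak density is one site per ~12 kb, the binding-site
density observed in the source study.  Unpaired genes are separated by
more than the 1 kb rule so planted pairs are exactly the discoverable
ones.  All generators are bit-reproducible under a fixed seed.

Deliberately absent: array dye and spatial artifacts, replicate batch
effects, sequence-dependent probe affinity, copy-number structure, and
irregular probe spacing.  Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical model, not
robustness to real-array systematics — the normalization steps that
address those (RMA, inter/intra-array median normalization) are upstream
of this pipeline and out of scope.

## Problem sizes and numerical choices

Default study conditions: 2 × 300 kb chromosomes, ~18,000 probes per
track, 60 genes, 50 planted peaks, 10 domains; recovery rates aggregate
20 seeded replicates, null calibration uses 500 trials of 200
permutations, and the exhaustive-placement check enumerates all
placements on a 1 kb toy chromosome.  These sizes keep every oracle
exact or near-exact while exercising the same code paths as a full
genome.  Tolerances: format round-trips to 1e-9; DP p-values agree with
enumeration to one lattice step; Monte-Carlo comparisons use 3 standard
errors; the calibration band is the 99% binomial interval around 0.05.

## Known limitations

- The empirical-null p-value is a stand-in for the unpublished per-probe
  model; peak *sets* are faithful to the neighborhood/run rules, but
  per-probe p-values on real arrays would differ.
- Exact ties in Pol II classification are excluded rather than
  arbitrated; on continuous synthetic data ties are measure-zero, on
  heavily rounded real data the excluded class would grow.
- `scan_pwm` reports lattice-quantized scores (1e-3 bit granularity).
- One transcript model per gene id; multi-isoform TSS selection is the
  caller's responsibility.
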