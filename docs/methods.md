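# Methods

`zgakit` re-implements, as a tested library, the computational analyses used
to characterise the shift from promiscuous (minor ZGA) to regulated (major
ZGA) transcription between the early and late two-cell stages of mouse
embryogenesis, and the role of the replication-dependent histone variants
H3.1/3.2 in that shift. It operates on standard text formats (GTF/BED count
tables, pairs-like contact lists, TSV time series) and ships a synthetic-data
generator that plants known truth for every quantity the pipeline measures.

## Genome model and intergenic space

Coordinates are 0-based half-open throughout; GTF input (1-based closed) is
converted on read. Intergenic space is the per-chromosome complement of all
gene bodies — protein-coding, non-coding and pseudogene alike, with all
isoforms merged — expanded by `distance_bp` (default 10 000 bp) on both
sides and clipped to the chromosome. Because the expansion covers bases at
distance `<= d`, a base exactly 10 kb from a gene is excluded: intergenic
bases are strictly farther than the cutoff. Repeat elements are *not*
subtracted; intergenic space deliberately includes them. Strand is read but
ignored (no strand rule is part of the definition). The implementation
(sorted-array merge/complement) is tested for exact equality against an
independent per-base distance-transform oracle on randomised toy genomes.

## Expression

**TPM/CPM.** Genes are quantified as transcripts per million
(`rate_i = count_i / length_i`, scaled so each sample sums to 1e6); repeats
as counts per million. Replicate columns (`stage.condition.repN`) are
averaged after normalisation.

**Maternal exclusion.** Transcripts deposited in the oocyte and degraded
after fertilisation must not contaminate embryonic clustering. The default
rule flags genes whose TPM decreases strictly through MII → early two-cell →
late two-cell; any rebound at the early two-cell stage is taken as evidence
of zygotic transcription. A looser `ends_only` mode (MII > late two-cell
only) is selectable, since the published description admits either reading;
the strict rule is the default because it retains minor-ZGA burst genes that
happen to start below their oocyte level.

**Clustering.** Embryo-transcribed features are split on
`r = log2((late + pc) / (early + pc))` with pseudocount `pc = 1`:
cluster I (increase) `r > 0.5`, cluster III (decrease) `r < -0.5`, cluster II
(little change) strictly between. Ties land in cluster II (both inequalities
strict). The pseudocount is a package choice: stage-specific genes with zero
abundance in one stage are the dominant case at ZGA and must not produce
infinite ratios; `pc` is exposed as configuration.

**Knockdown response.** Per-feature `log2((KD + pc) / (control + pc))` at
the late two-cell stage, summarised per cluster by median and quartiles;
empty clusters are reported with size 0 and no statistics.

**Intergenic ratio.** A paired-end template (leftmost to rightmost mapped
base of the pair) counts as intergenic only when completely contained in a
single intergenic interval; the ratio is intergenic templates over all
templates. Counting is per template, not per mate.

**Deposition metaprofiles.** A scale-regions profile: 2 kb flanks binned at
native scale (20 bins), gene bodies rescaled to 50 bins with fractional-base
weighting. Per-bin density is `coverage / (bin width in kb) /
(fragments/1e6)` — reads per kilobase per million mapped fragments — then
averaged over genes. Coverage is computed directly from fragment intervals
rather than from an intermediate binary coverage file, which preserves the
computed quantity while keeping all inputs plain text. A uniform-coverage
input yields a flat profile to machine precision (unit-tested).

**Deposition–expression correlation.** Spearman rank correlation (average
ranks on ties, via `scipy.stats.spearmanr`, cross-checked in tests against
the explicit rank formula) between per-gene mean body deposition density and
the expression log-ratio `r`.

## Hi-C

Contacts arrive as 5-column pairs (`chrom1 pos1 chrom2 pos2 count`). The
cis fraction is the count-weighted share of intra-chromosomal records.
Intra-chromosomal contacts are binned (default 100 kb — a desk-scale choice;
configurable) into symmetric per-chromosome matrices. The expected profile
is the mean count at each bin separation; O/E divides each cell by the
expected value at its distance (epsilon-guarded).

**Domain score.** TAD strength for a domain spanning bins `[a, b)` with
flank `L = flank_factor * (b - a)` (default factor 1) is the mean O/E over
the within-domain square divided by the mean O/E over the two equal-sized
blocks `[a-L, a) x [a, b)` and `[a, b) x [b, b+L)`, with main-diagonal cells
excluded from every mean. This centre/flank ratio is defined and documented
here so results are self-consistent within the package; it follows the
aggregate-pileup domain-score idea but is not claimed numerically identical
to any external implementation or version. Domains under 3 bins, or whose
flanked window leaves the chromosome, are skipped with a warning. TADs with
score strictly above 2.5 are counted as "strong". No ICE/KR balancing is
applied (none is part of the analysis being reproduced); the O/E step makes
the score invariant to global scaling of the raw matrix.

**Pileup.** Each domain window (domain plus one domain-length of flank each
side) is rescaled to a 99x99 grid by overlap-weighted block averaging and
averaged across domains; the centre third of the grid is the domain.

Known bias: planted (or real) TAD squares inflate the short-range expected
profile, so domain scores are biased low by roughly the TAD share of the
near-diagonal — about 3–5% at the synthetic defaults, ~10–13% when domains
cover a large fraction of a short chromosome. Orderings and threshold counts
at the default conditions are unaffected; the recovery test budgets 10%.

## FRAP and intensities

The mobile fraction of a recovery curve with `n_pre = 3` pre-bleach frames
and 10 post-bleach frames at 5 s intervals is
`MF = (F_inf - F_0) / (F_pre - F_0)`, with `F_pre` the mean pre-bleach
intensity, `F_0` the first post-bleach frame, and `F_inf` the mean of the
last 3 recovery frames. No exponential fit is performed — the index, not the
kinetics, is the quantity of interest; plateau truncation biases MF by at
most `MF * exp(-k * 35 s)` for recovery rate `k` (negligible at the default
simulated rate 0.25 /s). Results are clipped to [0, 1.5] with genuine
out-of-range values flagged. The estimator is invariant under pure gain
rescaling of the whole curve.

Immunofluorescence intensities are corrected per embryo by the DAPI signal
and normalised to the control-group mean ratio, so the control mean is 1 by
construction (to machine precision).

## Synthetic data

The generator emulates the study conditions; its defaults are fixed, not
tuning knobs.

* **Genome**: chr1 40 Mb + chr2 30 Mb; 400 non-overlapping genes of
  2–20 kb (80% protein-coding, 10% lncRNA, 10% pseudogene), 250 repeats.
  The emitted intergenic truth comes from the per-base oracle, independent
  of the interval-arithmetic derivation it tests.
* **Expression**: gene classes maternal 25%, I 25%, II 15%, III 35%.
  Planted log2(late/early) ratios (pseudocount space): I in (1.2, 3.2),
  II in (-0.1, 0.1), III in (-3.2, -1.2), maternal in (-3.3, -0.75);
  maternal genes additionally sit 0.3–0.7x below their MII level at the
  early two-cell stage. A single global shift (root-found) makes the late
  column renormalise exactly to the 1e6 TPM budget so planted ratios survive
  measurement; the generator raises an error if any planted ratio lands
  within 0.1 of a +-0.5 threshold. Knockdown folds: cluster III 2–6x up,
  cluster I 0.5–0.85x, cluster II and maternal ~1x. Counts are NB2 with
  dispersion 0.1 (3 replicates per sample); dispersion 0 gives rounded
  means, making truth recovery exact in the noise-free limit. Repeats use
  the same machinery on the CPM scale (fractions I 12% / II 48% / III 40% —
  repression-dominated, as at major ZGA).
* **Fragments**: 20 000 templates per sample of 100–500 bp; intergenic with
  probability MII 0.05, early two-cell 0.30, late two-cell control 0.10,
  late two-cell KD 0.28 (the promiscuous-transcription trajectory), placed
  fully inside a uniformly chosen intergenic interval, otherwise overlapping
  a uniformly chosen gene.
* **Deposition**: 40 000 fragments over genes with weight
  `length * exp(-0.35 * r + N(0, 1.2))`, coupling deposition negatively to
  expression change at a moderate strength (Spearman rho around -0.3 to
  -0.5), as observed for H3.1/3.2 at the late two-cell stage.
* **Hi-C**: background rate `(1 + |i - j|)^-1` per bin pair, Poisson-sampled
  at 1.2e6 contacts (5% inter-chromosomal); 5 TADs per chromosome of 8–15
  bins at conserved locations, with per-sample strengths — late two-cell
  control [3.4, 3.0, 2.8, 1.8, 1.4] (TADs formed), early two-cell and KD
  samples all below 2.5 (TADs absent/disrupted).
* **FRAP**: true mobile fractions 0.80 (one-cell), 0.55/0.60 (early 2C
  control/KD), 0.30 (late 2C control), 0.55 (late 2C KD) — chromatin closes
  by the late two-cell stage unless H3.1/3.2 are depleted; 20 curves per
  sample, bleach floor 0.35, rate 0.25 /s, noise sd 0.01.
* **Intensity**: 20 embryos per group; KD signal at 0.35x of control after
  DAPI correction, lognormal noise sd 0.15.

All randomness flows through `numpy.random.default_rng` seeded from the
config seed plus a per-component tag, so outputs are byte-identical across
runs and independent of generator invocation order.

### What the generator does not emulate

Real read alignment (mapping ambiguity, rRNA contamination, soft-clipping),
isoform structure and splicing, sequence content, GC/mappability bias,
Hi-C ligation artefacts and balancing-relevant coverage bias, the
aphidicolin (replication-inhibition) arm, and any hypothesis testing between
groups. Passing tests therefore demonstrate correctness of the computations
and recoverability of planted effects under idealised noise — not robustness
to upstream artefacts of real embryo sequencing data.

### Expected recovery at the default noise level

NB2 dispersion 0.1 imposes a coefficient-of-variation floor of
`sqrt(0.1) = 0.32` per replicate independent of depth, i.e. ~0.37 sd on a
3-replicate log2 ratio. Cluster II genes, with two thresholds within ~1.4
sd, are therefore misclassified at ~15–20% however deep the libraries; with
the default class mix the overall planted-label recovery is ~96% (and exact
at dispersion 0). Maternal exclusion is essentially exact at the defaults
because the planted decay margins are large relative to the noise.

## Problem sizes and numerical choices

Default analyses run on the sizes above (70 Mb genome, ~1e5 fragments,
~5e6 contact pairs across four Hi-C samples) in well under a minute; the
TAD-recovery check uses a single 40 Mb chromosome at 2e6 contacts, chosen so
Poisson error on the domain score is ~1%. Tolerances: TPM/CPM conservation
to 1e-9 relative; "exact" identities (control-mean normalisation, closed-form
mobile fraction) to 1e-12 absolute, the limit of float representability;
O/E epsilon guard 1e-12 with a logged warning when triggered. Degenerate
inputs (empty fragment lists, all-zero samples, constant vectors for
correlation, domains too small to score, curves without a bleach) raise
errors or are skipped with warnings, as documented per function.
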