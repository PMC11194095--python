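# zgakit

Analysis toolkit for the first transition of the embryonic gene-expression
program: the shift from promiscuous, enhancer-independent transcription
(minor zygotic genome activation) to regulated transcription (major ZGA)
between the early and late two-cell stages of the mouse embryo, and the role
of the replication-dependent histone variants H3.1/3.2 in closing chromatin
to execute that shift.

It is written for computational biologists who want the complete analysis
chain behind this kind of study as a reusable, tested library: RNA-seq
quantification and fold-change clustering, intergenic-read ratios, histone
deposition metaprofiles, Hi-C TAD strength, and FRAP/immunofluorescence
statistics — plus a synthetic-data generator with planted ground truth so
every stage is exercisable without any sequencing download.

## What it computes

* **TPM/CPM** per gene/repeat: `TPM_i = 1e6 · (c_i/ℓ_i) / Σ_j (c_j/ℓ_j)`.
* **Maternal exclusion**: drop genes with TPM(MII) > TPM(early 2C) >
  TPM(late 2C) (strictly decreasing — maternally deposited, decaying RNA).
* **Expression clusters** on r = log₂[(late+1)/(early+1)]:
  cluster I (increase) r > 0.5; cluster II (little change) −0.5 < r < 0.5;
  cluster III (decrease) r < −0.5 — and the knockdown response
  log₂[(KD+1)/(control+1)] summarised per cluster.
* **Intergenic ratio**: fraction of paired-end templates completely within
  regions > 10 kb from any gene (non-coding genes and pseudogenes count as
  genes; repeats are not subtracted) — the proxy for promiscuous
  transcription.
* **Deposition metaprofiles** (scale-regions, RPKM) and the Spearman
  correlation between per-gene deposition and expression change.
* **Hi-C**: cis-contact fraction, binned O/E matrices, rescaled TAD pileups,
  and TAD strength = mean O/E inside the domain square over mean O/E in the
  two flanking blocks (diagonal excluded); TADs with strength > 2.5 are
  "strong".
* **FRAP mobile fraction** MF = (F∞ − F₀)/(F_pre − F₀), the open-chromatin
  index, and DAPI-corrected relative intensities (control mean ≡ 1).

See `docs/methods.md` for definitions, defaults, and known limitations.

## Worked example

Simulate the default study (MII / early two-cell / late two-cell; control
vs H3.1/3.2 knockdown) and run every analysis:

```bash
zgakit run --seed 1 --out results/run
```

`results/run/report.json` then contains, among other sections (numbers from
this exact command):

```
"intergenic": { "ratio_by_sample": {
    "MII.none": 0.0498, "early2C.control": 0.3075,
    "late2C.control": 0.0994, "late2C.KD": 0.27585 } }
"expression": { "kd_median_log2_by_cluster": {
    "I": -0.640, "II": 0.111, "III": 1.896 } }
"deposition": { "spearman_rho_vs_expression_change": -0.536 }
"hic": { "late2C.control": { "cis_fraction": 0.950, "strong_tads_gt_2.5": 5 },
         "late2C.KD":      { "cis_fraction": 0.950, "strong_tads_gt_2.5": 0 } }
"frap": { "late2C.control": { "mean_mobile_fraction": 0.301 },
          "late2C.KD":      { "mean_mobile_fraction": 0.550 } }
```

Read: intergenic transcription peaks at the early two-cell stage (0.31) and
is silenced by the late stage in controls (0.10) but persists under
H3.1/3.2 knockdown (0.28); cluster III genes are strongly derepressed by
the knockdown (median +1.9 log₂) while cluster I genes dip (−0.64);
deposition anti-correlates with expression change (ρ ≈ −0.5); strong TADs
form at the late two-cell stage in controls (5) but not in the knockdown
(0); and chromatin that has closed by the late stage (MF 0.30) stays open
when H3.1/3.2 are depleted (MF 0.55). Over 90% of Hi-C contacts are
intra-chromosomal in both conditions.

Each step is also available separately (`zgakit simulate / quantify /
cluster / intergenic / hic / frap / intensity`), and as library functions
(`zgakit.assign_clusters`, `zgakit.intergenic_ratio`,
`zgakit.domain_score`, `zgakit.mobile_fraction`, ...).

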