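# Methods

## The screening model

The discovery stage is deliberately a deterministic decision rule, not a
statistical test: with only three tumor/adjacent pairs, a per-pair
consistency requirement is the replication filter. A gene is up-regulated
iff in *every* pair i

    E_ca(i) / E_adj(i) > fc_threshold   and   E_ca(i) − E_adj(i) > diff_threshold,

on RPKM values, with the symmetric conditions (roles of tumor and adjacent
swapped) defining down-regulation. The two sets are disjoint by construction
because the oriented differences cannot both exceed a positive threshold.
Zero denominators are resolved by convention: a positive tumor value over a
zero adjacent value passes the fold condition (ratio treated as +∞); a gene
at zero in both samples of a pair fails that pair. No pseudocounts are
added — the absolute-difference threshold already suppresses low-expression
noise. Whether the difference condition must hold in every pair or only on
average is genuinely open; the package defaults to every pair, mirroring the
per-pair form of the fold-change condition, and exposes `mode="mean"`
(geometric-mean fold change and mean difference) as the alternative.
The mapped-gene filter likewise defaults to keeping a gene expressed at
RPKM ≥ 0.5 in *any* sample, with an all-samples mode available.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `min_rpkm` | 0.5 | RPKM | expression floor defining a mapped gene; boundary inclusive |
| `fc_threshold` | 1.5 | ratio | per-pair fold-change cut, strict inequality |
| `diff_threshold` | 10 | RPKM | per-pair absolute-difference cut, strict inequality |
| `top_fraction` | 0.10 | — | degree decile for hub nodes; cutoff rank ceil(f·\|V\|), boundary ties kept |
| `p_threshold` | 0.05 | — | validation-cohort significance cut |
| `fc_up`, `fc_down` | 1.5, 2/3 | ratio | validation fold-change window, tumor over normal |
| `alpha` | 0.05 | — | enrichment significance on raw p (pathway mode) or BH-adjusted p (GO mode) |

All thresholds are strict (`>`/`<`) where the decision rules state them so;
boundary cases (fold change exactly 1.5, difference exactly 10) are
therefore *not* calls, and the RPKM filter boundary (exactly 0.5) *is* kept.

## Statistical components

* **Enrichment** uses the hypergeometric upper tail P(X ≥ k); the EASE
  variant (tail from k−1, floored at 0) is available but off by default —
  annotation services differ in which score they report, and neither choice
  is privileged here. The universe defaults to mapped genes intersected with
  the genes annotated in the collection, which is what annotation tools
  effectively condition on. Benjamini–Hochberg adjustment is the classic
  step-up with monotonicity enforcement; note BH-adjusted values are not a
  fixed point of re-adjustment (that is a property of the procedure, not a
  bug), so the code asserts only that adjustment never decreases a p-value.
* **Validation-cohort test.** The per-gene p-value is a two-sided Welch
  t-test on log2 counts-per-million with a 0.5 pseudocount. This is a
  deliberate, documented package-level choice of a simple, assumption-light
  two-group test; the decision *rule* (p < 0.05 and fold change > 1.5 or
  < 2/3) is independent of the engine, and `cohort_de(..., p_values=...)`
  accepts externally computed per-gene p-values from any DE method.
* **qRT-PCR.** Relative expression is 2^(−ΔΔCt). Per-gene significance uses
  a paired two-sided t-test on per-patient ΔCt, matching the paired design;
  a Wilcoxon signed-rank variant is available. Both are offered as labelled
  choices, not as "the" method.
* **Clinical association.** Spearman's ρ is the Pearson correlation of
  mid-ranks (average ranks under ties — essential for binary phenotypes),
  with a two-sided p from t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 df and an exact
  permutation p for n ≤ 9. Ordinal encodings are T1–T4 → 1–4, N0/N1 → 0/1,
  M0/M1 → 0/1, stage I–IV → 1–4, overridable; tumor size may be tested as
  the ordinal T category or as continuous centimetres (`tumor_size_cm`) —
  Spearman is invariant to any monotone recoding, so the choice only
  matters when the cm values reorder patients within a T category.
  The metastasis t-test defaults to Welch, robust to the unequal group
  sizes a rare phenotype produces.

## Network construction

Pathway files follow the KGML 0.7 subset: `entry` elements with one or more
space-separated gene ids, `group` entries with `component` children, and
`relation` elements with named subtypes. Gene-type entries become nodes
keyed by their sorted gene-id tuple — nodes merge across pathways only on
*identical* gene sets, matching entry semantics without inventing fuzzy
merging. Group relations are replicated to every (recursively resolved)
component; compound- and map-type entries, and `maplink` relations, are
dropped with a log line. Degrees are computed on the simple undirected
graph (relation direction is kept as metadata only); the alternative
directed/multigraph readings are not offered as defaults because nothing in
the workflow depends on them. Hub selection ranks nodes by degree, takes
cutoff rank ceil(top_fraction·|V|), keeps boundary ties (excludable by
flag), and reports the DEG genes contained in the selected nodes, split by
screen direction.

## The synthetic study

`SimulationConfig` defaults define the study the tests run under:

* **Discovery**: 12,000 genes, 3 tumor/adjacent pairs, 60 up- and 40
  down-regulated planted genes at fold 4 and a 30-RPKM normal-tissue
  baseline, negative-binomial counts with dispersion 0.1 at ~10 M mapped
  reads per sample, exon lengths uniform on 0.5–5 kb. Counts are realized
  as a Gamma–Poisson mixture whose Gamma draw is *shared between the two
  samples of a pair*: biological gene-level variation is patient-level, so
  it cancels within a pair while marginal counts remain NB with the stated
  dispersion. This is the structure that makes a paired design informative
  at n = 3, and it is the reading consistent with per-patient baseline
  heterogeneity; fully independent draws would put the whole biological
  CV (~0.32) into every within-pair ratio. Null baselines are lognormal,
  spanning the 0.5-RPKM filter boundary, and rescaled so each sample's
  realized library matches the nominal depth — the planted effects then
  perturb tumor library sizes by only ~1%, as in a real transcriptome,
  instead of dominating the normalization.
* **Validation cohort**: 60 tumor vs 10 normal samples (a desk-scale
  version of a ~500-vs-60 cohort), same genes and folds, with per-sample
  independent Gamma draws (different patients).
* **Pathways**: five pathway files of 12 gene entries each; one hub entry
  per pathway carries a planted up-regulated gene wired to `hub_degree`
  partners (one of them in the next pathway, so hub nodes span files and
  exercise merging); non-hub planted DEGs appear only in degree-1 leaf
  entries and background degrees top out at 2, so the top-decile cut has a
  structural margin. One compound entry per pathway exercises the parser's
  drop rule.
* **PPI/locations**: 300 random background edges plus three planted
  seed–seed pairs among the hub genes in the motif A–B, A–C, D–E, placed on
  pairwise different chromosomes.
* **Clinical**: 500 samples; ordinal phenotypes generated by discretizing a
  Gaussian copula of the designated gene's expression ranks. The latent
  correlation is calibrated by bisection against a fixed-seed Monte Carlo
  estimate so the *population* Spearman of the final (expression, ordinal)
  pair equals the planted value; discretization caps the attainable ρ
  (≈0.52 for a 90/10 binary), and unattainable requests raise. Category
  probabilities: T 0.4/0.3/0.2/0.1, node 0.55/0.45, metastasis 0.9/0.1,
  stage 0.4/0.3/0.2/0.1.

What passing tests on this generator do **not** show about real data: no
GC/length bias, batch effects, outlier samples, isoform-level ambiguity or
annotation error are simulated; pathway topology is stylized (hub-and-spoke
with known margins) rather than scale-free; clinical phenotypes depend on a
single gene each. The generator demonstrates that the pipeline's logic is
correct and calibrated under its stated assumptions, not that the
thresholds are optimal for any particular tissue.

## Numerical and engineering choices

* Hub genes sit on up-regulated planted genes: with the shared-Gamma paired
  design, up-regulated genes are recovered essentially always, while a
  down-regulated gene's difference condition (0.75 × a Gamma draw with mean
  30 must exceed 10 RPKM in all three pairs) fails in a few percent of
  genes — planting hubs on the robust direction keeps the end-to-end hub
  report a sharp, deterministic target while the screen's aggregate
  sensitivity is measured over both directions.
* All outputs are sorted and written with a fixed `%.6g` float format, and
  the run log contains no timestamps, so a rerun with the same seed and
  config is byte-identical.
* Every random stream derives from a (seed, stream-id) pair of a
  `numpy` `default_rng`; no global RNG state is used.
* Display rounding is half-up to the printed precision (`round_half_up`);
  stored values keep full precision. Cohort age dispersion is the sample
  standard deviation (n−1).
* Degenerate inputs fail loudly: unpaired samples name the orphan, a
  relation referencing a missing entry names the entry id, constant vectors
  are an undefined correlation, groups of fewer than two samples are
  errors; empty GMT files and seed genes absent from the PPI background are
  warnings with empty results, since partial inputs are expected there.

## Known limitations

* The cohort DE stand-in is a t-test on transformed counts, not a count
  model; at very low counts it is conservative. Plug in an external
  engine's p-values for production use.
* The KGML parser covers the subset described above, not the full schema
  (no reaction elements, no graphics, no entry-type "ortholog").
* `select_hub_degs` on very small graphs can have a cutoff rank of 1, in
  which case "top 10%" reduces to the maximum-degree node(s).
* The pipeline driver holds each stage's tables in memory; it targets
  desk-scale studies (10⁴ genes, 10²–10³ samples), not atlas-scale data.
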