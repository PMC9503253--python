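# Methods

## The screening model

The pipeline operationalizes the competing-endogenous-RNA (ceRNA)
hypothesis as a conjunction of observable filters rather than a generative
model. For a candidate triple (lncRNA *l*, miRNA *m*, mRNA *g*):

- **Differential expression.** Intensities (lncRNA/mRNA microarray) are
  quantile-normalized, log2-transformed and tested with a two-sided paired
  *t*-test across matched case/control pairs; counts (miRNA sequencing)
  are CPM-normalized and tested on log2(CPM+1) with the same paired-*t*
  machinery. A feature passes iff linear fold change
  FC = max(case/control, control/case) ≥ 1.5 and raw *p* < 0.05. Raw
  *p*-values are the default because the screening convention this mirrors
  uses raw *p* < 0.05; Benjamini–Hochberg adjustment is available behind a
  flag. The count test is deliberately *not* a negative-binomial GLM
  re-implementation: the downstream pipeline consumes only the pass/fail
  list, and at n = 3–10 pairs a paired *t* on log-CPM is transparent and
  adequately calibrated. An exact conditional binomial test (pooled case
  count vs case library fraction) is available for cohorts too small for
  the *t*.
- **Co-expression.** Pearson *r* between every DE lncRNA and DE mRNA on
  log2 values across *all* samples (cases and controls pooled — with three
  pairs per group, within-group correlation is not estimable). The
  threshold *r* ≥ 0.9 is **signed**: a ceRNA pair must share the same
  expression trend, so *r* = −0.95 is excluded. *p* is the *t*-transform
  of *r* with n−2 df.
- **Target support.** l→m and m→g must appear in user-supplied candidate
  databases, restricted to DE features on both sides. `combine="union"`
  (default) accepts support from any database label; `"intersection"`
  requires every label present in the pooled input. Union is the
  permissive reading and is logged at run time. ID matching is exact
  string; alias resolution is out of scope.
- **Negative regulation.** Pearson *r*(m, l) < `neg_max` and
  *r*(m, g) < `neg_max` with `neg_max = 0.0`: any negative correlation
  qualifies, since "negatively co-expressed" is not usefully quantifiable
  at these sample sizes. The bound is exposed as a flag.

Triples induce an undirected tripartite graph (lncRNA–miRNA and
miRNA–mRNA edges only). **Hubs** are the top `hub_fraction` (default 0.10)
of nodes by degree with k = ceil(fraction × n); ties with the k-th degree
are included by default — with tie expansion the selected set's minimum
degree strictly exceeds every unselected degree, which is how a 5-of-33
listing can arise from a nominal 10% cut. The **hub subnetwork** is the
triple closure: every whole triple containing at least one hub is kept, so
a hub miRNA brings its sponge lncRNAs and target mRNAs with it. An induced
subgraph on hubs alone would discard the partners that make the hub
interpretable.

## qPCR validation statistics

Relative expression uses the comparative-Ct method: per sample
ΔCt = Ct(target) − Ct(reference gene); ΔΔCt subtracts the **arithmetic
mean ΔCt of the calibrator group** (equivalently, expression is scaled by
the calibrator's geometric mean — the natural aggregation on the log scale
that exponential amplification implies); RQ = 2^−ΔΔCt. Group comparison
reports both the Mann–Whitney U *p* and Welch's *t* on log2 RQ. For
combined n ≤ 20 the U null distribution is enumerated exactly over all
C(n, n₁) group assignments of the pooled (average-rank) observations,
which handles ties exactly; the two-sided *p* is twice the smaller tail,
capped at 1 — so identical samples give *p* = 1. Larger samples use the
normal approximation with tie correction.

## The synthetic cohort generator

`generate_cohort` emulates a small paired plasma profiling study and is the
pipeline's ground-truth instrument. Per feature class:

- lncRNA/mRNA intensities: log-normal, log2 baseline ~ U(6, 12) (the
  array's usable dynamic range), per-sample Gaussian log2 noise
  (`intensity_sigma`, default 0.4) and a per-feature, per-pair offset
  shared by the two samples of a matched pair (`pair_sigma`, default
  0.3). The pair offset models subject-level variation and is exactly what
  gives the paired *t*-test its power advantage here.
- miRNA counts: gamma–Poisson (negative-binomial behaviour,
  var = μ + φμ², `count_dispersion` φ default 0.2) around baselines of
  ~16–1024 expected counts.

`n_motifs` planted sponge triples receive a ±`effect_log2fc` case shift
(lncRNA and mRNA same sign, miRNA opposite), and — because a real ceRNA
triple is mechanistically coupled rather than merely co-responding to the
diagnosis — the three members *share* their per-pair offset (sign-flipped
for the miRNA). Planted baselines are additionally placed so that both
group means stay inside the dynamic range: a feature shifted past the top
of the range is rank-saturated by quantile normalization and its apparent
fold change collapses, which is a property of the normalization, not of
the signal. Decoy features carry no group effect and independent pair
offsets.

Target databases contain the planted edges (under both of two synthetic
database labels, so they survive `combine="intersection"`) plus uniformly
drawn decoy edges; `db_decoy_rate` is the decoy fraction of the final DB.
The truth table records planted triples, per-feature true DE direction and
the true/decoy status of every DB edge.

Default sizes are 200 lncRNAs, 400 mRNAs, 40 miRNAs and 3 pairs. Real
arrays profile tens of thousands of probes; hundreds keep the test suite
fast while keeping the planted fraction small enough that quantile
normalization's reference distribution is essentially unperturbed (at ~40
features, 5 planted shifts visibly distort it). What the generator does
**not** emulate: sequencing-read artefacts, probe cross-hybridization,
batch effects, correlated null features, heavy-tailed baselines, or the
empirical distributions of any real cohort — so passing tests demonstrate
correctness of the screening logic and its calibration under idealized
noise, not performance on real plasma data.

## Numerical and degenerate-input choices

- Quantile normalization: ties within a column receive the mean of the
  reference quantiles they span (average ranks, linear interpolation);
  the operation is idempotent.
- Fold change requires positive group means; features violating this are
  flagged `untestable` and logged, never silently dropped, and excluded
  from pass counts. Zero-variance paired differences give *p* = 1 with a
  note.
- FC for counts is computed on CPM group means, not on
  2^mean(log2(CPM+1)), so the reported FC is the ratio a practitioner
  would compute by hand.
- Correlation on zero-variance profiles is an error at the single-pair
  level and a logged skip inside the all-pairs screen.
- Degree-ranking ties are broken (degree desc, miRNA < lncRNA < mRNA,
  then lexicographic) purely for stable output; hub selection itself uses
  only degrees.
- All randomness flows from a single integer seed via
  `numpy.random.default_rng`; identical configurations are byte-identical.

## Problem sizes

The recovery experiment uses the strong-effect configuration (5 motifs,
|log2 FC| = 3, σ = 0.2, 10 pairs, 640 features); a full pipeline run takes
well under a second, and the whole test suite a few seconds. Null
calibration uses 400 null mRNA features, for a 95% binomial band of
0.05 ± 0.021 around the nominal α.

## Known limitations

- The count DE test is not edgeR/DESeq2-equivalent and is not meant to be;
  at large n or strong library-composition imbalance a dedicated NB GLM is
  preferable.
- Pooling cases and controls for correlation inflates *r* for any feature
  pair with a shared group effect; this is intrinsic to the screening
  design it reproduces, and is why target-database support and the
  negative-correlation condition are required on top.
- Exact string ID matching means miRBase/Ensembl alias drift silently
  reduces DB support.
- The hub rule's tie expansion can select many more than 10% of nodes in
  degree-degenerate networks (all-tied graphs select everything).
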