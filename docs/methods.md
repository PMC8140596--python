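# Methods

## Model and procedure

`mirgrank` addresses two-class (case/control) transcriptomic studies in which
both miRNA and mRNA expression were profiled on the same samples. The working
assumption is the canonical one for miRNA regulation: a miRNA represses its
targets, so regulator–target pairs show negative expression correlation
across samples, and a regulator that matters for the phenotype drives a
coherent, class-separating block of genes.

The pipeline is a grouping function followed by a ranking function, wrapped
in an outer Monte-Carlo cross-validation (MCCV) loop:

1. **Preprocessing.** Features (columns) with any missing measurement are
   dropped — samples are the scarce resource in case/control designs, so
   missingness costs features, not samples. An optional prevalence filter
   (raw-scale expression ≥ 1 in ≥ 50 % of samples, both bounds inclusive) can
   precede normalization. Normalization defaults to log2(x+1) followed by
   per-feature z-scoring, the conventional choice for RPKM/RPM-scale input;
   `zscore` and `none` are available for data already on a suitable scale.
   Constant features are dropped rather than divided by zero.
2. **Differential-expression filter** (inside the loop, training samples
   only): per-feature two-sample t-test between classes, keeping p ≤ 0.05.
   Welch's unequal-variance form is the default — expression variance is
   rarely equal between tumor and normal groups — with the pooled-variance
   form available. Features with an undefined statistic (zero variance in
   both classes, equal means) are dropped with a warning.
3. **Grouping.** Pearson correlation of every (miRNA, gene) pair over
   training samples; the group of miRNA *m* is { g : r(m, g) ≤ −0.6 }. The
   threshold is inclusive and interpreted as |r| ≥ 0.6 with r < 0 — the
   anti-correlation direction is what carries the targeting signal.
   Undefined correlations (constant profiles) never pass. miRNAs with empty
   groups are omitted; a gene may belong to several groups.
4. **Ranking.** Each group is scored by internal cross-validation on its gene
   sub-matrix: r = 5 stratified 80:20 hold-outs, classifier trained on the
   80 %, confusion counts pooled over the five 20 % folds (micro-averaging;
   a per-repeat macro-average is available but micro is the default because
   the test folds are tiny and per-fold ratios are noisy). Seven metrics are
   derived from the pooled table: accuracy, sensitivity (= recall),
   specificity, precision, F-measure and Cohen's kappa. Groups are sorted by
   accuracy; ties break by higher F-measure, then larger group, then miRNA
   id — deterministic and order-independent (the per-group scoring seed is
   derived from the group's id, not its position).
5. **Top-j models.** For j = 1..10, a classifier is trained on the training
   samples restricted to the union of the top-j groups' genes and evaluated
   on the iteration's held-out test samples (accuracy, sensitivity,
   specificity, AUC). AUC uses the classifier's positive-class probability
   (or the signed decision value for margin classifiers — rank-based AUC is
   invariant to monotone transforms) and equals the Mann-Whitney statistic
   scaled to [0, 1] with ties counted 1/2.
6. **MCCV loop.** N = 100 iterations (configurable). Per iteration the
   majority class is under-sampled without replacement to at most twice the
   minority class (1:2), then a stratified 90/10 split is drawn; steps 2–4
   see only the 90 %, step 5's evaluation only the 10 %. Under-sampling
   before the split is the default (`undersample_scope="all"`); restricting
   it to the training side is exposed as an alternative since either reading
   of the protocol is defensible. Per-class training counts use
   floor(0.9·n), clamped so both parts keep ≥ 1 sample per class.
7. **Aggregation.** Each iteration emits a ranked miRNA list; genes inherit
   the rank of the best-ranked group containing them. For each item, the
   normalized ranks across the N lists (absence contributes the worst case,
   1.0 — the conservative treatment of partial lists) are compared against
   uniform order statistics: ρ = min over k of P(Binomial(N, r₍ₖ₎) ≥ k),
   computed via the exact Beta(k, N−k+1) CDF, and the reported p-value is
   min(1, N·ρ) (Bonferroni over the N depths considered). The item universe
   is all features surviving preprocessing, so never-grouped items appear at
   p = 1 rather than silently vanishing.

Two classifiers are built in with fixed hyperparameters: random forest
(100 trees, unrestricted depth; the default) and a linear-kernel SVM (C = 1).
Both appear in the method's lineage; the forest is the default scorer, and no
hyperparameter tuning is performed anywhere.

## Association score

Alongside the p-value ranking, each miRNA receives a persistence score:
per iteration, rank ≤ depth (default 10) contributes (depth − rank + 1)/depth,
and the sum is scaled by 10/N so a miRNA ranked first in every iteration
scores exactly 10. This formula is a **reconstruction**: the frequency-score
idea it implements is established for this method family, but no published
closed form exists, so the scale was fixed to the 0–10 range such scores are
reported on. It is exposed via `association_scores(records, depth)` and
written to `association_scores.tsv`.

## Synthetic data generator

`SyntheticSpec`/`generate` produce the study conditions every test runs
under: two classes of `n_samples_per_class` (default 200); `n_planted`
(default 5) regulator miRNAs whose latent profile is N(±d/2, 1) per class
with d = `class_effect` = 1.5; each regulator owns a disjoint block of
`targets_per_planted` (default 20) genes built as
ρ·u + √(1−ρ²)·ε, where u is the regulator profile standardized by its pooled
population sd √(1+d²/4) and ρ = `target_correlation` = −0.8 — so the
population Pearson correlation equals ρ exactly and targets inherit a class
shift of −ρ·d/√(1+d²/4) sd. All other miRNAs (45) and genes (900 of 1000)
are i.i.d. N(0, 1) decoys. Values are placed at baseline 10, sd 1 (clipped at
0; at that baseline clipping is a ~10⁻²³ event), giving non-negative,
expression-like magnitudes.

The generator is Gaussian, not negative-binomial: the pipeline consumes
normalized continuous expression, and after the log/z-score preprocessing a
Gaussian model reproduces the features the method actually uses
(class-mean shifts and cross-feature correlation). It does **not** emulate
count overdispersion, library-size effects, batch structure, correlated
decoys, shared targets between regulators, or miRNA biogenesis — so passing
tests demonstrate the machinery recovers planted linear anti-correlation
structure at realistic effect sizes, not robustness to every artefact of
real sequencing data.

## Numerical and design choices

- **Seeds.** Every stochastic step derives from one master seed through
  `numpy.random.SeedSequence` (per-iteration: (master, iteration); per-group:
  (iteration-seed, CRC32 of the miRNA id), keeping ranking independent of
  group insertion order). All derived seeds stay below 2³¹ and are logged to
  `iterations/seeds.tsv`. Two runs with the same configuration are
  bit-identical.
- **Undefined metrics.** A ratio with zero denominator (e.g. precision with
  no positive predictions) is reported as 0 and flagged, so every group keeps
  a complete row instead of being dropped.
- **Degenerate iterations.** An iteration in which no (miRNA, gene) pair
  reaches the correlation threshold is recorded as empty (its lists
  contribute worst-case ranks to aggregation). If more than half of the
  iterations are empty the run aborts with a pipeline error — a consensus
  over mostly-empty lists would be meaningless. On truly null data this
  error, reporting *no associations*, is the correct outcome.
- **Ties in aggregation** break by smaller mean normalized rank, then item
  id, with a stable sort — aggregation is invariant to list order.
- **Rounding in splits**: floor on the per-class training count, minimum one
  sample per class per side; an error if a class is too small to appear in
  both parts.

## Problem sizes used in the checks

The reference planted-regulator experiment runs 20 MCCV iterations on
200 samples/class, 50 miRNAs (5 planted) and 1000 genes; the null
counterpart sets class_effect = 0 and target_correlation = −0.05 (toward 0).
The external-validation contrast trains on 100 samples/class with 300 genes
and 6 iterations and compares significant-gene lists of sizes 1/2/5/30
against size-matched random lists averaged over 5 repeats. These sizes were
chosen as the smallest at which the planted signal regime is comfortably
identifiable; the MCCV iteration count and all thresholds remain
configurable up to the full published protocol (N = 100).

## Known limitations

- Pearson correlation captures linear monotone repression only; switched or
  saturating regulation is invisible at the −0.6 threshold.
- Normalization is computed on the full cohort before the MCCV loop (the
  loop re-runs the DE filter, correlation, grouping and ranking on training
  data only). Per-feature scaling leaks no class information, but a fully
  nested normalization is the stricter design if one intends formal
  generalization claims.
- The aggregated p-values are conservative (Bonferroni over depths, worst
  case ranks for absences) and calibrated under independence of lists;
  MCCV iterations share samples, so they are screening scores, not exact
  error probabilities.
- The association score is a reconstruction (see above) and should be read
  as a relative persistence measure.
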