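# Methods

This note documents the statistical procedures hoxpress implements, the
conventions chosen where a design was genuinely open, what the synthetic
cohorts do and do not emulate, and the package's known limitations.

## Data model

Expression is consumed on the log2(count+1) scale (Xena/Toil RSEM
normalized counts), genes in rows.  Matrix orientation is never guessed:
a transposed file fails validation (duplicate/shape checks) rather than
being silently flipped, because silent transposition is the classic failure
mode of expression I/O.  Gene rows containing missing cells are dropped with
a logged warning; the Toil matrices are dense, so missingness signals a
malformed file rather than a value to impute.

Cohorts pair one tumor arm (TCGA-style) with one healthy arm (GTEx-style)
per joint cancer-type category.  A pair enters analysis only when both arms
have at least `min_samples` (default 100) samples; excluded pairs are kept,
flagged, and reported.  Receptor statuses (HER2/PR/ER) are normalized
case-insensitively to `positive`/`negative`; any other entry (NA,
Equivocal, blanks) becomes `missing` and such samples are excluded from the
subtype comparisons that need them.

## Differential expression

Per gene: a two-sided Wilcoxon rank-sum test plus a fold change defined as
FC = 2^(mean_tumor − mean_healthy) of the log2 values.  Conventions:

* **Test.** Exact enumeration of the rank-sum null (midranks, ties handled)
  when the pooled sample size is ≤ 12; above that, the normal approximation
  with tie and continuity corrections (scipy).  Cohorts of 100+ per arm make
  the approximation safe; exactness matters in unit tests and tiny inputs.
* **Fold change scale.** The mean difference is taken on the analyzed log2
  scale (geometric-mean fold on the count scale).  A `scale="linear"`
  option back-transforms and takes the ratio of arithmetic means, and
  `center="median"` swaps means for medians, for sensitivity analyses.
* **Calls.** `up` iff FC ≥ 2 and Bonferroni-adjusted p < 0.05; `down`
  symmetric with FC ≤ ½; Bonferroni n is the panel size (39 for HOX).  A
  fold change within 1e-9 of the cutoff counts as reaching it, so boundary
  behavior is deterministic.
* **Bonferroni, not FDR**, throughout; adjusted p = min(1, n·p).

Gene-set profiling (`gene_set_de_profile`) applies the same machinery to an
arbitrary panel (housekeeping genes, TF families, literature markers) with
Bonferroni n equal to the panel size; symbols absent from the matrix are
reported, never silently dropped.  Subtype comparisons (HER2±,
triple-negative vs rest) reuse the same test/fold machinery within tumor
samples.

## Empirical nulls

All three resampling procedures share one convention: empirical
p = r/B with **no +1 smoothing**, so p = 0 is attainable when the
observation is more extreme than all B draws.  Random sets are drawn without
replacement within a set, independently across the B iterations; B is far
below the number of possible sets, so inter-set collisions are immaterial.

* **Concordance null.** Per-gene DE calls against two healthy references
  are computed once over the whole universe (a gene's call depends on the
  panel only through the constant Bonferroni factor), then panels are scored
  by set algebra; discordance is the symmetric difference of the two DE
  lists, and the focal panel is scored with tail=greater.
* **Posterior low-expression.** Statistic: grand mean (genes × tissues) of
  the 16 posterior genes' healthy expression; the default null universe is
  the 39 HOX genes themselves (16-subsets), with `universe="all"` exposed.
* **Housekeeping comparison.** Median healthy and tumor expression of B
  random 39-gene housekeeping panels versus the HOX panel, tail=less, plus a
  2-fold (≥ 1 log2 unit) median-gap criterion.

## Survival screens

The product-limit estimator and the k-sample log-rank test are implemented
with numpy (vectorized over event times — the calibration suites run tens of
thousands of tests); lifelines serves as an independent cross-check in the
test suite, where both agree to 1e-9.  At tied times deaths precede
censorings, the standard convention.  The comparison test behind all KM
screens is the log-rank test.

* **Tiered screen.** Median split (strictly greater = high; at-median goes
  low) → tertile thirds by sample count (sizes differ by ≤ 1) → upper vs
  lower quartile; the first tier whose Bonferroni-adjusted p (n = 39) is
  below 0.05 is reported.  Escalation is sequential with no correction
  across tiers.  Consequence, measured under the null (n = 200, 500
  simulated cohorts): the family-wise error of the full escalation is ≈
  0.15–0.18 rather than 0.05 — each individual tier is calibrated (its
  log-rank p is uniform under the null) but testing up to three tiers
  per gene inflates the union.  Users who need strict FWER control should
  either stop at the median tier or divide alpha by three.
* **Pair screen.** N1 = samples above the median on both genes, N2 = below
  on both (strict splits; at-median samples join neither, so N1 and N2 are
  each ⌊n/2⌋ at most and ≈ n/4 for independent genes).  Bonferroni n = 741.
  The matched single-gene control for gene g takes exactly the N1 top- and
  N2 bottom-ranked samples by g (rank ties broken by sample order, for
  determinism).  Selection requires the adjusted pair p below alpha **and**
  the raw pair p strictly below both raw single-gene p-values; raw values
  are compared because the inequality is scale-free only when both sides
  carry the same correction.  Degenerate pairs (empty intersection) are
  returned unselected rather than erroring.

## Coexpression

Pearson r per pair and arm, eligibility gated on **all four** gene×arm
vectors passing a one-sample KS test against a Normal with estimated
mean/SD (p > 0.05) — the strictest reading, preventing asymmetric
eligibility.  Plain KS with estimated parameters is anti-conservative (it
passes non-Normal data too easily is the safe direction here; it *fails*
true Normals slightly more than nominal); a Lilliefors-corrected option is
exposed.  Strength bins: |r| ≤ 0.4 weak, ≤ 0.7 moderate, > 0.7 strong —
boundary values fall to the lower bin (literal strict thresholds).
Categories are a pure function of the two strength classes and the DE flag;
only `correlated_both` requires both genes DE-called.  Pairs failing the
gate are reported with `passed_normality=False`, never dropped.

## Cohort geometry

The separation test compares two per-sample vectors by rank-sum: each
healthy sample's mean Euclidean distance to the other healthy samples, and
each tumor sample's mean distance to all healthy samples.  This reading
gives the test exactly one observation per sample.  Clustering is
average-linkage (UPGMA) with the Euclidean metric via scipy; leaf orders and
a Newick serialization are exported so any plotting layer can reproduce a
heatmap layout.  Gene selection for the distance space is a parameter
(default: the HOX panel present in the matrix).

## Synthetic cohorts

The generator works directly on the analyzed log2 scale: healthy values per
gene are Normal(mean, sd) clipped at 0, tumor values add log2(FC).  Defaults
— 100 samples per arm (the inclusion rule's floor), baseline mean 4.0 and sd
1.0 log2 units (mid-range expression typical of bulk log2(x+1) matrices
with realistic per-gene spread) — are fixed study conditions, not tuning
knobs.  Correlation blocks share a latent standard-Normal factor with
loading √ρ, giving every within-block pair population correlation ρ.
Survival is exponential with hazard λ0·exp(Σ β_g z_g) over standardized
log2 expression; censoring is an independent exponential tuned to the target
rate at the baseline hazard — with nonzero β the realized censoring
fraction deviates by a few points because exp(βz) shifts the event-time
scale.  One global seed drives crc32-keyed substreams per gene, block and
survival draw, so adding a gene never perturbs another gene's values.

Deliberately **not** modeled: count-level noise (overdispersion, library
size), batch effects, tumor purity, non-constant baseline hazards,
administrative censoring.  Passing tests therefore demonstrate procedure
correctness on the analyzed scale, not robustness to RNA-seq artifacts.

## Bundled result tables

The reference screen outputs ship as TSV fixtures: per-cancer cohort sizes,
the 28-entry pronounced-change table, the 14-entry KM-marker table, and the
19-pair correlated-pair table.  In the correlated-pair table one ESCA entry
(HOXA10–HOXB5) is reconstructed from the table's printed row totals and its
cross-tabulations (19 pairs total; 14 same-cluster; every mixed-cluster pair
contains a cluster-A gene; 9 same-group): the constraints admit that single
placement, and the reconstructed fixture reproduces all of those counts
exactly.  Summaries (`summarize_fixture`) recompute every headline count
from raw entries, validating symbols against the catalog.

## Numerical and testing choices

* Simulation sizes in the test and acceptance suites (e.g. 500 null cohorts
  at 100 per arm for DE calibration, 200 seeds at n = 200 tumors for
  survival detection, 100-seed uniformity checks at B = 200) are chosen so
  each property is measured with useful binomial precision while the whole
  suite runs in well under a minute per file; calibration assertions use
  binomial 99–99.5% bounds rather than point equalities.
* Fold-change recovery uses the planted-truth generator at 500 samples per
  arm, where the estimator's relative error concentrates below 5%.
* All Monte-Carlo procedures are bit-reproducible given (seed, B).

## Limitations

Bonferroni everywhere is conservative for correlated genes in one cluster.
The tiered screen's family-wise inflation is inherent to its sequential
design (see above).  The KS gate at large n rejects near-Normal vectors for
tiny deviations, shrinking the eligible pair set as cohorts grow.  The
pipeline assumes the two arms are already comparably normalized; it does not
attempt cross-source batch correction.
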