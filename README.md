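# hoxpress

A pipeline for pan-cancer screening of the 39 human **HOX** genes in
tumor-vs-healthy bulk expression cohorts (TCGA tumor arms against GTEx
healthy arms, in the UCSC Xena/Toil `log2(x+1)` RSEM unit), aimed at
computational biologists who want the whole screen — differential
expression, resampling nulls, survival markers, coexpression, cohort
geometry — as tested, reusable library code rather than one-off scripts.

## The model and statistics

**Gene model.** The human HOX genes sit in four clusters (A–D) with paralog
numbers 1–13; lineage losses leave 39 genes.  Paralogs map to developmental
groups: anterior (1–3), central (4–8), posterior (9–13).  All 39·38/2 = 741
unordered gene pairs are enumerated canonically.

**Differential expression.** For gene *g* with healthy values *x* and tumor
values *y* (log2(count+1)):

- two-sided Wilcoxon rank-sum test (exact enumeration for pooled n ≤ 12,
  tie/continuity-corrected normal approximation above);
- fold change FC = 2^(mean(y) − mean(x));
- call *up* iff FC ≥ 2 and Bonferroni-adjusted p < 0.05 (n = 39 for the HOX
  panel), *down* iff FC ≤ ½ at the same significance, else *none*.

A highlight filter (max(FC, 1/FC) ≥ 3 and ≥ 1 unit of mean expression on a
chosen arm) singles out pronounced changes.

**Empirical nulls.** Observed statistics are scored against B random
gene-set redraws; p = (#draws at least as extreme)/B, with p = 0 attainable.
Procedures: cross-source DE concordance of a focal panel, posterior-group
low-expression, and HOX-vs-housekeeping median expression.

**Survival markers.** Kaplan–Meier product-limit curves and the k-sample
log-rank test drive two screens: a tiered single-gene screen (median split →
tertile thirds → extreme quartiles, first Bonferroni-significant tier wins,
n = 39) and a pair screen comparing the both-above-median intersection (N1)
against the both-below-median intersection (N2), Bonferroni n = 741, where a
pair is selected only if it also beats both matched single-gene controls
built from the N1 top- and N2 bottom-ranked samples.

**Coexpression.** Pearson *r* per pair in each arm, gated by a KS normality
check on all four gene×arm vectors; |r| ≤ 0.4 is weak, ≤ 0.7 moderate, else
strong; pairs are classed as correlated-in-both (requires both genes DE),
gained (moderate/strong only in tumor) or lost (moderate only in healthy).

**Cohort geometry.** Per-healthy-sample mean intra distances vs
per-tumor-sample mean distances to the healthy cloud (Euclidean, rank-sum
compared), plus UPGMA/Euclidean clustering for heatmap leaf ordering.

A synthetic cohort generator plants known fold changes, correlation blocks
and expression-linked exponential survival, so every stage is testable with
no download; bundled TSV tables carry the screen's reference outputs
(pronounced changes, KM markers, correlated pairs, cohort sizes).

## Worked example

```python
from hoxpress import (SimulationConfig, SurvivalConfig, generate,
                      classify_de, tiered_km)

config = SimulationConfig(
    n_tumor=150, n_healthy=120,
    fold_changes={"HOXA13": 4.0, "HOXC10": 0.25},
    survival=SurvivalConfig(lambda0=1e-3, beta={"HOXA13": 0.9}, censoring_rate=0.2),
    seed=42,
)
syn = generate(config)

de = classify_de(syn.cohort, n_tests=39)
print(de.loc[de["call"] != "none", ["gene", "FC", "p_adj", "call"]].to_string(index=False))

surv = syn.survival
res = tiered_km(
    syn.cohort.tumor.data.loc["HOXA13"].to_numpy(),
    surv["time"].to_numpy(), surv["event"].to_numpy(),
    gene="HOXA13",
)
print(f"{res.gene}: tier={res.tier}, adjusted p={res.p_adj:.2e}")
```

prints

```
  gene       FC        p_adj call
HOXA13 4.077656 2.197894e-31   up
HOXC10 0.255598 5.105990e-29 down
HOXA13: tier=median2, adjusted p=2.44e-06
```

The two planted fold changes (4× up, 4× down) are recovered with the right
calls and estimated magnitudes, and the gene whose hazard was tied to its
expression is flagged by the survival screen at the first (median-split)
tier.

There is also a CLI over the same library (`hoxpress simulate|de|nulls|
survival|pairs|correlate|geometry|report --config cfg.yaml`), driven by one
YAML config; outputs are TSV plus a run manifest.

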