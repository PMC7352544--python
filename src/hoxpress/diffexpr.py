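"""Per-gene tumor-vs-healthy differential expression.

The core procedure: for each gene, a two-sided Wilcoxon rank-sum test of
tumor vs healthy expression plus a fold change defined on the log2(x+1)
scale as FC = 2^(mean_tumor - mean_healthy).  A gene is called differentially
expressed ("up"/"down") when the fold change clears a 2-fold cutoff and the
Bonferroni-adjusted p-value (n = 39 tests for the HOX panel) is below 0.05;
otherwise the call is "none".

Also here: the highlight filters used to single out pronounced changes (at
least 3-fold change with at least 1 unit of expression on a chosen side),
gene-set DE profiling for control panels (housekeeping genes, transcription
factor families, literature markers), and receptor-status subtype
comparisons within tumor samples (HER2-positive vs -negative, triple-negative
vs the rest).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortPair, ExpressionMatrix

__all__ = [
    "DE_COLUMNS",
    "HighlightFilter",
    "wilcoxon_rank_sum",
    "fold_change",
    "classify_de",
    "highlight",
    "gene_set_de_profile",
    "subtype_compare",
]

# Fold comparisons at the cutoff tolerate this much floating-point slack; a
# fold change within 1e-9 of the cutoff counts as reaching it.
FOLD_TOL = 1e-9

# Exact rank-sum enumeration below this pooled size, normal approximation
# (tie + continuity corrected) above.
EXACT_MAX_POOLED = 12

DE_COLUMNS = ["gene", "mean_healthy", "mean_tumor", "FC", "p_raw", "p_adj", "call"]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(statistic, p)`` where the statistic is the rank sum of ``x``
    in the pooled midrank ranking.  When the pooled size n+m <= 12 the null
    distribution is enumerated exactly over all C(n+m, n) group assignments
    (ties handled by midranks); the two-sided p doubles the smaller tail,
    capped at 1.  Larger samples use the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n].sum())
    if n + m <= EXACT_MAX_POOLED:
        total = 0
        count_le = 0
        count_ge = 0
        for idx in itertools.combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            total += 1
            if w <= w_obs + 1e-12:
                count_le += 1
            if w >= w_obs - 1e-12:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return w_obs, p
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def fold_change(
    healthy: Sequence[float],
    tumor: Sequence[float],
    center: Literal["mean", "median"] = "mean",
    scale: Literal["log2", "linear"] = "log2",
) -> float:
    """Linear fold change of tumor over healthy expression.

    Default (``scale='log2'``): FC = 2^(mean(tumor) - mean(healthy)) of the
    log2(x+1) values — the data's native unit.  ``scale='linear'`` instead
    back-transforms to counts and takes the ratio of linear means.
    ``center='median'`` swaps means for medians in either variant.
    """
    h = np.asarray(healthy, dtype=float)
    t = np.asarray(tumor, dtype=float)
    if h.size == 0 or t.size == 0:
        raise ValueError("both samples must be non-empty")
    agg = np.mean if center == "mean" else np.median
    if scale == "log2":
        return float(2.0 ** (agg(t) - agg(h)))
    ht, tt = 2.0**h - 1.0, 2.0**t - 1.0
    denom = float(agg(ht))
    if denom <= 0:
        raise ValueError("linear-scale fold change undefined: healthy center <= 0")
    return float(agg(tt)) / denom


def _de_row(
    gene: str,
    healthy: np.ndarray,
    tumor: np.ndarray,
    fold_cutoff: float,
    alpha: float,
    n_tests: int,
    center: Literal["mean", "median"],
    scale: Literal["log2", "linear"],
) -> dict:
    fc = fold_change(healthy, tumor, center=center, scale=scale)
    _, p_raw = wilcoxon_rank_sum(tumor, healthy)
    p_adj = min(1.0, n_tests * p_raw)
    call = "none"
    if p_adj < alpha:
        if fc >= fold_cutoff - FOLD_TOL:
            call = "up"
        elif fc <= 1.0 / fold_cutoff + FOLD_TOL:
            call = "down"
    return {
        "gene": gene,
        "mean_healthy": float(np.mean(healthy)),
        "mean_tumor": float(np.mean(tumor)),
        "FC": fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "call": call,
    }


def classify_de(
    cohort: CohortPair,
    genes: Iterable[str] | None = None,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
    n_tests: int | None = None,
    center: Literal["mean", "median"] = "mean",
    scale: Literal["log2", "linear"] = "log2",
) -> pd.DataFrame:
    """Differential-expression table for ``genes`` in one cohort pair.

    ``n_tests`` defaults to the number of genes tested (Bonferroni over the
    panel); for the 39-gene HOX panel this is 39.  Missing genes raise a
    KeyError listing every absent symbol.
    """
    genes = list(genes) if genes is not None else cohort.tumor.genes
    if not genes:
        raise ValueError("no genes to test")
    sub = cohort.subset_genes(genes)  # raises with the list of absent symbols
    if n_tests is None:
        n_tests = len(genes)
    rows = [
        _de_row(
            g,
            sub.healthy.gene_values(g),
            sub.tumor.gene_values(g),
            fold_cutoff,
            alpha,
            n_tests,
            center,
            scale,
        )
        for g in genes
    ]
    return pd.DataFrame(rows, columns=DE_COLUMNS)


@dataclass(frozen=True)
class HighlightFilter:
    """Pronounced-change filter: fold magnitude and an expression floor.

    ``min_fold`` thresholds max(FC, 1/FC); ``floor_side`` picks which arm's
    mean log2 expression must reach ``floor_value`` units.  The defaults
    (3-fold, healthy mean >= 1 unit) select genes whose change is large both
    relatively and absolutely.
    """

    min_fold: float = 3.0
    floor_side: Literal["healthy", "tumor"] = "healthy"
    floor_value: float = 1.0

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.floor_value < 0:
            raise ValueError("floor_value must be >= 0")


def highlight(results: pd.DataFrame, filt: HighlightFilter = HighlightFilter()) -> pd.DataFrame:
    """Rows whose fold magnitude and floor-side expression pass the filter."""
    fc = results["FC"].to_numpy(dtype=float)
    magnitude = np.maximum(fc, 1.0 / fc)
    floor_col = "mean_healthy" if filt.floor_side == "healthy" else "mean_tumor"
    keep = (magnitude >= filt.min_fold - FOLD_TOL) & (
        results[floor_col].to_numpy(dtype=float) >= filt.floor_value - FOLD_TOL
    )
    return results.loc[keep].reset_index(drop=True)


def gene_set_de_profile(
    cohort: CohortPair,
    gene_list: Iterable[str],
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """DE summary of an arbitrary gene panel (HK genes, TF families, markers).

    Bonferroni correction uses the panel size (genes actually present in the
    matrix).  Genes absent from the matrix are reported, not errors: curated
    lists routinely contain symbols missing from a given matrix.
    """
    gene_list = list(dict.fromkeys(gene_list))
    present = [g for g in gene_list if g in cohort.tumor.data.index]
    absent = [g for g in gene_list if g not in cohort.tumor.data.index]
    if not present:
        raise ValueError("no genes of the list are present in the matrix")
    results = classify_de(
        cohort, present, fold_cutoff=fold_cutoff, alpha=alpha, n_tests=len(present)
    )
    return {
        "n_tested": len(present),
        "n_absent": len(absent),
        "absent": absent,
        "n_de": int((results["call"] != "none").sum()),
        "median_expr_healthy": float(
            np.median(cohort.healthy.data.loc[present].to_numpy())
        ),
        "median_expr_tumor": float(np.median(cohort.tumor.data.loc[present].to_numpy())),
        "results": results,
    }


def subtype_compare(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    mode: Literal["her2", "triple_negative"],
    genes: Iterable[str] | None = None,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Receptor-subtype DE comparison within tumor samples.

    ``her2`` compares HER2-positive vs HER2-negative samples; samples whose
    HER2 status is missing are excluded.  ``triple_negative`` compares
    samples negative for all of HER2/PR/ER against all other status-complete
    samples.  The fold change is reported as group1 over group2
    (positive/negative and triple-negative/rest respectively), using the
    same test and fold machinery as the tumor-vs-healthy classification.
    """
    samples = [s for s in expr.samples if s in clinical.index]
    clin = clinical.loc[samples]
    if mode == "her2":
        ok = clin["her2"].isin(["positive", "negative"])
        group1 = clin.index[ok & (clin["her2"] == "positive")].tolist()
        group2 = clin.index[ok & (clin["her2"] == "negative")].tolist()
    elif mode == "triple_negative":
        ok = (
            clin["her2"].isin(["positive", "negative"])
            & clin["pr"].isin(["positive", "negative"])
            & clin["er"].isin(["positive", "negative"])
        )
        triple = (
            (clin["her2"] == "negative")
            & (clin["pr"] == "negative")
            & (clin["er"] == "negative")
        )
        group1 = clin.index[ok & triple].tolist()
        group2 = clin.index[ok & ~triple].tolist()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError(
            f"insufficient data for {mode} comparison: "
            f"{len(group1)} vs {len(group2)} status-complete samples"
        )
    genes = list(genes) if genes is not None else expr.genes
    if n_tests is None:
        n_tests = len(genes)
    m1 = expr.subset_samples(group1).subset_genes(genes)
    m2 = expr.subset_samples(group2).subset_genes(genes)
    rows = [
        _de_row(
            g,
            m2.gene_values(g),  # reference group plays the "healthy" role
            m1.gene_values(g),
            fold_cutoff,
            alpha,
            n_tests,
            "mean",
            "log2",
        )
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=DE_COLUMNS)
    return df.rename(columns={"mean_healthy": "mean_group2", "mean_tumor": "mean_group1"})
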