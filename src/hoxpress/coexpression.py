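"""Gene-pair coexpression classification.

For every unordered gene pair, Pearson correlation is computed separately in
the tumor and healthy cohorts.  Pairs are eligible only when all four
gene-by-cohort vectors look Normal by a one-sample Kolmogorov-Smirnov test
(p > 0.05 against a Normal with estimated mean and SD).  Correlation
magnitude is binned as weak (|r| <= 0.4), moderate (0.4 < |r| <= 0.7) or
strong (|r| > 0.7); boundary values fall in the lower bin, a literal reading
of the strict thresholds.

Pair categories:

* correlated_both        — at least moderate in both cohorts and both genes
                           called differentially expressed
* gained_strong_in_tumor — weak in healthy, strong in tumor
* gained_moderate_in_tumor — weak in healthy, moderate in tumor
* lost_in_tumor          — moderate in healthy, weak in tumor
* none                   — anything else
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import HoxCatalog, build_catalog, enumerate_pairs, pair_relation
from .io import CohortPair

__all__ = [
    "COEXPR_COLUMNS",
    "pearson_r",
    "ks_normality",
    "classify_strength",
    "categorize",
    "classify_pairs",
]

Strength = Literal["weak", "moderate", "strong"]

COEXPR_COLUMNS = [
    "gene_a",
    "gene_b",
    "r_healthy",
    "r_tumor",
    "class_healthy",
    "class_tumor",
    "passed_normality",
    "category",
    "same_cluster",
    "same_group",
]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires length >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def ks_normality(
    values: Sequence[float], lilliefors: bool = False
) -> tuple[float, float]:
    """One-sample KS test against a Normal with estimated mean/SD.

    Returns (D, p); the vector "passes" normality when p > 0.05.  Estimating
    the parameters from the same data makes the plain KS test
    anti-conservative; ``lilliefors=True`` switches to the Lilliefors
    correction (statsmodels) for calibrated p-values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 values for the normality test")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("normality test undefined for a constant vector")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(v, dist="norm")
        return float(d), float(p)
    d, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(d), float(p)


def classify_strength(r: float) -> Strength:
    """Bin |r|: weak <= 0.4 < moderate <= 0.7 < strong."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    a = abs(r)
    if a <= 0.4:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def categorize(
    class_healthy: Strength, class_tumor: Strength, both_de: bool
) -> str:
    """Pure category function of the two strength classes and the DE flag."""
    at_least_moderate = ("moderate", "strong")
    if class_healthy in at_least_moderate and class_tumor in at_least_moderate:
        return "correlated_both" if both_de else "none"
    if class_healthy == "weak" and class_tumor == "strong":
        return "gained_strong_in_tumor"
    if class_healthy == "weak" and class_tumor == "moderate":
        return "gained_moderate_in_tumor"
    if class_healthy == "moderate" and class_tumor == "weak":
        return "lost_in_tumor"
    return "none"


def classify_pairs(
    cohort: CohortPair,
    de_results: pd.DataFrame,
    catalog: HoxCatalog | None = None,
    genes: Iterable[str] | None = None,
    alpha_normality: float = 0.05,
    lilliefors: bool = False,
) -> pd.DataFrame:
    """Correlation classification of every gene pair in a cohort.

    ``de_results`` is a classify_de table for the same cohort (the
    correlated_both category requires both genes DE-called).  Pairs failing
    the four-vector normality gate are reported with
    ``passed_normality=False`` and category ``none`` rather than dropped.
    """
    if catalog is None:
        catalog = build_catalog()
    genes = list(genes) if genes is not None else [
        g for g in catalog.symbols if g in cohort.tumor.data.index
    ]
    de_call = de_results.set_index("gene")["call"]
    normal_ok: dict[tuple[str, str], bool] = {}
    vectors: dict[tuple[str, str], np.ndarray] = {}
    for g in genes:
        for arm, matrix in (("tumor", cohort.tumor), ("healthy", cohort.healthy)):
            v = matrix.gene_values(g)
            vectors[(g, arm)] = v
            try:
                _, p = ks_normality(v, lilliefors=lilliefors)
                normal_ok[(g, arm)] = p > alpha_normality
            except ValueError:
                normal_ok[(g, arm)] = False
    rows = []
    for ga, gb in enumerate_pairs(genes):
        rel = pair_relation((ga, gb), catalog)
        passed = all(
            normal_ok[(g, arm)] for g in (ga, gb) for arm in ("tumor", "healthy")
        )
        row = {
            "gene_a": ga,
            "gene_b": gb,
            "r_healthy": np.nan,
            "r_tumor": np.nan,
            "class_healthy": "",
            "class_tumor": "",
            "passed_normality": passed,
            "category": "none",
            "same_cluster": rel["same_cluster"],
            "same_group": rel["same_group"],
        }
        if passed:
            try:
                r_h = pearson_r(vectors[(ga, "healthy")], vectors[(gb, "healthy")])
                r_t = pearson_r(vectors[(ga, "tumor")], vectors[(gb, "tumor")])
            except ValueError:
                rows.append(row)
                continue
            c_h, c_t = classify_strength(r_h), classify_strength(r_t)
            both_de = bool(
                de_call.get(ga, "none") != "none" and de_call.get(gb, "none") != "none"
            )
            row.update(
                r_healthy=r_h,
                r_tumor=r_t,
                class_healthy=c_h,
                class_tumor=c_t,
                category=categorize(c_h, c_t, both_de),
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=COEXPR_COLUMNS)
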