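"""Kaplan-Meier survival-marker procedures.

Building blocks: the product-limit estimator and the k-sample log-rank test
(implemented with numpy; the tiered and pair screens below run tens of
thousands of log-rank tests in calibration studies, so the test is
vectorized over event times).

Screening procedures:

* tiered_km — for one gene, tumor samples are split at the median expression
  and compared by log-rank; if the Bonferroni-adjusted p (n = 39) is not
  significant, the split escalates to tertile thirds (3-group test), then to
  upper-vs-lower quartile.  The first significant tier is reported.
* pair_km — for a gene pair, the compared groups are the intersection of the
  two above-median sets (size N1) and the intersection of the two
  below-median sets (size N2).  The pair is selected as a joint marker when
  its Bonferroni-adjusted p (n = 741 pairs) is significant and its raw p
  beats both matched single-gene controls, each built from exactly the N1
  top-ranked and N2 bottom-ranked samples by that single gene's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "TieredKMResult",
    "PairKMResult",
    "km_estimate",
    "logrank_test",
    "tiered_km",
    "pair_km",
]

logger = logging.getLogger("hoxpress")

Tier = Literal["median2", "tertile3", "quartile_extremes", "none"]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function, S(0) = 1."""
        idx = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape:
        raise ValueError("time and event must have the same length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return t, e


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, deaths are counted before censorings (censored samples
    remain at risk through their censoring time), the standard convention.
    """
    t, e = _as_arrays(time, event)
    if t.size == 0:
        raise ValueError("at least one record required")
    if e.sum() == 0 and (t == 0).all():
        logger.warning("degenerate survival input: all times zero, no events")
    event_times = np.unique(t[e == 1])
    n_at_risk = (t[None, :] >= event_times[:, None]).sum(axis=1)
    d = np.array([(t[e == 1] == s).sum() for s in event_times])
    survival = np.cumprod(1.0 - d / n_at_risk) if event_times.size else np.array([])
    return KMCurve(event_times, n_at_risk, d, survival)


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> tuple[float, float]:
    """k-sample log-rank test.

    ``groups`` is a sequence of (time, event) pairs, one per group.  Returns
    the chi-square statistic (observed-minus-expected quadratic form with the
    hypergeometric covariance) and its p-value on k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    parsed = []
    for time, event in groups:
        t, e = _as_arrays(time, event)
        if t.size == 0:
            raise ValueError("every group must be non-empty")
        parsed.append((np.sort(t), np.sort(t[e == 1])))
    k = len(parsed)
    all_event_times = np.unique(np.concatenate([evt for _, evt in parsed]))
    if all_event_times.size == 0:
        return 0.0, 1.0
    J = all_event_times.size
    n_ij = np.empty((k, J))
    d_ij = np.empty((k, J))
    for i, (t_sorted, evt_sorted) in enumerate(parsed):
        n_ij[i] = t_sorted.size - np.searchsorted(t_sorted, all_event_times, side="left")
        d_ij[i] = np.searchsorted(evt_sorted, all_event_times, side="right") - np.searchsorted(
            evt_sorted, all_event_times, side="left"
        )
    n_j = n_ij.sum(axis=0)
    d_j = d_ij.sum(axis=0)
    valid = n_j > 0
    n_ij, d_ij, n_j, d_j = n_ij[:, valid], d_ij[:, valid], n_j[valid], d_j[valid]
    expected = d_j * n_ij / n_j
    z = (d_ij - expected).sum(axis=1)[: k - 1]
    # Hypergeometric covariance, summed over event times.
    with np.errstate(divide="ignore", invalid="ignore"):
        c_j = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1), 0.0)
    p_ij = n_ij / n_j  # proportions at risk
    V = np.zeros((k - 1, k - 1))
    for a in range(k - 1):
        for b in range(k - 1):
            delta = 1.0 if a == b else 0.0
            V[a, b] = np.sum(c_j * p_ij[a] * (delta - p_ij[b]))
    try:
        chi2 = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(V) @ z)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


@dataclass(frozen=True)
class TieredKMResult:
    gene: str
    tier: Tier
    p_raw: float
    p_adj: float
    significant: bool
    tier_pvalues: dict[str, float]


@dataclass(frozen=True)
class PairKMResult:
    gene_a: str
    gene_b: str
    n1: int
    n2: int
    p_pair: float
    p_pair_adj: float
    p_single_a: float
    p_single_b: float
    selected: bool


def _align(expression, time, event) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align an expression vector with survival columns.

    pandas inputs are joined on their index (sample_id); plain arrays are
    taken as positionally aligned.
    """
    if isinstance(expression, pd.Series) and isinstance(time, pd.Series):
        common = expression.index.intersection(time.index)
        expression = expression.loc[common]
        event = pd.Series(np.asarray(event), index=time.index).loc[common]
        time = time.loc[common]
    x = np.asarray(expression, dtype=float)
    t, e = _as_arrays(time, event)
    if x.size != t.size:
        raise ValueError("expression and survival records are not aligned")
    return x, t, e


def tiered_km(
    expression: Sequence[float] | pd.Series,
    time: Sequence[float] | pd.Series,
    event: Sequence[int] | pd.Series,
    gene: str = "",
    alpha: float = 0.05,
    n_tests: int = 39,
) -> TieredKMResult:
    """Tiered single-gene KM screen: median split, then tertiles, then
    extreme quartiles; the first Bonferroni-significant tier wins.

    Each tier's p is Bonferroni-adjusted across genes (``n_tests``) but no
    correction is applied across the tiers themselves (sequential
    escalation).
    """
    x, t, e = _align(expression, time, event)
    n = x.size
    if n < 8:
        raise ValueError(f"tiered KM needs >= 8 samples, got {n}")
    order = np.argsort(x, kind="stable")  # ties broken by sample order
    tier_pvalues: dict[str, float] = {}

    def result(tier: Tier, p_raw: float) -> TieredKMResult:
        p_adj = min(1.0, n_tests * p_raw)
        return TieredKMResult(gene, tier, p_raw, p_adj, tier != "none", tier_pvalues)

    # Tier 1: median split (strictly greater = high; at-median goes low).
    high = x > np.median(x)
    if high.any() and (~high).any():
        _, p1 = logrank_test([(t[high], e[high]), (t[~high], e[~high])])
        tier_pvalues["median2"] = p1
        if min(1.0, n_tests * p1) < alpha:
            return result("median2", p1)

    # Tier 2: tertile thirds by sample count (sizes differ by at most 1).
    thirds = np.array_split(order, 3)
    if all(len(g) for g in thirds):
        _, p2 = logrank_test([(t[g], e[g]) for g in thirds])
        tier_pvalues["tertile3"] = p2
        if min(1.0, n_tests * p2) < alpha:
            return result("tertile3", p2)

    # Tier 3: upper vs lower quartile.
    q = n // 4
    lower, upper = order[:q], order[-q:]
    _, p3 = logrank_test([(t[upper], e[upper]), (t[lower], e[lower])])
    tier_pvalues["quartile_extremes"] = p3
    if min(1.0, n_tests * p3) < alpha:
        return result("quartile_extremes", p3)
    return result("none", p3)


def pair_km(
    expr_a: Sequence[float] | pd.Series,
    expr_b: Sequence[float] | pd.Series,
    time: Sequence[float] | pd.Series,
    event: Sequence[int] | pd.Series,
    gene_a: str = "",
    gene_b: str = "",
    alpha: float = 0.05,
    n_tests: int = 741,
) -> PairKMResult:
    """Pair-intersection KM screen with matched single-gene controls.

    Groups: N1 = samples above the median on both genes, N2 = samples below
    the median on both (strict splits; at-median samples join neither).  The
    matched single-gene control for gene g compares exactly the N1 samples
    with the highest and the N2 samples with the lowest expression of g
    (rank ties broken by sample order).  ``selected`` requires the adjusted
    pair p below ``alpha`` and the raw pair p strictly below both single-gene
    raw p-values.
    """
    a, t, e = _align(expr_a, time, event)
    b, _, _ = _align(expr_b, time, event)
    if a.size != b.size:
        raise ValueError("expression vectors are not aligned")
    med_a, med_b = np.median(a), np.median(b)
    both_high = (a > med_a) & (b > med_b)
    both_low = (a < med_a) & (b < med_b)
    n1, n2 = int(both_high.sum()), int(both_low.sum())
    if n1 == 0 or n2 == 0:
        return PairKMResult(gene_a, gene_b, n1, n2, np.nan, np.nan, np.nan, np.nan, False)
    _, p_pair = logrank_test([(t[both_high], e[both_high]), (t[both_low], e[both_low])])
    p_pair_adj = min(1.0, n_tests * p_pair)

    def single_control(x: np.ndarray) -> float:
        order = np.argsort(x, kind="stable")
        top, bottom = order[-n1:], order[:n2]
        _, p = logrank_test([(t[top], e[top]), (t[bottom], e[bottom])])
        return p

    p_single_a = single_control(a)
    p_single_b = single_control(b)
    selected = p_pair_adj < alpha and p_pair < p_single_a and p_pair < p_single_b
    return PairKMResult(
        gene_a, gene_b, n1, n2, p_pair, p_pair_adj, p_single_a, p_single_b, selected
    )
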