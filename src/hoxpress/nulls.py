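"""Random-gene-set empirical null procedures.

Three resampling procedures share one convention: an observed statistic is
scored against B statistics recomputed on randomly drawn gene sets, and the
empirical p-value is the plain fraction of draws at least as extreme as the
observation — r/B with no +1 smoothing, so p = 0 is attainable when the
observation is more extreme than every draw.

* cross-source concordance: does a focal gene panel's DE-call disagreement
  between two healthy references (e.g. TCGA-normal vs GTEx) exceed that of
  random same-size panels?
* posterior low-expression: is the mean healthy expression of the 16
  posterior-group genes low relative to random 16-gene subsets?
* housekeeping comparison: are the HOX panel's median expression levels low
  relative to random 39-gene housekeeping panels?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import HoxCatalog, build_catalog
from .diffexpr import classify_de
from .io import CohortPair, ExpressionMatrix

__all__ = [
    "EmpiricalNull",
    "empirical_pvalue",
    "concordance_null",
    "posterior_low_expression_test",
    "hk_comparison",
]

Tail = Literal["greater", "less", "two_sided"]


@dataclass(frozen=True)
class EmpiricalNull:
    """Observed statistic, resampled draws and the empirical p-value."""

    observed: float
    draws: np.ndarray
    p_empirical: float
    tail: Tail

    def to_frame(self) -> pd.DataFrame:
        """Null draws as a single-column DataFrame (for TSV audit dumps)."""
        return pd.DataFrame({"draw": self.draws})


def empirical_pvalue(observed: float, draws: Sequence[float], tail: Tail = "greater") -> float:
    """Fraction of draws at least as extreme as ``observed``.

    ``greater`` counts draws >= observed, ``less`` counts <=, ``two_sided``
    doubles the smaller tail, capped at 1.  No smoothing: p = 0 is possible.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    p_ge = float(np.mean(draws >= observed))
    p_le = float(np.mean(draws <= observed))
    if tail == "greater":
        return p_ge
    if tail == "less":
        return p_le
    if tail == "two_sided":
        return min(1.0, 2.0 * min(p_ge, p_le))
    raise ValueError(f"unknown tail {tail!r}")


def _make_null(observed: float, draws: np.ndarray, tail: Tail) -> EmpiricalNull:
    return EmpiricalNull(
        observed=float(observed),
        draws=np.asarray(draws, dtype=float),
        p_empirical=empirical_pvalue(observed, draws, tail),
        tail=tail,
    )


def concordance_null(
    tumor: ExpressionMatrix,
    healthy_a: ExpressionMatrix,
    healthy_b: ExpressionMatrix,
    focal_set: Iterable[str],
    gene_universe: Iterable[str] | None = None,
    set_size: int = 39,
    B: int = 1000,
    seed: int = 0,
    fold_cutoff: float = 2.0,
    alpha: float = 0.05,
) -> tuple[EmpiricalNull, np.ndarray]:
    """Cross-source DE concordance of a focal panel vs random panels.

    For every gene in the universe, a DE call is computed twice — tumor vs
    ``healthy_a`` and tumor vs ``healthy_b`` — with Bonferroni n = set_size.
    A panel's discordance is the size of the symmetric difference of its two
    DE-gene lists.  B uniformly drawn ``set_size``-panels form the null; the
    focal panel's discordance is scored with tail=greater.  Returns the
    :class:`EmpiricalNull` and the per-draw discordance counts (identical to
    ``null.draws``).

    Per-gene calls do not depend on which panel a gene sits in (only the
    constant Bonferroni factor does), so calls are computed once per gene and
    panels are scored by set algebra; this makes B = 1000 cheap.
    """
    universe = list(gene_universe) if gene_universe is not None else tumor.genes
    focal = list(focal_set)
    if len(universe) < set_size:
        raise ValueError(f"gene universe ({len(universe)}) smaller than set_size ({set_size})")
    pair_a = CohortPair("A", tumor.subset_genes(universe), healthy_a.subset_genes(universe))
    pair_b = CohortPair("B", tumor.subset_genes(universe), healthy_b.subset_genes(universe))
    kwargs = dict(fold_cutoff=fold_cutoff, alpha=alpha, n_tests=set_size)
    calls_a = classify_de(pair_a, universe, **kwargs).set_index("gene")["call"]
    calls_b = classify_de(pair_b, universe, **kwargs).set_index("gene")["call"]
    discordant = {g for g in universe if (calls_a[g] != "none") != (calls_b[g] != "none")}

    # Also count genes called on both sides but in opposite directions.
    discordant |= {
        g
        for g in universe
        if calls_a[g] != "none" and calls_b[g] != "none" and calls_a[g] != calls_b[g]
    }
    observed = sum(1 for g in focal if g in discordant)
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe)
    draws = np.empty(B)
    for b in range(B):
        panel = rng.choice(universe_arr, size=set_size, replace=False)
        draws[b] = sum(1 for g in panel if g in discordant)
    return _make_null(observed, draws, "greater"), draws


def posterior_low_expression_test(
    healthy_means_by_tissue: pd.DataFrame,
    catalog: HoxCatalog | None = None,
    B: int = 1000,
    k: int = 16,
    universe: Literal["hox", "all"] = "hox",
    seed: int = 0,
) -> EmpiricalNull:
    """Are the posterior-group genes lowly expressed across healthy tissues?

    ``healthy_means_by_tissue`` is a genes x tissues table of mean healthy
    expression (log2 units).  The statistic is the grand mean over the 16
    posterior genes and all tissues; the null redraws the statistic for B
    random ``k``-subsets of the universe (the 39 HOX genes by default, or
    every row of the table with ``universe='all'``), and the observation is
    scored with tail=less.
    """
    if catalog is None:
        catalog = build_catalog()
    posterior = [g.symbol for g in catalog if g.group == "posterior"]
    missing = [g for g in posterior if g not in healthy_means_by_tissue.index]
    if missing:
        raise KeyError(f"posterior genes absent from table: {missing}")
    pool = (
        [g for g in catalog.symbols if g in healthy_means_by_tissue.index]
        if universe == "hox"
        else healthy_means_by_tissue.index.tolist()
    )
    if k > len(pool):
        raise ValueError(f"k = {k} exceeds universe size {len(pool)}")
    observed = float(healthy_means_by_tissue.loc[posterior].to_numpy().mean())
    rng = np.random.default_rng(seed)
    pool_values = healthy_means_by_tissue.loc[pool].to_numpy()
    per_gene_mean = pool_values.mean(axis=1)  # mean over tissues per gene
    draws = np.empty(B)
    for b in range(B):
        idx = rng.choice(len(pool), size=k, replace=False)
        draws[b] = per_gene_mean[idx].mean()
    return _make_null(observed, draws, "less")


def hk_comparison(
    cohorts: Mapping[str, CohortPair],
    hk_list: Iterable[str],
    hox_list: Iterable[str] | None = None,
    B: int = 1000,
    set_size: int = 39,
    seed: int = 0,
) -> dict[str, dict]:
    """HOX vs housekeeping expression levels, per cancer type.

    For each cohort, draws B random ``set_size``-gene housekeeping panels and
    records each panel's median healthy and median tumor expression.  The HOX
    panel's medians are scored against these nulls with tail=less (are HOX
    genes lower-expressed than like-sized HK panels?).  Also reports whether
    the full HK list's median exceeds the HOX median by the 2-fold criterion
    (>= 1 log2 unit) in each arm.
    """
    if hox_list is None:
        hox_list = build_catalog().symbols
    hox_list = list(hox_list)
    hk_list = list(dict.fromkeys(hk_list))
    out: dict[str, dict] = {}
    rng = np.random.default_rng(seed)
    for category, pair in cohorts.items():
        hk_present = [g for g in hk_list if g in pair.tumor.data.index]
        if len(hk_present) < set_size:
            raise ValueError(
                f"cohort {category}: only {len(hk_present)} HK genes present, "
                f"need >= {set_size}"
            )
        hox_present = [g for g in hox_list if g in pair.tumor.data.index]
        healthy_hk = pair.healthy.data.loc[hk_present].to_numpy()
        tumor_hk = pair.tumor.data.loc[hk_present].to_numpy()
        obs_healthy = float(np.median(pair.healthy.data.loc[hox_present].to_numpy()))
        obs_tumor = float(np.median(pair.tumor.data.loc[hox_present].to_numpy()))
        draws_h = np.empty(B)
        draws_t = np.empty(B)
        for b in range(B):
            idx = rng.choice(len(hk_present), size=set_size, replace=False)
            draws_h[b] = np.median(healthy_hk[idx])
            draws_t[b] = np.median(tumor_hk[idx])
        out[category] = {
            "healthy": _make_null(obs_healthy, draws_h, "less"),
            "tumor": _make_null(obs_tumor, draws_t, "less"),
            "hk_median_healthy": float(np.median(healthy_hk)),
            "hk_median_tumor": float(np.median(tumor_hk)),
            "hox_median_healthy": obs_healthy,
            "hox_median_tumor": obs_tumor,
            # 2-fold on the linear scale = 1 unit on the log2 scale.
            "hk_exceeds_2fold_healthy": bool(np.median(healthy_hk) - obs_healthy >= 1.0),
            "hk_exceeds_2fold_tumor": bool(np.median(tumor_hk) - obs_tumor >= 1.0),
        }
    return out
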