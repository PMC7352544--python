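"""Synthetic tumor/healthy cohort generator with planted truth.

Emulates the structure the analysis assumes in real Toil-recompute data:
paired tumor and healthy cohorts (>= 100 samples each by default), log2(x+1)
expression with a zero floor, planted per-gene fold changes, planted
inter-gene correlation blocks, and exponential survival whose hazard depends
on the expression of designated genes, with independent random censoring.

The generative model works directly on the analyzed log2 scale: each gene's
healthy values are Normal(mean, sd) clipped at zero, tumor values add
log2(FC).  Within a correlation block all genes share a latent standard
Normal factor with loading sqrt(rho), so every within-block pair has
population Pearson correlation rho.  Count-level noise (overdispersion,
library size), batch effects and tumor purity are deliberately not modeled.

Randomness is keyed per stream: each gene, each correlation block and the
survival/censoring draws get an independent substream derived from the global
seed and a stable string key, so adding a gene to the configuration does not
perturb any other gene's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import build_catalog
from .io import CohortPair, ExpressionMatrix

__all__ = [
    "CorrelationBlock",
    "SurvivalConfig",
    "SimulationConfig",
    "SyntheticCohort",
    "generate",
    "emit",
    "load_config",
]


@dataclass(frozen=True)
class CorrelationBlock:
    """Genes sharing one latent factor with loading sqrt(rho)."""

    genes: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if len(self.genes) < 2:
            raise ValueError("a correlation block needs at least 2 genes")


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential survival: hazard = lambda0 * exp(sum_g beta_g * z_g).

    ``lambda0`` is the baseline hazard per day; ``beta`` maps gene symbol to
    the log-hazard increase per standardized unit of that gene's log2
    expression; ``censoring_rate`` is the target fraction of tumor samples
    censored (independent exponential censoring, tuned at the baseline
    hazard).
    """

    lambda0: float = 1.0 / 1000.0
    beta: Mapping[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort; also the planted truth."""

    genes: tuple[str, ...] = ()
    n_tumor: int = 100
    n_healthy: int = 100
    baseline_mean: float | Mapping[str, float] = 4.0
    baseline_sd: float | Mapping[str, float] = 1.0
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    category: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        genes = tuple(self.genes) if self.genes else tuple(build_catalog().symbols)
        object.__setattr__(self, "genes", genes)
        if self.n_tumor < 1 or self.n_healthy < 1:
            raise ValueError("n_tumor and n_healthy must be >= 1")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols in config")
        known = set(genes)
        for g, fc in self.fold_changes.items():
            if g not in known:
                raise ValueError(f"fold change for unknown gene {g!r}")
            if fc <= 0:
                raise ValueError(f"fold change must be positive, got {g}={fc}")
        seen_in_block: set[str] = set()
        for block in self.correlation_blocks:
            for g in block.genes:
                if g not in known:
                    raise ValueError(f"correlation block names unknown gene {g!r}")
                if g in seen_in_block:
                    raise ValueError(f"gene {g!r} appears in two correlation blocks")
                seen_in_block.add(g)
        for g in self.survival.beta:
            if g not in known:
                raise ValueError(f"survival beta for unknown gene {g!r}")

    def mean_of(self, gene: str) -> float:
        m = self.baseline_mean
        return float(m[gene]) if isinstance(m, Mapping) else float(m)

    def sd_of(self, gene: str) -> float:
        s = self.baseline_sd
        return float(s[gene]) if isinstance(s, Mapping) else float(s)


@dataclass
class SyntheticCohort:
    cohort: CohortPair
    survival: pd.DataFrame  # index sample_id; columns time, event
    truth: SimulationConfig


def _stream(seed: int, key: str) -> np.random.Generator:
    """Independent substream keyed by (seed, stable string hash)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(key.encode())])
    )


def generate(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; identical config -> identical output."""
    genes = list(config.genes)
    n_h, n_t = config.n_healthy, config.n_tumor
    n = n_h + n_t

    # Latent block factors, one per sample per block.
    factor_of: dict[str, np.ndarray] = {}
    loading_of: dict[str, float] = {}
    for i, block in enumerate(config.correlation_blocks):
        f = _stream(config.seed, f"block:{i}").standard_normal(n)
        for g in block.genes:
            factor_of[g] = f
            loading_of[g] = block.rho

    values = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        eps = _stream(config.seed, f"gene:{g}").standard_normal(n)
        if g in factor_of:
            rho = loading_of[g]
            z = np.sqrt(rho) * factor_of[g] + np.sqrt(1.0 - rho) * eps
        else:
            z = eps
        row = config.mean_of(g) + config.sd_of(g) * z
        fc = config.fold_changes.get(g, 1.0)
        row[n_h:] += np.log2(fc)
        values[gi] = np.clip(row, 0.0, None)

    healthy_ids = [f"{config.category}-H{i:04d}" for i in range(n_h)]
    tumor_ids = [f"{config.category}-T{i:04d}" for i in range(n_t)]
    df = pd.DataFrame(
        values, index=pd.Index(genes, name="gene"), columns=healthy_ids + tumor_ids
    )
    cohort = CohortPair(
        config.category,
        ExpressionMatrix(df[tumor_ids]),
        ExpressionMatrix(df[healthy_ids]),
    )

    # Expression-dependent exponential survival for tumor samples.
    surv = config.survival
    eta = np.zeros(n_t)
    for g, beta in surv.beta.items():
        x = df.loc[g, tumor_ids].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n_t)
        eta += float(beta) * z
    hazard = surv.lambda0 * np.exp(eta)
    t_event = _stream(config.seed, "survival").exponential(1.0 / hazard)
    if surv.censoring_rate > 0:
        rate_c = surv.lambda0 * surv.censoring_rate / (1.0 - surv.censoring_rate)
        t_cens = _stream(config.seed, "censoring").exponential(1.0 / rate_c, size=n_t)
    else:
        t_cens = np.full(n_t, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(tumor_ids, name="sample_id")
    )
    return SyntheticCohort(cohort=cohort, survival=survival, truth=config)


def emit(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write genomicMatrix, phenotype and clinical TSVs readable by hoxpress.io."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pair = cohort.cohort
    joint = pd.concat([pair.healthy.data, pair.tumor.data], axis=1)
    joint.index.name = "gene"
    paths = {
        "expression": directory / "expression.tsv",
        "phenotype": directory / "phenotype.tsv",
        "clinical": directory / "clinical.tsv",
    }
    joint.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    pheno = pd.DataFrame(
        {
            "sample_id": joint.columns,
            "source": "synthetic",
            "condition": ["healthy"] * pair.n_healthy + ["tumor"] * pair.n_tumor,
            "category": pair.category,
        }
    )
    pheno.to_csv(paths["phenotype"], sep="\t", index=False)
    clin = cohort.survival.copy()
    clin["time"] = clin["time"].map(lambda t: f"{t:.6f}")
    clin.to_csv(paths["clinical"], sep="\t")
    return paths


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file.

    Recognized keys mirror the dataclass fields; ``correlation_blocks`` is a
    list of ``{genes: [...], rho: x}`` mappings and ``survival`` a mapping
    with ``lambda0``, ``beta`` and ``censoring_rate``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    blocks = tuple(
        CorrelationBlock(tuple(b["genes"]), float(b["rho"]))
        for b in raw.pop("correlation_blocks", [])
    )
    surv_raw = raw.pop("survival", {})
    survival = SurvivalConfig(
        lambda0=float(surv_raw.get("lambda0", 1.0 / 1000.0)),
        beta={str(k): float(v) for k, v in (surv_raw.get("beta") or {}).items()},
        censoring_rate=float(surv_raw.get("censoring_rate", 0.2)),
    )
    genes = tuple(raw.pop("genes", ()) or ())
    return SimulationConfig(
        genes=genes,
        correlation_blocks=blocks,
        survival=survival,
        **{k: v for k, v in raw.items()},
    )
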