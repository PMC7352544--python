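"""Tabular I/O for the expression pipeline.

Dialects handled:

* genomicMatrix — tab-separated genes x samples expression table, first
  column gene symbol, header row of sample IDs, values on the log2(x+1)
  scale (RSEM normalized counts).  Matrix orientation is fixed as
  genes-in-rows; transposed files are rejected, never guessed.
* phenotype    — sample_id, source (TCGA/GTEx/synthetic), condition
  (tumor/healthy), category (joint cancer-type label such as BRCA).
* clinical     — sample_id, time (days), event (1=death, 0=censored) and
  optional her2/pr/er receptor statuses, normalized to
  {positive, negative, missing}.
* category map — two columns mapping a source-specific tissue label to the
  joint cancer-type category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortPair",
    "IntegrityError",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "read_clinical",
    "read_category_map",
    "read_gene_list",
    "build_cohorts",
]

logger = logging.getLogger("hoxpress")

_VALID_SOURCES = {"TCGA", "GTEx", "synthetic"}
_VALID_CONDITIONS = {"tumor", "healthy"}


class IntegrityError(ValueError):
    """A table violates a structural invariant (duplicates, shape, range)."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix in log2(x+1) units.

    Thin wrapper around a pandas DataFrame (index = gene symbols, columns =
    sample IDs) that enforces nonnegative values and identifier uniqueness.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate sample identifiers: {dups}")
        n_missing = int(df.isna().sum().sum())
        if n_missing:
            # Toil matrices are dense; drop incomplete gene rows loudly.
            bad = df.index[df.isna().any(axis=1)].tolist()
            logger.warning("dropping %d gene rows with missing values: %s", len(bad), bad)
            self.data = df = df.dropna(axis=0)
        if (df.to_numpy() < 0).any():
            raise IntegrityError("negative expression values (expected log2(x+1) >= 0)")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes``; absent symbols raise, listing every one."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data[samples])

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise KeyError(f"genes absent from matrix: [{gene!r}]")
        return self.data.loc[gene].to_numpy(dtype=float)


@dataclass
class CohortPair:
    """Tumor and healthy expression matrices for one joint cancer category.

    ``included`` is true only when both sides reach ``min_samples`` (the
    at-least-100-per-arm inclusion rule).  Gene rows are identical and
    identically ordered on both sides.
    """

    category: str
    tumor: ExpressionMatrix
    healthy: ExpressionMatrix
    min_samples: int = 100
    included: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.tumor.genes != self.healthy.genes:
            raise IntegrityError(
                f"cohort {self.category}: tumor/healthy gene rows differ"
            )
        self.included = (
            len(self.tumor.samples) >= self.min_samples
            and len(self.healthy.samples) >= self.min_samples
        )

    @property
    def n_tumor(self) -> int:
        return len(self.tumor.samples)

    @property
    def n_healthy(self) -> int:
        return len(self.healthy.samples)

    def subset_genes(self, genes: Iterable[str]) -> "CohortPair":
        genes = list(genes)
        return CohortPair(
            self.category,
            self.tumor.subset_genes(genes),
            self.healthy.subset_genes(genes),
            self.min_samples,
        )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genomicMatrix TSV (genes in rows, header of sample IDs)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise IntegrityError(f"{path}: expected at least one sample column")
        samples = header[1:]
        n_cols = len(header)
        gene_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise IntegrityError(
                    f"{path}:{lineno}: expected {n_cols} fields, found {len(fields)}"
                )
            gene_ids.append(fields[0])
            rows.append(fields[1:])
    try:
        values = np.asarray(rows, dtype=float)
    except ValueError as exc:
        raise IntegrityError(f"{path}: non-numeric expression value ({exc})") from exc
    if values.size == 0:
        values = values.reshape(0, len(samples))
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=samples)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genomicMatrix TSV; round-trips through :func:`read_expression`."""
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table (sample_id, source, condition, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "source", "condition", "category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: phenotype table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate sample_id in phenotype table")
    bad_src = sorted(set(df["source"]) - _VALID_SOURCES)
    if bad_src:
        raise IntegrityError(f"{path}: unknown sources {bad_src}")
    bad_cond = sorted(set(df["condition"]) - _VALID_CONDITIONS)
    if bad_cond:
        raise IntegrityError(f"{path}: unknown conditions {bad_cond}")
    # GTEx contributes healthy tissue only; TCGA samples are used as tumor
    # (the few TCGA normals are removed upstream).
    gtex_tumor = df[(df["source"] == "GTEx") & (df["condition"] == "tumor")]
    if len(gtex_tumor):
        raise IntegrityError(f"{path}: GTEx samples must be condition=healthy")
    return df.set_index("sample_id")


def _normalize_status(value: object) -> str:
    if isinstance(value, str) and value.strip().lower() in ("positive", "negative"):
        return value.strip().lower()
    return "missing"


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table: sample_id, time, event, optional her2/pr/er.

    Receptor statuses are normalized case-insensitively: anything other than
    'positive'/'negative' (NA, Equivocal, Indeterminate, blank ...) becomes
    'missing'.  Negative follow-up times are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: clinical table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate sample_id in clinical table")
    out = pd.DataFrame(index=pd.Index(df["sample_id"], name="sample_id"))
    out["time"] = pd.to_numeric(df["time"].to_numpy(), errors="raise")
    out["event"] = pd.to_numeric(df["event"].to_numpy(), errors="raise").astype(int)
    if (out["time"] < 0).any():
        raise IntegrityError(f"{path}: negative survival time")
    if not out["event"].isin([0, 1]).all():
        raise IntegrityError(f"{path}: event flag must be 0 or 1")
    for col in ("her2", "pr", "er"):
        if col in df.columns:
            out[col] = [_normalize_status(v) for v in df[col]]
        else:
            out[col] = "missing"
    return out


def read_category_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: source-specific tissue label -> joint category."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] != 2:
        raise IntegrityError(f"{path}: category map must have exactly two columns")
    return dict(zip(df[0], df[1]))


def read_gene_list(path: str | Path) -> list[str]:
    """One-symbol-per-line gene list file (blank lines and # comments skipped)."""
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line.split("\t")[0])
    return symbols


def build_cohorts(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
    min_samples: int = 100,
) -> dict[str, CohortPair]:
    """Split a joint matrix into per-category tumor/healthy cohort pairs.

    Every sample in ``expr`` must be annotated; a sample without an annotation
    row is an integrity error, never silently dropped.  Categories whose tumor
    or healthy arm falls below ``min_samples`` are returned with
    ``included=False`` (downstream stages analyze included pairs only).
    """
    unannotated = [s for s in expr.samples if s not in annotations.index]
    if unannotated:
        raise IntegrityError(f"samples without annotation: {unannotated[:10]}")
    ann = annotations.loc[expr.samples].copy()
    if category_map is not None:
        ann["category"] = [category_map.get(c, c) for c in ann["category"]]
    cohorts: dict[str, CohortPair] = {}
    for category, sub in ann.groupby("category", sort=True):
        tumor_ids = sub.index[sub["condition"] == "tumor"].tolist()
        healthy_ids = sub.index[sub["condition"] == "healthy"].tolist()
        if not tumor_ids or not healthy_ids:
            logger.warning(
                "category %s has %d tumor / %d healthy samples; excluded",
                category, len(tumor_ids), len(healthy_ids),
            )
        pair = CohortPair(
            str(category),
            expr.subset_samples(tumor_ids) if tumor_ids else _empty_like(expr),
            expr.subset_samples(healthy_ids) if healthy_ids else _empty_like(expr),
            min_samples,
        )
        cohorts[str(category)] = pair
    return cohorts


def _empty_like(expr: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(index=expr.data.index.copy()))
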