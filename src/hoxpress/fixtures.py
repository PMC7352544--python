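"""Bundled machine-readable result tables and their summaries.

Four small TSV fixtures ship with the package:

* cohort sample counts per cancer type (healthy arm from GTEx, tumor arm
  from TCGA; the brain and lung healthy pools are shared by LGG/GBM and
  LUAD/LUSC respectively),
* the pronounced-change table: genes with >= 3-fold change and >= 1 unit of
  healthy expression, with their fold changes per cancer type,
* the survival-marker table: genes whose tiered KM screen was significant
  after Bonferroni adjustment, per cancer type,
* the coexpressed-pair table: gene pairs correlated in both tumor and
  healthy cohorts, per cancer type.  One ESCA entry (HOXA10-HOXB5) is
  reconstructed from the table's printed row totals and cross-tabulations;
  see docs/methods.md.

``summarize_fixture`` recomputes the headline counts (group composition,
same-cluster/same-group pair fractions, per-cancer tallies) from the raw
entries, validating every symbol against the 39-gene catalog.
"""

from __future__ import annotations

from importlib import resources
from typing import Literal

import pandas as pd

from .catalog import HoxCatalog, build_catalog, pair_relation

__all__ = [
    "CANCER_TYPES",
    "load_cohort_sizes",
    "load_pronounced_changes",
    "load_km_significant",
    "load_correlated_pairs",
    "summarize_fixture",
]

CANCER_TYPES = (
    "BRCA", "COAD", "ESCA", "GBM", "LAML", "LGG", "LIHC",
    "LUAD", "LUSC", "PAAD", "PCPG", "PRAD", "STAD", "THCA",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("hoxpress").joinpath("_data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _validate_genes(df: pd.DataFrame, columns: list[str], catalog: HoxCatalog) -> None:
    for col in columns:
        unknown = sorted(set(df[col]) - set(catalog.symbols))
        if unknown:
            raise ValueError(f"fixture column {col} has non-catalog symbols: {unknown}")


def _validate_cancers(df: pd.DataFrame) -> None:
    unknown = sorted(set(df["cancer_type"]) - set(CANCER_TYPES))
    if unknown:
        raise ValueError(f"fixture has unknown cancer types: {unknown}")


def load_cohort_sizes() -> pd.DataFrame:
    return _read("table1_cohort_sizes.tsv")


def load_pronounced_changes(catalog: HoxCatalog | None = None) -> pd.DataFrame:
    df = _read("table2_pronounced_changes.tsv")
    _validate_genes(df, ["gene"], catalog or build_catalog())
    _validate_cancers(df)
    return df


def load_km_significant(catalog: HoxCatalog | None = None) -> pd.DataFrame:
    df = _read("table3_km_significant.tsv")
    _validate_genes(df, ["gene"], catalog or build_catalog())
    _validate_cancers(df)
    return df


def load_correlated_pairs(catalog: HoxCatalog | None = None) -> pd.DataFrame:
    df = _read("table4_correlated_pairs.tsv")
    _validate_genes(df, ["gene_a", "gene_b"], catalog or build_catalog())
    _validate_cancers(df)
    return df


def summarize_fixture(
    fixture: pd.DataFrame,
    kind: Literal["pronounced_changes", "km_significant", "correlated_pairs"],
    catalog: HoxCatalog | None = None,
    fold_threshold: float = 4.0,
) -> dict:
    """Recompute a fixture's headline counts.

    * pronounced_changes: total entries, per paralog-group counts, per-cancer
      entry counts, maxima, and counts of entries whose fold change exceeds
      ``fold_threshold``.
    * km_significant: total entries and per-cancer counts.
    * correlated_pairs: total entries plus same-cluster / same-group counts
      via :func:`hoxpress.catalog.pair_relation`.
    """
    if catalog is None:
        catalog = build_catalog()
    if kind == "pronounced_changes":
        _validate_genes(fixture, ["gene"], catalog)
        groups = fixture["gene"].map(lambda s: catalog.get(s).group)
        per_cancer = fixture.groupby("cancer_type")
        return {
            "total": int(len(fixture)),
            "per_group": {g: int((groups == g).sum()) for g in ("anterior", "central", "posterior")},
            "per_cancer": per_cancer.size().to_dict(),
            "per_cancer_max_fold": per_cancer["fold_change"].max().to_dict(),
            "per_cancer_above_threshold": per_cancer["fold_change"]
            .apply(lambda s: int((s > fold_threshold).sum()))
            .to_dict(),
            "max_fold_change": float(fixture["fold_change"].max()),
        }
    if kind == "km_significant":
        _validate_genes(fixture, ["gene"], catalog)
        return {
            "total": int(len(fixture)),
            "per_cancer": fixture.groupby("cancer_type").size().to_dict(),
        }
    if kind == "correlated_pairs":
        _validate_genes(fixture, ["gene_a", "gene_b"], catalog)
        relations = [
            pair_relation(tuple(sorted((a, b))), catalog)
            for a, b in zip(fixture["gene_a"], fixture["gene_b"])
        ]
        return {
            "total": int(len(fixture)),
            "same_cluster": sum(r["same_cluster"] for r in relations),
            "same_group": sum(r["same_group"] for r in relations),
            "per_cancer": fixture.groupby("cancer_type").size().to_dict(),
        }
    raise ValueError(f"unknown fixture kind {kind!r}")
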