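"""The human HOX gene model.

The 39 human HOX genes sit in four genomic clusters (A on chromosome 7, B on
17, C on 12, D on 2), with paralog numbers 1-13.  Lineage-specific losses mean
no cluster carries all thirteen paralogs.  Paralogs are conventionally grouped
by their anterior-posterior expression domain during development:

* anterior  — paralogs 1-3
* central   — paralogs 4-8
* posterior — paralogs 9-13

This module encodes that nomenclature as a fixed catalog, plus pair
enumeration and pair-relation helpers used by the coexpression and reporting
stages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "HoxGene",
    "HoxCatalog",
    "build_catalog",
    "classify_group",
    "enumerate_pairs",
    "pair_relation",
    "GROUPS",
    "CLUSTERS",
]

CLUSTERS = ("A", "B", "C", "D")
GROUPS = ("anterior", "central", "posterior")

# Paralogs retained in each human HOX cluster (standard loci; 11+10+9+9 = 39).
_CLUSTER_PARALOGS: dict[str, tuple[int, ...]] = {
    "A": (1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 13),
    "B": (1, 2, 3, 4, 5, 6, 7, 8, 9, 13),
    "C": (4, 5, 6, 8, 9, 10, 11, 12, 13),
    "D": (1, 3, 4, 8, 9, 10, 11, 12, 13),
}


def classify_group(paralog: int) -> str:
    """Map a paralog number to its anterior/central/posterior group.

    Raises ``ValueError`` if ``paralog`` is outside 1..13.
    """
    if not 1 <= int(paralog) <= 13:
        raise ValueError(f"paralog must be in 1..13, got {paralog!r}")
    if paralog <= 3:
        return "anterior"
    if paralog <= 8:
        return "central"
    return "posterior"


@dataclass(frozen=True)
class HoxGene:
    """One HOX gene: cluster letter, paralog number, derived group label."""

    cluster: str
    paralog: int

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTERS:
            raise ValueError(f"cluster must be one of {CLUSTERS}, got {self.cluster!r}")
        classify_group(self.paralog)  # range check

    @property
    def symbol(self) -> str:
        return f"HOX{self.cluster}{self.paralog}"

    @property
    def group(self) -> str:
        return classify_group(self.paralog)


@dataclass(frozen=True)
class HoxCatalog:
    """Ordered, duplicate-free collection of :class:`HoxGene`."""

    genes: tuple[HoxGene, ...]
    _by_symbol: dict[str, HoxGene] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_symbol = {g.symbol: g for g in self.genes}
        if len(by_symbol) != len(self.genes):
            raise ValueError("duplicate gene symbols in catalog")
        object.__setattr__(self, "_by_symbol", by_symbol)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[HoxGene]:
        return iter(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._by_symbol

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def get(self, symbol: str) -> HoxGene:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"unknown gene symbol: {symbol!r}") from None

    def filter(self, *, cluster: str | None = None, group: str | None = None) -> "HoxCatalog":
        genes = tuple(
            g
            for g in self.genes
            if (cluster is None or g.cluster == cluster)
            and (group is None or g.group == group)
        )
        return HoxCatalog(genes)

    def to_tsv(self, path: str | Path) -> None:
        """Export as a two-column TSV (symbol, group) usable as a gene list."""
        with open(path, "w") as fh:
            fh.write("symbol\tgroup\n")
            for g in self.genes:
                fh.write(f"{g.symbol}\t{g.group}\n")


def build_catalog() -> HoxCatalog:
    """Return the fixed 39-gene human HOX catalog (idempotent)."""
    genes = tuple(
        HoxGene(cluster, paralog)
        for cluster in CLUSTERS
        for paralog in _CLUSTER_PARALOGS[cluster]
    )
    return HoxCatalog(genes)


def enumerate_pairs(catalog: HoxCatalog | Iterable[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs, each sorted lexicographically by symbol.

    For the 39-gene catalog this yields C(39,2) = 741 pairs.  Pair identity is
    canonical across the pipeline: every module refers to a pair as the
    lexicographically sorted 2-tuple of symbols.
    """
    symbols = catalog.symbols if isinstance(catalog, HoxCatalog) else list(catalog)
    return [tuple(sorted(p)) for p in itertools.combinations(symbols, 2)]


def pair_relation(
    pair: tuple[str, str], catalog: HoxCatalog | None = None
) -> dict[str, bool]:
    """Whether the two pair members share a cluster and/or a paralog group."""
    if catalog is None:
        catalog = build_catalog()
    a, b = (catalog.get(s) for s in pair)
    return {"same_cluster": a.cluster == b.cluster, "same_group": a.group == b.group}
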