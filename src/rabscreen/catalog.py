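"""Curated catalog of Rab GTPase genes and Rab-interacting genes.

The catalog groups genes into *Rab clusters*: a Rab (all of its isoforms)
together with its known guanine nucleotide exchange factors (GEFs), GTPase
activating proteins (GAPs) and effector proteins.  Six general-machinery
genes (the GDIs, the Rab escort proteins and the geranylgeranyl transferase
subunits) act on all Rabs and therefore belong to no individual cluster.

A bundled default catalog of 284 genes ships with the package.  Its Rab27
cluster membership is exact; the interactor membership of the remaining
clusters reproduces the published per-cluster role counts using synthetic
placeholder symbols (``SYNEF``/``SYNGEF``/``SYNGAP`` prefixes).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

ROLES = frozenset({"rab", "gef", "gap", "effector", "general_machinery"})

__all__ = [
    "GeneEntry", "Catalog", "RabCluster", "PlatformCatalog",
    "CatalogError", "load_catalog", "load_default_catalog",
    "default_absent_genes", "cluster_summary", "restrict_to_platform",
]


class CatalogError(ValueError):
    """Raised when a catalog file violates the catalog contract."""


@dataclass(frozen=True)
class GeneEntry:
    """One catalog gene: HUGO-style symbol, role, and cluster memberships."""

    symbol: str
    role: str
    clusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CatalogError(f"unknown role {self.role!r} for {self.symbol}")
        if self.role == "rab" and len(self.clusters) != 1:
            raise CatalogError(
                f"Rab gene {self.symbol} must belong to exactly one cluster")
        if self.role == "general_machinery" and self.clusters:
            raise CatalogError(
                f"general-machinery gene {self.symbol} must have no cluster")


@dataclass(frozen=True)
class RabCluster:
    """A Rab cluster: the Rab isoforms plus their GEFs, GAPs and effectors."""

    name: str
    members: tuple[str, ...]


@dataclass
class Catalog:
    """Validated, ordered collection of :class:`GeneEntry` objects."""

    entries: list[GeneEntry]
    _by_symbol: dict[str, GeneEntry] = field(init=False, repr=False)
    _clusters: dict[str, RabCluster] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise CatalogError("no entries")
        self._by_symbol = {}
        members: dict[str, list[str]] = {}
        for e in self.entries:
            if e.symbol in self._by_symbol:
                raise CatalogError(f"duplicate symbol {e.symbol!r}")
            self._by_symbol[e.symbol] = e
            for cl in e.clusters:
                members.setdefault(cl, []).append(e.symbol)
        self._clusters = {
            name: RabCluster(name, tuple(syms))
            for name, syms in members.items()
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> GeneEntry:
        return self._by_symbol[symbol]

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.entries)

    @property
    def cluster_names(self) -> tuple[str, ...]:
        return tuple(self._clusters)

    def cluster(self, name: str) -> RabCluster:
        try:
            return self._clusters[name]
        except KeyError:
            raise KeyError(f"unknown Rab cluster {name!r}") from None

    def genes_with_role(self, role: str) -> tuple[str, ...]:
        if role not in ROLES:
            raise CatalogError(f"unknown role {role!r}")
        return tuple(e.symbol for e in self.entries if e.role == role)


@dataclass
class PlatformCatalog:
    """A catalog restricted to the genes measurable on one array platform.

    Absent members are retained (and flagged) so that cluster bookkeeping
    can still report which published members were not measurable.
    """

    catalog: Catalog
    present: frozenset[str]

    @property
    def n_present(self) -> int:
        """Number of catalog genes measurable on the platform (``N``)."""
        return sum(1 for s in self.catalog.symbols if s in self.present)

    def is_present(self, symbol: str) -> bool:
        return symbol in self.present and symbol in self.catalog

    def present_symbols(self) -> tuple[str, ...]:
        return tuple(s for s in self.catalog.symbols if s in self.present)

    def absent_symbols(self) -> tuple[str, ...]:
        return tuple(s for s in self.catalog.symbols if s not in self.present)

    def cluster_present_members(self, name: str) -> tuple[str, ...]:
        cl = self.catalog.cluster(name)
        return tuple(s for s in cl.members if s in self.present)


def load_catalog(path: str | Path) -> Catalog:
    """Read a catalog TSV with columns ``symbol``, ``role``, ``clusters``.

    The ``clusters`` column is semicolon-separated and may be empty.
    Raises :class:`CatalogError` on duplicate symbols, unknown roles, a
    missing header, or an empty file.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
                "symbol", "role", "clusters"}.issubset(reader.fieldnames):
            raise CatalogError(
                f"{path}: expected header with symbol, role, clusters")
        entries = []
        for row in reader:
            clusters = tuple(
                c for c in (row["clusters"] or "").split(";") if c)
            entries.append(GeneEntry(row["symbol"], row["role"], clusters))
    if not entries:
        raise CatalogError(f"{path}: no entries")
    return Catalog(entries)


def load_default_catalog() -> Catalog:
    """Load the bundled 284-gene Rab/Rab-interactor catalog."""
    with resources.as_file(
            resources.files("rabscreen.data") / "catalog.tsv") as p:
        return load_catalog(p)


def default_absent_genes() -> frozenset[str]:
    """The 15 catalog genes absent from the primary expression platform."""
    text = (resources.files("rabscreen.data") / "u133_absent.txt").read_text()
    return frozenset(text.split())


def cluster_summary(catalog: Catalog, rab: str) -> dict[str, int]:
    """Count a cluster's members by role.

    Returns ``{"isoforms": ..., "gefs": ..., "gaps": ..., "effectors": ...}``.
    General-machinery genes never appear in clusters and are never counted.
    """
    cl = catalog.cluster(rab)  # raises KeyError for unknown clusters
    counts = {"isoforms": 0, "gefs": 0, "gaps": 0, "effectors": 0}
    key = {"rab": "isoforms", "gef": "gefs", "gap": "gaps",
           "effector": "effectors"}
    for sym in cl.members:
        counts[key[catalog[sym].role]] += 1
    return counts


def restrict_to_platform(
        catalog: Catalog, present_genes: Iterable[str]) -> PlatformCatalog:
    """Restrict a catalog to the genes measurable on a platform.

    ``present_genes`` may contain symbols outside the catalog; they are
    ignored.  An empty intersection is allowed (``n_present == 0``).
    """
    present = frozenset(present_genes) & frozenset(catalog.symbols)
    return PlatformCatalog(catalog=catalog, present=present)
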