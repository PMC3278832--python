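"""Group interactions into within-complex and between-complex clusters.

An interaction is *within-complex* when both genes belong to the same
protein complex, and *between-complex* for a specific unordered pair of
distinct complexes when one gene lies in each.  A cluster is the set of
interactions attached to one complex (within) or one complex pair
(between); only clusters with at least ``min_interactions`` members are
retained for population statistics.  Consensus complex catalogs overlap,
so one interaction may legitimately appear in several clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .interactions import InteractionSet

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCatalog:
    """Named gene sets: protein complexes or subsystem membership lists."""

    sets: dict[str, frozenset[str]]
    kind: str = "complexes"  # or "subsystem"

    def __post_init__(self) -> None:
        if self.kind not in ("complexes", "subsystem"):
            raise ValueError(f"unknown catalog kind: {self.kind!r}")
        self.sets = {
            name: frozenset(g.strip().upper() for g in members)
            for name, members in self.sets.items()
        }
        if self.kind == "complexes":
            small = [n for n, m in self.sets.items() if len(m) < 2]
            for name in small:
                logger.warning("dropping complex %r with < 2 members", name)
                del self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def membership(self) -> dict[str, frozenset[str]]:
        """Inverse index: gene -> frozenset of set names containing it."""
        index: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            for gene in members:
                index.setdefault(gene, set()).add(name)
        return {g: frozenset(s) for g, s in index.items()}


def read_gene_sets(path: str | Path, format: str = "gmt",
                   kind: str = "complexes") -> GeneSetCatalog:
    """Read a gene-set catalog.

    ``gmt``: tab-separated lines ``name<TAB>description<TAB>gene...``.
    ``two-column``: header-less TSV of ``set_name<TAB>gene`` rows.
    """
    sets: dict[str, set[str]] = {}
    if format == "gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets.setdefault(parts[0], set()).update(
                    g for g in parts[2:] if g.strip()
                )
    elif format == "two-column":
        table = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
        for name, grp in table.groupby("set"):
            sets.setdefault(str(name), set()).update(grp["gene"].astype(str))
    else:
        raise ValueError(f"unknown gene-set format: {format!r}")
    return GeneSetCatalog({k: frozenset(v) for k, v in sets.items()}, kind=kind)


@dataclass
class Cluster:
    """A labeled set of interactions attached to a complex or complex pair."""

    id: str
    kind: str  # "within" | "between"
    complexes: tuple[str, ...]
    interactions: pd.DataFrame

    @property
    def epsilons(self) -> np.ndarray:
        return self.interactions["epsilon"].to_numpy(dtype=float)

    @property
    def signs(self) -> np.ndarray:
        return np.where(self.epsilons > 0, 1, -1)

    @property
    def n_total(self) -> int:
        return len(self.interactions)

    @property
    def n_positive(self) -> int:
        return int((self.epsilons > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.epsilons < 0).sum())


@dataclass
class ClusterSet:
    """Retained clusters plus the retention threshold used to build them."""

    clusters: list[Cluster]
    min_interactions: int = 2

    def __post_init__(self) -> None:
        bad = [c.id for c in self.clusters if c.n_total < self.min_interactions]
        if bad:
            raise ValueError(f"clusters below min_interactions: {bad}")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self.clusters)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.n_total for c in self.clusters], dtype=int)

    @property
    def total_interactions(self) -> int:
        return int(self.sizes.sum()) if self.clusters else 0


def build_within_clusters(iset: InteractionSet, catalog: GeneSetCatalog,
                          min_interactions: int = 2) -> ClusterSet:
    """One cluster per complex holding interactions internal to it."""
    if catalog.kind != "complexes":
        raise ValueError("within clusters require a complexes catalog")
    mem = catalog.membership()
    empty: frozenset[str] = frozenset()
    by_complex: dict[str, list[int]] = {}
    a = iset.frame["gene_a"].to_numpy()
    b = iset.frame["gene_b"].to_numpy()
    for i in range(len(iset)):
        for name in mem.get(a[i], empty) & mem.get(b[i], empty):
            by_complex.setdefault(name, []).append(i)
    clusters = [
        Cluster(id=f"within:{name}", kind="within", complexes=(name,),
                interactions=iset.frame.iloc[idx].reset_index(drop=True))
        for name, idx in sorted(by_complex.items())
        if len(idx) >= min_interactions
    ]
    return ClusterSet(clusters, min_interactions=min_interactions)


def build_between_clusters(iset: InteractionSet, catalog: GeneSetCatalog,
                           min_interactions: int = 2,
                           exclude_within: bool = False) -> ClusterSet:
    """One cluster per unordered pair of distinct complexes.

    With ``exclude_within`` on, interactions whose two genes co-occur in
    any single complex are dropped from every between cluster.
    """
    if catalog.kind != "complexes":
        raise ValueError("between clusters require a complexes catalog")
    mem = catalog.membership()
    empty: frozenset[str] = frozenset()
    by_pair: dict[tuple[str, str], list[int]] = {}
    a = iset.frame["gene_a"].to_numpy()
    b = iset.frame["gene_b"].to_numpy()
    for i in range(len(iset)):
        in_a, in_b = mem.get(a[i], empty), mem.get(b[i], empty)
        if exclude_within and in_a & in_b:
            continue
        pairs = {
            (x, y) if x < y else (y, x)
            for x in in_a for y in in_b if x != y
        }
        for pair in pairs:
            by_pair.setdefault(pair, []).append(i)
    clusters = [
        Cluster(id=f"between:{x}|{y}", kind="between", complexes=(x, y),
                interactions=iset.frame.iloc[idx].reset_index(drop=True))
        for (x, y), idx in sorted(by_pair.items())
        if len(idx) >= min_interactions
    ]
    return ClusterSet(clusters, min_interactions=min_interactions)


def assign_subsystems(catalog: GeneSetCatalog,
                      subsystems: GeneSetCatalog) -> dict[str, tuple[str, ...]]:
    """Assign each complex to every subsystem that contains all its members.

    Returns a mapping complex name -> tuple of subsystem names (possibly
    empty, possibly more than one when the lists overlap).
    """
    if subsystems.kind != "subsystem":
        raise ValueError("assignment requires a subsystem catalog")
    return {
        name: tuple(sorted(
            s for s, genes in subsystems.sets.items() if members <= genes
        ))
        for name, members in catalog.sets.items()
    }


def write_cluster_table(clusters: ClusterSet, path: str | Path) -> None:
    """Write a TSV summary: one row per cluster with counts."""
    rows = [
        {
            "cluster_id": c.id,
            "kind": c.kind,
            "complexes": "|".join(c.complexes),
            "n_total": c.n_total,
            "n_positive": c.n_positive,
            "n_negative": c.n_negative,
        }
        for c in clusters
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
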