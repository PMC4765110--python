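"""Transitive closure of pairwise homology relations.

Orthology heuristics emit pairwise calls (A homologous-to B); clusters
are the connected components of that relation graph — if A relates to B
and B to C, all three belong to one cluster.  Implemented with
union–find (path compression + union by size), with deterministic
output: components are keyed and ordered by their lexicographically
smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .cluster_io import (
    Cluster,
    PairwiseRelation,
    SequenceRecord,
)


@dataclass(frozen=True)
class ClusterPartition:
    """Disjoint id-sets covering every id seen in the input relations."""

    components: tuple[frozenset, ...]

    @property
    def n_items(self) -> int:
        return sum(len(c) for c in self.components)

    def __len__(self) -> int:
        return len(self.components)

    def component_of(self, gene_id: str) -> frozenset | None:
        for comp in self.components:
            if gene_id in comp:
                return comp
        return None


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}
        self.size: dict[str, int] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def add(self, x: str) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.size[x] = 1

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def transitive_closure(
    relations: Iterable[PairwiseRelation],
) -> ClusterPartition:
    """Connected components of the pairwise relation graph."""
    uf = _UnionFind()
    for rel in relations:
        uf.add(rel.gene_a)
        uf.add(rel.gene_b)
        uf.union(rel.gene_a, rel.gene_b)
    groups: dict[str, set[str]] = {}
    for gene in uf.parent:
        groups.setdefault(uf.find(gene), set()).add(gene)
    components = sorted(
        (frozenset(g) for g in groups.values()), key=lambda c: min(c)
    )
    return ClusterPartition(components=tuple(components))


def pair_count(n_proteomes: int) -> int:
    """Number of pairwise all-against-all queries for N proteomes."""
    if n_proteomes < 2:
        raise ValueError(f"need at least 2 proteomes, got {n_proteomes}")
    return n_proteomes * (n_proteomes - 1) // 2


def partition_to_clusters(
    partition: ClusterPartition,
    proteome: Mapping[str, SequenceRecord],
    prefix: str = "cluster",
) -> list[Cluster]:
    """Materialize components as clusters using sequences from a proteome.

    Components containing ids missing from the proteome raise KeyError.
    """
    clusters = []
    for k, comp in enumerate(partition.components):
        members = [proteome[g] for g in sorted(comp)]
        clusters.append(Cluster(cluster_id=f"{prefix}_{k:05d}", members=members))
    return clusters


def write_membership_tsv(partition: ClusterPartition, path: str | Path) -> None:
    """Two-column TSV: cluster_id <TAB> gene_id, deterministic order."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene_id\n")
        for k, comp in enumerate(partition.components):
            for gene in sorted(comp):
                fh.write(f"cluster_{k:05d}\t{gene}\n")
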