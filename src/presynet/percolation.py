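"""k-clique percolation: overlapping community detection.

A k-clique is a complete subgraph on k nodes; two k-cliques are adjacent
when they share k-1 nodes.  A percolation cluster is the node union of a
maximal family of k-cliques connected through chains of adjacent
k-cliques.  Because any two k-subsets of one clique are linked by such a
chain, percolation can be computed on maximal cliques: k-cliques lie in
the same cluster exactly when their maximal cliques are connected through
pairwise overlaps of at least k-1 nodes.  That shortcut (the standard
CFinder-style bookkeeping) is what this module implements; tests verify
it against exhaustive k-subset enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

__all__ = [
    "ClusterSet",
    "enumerate_k_cliques",
    "percolation_clusters",
    "cluster_report",
    "write_clusters",
]


@dataclass
class ClusterSet:
    """Overlapping percolation clusters at one clique size k.

    Clusters are ordered by size descending, then by lexicographically
    smallest member, so reports are deterministic.
    """

    k: int
    clusters: list[frozenset] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def node_memberships(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.clusters):
            for n in c:
                out.setdefault(n, []).append(i)
        return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def enumerate_k_cliques(graph: nx.Graph, k: int) -> list[frozenset]:
    """All distinct complete k-node subgraphs.

    Derived from maximal cliques: every k-clique is a k-subset of some
    maximal clique.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    found: set[frozenset] = set()
    for mc in nx.find_cliques(graph):
        if len(mc) >= k:
            for sub in combinations(sorted(mc), k):
                found.add(frozenset(sub))
    return sorted(found, key=lambda c: tuple(sorted(c)))


def percolation_clusters(graph: nx.Graph, k: int) -> ClusterSet:
    """k-clique percolation clusters via maximal-clique overlaps.

    Maximal cliques of size >= k are grouped by union-find over pairwise
    overlaps of >= k-1 nodes; each group's node union is one cluster.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    maximal = [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= k]
    uf = _UnionFind(len(maximal))
    for i, j in combinations(range(len(maximal)), 2):
        if len(maximal[i] & maximal[j]) >= k - 1:
            uf.union(i, j)
    groups: dict[int, set] = {}
    for i, clique in enumerate(maximal):
        groups.setdefault(uf.find(i), set()).update(clique)
    clusters = [frozenset(g) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return ClusterSet(k=k, clusters=clusters)


def cluster_report(sets: list[ClusterSet]) -> dict:
    """Per-k counts, sizes, memberships, and within-k overlap matrices."""
    report: dict = {"per_k": {}, "summary_line": ""}
    parts = []
    for cs in sorted(sets, key=lambda s: -s.k):
        overlaps = [
            [len(a & b) for b in cs.clusters] for a in cs.clusters
        ]
        report["per_k"][str(cs.k)] = {
            "n_clusters": len(cs),
            "sizes": [len(c) for c in cs.clusters],
            "members": [sorted(c) for c in cs.clusters],
            "overlap_matrix": overlaps,
        }
        parts.append(f"{len(cs)} clusters with k={cs.k}")
    report["summary_line"] = " and ".join(parts)
    return report


def write_clusters(sets: list[ClusterSet], path: str | Path) -> None:
    """CFinder-like text: one line per cluster, 'k<TAB>id<TAB>members'."""
    with open(path, "w") as fh:
        for cs in sorted(sets, key=lambda s: -s.k):
            for i, cluster in enumerate(cs.clusters):
                members = ",".join(sorted(cluster))
                fh.write(f"{cs.k}\t{i}\t{members}\n")


def write_cluster_report(sets: list[ClusterSet], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(cluster_report(sets), indent=2, sort_keys=True) + "\n"
    )
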