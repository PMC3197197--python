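"""Seed-subnetwork expansion: connect seed proteins through at most two
intermediates from the filtered background network.

For every pair of seed proteins, all simple paths of at most
``max_intermediates + 1`` links whose interior nodes are all non-seed are
enumerated; the interior nodes become intermediates and every edge on a
qualifying path (plus direct seed-seed edges) enters the subnetwork.
Paths running through another seed are not counted as single paths — each
seed-seed segment stands on its own — so "intermediate" is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import networkx as nx

from .background import BackgroundNetwork
from .quant import SeedList

__all__ = ["Subnetwork", "expand_subnetwork", "subnetwork_summary"]


@dataclass
class Subnetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)
    seed_nodes: frozenset = frozenset()  # seeds appearing in the subnetwork
    intermediates: frozenset = frozenset()
    unmapped_seeds: frozenset = frozenset()  # seeds absent from the background

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role(self, node: str) -> str:
        return "seed" if node in self.seed_nodes else "intermediate"

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, self.graph.edges())):
                fh.write(f"{a}\tpp\t{b}\n")

    def write_node_roles(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\trole\n")
            for n in sorted(self.graph.nodes):
                fh.write(f"{n}\t{self.role(n)}\n")


def _seed_set(seeds: SeedList | Iterable[str]) -> set[str]:
    names = seeds.proteins if isinstance(seeds, SeedList) else set(seeds)
    return {s.strip().upper() for s in names}


def expand_subnetwork(
    seeds: SeedList | Iterable[str],
    net: BackgroundNetwork,
    max_intermediates: int = 2,
) -> Subnetwork:
    """Build the seed-plus-intermediates subnetwork.

    Enumerates, for every unordered pair of mapped seeds, every simple
    path of length <= ``max_intermediates + 1`` links whose interior nodes
    are all outside the seed list, and unions the edges of those paths.
    """
    seed_names = _seed_set(seeds)
    if not seed_names:
        raise ValueError("seed list is empty")
    if net.n_nodes == 0:
        raise ValueError("background network is empty")
    if max_intermediates < 0:
        raise ValueError("max_intermediates must be >= 0")

    g = net.graph
    mapped = sorted(seed_names & set(g.nodes))
    unmapped = frozenset(seed_names - set(g.nodes))

    sub = nx.Graph()
    intermediates: set[str] = set()
    max_links = max_intermediates + 1

    for a, b in combinations(mapped, 2):
        # bounded DFS from a to b; interior nodes must be non-seed
        stack: list[tuple[str, list[str]]] = [(a, [a])]
        while stack:
            node, path = stack.pop()
            for nxt in g.neighbors(node):
                if nxt == b:
                    if len(path) <= max_links:  # path edges = len(path)
                        full = path + [b]
                        sub.add_edges_from(zip(full[:-1], full[1:]))
                        intermediates.update(full[1:-1])
                    continue
                if nxt in seed_names or nxt in path:
                    continue
                if len(path) < max_links:  # room for another interior hop
                    stack.append((nxt, path + [nxt]))

    seed_in_sub = frozenset(n for n in sub.nodes if n in seed_names)
    return Subnetwork(
        graph=sub,
        seed_nodes=seed_in_sub,
        intermediates=frozenset(intermediates),
        unmapped_seeds=unmapped,
    )


def subnetwork_summary(sub: Subnetwork) -> dict:
    """Counts triple: connected seeds, intermediates, edges."""
    return {
        "n_seed_connected": len(sub.seed_nodes),
        "n_intermediates": len(sub.intermediates),
        "n_edges": sub.n_edges,
    }


def write_summary(sub: Subnetwork, path: str | Path) -> None:
    payload = subnetwork_summary(sub)
    payload["unmapped_seeds"] = sorted(sub.unmapped_seeds)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
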