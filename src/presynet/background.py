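"""Consolidation of binary interaction records into a simple background
network, and the literature filter that removes interactions whose only
support comes from high-throughput articles.

High-throughput screens inflate false-positive rates in interaction
databases; following the common curation heuristic, an article that
contributes five or more interactions is flagged high-throughput, and an
edge is dropped only when every article supporting it is so flagged.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx

from .synthetic import InteractionRecord

__all__ = ["BackgroundNetwork", "consolidate", "filter_articles"]


class ParseError(ValueError):
    pass


class BackgroundNetwork:
    """Simple undirected graph whose edges carry supporting article ids."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_articles(self, a: str, b: str) -> frozenset:
        return self.graph.edges[a, b]["articles"]

    def article_edge_counts(self) -> dict[str, int]:
        """Distinct edges supported per article (counted after dedup)."""
        counts: dict[str, int] = {}
        for _, _, data in self.graph.edges(data=True):
            for art in data["articles"]:
                counts[art] = counts.get(art, 0) + 1
        return counts

    def summary(self) -> dict:
        return {"n_nodes": self.n_nodes, "n_edges": self.n_edges}

    # -- serialization ------------------------------------------------------

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, self.graph.edges())):
                fh.write(f"{a}\tpp\t{b}\n")

    def write_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tarticles\n")
            for a, b in sorted(map(sorted, self.graph.edges())):
                arts = ",".join(sorted(self.graph.edges[a, b]["articles"]))
                fh.write(f"{a}\t{b}\t{arts}\n")

    @classmethod
    def read_edge_tsv(cls, path: str | Path) -> "BackgroundNetwork":
        g = nx.Graph()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                a, b, arts = line.rstrip("\n").split("\t")
                g.add_edge(a, b, articles=frozenset(arts.split(",")))
        return cls(g)


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def consolidate(records: Iterable[InteractionRecord]) -> BackgroundNetwork:
    """Merge interaction records into one simple undirected network.

    Symbols are whitespace-trimmed and upper-cased (case-insensitive
    identity); (A,B) and (B,A) records merge into one edge carrying the
    union of their supporting article ids; self-loops are dropped.
    """
    g = nx.Graph()
    for lineno, rec in enumerate(records, start=1):
        a, b = _norm(rec.node_a), _norm(rec.node_b)
        if not a or not b:
            raise ParseError(f"record {lineno}: empty symbol")
        if a == b:
            continue  # self-loop after normalization
        if g.has_edge(a, b):
            g.edges[a, b]["articles"] = g.edges[a, b]["articles"] | {rec.article_id}
            g.edges[a, b]["datasets"] = g.edges[a, b]["datasets"] | {rec.dataset}
        else:
            g.add_edge(a, b, articles=frozenset({rec.article_id}),
                       datasets=frozenset({rec.dataset}))
    return BackgroundNetwork(g)


def filter_articles(
    net: BackgroundNetwork, max_per_article: int = 4
) -> tuple[BackgroundNetwork, set[str]]:
    """Remove edges supported only by high-throughput articles.

    An article supporting more than ``max_per_article`` distinct edges
    (i.e. >= max_per_article + 1, the "five or more" rule at the default)
    is high-throughput.  An edge survives if at least one supporting
    article is not high-throughput.  Isolated nodes are removed.  Returns
    the filtered network and the set of excluded article ids.
    """
    counts = net.article_edge_counts()
    high = {a for a, c in counts.items() if c >= max_per_article + 1}
    g = nx.Graph()
    for a, b, data in net.graph.edges(data=True):
        if data["articles"] - high:
            g.add_edge(a, b, **data)
    return BackgroundNetwork(g), high


def write_summary(net: BackgroundNetwork, excluded: set[str], path: str | Path) -> None:
    payload = net.summary()
    payload["n_articles_excluded"] = len(excluded)
    payload["articles_excluded"] = sorted(excluded)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
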