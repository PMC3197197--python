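"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package: exhaustive subset
enumeration, all-pairs predicate checks, direct triangle counting, plain
dict-based aggregation.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd


# --- k-clique percolation ---------------------------------------------------

def brute_k_cliques(graph: nx.Graph, k: int) -> list[frozenset]:
    """All complete k-subsets, by checking every k-combination of nodes."""
    adj = {n: set(graph.neighbors(n)) for n in graph.nodes}
    out = []
    for combo in combinations(sorted(graph.nodes), k):
        if all(b in adj[a] for a, b in combinations(combo, 2)):
            out.append(frozenset(combo))
    return out


def brute_percolation(graph: nx.Graph, k: int) -> set[frozenset]:
    """Percolate exhaustively: BFS over the k-clique adjacency relation."""
    cliques = brute_k_cliques(graph, k)
    unvisited = set(range(len(cliques)))
    clusters = set()
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in list(unvisited):
                if len(cliques[i] & cliques[j]) == k - 1:
                    unvisited.discard(j)
                    comp.add(j)
                    frontier.append(j)
        nodes = frozenset().union(*(cliques[i] for i in comp))
        clusters.add(nodes)
    return clusters


# --- peak-pair matching ------------------------------------------------------

def brute_match_pairs(features: pd.DataFrame, rt_window=30.0, snr_min=10.0,
                      mz_tol=0.05) -> set[tuple[int, int]]:
    """All-pairs predicate check plus the documented greedy tie-break."""
    rows = list(features.itertuples())
    cand = []
    for fi in rows:
        for fj in rows:
            if fj.mz <= fi.mz:
                continue
            if (fi.protein_id, fi.peptide_seq, fi.charge, fi.label_sites) != (
                fj.protein_id, fj.peptide_seq, fj.charge, fj.label_sites
            ):
                continue
            if fi.snr <= snr_min or fj.snr <= snr_min:
                continue
            sep = fj.mz - fi.mz
            expected = 4.0 * fi.label_sites / fi.charge
            if abs(sep - expected) > mz_tol:
                continue
            if round(sep * fi.charge) not in (2, 4, 8):
                continue
            drt = abs(fj.rt_seconds - fi.rt_seconds)
            if drt > rt_window:
                continue
            cand.append((abs(sep - expected), drt, fi.Index, fj.Index))
    cand.sort()
    used, pairs = set(), set()
    for _, _, i, j in cand:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.add((i, j))
    return pairs


# --- aggregation -------------------------------------------------------------

def brute_protein_means(peptide_ratios: pd.DataFrame, bad_proteins: set[str]) -> dict:
    """Plain-dict mean of peptide ratios per (protein, experiment)."""
    sums: dict[tuple[str, str], list[float]] = {}
    for row in peptide_ratios.itertuples():
        if row.protein_id in bad_proteins:
            continue
        sums.setdefault((row.protein_id, row.experiment_id), []).append(row.ratio)
    return {key: sum(v) / len(v) for key, v in sums.items()}


# --- clustering coefficient --------------------------------------------------

def brute_avg_clustering(graph: nx.Graph) -> float:
    """Direct per-node triangle enumeration."""
    total = 0.0
    for n in graph.nodes:
        nbrs = list(graph.neighbors(n))
        d = len(nbrs)
        if d < 2:
            continue
        tri = sum(
            1 for a, b in combinations(nbrs, 2) if graph.has_edge(a, b)
        )
        total += tri / (d * (d - 1) / 2)
    return total / graph.number_of_nodes()


# --- subnetwork expansion ----------------------------------------------------

def brute_expansion(seed_names: set[str], graph: nx.Graph, max_links: int = 3):
    """Exhaustive simple-path enumeration between seed pairs with non-seed
    interiors, via networkx all_simple_paths with a cutoff."""
    edges: set[frozenset] = set()
    intermediates: set[str] = set()
    mapped = sorted(seed_names & set(graph.nodes))
    for a, b in combinations(mapped, 2):
        for path in nx.all_simple_paths(graph, a, b, cutoff=max_links):
            if any(n in seed_names for n in path[1:-1]):
                continue
            edges.update(frozenset(e) for e in zip(path[:-1], path[1:]))
            intermediates.update(path[1:-1])
    return edges, intermediates
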