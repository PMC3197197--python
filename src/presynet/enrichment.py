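"""Enrichment of seed-list neighbors around network intermediates, scored
with a pooled two-sample binomial proportions z-test.

For a node of background degree ``d`` with ``s`` neighbors in the seed
list, against a background holding ``S`` seed nodes among ``N`` total::

    p1 = s/d,  p0 = S/N,  pbar = (s+S)/(d+N)
    z  = (p1 - p0) / sqrt(pbar*(1-pbar)*(1/d + 1/N))

Nodes scoring above 2 are significant interactors with the seed list;
above 3, highly significant (strict inequalities at both boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .background import BackgroundNetwork
from .quant import SeedList

__all__ = [
    "EnrichmentScore",
    "intermediate_zscore",
    "classify_score",
    "score_intermediates",
    "tier_counts",
]

TIER_NONE = "none"
TIER_SIG = "significant"
TIER_HIGH = "highly_significant"


@dataclass(frozen=True)
class EnrichmentScore:
    node: str
    degree_background: int
    seed_neighbors: int
    z: float
    tier: str


def two_proportion_z(s: int, d: int, S: int, N: int) -> float:
    """Pooled two-sample proportions z; 0 when the variance term vanishes."""
    if d <= 0 or N <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= s <= d and 0 <= S <= N):
        raise ValueError("successes cannot exceed trials")
    p1, p0 = s / d, S / N
    pbar = (s + S) / (d + N)
    var = pbar * (1.0 - pbar) * (1.0 / d + 1.0 / N)
    if var == 0.0:
        return 0.0
    return (p1 - p0) / math.sqrt(var)


def intermediate_zscore(
    node: str,
    seeds: SeedList | Iterable[str],
    net: BackgroundNetwork,
    sig_threshold: float = 2.0,
    high_threshold: float = 3.0,
) -> EnrichmentScore:
    """Score one node's seed-neighbor enrichment against the background.

    The node's own seed membership is irrelevant (a node is never its own
    neighbor).  Raises ``KeyError`` for nodes absent from the network and
    ``ValueError`` for isolated nodes (degree 0, score undefined).
    """
    seed_names = seeds.proteins if isinstance(seeds, SeedList) else set(seeds)
    g = net.graph
    if node not in g:
        raise KeyError(f"node {node!r} not in background network")
    d = g.degree(node)
    if d == 0:
        raise ValueError(f"node {node!r} has degree 0; score undefined")
    s = sum(1 for nb in g.neighbors(node) if nb in seed_names)
    S = len(seed_names & set(g.nodes))
    N = g.number_of_nodes()
    z = two_proportion_z(s, d, S, N)
    return EnrichmentScore(
        node=node,
        degree_background=d,
        seed_neighbors=s,
        z=z,
        tier=classify_score(z, sig_threshold, high_threshold),
    )


def classify_score(z: float, sig_threshold: float = 2.0, high_threshold: float = 3.0) -> str:
    """Tier a z-score: strict > at both thresholds (2 -> none, 3 -> significant)."""
    if sig_threshold > high_threshold:
        raise ValueError("thresholds must be ordered")
    if z > high_threshold:
        return TIER_HIGH
    if z > sig_threshold:
        return TIER_SIG
    return TIER_NONE


def score_intermediates(
    intermediates: Iterable[str],
    seeds: SeedList | Iterable[str],
    net: BackgroundNetwork,
    sig_threshold: float = 2.0,
    high_threshold: float = 3.0,
) -> pd.DataFrame:
    """Score every intermediate; rows sorted by z descending, ties by name."""
    scores = [
        intermediate_zscore(n, seeds, net, sig_threshold, high_threshold)
        for n in intermediates
    ]
    df = pd.DataFrame(
        [
            dict(
                node=sc.node,
                degree=sc.degree_background,
                seed_neighbors=sc.seed_neighbors,
                z=sc.z,
                tier=sc.tier,
            )
            for sc in scores
        ],
        columns=["node", "degree", "seed_neighbors", "z", "tier"],
    )
    return df.sort_values(["z", "node"], ascending=[False, True], ignore_index=True)


def tier_counts(scored: pd.DataFrame) -> dict[str, int]:
    """Counts in the report format n(score>2), n(score>3)."""
    n_high = int((scored["tier"] == TIER_HIGH).sum())
    n_sig = int((scored["tier"] == TIER_SIG).sum())
    return {"n_score_gt2": n_sig + n_high, "n_score_gt3": n_high}


def write_scores(scored: pd.DataFrame, path: str | Path) -> None:
    scored.to_csv(path, sep="\t", index=False, float_format="%.6g")
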