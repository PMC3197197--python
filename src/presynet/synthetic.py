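"""Synthetic study generator: PPI background with article provenance and
differential-isotope-labeling feature tables with planted regulation.

Every downstream stage of the pipeline is exercised against data produced
here, so the generator records ground truth (which proteins are regulated,
which nodes form a planted dense module) alongside the raw-looking inputs.

The emulated study design: five labeling experiments on a presynaptic
protein fraction, alternating forward (control = light, treatment = heavy)
and reverse labeling, ~175 identified proteins of which ~143 are
quantifiable, ~30 truly regulated (mostly down).  The interaction
background is a degree-heterogeneous random graph whose edges carry
literature-article provenance, including a configured fraction of
high-throughput articles contributing five or more interactions each.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "InteractionRecord",
    "gen_background",
    "plant_module",
    "make_truth",
    "gen_quant_experiments",
    "write_feature_table",
    "read_feature_table",
    "write_interactions",
    "read_interactions",
    "write_truth",
    "read_truth",
]

FEATURE_COLUMNS = [
    "experiment_id",
    "direction",
    "protein_id",
    "peptide_seq",
    "label_sites",
    "charge",
    "channel",
    "mz",
    "rt_seconds",
    "intensity",
    "snr",
    "id_score",
]

# label mass increment per site (deuterated vs light tag), Daltons
LABEL_MASS_DA = 4.0

_AMINO = "ACDEFGHILMNPQSTVWY"  # K/R reserved for the tryptic terminus


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class InteractionRecord:
    """One literature-supported binary interaction: an edge plus provenance."""

    node_a: str
    node_b: str
    dataset: str
    article_id: str


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic study.

    regulated: protein id -> (direction 'up'|'down', true fold-change
    expressed as treatment/control). planted_module_nodes: nodes whose
    induced subgraph was densified to a known edge density.
    """

    regulated: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_module_nodes: frozenset = frozenset()
    rng_seed: int = 0

    @property
    def regulated_proteins(self) -> set[str]:
        return set(self.regulated)


@dataclass
class GeneratorConfig:
    n_proteins: int = 175
    n_quantified: int = 143
    n_regulated: int = 30
    n_down: int = 23
    n_experiments: int = 5
    labeling_schedule: tuple[str, ...] = (
        "forward",
        "reverse",
        "forward",
        "reverse",
        "forward",
    )
    noise_cv: float = 0.15
    min_abs_log2_fold: float = 1.0
    max_abs_log2_fold: float = 2.0
    min_peptides: int = 1
    max_peptides: int = 5
    frac_decoy: float = 0.05
    background_n_nodes: int = 3000
    background_mean_degree: float = 8.0
    n_articles: int = 400
    frac_highthroughput_articles: float = 0.2
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_down <= self.n_regulated <= self.n_quantified):
            raise ConfigError("need n_down <= n_regulated <= n_quantified")
        if self.n_quantified > self.n_proteins:
            raise ConfigError("n_quantified cannot exceed n_proteins")
        if self.n_proteins < 0 or self.n_experiments <= 0:
            raise ConfigError("counts must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if len(self.labeling_schedule) != self.n_experiments:
            raise ConfigError("labeling_schedule length must equal n_experiments")
        if any(d not in ("forward", "reverse") for d in self.labeling_schedule):
            raise ConfigError("labeling_schedule entries must be forward|reverse")
        if self.background_n_nodes < 0 or self.background_mean_degree < 0:
            raise ConfigError("background size parameters must be >= 0")
        if not (0 <= self.frac_highthroughput_articles <= 1):
            raise ConfigError("frac_highthroughput_articles must be in [0,1]")
        if not (0 <= self.frac_decoy <= 1):
            raise ConfigError("frac_decoy must be in [0,1]")
        if not (1 <= self.min_peptides <= self.max_peptides):
            raise ConfigError("peptide count range invalid")


def protein_ids(config: GeneratorConfig) -> list[str]:
    """Stable protein universe: P0001..P{n_proteins}."""
    return [f"P{i:04d}" for i in range(1, config.n_proteins + 1)]


# ---------------------------------------------------------------------------
# background network
# ---------------------------------------------------------------------------

def _degree_sequence(n: int, mean_degree: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-ish tailed degrees (geometric) with the requested mean, even sum."""
    if n == 0:
        return np.zeros(0, dtype=int)
    p = 1.0 / (1.0 + mean_degree)
    deg = rng.geometric(p, size=n) - 1  # support 0,1,2,... mean ~ mean_degree
    deg = np.minimum(deg, n - 1)
    if deg.sum() % 2:  # pairing requires an even number of stubs
        deg[int(rng.integers(n))] += 1 if deg.max() < n - 1 else -1
    return deg


def gen_background(config: GeneratorConfig) -> list[InteractionRecord]:
    """Generate provenance-annotated interaction records.

    Configuration-model-style pairing of degree stubs with rejection of
    self-loops and duplicate edges gives a simple undirected graph with
    heterogeneous degrees.  Edges are then apportioned to articles:
    high-throughput articles contribute >= 5 records each, low-throughput
    articles 1-4; extra low-throughput article ids are minted when the base
    pool cannot carry all edges without breaking those bounds, so the
    high-throughput flag matches the record counts exactly.  Surplus
    article slots become second supporting records on random edges,
    creating mixed-evidence edges for the literature filter.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.background_n_nodes
    if n == 0:
        return []

    prot = protein_ids(config)
    nodes = prot[:n] + [f"B{i:04d}" for i in range(1, n - min(n, len(prot)) + 1)]
    nodes = nodes[:n]

    deg = _degree_sequence(n, config.background_mean_degree, rng)
    stubs = np.repeat(np.arange(n), deg)
    rng.shuffle(stubs)
    edges: set[tuple[int, int]] = set()
    for i in range(0, len(stubs) - 1, 2):
        a, b = int(stubs[i]), int(stubs[i + 1])
        if a == b:
            continue
        e = (a, b) if a < b else (b, a)
        edges.add(e)
    edge_list = sorted(edges)
    rng.shuffle(edge_list)  # type: ignore[arg-type]

    # article pool: counts fixed up front so the >=5 / <=4 split is exact;
    # high-throughput slots are assigned to distinct edges first, so their
    # record counts hold exactly as long as enough edges exist
    n_ht = int(round(config.frac_highthroughput_articles * config.n_articles))
    n_ht = min(n_ht, len(edge_list) // 13)  # worst case 12 slots per article
    ht_ids = [f"ART-HT{i:04d}" for i in range(1, n_ht + 1)]
    lt_ids = [f"ART-LT{i:04d}" for i in range(1, config.n_articles - n_ht + 1)]
    ht_counts = rng.integers(5, 13, size=len(ht_ids))
    lt_counts = rng.integers(1, 5, size=len(lt_ids))

    slots: list[str] = []
    for aid, c in zip(ht_ids, ht_counts):
        slots.extend([aid] * int(c))
    for aid, c in zip(lt_ids, lt_counts):
        slots.extend([aid] * int(c))
    # mint extra low-throughput articles until every edge has a slot
    extra = 0
    while len(slots) < len(edge_list):
        extra += 1
        aid = f"ART-LX{extra:05d}"
        slots.extend([aid] * int(rng.integers(1, 5)))
    slots = slots[: max(len(edge_list), len(slots))]

    datasets = ["bind", "dip", "hprd", "intact", "mint", "presyn"]
    records: list[InteractionRecord] = []
    seen: set[tuple[int, int, str]] = set()
    n_edges = len(edge_list)
    for i, aid in enumerate(slots):
        e = edge_list[i] if i < n_edges else edge_list[int(rng.integers(n_edges))]
        if (e[0], e[1], aid) in seen:
            continue
        seen.add((e[0], e[1], aid))
        records.append(
            InteractionRecord(
                node_a=nodes[e[0]],
                node_b=nodes[e[1]],
                dataset=datasets[int(rng.integers(len(datasets)))],
                article_id=aid,
            )
        )
    return records


def plant_module(
    records: list[InteractionRecord],
    module_size: int,
    density: float,
    rng_seed: int,
    candidate_nodes: Sequence[str] | None = None,
    truth: PlantedTruth | None = None,
) -> tuple[list[InteractionRecord], PlantedTruth]:
    """Densify the induced subgraph on ``module_size`` chosen nodes.

    Edges are added until the induced edge count reaches
    ``ceil(density * C(module_size, 2))``; added records carry fresh
    low-throughput article ids (<= 4 records per article) so they survive
    the literature filter.  ``candidate_nodes`` restricts where the module
    may be planted (e.g. around seed proteins).
    """
    if not (0 <= density <= 1):
        raise ConfigError("density must be in [0, 1]")
    nodes = sorted({r.node_a for r in records} | {r.node_b for r in records})
    pool = sorted(set(candidate_nodes)) if candidate_nodes is not None else nodes
    pool = [p for p in pool if p in set(nodes)]
    if module_size > len(pool):
        raise ConfigError("module_size exceeds available node count")

    rng = np.random.default_rng(rng_seed)
    chosen = sorted(rng.choice(pool, size=module_size, replace=False).tolist())
    out = list(records)
    truth = truth or PlantedTruth(rng_seed=rng_seed)
    truth.planted_module_nodes = frozenset(chosen)
    if density == 0.0 or module_size < 2:
        return out, truth

    chosen_set = set(chosen)
    have = {
        frozenset((r.node_a, r.node_b))
        for r in records
        if r.node_a in chosen_set and r.node_b in chosen_set
    }
    target = math.ceil(density * module_size * (module_size - 1) / 2)
    missing = [
        (a, b)
        for i, a in enumerate(chosen)
        for b in chosen[i + 1 :]
        if frozenset((a, b)) not in have
    ]
    rng.shuffle(missing)  # type: ignore[arg-type]
    need = max(0, target - len(have))
    art_i, art_load = 0, 0
    for a, b in missing[:need]:
        if art_load == 0:
            art_i += 1
        out.append(
            InteractionRecord(a, b, "presyn", f"ART-PM{rng_seed % 10_000:04d}-{art_i:04d}")
        )
        art_load = (art_load + 1) % 4  # keep planted articles low-throughput
    return out, truth


# ---------------------------------------------------------------------------
# quantitative experiments
# ---------------------------------------------------------------------------

def make_truth(config: GeneratorConfig) -> PlantedTruth:
    """Choose the quantified subset and plant regulated proteins with
    |log2 fold| drawn in the configured band (down: fold < 1, up: fold > 1)."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    prot = protein_ids(config)
    quantified = sorted(rng.choice(prot, size=config.n_quantified, replace=False).tolist())
    regulated = sorted(
        rng.choice(quantified, size=config.n_regulated, replace=False).tolist()
    )
    truth = PlantedTruth(rng_seed=config.rng_seed)
    lo, hi = config.min_abs_log2_fold, config.max_abs_log2_fold
    for i, p in enumerate(regulated):
        mag = float(rng.uniform(lo, hi))
        if i < config.n_down:
            truth.regulated[p] = ("down", 2.0 ** (-mag))
        else:
            truth.regulated[p] = ("up", 2.0 ** mag)
    return truth


def _quantified_set(config: GeneratorConfig) -> list[str]:
    rng = np.random.default_rng(config.rng_seed)
    prot = protein_ids(config)
    return sorted(rng.choice(prot, size=config.n_quantified, replace=False).tolist())


def _random_peptide(rng: np.random.Generator, used: set[str]) -> tuple[str, int]:
    """Tryptic-style peptide: random body, K or R terminus.

    Returns (sequence, label_sites): a C-terminal K carries a second label
    site (its epsilon-amine) in addition to the always-labeled N-terminus.
    """
    while True:
        length = int(rng.integers(6, 15))
        body = "".join(_AMINO[int(i)] for i in rng.integers(len(_AMINO), size=length))
        term = "K" if rng.random() < 0.5 else "R"
        seq = body + term
        if seq not in used:
            used.add(seq)
            return seq, (2 if term == "K" else 1)


def gen_quant_experiments(
    config: GeneratorConfig, truth: PlantedTruth
) -> list[pd.DataFrame]:
    """Generate one feature table per experiment.

    Each quantified protein yields 1-5 peptides; each peptide yields a
    light/heavy feature pair whose intensity ratio equals the protein's
    true fold-change perturbed by multiplicative log-normal noise with the
    configured CV (mean-one correction applied).  Pair m/z separation is
    exactly 4*label_sites/charge; RT separation is within 30 s; S/N is
    drawn above 10.  Reverse experiments swap the treatment onto the light
    channel.  Identified-but-not-quantified proteins emit single-channel
    features or sub-60 identification scores.  Decoy features (fraction
    ``frac_decoy``) are unpaired low-S/N spurious peaks.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)
    quantified = _quantified_set(config)
    others = [p for p in protein_ids(config) if p not in set(quantified)]

    # per-peptide attributes fixed across experiments
    used_seqs: set[str] = set()
    peptides: dict[str, list[dict]] = {}
    for p in quantified:
        n_pep = int(rng.integers(config.min_peptides, config.max_peptides + 1))
        peps = []
        for _ in range(n_pep):
            seq, sites = _random_peptide(rng, used_seqs)
            peps.append(
                dict(
                    seq=seq,
                    sites=sites,
                    charge=int(rng.integers(1, 3)),
                    mz=float(rng.uniform(300, 1400)),
                    rt=float(rng.uniform(1200, 2700)),
                    score=float(rng.uniform(60, 150)),
                    base=float(rng.uniform(5e4, 5e6)),
                )
            )
        peptides[p] = peps
    unquant: dict[str, list[dict]] = {}
    for j, p in enumerate(others):
        seq, sites = _random_peptide(rng, used_seqs)
        mode = "lowscore" if j % 2 == 0 else "single"
        unquant[p] = [
            dict(
                seq=seq,
                sites=sites,
                charge=int(rng.integers(1, 3)),
                mz=float(rng.uniform(300, 1400)),
                rt=float(rng.uniform(1200, 2700)),
                score=float(rng.uniform(20, 59)) if mode == "lowscore" else float(rng.uniform(60, 150)),
                base=float(rng.uniform(5e4, 5e6)),
                mode=mode,
            )
        ]

    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))

    def noisy(x: float) -> float:
        if sigma == 0:
            return x
        return x * float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))

    tables: list[pd.DataFrame] = []
    for e, direction in enumerate(config.labeling_schedule, start=1):
        rows: list[dict] = []
        exp_id = f"exp{e}"

        def emit(p: str, pep: dict, channel: str, mz: float, rt: float,
                 intensity: float, snr: float, score: float) -> None:
            rows.append(
                dict(
                    experiment_id=exp_id,
                    direction=direction,
                    protein_id=p,
                    peptide_seq=pep["seq"],
                    label_sites=pep["sites"],
                    charge=pep["charge"],
                    channel=channel,
                    mz=mz,
                    rt_seconds=rt,
                    intensity=intensity,
                    snr=snr,
                    id_score=score,
                )
            )

        for p in quantified:
            fold = truth.regulated.get(p, ("none", 1.0))[1]
            for pep in peptides[p]:
                # one log-normal draw per pair: the observed intensity
                # ratio is the true fold-change times noise with the
                # configured CV (control channel held at the peptide base)
                saline = pep["base"]
                morphine = noisy(pep["base"] * fold)
                if direction == "forward":
                    light_i, heavy_i = saline, morphine
                else:
                    light_i, heavy_i = morphine, saline
                sep = LABEL_MASS_DA * pep["sites"] / pep["charge"]
                rt_l = pep["rt"] + float(rng.uniform(-5, 5))
                rt_h = rt_l + float(rng.uniform(-15, 15))
                snr_l = float(rng.uniform(11, 100))
                snr_h = float(rng.uniform(11, 100))
                emit(p, pep, "light", pep["mz"], rt_l, light_i, snr_l, pep["score"])
                emit(p, pep, "heavy", pep["mz"] + sep, rt_h, heavy_i, snr_h, pep["score"])
                if config.frac_decoy > 0 and rng.random() < config.frac_decoy:
                    emit(
                        p,
                        pep,
                        "light",
                        float(rng.uniform(300, 1400)),
                        float(rng.uniform(1200, 2700)),
                        noisy(pep["base"] * 0.1),
                        float(rng.uniform(2, 10)),
                        pep["score"],
                    )
        for p, peps in unquant.items():
            for pep in peps:
                saline = noisy(pep["base"])
                if pep["mode"] == "single":
                    emit(p, pep, "light", pep["mz"], pep["rt"], saline,
                         float(rng.uniform(11, 100)), pep["score"])
                else:
                    sep = LABEL_MASS_DA * pep["sites"] / pep["charge"]
                    emit(p, pep, "light", pep["mz"], pep["rt"], saline,
                         float(rng.uniform(11, 100)), pep["score"])
                    emit(p, pep, "heavy", pep["mz"] + sep,
                         pep["rt"] + float(rng.uniform(-15, 15)), noisy(pep["base"]),
                         float(rng.uniform(11, 100)), pep["score"])
        tables.append(pd.DataFrame(rows, columns=FEATURE_COLUMNS))
    return tables


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df[FEATURE_COLUMNS]


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tdataset\tarticle_id\n")
        for r in records:
            fh.write(f"{r.node_a}\t{r.node_b}\t{r.dataset}\t{r.article_id}\n")


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    records: list[InteractionRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node_a"):
            raise ValueError(f"{path}: line 1: expected interaction TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
            records.append(InteractionRecord(*parts))
    return records


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "regulated": {p: {"direction": d, "fold_change": f}
                      for p, (d, f) in sorted(truth.regulated.items())},
        "planted_module_nodes": sorted(truth.planted_module_nodes),
        "rng_seed": truth.rng_seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    truth = PlantedTruth(rng_seed=payload["rng_seed"])
    truth.regulated = {
        p: (v["direction"], v["fold_change"]) for p, v in payload["regulated"].items()
    }
    truth.planted_module_nodes = frozenset(payload["planted_module_nodes"])
    return truth
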