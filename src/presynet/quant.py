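"""Peak-pair matching, peptide ratios, protein ratio aggregation and
regulated-seed selection for differential isotope-labeling proteomics.

The label adds 4 Da per site (deuterated vs light succinic anhydride), so
a peptide with ``s`` label sites observed at charge ``z`` shows a light/
heavy m/z separation of ``4*s/z`` — mass differences of 2, 4 or 8 Da over
charges 1-2 and one or two sites.  A valid pair further requires retention
times within 30 s and both signal-to-noise ratios above 10.  Per-protein
treatment/control ratios are the arithmetic mean of peptide ratios, after
discarding proteins with any peptide identified below a Mascot-style score
of 60.  Seeds are proteins whose log-ratio deviates from the per-experiment
mean by at least 0.5 SD in two or more experiments, consistently in one
direction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PAIR_MASS_CLASSES_DA",
    "SeedList",
    "match_peak_pairs",
    "peptide_ratio",
    "pair_table_ratios",
    "aggregate_protein_ratios",
    "select_seeds",
    "write_ratio_matrix",
    "read_ratio_matrix",
    "write_seed_list",
    "read_seed_list",
]

# accepted pair mass-difference classes (separation * charge), Daltons
PAIR_MASS_CLASSES_DA = (2.0, 4.0, 8.0)

LABEL_MASS_DA = 4.0


class DataError(ValueError):
    """Malformed measurement data (non-positive intensity, missing protein)."""


@dataclass
class SeedList:
    """Regulated proteins with direction, plus the thresholds that chose them."""

    entries: dict[str, str] = field(default_factory=dict)  # protein -> up|down
    sd_multiple: float = 0.5
    min_consistent: int = 2

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))

    @property
    def proteins(self) -> set[str]:
        return set(self.entries)

    def direction_counts(self) -> dict[str, int]:
        counts = {"down": 0, "up": 0}
        for d in self.entries.values():
            counts[d] += 1
        return counts


def match_peak_pairs(
    features: pd.DataFrame,
    rt_window: float = 30.0,
    snr_min: float = 10.0,
    mz_tol: float = 0.05,
) -> pd.DataFrame:
    """Match light/heavy features of one experiment into peak pairs.

    A candidate pair is two features of the same protein, peptide, charge
    and label-site count whose m/z separation matches ``4*sites/charge``
    within ``mz_tol``, whose implied mass difference (separation*charge)
    falls in {2, 4, 8} Da, whose RT separation is <= ``rt_window`` and
    whose members both exceed ``snr_min``.  The lighter member is the
    light channel.  Each feature joins at most one pair: candidates are
    ranked by m/z agreement, then RT separation, then feature order, and
    matched greedily.

    Returns a DataFrame with one row per pair: light_idx/heavy_idx (row
    indices into ``features``), protein_id, peptide_seq, charge,
    label_sites, mass_diff_da, and ratio_heavy_over_light.
    """
    if rt_window < 0 or snr_min < 0 or mz_tol < 0:
        raise ValueError("rt_window, snr_min and mz_tol must be non-negative")
    if features.empty:
        return _empty_pairs()
    if features["experiment_id"].nunique() > 1:
        raise ValueError("match_peak_pairs expects features from a single experiment")
    if (features["intensity"] <= 0).any():
        raise DataError("non-positive intensity in feature table")

    candidates: list[tuple[float, float, int, int, float]] = []
    cols = ["mz", "rt_seconds", "snr", "intensity"]
    for (_, _, charge, sites), grp in features.groupby(
        ["protein_id", "peptide_seq", "charge", "label_sites"], sort=True
    ):
        ok = grp[grp["snr"] > snr_min]
        if len(ok) < 2:
            continue
        expected = LABEL_MASS_DA * sites / charge
        idx = ok.index.to_numpy()
        mz = ok["mz"].to_numpy()
        rt = ok["rt_seconds"].to_numpy()
        for i in range(len(idx)):
            for j in range(len(idx)):
                if mz[j] <= mz[i]:
                    continue  # feature i is the light member
                sep = mz[j] - mz[i]
                dev = abs(sep - expected)
                if dev > mz_tol:
                    continue
                if round(sep * charge) not in PAIR_MASS_CLASSES_DA:
                    continue
                drt = abs(rt[j] - rt[i])
                if drt > rt_window:
                    continue
                candidates.append((dev, drt, int(idx[i]), int(idx[j]), sep * charge))

    candidates.sort()
    used: set[int] = set()
    rows = []
    feat = features
    for dev, drt, li, hi, mass in candidates:
        if li in used or hi in used:
            continue
        used.update((li, hi))
        light, heavy = feat.loc[li], feat.loc[hi]
        rows.append(
            dict(
                light_idx=li,
                heavy_idx=hi,
                protein_id=light["protein_id"],
                peptide_seq=light["peptide_seq"],
                charge=int(light["charge"]),
                label_sites=int(light["label_sites"]),
                mass_diff_da=float(mass),
                rt_separation=float(drt),
                ratio_heavy_over_light=float(heavy["intensity"] / light["intensity"]),
            )
        )
    if not rows:
        return _empty_pairs()
    out = pd.DataFrame(rows)
    return out.sort_values(["light_idx", "heavy_idx"], ignore_index=True)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "light_idx",
            "heavy_idx",
            "protein_id",
            "peptide_seq",
            "charge",
            "label_sites",
            "mass_diff_da",
            "rt_separation",
            "ratio_heavy_over_light",
        ]
    )


def peptide_ratio(ratio_heavy_over_light: float, direction: str) -> float:
    """Express a pair's intensity ratio as treatment/control.

    Forward labeling puts the treatment sample on the heavy channel, so
    the ratio is heavy/light as observed; reverse labeling swaps the
    channels, so the observed heavy/light ratio is inverted.
    """
    if ratio_heavy_over_light <= 0 or not math.isfinite(ratio_heavy_over_light):
        raise DataError("pair ratio must be positive and finite")
    if direction == "forward":
        return ratio_heavy_over_light
    if direction == "reverse":
        return 1.0 / ratio_heavy_over_light
    raise ValueError(f"unknown labeling direction: {direction!r}")


def pair_table_ratios(pairs: pd.DataFrame, direction: str, experiment_id: str) -> pd.DataFrame:
    """Peptide-level treatment/control ratios for one experiment's pairs."""
    out = pairs[["protein_id", "peptide_seq"]].copy()
    out["experiment_id"] = experiment_id
    out["ratio"] = [
        peptide_ratio(r, direction) for r in pairs["ratio_heavy_over_light"]
    ]
    return out


def aggregate_protein_ratios(
    peptide_ratios: pd.DataFrame,
    features: pd.DataFrame,
    min_id_score: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average peptide ratios to per-protein, per-experiment ratios.

    Proteins with any feature identified below ``min_id_score`` are
    excluded entirely (the identification gate applies to every peptide of
    a protein).  Returns (ratio_matrix, n_peptides): both protein x
    experiment DataFrames, the first holding arithmetic-mean ratios (NaN
    where unquantified), the second the count of peptide ratios averaged.
    """
    if peptide_ratios.empty:
        return pd.DataFrame(), pd.DataFrame()
    if peptide_ratios["protein_id"].isna().any():
        raise DataError("peptide ratio with no protein assignment")
    low = features.loc[features["id_score"] < min_id_score, "protein_id"]
    gated = peptide_ratios[~peptide_ratios["protein_id"].isin(set(low))]
    ratios = (
        gated.groupby(["protein_id", "experiment_id"])["ratio"]
        .mean()
        .unstack("experiment_id")
        .sort_index()
    )
    counts = (
        gated.groupby(["protein_id", "experiment_id"])["ratio"]
        .size()
        .unstack("experiment_id", fill_value=0)
        .sort_index()
    )
    return ratios, counts


def select_seeds(
    matrix: pd.DataFrame,
    sd_multiple: float = 0.5,
    min_consistent: int = 2,
) -> SeedList:
    """Select consistently regulated proteins from a ratio matrix.

    Per experiment, the mean and sample SD of natural-log ratios are taken
    across all proteins quantified in that experiment.  A protein
    "changes" in an experiment when its log-ratio deviates from that mean
    by at least ``sd_multiple`` SDs; the change direction is the sign of
    the deviation.  A protein is selected when it changes in at least
    ``min_consistent`` experiments and every one of its changes has the
    same direction (any conflicting change disqualifies it).
    """
    if matrix.empty:
        raise DataError("ratio matrix is empty")
    if (matrix.stack() <= 0).any():
        raise DataError("ratio matrix contains non-positive ratios")

    log = np.log(matrix)
    changes: dict[str, list[int]] = {p: [] for p in matrix.index}
    for col in log.columns:
        x = log[col].dropna()
        if len(x) < 2:
            raise DataError(f"experiment {col!r} quantifies fewer than 2 proteins")
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            continue  # degenerate: no protein deviates
        dev = x - mean
        for p, d in dev[abs(dev) >= sd_multiple * sd].items():
            changes[p].append(1 if d > 0 else -1)

    seeds = SeedList(sd_multiple=sd_multiple, min_consistent=min_consistent)
    for p, signs in changes.items():
        if len(signs) >= min_consistent and len(set(signs)) == 1:
            seeds.entries[p] = "up" if signs[0] > 0 else "down"
    return seeds


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_ratio_matrix(
    ratios: pd.DataFrame, counts: pd.DataFrame, path: str | Path
) -> None:
    """TSV: protein_id, one ratio column per experiment, n_peptides."""
    out = ratios.copy()
    out["n_peptides"] = counts.sum(axis=1).astype(int)
    out.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g")


def read_ratio_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    return df.drop(columns=["n_peptides"], errors="ignore")


def write_seed_list(seeds: SeedList, path: str | Path) -> None:
    p = Path(path)
    with open(p, "w") as fh:
        fh.write("protein_id\tdirection\n")
        for prot in sorted(seeds.entries):
            fh.write(f"{prot}\t{seeds.entries[prot]}\n")
    sidecar = p.with_suffix(p.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"sd_multiple": seeds.sd_multiple, "min_consistent": seeds.min_consistent},
            sort_keys=True,
        )
        + "\n"
    )


def read_seed_list(path: str | Path) -> SeedList:
    p = Path(path)
    seeds = SeedList()
    with open(p) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                prot, direction = line.rstrip("\n").split("\t")
                seeds.entries[prot] = direction
    sidecar = p.with_suffix(p.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seeds.sd_multiple = meta["sd_multiple"]
        seeds.min_consistent = meta["min_consistent"]
    return seeds
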