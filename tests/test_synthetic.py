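"""Generator unit tests: determinism, provenance bookkeeping, planted
modules and the constructed peak-pair geometry."""

import math

import numpy as np
import pandas as pd
import pytest

from presynet.synthetic import (
    ConfigError,
    GeneratorConfig,
    gen_background,
    gen_quant_experiments,
    make_truth,
    plant_module,
    read_feature_table,
    read_interactions,
    write_feature_table,
    write_interactions,
)
from conftest import small_config


class TestBackground:
    def test_empty_graph(self):
        cfg = small_config(background_n_nodes=0)
        assert gen_background(cfg) == []

    def test_seeded_determinism(self):
        cfg = small_config(background_n_nodes=500, background_mean_degree=8, rng_seed=1)
        assert gen_background(cfg) == gen_background(cfg)

    def test_highthroughput_articles_by_brute_count(self):
        cfg = small_config(
            background_n_nodes=500,
            background_mean_degree=8,
            n_articles=100,
            frac_highthroughput_articles=0.2,
            rng_seed=3,
        )
        records = gen_background(cfg)
        counts: dict[str, int] = {}
        for r in records:
            counts[r.article_id] = counts.get(r.article_id, 0) + 1
        flagged = {a for a in counts if a.startswith("ART-HT")}
        big = {a for a, c in counts.items() if c >= 5}
        assert flagged == big and flagged  # exactly the flagged ones, and some exist

    def test_no_self_loops_and_every_edge_has_article(self):
        records = gen_background(small_config(rng_seed=2))
        assert all(r.node_a != r.node_b for r in records)
        assert all(r.article_id for r in records)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            small_config(noise_cv=-1).validate()
        with pytest.raises(ConfigError):
            small_config(n_down=10, n_regulated=5).validate()
        with pytest.raises(ConfigError):
            small_config(labeling_schedule=("forward",)).validate()


class TestPlantModule:
    def _induced_edges(self, records, nodes):
        nodes = set(nodes)
        return {
            frozenset((r.node_a, r.node_b))
            for r in records
            if r.node_a in nodes and r.node_b in nodes
        }

    def test_full_density_is_clique(self):
        records = gen_background(small_config(rng_seed=5))
        out, truth = plant_module(records, 5, 1.0, rng_seed=5)
        assert len(self._induced_edges(out, truth.planted_module_nodes)) == 10

    def test_zero_density_noop(self):
        records = gen_background(small_config(rng_seed=5))
        out, _ = plant_module(records, 5, 0.0, rng_seed=5)
        assert out == records

    def test_density_hits_requested_edge_count(self):
        records = gen_background(small_config(rng_seed=7))
        out, truth = plant_module(records, 8, 0.9, rng_seed=7)
        got = len(self._induced_edges(out, truth.planted_module_nodes))
        assert got == math.ceil(0.9 * 28)

    def test_planted_articles_stay_lowthroughput(self):
        records = gen_background(small_config(rng_seed=7))
        out, _ = plant_module(records, 10, 1.0, rng_seed=7)
        added = [r for r in out[len(records):]]
        counts: dict[str, int] = {}
        for r in added:
            counts[r.article_id] = counts.get(r.article_id, 0) + 1
        assert added and max(counts.values()) <= 4

    def test_oversized_module_rejected(self):
        records = gen_background(small_config(background_n_nodes=10, rng_seed=1))
        with pytest.raises(ConfigError):
            plant_module(records, 10_000, 0.5, rng_seed=1)


class TestQuantExperiments:
    def test_noiseless_ratio_exact(self):
        cfg = small_config(noise_cv=0.0)
        truth = make_truth(cfg)
        tables = gen_quant_experiments(cfg, truth)
        regulated = truth.regulated
        for table, direction in zip(tables, cfg.labeling_schedule):
            for (prot, pep), grp in table.groupby(["protein_id", "peptide_seq"]):
                if len(grp) != 2 or prot not in regulated:
                    continue
                light = grp[grp.channel == "light"]["intensity"].iloc[0]
                heavy = grp[grp.channel == "heavy"]["intensity"].iloc[0]
                fold = regulated[prot][1]
                observed = heavy / light if direction == "forward" else light / heavy
                assert observed == pytest.approx(fold, rel=1e-12)

    def test_pair_mz_separation_matches_label_mass(self):
        cfg = small_config(noise_cv=0.0)
        truth = make_truth(cfg)
        table = gen_quant_experiments(cfg, truth)[0]
        for _, grp in table.groupby(["protein_id", "peptide_seq"]):
            if len(grp) != 2:
                continue
            sep = grp["mz"].max() - grp["mz"].min()
            sites = grp["label_sites"].iloc[0]
            charge = grp["charge"].iloc[0]
            assert sep == pytest.approx(4.0 * sites / charge, abs=1e-9)
        # the classic two-site charge-2 case: 8 Da mass difference, 4 Th apart
        two_site = table[(table.label_sites == 2) & (table.charge == 2)]
        if not two_site.empty:
            g = two_site.groupby("peptide_seq")["mz"]
            assert np.allclose(g.max() - g.min(), 4.0)

    def test_determinism(self):
        cfg = small_config(rng_seed=9)
        truth = make_truth(cfg)
        t1 = gen_quant_experiments(cfg, truth)
        t2 = gen_quant_experiments(cfg, truth)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a, b)

    def test_schedule_mismatch_rejected(self):
        cfg = small_config()
        cfg.labeling_schedule = ("forward",)
        with pytest.raises(ConfigError):
            gen_quant_experiments(cfg, make_truth(small_config()))


class TestRoundTrips:
    def test_feature_table_csv(self, tmp_path, feature_table):
        p = tmp_path / "features.csv"
        write_feature_table(feature_table, p)
        back = read_feature_table(p)
        assert list(back.columns) == list(feature_table.columns)
        assert len(back) == len(feature_table)

    def test_interactions_tsv(self, tmp_path):
        records = gen_background(small_config(rng_seed=4))
        p = tmp_path / "net.tsv"
        write_interactions(records, p)
        assert read_interactions(p) == records
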