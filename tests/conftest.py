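import numpy as np
import pandas as pd
import pytest

from presynet.synthetic import GeneratorConfig, gen_quant_experiments, make_truth


def small_config(**kw) -> GeneratorConfig:
    """A scaled-down study configuration for fast unit tests."""
    defaults = dict(
        n_proteins=25,
        n_quantified=20,
        n_regulated=6,
        n_down=4,
        n_experiments=3,
        labeling_schedule=("forward", "reverse", "forward"),
        noise_cv=0.1,
        frac_decoy=0.0,
        background_n_nodes=200,
        background_mean_degree=6.0,
        n_articles=40,
        rng_seed=0,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture
def feature_table() -> pd.DataFrame:
    """One noiseless forward experiment from the small study."""
    cfg = small_config(noise_cv=0.0, n_experiments=1, labeling_schedule=("forward",))
    truth = make_truth(cfg)
    return gen_quant_experiments(cfg, truth)[0]


def make_feature(
    idx_mz, protein="P0001", peptide="ACDEFK", sites=2, charge=2,
    rt=1000.0, intensity=1e5, snr=25.0, score=80.0, experiment="exp1",
    direction="forward",
):
    return dict(
        experiment_id=experiment,
        direction=direction,
        protein_id=protein,
        peptide_seq=peptide,
        label_sites=sites,
        charge=charge,
        channel="light",
        mz=idx_mz,
        rt_seconds=rt,
        intensity=intensity,
        snr=snr,
        id_score=score,
    )


def features_df(rows) -> pd.DataFrame:
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
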