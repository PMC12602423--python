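"""Shared fixtures: a simulated T1 time series and a classifier trained on
it. Session-scoped because several test modules probe the same trained
model from different angles."""

import numpy as np
import pytest

import paddycd as p


@pytest.fixture(scope="session")
def t1_scenes():
    cfg = p.SceneConfig(
        height=128, width=128, initial_fractions=(0.55, 0.35, 0.10),
        patchiness=6.0, nodata_fraction=0.02, seed=11,
    )
    rates = p.TransitionRates(
        weed_expansion_prob=0.25, paddy_closure_prob=0.10,
        suppression_prob=0.0, seed=5,
    )
    return p.simulate_time_series(cfg, rates, steps_between=3)


@pytest.fixture(scope="session")
def t1_table(t1_scenes):
    counts = {(d, c): 1500 for d in ("34DAS", "41DAS") for c in (0, 1, 2)}
    return p.extract_training_samples(t1_scenes, counts, seed=2)


@pytest.fixture(scope="session")
def t1_model(t1_table):
    tr, va, _ = p.shuffle_split(t1_table, p.SplitSpec(seed=3))
    scaler = p.fit_scaler(tr)
    model = p.build_model(p.ModelSpec(n_classes=3), seed=4)
    return p.train(
        model, p.apply_scaler(tr, scaler), p.apply_scaler(va, scaler),
        p.TrainingConfig(seed=6), scaler=scaler,
    )


@pytest.fixture(scope="session")
def t1_test_table(t1_table):
    _, _, te = p.shuffle_split(t1_table, p.SplitSpec(seed=3))
    return te


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
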