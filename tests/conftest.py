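"""Shared fixtures: simulated corpora, trained forecasters, control campaigns.

Everything heavy is session-scoped and generated programmatically from
fixed seeds, so the suite is fully reproducible and needs no stored data.
Problem sizes follow the package's desk-scale study conditions (500
training cells, 100x50x64 scaled training for the reference model,
30x50x64 for the horizon family, 15x30x64 for the ablation trio).
"""

import numpy as np
import pytest

from optoctrl.baselines import (LinearForecaster, OdeKalmanForecaster,
                                PersistenceForecaster)
from optoctrl.control import ControlConfig
from optoctrl.datastore import fit_normalizer
from optoctrl.forecast import DeepForecaster, extract_samples
from optoctrl.objectives import sinewave_objective
from optoctrl.runner import ExperimentConfig, run_closed_loop, run_open_loop

HORIZON = 12          # 1 h reference horizon (exhaustive oracle tractable)
DURATION_H = 10.0     # closed-loop campaign length (3 h equilibration + 7 h)
T_CAMPAIGN = int(DURATION_H * 12)


@pytest.fixture(scope="session")
def train_corpus():
    cfg = ExperimentConfig(mode="open_loop", n_cells=500, duration_h=16.0,
                           rng_seed=10)
    return run_open_loop(cfg).dataset


@pytest.fixture(scope="session")
def val_corpus():
    cfg = ExperimentConfig(mode="open_loop", n_cells=150, duration_h=16.0,
                           rng_seed=11)
    return run_open_loop(cfg).dataset


@pytest.fixture(scope="session")
def normalizer(train_corpus):
    return fit_normalizer(list(train_corpus))


@pytest.fixture(scope="session")
def deep_model(train_corpus, normalizer):
    """Reference H=12 forecaster at the scaled training profile."""
    model = DeepForecaster(horizon=HORIZON, epochs=100, steps_per_epoch=50,
                           batch_size=64, rng_seed=0)
    return model.fit(train_corpus, normalizer=normalizer)


@pytest.fixture(scope="session")
def val_samples(val_corpus, normalizer):
    return extract_samples(val_corpus, normalizer, HORIZON, 1000,
                           np.random.default_rng(42))


@pytest.fixture(scope="session")
def train_samples(train_corpus, normalizer):
    return extract_samples(train_corpus, normalizer, HORIZON, 4000,
                           np.random.default_rng(7))


@pytest.fixture(scope="session")
def linear_model(train_samples):
    return LinearForecaster(horizon=HORIZON).fit(train_samples)


@pytest.fixture(scope="session")
def ode_model(train_corpus, normalizer):
    corpus = [normalizer.transform(train_corpus.values[i]) for i in range(100)]
    return OdeKalmanForecaster(horizon=HORIZON, n_fit_cells=30).fit(corpus)


@pytest.fixture(scope="session")
def persistence_model():
    return PersistenceForecaster(HORIZON)


@pytest.fixture(scope="session")
def ablation_models(train_corpus, normalizer):
    """Equal-profile trio: full features, fluorescence-blind, all-masked."""
    out = {}
    for name, mask in [("full", ()), ("fluo_blind", (1, 3)),
                       ("all_masked", tuple(range(8)))]:
        model = DeepForecaster(horizon=HORIZON, epochs=15, steps_per_epoch=30,
                               batch_size=64, rng_seed=0, mask_channels=mask)
        out[name] = model.fit(train_corpus, normalizer=normalizer)
    return out


@pytest.fixture(scope="session")
def horizon_models(train_corpus, normalizer):
    """Independently trained forecasters for 1-4 h horizons, equal profile."""
    out = {}
    for L in (1, 2, 3, 4):
        model = DeepForecaster(horizon=12 * L, epochs=30, steps_per_epoch=50,
                               batch_size=64, rng_seed=7)
        out[L] = model.fit(train_corpus, normalizer=normalizer)
    return out


@pytest.fixture(scope="session")
def sinewave_tracks():
    """40 identical sinewave objectives extending one horizon past the end."""
    return [sinewave_objective(400.0, 6.0, 0.0, 1200.0, T_CAMPAIGN + 48,
                               cell_id=f"c{i:03d}") for i in range(40)]


@pytest.fixture(scope="session")
def closedloop_controlled(deep_model, sinewave_tracks):
    cfg = ExperimentConfig(
        mode="closed_loop", n_cells=40, duration_h=DURATION_H,
        predictor="deep", rng_seed=5,
        control=ControlConfig(horizon_hours=1.0, rng_seed=5))
    return run_closed_loop(cfg, deep_model, sinewave_tracks)


@pytest.fixture(scope="session")
def closedloop_random(deep_model, sinewave_tracks):
    """Matched no-feedback condition: random-walk stimulations."""
    cfg = ExperimentConfig(
        mode="closed_loop", n_cells=40, duration_h=DURATION_H,
        predictor="none", rng_seed=5,
        control=ControlConfig(horizon_hours=1.0, rng_seed=5))
    return run_closed_loop(cfg, deep_model, sinewave_tracks)


@pytest.fixture(scope="session")
def closedloop_horizon(horizon_models, sinewave_tracks):
    """The same 25-cell cohort controlled by the four horizon lengths."""
    out = {}
    tracks = sinewave_tracks[:25]
    for L, model in horizon_models.items():
        cfg = ExperimentConfig(
            mode="closed_loop", n_cells=25, duration_h=DURATION_H,
            predictor="deep", rng_seed=50,
            control=ControlConfig(horizon_hours=float(L), rng_seed=50))
        out[L] = run_closed_loop(cfg, model, tracks)
    return out
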