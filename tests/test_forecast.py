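"""Encoder-decoder forecaster: contracts, training, ablation and horizon studies."""

import numpy as np
import pytest

from optoctrl.datastore import truncate_past
from optoctrl.forecast import (DeepForecaster, ForecastConfig, LatentVector,
                               evaluate, extract_samples)
from optoctrl.runner import ExperimentConfig, run_open_loop


@pytest.fixture(scope="module")
def tiny_corpus():
    cfg = ExperimentConfig(mode="open_loop", n_cells=30, duration_h=16.0,
                           rng_seed=99)
    return run_open_loop(cfg).dataset


def tiny_forecaster(**kw):
    base = dict(horizon=12, epochs=2, steps_per_epoch=10, batch_size=16,
                rng_seed=0)
    base.update(kw)
    return DeepForecaster(**base)


class TestConfig:
    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            ForecastConfig(horizon=10)

    def test_invalid_learning_rate(self):
        with pytest.raises(ValueError):
            ForecastConfig(learning_rate=0.0)

    def test_latent_vector_validation(self):
        with pytest.raises(ValueError):
            LatentVector(np.zeros(16))
        assert LatentVector(np.zeros(32)).z.shape == (32,)


class TestEncodeDecode:
    def test_latent_is_32d_for_any_past_length(self):
        model = tiny_forecaster()
        model._build(np.random.default_rng(0))
        rng = np.random.default_rng(1)
        for P in (1, 36, 144):
            z = model.encode(rng.random((8, P)))
            assert z.shape == (32,)
            assert np.all(np.isfinite(z))

    def test_encode_deterministic(self):
        model = tiny_forecaster()
        model._build(np.random.default_rng(0))
        past = np.random.default_rng(2).random((8, 40))
        np.testing.assert_array_equal(model.encode(past), model.encode(past))

    def test_encode_warns_on_unnormalized_input(self):
        model = tiny_forecaster()
        model._build(np.random.default_rng(0))
        with pytest.warns(UserWarning):
            model.encode(np.full((8, 40), 1500.0))

    def test_decode_output_length_matches_horizon(self):
        model = tiny_forecaster(horizon=24)
        model._build(np.random.default_rng(0))
        out = model.decode(np.zeros(32), np.zeros(24))
        assert out.shape == (24,)
        with pytest.raises(ValueError):
            model.decode(np.zeros(32), np.zeros(12))

    def test_batched_decode_equals_single_calls(self):
        model = tiny_forecaster()
        model._build(np.random.default_rng(0))
        rng = np.random.default_rng(3)
        z = rng.random(32)
        candidates = rng.integers(0, 2, (1000, 12)).astype(float)
        batched = model.decode(z, candidates)
        singles = np.stack([model.decode(z, c) for c in candidates])
        np.testing.assert_allclose(batched, singles, atol=1e-5)

    def test_wrong_channel_count_rejected(self):
        model = tiny_forecaster()
        model._build(np.random.default_rng(0))
        with pytest.raises(ValueError):
            model.encode(np.zeros((7, 40)))


class TestTraining:
    def test_loss_decreases_across_seeds(self, tiny_corpus):
        wins = 0
        for seed in range(10):
            model = tiny_forecaster(rng_seed=seed).fit(tiny_corpus)
            if model.loss_curve_[1] <= model.loss_curve_[0]:
                wins += 1
        assert wins >= 8

    def test_same_seed_identical_weights(self, tiny_corpus):
        a = tiny_forecaster(rng_seed=5).fit(tiny_corpus)
        b = tiny_forecaster(rng_seed=5).fit(tiny_corpus)
        for pa, pb in zip(a._params(), b._params()):
            np.testing.assert_array_equal(pa, pb)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            tiny_forecaster().fit([])

    def test_save_load_roundtrip(self, tiny_corpus, tmp_path):
        model = tiny_forecaster().fit(tiny_corpus)
        path = tmp_path / "model.npz"
        model.save(path)
        back = DeepForecaster.load(path)
        rng = np.random.default_rng(4)
        past = rng.random((8, 50))
        stims = rng.integers(0, 2, 12).astype(float)
        np.testing.assert_allclose(back.decode(back.encode(past), stims),
                                   model.decode(model.encode(past), stims),
                                   atol=1e-7)
        assert back.mask_channels == model.mask_channels

    def test_validation_curve_recorded(self, tiny_corpus):
        model = tiny_forecaster()
        model.fit(tiny_corpus, validation=tiny_corpus, n_val_samples=20)
        assert len(model.validation_curve_) == model.epochs


class TestEvaluate:
    def test_perfect_predictions_give_zero_percentiles(self, val_samples):
        class Oracle:
            horizon = 12

            def predict_samples(self, samples):
                return np.stack([s.future_fluo for s in samples])

        report = evaluate(Oracle(), val_samples[:50])
        assert all(v == 0.0 for v in report["percentiles"].values())
        np.testing.assert_allclose(report["rmse_cells"], 0.0)

    def test_error_grows_into_the_future(self, deep_model, val_samples):
        from scipy.stats import spearmanr
        report = evaluate(deep_model, val_samples)
        rho = spearmanr(np.arange(12), report["rmse_cells"]).statistic
        assert rho > 0

    def test_percentile_bands_ordered(self, deep_model, val_samples):
        pct = evaluate(deep_model, val_samples)["percentiles"]
        assert pct[25] <= pct[50] <= pct[75] <= pct[95]


class TestTrainedModelProperties:
    def test_latent_separates_expression_levels(self, deep_model, normalizer,
                                                train_corpus):
        from optoctrl.simcell import SimParams, simulate_chamber
        p = SimParams(cv_cell=0.0)
        low = normalizer.transform(
            simulate_chamber(p, np.zeros(60), 60, rng_seed=1))
        high = normalizer.transform(
            simulate_chamber(p, np.ones(60), 60, rng_seed=1))
        z_low = deep_model.encode(low[:, -40:])
        z_high = deep_model.encode(high[:, -40:])
        assert np.linalg.norm(z_low - z_high) > 0

    def test_learned_monotone_light_response(self, deep_model, normalizer):
        from optoctrl.simcell import SimParams, simulate_chamber
        p = SimParams(cv_cell=0.0)
        # mid-level past: alternating light
        trace = simulate_chamber(p, np.tile([1, 0], 30), 60, rng_seed=2)
        z = deep_model.encode(normalizer.transform(trace)[:, -40:])
        green = deep_model.decode(z, np.ones(12))
        red = deep_model.decode(z, np.zeros(12))
        assert green.mean() > red.mean()

    def test_beats_persistence_baseline(self, deep_model, persistence_model,
                                        val_samples):
        deep = evaluate(deep_model, val_samples)["median_rmse_time"]
        pers = evaluate(persistence_model, val_samples)["median_rmse_time"]
        assert deep < pers

    def test_truncation_error_plateaus_by_90_minutes(self, deep_model,
                                                     val_samples):
        med = {}
        for keep in (1, 18, 36):
            truncated = [truncate_past(s, keep) for s in val_samples]
            med[keep] = evaluate(deep_model, truncated)["median_rmse_time"]
        assert med[18] / med[36] <= 1.1   # plateau after 1.5 h of past
        assert med[1] > med[36]           # but a single point is not enough

    def test_truncation_at_full_length_is_identity(self, deep_model,
                                                   val_samples):
        subset = val_samples[:20]
        full = deep_model.predict_samples(subset)
        same = deep_model.predict_samples(
            [truncate_past(s, s.P) for s in subset])
        np.testing.assert_allclose(full, same, atol=1e-7)


class TestAblation:
    def test_feature_ablation_ordering(self, ablation_models, val_samples):
        """Removing fluorescence history degrades retrained models in order."""
        med = {name: evaluate(m, val_samples)["median_rmse_time"]
               for name, m in ablation_models.items()}
        assert med["full"] <= med["fluo_blind"] <= med["all_masked"]

    def test_all_masked_collapse(self, ablation_models, val_samples,
                                 train_samples):
        from optoctrl.evalmetrics import rmse_time
        med_all = evaluate(ablation_models["all_masked"],
                           val_samples)["median_rmse_time"]
        med_full = evaluate(ablation_models["full"],
                            val_samples)["median_rmse_time"]
        # collapse: far worse than the full model, but still bounded by the
        # unconditional-mean predictor (future stimulations remain visible
        # and are correlated with the cell's state)
        level = float(np.mean([s.future_fluo.mean()
                               for s in train_samples[:500]]))
        med_mean = float(np.median(
            [rmse_time(np.full(12, level), s.future_fluo)
             for s in val_samples]))
        assert med_all >= 1.5 * med_full
        assert med_all <= med_mean

    def test_masked_channels_ignored_at_inference(self, ablation_models,
                                                  val_samples):
        from optoctrl.datastore import mask_feature
        model = ablation_models["fluo_blind"]
        subset = val_samples[:20]
        masked = [mask_feature(s, [1, 3]) for s in subset]
        np.testing.assert_allclose(model.predict_samples(subset),
                                   model.predict_samples(masked), atol=1e-7)


class TestHorizonStudy:
    def test_error_curves_rise_along_every_horizon(self, horizon_models,
                                                   val_corpus, normalizer):
        from scipy.stats import spearmanr
        for L, model in horizon_models.items():
            samples = extract_samples(val_corpus, normalizer, 12 * L, 400,
                                      np.random.default_rng(1))
            curve = evaluate(model, samples)["rmse_cells"]
            assert spearmanr(np.arange(curve.size), curve).statistic > 0

    def test_output_dim_follows_horizon(self, horizon_models):
        for L, model in horizon_models.items():
            assert model.decoder_[-1].b.shape == (12 * L,)
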