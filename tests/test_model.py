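"""Training, grid search, MC-dropout prediction and model persistence."""

import numpy as np
import pytest

from weanest.nn.model import (
    ModelConfig,
    TrainedModel,
    build_model,
    grid_search,
    mc_dropout_predict,
    train,
)
from weanest.labeler import RobustScaleParams
from weanest.pipeline import prepare
from weanest.simulate import simulate_dataset


@pytest.fixture(scope="module")
def small_prepared():
    inds = simulate_dataset(40, seed=3)
    return prepare([i.series for i in inds], seed=3)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(lstm_units=8, dropout_rate=0.2, learning_rate=3e-3,
                       batch_size=8, max_epochs=15, patience=50, seed=5)


@pytest.fixture(scope="module")
def tiny_trained(small_prepared, tiny_cfg):
    net = build_model(tiny_cfg, small_prepared.train_batch.t_max)
    return train(net, small_prepared.train_batch, small_prepared.val_batch, tiny_cfg,
                 robust_scale=small_prepared.robust_scale)


class TestTrain:
    def test_loss_decreases_on_learnable_toy(self, small_prepared):
        cfg = ModelConfig(lstm_units=8, dropout_rate=0.0, learning_rate=3e-3,
                          batch_size=8, max_epochs=40, patience=1000, seed=1)
        net = build_model(cfg, small_prepared.train_batch.t_max)
        fitted = train(net, small_prepared.train_batch, small_prepared.val_batch, cfg)
        hist = fitted.history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_patience_zero_stops_at_first_non_improving_epoch(self, small_prepared):
        cfg = ModelConfig(lstm_units=4, learning_rate=0.5, batch_size=8,
                          max_epochs=100, patience=0, seed=0, dropout_rate=0.0)
        net = build_model(cfg, small_prepared.train_batch.t_max)
        fitted = train(net, small_prepared.train_batch, small_prepared.val_batch, cfg)
        val = fitted.history["val_loss"].to_numpy()
        # stopped exactly when the last epoch failed to improve on the best
        assert fitted.epochs_run < 100
        assert val[-1] >= val[:-1].min()
        assert all(val[i] < val[:i].min() for i in range(1, len(val) - 1)) or len(val) <= 2

    def test_epoch_cap_respected_under_defaults(self, tiny_trained):
        assert tiny_trained.epochs_run <= ModelConfig().max_epochs

    def test_history_records_every_epoch(self, tiny_trained, tiny_cfg):
        assert list(tiny_trained.history.columns) == ["epoch", "train_loss", "val_loss"]
        assert len(tiny_trained.history) == tiny_trained.epochs_run <= tiny_cfg.max_epochs

    def test_training_is_seed_deterministic(self, small_prepared, tiny_cfg):
        preds = []
        for _ in range(2):
            net = build_model(tiny_cfg, small_prepared.train_batch.t_max)
            m = train(net, small_prepared.train_batch, small_prepared.val_batch, tiny_cfg)
            preds.append(m.net.predict(small_prepared.test_batch))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestMCDropout:
    def test_zero_dropout_gives_exactly_zero_sd(self, small_prepared):
        cfg = ModelConfig(lstm_units=6, dropout_rate=0.0, max_epochs=2, seed=2)
        net = build_model(cfg, small_prepared.train_batch.t_max)
        m = train(net, small_prepared.train_batch, small_prepared.val_batch, cfg,
                  robust_scale=small_prepared.robust_scale)
        results = mc_dropout_predict(m, small_prepared.test_batch, n_passes=10, seed=0)
        assert all(r.sd_age == 0.0 for r in results)

    def test_seeded_runs_are_identical(self, tiny_trained, small_prepared):
        r1 = mc_dropout_predict(tiny_trained, small_prepared.test_batch, 20, seed=4)
        r2 = mc_dropout_predict(tiny_trained, small_prepared.test_batch, 20, seed=4)
        assert r1 == r2
        r3 = mc_dropout_predict(tiny_trained, small_prepared.test_batch, 20, seed=5)
        assert any(a.mean_age != b.mean_age for a, b in zip(r1, r3))

    def test_interval_brackets_mean_and_is_on_year_scale(self, tiny_trained,
                                                         small_prepared):
        results = mc_dropout_predict(tiny_trained, small_prepared.test_batch, 20, seed=0)
        rs = tiny_trained.robust_scale
        for r in results:
            assert r.interval[0] <= r.mean_age <= r.interval[1]
            assert r.sd_age >= 0.0
        # inverse robust scaling was applied: predictions on the years scale
        means = np.array([r.mean_age for r in results])
        assert means.std() == pytest.approx(
            np.std([(m - rs.median) / rs.iqr for m in means]) * rs.iqr, rel=1e-9
        )

    def test_sd_grows_with_dropout_rate(self, small_prepared):
        sds = []
        for rate in (0.1, 0.3, 0.5):
            cfg = ModelConfig(lstm_units=8, dropout_rate=rate, max_epochs=5, seed=7)
            net = build_model(cfg, small_prepared.train_batch.t_max)
            m = train(net, small_prepared.train_batch, small_prepared.val_batch, cfg,
                      robust_scale=small_prepared.robust_scale)
            res = mc_dropout_predict(m, small_prepared.test_batch, 30, seed=1)
            sds.append(np.mean([r.sd_age for r in res]))
        assert sds[0] < sds[1] < sds[2]


class TestGridSearch:
    def test_singleton_grid_returns_that_config(self, small_prepared):
        base = ModelConfig(lstm_units=4, max_epochs=3, seed=1)
        best, table = grid_search({"dropout_rate": [0.3]},
                                  small_prepared.train_batch,
                                  small_prepared.val_batch, base)
        assert best.dropout_rate == 0.3 and len(table) == 1

    def test_two_by_two_grid_sweeps_cartesian_product(self, small_prepared):
        base = ModelConfig(lstm_units=4, max_epochs=3, seed=1)
        best, table = grid_search(
            {"lstm_units": [4, 8], "learning_rate": [1e-3, 3e-3]},
            small_prepared.train_batch, small_prepared.val_batch, base,
        )
        assert len(table) == 4
        assert set(table.columns) >= {"lstm_units", "learning_rate", "val_rmse", "val_r2"}
        assert table["val_rmse"].min() == pytest.approx(
            table.loc[
                (table.lstm_units == best.lstm_units)
                & (table.learning_rate == best.learning_rate),
                "val_rmse",
            ].iloc[0]
        )

    def test_default_grid_contains_reported_optimum(self):
        from weanest.nn.model import DEFAULT_GRID

        assert 128 in DEFAULT_GRID["lstm_units"]
        assert 0.4 in DEFAULT_GRID["dropout_rate"]
        assert 0.001 in DEFAULT_GRID["learning_rate"]
        assert 8 in DEFAULT_GRID["batch_size"]


class TestPersistence:
    def test_bundle_round_trips_to_identical_predictions(self, tiny_trained,
                                                         small_prepared, tmp_path):
        tiny_trained.save(tmp_path / "bundle")
        loaded = TrainedModel.load(tmp_path / "bundle")
        p1 = tiny_trained.net.predict(small_prepared.test_batch)
        p2 = loaded.net.predict(small_prepared.test_batch)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        assert loaded.config == tiny_trained.config
        assert loaded.t_max == tiny_trained.t_max
        assert isinstance(loaded.robust_scale, RobustScaleParams)

    def test_prediction_rejects_oversized_sequences(self, tiny_trained, small_prepared):
        batch = small_prepared.test_batch
        big = type(batch)(
            tensor=np.concatenate([batch.tensor, np.zeros_like(batch.tensor)], axis=1),
            mask=np.concatenate([batch.mask, batch.mask], axis=1),
            sample_ids=batch.sample_ids,
        )
        with pytest.raises(ValueError, match="longer than the trained t_max"):
            mc_dropout_predict(tiny_trained, big, 2, seed=0)
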