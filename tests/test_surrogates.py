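"""Surrogate model/results objects: contracts, determinism, early stopping."""

import numpy as np
import pandas as pd
import pytest

from lvemu.doe import (
    STRESS_FEATURES,
    FeatureTable,
    SequenceDataset,
    build_sequences,
)
from lvemu.surrogates import (
    FFConfig,
    FeedForwardSurrogate,
    LSTMSurrogate,
    RNNConfig,
    SchemaMismatchError,
)


def _stress_table(y_fn, n_models=6, n_rows=40, seed=0):
    """Small synthetic stress-schema table with a controllable target."""
    rng = np.random.default_rng(seed)
    frames = []
    for m in range(n_models):
        params = rng.uniform(0.5, 1.5, size=4)
        X = rng.uniform(-1, 1, size=(n_rows, 3))
        frame = pd.DataFrame({
            "model_id": f"m{m:02d}",
            "a": params[0], "a_f": params[1], "a_s": params[2],
            "a_fs": params[3],
            "x": X[:, 0], "y": X[:, 1], "z": X[:, 2],
        })
        frame["sigma"] = y_fn(frame)
        frames.append(frame)
    return FeatureTable(frame=pd.concat(frames, ignore_index=True),
                        schema="stress_ff",
                        feature_columns=list(STRESS_FEATURES),
                        target_column="sigma")


CONST = 3.7


@pytest.fixture(scope="module")
def const_fit():
    """Surrogate trained on a constant target."""
    table = _stress_table(lambda f: np.full(len(f), CONST))
    train = table.subset([f"m{m:02d}" for m in range(4)])
    val = table.subset(["m04"])
    cfg = FFConfig(hidden_layers=2, neurons=16, epochs=3000, batch_size=8)
    return FeedForwardSurrogate(train, val, cfg).fit(), table


class TestFeedForward:
    def test_constant_target_learned(self, const_fit):
        res, table = const_fit
        assert res.validation_loss() * CONST < 1e-3 * CONST  # scaled units

    def test_constant_prediction_near_constant(self, const_fit):
        res, table = const_fit
        pred = res.predict(table.subset(["m05"]))
        assert np.abs(pred - CONST).max() < 1e-3 * CONST

    def test_deterministic_history(self):
        table = _stress_table(lambda f: f["x"] + f["a"])
        train = table.subset([f"m{m:02d}" for m in range(4)])
        val = table.subset(["m04"])
        cfg = FFConfig(hidden_layers=2, neurons=8, epochs=40, batch_size=32,
                       seed=5)
        r1 = FeedForwardSurrogate(train, val, cfg).fit()
        r2 = FeedForwardSurrogate(train, val, cfg).fit()
        assert np.array_equal(r1.history.train_loss, r2.history.train_loss)
        assert np.array_equal(r1.history.val_loss, r2.history.val_loss)
        for a, b in zip(r1.net.params, r2.net.params):
            assert np.array_equal(a, b)

    def test_best_epoch_definition(self, const_fit):
        res, _ = const_fit
        h = res.history
        assert h.best_epoch == int(np.argmin(h.val_loss))

    def test_early_stopping_restores_best_weights(self, const_fit):
        """Re-evaluating the returned weights on the validation set
        reproduces the stored minimum validation loss."""
        res, _ = const_fit
        assert res.validation_loss() == pytest.approx(
            float(res.history.val_loss[res.best_epoch]), abs=1e-7)

    def test_schema_mismatch_rejected(self, const_fit):
        res, table = const_fit
        other = FeatureTable(frame=table.frame.rename(
            columns={"sigma": "q"}).assign(sigma=0.0),
            schema="stress_cc", feature_columns=table.feature_columns,
            target_column="sigma")
        with pytest.raises(SchemaMismatchError):
            res.predict(other)
        with pytest.raises(SchemaMismatchError):
            res.predict(np.zeros((3, 5)))

    def test_row_permutation_permutes_predictions(self, const_fit):
        res, table = const_fit
        X = table.subset(["m05"]).X
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.allclose(res.predict(X)[perm], res.predict(X[perm]))

    def test_duplicated_row_duplicated_prediction(self, const_fit):
        res, table = const_fit
        X = table.subset(["m05"]).X[:4]
        X2 = np.vstack([X, X[1:2]])
        p = res.predict(X2)
        assert p[-1] == p[1]

    def test_config_depth_readings(self):
        assert FFConfig.stress().hidden_layers == 7
        assert FFConfig.stress(nine_layer_reading=False).hidden_layers == 3
        assert FFConfig.stress().neurons == 128
        assert FFConfig.stress().epochs == 2000
        assert FFConfig.pv().neurons == 20
        assert FFConfig.pv().epochs == 200
        assert FFConfig.pv().learning_rate == 1e-3

    def test_save_checkpoint(self, const_fit, tmp_path):
        res, _ = const_fit
        res.save(tmp_path / "ck")
        assert (tmp_path / "ck.npz").exists()
        sidecar = (tmp_path / "ck.json").read_text()
        assert "best_epoch" in sidecar and "stress_ff" in sidecar

    def test_summary_mentions_architecture(self, const_fit):
        res, _ = const_fit
        s = res.summary()
        assert "best epoch" in s and "MAE" in s


def _ar_sequence_dataset(n_models=6, n_rows=120, seed=0):
    """Order-1 autoregressive target with a property-dependent gain:
    learnable from the history, opaque to a history-blind model."""
    rng = np.random.default_rng(seed)
    frames = []
    for m in range(n_models):
        gain = rng.uniform(0.5, 1.5)
        u = rng.standard_normal(n_rows)
        y = np.zeros(n_rows)
        for t in range(1, n_rows):
            y[t] = 0.95 * y[t - 1] + gain * u[t - 1] * 0.1
        frame = pd.DataFrame({
            "model_id": f"m{m:02d}",
            "a": gain, "a_f": 1.0, "a_s": 1.0, "a_fs": 1.0,
            "x": u, "y": 0.0, "z": 0.0, "sigma": y,
        })
        frames.append(frame)
    table = FeatureTable(frame=pd.concat(frames, ignore_index=True),
                         schema="stress_ff",
                         feature_columns=list(STRESS_FEATURES),
                         target_column="sigma")
    return build_sequences(table, lookback=20), table


@pytest.fixture(scope="module")
def const_seq_fit():
    table = _stress_table(lambda f: np.full(len(f), CONST), n_rows=60)
    seq = build_sequences(table, lookback=10)
    cfg = RNNConfig(lstm_units=8, lookback=10, epochs=400, batch_size=32)
    return LSTMSurrogate(seq, cfg).fit(), seq


class TestLSTM:
    def test_constant_signal_learned(self, const_seq_fit):
        res, seq = const_seq_fit
        pred = res.predict(seq)
        assert np.abs(pred - CONST).max() < 1e-3 * CONST

    def test_best_epoch_tracks_training_loss(self, const_seq_fit):
        res, _ = const_seq_fit
        h = res.history
        assert h.val_loss is None
        assert res.best_epoch == int(np.argmin(h.train_loss))

    def test_prediction_count_equals_window_count(self, const_seq_fit):
        res, seq = const_seq_fit
        assert len(res.predict(seq)) == len(seq)

    def test_window_permutation_permutes_predictions(self, const_seq_fit):
        res, seq = const_seq_fit
        idx = np.random.default_rng(1).permutation(len(seq))
        assert np.allclose(res.predict(seq)[idx],
                           res.predict(seq.subset(idx)))

    def test_deterministic_weights(self):
        seq, _ = _ar_sequence_dataset()
        cfg = RNNConfig(lstm_units=8, lookback=20, epochs=10, batch_size=64,
                        seed=2)
        r1 = LSTMSurrogate(seq, cfg).fit()
        r2 = LSTMSurrogate(seq, cfg).fit()
        for a, b in zip(r1.net.params, r2.net.params):
            assert np.array_equal(a, b)

    def test_lookback_mismatch_rejected(self):
        seq, _ = _ar_sequence_dataset()
        with pytest.raises(SchemaMismatchError):
            LSTMSurrogate(seq, RNNConfig(lookback=10))

    def test_history_beats_history_blind_feedforward(self):
        """On an autoregressive signal the sequence model's teacher-forced
        MAE undercuts a feed-forward model that sees only the current-step
        properties: time history carries the signal."""
        seq, table = _ar_sequence_dataset(n_models=8, n_rows=150, seed=3)
        train_ids = [f"m{m:02d}" for m in range(6)]
        test_ids = ["m06", "m07"]
        n_train_rows = 6 * 150 - 20
        idx_train = np.arange(n_train_rows)
        idx_test = np.arange(n_train_rows + 20, len(seq))  # skip boundary
        rnn = LSTMSurrogate(
            seq.subset(idx_train),
            RNNConfig(lstm_units=16, lookback=20, epochs=60, batch_size=128),
        ).fit()
        rnn_mae = float(np.mean(np.abs(
            rnn.predict(seq.subset(idx_test)) - seq.target[idx_test])))
        ff = FeedForwardSurrogate(
            table.subset(train_ids), table.subset(train_ids[-1:]),
            FFConfig(hidden_layers=2, neurons=16, epochs=60, batch_size=128),
        ).fit()
        ff_mae = float(np.mean(np.abs(
            ff.predict(table.subset(test_ids)) - table.subset(test_ids).y)))
        assert rnn_mae < ff_mae

    def test_rollout_matches_lookback_contract(self):
        seq, _ = _ar_sequence_dataset()
        cfg = RNNConfig(lstm_units=8, lookback=20, epochs=5, batch_size=64)
        res = LSTMSurrogate(seq, cfg).fit()
        with pytest.raises(SchemaMismatchError):
            res.rollout(np.zeros(5), np.zeros((3, 7)))
        out = res.rollout(seq.history[0], seq.static[:4])
        assert out.shape == (4,)
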