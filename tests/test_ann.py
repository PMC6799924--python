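"""Tests for scaling, splitting and the quickprop MLP."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from planacast.ann import (
    MLPNetwork,
    TrainConfig,
    _encode_target,
    ann_predict,
    forward_select_features,
    quickprop_step,
    quickprop_train,
    scale_columns,
    search_architecture,
    split_dataset,
    train_ann,
)
from planacast.zonal import COUNT_COLUMN


class TestScaleColumns:
    def test_endpoints_and_midpoint(self):
        frame = pd.DataFrame({"x": [2.0, 4.0, 6.0], "y": [0.0, 5.0, 10.0]})
        scaled, scaler = scale_columns(frame, ["x"], "y")
        assert list(scaled["x"]) == [-1.0, 0.0, 1.0]
        assert list(scaled["y"]) == [-1.0, 0.0, 1.0]

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": rng.uniform(47, 71, 50),
                              "y": rng.uniform(0, 32, 50)})
        scaled, scaler = scale_columns(frame, ["x"], "y")
        back = scaler.inverse_col("x", scaled["x"].to_numpy())
        assert np.allclose(back, frame["x"], atol=1e-12)

    def test_constant_column_maps_to_zero(self):
        frame = pd.DataFrame({"x": [3.0, 3.0, 3.0], "y": [1.0, 2.0, 3.0]})
        scaled, _ = scale_columns(frame, ["x"], "y")
        assert np.all(scaled["x"] == 0.0)


class TestSplitDataset:
    @pytest.mark.parametrize("n,expected", [(282, (170, 56, 56)),
                                            (10, (6, 2, 2)),
                                            (5, (3, 1, 1))])
    def test_floor_rule_sizes(self, n, expected):
        ds = make_dataset({COUNT_COLUMN: np.arange(float(n))})
        train, test, val = split_dataset(ds, seed=1)
        assert (len(train), len(test), len(val)) == expected

    def test_partitions_disjoint_and_exhaustive(self):
        ds = make_dataset({COUNT_COLUMN: np.arange(97.0)})
        train, test, val = split_dataset(ds, seed=2)
        ids = [set(f[COUNT_COLUMN]) for f in (train, test, val)]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])
        assert ids[0] | ids[1] | ids[2] == set(np.arange(97.0))

    def test_seed_determinism(self):
        ds = make_dataset({COUNT_COLUMN: np.arange(50.0)})
        a = split_dataset(ds, seed=3)
        b = split_dataset(ds, seed=3)
        for fa, fb in zip(a, b):
            assert fa.equals(fb)

    def test_too_small_rejected(self):
        ds = make_dataset({COUNT_COLUMN: np.arange(4.0)})
        with pytest.raises(ValueError):
            split_dataset(ds)


class TestNetworkForward:
    def test_zero_network_outputs_half(self):
        net = MLPNetwork.zero(3, 4)
        x = np.random.default_rng(1).normal(size=(5, 3))
        assert np.allclose(net.forward(x), 0.5)

    def test_forward_deterministic(self):
        net = MLPNetwork.initialise(2, 3, seed=4)
        x = np.random.default_rng(2).normal(size=(4, 2))
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_json_round_trip(self):
        net = MLPNetwork.initialise(2, 3, seed=5)
        back = MLPNetwork.from_json(net.to_json())
        assert np.allclose(back.w1, net.w1) and np.allclose(back.w2, net.w2)
        assert back.b2 == net.b2


class TestQuickpropStep:
    def test_first_step_is_gradient_descent(self):
        g = np.array([0.5, -0.2])
        cfg = TrainConfig(learning_rate=0.1)
        assert np.allclose(quickprop_step(g, None, None, cfg), -0.1 * g)

    def test_secant_step_formula(self):
        cfg = TrainConfig(learning_rate=0.1, mu=1.75)
        prev_g, g = np.array([1.0]), np.array([0.5])
        prev_s = np.array([-0.1])
        # S/(S_prev - S) * prev = 0.5/0.5 * -0.1 = -0.1, below the cap
        assert np.allclose(quickprop_step(g, prev_g, prev_s, cfg), [-0.1])

    def test_step_capped_at_mu_times_previous(self):
        cfg = TrainConfig(learning_rate=0.1, mu=1.75)
        prev_g, g = np.array([1.0]), np.array([0.99])  # tiny denominator
        prev_s = np.array([-0.1])
        step = quickprop_step(g, prev_g, prev_s, cfg)
        assert abs(step[0]) <= 1.75 * 0.1 + 1e-15

    def test_zero_previous_step_falls_back(self):
        cfg = TrainConfig(learning_rate=0.1)
        g = np.array([0.4])
        step = quickprop_step(g, np.array([0.4]), np.array([0.0]), cfg)
        assert np.allclose(step, -0.04)


class TestQuickpropTraining:
    def test_first_epoch_matches_hand_gradients_1_1_1(self):
        """One quickprop epoch on a 1-1-1 net equals the hand-derived
        gradient-descent step for the MSE/2 loss."""
        net = MLPNetwork.initialise(1, 1, seed=7)
        w1, b1 = float(net.w1[0, 0]), float(net.b1[0])
        w2, b2 = float(net.w2[0]), float(net.b2)
        x, y = 0.3, 0.8
        lr = 0.1
        # hand-derived forward and backward pass
        h = 1 / (1 + np.exp(-(w1 * x + b1)))
        o = 1 / (1 + np.exp(-(w2 * h + b2)))
        d2 = (o - y) * o * (1 - o)
        g_w2, g_b2 = d2 * h, d2
        d1 = d2 * w2 * h * (1 - h)
        g_w1, g_b1 = d1 * x, d1
        cfg = TrainConfig(learning_rate=lr, max_epochs=1, patience=5)
        trained, hist = quickprop_train(
            net, (np.array([[x]]), np.array([y])), (np.array([[x]]), np.array([y])),
            cfg,
        )
        assert trained.w1[0, 0] == pytest.approx(w1 - lr * g_w1, rel=1e-12)
        assert trained.b1[0] == pytest.approx(b1 - lr * g_b1, rel=1e-12)
        assert trained.w2[0] == pytest.approx(w2 - lr * g_w2, rel=1e-12)
        assert trained.b2 == pytest.approx(b2 - lr * g_b2, rel=1e-12)

    def test_noiseless_linear_target_converges(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-1, 1, (60, 1))
        y01 = _encode_target(0.8 * x[:, 0])
        net = MLPNetwork.initialise(1, 4, seed=8)
        cfg = TrainConfig(max_epochs=500, patience=100, seed=8)
        trained, hist = quickprop_train(net, (x, y01), (x, y01), cfg)
        assert float(np.mean((trained.forward(x) - y01) ** 2)) < 1e-3

    def test_xor_pattern_fit(self):
        x = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
        y01 = np.array([0.1, 0.9, 0.9, 0.1])
        net = MLPNetwork.initialise(2, 4, seed=12)
        cfg = TrainConfig(max_epochs=3000, patience=3000, learning_rate=0.5, seed=12)
        trained, _ = quickprop_train(net, (x, y01), (x, y01), cfg)
        assert float(np.mean((trained.forward(x) - y01) ** 2)) < 0.05

    def test_training_determinism(self):
        frame = make_dataset(
            {COUNT_COLUMN: np.random.default_rng(1).uniform(0, 10, 40),
             "rh_T1": np.random.default_rng(2).uniform(47, 71, 40)}
        ).frame
        a = train_ann(frame, frame, ["rh_T1"], 3, TrainConfig(seed=13, max_epochs=50))
        b = train_ann(frame, frame, ["rh_T1"], 3, TrainConfig(seed=13, max_epochs=50))
        assert a.network.to_json() == b.network.to_json()
        assert a.history.equals(b.history)

    def test_returns_best_validation_weights(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (40, 1))
        y01 = _encode_target(0.5 * x[:, 0])
        net = MLPNetwork.initialise(1, 2, seed=3)
        cfg = TrainConfig(max_epochs=200, patience=10)
        trained, hist = quickprop_train(net, (x, y01), (x, y01), cfg)
        final_err = float(np.mean((trained.forward(x) - y01) ** 2))
        assert final_err <= hist["validation_mse"].min() + 1e-9


class TestAnnPredict:
    @staticmethod
    def fitted(n=60, seed=20):
        rng = np.random.default_rng(seed)
        t1 = rng.uniform(47, 71, n)
        counts = np.clip(12 - 0.3 * np.abs(t1 - 59) ** 1.5, 0, 32)
        frame = make_dataset({COUNT_COLUMN: counts, "rh_T1": t1}).frame
        return frame, train_ann(frame, frame, ["rh_T1"], 4,
                                TrainConfig(seed=seed, max_epochs=300))

    def test_predictions_track_noiseless_targets(self):
        frame, fitted = self.fitted()
        pred = fitted.predict_frame(frame)
        actual = frame[COUNT_COLUMN].to_numpy()
        assert float(np.mean(np.abs(pred - actual))) < 1.5

    def test_predictions_bounded_by_training_range(self):
        frame, fitted = self.fitted()
        wild = frame.copy()
        wild["rh_T1"] = np.linspace(0, 120, len(wild))  # far outside training
        pred = ann_predict(fitted.network, wild)
        lo = fitted.network.scaler.mins[COUNT_COLUMN]
        hi = fitted.network.scaler.maxs[COUNT_COLUMN]
        assert np.all(pred >= lo - 1e-9) and np.all(pred <= hi + 1e-9)

    def test_identical_inputs_identical_outputs(self):
        frame, fitted = self.fitted()
        assert np.array_equal(fitted.predict_frame(frame), fitted.predict_frame(frame))

    def test_feature_mismatch_rejected(self):
        frame, fitted = self.fitted()
        with pytest.raises(ValueError, match="missing feature"):
            ann_predict(fitted.network, frame.drop(columns=["rh_T1"]))


class TestArchitectureSearch:
    @staticmethod
    def frames(seed=30, n=80):
        rng = np.random.default_rng(seed)
        t1 = rng.uniform(47, 71, n)
        counts = np.clip(14 - 0.25 * np.abs(t1 - 58) ** 1.4 + rng.normal(0, 0.5, n),
                         0, 32)
        frame = make_dataset({COUNT_COLUMN: counts, "rh_T1": t1}).frame
        return frame.iloc[: n // 2], frame.iloc[n // 2 :]

    def test_singleton_range_returned(self):
        train, val = self.frames()
        cfg = TrainConfig(seed=30, max_epochs=50)
        best, table = search_architecture(train, val, ["rh_T1"], [4], cfg)
        assert best == 4 and len(table) == 1

    def test_winner_within_range_with_full_table(self):
        train, val = self.frames()
        cfg = TrainConfig(seed=31, max_epochs=60)
        best, table = search_architecture(train, val, ["rh_T1"], range(1, 5), cfg)
        assert best in range(1, 5)
        assert list(table["n_hidden"]) == [1, 2, 3, 4]
        assert table["fitness"].between(0, 1).all()

    def test_empty_range_rejected(self):
        train, val = self.frames()
        with pytest.raises(ValueError):
            search_architecture(train, val, ["rh_T1"], [], TrainConfig())


class TestForwardSelectFeatures:
    def test_informative_feature_recovered_among_noise(self):
        rng = np.random.default_rng(40)
        n = 120
        cols = {f"rh_T{k}": rng.uniform(47, 71, n) for k in (1, 2, 3)}
        counts = np.clip(12 - 0.4 * np.abs(cols["rh_T2"] - 59), 0, 32)
        frame = make_dataset({COUNT_COLUMN: counts, **cols}).frame
        train, val = frame.iloc[: n // 2], frame.iloc[n // 2 :]
        cfg = TrainConfig(seed=40, max_epochs=120)
        mask, trace = forward_select_features(
            train, val, ["rh_T1", "rh_T2", "rh_T3"], n_hidden=3, cfg=cfg
        )
        assert "rh_T2" in mask
        # exhaustive single-feature oracle agrees on the first pick
        firsts = trace[trace["with"].map(len) == 1]
        assert firsts.loc[firsts["fitness"].idxmax(), "candidate"] == "rh_T2"
        assert mask[0] == "rh_T2"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            forward_select_features(pd.DataFrame(), pd.DataFrame(), [])
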