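"""Quickprop-trained multilayer perceptron for count prediction.

A single-hidden-layer perceptron (k inputs, x hidden units, 1 output)
with logistic activations on both the hidden and output layers. Inputs
and the target are min-max scaled to [-1, 1]; because the logistic
output lives in (0, 1), the scaled target is mapped internally onto
[0.1, 0.9] — keeping it away from the activation's asymptotes — and
predictions are mapped back and inverse-scaled to counts, which also
bounds them by the training target range.

Training is full-batch quickprop: each weight's step is the secant
approximation to Newton's method on its own error slope,

    dw(t) = S(t) / (S(t-1) - S(t)) * dw(t-1),

with the step magnitude capped at ``mu`` times the previous step, and a
plain gradient-descent step as fallback whenever there is no previous
step or the secant denominator vanishes. Training keeps the weights
with the lowest validation error and stops early when validation error
fails to improve for ``patience`` epochs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .zonal import COUNT_COLUMN, LaggedDataset

log = logging.getLogger(__name__)

_Y_LO, _Y_HI = 0.1, 0.9  # logistic-space band used for the target


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 500
    learning_rate: float = 0.1
    mu: float = 1.75  # quickprop maximum growth factor
    weight_decay: float = 0.0
    patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 1:
            raise ValueError("mu must exceed 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class ColumnScaler:
    """Per-column min-max scaling to [-1, 1] with exact inverse."""

    columns: tuple[str, ...]
    mins: dict
    maxs: dict

    def transform_col(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.mins[name], self.maxs[name]
        if hi == lo:
            return np.zeros_like(np.asarray(values, dtype=float))
        return 2.0 * (np.asarray(values, dtype=float) - lo) / (hi - lo) - 1.0

    def inverse_col(self, name: str, scaled: np.ndarray) -> np.ndarray:
        lo, hi = self.mins[name], self.maxs[name]
        if hi == lo:
            return np.full_like(np.asarray(scaled, dtype=float), lo)
        return (np.asarray(scaled, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


def scale_columns(
    frame: pd.DataFrame, feature_cols: Sequence[str], target_col: str
) -> tuple[pd.DataFrame, ColumnScaler]:
    """Min-max scale features and target to [-1, 1].

    Constant columns map to 0 (with a warning); the scaler's inverse
    restores originals exactly.
    """
    cols = tuple([*feature_cols, target_col])
    mins, maxs = {}, {}
    out = frame.copy()
    for c in cols:
        v = frame[c].to_numpy(dtype=float)
        mins[c], maxs[c] = float(np.min(v)), float(np.max(v))
        if maxs[c] == mins[c]:
            log.warning("scale_columns: column %r is constant, mapped to 0", c)
    scaler = ColumnScaler(columns=cols, mins=mins, maxs=maxs)
    for c in cols:
        out[c] = scaler.transform_col(c, frame[c].to_numpy(dtype=float))
    return out, scaler


def split_dataset(
    ds: LaggedDataset | pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle split into (train, test, validation).

    Test and validation sizes are floor(fraction * n); training takes the
    remainder — so 282 rows split as 170/56/56. Partitions are disjoint
    and exhaustive.
    """
    frame = ds.frame if isinstance(ds, LaggedDataset) else ds
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(frame)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = int(np.floor(fractions[1] * n))
    n_val = int(np.floor(fractions[2] * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    return (
        frame.iloc[np.sort(train_idx)].reset_index(drop=True),
        frame.iloc[np.sort(test_idx)].reset_index(drop=True),
        frame.iloc[np.sort(val_idx)].reset_index(drop=True),
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


@dataclass
class MLPNetwork:
    """k-x-1 perceptron, logistic hidden and output units."""

    n_in: int
    n_hidden: int
    w1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    feature_cols: tuple[str, ...] = ()
    target_col: str = COUNT_COLUMN
    scaler: ColumnScaler | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def initialise(cls, n_in: int, n_hidden: int, seed: int = 0) -> "MLPNetwork":
        rng = np.random.default_rng(seed)
        return cls(
            n_in=n_in,
            n_hidden=n_hidden,
            w1=rng.uniform(-0.5, 0.5, (n_hidden, n_in)),
            b1=rng.uniform(-0.5, 0.5, n_hidden),
            w2=rng.uniform(-0.5, 0.5, n_hidden),
            b2=float(rng.uniform(-0.5, 0.5)),
        )

    @classmethod
    def zero(cls, n_in: int, n_hidden: int) -> "MLPNetwork":
        return cls(
            n_in=n_in, n_hidden=n_hidden,
            w1=np.zeros((n_hidden, n_in)), b1=np.zeros(n_hidden),
            w2=np.zeros(n_hidden), b2=0.0,
        )

    def forward(self, x_scaled: np.ndarray) -> np.ndarray:
        """Output in logistic (0, 1) space for scaled inputs (n, k)."""
        x = np.atleast_2d(np.asarray(x_scaled, dtype=float))
        h = _logistic(x @ self.w1.T + self.b1)
        return _logistic(h @ self.w2 + self.b2)

    def parameters(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, np.atleast_1d(np.float64(self.b2))]

    def to_json(self) -> str:
        d = {
            "type": "mlp",
            "architecture": [self.n_in, self.n_hidden, 1],
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "feature_cols": list(self.feature_cols),
            "target_col": self.target_col,
            "scaler": None
            if self.scaler is None
            else {"columns": list(self.scaler.columns),
                  "mins": self.scaler.mins, "maxs": self.scaler.maxs},
            "meta": self.meta,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MLPNetwork":
        d = json.loads(text)
        scaler = None
        if d.get("scaler"):
            scaler = ColumnScaler(
                columns=tuple(d["scaler"]["columns"]),
                mins=d["scaler"]["mins"], maxs=d["scaler"]["maxs"],
            )
        return cls(
            n_in=d["architecture"][0],
            n_hidden=d["architecture"][1],
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            feature_cols=tuple(d["feature_cols"]),
            target_col=d["target_col"],
            scaler=scaler,
            meta=d.get("meta", {}),
        )


def _grads(net: MLPNetwork, x: np.ndarray, y01: np.ndarray):
    """Mean-squared-error/2 loss and its gradients (full batch)."""
    n = len(x)
    z1 = x @ net.w1.T + net.b1
    h = _logistic(z1)
    z2 = h @ net.w2 + net.b2
    out = _logistic(z2)
    err = out - y01
    loss = float(err @ err) / (2 * n)
    d2 = err * out * (1 - out) / n  # (n,)
    g_w2 = d2 @ h
    g_b2 = float(d2.sum())
    d1 = np.outer(d2, net.w2) * h * (1 - h)  # (n, n_hidden)
    g_w1 = d1.T @ x
    g_b1 = d1.sum(axis=0)
    return loss, [g_w1, g_b1, g_w2, np.atleast_1d(np.float64(g_b2))]


def _encode_target(t_scaled: np.ndarray) -> np.ndarray:
    """Map [-1, 1]-scaled target onto the logistic band [0.1, 0.9]."""
    return _Y_LO + (_Y_HI - _Y_LO) * (np.asarray(t_scaled, dtype=float) + 1.0) / 2.0


def _decode_output(y01: np.ndarray) -> np.ndarray:
    frac = (np.asarray(y01, dtype=float) - _Y_LO) / (_Y_HI - _Y_LO)
    return 2.0 * np.clip(frac, 0.0, 1.0) - 1.0


def quickprop_step(
    grad: np.ndarray,
    prev_grad: np.ndarray | None,
    prev_step: np.ndarray | None,
    cfg: TrainConfig,
) -> np.ndarray:
    """One quickprop update for a parameter array.

    Falls back to a plain gradient-descent step (-lr * grad) elementwise
    wherever there is no usable previous step or the secant denominator
    vanishes; otherwise applies the secant step capped at mu times the
    previous step magnitude.
    """
    fallback = -cfg.learning_rate * grad
    if prev_grad is None or prev_step is None:
        return fallback
    denom = prev_grad - grad
    with np.errstate(divide="ignore", invalid="ignore"):
        step = grad / denom * prev_step
    cap = cfg.mu * np.abs(prev_step)
    step = np.clip(step, -cap, cap)
    invalid = ~np.isfinite(step) | (prev_step == 0.0)
    return np.where(invalid, fallback, step)


def quickprop_train(
    net: MLPNetwork,
    train_xy: tuple[np.ndarray, np.ndarray],
    validation_xy: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[MLPNetwork, pd.DataFrame]:
    """Train in place on scaled data; returns (best network, history).

    ``train_xy``/``validation_xy`` are (X_scaled, y01) with X in [-1, 1]
    and targets already encoded into the logistic band. The returned
    network carries the weights that minimised validation error; the
    history frame has one row per epoch (train and validation MSE).
    """
    x_tr, y_tr = train_xy
    x_va, y_va = validation_xy
    params = net.parameters()
    prev_grads = prev_steps = None
    best = [p.copy() for p in params]
    best_val = np.inf
    stall = 0
    hist = []
    for epoch in range(cfg.max_epochs):
        loss, grads = _grads(net, x_tr, y_tr)
        if cfg.weight_decay:
            grads = [g + cfg.weight_decay * p for g, p in zip(grads, params)]
        if loss > 1e6 or not np.isfinite(loss):
            raise RuntimeError(f"quickprop diverged at epoch {epoch}: loss={loss}")
        steps = [
            quickprop_step(g, None if prev_grads is None else prev_grads[i],
                           None if prev_steps is None else prev_steps[i], cfg)
            for i, g in enumerate(grads)
        ]
        for p, s in zip(params, steps):
            p += s
        net.b2 = float(params[3][0])
        prev_grads, prev_steps = grads, steps
        val_err = float(np.mean((net.forward(x_va) - y_va) ** 2)) if len(x_va) else loss
        hist.append({"epoch": epoch, "train_mse": loss, "validation_mse": val_err})
        if val_err < best_val - 1e-12:
            best_val = val_err
            best = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    net.w1, net.b1, net.w2 = best[0], best[1], best[2]
    net.b2 = float(best[3][0])
    return net, pd.DataFrame(hist)


@dataclass
class FittedANN:
    """A trained network bundled with its scaling and provenance."""

    network: MLPNetwork
    history: pd.DataFrame
    config: TrainConfig

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return ann_predict(self.network, frame)


def _prepare(frame: pd.DataFrame, scaler: ColumnScaler, features, target):
    x = np.column_stack(
        [scaler.transform_col(c, frame[c].to_numpy(dtype=float)) for c in features]
    )
    y = _encode_target(scaler.transform_col(target, frame[target].to_numpy(dtype=float)))
    return x, y


def train_ann(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    feature_cols: Sequence[str],
    n_hidden: int,
    cfg: TrainConfig = TrainConfig(),
    target_col: str = COUNT_COLUMN,
) -> FittedANN:
    """Scale on the training split, initialise and quickprop-train."""
    _, scaler = scale_columns(train, feature_cols, target_col)
    x_tr, y_tr = _prepare(train, scaler, feature_cols, target_col)
    x_va, y_va = _prepare(validation, scaler, feature_cols, target_col)
    net = MLPNetwork.initialise(len(feature_cols), n_hidden, seed=cfg.seed)
    net.feature_cols = tuple(feature_cols)
    net.target_col = target_col
    net.scaler = scaler
    net, hist = quickprop_train(net, (x_tr, y_tr), (x_va, y_va), cfg)
    net.meta = {"n_hidden": n_hidden, "seed": cfg.seed,
                "fitness_definition": "1/(1+validation_absolute_error)"}
    return FittedANN(network=net, history=hist, config=cfg)


def ann_predict(net: MLPNetwork, frame: pd.DataFrame) -> np.ndarray:
    """Predict counts on the original scale for a feature frame."""
    if net.scaler is None:
        raise ValueError("network has no scaling parameters")
    missing = [c for c in net.feature_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    x = np.column_stack(
        [net.scaler.transform_col(c, frame[c].to_numpy(dtype=float))
         for c in net.feature_cols]
    )
    y01 = net.forward(x)
    return net.scaler.inverse_col(net.target_col, _decode_output(y01))


def _fitness(fitted: FittedANN, validation: pd.DataFrame) -> float:
    """Fitness = 1 / (1 + validation absolute error), on the count scale."""
    pred = fitted.predict_frame(validation)
    actual = validation[fitted.network.target_col].to_numpy(dtype=float)
    return 1.0 / (1.0 + float(np.mean(np.abs(pred - actual))))


def search_architecture(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    feature_cols: Sequence[str],
    hidden_range: Sequence[int] = range(1, 11),
    cfg: TrainConfig = TrainConfig(),
) -> tuple[int, pd.DataFrame]:
    """Pick the hidden size with the best validation fitness.

    Ties (and near-ties within 1e-12) break toward the smaller size; the
    full fitness table is returned alongside the winner.
    """
    hidden_range = list(hidden_range)
    if not hidden_range:
        raise ValueError("empty hidden range")
    rows = []
    best_h, best_fit = None, -np.inf
    for h in sorted(hidden_range):
        sub_cfg = replace(cfg, seed=(cfg.seed * 1000003 + 97 * h) % (2**31 - 1))
        fitted = train_ann(train, validation, feature_cols, h, sub_cfg)
        fit = _fitness(fitted, validation)
        rows.append({"n_hidden": h, "fitness": fit})
        if fit > best_fit + 1e-12:
            best_h, best_fit = h, fit
    return best_h, pd.DataFrame(rows)


def forward_select_features(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    candidate_cols: Sequence[str],
    n_hidden: int = 6,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Greedy forward feature selection maximising validation fitness.

    Starts empty, repeatedly adds the candidate whose inclusion gives the
    best fitness, and stops when no addition improves on the incumbent.
    Returns the selected mask and the per-step trace.
    """
    if not candidate_cols:
        raise ValueError("need at least one candidate feature")
    selected: list[str] = []
    best_fit = -np.inf
    trace = []
    remaining = list(candidate_cols)
    while remaining:
        step_best, step_fit = None, -np.inf
        for c in remaining:
            feats = selected + [c]
            sub_cfg = replace(
                cfg,
                seed=(cfg.seed * 1000003 + sum(map(ord, "".join(feats)))) % (2**31 - 1),
            )
            fitted = train_ann(train, validation, feats, n_hidden, sub_cfg)
            fit = _fitness(fitted, validation)
            trace.append({"candidate": c, "with": tuple(feats), "fitness": fit})
            if fit > step_fit + 1e-12:
                step_best, step_fit = c, fit
        if step_best is None or step_fit <= best_fit + 1e-12:
            break
        selected.append(step_best)
        remaining.remove(step_best)
        best_fit = step_fit
    return tuple(selected), pd.DataFrame(trace)
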