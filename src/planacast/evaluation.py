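"""Model-quality metrics: absolute error, min-max accuracy, adjusted R2.

Absolute error is the mean |predicted - actual|. Min-max accuracy is the
mean of min/max ratios between actual and predicted, times 100 (100% is
perfect agreement); a pooled mode divides the smaller of the two vector
means by the larger instead. Model quality across methods is compared by
the adjusted R2 of regressing actual on predicted values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .zonal import COUNT_COLUMN

log = logging.getLogger(__name__)


def _check_pair(actual, predicted):
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size < 1:
        raise ValueError("empty vectors")
    return a, p


def absolute_error(actual, predicted) -> float:
    """Mean absolute difference between predicted and actual values."""
    a, p = _check_pair(actual, predicted)
    return float(np.mean(np.abs(p - a)))


def minmax_accuracy(actual, predicted, mode: str = "elementwise") -> float:
    """Min-max accuracy in percent, for non-negative vectors.

    ``elementwise`` (default): mean over rows of min(a, p)/max(a, p).
    Rows where both values are zero count as perfect agreement (ratio 1);
    rows where exactly one is zero are excluded with a warning.
    ``pooled``: min(mean a, mean p) / max(mean a, mean p).
    """
    a, p = _check_pair(actual, predicted)
    if np.any(a < 0) or np.any(p < 0):
        raise ValueError(
            "min-max accuracy requires non-negative values; shift or clamp first"
        )
    if mode == "pooled":
        ma, mp = float(a.mean()), float(p.mean())
        if max(ma, mp) == 0:
            return 100.0
        return 100.0 * min(ma, mp) / max(ma, mp)
    if mode != "elementwise":
        raise ValueError(f"unknown mode {mode!r}")
    lo = np.minimum(a, p)
    hi = np.maximum(a, p)
    both_zero = (a == 0) & (p == 0)
    one_zero = (hi > 0) & (lo == 0) & ((a == 0) | (p == 0))
    n_excluded = int(one_zero.sum())
    if n_excluded:
        log.warning(
            "minmax_accuracy: excluding %d rows where exactly one value is zero",
            n_excluded,
        )
    ratio = np.where(both_zero, 1.0, np.divide(lo, hi, where=hi > 0,
                                               out=np.ones_like(lo)))
    keep = ~one_zero
    if not keep.any():
        raise ValueError("no usable rows after excluding single-zero pairs")
    return 100.0 * float(ratio[keep].mean())


def adjusted_r2_actual_vs_predicted(actual, predicted, p_terms: int = 1) -> float:
    """Adjusted R2 of the OLS regression of actual on predicted.

    R2 comes from the simple (intercept + slope) regression of the actual
    values on the predictions; the adjustment uses ``p_terms`` — 1 for
    that simple regression, or the number of fitted terms when scoring a
    regression model's own design. Negative values are possible and mean
    the predictions carry no linear information.
    """
    a, p = _check_pair(actual, predicted)
    n = a.size
    if n <= p_terms + 1:
        raise ValueError(f"need n > p_terms + 1; n={n}, p_terms={p_terms}")
    if np.ptp(p) == 0:
        raise ValueError("zero variance in predicted values")
    X = np.column_stack([np.ones(n), p])
    beta, _, _, _ = np.linalg.lstsq(X, a, rcond=None)
    resid = a - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_terms - 1)


@dataclass
class EvalReport:
    """Per-split metrics for one fitted model."""

    splits: dict  # name -> {n, absolute_error, minmax_accuracy_percent, adjusted_r2}
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"splits": self.splits, "metadata": self.metadata},
                          sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"split": k, **v} for k, v in self.splits.items()]
        )


def evaluate_model(
    model,
    splits: Mapping[str, pd.DataFrame],
    p_terms: int | None = None,
    accuracy_mode: str = "elementwise",
    metadata: dict | None = None,
) -> EvalReport:
    """All three metrics on each split for any model with predict_frame.

    ``p_terms`` defaults to 1 (actual-on-predicted simple regression);
    pass the number of fitted terms to score a regression model against
    its own design size. Predictions are clamped at zero only inside the
    min-max accuracy (which requires non-negative values); the error and
    R2 metrics see the raw predictions.
    """
    if p_terms is None:
        p_terms = 1
    out: dict = {}
    for name, frame in splits.items():
        if len(frame) == 0:
            raise ValueError(f"empty split {name!r}")
        actual = frame[COUNT_COLUMN].to_numpy(dtype=float)
        pred = np.asarray(model.predict_frame(frame), dtype=float)
        out[name] = {
            "n": int(len(frame)),
            "absolute_error": absolute_error(actual, pred),
            "minmax_accuracy_percent": minmax_accuracy(
                np.maximum(actual, 0.0), np.maximum(pred, 0.0), mode=accuracy_mode
            ),
            "adjusted_r2": adjusted_r2_actual_vs_predicted(actual, pred, p_terms),
        }
    return EvalReport(splits=out, metadata={"accuracy_mode": accuracy_mode,
                                            "p_terms": p_terms,
                                            **(metadata or {})})
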