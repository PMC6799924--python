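"""Correlation screening and linear/polynomial regression on lagged RH.

Models are ordinary least squares of the block-level mean larval count
on lagged RH means: y = a + sum_k beta_k * term_k, where each term is a
lag at power 1 (linear) or powers 1 and 2 (polynomial). Stepwise
selection is the classical forward/backward procedure on partial-F
p-values; in degree-2 mode a lag enters or leaves with both of its
powers as a unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import LAG_INDICES
from .zonal import COUNT_COLUMN, LaggedDataset

log = logging.getLogger(__name__)

#: Significance thresholds and their star labels for the correlation table.
STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, label in STAR_LEVELS:
        if p <= level:
            return label
    return ""


@dataclass
class CorrelationTable:
    """Per (cycle, lag) Pearson correlations across blocks, with stars."""

    frame: pd.DataFrame  # columns: cycle, lag, r, p_value, n, stars
    log_entries: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)


def pearson_by_cycle(ds: LaggedDataset, min_pairs: int = 3) -> CorrelationTable:
    """Pearson r between count and each lagged RH, per census cycle.

    Pools blocks within each cycle (one row of the census layout per
    cycle); two-sided p-values from the t distribution, uncorrected.
    Zero-variance cells are omitted with a log entry.
    """
    rows, log_entries = [], []
    for cycle, grp in ds.frame.groupby("cycle_index"):
        for k in LAG_INDICES:
            sub = grp[[COUNT_COLUMN, f"rh_T{k}"]].dropna()
            n = len(sub)
            if n < min_pairs:
                log_entries.append(f"cycle {cycle} T{k}: only {n} pairs, skipped")
                continue
            x = sub[f"rh_T{k}"].to_numpy()
            y = sub[COUNT_COLUMN].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                log_entries.append(f"cycle {cycle} T{k}: zero variance, skipped")
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"cycle": cycle, "lag": k, "r": r, "p_value": p, "n": n,
                 "stars": _stars(p)}
            )
    return CorrelationTable(
        frame=pd.DataFrame(rows, columns=["cycle", "lag", "r", "p_value", "n", "stars"]),
        log_entries=log_entries,
    )


@dataclass
class RegressionModel:
    """OLS fit of count on lagged RH terms.

    ``terms`` lists (lag, power) in design order; ``coefficients`` holds
    one slope per term; prediction is exact arithmetic on the stored
    numbers (no clamping — like the published block-level models,
    negative predictions are possible).
    """

    intercept: float
    terms: tuple[tuple[int, int], ...]
    coefficients: tuple[float, ...]
    degree: int = 1
    fit_stats: dict = field(default_factory=dict)
    selection_trace: list[dict] = field(default_factory=list)

    def predict(self, rh_values: Mapping[int, float]) -> float:
        out = self.intercept
        for (lag, power), beta in zip(self.terms, self.coefficients):
            if lag not in rh_values:
                raise KeyError(f"missing RH value for lag T{lag}")
            out += beta * rh_values[lag] ** power
        return out

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.full(len(frame), self.intercept, dtype=float)
        for (lag, power), beta in zip(self.terms, self.coefficients):
            out += beta * frame[f"rh_T{lag}"].to_numpy() ** power
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "regression",
                "intercept": self.intercept,
                "terms": [list(t) for t in self.terms],
                "coefficients": list(self.coefficients),
                "degree": self.degree,
                "fit_stats": self.fit_stats,
                "selection_trace": self.selection_trace,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegressionModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            terms=tuple(tuple(t) for t in d["terms"]),
            coefficients=tuple(d["coefficients"]),
            degree=d["degree"],
            fit_stats=d.get("fit_stats", {}),
            selection_trace=d.get("selection_trace", []),
        )


def _terms_for(lags: Sequence[int], degree: int) -> tuple[tuple[int, int], ...]:
    terms: list[tuple[int, int]] = []
    for lag in lags:
        for power in range(1, degree + 1):
            terms.append((lag, power))
    return tuple(terms)


def _design(frame: pd.DataFrame, terms: Sequence[tuple[int, int]]) -> np.ndarray:
    cols = [np.ones(len(frame))]
    for lag, power in terms:
        cols.append(frame[f"rh_T{lag}"].to_numpy(dtype=float) ** power)
    return np.column_stack(cols)


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with RSS; raises on rank deficiency."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: rank {rank} < {X.shape[1]} columns "
            "(collinear terms)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_regression(
    ds: LaggedDataset, lags: Sequence[int], degree: int = 1
) -> RegressionModel:
    """OLS of count on the chosen lags at powers 1..degree."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    terms = _terms_for(lags, degree)
    frame = ds.frame.dropna(subset=[COUNT_COLUMN, *[f"rh_T{l}" for l in lags]])
    n, p = len(frame), len(terms)
    if n <= p + 1:
        raise ValueError(f"need n > terms + 1; n={n}, terms={p}")
    y = frame[COUNT_COLUMN].to_numpy(dtype=float)
    X = _design(frame, terms)
    try:
        beta, rss = _ols(y, X)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"{exc}; terms={terms}") from exc
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return RegressionModel(
        intercept=float(beta[0]),
        terms=terms,
        coefficients=tuple(float(b) for b in beta[1:]),
        degree=degree,
        fit_stats={"n": n, "r2": r2, "adjusted_r2": adj, "rss": rss},
    )


def _partial_f_p(y, frame, base_terms, full_terms) -> float:
    """p-value of the F test comparing nested OLS term sets."""
    n = len(frame)
    X_full = _design(frame, full_terms)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        return 1.0  # collinear addition explains nothing new
    _, rss_full = _ols(y, X_full)
    _, rss_base = _ols(y, _design(frame, base_terms))
    q = len(full_terms) - len(base_terms)
    df_full = n - X_full.shape[1]
    if df_full <= 0:
        return 1.0
    if rss_full <= 0:
        return 0.0
    f = ((rss_base - rss_full) / q) / (rss_full / df_full)
    return float(stats.f.sf(max(f, 0.0), q, df_full))


def stepwise_select(
    ds: LaggedDataset,
    degree: int = 1,
    entry_p: float = 0.15,
    stay_p: float = 0.15,
    candidate_lags: Sequence[int] = LAG_INDICES,
) -> RegressionModel:
    """Forward/backward stepwise selection over the six lags.

    Lags enter (with both powers when degree 2) if their partial-F
    p-value is below ``entry_p``, the smallest p first with ties broken
    toward the smaller lag index; after each entry, included lags whose
    removal p-value exceeds ``stay_p`` are dropped. May return an
    intercept-only model. The selection trace is stored on the result.
    """
    frame = ds.frame.dropna(
        subset=[COUNT_COLUMN, *[f"rh_T{l}" for l in candidate_lags]]
    )
    y = frame[COUNT_COLUMN].to_numpy(dtype=float)
    included: list[int] = []
    trace: list[dict] = []
    while True:
        changed = False
        # forward step: smallest entry p; ascending lag order breaks ties
        # toward the smaller lag index
        best_lag, best_p = None, entry_p
        for lag in sorted(set(candidate_lags) - set(included)):
            p = _partial_f_p(
                y, frame, _terms_for(included, degree),
                _terms_for(sorted(included + [lag]), degree),
            )
            if p < best_p - 1e-15:
                best_lag, best_p = lag, p
        if best_lag is not None:
            included = sorted(included + [best_lag])
            trace.append({"action": "add", "lag": best_lag, "p": best_p})
            changed = True
        # backward step: drop the worst stayer above stay_p, repeatedly
        while len(included) > 0:
            worst_lag, worst_p = None, stay_p
            for lag in included:
                rest = [l for l in included if l != lag]
                p = _partial_f_p(
                    y, frame, _terms_for(rest, degree), _terms_for(included, degree)
                )
                if p > worst_p + 1e-15:
                    worst_lag, worst_p = lag, p
            if worst_lag is None:
                break
            included = [l for l in included if l != worst_lag]
            trace.append({"action": "drop", "lag": worst_lag, "p": worst_p})
            changed = True
        if not changed:
            break
    if included:
        model = fit_regression(ds, included, degree)
    else:
        n = len(frame)
        model = RegressionModel(
            intercept=float(y.mean()), terms=(), coefficients=(), degree=degree,
            fit_stats={"n": n, "r2": 0.0, "adjusted_r2": 0.0,
                       "rss": float(np.sum((y - y.mean()) ** 2))},
        )
    model.selection_trace = trace
    return model
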