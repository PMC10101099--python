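"""Generalized Lotka-Volterra models and their inference from time series.

A community of n taxa follows gLV dynamics dx_i/dt = x_i (r_i + sum_j A_ij x_j),
with A the interaction matrix (per-capita effect of taxon j on taxon i's
growth rate) and r the intrinsic growth rates. Sampled weekly, the standard
discrete-time analogue is the Ricker map

    x_i(t+1) = x_i(t) * exp(r_i + (A x(t))_i),

whose log-abundance increment ln x_i(t+1) - ln x_i(t) is *linear* in the
abundances x_j(t). Inference therefore reduces, per taxon, to a sparse
linear regression of log increments on lagged abundances. The estimator
here is a forward-stepwise regression with bagging: candidate predictors
are admitted one at a time if they improve the median held-out error over
many random train/test splits, and final coefficients are the median of the
per-split ordinary-least-squares fits. Never-admitted predictors keep
A_ij = 0, which yields sparse, noise-robust interaction matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .community import CoreTimeSeries


class InferenceError(ValueError):
    """Raised when a time series cannot support interaction inference."""


@dataclass
class GlvModel:
    """Interaction matrix A (n x n) and growth-rate vector r (length n)."""

    A: np.ndarray
    r: np.ndarray
    otu_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if self.r.shape != (self.A.shape[0],):
            raise ValueError("r length must match A")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.r))):
            raise ValueError("A and r must be finite")
        if not self.otu_ids:
            self.otu_ids = [f"sp{i}" for i in range(self.A.shape[0])]
        if len(self.otu_ids) != self.A.shape[0]:
            raise ValueError("otu_ids length must match A")

    @property
    def n(self) -> int:
        return self.A.shape[0]


def predict_step(model: GlvModel, x: np.ndarray) -> np.ndarray:
    """One step of the Ricker map; zero abundance is absorbing."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    out = x * np.exp(model.r + model.A @ x)
    out[x == 0] = 0.0
    return out


@dataclass
class InferenceConfig:
    """Settings for the bagged stepwise regression.

    n_bags random train/test splits of the observed transitions are drawn;
    a candidate predictor is admitted when it lowers the median held-out
    mean squared error by a relative margin > improvement_threshold.
    """

    n_bags: int = 100
    test_fraction: float = 0.5
    improvement_threshold: float = 0.0
    max_predictors: int | None = None
    seed: int = 0
    min_samples: int = 9

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.improvement_threshold < 0:
            raise ValueError("improvement_threshold must be >= 0")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3 "
                             "(regression needs >= 2 transitions)")


def _bag_splits(n_obs: int, config: InferenceConfig,
                rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    n_test = max(1, int(round(config.test_fraction * n_obs)))
    n_test = min(n_test, n_obs - 2)  # keep >= 2 training rows
    splits = []
    for _ in range(config.n_bags):
        perm = rng.permutation(n_obs)
        splits.append((perm[n_test:], perm[:n_test]))
    return splits


def _median_holdout_mse(X: np.ndarray, y: np.ndarray, cols: list[int],
                        splits) -> float:
    errs = []
    for train, test in splits:
        Xtr = X[np.ix_(train, cols)]
        if Xtr.shape[0] < len(cols):
            continue  # underdetermined bag
        beta, _, rank, _ = np.linalg.lstsq(Xtr, y[train], rcond=None)
        if rank < len(cols):
            continue  # rank-deficient bag dropped
        resid = X[np.ix_(test, cols)] @ beta - y[test]
        errs.append(float(np.mean(resid ** 2)))
    if not errs:
        return np.inf
    return float(np.median(errs))


def _median_coefficients(X: np.ndarray, y: np.ndarray, cols: list[int],
                         splits) -> np.ndarray:
    betas = []
    for train, _ in splits:
        Xtr = X[np.ix_(train, cols)]
        if Xtr.shape[0] < len(cols):
            continue
        beta, _, rank, _ = np.linalg.lstsq(Xtr, y[train], rcond=None)
        if rank < len(cols):
            continue
        betas.append(beta)
    if not betas:
        raise InferenceError("all bags rank-deficient; series uninformative")
    return np.median(np.asarray(betas), axis=0)


def transitions(weeks: np.ndarray, abundances: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (x(t), x(t+1)) for consecutive-week transitions only.

    Gaps in the weekly series break the chain; a one-step map cannot be
    regressed across a missed week.
    """
    weeks = np.asarray(weeks)
    order = np.argsort(weeks)
    weeks = weeks[order]
    ab = np.asarray(abundances, dtype=float)[order]
    step = np.diff(weeks) == 1
    idx = np.nonzero(step)[0]
    return ab[idx], ab[idx + 1]


def limits_infer(series: "CoreTimeSeries",
                 config: InferenceConfig | None = None) -> GlvModel:
    """Infer a gLV model from one participant's core time series.

    For each taxon i the regression target is
    y_i(t) = ln x_i(t+1) - ln x_i(t) over transitions where both abundances
    are positive; predictors are the lagged abundances x_j(t) plus an
    intercept (the growth rate r_i). The self-term x_i(t) is always kept in
    the model; other predictors enter by bagged forward selection.
    """
    config = config or InferenceConfig()
    weeks = np.asarray(series.weeks)
    ab = np.asarray(series.abundances, dtype=float)
    if ab.shape[0] < config.min_samples:
        raise InferenceError(
            f"participant {series.participant_id}: {ab.shape[0]} samples "
            f"< required {config.min_samples}")
    x_now, x_next = transitions(weeks, ab)
    if x_now.shape[0] < 2:
        raise InferenceError(
            f"participant {series.participant_id}: fewer than 2 "
            "consecutive-week transitions")
    n = ab.shape[1]
    max_pred = config.max_predictors if config.max_predictors is not None else n
    rng = np.random.default_rng(config.seed)

    A = np.zeros((n, n))
    r = np.zeros(n)
    for i in range(n):
        valid = (x_now[:, i] > 0) & (x_next[:, i] > 0)
        if valid.sum() < 3:
            raise InferenceError(
                f"participant {series.participant_id}, taxon "
                f"{series.core_otu_ids[i]}: too few positive transitions")
        y = np.log(x_next[valid, i]) - np.log(x_now[valid, i])
        X = np.column_stack([np.ones(valid.sum()), x_now[valid]])
        if np.allclose(X[:, 1:].std(axis=0), 0.0) and np.allclose(y.std(), 0.0):
            raise InferenceError(
                f"participant {series.participant_id}: no dynamics to fit "
                "(constant series)")
        splits = _bag_splits(X.shape[0], config, rng)
        selected = [0, i + 1]  # intercept + self-term, always present
        current = _median_holdout_mse(X, y, selected, splits)
        while len(selected) - 1 < max_pred:
            candidates = [j for j in range(1, n + 1) if j not in selected]
            if not candidates:
                break
            scores = [(_median_holdout_mse(X, y, selected + [j], splits), j)
                      for j in candidates]
            best_err, best_j = min(scores)
            if not np.isfinite(best_err) or best_err >= current:
                break
            rel_gain = ((current - best_err) / current
                        if current > 0 else 0.0)
            if rel_gain <= config.improvement_threshold:
                break
            selected.append(best_j)
            current = best_err
        beta = _median_coefficients(X, y, selected, splits)
        r[i] = beta[0]
        for col, b in zip(selected[1:], beta[1:]):
            A[i, col - 1] = b
    return GlvModel(A, r, list(series.core_otu_ids))
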