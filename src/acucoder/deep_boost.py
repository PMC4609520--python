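"""Capacity-regularized boosting weights, the AdaBoost baseline, and the
multi-output lifting onto the clinical-coding tasks.

The central solver minimizes, over nonnegative combination weights
``alpha`` with ``sum(alpha) <= cap``,

    (1/n) * sum_j Phi(1 - y_j * sum_i alpha_i h_i(x_j)) + lambda * sum_i alpha_i r_i

where ``Phi`` is a convex margin surrogate (exponential by default,
logistic available), ``h_i(x_j)`` are base-learner margins in [-1, 1],
``y_j`` are labels in {-1, +1} and ``r_i`` are per-learner capacity
penalties.  The problem is convex; it is solved by cyclic coordinate
descent with bounded scalar line searches, augmented with pairwise
mass-transfer moves so the solver cannot stall on the simplex face
``sum(alpha) = cap``.

The printed constraint bound ``1/n`` shrinks to zero with the sample size,
which contradicts the stated decision rule; both readings are available:
``weight_cap="unit"`` (default, bound 1) and ``weight_cap="paper"``
(bound ``1/n``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import ConfigurationError, NotFittedError
from .records_io import Dataset

__all__ = [
    "BoostConfig",
    "BoostModel",
    "AdaboostModel",
    "MultiOutputBoost",
    "deepboost_objective",
    "deepboost_weights",
    "predict_binary",
    "vote_score",
    "adaboost_fit",
    "adaboost_round_weight",
    "fit_multioutput_boost",
    "complexity_estimates",
]


def _phi_exp(u: np.ndarray) -> np.ndarray:
    return np.exp(u)


def _phi_logistic(u: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, u)


_SURROGATES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "exp": _phi_exp,
    "logistic": _phi_logistic,
}


@dataclass(frozen=True)
class BoostConfig:
    """Solver configuration.

    ``weight_cap`` is ``"unit"`` (sum of weights bounded by 1),
    ``"paper"`` (bounded by 1/n) or an explicit positive float.
    """

    lambda_: float = 1e-3
    surrogate: str = "exp"
    complexities: tuple[float, ...] | None = None
    weight_cap: str | float = "unit"
    max_iters: int = 200
    tolerance: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ConfigurationError("lambda_ must be nonnegative")
        if self.surrogate not in _SURROGATES:
            raise ConfigurationError(f"unknown surrogate {self.surrogate!r}")
        if isinstance(self.weight_cap, str):
            if self.weight_cap not in ("unit", "paper"):
                raise ConfigurationError("weight_cap must be 'unit', 'paper' or a float")
        elif self.weight_cap <= 0:
            raise ConfigurationError("weight_cap must be positive")
        if self.complexities is not None:
            r = np.asarray(self.complexities, dtype=float)
            if not np.isfinite(r).all() or (r < 0).any():
                raise ConfigurationError("complexities must be finite and nonnegative")

    def cap_for(self, n_samples: int) -> float:
        if self.weight_cap == "unit":
            return 1.0
        if self.weight_cap == "paper":
            return 1.0 / n_samples
        return float(self.weight_cap)


@dataclass
class BoostModel:
    """Fitted weight vector for one binary task."""

    alpha: np.ndarray
    objective_trace: list[float]
    task: object = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if (self.alpha < 0).any():
            raise ConfigurationError("alpha must be elementwise nonnegative")


def deepboost_objective(
    alpha: np.ndarray,
    H: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    r: np.ndarray,
    surrogate: str = "exp",
) -> float | np.ndarray:
    """Objective value; ``alpha`` may be a single vector or a (G, m) batch."""
    phi = _SURROGATES[surrogate]
    A = np.atleast_2d(np.asarray(alpha, dtype=float))
    margins = (y[:, None] * H) @ A.T  # (n, G)
    loss = phi(1.0 - margins).mean(axis=0)
    penalty = lambda_ * (A @ np.asarray(r, dtype=float))
    out = loss + penalty
    return float(out[0]) if np.ndim(alpha) == 1 else out


def _validate_binary_inputs(H: np.ndarray, y: np.ndarray, r: np.ndarray) -> None:
    if H.ndim != 2 or H.shape[0] != len(y):
        raise ConfigurationError("H must be (n_samples, n_learners) matching y")
    if not np.isin(y, (-1, 1)).all():
        raise ConfigurationError("labels must be in {-1, +1}")
    if np.abs(H).max(initial=0.0) > 1.0 + 1e-9:
        raise ConfigurationError("learner scores must lie in [-1, 1]")
    if len(r) != H.shape[1]:
        raise ConfigurationError("complexity vector length must match learner count")


def deepboost_weights(
    H: np.ndarray,
    y: np.ndarray,
    cfg: BoostConfig = BoostConfig(),
    task: object = None,
) -> BoostModel:
    """Fit combination weights for one binary task.

    Parameters
    ----------
    H:
        ``(n_samples, n_learners)`` matrix of base-learner margins in
        [-1, 1].
    y:
        Labels in {-1, +1}.
    cfg:
        Solver configuration; ``cfg.complexities`` defaults to zeros.

    Returns
    -------
    BoostModel
        With a non-increasing per-sweep ``objective_trace``.
    """
    H = np.asarray(H, dtype=float)
    y = np.asarray(y)
    n, m = H.shape
    r = (
        np.zeros(m)
        if cfg.complexities is None
        else np.asarray(cfg.complexities, dtype=float)
    )
    _validate_binary_inputs(H, y, r)
    cap = cfg.cap_for(n)
    phi = _SURROGATES[cfg.surrogate]
    M = y[:, None] * H  # per-sample signed margins of each learner

    alpha = np.zeros(m)
    margin = np.zeros(n)  # M @ alpha, maintained incrementally

    def objective(margin_vec: np.ndarray, a: np.ndarray) -> float:
        return float(phi(1.0 - margin_vec).mean() + cfg.lambda_ * (a @ r))

    current = objective(margin, alpha)
    trace = [current]

    def try_single(i: int, current: float) -> float:
        nonlocal margin
        lo = -alpha[i]
        hi = cap - alpha.sum()
        if hi - lo < 1e-14:
            return current

        def f(t: float) -> float:
            return float(
                phi(1.0 - (margin + t * M[:, i])).mean()
                + cfg.lambda_ * (alpha @ r + t * r[i])
            )

        res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
        t = float(res.x)
        val = f(t)
        for t_edge in (lo, hi):
            v_edge = f(t_edge)
            if v_edge < val:
                t, val = t_edge, v_edge
        if val < current - 1e-15:
            alpha[i] += t
            margin += t * M[:, i]
            return val
        return current

    def try_pair(i: int, j: int, current: float) -> float:
        # transfer t from j to i, keeping the sum fixed
        nonlocal margin
        lo, hi = -alpha[i], alpha[j]
        if hi - lo < 1e-14:
            return current
        d = M[:, i] - M[:, j]
        dr = r[i] - r[j]

        def f(t: float) -> float:
            return float(
                phi(1.0 - (margin + t * d)).mean() + cfg.lambda_ * (alpha @ r + t * dr)
            )

        res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
        t = float(res.x)
        val = f(t)
        for t_edge in (lo, hi):
            v_edge = f(t_edge)
            if v_edge < val:
                t, val = t_edge, v_edge
        if val < current - 1e-15:
            alpha[i] += t
            alpha[j] -= t
            margin += t * d
            return val
        return current

    for _ in range(cfg.max_iters):
        before = current
        for i in range(m):
            current = try_single(i, current)
        # pairwise transfers matter only when the cap constraint binds
        if alpha.sum() >= cap - 1e-10:
            for i in range(m):
                for j in range(m):
                    if i != j:
                        current = try_pair(i, j, current)
        np.clip(alpha, 0.0, None, out=alpha)
        trace.append(current)
        if before - current < cfg.tolerance:
            break
    return BoostModel(alpha=alpha, objective_trace=trace, task=task)


def vote_score(alpha: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Map weighted learner scores to a vote value in [0, 1].

    The weighted mean margin ``sum_i alpha_i s_i / sum_i alpha_i`` lies in
    [-1, 1]; negative evidence is floored at 0 so that all-zero scores (or
    an all-zero weight vector) yield 0, not the threshold value.
    """
    alpha = np.asarray(alpha, dtype=float)
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    total = alpha.sum()
    if total <= 0:
        return np.zeros(S.shape[0])
    raw = (S @ alpha) / total
    return np.clip(raw, 0.0, 1.0)


def predict_binary(model: BoostModel, scores: np.ndarray) -> np.ndarray:
    """Threshold rule: predict 1 iff the vote value is at least 0.5."""
    if model.alpha is None:
        raise NotFittedError("boost model has no weights")
    return (vote_score(model.alpha, scores) >= 0.5).astype(np.int64)


# --------------------------------------------------------------------------
# AdaBoost baseline
# --------------------------------------------------------------------------


@dataclass
class AdaboostModel:
    alpha: list[float]
    round_learners: list
    distribution_trace: list[np.ndarray]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.round_learners:
            raise NotFittedError("no boosting rounds were completed")
        agg = np.zeros(len(np.atleast_2d(X)))
        for a, h in zip(self.alpha, self.round_learners):
            agg += a * np.asarray(h(X), dtype=float)
        return np.where(agg >= 0, 1, -1)


def adaboost_round_weight(eps: float) -> float:
    """Round weight 0.5 * ln((1 - eps) / eps), with eps clipped away from 0."""
    eps = max(float(eps), 1e-12)
    return 0.5 * np.log((1.0 - eps) / eps)


def adaboost_fit(
    weak_family: Callable,
    X: np.ndarray,
    y: np.ndarray,
    rounds: int,
    seed: int = 0,
) -> AdaboostModel:
    """Discrete AdaBoost over a weak-learner trainer.

    ``weak_family(X, y, sample_weight, rng)`` must return a callable
    ``predict(X) -> {-1, +1}`` array.  Starts from the uniform sample
    distribution; per round the weighted error ``eps_t`` sets the round
    weight ``0.5 * ln((1 - eps_t)/eps_t)`` and the distribution is
    exponentially reweighted and renormalized.  Stops early on ``eps_t = 0``
    (perfect round, capped weight) or ``eps_t >= 0.5`` (no-better-than-chance
    round, dropped with a warning).
    """
    X = np.atleast_2d(X)
    y = np.asarray(y)
    if not np.isin(y, (-1, 1)).all():
        raise ConfigurationError("labels must be in {-1, +1}")
    n = len(y)
    rng = np.random.default_rng(seed)
    V = np.full(n, 1.0 / n)
    model = AdaboostModel(alpha=[], round_learners=[], distribution_trace=[V.copy()])
    for _ in range(rounds):
        h = weak_family(X, y, V.copy(), rng)
        pred = np.asarray(h(X))
        miss = pred != y
        eps = float(V[miss].sum())
        if eps >= 0.5:
            warnings.warn(
                f"weak learner no better than chance (eps={eps:.3f}); stopping",
                stacklevel=2,
            )
            break
        a = adaboost_round_weight(eps)
        model.alpha.append(a)
        model.round_learners.append(h)
        if eps == 0.0:
            model.distribution_trace.append(V.copy())
            break
        V = V * np.exp(np.where(miss, a, -a))
        V /= V.sum()
        model.distribution_trace.append(V.copy())
    return model


# --------------------------------------------------------------------------
# Multi-output lifting
# --------------------------------------------------------------------------


def complexity_estimates(pool: Sequence, normalize: bool = True) -> np.ndarray:
    """Capacity penalty ``r_i = sqrt(c_i / n_i)`` per learner.

    ``c_i`` is the leaf count for trees and the total support-vector count
    for margin learners; ``n_i`` the learner's training sample size.  With
    ``normalize=True`` (default) the vector is scaled to max 1.
    """
    r = np.array([np.sqrt(h.capacity() / h.n_train_) for h in pool], dtype=float)
    if normalize and r.max(initial=0.0) > 0:
        r = r / r.max()
    return r


class MultiOutputBoost:
    """Per-task boosted models lifted to tuple + acupoint prediction.

    One weight vector per ICD-10 label and per diagnosis code (one-vs-rest,
    combined by argmax over vote values) and one per acupoint (0.5
    threshold).  Tasks constant in the training data get constant
    predictors.
    """

    def __init__(
        self,
        pool: Sequence,
        label_models: dict[int, BoostModel],
        tcm_models: dict[int, BoostModel],
        acu_models: list[BoostModel | int],
        r: np.ndarray,
    ):
        self.pool = list(pool)
        self.label_models = label_models
        self.tcm_models = tcm_models
        self.acu_models = acu_models
        self.r = r

    def _scores(self, X: np.ndarray, task) -> np.ndarray:
        return np.column_stack([h.score_binary(X, task) for h in self.pool])

    def _argmax_head(self, X: np.ndarray, models: dict[int, BoostModel], group: str) -> np.ndarray:
        labels = sorted(models)
        votes = np.column_stack(
            [vote_score(models[k].alpha, self._scores(X, (group, k))) for k in labels]
        )
        return np.asarray(labels, dtype=np.int64)[np.argmax(votes, axis=1)]

    def predict_tuple(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(X)
        return (
            self._argmax_head(X, self.label_models, "icd10"),
            self._argmax_head(X, self.tcm_models, "tcm"),
        )

    def predict_acupoints(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        cols = []
        for j, model in enumerate(self.acu_models):
            if isinstance(model, BoostModel):
                cols.append(predict_binary(model, self._scores(X, ("acu", j))))
            else:
                cols.append(np.full(len(X), model, dtype=np.int64))
        return np.column_stack(cols).astype(np.uint8)


def fit_multioutput_boost(
    pool: Sequence,
    ds: Dataset,
    cfg: BoostConfig = BoostConfig(),
) -> MultiOutputBoost:
    """Fit one capacity-regularized weight vector per output task."""
    if len(pool) == 0:
        raise ConfigurationError("pool must not be empty")
    if len(ds) == 0:
        raise ConfigurationError("training dataset is empty")
    X = ds.feature_matrix()
    r = (
        np.asarray(cfg.complexities, dtype=float)
        if cfg.complexities is not None
        else complexity_estimates(pool)
    )
    if len(r) != len(pool):
        raise ConfigurationError("complexity vector length must match pool size")
    task_cfg = replace(cfg, complexities=tuple(r.tolist()))

    def fit_task(group: str, k: int, positive: np.ndarray) -> BoostModel:
        H = np.column_stack([h.score_binary(X, (group, k)) for h in pool])
        y = np.where(positive, 1, -1)
        return deepboost_weights(H, y, task_cfg, task=(group, k))

    y_true = ds.icd10_labels()
    z_true = ds.tcm_labels()
    acu = ds.acupoint_matrix()

    label_models = {int(k): fit_task("icd10", int(k), y_true == k) for k in np.unique(y_true)}
    missing = set(range(ds.schema.n_icd10)) - set(label_models)
    if missing:
        warnings.warn(
            f"{len(missing)} ICD-10 labels absent from training data; excluded",
            stacklevel=2,
        )
    tcm_models = {int(k): fit_task("tcm", int(k), z_true == k) for k in np.unique(z_true)}

    acu_models: list[BoostModel | int] = []
    for j in range(ds.schema.n_acupoints):
        col = acu[:, j]
        if col.min() == col.max():
            acu_models.append(int(col[0]))
        else:
            acu_models.append(fit_task("acu", j, col == 1))
    return MultiOutputBoost(pool, label_models, tcm_models, acu_models, r)
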