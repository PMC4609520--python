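"""Accuracy/diversity scoring, nondominated-sort ranking and top-b% voting.

The selective path works on the joint (ICD-10 label, diagnosis code) tuple
a learner emits for each record:

* tuple accuracy — a weighted mean of three indicators per record: the
  ICD-10 component matches, the diagnosis component matches, and the whole
  tuple matches (weights ``alpha``, ``beta``, ``gamma``);
* tuple diversity — the squared tuple Hamming distance (0, 1 or 4) between
  a learner and the full-pool majority vote, counted only on records the
  learner gets fully right, summed and divided by ``|D|**2``;
* nondominated sort — learners are ranked 1..m on each metric (descending,
  metric ties broken by learner index), partitioned into Pareto fronts on
  the rank pairs, and ordered by (front, accuracy rank + diversity rank,
  learner index);
* selection — the top ``max(1, round(m * b / 100))`` learners form a
  per-component majority-vote ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .records_io import Dataset

__all__ = [
    "MetricConfig",
    "SelectionConfig",
    "LearnerScore",
    "VotingEnsemble",
    "tuple_accuracy",
    "tuple_diversity",
    "majority_vote",
    "vote_tuples",
    "nds_sort",
    "select_top",
    "fit_selective_ensemble",
    "score_table_rows",
]


@dataclass(frozen=True)
class MetricConfig:
    """Importance weights for the tuple-accuracy terms (diagnosis, ICD-10, both)."""

    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    gamma: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ConfigurationError("metric weights must be nonnegative")
        if self.alpha + self.beta + self.gamma <= 0:
            raise ConfigurationError("metric weights must not all be zero")


@dataclass(frozen=True)
class SelectionConfig:
    b_percent: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.b_percent <= 100:
            raise ConfigurationError("b_percent must lie in (0, 100]")


@dataclass(frozen=True)
class LearnerScore:
    """One learner's metrics and the ranks derived from them (all 1-based)."""

    learner_id: int
    accuracy: float
    diversity: float
    acc_rank: int
    div_rank: int
    sum_rank: int
    nds_rank: int


def _tuples_of(h, ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    y, z = h.predict_tuple(ds.feature_matrix())
    return np.asarray(y), np.asarray(z)


def tuple_accuracy(h, ds: Dataset, mc: MetricConfig = MetricConfig()) -> float:
    """Weighted tuple accuracy of ``h`` on ``ds``; range [0, alpha+beta+gamma].

    ``h`` is anything exposing ``predict_tuple`` (a base learner or an
    ensemble).
    """
    if len(ds) == 0:
        raise ConfigurationError("cannot score on an empty dataset")
    y_pred, z_pred = _tuples_of(h, ds)
    y_hit = y_pred == ds.icd10_labels()
    z_hit = z_pred == ds.tcm_labels()
    both = y_hit & z_hit
    return float(
        np.mean(mc.alpha * y_hit + mc.beta * z_hit + mc.gamma * both)
    )


def tuple_diversity(h, h_ens, ds: Dataset) -> float:
    """Correctness-gated squared tuple Hamming distance from the ensemble vote.

    Per record the tuple Hamming distance between ``h`` and ``h_ens`` is in
    {0, 1, 2}; its square is counted only when ``h``'s tuple equals the
    ground truth, and the sum is divided by ``|D|**2``.
    """
    if len(ds) == 0:
        raise ConfigurationError("cannot score on an empty dataset")
    y_h, z_h = _tuples_of(h, ds)
    y_e, z_e = _tuples_of(h_ens, ds)
    dist = (y_h != y_e).astype(np.int64) + (z_h != z_e).astype(np.int64)
    correct = (y_h == ds.icd10_labels()) & (z_h == ds.tcm_labels())
    return float(np.sum((dist**2) * correct) / len(ds) ** 2)


def _plurality(votes: np.ndarray) -> np.ndarray:
    """Column-wise plurality of an (m, n) integer vote matrix; ties go to the
    lowest label index."""
    n = votes.shape[1]
    out = np.empty(n, dtype=np.int64)
    for j in range(n):
        out[j] = np.argmax(np.bincount(votes[:, j]))
    return out


def vote_tuples(learners: Sequence, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-component majority vote of ``learners`` over feature rows ``X``."""
    if len(learners) == 0:
        raise ConfigurationError("majority vote requires at least one learner")
    ys, zs = [], []
    for h in learners:
        y, z = h.predict_tuple(X)
        ys.append(y)
        zs.append(z)
    return _plurality(np.asarray(ys)), _plurality(np.asarray(zs))


def majority_vote(learners: Sequence, x: np.ndarray) -> tuple[int, int]:
    """Majority-vote tuple for a single feature vector."""
    y, z = vote_tuples(learners, np.atleast_2d(x))
    return int(y[0]), int(z[0])


def _rank_descending(values: np.ndarray) -> np.ndarray:
    """1-based ranks, rank 1 = largest value; exact ties broken by index."""
    order = np.lexsort((np.arange(len(values)), -values))
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def _pareto_fronts(acc_rank: np.ndarray, div_rank: np.ndarray) -> np.ndarray:
    """Front index per learner (0 = nondominated) on the two rank axes,
    lower rank better.  Fast nondominated sort."""
    m = len(acc_rank)
    dominated_by = [[] for _ in range(m)]
    n_dominating = np.zeros(m, dtype=np.int64)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            if (
                acc_rank[i] <= acc_rank[j]
                and div_rank[i] <= div_rank[j]
                and (acc_rank[i] < acc_rank[j] or div_rank[i] < div_rank[j])
            ):
                dominated_by[i].append(j)
                n_dominating[j] += 1
    front = np.full(m, -1, dtype=np.int64)
    current = [i for i in range(m) if n_dominating[i] == 0]
    level = 0
    while current:
        nxt = []
        for i in current:
            front[i] = level
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
        level += 1
    return front


def nds_sort(
    pairs: Sequence[tuple[float, float]],
    *,
    from_ranks: bool = False,
) -> list[LearnerScore]:
    """Nondominated sort of (accuracy, diversity) pairs.

    With ``from_ranks=True`` the pairs are taken as precomputed 1-based
    (accuracy rank, diversity rank) pairs; otherwise ranks are assigned by
    descending metric.  The final order is (Pareto front on the rank pairs,
    then sum of ranks, then learner index); ``nds_rank`` is the 1-based
    position in that order.  The returned list is sorted by ``nds_rank``.
    """
    if len(pairs) == 0:
        raise ConfigurationError("nds_sort requires at least one learner")
    arr = np.asarray(pairs, dtype=float)
    if not np.isfinite(arr).all():
        raise ConfigurationError("metric values must be finite")
    if from_ranks:
        acc_rank = arr[:, 0].astype(np.int64)
        div_rank = arr[:, 1].astype(np.int64)
        accuracy = -arr[:, 0]
        diversity = -arr[:, 1]
    else:
        accuracy, diversity = arr[:, 0], arr[:, 1]
        acc_rank = _rank_descending(accuracy)
        div_rank = _rank_descending(diversity)
    front = _pareto_fronts(acc_rank, div_rank)
    sum_rank = acc_rank + div_rank
    m = len(arr)
    order = sorted(range(m), key=lambda i: (front[i], sum_rank[i], i))
    nds_rank = np.empty(m, dtype=np.int64)
    nds_rank[order] = np.arange(1, m + 1)
    return [
        LearnerScore(
            learner_id=i,
            accuracy=float(accuracy[i]),
            diversity=float(diversity[i]),
            acc_rank=int(acc_rank[i]),
            div_rank=int(div_rank[i]),
            sum_rank=int(sum_rank[i]),
            nds_rank=int(nds_rank[i]),
        )
        for i in order
    ]


def select_top(
    sorted_scores: Sequence[LearnerScore], sel: SelectionConfig = SelectionConfig()
) -> list[int]:
    """Ids of the first ``max(1, round(m * b / 100))`` learners by NDS rank."""
    m = len(sorted_scores)
    if m == 0:
        raise ConfigurationError("no scores to select from")
    k = max(1, int(np.floor(m * sel.b_percent / 100.0 + 0.5)))
    ordered = sorted(sorted_scores, key=lambda s: s.nds_rank)
    return [s.learner_id for s in ordered[:k]]


class VotingEnsemble:
    """Top-b% majority-vote ensemble with the full pool score table attached."""

    def __init__(self, learners: Sequence, learner_ids: Sequence[int], scores: list[LearnerScore]):
        if len(learners) == 0:
            raise ConfigurationError("ensemble needs at least one learner")
        self.learners = list(learners)
        self.learner_ids = list(learner_ids)
        self.scores = scores

    def predict_tuple(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return vote_tuples(self.learners, X)

    def predict_acupoints(self, X: np.ndarray) -> np.ndarray:
        """Bit-wise majority vote over the learners' acupoint plans."""
        stacked = np.stack([h.predict_acupoints(X) for h in self.learners])
        return (stacked.mean(axis=0) >= 0.5).astype(np.uint8)


class _FixedVote:
    """Precomputed ensemble predictions, so the pool vote is computed once."""

    def __init__(self, y: np.ndarray, z: np.ndarray):
        self._y, self._z = y, z

    def predict_tuple(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self._y, self._z


def fit_selective_ensemble(
    pool: Sequence,
    ds_eval: Dataset,
    mc: MetricConfig = MetricConfig(),
    sel: SelectionConfig = SelectionConfig(),
) -> VotingEnsemble:
    """Score the pool on ``ds_eval``, NDS-sort, and keep the top b% as voters."""
    if len(pool) == 0:
        raise ConfigurationError("pool must not be empty")
    X = ds_eval.feature_matrix()
    y_ens, z_ens = vote_tuples(pool, X)
    reference = _FixedVote(y_ens, z_ens)
    pairs = [
        (tuple_accuracy(h, ds_eval, mc), tuple_diversity(h, reference, ds_eval))
        for h in pool
    ]
    scores = nds_sort(pairs)
    chosen = select_top(scores, sel)
    return VotingEnsemble([pool[i] for i in chosen], chosen, scores)


def score_table_rows(scores: Sequence[LearnerScore]) -> list[dict]:
    """Score table in table layout: one dict per learner, sorted by NDS rank."""
    return [
        {
            "learner": s.learner_id,
            "accuracy": s.accuracy,
            "diversity": s.diversity,
            "acc_rank": s.acc_rank,
            "div_rank": s.div_rank,
            "sum_rank": s.sum_rank,
            "nds_rank": s.nds_rank,
        }
        for s in sorted(scores, key=lambda s: s.nds_rank)
    ]
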