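"""Loss functions, repeated ten-fold cross-validation, and report tables.

Two losses are implemented: exact-match zero-one accuracy for single-label
outputs, and a per-record Hamming loss for label sets normalized by the
truth-set size (the label-universe normalization is available as an
option).  The protocol shuffles the data into equal-sized folds
``n_repeats`` times and evaluates one run per held-out fold; means and
standard deviations are taken across all runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .records_io import Dataset

__all__ = [
    "CVPlan",
    "PerDiseaseStat",
    "EvalResult",
    "zero_one_accuracy",
    "hamming_loss",
    "hamming_accuracy",
    "make_folds",
    "run_crossval",
    "count_best_method",
    "render_report",
    "round_half_away",
]


def zero_one_accuracy(pred: Sequence, truth: Sequence) -> float:
    """Fraction of positions where prediction equals truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ConfigurationError("prediction and truth lengths differ")
    if pred.size == 0:
        raise ConfigurationError("cannot score empty predictions")
    return float(np.mean(pred == truth))


def _record_hamming(pred: frozenset, truth: frozenset, n_labels: int | None) -> float:
    if n_labels is None:
        if len(truth) == 0:
            raise ConfigurationError("empty truth set: truth-normalized loss undefined")
        denom = len(truth)
    else:
        denom = n_labels
    return len(pred ^ truth) / denom


def hamming_loss(
    pred_sets: Sequence[Iterable[int]],
    truth_sets: Sequence[Iterable[int]],
    n_labels: int | None = None,
) -> float:
    """Mean per-record normalized symmetric difference.

    By default each record is normalized by its truth-set size (so the loss
    can exceed 1 for over-predicting models); pass ``n_labels`` to
    normalize by the label-universe size instead.
    """
    if len(pred_sets) != len(truth_sets):
        raise ConfigurationError("prediction and truth lengths differ")
    if len(pred_sets) == 0:
        raise ConfigurationError("cannot score empty predictions")
    losses = [
        _record_hamming(frozenset(p), frozenset(t), n_labels)
        for p, t in zip(pred_sets, truth_sets)
    ]
    return float(np.mean(losses))


def hamming_accuracy(
    pred_sets: Sequence[Iterable[int]],
    truth_sets: Sequence[Iterable[int]],
    n_labels: int | None = None,
) -> float:
    """Reported accuracy ``1 - loss``, floored at 0."""
    return max(0.0, 1.0 - hamming_loss(pred_sets, truth_sets, n_labels))


@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 10
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be at least 1")


def make_folds(n: int, plan: CVPlan) -> list[np.ndarray]:
    """Per-repeat fold assignments: one length-``n`` integer array per repeat.

    Fold sizes differ by at most 1 and every index appears exactly once per
    repeat.  Each repeat is an independent seeded shuffle.
    """
    if n < plan.n_folds:
        raise ConfigurationError("need at least one record per fold")
    rng = np.random.default_rng(plan.seed)
    base, extra = divmod(n, plan.n_folds)
    sizes = [base + 1 if f < extra else base for f in range(plan.n_folds)]
    assignments = []
    for _ in range(plan.n_repeats):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=np.int64)
        start = 0
        for f, size in enumerate(sizes):
            folds[perm[start : start + size]] = f
            start += size
        assignments.append(folds)
    return assignments


@dataclass(frozen=True)
class PerDiseaseStat:
    disease: int
    n: int
    mean: float  # percent
    std: float  # percent


@dataclass(frozen=True)
class EvalResult:
    loss_kind: str
    per_disease: tuple[PerDiseaseStat, ...]
    overall: tuple[float, float]  # (mean %, std %)
    n_runs: int
    n_failed: int = 0


Trainer = Callable[[Dataset, int], Callable[[Dataset], object]]


def _run_accuracy(preds, test: Dataset, loss_kind: str, n_labels: int | None):
    """Per-run overall accuracy and per-record accuracy contributions."""
    if loss_kind == "zero_one":
        truth = test.icd10_labels()
        pred = np.asarray(preds)
        per_record = (pred == truth).astype(float)
    elif loss_kind == "hamming":
        truth_sets = test.acupoint_sets()
        per_record = np.array(
            [
                max(0.0, 1.0 - _record_hamming(frozenset(p), t, n_labels))
                for p, t in zip(preds, truth_sets)
            ]
        )
    else:
        raise ConfigurationError(f"unknown loss kind {loss_kind!r}")
    return per_record


def run_crossval(
    ds: Dataset,
    trainer: Trainer,
    plan: CVPlan = CVPlan(),
    loss_kind: str = "zero_one",
    n_labels: int | None = None,
) -> EvalResult:
    """Repeated k-fold evaluation of ``trainer`` on ``ds``.

    ``trainer(train_ds, seed)`` must return a predictor mapping a test
    dataset to either a label array (``zero_one``) or a sequence of label
    sets (``hamming``).  Each of the ``n_repeats * n_folds`` runs fits on
    the other folds and scores the held-out fold; failing runs are dropped
    with their count reported.
    """
    if loss_kind not in ("zero_one", "hamming"):
        raise ConfigurationError(f"unknown loss kind {loss_kind!r}")
    n = len(ds)
    assignments = make_folds(n, plan)
    diseases = np.unique(ds.icd10_labels())
    all_labels = ds.icd10_labels()
    disease_counts = {int(c): int(np.sum(all_labels == c)) for c in diseases}

    overall_runs: list[float] = []
    per_disease_runs: dict[int, list[float]] = {int(c): [] for c in diseases}
    n_failed = 0
    run_seed = plan.seed
    for folds in assignments:
        for f in range(plan.n_folds):
            run_seed += 1
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            try:
                predictor = trainer(ds.subset(train_idx), run_seed)
                preds = predictor(ds.subset(test_idx))
                test = ds.subset(test_idx)
                per_record = _run_accuracy(preds, test, loss_kind, n_labels)
            except Exception as exc:  # noqa: BLE001 - runs are isolated by design
                warnings.warn(f"cross-validation run failed and was dropped: {exc}", stacklevel=2)
                n_failed += 1
                continue
            overall_runs.append(float(per_record.mean()))
            test_labels = test.icd10_labels()
            for c in diseases:
                mask = test_labels == c
                if mask.any():
                    per_disease_runs[int(c)].append(float(per_record[mask].mean()))

    if not overall_runs:
        raise ConfigurationError("every cross-validation run failed")
    per_disease = tuple(
        PerDiseaseStat(
            disease=int(c),
            n=disease_counts[int(c)],
            mean=100.0 * float(np.mean(per_disease_runs[int(c)])),
            std=100.0 * float(np.std(per_disease_runs[int(c)])),
        )
        for c in diseases
        if per_disease_runs[int(c)]
    )
    overall = (
        100.0 * float(np.mean(overall_runs)),
        100.0 * float(np.std(overall_runs)),
    )
    return EvalResult(
        loss_kind=loss_kind,
        per_disease=per_disease,
        overall=overall,
        n_runs=len(overall_runs),
        n_failed=n_failed,
    )


def count_best_method(table: np.ndarray) -> int:
    """Rows of a (diseases x methods) accuracy table where method 0 strictly
    beats every other method."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 1:
        raise ConfigurationError("table must be 2-D with at least one method column")
    if np.isnan(table).any():
        raise ConfigurationError("table contains missing cells")
    if table.shape[1] == 1:
        return int(table.shape[0])
    return int(np.sum(np.all(table[:, [0]] > table[:, 1:], axis=1)))


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (0.25 -> 0.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float) -> str:
    return f"{round_half_away(x, 1):.1f}"


def render_report(
    result: EvalResult,
    style: str = "table4",
    names: Sequence[str] | None = None,
) -> str:
    """Deterministic per-disease report with a final Total row.

    ``table4`` shows per-disease ``mean ± std``; ``table5`` shows per-disease
    means only, with the ± spread on the Total row (matching the published
    layouts).
    """
    if style not in ("table4", "table5"):
        raise ConfigurationError(f"unknown report style {style!r}")
    lines = ["No.\tName\tSize\tAccuracy"]
    total_n = 0
    for i, stat in enumerate(result.per_disease, start=1):
        name = names[i - 1] if names else f"disease_{stat.disease}"
        cell = (
            f"{_fmt(stat.mean)} ± {_fmt(stat.std)}"
            if style == "table4"
            else _fmt(stat.mean)
        )
        lines.append(f"{i}\t{name}\t{stat.n}\t{cell}")
        total_n += stat.n
    mean, std = result.overall
    lines.append(f"{len(result.per_disease) + 1}\tTotal\t{total_n}\t{_fmt(mean)} ± {_fmt(std)}")
    return "\n".join(lines)
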