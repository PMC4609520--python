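"""Bootstrap pool of base learners: decision trees and RBF max-margin models.

Each learner is trained on an independent bootstrap sample (with
replacement) and exposes a uniform contract:

* ``predict_tuple(X)`` — joint (ICD-10 label, diagnosis code) prediction;
* ``predict_acupoints(X)`` — 53-way (schema-sized) binary acupoint plan;
* ``score_binary(X, task)`` — a margin in [-1, 1] for one binary task,
  where a task is ``("icd10", label)``, ``("tcm", code)`` or
  ``("acu", index)``.

Tree learners fit a single multi-output CART over all targets; margin
learners fit one standardized RBF-SVM per target (per-class membership is
exposed as a hard vote, per-acupoint margins via a squashed decision
function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigurationError, NotFittedError
from .records_io import Dataset

__all__ = [
    "BaseLearner",
    "PoolConfig",
    "bootstrap_sample",
    "train_pool",
    "predict_tuple",
]

Task = tuple[str, int]


class _ConstantBinary:
    """Stand-in classifier for a target that is constant in the sample."""

    def __init__(self, value: int):
        self.value = int(value)

    def predict(self, X):
        return np.full(len(X), self.value)

    def margin(self, X):
        return np.full(len(X), 1.0 if self.value else -1.0)


@dataclass
class PoolConfig:
    """Pool construction parameters; defaults follow the published setup
    (500 trees + 500 margin learners, full-size bootstrap samples)."""

    m_tree: int = 500
    m_margin: int = 500
    bootstrap_fraction: float = 1.0
    seed: int = 0
    tree_max_depth: int | None = None
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    retry_cap: int = 20
    fit_acupoints: bool = True

    def validate(self) -> "PoolConfig":
        if self.m_tree < 0 or self.m_margin < 0 or self.m_tree + self.m_margin < 1:
            raise ConfigurationError("pool must contain at least one learner")
        if self.bootstrap_fraction <= 0:
            raise ConfigurationError("bootstrap_fraction must be positive")
        return self

    @property
    def m(self) -> int:
        return self.m_tree + self.m_margin


class BaseLearner:
    """One bootstrap-trained base learner (``kind`` is ``"tree"`` or ``"margin"``)."""

    def __init__(
        self,
        kind: str,
        *,
        tree_max_depth: int | None = None,
        svm_c: float = 1.0,
        svm_gamma: str | float = "scale",
        fit_acupoints: bool = True,
        seed: int = 0,
    ):
        if kind not in ("tree", "margin"):
            raise ConfigurationError(f"unknown learner kind {kind!r}")
        self.kind = kind
        self.tree_max_depth = tree_max_depth
        self.svm_c = svm_c
        self.svm_gamma = svm_gamma
        self.fit_acupoints = fit_acupoints
        self.seed = seed
        self._fitted = False

    # --- fitting -----------------------------------------------------------

    def _svc(self) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", C=self.svm_c, gamma=self.svm_gamma)),
            ]
        )

    @staticmethod
    def _fit_or_constant(model, X, y):
        if len(np.unique(y)) < 2:
            return _ConstantBinary(int(y[0]))
        model.fit(X, y)
        return model

    def fit(self, ds: Dataset) -> "BaseLearner":
        if len(ds) == 0:
            raise ConfigurationError("cannot fit a learner on an empty dataset")
        X = ds.feature_matrix()
        y = ds.icd10_labels()
        z = ds.tcm_labels()
        acu = ds.acupoint_matrix()
        self.n_train_ = len(ds)
        self._n_acu = ds.schema.n_acupoints
        if self.kind == "tree":
            targets = [y, z] + ([acu[:, j] for j in range(acu.shape[1])] if self.fit_acupoints else [])
            self._tree = DecisionTreeClassifier(
                max_depth=self.tree_max_depth, random_state=self.seed
            )
            self._tree.fit(X, np.column_stack(targets))
        else:
            self._y_clf = self._fit_or_constant(self._svc(), X, y)
            self._z_clf = self._fit_or_constant(self._svc(), X, z)
            self._acu_clfs = (
                [self._fit_or_constant(self._svc(), X, acu[:, j]) for j in range(acu.shape[1])]
                if self.fit_acupoints
                else []
            )
        self._fitted = True
        return self

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise NotFittedError("learner has not been fitted")

    # --- prediction --------------------------------------------------------

    def predict_tuple(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-row (ICD-10 label, diagnosis code) predictions."""
        self._require_fitted()
        X = np.atleast_2d(X)
        if self.kind == "tree":
            out = np.atleast_2d(self._tree.predict(X))
            return out[:, 0].astype(np.int64), out[:, 1].astype(np.int64)
        return (
            np.asarray(self._y_clf.predict(X), dtype=np.int64),
            np.asarray(self._z_clf.predict(X), dtype=np.int64),
        )

    def predict_acupoints(self, X: np.ndarray) -> np.ndarray:
        self._require_fitted()
        if not self.fit_acupoints:
            raise ConfigurationError("learner was trained without acupoint heads")
        X = np.atleast_2d(X)
        if self.kind == "tree":
            out = np.atleast_2d(self._tree.predict(X))
            return out[:, 2:].astype(np.uint8)
        return np.column_stack(
            [np.asarray(clf.predict(X)) for clf in self._acu_clfs]
        ).astype(np.uint8)

    def score_binary(self, X: np.ndarray, task: Task) -> np.ndarray:
        """Margin in [-1, 1] for one binary task.

        Trees report ``2 * P(positive) - 1`` from leaf class frequencies;
        margin learners report a hard vote for class-membership tasks and a
        tanh-squashed decision-function value for acupoint tasks.
        """
        self._require_fitted()
        X = np.atleast_2d(X)
        group, idx = task
        if group not in ("icd10", "tcm", "acu"):
            raise ConfigurationError(f"unknown task group {group!r}")
        if group == "acu" and not self.fit_acupoints:
            raise ConfigurationError("learner was trained without acupoint heads")
        if self.kind == "tree":
            out_idx = {"icd10": 0, "tcm": 1}.get(group, 2 + idx)
            proba = self._tree.predict_proba(X)[out_idx]
            classes = self._tree.classes_[out_idx]
            positive = idx if group in ("icd10", "tcm") else 1
            hit = np.flatnonzero(classes == positive)
            p = proba[:, hit[0]] if hit.size else np.zeros(len(X))
            return 2.0 * p - 1.0
        if group == "acu":
            clf = self._acu_clfs[idx]
            if isinstance(clf, _ConstantBinary):
                return clf.margin(X)
            return np.tanh(clf.decision_function(X))
        clf = self._y_clf if group == "icd10" else self._z_clf
        if isinstance(clf, _ConstantBinary):
            return np.where(clf.predict(X) == idx, 1.0, -1.0)
        return np.where(np.asarray(clf.predict(X)) == idx, 1.0, -1.0)

    def capacity(self) -> int:
        """Size proxy: leaf count for trees, total support vectors for margins."""
        self._require_fitted()
        if self.kind == "tree":
            return int(self._tree.tree_.n_leaves)
        total = 0
        clfs = [self._y_clf, self._z_clf] + list(getattr(self, "_acu_clfs", []))
        for clf in clfs:
            if isinstance(clf, _ConstantBinary):
                total += 1
            else:
                total += int(clf.named_steps["svc"].n_support_.sum())
        return total


def predict_tuple(h: BaseLearner, x: np.ndarray) -> tuple[int, int]:
    """Single-record convenience wrapper around :meth:`BaseLearner.predict_tuple`."""
    y, z = h.predict_tuple(np.atleast_2d(x))
    return int(y[0]), int(z[0])


def _bootstrap_indices(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    return rng.integers(0, n, size=size)


def bootstrap_sample(ds: Dataset, fraction: float = 1.0, seed: int = 0) -> Dataset:
    """Draw ``round(fraction * n)`` records with replacement, seeded."""
    if len(ds) == 0:
        raise ConfigurationError("cannot bootstrap an empty dataset")
    if fraction <= 0:
        raise ConfigurationError("fraction must be positive")
    rng = np.random.default_rng(seed)
    size = max(1, int(round(fraction * len(ds))))
    return ds.subset(_bootstrap_indices(rng, len(ds), size))


def train_pool(ds: Dataset, cfg: PoolConfig) -> list[BaseLearner]:
    """Train ``cfg.m`` learners on independent bootstrap samples.

    Learner ``i`` depends only on ``cfg.seed`` and ``i`` (trees first, then
    margin learners), so pool construction is order-independent and
    reproducible.  Bootstrap samples missing one of the training classes
    are redrawn up to ``cfg.retry_cap`` times.
    """
    cfg.validate()
    if len(ds) == 0:
        raise ConfigurationError("cannot train a pool on an empty dataset")
    y_classes = set(ds.icd10_labels().tolist())
    z_classes = set(ds.tcm_labels().tolist())
    size = max(1, int(round(cfg.bootstrap_fraction * len(ds))))
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.m)
    learners: list[BaseLearner] = []
    for i in range(cfg.m):
        kind = "tree" if i < cfg.m_tree else "margin"
        rng = np.random.default_rng(children[i])
        sample = None
        for _ in range(cfg.retry_cap):
            idx = _bootstrap_indices(rng, len(ds), size)
            sub = ds.subset(idx)
            if (
                set(sub.icd10_labels().tolist()) == y_classes
                and set(sub.tcm_labels().tolist()) == z_classes
            ):
                sample = sub
                break
        if sample is None:
            raise ConfigurationError(
                f"learner {i}: bootstrap sample missed a class in "
                f"{cfg.retry_cap} attempts (n={len(ds)}, classes={len(y_classes)}); "
                "increase bootstrap_fraction or reduce class count"
            )
        learner = BaseLearner(
            kind,
            tree_max_depth=cfg.tree_max_depth,
            svm_c=cfg.svm_c,
            svm_gamma=cfg.svm_gamma,
            fit_acupoints=cfg.fit_acupoints,
            seed=i,
        )
        learner.fit(sample)
        learners.append(learner)
    return learners
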