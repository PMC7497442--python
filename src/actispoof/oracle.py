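"""User-identification models and the black-box query oracle.

The target model maps a normalized 24-hour biometric profile to a
confidence score per user.  The attack never touches the model directly:
it sees only an :class:`Oracle`, which answers confidence queries
``f(x, t) -> [0, 1]`` (or, in ``binary`` mode, just whether the model's
top prediction equals ``t``) and counts every query it answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import N_HOURS, FeatureMatrix

__all__ = [
    "IdentificationReport",
    "LabeledDataset",
    "ModelSpec",
    "Oracle",
    "TRANSFER_SPECS",
    "evaluate_identification",
    "make_oracle",
    "split_per_user",
    "train_model",
]


@dataclass
class LabeledDataset:
    """Feature rows in [0,1]^24 with user-id labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or self.X.shape[1] != N_HOURS:
            raise ValueError("features must be (n, 24)")
        if len(self.y) != len(self.X):
            raise ValueError("labels and rows must align")
        if len(self.labels) < 2:
            raise ValueError("need at least two distinct users")

    @classmethod
    def from_feature_matrix(cls, matrix: FeatureMatrix) -> "LabeledDataset":
        return cls(matrix.X, matrix.user_ids)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.y))

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx])


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its (documented-default) hyperparameters.

    Supported families: ``random_forest`` (500 trees — the target model),
    ``naive_bayes``, ``knn`` (params: ``k``), ``svm`` (RBF, Platt-scaled
    probabilities), ``neural_net`` (one 64-unit hidden layer), ``lda``.
    """

    family: Literal["random_forest", "naive_bayes", "knn", "svm", "neural_net", "lda"]
    params: tuple = ()

    def build(self, seed: int = 0) -> BaseEstimator:
        p = dict(self.params)
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(p.get("n_estimators", 500)),
                random_state=seed,
                n_jobs=1,
            )
        if self.family == "naive_bayes":
            return GaussianNB()
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=int(p.get("k", 1)))
        if self.family == "svm":
            return SVC(kernel="rbf", C=1.0, probability=True, random_state=seed)
        if self.family == "neural_net":
            return MLPClassifier(
                hidden_layer_sizes=(64,), max_iter=1000, random_state=seed
            )
        if self.family == "lda":
            return LinearDiscriminantAnalysis()
        raise ValueError(f"unknown model family {self.family!r}")

    @property
    def name(self) -> str:
        p = dict(self.params)
        return f"knn{p['k']}" if self.family == "knn" and "k" in p else self.family


#: The transfer-study model zoo: five families, knn at k = 1, 3, 5.
TRANSFER_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("naive_bayes"),
    ModelSpec("knn", (("k", 1),)),
    ModelSpec("knn", (("k", 3),)),
    ModelSpec("knn", (("k", 5),)),
    ModelSpec("svm"),
    ModelSpec("neural_net"),
    ModelSpec("lda"),
)


def split_per_user(
    dataset: LabeledDataset, fraction: float = 0.5, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split each user's rows independently: ceil(fraction*n_u) to train.

    Both halves cover every user; a user with a single row cannot be
    split and raises a ValueError naming them.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for user in dataset.labels:
        idx = np.flatnonzero(dataset.y == user)
        if len(idx) < 2:
            raise ValueError(f"user {user!r} has fewer than 2 rows; cannot split")
        idx = rng.permutation(idx)
        k = int(np.ceil(fraction * len(idx)))
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return dataset.subset(np.array(train_idx)), dataset.subset(np.array(test_idx))


def train_model(spec: ModelSpec, train: LabeledDataset, seed: int = 0) -> BaseEstimator:
    """Fit the classifier; it then exposes ``predict_proba`` over sorted labels."""
    model = spec.build(seed)
    with warnings.catch_warnings():
        # SVC's built-in Platt scaling is the documented probability route
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        model.fit(train.X, train.y.astype(str))
    return model


@dataclass
class IdentificationReport:
    """Identification quality averaged over split iterations.

    TPR/TNR are one-vs-rest per user, macro-averaged (the standard way to
    report single sensitivity/specificity numbers for a multiclass
    identification task); balanced accuracy = (TPR + TNR) / 2.
    """

    accuracy: float
    true_positive_rate: float
    true_negative_rate: float

    @property
    def balanced_accuracy(self) -> float:
        return (self.true_positive_rate + self.true_negative_rate) / 2.0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "true_positive_rate": self.true_positive_rate,
            "true_negative_rate": self.true_negative_rate,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _macro_rates(y_true: np.ndarray, y_pred: np.ndarray, labels: list[str]) -> tuple[float, float]:
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    total = cm.sum()
    fn = support - tp
    fp = predicted - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore"):
        tpr = np.where(support > 0, tp / np.maximum(support, 1), np.nan)
        tnr = tn / (tn + fp)
    return float(np.nanmean(tpr)), float(np.nanmean(tnr))


def evaluate_identification(
    spec: ModelSpec,
    dataset: LabeledDataset,
    iterations: int = 10,
    fraction: float = 0.5,
    seed: int = 0,
) -> IdentificationReport:
    """Repeated per-user-split evaluation of identification quality."""
    labels = dataset.labels
    seeds = np.random.SeedSequence(seed).generate_state(iterations)
    accs, tprs, tnrs = [], [], []
    for i in range(iterations):
        s = int(seeds[i]) % 2**31
        train, test = split_per_user(dataset, fraction, seed=s)
        model = train_model(spec, train, seed=s)
        pred = model.predict(test.X)
        accs.append(float(np.mean(pred == test.y.astype(str))))
        tpr, tnr = _macro_rates(test.y.astype(str), pred, labels)
        tprs.append(tpr)
        tnrs.append(tnr)
    return IdentificationReport(
        accuracy=float(np.mean(accs)),
        true_positive_rate=float(np.mean(tprs)),
        true_negative_rate=float(np.mean(tnrs)),
    )


class UnknownTargetError(KeyError):
    """The queried target user is not in the model's label universe."""


@dataclass
class Oracle:
    """Black-box view of a fitted identification model.

    In ``confidence`` mode, :meth:`query` returns the model's probability
    that each queried profile belongs to the target user; in ``binary``
    mode it returns 1.0 where the model's top prediction is the target
    and 0.0 elsewhere.  Every evaluated row increments ``query_count``
    (the attacker's query budget accounting).
    """

    model: BaseEstimator
    mode: Literal["confidence", "binary"] = "confidence"
    query_count: int = field(default=0)

    def __post_init__(self) -> None:
        if self.mode not in ("confidence", "binary"):
            raise ValueError("mode must be 'confidence' or 'binary'")

    @property
    def labels(self) -> np.ndarray:
        return self.model.classes_

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_HOURS:
            raise ValueError("queries must be 24-dimensional")
        if (X < 0).any() or (X > 1).any():
            raise ValueError("queries must lie in [0, 1]^24")
        return X

    def _target_index(self, t) -> np.ndarray:
        t_arr = np.atleast_1d(np.asarray(t, dtype=object)).astype(str)
        label_pos = {label: i for i, label in enumerate(self.labels)}
        try:
            return np.array([label_pos[u] for u in t_arr])
        except KeyError as exc:
            raise UnknownTargetError(f"unknown target user {exc.args[0]!r}") from exc

    def query(self, X: np.ndarray, t) -> np.ndarray | float:
        """Confidence (or binary agreement) that each row of X is user t.

        ``t`` may be a single user id or one id per row.
        """
        X = self._check(X)
        idx = self._target_index(t)
        if len(idx) == 1:
            idx = np.repeat(idx, len(X))
        elif len(idx) != len(X):
            raise ValueError("one target, or one target per row")
        proba = self.model.predict_proba(X)
        self.query_count += len(X)
        if self.mode == "binary":
            out = (proba.argmax(axis=1) == idx).astype(float)
        else:
            out = proba[np.arange(len(X)), idx]
        return float(out[0]) if out.shape == (1,) else out

    def label_query(self, X: np.ndarray) -> np.ndarray | str:
        """The model's top predicted user for each row (ties -> lowest id)."""
        X = self._check(X)
        proba = self.model.predict_proba(X)
        self.query_count += len(X)
        labels = self.labels[proba.argmax(axis=1)]
        return str(labels[0]) if len(labels) == 1 and X.shape[0] == 1 else labels


def make_oracle(
    model: BaseEstimator, mode: Literal["confidence", "binary"] = "confidence"
) -> Oracle:
    """Wrap a fitted model as a query-counting black-box oracle."""
    if not hasattr(model, "classes_"):
        raise ValueError("model must be fitted before wrapping in an oracle")
    return Oracle(model=model, mode=mode)
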