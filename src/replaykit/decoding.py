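"""L1-regularised one-vs-rest state decoders for sensor epochs.

One binomial (logistic) classifier is trained per building-block class on
localizer epochs at a fixed training latency; positives are the class's own
epochs, negatives are all other classes' epochs plus "null" samples taken
from the pre-stimulus window, which decorrelates the classifiers.  Applied
sample-by-sample to task epochs, the classifiers yield the state-reactivation
probability series that all sequenceness analysis consumes.

The L1 penalty is specified on a lassoglm-style scale; ``penalty_to_C`` maps
it to scikit-learn's inverse regularisation ``C = 1 / (penalty * n_samples)``
(the mapping constant is configurable; the default of 0.006 produces sparse
but non-empty sensor weights on synthetic data).  One-vs-rest probabilities
are intentionally *not* renormalised across states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import EpochTensor, ReactivationSeries, ShapeError


class TrainingError(ValueError):
    """Raised when a class has no training epochs."""


class CVError(ValueError):
    """Raised when a cross-validation fold is missing a class."""


def penalty_to_C(penalty: float, n_samples: int, scale: float = 1.0) -> float:
    """Map a lassoglm-style L1 penalty to scikit-learn's ``C``."""
    return scale / (penalty * n_samples)


@dataclass
class ClassifierSet:
    """Per-state L1-logistic decoders over sensors.

    ``weights`` is states x sensors, ``intercepts`` states; standardisation
    statistics (from the localizer) are stored so decoding applies the same
    transform.
    """

    weights: np.ndarray
    intercepts: np.ndarray
    state_labels: tuple[str, ...]
    train_time_ms: float
    penalty: float
    sensor_mask: np.ndarray
    standardize: bool = True
    sensor_mean: np.ndarray | None = None
    sensor_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def nonzero_counts(self) -> np.ndarray:
        return (self.weights != 0).sum(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Independent one-vs-rest probabilities, rows x states, in [0, 1]."""
        if X.shape[-1] != self.weights.shape[1]:
            raise ShapeError("sensor dimension mismatch")
        if self.standardize:
            X = (X - self.sensor_mean) / self.sensor_sd
        z = X @ self.weights.T + self.intercepts
        return 1.0 / (1.0 + np.exp(-z))

    def save_hdf5(self, path: str) -> None:
        from .containers import _save

        _save(path, weights=self.weights, intercepts=self.intercepts,
              sensor_mask=self.sensor_mask.astype(np.int8),
              sensor_mean=self.sensor_mean, sensor_sd=self.sensor_sd,
              attrs={"state_labels": list(self.state_labels),
                     "train_time_ms": self.train_time_ms,
                     "penalty": self.penalty, "standardize": self.standardize,
                     "meta": self.meta})

    @classmethod
    def load_hdf5(cls, path: str) -> "ClassifierSet":
        from .containers import _load

        data, attrs = _load(path)
        return cls(data["weights"], data["intercepts"],
                   tuple(attrs["state_labels"]), attrs["train_time_ms"],
                   attrs["penalty"], data["sensor_mask"].astype(bool),
                   standardize=attrs["standardize"],
                   sensor_mean=data["sensor_mean"], sensor_sd=data["sensor_sd"],
                   meta=attrs.get("meta", {}))


def _training_rows(
    epochs: EpochTensor,
    states: Sequence[str],
    train_time_ms: float,
    null_window_ms: tuple[float, float],
    null_samples_per_epoch: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus rows (one per epoch at the training time) and null rows
    (pre-onset samples, ``null_samples_per_epoch`` per epoch cycling through
    the window)."""
    t_idx = epochs.time_index(train_time_ms)
    X_stim = epochs.values[:, :, t_idx]
    lo, hi = null_window_ms
    if hi > 0:
        raise ValueError("null window must precede stimulus onset")
    null_idx = np.nonzero((epochs.times_ms >= lo) & (epochs.times_ms < hi))[0]
    rows = []
    for e in range(epochs.n_trials):
        for k in range(null_samples_per_epoch):
            pick = null_idx[(e + k * epochs.n_trials) % null_idx.size]
            rows.append(epochs.values[e, :, pick])
    return X_stim, np.array(rows)


def train_classifiers(
    localizer: EpochTensor,
    train_time_ms: float = 200.0,
    penalty: float = 0.006,
    null_window_ms: tuple[float, float] = (-500.0, 0.0),
    states: Sequence[str] | None = None,
    standardize: bool = True,
    null_samples_per_epoch: int = 1,
    penalty_scale: float = 1.0,
) -> ClassifierSet:
    """Train one L1-logistic decoder per state at ``train_time_ms``.

    Positives: the state's epochs at the training time.  Negatives: all other
    states' epochs at the training time plus null-window samples (one per
    epoch by default).  Training is deterministic given the data and penalty.
    """
    states = tuple(states or sorted(set(localizer.labels)))
    labels = np.asarray(localizer.labels)
    for s in states:
        if not np.any(labels == s):
            raise TrainingError(f"class {s!r} has no epochs")
    X_stim, X_null = _training_rows(localizer, states, train_time_ms,
                                    null_window_ms, null_samples_per_epoch)
    X = np.vstack([X_stim, X_null])
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xz = (X - mean) / sd
    else:
        mean = sd = None
        Xz = X
    C = penalty_to_C(penalty, X.shape[0], penalty_scale)
    n_sensors = localizer.n_sensors
    weights = np.zeros((len(states), n_sensors))
    intercepts = np.zeros(len(states))
    for i, s in enumerate(states):
        y = np.concatenate([(labels == s).astype(int),
                            np.zeros(X_null.shape[0], dtype=int)])
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=1000, tol=1e-7, random_state=0)
        clf.fit(Xz, y)
        weights[i] = clf.coef_[0]
        intercepts[i] = clf.intercept_[0]
    return ClassifierSet(
        weights=weights, intercepts=intercepts, state_labels=states,
        train_time_ms=train_time_ms, penalty=penalty,
        sensor_mask=np.ones(n_sensors, dtype=bool), standardize=standardize,
        sensor_mean=mean, sensor_sd=sd,
        meta={"n_null_rows": int(X_null.shape[0]), "C": C},
    )


def decode_timecourse(clf: ClassifierSet, epochs: EpochTensor) -> ReactivationSeries:
    """Apply the decoders to every sample of every epoch.

    Returns the concatenated probability series; trial boundaries are carried
    by the series' trial structure so lagged regressions never straddle them.
    """
    if epochs.n_sensors != clf.weights.shape[1]:
        raise ShapeError("sensor dimension mismatch between epochs and decoders")
    # trials x time x sensors -> rows
    X = np.moveaxis(epochs.values, 1, 2).reshape(-1, epochs.n_sensors)
    probs = clf.predict_proba(X)
    return ReactivationSeries(
        probs, epochs.sfreq, clf.state_labels, epochs.n_trials, epochs.times_ms,
        probabilistic=True, meta={"train_time_ms": clf.train_time_ms},
    )


def decodability_curve(
    localizer: EpochTensor,
    times_ms: Sequence[float] | None = None,
    cv_folds: int = 5,
    penalty: float = 0.006,
    states: Sequence[str] | None = None,
    null_window_ms: tuple[float, float] = (-500.0, 0.0),
) -> "pd.DataFrame":
    """Cross-validated decodability per training time.

    A held-out epoch counts as correct iff the true class's classifier emits
    the highest probability among all classifiers (ties broken by the fixed
    state order).  Returns a DataFrame with columns ``time_ms`` and
    ``accuracy``.
    """
    import pandas as pd

    states = tuple(states or sorted(set(localizer.labels)))
    labels = np.asarray(localizer.labels)
    if times_ms is None:
        times_ms = localizer.times_ms[localizer.times_ms >= 0]
    if cv_folds < 2:
        raise CVError("need at least two folds")
    y_all = np.array([states.index(l) for l in labels])
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=False)
    acc = np.zeros(len(times_ms))
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), y_all):
        if len(set(y_all[train_idx])) < len(states):
            raise CVError("fold is missing a class")
        sub_train = EpochTensor(localizer.values[train_idx], localizer.times_ms,
                                list(labels[train_idx]), localizer.sfreq,
                                baseline_ms=localizer.baseline_ms)
        for ti, t in enumerate(times_ms):
            clf = train_classifiers(sub_train, train_time_ms=t, penalty=penalty,
                                    null_window_ms=null_window_ms, states=states)
            t_idx = localizer.time_index(t)
            probs = clf.predict_proba(localizer.values[test_idx, :, t_idx])
            pred = probs.argmax(axis=1)  # ties -> lowest state index
            acc[ti] += np.sum(pred == y_all[test_idx])
    acc /= len(labels)
    return pd.DataFrame({"time_ms": np.asarray(times_ms, float), "accuracy": acc})


def confusion_matrix(
    clf: ClassifierSet, epochs: EpochTensor, at_time_ms: float | None = None
) -> np.ndarray:
    """Row-normalised identifiability matrix: fraction of each true class's
    epochs whose highest-probability classifier is each state."""
    t_idx = epochs.time_index(at_time_ms if at_time_ms is not None
                              else clf.train_time_ms)
    probs = clf.predict_proba(epochs.values[:, :, t_idx])
    pred = probs.argmax(axis=1)
    out = np.zeros((clf.n_states, clf.n_states))
    labels = np.asarray(epochs.labels)
    for i, s in enumerate(clf.state_labels):
        mask = labels == s
        if mask.any():
            for j in range(clf.n_states):
                out[i, j] = np.mean(pred[mask] == j)
    return out
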