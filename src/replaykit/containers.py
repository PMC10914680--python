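"""Array containers shared across the analysis stages.

Three light dataclasses wrap the numpy arrays that flow through the pipeline:
epoched sensor data (:class:`EpochTensor`), decoded state-reactivation
probability series (:class:`ReactivationSeries`) and condition x feature x
session response patterns (:class:`PatternSet`).  Each can round-trip through
HDF5 with a JSON attribute block for metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np


class ShapeError(ValueError):
    """Raised when array dimensions disagree with metadata."""


@dataclass
class EpochTensor:
    """Epoched multichannel data: ``values`` is trials x sensors x time.

    ``times_ms`` gives the per-epoch time axis relative to stimulus onset;
    ``onset_idx`` is the sample index of onset; ``baseline_ms`` the window
    used for baseline correction (must precede onset); ``labels`` one label
    per trial.
    """

    values: np.ndarray
    times_ms: np.ndarray
    labels: Sequence[str]
    sfreq: float
    baseline_ms: tuple[float, float] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError("values must be trials x sensors x time")
        if self.values.shape[2] != self.times_ms.size:
            raise ShapeError("time axis mismatch")
        if self.values.shape[0] != len(self.labels):
            raise ShapeError("one label per trial required")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("non-finite epoch values")
        if self.baseline_ms is not None and self.baseline_ms[1] > 0:
            raise ShapeError("baseline window must precede onset")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    @property
    def onset_idx(self) -> int:
        return int(np.searchsorted(self.times_ms, 0.0))

    def time_index(self, t_ms: float) -> int:
        idx = int(np.argmin(np.abs(self.times_ms - t_ms)))
        if abs(self.times_ms[idx] - t_ms) > 1000.0 / self.sfreq:
            raise IndexError(f"time {t_ms} ms outside epoch")
        return idx

    def baseline_correct(self) -> "EpochTensor":
        """Subtract the mean pre-onset baseline per trial and sensor."""
        if self.baseline_ms is None:
            return self
        lo, hi = self.baseline_ms
        mask = (self.times_ms >= lo) & (self.times_ms < hi)
        base = self.values[:, :, mask].mean(axis=2, keepdims=True)
        return EpochTensor(
            self.values - base, self.times_ms, list(self.labels), self.sfreq,
            baseline_ms=None, meta=dict(self.meta),
        )

    def save_hdf5(self, path: str) -> None:
        _save(path, values=self.values, times_ms=self.times_ms,
              labels=np.array(self.labels, dtype="S"),
              attrs={"sfreq": self.sfreq, "baseline_ms": self.baseline_ms,
                     "meta": self.meta})

    @classmethod
    def load_hdf5(cls, path: str) -> "EpochTensor":
        data, attrs = _load(path)
        baseline = attrs.get("baseline_ms")
        return cls(data["values"], data["times_ms"],
                   [lab.decode() for lab in data["labels"]], attrs["sfreq"],
                   baseline_ms=tuple(baseline) if baseline else None,
                   meta=attrs.get("meta", {}))


@dataclass
class ReactivationSeries:
    """Time x state matrix of decoded probabilities or planted intensities.

    Stored as the concatenation of equal-length trials; ``n_trials`` and
    ``times_ms`` (the within-trial time axis) recover the per-trial view.
    Lagged regressions must never straddle trial boundaries, which downstream
    code enforces through :meth:`as_trials`.
    """

    values: np.ndarray
    sfreq: float
    state_labels: Sequence[str]
    n_trials: int
    times_ms: np.ndarray
    probabilistic: bool = True
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.state_labels):
            raise ShapeError("values must be time x state")
        if self.values.shape[0] != self.n_trials * self.times_ms.size:
            raise ShapeError("length must equal n_trials * trial length")
        if self.probabilistic and (self.values.min() < 0 or self.values.max() > 1):
            raise ShapeError("probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    @property
    def trial_len(self) -> int:
        return self.times_ms.size

    @property
    def boundaries(self) -> np.ndarray:
        """Start indices of each trial in the concatenated series."""
        return np.arange(self.n_trials) * self.trial_len

    def as_trials(self) -> np.ndarray:
        """View as trials x time x state."""
        return self.values.reshape(self.n_trials, self.trial_len, self.n_states)

    def save_hdf5(self, path: str) -> None:
        _save(path, values=self.values, times_ms=self.times_ms,
              attrs={"sfreq": self.sfreq, "state_labels": list(self.state_labels),
                     "n_trials": self.n_trials, "probabilistic": self.probabilistic,
                     "meta": self.meta})

    @classmethod
    def load_hdf5(cls, path: str) -> "ReactivationSeries":
        data, attrs = _load(path)
        return cls(data["values"], attrs["sfreq"], attrs["state_labels"],
                   attrs["n_trials"], data["times_ms"],
                   probabilistic=attrs["probabilistic"], meta=attrs.get("meta", {}))


@dataclass
class PatternSet:
    """Condition x feature x session response patterns for RSA.

    ``feature_coords`` (features x d) supplies synthetic geometry for
    searchlight neighbourhoods.
    """

    values: np.ndarray
    condition_labels: Sequence[str]
    feature_coords: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError("values must be condition x feature x session")
        if self.values.shape[0] != len(self.condition_labels):
            raise ShapeError("one label per condition required")
        if self.feature_coords is not None:
            self.feature_coords = np.asarray(self.feature_coords, dtype=float)
            if self.feature_coords.shape[0] != self.values.shape[1]:
                raise ShapeError("one coordinate row per feature required")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[2]

    def pattern(self, label: str, session: int | None = None) -> np.ndarray:
        idx = list(self.condition_labels).index(label)
        return self.values[idx] if session is None else self.values[idx, :, session]

    def subset_features(self, feature_idx: np.ndarray) -> "PatternSet":
        coords = None if self.feature_coords is None else self.feature_coords[feature_idx]
        return PatternSet(self.values[:, feature_idx, :], list(self.condition_labels),
                          coords, dict(self.meta))

    def save_hdf5(self, path: str) -> None:
        extra = {}
        if self.feature_coords is not None:
            extra["feature_coords"] = self.feature_coords
        _save(path, values=self.values,
              labels=np.array(self.condition_labels, dtype="S"),
              attrs={"meta": self.meta}, **extra)

    @classmethod
    def load_hdf5(cls, path: str) -> "PatternSet":
        data, attrs = _load(path)
        return cls(data["values"], [lab.decode() for lab in data["labels"]],
                   data.get("feature_coords"), attrs.get("meta", {}))


def _save(path: str, attrs: dict | None = None, **arrays: np.ndarray) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr)
        f.attrs["json"] = json.dumps(attrs or {}, default=_jsonable)


def _load(path: str) -> tuple[dict, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        data = {name: f[name][()] for name in f}
        attrs = json.loads(f.attrs["json"])
    return data, attrs


def _jsonable(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
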