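"""Temporally delayed linear modelling (TDLM) of replay sequenceness.

Sequenceness asks whether decoded state reactivations follow each other in
systematic order at short temporal lags.  The measure is a two-level GLM:

* **first level** — for every lag Δ, each state's reactivation series is
  regressed on *all* states' series shifted by Δ (multiple regression plus
  intercept), giving an empirical state-to-state transition matrix per lag
  (entry i→j: how strongly state i's past predicts state j's present);
* **second level** — for every lag, the vectorised empirical matrix is
  regressed on theoretical transition matrices (one per sequence type) while
  controlling for the mean (all-ones matrix) and self-transitions (identity).

Theoretical matrices are built per trial from the trial's role assignment
(stable / present / distant-present / absent blocks); the second level is
computed per trial and averaged, so trials where a sequence type does not
apply (no present-to-present connection when the stable block is in the
middle) simply contribute no rows for that type.

Statistical bounds come from control sequences: in each true matrix one role
is substituted by the absent block (source- or destination-substituted, two
controls per type); the min and max of the trial-averaged control
coefficients across lags bound the true coefficient.

Length-3 sequenceness regresses a third state's reactivation on all ordered
pairwise sequence products (state i at t−2Δ times state j at t−Δ) while
controlling for all single lagged states at Δ and 2Δ.

Lagged design rows never straddle trial boundaries (they are dropped, not
zero-padded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ReactivationSeries
from .stimuli import RoleAssignment, RoleError

SEQ_TYPES = ("stable_to_present", "present_to_stable", "present_to_present")
CONTRAST = "present_minus_stable"


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# theoretical matrices
# ---------------------------------------------------------------------------


@dataclass
class TheoreticalMatrices:
    """Binary 4x4 transition matrices (rows = from-state, cols = to-state)
    for one trial: the true matrix per sequence type plus its two
    absent-substituted controls.  Diagonals are always zero;
    ``present_to_present`` is all-zero (inapplicable) on stable-middle
    trials."""

    state_labels: tuple[str, ...]
    true: dict[str, np.ndarray]
    controls: dict[str, list[np.ndarray]]
    applicable: dict[str, bool]

    def key(self) -> tuple:
        return tuple(m.tobytes() for m in self.true.values())


def _mat(n: int, idx: Sequence[tuple[int, int]]) -> np.ndarray:
    m = np.zeros((n, n))
    for i, j in idx:
        if i != j:
            m[i, j] = 1.0
    return m


def build_theoretical_matrices(
    roles: RoleAssignment,
    state_labels: Sequence[str],
    basis: str = "category",
    edges: Sequence[tuple[str, str]] | None = None,
) -> TheoreticalMatrices:
    """Theoretical transition matrices for one trial's role assignment.

    ``basis='category'`` (default) connects role categories regardless of
    geometry (stable→both presents, etc.); ``basis='edge'`` restricts entries
    to block pairs actually connected in the silhouette (``edges`` required).
    Controls substitute the absent block for the source role or the
    destination role of each type.
    """
    labels = tuple(state_labels)
    ix = {s: i for i, s in enumerate(labels)}
    missing = {roles.stable, roles.absent, *roles.present} - set(labels)
    if missing:
        raise RoleError(f"roles reference unknown states {missing}")
    s, a = ix[roles.stable], ix[roles.absent]
    p1, p2 = sorted(ix[p] for p in roles.present)
    n = len(labels)

    if basis == "edge":
        if edges is None:
            raise RoleError("edge basis requires the silhouette's edges")
        connected = {frozenset((ix[x], ix[y])) for x, y in edges}

        def keep(pairs):
            return [(i, j) for i, j in pairs if frozenset((i, j)) in connected]
    elif basis == "category":
        def keep(pairs):
            return list(pairs)
    else:
        raise ConfigError(f"unknown basis {basis!r}")

    p2p_pairs = [] if roles.stable_middle else keep([(p1, p2), (p2, p1)])
    spec = {
        "stable_to_present": keep([(s, p1), (s, p2)]),
        "present_to_stable": keep([(p1, s), (p2, s)]),
        "present_to_present": p2p_pairs,
    }
    true = {t: _mat(n, idx) for t, idx in spec.items()}
    sub_src = {"stable_to_present": [(a, p1), (a, p2)],
               "present_to_stable": [(a, s)],
               "present_to_present": [(a, p1), (a, p2)]}
    sub_dst = {"stable_to_present": [(s, a)],
               "present_to_stable": [(p1, a), (p2, a)],
               "present_to_present": [(p1, a), (p2, a)]}
    controls = {t: [_mat(n, sub_src[t]), _mat(n, sub_dst[t])] for t in SEQ_TYPES}
    applicable = {t: bool(spec[t]) for t in SEQ_TYPES}
    return TheoreticalMatrices(labels, true, controls, applicable)


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalTransitions:
    """Per-lag empirical transition coefficients: ``coef[d, i, j]`` is the
    weight of state i's series, lagged by ``lags_ms[d]``, in the multiple
    regression predicting state j."""

    lags_ms: np.ndarray
    coef: np.ndarray
    state_labels: tuple[str, ...]


def _lag_grid(series: ReactivationSeries, max_lag_ms: float) -> np.ndarray:
    step = 1000.0 / series.sfreq
    n = int(round(max_lag_ms / step))
    if n < 1 or n >= series.trial_len:
        raise ConfigError("max lag must fit inside a trial")
    return np.arange(1, n + 1)


def _is_flat(X: np.ndarray, axis: int) -> np.ndarray:
    """Zero-variance predictor columns, up to float roundoff."""
    return X.std(axis=axis) <= 1e-10 * (1.0 + np.abs(X.mean(axis=axis)))


def _first_level_trials(
    Y: np.ndarray,
    lags: np.ndarray,
    target_range: tuple[int, int] | None = None,
    zscore: bool = False,
) -> np.ndarray:
    """Per-trial lagged multiple regression.

    Y is trials x time x states; returns trials x lags x states x states
    (i→j).  ``target_range`` restricts the predicted samples to a half-open
    index window (used by the sliding-window analysis); lagged predictors may
    reach back before the window but never before the trial start.
    """
    n_trials, T, S = Y.shape
    if zscore:
        mu = Y.mean(axis=1, keepdims=True)
        sd = Y.std(axis=1, keepdims=True)
        Y = (Y - mu) / np.where(sd == 0, 1.0, sd)
    w0, w1 = target_range if target_range is not None else (0, T)
    out = np.full((n_trials, lags.size, S, S), np.nan)
    warned = False
    for di, d in enumerate(lags):
        t0 = max(int(d), w0)
        t1 = w1
        if t1 - t0 < S + 2:
            continue
        X = Y[:, t0 - d:t1 - d, :]
        tgt = Y[:, t0:t1, :]
        A = np.concatenate([X, np.ones((n_trials, t1 - t0, 1))], axis=2)
        flat = _is_flat(X, axis=1)  # zero-variance predictors, per trial
        if not warned and flat.any():
            warnings.warn("zero-variance state series in first-level design; "
                          "their coefficients are set to 0")
            warned = True
        G = np.einsum("nti,ntj->nij", A, A)
        B = np.einsum("nti,ntj->nij", A, tgt)
        beta = np.linalg.pinv(G) @ B  # (n, S+1, S), minimum-norm if singular
        beta[:, :S, :][flat] = 0.0
        out[:, di] = beta[:, :S, :]
    return out


def first_level(
    series: ReactivationSeries,
    max_lag_ms: float = 500.0,
    zscore: bool = False,
    mode: str = "multiple",
) -> EmpiricalTransitions:
    """Pooled first-level GLM over all trials (design rows that would cross a
    trial boundary are dropped).

    ``mode='multiple'`` (default) regresses each target state on all four
    lagged states simultaneously; ``mode='simple'`` fits one pairwise
    regression per (predictor, target) pair (used by oracle and symmetry
    checks)."""
    if mode not in ("multiple", "simple"):
        raise ConfigError(f"unknown first-level mode {mode!r}")
    lags = _lag_grid(series, max_lag_ms)
    Y = series.as_trials()
    n_trials, T, S = Y.shape
    if zscore:
        mu = Y.mean(axis=1, keepdims=True)
        sd = Y.std(axis=1, keepdims=True)
        Y = (Y - mu) / np.where(sd == 0, 1.0, sd)
    coef = np.zeros((lags.size, S, S))
    for di, d in enumerate(lags):
        X = Y[:, :-d, :].reshape(-1, S)
        tgt = Y[:, d:, :].reshape(-1, S)
        flat = _is_flat(X, axis=0)
        if flat.any():
            warnings.warn("zero-variance state series in first-level design; "
                          "their coefficients are set to 0")
        if mode == "multiple":
            A = np.column_stack([X, np.ones(X.shape[0])])
            beta = np.linalg.pinv(A.T @ A) @ (A.T @ tgt)
            coef[di] = beta[:S, :]
        else:
            xc = X - X.mean(axis=0)
            yc = tgt - tgt.mean(axis=0)
            var = (xc**2).sum(axis=0)
            var[var == 0] = np.inf
            coef[di] = (xc.T @ yc) / var[:, None]
        coef[di][flat] = 0.0
    return EmpiricalTransitions(lags * 1000.0 / series.sfreq, coef,
                                tuple(series.state_labels))


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------


def _second_level_design(theo: TheoreticalMatrices,
                         replace: tuple[str, int] | None = None
                         ) -> tuple[np.ndarray, list[str]]:
    """Vectorised design: applicable sequence-type matrices (optionally one
    replaced by its control), the all-ones matrix, and the identity."""
    n = len(theo.state_labels)
    cols, names = [], []
    for t in SEQ_TYPES:
        if not theo.applicable[t]:
            continue
        m = theo.true[t]
        if replace is not None and replace[0] == t:
            m = theo.controls[t][replace[1]]
        cols.append(m.ravel())
        names.append(t)
    cols.append(np.ones(n * n))
    names.append("mean")
    cols.append(np.eye(n).ravel())
    names.append("self")
    return np.column_stack(cols), names


def second_level(
    emp: EmpiricalTransitions, theo: TheoreticalMatrices
) -> pd.DataFrame:
    """Regress each lag's empirical matrix on the theoretical matrices,
    controlling for mean and self-transitions.  Returns a tidy frame with
    columns lag_ms, sequence_type, coefficient (NaN for inapplicable types).
    """
    X, names = _second_level_design(theo)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("collinear theoretical matrices; pseudoinverse solve")
    P = np.linalg.pinv(X)
    Yv = emp.coef.reshape(emp.coef.shape[0], -1).T  # 16 x lags
    coefs = P @ Yv  # k x lags
    rows = []
    for di, lag in enumerate(emp.lags_ms):
        for t in SEQ_TYPES:
            val = coefs[names.index(t), di] if t in names else np.nan
            rows.append({"lag_ms": lag, "sequence_type": t, "coefficient": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------


@dataclass
class SequencenessResults:
    """Trial-averaged sequenceness per lag and sequence type, with
    control-sequence bounds.

    ``coef[t]`` is the per-lag coefficient curve of sequence type ``t``;
    ``bounds[t] = (lo, hi)`` is the statistical bound — the min/max across
    lags of the trial-averaged control coefficients, pooled over all types'
    controls into a single bound (so every type currently shares it), with
    the per-type control curves kept in ``control_curves``.  The headline
    contrast — sequences starting from present blocks minus sequences
    starting from the stable block — is in ``contrast`` with its own bounds.
    """

    lags_ms: np.ndarray
    coef: dict[str, np.ndarray]
    control_curves: dict[str, np.ndarray]  # type -> (2, lags)
    bounds: dict[str, tuple[float, float]]
    contrast: np.ndarray
    contrast_bounds: tuple[float, float]
    n_trials: int
    per_window: pd.DataFrame | None = None

    def peak(self, which: str = CONTRAST) -> tuple[float, float]:
        """(lag_ms, value) of the maximum coefficient."""
        c = self.contrast if which == CONTRAST else self.coef[which]
        i = int(np.nanargmax(c))
        return float(self.lags_ms[i]), float(c[i])

    def exceeds_bound(self, which: str) -> bool:
        """True where the curve's maximum exceeds its max control bound."""
        if which == CONTRAST:
            return bool(np.nanmax(self.contrast) > self.contrast_bounds[1])
        return bool(np.nanmax(self.coef[which]) > self.bounds[which][1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in (*SEQ_TYPES, CONTRAST):
            curve = self.contrast if t == CONTRAST else self.coef[t]
            lo, hi = self.contrast_bounds if t == CONTRAST else self.bounds[t]
            for lag, val in zip(self.lags_ms, curve):
                rows.append({"lag_ms": lag, "sequence_type": t,
                             "coefficient": val, "ctrl_min": lo, "ctrl_max": hi})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Sequenceness ({self.n_trials} trials, "
                 f"lags {self.lags_ms[0]:.0f}-{self.lags_ms[-1]:.0f} ms)",
                 f"{'sequence type':<24}{'peak lag':>9}{'peak coef':>11}"
                 f"{'ctrl lo':>10}{'ctrl hi':>10}{'exceeds':>9}"]
        for t in (*SEQ_TYPES, CONTRAST):
            lag, val = self.peak(t)
            lo, hi = self.contrast_bounds if t == CONTRAST else self.bounds[t]
            lines.append(f"{t:<24}{lag:>7.0f}ms{val:>11.4f}"
                         f"{lo:>10.4f}{hi:>10.4f}{str(self.exceeds_bound(t)):>9}")
        return "\n".join(lines)


class SequencenessModel:
    """Two-level TDLM sequenceness model for one subject's task run.

    Parameters
    ----------
    series : ReactivationSeries
        Decoded probability (or ground-truth intensity) series, trial-wise.
    trial_roles : sequence of RoleAssignment (one per trial) or a
        TrialSchedule.
    max_lag_ms : maximum first-level lag (default 500 ms).
    zscore : z-score each state's series per trial before the first level
        (default off: raw probabilities).
    basis : 'category' or 'edge' theoretical matrices.
    """

    def __init__(self, series: ReactivationSeries, trial_roles,
                 max_lag_ms: float = 500.0, zscore: bool = False,
                 basis: str = "category") -> None:
        self.series = series
        if hasattr(trial_roles, "trials"):  # TrialSchedule
            self._roles = [t.roles for t in trial_roles.trials]
            self._edges = [
                [(a, b) for a, _, b in trial_roles.stimuli[t.stim_id].edges]
                for t in trial_roles.trials
            ]
        else:
            self._roles = list(trial_roles)
            self._edges = [None] * len(self._roles)
        if len(self._roles) != series.n_trials:
            raise ConfigError("one role assignment per trial required")
        self.max_lag_ms = max_lag_ms
        self.zscore = zscore
        self.basis = basis

    def theoretical(self, trial: int) -> TheoreticalMatrices:
        return build_theoretical_matrices(
            self._roles[trial], tuple(self.series.state_labels),
            basis=self.basis, edges=self._edges[trial])

    def _designs(self) -> list[dict]:
        """Per-trial second-level pseudoinverses (true + control variants),
        cached by role structure."""
        cache: dict[tuple, dict] = {}
        out = []
        for ti in range(self.series.n_trials):
            theo = self.theoretical(ti)
            key = theo.key()
            if key not in cache:
                X, names = _second_level_design(theo)
                entry = {"names": names, "P_true": np.linalg.pinv(X),
                         "P_ctrl": {}}
                for t in SEQ_TYPES:
                    if not theo.applicable[t]:
                        continue
                    entry["P_ctrl"][t] = [
                        np.linalg.pinv(_second_level_design(theo, (t, c))[0])
                        for c in (0, 1)
                    ]
                cache[key] = entry
            out.append(cache[key])
        return out

    def fit(self, target_range: tuple[int, int] | None = None,
            lags: np.ndarray | None = None) -> SequencenessResults:
        series = self.series
        if lags is None:
            lags = _lag_grid(series, self.max_lag_ms)
        Y = series.as_trials()
        E = _first_level_trials(Y, lags, target_range, self.zscore)
        n_trials, n_lags = E.shape[:2]
        Ev = E.reshape(n_trials, n_lags, -1)
        designs = self._designs()
        coef = np.full((n_trials, n_lags, len(SEQ_TYPES)), np.nan)
        ctrl = np.full((n_trials, n_lags, len(SEQ_TYPES), 2), np.nan)
        for ti, d in enumerate(designs):
            names = d["names"]
            c_true = d["P_true"] @ Ev[ti].T  # k x lags
            for si, t in enumerate(SEQ_TYPES):
                if t not in names:
                    continue
                coef[ti, :, si] = c_true[names.index(t)]
                for c in (0, 1):
                    cc = d["P_ctrl"][t][c] @ Ev[ti].T
                    ctrl[ti, :, si, c] = cc[names.index(t)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_coef = np.nanmean(coef, axis=0)       # lags x types
            mean_ctrl = np.nanmean(ctrl, axis=0)       # lags x types x 2
        lags_ms = lags * 1000.0 / series.sfreq
        coef_d = {t: mean_coef[:, i] for i, t in enumerate(SEQ_TYPES)}
        curves = {t: mean_ctrl[:, i, :].T for i, t in enumerate(SEQ_TYPES)}
        # one statistical bound from the pooled control sequences of all
        # types (min/max across lags and controls), as in the TDLM convention
        # of a single significance line
        pooled = np.concatenate([c[np.isfinite(c).any(axis=1)] for c in
                                 curves.values()])
        lo, hi = float(np.nanmin(pooled)), float(np.nanmax(pooled))
        bounds = {t: (lo, hi) for t in SEQ_TYPES}
        contrast, c_lo, c_hi = self._contrast(mean_coef, mean_ctrl)
        return SequencenessResults(
            lags_ms=lags_ms, coef=coef_d, control_curves=curves, bounds=bounds,
            contrast=contrast, contrast_bounds=(c_lo, c_hi), n_trials=n_trials)

    @staticmethod
    def _contrast(mean_coef: np.ndarray, mean_ctrl: np.ndarray
                  ) -> tuple[np.ndarray, float, float]:
        """Sequences starting from present blocks (average of present→stable
        and present→present) minus sequences starting from stable."""
        i = {t: k for k, t in enumerate(SEQ_TYPES)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            present = np.nanmean(
                np.stack([mean_coef[:, i["present_to_stable"]],
                          mean_coef[:, i["present_to_present"]]]), axis=0)
            contrast = present - mean_coef[:, i["stable_to_present"]]
            ctr = []
            for c in (0, 1):
                pres_c = np.nanmean(
                    np.stack([mean_ctrl[:, i["present_to_stable"], c],
                              mean_ctrl[:, i["present_to_present"], c]]), axis=0)
                ctr.append(pres_c - mean_ctrl[:, i["stable_to_present"], c])
        ctr = np.stack(ctr)
        return contrast, float(np.nanmin(ctr)), float(np.nanmax(ctr))

    # -- sliding windows ---------------------------------------------------

    def sliding_window(
        self,
        window_ms: float = 1000.0,
        step_ms: float = 10.0,
        lag_band_ms: tuple[float, float] = (10.0, 200.0),
        span_ms: tuple[float, float] | None = None,
    ) -> pd.DataFrame:
        """Windowed sequenceness: per window, the two-level model restricted
        to target samples inside the window, averaged over the lag band.

        Default parameters reproduce the canonical grid: 1000-ms windows
        stepped by 10 ms over [-500, 3500] ms → 301 windows, the first
        covering [-500, 500] and the last [2500, 3500].  The non-overlapping
        500-ms variant is ``window_ms=step_ms=500``.

        Returns a tidy frame: window_start_ms, window_center_ms,
        sequence_type (the three types plus the present-minus-stable
        contrast), coefficient, ctrl_min, ctrl_max.
        """
        series = self.series
        times = series.times_ms
        if span_ms is None:
            span_ms = (float(times[0]), float(times[-1]) + series.sfreq ** -1 * 1000)
        step = 1000.0 / series.sfreq
        band = np.arange(int(round(lag_band_ms[0] / step)),
                         int(round(lag_band_ms[1] / step)) + 1)
        band = band[band >= 1]
        if window_ms < 2 * lag_band_ms[1]:
            raise ConfigError("window must be at least twice the max lag")
        starts = np.arange(span_ms[0], span_ms[1] - window_ms + step_ms / 2, step_ms)
        rows = []
        for w0 in starts:
            mask = (times >= w0) & (times < w0 + window_ms)
            idx = np.nonzero(mask)[0]
            res = self.fit(target_range=(int(idx[0]), int(idx[-1]) + 1), lags=band)
            for t in (*SEQ_TYPES, CONTRAST):
                curve = res.contrast if t == CONTRAST else res.coef[t]
                lo, hi = res.contrast_bounds if t == CONTRAST else res.bounds[t]
                rows.append({
                    "window_start_ms": w0,
                    "window_center_ms": w0 + window_ms / 2,
                    "sequence_type": t,
                    "coefficient": float(np.nanmean(curve)),
                    "ctrl_min": lo, "ctrl_max": hi,
                })
        return pd.DataFrame(rows)


def sliding_window(series: ReactivationSeries, trial_roles, **kwargs) -> pd.DataFrame:
    """Functional wrapper around :meth:`SequencenessModel.sliding_window`."""
    model_kwargs = {k: kwargs.pop(k) for k in ("max_lag_ms", "zscore", "basis")
                    if k in kwargs}
    return SequencenessModel(series, trial_roles, **model_kwargs).sliding_window(**kwargs)


def n_windows(span_ms: tuple[float, float] = (-500.0, 3500.0),
              window_ms: float = 1000.0, step_ms: float = 10.0) -> int:
    """Number of sliding windows on the given span (301 for the defaults)."""
    return int(np.floor((span_ms[1] - span_ms[0] - window_ms) / step_ms)) + 1


# ---------------------------------------------------------------------------
# length-3 sequences
# ---------------------------------------------------------------------------


@dataclass
class Length3Result:
    """Trial-averaged length-3 coefficients: ``coef[d, i, j, k]`` is the
    weight of the sequence product (state i at t−2Δ, state j at t−Δ) in
    predicting state k, controlling for all single lagged states."""

    lags_ms: np.ndarray
    coef: np.ndarray
    state_labels: tuple[str, ...]

    def get(self, pair: tuple[str, str], third: str) -> np.ndarray:
        ix = {s: i for i, s in enumerate(self.state_labels)}
        return self.coef[:, ix[pair[0]], ix[pair[1]], ix[third]]

    def argmax_triple(self, lag_ms: float) -> tuple[str, str, str]:
        """The ordered (A, B, C) triple with the largest coefficient at the
        given lag (A, B, C distinct)."""
        d = int(np.argmin(np.abs(self.lags_ms - lag_ms)))
        best, best_val = None, -np.inf
        S = len(self.state_labels)
        for i in range(S):
            for j in range(S):
                for k in range(S):
                    if len({i, j, k}) < 3:
                        continue
                    v = self.coef[d, i, j, k]
                    if np.isfinite(v) and v > best_val:
                        best_val = v
                        best = (self.state_labels[i], self.state_labels[j],
                                self.state_labels[k])
        return best


def length3(
    series: ReactivationSeries,
    max_lag_ms: float = 500.0,
    target_range: tuple[int, int] | None = None,
) -> Length3Result:
    """Length-3 TDLM over all ordered state triples.

    For each lag Δ and each target state C, C's series is regressed on the 12
    ordered pairwise sequence products plus all single state series at lags Δ
    and 2Δ (plus intercept); computed per trial and trial-averaged.
    """
    lags = _lag_grid(series, max_lag_ms)
    # 2Δ must also fit in a trial
    lags = lags[2 * lags < series.trial_len - 2]
    Y = series.as_trials()
    n_trials, T, S = Y.shape
    pairs = [(i, j) for i in range(S) for j in range(S) if i != j]
    w0, w1 = target_range if target_range is not None else (0, T)
    acc = np.zeros((lags.size, S, S, S))
    cnt = np.zeros(lags.size)
    for di, d in enumerate(lags):
        t0 = max(2 * int(d), w0)
        if w1 - t0 < 2 * (len(pairs) + 2 * S + 1):
            continue
        X2 = Y[:, t0 - 2 * d:w1 - 2 * d, :]   # states at t-2Δ
        X1 = Y[:, t0 - d:w1 - d, :]           # states at t-Δ
        tgt = Y[:, t0:w1, :]
        prod = np.stack([X2[:, :, i] * X1[:, :, j] for i, j in pairs], axis=2)
        A = np.concatenate(
            [prod, X1, X2, np.ones((n_trials, w1 - t0, 1))], axis=2)
        G = np.einsum("nti,ntj->nij", A, A)
        B = np.einsum("nti,ntj->nij", A, tgt)
        beta = np.linalg.pinv(G) @ B  # (n, cols, S)
        pair_beta = beta[:, :len(pairs), :].mean(axis=0)  # pairs x S
        for pi, (i, j) in enumerate(pairs):
            acc[di, i, j, :] = pair_beta[pi]
        cnt[di] = 1
    coef = np.where(cnt[:, None, None, None] > 0, acc, np.nan)
    return Length3Result(lags * 1000.0 / series.sfreq, coef,
                         tuple(series.state_labels))
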