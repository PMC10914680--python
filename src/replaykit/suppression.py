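"""Repetition-suppression designs and the behavioral similarity model.

Repetition suppression (fMRI adaptation) indexes shared representational
content between consecutive stimuli: responses are weaker when the current
silhouette repeats building blocks, relations, or visual properties of the
previous one.  :func:`build_rs_design` turns a trial sequence of silhouettes
into the parametric design — visual control columns (size / pixel
non-overlap, block counts) plus the compositional columns of interest
(basic / hierarchical building-block non-overlap, relational non-overlap) —
each projected onto [-1, 1].  :class:`AdaptationGLM` convolves the
stick-modulated columns with a canonical double-gamma HRF and fits the
resulting GLM to a BOLD-like signal.

:class:`SimilarityLogit` fits the behavioral similarity logistic model
``p(choose left) = 1 / (1 + exp(-(b0 + b1*Diff_pixel + b2*Diff_size +
b3*Diff_relation + b4*Diff_basicBBs [+ b5*Diff_hierBBs])))`` per subject with
a group one-sample t-test over subject coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import Silhouette, block_overlap, overlap_metrics

TRANSITION_COLUMNS = (
    "delta_n_blocks", "size_nonoverlap", "pixel_nonoverlap",
    "basicBB_nonoverlap_small", "basicBB_nonoverlap_large",
    "hierBB_nonoverlap", "relational_nonoverlap_small",
    "relational_nonoverlap_large", "relational_nonoverlap_cross",
)


@dataclass
class RSDesign:
    """Trial x regressor repetition-suppression design.

    ``raw`` holds unprojected values, ``mask`` their applicability (a column
    is defined only on its transition class; the first trial of a session has
    no transition regressors), and ``projected`` the per-session min-max
    projection onto [-1, 1] with inapplicable entries set to 0.  Columns that
    had zero variance on their applicable entries are dropped from
    ``projected`` and listed in ``dropped``.
    """

    raw: pd.DataFrame
    mask: pd.DataFrame
    projected: pd.DataFrame
    sessions: np.ndarray
    dropped: tuple[str, ...] = ()
    manifest: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.raw)

    def to_csv(self, path: str) -> None:
        self.projected.assign(session=self.sessions).to_csv(path, index=False)


def _project_minmax(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    vals = x[mask]
    lo, hi = vals.min(), vals.max()
    out[mask] = 0.0 if hi == lo else 2 * (vals - lo) / (hi - lo) - 1
    return out


def _project_absmax(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    m = np.abs(x[mask]).max()
    out[mask] = x[mask] / m if m > 0 else 0.0
    return out


def build_rs_design(
    trials: Sequence[Silhouette],
    sessions: Sequence[int] | None = None,
    basic_solutions: Mapping[int, Sequence[frozenset[str]]] | None = None,
    hier_blocks: Mapping[int, frozenset[str]] | None = None,
    small_max_blocks: int = 2,
    projection: str = "minmax",
    pixel_norm: str = "jaccard",
) -> RSDesign:
    """Build the parametric repetition-suppression design for a trial
    sequence.

    Parameters
    ----------
    trials : consecutive silhouettes (>= 2).
    sessions : session index per trial (transition regressors reset at
        session starts); one session by default.
    basic_solutions : per trial index, alternative basic-block decompositions
        of large silhouettes (equal weights); large-trial block non-overlap
        averages over them.
    hier_blocks : per trial index, the hierarchical-block set of a large
        silhouette (enables the hierarchical non-overlap column).
    small_max_blocks : a silhouette with at most this many blocks is "small".
    projection : 'minmax' (affine onto [-1, 1]) or 'absmax' (divide by the
        maximum absolute value).
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    sessions = np.asarray(sessions if sessions is not None else [0] * len(trials))
    basic_solutions = basic_solutions or {}
    hier_blocks = hier_blocks or {}
    small = [len(s.block_ids) <= small_max_blocks for s in trials]

    n = len(trials)
    cols = {"n_blocks": np.array([float(len(s.block_ids)) for s in trials])}
    masks = {"n_blocks": np.ones(n, dtype=bool)}
    for name in TRANSITION_COLUMNS:
        cols[name] = np.zeros(n)
        masks[name] = np.zeros(n, dtype=bool)

    for t in range(1, n):
        if sessions[t] != sessions[t - 1]:
            continue  # first trial of a session: no transition regressors
        prev, cur = trials[t - 1], trials[t]
        m = overlap_metrics(prev, cur, pixel_norm=pixel_norm)
        cols["delta_n_blocks"][t] = abs(len(cur.block_ids) - len(prev.block_ids))
        cols["size_nonoverlap"][t] = m["size_nonoverlap"]
        cols["pixel_nonoverlap"][t] = 1.0 - m["pixel_overlap"]
        for name in ("delta_n_blocks", "size_nonoverlap", "pixel_nonoverlap"):
            masks[name][t] = True

        decomp = {}
        if t - 1 in basic_solutions:
            decomp[1] = basic_solutions[t - 1]
        if t in basic_solutions:
            decomp[2] = basic_solutions[t]
        bb = 1.0 - block_overlap(prev, cur, decompositions=decomp or None)
        if small[t]:
            cols["basicBB_nonoverlap_small"][t] = bb
            masks["basicBB_nonoverlap_small"][t] = True
        else:
            cols["basicBB_nonoverlap_large"][t] = bb
            masks["basicBB_nonoverlap_large"][t] = True

        if not small[t] and not small[t - 1] and t in hier_blocks and t - 1 in hier_blocks:
            h1, h2 = frozenset(hier_blocks[t - 1]), frozenset(hier_blocks[t])
            cols["hierBB_nonoverlap"][t] = 1.0 - len(h1 & h2) / len(h1 | h2)
            masks["hierBB_nonoverlap"][t] = True

        rel_diff = float(m["relation_same"] == 0)
        if small[t] and small[t - 1]:
            key = "relational_nonoverlap_small"
        elif not small[t] and not small[t - 1]:
            key = "relational_nonoverlap_large"
        else:
            key = "relational_nonoverlap_cross"
        cols[key][t] = rel_diff
        masks[key][t] = True

    raw = pd.DataFrame(cols)
    mask = pd.DataFrame(masks)
    proj_fn = {"minmax": _project_minmax, "absmax": _project_absmax}.get(projection)
    if proj_fn is None:
        raise ValueError(f"unknown projection {projection!r}")
    projected = {}
    dropped = []
    for name in raw.columns:
        out = np.zeros(n)
        any_var = False
        for sess in np.unique(sessions):
            sm = mask[name].to_numpy() & (sessions == sess)
            if not sm.any():
                continue
            seg = proj_fn(raw[name].to_numpy(), sm)
            out[sm] = seg[sm]
            if raw[name].to_numpy()[sm].std() > 0:
                any_var = True
        if any_var:
            projected[name] = out
        else:
            if mask[name].to_numpy().any():
                warnings.warn(f"zero-variance regressor {name!r} dropped")
            dropped.append(name)
    return RSDesign(raw=raw, mask=mask, projected=pd.DataFrame(projected),
                    sessions=sessions, dropped=tuple(dropped),
                    manifest={"projection": projection, "pixel_norm": pixel_norm,
                              "small_max_blocks": small_max_blocks})


# ---------------------------------------------------------------------------
# adaptation GLM
# ---------------------------------------------------------------------------


def canonical_hrf(tr_s: float = 1.0, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the scan rate."""
    from nilearn.glm.first_level.hemodynamic_models import spm_hrf

    return spm_hrf(tr_s, oversampling=1, time_length=duration_s)


@dataclass
class AdaptationGLMResults:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    nobs: int

    def summary(self) -> str:
        lines = [f"Adaptation GLM ({self.nobs} scans)",
                 f"{'regressor':<28}{'coef':>10}{'se':>10}{'t':>8}"]
        for name in self.params.index:
            lines.append(f"{name:<28}{self.params[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}{self.tvalues[name]:>8.2f}")
        return "\n".join(lines)


class AdaptationGLM:
    """Least-squares fit of the convolved repetition-suppression design.

    Trial onsets are stick functions on the scan grid (one trial every
    ``isi_scans`` scans), parametrically modulated by each projected design
    column, convolved with the HRF.  An onset column (unmodulated sticks) and
    an intercept are always included.
    """

    def __init__(self, design: RSDesign, isi_scans: int = 2,
                 hrf: np.ndarray | None = None, tr_s: float = 1.0) -> None:
        self.design = design
        self.isi_scans = isi_scans
        self.hrf = hrf if hrf is not None else canonical_hrf(tr_s)
        self.n_scans = design.n_trials * isi_scans + self.hrf.size

    def convolved_design(self) -> pd.DataFrame:
        n = self.n_scans
        onsets = np.arange(self.design.n_trials) * self.isi_scans
        X = {}
        stick = np.zeros(n)
        stick[onsets] = 1.0
        X["onset"] = np.convolve(stick, self.hrf)[:n]
        for name in self.design.projected.columns:
            s = np.zeros(n)
            s[onsets] = self.design.projected[name].to_numpy()
            X[name] = np.convolve(s, self.hrf)[:n]
        return pd.DataFrame(X)

    def fit(self, signal: np.ndarray) -> AdaptationGLMResults:
        import statsmodels.api as sm

        signal = np.asarray(signal, dtype=float)
        X = self.convolved_design()
        if signal.size != len(X):
            raise ValueError(f"signal length {signal.size} != design rows {len(X)}")
        Xc = sm.add_constant(X)
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            warnings.warn("rank-deficient adaptation design; pseudoinverse fit")
        fit = sm.OLS(signal, Xc).fit()
        return AdaptationGLMResults(params=fit.params, bse=fit.bse,
                                    tvalues=fit.tvalues, nobs=int(fit.nobs))


def fit_adaptation_glm(design: RSDesign, signal: np.ndarray,
                       **kwargs) -> AdaptationGLMResults:
    return AdaptationGLM(design, **kwargs).fit(signal)


# ---------------------------------------------------------------------------
# behavioral similarity logistic model
# ---------------------------------------------------------------------------

SMALL_PREDICTORS = ("Diff_pixel", "Diff_size", "Diff_relation", "Diff_basicBBs")
LARGE_PREDICTORS = SMALL_PREDICTORS + ("Diff_hierBBs",)


@dataclass
class SimilarityLogitResults:
    """Per-subject logistic coefficients and the group one-sample t-test."""

    subject_params: pd.DataFrame  # subjects x coefficients
    subject_bse: pd.DataFrame
    group_t: pd.Series
    group_p: pd.Series
    silhouette_class: str

    def summary(self) -> str:
        lines = [f"Similarity logistic model ({self.silhouette_class} "
                 f"silhouettes, {len(self.subject_params)} subjects)",
                 f"{'predictor':<16}{'mean beta':>11}{'sd':>9}{'t':>8}{'p':>10}"]
        for name in self.subject_params.columns:
            b = self.subject_params[name]
            lines.append(f"{name:<16}{b.mean():>11.3f}{b.std():>9.3f}"
                         f"{self.group_t[name]:>8.2f}{self.group_p[name]:>10.4f}")
        return "\n".join(lines)


class SimilarityLogit:
    """Per-subject maximum-likelihood logistic fit of left/right similarity
    choices on Diff predictors, with a penalized fallback when the data are
    perfectly separated."""

    def __init__(self, tables: Sequence[pd.DataFrame],
                 predictors: Sequence[str] = SMALL_PREDICTORS,
                 silhouette_class: str = "small") -> None:
        self.tables = list(tables)
        self.predictors = tuple(predictors)
        self.silhouette_class = silhouette_class

    def _fit_one(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                     PerfectSeparationWarning)

        for col in self.predictors:
            if not np.all(np.isfinite(table[col])):
                raise ValueError(f"non-finite predictor {col!r}")
        y = (table["choice"] == "left").astype(int).to_numpy()
        X = sm.add_constant(table[list(self.predictors)].to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.Logit(y, X).fit(disp=0)
            if np.all(np.isfinite(fit.bse)):
                return fit.params, fit.bse
            raise PerfectSeparationError("non-finite standard errors")
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError):
            warnings.warn("perfect separation; falling back to a ridge-"
                          "penalized logistic fit (no standard errors)")
            fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
            return fit.params, np.full(X.shape[1], np.nan)

    def fit(self) -> SimilarityLogitResults:
        names = ["const", *self.predictors]
        params, bses = [], []
        for table in self.tables:
            p, b = self._fit_one(table)
            params.append(p)
            bses.append(b)
        params = pd.DataFrame(params, columns=names)
        bses = pd.DataFrame(bses, columns=names)
        t, p = stats.ttest_1samp(params.to_numpy(), 0.0, axis=0)
        return SimilarityLogitResults(
            subject_params=params, subject_bse=bses,
            group_t=pd.Series(t, index=names), group_p=pd.Series(p, index=names),
            silhouette_class=self.silhouette_class)


def fit_similarity_logistic(tables: Sequence[pd.DataFrame],
                            predictors: Sequence[str] = SMALL_PREDICTORS,
                            **kwargs) -> SimilarityLogitResults:
    return SimilarityLogit(tables, predictors, **kwargs).fit()
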