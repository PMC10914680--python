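"""GLM-based representational similarity analysis.

Two analyses share this module:

* the silhouette-algebra contrast — composite patterns ``+WX - YX + YZ`` are
  compared, via cross-session correlation distances, against the target
  (``WZ``) and the reference (``ZW``, same blocks, swapped relational
  positions); a GLM asks whether composite-target distances are smaller than
  composite-reference distances while controlling for pixel- and size-based
  theoretical distances;
* the time-resolved variant for sensor epochs — a one-hot GLM yields a
  sensor x silhouette coefficient pattern per time point; empirical pattern
  similarities are regressed on z-scored theoretical similarities
  (conjunctive overlap, pixel overlap, size), with shuffle-percentile
  significance thresholds.

Pattern prewhitening uses a Ledoit-Wolf shrinkage covariance estimated from
condition-mean-removed residuals.  Searchlights replace geodesic cortical
neighbourhoods by k-nearest features on the synthetic feature coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf, empirical_covariance, shrunk_covariance
from sklearn.neighbors import NearestNeighbors

from .containers import EpochTensor, PatternSet
from .stimuli import AlgebraTriplet, Silhouette, conjunctive_overlap, overlap_metrics


class NumericalError(ValueError):
    pass


class EmptyDesignError(ValueError):
    pass


class DesignError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# prewhitening
# ---------------------------------------------------------------------------


def _inv_sqrt(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if np.any(vals <= floor * vals.max()):
        vals = np.maximum(vals, floor * vals.max())
    return (vecs / np.sqrt(vals)) @ vecs.T


def prewhiten(patterns: PatternSet, shrinkage: float | None = None) -> PatternSet:
    """Multiply patterns by the inverse square root of a shrinkage-regularised
    feature covariance estimated from condition-mean-removed residuals.

    ``shrinkage=None`` uses the Ledoit-Wolf estimate; ``shrinkage=1`` reduces
    to a global univariate scaling.  An identity noise covariance leaves the
    patterns unchanged up to scale.
    """
    if patterns.n_conditions < 2:
        raise NumericalError("need at least two conditions")
    resid = patterns.values - patterns.values.mean(axis=2, keepdims=True)
    obs = np.moveaxis(resid, 1, 2).reshape(-1, patterns.n_features)
    if shrinkage is None:
        cov = LedoitWolf(assume_centered=True).fit(obs).covariance_
    else:
        cov = shrunk_covariance(empirical_covariance(obs, assume_centered=True),
                                shrinkage=shrinkage)
    if not np.all(np.isfinite(cov)) or np.all(cov == 0):
        raise NumericalError("degenerate residual covariance")
    W = _inv_sqrt(cov)
    white = np.einsum("fg,cgs->cfs", W, patterns.values)
    return PatternSet(white, list(patterns.condition_labels),
                      patterns.feature_coords,
                      {**patterns.meta, "prewhitened": True})


def _corr_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation between two patterns."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise NumericalError("zero-variance pattern in distance computation")
    return float(1.0 - (xc @ yc) / denom)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


# ---------------------------------------------------------------------------
# silhouette-algebra RSA
# ---------------------------------------------------------------------------


def _pair_label(s: Silhouette) -> str:
    """Condition label of a two-block compound: active block then passive
    block of its single edge (below/right-of folded onto on-top/left-of)."""
    from .stimuli import _canonical_pair

    key = _canonical_pair(s)
    if key is None:
        raise KeyError("not a two-block compound")
    return key[0] + key[1]


@dataclass
class AlgebraRSAResults:
    """Fit of the silhouette-algebra contrast.

    ``params``/``bse``/``tvalues`` index the regressors (``conjunctive`` is
    the quantity of interest: positive when composite-target distances are
    smaller than composite-reference distances).  ``pair_table`` holds every
    cross-session distance that entered the GLM.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    nobs: int
    pair_table: pd.DataFrame

    @property
    def conjunctive_coef(self) -> float:
        return float(self.params["conjunctive"])

    def mean_distance(self, kind: str) -> float:
        """Mean composite distance to 'target' or 'reference' silhouettes."""
        t = self.pair_table
        return float(t.loc[t["pair_kind"] == kind, "distance"].mean())

    def summary(self) -> str:
        lines = [f"Silhouette-algebra RSA ({self.nobs} cross-session pairs)",
                 f"{'regressor':<14}{'coef':>10}{'se':>10}{'t':>8}"]
        for name in self.params.index:
            lines.append(f"{name:<14}{self.params[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}{self.tvalues[name]:>8.2f}")
        lines.append(f"mean distance composite-target:    "
                     f"{self.mean_distance('target'):.4f}")
        lines.append(f"mean distance composite-reference: "
                     f"{self.mean_distance('reference'):.4f}")
        return "\n".join(lines)


class AlgebraRSA:
    """Model object for the silhouette-algebra contrast on a pattern set.

    For every algebra triplet the composite pattern ``+WX - YX + YZ`` is
    formed per session; distances (1 - correlation) from composites to
    targets and references are computed across sessions only, and regressed
    on a conjunctive predictor (reference pairs +0.5, target pairs -0.5) plus
    z-scored pixel- and size-based control distances.
    """

    def __init__(self, patterns: PatternSet, triplets: Sequence[AlgebraTriplet],
                 whiten: bool = True, shrinkage: float | None = None) -> None:
        if patterns.n_sessions < 2:
            raise EmptyDesignError("cross-session distances need >= 2 sessions")
        self.patterns = prewhiten(patterns, shrinkage) if whiten else patterns
        self.triplets = list(triplets)

    def _theoretical_controls(self, trip: AlgebraTriplet, sil: Silhouette
                              ) -> tuple[float, float]:
        """Visual-space analogues of the empirical composite distance.

        The pixel control applies the same signed combination to the terms'
        occupancy rasters and takes the correlation distance to the
        candidate's raster; the size control does the same in (height,
        width) space.  This mirrors how a purely visual pattern code would
        shape the empirical distances, so shared variance between the
        conjunctive contrast and visual structure is removed."""
        from .synthetic import _visual_vector

        v_comp = sum(sign * _visual_vector(term) for sign, term in trip.terms)
        v_sil = _visual_vector(sil)
        na, nb = np.linalg.norm(v_comp), np.linalg.norm(v_sil)
        pix = 1.0 if na == 0 or nb == 0 else 1.0 - float(v_comp @ v_sil / (na * nb))
        dims = lambda s: np.array([s.height, s.width], float)
        s_comp = sum(sign * dims(term) for sign, term in trip.terms)
        size = float(np.abs(s_comp - dims(sil)).sum())
        return pix, size

    def fit(self) -> AlgebraRSAResults:
        import statsmodels.api as sm

        pats = self.patterns
        rows = []
        for k, trip in enumerate(self.triplets):
            term_idx = [(sign, _pair_label(s)) for sign, s in trip.terms]
            for lbl in [l for _, l in term_idx]:
                if lbl not in pats.condition_labels:
                    raise KeyError(f"condition {lbl!r} missing from pattern set")
            composite = sum(sign * pats.pattern(lbl) for sign, lbl in term_idx)
            for kind, sil in (("target", trip.target), ("reference", trip.reference)):
                lbl = _pair_label(sil)
                if lbl not in pats.condition_labels:
                    raise KeyError(f"condition {lbl!r} missing from pattern set")
                other = pats.pattern(lbl)
                pix, size = self._theoretical_controls(trip, sil)
                for s1 in range(pats.n_sessions):
                    for s2 in range(pats.n_sessions):
                        if s1 == s2:
                            continue  # cross-session distances only
                        rows.append({
                            "triplet": k, "pair_kind": kind,
                            "session_pair": (s1, s2),
                            "distance": _corr_distance(composite[:, s1],
                                                       other[:, s2]),
                            "pixel_ctrl": pix, "size_ctrl": size,
                        })
        if not rows:
            raise EmptyDesignError("no cross-session pairs")
        table = pd.DataFrame(rows)
        conj = np.where(table["pair_kind"] == "reference", 0.5, -0.5)
        X = pd.DataFrame({
            "conjunctive": conj,
            "pixel": _zscore(table["pixel_ctrl"].to_numpy()),
            "size": _zscore(table["size_ctrl"].to_numpy()),
        })
        X = sm.add_constant(X)
        fit = sm.OLS(table["distance"].to_numpy(), X).fit()
        return AlgebraRSAResults(params=fit.params, bse=fit.bse,
                                 tvalues=fit.tvalues, nobs=int(fit.nobs),
                                 pair_table=table)


def algebra_rsa(patterns: PatternSet, triplets: Sequence[AlgebraTriplet],
                **kwargs) -> AlgebraRSAResults:
    """Functional wrapper: fit the silhouette-algebra contrast."""
    return AlgebraRSA(patterns, triplets, **kwargs).fit()


def algebra_rsa_group(
    pattern_sets: Sequence[PatternSet], triplets: Sequence[AlgebraTriplet],
    **kwargs,
) -> pd.DataFrame:
    """Per-subject conjunctive coefficients plus a group one-sample t-test.

    Returns a one-row-per-subject frame; the group statistic is in
    ``frame.attrs['t']`` / ``attrs['p']``.
    """
    coefs = [AlgebraRSA(p, triplets, **kwargs).fit().conjunctive_coef
             for p in pattern_sets]
    out = pd.DataFrame({"subject": range(len(coefs)), "conjunctive": coefs})
    t, p = stats.ttest_1samp(coefs, 0.0)
    out.attrs["t"] = float(t)
    out.attrs["p"] = float(p)
    return out


def searchlight_map(
    patterns: PatternSet,
    triplets: Sequence[AlgebraTriplet],
    k: int = 100,
    op: Callable[..., AlgebraRSAResults] | None = None,
    **kwargs,
) -> np.ndarray:
    """Searchlight contrast map: for every feature, run the algebra contrast
    on its ``k`` nearest features (Euclidean distance on the synthetic
    feature coordinates) and return the per-feature conjunctive coefficient.
    """
    if patterns.feature_coords is None:
        raise ConfigError("pattern set has no feature coordinates")
    if k > patterns.n_features:
        raise ConfigError("searchlight size exceeds feature count")
    op = op or algebra_rsa
    nn = NearestNeighbors(n_neighbors=k).fit(patterns.feature_coords)
    _, idx = nn.kneighbors(patterns.feature_coords)
    out = np.zeros(patterns.n_features)
    for f in range(patterns.n_features):
        res = op(patterns.subset_features(idx[f]), triplets, **kwargs)
        out[f] = res.conjunctive_coef
    return out


# ---------------------------------------------------------------------------
# time-resolved RSA on sensor epochs
# ---------------------------------------------------------------------------


def theoretical_similarities(
    stimuli: Mapping[str, Silhouette]
) -> dict[str, np.ndarray]:
    """Named theoretical similarity matrices over a stimulus set (sorted by
    label): conjunctive overlap counts, maximal pixel overlap, and negative
    size difference (larger = more similar)."""
    labels = sorted(stimuli)
    n = len(labels)
    conj = np.zeros((n, n))
    pixel = np.zeros((n, n))
    size = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            m = overlap_metrics(stimuli[a], stimuli[b])
            conj[i, j] = conjunctive_overlap(stimuli[a], stimuli[b])
            pixel[i, j] = m["pixel_overlap"]
            size[i, j] = -m["size_nonoverlap"]
    return {"conjunctive": conj, "pixel": pixel, "size": size}


@dataclass
class MegRsaResults:
    """Per-time predictor coefficients with shuffle-percentile thresholds."""

    times_ms: np.ndarray
    coef: pd.DataFrame  # one column per predictor, one row per time
    thresholds: dict[str, tuple[float, float]]
    n_shuffles: int

    def significant(self, predictor: str) -> np.ndarray:
        lo, hi = self.thresholds[predictor]
        c = self.coef[predictor].to_numpy()
        return (c < lo) | (c > hi)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.coef.columns:
            lo, hi = self.thresholds[name]
            for t, v in zip(self.times_ms, self.coef[name]):
                rows.append({"time_ms": t, "predictor": name,
                             "coefficient": v, "lo": lo, "hi": hi})
        return pd.DataFrame(rows)


def meg_rsa_timecourse(
    epochs: EpochTensor,
    theos: Mapping[str, np.ndarray],
    n_shuffles: int = 5000,
    whiten: bool = True,
    seed: int = 0,
    times_ms: Sequence[float] | None = None,
) -> MegRsaResults:
    """Time-resolved RSA from a one-hot GLM on sensor epochs.

    Per time sample: a one-hot design (one regressor per stimulus plus a mean
    column) yields a sensor x stimulus coefficient pattern; patterns are
    prewhitened (Ledoit-Wolf on the GLM residuals); pairwise Pearson
    similarities between stimulus patterns are regressed on the z-scored
    theoretical similarities.  Two-sided significance thresholds are the
    2.5th/97.5th percentiles of coefficients recomputed under random
    relabelings of the stimulus conditions (the same label permutation is
    applied to every theoretical matrix, preserving their structure).
    """
    conditions = sorted(set(epochs.labels))
    n_cond = len(conditions)
    for name, m in theos.items():
        if m.shape != (n_cond, n_cond):
            raise DesignError(f"theoretical matrix {name!r} has wrong shape")
    counts = pd.Series(list(epochs.labels)).value_counts()
    if len(counts) != n_cond or counts.min() == 0:
        raise DesignError("every stimulus condition needs at least one epoch")
    cidx = {c: i for i, c in enumerate(conditions)}
    D = np.zeros((epochs.n_trials, n_cond + 1))
    for t, lab in enumerate(epochs.labels):
        D[t, cidx[lab]] = 1.0
    D[:, -1] = 1.0  # mean regressor
    Pd = np.linalg.pinv(D)

    if times_ms is None:
        tmask = np.ones(epochs.times_ms.size, dtype=bool)
    else:
        tmask = np.isin(epochs.times_ms, np.asarray(times_ms))
    times = epochs.times_ms[tmask]
    V = epochs.values[:, :, tmask]  # trials x sensors x times
    Bfull = np.einsum("cn,nst->cst", Pd, V)  # (cond+1) x sensors x times
    B = Bfull[:n_cond]

    iu = np.triu_indices(n_cond, k=1)
    names = list(theos)
    Xcols = [_zscore(theos[name][iu]) for name in names]
    X = np.column_stack(Xcols + [np.ones(iu[0].size)])
    PX = np.linalg.pinv(X)

    emp = np.zeros((iu[0].size, times.size))
    for ti in range(times.size):
        pat = B[:, :, ti]
        if whiten:
            resid = V[:, :, ti] - D @ Bfull[:, :, ti]
            cov = LedoitWolf(assume_centered=True).fit(resid).covariance_
            pat = pat @ _inv_sqrt(cov)
        emp[:, ti] = np.corrcoef(pat)[iu]
    coefs = PX @ emp  # (k+1) x times

    rng = np.random.default_rng(seed)
    shuf_vals: dict[str, list[np.ndarray]] = {name: [] for name in names}
    for _ in range(n_shuffles):
        perm = rng.permutation(n_cond)
        Xs = np.column_stack(
            [_zscore(theos[name][np.ix_(perm, perm)][iu]) for name in names]
            + [np.ones(iu[0].size)])
        cs = np.linalg.pinv(Xs) @ emp
        for i, name in enumerate(names):
            shuf_vals[name].append(cs[i])
    thresholds = {}
    for name in names:
        pool = np.concatenate(shuf_vals[name])
        thresholds[name] = (float(np.percentile(pool, 2.5)),
                            float(np.percentile(pool, 97.5)))
    coef_df = pd.DataFrame({name: coefs[i] for i, name in enumerate(names)})
    return MegRsaResults(times_ms=times, coef=coef_df, thresholds=thresholds,
                         n_shuffles=n_shuffles)
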