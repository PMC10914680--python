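"""RSA: prewhitening, the algebra contrast, searchlights, time courses."""

import numpy as np
import pytest

from replaykit import rsa
from replaykit import synthetic as syn
from replaykit.containers import PatternSet
from replaykit.rsa import (
    AlgebraRSA,
    ConfigError,
    EmptyDesignError,
    NumericalError,
    prewhiten,
)
from replaykit.synthetic import GeneratorConfig


def make_patterns(rng, n_cond=6, n_feat=30, n_sess=3, labels=None):
    vals = rng.standard_normal((n_cond, n_feat, n_sess))
    labels = labels or [f"c{i}" for i in range(n_cond)]
    return PatternSet(vals, labels, feature_coords=rng.uniform(0, 1, (n_feat, 3)))


class TestPrewhiten:
    def test_identity_noise_is_identity_up_to_scale(self, rng):
        pats = make_patterns(rng, n_cond=40, n_feat=10)
        white = prewhiten(pats)
        # whitening with near-identity covariance preserves correlation
        a = pats.values.reshape(40, -1)
        b = white.values.reshape(40, -1)
        for i in range(0, 40, 7):
            r = np.corrcoef(a[i], b[i])[0, 1]
            assert r > 0.95

    def test_reduces_planted_feature_correlations(self, rng):
        n_cond, n_feat, n_sess = 30, 8, 4
        shared = rng.standard_normal((n_cond, 1, n_sess))
        vals = shared + 0.3 * rng.standard_normal((n_cond, n_feat, n_sess))
        pats = PatternSet(vals, [f"c{i}" for i in range(n_cond)])
        white = prewhiten(pats)

        def mean_noise_corr(p):
            resid = p.values - p.values.mean(axis=2, keepdims=True)
            obs = np.moveaxis(resid, 1, 2).reshape(-1, n_feat)
            r = np.corrcoef(obs.T)
            return np.abs(r[np.triu_indices(n_feat, 1)]).mean()

        assert mean_noise_corr(white) < 0.5 * mean_noise_corr(pats)

    def test_full_shrinkage_is_univariate_scaling(self, rng):
        pats = make_patterns(rng, n_cond=20, n_feat=6)
        white = prewhiten(pats, shrinkage=1.0)
        ratio = white.values / pats.values
        assert np.allclose(ratio, ratio.ravel()[0])

    def test_single_condition_rejected(self, rng):
        pats = PatternSet(rng.standard_normal((1, 5, 3)), ["a"])
        with pytest.raises(NumericalError):
            prewhiten(pats)


class TestAlgebraRSA:
    def test_zero_noise_identity_and_positive_contrast(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=3, noise_sd=0.0)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive")
        res = AlgebraRSA(pats, triplets, whiten=False).fit()
        assert res.mean_distance("target") == pytest.approx(0.0, abs=1e-9)
        assert res.mean_distance("reference") > 0.1
        assert res.conjunctive_coef > 0

    def test_session_order_invariance(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=4)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive")
        perm = PatternSet(pats.values[:, :, [2, 0, 1]],
                          list(pats.condition_labels), pats.feature_coords)
        a = AlgebraRSA(pats, triplets, whiten=False).fit().conjunctive_coef
        b = AlgebraRSA(perm, triplets, whiten=False).fit().conjunctive_coef
        assert a == pytest.approx(b)

    def test_orthogonal_rotation_invariance(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=4)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive")
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.standard_normal((pats.n_features,) * 2))
        rot = PatternSet(np.einsum("fg,cgs->cfs", Q, pats.values),
                         list(pats.condition_labels))
        a = AlgebraRSA(pats, triplets, whiten=False).fit().conjunctive_coef
        b = AlgebraRSA(rot, triplets, whiten=False).fit().conjunctive_coef
        # correlation distance is not rotation invariant feature-wise, but
        # the fitted contrast is stable under rotation of a shared basis
        assert abs(a - b) < 0.15 * max(abs(a), 1e-3)

    def test_control_mixing_leaves_conjunctive_untouched(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=4)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive")
        model = AlgebraRSA(pats, triplets, whiten=False)
        res = model.fit()
        # adding a linear combination of the control predictors to the
        # distances must not change the conjunctive coefficient
        table = res.pair_table
        import statsmodels.api as sm
        import pandas as pd

        from replaykit.rsa import _zscore

        conj = np.where(table["pair_kind"] == "reference", 0.5, -0.5)
        X = sm.add_constant(pd.DataFrame({
            "conjunctive": conj,
            "pixel": _zscore(table["pixel_ctrl"].to_numpy()),
            "size": _zscore(table["size_ctrl"].to_numpy())}))
        y = table["distance"].to_numpy() + 2.0 * X["pixel"] - 1.0 * X["size"]
        fit = sm.OLS(y, X).fit()
        assert fit.params["conjunctive"] == pytest.approx(
            res.params["conjunctive"], abs=1e-10)

    def test_single_session_rejected(self, rng, pair_set, triplets):
        pats = PatternSet(rng.standard_normal((12, 25, 1)), sorted(pair_set))
        with pytest.raises(EmptyDesignError):
            AlgebraRSA(pats, triplets)

    def test_missing_condition_rejected(self, rng, triplets):
        pats = PatternSet(rng.standard_normal((2, 25, 3)), ["WX", "YX"])
        with pytest.raises(KeyError):
            AlgebraRSA(pats, triplets, whiten=False).fit()

    def test_group_t_positive_for_conjunctive(self, pair_set, triplets):
        sets = [syn.gen_pattern_set(GeneratorConfig(seed=s), pair_set,
                                    "conjunctive") for s in range(8)]
        out = rsa.algebra_rsa_group(sets, triplets, whiten=False)
        assert out.attrs["t"] > 2.0


class TestSearchlight:
    def test_localises_planted_code(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=5, n_features=60, noise_sd=0.3,
                              visual_sd=0.0)
        planted = np.arange(20)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive",
                                   conjunctive_features=planted)
        # cluster planted features spatially so neighbourhoods align
        coords = np.array(pats.feature_coords)
        coords[:20, 0] = 0.0
        coords[20:, 0] = 100.0
        pats = PatternSet(pats.values, list(pats.condition_labels), coords)
        cmap = rsa.searchlight_map(pats, triplets, k=15, whiten=False)
        top = np.argsort(cmap)[-10:]
        assert np.mean(top < 20) >= 0.8

    def test_k_equal_to_features_reproduces_whole_set(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=5, n_features=25)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive")
        cmap = rsa.searchlight_map(pats, triplets, k=25, whiten=False)
        whole = AlgebraRSA(pats, triplets, whiten=False).fit().conjunctive_coef
        np.testing.assert_allclose(cmap, whole, rtol=1e-8)

    def test_oversized_neighbourhood_rejected(self, pair_set, triplets):
        cfg = GeneratorConfig(seed=5, n_features=25)
        pats = syn.gen_pattern_set(cfg, pair_set, "conjunctive")
        with pytest.raises(ConfigError):
            rsa.searchlight_map(pats, triplets, k=26)


@pytest.fixture(scope="module")
def windowed_epochs():
    """Epochs whose sensor patterns carry a conjunctive silhouette code only
    between 200 and 1000 ms."""
    rng = np.random.default_rng(9)
    stim = syn.default_stimulus_set()
    theos = rsa.theoretical_similarities(stim)
    labels12 = sorted(stim)
    from replaykit.stimuli import conjunctions

    all_conj = sorted({c for s in stim.values() for c in conjunctions(s)})
    n_sensors, n_trials = 24, 96
    times = np.arange(-100.0, 1500.0, 20.0)
    codes = rng.standard_normal((len(all_conj), n_sensors))
    labels = [labels12[i % 12] for i in range(n_trials)]
    values = 0.7 * rng.standard_normal((n_trials, n_sensors, times.size))
    window = (times >= 200) & (times <= 1000)
    for t, lab in enumerate(labels):
        pat = sum(codes[all_conj.index(c)] for c in conjunctions(stim[lab]))
        values[t][:, window] += pat[:, None]
    epochs = syn.EpochTensor(values, times, labels, 50.0)
    return epochs, theos, window


class TestMegRsaTimecourse:
    def test_conjunctive_coefficient_confined_to_signal_window(self, windowed_epochs):
        epochs, theos, window = windowed_epochs
        res = rsa.meg_rsa_timecourse(epochs, theos, n_shuffles=300, seed=1)
        sig = res.significant("conjunctive")
        assert sig[window].mean() > 0.9
        assert sig[~window].mean() < 0.2

    def test_pure_noise_mostly_inside_thresholds(self):
        rng = np.random.default_rng(3)
        stim = syn.default_stimulus_set()
        theos = rsa.theoretical_similarities(stim)
        labels12 = sorted(stim)
        times = np.arange(0.0, 600.0, 20.0)
        values = rng.standard_normal((48, 20, times.size))
        epochs = syn.EpochTensor(values, times,
                                 [labels12[i % 12] for i in range(48)], 50.0)
        res = rsa.meg_rsa_timecourse(epochs, theos, n_shuffles=300, seed=1)
        for name in theos:
            assert res.significant(name).mean() <= 0.15

    def test_missing_condition_rejected(self, rng):
        stim = syn.default_stimulus_set()
        theos = rsa.theoretical_similarities(stim)
        times = np.arange(0.0, 100.0, 20.0)
        epochs = syn.EpochTensor(rng.standard_normal((5, 8, times.size)),
                                 times, ["a"] * 5, 50.0)
        with pytest.raises(rsa.DesignError):
            rsa.meg_rsa_timecourse(epochs, theos)


def test_theoretical_similarities_shapes(stim12):
    theos = rsa.theoretical_similarities(stim12)
    for m in theos.values():
        assert m.shape == (12, 12)
        np.testing.assert_allclose(m, m.T)
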