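"""Two-level sequenceness GLM: oracles, invariants and recovery."""

import numpy as np
import pytest

from replaykit import synthetic as syn
from replaykit import tdlm
from replaykit.containers import ReactivationSeries
from replaykit.stimuli import RoleAssignment
from replaykit.synthetic import GeneratorConfig
from replaykit.tdlm import (
    SEQ_TYPES,
    EmpiricalTransitions,
    SequencenessModel,
    build_theoretical_matrices,
    first_level,
    second_level,
)

STATES = ("W", "X", "Y", "Z")


def make_series(values, sfreq=100.0, n_trials=1):
    values = np.asarray(values, float)
    T = values.shape[0] // n_trials
    return ReactivationSeries(values, sfreq, STATES, n_trials,
                              np.arange(T) * 10.0, probabilistic=False)


def roles_end():
    """Stable at the end of the chain: W-X-Y, Z absent, Y distant present."""
    return RoleAssignment(stable="W", present=frozenset({"X", "Y"}),
                          absent="Z", distant_present="Y")


def roles_middle():
    return RoleAssignment(stable="W", present=frozenset({"X", "Y"}), absent="Z")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def naive_first_level(trials, lags):
    """Loop-and-lstsq reimplementation of the lagged multiple regression."""
    S = trials[0].shape[1]
    out = np.zeros((len(lags), S, S))
    for di, d in enumerate(lags):
        rows_X, rows_y = [], []
        for Y in trials:
            T = Y.shape[0]
            for t in range(d, T):
                rows_X.append(np.append(Y[t - d], 1.0))
                rows_y.append(Y[t])
        X = np.array(rows_X)
        y = np.array(rows_y)
        for j in range(S):
            beta, *_ = np.linalg.lstsq(X, y[:, j], rcond=None)
            out[di, :, j] = beta[:S]
    return out


def naive_second_level(emp, matrices):
    """Per-lag lstsq of the vectorised empirical matrix on named predictors
    plus ones and identity."""
    names = list(matrices)
    S = emp.shape[1]
    X = np.column_stack([matrices[n].ravel() for n in names]
                        + [np.ones(S * S), np.eye(S).ravel()])
    out = {n: np.zeros(emp.shape[0]) for n in names}
    for d in range(emp.shape[0]):
        beta, *_ = np.linalg.lstsq(X, emp[d].ravel(), rcond=None)
        for i, n in enumerate(names):
            out[n][d] = beta[i]
    return out


# ---------------------------------------------------------------------------
# theoretical matrices
# ---------------------------------------------------------------------------


class TestTheoreticalMatrices:
    def test_entries_binary_zero_diagonal(self):
        theo = build_theoretical_matrices(roles_end(), STATES)
        for m in [*theo.true.values(),
                  *(c for cs in theo.controls.values() for c in cs)]:
            assert set(np.unique(m)) <= {0.0, 1.0}
            assert np.all(np.diag(m) == 0)

    def test_stable_middle_has_no_present_to_present(self):
        theo = build_theoretical_matrices(roles_middle(), STATES)
        assert not theo.applicable["present_to_present"]
        assert np.all(theo.true["present_to_present"] == 0)
        theo2 = build_theoretical_matrices(roles_end(), STATES)
        assert theo2.applicable["present_to_present"]

    def test_two_controls_per_type_substitute_absent(self):
        theo = build_theoretical_matrices(roles_end(), STATES)
        a = STATES.index("Z")
        for t in SEQ_TYPES:
            assert len(theo.controls[t]) == 2
            for ctrl in theo.controls[t]:
                # every control transition involves the absent block
                ii, jj = np.nonzero(ctrl)
                assert np.all((ii == a) | (jj == a))

    def test_expected_entries(self):
        theo = build_theoretical_matrices(roles_end(), STATES)
        s, x, y = (STATES.index(k) for k in "WXY")
        assert theo.true["stable_to_present"][s, x] == 1
        assert theo.true["stable_to_present"][s, y] == 1
        assert theo.true["present_to_stable"][x, s] == 1
        assert theo.true["present_to_present"][x, y] == 1

    def test_edge_basis_restricts_to_connected_pairs(self):
        # chain W-X-Y: W touches only X
        theo = build_theoretical_matrices(
            roles_end(), STATES, basis="edge",
            edges=[("W", "X"), ("X", "Y")])
        s, x, y = (STATES.index(k) for k in "WXY")
        assert theo.true["stable_to_present"][s, x] == 1
        assert theo.true["stable_to_present"][s, y] == 0


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------


class TestFirstLevel:
    def test_white_noise_coefficients_unbiased(self):
        rng = np.random.default_rng(11)
        means = []
        for _ in range(100):
            series = make_series(rng.standard_normal((200, 4)))
            emp = first_level(series, max_lag_ms=50.0)
            means.append(emp.coef[2, 0, 1])
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se

    def test_planted_pair_is_global_maximum(self, cfg):
        sch = syn.gen_trial_schedule(cfg, 1, 24)
        _, truth = syn.gen_task_run(cfg, sch, planted=[(("X", "Y"), 60.0, 1.0)])
        emp = first_level(truth, max_lag_ms=300.0)
        off = emp.coef.copy()
        off[:, np.arange(4), np.arange(4)] = -np.inf  # exclude self-transitions
        d, i, j = np.unravel_index(np.argmax(off), off.shape)
        assert emp.lags_ms[d] == 60.0
        assert (STATES[i], STATES[j]) == ("X", "Y")

    def test_matches_naive_oracle_pooled(self, rng):
        trials = [rng.standard_normal((120, 4)) for _ in range(3)]
        series = make_series(np.vstack(trials), n_trials=3)
        emp = first_level(series, max_lag_ms=80.0)
        lags = np.arange(1, 9)
        expected = naive_first_level(trials, lags)
        np.testing.assert_allclose(emp.coef, expected, rtol=1e-8, atol=1e-10)

    def test_zero_variance_state_flagged_and_zeroed(self, rng):
        vals = rng.standard_normal((150, 4))
        vals[:, 2] = 0.7
        series = make_series(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            emp = first_level(series, max_lag_ms=50.0)
        assert np.all(emp.coef[:, 2, :] == 0)

    def test_time_reversal_antisymmetry_on_periodic_data(self, rng):
        # boundary-free check: on long periodic standardized data, reversing
        # time swaps the (i->j) and (j->i) pairwise coefficients
        base = rng.standard_normal((500, 4))
        vals = np.tile(base, (8, 1))
        vals = (vals - vals.mean(0)) / vals.std(0)
        fwd = first_level(make_series(vals), max_lag_ms=40.0, mode="simple")
        rev = first_level(make_series(vals[::-1]), max_lag_ms=40.0,
                          mode="simple")
        np.testing.assert_allclose(fwd.coef, np.swapaxes(rev.coef, 1, 2),
                                   atol=5e-3)

    def test_max_lag_must_fit_trial(self, rng):
        series = make_series(rng.standard_normal((30, 4)))
        with pytest.raises(tdlm.ConfigError):
            first_level(series, max_lag_ms=500.0)


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------


class TestSecondLevel:
    def test_regression_identity(self):
        theo = build_theoretical_matrices(roles_end(), STATES)
        emp = EmpiricalTransitions(
            np.array([10.0]), theo.true["present_to_stable"][None], STATES)
        out = second_level(emp, theo)
        vals = out.set_index("sequence_type")["coefficient"]
        assert vals["present_to_stable"] == pytest.approx(1.0)
        assert vals["stable_to_present"] == pytest.approx(0.0, abs=1e-12)
        assert vals["present_to_present"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_offset_invariance(self, rng):
        theo = build_theoretical_matrices(roles_end(), STATES)
        base = rng.standard_normal((5, 4, 4))
        emp0 = EmpiricalTransitions(np.arange(5.0), base, STATES)
        emp1 = EmpiricalTransitions(np.arange(5.0), base + 3.7, STATES)
        a = second_level(emp0, theo)["coefficient"].to_numpy()
        b = second_level(emp1, theo)["coefficient"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_matches_naive_oracle(self, rng):
        theo = build_theoretical_matrices(roles_end(), STATES)
        emp = rng.standard_normal((6, 4, 4))
        out = second_level(EmpiricalTransitions(np.arange(6.0), emp, STATES),
                           theo)
        expected = naive_second_level(emp, theo.true)
        for t in SEQ_TYPES:
            got = out[out.sequence_type == t]["coefficient"].to_numpy()
            np.testing.assert_allclose(got, expected[t], rtol=1e-8)


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------


class TestSequencenessModel:
    def test_whole_stack_matches_naive_oracle(self, rng):
        """First + second level on a short series against the independently
        coded loop/lstsq implementation."""
        n_trials, T = 4, 120
        trials = [np.abs(rng.standard_normal((T, 4))) * 0.2 for _ in range(n_trials)]
        series = make_series(np.vstack(trials), n_trials=n_trials)
        roles = [roles_end()] * n_trials
        res = SequencenessModel(series, roles, max_lag_ms=100.0).fit()
        lags = np.arange(1, 11)
        theo = build_theoretical_matrices(roles_end(), STATES)
        per_trial = [naive_first_level([tr], lags) for tr in trials]
        expected = {t: np.zeros(lags.size) for t in SEQ_TYPES}
        for emp in per_trial:
            naive = naive_second_level(emp, theo.true)
            for t in SEQ_TYPES:
                expected[t] += naive[t] / n_trials
        for t in SEQ_TYPES:
            np.testing.assert_allclose(res.coef[t], expected[t], rtol=1e-8,
                                       atol=1e-12)

    def test_planted_sequence_recovered_and_exceeds_bound(self, cfg):
        sch = syn.gen_trial_schedule(cfg, 1, 48)
        _, truth = syn.gen_task_run(cfg, sch,
                                    planted=[(("present", "stable"), 60.0, 0.8)])
        res = SequencenessModel(truth, sch).fit()
        lag, _ = res.peak("present_to_stable")
        assert abs(lag - 60.0) <= 10.0
        assert res.exceeds_bound("present_to_stable")

    def test_tidy_frame_and_summary(self, cfg):
        sch = syn.gen_trial_schedule(cfg, 1, 24)
        _, truth = syn.gen_task_run(cfg, sch)
        res = SequencenessModel(truth, sch).fit()
        df = res.to_frame()
        assert set(df.columns) == {"lag_ms", "sequence_type", "coefficient",
                                   "ctrl_min", "ctrl_max"}
        assert (df.ctrl_min <= df.ctrl_max).all()
        assert "present_minus_stable" in res.summary()

    def test_role_count_mismatch_rejected(self, rng):
        series = make_series(rng.standard_normal((100, 4)), n_trials=2)
        with pytest.raises(tdlm.ConfigError):
            SequencenessModel(series, [roles_end()] * 3)


class TestSlidingWindow:
    def test_canonical_grid_has_301_windows(self):
        assert tdlm.n_windows() == 301
        assert tdlm.n_windows(window_ms=500.0, step_ms=500.0) == 8

    def test_window_frame_matches_canonical_grid(self, rng):
        T = 400  # -500..3490 ms at 100 Hz
        n_trials = 3
        vals = np.abs(rng.standard_normal((n_trials * T, 4))) * 0.1
        series = ReactivationSeries(vals, 100.0, STATES, n_trials,
                                    np.arange(-500.0, 3500.0, 10.0),
                                    probabilistic=False)
        model = SequencenessModel(series, [roles_end()] * n_trials)
        df = model.sliding_window(lag_band_ms=(10.0, 100.0))
        starts = df["window_start_ms"].unique()
        assert len(starts) == 301
        assert starts[0] == -500.0 and starts[-1] == 2500.0

    def test_localised_sequence_peaks_in_overlapping_windows(self, rng):
        # plant X->W (present->stable) events only inside 1500-2500 ms
        T, n_trials, lag = 400, 40, 6
        times = np.arange(-500.0, 3500.0, 10.0)
        vals = rng.uniform(0, 0.05, size=(n_trials, T, 4))
        for tr in range(n_trials):
            for t0 in rng.integers(200, 290, size=4):  # 1500-2400 ms
                vals[tr, t0, 1] += 1.0          # X
                vals[tr, t0 + lag, 0] += 1.0    # W
        series = ReactivationSeries(np.clip(vals, 0, 1).reshape(-1, 4), 100.0,
                                    STATES, n_trials, times)
        model = SequencenessModel(series, [roles_end()] * n_trials)
        df = model.sliding_window(window_ms=1000.0, step_ms=100.0,
                                  lag_band_ms=(10.0, 100.0))
        p2s = df[df.sequence_type == "present_to_stable"]
        best = p2s.loc[p2s.coefficient.idxmax(), "window_center_ms"]
        assert 1000.0 <= best <= 3000.0
        inside = p2s[(p2s.window_center_ms >= 1500) & (p2s.window_center_ms <= 2500)]
        outside = p2s[p2s.window_center_ms < 500]
        assert inside.coefficient.mean() > 3 * abs(outside.coefficient.mean())

    def test_window_shorter_than_lag_band_rejected(self, rng):
        series = make_series(np.abs(rng.standard_normal((400, 4))) * 0.1)
        model = SequencenessModel(series, [roles_end()])
        with pytest.raises(tdlm.ConfigError):
            model.sliding_window(window_ms=300.0, lag_band_ms=(10.0, 200.0))


class TestLength3:
    def test_white_noise_near_zero(self, rng):
        vals = rng.standard_normal((3 * 200, 4))
        series = make_series(vals, n_trials=3)
        res = tdlm.length3(series, max_lag_ms=60.0)
        assert np.nanmax(np.abs(res.coef)) < 0.5

    def test_planted_chain_recovered(self, cfg):
        sch = syn.gen_trial_schedule(cfg, 1, 48)
        _, truth = syn.gen_task_run(cfg, sch,
                                    planted=[(("X", "Y", "Z"), 60.0, 0.9)])
        rng = np.random.default_rng(0)
        noisy = ReactivationSeries(
            np.clip(truth.values + rng.normal(0, 0.05, truth.values.shape), 0, 1),
            truth.sfreq, STATES, truth.n_trials, truth.times_ms)
        res = tdlm.length3(noisy, max_lag_ms=200.0)
        assert res.argmax_triple(60.0) == ("X", "Y", "Z")
        assert res.get(("X", "Y"), "Z")[np.argmin(np.abs(res.lags_ms - 60))] > 0
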