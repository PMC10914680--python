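"""End-to-end recovery and calibration experiments.

Each function runs a complete analysis recipe on synthetic data with known
ground truth and returns a dictionary of summary numbers.  These recipes
back the reproducibility script (``scripts/acceptance.py``) and the
integration tests; their default problem sizes (20 synthetic subjects, 3
sessions of 48 trials, 200 calibration simulations) are the package's
standard validation scale.
"""

from __future__ import annotations

import numpy as np

from . import decoding, rsa, stats_perm, stimuli, synthetic, tdlm


def _subject_seed(seed: int, i: int) -> int:
    return int((int(seed) * 100_003 + 7919 * i + 1) % (2**31 - 1))


def _noisy_truth(series, rng, sd: float = 0.05):
    """Ground-truth intensities plus clipped observation noise — a cheap
    stand-in for the decoded-probability noise floor in calibration loops."""
    from .containers import ReactivationSeries

    vals = np.clip(series.values + rng.normal(0.0, sd, series.values.shape), 0, 1)
    return ReactivationSeries(vals, series.sfreq, list(series.state_labels),
                              series.n_trials, series.times_ms)


def _post_onset_range(series, from_ms: float = 500.0) -> tuple[int, int]:
    """Target-sample window for the inference period, skipping the first
    ``from_ms`` after onset (basic visual processing)."""
    idx = np.nonzero(series.times_ms >= from_ms)[0]
    return int(idx[0]), int(series.trial_len)


def replay_recovery(
    seed: int,
    n_subjects: int = 20,
    n_sessions: int = 3,
    trials_per_session: int = 48,
    planted_lag_ms: float = 60.0,
    planted_rate: float = 0.8,
    max_lag_ms: float = 500.0,
) -> dict:
    """Full localizer → decoder → reactivation → TDLM chain with a planted
    present→stable replay sequence.

    Returns the group-mean sequenceness curves, the present→stable peak lag,
    and whether the peak exceeds the group-mean max control bound.
    """
    curves, bounds_hi, contrast = [], [], []
    lags_ms = None
    for i in range(n_subjects):
        cfg = synthetic.GeneratorConfig(seed=_subject_seed(seed, i))
        schedule = synthetic.gen_trial_schedule(cfg, n_sessions, trials_per_session)
        localizer = synthetic.gen_localizer(cfg)
        clf = decoding.train_classifiers(localizer, train_time_ms=200.0)
        epochs, _truth = synthetic.gen_task_run(
            cfg, schedule, planted=[(("present", "stable"), planted_lag_ms,
                                     planted_rate)])
        series = decoding.decode_timecourse(clf, epochs)
        model = tdlm.SequencenessModel(series, schedule, max_lag_ms=max_lag_ms)
        res = model.fit(target_range=_post_onset_range(series))
        lags_ms = res.lags_ms
        curves.append(res.coef["present_to_stable"])
        bounds_hi.append(res.bounds["present_to_stable"][1])
        contrast.append(res.contrast)
    mean_curve = np.mean(curves, axis=0)
    peak_idx = int(np.nanargmax(mean_curve))
    return {
        "lags_ms": lags_ms,
        "mean_present_to_stable": mean_curve,
        "mean_contrast": np.nanmean(contrast, axis=0),
        "peak_lag_ms": float(lags_ms[peak_idx]),
        "peak_coef": float(mean_curve[peak_idx]),
        "control_max": float(np.mean(bounds_hi)),
        "exceeds_bound": bool(mean_curve[peak_idx] > np.mean(bounds_hi)),
        "n_subjects": n_subjects,
    }


def null_sequenceness_calibration(
    seed: int,
    n_runs: int = 40,
    trials_per_session: int = 48,
    lag_band_ms: tuple[float, float] = (10.0, 200.0),
    obs_noise_sd: float = 0.05,
) -> dict:
    """Calibration of the control-sequence bounds on null task runs (no
    planted sequences).

    Reports the fraction of runs in which the present→stable sequenceness —
    the statistic the planted-replay experiment tests — stays within the
    control bounds at every lag in the band, plus the stricter any-type
    exceedance rate (any of the three sequence types above the bound at any
    band lag)."""
    n_within = 0
    n_any_exceed = 0
    for i in range(n_runs):
        cfg = synthetic.GeneratorConfig(seed=_subject_seed(seed, 1000 + i))
        schedule = synthetic.gen_trial_schedule(cfg, 1, trials_per_session)
        _, truth = synthetic.gen_task_run(cfg, schedule, planted=())
        rng = np.random.default_rng(_subject_seed(seed, 2000 + i))
        series = _noisy_truth(truth, rng, obs_noise_sd)
        res = tdlm.SequencenessModel(series, schedule).fit(
            target_range=_post_onset_range(series))
        band = (res.lags_ms >= lag_band_ms[0]) & (res.lags_ms <= lag_band_ms[1])

        def exceeds(t: str) -> bool:
            vals = np.nan_to_num(res.coef[t][band], nan=-np.inf)
            return bool(np.any(vals > res.bounds[t][1]))

        n_within += not exceeds("present_to_stable")
        n_any_exceed += any(exceeds(t) for t in tdlm.SEQ_TYPES)
    return {"n_runs": n_runs,
            "within_bounds_frac": n_within / n_runs,
            "any_type_exceed_frac": n_any_exceed / n_runs}


def length3_recovery(
    seed: int,
    trials_per_session: int = 48,
    planted_lag_ms: float = 60.0,
    planted_rate: float = 0.9,
    obs_noise_sd: float = 0.05,
    chain_states: tuple[str, str, str] = ("X", "Y", "Z"),
) -> dict:
    """Length-3 TDLM on a planted A→B→C chain versus independent, unchained
    A→B and B→C pairs (pair planting only follows spontaneous leader events,
    so the two pairs never concatenate into triples)."""
    a, b, c = chain_states
    out = {}
    for kind, planted in (
        ("chained", [((a, b, c), planted_lag_ms, planted_rate)]),
        ("unchained", [((a, b), planted_lag_ms, planted_rate),
                       ((b, c), planted_lag_ms, planted_rate)]),
    ):
        cfg = synthetic.GeneratorConfig(seed=_subject_seed(seed, 10 + len(kind)))
        schedule = synthetic.gen_trial_schedule(cfg, 1, trials_per_session)
        _, truth = synthetic.gen_task_run(cfg, schedule, planted=planted)
        rng = np.random.default_rng(_subject_seed(seed, 20 + len(kind)))
        series = _noisy_truth(truth, rng, obs_noise_sd)
        res = tdlm.length3(series, max_lag_ms=300.0)
        lag_i = int(np.argmin(np.abs(res.lags_ms - planted_lag_ms)))
        out[kind] = {
            "coef_at_lag": float(res.get((a, b), c)[lag_i]),
            "argmax_triple": res.argmax_triple(planted_lag_ms),
            "lags_ms": res.lags_ms,
        }
    out["planted_lag_ms"] = planted_lag_ms
    return out


def algebra_recovery(seed: int, n_subjects: int = 20) -> dict:
    """Silhouette-algebra contrast on planted pattern codes.

    Zero-noise conjunctive patterns must satisfy the algebra identity exactly
    (composite-target distance 0); noisy conjunctive patterns must give a
    positive group conjunctive coefficient, and visual-only patterns must
    not (|t| < 2).
    """
    pairs = synthetic.pair_stimulus_set()
    triplets = stimuli.enumerate_algebra_triplets(list(pairs.values()))

    cfg0 = synthetic.GeneratorConfig(seed=_subject_seed(seed, 0), noise_sd=0.0)
    pats0 = synthetic.gen_pattern_set(cfg0, pairs, "conjunctive")
    res0 = rsa.AlgebraRSA(pats0, triplets, whiten=False).fit()

    groups = {}
    for model in ("conjunctive", "visual_only"):
        sets = [
            synthetic.gen_pattern_set(
                synthetic.GeneratorConfig(seed=_subject_seed(seed, 100 + i)),
                pairs, model)
            for i in range(n_subjects)
        ]
        groups[model] = rsa.algebra_rsa_group(sets, triplets)
    return {
        "n_triplets": len(triplets),
        "zero_noise_target_distance": res0.mean_distance("target"),
        "zero_noise_reference_distance": res0.mean_distance("reference"),
        "zero_noise_conjunctive_coef": res0.conjunctive_coef,
        "conjunctive_group_t": groups["conjunctive"].attrs["t"],
        "conjunctive_mean_coef": float(groups["conjunctive"]["conjunctive"].mean()),
        "visual_only_group_t": groups["visual_only"].attrs["t"],
        "n_subjects": n_subjects,
    }


def permutation_calibration(
    seed: int,
    n_sims: int = 200,
    n_subjects: int = 20,
    grid: tuple[int, int] = (16, 16),
    n_time: int = 301,
    n_perm_maps: int = 300,
    n_perm_series: int = 400,
) -> dict:
    """Family-wise type-I error of the two cluster procedures under the null
    (standard-normal subject data), over ``n_sims`` simulations each."""
    rng = np.random.default_rng(int(seed) % (2**31 - 1))
    adj = stats_perm.grid_adjacency(grid)
    n_feat = int(np.prod(grid))
    fp_maps = 0
    for i in range(n_sims):
        maps = rng.standard_normal((n_subjects, n_feat))
        cfg = stats_perm.PermutationConfig(n_perm=n_perm_maps,
                                           seed=_subject_seed(seed, 3000 + i))
        table = stats_perm.signflip_max_cluster(maps, adj, cfg)
        fp_maps += bool(len(table) and (table["p_corrected"] < 0.05).any())
    fp_series = 0
    for i in range(n_sims):
        series = rng.standard_normal((n_subjects, n_time))
        cfg = stats_perm.PermutationConfig(n_perm=n_perm_series, flip_mode="half",
                                           seed=_subject_seed(seed, 4000 + i))
        table = stats_perm.cluster_length_threshold(series, cfg)
        fp_series += bool(len(table))
    return {
        "n_sims": n_sims,
        "signflip_fwe_rate": fp_maps / n_sims,
        "cluster_length_fwe_rate": fp_series / n_sims,
    }


def behavioral_recovery(
    seed: int,
    n_trials: int = 600,
    betas: tuple[float, ...] = (0.0, 1.5, 0.8, 0.4, 0.6),
) -> dict:
    """Planted-coefficient recovery for the behavioral similarity logistic
    model: max |planted - recovered| / SE over coefficients."""
    import pandas as pd

    from .suppression import SMALL_PREDICTORS, SimilarityLogit

    cfg = synthetic.GeneratorConfig(seed=_subject_seed(seed, 5))
    rng = np.random.default_rng(_subject_seed(seed, 6))
    preds = pd.DataFrame(rng.standard_normal((n_trials, len(SMALL_PREDICTORS))),
                         columns=SMALL_PREDICTORS)
    table = synthetic.gen_behavioral_choices(cfg, betas, preds)
    res = SimilarityLogit([table]).fit()
    est = res.subject_params.iloc[0].to_numpy()
    se = res.subject_bse.iloc[0].to_numpy()
    z = np.abs(est - np.asarray(betas)) / se
    return {"betas": np.asarray(betas), "estimates": est, "se": se,
            "max_abs_z": float(np.max(z))}


def adaptation_recovery(
    seed: int,
    n_trials: int = 300,
    planted_beta: float = -0.5,
    noise_sd: float = 1.0,
) -> dict:
    """Planted-coefficient recovery for the repetition-suppression GLM: a
    BOLD-like signal built as ``planted_beta`` times the convolved basic
    block non-overlap regressor plus noise, refit with the full design."""
    from .suppression import AdaptationGLM, build_rs_design

    cfg = synthetic.GeneratorConfig(seed=_subject_seed(seed, 7))
    pairs = synthetic.pair_stimulus_set()
    ids = sorted(pairs)
    rng = np.random.default_rng(_subject_seed(seed, 8))
    seq = [pairs[ids[i]] for i in rng.integers(0, len(ids), n_trials)]
    design = build_rs_design(seq)
    model = AdaptationGLM(design)
    X = model.convolved_design()
    signal = (planted_beta * X["basicBB_nonoverlap_small"].to_numpy()
              + rng.normal(0.0, noise_sd, len(X)))
    res = model.fit(signal)
    est = res.params["basicBB_nonoverlap_small"]
    se = res.bse["basicBB_nonoverlap_small"]
    return {"planted_beta": planted_beta, "estimate": float(est),
            "se": float(se), "abs_z": float(abs(est - planted_beta) / se)}


def localizer_decodability(seed: int, step_ms: float = 10.0) -> dict:
    """Cross-validated decodability curve of the synthetic localizer; the
    argmax should recover the planted 200-ms topography peak."""
    cfg = synthetic.GeneratorConfig(seed=_subject_seed(seed, 9))
    localizer = synthetic.gen_localizer(cfg)
    times = np.arange(0.0, 400.0 + step_ms / 2, step_ms)
    curve = decoding.decodability_curve(localizer, times, cv_folds=5)
    best = curve.loc[curve["accuracy"].idxmax()]
    return {"curve": curve, "peak_time_ms": float(best["time_ms"]),
            "peak_accuracy": float(best["accuracy"])}
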