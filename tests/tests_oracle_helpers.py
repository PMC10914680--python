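"""Independent naive TDLM solver used as the oracle for the full stack.

This deliberately re-derives the two-level sequenceness computation with
plain Python loops and ``np.linalg.lstsq``, sharing no code with
``replaykit.tdlm`` beyond the theoretical matrix definitions it is checking
against.
"""

import numpy as np

from replaykit.containers import ReactivationSeries
from replaykit.stimuli import RoleAssignment
from replaykit.tdlm import SEQ_TYPES, SequencenessModel, build_theoretical_matrices

STATES = ("W", "X", "Y", "Z")


def naive_sequenceness(trials, roles, lags):
    """Per-trial lagged lstsq regressions + per-lag second-level lstsq,
    averaged over trials."""
    theo = build_theoretical_matrices(roles, STATES)
    S = 4
    design_cols = [theo.true[t].ravel() for t in SEQ_TYPES if theo.applicable[t]]
    names = [t for t in SEQ_TYPES if theo.applicable[t]]
    X2 = np.column_stack(design_cols + [np.ones(S * S), np.eye(S).ravel()])
    acc = {t: np.zeros(len(lags)) for t in names}
    for Y in trials:
        T = Y.shape[0]
        for di, d in enumerate(lags):
            rows_X = [np.append(Y[t - d], 1.0) for t in range(d, T)]
            rows_y = [Y[t] for t in range(d, T)]
            A = np.array(rows_X)
            B = np.array(rows_y)
            emp = np.zeros((S, S))
            for j in range(S):
                beta, *_ = np.linalg.lstsq(A, B[:, j], rcond=None)
                emp[:, j] = beta[:S]
            beta2, *_ = np.linalg.lstsq(X2, emp.ravel(), rcond=None)
            for i, t in enumerate(names):
                acc[t][di] += beta2[i] / len(trials)
    return acc


def run_oracle_comparison(seed, n_trials=4, trial_len=120):
    """Max relative disagreement between the package stack and the naive
    solver on random short series."""
    rng = np.random.default_rng(seed)
    trials = [np.abs(rng.standard_normal((trial_len, 4))) * 0.3
              for _ in range(n_trials)]
    series = ReactivationSeries(np.vstack(trials), 100.0, STATES, n_trials,
                                np.arange(trial_len) * 10.0,
                                probabilistic=False)
    roles = RoleAssignment(stable="W", present=frozenset({"X", "Y"}),
                           absent="Z", distant_present="Y")
    res = SequencenessModel(series, [roles] * n_trials, max_lag_ms=100.0).fit()
    lags = np.arange(1, 11)
    expected = naive_sequenceness(trials, roles, lags)
    max_rel = 0.0
    for t, exp in expected.items():
        got = res.coef[t]
        rel = np.max(np.abs(got - exp) / np.maximum(np.abs(exp), 1e-12))
        max_rel = max(max_rel, float(rel))
    return max_rel
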