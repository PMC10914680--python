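"""Synthetic-data generators for end-to-end parameter recovery.

Every analysis stage in this package can be validated without real
recordings: this module plants known ground truth — conjunctive
(block-in-relational-position) pattern codes, onset-locked localizer
topographies, and replay sequences at configurable lags — inside otherwise
noisy data, so that each estimator can be checked by recovering what was
planted.

All generators are pure functions of ``(GeneratorConfig, arguments)``:
identical inputs produce bit-identical outputs.  Independent random streams
are derived from the single config seed, one per generator.

What the generator emulates (and what it does not) is documented in
``docs/methods.md``: multi-session "voxel" patterns are additive conjunctive
codes plus visual (pixel/size) components plus white Gaussian noise; sensor
epochs are random Gaussian state topographies driven by half-sine activation
kernels with AR(1) sensor noise.  No biophysical forward model, artifacts or
realistic spectra are simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import EpochTensor, PatternSet, ReactivationSeries
from .stimuli import (
    BlockShape,
    RoleAssignment,
    Relation,
    Silhouette,
    assign_roles,
    chain,
    conjunctions,
    default_blocks,
)


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


# random stream keys, one per generator
_STREAM = {"schedule": 1, "patterns": 2, "localizer": 3, "task": 4,
           "behavior": 5, "topo": 6, "coords": 7}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world.

    Parameters
    ----------
    seed : master seed; every generator derives its own stream from it.
    noise_sd : SD of the white pattern noise added per condition and session.
    code_sd : SD of the conjunctive code vectors (one per block-in-position).
    visual_sd : SD scale of the pixel/size visual components.
    n_features : number of synthetic "voxel" features in pattern sets.
    n_sessions : sessions per pattern set (noise independent per session).
    localizer_peak_ms : latency of the class topography peak (default 200 ms,
        where localizer decodability is maximal).
    sfreq_hz : sampling rate of all time series (default 100 Hz, i.e. a 10-ms
        sample period so planted lags sit on the sample grid).
    kernel_ms : width of the half-sine state activation kernel (default
        100 ms, roughly the width of the localizer decodability peak).
    n_sensors : synthetic sensor count.
    sensor_noise_sd : SD of the AR(1) sensor noise.
    ar_rho : temporal autocorrelation of the sensor noise.
    spont_rate_hz : spontaneous state-event rate per state (events/s) during
        the task period.
    alpha_amplitude : amplitude of an optional 10-Hz confound oscillation
        added to all sensors (off by default).
    """

    seed: int = 0
    noise_sd: float = 0.5
    code_sd: float = 1.0
    visual_sd: float = 1.0
    n_features: int = 60
    n_sessions: int = 3
    localizer_peak_ms: float = 200.0
    planted_lags_ms: tuple[float, ...] = (60.0,)
    state_kernel: str = "halfsine"
    kernel_ms: float = 100.0
    sfreq_hz: float = 100.0
    n_sensors: int = 32
    sensor_noise_sd: float = 2.0
    ar_rho: float = 0.5
    spont_rate_hz: float = 0.6
    alpha_amplitude: float = 0.0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "code_sd", "visual_sd", "sensor_noise_sd",
                     "spont_rate_hz", "alpha_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.state_kernel != "halfsine":
            raise ConfigError(f"unknown state kernel {self.state_kernel!r}")
        period = 1000.0 / self.sfreq_hz
        if abs(period - round(period)) > 1e-9:
            raise ConfigError("sampling rate must divide 1000 ms evenly")

    @property
    def sample_ms(self) -> float:
        return 1000.0 / self.sfreq_hz

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    def kernel(self) -> np.ndarray:
        """Half-sine activation waveform sampled at sfreq."""
        n = max(2, int(round(self.kernel_ms / self.sample_ms)))
        return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(cfg, seed=int(seed))


# ---------------------------------------------------------------------------
# stimulus sets
# ---------------------------------------------------------------------------


def default_stimulus_set(
    blocks: Sequence[BlockShape] | None = None, stable_id: str = "W"
) -> dict[str, Silhouette]:
    """The 12 three-block task silhouettes over a four-block universe.

    For each of the three present-block pairs (a, b) there are four
    configurations: two towers with the stable block in the middle
    (a/stable/b and b/stable/a) and two chains with the stable block at one
    end (a vertical tower stable/a/b and a horizontal row stable-a-b), so
    exactly half of the set has the stable block in the middle.
    """
    blocks = list(blocks) if blocks is not None else default_blocks()
    by_id = {b.id: b for b in blocks}
    if stable_id not in by_id or len(by_id) != 4:
        raise ConfigError("need four distinct blocks including the stable one")
    s = by_id[stable_id]
    others = sorted(bid for bid in by_id if bid != stable_id)
    out: dict[str, Silhouette] = {}
    for a, b in itertools.combinations(others, 2):
        ba, bb = by_id[a], by_id[b]
        v = [Relation.ON_TOP, Relation.ON_TOP]
        h = [Relation.LEFT_OF, Relation.LEFT_OF]
        out[f"{a}|{stable_id}|{b}"] = chain([ba, s, bb], v)
        out[f"{b}|{stable_id}|{a}"] = chain([bb, s, ba], v)
        out[f"{stable_id}|{a}|{b}"] = chain([s, ba, bb], v)
        out[f"{stable_id}-{a}-{b}"] = chain([s, ba, bb], h)
    return out


def pair_stimulus_set(
    blocks: Sequence[BlockShape] | None = None, relation: Relation = Relation.ON_TOP
) -> dict[str, Silhouette]:
    """All two-block compounds over the block universe under one relation —
    the substrate of silhouette-algebra triplet enumeration."""
    from .stimuli import compose

    blocks = list(blocks) if blocks is not None else default_blocks()
    out = {}
    for a, b in itertools.permutations(blocks, 2):
        out[f"{a.id}{b.id}"] = compose(a, b, relation)
    return out


# ---------------------------------------------------------------------------
# trial schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    index: int
    session: int
    stim_id: str
    roles: RoleAssignment
    epoch_ms: tuple[float, float] = (-500.0, 3500.0)


@dataclass
class TrialSchedule:
    """Ordered trials with roles and the stimulus dictionary they refer to."""

    trials: list[Trial]
    stimuli: Mapping[str, Silhouette]
    n_sessions: int
    stable_id: str

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def session_bounds(self) -> list[tuple[int, int]]:
        per = self.n_trials // self.n_sessions
        return [(s * per, (s + 1) * per) for s in range(self.n_sessions)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "trial": t.index, "session": t.session, "stim_id": t.stim_id,
                "stable": t.roles.stable,
                "present": "+".join(sorted(t.roles.present)),
                "distant_present": t.roles.distant_present or "",
                "absent": t.roles.absent,
                "stable_middle": t.roles.stable_middle,
            })
        return pd.DataFrame(rows)


def gen_trial_schedule(
    cfg: GeneratorConfig,
    n_sessions: int = 3,
    trials_per_session: int = 48,
    stable_id: str = "W",
    stimuli: Mapping[str, Silhouette] | None = None,
) -> TrialSchedule:
    """Balanced trial schedule: per session, half the trials have the stable
    block in the middle, and the 12 silhouettes appear equally often (up to
    rounding when trials_per_session is not a multiple of 12)."""
    if trials_per_session % 2:
        raise ConfigError("trials_per_session must be even")
    stimuli = stimuli if stimuli is not None else default_stimulus_set(stable_id=stable_id)
    universe = sorted({bid for s in stimuli.values() for bid in s.block_ids})
    roles = {sid: assign_roles(s, universe, stable_id) for sid, s in stimuli.items()}
    middle = sorted(sid for sid in stimuli if roles[sid].stable_middle)
    ends = sorted(sid for sid in stimuli if not roles[sid].stable_middle)
    rng = cfg.rng("schedule")
    trials: list[Trial] = []
    for sess in range(n_sessions):
        half = trials_per_session // 2
        ids = [middle[i % len(middle)] for i in range(half)]
        ids += [ends[i % len(ends)] for i in range(half)]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for sid in ids:
            trials.append(Trial(index=len(trials), session=sess, stim_id=sid,
                                roles=roles[sid]))
    return TrialSchedule(trials=trials, stimuli=dict(stimuli),
                         n_sessions=n_sessions, stable_id=stable_id)


# ---------------------------------------------------------------------------
# pattern sets with planted codes
# ---------------------------------------------------------------------------


def _visual_vector(s: Silhouette, grid: int = 8) -> np.ndarray:
    """Pixel raster (grid x grid) plus height/width of a silhouette."""
    img = np.zeros((grid, grid))
    for r, c in s.occupancy:
        if r < grid and c < grid:
            img[r, c] = 1.0
    return np.concatenate([img.ravel(), [s.height, s.width]])


def gen_pattern_set(
    cfg: GeneratorConfig,
    stimulus_set: Mapping[str, Silhouette],
    code_model: str = "conjunctive",
    conjunctive_features: np.ndarray | None = None,
) -> PatternSet:
    """Condition x feature x session patterns with a planted code.

    ``code_model``:
      * ``conjunctive`` — each (block, relational-position) conjunction has a
        fixed random code vector; a silhouette's pattern is the sum over its
        conjunctions.  This makes the silhouette algebra hold exactly at zero
        noise.
      * ``visual_only`` — patterns are linear projections of the silhouette's
        pixel raster and size only.
      * ``mixed`` — sum of both.

    Noise is white, independent per session.  ``conjunctive_features``
    restricts the conjunctive code to a feature subset (for searchlight
    localisation recovery).
    """
    if code_model not in ("conjunctive", "visual_only", "mixed"):
        raise ConfigError(f"unknown code model {code_model!r}")
    if not stimulus_set:
        raise ConfigError("empty stimulus set")
    if cfg.n_features < 20:
        raise ConfigError("n_features must be >= 20")
    rng = cfg.rng("patterns")
    labels = sorted(stimulus_set)
    all_conj = sorted({c for s in stimulus_set.values() for c in conjunctions(s)})
    codes = rng.normal(0.0, cfg.code_sd, size=(len(all_conj), cfg.n_features))
    if conjunctive_features is not None:
        mask = np.zeros(cfg.n_features, dtype=bool)
        mask[np.asarray(conjunctive_features)] = True
        codes = codes * mask
    conj_idx = {c: i for i, c in enumerate(all_conj)}
    vdim = _visual_vector(next(iter(stimulus_set.values()))).size
    vproj = rng.normal(0.0, cfg.visual_sd / np.sqrt(vdim), size=(vdim, cfg.n_features))
    values = np.zeros((len(labels), cfg.n_features, cfg.n_sessions))
    for i, sid in enumerate(labels):
        s = stimulus_set[sid]
        signal = np.zeros(cfg.n_features)
        if code_model in ("conjunctive", "mixed"):
            for c in conjunctions(s):
                signal += codes[conj_idx[c]]
        if code_model in ("visual_only", "mixed"):
            signal += _visual_vector(s) @ vproj
        values[i] = signal[:, None]
    values += rng.normal(0.0, cfg.noise_sd,
                         size=(len(labels), cfg.n_features, cfg.n_sessions))
    coords = cfg.rng("coords").uniform(0, 10, size=(cfg.n_features, 3))
    return PatternSet(values, labels, feature_coords=coords,
                      meta={"code_model": code_model, "seed": cfg.seed})


# ---------------------------------------------------------------------------
# sensor-space generators
# ---------------------------------------------------------------------------


def state_topographies(cfg: GeneratorConfig, states: Sequence[str]) -> np.ndarray:
    """One random Gaussian sensor topography per state, shared between the
    localizer and the task render so classifier transfer is meaningful."""
    rng = cfg.rng("topo")
    return rng.normal(0.0, 1.0, size=(len(states), cfg.n_sensors))


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               rho: float, sd: float) -> np.ndarray:
    """AR(1)-in-time noise along the last axis, unit marginal variance * sd."""
    e = rng.normal(0.0, 1.0, size=shape)
    out = lfilter([np.sqrt(max(1.0 - rho**2, 1e-12))], [1.0, -rho], e, axis=-1)
    return sd * out


def _alpha(rng: np.random.Generator, cfg: GeneratorConfig,
           n_trials: int, times_ms: np.ndarray) -> np.ndarray:
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    wave = np.sin(2 * np.pi * 10.0 * times_ms[None, :] / 1000.0 + phases[:, None])
    return cfg.alpha_amplitude * wave[:, None, :]


def gen_localizer(
    cfg: GeneratorConfig,
    n_trials_per_class: int = 25,
    states: Sequence[str] = ("W", "X", "Y", "Z"),
    epoch_ms: tuple[float, float] = (-500.0, 800.0),
) -> EpochTensor:
    """Localizer epochs: one block class per epoch, with the class topography
    driven by a half-sine kernel peaking at ``localizer_peak_ms``."""
    rng = cfg.rng("localizer")
    times = np.arange(epoch_ms[0], epoch_ms[1], cfg.sample_ms)
    if epoch_ms[1] < cfg.localizer_peak_ms + cfg.kernel_ms:
        raise ConfigError("epoch too short for the activation kernel")
    topo = state_topographies(cfg, states)
    labels = [s for s in states for _ in range(n_trials_per_class)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    kern = cfg.kernel()
    onset = int(round((cfg.localizer_peak_ms - cfg.kernel_ms / 2 - epoch_ms[0])
                      / cfg.sample_ms))
    activation = np.zeros(times.size)
    activation[onset:onset + kern.size] = kern[: max(0, times.size - onset)]
    values = np.zeros((len(labels), cfg.n_sensors, times.size))
    sidx = {s: i for i, s in enumerate(states)}
    for t, lab in enumerate(labels):
        values[t] = topo[sidx[lab]][:, None] * activation[None, :]
    values += _ar1_noise(rng, values.shape, cfg.ar_rho, cfg.sensor_noise_sd)
    if cfg.alpha_amplitude > 0:
        values += _alpha(rng, cfg, len(labels), times)
    return EpochTensor(values, times, labels, cfg.sfreq_hz,
                       baseline_ms=(-100.0, 0.0),
                       meta={"kind": "localizer", "states": list(states)})


def _resolve_planted(states: Sequence[str], roles: RoleAssignment,
                     spec_states: Sequence[str]) -> list[tuple[str, ...]]:
    """Expand role names ('stable', 'present', 'distant_present', 'absent')
    in a planted tuple into concrete state tuples for one trial."""
    options: list[list[str]] = []
    present = sorted(roles.present)
    for s in spec_states:
        if s == "stable":
            options.append([roles.stable])
        elif s == "absent":
            options.append([roles.absent])
        elif s == "present":
            options.append(present)
        elif s == "distant_present":
            if roles.distant_present is None:
                return []
            options.append([roles.distant_present])
        elif s in states:
            options.append([s])
        else:
            raise ConfigError(f"unknown state or role {s!r}")
    out = [t for t in itertools.product(*options) if len(set(t)) == len(t)]
    return out


def gen_task_run(
    cfg: GeneratorConfig,
    schedule: TrialSchedule,
    planted: Sequence[tuple[Sequence[str], float, float]] = (),
) -> tuple[EpochTensor, ReactivationSeries]:
    """Task-period epochs with planted replay sequences.

    ``planted`` is a list of ``(ordered state tuple, lag_ms, rate)``; tuple
    elements may be concrete state ids or role names resolved per trial
    against the trial's role assignment.  For each pair ``(A, B)``, a B event
    is injected ``lag_ms`` after a fraction ``rate`` of A's *spontaneous*
    events (so two planted pairs sharing a middle state do not chain); for a
    triple ``(A, B, C)``, C additionally follows at ``2 * lag_ms``.

    Returns the rendered sensor epochs and the ground-truth intensity series.
    Boundary-truncated follower events are counted in ``series.meta``.
    """
    rng = cfg.rng("task")
    states = tuple(sorted({b for s in schedule.stimuli.values() for b in s.block_ids}))
    sidx = {s: i for i, s in enumerate(states)}
    epoch = schedule.trials[0].epoch_ms
    times = np.arange(epoch[0], epoch[1], cfg.sample_ms)
    n_t = times.size
    onset_idx = int(round(-epoch[0] / cfg.sample_ms))
    kern = cfg.kernel()
    lag_samples = []
    for spec_states, lag_ms, rate in planted:
        lag = lag_ms / cfg.sample_ms
        if abs(lag - round(lag)) > 1e-9:
            raise ConfigError(f"lag {lag_ms} ms not on the sample grid")
        lag_samples.append((tuple(spec_states), int(round(lag)), float(rate)))

    topo = state_topographies(cfg, states)
    n_trials = schedule.n_trials
    intensities = np.zeros((n_trials, n_t, len(states)))
    n_planted = 0
    n_truncated = 0
    active = (onset_idx, n_t - kern.size)  # spontaneous events post-onset
    for ti, trial in enumerate(schedule.trials):
        events: dict[str, list[int]] = {s: [] for s in states}
        dur_s = (active[1] - active[0]) * cfg.sample_ms / 1000.0
        for s in states:
            k = rng.poisson(cfg.spont_rate_hz * dur_s)
            if k:
                events[s] = sorted(rng.integers(active[0], active[1], size=k).tolist())
        spont = {s: list(ev) for s, ev in events.items()}
        for spec_states, lag, rate in lag_samples:
            for concrete in _resolve_planted(states, trial.roles, spec_states):
                leaders = spont[concrete[0]]
                if not leaders:
                    continue
                n_follow = int(round(rate * len(leaders)))
                chosen = rng.choice(len(leaders), size=n_follow, replace=False)
                for li in sorted(chosen):
                    t0 = leaders[li]
                    for step, st in enumerate(concrete[1:], start=1):
                        t_ev = t0 + step * lag
                        n_planted += 1
                        if t_ev >= n_t:
                            n_truncated += 1
                            continue
                        events[st].append(t_ev)
        for s, evs in events.items():
            col = sidx[s]
            for e in evs:
                stop = min(n_t, e + kern.size)
                intensities[ti, e:stop, col] += kern[: stop - e]
    intensities = np.clip(intensities, 0.0, 1.0)

    values = np.einsum("ktS,Sm->kmt", intensities, topo)
    values += _ar1_noise(rng, values.shape, cfg.ar_rho, cfg.sensor_noise_sd)
    if cfg.alpha_amplitude > 0:
        values += _alpha(rng, cfg, n_trials, times)
    labels = [t.stim_id for t in schedule.trials]
    epochs = EpochTensor(values, times, labels, cfg.sfreq_hz,
                         baseline_ms=(-100.0, 0.0),
                         meta={"kind": "task", "states": list(states)})
    series = ReactivationSeries(
        intensities.reshape(-1, len(states)), cfg.sfreq_hz, states, n_trials,
        times, probabilistic=True,
        meta={"planted_events": n_planted, "truncated_events": n_truncated},
    )
    return epochs, series


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def gen_behavioral_choices(
    cfg: GeneratorConfig, betas: Sequence[float], predictors: pd.DataFrame
) -> pd.DataFrame:
    """Bernoulli choices from the similarity logistic model
    ``p(left) = 1 / (1 + exp(-(b0 + X @ b)))``; seeded and reproducible."""
    betas = np.asarray(betas, dtype=float)
    X = predictors.to_numpy(dtype=float)
    if X.shape[1] != betas.size - 1:
        raise ConfigError("predictor columns must match beta length minus intercept")
    eta = betas[0] + X @ betas[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = cfg.rng("behavior")
    left = rng.random(p.size) < p
    out = predictors.copy()
    out["p_left"] = p
    out["choice"] = np.where(left, "left", "right")
    return out
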