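"""Pipeline orchestration: configuration, stage execution, provenance.

A :class:`RunConfig` names the stages to execute (``simulate``, ``decode``,
``tdlm``, ``rsa``, ``suppress``, ``stats``) plus the generator settings;
:func:`run_pipeline` executes them in dependency order, writes each stage's
outputs under the run directory, and returns a manifest keyed by a hash of
the configuration, so identical configs produce identical outputs.
Higher-level experiment recipes live in :mod:`replaykit.experiments`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, decoding, experiments, rsa, stimuli, synthetic, tdlm
from .synthetic import GeneratorConfig

STAGES = ("simulate", "decode", "tdlm", "rsa", "suppress", "stats")
RECIPES = ("replay-recovery", "algebra-recovery", "calibration")


class DependencyError(RuntimeError):
    """A stage was requested without the artifacts it depends on."""


@dataclass
class RunConfig:
    """Validated run configuration (YAML/JSON serialisable)."""

    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "decode", "tdlm")
    out_dir: str = "replaykit_run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_sessions: int = 3
    trials_per_session: int = 48
    planted: list = field(default_factory=lambda: [[["present", "stable"], 60.0, 0.8]])
    train_time_ms: float = 200.0
    max_lag_ms: float = 500.0
    stats_n_sims: int = 50
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        self.generator = dataclasses.replace(self.generator, seed=int(self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def hash(self) -> str:
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_simulate(cfg: RunConfig, art: dict, out: Path) -> dict:
    gen = cfg.generator
    schedule = synthetic.gen_trial_schedule(gen, cfg.n_sessions,
                                            cfg.trials_per_session)
    localizer = synthetic.gen_localizer(gen)
    planted = [(tuple(p[0]), float(p[1]), float(p[2])) for p in cfg.planted]
    epochs, truth = synthetic.gen_task_run(gen, schedule, planted)
    art.update(schedule=schedule, localizer=localizer, task_epochs=epochs,
               truth_series=truth)
    schedule.to_frame().to_csv(out / "schedule.csv", index=False)
    localizer.save_hdf5(str(out / "localizer.h5"))
    epochs.save_hdf5(str(out / "task_epochs.h5"))
    truth.save_hdf5(str(out / "truth_series.h5"))
    return {"n_trials": schedule.n_trials, "files": ["schedule.csv",
            "localizer.h5", "task_epochs.h5", "truth_series.h5"]}


def _stage_decode(cfg: RunConfig, art: dict, out: Path) -> dict:
    for need in ("localizer", "task_epochs"):
        if need not in art:
            raise DependencyError(f"decode requires the simulate stage ({need})")
    clf = decoding.train_classifiers(art["localizer"],
                                     train_time_ms=cfg.train_time_ms)
    series = decoding.decode_timecourse(clf, art["task_epochs"])
    art.update(classifiers=clf, series=series)
    clf.save_hdf5(str(out / "classifiers.h5"))
    series.save_hdf5(str(out / "reactivation.h5"))
    return {"nonzero_weights": clf.nonzero_counts().tolist(),
            "files": ["classifiers.h5", "reactivation.h5"]}


def _stage_tdlm(cfg: RunConfig, art: dict, out: Path) -> dict:
    series = art.get("series") or art.get("truth_series")
    if series is None or "schedule" not in art:
        raise DependencyError(
            "tdlm requires decode outputs or a ground-truth series plus the schedule")
    model = tdlm.SequencenessModel(series, art["schedule"],
                                   max_lag_ms=cfg.max_lag_ms)
    res = model.fit(target_range=experiments._post_onset_range(series))
    art["sequenceness"] = res
    res.to_frame().to_csv(out / "sequenceness.csv", index=False)
    lag, coef = res.peak("present_to_stable")
    return {"present_to_stable_peak_lag_ms": lag,
            "present_to_stable_peak_coef": coef,
            "files": ["sequenceness.csv"]}


def _stage_rsa(cfg: RunConfig, art: dict, out: Path) -> dict:
    pairs = synthetic.pair_stimulus_set()
    triplets = stimuli.enumerate_algebra_triplets(list(pairs.values()))
    pats = synthetic.gen_pattern_set(cfg.generator, pairs, "conjunctive")
    res = rsa.AlgebraRSA(pats, triplets).fit()
    art["algebra_rsa"] = res
    res.pair_table.drop(columns=["session_pair"]).to_csv(
        out / "algebra_rsa_pairs.csv", index=False)
    return {"conjunctive_coef": res.conjunctive_coef,
            "files": ["algebra_rsa_pairs.csv"]}


def _stage_suppress(cfg: RunConfig, art: dict, out: Path) -> dict:
    from .suppression import AdaptationGLM, build_rs_design

    if "schedule" not in art:
        raise DependencyError("suppress requires the simulate stage (schedule)")
    schedule = art["schedule"]
    seq = [schedule.stimuli[t.stim_id] for t in schedule.trials]
    sessions = [t.session for t in schedule.trials]
    design = build_rs_design(seq, sessions)
    design.to_csv(str(out / "rs_design.csv"))
    (out / "rs_design_manifest.json").write_text(
        json.dumps({"columns": list(design.projected.columns),
                    "dropped": list(design.dropped), **design.manifest},
                   indent=2))
    art["rs_design"] = design
    return {"n_columns": design.projected.shape[1],
            "dropped": list(design.dropped),
            "files": ["rs_design.csv", "rs_design_manifest.json"]}


def _stage_stats(cfg: RunConfig, art: dict, out: Path) -> dict:
    res = experiments.permutation_calibration(cfg.seed, n_sims=cfg.stats_n_sims)
    art["calibration"] = res
    (out / "calibration.json").write_text(json.dumps(res, indent=2))
    return {**res, "files": ["calibration.json"]}


_STAGE_FN = {"simulate": _stage_simulate, "decode": _stage_decode,
             "tdlm": _stage_tdlm, "rsa": _stage_rsa,
             "suppress": _stage_suppress, "stats": _stage_stats}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write a provenance manifest.

    Returns the manifest: config hash, effective parameters, and per-stage
    summaries.  Raises :class:`DependencyError` when a stage's required
    artifacts were not produced by an earlier stage in this run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}
    manifest = {"config_hash": cfg.hash(), "config": cfg.to_dict(),
                "version": __version__, "stages": {}}
    for stage in STAGES:
        if stage in cfg.stages:
            manifest["stages"][stage] = _STAGE_FN[stage](cfg, artifacts, out)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def run_recipe(name: str, seed: int, scale: float = 1.0) -> dict:
    """Run a named experiment recipe at (optionally reduced) scale."""
    if name == "replay-recovery":
        n = max(2, int(round(20 * scale)))
        out = experiments.replay_recovery(seed, n_subjects=n)
    elif name == "algebra-recovery":
        n = max(2, int(round(20 * scale)))
        out = experiments.algebra_recovery(seed, n_subjects=n)
    elif name == "calibration":
        n = max(20, int(round(200 * scale)))
        out = experiments.permutation_calibration(seed, n_sims=n)
    else:
        raise ValueError(f"unknown recipe {name!r}; choose from {RECIPES}")
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in out.items()}
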