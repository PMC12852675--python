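"""Configuration, serialization, and the staged analysis pipeline.

A :class:`PipelineConfig` (YAML-loadable, unknown keys rejected) drives the
stages in dependency order — synthesize behavior, fit behavior, group
statistics; or simulate a flow field; or train/probe the recurrent network.
Every randomized stage receives a logged sub-seed spawned from the global
seed, and each run writes a :class:`RunManifest` recording the config hash
and SHA-256 digests of all inputs/outputs so deterministic stages are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pivotflow")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "validate_trial_table",
    "save_json",
]

KNOWN_STAGES = ("synth-behavior", "fit-behavior", "group-stats", "simulate-flow",
                "train-rnn", "probe-rnn", "tuning-shift")


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


@dataclass
class PipelineConfig:
    """Parameters for a pipeline run; unknown keys are rejected on load."""

    stages: list = field(default_factory=lambda: ["synth-behavior", "fit-behavior"])
    seed: int = 0
    out_dir: str = "pivotflow_out"
    verbosity: str = "INFO"
    # stage parameters
    experiment: str = "Exp1"
    n_observers: int = 3
    reps: int = 7
    bootstrap_n: int = 0
    alpha_grid: list | None = None
    pprime: float = 1.0
    omega_eye: float = 5.3
    n_dots: int = 200
    rnn_epochs: int = 5000
    rnn_batch: int = 64
    rnn_lr: float = 1e-3

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, sub-seeds, file digests."""

    config_hash: str
    version: str
    stages: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def add_file(self, label: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.digests[label] = digest


def _spawn_seeds(seed: int, stages) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the requested stages in dependency order."""
    from . import __version__
    from .geometry import ViewingGeometry, simulate_flow_field
    from .synth import ExperimentDesign, default_cohort, generate_trials
    from .behavior import fit_linear_observer, group_stats
    from . import rnn as rnn_mod

    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    manifest.seeds = _spawn_seeds(config.seed, KNOWN_STAGES)
    order = [s for s in KNOWN_STAGES if s in config.stages]
    state: dict = {}
    for stage in order:
        t0 = time.time()
        logger.info("stage %s starting", stage)
        try:
            _run_stage(stage, config, manifest, state, out)
        except Exception:
            logger.error("stage %s failed; partial outputs kept in %s", stage, out)
            raise
        manifest.timestamps[stage] = round(time.time() - t0, 3)
        manifest.stages.append(stage)
    save_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest


def _run_stage(stage, config, manifest, state, out: Path):
    from .geometry import ViewingGeometry, simulate_flow_field
    from .synth import ExperimentDesign, default_cohort, generate_trials
    from .behavior import fit_linear_observer, group_stats
    from . import rnn as rnn_mod

    seed = manifest.seeds[stage]
    if stage == "synth-behavior":
        design = (
            ExperimentDesign.exp1(reps=config.reps)
            if config.experiment == "Exp1"
            else ExperimentDesign.exp2(reps=config.reps)
        )
        cohort = default_cohort(config.n_observers, seed=seed)
        tables = [generate_trials(design, obs) for obs in cohort]
        trials = pd.concat(tables, ignore_index=True)
        path = out / "trials.csv"
        trials.to_csv(path, index=False)
        manifest.add_file("trials", path)
        state["trials"] = trials
        state["cohort"] = cohort
    elif stage == "fit-behavior":
        trials = state.get("trials")
        if trials is None:
            path = out / "trials.csv"
            if not path.exists():
                raise RuntimeError("fit-behavior requires synth-behavior or trials.csv")
            trials = pd.read_csv(path)
        fits = []
        rng = np.random.default_rng(seed)
        for (pid, geometry, eye_cond), grp in trials.groupby(
            ["participant", "geometry", "eye_condition"]
        ):
            if grp["report_dir_deg"].notna().sum() == 0:
                continue
            fit = fit_linear_observer(
                grp, alpha_grid=[1e-3], bootstrap_n=config.bootstrap_n,
                seed=int(rng.integers(2**31)),
            )
            fits.append(
                {
                    "participant": pid, "geometry": geometry,
                    "eye_condition": eye_cond, "a_ret": fit.a_ret,
                    "a_eye": fit.a_eye, "loss": fit.loss,
                }
            )
        fits_df = pd.DataFrame(fits)
        path = out / "observer_fits.csv"
        fits_df.to_csv(path, index=False)
        manifest.add_file("observer_fits", path)
        state["fits"] = fits_df
    elif stage == "group-stats":
        fits = state.get("fits")
        if fits is None:
            fits = pd.read_csv(out / "observer_fits.csv")
        results = {}
        for eye_cond, grp in fits.groupby("eye_condition"):
            wide = grp.pivot(index="participant", columns="geometry")
            try:
                results[eye_cond] = {
                    "a_ret_RT_vs_R": group_stats(
                        wide[("a_ret", "RT")], wide[("a_ret", "R")]
                    ),
                    "a_eye_R_vs_RT": group_stats(
                        wide[("a_eye", "R")], wide[("a_eye", "RT")]
                    ),
                }
            except (KeyError, ValueError) as exc:
                results[eye_cond] = {"error": str(exc)}
        path = out / "group_stats.json"
        save_json(results, path)
        manifest.add_file("group_stats", path)
    elif stage == "simulate-flow":
        geom = ViewingGeometry.from_pprime(config.pprime, config.omega_eye)
        flow = simulate_flow_field(geom, n_dots=config.n_dots, seed=seed)
        path = out / "flow_field.csv"
        flow.to_dataframe().to_csv(path, index=False)
        manifest.add_file("flow_field", path)
    elif stage == "train-rnn":
        cfg = rnn_mod.TrainConfig(
            epochs=config.rnn_epochs, batch=config.rnn_batch,
            lr=config.rnn_lr, seed=seed,
        )
        params, history = rnn_mod.train(cfg)
        state["rnn_params"] = params
        ckpt = {
            "seed": seed, "epochs": cfg.epochs, "batch": cfg.batch,
            "loss_history": history,
            **{k: getattr(params, k) for k in ("W_in", "W_rec", "W_out", "b_rec", "b_out")},
        }
        path = out / "rnn_checkpoint.json"
        save_json(ckpt, path)
        manifest.add_file("rnn_checkpoint", path)
    elif stage == "probe-rnn":
        params = state.get("rnn_params") or _load_checkpoint(out)
        curves = rnn_mod.probe_psychometrics(params, seed=seed)
        path = out / "rnn_probe.csv"
        curves.to_csv(path, index=False)
        manifest.add_file("rnn_probe", path)
    elif stage == "tuning-shift":
        params = state.get("rnn_params") or _load_checkpoint(out)
        rows = []
        for geometry in ("R", "RT"):
            maps, _ = rnn_mod.joint_tuning_maps(params, geometry)
            for ui, m in enumerate(maps):
                try:
                    shift = rnn_mod.tuning_shift(m)
                except rnn_mod.UndefinedShiftError:
                    shift = np.nan
                rows.append({"unit": ui, "geometry": geometry, "shift_pct": shift})
        path = out / "tuning_shifts.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        manifest.add_file("tuning_shifts", path)
    else:  # pragma: no cover - guarded by PipelineConfig validation
        raise ValueError(f"unknown stage {stage}")


def _load_checkpoint(out: Path):
    from .rnn import RNNParams

    path = out / "rnn_checkpoint.json"
    if not path.exists():
        raise RuntimeError("probe stages require train-rnn or a checkpoint file")
    data = json.loads(path.read_text())
    return RNNParams(
        W_in=np.array(data["W_in"]), W_rec=np.array(data["W_rec"]),
        W_out=np.array(data["W_out"]), b_rec=np.array(data["b_rec"]),
        b_out=np.array(data["b_out"]),
    )


# --------------------------------------------------------------------------
# Trial-table validation
# --------------------------------------------------------------------------

def validate_trial_table(path) -> list[str]:
    """Schema/range/invariant checks on a trial-table CSV.

    Returns a list of human-readable error strings (empty when valid),
    each prefixed with the offending CSV line number where applicable.
    """
    from .behavior import TRIAL_COLUMNS

    df = pd.read_csv(path)
    errors = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return errors
    for i, row in df.iterrows():
        line = i + 2  # header + 1-based
        d = row["retinal_dir_deg"]
        if not (-90.0 <= d <= 270.0):
            errors.append(f"line {line}: retinal_dir_deg {d} outside [-90, 270]")
        if row["eye_dir"] not in (-1.0, 1.0, -1, 1):
            errors.append(f"line {line}: eye_dir must be -1 or +1")
        has_dir = pd.notna(row["report_dir_deg"])
        has_depth = pd.notna(row["depth_report"]) and row["depth_report"] != ""
        if has_dir == has_depth:
            errors.append(
                f"line {line}: exactly one of report_dir_deg/depth_report required"
            )
        if has_depth and row["depth_report"] not in ("near", "far"):
            errors.append(f"line {line}: depth_report must be 'near' or 'far'")
    return errors
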