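"""Config-driven experiments: replicate runs, parameter sweeps, presets.

The figure presets encode the published experiment grid: n=100, t=400,
k=5 unless swept; amplification settings per panel. ``fig2*`` are single
trajectory panels, ``fig3*`` are conflict sweeps, ``fig4*``/``fig5*`` the
intervention comparisons.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams, Trajectory, run
from .interventions import DisseminationConfig, InterventionConfig
from .metrics import summarize


@dataclass(frozen=True)
class ExperimentConfig:
    model: ModelParams = field(default_factory=ModelParams)
    interventions: InterventionConfig | None = None
    replicates: int = 1
    base_seed: int = 0
    outputs: str | None = None
    record_every: int = 1
    grid: dict = field(default_factory=dict)  # optional sweep, name -> values

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        valid = {f.name for f in dataclasses.fields(ModelParams)}
        for key in self.grid:
            if key not in valid:
                raise ValueError(f"unknown sweep parameter {key!r}")


@dataclass
class RunResult:
    seed: int
    params: ModelParams
    summary: dict
    trajectory: Trajectory
    trajectory_path: str | None = None
    conflict_path: str | None = None


def _write_outputs(
    traj: Trajectory, outdir: Path, tag: str, record_every: int
) -> tuple[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    df = traj.to_long_dataframe()
    if record_every > 1:
        df = df[df["timestep"] % record_every == 0]
    tpath = outdir / f"{tag}_trajectory.csv"
    cpath = outdir / f"{tag}_conflict.csv"
    df.to_csv(tpath, index=False)
    traj.conflict_dataframe().to_csv(cpath, index=False)
    with open(outdir / f"{tag}_summary.json", "w") as fh:
        json.dump(summarize(traj), fh, indent=2)
    return str(tpath), str(cpath)


def run_experiment(cfg: ExperimentConfig) -> list[RunResult]:
    """Run ``cfg.replicates`` seeded replicates (seeds base_seed,
    base_seed+1, ...). Identical config and seed give identical outputs."""
    results = []
    for r in range(cfg.replicates):
        seed = cfg.base_seed + r
        params = replace(cfg.model, seed=seed)
        traj = run(params, interventions=cfg.interventions)
        res = RunResult(seed=seed, params=params, summary=summarize(traj), trajectory=traj)
        if cfg.outputs:
            res.trajectory_path, res.conflict_path = _write_outputs(
                traj, Path(cfg.outputs), f"seed{seed}", cfg.record_every
            )
        results.append(res)
    return results


def sweep(
    grid: dict, base: ExperimentConfig, record_at: tuple[int, ...] = ()
) -> pd.DataFrame:
    """Cartesian-product sweep over ModelParams fields.

    Each row is one grid cell with seed-averaged final conflict, maximum
    conflict over the run, and conflict at any requested timesteps. An
    empty grid yields a single row for the base configuration.
    """
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    for key in grid:
        if key not in valid:
            raise ValueError(f"unknown sweep parameter {key!r}")
    keys = list(grid)
    rows = []
    combos = itertools.product(*(grid[k] for k in keys)) if keys else [()]
    for combo in combos:
        cell = dict(zip(keys, combo))
        cfg = replace(base, model=replace(base.model, **cell), outputs=None)
        results = run_experiment(cfg)
        conflicts = np.array([r.trajectory.conflict for r in results])
        row = dict(cell)
        row["replicates"] = cfg.replicates
        row["mean_final_conflict"] = float(conflicts[:, -1].mean())
        row["mean_max_conflict"] = float(conflicts.max(axis=1).mean())
        row["mean_max_abs_opinion"] = float(
            np.mean([r.summary["max_abs_opinion"] for r in results])
        )
        for t in record_at:
            row[f"mean_conflict_t{t}"] = float(conflicts[:, t].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _amp(eps, pi, p=0.5, s=0.5) -> ModelParams:
    return ModelParams(n=100, k=5, epsilon=eps, pi=pi, p=p, s=s, t_max=400)


_FIG4_BASE = {"pi": 0.5, "p": 0.5, "s": 0.5}


def figure_presets(name: str) -> ExperimentConfig:
    """Experiment configuration for one published figure panel."""
    presets: dict[str, ExperimentConfig] = {
        # Single-trajectory panels: no amplification vs pi=0.2 / 0.5,
        # p=0.5, s=0.5, at high (0.8) and low (0.2) confidence thresholds.
        "fig2a": ExperimentConfig(model=_amp(0.8, 0.0)),
        "fig2b": ExperimentConfig(model=_amp(0.2, 0.0)),
        "fig2c": ExperimentConfig(model=_amp(0.8, 0.2)),
        "fig2d": ExperimentConfig(model=_amp(0.2, 0.2)),
        "fig2e": ExperimentConfig(model=_amp(0.8, 0.5)),
        "fig2f": ExperimentConfig(model=_amp(0.2, 0.5)),
        # Conflict sweeps (seed-averaged): each varies one parameter.
        "fig3a": ExperimentConfig(
            model=ModelParams(n=100, k=5, pi=0.0, t_max=400),
            grid={"epsilon": [0.2, 0.5, 0.8]},
        ),
        "fig3b": ExperimentConfig(
            model=ModelParams(n=100, epsilon=0.8, pi=0.0, t_max=400),
            grid={"k": [2, 5, 10]},
        ),
        "fig3c": ExperimentConfig(
            model=ModelParams(n=100, k=5, pi=0.2, p=0.5, s=0.2, t_max=400),
            grid={"epsilon": [0.2, 0.5, 0.8]},
        ),
        "fig3d": ExperimentConfig(
            model=ModelParams(n=100, k=5, epsilon=0.2, pi=0.2, p=0.5, t_max=400),
            grid={"s": [0.2, 0.5, 0.8]},
        ),
        "fig3e": ExperimentConfig(
            model=ModelParams(n=100, k=5, epsilon=0.2, p=0.5, s=0.2, t_max=400),
            grid={"pi": [0.2, 0.5, 0.8]},
        ),
        "fig3f": ExperimentConfig(
            model=ModelParams(n=100, k=5, epsilon=0.2, pi=0.2, s=0.2, t_max=400),
            grid={"p": [0.2, 0.5, 0.8]},
        ),
        # Intervention comparisons at pi=0.5, p=0.5, s=0.5.
        "fig4a": ExperimentConfig(model=_amp(0.2, **_FIG4_BASE)),
        "fig4b": ExperimentConfig(
            model=_amp(0.2, **_FIG4_BASE),
            interventions=InterventionConfig(max_amplify=5),
        ),
        "fig4c": ExperimentConfig(model=_amp(0.8, **_FIG4_BASE)),
        "fig4d": ExperimentConfig(
            model=_amp(0.8, **_FIG4_BASE),
            interventions=InterventionConfig(max_amplify=5),
        ),
        "fig5a": ExperimentConfig(model=_amp(0.2, **_FIG4_BASE)),
        "fig5b": ExperimentConfig(
            model=_amp(0.2, **_FIG4_BASE),
            interventions=InterventionConfig(dissemination=DisseminationConfig()),
        ),
        "fig5c": ExperimentConfig(model=_amp(0.8, **_FIG4_BASE)),
        "fig5d": ExperimentConfig(
            model=_amp(0.8, **_FIG4_BASE),
            interventions=InterventionConfig(dissemination=DisseminationConfig()),
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


def _interventions_from_dict(d: dict | None) -> InterventionConfig | None:
    if not d:
        return None
    diss = d.get("dissemination")
    return InterventionConfig(
        max_amplify=d.get("max_amplify"),
        dissemination=DisseminationConfig(**diss) if diss else None,
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an ExperimentConfig from a YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = ModelParams(**(raw.get("model") or {}))
    return ExperimentConfig(
        model=model,
        interventions=_interventions_from_dict(raw.get("interventions")),
        replicates=raw.get("replicates", 1),
        base_seed=raw.get("base_seed", 0),
        outputs=raw.get("outputs"),
        record_every=raw.get("record_every", 1),
        grid=raw.get("grid", {}) or {},
    )
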