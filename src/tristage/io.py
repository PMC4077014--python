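"""Result serialization: CSV tables, JSON run manifest, HDF5 checkpoints."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import config_to_dict
from .consolidation import SimulationResult, ThreeStageSystem
from .patterns import Pattern, PatternSet, SeparatorMatrix, SubsetMap
from .recall import consolidation_curves

__all__ = [
    "write_results",
    "save_checkpoint",
    "load_checkpoint",
    "batch_curves",
    "patterns_to_csv",
    "patterns_from_csv",
]


def patterns_to_csv(pattern_set: PatternSet, path: str | Path) -> None:
    """Export the pattern inventory: one row per (pattern, stage).

    Active units are stored as a space-separated index list, so the file
    stays small and diff-friendly.
    """
    rows = []
    for p in pattern_set.patterns:
        for stage in ("ctx", "pfc", "hip"):
            rows.append(
                {
                    "pattern_id": p.id,
                    "day": p.day,
                    "percept": p.percept,
                    "stage": stage,
                    "active_units": " ".join(
                        str(i) for i in np.flatnonzero(p.encoding(stage))
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def patterns_from_csv(path: str | Path) -> dict[int, dict[str, np.ndarray]]:
    """Read exported patterns back as {id: {stage: active-unit index array}}."""
    df = pd.read_csv(path)
    out: dict[int, dict[str, np.ndarray]] = {}
    for _, row in df.iterrows():
        units = str(row["active_units"])
        idx = np.array([int(i) for i in units.split()] if units.strip() else [])
        out.setdefault(int(row["pattern_id"]), {})[row["stage"]] = idx
    return out


def batch_curves(results: list[SimulationResult]) -> pd.DataFrame:
    """Pooled consolidation curves over a batch with per-age mean and std.

    The std is computed over the per-run rates (the stochasticity of the
    consolidation process, not the standard error).
    """
    per_run = []
    for r in results:
        c = consolidation_curves(r.recall)
        c["seed"] = r.seed
        per_run.append(c)
    allc = pd.concat(per_run, ignore_index=True)
    out = (
        allc.groupby(["stage", "age_days"])["rate"]
        .agg(rate="mean", rate_std="std", n_runs="size")
        .reset_index()
    )
    return out


def write_results(
    result: SimulationResult | list[SimulationResult],
    out_dir: str | Path,
    checkpoint: bool = True,
) -> dict[str, Path]:
    """Write recall/event/curve CSV tables, a JSON manifest and a checkpoint.

    Accepts a single run or a batch; batch tables carry the per-run seed.
    Returns the paths written.  The manifest records the configuration, the
    seeds and the package version, so a run can be reproduced bit-identically.
    """
    results = result if isinstance(result, list) else [result]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recall = pd.concat([r.recall for r in results], ignore_index=True)
    events = pd.concat(
        [r.events.assign(seed=r.seed) for r in results], ignore_index=True
    )
    curves = batch_curves(results)
    paths = {
        "recall": out / "recall.csv",
        "events": out / "events.csv",
        "curves": out / "curves.csv",
        "manifest": out / "manifest.json",
    }
    recall.to_csv(paths["recall"], index=False)
    events.to_csv(paths["events"], index=False)
    curves.to_csv(paths["curves"], index=False)
    cfg_dict = config_to_dict(results[0].config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "package": "tristage",
        "version": _pkg_version,
        "seeds": [r.seed for r in results],
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_runs": len(results),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    if checkpoint:
        paths["checkpoint"] = out / "checkpoint.h5"
        save_checkpoint(results[-1].system, paths["checkpoint"])
    return paths


def _save_projection(grp: h5py.Group, proj) -> None:
    grp.create_dataset("pre_rates", data=proj.traces.pre_rates)
    if not proj.traces.auto:
        grp.create_dataset("post_rates", data=proj.traces.post_rates)
    grp.create_dataset("pair_rates", data=proj.traces.pair_rates)
    grp.attrs["pre_floor"] = proj.traces.pre_floor
    grp.attrs["post_floor"] = proj.traces.post_floor
    grp.attrs["tau"] = proj.tau


def _load_projection(grp: h5py.Group, proj) -> None:
    proj.traces.pre_rates[:] = grp["pre_rates"][...]
    if not proj.traces.auto:
        proj.traces.post_rates[:] = grp["post_rates"][...]
    proj.traces.pair_rates[:] = grp["pair_rates"][...]
    proj.traces.pre_floor = float(grp.attrs["pre_floor"])
    proj.traces.post_floor = float(grp.attrs["post_floor"])
    proj.tau = float(grp.attrs["tau"])
    proj._invalidate()


_PROJECTIONS = (
    "pfc_auto", "pfc_adapt", "hip_auto", "hip_adapt", "ctx_auto",
    "pfc2hip", "hip2ctx",
)


def save_checkpoint(system: ThreeStageSystem, path: str | Path) -> None:
    """Snapshot the full system state (traces, supports, activities, clock)."""
    system.flush_all()
    with h5py.File(path, "w") as f:
        f.attrs["clock"] = system.clock
        f.attrs["n_presented"] = system.n_presented
        f.attrs["dt"] = system.dt
        for name in _PROJECTIONS:
            _save_projection(f.create_group(name), getattr(system, name))
        for pop_name in ("pfc", "hip", "ctx"):
            pop = system.stage(pop_name)
            g = f.create_group(pop_name)
            g.create_dataset("support", data=pop.support)
            g.create_dataset("activity", data=pop.activity)
            g.create_dataset("alive", data=pop.alive)
            if pop.k is not None:
                g.attrs["k"] = pop.k
        pats = system.patterns
        g = f.create_group("patterns")
        g.attrs["n_days"] = pats.n_days
        g.attrs["percepts_per_day"] = pats.percepts_per_day
        g.attrs["patterns_per_percept"] = pats.patterns_per_percept
        g.create_dataset("ctx", data=pats.stage_matrix("ctx").astype(np.uint8))
        g.create_dataset("separator", data=pats.separator.weights)
        g.create_dataset(
            "subset_hypercolumns", data=np.asarray(pats.subset_map.ctx_hypercolumns)
        )


def load_checkpoint(path: str | Path) -> ThreeStageSystem:
    """Rebuild a system (including its pattern inventory) from a checkpoint."""
    from .patterns import derive_hip_pattern, derive_pfc_pattern

    with h5py.File(path, "r") as f:
        g = f["patterns"]
        subset = SubsetMap(tuple(int(h) for h in g["subset_hypercolumns"][...]))
        sep = SeparatorMatrix(weights=g["separator"][...])
        ctx_mat = g["ctx"][...]
        per_day = int(g.attrs["percepts_per_day"]) * int(g.attrs["patterns_per_percept"])
        patterns = []
        for i, ctx in enumerate(ctx_mat):
            ctx = ctx.astype(np.uint8)
            patterns.append(
                Pattern(
                    id=i + 1,
                    day=i // per_day + 1,
                    percept=i // int(g.attrs["patterns_per_percept"]) + 1,
                    ctx=ctx,
                    pfc=derive_pfc_pattern(ctx, subset),
                    hip=derive_hip_pattern(ctx, sep),
                )
            )
        pattern_set = PatternSet(
            patterns=patterns,
            subset_map=subset,
            separator=sep,
            n_days=int(g.attrs["n_days"]),
            percepts_per_day=int(g.attrs["percepts_per_day"]),
            patterns_per_percept=int(g.attrs["patterns_per_percept"]),
        )
        system = ThreeStageSystem(pattern_set, dt=float(f.attrs["dt"]))
        system.clock = int(f.attrs["clock"])
        system.n_presented = int(f.attrs["n_presented"])
        for name in _PROJECTIONS:
            _load_projection(f[name], getattr(system, name))
        for pop_name in ("pfc", "hip", "ctx"):
            pop = system.stage(pop_name)
            gp = f[pop_name]
            pop.support = gp["support"][...]
            pop.activity = gp["activity"][...]
            pop.alive = gp["alive"][...].astype(bool)
            if "k" in gp.attrs:
                pop.k = int(gp.attrs["k"])
    dead = np.flatnonzero(~system.hip.alive)
    if dead.size:
        system.hip_auto.nullify_units(dead, dead)
        system.hip_adapt.nullify_units(dead, dead)
        system.pfc2hip.nullify_units(None, dead)
        system.hip2ctx.nullify_units(dead, None)
        system.ctx2hip.nullify_units(None, dead)
        system.lesioned = True
    return system
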