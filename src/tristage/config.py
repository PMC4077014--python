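"""Run configuration: stage, phase and experiment parameters with defaults.

The defaults encode the reference parameterization of the three-stage model:
network sizes 50/250/500, hypercolumns 5/-/50, activity levels 10/5/10%,
learning time constants 8/400/18500 ms (scaled: 3 min / 3 h / 6 days),
inter-stage plastic projections at 20 ms (9 min), the per-phase gain/time
constant gating, and phase lengths 3/52/165 steps of 10 ms - one simulated
day and night in 330 steps, a temporal compression of roughly 26,000x.

Configurations load from YAML or JSON; unknown keys are rejected by name so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .bcpnn import INF, PopulationParams

__all__ = [
    "PhaseConfig",
    "LesionSpec",
    "ModulationSpec",
    "RunConfig",
    "default_phases",
    "default_stage_params",
    "load_config",
    "config_to_dict",
    "ConfigError",
    "temporal_scale_factor",
    "SECONDS_PER_DAY",
]

SECONDS_PER_DAY = 86400.0


def temporal_scale_factor(steps_per_day: int = 330, dt_ms: float = 10.0) -> float:
    """Real seconds per model second: 24 h against one simulated day-night cycle."""
    return SECONDS_PER_DAY / (steps_per_day * dt_ms / 1000.0)


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass
class PhaseConfig:
    """Per-phase gain/time-constant gating of the three stages.

    ``tau`` values are learning (``_L``) or adaptation (``_A``) time constants
    in model ms, ``inf`` meaning frozen.  ``g_*`` are projection gains; a gain
    of zero disables the projection for the phase.  ``tau_pfc2hip`` and
    ``tau_hip2ctx`` gate the plastic inter-stage projections (they learn while
    both ends are clamped during perception and are frozen while driving).
    """

    name: str
    length_steps: int
    pfc_g_L: float = 1.0
    pfc_tau_L: float = INF
    pfc_g_A: float = 0.0
    pfc_tau_A: float = INF
    hip_g_L: float = 1.0
    hip_tau_L: float = INF
    hip_g_A: float = 0.0
    hip_tau_A: float = INF
    ctx_g_L: float = 1.0
    ctx_tau_L: float = INF
    g_pfc2hip: float = 0.0
    g_pfc2ctx: float = 0.0
    g_hip2ctx: float = 0.0
    g_ctx2pfc: float = 0.0
    g_ctx2hip: float = 0.0
    tau_pfc2hip: float = INF
    tau_hip2ctx: float = INF


def default_phases(interstage_tau_L: float = 20.0) -> dict[str, PhaseConfig]:
    """The reference gating table for perception, reflection, sleep, recall."""
    return {
        "perception": PhaseConfig(
            name="perception",
            length_steps=3,
            pfc_g_L=1.0, pfc_tau_L=5.0, pfc_g_A=-1.2, pfc_tau_A=120.0,
            hip_g_L=1.0, hip_tau_L=400.0, hip_g_A=-0.8, hip_tau_A=400.0,
            ctx_g_L=1.0, ctx_tau_L=18500.0,
            g_ctx2pfc=1.0, g_ctx2hip=1.0,
            tau_pfc2hip=interstage_tau_L, tau_hip2ctx=interstage_tau_L,
        ),
        "reflection": PhaseConfig(
            name="reflection",
            length_steps=52,
            pfc_g_L=1.0, pfc_tau_L=INF, pfc_g_A=-1.2, pfc_tau_A=120.0,
            hip_g_L=0.0, hip_tau_L=400.0, hip_g_A=0.0, hip_tau_A=400.0,
            ctx_g_L=0.0, ctx_tau_L=18500.0,
            g_pfc2hip=1.0, g_pfc2ctx=1.0,
        ),
        "sleep": PhaseConfig(
            name="sleep",
            length_steps=165,
            pfc_g_L=0.0, pfc_tau_L=5.0, pfc_g_A=0.0, pfc_tau_A=120.0,
            hip_g_L=1.0, hip_tau_L=INF, hip_g_A=-0.8, hip_tau_A=400.0,
            ctx_g_L=0.0, ctx_tau_L=18500.0,
            g_hip2ctx=1.0,
        ),
        "recall": PhaseConfig(
            name="recall",
            length_steps=0,
            pfc_g_L=1.0, pfc_tau_L=INF, pfc_g_A=0.0, pfc_tau_A=INF,
            hip_g_L=1.0, hip_tau_L=INF, hip_g_A=0.0, hip_tau_A=INF,
            ctx_g_L=1.0, ctx_tau_L=INF,
            g_ctx2pfc=1.0, g_ctx2hip=1.0,
        ),
    }


def default_stage_params() -> dict[str, PopulationParams]:
    """Stage-level reference parameters (PFC / HIP / CTX columns)."""
    return {
        "pfc": PopulationParams(
            tau_L=8.0, tau_A=160.0, g_L=1.0, g_A=-1.2,
            activity_level=0.1, theta=0.093,
        ),
        "hip": PopulationParams(
            tau_L=400.0, tau_A=400.0, g_L=1.0, g_A=-0.8,
            activity_level=0.05, theta=0.252,
        ),
        "ctx": PopulationParams(
            tau_L=18500.0, tau_A=INF, g_L=1.0, g_A=0.0,
            activity_level=0.1, theta=0.383,
        ),
    }


@dataclass
class LesionSpec:
    """Random hippocampal lesion: disable a fraction of HIP units.

    ``timing='before'`` lesions the naive system (anterograde protocol);
    ``'after'`` lesions the trained system before recall testing (retrograde
    protocol).
    """

    fraction: float = 1.0
    timing: str = "after"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("lesion fraction must lie in [0, 1]")
        if self.timing not in ("before", "after"):
            raise ConfigError("lesion timing must be 'before' or 'after'")


@dataclass
class ModulationSpec:
    """Transient up/down-regulation of hippocampal plasticity.

    The effective rate multiplier is
    ``m(t) = 1 - (1 - factor) * 2**(-(t - t_onset)/half_life_ms)`` for
    t >= onset; with ``half_life_ms = inf`` the constant ``factor`` applies
    during the target percept's perception steps only (a brief relevance /
    attention boost).  A factor of 2 halves tau_L; 0.1 models benzodiazepine-
    like suppression of acquisition.
    """

    factor: float = 2.0
    onset_percept: int = 89
    half_life_ms: float = INF
    target_stage: str = "hip"

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ConfigError("modulation factor must be positive")

    def multiplier(self, t_ms: float, onset_ms: float | None) -> float:
        """Decaying-modulation multiplier at time t (finite half-life only)."""
        if onset_ms is None or t_ms < onset_ms:
            return 1.0
        if self.half_life_ms == INF:
            return self.factor
        return 1.0 - (1.0 - self.factor) * 2.0 ** (
            -(t_ms - onset_ms) / self.half_life_ms
        )


#: half-life of a 2 h pharmacological modulation expressed in model ms
def scaled_half_life_ms(real_seconds: float, steps_per_day: int = 330, dt_ms: float = 10.0) -> float:
    return real_seconds / temporal_scale_factor(steps_per_day, dt_ms) * 1000.0


@dataclass
class RunConfig:
    """Everything a simulation run needs besides the master seed."""

    n_days: int = 39
    percepts_per_day: int = 3
    patterns_per_percept: int = 3
    dt_ms: float = 10.0
    validation_days: int = 1
    interstage_tau_L: float = 20.0
    sleep_reduction: float = 0.0
    replay_threshold: float = 0.9
    pre_sleep_pfc_eval: bool = True
    record_replay: bool = True
    stage_params: dict = field(default_factory=default_stage_params)
    phases: dict = field(default_factory=default_phases)
    lesion: LesionSpec | None = None
    modulation: ModulationSpec | None = None
    recall_days: dict = field(default_factory=dict)  #: day -> list of pattern ids

    def __post_init__(self) -> None:
        if not 0.0 <= self.sleep_reduction < 1.0:
            raise ConfigError("sleep_reduction must lie in [0, 1)")
        if self.n_days <= 0:
            raise ConfigError("n_days must be positive")

    @property
    def patterns_per_day(self) -> int:
        return self.percepts_per_day * self.patterns_per_percept

    @property
    def n_training_patterns(self) -> int:
        return self.n_days * self.patterns_per_day

    def sleep_length(self) -> int:
        """Sleep phase length after any persistent sleep deprivation (floor)."""
        return int(self.phases["sleep"].length_steps * (1.0 - self.sleep_reduction))

    def steps_per_day(self) -> int:
        p = self.phases
        return (
            self.percepts_per_day
            * (p["perception"].length_steps + p["reflection"].length_steps)
            + self.sleep_length()
        )


def sleep_deprive(config: RunConfig, reduction: float = 0.5) -> RunConfig:
    """Persistent sleep deprivation: shorten every sleep phase by ``reduction``."""
    if not 0.0 <= reduction < 1.0:
        raise ConfigError("reduction must lie in [0, 1)")
    out = dataclasses.replace(config)
    out.sleep_reduction = reduction
    return out


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

_INF_TOKENS = {"inf", ".inf", "Infinity"}


def _decode(value, typ):
    if isinstance(value, str) and value in _INF_TOKENS:
        return INF
    return value


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at '{path or cls.__name__}'")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown configuration key '{path}{key}'")
        kwargs[key] = _decode(value, known[key].type)
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration, filling every default.

    Unknown keys raise :class:`ConfigError` naming the offending key.  An
    empty file yields the full default configuration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml", "") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    data = dict(data)
    phases = default_phases(float(data.get("interstage_tau_L", 20.0)))
    for name, overrides in (data.pop("phases", {}) or {}).items():
        if name not in phases:
            raise ConfigError(f"unknown configuration key 'phases.{name}'")
        base = phases[name]
        known = {f.name for f in fields(PhaseConfig)}
        for key, value in (overrides or {}).items():
            if key not in known:
                raise ConfigError(f"unknown configuration key 'phases.{name}.{key}'")
            setattr(base, key, _decode(value, float))
    stage_params = default_stage_params()
    for name, overrides in (data.pop("stage_params", {}) or {}).items():
        if name not in stage_params:
            raise ConfigError(f"unknown configuration key 'stage_params.{name}'")
        known = {f.name for f in fields(PopulationParams)}
        for key, value in (overrides or {}).items():
            if key not in known:
                raise ConfigError(
                    f"unknown configuration key 'stage_params.{name}.{key}'"
                )
            setattr(stage_params[name], key, _decode(value, float))
    lesion = data.pop("lesion", None)
    modulation = data.pop("modulation", None)
    recall_days = {
        int(k): v for k, v in (data.pop("recall_days", {}) or {}).items()
    }
    cfg = _from_dict(RunConfig, data)
    cfg.phases = phases
    cfg.stage_params = stage_params
    cfg.recall_days = recall_days
    if lesion is not None:
        cfg.lesion = _from_dict(LesionSpec, lesion, "lesion.")
    if modulation is not None:
        cfg.modulation = _from_dict(ModulationSpec, modulation, "modulation.")
    return cfg


def _encode(obj):
    if isinstance(obj, float) and obj == INF:
        return ".inf"
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _encode(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def config_to_dict(config: RunConfig) -> dict:
    """Losslessly serializable dict form of a configuration."""
    return _encode(config)
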