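"""The three-stage memory system and its day/night simulation cycle.

One simulated day is 330 steps of 10 ms: three perception-reflection blocks
(3 + 52 steps each) followed by one sleep phase (165 steps), a temporal
compression of roughly 26,000x against a real day.

* Perception: the three stages are clamped to each pattern's encodings (the
  idealized limit of feed-forward drive); all plastic projections learn,
  including the inter-stage associations.  One step per pattern forces
  one-shot learning - only the fast PFC stage can retain a pattern from a
  single exposure.
* Reflection: PFC replays the day's patterns autonomously (auto-association
  against adaptation); its replay drives HIP through the plastic forward
  projection, and the repeated HIP reinstatements build the hippocampal
  trace.
* Sleep: PFC is silenced and forgets (fast plasticity onto uniform activity);
  HIP replays autonomously and drives CTX through the learned back-
  projection, gradually consolidating the neocortical trace.

Learning continues throughout convergence and depression of reinstated
patterns - there is no wait-for-convergence gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bcpnn import (
    INF,
    FixedProjection,
    Population,
    PopulationParams,
    Projection,
    normalize_kwta,
    normalize_softmax,
    _alpha,
)
from .config import (
    LesionSpec,
    ModulationSpec,
    PhaseConfig,
    RunConfig,
    default_phases,
    default_stage_params,
    temporal_scale_factor,
)
from .layout import HypercolumnLayout
from .patterns import (
    HIP_K,
    HIP_UNITS,
    Pattern,
    PatternSet,
    build_training_set,
)
from .replay import ReinstatementEvent, detect_reinstatements, events_to_frame

__all__ = [
    "ThreeStageSystem",
    "SimulationResult",
    "run_phase",
    "run_day",
    "run_simulation",
    "run_batch",
    "apply_lesion",
    "apply_modulation",
    "temporal_scale_factor",
]


class ThreeStageSystem:
    """PFC, HIP and CTX populations with all intra- and inter-stage projections.

    Plastic projections: the three auto-associations, the PFC and HIP
    adaptation projections (negative gain, fast time constant - same
    Hebbian-Bayesian rule), and the PFC->HIP / HIP->CTX associations.
    Fixed projections: the 1-to-1 CTX<->PFC subset maps and the random
    CTX->HIP pattern-separation matrix.
    """

    def __init__(
        self,
        pattern_set: PatternSet,
        stage_params: dict[str, PopulationParams] | None = None,
        dt: float = 10.0,
    ) -> None:
        sp = stage_params or default_stage_params()
        self.dt = dt
        self.patterns = pattern_set
        self.pfc = Population(HypercolumnLayout.uniform(5, 10), sp["pfc"], name="pfc")
        self.hip = Population(
            HypercolumnLayout.flat(HIP_UNITS), sp["hip"], k=HIP_K, name="hip"
        )
        self.ctx = Population(HypercolumnLayout.uniform(50, 10), sp["ctx"], name="ctx")

        self.pfc_auto = Projection(self.pfc, self.pfc, sp["pfc"].tau_L, name="pfc_auto")
        self.pfc_adapt = Projection(self.pfc, self.pfc, sp["pfc"].tau_A, name="pfc_adapt")
        self.hip_auto = Projection(self.hip, self.hip, sp["hip"].tau_L, name="hip_auto")
        self.hip_adapt = Projection(self.hip, self.hip, sp["hip"].tau_A, name="hip_adapt")
        # Adaptation traces model a biophysical fatigue variable and relax
        # toward the stage's resting activity, never below it: uniform soft-WTA
        # rest (1/M) for the modular PFC, the background noise rate lambda_0
        # for the silent-at-rest kWTA stage.  (Associative traces keep the
        # deeper lambda_0-scaled floors: they are long-run memory and carry
        # anticorrelation information.)
        self.pfc_adapt.traces.pre_floor = self.pfc_adapt.traces.post_floor = float(
            self.pfc.unit_prior().min()
        )
        self.hip_adapt.traces.pre_floor = self.hip_adapt.traces.post_floor = (
            sp["hip"].lambda_0
        )
        self.ctx_auto = Projection(self.ctx, self.ctx, sp["ctx"].tau_L, name="ctx_auto")
        self.pfc2hip = Projection(self.pfc, self.hip, 20.0, name="pfc2hip")
        self.hip2ctx = Projection(self.hip, self.ctx, 20.0, name="hip2ctx")
        m = pattern_set.subset_map.matrix()
        self.ctx2pfc = FixedProjection(self.ctx, self.pfc, m, gain=0.0)
        self.pfc2ctx = FixedProjection(self.pfc, self.ctx, m.T, gain=0.0)
        self.ctx2hip = FixedProjection(
            self.ctx, self.hip, pattern_set.separator.weights.copy(), gain=0.0
        )

        self.clock = 0  #: global step counter
        self.n_presented = 0  #: training patterns shown so far
        self.current_percept: int | None = None  #: percept of the ongoing block
        self.modulation: ModulationSpec | None = None
        self.modulation_onset_ms: float | None = None
        self.lesioned = False

    # -- time and modulation ---------------------------------------------

    @property
    def t_ms(self) -> float:
        return self.clock * self.dt

    def stage(self, name: str) -> Population:
        return {"pfc": self.pfc, "hip": self.hip, "ctx": self.ctx}[name.lower()]

    def hip_rate_multiplier(self, percept: int | None = None) -> float:
        """Current multiplier on the HIP associative plasticity rate 1/tau_L."""
        spec = self.modulation
        if spec is None:
            return 1.0
        if spec.half_life_ms == INF:
            # constant boost, active only while the target percept is being
            # learned (its perception steps and the following reflection)
            return spec.factor if percept == spec.onset_percept else 1.0
        return spec.multiplier(self.t_ms, self.modulation_onset_ms)

    def plastic_projections(self) -> list[Projection]:
        return [
            self.pfc_auto,
            self.pfc_adapt,
            self.hip_auto,
            self.hip_adapt,
            self.ctx_auto,
            self.pfc2hip,
            self.hip2ctx,
        ]

    def flush_all(self) -> None:
        for p in self.plastic_projections():
            p.flush()


def apply_modulation(
    system: ThreeStageSystem, spec: ModulationSpec, t_ms: float | None = None
) -> float:
    """Install a plasticity modulation and return the effective HIP rate 1/tau_L.

    The onset time is bound to the target percept's first perception step by
    the simulation loop; this helper reports the rate that applies at ``t_ms``
    (now by default).
    """
    system.modulation = spec
    t = system.t_ms if t_ms is None else t_ms
    base = 1.0 / system.hip.params.tau_L
    if spec.half_life_ms == INF:
        return base * spec.factor
    return base * spec.multiplier(t, system.modulation_onset_ms)


def apply_lesion(
    system: ThreeStageSystem, spec: LesionSpec, rng: np.random.Generator
) -> ThreeStageSystem:
    """Disable a random fraction of HIP units and nullify their connections.

    Dead units are clamped to zero activity forever; every row/column through
    them in the HIP auto-associative, adaptation, PFC->HIP, HIP->CTX and
    CTX->HIP matrices is nullified, and the kWTA k shrinks proportionally
    (k = round(0.05 * surviving units)).
    """
    n = int(round(spec.fraction * system.hip.n_units))
    dead = rng.choice(system.hip.n_units, size=n, replace=False)
    system.hip.lesion(dead)
    system.hip_auto.nullify_units(dead, dead)
    system.hip_adapt.nullify_units(dead, dead)
    system.pfc2hip.nullify_units(None, dead)
    system.hip2ctx.nullify_units(dead, None)
    system.ctx2hip.nullify_units(None, dead)
    system.lesioned = True
    return system


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------


def _relax_support(pop: Population, target: np.ndarray, dt: float) -> None:
    a = _alpha(dt, pop.params.tau_C)
    pop.support = pop.support + a * (target - pop.support)


def run_phase(
    system: ThreeStageSystem,
    phase: PhaseConfig,
    stimuli: list[Pattern] | None = None,
    collect: tuple[str, ...] = (),
) -> dict[str, np.ndarray]:
    """Advance the system through one phase; returns per-step activity logs.

    ``stimuli`` is required for (and only for) perception: exactly
    ``length_steps`` patterns, one shown per step.  ``collect`` names the
    stages whose activities should be logged (for replay detection).
    """
    dt = system.dt
    logs: dict[str, list[np.ndarray]] = {s: [] for s in collect}
    if phase.name == "perception":
        if stimuli is None or len(stimuli) != phase.length_steps:
            raise ValueError(
                f"perception needs exactly {phase.length_steps} stimuli, one per step"
            )
    elif stimuli is not None:
        raise ValueError(f"phase '{phase.name}' takes no stimuli")

    for step in range(phase.length_steps):
        if phase.name == "perception":
            pat = stimuli[step]
            mult = system.hip_rate_multiplier(percept=pat.percept)
            pfc_act = pat.pfc.astype(float)
            hip_act = pat.hip.astype(float) * system.hip.alive
            ctx_act = pat.ctx.astype(float)
            system.pfc.activity = pfc_act
            system.hip.activity = hip_act
            system.ctx.activity = ctx_act
            system.pfc_auto.tau = phase.pfc_tau_L
            system.pfc_auto.observe(pfc_act, pfc_act, dt)
            system.pfc_adapt.tau = phase.pfc_tau_A
            system.pfc_adapt.observe(pfc_act, pfc_act, dt)
            system.hip_auto.tau = phase.hip_tau_L
            system.hip_auto.observe(hip_act, hip_act, dt, rate_multiplier=mult)
            system.hip_adapt.tau = phase.hip_tau_A
            system.hip_adapt.observe(hip_act, hip_act, dt)
            system.ctx_auto.tau = phase.ctx_tau_L
            system.ctx_auto.observe(ctx_act, ctx_act, dt)
            system.pfc2hip.tau = phase.tau_pfc2hip
            system.pfc2hip.observe(pfc_act, hip_act, dt)
            system.hip2ctx.tau = phase.tau_hip2ctx
            system.hip2ctx.observe(hip_act, ctx_act, dt)
        elif phase.name == "reflection":
            mult = system.hip_rate_multiplier(percept=system.current_percept)
            # PFC free-runs: frozen auto-association against adapting depression
            target = phase.pfc_g_L * system.pfc_auto.support_term(system.pfc.activity)
            if phase.pfc_g_A != 0.0:
                target = target + phase.pfc_g_A * system.pfc_adapt.support_term(
                    system.pfc.activity
                )
            _relax_support(system.pfc, target, dt)
            system.pfc.activity = normalize_softmax(system.pfc.support, system.pfc.layout)
            # PFC replay drives HIP (kWTA) and CTX (soft-WTA) feed-forward
            hip_target = phase.g_pfc2hip * system.pfc2hip.support_term(
                system.pfc.activity
            )
            _relax_support(system.hip, hip_target, dt)
            system.hip.activity = system.hip.normalize(system.hip.support)
            ctx_target = phase.g_pfc2ctx * system.pfc2ctx.support_term(
                system.pfc.activity
            )
            _relax_support(system.ctx, ctx_target, dt)
            system.ctx.activity = normalize_softmax(system.ctx.support, system.ctx.layout)
            system.pfc_adapt.tau = phase.pfc_tau_A
            system.pfc_adapt.observe(system.pfc.activity, system.pfc.activity, dt)
            system.hip_auto.tau = phase.hip_tau_L
            system.hip_auto.observe(
                system.hip.activity, system.hip.activity, dt, rate_multiplier=mult
            )
            system.hip_adapt.tau = phase.hip_tau_A
            system.hip_adapt.observe(system.hip.activity, system.hip.activity, dt)
            system.ctx_auto.tau = phase.ctx_tau_L
            system.ctx_auto.observe(system.ctx.activity, system.ctx.activity, dt)
            if phase.tau_pfc2hip != INF:
                system.pfc2hip.tau = phase.tau_pfc2hip
                system.pfc2hip.observe(system.pfc.activity, system.hip.activity, dt)
        elif phase.name == "sleep":
            # HIP free-runs: frozen auto-association against adapting depression
            active = np.flatnonzero(system.hip.activity)
            hip_target = phase.hip_g_L * system.hip_auto.support_term(
                system.hip.activity, active=active
            )
            if phase.hip_g_A != 0.0:
                hip_target = hip_target + phase.hip_g_A * system.hip_adapt.support_term(
                    system.hip.activity, active=active
                )
            _relax_support(system.hip, hip_target, dt)
            system.hip.activity = system.hip.normalize(system.hip.support)
            active = np.flatnonzero(system.hip.activity)
            # HIP replay drives CTX reinstatement through the back-projection
            ctx_target = phase.g_hip2ctx * system.hip2ctx.support_term(
                system.hip.activity, active=active
            )
            _relax_support(system.ctx, ctx_target, dt)
            system.ctx.activity = normalize_softmax(system.ctx.support, system.ctx.layout)
            # PFC is silenced: zero support, uniform activity, fast forgetting
            _relax_support(system.pfc, np.zeros(system.pfc.n_units), dt)
            system.pfc.activity = normalize_softmax(system.pfc.support, system.pfc.layout)
            system.hip_adapt.tau = phase.hip_tau_A
            system.hip_adapt.observe(system.hip.activity, system.hip.activity, dt)
            system.ctx_auto.tau = phase.ctx_tau_L
            system.ctx_auto.observe(system.ctx.activity, system.ctx.activity, dt)
            system.pfc_auto.tau = phase.pfc_tau_L
            system.pfc_auto.observe(system.pfc.activity, system.pfc.activity, dt)
            system.pfc_adapt.tau = phase.pfc_tau_A
            system.pfc_adapt.observe(system.pfc.activity, system.pfc.activity, dt)
            if phase.tau_hip2ctx != INF:
                system.hip2ctx.tau = phase.tau_hip2ctx
                system.hip2ctx.observe(system.hip.activity, system.ctx.activity, dt)
        else:
            raise ValueError(f"unknown phase '{phase.name}'")
        system.clock += 1
        for s in collect:
            logs[s].append(system.stage(s).activity.copy())

    return {s: np.stack(v) if v else np.empty((0, system.stage(s).n_units)) for s, v in logs.items()}


def run_day(
    system: ThreeStageSystem,
    day_patterns: list[Pattern],
    phases: dict[str, PhaseConfig] | None = None,
    sleep_length: int | None = None,
    replay_threshold: float = 0.9,
    record_replay: bool = True,
) -> list[ReinstatementEvent]:
    """One day-night cycle: 3 x (perception + reflection) + sleep.

    Returns the reinstatement events detected in HIP during the reflection
    phases and in CTX during sleep (candidates are the training patterns
    presented so far).
    """
    phases = phases or default_phases()
    n_per_percept = len(day_patterns) // 3
    if len(day_patterns) != 3 * n_per_percept or n_per_percept == 0:
        raise ValueError("a day needs percepts_per_day x patterns_per_percept patterns")
    events = _run_day_until_sleep(
        system, day_patterns, phases, 3, n_per_percept, replay_threshold, record_replay
    )
    events.extend(
        _run_sleep(system, phases, sleep_length, replay_threshold, record_replay)
    )
    return events


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Outcome of one simulation run."""

    seed: int
    config: RunConfig
    system: ThreeStageSystem
    pattern_set: PatternSet
    recall: pd.DataFrame  #: per-pattern recall table (all evaluations)
    events: pd.DataFrame  #: reinstatement events
    reflection_steps: int  #: total reflection steps simulated
    sleep_steps: int  #: total sleep steps simulated

    def replay_stats(self, stage: str, phase: str) -> dict:
        from .replay import replay_statistics

        duration = {
            "reflection": self.reflection_steps,
            "sleep": self.sleep_steps,
        }[phase] * self.system.dt
        ev = self.events
        sel = ev[(ev["stage"] == stage) & (ev["phase"] == phase)]
        return replay_statistics(sel, duration, self.system.dt)


def run_simulation(
    config: RunConfig | None = None, seed: int = 0
) -> SimulationResult:
    """Run the full multi-day consolidation protocol and evaluate recall.

    All randomness (patterns, separator matrix, lesion selection) derives
    from ``seed``; two runs with the same seed and configuration are
    bit-identical.  Recall is tested with plasticity frozen after the final
    sleep phase (plus a pre-sleep PFC evaluation, since PFC forgets
    overnight), and additionally on any day listed in ``config.recall_days``.
    """
    from .recall import evaluate_recall

    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    pattern_set = build_training_set(
        config.n_days,
        rng,
        percepts_per_day=config.percepts_per_day,
        patterns_per_percept=config.patterns_per_percept,
        validation_days=config.validation_days,
    )
    system = ThreeStageSystem(pattern_set, config.stage_params, dt=config.dt_ms)
    phases = config.phases
    if config.modulation is not None:
        system.modulation = config.modulation
    if config.lesion is not None and config.lesion.timing == "before":
        lesion_rng = np.random.default_rng([seed, 7, config.lesion.seed])
        apply_lesion(system, config.lesion, lesion_rng)

    sleep_length = config.sleep_length()
    all_events: list[ReinstatementEvent] = []
    recall_frames: list[pd.DataFrame] = []
    for day in range(1, config.n_days + 1):
        day_pats = pattern_set.day_patterns(day)
        if day == config.n_days and config.pre_sleep_pfc_eval:
            # evaluate PFC before its overnight wipe, after the day's blocks
            all_events.extend(
                _run_day_until_sleep(
                    system,
                    day_pats,
                    phases,
                    config.percepts_per_day,
                    config.patterns_per_percept,
                    config.replay_threshold,
                    config.record_replay,
                )
            )
            recall_frames.append(
                evaluate_recall(
                    system, pattern_set, stages=("pfc",), eval_day=day, tag="pre_sleep"
                )
            )
            all_events.extend(
                _run_sleep(
                    system,
                    phases,
                    sleep_length,
                    config.replay_threshold,
                    config.record_replay,
                )
            )
        else:
            all_events.extend(
                run_day(
                    system,
                    day_pats,
                    phases,
                    sleep_length=sleep_length,
                    replay_threshold=config.replay_threshold,
                    record_replay=config.record_replay,
                )
            )
        if day in config.recall_days:
            ids = config.recall_days[day]
            ids = None if ids in ("all", "training") else list(ids)
            recall_frames.append(
                evaluate_recall(
                    system, pattern_set, pattern_ids=ids, eval_day=day, tag=f"day{day}"
                )
            )

    if config.lesion is not None and config.lesion.timing == "after":
        lesion_rng = np.random.default_rng([seed, 7, config.lesion.seed])
        apply_lesion(system, config.lesion, lesion_rng)
    recall_frames.append(
        evaluate_recall(system, pattern_set, eval_day=config.n_days, tag="final")
    )
    recall = pd.concat(recall_frames, ignore_index=True)
    recall.insert(0, "seed", seed)
    events = events_to_frame(all_events)
    refl_steps = config.n_days * config.percepts_per_day * phases["reflection"].length_steps
    return SimulationResult(
        seed=seed,
        config=config,
        system=system,
        pattern_set=pattern_set,
        recall=recall,
        events=events,
        reflection_steps=refl_steps,
        sleep_steps=config.n_days * sleep_length,
    )


def _run_day_until_sleep(
    system,
    day_pats,
    phases,
    percepts_per_day,
    patterns_per_percept,
    replay_threshold,
    record_replay,
):
    """The perception+reflection blocks of one day (no sleep)."""
    n = patterns_per_percept
    events: list[ReinstatementEvent] = []
    for block in range(percepts_per_day):
        percept = day_pats[block * n : (block + 1) * n]
        system.current_percept = percept[0].percept
        if (
            system.modulation is not None
            and system.modulation_onset_ms is None
            and percept[0].percept == system.modulation.onset_percept
        ):
            system.modulation_onset_ms = system.t_ms
        run_phase(system, phases["perception"], stimuli=percept)
        system.n_presented += n
        t0 = system.t_ms
        logs = run_phase(
            system,
            phases["reflection"],
            collect=("hip",) if record_replay else (),
        )
        if record_replay:
            events.extend(
                detect_reinstatements(
                    logs["hip"],
                    system.patterns.stage_matrix("hip", upto=system.n_presented),
                    threshold=replay_threshold,
                    dt=system.dt,
                    stage="hip",
                    phase="reflection",
                    t0_ms=t0,
                )
            )
    return events


def _run_sleep(system, phases, sleep_length, replay_threshold, record_replay):
    system.current_percept = None
    sleep = phases["sleep"]
    if sleep_length is not None and sleep_length != sleep.length_steps:
        sleep = PhaseConfig(**{**sleep.__dict__, "length_steps": sleep_length})
    t0 = system.t_ms
    logs = run_phase(system, sleep, collect=("ctx",) if record_replay else ())
    if not record_replay:
        return []
    return detect_reinstatements(
        logs["ctx"],
        system.patterns.stage_matrix("ctx", upto=system.n_presented),
        threshold=replay_threshold,
        dt=system.dt,
        stage="ctx",
        phase="sleep",
        t0_ms=t0,
    )


def run_batch(
    config: RunConfig | None = None,
    n_runs: int = 20,
    master_seed: int = 0,
) -> list[SimulationResult]:
    """Repeated runs with independent per-run seeds spawned from a master seed.

    The i-th run's seed depends only on ``master_seed`` and i, so experiment
    and control batches sharing a master seed see identical patterns and
    differ only in the manipulated factor (paired comparisons).
    """
    seeds = batch_seeds(master_seed, n_runs)
    return [run_simulation(config, seed=s) for s in seeds]


def batch_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds (below 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_runs, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]
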