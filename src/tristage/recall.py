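"""Cued recall: distance metric, convergence protocol, curves and gradients.

Recall is tested with plasticity fully frozen.  Cueing clamps the neocortical
input to a pattern's CTX encoding for one step, which seeds the PFC and HIP
cues through the fixed forward maps; the clamp is then released and each
network relaxes independently under its auto-associative projection.  The
recall distance between the cue state a (at clamp release) and the converged
state b is

    d(a, b) = (1 - a.b / (|a| |b|)) / 2

i.e. half of one minus the cosine similarity: 0 for perfect recall, 0.5 for
orthogonal states, 1 for antipodal ones.  A pattern counts as recalled when
d falls below the stage's decision threshold Theta; the thresholds are
optimized by minimizing summed type I + type II errors against unstudied
patterns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bcpnn import Population, Projection, normalize_kwta, normalize_softmax
from .patterns import Pattern, PatternSet

__all__ = [
    "recall_distance",
    "cue_and_converge",
    "evaluate_recall",
    "optimize_threshold",
    "combined_recall",
    "consolidation_curves",
    "amnesia_gradient",
]

STAGES = ("pfc", "hip", "ctx")


def recall_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Half of one minus the cosine similarity of the two activity vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("recall distance is undefined for a zero vector")
    cos = min(1.0, max(-1.0, float(a @ b / (na * nb))))  # clip rounding spill
    return 0.5 * (1.0 - cos)


def _relax(
    pop: Population,
    auto: Projection,
    cue: np.ndarray,
    g_L: float = 1.0,
    max_steps: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Free relaxation under the auto-associative projection from a cue state.

    Returns the converged activity and a convergence flag (activity change
    below ``tol`` in the max norm within ``max_steps``, else the last state).
    """
    act = np.asarray(cue, dtype=float).copy()
    if not np.any(act):
        return act, False  # fully lesioned stage: no dynamics
    for _ in range(max_steps):
        support = g_L * auto.support_term(act, active=_active_or_none(pop, act))
        if pop.layout.modular:
            new = normalize_softmax(support, pop.layout)
        else:
            new = normalize_kwta(support, pop.k, alive=pop.alive)
        if np.max(np.abs(new - act)) < tol:
            return new, True
        act = new
    return act, False


def _active_or_none(pop: Population, act: np.ndarray) -> np.ndarray | None:
    if pop.layout.modular:
        return None
    return np.flatnonzero(act)


def cue_and_converge(
    system,
    pattern: Pattern,
    stages: tuple[str, ...] = STAGES,
    max_steps: int = 50,
    tol: float = 1e-6,
) -> dict[str, dict]:
    """Cue the system with a pattern and let each stage converge independently.

    The CTX cue is the pattern's encoding itself; the PFC and HIP cues are its
    images under the fixed forward maps (the idealized one-step clamp), which
    for an intact system equal the stored PFC/HIP encodings.  Plasticity is
    frozen throughout: the system state is not modified.

    Returns per stage: cue, converged state b, distance d(a, b), convergence
    flag.  A stage whose cue or converged state is silent (fully lesioned)
    gets the maximal distance 1.0.
    """
    ctx_cue = pattern.ctx.astype(float)
    cues = {
        "ctx": ctx_cue,
        "pfc": ctx_cue[system.patterns.subset_map.ctx_units],
        "hip": _hip_cue(system, ctx_cue),
    }
    autos = {"pfc": system.pfc_auto, "hip": system.hip_auto, "ctx": system.ctx_auto}
    out: dict[str, dict] = {}
    for s in stages:
        pop = system.stage(s)
        cue = cues[s]
        b, converged = _relax(pop, autos[s], cue, max_steps=max_steps, tol=tol)
        if not np.any(cue) or not np.any(b):
            d = 1.0
            converged = False
        else:
            d = recall_distance(cue, b)
        out[s] = {"cue": cue, "converged": b, "distance": d, "converged_flag": converged}
    return out


def _hip_cue(system, ctx_cue: np.ndarray) -> np.ndarray:
    """HIP cue through the (possibly lesioned) separator: kWTA of the drive."""
    if system.hip.k == 0:
        return np.zeros(system.hip.n_units)
    drive = system.ctx2hip.support_term(ctx_cue)
    return normalize_kwta(drive, system.hip.k, alive=system.hip.alive)


def evaluate_recall(
    system,
    pattern_set: PatternSet,
    pattern_ids: list[int] | None = None,
    stages: tuple[str, ...] = STAGES,
    thresholds: dict[str, float] | None = None,
    eval_day: int | None = None,
    tag: str = "final",
    max_steps: int = 50,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Cued-recall table over patterns: one row per (pattern, stage).

    ``age_days`` is the age of the pattern at test time: patterns of the last
    training day are 1 day old at the post-sleep test and the unstudied
    validation patterns are 0 days old.
    """
    if thresholds is None:
        thresholds = {s: system.stage(s).params.theta for s in stages}
    if pattern_ids is None:
        patterns = pattern_set.patterns
    else:
        patterns = [pattern_set.by_id(i) for i in pattern_ids]
    eval_day = pattern_set.n_days if eval_day is None else eval_day
    rows = []
    system.flush_all()
    for pat in patterns:
        res = cue_and_converge(system, pat, stages=stages, max_steps=max_steps, tol=tol)
        for s in stages:
            d = res[s]["distance"]
            rows.append(
                {
                    "eval": tag,
                    "eval_day": eval_day,
                    "pattern_id": pat.id,
                    "day": pat.day,
                    "percept": pat.percept,
                    "age_days": eval_day + 1 - pat.day,
                    "studied": pat.id <= pattern_set.n_training,
                    "stage": s,
                    "distance": d,
                    "success": bool(d < thresholds[s]),
                    "converged": res[s]["converged_flag"],
                }
            )
    return pd.DataFrame(rows)


def optimize_threshold(
    distances_studied: np.ndarray, distances_unstudied: np.ndarray
) -> tuple[float, float]:
    """Decision boundary minimizing the summed type I and type II error rates.

    Scans the midpoints of the pooled sorted distances (plus the two outer
    boundaries); a studied pattern with d >= Theta is a miss (type II), an
    unstudied one with d < Theta a false positive (type I).  The summed error
    is alpha + beta, i.e. the error *rates*, so the optimum is insensitive to
    the strong class imbalance between studied and unstudied patterns.  Ties
    go to the smallest Theta.  Returns (Theta, alpha + beta at Theta).
    """
    s = np.asarray(distances_studied, dtype=float)
    u = np.asarray(distances_unstudied, dtype=float)
    if s.size == 0 or u.size == 0:
        raise ValueError("both distance lists must be non-empty")
    pooled = np.sort(np.concatenate((s, u)))
    candidates = np.concatenate(
        ([0.0], (pooled[1:] + pooled[:-1]) / 2.0, [np.nextafter(pooled[-1], 2.0)])
    )
    best_theta, best_err = 0.0, 1.0  # theta=0: all studied missed
    for theta in candidates:
        err = (
            np.count_nonzero(s >= theta) / s.size
            + np.count_nonzero(u < theta) / u.size
        )
        if err < best_err - 1e-12 or (
            abs(err - best_err) <= 1e-12 and theta < best_theta
        ):
            best_theta, best_err = float(theta), float(err)
    return best_theta, best_err


def combined_recall(success_by_stage: dict[str, bool]) -> bool:
    """Behavioral recall: success iff any stage recalls the pattern.

    Where a memory lives makes no behavioral difference; a lesioned (silent)
    stage simply never succeeds.
    """
    return any(bool(v) for v in success_by_stage.values())


def consolidation_curves(
    recall: pd.DataFrame,
    include_combined: bool = True,
    pfc_tag: str | None = "pre_sleep",
) -> pd.DataFrame:
    """Recall rate against pattern age in days, per stage and combined.

    Averages the per-pattern successes of patterns introduced on the same day
    (over every run present in the table).  The combined curve takes the
    disjunction over stages per pattern; because PFC forgets during sleep,
    its contribution uses the pre-sleep PFC evaluation when one is present
    (``pfc_tag``), matching a recall test of the running system.
    """
    df = recall.copy()
    if "seed" not in df.columns:
        df["seed"] = 0
    final = df[df["eval"] == "final"]
    pre = df[(df["eval"] == pfc_tag) & (df["stage"] == "pfc")] if pfc_tag else df[:0]
    per_stage = final
    if len(pre):
        # age at the pre-sleep test equals the final-test age (same day)
        per_stage = pd.concat(
            [final[final["stage"] != "pfc"], pre.assign(eval="final")],
            ignore_index=True,
        )
    curves = (
        per_stage.groupby(["stage", "age_days"])["success"]
        .agg(rate="mean", n="size")
        .reset_index()
    )
    if include_combined:
        wide = (
            per_stage.pivot_table(
                index=["seed", "pattern_id", "age_days"],
                columns="stage",
                values="success",
                aggfunc="first",
            )
            .fillna(False)
            .astype(bool)
        )
        comb = wide.any(axis=1).rename("success").reset_index()
        comb_curve = (
            comb.groupby("age_days")["success"].agg(rate="mean", n="size").reset_index()
        )
        comb_curve.insert(0, "stage", "combined")
        curves = pd.concat([curves, comb_curve], ignore_index=True)
    return curves


def amnesia_gradient(
    lesioned_curves: pd.DataFrame, control_curves: pd.DataFrame
) -> pd.DataFrame:
    """Per-age recall-loss ratio (control - lesioned) / control.

    Zero where the control rate is zero.  Curves are matched on stage and
    pattern age.
    """
    merged = control_curves.merge(
        lesioned_curves,
        on=["stage", "age_days"],
        suffixes=("_control", "_lesioned"),
    )
    c = merged["rate_control"].to_numpy()
    l = merged["rate_lesioned"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        loss = np.where(c > 0, (c - l) / c, 0.0)
    out = merged[["stage", "age_days", "rate_control", "rate_lesioned"]].copy()
    out["loss_ratio"] = loss
    return out
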