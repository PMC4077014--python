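"""Detection and statistics of reinstatement (replay) events in activity logs.

A pattern counts as reinstated while the stage's activity overlaps one
particular training pattern by at least 90% (cosine overlap of the graded
activity against the binary encoding).  Contiguous supra-threshold steps for
the same pattern form one event; when several patterns exceed the threshold
simultaneously the one with the larger overlap wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReinstatementEvent", "detect_reinstatements", "replay_statistics", "events_to_frame"]

DEFAULT_THRESHOLD = 0.9


@dataclass(frozen=True)
class ReinstatementEvent:
    """One detected reinstatement of a stored pattern."""

    stage: str
    pattern_id: int
    phase: str
    start_ms: float
    length_ms: float


def detect_reinstatements(
    activity_log: np.ndarray,
    patterns: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    dt: float = 10.0,
    stage: str = "",
    phase: str = "",
    t0_ms: float = 0.0,
    pattern_ids: np.ndarray | None = None,
) -> list[ReinstatementEvent]:
    """Find reinstatement events in a per-step activity log.

    Parameters
    ----------
    activity_log:
        (n_steps, n_units) activities of one stage.
    patterns:
        (n_patterns, n_units) binary encodings of the candidate patterns
        (typically the training patterns presented so far).
    pattern_ids:
        Ids reported for the rows of ``patterns`` (default 1..n).
    """
    log = np.asarray(activity_log, dtype=float)
    pats = np.asarray(patterns, dtype=float)
    if log.ndim != 2 or pats.ndim != 2 or log.shape[1] != pats.shape[1]:
        raise ValueError("activity log and patterns must agree on the unit axis")
    if pattern_ids is None:
        pattern_ids = np.arange(1, pats.shape[0] + 1)
    if pats.shape[0] == 0 or log.shape[0] == 0:
        return []
    act_norm = np.linalg.norm(log, axis=1)
    pat_norm = np.linalg.norm(pats, axis=1)
    denom = np.multiply.outer(act_norm, pat_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        ov = np.where(denom > 0, (log @ pats.T) / denom, 0.0)
    best = np.argmax(ov, axis=1)  # ties -> lowest row index
    best_ov = ov[np.arange(log.shape[0]), best]
    active = best_ov >= threshold
    events: list[ReinstatementEvent] = []
    run_start: int | None = None
    run_pat = -1
    for t in range(log.shape[0] + 1):
        here = t < log.shape[0] and active[t]
        pat = best[t] if here else -1
        if run_start is not None and (not here or pat != run_pat):
            events.append(
                ReinstatementEvent(
                    stage=stage,
                    pattern_id=int(pattern_ids[run_pat]),
                    phase=phase,
                    start_ms=t0_ms + run_start * dt,
                    length_ms=(t - run_start) * dt,
                )
            )
            run_start = None
        if here and run_start is None:
            run_start = t
            run_pat = pat
    return events


def events_to_frame(events: list[ReinstatementEvent]) -> pd.DataFrame:
    cols = ["stage", "pattern_id", "phase", "start_ms", "length_ms"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in events])[cols]


def replay_statistics(
    events: list[ReinstatementEvent] | pd.DataFrame,
    total_duration_ms: float,
    dt: float = 10.0,
) -> dict:
    """Event frequency (model-time Hz), length summary and length histogram."""
    if total_duration_ms <= 0:
        raise ValueError("total duration must be positive")
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    lengths = df["length_ms"].to_numpy(dtype=float)
    n = len(lengths)
    if n:
        edges = np.arange(dt / 2, lengths.max() + 1.5 * dt, dt)
        hist, _ = np.histogram(lengths, bins=edges)
    else:
        edges = np.array([dt / 2, 1.5 * dt])
        hist = np.zeros(1, dtype=int)
    return {
        "n_events": n,
        "frequency_hz": n / (total_duration_ms / 1000.0),
        "mean_length_ms": float(lengths.mean()) if n else float("nan"),
        "median_length_ms": float(np.median(lengths)) if n else float("nan"),
        "length_histogram": hist,
        "length_bin_edges_ms": edges,
    }
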