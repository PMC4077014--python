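"""Stimulus encodings for the three stages and the pattern-separation transform.

Each stimulus has three coordinated binary encodings:

* CTX: one active unit per ten-unit hypercolumn (50 hypercolumns, 10% activity),
  drawn uniformly at random - the neocortical input pattern.
* PFC: the restriction of the CTX pattern to five designated hypercolumns,
  mapped unit-for-unit onto the five PFC hypercolumns (a fixed 1-to-1 subset
  map; 10% activity).
* HIP: a sparsified, pattern-separated encoding - the k = 13 hippocampal units
  (5% of 250) receiving the largest summed drive from the active CTX units
  through a fixed random connection matrix.  Small changes of the cortical
  input therefore produce disproportionately large changes of the hippocampal
  code, emulating dentate-gyrus pattern separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pattern",
    "SeparatorMatrix",
    "SubsetMap",
    "PatternSet",
    "generate_ctx_pattern",
    "perturb_ctx_pattern",
    "derive_pfc_pattern",
    "derive_hip_pattern",
    "overlap",
    "build_training_set",
]

# stage geometry (network sizes 50 / 250 / 500)
CTX_HYPERCOLUMNS = 50
PFC_HYPERCOLUMNS = 5
HYPERCOLUMN_SIZE = 10
CTX_UNITS = CTX_HYPERCOLUMNS * HYPERCOLUMN_SIZE
PFC_UNITS = PFC_HYPERCOLUMNS * HYPERCOLUMN_SIZE
HIP_UNITS = 250
HIP_K = 13  # 5% of 250, rounded


@dataclass(frozen=True)
class Pattern:
    """One stimulus with its three coordinated binary encodings."""

    id: int
    day: int
    percept: int
    ctx: np.ndarray
    pfc: np.ndarray
    hip: np.ndarray

    def encoding(self, stage: str) -> np.ndarray:
        return getattr(self, stage.lower())


@dataclass(frozen=True)
class SeparatorMatrix:
    """Fixed random CTX -> HIP connection matrix, constant for a whole run."""

    weights: np.ndarray
    seed: int | None = None

    @classmethod
    def draw(cls, rng: np.random.Generator, seed: int | None = None) -> "SeparatorMatrix":
        w = rng.uniform(0.0, 1.0, size=(CTX_UNITS, HIP_UNITS))
        return cls(weights=w, seed=seed)


@dataclass(frozen=True)
class SubsetMap:
    """1-to-1 map from five designated CTX hypercolumns onto the PFC hypercolumns.

    ``ctx_hypercolumns[p]`` is the CTX hypercolumn feeding PFC hypercolumn p;
    units map index-for-index.  The default picks evenly spaced hypercolumns
    0, 10, 20, 30, 40 - any fixed choice is statistically equivalent since
    CTX hypercolumn winners are i.i.d.
    """

    ctx_hypercolumns: tuple[int, ...] = (0, 10, 20, 30, 40)

    def __post_init__(self) -> None:
        if len(set(self.ctx_hypercolumns)) != len(self.ctx_hypercolumns):
            raise ValueError("subset map must be injective")
        if len(self.ctx_hypercolumns) != PFC_HYPERCOLUMNS:
            raise ValueError(f"need {PFC_HYPERCOLUMNS} CTX hypercolumns")
        if any(not 0 <= h < CTX_HYPERCOLUMNS for h in self.ctx_hypercolumns):
            raise ValueError("CTX hypercolumn index out of range")

    @property
    def ctx_units(self) -> np.ndarray:
        """The CTX unit indices feeding PFC units 0..49, in PFC order."""
        idx = []
        for h in self.ctx_hypercolumns:
            idx.extend(range(h * HYPERCOLUMN_SIZE, (h + 1) * HYPERCOLUMN_SIZE))
        return np.asarray(idx)

    def matrix(self) -> np.ndarray:
        """Dense 0/1 CTX x PFC weight matrix of the map."""
        w = np.zeros((CTX_UNITS, PFC_UNITS))
        w[self.ctx_units, np.arange(PFC_UNITS)] = 1.0
        return w


def generate_ctx_pattern(rng: np.random.Generator) -> np.ndarray:
    """Random neocortical input: one active unit per ten-unit hypercolumn."""
    out = np.zeros(CTX_UNITS, dtype=np.uint8)
    winners = rng.integers(0, HYPERCOLUMN_SIZE, size=CTX_HYPERCOLUMNS)
    out[np.arange(CTX_HYPERCOLUMNS) * HYPERCOLUMN_SIZE + winners] = 1
    return out


def perturb_ctx_pattern(
    ctx: np.ndarray, n_hypercolumns: int, rng: np.random.Generator
) -> np.ndarray:
    """Redraw the winner in ``n_hypercolumns`` random hypercolumns.

    The new winner is drawn among the other nine units, so every perturbed
    hypercolumn really changes (perturbing one of fifty hypercolumns is
    exactly a 2% pattern change).
    """
    out = ctx.copy()
    cols = rng.choice(CTX_HYPERCOLUMNS, size=n_hypercolumns, replace=False)
    for h in cols:
        sl = slice(h * HYPERCOLUMN_SIZE, (h + 1) * HYPERCOLUMN_SIZE)
        old = int(np.argmax(out[sl]))
        new = int(rng.integers(0, HYPERCOLUMN_SIZE - 1))
        if new >= old:
            new += 1
        out[sl] = 0
        out[h * HYPERCOLUMN_SIZE + new] = 1
    return out


def derive_pfc_pattern(ctx: np.ndarray, subset_map: SubsetMap) -> np.ndarray:
    """PFC encoding: the CTX activity restricted to the mapped units."""
    return ctx[subset_map.ctx_units].astype(np.uint8)


def derive_hip_pattern(
    ctx: np.ndarray, sep: SeparatorMatrix, k: int = HIP_K
) -> np.ndarray:
    """HIP encoding: the k units with the largest summed separator drive.

    Ties are broken toward the lowest unit index (they have probability zero
    under the continuous weight distribution but the rule keeps the transform
    deterministic).
    """
    active = np.flatnonzero(ctx)
    drive = sep.weights[active].sum(axis=0)
    winners = np.argsort(-drive, kind="stable")[:k]
    out = np.zeros(sep.weights.shape[1], dtype=np.uint8)
    out[winners] = 1
    return out


def overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized activity overlap: the cosine of the two vectors.

    For equal-sparsity binary patterns this equals |a & b| / |a|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("overlap is undefined for a zero vector")
    return min(1.0, max(-1.0, float(a @ b / (na * nb))))  # clip rounding spill


@dataclass
class PatternSet:
    """The full training + validation pattern inventory of one simulation run.

    Patterns are numbered from 1 and grouped into percepts of
    ``patterns_per_percept`` consecutive patterns, ``percepts_per_day``
    percepts per day.  One extra unstudied day is generated after the training
    days for false-positive validation of the recall thresholds.
    """

    patterns: list[Pattern]
    subset_map: SubsetMap
    separator: SeparatorMatrix
    n_days: int
    percepts_per_day: int = 3
    patterns_per_percept: int = 3

    def __post_init__(self) -> None:
        self._ctx = np.stack([p.ctx for p in self.patterns]).astype(float)
        self._pfc = np.stack([p.pfc for p in self.patterns]).astype(float)
        self._hip = np.stack([p.hip for p in self.patterns]).astype(float)

    @property
    def per_day(self) -> int:
        return self.percepts_per_day * self.patterns_per_percept

    @property
    def n_training(self) -> int:
        return self.n_days * self.per_day

    @property
    def training(self) -> list[Pattern]:
        return self.patterns[: self.n_training]

    @property
    def validation(self) -> list[Pattern]:
        return self.patterns[self.n_training :]

    def by_id(self, pattern_id: int) -> Pattern:
        return self.patterns[pattern_id - 1]

    def day_patterns(self, day: int) -> list[Pattern]:
        """The patterns shown on one day (days numbered from 1)."""
        lo = (day - 1) * self.per_day
        return self.patterns[lo : lo + self.per_day]

    def percept_patterns(self, percept: int) -> list[Pattern]:
        """The patterns of one percept (percepts numbered from 1)."""
        lo = (percept - 1) * self.patterns_per_percept
        return self.patterns[lo : lo + self.patterns_per_percept]

    def stage_matrix(self, stage: str, upto: int | None = None) -> np.ndarray:
        """Dense (n_patterns x n_units) float encoding matrix for one stage."""
        m = {"pfc": self._pfc, "hip": self._hip, "ctx": self._ctx}[stage.lower()]
        return m[:upto] if upto is not None else m


def build_training_set(
    n_days: int,
    rng: np.random.Generator,
    percepts_per_day: int = 3,
    patterns_per_percept: int = 3,
    subset_map: SubsetMap | None = None,
    separator: SeparatorMatrix | None = None,
    validation_days: int = 1,
) -> PatternSet:
    """Generate the sequentially numbered patterns of a multi-day schedule.

    ``n_days = 39`` gives training patterns 1-351 (percept 89 = patterns
    265-267) plus one unstudied validation day (patterns 352-360).
    """
    subset_map = subset_map or SubsetMap()
    separator = separator or SeparatorMatrix.draw(rng)
    per_day = percepts_per_day * patterns_per_percept
    patterns: list[Pattern] = []
    for i in range((n_days + validation_days) * per_day):
        ctx = generate_ctx_pattern(rng)
        patterns.append(
            Pattern(
                id=i + 1,
                day=i // per_day + 1,
                percept=i // patterns_per_percept + 1,
                ctx=ctx,
                pfc=derive_pfc_pattern(ctx, subset_map),
                hip=derive_hip_pattern(ctx, separator),
            )
        )
    return PatternSet(
        patterns=patterns,
        subset_map=subset_map,
        separator=separator,
        n_days=n_days,
        percepts_per_day=percepts_per_day,
        patterns_per_percept=patterns_per_percept,
    )
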