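"""Core BCPNN machinery: populations, projections, and the Hebbian-Bayesian rule.

A Bayesian Confidence Propagation Neural Network (BCPNN) stores memories in
log-odds weights derived from exponentially smoothed estimates of unit
activation rates (``Lambda_i``) and co-activation rates (``Lambda_ij``).  The
support of a post-synaptic unit j driven by a projection is

    bias_j + sum_k log( sum_{i in H(k)} w_ij * pi_i )

with one log term per pre-synaptic hypercolumn (a single log-sum over all pre
units when the pre population is non-modular), ``bias_j = log Lambda_j`` and

    w_ij = ((1 - l0^2) Lambda_ij + l0^2)
           / (((1 - l0) Lambda_i + l0) * ((1 - l0) Lambda_j + l0))

where ``l0`` is the background activity rate regularizing the estimates.
Weights are therefore strictly positive and bounded, and forgetting is
graceful: old traces decay multiplicatively toward the uniform prior
(palimpsest memory).  Cellular adaptation / synaptic depression is modeled as
a second projection of exactly the same form with a fast time constant and a
negative gain; it destabilizes attractors and produces autonomous replay.

Rate estimates follow ``tau dLambda/dt = pi - Lambda`` and are integrated with
the exact exponential step ``Lambda += (1 - exp(-dt/tau)) (pi - Lambda)``,
which is stable for every ``tau > 0`` including learning time constants
shorter than the 10 ms simulation step.  ``tau = inf`` is the frozen
(plasticity off) sentinel and skips the update entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import expm1, isinf

import numpy as np

from .layout import HypercolumnLayout

__all__ = [
    "INF",
    "PopulationParams",
    "TraceState",
    "Population",
    "Projection",
    "FixedProjection",
    "normalize_softmax",
    "normalize_kwta",
    "update_traces",
    "compute_bias",
    "compute_weights",
    "compute_support",
    "step_population",
]

INF = float("inf")

#: floor inside log() terms; only reached for structurally zero drive
#: (e.g. hypercolumns without afferents through a fixed 1-to-1 map), where it
#: acts as a very negative but finite support.
_LOG_FLOOR = 1e-12


def _alpha(dt: float, tau: float, rate_multiplier: float = 1.0) -> float:
    """Per-step relaxation fraction 1 - exp(-m*dt/tau); 0 when frozen."""
    if tau is None or isinf(tau):
        return 0.0
    if tau <= 0:
        raise ValueError(f"time constant must be positive or inf, got {tau}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -expm1(-rate_multiplier * dt / tau)


@dataclass
class PopulationParams:
    """Stage-level parameters (defaults follow the cortical-stage column)."""

    tau_L: float = 18500.0  #: associative learning time constant [model ms]
    tau_A: float = INF  #: adaptation time constant [model ms]; inf = no adaptation
    g_L: float = 1.0  #: associative gain
    g_A: float = 0.0  #: adaptation gain (negative when active)
    tau_C: float = 1.0  #: membrane time constant [model ms]
    lambda_0: float = 0.025  #: background activity rate
    activity_level: float = 0.1  #: target sparsity A
    theta: float = 0.383  #: recall detection threshold on the distance d

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_0 < 1.0:
            raise ValueError("lambda_0 must lie in (0, 1)")
        for name in ("tau_L", "tau_A", "tau_C"):
            v = getattr(self, name)
            if not (v > 0):  # inf passes
                raise ValueError(f"{name} must be strictly positive or inf")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_softmax(support: np.ndarray, layout: HypercolumnLayout) -> np.ndarray:
    """Soft-WTA: exponentiate and normalize within each hypercolumn.

    Computed with a per-hypercolumn max shift for numerical stability; the
    result sums to exactly one within each hypercolumn.
    """
    if not layout.modular:
        raise ValueError("softmax normalization requires a modular layout")
    support = np.asarray(support, dtype=float)
    m = layout.uniform_size
    if m is not None:
        shaped = support.reshape(layout.n_hypercolumns, m)
        shifted = shaped - shaped.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return (e / e.sum(axis=1, keepdims=True)).reshape(-1)
    out = np.empty_like(support)
    for sl in layout.slices():
        e = np.exp(support[sl] - support[sl].max())
        out[sl] = e / e.sum()
    return out


def normalize_kwta(
    support: np.ndarray,
    k: int,
    floor: float = 0.0,
    alive: np.ndarray | None = None,
) -> np.ndarray:
    """k-winner-take-all: the k highest-support units get activity 1.

    Losers get ``floor`` (default 0).  Ties are broken toward the lowest unit
    index for determinism.  Units excluded by ``alive`` never win.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    support = np.asarray(support, dtype=float)
    if k > support.size:
        raise ValueError("k exceeds the number of units")
    if alive is not None:
        support = np.where(alive, support, -np.inf)
        k = min(k, int(np.count_nonzero(alive)))
    out = np.full(support.size, floor, dtype=float)
    if k == 0:
        return out
    # stable sort on the negated support -> lowest index wins ties
    winners = np.argsort(-support, kind="stable")[:k]
    out[winners] = 1.0
    return out


# ---------------------------------------------------------------------------
# traces and the learning rule
# ---------------------------------------------------------------------------


@dataclass
class TraceState:
    """Running-average rate estimates of a projection.

    ``pre_rates``/``post_rates`` estimate unit activation probabilities and
    ``pair_rates`` the pre x post co-activation probabilities.  For an
    auto-associative projection the two rate vectors are the same array.
    Unit rates are floored at ``lambda_0 * prior`` to keep logs finite; pair
    rates at the product of the two unit floors.
    """

    pre_rates: np.ndarray
    post_rates: np.ndarray
    pair_rates: np.ndarray
    pre_floor: float = 0.0
    post_floor: float = 0.0

    @property
    def unit_rates(self) -> np.ndarray:
        """Post-side unit rates (equal to pre-side for auto-association)."""
        return self.post_rates

    @property
    def pair_floor(self) -> float:
        return self.pre_floor * self.post_floor

    @property
    def auto(self) -> bool:
        return self.pre_rates is self.post_rates

    def apply_floor(self) -> None:
        np.maximum(self.pre_rates, self.pre_floor, out=self.pre_rates)
        if not self.auto:
            np.maximum(self.post_rates, self.post_floor, out=self.post_rates)
        np.maximum(self.pair_rates, self.pair_floor, out=self.pair_rates)

    def copy(self) -> "TraceState":
        pre = self.pre_rates.copy()
        post = pre if self.auto else self.post_rates.copy()
        return TraceState(
            pre, post, self.pair_rates.copy(), self.pre_floor, self.post_floor
        )

    @classmethod
    def uniform(
        cls,
        pre_prior: np.ndarray,
        post_prior: np.ndarray | None,
        lambda_0: float,
    ) -> "TraceState":
        """Uninformative initialization: unit rates at the uniform prior and
        pair rates at their product (zero initial log-weights)."""
        pre = np.asarray(pre_prior, dtype=float).copy()
        auto = post_prior is None
        post = pre if auto else np.asarray(post_prior, dtype=float).copy()
        pair = np.multiply.outer(pre, post)
        return cls(
            pre,
            post,
            pair,
            pre_floor=lambda_0 * float(pre.min()),
            post_floor=lambda_0 * float(post.min()),
        )


def update_traces(
    traces: TraceState,
    pre_activity: np.ndarray,
    post_activity: np.ndarray,
    tau: float,
    dt: float,
    rate_multiplier: float = 1.0,
) -> TraceState:
    """One exponential-smoothing step of the rate estimates.

    ``rate_multiplier`` scales the plasticity rate 1/tau (used by transient
    plasticity modulation).  A frozen ``tau`` (inf) leaves the traces
    unchanged.  Updates in place and returns ``traces``.
    """
    a = _alpha(dt, tau, rate_multiplier)
    if a == 0.0:
        return traces
    traces.pre_rates += a * (pre_activity - traces.pre_rates)
    if not traces.auto:
        traces.post_rates += a * (post_activity - traces.post_rates)
    traces.pair_rates += a * (
        np.multiply.outer(pre_activity, post_activity) - traces.pair_rates
    )
    traces.apply_floor()
    return traces


def compute_bias(traces: TraceState) -> np.ndarray:
    """Bias of the post units: log of each unit's own rate estimate."""
    rates = traces.post_rates
    if np.any(rates <= 0):
        raise ValueError("unit rates must be strictly positive (floored upstream)")
    return np.log(rates)


def compute_weights(traces: TraceState, lambda_0: float) -> np.ndarray:
    """Hebbian-Bayesian weights from the rate estimates (strictly positive)."""
    if not 0.0 < lambda_0 < 1.0:
        raise ValueError("lambda_0 must lie in (0, 1)")
    l2 = lambda_0 * lambda_0
    num = (1.0 - l2) * traces.pair_rates + l2
    f_pre = (1.0 - lambda_0) * traces.pre_rates + lambda_0
    f_post = (1.0 - lambda_0) * traces.post_rates + lambda_0
    return num / np.multiply.outer(f_pre, f_post)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


class Population:
    """One network stage: layout, supports, activities and an alive mask."""

    def __init__(
        self,
        layout: HypercolumnLayout,
        params: PopulationParams | None = None,
        k: int | None = None,
        name: str = "",
    ) -> None:
        self.layout = layout
        self.params = params or PopulationParams()
        self.name = name
        if not layout.modular:
            if k is None:
                raise ValueError("kWTA populations need k")
            if not 0 < k <= layout.n_units:
                raise ValueError("k must lie in [1, n_units]")
        self.k = k
        self.alive = np.ones(layout.n_units, dtype=bool)
        self.support = np.zeros(layout.n_units)
        self.activity = self.unit_prior()

    @property
    def n_units(self) -> int:
        return self.layout.n_units

    def unit_prior(self) -> np.ndarray:
        """Per-unit uniform activation prior: 1/M_k (modular) or A = k/N (kWTA)."""
        if self.layout.modular:
            return self.layout.uniform_activity()
        return np.full(self.n_units, self.k / self.n_units)

    def normalize(self, support: np.ndarray) -> np.ndarray:
        if self.layout.modular:
            return normalize_softmax(support, self.layout)
        if self.k == 0 or not self.alive.any():
            return np.zeros(self.n_units)  # fully lesioned stage stays silent
        return normalize_kwta(support, self.k, alive=self.alive)

    def lesion(self, dead: np.ndarray, sparsity: float | None = None) -> None:
        """Permanently disable the given units (kWTA populations only).

        The kWTA k is rescaled to keep the target sparsity among survivors.
        """
        self.alive[dead] = False
        if not np.asarray(dead).size:
            return
        self.activity[~self.alive] = 0.0
        if not self.layout.modular:
            a = sparsity if sparsity is not None else self.params.activity_level
            # round half up: 5% of 250 units is k = 13
            self.k = int(np.floor(a * int(np.count_nonzero(self.alive)) + 0.5))


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


class Projection:
    """A plastic (or frozen) BCPNN projection between two populations.

    Trace updates are buffered: :meth:`observe` records one step's activities
    and :meth:`flush` folds the whole buffer into the rate estimates in one
    matrix product (the exponential smoothing is a linear recursion, so a
    phase worth of steps collapses exactly into pre' C post with per-step
    coefficients).  Weights and bias are pure functions of the traces and are
    computed lazily on access, so a projection that learns during a phase but
    does not drive anything costs one GEMM per phase instead of an outer
    product and a weight recomputation per step.
    """

    def __init__(
        self,
        pre: Population,
        post: Population,
        tau: float,
        gain: float = 0.0,
        lambda_0: float | None = None,
        exclude: str | None = None,
        name: str = "",
    ) -> None:
        self.pre = pre
        self.post = post
        self.tau = float(tau)
        self.gain = float(gain)
        self.lambda_0 = (
            post.params.lambda_0 if lambda_0 is None else float(lambda_0)
        )
        self.name = name
        auto = pre is post
        if exclude not in (None, "diagonal", "hypercolumn"):
            raise ValueError("exclude must be None, 'diagonal' or 'hypercolumn'")
        if exclude is not None and not auto:
            raise ValueError("weight exclusion applies to auto-associative projections")
        #: non-modular pre populations: treat every unit as a singleton
        #: hypercolumn, i.e. sum log-weights over the active (binary) pre units
        self.unit_evidence = not pre.layout.modular
        self._exclusion: np.ndarray | None = None
        if exclude == "diagonal":
            self._exclusion = ~np.eye(pre.n_units, dtype=bool)
        elif exclude == "hypercolumn":
            mem = pre.layout.membership
            self._exclusion = mem[:, None] != mem[None, :]
        self.traces = TraceState.uniform(
            pre.unit_prior(), None if auto else post.unit_prior(), self.lambda_0
        )
        self._buf_pre: list[np.ndarray] = []
        self._buf_post: list[np.ndarray] = []
        self._buf_alpha: list[float] = []
        self._w: np.ndarray | None = None
        self._w_grouped: np.ndarray | None = None
        self._bias: np.ndarray | None = None
        self.pre_mask: np.ndarray | None = None
        self.post_mask: np.ndarray | None = None

    # -- plasticity -------------------------------------------------------

    @property
    def plastic(self) -> bool:
        return not isinf(self.tau)

    def observe(
        self,
        pre_activity: np.ndarray,
        post_activity: np.ndarray,
        dt: float,
        rate_multiplier: float = 1.0,
    ) -> None:
        """Record one step of activity for the (possibly deferred) trace update."""
        a = _alpha(dt, self.tau, rate_multiplier)
        if a == 0.0:
            return
        self._buf_pre.append(np.array(pre_activity, dtype=float, copy=True))
        self._buf_post.append(np.array(post_activity, dtype=float, copy=True))
        self._buf_alpha.append(a)

    def flush(self) -> None:
        """Apply all buffered trace updates exactly (order preserved)."""
        if not self._buf_alpha:
            return
        alphas = np.asarray(self._buf_alpha)
        decays = 1.0 - alphas
        # coeff_t = alpha_t * prod_{s>t} (1 - alpha_s); total decay D = prod(1-alpha)
        suffix = np.concatenate((np.cumprod(decays[::-1])[-2::-1], [1.0]))
        coeff = alphas * suffix
        total_decay = float(np.prod(decays))
        a_pre = np.stack(self._buf_pre)
        a_post = np.stack(self._buf_post)
        tr = self.traces
        tr.pre_rates *= total_decay
        tr.pre_rates += a_pre.T @ coeff
        if not tr.auto:
            tr.post_rates *= total_decay
            tr.post_rates += a_post.T @ coeff
        tr.pair_rates *= total_decay
        tr.pair_rates += a_pre.T @ (coeff[:, None] * a_post)
        tr.apply_floor()
        self._buf_pre.clear()
        self._buf_post.clear()
        self._buf_alpha.clear()
        self._invalidate()

    def _invalidate(self) -> None:
        self._w = None
        self._w_grouped = None
        self._bias = None

    # -- read-out ---------------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        self.flush()
        if self._w is None:
            w = compute_weights(self.traces, self.lambda_0)
            if self._exclusion is not None:
                w *= self._exclusion
            if self.pre_mask is not None:
                w[~self.pre_mask, :] = 0.0
            if self.post_mask is not None:
                w[:, ~self.post_mask] = 0.0
            self._w = w
        return self._w

    @property
    def bias(self) -> np.ndarray:
        self.flush()
        if self._bias is None:
            self._bias = compute_bias(self.traces)
        return self._bias

    def support_term(
        self,
        pre_activity: np.ndarray | None = None,
        active: np.ndarray | None = None,
    ) -> np.ndarray:
        """bias + per-pre-hypercolumn log-sums of w * activity (gain not applied).

        ``active`` may give the indices of the (binary) active pre units; for a
        non-modular pre population with pending trace updates this path
        computes only the needed weight rows and avoids materializing the full
        matrix.
        """
        if pre_activity is None:
            pre_activity = self.pre.activity
        layout = self.pre.layout
        if not layout.modular:
            if active is None:
                active = np.flatnonzero(pre_activity)
            if len(active) == 0:
                # a silent pre population provides no evidence: flat drive
                return np.zeros(self.post.n_units)
            if self._w is None and self._buf_alpha:
                self.flush()
            rows = (
                self._w[active] if self._w is not None else self._lazy_rows(active)
            )
            if self.unit_evidence:
                # singleton pre hypercolumns: one log term per active pre unit
                drive = np.log(np.maximum(rows, _LOG_FLOOR)).T @ pre_activity[active]
                return self.bias + drive
            drive = rows.T @ pre_activity[active]
            return self.bias + np.log(np.maximum(drive, _LOG_FLOOR))
        w = self.weights
        if layout.modular:
            if self._w_grouped is None:
                m = layout.uniform_size
                if m is not None:
                    self._w_grouped = w.reshape(
                        layout.n_hypercolumns, m, self.post.n_units
                    )
            if self._w_grouped is not None:
                act = pre_activity.reshape(layout.n_hypercolumns, -1)
                drive = np.einsum("hmj,hm->hj", self._w_grouped, act)
            else:
                drive = layout.group_sum(w * pre_activity[:, None])
            return self.bias + np.log(np.maximum(drive, _LOG_FLOOR)).sum(axis=0)
        drive = w.T @ pre_activity
        return self.bias + np.log(np.maximum(drive, _LOG_FLOOR))

    def _lazy_rows(self, rows: np.ndarray) -> np.ndarray:
        """Weight rows for the given pre units, straight from the traces."""
        tr = self.traces
        l0 = self.lambda_0
        l2 = l0 * l0
        num = (1.0 - l2) * tr.pair_rates[rows, :] + l2
        f_pre = (1.0 - l0) * tr.pre_rates[rows] + l0
        f_post = (1.0 - l0) * tr.post_rates + l0
        w = num / (f_pre[:, None] * f_post[None, :])
        if self._exclusion is not None:
            w *= self._exclusion[rows, :]
        if self.post_mask is not None:
            w[:, ~self.post_mask] = 0.0
        return w

    # -- lesioning --------------------------------------------------------

    def nullify_units(self, pre_dead: np.ndarray | None, post_dead: np.ndarray | None) -> None:
        """Zero every connection touching the given dead units."""
        if pre_dead is not None and pre_dead.size:
            if self.pre_mask is None:
                self.pre_mask = np.ones(self.pre.n_units, dtype=bool)
            self.pre_mask[pre_dead] = False
        if post_dead is not None and post_dead.size:
            if self.post_mask is None:
                self.post_mask = np.ones(self.post.n_units, dtype=bool)
            self.post_mask[post_dead] = False
        self._invalidate()


class FixedProjection:
    """A non-plastic projection with a constant weight matrix.

    Used for the 1-to-1 cortical subset maps and the random pattern-separation
    matrix.  For a modular post population the contribution enters the support
    in log form like any other drive; for a kWTA post population the summed
    linear drive is used directly (the kWTA ranking is what matters, and the
    pattern separator is defined on the linear drive).
    """

    gain: float

    def __init__(
        self, pre: Population, post: Population, weights: np.ndarray, gain: float = 0.0
    ) -> None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (pre.n_units, post.n_units):
            raise ValueError("weight matrix shape mismatch")
        if np.any(weights < 0):
            raise ValueError("fixed weights must be non-negative")
        self.pre = pre
        self.post = post
        self.W = weights
        self.gain = float(gain)

    plastic = False
    tau = INF

    def observe(self, *args, **kwargs) -> None:  # noqa: D401 - uniform interface
        """Fixed projections never learn."""

    def flush(self) -> None:
        pass

    def support_term(
        self,
        pre_activity: np.ndarray | None = None,
        active: np.ndarray | None = None,
    ) -> np.ndarray:
        if pre_activity is None:
            pre_activity = self.pre.activity
        if active is not None:
            drive = self.W[active].T @ pre_activity[active]
        else:
            drive = self.W.T @ pre_activity
        if self.post.layout.modular:
            return np.log(np.maximum(drive, _LOG_FLOOR))
        return drive

    def nullify_units(self, pre_dead: np.ndarray | None, post_dead: np.ndarray | None) -> None:
        if pre_dead is not None and pre_dead.size:
            self.W[pre_dead, :] = 0.0
        if post_dead is not None and post_dead.size:
            self.W[:, post_dead] = 0.0


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def compute_support(
    post: Population,
    projections: list,
    dt: float = 10.0,
) -> np.ndarray:
    """Target-and-relax support update for one population.

    The target is the gain-weighted sum of every projection's support term;
    the support relaxes toward it with the membrane time constant tau_C.
    With tau_C = 1 ms << dt = 10 ms this is effectively instantaneous.
    """
    target = np.zeros(post.n_units)
    for p in projections:
        if p.post is not post:
            raise ValueError("all projections must share the same post population")
        if p.gain != 0.0:
            target += p.gain * p.support_term()
    a = _alpha(dt, post.params.tau_C)
    return post.support + a * (target - post.support)


def step_population(
    post: Population,
    projections: list,
    clamp: np.ndarray | None = None,
    dt: float = 10.0,
    rate_multiplier: float = 1.0,
) -> Population:
    """One 10 ms update of a population and its plastic afferents.

    Order: support from the previous activities, normalization (soft-WTA or
    kWTA), optional clamp override, then one trace-update step for every
    plastic projection (bias and weights follow lazily from the traces).
    """
    post.support = compute_support(post, projections, dt)
    activity = post.normalize(post.support)
    if clamp is not None:
        if len(clamp) != post.n_units:
            raise ValueError("clamp length mismatch")
        activity = np.asarray(clamp, dtype=float).copy()
    post.activity = activity
    for p in projections:
        if p.plastic:
            p.observe(p.pre.activity, post.activity, dt, rate_multiplier)
    return post
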