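"""Adaptive-threshold IF neurons (trainable quantizers).

Two trainable variants of the soft-reset IF neuron:

* **ATIF-u** — a single trainable threshold ``V_th`` shared over time; the
  neuron remains a *uniform* quantizer whose range adapts to the input
  distribution.
* **ATIF-nu** — ``T`` trainable breakpoints ``p_1 >= ... >= p_T > 0``
  that induce a *time-varying* threshold schedule ``V_th(t)`` and hence a
  non-uniform quantizer.  ``p_1`` is the clipping point; a constant input
  equal to ``p_j`` makes the neuron spike at timesteps ``j..T`` and
  nowhere else, so the quantizer's output steps sit exactly at the
  breakpoints.

Schedule construction (from the spike-pattern conditions):

    V_th(1) = p_1
    V_th(j) = T * (p_j - p_{j+1})     for 1 < j < T
    V_th(T) = T * p_T

Training uses the surrogate-gradient method: the forward pass keeps the
hard Heaviside spike, while the backward pass substitutes the unit
sigmoid derivative sigma'(q) with q = H(t) - V_th(t) everywhere the
Heaviside derivative appears (including through the soft reset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .neuron_core import FIRE_RTOL, SpikeTrain, simulate_constant


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakpointVector:
    """Ordered breakpoints ``p_1 >= ... >= p_T > 0`` of the non-uniform
    quantizer (``p_1`` is the clipping point)."""

    p: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.p, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("breakpoints must form a non-empty 1-D vector")
        if not (arr[-1] > 0):
            raise InvalidParameterError(f"p_T must be > 0, got {arr[-1]}")
        if np.any(np.diff(arr) > 0):
            raise InvalidParameterError(
                "breakpoints must be in descending order (p_1 >= ... >= p_T)"
            )
        object.__setattr__(self, "p", arr)

    @property
    def T(self) -> int:
        return int(self.p.size)


@dataclass(frozen=True)
class ThresholdSchedule:
    """Per-timestep firing thresholds ``V_th(t)``.

    ``origin`` records the breakpoint vector the schedule was derived
    from; it is ``None`` for uniform (constant-threshold) schedules.
    """

    V: np.ndarray
    origin: Optional[BreakpointVector] = None

    def __post_init__(self):
        arr = np.asarray(self.V, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("schedule must be a non-empty 1-D vector")
        if not (arr > 0).all():
            raise InvalidParameterError("all schedule thresholds must be > 0")
        object.__setattr__(self, "V", arr)

    @property
    def T(self) -> int:
        return int(self.V.size)

    @property
    def is_uniform(self) -> bool:
        return bool(np.all(self.V == self.V[0]))

    @classmethod
    def uniform(cls, V_th: float, T: int) -> "ThresholdSchedule":
        if not V_th > 0:
            raise InvalidParameterError(f"V_th must be > 0, got {V_th}")
        return cls(V=np.full(int(T), float(V_th)))


@dataclass(frozen=True)
class SurrogateConfig:
    """Surrogate family used in the backward pass only (forward stays a
    hard Heaviside).  ``alpha`` is the sigmoid sharpness (see
    :func:`surrogate_derivative`)."""

    kind: str = "sigmoid"
    alpha: float = 1.0

    def __post_init__(self):
        if self.kind != "sigmoid":
            raise InvalidParameterError(f"unsupported surrogate: {self.kind}")
        if not self.alpha > 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class QuantizerGradient:
    """Gradient of a loss w.r.t. a trainable threshold, with the
    pre-activation ``q = H(t) - V_th(t)`` it was evaluated at."""

    d_loss_d_threshold: float
    q: float


# ---------------------------------------------------------------------------
# Breakpoints -> threshold schedule
# ---------------------------------------------------------------------------


def threshold_schedule_from_breakpoints(p) -> ThresholdSchedule:
    """Build the time-varying threshold schedule from breakpoints.

    Raises
    ------
    InvalidParameterError
        naming the violated inequality if the breakpoints are not
        strictly descending and positive (which would give a
        non-positive threshold somewhere in the schedule).
    """
    if not isinstance(p, BreakpointVector):
        p = BreakpointVector(p=np.asarray(p, dtype=float))
    arr, T = p.p, p.T
    if T == 1:
        # single timestep: one spike iff i >= p_1, so V_th(1) = p_1
        return ThresholdSchedule(V=np.array([arr[0]]), origin=p)
    V = np.empty(T)
    V[0] = arr[0]
    V[1:-1] = T * (arr[1:-1] - arr[2:])
    V[-1] = T * arr[-1]
    for j in range(1, T - 1):
        if not V[j] > 0:
            raise InvalidParameterError(
                f"p_{j + 1} > p_{j + 2} violated: V_th({j + 1}) = "
                f"T*(p_{j + 1} - p_{j + 2}) = {V[j]} <= 0"
            )
    return ThresholdSchedule(V=V, origin=p)


def schedule_jacobian(T: int) -> np.ndarray:
    """Jacobian ``J[t, j] = dV_th(t+1) / dp_{j+1}`` of the construction.

    ``dV(1)/dp_1 = 1``; for interior ``j``, ``dV(j)/dp_j = T`` and
    ``dV(j)/dp_{j+1} = -T``; ``dV(T)/dp_T = T``.
    """
    J = np.zeros((T, T))
    J[0, 0] = 1.0
    for t in range(1, T - 1):
        J[t, t] = T
        J[t, t + 1] = -T
    if T > 1:
        J[T - 1, T - 1] = T
    return J


@dataclass(frozen=True)
class BreakpointDiagnostics:
    """Per-condition feasibility report for a breakpoint vector."""

    conditions: List[Tuple[str, bool, str]]

    @property
    def all_ok(self) -> bool:
        return all(ok for _, ok, _ in self.conditions)

    def failures(self) -> List[str]:
        return [name for name, ok, _ in self.conditions if not ok]


def validate_breakpoints(p, T: Optional[int] = None) -> BreakpointDiagnostics:
    """Check the feasibility inequalities of the spike-pattern system.

    A vector is *valid* when a constant input ``p_j`` produces the exact
    pattern ``0^(j-1) 1^(T-j+1)``.  Writing ``S(j, t) = sum_{s=j}^{t}
    V_th(s)``, the conditions are, for every breakpoint ``j``:

    * no premature firing:  ``t * p_j <= V_th(t)`` for ``t < j``;
    * first / sustained firing:  ``t * p_j >= S(j, t)`` for ``j <= t <= T``
      (``t = j`` is the "first line" condition ``j * p_j >= V_th(j)`` of
      the pattern system; ``t = T`` holds with equality by construction).

    Both families are checked with the firing tolerance.  Exactly *on* a
    cell boundary (``t * p_j == V_th(t)``, e.g. the equally-spaced
    configuration that reduces to the uniform neuron) the fire-on-equality
    rule shifts spikes earlier, so the canonical timing pattern
    ``0^(j-1) 1^(T-j+1)`` degenerates — but the spike *count* and the
    decoded amplitude are unchanged; boundary equality therefore counts
    as a pass.  Strictly interior vectors produce the exact pattern.

    This is a diagnostic operation: it never raises, it reports each
    condition with pass/fail.
    """
    arr = np.asarray(p.p if isinstance(p, BreakpointVector) else p, dtype=float)
    n = arr.size
    if T is not None and int(T) != n:
        return BreakpointDiagnostics(
            conditions=[("length", False, f"expected T={T} breakpoints, got {n}")]
        )
    conds: List[Tuple[str, bool, str]] = []
    conds.append(
        ("positivity", bool(np.all(arr > 0)), f"min(p) = {arr.min()}")
    )
    strictly_desc = bool(np.all(np.diff(arr) < 0)) if n > 1 else True
    conds.append(("descending", strictly_desc, "p_1 > p_2 > ... > p_T required"))
    if not (conds[0][1] and conds[1][1]):
        return BreakpointDiagnostics(conditions=conds)

    V = _schedule_values_unchecked(arr)
    csum = np.concatenate(([0.0], np.cumsum(V)))  # csum[t] = sum of V[:t]

    for j in range(1, n + 1):
        pj = arr[j - 1]
        for t in range(1, j):
            ok = t * pj <= V[t - 1] + FIRE_RTOL * max(1.0, V[t - 1])
            conds.append(
                (
                    f"no_premature_fire[j={j},t={t}]",
                    bool(ok),
                    f"{t}*p_{j} = {t * pj:.6g} <= V_th({t}) = {V[t - 1]:.6g}",
                )
            )
        for t in range(j, n + 1):
            lhs, rhs = t * pj, csum[t] - csum[j - 1]
            ok = lhs >= rhs - FIRE_RTOL * max(1.0, abs(rhs))
            name = "first_fire" if t == j else "sustained_fire"
            conds.append(
                (
                    f"{name}[j={j},t={t}]",
                    bool(ok),
                    f"{t}*p_{j} = {lhs:.6g} >= sum V_th({j}..{t}) = {rhs:.6g}",
                )
            )
    return BreakpointDiagnostics(conditions=conds)


def _schedule_values_unchecked(arr: np.ndarray) -> np.ndarray:
    T = arr.size
    if T == 1:
        return arr[:1].copy()
    V = np.empty(T)
    V[0] = arr[0]
    V[1:-1] = T * (arr[1:-1] - arr[2:])
    V[-1] = T * arr[-1]
    return V


# ---------------------------------------------------------------------------
# Forward / decode
# ---------------------------------------------------------------------------


def atif_forward(i: float, schedule: ThresholdSchedule) -> SpikeTrain:
    """Run the soft-reset dynamics with per-timestep thresholds."""
    spikes = simulate_constant(np.asarray(float(i)), schedule.V)
    return SpikeTrain(values=spikes)


def decode_amplitude(train, schedule: ThresholdSchedule) -> float:
    """Amplitude estimate of a spike train under a threshold schedule.

    Spikes are binary and carry no amplitude, so the decoded estimate is
    the firing rate scaled by the quantizer's full-scale (clipping)
    value, which is the first-timestep threshold ``V_th(1)``:

        y_hat = V_th(1) * count / T

    For a uniform neuron ``V_th(1) = V_th`` and this is the classic
    ``count * V_th / T`` staircase saturating exactly at ``V_th``; for a
    breakpoint-derived schedule ``V_th(1) = p_1``, the clipping point.
    The same rule for every neuron variant keeps the reconstruction
    levels uniform while the trainable breakpoints shape the *cell
    boundaries* — this is what makes the non-uniform neuron's extra SQNR
    measurable with a decoder the downstream network could implement
    (rate decoding times a learned scale).
    """
    values = train.values if isinstance(train, SpikeTrain) else np.asarray(train)
    if values.shape[-1] != schedule.T:
        raise InvalidInputError(
            f"train length {values.shape[-1]} != schedule length {schedule.T}"
        )
    return float(schedule.V[0] * values.sum(-1) / schedule.T)


# ---------------------------------------------------------------------------
# Surrogate gradients
# ---------------------------------------------------------------------------


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def surrogate_derivative(q, alpha: float = 1.0):
    """Sigmoid surrogate of the Heaviside derivative.

    For the unit sigmoid (``alpha = 1``) this is sigma'(q) =
    sigma(q)(1 - sigma(q)), maximal (0.25) at q = 0.  ``alpha`` sharpens
    the surrogate to ``alpha * sigma'(alpha q)`` (unit mass preserved);
    it should match the scale of the membrane fluctuations — e.g.
    ``alpha ~ 1/sigma`` for inputs of standard deviation sigma —
    otherwise the threshold gradient loses localization.
    """
    s = sigmoid(alpha * np.asarray(q, dtype=float))
    return alpha * s * (1.0 - s)


def threshold_gradient(upstream, q, alpha: float = 1.0):
    """Single-event threshold gradient: dL/dV_th = -dL/dz * sigma'(q).

    Contributions from a threshold shared across timesteps (or across a
    layer) are summed by the caller, following reverse-mode semantics.
    """
    return -np.asarray(upstream, dtype=float) * surrogate_derivative(q, alpha)


def forward_traces(currents, thresholds, relaxed: bool = False,
                   alpha: float = 1.0):
    """Soft-reset forward pass recording per-timestep traces.

    Parameters
    ----------
    currents : array (...,)
        Constant per-timestep input current per sample.
    thresholds : array (T,)
    relaxed:
        If True, emit *soft* spikes ``z = sigma(q)`` instead of the hard
        Heaviside.  The relaxed forward is differentiable and serves as
        the finite-difference oracle for the backward pass; training
        always uses the hard forward.

    Returns
    -------
    z, q : arrays of shape ``currents.shape + (T,)``
    """
    currents = np.asarray(currents, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    T = thresholds.size
    V = np.zeros_like(currents)
    z = np.empty(currents.shape + (T,))
    q = np.empty(currents.shape + (T,))
    for t in range(T):
        H = V + currents
        qt = H - thresholds[t]
        zt = sigmoid(alpha * qt) if relaxed else (
            qt >= -FIRE_RTOL * abs(thresholds[t])
        ).astype(float)
        V = H - thresholds[t] * zt
        z[..., t] = zt
        q[..., t] = qt
    return z, q


def backward_through_time(z, q, thresholds, gz_ext, gV_final=None,
                          alpha: float = 1.0):
    """Reverse-mode pass through the unrolled soft-reset dynamics.

    Given forward traces ``z`` and ``q`` (shape ``(..., T)``), per-timestep
    thresholds (shape ``(T,)``) and external gradients ``gz_ext`` w.r.t.
    the spikes, propagate backwards substituting ``sigma'(q)`` for the
    Heaviside derivative everywhere (spike decision *and* soft reset).

    Returns
    -------
    g_current : array (...,)
        Gradient w.r.t. the constant input current (summed over time).
    g_thresholds : array ``(..., T)``
        Per-timestep, per-sample threshold gradients from the dynamics
        (the decode's explicit threshold dependence is the caller's).
    """
    z = np.asarray(z, dtype=float)
    q = np.asarray(q, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    gz_ext = np.asarray(gz_ext, dtype=float)
    T = thresholds.size
    sd = surrogate_derivative(q, alpha)
    g_current = np.zeros(z.shape[:-1])
    g_thr = np.zeros_like(z)
    gV = np.zeros(z.shape[:-1]) if gV_final is None else np.asarray(gV_final, float)
    for t in range(T - 1, -1, -1):
        gz_total = gz_ext[..., t] - gV * thresholds[t]
        gH = gz_total * sd[..., t] + gV
        g_thr[..., t] = -gz_total * sd[..., t] - gV * z[..., t]
        g_current += gH
        gV = gH  # dH(t)/dV(t-1) = 1
    return g_current, g_thr


def breakpoint_gradients(upstream, q, p, z=None, relaxed: bool = False,
                         alpha: float = 1.0):
    """Chain per-timestep spike gradients back to the breakpoints.

    ``upstream`` are the external gradients dL/dz(t); ``q`` the recorded
    pre-activations.  The per-timestep threshold gradients (full
    reverse-mode through the soft reset) are composed with the Jacobian
    of the schedule construction.  With ``relaxed=True`` the spikes are
    taken as ``sigma(q)`` (matching the relaxed forward), which makes the
    result agree with central finite differences.
    """
    if not isinstance(p, BreakpointVector):
        p = BreakpointVector(p=np.asarray(p, dtype=float))
    upstream = np.asarray(upstream, dtype=float)
    q = np.asarray(q, dtype=float)
    if upstream.shape != q.shape or upstream.shape[-1] != p.T:
        raise InvalidInputError("upstream/q/p lengths must agree")
    schedule = threshold_schedule_from_breakpoints(p)
    if z is None:
        z = sigmoid(alpha * q) if relaxed else (
            q >= -FIRE_RTOL * np.abs(schedule.V)
        ).astype(float)
    _, g_thr = backward_through_time(z, q, schedule.V, upstream, alpha=alpha)
    g_thr = g_thr.reshape(-1, p.T).sum(axis=0)
    return schedule_jacobian(p.T).T @ g_thr


# ---------------------------------------------------------------------------
# Positivity/ordering-preserving reparameterization for training
# ---------------------------------------------------------------------------


def softplus(x):
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def softplus_inverse(y):
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def breakpoints_from_unconstrained(a) -> BreakpointVector:
    """Map free parameters ``a`` (length T) to valid descending breakpoints:
    ``p_T = softplus(a_T)`` and ``p_j = p_{j+1} + softplus(a_j)``.

    This guarantees strict ordering and positivity throughout gradient
    optimization (full pattern feasibility is not enforced; the forward
    dynamics remain well defined regardless).
    """
    a = np.asarray(a, dtype=float)
    d = softplus(a)
    p = np.cumsum(d[::-1])[::-1]
    return BreakpointVector(p=p)


def unconstrained_from_breakpoints(p) -> np.ndarray:
    arr = p.p if isinstance(p, BreakpointVector) else np.asarray(p, float)
    d = np.empty_like(arr)
    d[-1] = arr[-1]
    d[:-1] = arr[:-1] - arr[1:]
    if not (d > 0).all():
        raise InvalidParameterError("breakpoints must be strictly descending > 0")
    return softplus_inverse(d)


def unconstrained_gradient(a, g_p) -> np.ndarray:
    """Chain dL/dp through the cumulative softplus map: since p_j depends
    on increments d_m for m >= j, dL/da_m = sigma(a_m) * sum_{j<=m} dL/dp_j."""
    a = np.asarray(a, dtype=float)
    g_p = np.asarray(g_p, dtype=float)
    return sigmoid(a) * np.cumsum(g_p)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def schedule_to_json(schedule: ThresholdSchedule, model_kind: str = "atif-nu") -> str:
    payload = {
        "T": schedule.T,
        "p": None if schedule.origin is None else schedule.origin.p.tolist(),
        "V": schedule.V.tolist(),
        "model_kind": model_kind,
    }
    return json.dumps(payload, indent=2)


def schedule_from_json(text: str) -> ThresholdSchedule:
    payload = json.loads(text)
    origin = (
        None if payload.get("p") is None
        else BreakpointVector(p=np.asarray(payload["p"], dtype=float))
    )
    schedule = ThresholdSchedule(
        V=np.asarray(payload["V"], dtype=float), origin=origin
    )
    if schedule.T != int(payload["T"]):
        raise InvalidInputError("schedule length disagrees with stored T")
    return schedule


def save_schedule(schedule: ThresholdSchedule, path, model_kind: str = "atif-nu"):
    Path(path).write_text(schedule_to_json(schedule, model_kind))


def load_schedule(path) -> ThresholdSchedule:
    return schedule_from_json(Path(path).read_text())
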