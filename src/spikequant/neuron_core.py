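"""Integrate-and-fire neuron with soft reset: exact forward dynamics.

The IF neuron with soft reset is a uniform scalar quantizer: over ``T``
timesteps a constant input current ``i`` is integrated into the membrane
potential, a spike is emitted whenever the potential reaches the firing
threshold ``V_th``, and the threshold is *subtracted* (soft reset) instead
of zeroing the membrane.  Decoding the spike count as ``count / T``
therefore yields a staircase transfer function with exactly ``T + 1``
uniform levels, saturating at input ``V_th`` (for zero bias) and clamping
negative inputs to zero like a ReLU.

Per timestep ``t`` (membrane starts at ``V = 0``):

    H(t) = V(t-1) + i(t)            # integration
    z(t) = Θ(H(t) - V_th)           # spike if H reaches threshold
    V(t) = H(t) - V_th * z(t)       # soft reset

The closed form for the spike count under a constant current is

    count = min(T, floor(max(0, T * i) / V_th))

and the step-by-step simulation is the normative definition: the closed
form is validated against it, not the other way around.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

#: Relative tolerance on the threshold comparison.  Firing happens on
#: equality (H >= V_th), and the tolerance absorbs float accumulation so
#: that exact-rational crossings (e.g. i = V_th) fire at every timestep.
FIRE_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Binary spike sequence of length ``T``."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError("spike train must be a non-empty 1-D sequence")
        if not np.isin(arr, (0, 1)).all():
            raise InvalidInputError("spike train entries must be exactly 0 or 1")
        object.__setattr__(self, "values", arr.astype(np.int8))

    @property
    def T(self) -> int:
        return int(self.values.size)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def __iter__(self):
        return iter(self.values.tolist())

    def __len__(self):
        return self.T


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential after integration (``H``) and after reset (``V``)."""

    H: float = 0.0
    V: float = 0.0


@dataclass(frozen=True)
class UniformNeuronParams:
    """Constant-threshold IF neuron parameters.

    Parameters
    ----------
    V_th:
        Firing threshold (> 0).  Sets the saturation point of the
        quantizer and the step size ``V_th / T``.
    b:
        Bias current added to the membrane at *every* timestep, shifting
        the transfer curve horizontally by ``-b``.
    T:
        Number of timesteps per presentation (quantizer resolution).
    """

    V_th: float = 1.0
    b: float = 0.0
    T: int = 8

    def __post_init__(self):
        if not (self.V_th > 0):
            raise InvalidParameterError(f"V_th must be > 0, got {self.V_th}")
        if int(self.T) < 1:
            raise InvalidParameterError(f"T must be >= 1, got {self.T}")
        object.__setattr__(self, "T", int(self.T))


@dataclass(frozen=True)
class SynapticInput:
    """Weighted spike input plus bias: ``i(t) = z_prev(t) . W + b``."""

    weights: np.ndarray
    bias: float = 0.0
    source_spikes: Union[np.ndarray, None] = None

    def current(self, prev_spikes=None) -> float:
        spikes = self.source_spikes if prev_spikes is None else prev_spikes
        if spikes is None:
            raise InvalidInputError("no source spikes supplied")
        return synaptic_input(spikes, self.weights, self.bias)


@dataclass(frozen=True)
class RateCode:
    """Rate-decoded spike train: ``rate = count / T`` exactly."""

    count: int
    T: int

    @property
    def rate(self) -> float:
        return self.count / self.T

    @property
    def rate_exact(self) -> Fraction:
        return Fraction(self.count, self.T)


# ---------------------------------------------------------------------------
# Forward dynamics
# ---------------------------------------------------------------------------


def fire(H, threshold):
    """Spike decision ``H >= threshold`` with relative tolerance FIRE_RTOL."""
    return np.asarray(H) - threshold >= -FIRE_RTOL * abs(threshold)


def if_step(state: NeuronState, input_current: float, threshold: float):
    """One timestep of the soft-reset IF neuron.

    Returns ``(spike, next_state)`` where ``next_state.H`` is the membrane
    after integration and ``next_state.V`` the membrane after the
    (conditional) soft reset ``V = H - V_th * z``.
    """
    if not threshold > 0:
        raise InvalidParameterError(f"threshold must be > 0, got {threshold}")
    H = state.V + input_current
    z = int(bool(fire(H, threshold)))
    V = H - threshold * z
    return z, NeuronState(H=H, V=V)


def synaptic_input(prev_spikes, W, b: float = 0.0) -> float:
    """Input current from upstream spikes: weighted sum of active spikes
    plus a bias that is applied every timestep regardless of activity."""
    spikes = np.asarray(prev_spikes, dtype=float)
    weights = np.asarray(W, dtype=float)
    if spikes.shape != weights.shape:
        raise InvalidInputError(
            f"spike/weight shape mismatch: {spikes.shape} vs {weights.shape}"
        )
    return float(spikes @ weights + b)


def simulate_constant(currents, thresholds):
    """Vectorized soft-reset IF simulation under constant input currents.

    Parameters
    ----------
    currents:
        Array of shape ``(...,)`` — effective per-timestep input current
        (bias already included) for each independent neuron/sample.
    thresholds:
        Per-timestep thresholds, shape ``(T,)`` (constant vector for the
        uniform neuron, time-varying for the non-uniform one).

    Returns
    -------
    spikes : int8 array of shape ``currents.shape + (T,)``.
    """
    currents = np.asarray(currents, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    T = thresholds.size
    V = np.zeros_like(currents)
    out = np.empty(currents.shape + (T,), dtype=np.int8)
    for t in range(T):
        H = V + currents
        z = fire(H, thresholds[t])
        V = H - thresholds[t] * z
        out[..., t] = z
    return out


def run_constant_input(i: float, params) -> SpikeTrain:
    """Present the constant current ``i`` for ``T`` timesteps from ``V = 0``.

    ``params`` is either :class:`UniformNeuronParams` (the per-timestep
    current is ``i + b``) or any object with a per-timestep threshold
    vector attribute ``V`` (e.g. ``atif.ThresholdSchedule``).
    """
    if hasattr(params, "V_th"):
        thresholds = np.full(params.T, float(params.V_th))
        eff = i + params.b
    elif hasattr(params, "V"):
        thresholds = np.asarray(params.V, dtype=float)
        if not (thresholds > 0).all():
            raise InvalidParameterError("all schedule thresholds must be > 0")
        eff = i
    else:
        raise InvalidParameterError(f"unsupported parameter object: {params!r}")
    spikes = simulate_constant(np.asarray(float(eff)), thresholds)
    return SpikeTrain(values=spikes)


def closed_form_spike_count(total_input: float, T: int, V_th: float) -> int:
    """Closed-form spike count of the uniform quantizer.

    ``total_input`` is the integral of the input current over the ``T``
    timesteps (i.e. ``T * (i + b)`` for a constant current).  Returns
    ``min(T, floor(max(0, total_input) / V_th))``; the floor and the clamp
    at zero mirror the step simulation, which is the ground truth.
    """
    if not V_th > 0:
        raise InvalidParameterError(f"V_th must be > 0, got {V_th}")
    if int(T) < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    total = max(0.0, float(total_input))
    # + FIRE_RTOL mirrors fire-on-equality under float accumulation
    return int(min(int(T), np.floor(total / V_th + FIRE_RTOL)))


def decode_rate(train: SpikeTrain) -> RateCode:
    """Rate decoding: spike count over window length (``count / T``)."""
    if not isinstance(train, SpikeTrain):
        train = SpikeTrain(values=np.asarray(train))
    return RateCode(count=train.count, T=train.T)


# ---------------------------------------------------------------------------
# Transfer curves
# ---------------------------------------------------------------------------


def transfer_curve(params: UniformNeuronParams, input_grid) -> pd.DataFrame:
    """Quantization transfer curve: decoded output rate vs. input current.

    Returns a DataFrame with columns ``input``, ``rate`` and ``count``.
    The curve is a nondecreasing staircase with at most ``T + 1`` distinct
    levels (exactly ``T + 1`` over a grid spanning the full range).
    """
    grid = np.asarray(input_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise InvalidInputError("input_grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) < 0):
        raise InvalidInputError("input_grid must be sorted ascending")
    thresholds = np.full(params.T, params.V_th)
    spikes = simulate_constant(grid + params.b, thresholds)
    counts = spikes.sum(axis=-1).astype(int)
    return pd.DataFrame(
        {"input": grid, "rate": counts / params.T, "count": counts}
    )


def distinct_levels(curve: pd.DataFrame) -> int:
    """Number of distinct output levels of a transfer curve.

    Counts unique integer spike counts (exact rationals ``k/T``), never
    floating-point rate values.
    """
    return int(np.unique(curve["count"].to_numpy()).size)


def export_transfer_curve(curve: pd.DataFrame, path, params: UniformNeuronParams):
    """Write the curve as CSV plus a JSON sidecar echoing the parameters."""
    path = Path(path)
    curve.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"V_th": params.V_th, "b": params.b, "T": params.T,
             "n_points": int(len(curve))},
            indent=2,
        )
    )
    return sidecar
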