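"""Quantization-noise lab: SQNR measurement and single-neuron training.

The soft-reset IF neuron implements a rectifying scalar quantizer: the
analog value it must represent is the ReLU activation x = max(0, i), and
its decoded output y_hat is the quantized reconstruction of x.  The
signal-to-quantization-noise ratio

    SQNR = 10 * log10( E[x^2] / E[(x - y_hat)^2] )

is estimated with sample means over a zero-mean Gaussian input current
i ~ N(0, sigma^2).  Negative currents stay in both expectations; they
contribute zero error because the ReLU reference and the neuron both
output 0 there.

The optimization protocol trains the neuron's threshold parameters
(scalar V_th for ATIF-u, T breakpoints for ATIF-nu) to minimize the mean
squared reconstruction error E[(x - y_hat)^2] with Adam (lr 1e-3) from
V_th = 1, using sigmoid surrogate gradients through the unrolled
dynamics.  SQNR is logged on a fixed held-out batch; a fixed-threshold
neuron run records a flat trace for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import atif
from .errors import (
    DivergenceError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedSignalError,
)

MODEL_KINDS = ("fixed-if", "atif-u", "atif-nu")


def normalize_model_kind(kind: str) -> str:
    k = str(kind).strip().lower().replace("_", "-")
    if k not in MODEL_KINDS:
        raise InvalidParameterError(
            f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}"
        )
    return k


# ---------------------------------------------------------------------------
# Sources and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianSource:
    """I.i.d. zero-mean Gaussian input currents, i ~ N(0, sigma^2)."""

    sigma: float = 0.1
    n: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if int(self.n) < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def sample(self, size: Optional[int] = None, rng=None) -> np.ndarray:
        rng = self.rng() if rng is None else rng
        return rng.normal(0.0, self.sigma, self.n if size is None else size)

    def eval_batch(self, size: int) -> np.ndarray:
        """Held-out evaluation batch on a dedicated stream (independent of
        the training draws for the same seed)."""
        return self.rng(stream=1).normal(0.0, self.sigma, size)


@dataclass(frozen=True)
class SQNRResult:
    sqnr_db: float
    signal_power: float
    noise_power: float


def sqnr(x, x_hat) -> SQNRResult:
    """Signal-to-quantization-noise ratio in dB, with sample-mean powers.

    Zero noise is reported as ``+inf``, never as an error; an
    identically-zero reference signal is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise InvalidInputError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if x.size < 1:
        raise InvalidInputError("empty input")
    signal = float(np.mean(x**2))
    if signal == 0.0:
        raise UndefinedSignalError("SQNR undefined for an all-zero signal")
    noise = float(np.mean((x - x_hat) ** 2))
    db = np.inf if noise == 0.0 else 10.0 * np.log10(signal / noise)
    return SQNRResult(sqnr_db=float(db), signal_power=signal, noise_power=noise)


@dataclass(frozen=True)
class ErrorDecomposition:
    """Quantization MSE split at the saturation point: granular error for
    x <= saturation (bounded), overload error for x > saturation
    (unbounded in the input)."""

    granular_mse: float
    overload_mse: float

    @property
    def total_mse(self) -> float:
        return self.granular_mse + self.overload_mse


def error_decomposition(x, x_hat, saturation: float) -> ErrorDecomposition:
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise InvalidInputError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    sq = (x - x_hat) ** 2
    below = x <= saturation
    n = x.size
    return ErrorDecomposition(
        granular_mse=float(sq[below].sum() / n),
        overload_mse=float(sq[~below].sum() / n),
    )


# ---------------------------------------------------------------------------
# Neuron evaluation
# ---------------------------------------------------------------------------


def encode_decode(currents, thresholds):
    """Hard forward + amplitude decode for a batch of constant currents.

    The decoded estimate is the firing rate scaled by the quantizer's
    clipping point, the first-timestep threshold:

        y_hat = V_th(1) * count / T

    which for a uniform neuron is the classic ``count * V_th / T``
    (see :func:`spikequant.atif.decode_amplitude`).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    z, _ = atif.forward_traces(currents, thresholds, relaxed=False)
    return thresholds[0] * z.sum(axis=-1) / thresholds.size


def evaluate_sqnr(currents, thresholds) -> SQNRResult:
    """SQNR of a (possibly time-varying-threshold) neuron on a batch of
    input currents, against the ReLU reference x = max(0, i)."""
    x = np.maximum(np.asarray(currents, dtype=float), 0.0)
    return sqnr(x, encode_decode(currents, thresholds))


# ---------------------------------------------------------------------------
# Optimization protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizerConfig:
    """Gradient-based training settings for the single-neuron protocol.

    Defaults: Adam, lr 1e-3, batches of 256 for 10_000 iterations, SQNR
    and loss logged every 100 iterations on a fixed held-out batch of
    100_000 samples, converged values averaged over the final 10 logged
    points.
    """

    rule: str = "adam"
    lr: float = 1e-3
    iterations: int = 10_000
    batch_size: int = 256
    eval_every: int = 100
    eval_size: int = 100_000
    final_window: int = 10
    #: sigmoid surrogate sharpness; None selects the scale-matched value
    #: 1/sigma of the input source (see atif.surrogate_derivative)
    surrogate_alpha: Optional[float] = None
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.rule not in ("adam", "sgd"):
            raise InvalidParameterError(f"unknown optimizer rule {self.rule!r}")
        if not self.lr > 0:
            raise InvalidParameterError("lr must be > 0")


class _Adam:
    def __init__(self, n, cfg: OptimizerConfig):
        self.cfg = cfg
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params, grad):
        c = self.cfg
        if c.rule == "sgd":
            return params - c.lr * grad
        self.t += 1
        self.m = c.beta1 * self.m + (1 - c.beta1) * grad
        self.v = c.beta2 * self.v + (1 - c.beta2) * grad**2
        mhat = self.m / (1 - c.beta1**self.t)
        vhat = self.v / (1 - c.beta2**self.t)
        return params - c.lr * mhat / (np.sqrt(vhat) + c.eps)


@dataclass
class SQNRTrace:
    """Optimization trajectory logged at evaluation points."""

    model_kind: str
    T: int
    sigma: float
    seed: int
    iterations: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    sqnr_db: np.ndarray = field(default_factory=lambda: np.empty(0))
    loss: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: shape (k,) for scalar thresholds, (k, T) for breakpoints
    threshold_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    diverged: bool = False

    def final_sqnr(self, window: Optional[int] = None) -> float:
        w = len(self.sqnr_db) if window is None else min(window, len(self.sqnr_db))
        if w < 1:
            raise InvalidInputError("empty trace")
        return float(np.mean(self.sqnr_db[-w:]))

    def final_threshold(self, window: int = 10):
        w = min(window, len(self.threshold_values))
        return np.mean(self.threshold_values[-w:], axis=0)

    def to_frame(self):
        import pandas as pd

        data = {"iteration": self.iterations, "loss": self.loss,
                "sqnr_db": self.sqnr_db}
        tv = np.atleast_2d(np.asarray(self.threshold_values))
        if tv.shape[0] != len(self.iterations):
            tv = tv.T
        if tv.shape[1] == 1:
            data["threshold"] = tv[:, 0]
        else:
            for j in range(tv.shape[1]):
                data[f"p{j + 1}"] = tv[:, j]
        return pd.DataFrame(data)


def _loss_and_grads(i_batch, thresholds, alpha: float = 1.0):
    """MSE reconstruction loss and per-timestep threshold gradients.

    y_hat = V_th(1) * count / T; L = mean((relu(i) - y_hat)^2).  The
    backward pass combines the decode's explicit dependence on the
    clipping threshold with the full reverse pass through the unrolled
    dynamics (surrogate of sharpness ``alpha`` everywhere).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    T = thresholds.size
    B = i_batch.size
    z, q = atif.forward_traces(i_batch, thresholds, relaxed=False)
    count = z.sum(axis=-1)
    y_hat = thresholds[0] * count / T
    x = np.maximum(i_batch, 0.0)
    resid = y_hat - x
    loss = float(np.mean(resid**2))
    g_yhat = 2.0 * resid / B                            # dL/dy_hat per sample
    gz_ext = np.broadcast_to(
        (g_yhat * thresholds[0] / T)[:, None], z.shape
    )                                                   # decode -> spikes
    _, g_thr_dyn = atif.backward_through_time(z, q, thresholds, gz_ext,
                                              alpha=alpha)
    g_thr = g_thr_dyn.sum(axis=0)
    g_thr[0] += float((g_yhat * count).sum()) / T       # explicit V_th(1)
    return loss, g_thr


def optimize_single_neuron(
    model_kind: str,
    source: GaussianSource,
    T: int,
    opt: Optional[OptimizerConfig] = None,
) -> SQNRTrace:
    """Run the single-neuron threshold-learning protocol.

    * ``fixed-if``: no updates; the trace is flat (same held-out batch at
      every logging point).
    * ``atif-u``: the scalar threshold, initialized at 1.0, is trained.
    * ``atif-nu``: T breakpoints, initialized at the equally-spaced
      configuration p_j = (T - j + 1)/T (the uniform V_th = 1 neuron, so
      all three variants start from the same SQNR), trained through the
      ordering-preserving reparameterization.

    Raises :class:`DivergenceError` (with the partial trace attached) if
    the loss becomes non-finite.
    """
    kind = normalize_model_kind(model_kind)
    opt = OptimizerConfig() if opt is None else opt
    if int(T) < 1:
        raise InvalidParameterError(f"T must be >= 1, got {T}")
    T = int(T)

    alpha = (1.0 / source.sigma if opt.surrogate_alpha is None
             else opt.surrogate_alpha)
    train_rng = source.rng(stream=0)
    i_eval = source.eval_batch(opt.eval_size)
    trace = SQNRTrace(model_kind=kind, T=T, sigma=source.sigma, seed=source.seed)

    if kind == "atif-nu":
        p0 = np.arange(T, 0, -1) / T
        a = atif.unconstrained_from_breakpoints(p0)
        optimizer = _Adam(T, opt)
    else:
        V_th = 1.0
        optimizer = _Adam(1, opt)

    its, sqnrs, losses, thr_log = [], [], [], []

    def thresholds_now():
        if kind == "atif-nu":
            p = atif.breakpoints_from_unconstrained(a)
            return atif.threshold_schedule_from_breakpoints(p).V, p.p
        return np.full(T, V_th), V_th

    def log(it):
        thr, record = thresholds_now()
        res = evaluate_sqnr(i_eval, thr)
        x = np.maximum(i_eval, 0.0)
        eval_loss = float(np.mean((x - encode_decode(i_eval, thr)) ** 2))
        its.append(it)
        sqnrs.append(res.sqnr_db)
        losses.append(eval_loss)
        thr_log.append(np.array(record, ndmin=1))
        return eval_loss

    log(0)
    if kind != "fixed-if":
        for it in range(1, opt.iterations + 1):
            batch = train_rng.normal(0.0, source.sigma, opt.batch_size)
            thr, _ = thresholds_now()
            loss, g_thr = _loss_and_grads(batch, thr, alpha=alpha)
            if not np.isfinite(loss):
                trace.diverged = True
                _finalize(trace, its, sqnrs, losses, thr_log)
                raise DivergenceError(
                    f"non-finite loss at iteration {it}", trace=trace
                )
            if kind == "atif-u":
                g = np.array([g_thr.sum()])
                V_th = float(optimizer.step(np.array([V_th]), g)[0])
                V_th = max(V_th, 1e-6)
            else:
                g_p = atif.schedule_jacobian(T).T @ g_thr
                g_a = atif.unconstrained_gradient(a, g_p)
                a = optimizer.step(a, g_a)
            if it % opt.eval_every == 0:
                log(it)
    else:
        for it in range(opt.eval_every, opt.iterations + 1, opt.eval_every):
            log(it)

    _finalize(trace, its, sqnrs, losses, thr_log)
    return trace


def _finalize(trace, its, sqnrs, losses, thr_log):
    trace.iterations = np.asarray(its, dtype=int)
    trace.sqnr_db = np.asarray(sqnrs, dtype=float)
    trace.loss = np.asarray(losses, dtype=float)
    trace.threshold_values = np.asarray(thr_log, dtype=float).squeeze()
    if trace.threshold_values.ndim == 0:
        trace.threshold_values = trace.threshold_values.reshape(1)


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------


def sqnr_gain(trace_a: SQNRTrace, trace_b: SQNRTrace, window: int = 10) -> float:
    """Converged SQNR of ``a`` minus that of ``b`` (mean over the final
    logging window), in dB.  Traces must share source configuration."""
    for attr in ("T", "sigma", "seed"):
        if getattr(trace_a, attr) != getattr(trace_b, attr):
            raise InvalidInputError(
                f"traces differ in {attr}: "
                f"{getattr(trace_a, attr)} vs {getattr(trace_b, attr)}"
            )
    return trace_a.final_sqnr(window) - trace_b.final_sqnr(window)


def min_timesteps_to_match(
    target_sqnr_db: float,
    V_th: float,
    source: GaussianSource,
    T_max: int,
    eval_size: int = 100_000,
) -> Optional[int]:
    """Smallest T <= T_max at which the fixed-threshold neuron reaches the
    target SQNR on a held-out batch (exhaustive ascending scan).

    Returns ``None`` (sentinel) if the target is not reached by ``T_max``.
    """
    if int(T_max) < 1:
        raise InvalidParameterError(f"T_max must be >= 1, got {T_max}")
    if not V_th > 0:
        raise InvalidParameterError(f"V_th must be > 0, got {V_th}")
    i_eval = source.eval_batch(eval_size)
    for T in range(1, int(T_max) + 1):
        res = evaluate_sqnr(i_eval, np.full(T, float(V_th)))
        if res.sqnr_db >= target_sqnr_db:
            return T
    return None
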