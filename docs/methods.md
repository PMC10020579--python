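# Methods

## The neuron as a quantizer

The package is built around the integrate-and-fire neuron with soft
reset, simulated in discrete time from a zeroed membrane:

    H(t) = V(t-1) + i(t)              (integration)
    z(t) = Θ(H(t) - V_th(t))          (spike decision; Θ(0) = 1)
    V(t) = H(t) - V_th(t) · z(t)      (soft reset)

for `t = 1..T`, with the input current `i(t) = z_prev(t)·W + b` (the
bias is injected at every timestep).  Each presentation starts from
`V = 0`; there is no carry-over between inputs — all experiments present
samples independently, so statefulness across presentations would only
add an uncontrolled bias.

For a *constant* positive current and a constant threshold the spike
count has the closed form `min(T, floor(max(0, T·i) / V_th))`, which the
simulation is the normative definition of: the implementation validates
the closed form against step-by-step simulation over a parameter grid,
not the other way around.  Two numerical conventions make this exact:

* **Fire on equality, with tolerance.**  `H ≥ V_th` fires, compared with
  a relative tolerance of 1e-9 so that exact-rational crossings
  (e.g. `i = V_th`, which must yield rate 1.0) survive float
  accumulation.  The closed form adds the same 1e-9 inside the floor.
* **Exact level counting.**  Transfer-curve levels are counted on
  integer spike counts (`k/T` as rationals), never on floating rates.

Rate decoding is `count / T`; the decoded *amplitude* is the rate scaled
by the quantizer's full-scale value (see below).  Negative constant
inputs never fire: the neuron implements a rectifying (ReLU-like)
quantizer with `T + 1` uniform levels, step `V_th/T`, saturating at
`V_th`.  Quantization error splits into a bounded *granular* part
(inputs at or below the saturation point) and an unbounded *overload*
part (inputs above it); `error_decomposition` partitions the MSE by that
rule, and setting `V_th` is exactly the trade between the two.

## Reconstruction target and SQNR reference

The quantity the neuron reproduces is the ReLU activation
`x = max(0, i)`, not the raw current: the neuron's job in a network is
to stand in for a ReLU, and its output is structurally nonnegative.  The
training loss is `E[(x − ŷ)²]` and the SQNR reference signal is `x`,
with the full Gaussian kept in both expectations (negative currents
contribute zero error, since reference and neuron both output 0).  Had
the raw signed current been the target, the negative half-axis alone
would put a floor of `σ²/2` under the noise power and cap every SQNR at
3.01 dB, making threshold learning pointless by construction — the
rectified target is the only reading under which threshold adaptation
can matter, and the package adopts it throughout.

## Amplitude decoder

Spikes are binary and carry no amplitude, so decoding a spike train to
an analog estimate requires a convention.  The package uses one rule for
every neuron variant:

    ŷ = V_th(1) · count / T      (firing rate × clipping point)

For a constant threshold this is the classic `count·V_th/T` staircase
that saturates exactly at `V_th`.  For the non-uniform neuron the
clipping point is `p_1`.  Two alternatives were considered and rejected:

* *Per-timestep amplitudes* `ŷ = Σ_t z(t)·V_th(t)/T` reconstruct each
  cell at its lower edge.  Direct search over the entire breakpoint
  family (a test in the suite performs it) shows this decoder caps the
  non-uniform neuron within about 1 dB of the best uniform neuron — the
  non-uniform cells buy almost nothing if the reconstruction levels are
  chained to the cell edges.
* *Mid-cell reconstruction weights* decode each cell at its midpoint;
  this is the textbook choice for a designed quantizer but is not
  something a downstream spiking layer could implement (it assigns
  different analog weights to different spike times).

The rate × clipping-point rule keeps the reconstruction levels uniform
(a downstream layer sees plain rate coding through a learned scale)
while the trainable breakpoints shape the *cell boundaries*; the
non-uniform SQNR gain measured by the acceptance script is obtained
under this decoder.

## Surrogate gradients and the sharpness α

Forward passes always use the hard Heaviside; backward passes substitute
the sigmoid surrogate derivative everywhere the Heaviside derivative
appears — the spike decision *and* the soft reset — with
`q = H(t) − V_th(t)`:

    ∂z/∂q ≈ α·σ'(α·q),    ∂L/∂V_th = −∂L/∂z · α·σ'(α·q)

The sharpness `α` matters more than is usually acknowledged.  The
surrogate is a smooth stand-in for the Dirac comb of the quantizer's
true distributional derivative; if its window `~1/α` is wide compared to
the scale of the membrane fluctuations, the threshold gradient loses all
localization and its zero crossing lands far from the MSE optimum (with
`α = 1` on a σ = 0.1 source the learned threshold stalls at ≈ 0.38,
roughly twice the optimum — the gradient field is nearly flat there).
Defaults are therefore scale-matched:

* single-neuron lab: `α = 1/σ` of the input source (10 for σ = 0.1),
* network training: `α = 4` (membrane scale is O(V_th) = O(1) there; a
  very sharp surrogate would leave the fixed-threshold baseline
  gradient-dead at initialization).

Both are configurable (`OptimizerConfig.surrogate_alpha`,
`TrainConfig.surrogate_alpha`); the bare ops (`surrogate_derivative`,
`threshold_gradient`) default to the unit sigmoid.

All backward passes are exact reverse-mode for the surrogate-relaxed
network (soft spikes `z = σ(α·q)`), and the test suite checks them
against central finite differences of that relaxed forward at 1e-4
relative tolerance — for the single neuron, the breakpoint chain rule,
and the full two-layer BPTT.  Shared (layer-wise) thresholds accumulate
gradient by summation over timesteps, neurons and the batch-mean loss,
i.e. true reverse-mode semantics for a shared parameter; anything else
would break the finite-difference identity.

## The non-uniform threshold schedule

The breakpoints `p_1 ≥ … ≥ p_T > 0` define where the quantizer's output
steps sit; the induced per-timestep thresholds are

    V_th(1) = p_1,   V_th(j) = T·(p_j − p_{j+1})  (1 < j < T),
    V_th(T) = T·p_T.

The interior rule is derived from the spike-pattern conditions — a
constant input `p_j` must fire at timesteps `j..T` and nowhere else —
which form a linear system whose per-cell solution telescopes to
`T·(p_j − p_{j+1})`.  (A closed-form expression sometimes quoted for the
second threshold, `(T−1)p_2 − T(p_3 − p_4)`, is inconsistent with that
system; simulating it produces a non-contiguous pattern, so the package
uses the recurrence and validates it with a brute-force pattern oracle.)

Three structural facts worth knowing:

* **Feasibility is a polytope, and it is empty for T ≥ 6.**  Writing the
  no-premature-fire, first-fire and sustained-fire conditions out (see
  `validate_breakpoints`), the chain  `p_3 ≤ T·p_2/(T+2)` (no premature
  fire of `p_3` at t = 2), `p_4 < T·p_3/(T+3)` (same for `p_4` at
  t = 3) and `p_4 ≥ (T−3)/T·p_2` (sustained firing of `p_2` at t = 3)
  is contradictory once `T ≥ 6`:  `T²/((T+2)(T+3)) < (T−3)/T` fails for
  T ≤ 5 only.  Exact canonical patterns therefore exist only for
  `T ≤ 5`; the pattern oracle samples `T ∈ {2,3,4,5}`.  The neuron
  itself is unaffected at larger T — the quantizer remains monotone with
  at least `T + 1` levels; only the "breakpoint = first-spike time"
  reading disappears.
* **Cell boundaries are degenerate.**  Exactly *on* a boundary
  (`t·p_j = V_th(t)`, e.g. the equally-spaced configuration
  `p_j = (T−j+1)c/T` that reduces to the uniform neuron with
  `V_th = c`), fire-on-equality shifts spikes earlier; the count and the
  decoded amplitude are unchanged, only the timing pattern degenerates.
  `validate_breakpoints` treats boundary equality as a pass.
* **Off the canonical inputs the quantizer is finer than T + 1 levels.**
  Inputs inside a cell can realize non-contiguous timing patterns; with
  a time-varying schedule different timings at the same count are
  distinct internal states, and the effective staircase acquires extra
  steps.  This is part of why the trained non-uniform neuron beats the
  uniform one at equal latency.

During training the breakpoints are reparameterized as cumulative
softplus increments (`p_T = softplus(a_T)`,
`p_j = p_{j+1} + softplus(a_j)`), which keeps strict ordering and
positivity under any gradient step; full pattern feasibility is *not*
enforced — the forward dynamics are well defined regardless, and the
loss is free to use the interior of the family.

## Single-neuron protocol

Per variant (fixed-IF / ATIF-u / ATIF-nu), `T = 4` unless stated:

| setting | value | note |
|---|---|---|
| source | i ~ N(0, σ²), σ = 0.1 | configurable |
| init | V_th = 1 (ATIF-nu: `p_j = (T−j+1)/T`, the same uniform neuron) | all variants start at identical SQNR |
| optimizer | Adam, lr 1e-3 (β 0.9/0.999) | SGD available |
| batch / iterations | 256 × 10 000 | converges in seconds–minutes on one CPU |
| evaluation | every 100 iterations, fixed held-out batch of 100 000 samples on a dedicated RNG stream | loss and SQNR both logged on the held-out batch |
| converged value | mean over the final 10 logged points | suppresses optimizer jitter |
| seeds | explicit everywhere; multi-seed summaries use 10 seeds | bit-identical traces for identical seed + config |

`min_timesteps_to_match` scans `T = 1..T_max` of the fixed-threshold
neuron (evaluation only) and returns the first `T` whose SQNR reaches a
target, or `None` if unreachable.  A non-finite training loss aborts the
run with a `DivergenceError` carrying the partial trace.

## Network harness and synthetic data

The network module trains a dense spiking MLP (2 hidden layers of width
64 by default) with analog input coding (the raw feature is the input
current at every timestep), layer-wise shared thresholds, and a linear
head on the rate-decoded last spiking layer fed to softmax
cross-entropy.  Cross-entropy on decoded rates is a choice, not a given:
rate decoding is the network's output convention, and cross-entropy is
the standard readout for direct training of rate-coded classifiers.
Convolutional layers are declared in `LayerSpec` but not implemented;
the desk-scale experiments need only the MLP.

The synthetic task is Gaussian-blob classification: 8 classes on a
circle of radius 0.15 in 2-D, cluster σ = 0.035, 128 train / 64 test
samples per class, T = 4, 30 epochs of Adam at 1e-3, batch 128.  The
geometry is deliberately small-signal — first-layer currents sit well
below a unit threshold, the regime where a fixed `V_th = 1` quantizes
coarsely and threshold adaptation has something to do — while leaving
headroom below the Bayes ceiling so accuracy can resolve differences
between variants (an earlier, easier geometry put every variant at the
ceiling and could express no ordering).

What the generator does *not* emulate: real image/audio statistics,
feature correlations, deep architectures, data augmentation, or long
training schedules.  Passing the toy ablation shows that the
trainable-threshold mechanism produces the expected qualitative ordering
(trainable ≥ fixed at equal budget) in the regime the theory addresses —
it says nothing quantitative about large benchmarks.

Sparsity is reported as `θ` = fraction of active neuron-timesteps per
activity tensor, the network value being the unweighted mean over layer
tensors and `θ·T` the spikes per neuron per inference.  Whether the
input-encoding (first spiking) layer belongs in the average is a
convention; the report exposes both (`network_theta`,
`network_theta_excluding_input`).

## Degenerate inputs and tie-breaks

* Non-positive thresholds, ascending breakpoints, σ ≤ 0, T < 1 and
  shape mismatches raise typed errors (`InvalidParameterError`,
  `InvalidInputError`); the schedule constructor names the violated
  inequality.
* ATIF-u's threshold is clamped at 1e-6 during optimization (the loss
  surface never drives it there under the defaults; the clamp only
  guards pathological configurations).
* Zero quantization noise reports SQNR = +inf; an identically zero
  reference signal raises `UndefinedSignalError`.
* `sqnr_gain` refuses traces from mismatched source configurations.

## Problem sizes

Everything is sized for a single CPU: 10k-iteration single-neuron runs
(seconds each), 100k-sample evaluation batches, a 1k-sample toy dataset,
and 15 short network trainings for the ablation.  The full test suite,
including the end-to-end acceptance checks, runs in a few minutes.

## Known limitations

* The decoder convention (rate × clipping point) is part of the model;
  other decoders change the non-uniform neuron's measured advantage (see
  above).
* Exact breakpoint spike patterns do not exist for `T ≥ 6` (derivation
  above); ATIF-nu at larger T is a well-defined trainable quantizer but
  loses the closed-form breakpoint interpretation.
* The network harness is dense-only, desk-scale, and uses plain rate
  readout; it is a mechanism testbed, not a benchmark rig.
* Surrogate sharpness is a real hyperparameter.  The scale-matched
  defaults are principled but not adaptive; sources with very different
  scales need `surrogate_alpha` set accordingly.
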