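# spikequant

Trainable quantization for integrate-and-fire spiking neurons: soft-reset
IF dynamics, adaptive-threshold neurons (ATIF-u / ATIF-nu), a
signal-to-quantization-noise (SQNR) lab, and a desk-scale
surrogate-gradient training harness for rate-coded spiking networks.

## Why

A rate-coded spiking neuron is a scalar quantizer.  The
integrate-and-fire neuron with *soft reset* integrates its input current
over `T` timesteps,

    H(t) = V(t-1) + i(t),    z(t) = Θ(H(t) − V_th),    V(t) = H(t) − V_th·z(t),

and its decoded output `ŷ = V_th · (Σ_t z(t)) / T` is a uniform
staircase with exactly `T + 1` levels, clamping negative inputs to zero
(ReLU-like) and saturating at `V_th`.  The number of timesteps `T` is
the network's latency, so the only way to encode analog activations
precisely *without* paying latency is to shape the quantizer itself.
That is the quantization-noise view of the latency/accuracy trade-off in
spiking networks, and this package implements the two trainable neuron
families that exploit it:

* **ATIF-u** — `V_th` is a trainable parameter, learned by minimizing
  the reconstruction error `E[(max(0,i) − ŷ)²]` with the sigmoid
  surrogate-gradient trick (forward pass stays a hard Heaviside;
  backward substitutes `σ'(q)` with `q = H(t) − V_th`, so
  `∂L/∂V_th = −∂L/∂z · σ'(q)`).  The threshold adapts to the input
  distribution: for `i ~ N(0, 0.1²)` it drops from 1.0 to ≈ 0.19 and
  buys **more than 10 dB** of SQNR at `T = 4` — the fixed-threshold
  neuron needs `T = 20`, five times the latency, to match it.
* **ATIF-nu** — `T` trainable breakpoints `p_1 ≥ … ≥ p_T > 0` induce a
  *time-varying* threshold schedule
  `V_th(1) = p_1`, `V_th(j) = T(p_j − p_{j+1})`, `V_th(T) = T·p_T`,
  turning the neuron into a non-uniform quantizer whose output steps sit
  at the breakpoints (input `p_j` fires at timesteps `j..T` exactly).
  Shaping the cells to the Gaussian's mass adds **≈ 3 dB** on top of the
  trained uniform neuron at the same latency.

A small BPTT harness (`spiking_net`) trains dense spiking networks with
layer-wise shared thresholds on synthetic Gaussian-blob data, reports
the spike-sparsity statistic `θ` (fraction of active neuron-timesteps;
`θ·T` = spikes per neuron per inference), and reproduces the
fixed-vs-trainable ablation ordering at desk scale.

## Worked example

```python
import numpy as np
from spikequant import (
    GaussianSource, OptimizerConfig, optimize_single_neuron,
    sqnr_gain, min_timesteps_to_match,
)

source = GaussianSource(sigma=0.1, seed=0)
opt = OptimizerConfig()  # Adam lr 1e-3, 10k iterations, batch 256

fixed = optimize_single_neuron("fixed-if", source, T=4, opt=opt)
atif_u = optimize_single_neuron("atif-u", source, T=4, opt=opt)
atif_nu = optimize_single_neuron("atif-nu", source, T=4, opt=opt)

print(f"fixed V_th=1 : {fixed.final_sqnr(10):6.2f} dB")
print(f"ATIF-u       : {atif_u.final_sqnr(10):6.2f} dB  "
      f"(V_th -> {float(atif_u.final_threshold()):.3f})")
print(f"ATIF-nu      : {atif_nu.final_sqnr(10):6.2f} dB  "
      f"(p -> {np.round(atif_nu.final_threshold(), 3)})")
print(f"gain trainable vs fixed  : {sqnr_gain(atif_u, fixed):5.2f} dB")
print(f"gain non-uniform vs unif.: {sqnr_gain(atif_nu, atif_u):5.2f} dB")
print("fixed neuron matches trained SQNR first at T =",
      min_timesteps_to_match(atif_u.final_sqnr(10), 1.0, source, T_max=64))
```

prints

```
fixed V_th=1 :   0.47 dB
ATIF-u       :  10.94 dB  (V_th -> 0.189)
ATIF-nu      :  14.09 dB  (p -> [0.205 0.119 0.073 0.032])
gain trainable vs fixed  : 10.47 dB
gain non-uniform vs unif.:  3.15 dB
fixed neuron matches trained SQNR first at T = 20
```

Read it as: at `T = 4` the fixed unit threshold wastes almost its whole
range on a σ = 0.1 source (0.47 dB ≈ the neuron outputs ~0); learning
the threshold recovers 10.5 dB, which a fixed threshold only reaches at
5× the latency; learning the breakpoint schedule adds another 3 dB by
packing quantization cells where the Gaussian has mass.

## Command line

Four experiment runners with validated YAML/JSON configs, CSV/JSON
outputs and a checksum manifest per run:

```
spikequant sqnr-single    --config cfg.yaml --out results/run1
spikequant transfer-curve --out results/curve --seed 0
spikequant train-toy      --out results/toy --seed 0
spikequant ablation       --out results/ablation --seed 0
```

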