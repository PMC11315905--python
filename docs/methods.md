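# Methods

## Model and assumptions

A TTFS network is a feed-forward layered network of integrate-and-fire
neurons with a linear post-synaptic potential (a linearization of the
classical double-exponential synaptic filter). Every neuron fires at
most once (a long refractory period is assumed), and information is
carried by *when* the single spike occurs: the decoded activation of a
spiking neuron is `x_i = (t_max⁽ⁿ⁾ − t_i)/tau_c`, so earlier means
larger. Layers own consecutive half-open processing windows,
`t_min⁽ⁿ⁺¹⁾ = t_max⁽ⁿ⁾`; a membrane crossing exactly at `t_max` is
*not* a spike (the de-charge makes emission impossible from `t_max`
onward), which makes the spike mask equal the ReLU activity mask
including the boundary case `x = 0`.

The two-regime dynamics (accumulating step currents before `t_min`, a
fixed ramp `B_i` inside the window) admit a closed-form spike time,

```
t_i = t_min + tau_c (ϑ_i − V_i(t_min)) / B_i,
V_i(t_min) = (1/tau_c) Σ_{j spiked} W_ij (t_min − t_j),
```

which is what the forward pass computes. An independent oracle
(`simulate_layer_grid`) integrates the same ODE on a uniform time grid
(slopes evaluated at interval midpoints, crossings located by linear
interpolation) and agrees with the closed form to within one grid step;
unlike the closed form it can also *detect* crossings before `t_min`
and reports them as violations of the base-threshold condition instead
of clamping them.

Hidden layers always have initial slope `A = 0`; only the non-spiking
readout carries a trainable `A`, integrating last-window spikes into
logits `V_m = A_m Δ⁽ᴺ⁾ + Σ_j W_mj x_j`. Loss is softmax cross-entropy
on these potentials, averaged over the batch (so learning rates
transfer between the spiking net and its ReLU twin).

## Windows, base thresholds and sentinels

Windows are stored as lengths `Δ⁽ⁿ⁾` in units of `tau_c`; absolute
times are cumulative sums, so the tiling recursion holds exactly and an
adaptive update of one length propagates automatically. Silent neurons
carry the sentinel time `t_max⁽ⁿ⁾` (the value is not pinned down by the
dynamics; `t_max` is our choice): it decodes to activation 0, drops out
of downstream weighted sums identically, and has zero derivative.

The *bound* window mode uses
`Δ⁽ⁿ⁾ = (1+margin)·max_i(max(b_i,0) + Σ_j max(w_ij,0)·Δ⁽ⁿ⁻¹⁾)` with
`Δ⁽⁰⁾ = 1` for inputs in `[0,1]`. Together with the base-threshold
convention `ϑ̃ = B·Δ` this is sufficient for both guarantees at once:
the worst-case positive drive accumulated before `t_min` is
`Σ_j W⁺_ij Δ⁽ⁿ⁻¹⁾ ≤ B_i Δ⁽ⁿ⁾ − D_i = ϑ_i` (no early spike), and
activations are bounded by the same expression, so every ReLU-active
unit fires inside its window. This sufficient condition is conservative
— windows may be larger than strictly necessary, growing roughly
geometrically with depth — but it is distribution-free and verified
against the grid oracle. The `ϑ̃ = B·Δ` convention has a second payoff:
the reverse-mapped bias is `b = D/B` *independently of Δ*, so window
growth never changes the equivalent ReLU network.

The *percentile* mode sizes each window to the p-th percentile of the
layer's **positive** ReLU activations on calibration data. Positive
activations (= firing times) rather than all activations are used so
that "p percent covered" means p percent of *spikes* arrive inside the
window — with sparse activity a percentile over all values (mostly
zeros) would cover far fewer spikes than advertised.

## Mappings

Reverse (TTFS → ReLU): `w = W/B`, `b = −ϑ/B + Δ`; readout `w = W`,
`b = Δ⁽ᴺ⁾·A`. Forward B1: `W = w`, `B = 1`, `D = b`. Forward alpha1:
`B_i = 1/(1 − Σ_j w_ij)`, `W = w·B`, `D = B·b`, which requires row sums
below 1; layers are rescaled by the intrinsic ReLU scaling symmetry
(incoming weights and bias by `λ ≤ 1`, next layer's incoming weights by
`1/λ`, max pooling is positively homogeneous) until all row sums are at
most `1 − margin`. The factors are recorded in `meta["layer_scales"]`
and `undo_layer_rescale` inverts them, so the round trip is exact up to
the recorded rescale. Margin defaults: 0 for exact-equivalence work,
0.1 for training (headroom for weight drift between window updates).
Convolutions map filter-wise (one `B`, `ϑ̃`, `D` per output channel);
batch-norm statistics are fused affinely into the neighboring dense or
conv layer before conversion.

## Gradients

Backpropagation goes through spike times. From the closed form:
`dt_i/dt_j = W_ij/B_i` (both spiked), `dt_i/dW_ij = −(t_min − t_j)/B_i`,
`dt_i/dD_i = −tau_c/B_i`; windows and base thresholds are treated as
constants (the adaptive rule is assumed at equilibrium). The layer
Jacobian is the masked matrix `M·(1/B)·W`. We apply **both** masks —
zero rows for silent postsynaptic neurons (their sentinel time is
constant) and zero columns for silent presynaptic neurons — which is
the literal derivative of the closed form; chained products then equal
the chained ReLU Jacobians exactly, which is the acceptance check.

For B1, `dL/dW = dL/dw` and `dL/dD = dL/db` elementwise, so a spiking
SGD step *is* the ReLU step. One subtlety concerns the readout: its
bias image is `b = Δ⁽ᴺ⁾·A`, so raw gradient descent on `A` scales the
effective bias step by `Δ²`. The optimizer therefore updates the
readout offset in its bias parametrization by default
(`δA = −η·(dL/dA)/Δ²`, i.e. plain SGD on `b`); this is a
parametrization choice, keeps the learning-rate scale of the bias
consistent with the ReLU convention, and is the premise under which the
B1 trajectory identity holds for deep windows. The raw-gradient update
is available behind `TrainConfig(readout_bias_param=False)`.

For alpha1 the slope is structurally tied to the weights
(`B = 1 + Σ W` is the accumulated drive continuing into the window), so
after every optimizer step `B` is recomputed and `ϑ̃` reset; within a
step, backprop treats `B` as a constant. The ReLU-space image of a
spiking step (`update_delta`) is the full first-order linearization of
the row-wise map `M(W)_ij = W_ij/(1 + Σ_k W_ik)` — including the
cross-terms through the row sum — whose prediction error against the
exact finite-step remap is O(η²); its diagonal part is the per-pair
factor `(B_i − W_ij)/B_i²` that makes the alpha1 trajectory
uncorrectable by any single learning rate. Under large updates the
tied model can leave its admissible region (`B ≤ 0`); training aborts
with a diagnostic, and the lock-step comparison records the divergence
instead of crashing — this is the exploding-gradient instability, not
an implementation failure.

Finite-difference checks use central differences with step
`h = 1e-6·max(1, |θ|)`, balancing truncation against round-off in
64-bit. All equivalence-grade computation is 64-bit; trained network
pairs can otherwise drift apart through accumulated rounding.

## Spectrum diagnostics

`jacobian_spectrum` reports eigenvalues of `(1/B)·W` per layer,
ignoring the spike mask by default (the initialization-time assumption
that the mask barely moves the spectrum; a masked variant backs the
gradient-norm profile). Non-square layers fall back to singular values
with a note. The gradient-norm-by-depth profile propagates a random
unit cotangent vector through the transposed chained Jacobians. Under
`W ~ N(0,1)/√n` the B1 radius sits at the circular-law edge: at
`n = 340` the finite-size radius is ≈ 1.04 ± 0.02, i.e. within
[0.9, 1.1] but typically a few percent above 1 — the contrast with the
alpha1 family (median radius > 10, chained norms growing by orders of
magnitude over 8 layers) is what the diagnostics establish, not radius
≤ 1 exactly.

## Training

Defaults follow the study conditions: batch size 8, initial learning
rate 5·10⁻⁴ with the exponential schedule `lr₀·0.9^(it/5000)`, Adam
with standard moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8; unstated
upstream, so standard values), window-slack constant γ = 10.
Trajectory-equivalence claims are asserted under plain SGD without the
schedule. The adaptive window rule runs after the optimizer step of
each batch (the within-batch forward pass stays consistent with the
windows it used); the minimum is taken over spiking neurons of the
current batch only, since sentinel times equal `t_max` and would
nullify the update. Windows only ever grow; when the last hidden
window grows, the readout slope is rescaled to keep its bias image
unchanged.

L1 sparsity regularization penalizes the mean decoded activation of
spiking hidden neurons (over samples and neurons) — the spiking-rate
interpretation; a plain weight-L1 is available via
`TrainConfig(l1_on="weights")`. The penalty weight for the sparsity
experiments is 1e-2, chosen once as a value that visibly moves
spikes/neuron on the synthetic tasks without hurting accuracy.

## Hardware constraints

Jitter adds Gaussian noise to every spiking time of the input encoding
and of each layer's output, fresh draws per batch during fine-tuning
(the noise models the device, so it is present in training and
evaluation); jittered times are clipped back into the window by
default, with an optional harsher mode that silences spikes pushed past
`t_max`. Evaluation under jitter averages over a configurable number
of draws. Time quantization snaps spike times to `n` uniform grid
points per (frozen) window — windows sized to cover 99% of firing
times, early spikes treated as occurring at `t_min`, ties rounded to
the earlier point (larger activation, conservative against silencing).
Weight quantization clips to the [1st, 99th] percentile range ([4th,
96th] at 4 bits), maps uniformly onto signed integers
`[−2^(q−1), 2^(q−1)−1]`, freezes the grid, and fine-tunes
full-precision shadow weights through a straight-through estimator (the
minimal standard choice for quantization-aware training). Latency
reduction shrinks windows to a percentile (100/99/95/92/90) of the ReLU
twin's activations; spikes arriving before a window opens are blocked
until it opens, which in the ReLU picture is exactly clipping
activations at the window length — an identity the tests verify to
1e-9 on data outside the calibration set. Every constraint at its
neutral setting reproduces unconstrained behavior bit for bit.

## Synthetic data

`make_blobs` draws Gaussian class clusters whose centres are
`separation` within-class standard deviations apart, then squashes all
features affinely into `[0,1]` (TTFS encoding requires bounded inputs);
large separations give linearly separable tasks. `make_toy_images`
produces oriented-bar patterns with pixel noise for the conv/pool path.
These generators emulate only what the theory needs — bounded inputs,
controllable difficulty, determinism per seed — and none of the
statistics of natural images; passing tests demonstrate the *exactness*
and *direction* claims (equivalence, trajectory identity, sparsity and
constraint effects), not benchmark-level accuracy on real data.

Experiments use desk-scale problem sizes chosen to keep the whole suite
in seconds: 8×64-unit networks for equivalence and trajectory suites,
340×340 layers only for the spectrum reproduction, 512-sample blob
tasks (2 classes, separation 3 for separable smoke tests; 4 classes,
separation 1.2 where a constraint must visibly cost accuracy before
fine-tuning recovers it).

## Known limitations

* Only the linear post-synaptic potential is modelled (no leaky or
  double-exponential kernels), and only feed-forward dense/conv/maxpool
  architectures (no skip connections, recurrence, or live batch norm).
* Bound-mode windows grow geometrically with depth; percentile windows
  or the adaptive rule are the practical choice for deep networks.
* The alpha1 family is faithfully unstable: at learning rates where B1
  trains comfortably, tied-slope updates can push `B ≤ 0` and abort.
* Whether the sparsity metric should count input-layer spikes is
  ambiguous; hidden layers only is the default, with
  `spike_sparsity(..., include_input=True)` as the alternative.
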