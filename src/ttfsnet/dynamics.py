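"""Forward pass of a TTFS network.

The membrane potential of a hidden neuron obeys a two-regime dynamics:
before its layer's window opens at ``t_min`` the slope is the initial
slope (zero for hidden layers) plus the sum of step currents triggered by
presynaptic spikes; from ``t_min`` on, the slope switches to the fixed
positive value ``B``.  A spike is emitted when the potential crosses the
effective threshold ``theta = theta_base - D`` inside ``[t_min, t_max)``;
at ``t_max`` the neuron is de-charged, so a crossing at or after ``t_max``
is not a spike.  Each neuron fires at most once (long refractory period).

Because the slope is constant inside the window, the spike time has the
closed form

    t_i = t_min + tau_c * (theta_i - V_i(t_min)) / B_i,

with ``V_i(t_min) = (1/tau_c) * sum_{j spiked} W_ij (t_min - t_j)``.
:func:`layer_spike_times` implements this closed form;
:func:`simulate_layer_grid` integrates the two-regime ODE on a time grid
and serves as an independent oracle for it.

The readout layer is non-spiking: it integrates presynaptic spikes over
the last hidden window and adds a trainable baseline slope ``A``, giving
logits ``V_m = A_m * Delta^(N) + (1/tau_c) sum_{j spiked} W_mj
(t_max^(N) - t_j)``; softmax cross-entropy is computed on these
real-valued potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _convops as cv
from .network_model import SpikeFrame, TTFSLayer, TTFSNetwork

__all__ = [
    "ForwardResult",
    "EnergyReport",
    "encode_input",
    "layer_spike_times",
    "simulate_layer_grid",
    "ttfs_maxpool",
    "forward",
    "spike_sparsity",
    "energy_estimate",
]


@dataclass
class ForwardResult:
    """Output of :func:`forward`.

    ``frames[0]`` is the encoded input; ``frames[k]`` (k >= 1) is the
    spike frame of hidden layer ``k - 1``; ``kinds`` labels each frame
    (``input``/``dense``/``conv``/``maxpool``).  ``patches`` caches the
    im2col views of conv-layer inputs for the backward pass.
    """

    frames: list
    kinds: list
    logits: np.ndarray
    probs: Optional[np.ndarray] = None
    loss: Optional[float] = None
    accuracy: Optional[float] = None
    labels: Optional[np.ndarray] = None
    patches: dict = field(default_factory=dict)
    pool_argmin: dict = field(default_factory=dict)


@dataclass
class EnergyReport:
    """Dominant-energy estimate for processing a batch.

    ``total_energy`` is the per-sample average of
    ``sum_{spiking} (T_r + 0.5 theta^2 C) + 0.5 sum_{silent} V(t_max)^2 C``.
    ``spikes_per_neuron`` is the spiking sparsity, ``theta_sq`` the mean
    squared effective threshold, and ``r_fraction`` the mean ratio of
    silent-neuron charging to threshold charging.
    """

    total_energy: float
    spikes_per_neuron: float
    theta_sq: float
    r_fraction: float


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_input(x: np.ndarray, window0: tuple, tau_c: float) -> SpikeFrame:
    """TTFS-encode inputs in ``[0, 1]``: ``t_j = t_max^(0) - tau_c * x_j``.

    A larger input fires earlier; a zero input emits no spike (sentinel
    time ``t_max^(0)``, mask 0).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("inputs must lie in [0, 1] for TTFS encoding")
    t_min, t_max = window0
    times = t_max - tau_c * x
    mask = x > 0
    return SpikeFrame(times=times, mask=mask, t_min=t_min, t_max=t_max)


# ---------------------------------------------------------------------------
# Closed-form layer dynamics
# ---------------------------------------------------------------------------

def _layer_drive(prev: SpikeFrame, layer: TTFSLayer, tau_c: float,
                 clip_early: bool = True):
    """Potential at window opening, ``V(t_min)``, plus conv patches.

    Uses the decoded view ``(prev.t_max - t_j)/tau_c``: silent neurons
    (sentinel ``prev.t_max``) contribute exactly zero, and early arrivals
    are counted only from the previous window's opening onward (activation
    clipping in the ReLU twin).
    """
    x = prev.decoded(tau_c, clip_early=clip_early)
    if layer.kind == "dense":
        xf = x.reshape(x.shape[0], -1)
        return xf @ layer.W.T, None
    if layer.kind == "conv":
        v, patches = cv.conv_forward(x, layer.W, layer.padding)
        return v, patches
    raise ValueError(f"no membrane drive for layer kind {layer.kind!r}")


def layer_spike_times(prev: SpikeFrame, layer: TTFSLayer, window: tuple,
                      tau_c: float, clip_early: bool = True):
    """Closed-form spike times of a dense/conv hidden layer.

    Returns ``(frame, patches)``; ``patches`` is ``None`` for dense
    layers.  The candidate crossing time is kept even when it precedes
    ``t_min`` (possible only with reduced windows); consumers clamp it.
    """
    if np.any(layer.B <= 0):
        raise ValueError("slope parameter B must be strictly positive")
    t_min, t_max = window
    v, patches = _layer_drive(prev, layer, tau_c, clip_early)
    theta = layer.theta
    t_cand = t_min + tau_c * (theta - v) / layer.B
    mask = t_cand < t_max
    times = np.where(mask, t_cand, t_max)
    frame = SpikeFrame(times=times, mask=mask, t_min=t_min, t_max=t_max,
                       v_tmin=v)
    return frame, patches


def simulate_layer_grid(prev: SpikeFrame, layer: TTFSLayer, window: tuple,
                        tau_c: float, dt: float) -> SpikeFrame:
    """Integrate the two-regime membrane ODE on a time grid (oracle).

    Dense layers only.  Walks a grid of step ``dt`` from the previous
    window's opening to ``t_max``, accumulating the step-current drive
    before ``t_min`` and the fixed slope ``B`` afterwards; the threshold
    crossing is located by linear interpolation inside the crossing step,
    and at most one spike is emitted per neuron (refractoriness).  A
    crossing strictly before ``t_min`` marks the neuron in the
    ``early_violation`` attribute of the returned frame (the base
    threshold was too small); the reported time is still the first
    crossing.  Emission at or after ``t_max`` is impossible (de-charge).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if layer.kind != "dense":
        raise ValueError("grid oracle supports dense layers only")
    t_min, t_max = window
    t_in = np.maximum(prev.times, prev.t_min)  # early arrivals blocked
    batch = t_in.shape[0]
    t_in = t_in.reshape(batch, -1)
    grid = np.arange(prev.t_min, t_max + dt, dt)
    # slopes evaluated at interval midpoints; step currents: silent
    # sentinel equals this layer's t_min, so its Heaviside never opens
    # inside regime 1
    mid = grid[None, None, :] + 0.5 * dt
    heav = (mid > t_in[:, :, None]).astype(float)
    drive = np.einsum("oj,bjt->bot", layer.W, heav)
    slope = np.where(mid < t_min, drive, layer.B[None, :, None])
    v = np.concatenate(
        [np.zeros((batch, layer.W.shape[0], 1)),
         np.cumsum(slope[:, :, :-1], axis=2) * (dt / tau_c)], axis=2)
    theta = layer.theta[None, :, None]
    crossed = v >= theta
    first = np.argmax(crossed, axis=2)
    any_cross = crossed.any(axis=2)
    # linear interpolation within the crossing step
    i0 = np.maximum(first - 1, 0)
    v0 = np.take_along_axis(v, i0[:, :, None], axis=2)[:, :, 0]
    v1 = np.take_along_axis(v, first[:, :, None], axis=2)[:, :, 0]
    dv = np.where(v1 > v0, v1 - v0, 1.0)
    t_cross = grid[i0] + dt * (layer.theta[None, :] - v0) / dv
    t_cross = np.where(first == 0, grid[0], t_cross)
    spiked = any_cross & (t_cross < t_max)
    times = np.where(spiked, t_cross, t_max)
    frame = SpikeFrame(times=times, mask=spiked, t_min=t_min, t_max=t_max)
    frame.early_violation = any_cross & (t_cross < t_min)
    return frame


def ttfs_maxpool(frame: SpikeFrame, layer: TTFSLayer) -> SpikeFrame:
    """Spiking max pooling: relay the earliest spike in each window.

    The earliest time is the largest activation, so pooled-then-decoded
    values equal max-pooled ReLU activations.  An all-silent window stays
    silent (sentinel min is ``t_max`` itself).  Returns the pooled frame
    and records the argmin used (for gradient routing).
    """
    if frame.times.ndim != 4:
        raise ValueError("maxpool expects a (batch, h, w, c) frame")
    win_t = cv.pool_view(frame.times, layer.pool, layer.stride)
    win_m = cv.pool_view(frame.mask.astype(bool), layer.pool, layer.stride)
    argmin = np.argmin(win_t, axis=3)
    times = np.take_along_axis(win_t, argmin[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    mask = win_m.any(axis=3)
    pooled = SpikeFrame(times=times, mask=mask, t_min=frame.t_min,
                        t_max=frame.t_max)
    pooled.argmin = argmin
    return pooled


# ---------------------------------------------------------------------------
# Full forward pass
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy; returns ``(loss, probs)``."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    ll = z[np.arange(len(labels)), labels] - np.log(ez.sum(axis=1))
    return float(-ll.mean()), probs


def forward(net: TTFSNetwork, X: np.ndarray, y: Optional[np.ndarray] = None,
            *, clip_early: bool = True,
            frame_hook: Optional[Callable] = None) -> ForwardResult:
    """Run the TTFS network on a batch of samples in ``[0, 1]``.

    ``frame_hook(frame, stage_index) -> frame`` is applied to the encoded
    input and to the output frame of every spiking layer (hardware
    constraints such as jitter or time quantization plug in here).
    """
    X = np.asarray(X, dtype=float)
    frame = encode_input(X, net.input_bounds(), net.tau_c)
    if frame_hook is not None:
        frame = frame_hook(frame, 0)
    frames, kinds = [frame], ["input"]
    patches_cache, pool_argmin = {}, {}
    stage = 0
    for k, layer in enumerate(net.layers):
        if layer.kind == "maxpool":
            frame = ttfs_maxpool(frame, layer)
            pool_argmin[k] = frame.argmin
        else:
            stage += 1
            frame, patches = layer_spike_times(
                frame, layer, net.layer_bounds(k), net.tau_c,
                clip_early=clip_early)
            if patches is not None:
                patches_cache[k] = patches
            if frame_hook is not None:
                frame = frame_hook(frame, stage)
        frames.append(frame)
        kinds.append(layer.kind)

    xN = frame.decoded(net.tau_c, clip_early=clip_early)
    xN = xN.reshape(xN.shape[0], -1)
    delta_N = (frame.t_max - frame.t_min) / net.tau_c
    logits = xN @ net.readout.W.T + net.readout.A[None, :] * delta_N
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite readout potentials")

    result = ForwardResult(frames=frames, kinds=kinds, logits=logits,
                           patches=patches_cache, pool_argmin=pool_argmin)
    if y is not None:
        y = np.asarray(y, dtype=int)
        result.labels = y
        result.loss, result.probs = softmax_cross_entropy(logits, y)
        result.accuracy = float((logits.argmax(axis=1) == y).mean())
    return result


# ---------------------------------------------------------------------------
# Sparsity and energy
# ---------------------------------------------------------------------------

def spike_sparsity(result: ForwardResult, include_input: bool = False) -> float:
    """Average fraction of spikes per neuron per data point.

    Counts hidden spiking (dense/conv) layers only by default; the input
    layer can be included with ``include_input``.
    """
    spikes = total = 0
    for frame, kind in zip(result.frames, result.kinds):
        if kind in ("dense", "conv") or (include_input and kind == "input"):
            spikes += int(frame.mask.sum())
            total += frame.mask.size
    return spikes / total if total else 0.0


def energy_estimate(result: ForwardResult, net: TTFSNetwork,
                    T_r: float, C: float) -> EnergyReport:
    """Dominant-energy model for neuromorphic inference.

    Every spiking neuron costs the transmission energy ``T_r`` plus the
    capacitor charge to its threshold, ``0.5 * theta^2 * C``; every silent
    neuron costs only the charge actually accumulated by ``t_max``,
    ``0.5 * V(t_max)^2 * C`` with ``V(t_max) = V(t_min) + B * Delta``
    (capped below the threshold).  Energies are averaged per sample.
    """
    if T_r < 0 or C < 0:
        raise ValueError("T_r and C must be non-negative")
    total = 0.0
    th_sq_sum, n_neurons = 0.0, 0
    r_vals = []
    batch = result.frames[0].times.shape[0]
    layer_iter = [(f, k, lay) for (f, k), lay
                  in zip(zip(result.frames[1:], result.kinds[1:]), net.layers)]
    for frame, kind, layer in layer_iter:
        if kind not in ("dense", "conv"):
            continue
        theta = layer.theta
        delta = (frame.t_max - frame.t_min) / net.tau_c
        th_full = np.broadcast_to(theta, frame.mask.shape[1:] if kind == "dense"
                                  else frame.mask.shape[1:])
        # spiking occurrences
        n_spk = frame.mask.sum(axis=0)
        total += float((n_spk * (T_r + 0.5 * C * th_full ** 2)).sum())
        # silent occurrences: potential reached by t_max
        v_tmax = frame.v_tmin + layer.B * delta
        v_tmax = np.minimum(v_tmax, th_full)
        silent = ~frame.mask
        total += float(0.5 * C * ((v_tmax ** 2) * silent).sum())
        th_sq_sum += float((th_full ** 2).sum())
        n_neurons += th_full.size
        n_sil = silent.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_v2 = np.where(n_sil > 0, (v_tmax ** 2 * silent).sum(axis=0)
                               / np.maximum(n_sil, 1), np.nan)
            r_i = mean_v2 / th_full ** 2
        r_vals.append(r_i[np.isfinite(r_i)])
    r_all = np.concatenate(r_vals) if r_vals else np.array([])
    return EnergyReport(
        total_energy=total / batch,
        spikes_per_neuron=spike_sparsity(result),
        theta_sq=th_sq_sum / n_neurons if n_neurons else 0.0,
        r_fraction=float(np.clip(r_all.mean(), 0.0, 1.0)) if r_all.size else 0.0,
    )
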