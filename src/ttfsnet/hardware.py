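"""Hardware imperfections for evaluation and fine-tuning.

Four independent device constraints are modelled:

i.   **Spike-time jitter** -- Gaussian noise added to every spiking time
     of the encoded input and of each layer's output.
ii.  **Time quantization** -- spike times snapped to a uniform grid of
     ``n_steps`` points over the (frozen) layer window; early spikes are
     treated as if they occurred at ``t_min``.
iii. **Weight quantization** -- weights clipped to a percentile range
     ([1st, 99th], or [4th, 96th] for 4-bit) and represented on the
     signed integer range ``[-2^(q-1), 2^(q-1)-1]``; fine-tuning keeps
     full-precision shadow weights and passes gradients straight through
     the (frozen-grid) quantizer.
iv.  **Latency reduction** -- layer windows shrunk to a percentile of
     the ReLU twin's activations; spikes that then occur before a window
     opens are blocked until it does, which in the ReLU picture is
     activation clipping at the window length.

Every constraint at its neutral setting is an exact no-op, so the
unconstrained forward pass is reproduced bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import forward
from .mapping import base_thresholds, compute_windows, reverse_map
from .network_model import SpikeFrame, TTFSNetwork, WindowSchedule
from .training import TrainConfig, train, _get_xy, _last_spiking_index

__all__ = [
    "ConstraintSpec",
    "apply_jitter",
    "quantize_times",
    "quantize_weights",
    "reduce_latency",
    "make_weight_transform",
    "make_frame_hook",
    "evaluate_constrained",
    "finetune_constrained",
]

LATENCY_PERCENTILES = (100, 99, 95, 92, 90)


@dataclass
class ConstraintSpec:
    """Which device constraints are enabled.

    Neutral values (``jitter_sd=0``, ``time_steps=0``, ``weight_bits=0``,
    ``latency_percentile=None``) disable the corresponding constraint
    exactly.  ``eval_draws`` controls how many jitter draws an accuracy
    evaluation averages over.
    """

    jitter_sd: float = 0.0
    time_steps: int = 0
    weight_bits: int = 0
    latency_percentile: Optional[int] = None
    rng_seed: int = 0
    jitter_flip: bool = False
    eval_draws: int = 1

    def __post_init__(self):
        if self.jitter_sd < 0 or self.time_steps < 0 or self.weight_bits < 0:
            raise ValueError("constraint magnitudes must be non-negative")
        if (self.latency_percentile is not None
                and self.latency_percentile not in LATENCY_PERCENTILES):
            raise ValueError(
                f"latency percentile must be one of {LATENCY_PERCENTILES}")

    @property
    def any_enabled(self) -> bool:
        return bool(self.jitter_sd or self.time_steps or self.weight_bits
                    or self.latency_percentile is not None)


# ---------------------------------------------------------------------------
# (i) jitter
# ---------------------------------------------------------------------------

def apply_jitter(frame: SpikeFrame, sd: float,
                 rng: np.random.Generator, flip: bool = False) -> SpikeFrame:
    """Add Gaussian noise to the spiking times of a frame.

    Silent neurons keep their sentinel.  By default jittered times are
    clipped back into ``[t_min, t_max)`` so the spiked mask is unchanged;
    with ``flip`` a time pushed past ``t_max`` silences the neuron (a
    harsher device model).
    """
    if sd == 0:
        return frame
    out = frame.copy()
    noise = rng.normal(0.0, sd, size=frame.times.shape)
    t = frame.times + noise * frame.mask
    hi = np.nextafter(frame.t_max, -np.inf)
    if flip:
        late = frame.mask & (t >= frame.t_max)
        out.mask = frame.mask & ~late
        t = np.where(late, frame.t_max, t)
        out.times = np.where(out.mask, np.clip(t, frame.t_min, hi),
                             frame.t_max)
    else:
        out.times = np.where(frame.mask, np.clip(t, frame.t_min, hi),
                             frame.times)
    return out


# ---------------------------------------------------------------------------
# (ii) time quantization
# ---------------------------------------------------------------------------

def quantize_times(frame: SpikeFrame, n_steps: int) -> SpikeFrame:
    """Snap spiking times to ``n_steps`` uniform grid points in the window.

    The grid is ``t_min + k * Delta / n_steps`` for ``k = 0..n_steps-1``;
    rounding is to the nearest point with ties to the earlier one (an
    earlier spike is a larger activation, conservative against silencing).
    Times before ``t_min`` are clamped to ``t_min`` first.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    out = frame.copy()
    step = (frame.t_max - frame.t_min) / n_steps
    t = np.maximum(frame.times, frame.t_min)
    q = (t - frame.t_min) / step
    k = np.floor(q + 0.5)
    tie = (q % 1.0) == 0.5
    k = np.where(tie, np.floor(q), k)
    k = np.clip(k, 0, n_steps - 1)
    out.times = np.where(frame.mask, frame.t_min + k * step, frame.times)
    return out


# ---------------------------------------------------------------------------
# (iii) weight quantization
# ---------------------------------------------------------------------------

def quantize_weights(W: np.ndarray, bits: int, clip_percentiles=None):
    """Uniformly quantize weights onto the signed ``bits``-bit range.

    Outliers are removed first: the [1st, 99th] percentile range is kept,
    tightened to [4th, 96th] at 4 bits or fewer.  The clipped range is
    divided into ``2**bits`` levels mapped to integers in
    ``[-2**(bits-1), 2**(bits-1) - 1]``.  Returns the dequantized array
    and the codebook ``{lo, hi, scale, bits, int_min, int_max, ints}``.
    """
    if bits < 2:
        raise ValueError("weight quantization needs at least 2 bits")
    if clip_percentiles is None:
        clip_percentiles = (4.0, 96.0) if bits <= 4 else (1.0, 99.0)
    lo, hi = np.percentile(W, clip_percentiles)
    n_levels = 2 ** bits
    int_min, int_max = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    if hi <= lo:
        warnings.warn("degenerate weight range: single-level codebook")
        codebook = {"lo": float(lo), "hi": float(lo), "scale": 0.0,
                    "bits": bits, "int_min": int_min, "int_max": int_max,
                    "ints": np.zeros(W.shape, dtype=int)}
        return np.full_like(W, lo), codebook
    scale = (hi - lo) / (n_levels - 1)
    ints = np.round((np.clip(W, lo, hi) - lo) / scale).astype(int) + int_min
    deq = lo + (ints - int_min) * scale
    codebook = {"lo": float(lo), "hi": float(hi), "scale": float(scale),
                "bits": bits, "int_min": int_min, "int_max": int_max,
                "ints": ints}
    return deq, codebook


def make_weight_transform(net: TTFSNetwork, bits: int, clip_percentiles=None):
    """Freeze per-layer quantization grids from the current weights and
    return the straight-through weight transform used during fine-tuning."""
    grids = {}
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        _, cb = quantize_weights(lay.W, bits, clip_percentiles)
        grids[k] = cb
    _, grids["out"] = quantize_weights(net.readout.W, bits, clip_percentiles)

    def transform(key, W):
        cb = grids[key]
        if cb["scale"] == 0.0:
            return np.full_like(W, cb["lo"])
        ints = np.round((np.clip(W, cb["lo"], cb["hi"]) - cb["lo"])
                        / cb["scale"]).astype(int)
        return cb["lo"] + ints * cb["scale"]

    transform.grids = grids
    return transform


# ---------------------------------------------------------------------------
# (iv) latency reduction
# ---------------------------------------------------------------------------

def reduce_latency(net: TTFSNetwork, data: np.ndarray,
                   percentile: int) -> WindowSchedule:
    """Shrink layer windows to a percentile of the ReLU twin's activations.

    The adaptive window rule must stay off afterwards.  Base thresholds
    are reset to ``B * Delta`` and the readout slope is rescaled so its
    bias image is unchanged; the resulting forward pass (with early
    arrivals blocked until the window opens) equals the ReLU twin with
    activations clipped at the window lengths.
    """
    if percentile not in LATENCY_PERCENTILES:
        raise ValueError(
            f"latency percentile must be one of {LATENCY_PERCENTILES}")
    relu = reverse_map(net)
    windows = compute_windows(relu, "percentile", data=data,
                              percentile=percentile,
                              origin=net.windows.origin)
    stage_N = net.stage_of_layer(_last_spiking_index(net))
    old_delta_N = net.windows.deltas[stage_N]
    net.windows = windows
    net.readout.A *= old_delta_N / windows.deltas[stage_N]
    base_thresholds(net)
    return windows


# ---------------------------------------------------------------------------
# Constrained forward / fine-tuning
# ---------------------------------------------------------------------------

def make_frame_hook(spec: ConstraintSpec, rng: np.random.Generator):
    """Forward-pass hook applying jitter then time quantization."""
    if not (spec.jitter_sd or spec.time_steps):
        return None

    def hook(frame, stage):
        if spec.jitter_sd:
            frame = apply_jitter(frame, spec.jitter_sd, rng,
                                 flip=spec.jitter_flip)
        if spec.time_steps:
            frame = quantize_times(frame, spec.time_steps)
        return frame

    return hook


def evaluate_constrained(net: TTFSNetwork, X, y, spec: ConstraintSpec,
                         rng: Optional[np.random.Generator] = None,
                         weight_transform=None) -> float:
    """Mean accuracy under the constraints (averaged over jitter draws)."""
    from .training import _transformed_net
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    if weight_transform is None and spec.weight_bits:
        weight_transform = make_weight_transform(net, spec.weight_bits)
    fnet = _transformed_net(net, weight_transform)
    draws = spec.eval_draws if spec.jitter_sd else 1
    accs = []
    for _ in range(draws):
        res = forward(fnet, X, y, frame_hook=make_frame_hook(spec, rng))
        accs.append(res.accuracy)
    return float(np.mean(accs))


def finetune_constrained(net: TTFSNetwork, data, config: TrainConfig,
                         constraints: ConstraintSpec):
    """Fine-tune a TTFS network with device constraints in the loop.

    Latency reduction and time quantization freeze the window schedule
    (the adaptive rule is disabled); weight quantization trains
    full-precision shadow weights through a frozen-grid straight-through
    quantizer.  Pre- and post-fine-tuning accuracies under the same
    constraints are recorded in ``history.meta``.  With no constraint
    enabled this is exactly :func:`ttfsnet.training.train`.
    """
    rng_c = np.random.default_rng(constraints.rng_seed)
    if constraints.latency_percentile is not None:
        X, _ = _get_xy(data, "train")
        reduce_latency(net, X, constraints.latency_percentile)
    elif constraints.time_steps:
        # discrete time steps use outlier-robust windows covering 99% of
        # the ReLU twin's firing times
        X, _ = _get_xy(data, "train")
        reduce_latency(net, X, 99)
    if constraints.time_steps or constraints.latency_percentile is not None:
        config = TrainConfig(**{**config.__dict__, "adaptive_windows": False})
    weight_transform = (make_weight_transform(net, constraints.weight_bits)
                        if constraints.weight_bits else None)
    Xt, yt = _get_xy(data, "test")
    pre = evaluate_constrained(net, Xt, yt, constraints,
                               np.random.default_rng(constraints.rng_seed),
                               weight_transform)
    net, history = train(net, data, config,
                         frame_hook=make_frame_hook(constraints, rng_c),
                         weight_transform=weight_transform)
    post = evaluate_constrained(net, Xt, yt, constraints,
                                np.random.default_rng(constraints.rng_seed),
                                weight_transform)
    history.meta["pre_accuracy"] = pre
    history.meta["post_accuracy"] = post
    return net, history
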