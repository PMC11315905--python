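"""Exact mappings between TTFS networks and ReLU networks.

The reverse mapping takes spiking parameters ``(W, B, theta)`` to ReLU
parameters

    w_ij = W_ij / B_i,      b_i = -theta_i / B_i + Delta^(n),

(window length ``Delta`` in units of ``tau_c``); the readout maps as
``w = W`` and ``b = Delta^(N) * A``.  Two forward mappings invert it:

* **B1 / identity** -- fix ``B = 1`` everywhere, then ``W = w`` and, with
  the base-threshold convention ``theta_base = B * Delta``, the trainable
  offset ``D`` equals the ReLU bias ``b`` exactly.
* **alpha1** -- tie the slope to the weights, ``B_i = 1 + sum_k W_ik``;
  inverting gives ``B_i = 1 / (1 - sum_j w_ij)`` and ``W = w * B``, which
  requires every row sum of ``w`` to stay below 1.  ReLU units are
  invariant under rescaling incoming weights/bias by ``lambda`` and
  outgoing weights by ``1/lambda``, so layers are rescaled (factors
  recorded, hence invertible) until the row sums fit.

Window construction lives here too: the *bound* mode picks window lengths
large enough that (a) no neuron can cross threshold before its window
opens and (b) every unit active in the ReLU twin spikes inside its
window, for every input in ``[0, 1]^D``; the *percentile* mode sizes each
window to cover a chosen percentile of the layer's empirical ReLU
activations (used for latency reduction and time quantization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network_model import (
    MIN_DELTA, ReLULayer, ReLUNetwork, TTFSLayer, TTFSNetwork, WindowSchedule,
)

__all__ = [
    "MappingSpec",
    "reverse_map",
    "forward_map_identity",
    "forward_map_alpha1",
    "compute_windows",
    "base_thresholds",
    "fuse_batchnorm",
    "rescale_for_alpha1",
    "undo_layer_rescale",
]


@dataclass
class MappingSpec:
    """Mapping family and safety factors.

    ``margin`` is the row-sum headroom of the alpha1 mapping (row sums are
    rescaled to at most ``1 - margin``); ``alpha`` is the auxiliary slope,
    fixed at 1 for the alpha1 family.
    """

    model: str = "B1"
    margin: float = 0.1
    alpha: float = 1.0

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def _row_pos_sum(w, kind):
    """Sum of positive incoming weights per output unit (channel for conv)."""
    wp = np.maximum(w, 0.0)
    if kind == "dense":
        return wp.sum(axis=1)
    return wp.sum(axis=(0, 1, 2))


def _row_sum(w, kind):
    if kind == "dense":
        return w.sum(axis=1)
    return w.sum(axis=(0, 1, 2))


# ---------------------------------------------------------------------------
# Reverse mapping (TTFS -> ReLU)
# ---------------------------------------------------------------------------

def reverse_map(net: TTFSNetwork) -> ReLUNetwork:
    """Exact ReLU twin of a TTFS network (same architecture)."""
    layers = []
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            layers.append(ReLULayer(kind="maxpool", in_shape=lay.in_shape,
                                    out_shape=lay.out_shape, pool=lay.pool,
                                    stride=lay.stride))
            continue
        if np.any(lay.B <= 0):
            raise ValueError(f"layer {k}: B must be positive for the reverse map")
        delta = net.windows.deltas[net.stage_of_layer(k)]
        if lay.kind == "dense":
            w = lay.W / lay.B[:, None]
        else:
            w = lay.W / lay.B  # per output channel, broadcast on last axis
        b = -lay.theta / lay.B + delta
        layers.append(ReLULayer(kind=lay.kind, w=w, b=b, in_shape=lay.in_shape,
                                out_shape=lay.out_shape, padding=lay.padding))
    delta_N = net.windows.deltas[-1]
    readout = ReLULayer(kind="dense", w=net.readout.W.copy(),
                        b=delta_N * net.readout.A)
    return ReLUNetwork(layers, readout)


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def compute_windows(net: ReLUNetwork, mode: str = "bound",
                    data: np.ndarray = None, percentile: float = 99.0,
                    margin: float = 0.0, min_delta: float = 1e-6,
                    origin: float = 0.0) -> WindowSchedule:
    """Build per-layer window lengths for a ReLU network.

    bound mode
        ``Delta^(0) = 1`` (inputs live in [0, 1]) and recursively
        ``Delta^(n) = (1+margin) * max_i (max(b_i, 0) +
        sum_j max(w_ij, 0) * Delta^(n-1))``.  This is sufficient both for
        the no-early-spike guarantee and for every active ReLU unit to
        spike inside its window, since activations are bounded by the
        positive-drive worst case.
    percentile mode
        ``Delta^(n)`` is the ``percentile``-th percentile of layer-n
        activations on ``data`` (requires data); used to shrink latency
        at the price of activation clipping.
    """
    deltas = [1.0]
    if mode == "bound":
        cur = 1.0
        for lay in net.layers:
            if lay.kind == "maxpool":
                continue  # pooling relays spikes inside the same window
            cap = np.maximum(lay.b, 0.0) + _row_pos_sum(lay.w, lay.kind) * cur
            d = (1.0 + margin) * float(cap.max())
            if d < min_delta:
                warnings.warn("degenerate window clamped to min_delta")
                d = min_delta
            deltas.append(d)
            cur = d
    elif mode == "percentile":
        if data is None:
            raise ValueError("percentile mode needs representative samples")
        from .gradients import relu_forward
        acts, _ = relu_forward(net, data)
        for lay, a in zip([l for l in net.layers], acts[1:]):
            if lay.kind == "maxpool":
                continue
            pos = a[a > 0]  # windows cover firing times; silent units have none
            d = float(np.percentile(pos, percentile)) if pos.size else min_delta
            deltas.append(max(d, min_delta))
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return WindowSchedule(np.array(deltas), origin=origin)


def base_thresholds(net: TTFSNetwork, windows: WindowSchedule = None) -> list:
    """Set base thresholds ``theta_base = B * Delta`` and audit them.

    With this convention the trainable offset ``D`` maps to the ReLU bias
    as ``b = D / B`` (equality for B1) for any window length, so adaptive
    window growth never changes the ReLU twin.  Returns the list of
    violations of the no-early-spike sufficient condition
    ``theta_i >= sum_j max(W_ij, 0) * Delta^(n-1)``.
    """
    if windows is not None:
        net.windows = windows
    report = []
    prev_delta = net.windows.deltas[0]
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        delta = net.windows.deltas[net.stage_of_layer(k)]
        lay.theta_base = lay.B * delta
        worst = _row_pos_sum(lay.W, lay.kind) * prev_delta
        bad = lay.theta < worst - 1e-9 * (1.0 + np.abs(worst))
        if np.any(bad):
            report.append(
                f"layer {k}: {int(bad.sum())} neuron(s) may fire before t_min "
                f"(threshold below worst-case accumulated drive)")
        prev_delta = delta
    return report


# ---------------------------------------------------------------------------
# Forward mappings (ReLU -> TTFS)
# ---------------------------------------------------------------------------

def _ttfs_layer_from(lay: ReLULayer, W, B, D) -> TTFSLayer:
    return TTFSLayer(kind=lay.kind, W=W, B=B, theta_base=np.zeros_like(B),
                     D=D, A=np.zeros_like(B), in_shape=lay.in_shape,
                     out_shape=lay.out_shape, padding=lay.padding)


def _pool_layer_from(lay: ReLULayer) -> TTFSLayer:
    return TTFSLayer(kind="maxpool", in_shape=lay.in_shape,
                     out_shape=lay.out_shape, pool=lay.pool, stride=lay.stride)


def forward_map_identity(net: ReLUNetwork, windows: WindowSchedule = None,
                         tau_c: float = 1.0, window_margin: float = 0.0,
                         strict: bool = True) -> TTFSNetwork:
    """Map a ReLU network to its B1 (identity) TTFS twin: ``W = w``,
    ``B = 1``, ``theta = Delta - b``.

    Windows default to bound mode.  With ``strict`` the construction is
    refused if the no-early-spike condition fails for the given windows.
    """
    if windows is None:
        windows = compute_windows(net, "bound", margin=window_margin)
    layers = []
    for lay in net.layers:
        if lay.kind == "maxpool":
            layers.append(_pool_layer_from(lay))
            continue
        n_out = lay.b.shape[0]
        layers.append(_ttfs_layer_from(lay, lay.w.copy(), np.ones(n_out),
                                       lay.b.copy()))
    delta_N = windows.deltas[-1]
    readout = TTFSLayer(kind="dense", W=net.readout.w.copy(),
                        A=net.readout.b / delta_N,
                        B=np.ones_like(net.readout.b))
    snn = TTFSNetwork(layers=layers, readout=readout, tau_c=tau_c,
                      windows=windows, model="B1")
    report = base_thresholds(snn)
    if report and strict:
        raise ValueError("windows too small for a valid base threshold: "
                         + "; ".join(report))
    return snn


def rescale_for_alpha1(net: ReLUNetwork, margin: float = 0.1):
    """Rescale layers so every signed row sum is at most ``1 - margin``.

    Uses the intrinsic scaling symmetry of ReLU units: incoming weights
    and bias of a layer are multiplied by ``lambda <= 1`` and the next
    layer's incoming weights by ``1/lambda`` (max pooling is positively
    homogeneous, so the factor passes through).  Returns the rescaled
    network and the per-parametric-layer factors.
    """
    if margin >= 1.0:
        raise ValueError("margin must be below 1")
    out = net.copy()
    scales = []
    carry = 1.0
    for lay in out.layers:
        if lay.kind == "maxpool":
            continue
        lay.w = lay.w / carry
        s_max = float(_row_sum(lay.w, lay.kind).max())
        lam = min(1.0, (1.0 - margin) / s_max) if s_max > 1.0 - margin else 1.0
        lay.w = lam * lay.w
        lay.b = lam * lay.b
        scales.append(lam)
        carry = lam
    out.readout.w = out.readout.w / carry
    return out, scales


def undo_layer_rescale(net: ReLUNetwork, scales: list) -> ReLUNetwork:
    """Invert :func:`rescale_for_alpha1` given its recorded factors."""
    out = net.copy()
    carry = 1.0
    it = iter(scales)
    for lay in out.layers:
        if lay.kind == "maxpool":
            continue
        lam = next(it)
        lay.w = lay.w * (carry / lam)
        lay.b = lay.b / lam
        carry = lam
    out.readout.w = out.readout.w * carry
    return out


def forward_map_alpha1(net: ReLUNetwork, tau_c: float = 1.0,
                       margin: float = 0.1, window_margin: float = 0.0,
                       windows: WindowSchedule = None) -> TTFSNetwork:
    """Map a ReLU network to the alpha1 TTFS family.

    After the row-sum rescale, ``B_i = 1 / (1 - sum_j w_ij)`` and
    ``W = w * B``; the reverse map recovers the rescaled network exactly
    (the rescale factors are recorded in ``meta['layer_scales']``).
    """
    scaled, scales = rescale_for_alpha1(net, margin=margin)
    if windows is None:
        windows = compute_windows(scaled, "bound", margin=window_margin)
    layers = []
    for lay in scaled.layers:
        if lay.kind == "maxpool":
            layers.append(_pool_layer_from(lay))
            continue
        s = _row_sum(lay.w, lay.kind)
        if np.any(s >= 1.0):
            raise ValueError("row sum >= 1 after maximal allowed rescale")
        B = 1.0 / (1.0 - s)
        W = lay.w * B[:, None] if lay.kind == "dense" else lay.w * B
        layers.append(_ttfs_layer_from(lay, W, B, B * lay.b))
    delta_N = windows.deltas[-1]
    readout = TTFSLayer(kind="dense", W=scaled.readout.w.copy(),
                        A=scaled.readout.b / delta_N,
                        B=np.ones_like(scaled.readout.b))
    snn = TTFSNetwork(layers=layers, readout=readout, tau_c=tau_c,
                      windows=windows, model="alpha1",
                      meta={"layer_scales": scales, "margin": margin})
    base_thresholds(snn)
    return snn


# ---------------------------------------------------------------------------
# Batch-norm fusion
# ---------------------------------------------------------------------------

def fuse_batchnorm(net: ReLUNetwork) -> ReLUNetwork:
    """Fold attached batch-norm statistics into dense/conv parameters.

    For ``y = gamma * (z - mean)/sqrt(var + eps) + beta`` applied to the
    pre-activation ``z = w x + b``, the fused layer is
    ``w' = w * s``, ``b' = (b - mean) * s + beta`` with
    ``s = gamma / sqrt(var + eps)``.
    """
    out = net.copy()
    for k, lay in enumerate(out.layers):
        if lay.bn is None:
            continue
        bn = lay.bn
        var = np.asarray(bn["var"], dtype=float)
        if np.any(var <= 0):
            raise ValueError(f"layer {k}: batch-norm variance must be positive")
        s = np.asarray(bn["gamma"], dtype=float) / np.sqrt(var + bn.get("eps", 0.0))
        if lay.kind == "dense":
            lay.w = lay.w * s[:, None]
        else:
            lay.w = lay.w * s
        lay.b = (lay.b - np.asarray(bn["mean"], dtype=float)) * s \
            + np.asarray(bn["beta"], dtype=float)
        lay.bn = None
    return out
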