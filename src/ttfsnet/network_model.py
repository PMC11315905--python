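"""Network and time-window data model for TTFS spiking networks.

A time-to-first-spike (TTFS) network is a layered feed-forward spiking
network in which every hidden neuron fires at most once, and the value it
transmits is encoded in *when* it fires: an earlier spike means a larger
activation.  Each layer ``n`` owns a processing window ``[t_min^(n),
t_max^(n))`` and the windows tile the time axis recursively,
``t_min^(n+1) = t_max^(n)``.

Two network families live here:

* :class:`ReLUNetwork` -- an ordinary rectifier network with an affine
  (non-rectified) readout, used as the analytically equivalent twin of a
  TTFS network.
* :class:`TTFSNetwork` -- the spiking network proper, with weights ``W``,
  second-regime slopes ``B > 0``, base thresholds ``theta_base`` and
  trainable threshold offsets ``D`` (the effective threshold is
  ``theta_base - D``).  The readout layer is non-spiking and carries a
  trainable initial slope ``A``.

Windows are stored as per-layer lengths ``Delta^(n)`` in units of the
conversion constant ``tau_c``; absolute times are derived by a cumulative
sum, so the tiling recursion holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ReLULayer",
    "ReLUNetwork",
    "TTFSLayer",
    "TTFSNetwork",
    "WindowSchedule",
    "SpikeFrame",
    "validate",
]

#: Minimum admissible window length (in units of tau_c) for a spiking layer.
MIN_DELTA = 1e-9


# ---------------------------------------------------------------------------
# ReLU side
# ---------------------------------------------------------------------------

@dataclass
class ReLULayer:
    """One layer of a rectifier network.

    Parameters
    ----------
    kind:
        ``"dense"``, ``"conv"`` or ``"maxpool"``.
    w:
        Weight matrix ``(out, in)`` for dense layers, kernel tensor
        ``(kh, kw, cin, cout)`` for conv layers, ``None`` for maxpool.
    b:
        Bias vector ``(out,)`` for dense, ``(cout,)`` for conv.
    in_shape / out_shape:
        Spatial geometry ``(h, w, c)`` for conv/maxpool layers.
    pool / stride:
        Pooling window and stride (maxpool only).
    padding:
        ``"valid"`` or ``"same"`` (conv only).
    bn:
        Optional un-fused batch-norm statistics
        ``{"mean", "var", "gamma", "beta", "eps"}`` attached to a
        dense/conv layer; see :func:`ttfsnet.mapping.fuse_batchnorm`.
    """

    kind: str
    w: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None
    in_shape: Optional[tuple] = None
    out_shape: Optional[tuple] = None
    pool: int = 2
    stride: int = 2
    padding: str = "valid"
    bn: Optional[dict] = None

    def copy(self) -> "ReLULayer":
        return ReLULayer(
            kind=self.kind,
            w=None if self.w is None else np.array(self.w, dtype=float),
            b=None if self.b is None else np.array(self.b, dtype=float),
            in_shape=self.in_shape,
            out_shape=self.out_shape,
            pool=self.pool,
            stride=self.stride,
            padding=self.padding,
            bn=None if self.bn is None else dict(self.bn),
        )

    @property
    def n_out(self) -> int:
        if self.kind == "dense":
            return self.w.shape[0]
        if self.kind == "conv":
            return int(np.prod(self.out_shape))
        return int(np.prod(self.out_shape))


@dataclass
class ReLUNetwork:
    """Feed-forward rectifier network with an affine readout (logits)."""

    layers: list
    readout: ReLULayer

    def copy(self) -> "ReLUNetwork":
        return ReLUNetwork([l.copy() for l in self.layers], self.readout.copy())

    @property
    def hidden_kinds(self) -> list:
        return [l.kind for l in self.layers]


# ---------------------------------------------------------------------------
# Spiking side
# ---------------------------------------------------------------------------

@dataclass
class TTFSLayer:
    """One layer of a TTFS network.

    ``W`` mirrors the ReLU weight container (matrix or kernel).  ``B`` is
    the strictly positive slope of the membrane potential inside the
    layer's own window; ``theta_base`` is the fixed base threshold chosen
    so that no neuron can fire before the window opens, and ``D`` is the
    trainable offset: the effective threshold is ``theta_base - D``.
    ``A`` is the initial slope, fixed at 0 for hidden layers; only the
    non-spiking readout layer carries a trainable ``A``.
    """

    kind: str
    W: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    theta_base: Optional[np.ndarray] = None
    D: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    in_shape: Optional[tuple] = None
    out_shape: Optional[tuple] = None
    pool: int = 2
    stride: int = 2
    padding: str = "valid"

    def copy(self) -> "TTFSLayer":
        arr = lambda a: None if a is None else np.array(a, dtype=float)
        return TTFSLayer(
            kind=self.kind, W=arr(self.W), B=arr(self.B),
            theta_base=arr(self.theta_base), D=arr(self.D), A=arr(self.A),
            in_shape=self.in_shape, out_shape=self.out_shape,
            pool=self.pool, stride=self.stride, padding=self.padding,
        )

    @property
    def theta(self) -> np.ndarray:
        """Effective threshold ``theta_base - D``."""
        return self.theta_base - self.D


@dataclass
class WindowSchedule:
    """Per-layer processing intervals stored as lengths.

    ``deltas[0]`` is the input-encoding window; ``deltas[k]`` for
    ``k >= 1`` is the window of the k-th *spiking* stage (dense/conv
    hidden layer).  Maxpool layers do not own a window: they relay spikes
    inside the window of the layer they pool.  Absolute boundary times are
    ``origin + tau_c * cumsum(deltas)`` and therefore satisfy
    ``t_min^(n+1) == t_max^(n)`` exactly.
    """

    deltas: np.ndarray
    origin: float = 0.0

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=float)

    def copy(self) -> "WindowSchedule":
        return WindowSchedule(self.deltas.copy(), self.origin)

    def edges(self, tau_c: float = 1.0) -> np.ndarray:
        """Absolute window boundaries ``t_0 .. t_K`` (length K+1)."""
        return self.origin + tau_c * np.concatenate(([0.0], np.cumsum(self.deltas)))

    def bounds(self, stage: int, tau_c: float = 1.0) -> tuple:
        """``(t_min, t_max)`` of a stage (0 = input encoding)."""
        e = self.edges(tau_c)
        return float(e[stage]), float(e[stage + 1])


@dataclass
class TTFSNetwork:
    """TTFS network: spiking hidden layers plus a non-spiking readout.

    ``model`` records the parameter family: ``"B1"`` (all slopes B = 1,
    the identity mapping to the ReLU twin) or ``"alpha1"``
    (``B_i = 1 + sum_k W_ik``).  ``meta`` carries bookkeeping such as the
    per-layer rescale factors applied by the alpha1 forward mapping.
    """

    layers: list
    readout: TTFSLayer
    tau_c: float
    windows: WindowSchedule
    model: str = "B1"
    meta: dict = field(default_factory=dict)

    def copy(self) -> "TTFSNetwork":
        return TTFSNetwork(
            [l.copy() for l in self.layers], self.readout.copy(),
            self.tau_c, self.windows.copy(), self.model, dict(self.meta),
        )

    def stage_of_layer(self, idx: int) -> int:
        """Window stage owned by hidden layer ``idx`` (maxpool layers
        share the stage of the spiking layer they pool)."""
        stage = 0
        for k in range(idx + 1):
            if self.layers[k].kind != "maxpool":
                stage += 1
        return stage

    def layer_bounds(self, idx: int) -> tuple:
        """Absolute ``(t_min, t_max)`` of hidden layer ``idx``."""
        return self.windows.bounds(self.stage_of_layer(idx), self.tau_c)

    def input_bounds(self) -> tuple:
        return self.windows.bounds(0, self.tau_c)

    @property
    def n_stages(self) -> int:
        return 1 + sum(1 for l in self.layers if l.kind != "maxpool")


@dataclass
class SpikeFrame:
    """Spike times and spiked/silent mask of one layer on a batch.

    ``times`` has shape ``(batch, ...)``; silent neurons carry the
    sentinel time ``t_max`` and mask 0 so that the decoded activation
    ``(t_max - t) / tau_c`` is uniformly zero for them.  Masked-in times
    lie in ``[t_min, t_max)`` during nominal operation; in
    reduced-latency mode candidate times may precede ``t_min`` and are
    clamped at the point of consumption.  ``v_tmin`` optionally records
    the membrane potential at window opening (used by the energy model).
    """

    times: np.ndarray
    mask: np.ndarray
    t_min: float
    t_max: float
    v_tmin: Optional[np.ndarray] = None

    def copy(self) -> "SpikeFrame":
        return SpikeFrame(
            self.times.copy(), self.mask.copy(), self.t_min, self.t_max,
            None if self.v_tmin is None else self.v_tmin.copy(),
        )

    def decoded(self, tau_c: float, clip_early: bool = True) -> np.ndarray:
        """Activation-space view ``x = (t_max - t)/tau_c`` (zero when silent).

        With ``clip_early`` (the default) times earlier than ``t_min``
        count as if they occurred at ``t_min``, which caps the decoded
        value at the window length."""
        t = np.maximum(self.times, self.t_min) if clip_early else self.times
        return (self.t_max - t) / tau_c


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _chain_shapes(layers, readout) -> list:
    report = []
    n_prev = None
    for k, lay in enumerate(layers):
        wk = lay.W if hasattr(lay, "W") else lay.w
        if lay.kind == "dense":
            if wk is None or wk.ndim != 2:
                report.append(f"layer {k}: dense layer needs a 2-d weight matrix")
                continue
            if n_prev is not None and wk.shape[1] != n_prev:
                report.append(
                    f"layer {k}: input size {wk.shape[1]} != previous output {n_prev}"
                )
            n_prev = wk.shape[0]
        elif lay.kind == "conv":
            if wk is None or wk.ndim != 4:
                report.append(f"layer {k}: conv layer needs a 4-d kernel")
                continue
            n_prev = int(np.prod(lay.out_shape)) if lay.out_shape else None
        elif lay.kind == "maxpool":
            if wk is not None:
                report.append(f"layer {k}: maxpool layers carry no parameters")
            n_prev = int(np.prod(lay.out_shape)) if lay.out_shape else None
        else:
            report.append(f"layer {k}: unknown kind {lay.kind!r}")
    wr = readout.W if hasattr(readout, "W") else readout.w
    if wr is not None and n_prev is not None and wr.shape[1] != n_prev:
        report.append(
            f"readout: input size {wr.shape[1]} != last hidden output {n_prev}"
        )
    return report


def validate(net) -> list:
    """Return the list of violated structural invariants (empty if valid).

    Accepts either network family.  This is a reporting operation: it
    never raises on an invalid network.
    """
    report = []
    if isinstance(net, ReLUNetwork):
        report += _chain_shapes(net.layers, net.readout)
        if net.readout.kind != "dense":
            report.append("readout must be an affine dense layer")
        return report

    if not isinstance(net, TTFSNetwork):
        return [f"unsupported network type {type(net).__name__}"]

    report += _chain_shapes(net.layers, net.readout)
    if not np.isfinite(net.tau_c) or net.tau_c <= 0:
        report.append(f"tau_c must be positive, got {net.tau_c}")
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        if lay.B is None or np.any(lay.B <= 0):
            report.append(f"layer {k}: B must be positive")
        if lay.A is not None and np.any(lay.A != 0):
            report.append(f"layer {k}: hidden layers must have A = 0")
        for name in ("theta_base", "D"):
            a = getattr(lay, name)
            if a is None or not np.all(np.isfinite(a)):
                report.append(f"layer {k}: {name} must be finite")
        if lay.theta_base is not None and lay.D is not None:
            if not np.all(np.isfinite(lay.theta)):
                report.append(f"layer {k}: effective threshold not finite")

    d = net.windows.deltas
    if len(d) != net.n_stages:
        report.append(
            f"window schedule has {len(d)} stages, network needs {net.n_stages}"
        )
    if np.any(d < 0):
        bad = np.nonzero(d < 0)[0]
        report.append(f"negative window length at stage(s) {bad.tolist()}")
    if np.any((d >= 0) & (d < MIN_DELTA)):
        bad = np.nonzero((d >= 0) & (d < MIN_DELTA))[0]
        report.append(f"zero-length window at spiking stage(s) {bad.tolist()}")
    if net.model not in ("B1", "alpha1"):
        report.append(f"unknown model tag {net.model!r}")
    return report
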