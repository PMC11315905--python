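"""Exact spike-time backpropagation and gradient-stability diagnostics.

The loss gradient factorizes through the spike-time vectors: with the
closed-form spike time

    t_i^(n) = t_min^(n) + tau_c * (theta_i - V_i(t_min)) / B_i,

the layer Jacobian is ``dt^(n)/dt^(n-1) = M . (1/B) . W`` where ``M`` is
the binary spiked mask (silent neurons carry a constant sentinel time, so
their rows and columns vanish), and the parameter derivatives are
``dt_i/dW_ij = -(t_min^(n) - t_j^(n-1))/B_i`` and
``dt_i/dD_i = -tau_c/B_i``.  For the B1 family these gradients coincide
elementwise with the backpropagation gradients of the equivalent ReLU
network, which is implemented here independently as the reference oracle
(:func:`relu_oracle`).

The spectrum of ``(1/B) W`` per layer diagnoses vanishing/exploding
gradients: under the standard ``N(0,1)/sqrt(fan_in)`` initialization the
B1 Jacobian spectral radius sits near the circular-law edge 1, while
tying ``B = 1 + sum_k W_ik`` (alpha1) spreads eigenvalues far outside the
unit circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _convops as cv
from .dynamics import ForwardResult, softmax_cross_entropy
from .network_model import ReLUNetwork, TTFSLayer, TTFSNetwork

__all__ = [
    "GradientSet",
    "SpectrumReport",
    "spike_time_jacobian",
    "backprop",
    "relu_forward",
    "relu_oracle",
    "update_delta",
    "alpha1_pair_factor",
    "jacobian_spectrum",
]


@dataclass
class GradientSet:
    """Loss gradients w.r.t. TTFS parameters, keyed by hidden-layer index."""

    dW: dict
    dD: dict
    dW_out: np.ndarray
    dA_out: np.ndarray
    loss: float

    def finite(self) -> bool:
        arrs = [*self.dW.values(), *self.dD.values(), self.dW_out, self.dA_out]
        return all(np.all(np.isfinite(a)) for a in arrs)


@dataclass
class SpectrumReport:
    """Per-layer Jacobian spectra and a gradient-norm depth profile."""

    eigenvalues: list
    spectral_radius: np.ndarray
    grad_norms: np.ndarray          # index 0 = deepest (first) hidden layer
    used_singular: bool = False
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def spike_time_jacobian(layer: TTFSLayer, pre_mask: np.ndarray,
                        post_mask: np.ndarray) -> np.ndarray:
    """``dt^(n)/dt^(n-1)`` for one dense layer and one sample.

    Both masks are applied: silent postsynaptic neurons have constant
    (sentinel) times -> zero rows; silent presynaptic neurons contribute
    no step current -> zero columns.  This is the literal derivative of
    the closed-form spike time and matches the chained ReLU product.
    """
    if np.any(layer.B <= 0):
        raise ValueError("B must be positive")
    J = layer.W / layer.B[:, None]
    return J * post_mask[:, None].astype(float) * pre_mask[None, :].astype(float)


# ---------------------------------------------------------------------------
# TTFS backpropagation
# ---------------------------------------------------------------------------

def backprop(net: TTFSNetwork, result: ForwardResult,
             labels: Optional[np.ndarray] = None,
             l1_weight: float = 0.0, include_ce: bool = True) -> GradientSet:
    """Exact gradients of the softmax cross-entropy w.r.t. W, D, A^(N+1).

    Windows and base thresholds are held fixed (they are hyperparameters
    at gradient equilibrium).  ``l1_weight`` adds the subgradient of an
    L1 penalty on the decoded activations of spiking hidden neurons
    (mean over samples), the spiking-sparsity regularizer.
    """
    batch = result.logits.shape[0]
    if include_ce:
        y = result.labels if labels is None else np.asarray(labels, dtype=int)
        if y is None:
            raise ValueError("labels are required for backprop")
        if result.probs is None:
            loss, probs = softmax_cross_entropy(result.logits, y)
        else:
            loss, probs = result.loss, result.probs
        onehot = np.zeros_like(probs)
        onehot[np.arange(batch), y] = 1.0
        dV = (probs - onehot) / batch
    else:  # penalty-only backward pass
        loss = result.loss if result.loss is not None else 0.0
        dV = np.zeros_like(result.logits)

    tau_c = net.tau_c
    frameN = result.frames[-1]
    delta_N = (frameN.t_max - frameN.t_min) / tau_c
    xN = frameN.decoded(tau_c).reshape(batch, -1)
    dW_out = dV.T @ xN
    dA_out = delta_N * dV.sum(axis=0)

    # dL/dt of the last hidden frame; clamped (early) times are constants
    active = frameN.mask & (frameN.times >= frameN.t_min)
    g_t = -(dV @ net.readout.W) / tau_c
    g_t = (g_t.reshape(frameN.times.shape)) * active

    # L1 penalty is the mean decoded activation over samples and hidden
    # spiking neurons
    n_hidden = sum(f.mask[0].size for f, kind in
                   zip(result.frames[1:], result.kinds[1:])
                   if kind in ("dense", "conv"))
    l1_seed = l1_weight / (batch * n_hidden) if l1_weight else 0.0

    dW, dD = {}, {}
    for k in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[k]
        frame = result.frames[k + 1]
        prev = result.frames[k]
        if layer.kind == "maxpool":
            g_prev = cv.pool_scatter(g_t, frame.argmin, prev.times.shape[1:],
                                     layer.pool, layer.stride)
            g_t = g_prev
            continue
        if l1_weight:
            act = frame.mask & (frame.times >= frame.t_min)
            g_t = g_t + l1_seed * (-1.0 / tau_c) * act
        # dL/dV(t_min): dt/dV = -tau_c/B for spiking neurons
        gV = g_t * frame.mask * (-tau_c / layer.B)
        x_prev = prev.decoded(tau_c)
        if layer.kind == "dense":
            gVf = gV.reshape(batch, -1)
            dW[k] = gVf.T @ x_prev.reshape(batch, -1)
            dD[k] = gVf.sum(axis=0)
            g_x = (gVf @ layer.W).reshape(prev.times.shape)
        else:
            gk, g_x = cv.conv_backward(gV, result.patches[k], layer.W,
                                       prev.times.shape[1:], layer.padding)
            dW[k] = gk
            dD[k] = gV.sum(axis=(0, 1, 2))
        active_prev = prev.mask & (prev.times >= prev.t_min)
        g_t = g_x * (-1.0 / tau_c) * active_prev

    return GradientSet(dW=dW, dD=dD, dW_out=dW_out, dA_out=dA_out, loss=loss)


# ---------------------------------------------------------------------------
# ReLU reference network
# ---------------------------------------------------------------------------

def relu_forward(net: ReLUNetwork, X: np.ndarray, clip=None):
    """Forward pass of the rectifier network.

    Returns ``(activations, caches)``; ``activations[0]`` is the input
    and ``activations[-1]`` the logits.  ``clip`` optionally caps each
    spiking stage's activations (a window-schedule ``deltas`` array),
    which is the ReLU-space picture of latency-reduced TTFS inference.
    """
    X = np.asarray(X, dtype=float)
    acts = [X]
    caches = {"clipped": {}}
    x = X
    stage = 0
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            win = cv.pool_view(x, lay.pool, lay.stride)
            sel = np.argmax(win, axis=3)
            x = np.take_along_axis(win, sel[:, :, :, None, :], axis=3)[:, :, :, 0, :]
            caches[k] = sel
        elif lay.kind == "dense":
            z = x.reshape(x.shape[0], -1) @ lay.w.T + lay.b
            x = np.maximum(z, 0.0)
            stage += 1
        else:
            z, patches = cv.conv_forward(x, lay.w, lay.padding)
            z = z + lay.b
            x = np.maximum(z, 0.0)
            caches[k] = patches
            stage += 1
        if clip is not None and lay.kind != "maxpool":
            cap = clip[stage]
            caches["clipped"][k] = x > cap
            x = np.minimum(x, cap)
        acts.append(x)
    logits = x.reshape(x.shape[0], -1) @ net.readout.w.T + net.readout.b
    acts.append(logits)
    return acts, caches


def relu_oracle(net: ReLUNetwork, X: np.ndarray, labels: np.ndarray,
                l1_weight: float = 0.0, clip=None):
    """Reference forward/backward pass for the equivalent ReLU network.

    Returns ``(activations, logits, loss, grads)`` where ``grads`` has
    ``dw``/``db`` dicts keyed by hidden-layer index plus ``dw_out`` and
    ``db_out``.  ``l1_weight`` mirrors the activation-L1 penalty of the
    spiking trainer; ``clip`` mirrors latency-limited windows.
    """
    y = np.asarray(labels, dtype=int)
    acts, caches = relu_forward(net, X, clip=clip)
    logits = acts[-1]
    loss, probs = softmax_cross_entropy(logits, y)
    batch = logits.shape[0]
    onehot = np.zeros_like(probs)
    onehot[np.arange(batch), y] = 1.0
    dlogits = (probs - onehot) / batch

    xN = acts[-2].reshape(batch, -1)
    grads = {"dw": {}, "db": {},
             "dw_out": dlogits.T @ xN, "db_out": dlogits.sum(axis=0)}
    n_hidden = sum(acts[k + 1][0].size for k, lay in enumerate(net.layers)
                   if lay.kind != "maxpool")
    l1_seed = l1_weight / (batch * n_hidden) if l1_weight else 0.0
    g = (dlogits @ net.readout.w).reshape(acts[-2].shape)
    for k in range(len(net.layers) - 1, -1, -1):
        lay = net.layers[k]
        x_out, x_in = acts[k + 1], acts[k]
        if lay.kind == "maxpool":
            g = cv.pool_scatter(g, caches[k], x_in.shape[1:], lay.pool, lay.stride)
            continue
        mask = (x_out > 0)
        if k in caches["clipped"]:
            mask = mask & ~caches["clipped"][k]
        g = g * mask
        if l1_weight:
            g = g + l1_seed * mask
        if lay.kind == "dense":
            gf = g.reshape(batch, -1)
            grads["dw"][k] = gf.T @ x_in.reshape(batch, -1)
            grads["db"][k] = gf.sum(axis=0)
            g = (gf @ lay.w).reshape(x_in.shape)
        else:
            grads["db"][k] = g.sum(axis=(0, 1, 2))
            gk, g = cv.conv_backward(g, caches[k], lay.w, x_in.shape[1:],
                                     lay.padding)
            grads["dw"][k] = gk
    return acts, logits, loss, grads


# ---------------------------------------------------------------------------
# Update equivalence (ReLU-space image of a TTFS gradient step)
# ---------------------------------------------------------------------------

def alpha1_pair_factor(layer: TTFSLayer) -> np.ndarray:
    """Per-pair multiplicative bias ``dM/dW_ij = (B_i - W_ij)/B_i^2`` of
    the tied alpha1 map (the diagonal term of its linearization)."""
    B = layer.B[:, None]
    return (B - layer.W) / B ** 2


def update_delta(net: TTFSNetwork, grads: GradientSet, eta: float,
                 model: Optional[str] = None) -> dict:
    """Predict the ReLU-space weight update ``delta w`` caused by the
    spiking gradient step ``Delta W = -eta * dL/dW``.

    B1: the identity -- ``delta w = -eta * dL/dW`` exactly.  alpha1: the
    first-order image under the tied map
    ``M(W)_ij = W_ij / (1 + sum_k W_ik)``, whose linearization is
    ``delta w_ij = dW_ij/B_i - W_ij * (sum_k dW_ik)/B_i^2`` applied to
    ``Delta W`` (the per-pair factor ``(B_i - W_ij)/B_i^2`` is its
    diagonal part).
    """
    model = net.model if model is None else model
    out = {}
    for k, g in grads.dW.items():
        dWk = -eta * g
        if model == "B1":
            out[k] = dWk
        elif model == "alpha1":
            layer = net.layers[k]
            B = layer.B[:, None]
            row = dWk.sum(axis=1, keepdims=True)
            out[k] = dWk / B - layer.W * row / B ** 2
        else:
            raise ValueError(f"unknown model {model!r}")
    return out


# ---------------------------------------------------------------------------
# Spectrum diagnostics
# ---------------------------------------------------------------------------

def _layer_WB(net_or_layers):
    if isinstance(net_or_layers, TTFSNetwork):
        return [(l.W, l.B) for l in net_or_layers.layers if l.kind == "dense"]
    return [(np.asarray(W, dtype=float), np.asarray(B, dtype=float))
            for W, B in net_or_layers]


def jacobian_spectrum(net_or_layers, masks: Optional[list] = None,
                      seed: int = 0) -> SpectrumReport:
    """Eigen-spectrum of the per-layer Jacobians ``(1/B) W`` plus a
    gradient-norm-by-depth profile.

    Masks are ignored by default (the initialization-time assumption that
    the spiked mask barely moves the spectrum); pass per-layer 0/1
    ``masks`` from a forward pass for the masked profile.  Non-square
    layers fall back to singular values with a note.  The profile tracks
    the norm of a random unit cotangent vector propagated backwards
    through the chained Jacobians; index 0 is the deepest (first) layer.
    """
    pairs = _layer_WB(net_or_layers)
    eigs, radii, notes = [], [], []
    used_sv = False
    for W, B in pairs:
        J = W / B[:, None]
        if J.shape[0] == J.shape[1]:
            ev = np.linalg.eigvals(J)
        else:
            ev = np.linalg.svd(J, compute_uv=False).astype(complex)
            used_sv = True
            notes.append(f"non-square layer {J.shape}: singular values reported")
        eigs.append(ev)
        radii.append(float(np.abs(ev).max()))

    rng = np.random.default_rng(seed)
    v = rng.standard_normal(pairs[-1][0].shape[0])
    v /= np.linalg.norm(v)
    norms = []
    for idx in range(len(pairs) - 1, -1, -1):
        W, B = pairs[idx]
        J = W / B[:, None]
        if masks is not None:
            post = np.asarray(masks[idx], dtype=float)
            J = J * post[:, None]
        v = J.T @ v
        norms.append(float(np.linalg.norm(v)))
    return SpectrumReport(eigenvalues=eigs, spectral_radius=np.array(radii),
                          grad_norms=np.array(norms[::-1]),
                          used_singular=used_sv, notes=notes)
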