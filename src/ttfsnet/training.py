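"""Gradient-descent training of TTFS networks.

Training iterates the closed-form forward pass, exact spike-time
backpropagation, an optimizer step on ``(W, D, A)`` and, optionally, the
adaptive window rule: whenever spikes in a layer drift too close to the
end of the window, ``t_max`` is pushed out so that the window is at
least ``gamma`` times the span between its opening and the earliest
spike of the batch, and the subsequent windows shift accordingly.  With
the base-threshold convention ``theta_base = B * Delta`` the ReLU twin
is untouched by window growth, so adaptivity never breaks equivalence.

For the B1 family a gradient step on the spiking parameters is *the
same* step the equivalent ReLU network takes (``delta w = -eta dL/dW =
Delta W``; ``D`` is the bias), so B1 training reproduces ReLU training
exactly under lock-step SGD.  For the alpha1 family the step maps into
ReLU space with a per-pair multiplicative bias that no learning rate can
undo, and the trajectories drift apart; :func:`trajectory_compare`
measures the drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .dynamics import forward, spike_sparsity
from .gradients import GradientSet, backprop, relu_forward, relu_oracle
from .mapping import _row_sum, base_thresholds, reverse_map
from .network_model import ReLUNetwork, TTFSNetwork

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "adaptive_window_update",
    "l1_regularize",
    "trajectory_compare",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the spiking trainer.

    ``lr_decay`` applies the exponential schedule
    ``lr0 * 0.9**(it/5000)`` on the iteration counter.  ``gamma`` is the
    window-slack constant of the adaptive rule (>= 1).  ``l1_weight``
    scales the activation-L1 sparsity penalty (``l1_on="weights"``
    switches to a plain weight penalty).  With ``readout_bias_param``
    (default) the readout slope ``A`` is updated in its bias
    parametrization ``b = Delta * A``, i.e. plain SGD on ``b``; the raw
    ``A`` gradient scales the effective bias step by ``Delta^2`` and is
    kept behind the flag for completeness.
    """

    optimizer: str = "sgd"
    lr0: float = 5e-4
    lr_decay: bool = True
    batch_size: int = 8
    epochs: int = 1
    gamma: float = 10.0
    l1_weight: float = 0.0
    l1_on: str = "activations"
    seed: int = 0
    adaptive_windows: bool = True
    readout_bias_param: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.gamma < 1:
            raise ValueError("gamma must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-iteration training records (and optional per-epoch test rows)."""

    rows: list = field(default_factory=list)
    epoch_rows: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def log(self, **kw):
        self.rows.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def epoch_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epoch_rows)

    @property
    def losses(self) -> np.ndarray:
        return np.array([r["loss"] for r in self.rows])


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class _SGD:
    def step(self, params: dict, grads: dict, lr: float):
        for key, p in params.items():
            p -= lr * grads[key]


class _Adam:
    def __init__(self, beta1, beta2, eps):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict, lr: float):
        self.t += 1
        for key, p in params.items():
            g = grads[key]
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= lr * mh / (np.sqrt(vh) + self.eps)


def _make_optimizer(config: TrainConfig):
    if config.optimizer == "adam":
        return _Adam(config.adam_beta1, config.adam_beta2, config.adam_eps)
    return _SGD()


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _net_params(net: TTFSNetwork) -> dict:
    params = {}
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        params[("W", k)] = lay.W
        params[("D", k)] = lay.D
    params[("W", "out")] = net.readout.W
    params[("A", "out")] = net.readout.A
    return params


def _grad_dict(net: TTFSNetwork, grads: GradientSet,
               config: TrainConfig) -> dict:
    g = {}
    for k in grads.dW:
        gW = grads.dW[k]
        if config.l1_weight and config.l1_on == "weights":
            gW = gW + config.l1_weight * np.sign(net.layers[k].W)
        g[("W", k)] = gW
        g[("D", k)] = grads.dD[k]
    g[("W", "out")] = grads.dW_out
    t_min, t_max = net.layer_bounds(len(net.layers) - 1)
    delta_N = (t_max - t_min) / net.tau_c
    if config.readout_bias_param:
        # SGD in the bias parametrization b = Delta * A
        g[("A", "out")] = grads.dA_out / delta_N ** 2
    else:
        g[("A", "out")] = grads.dA_out
    return g


def _retie_alpha1(net: TTFSNetwork):
    """Recompute the tied slopes ``B = 1 + sum_k W_ik`` after a step."""
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        B = 1.0 + _row_sum(lay.W, lay.kind)
        if np.any(B <= 0):
            raise FloatingPointError(
                f"alpha1 slope became non-positive in layer {k}; "
                "the tied model left its admissible region")
        lay.B = B
    base_thresholds(net)


def adaptive_window_update(net: TTFSNetwork, frames: list,
                           gamma: float) -> None:
    """Grow windows so spikes keep a slack factor ``gamma`` from ``t_max``.

    For each spiking layer, if ``gamma * (t_max - earliest spike)``
    exceeds the current window length the window is enlarged to exactly
    that value (windows never shrink); the recursion then shifts all
    subsequent windows.  Base thresholds are reset to ``B * Delta`` and
    the readout slope is rescaled to keep its bias image ``Delta * A``
    unchanged, so the equivalent ReLU network is preserved.  Layers with
    no spike in the batch are left alone.
    """
    old_delta_N = None
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        frame = frames[k + 1]
        if not frame.mask.any():
            continue
        t_earliest = frame.times[frame.mask].min()
        span = frame.t_max - t_earliest
        delta_abs = frame.t_max - frame.t_min
        if gamma * span > delta_abs:
            stage = net.stage_of_layer(k)
            if k == _last_spiking_index(net):
                old_delta_N = net.windows.deltas[stage]
            net.windows.deltas[stage] = gamma * span / net.tau_c
    if old_delta_N is not None:
        stage = net.stage_of_layer(_last_spiking_index(net))
        net.readout.A *= old_delta_N / net.windows.deltas[stage]
    base_thresholds(net)


def _last_spiking_index(net: TTFSNetwork) -> int:
    for k in range(len(net.layers) - 1, -1, -1):
        if net.layers[k].kind != "maxpool":
            return k
    raise ValueError("network has no spiking layer")


def l1_regularize(net: TTFSNetwork, result, grads: GradientSet,
                  l1_weight: float) -> GradientSet:
    """Add the activation-L1 subgradient to an existing gradient set."""
    if l1_weight < 0:
        raise ValueError("l1_weight must be non-negative")
    if l1_weight == 0:
        return grads
    extra = backprop(net, result, l1_weight=l1_weight, include_ce=False)
    return GradientSet(
        dW={k: grads.dW[k] + extra.dW[k] for k in grads.dW},
        dD={k: grads.dD[k] + extra.dD[k] for k in grads.dD},
        dW_out=grads.dW_out, dA_out=grads.dA_out, loss=grads.loss)


def _get_xy(data, split: str = "train"):
    if isinstance(data, tuple):
        return data
    idx = data.train_idx if split == "train" else data.test_idx
    return data.X[idx], data.y[idx]


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def train(net: TTFSNetwork, data, config: TrainConfig, *,
          steps: Optional[int] = None,
          frame_hook: Optional[Callable] = None,
          weight_transform: Optional[Callable] = None,
          rng: Optional[np.random.Generator] = None):
    """Train a TTFS network in place; returns ``(net, history)``.

    ``steps`` caps the total number of iterations (otherwise
    ``config.epochs`` full passes).  ``frame_hook`` and
    ``weight_transform`` inject hardware constraints: the hook perturbs
    spike frames in the forward pass, and the transform maps each weight
    array before use while updates accumulate in the full-precision
    shadow parameters (straight-through estimator).  Deterministic given
    ``config.seed``.
    """
    X, y = _get_xy(data, "train")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    opt = _make_optimizer(config)
    history = TrainHistory(meta={"config": config})
    params = _net_params(net)
    it = 0
    done = False
    for epoch in range(config.epochs if steps is None else 10 ** 9):
        perm = rng.permutation(len(X))
        for start in range(0, len(X), config.batch_size):
            sel = perm[start:start + config.batch_size]
            fnet = _transformed_net(net, weight_transform)
            result = forward(fnet, X[sel], y[sel], frame_hook=frame_hook)
            if not np.isfinite(result.loss):
                raise RuntimeError(
                    f"training diverged at iteration {it}: loss={result.loss}")
            grads = backprop(
                fnet, result,
                l1_weight=config.l1_weight
                if config.l1_on == "activations" else 0.0)
            lr = config.lr0 * (0.9 ** (it / 5000) if config.lr_decay else 1.0)
            opt.step(params, _grad_dict(net, grads, config), lr)
            if net.model == "alpha1":
                _retie_alpha1(net)
            if config.adaptive_windows:
                adaptive_window_update(net, result.frames, config.gamma)
            history.log(it=it, epoch=epoch, loss=result.loss,
                        accuracy=result.accuracy, lr=lr,
                        sparsity=spike_sparsity(result),
                        delta_sum=float(net.windows.deltas.sum()))
            it += 1
            if steps is not None and it >= steps:
                done = True
                break
        if done:
            break
        if not isinstance(data, tuple) and len(data.test_idx):
            Xt, yt = _get_xy(data, "test")
            res = forward(_transformed_net(net, weight_transform), Xt, yt,
                          frame_hook=frame_hook)
            history.epoch_rows.append(
                {"epoch": epoch, "test_loss": res.loss,
                 "test_accuracy": res.accuracy,
                 "test_sparsity": spike_sparsity(res)})
    return net, history


def _transformed_net(net: TTFSNetwork, weight_transform):
    if weight_transform is None:
        return net
    qnet = net.copy()
    for k, lay in enumerate(qnet.layers):
        if lay.kind == "maxpool":
            continue
        lay.W = weight_transform(k, lay.W)
    qnet.readout.W = weight_transform("out", qnet.readout.W)
    return qnet


# ---------------------------------------------------------------------------
# Lock-step trajectory comparison with the ReLU twin
# ---------------------------------------------------------------------------

def _relu_params(net: ReLUNetwork) -> dict:
    params = {}
    for k, lay in enumerate(net.layers):
        if lay.kind == "maxpool":
            continue
        params[("w", k)] = lay.w
        params[("b", k)] = lay.b
    params[("w", "out")] = net.readout.w
    params[("b", "out")] = net.readout.b
    return params


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a.ravel()), np.linalg.norm(b.ravel())
    if na == 0 or nb == 0:
        return 1.0 if na == nb else 0.0
    return float(a.ravel() @ b.ravel() / (na * nb))


def _layer_cosines(snn: TTFSNetwork, relu: ReLUNetwork) -> np.ndarray:
    mapped = reverse_map(snn)
    cos = []
    for lm, lr in zip(mapped.layers, relu.layers):
        if lm.kind == "maxpool":
            continue
        cos.append(_cosine(lm.w, lr.w))
    cos.append(_cosine(mapped.readout.w, relu.readout.w))
    return np.array(cos)


def trajectory_compare(relu: ReLUNetwork, snn: TTFSNetwork, data,
                       config: TrainConfig, steps: int) -> dict:
    """Train the ReLU network and the TTFS network in lock-step.

    Both sides see identical batch sequences and learning rates (plain
    SGD unless configured otherwise) starting from equivalent networks.
    Records, per step, the training losses and the per-layer cosine
    similarity between the reverse-mapped spiking weights and the ReLU
    weights (hidden layers first, readout last).
    """
    relu = relu.copy()
    snn = snn.copy()
    X, y = _get_xy(data, "train")
    rng = np.random.default_rng(config.seed)
    opt_s = _make_optimizer(config)
    opt_r = _make_optimizer(config)
    params_s = _net_params(snn)
    params_r = _relu_params(relu)
    cosines = [_layer_cosines(snn, relu)]
    loss_s, loss_r = [], []
    it = 0
    diverged = False
    while it < steps and not diverged:
        perm = rng.permutation(len(X))
        for start in range(0, len(X), config.batch_size):
            sel = perm[start:start + config.batch_size]
            lr = config.lr0 * (0.9 ** (it / 5000) if config.lr_decay else 1.0)
            # spiking side; the tied alpha1 model can leave its admissible
            # region (B <= 0) under large updates -- exploding gradients.
            # The comparison then stops and reports the divergence.
            try:
                result = forward(snn, X[sel], y[sel])
                if not np.isfinite(result.loss):
                    raise FloatingPointError("non-finite loss")
                grads = backprop(snn, result, l1_weight=config.l1_weight)
                opt_s.step(params_s, _grad_dict(snn, grads, config), lr)
                if snn.model == "alpha1":
                    _retie_alpha1(snn)
            except FloatingPointError:
                diverged = True
                break
            if config.adaptive_windows:
                adaptive_window_update(snn, result.frames, config.gamma)
            # rectifier side
            _, _, rloss, rg = relu_oracle(relu, X[sel], y[sel],
                                          l1_weight=config.l1_weight)
            gr = {("w", k): rg["dw"][k] for k in rg["dw"]}
            gr.update({("b", k): rg["db"][k] for k in rg["db"]})
            gr[("w", "out")] = rg["dw_out"]
            gr[("b", "out")] = rg["db_out"]
            opt_r.step(params_r, gr, lr)
            loss_s.append(result.loss)
            loss_r.append(rloss)
            cosines.append(_layer_cosines(snn, relu))
            it += 1
            if it >= steps:
                break
    return {
        "cosine": np.array(cosines),       # (steps+1, n_param_layers+1)
        "loss_snn": np.array(loss_s),
        "loss_relu": np.array(loss_r),
        "diverged": diverged,
        "snn": snn,
        "relu": relu,
    }
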