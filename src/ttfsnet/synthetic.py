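"""Synthetic datasets and network initializations.

Everything the rest of the package needs can be generated here
deterministically: Gaussian-blob classification data squashed into
``[0, 1]^d`` (TTFS encoding requires bounded inputs), oriented-bar toy
images for the conv/max-pool path, the standard deep-learning weight
initialization ``W ~ N(0, 1)/sqrt(fan_in)`` with zero biases, and the
smart alpha1 initialization (standard init in ReLU space followed by the
alpha1 forward mapping).  Every generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import forward_map_alpha1
from .network_model import ReLULayer, ReLUNetwork
from ._convops import conv_out_shape

__all__ = [
    "ToyDataset",
    "make_blobs",
    "make_toy_images",
    "init_standard",
    "init_conv_standard",
    "init_smart_alpha1",
]


@dataclass
class ToyDataset:
    """Samples in ``[0, 1]``, integer labels and a train/test split."""

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        assert self.X.min() >= 0.0 and self.X.max() <= 1.0, \
            "toy data must live in [0, 1]"


def _stratified_split(y, test_fraction, rng):
    train, test = [], []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def make_blobs(n: int = 512, d: int = 16, classes: int = 2,
               separation: float = 3.0, seed: int = 0,
               test_fraction: float = 0.2) -> ToyDataset:
    """Gaussian class clusters squashed into ``[0, 1]^d``.

    Class centres are drawn at distance ~``separation`` (in units of the
    within-class standard deviation); large separations make the task
    linearly separable.  Deterministic per seed.
    """
    if n < 1 or d < 1 or classes < 1:
        raise ValueError("n, d and classes must all be at least 1")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((classes, d))
    centers *= separation / np.linalg.norm(centers, axis=1, keepdims=True) \
        * np.sqrt(d) / 2.0
    y = np.arange(n) % classes
    rng.shuffle(y)
    X = centers[y] + rng.standard_normal((n, d))
    lo, hi = X.min(axis=0), X.max(axis=0)
    X = (X - lo) / np.where(hi > lo, hi - lo, 1.0)
    train_idx, test_idx = _stratified_split(y, test_fraction, rng)
    return ToyDataset(X=X, y=y, train_idx=train_idx, test_idx=test_idx,
                      seed=seed, meta={"kind": "blobs",
                                       "separation": separation})


def make_toy_images(n: int = 256, side: int = 8, classes: int = 2,
                    noise: float = 0.1, seed: int = 0,
                    test_fraction: float = 0.2) -> ToyDataset:
    """Oriented-bar images ``(n, side, side, 1)`` with pixel noise.

    Class 0 is a horizontal bar, class 1 vertical, further classes are
    diagonals; with ``noise=0`` images within a class are identical.
    """
    if side < 4:
        raise ValueError("side must be at least 4")
    rng = np.random.default_rng(seed)
    patterns = np.zeros((classes, side, side, 1))
    mid = side // 2
    for c in range(classes):
        if c % 4 == 0:
            patterns[c, mid, :, 0] = 0.8
        elif c % 4 == 1:
            patterns[c, :, mid, 0] = 0.8
        elif c % 4 == 2:
            np.fill_diagonal(patterns[c, :, :, 0], 0.8)
        else:
            np.fill_diagonal(np.fliplr(patterns[c, :, :, 0]), 0.8)
    y = np.arange(n) % classes
    rng.shuffle(y)
    X = patterns[y]
    if noise:
        X = X + noise * rng.standard_normal(X.shape)
    X = np.clip(X, 0.0, 1.0)
    train_idx, test_idx = _stratified_split(y, test_fraction, rng)
    return ToyDataset(X=X, y=y, train_idx=train_idx, test_idx=test_idx,
                      seed=seed, meta={"kind": "images", "noise": noise})


# ---------------------------------------------------------------------------
# Initializations
# ---------------------------------------------------------------------------

def init_standard(dims, seed: int = 0) -> ReLUNetwork:
    """Fully connected ReLU network with ``W ~ N(0,1)/sqrt(fan_in)``,
    zero biases.

    ``dims = [d_in, h_1, ..., h_N, n_classes]``; the last entry is the
    affine readout.
    """
    rng = np.random.default_rng(seed)
    layers = []
    for fan_in, fan_out in zip(dims[:-2], dims[1:-1]):
        w = rng.standard_normal((fan_out, fan_in)) / np.sqrt(fan_in)
        layers.append(ReLULayer(kind="dense", w=w, b=np.zeros(fan_out)))
    w = rng.standard_normal((dims[-1], dims[-2])) / np.sqrt(dims[-2])
    readout = ReLULayer(kind="dense", w=w, b=np.zeros(dims[-1]))
    return ReLUNetwork(layers, readout)


def init_conv_standard(in_shape, channels=(4,), kernel: int = 3,
                       pool: int = 2, dense=(16,), classes: int = 2,
                       seed: int = 0, padding: str = "valid") -> ReLUNetwork:
    """Small LeNet-style conv network: conv/pool blocks then dense layers.

    Each entry of ``channels`` adds a ``kernel x kernel`` conv layer
    followed by a ``pool x pool`` max pool; ``dense`` lists the fully
    connected hidden widths.  Same fan-in-scaled initialization as
    :func:`init_standard`.
    """
    rng = np.random.default_rng(seed)
    layers = []
    shape = tuple(in_shape)
    for cout in channels:
        cin = shape[2]
        fan_in = kernel * kernel * cin
        w = rng.standard_normal((kernel, kernel, cin, cout)) / np.sqrt(fan_in)
        out_shape = conv_out_shape(shape, w.shape, padding)
        layers.append(ReLULayer(kind="conv", w=w, b=np.zeros(cout),
                                in_shape=shape, out_shape=out_shape,
                                padding=padding))
        shape = out_shape
        pooled = (shape[0] // pool, shape[1] // pool, shape[2])
        layers.append(ReLULayer(kind="maxpool", in_shape=shape,
                                out_shape=pooled, pool=pool, stride=pool))
        shape = pooled
    fan_in = int(np.prod(shape))
    for units in dense:
        w = rng.standard_normal((units, fan_in)) / np.sqrt(fan_in)
        layers.append(ReLULayer(kind="dense", w=w, b=np.zeros(units)))
        fan_in = units
    w = rng.standard_normal((classes, fan_in)) / np.sqrt(fan_in)
    readout = ReLULayer(kind="dense", w=w, b=np.zeros(classes))
    return ReLUNetwork(layers, readout)


def init_smart_alpha1(dims, seed: int = 0, margin: float = 0.1,
                      tau_c: float = 1.0):
    """Smart alpha1 initialization: standard init in ReLU-parameter
    space, then the alpha1 forward mapping (with its recorded row-sum
    rescale).  Returns the TTFS network."""
    relu = init_standard(dims, seed)
    return forward_map_alpha1(relu, tau_c=tau_c, margin=margin)
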