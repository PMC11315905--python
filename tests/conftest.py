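"""Shared fixtures and oracles for the test suite."""

import numpy as np
import pytest

import ttfsnet as t
from ttfsnet.network_model import SpikeFrame, TTFSLayer


@pytest.fixture
def micro_layer():
    """Hand-checkable 2x2 layer: window [1, 2), B = 1, tau_c = 1.

    Row 0: W = (1, 0), theta = 1; row 1: W = (0.5, -0.5), theta = 0.75.
    For input spikes (0.4, 0.8) (activations 0.6, 0.2) the closed form
    gives V(1) = (0.6, 0.2), spike times (1.4, 1.55), activations
    (0.6, 0.45).
    """
    layer = TTFSLayer(
        kind="dense",
        W=np.array([[1.0, 0.0], [0.5, -0.5]]),
        B=np.ones(2),
        theta_base=np.array([1.0, 0.75]),
        D=np.zeros(2),
        A=np.zeros(2),
    )
    prev = SpikeFrame(times=np.array([[0.4, 0.8]]),
                      mask=np.array([[True, True]]),
                      t_min=0.0, t_max=1.0)
    return layer, prev


@pytest.fixture(scope="session")
def blobs():
    return t.make_blobs(n=512, d=16, classes=2, separation=3.0, seed=0)


@pytest.fixture(scope="session")
def hard_blobs():
    """4-class task where hardware constraints visibly cost accuracy."""
    return t.make_blobs(n=512, d=16, classes=4, separation=1.2, seed=0)


def b1_pair(dims, seed):
    """Standard-init ReLU network and its B1 twin."""
    relu = t.init_standard(dims, seed=seed)
    return relu, t.forward_map_identity(relu)


def central_diff(f, x0, h):
    """Central finite difference of a scalar function of one coordinate."""
    return (f(x0 + h) - f(x0 - h)) / (2.0 * h)


def fd_check_param(snn, X, y, arr, idx, h=1e-6):
    """Finite-difference loss derivative w.r.t. one parameter entry,
    computed through the full closed-form forward pass."""
    orig = arr[idx]

    def loss_at(v):
        arr[idx] = v
        res = t.forward(snn, X, y)
        arr[idx] = orig
        return res.loss

    step = h * max(1.0, abs(orig))
    return central_diff(loss_at, orig, step)
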