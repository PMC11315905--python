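"""Exact TTFS <-> ReLU mappings, windows, thresholds, BN fusion."""

import numpy as np
import pytest

import ttfsnet as t
from ttfsnet.network_model import TTFSLayer, TTFSNetwork, WindowSchedule
from tests.conftest import b1_pair


# ---------------------------------------------------------------------------
# Reverse mapping
# ---------------------------------------------------------------------------

def _single_layer_net(W, B, theta, delta, A_out=None, W_out=None):
    n = len(B)
    lay = TTFSLayer(kind="dense", W=W, B=B, theta_base=B * delta,
                    D=B * delta - theta, A=np.zeros(n))
    readout = TTFSLayer(kind="dense",
                        W=np.eye(n) if W_out is None else W_out,
                        A=np.zeros(n) if A_out is None else A_out,
                        B=np.ones(n))
    return TTFSNetwork(layers=[lay], readout=readout, tau_c=1.0,
                       windows=WindowSchedule(np.array([1.0, delta])))


def test_reverse_map_substitution_b1():
    """W = 0.5, theta = 0.75, Delta = 1 maps to w = 0.5, b = 0.25."""
    net = _single_layer_net(np.array([[0.5]]), np.ones(1),
                            np.array([0.75]), 1.0)
    relu = t.reverse_map(net)
    assert relu.layers[0].w[0, 0] == pytest.approx(0.5)
    assert relu.layers[0].b[0] == pytest.approx(0.25)


def test_reverse_map_alpha1_row():
    """Row W = (0.5, 0.5) with B = 1 + sum(W) = 2 maps to w = (0.25, 0.25),
    the nonlinear map W / (1 + sum_k W_ik)."""
    lay = TTFSLayer(kind="dense", W=np.array([[0.5, 0.5]]),
                    B=np.array([2.0]), theta_base=np.array([2.0]),
                    D=np.zeros(1), A=np.zeros(1))
    readout = TTFSLayer(kind="dense", W=np.ones((1, 1)), A=np.zeros(1),
                        B=np.ones(1))
    net = TTFSNetwork(layers=[lay], readout=readout, tau_c=1.0,
                      windows=WindowSchedule(np.array([1.0, 1.0])))
    relu = t.reverse_map(net)
    assert relu.layers[0].w[0] == pytest.approx([0.25, 0.25])


def test_reverse_map_readout_bias():
    """Readout A = 0.3 with Delta^(N) = 2 gives b = 0.6."""
    net = _single_layer_net(np.array([[0.1]]), np.ones(1), np.array([1.0]),
                            2.0, A_out=np.array([0.3]))
    relu = t.reverse_map(net)
    assert relu.readout.b[0] == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# Forward mappings and round trips
# ---------------------------------------------------------------------------

def test_identity_map_inverts_example():
    """w = 0.5, b = 0.25, Delta = 1 gives W = 0.5, theta = 0.75."""
    relu = t.ReLUNetwork(
        [t.ReLULayer(kind="dense", w=np.array([[0.5]]), b=np.array([0.25]))],
        t.ReLULayer(kind="dense", w=np.ones((1, 1)), b=np.zeros(1)))
    snn = t.forward_map_identity(
        relu, windows=WindowSchedule(np.array([1.0, 1.0])))
    assert snn.layers[0].W[0, 0] == pytest.approx(0.5)
    assert snn.layers[0].theta[0] == pytest.approx(0.75)


def test_identity_map_rejects_oversized_bias():
    """b > Delta would need a negative threshold."""
    relu = t.ReLUNetwork(
        [t.ReLULayer(kind="dense", w=np.array([[0.1]]), b=np.array([1.5]))],
        t.ReLULayer(kind="dense", w=np.ones((1, 1)), b=np.zeros(1)))
    with pytest.raises(ValueError):
        t.forward_map_identity(relu, windows=WindowSchedule(np.array([1., 1.])))


@pytest.mark.parametrize("seed", range(4))
def test_b1_round_trip(seed):
    relu, snn = b1_pair([10, 20, 20, 20, 20, 3], seed=seed)
    back = t.reverse_map(snn)
    for a, b in zip(back.layers, relu.layers):
        assert np.abs(a.w - b.w).max() <= 1e-12
        assert np.abs(a.b - b.b).max() <= 1e-12
    assert np.abs(back.readout.w - relu.readout.w).max() <= 1e-12
    assert np.abs(back.readout.b - relu.readout.b).max() <= 1e-12


@pytest.mark.parametrize("seed", range(4))
def test_alpha1_round_trip_up_to_recorded_rescale(seed):
    relu = t.init_standard([10, 20, 20, 20, 20, 3], seed=seed)
    snn = t.forward_map_alpha1(relu, margin=0.1)
    assert all(np.all(l.B > 0) for l in snn.layers)
    undone = t.undo_layer_rescale(t.reverse_map(snn),
                                  snn.meta["layer_scales"])
    for a, b in zip(undone.layers, relu.layers):
        assert np.abs(a.w - b.w).max() <= 1e-12
        assert np.abs(a.b - b.b).max() <= 1e-12
    assert np.abs(undone.readout.w - relu.readout.w).max() <= 1e-12


def test_alpha1_fixed_point_zero_row():
    relu = t.ReLUNetwork(
        [t.ReLULayer(kind="dense", w=np.zeros((2, 2)), b=np.zeros(2))],
        t.ReLULayer(kind="dense", w=np.eye(2), b=np.zeros(2)))
    snn = t.forward_map_alpha1(relu, margin=0.1)
    assert np.allclose(snn.layers[0].B, 1.0)
    assert np.allclose(snn.layers[0].W, 0.0)


def test_alpha1_rescale_caps_row_sums():
    rng = np.random.default_rng(0)
    relu = t.ReLUNetwork(
        [t.ReLULayer(kind="dense", w=np.full((3, 3), 0.333), b=rng.random(3))],
        t.ReLULayer(kind="dense", w=np.eye(3), b=np.zeros(3)))
    scaled, scales = t.rescale_for_alpha1(relu, margin=0.1)
    assert scaled.layers[0].w.sum(axis=1).max() <= 0.9 + 1e-12
    assert scales[0] < 1.0


# ---------------------------------------------------------------------------
# Windows and base thresholds
# ---------------------------------------------------------------------------

def test_bound_window_hand_example():
    """Rows (1,0)/(0.5,-0.5), b = (0, 0.25), Delta0 = 1, margin 0:
    Delta1 = max(1, 0.75) = 1."""
    relu = t.ReLUNetwork(
        [t.ReLULayer(kind="dense", w=np.array([[1.0, 0.0], [0.5, -0.5]]),
                     b=np.array([0.0, 0.25]))],
        t.ReLULayer(kind="dense", w=np.eye(2), b=np.zeros(2)))
    ws = t.compute_windows(relu, "bound", margin=0.0)
    assert ws.deltas[1] == pytest.approx(1.0)


def test_degenerate_window_clamps_with_warning():
    relu = t.ReLUNetwork(
        [t.ReLULayer(kind="dense", w=-np.ones((2, 2)), b=np.zeros(2))],
        t.ReLULayer(kind="dense", w=np.eye(2), b=np.zeros(2)))
    with pytest.warns(UserWarning):
        ws = t.compute_windows(relu, "bound")
    assert ws.deltas[1] > 0


def test_percentile_windows_p100_is_empirical_max(blobs):
    relu = t.init_standard([16, 32, 2], seed=0)
    X = blobs.X[:128]
    ws = t.compute_windows(relu, "percentile", data=X, percentile=100)
    acts, _ = t.relu_forward(relu, X)
    assert ws.deltas[1] == pytest.approx(acts[1].max())


def test_percentile_mode_requires_data():
    relu = t.init_standard([4, 8, 2], seed=0)
    with pytest.raises(ValueError):
        t.compute_windows(relu, "percentile")


def test_base_threshold_flags_oversized_offset():
    _, snn = b1_pair([4, 8, 2], seed=0)
    snn.layers[0].D[:] = snn.windows.deltas[1] + 1.0  # threshold below drive
    report = t.base_thresholds(snn)
    assert report and "fire before t_min" in report[0]


@pytest.mark.parametrize("seed", range(12))
def test_no_early_spikes_in_grid_oracle(seed):
    """Bound-mode windows guarantee zero early crossings in the ODE
    oracle for inputs across [0,1]^D."""
    rng = np.random.default_rng(seed)
    relu = t.init_standard([6, 10, 10, 2], seed=seed)
    relu.layers[0].b = rng.normal(0, 0.3, 10)
    relu.layers[1].b = rng.normal(0, 0.3, 10)
    snn = t.forward_map_identity(relu)
    X = rng.random((4, 6))
    frame = t.encode_input(X, snn.input_bounds(), snn.tau_c)
    for k, lay in enumerate(snn.layers):
        grid = t.simulate_layer_grid(frame, lay, snn.layer_bounds(k),
                                     snn.tau_c, dt=1e-3)
        assert not grid.early_violation.any(), f"layer {k}"
        frame, _ = t.layer_spike_times(frame, lay, snn.layer_bounds(k),
                                       snn.tau_c)


# ---------------------------------------------------------------------------
# Batch-norm fusion
# ---------------------------------------------------------------------------

def test_identity_bn_is_noop():
    relu = t.init_standard([4, 8, 2], seed=0)
    relu.layers[0].bn = {"mean": np.zeros(8), "var": np.ones(8),
                         "gamma": np.ones(8), "beta": np.zeros(8), "eps": 0.0}
    fused = t.fuse_batchnorm(relu)
    assert np.allclose(fused.layers[0].w, relu.layers[0].w)
    assert np.allclose(fused.layers[0].b, relu.layers[0].b)


def test_affine_bn_algebra():
    """scale 2, shift 1, mean 0, var 1: w doubles and b -> 2b + 1."""
    relu = t.init_standard([4, 8, 2], seed=1)
    relu.layers[0].b = np.random.default_rng(0).random(8)
    relu.layers[0].bn = {"mean": np.zeros(8), "var": np.ones(8),
                         "gamma": np.full(8, 2.0), "beta": np.ones(8),
                         "eps": 0.0}
    fused = t.fuse_batchnorm(relu)
    assert np.allclose(fused.layers[0].w, 2 * relu.layers[0].w)
    assert np.allclose(fused.layers[0].b, 2 * relu.layers[0].b + 1)


def test_random_bn_output_equality():
    rng = np.random.default_rng(5)
    relu = t.init_standard([6, 12, 3], seed=5)
    bn = {"mean": rng.normal(size=12), "var": rng.random(12) + 0.5,
          "gamma": rng.normal(size=12), "beta": rng.normal(size=12),
          "eps": 1e-5}
    relu.layers[0].bn = dict(bn)
    fused = t.fuse_batchnorm(relu)
    X = rng.random((32, 6))
    z = X @ relu.layers[0].w.T + relu.layers[0].b
    zb = bn["gamma"] * (z - bn["mean"]) / np.sqrt(bn["var"] + bn["eps"]) \
        + bn["beta"]
    ref = np.maximum(zb, 0) @ relu.readout.w.T + relu.readout.b
    acts, _ = t.relu_forward(fused, X)
    assert np.abs(acts[-1] - ref).max() <= 1e-9


def test_bn_rejects_bad_variance():
    relu = t.init_standard([4, 8, 2], seed=0)
    relu.layers[0].bn = {"mean": np.zeros(8), "var": np.zeros(8),
                         "gamma": np.ones(8), "beta": np.zeros(8), "eps": 0.0}
    with pytest.raises(ValueError):
        t.fuse_batchnorm(relu)
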