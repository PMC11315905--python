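"""Forward pass: encoding, closed-form spike times, the grid-simulation
oracle, pooling, sparsity and the energy model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ttfsnet as t
from ttfsnet.network_model import SpikeFrame, TTFSLayer
from tests.conftest import b1_pair


# ---------------------------------------------------------------------------
# Input encoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, expected_t, expected_mask", [
    (0.0, 1.0, False),   # zero input emits no spike (sentinel at t_max)
    (1.0, 0.0, True),
    (0.6, 0.4, True),
])
def test_encode_examples(x, expected_t, expected_mask):
    frame = t.encode_input(np.array([[x]]), (0.0, 1.0), tau_c=1.0)
    assert frame.times[0, 0] == pytest.approx(expected_t)
    assert bool(frame.mask[0, 0]) is expected_mask


def test_encode_rejects_out_of_range():
    with pytest.raises(ValueError):
        t.encode_input(np.array([[1.2]]), (0.0, 1.0), 1.0)
    with pytest.raises(ValueError):
        t.encode_input(np.array([[-0.1]]), (0.0, 1.0), 1.0)


@given(st.lists(st.integers(0, 10 ** 6), min_size=2, max_size=8, unique=True))
@settings(max_examples=50, derandomize=True)
def test_encoding_is_monotone(grid):
    """A larger input always fires earlier: x_a > x_b implies t_a < t_b."""
    xs = [v / 10 ** 6 for v in grid]
    frame = t.encode_input(np.array([xs]), (0.0, 1.0), tau_c=0.7)
    order_x = np.argsort(xs)
    order_t = np.argsort(-frame.times[0])
    assert (order_x == order_t).all()


# ---------------------------------------------------------------------------
# Closed-form spike times and the grid oracle
# ---------------------------------------------------------------------------

def test_micro_layer_closed_form(micro_layer):
    layer, prev = micro_layer
    frame, _ = t.layer_spike_times(prev, layer, (1.0, 2.0), 1.0)
    assert frame.times[0] == pytest.approx([1.4, 1.55])
    assert frame.mask.all()
    assert frame.v_tmin[0] == pytest.approx([0.6, 0.2])
    # decoded activations equal the ReLU values 0.6 and 0.45
    assert frame.decoded(1.0)[0] == pytest.approx([0.6, 0.45])


def test_boundary_crossing_is_not_a_spike():
    """A candidate time exactly at t_max stays silent, matching
    ReLU(0) = 0 at the half-open window boundary."""
    layer = TTFSLayer(kind="dense", W=np.zeros((1, 1)), B=np.ones(1),
                      theta_base=np.ones(1), D=np.zeros(1), A=np.zeros(1))
    prev = SpikeFrame(times=np.array([[1.0]]), mask=np.array([[False]]),
                      t_min=0.0, t_max=1.0)
    frame, _ = t.layer_spike_times(prev, layer, (1.0, 2.0), 1.0)
    assert not frame.mask[0, 0]
    assert frame.times[0, 0] == 2.0
    assert frame.decoded(1.0)[0, 0] == 0.0


def test_grid_oracle_matches_micro_layer(micro_layer):
    layer, prev = micro_layer
    closed, _ = t.layer_spike_times(prev, layer, (1.0, 2.0), 1.0)
    grid = t.simulate_layer_grid(prev, layer, (1.0, 2.0), 1.0, dt=1e-4)
    assert np.abs(grid.times - closed.times).max() <= 1e-4
    assert (grid.mask == closed.mask).all()
    assert not grid.early_violation.any()


def test_grid_oracle_pure_ramp():
    """Zero weights, threshold B*Delta/2: spike at the window midpoint."""
    layer = TTFSLayer(kind="dense", W=np.zeros((1, 1)), B=np.full(1, 2.0),
                      theta_base=np.full(1, 2.0), D=np.zeros(1),
                      A=np.zeros(1))  # theta = 2 = B * Delta/2 for Delta=2
    prev = SpikeFrame(times=np.array([[0.5]]), mask=np.array([[True]]),
                      t_min=0.0, t_max=1.0)
    grid = t.simulate_layer_grid(prev, layer, (1.0, 3.0), 1.0, dt=1e-4)
    assert grid.times[0, 0] == pytest.approx(2.0, abs=1e-4)


def test_grid_oracle_flags_early_crossing():
    """A threshold below the accumulated drive fires before t_min; the
    oracle reports the violation instead of clamping."""
    layer = TTFSLayer(kind="dense", W=np.array([[2.0]]), B=np.ones(1),
                      theta_base=np.array([0.5]), D=np.zeros(1), A=np.zeros(1))
    prev = SpikeFrame(times=np.array([[0.2]]), mask=np.array([[True]]),
                      t_min=0.0, t_max=1.0)
    grid = t.simulate_layer_grid(prev, layer, (1.0, 2.0), 1.0, dt=1e-4)
    assert grid.early_violation[0, 0]


def test_grid_oracle_rejects_bad_dt(micro_layer):
    layer, prev = micro_layer
    with pytest.raises(ValueError):
        t.simulate_layer_grid(prev, layer, (1.0, 2.0), 1.0, dt=0.0)


# ---------------------------------------------------------------------------
# Full forward pass
# ---------------------------------------------------------------------------

def test_uniform_softmax_on_dead_network():
    relu = t.init_standard([4, 8, 3], seed=0)
    relu.layers[0].w[:] = 0.0
    relu.readout.w[:] = 0.0
    snn = t.forward_map_identity(relu)
    res = t.forward(snn, np.zeros((5, 4)), np.zeros(5, dtype=int))
    assert np.allclose(res.logits, 0.0)
    assert res.loss == pytest.approx(np.log(3))


def test_affine_only_network_is_exact():
    """A network with no hidden layer reduces to w x + b exactly."""
    rng = np.random.default_rng(3)
    relu = t.ReLUNetwork([], t.ReLULayer(kind="dense",
                                         w=rng.standard_normal((3, 5)),
                                         b=rng.standard_normal(3)))
    snn = t.forward_map_identity(relu, windows=t.WindowSchedule(np.array([1.0])))
    X = rng.random((7, 5))
    res = t.forward(snn, X)
    assert np.allclose(res.logits, X @ relu.readout.w.T + relu.readout.b,
                       atol=1e-12)


# ---------------------------------------------------------------------------
# Spiking max pooling
# ---------------------------------------------------------------------------

def test_maxpool_earliest_spike_and_silence():
    times = np.full((1, 2, 2, 1), 3.0)
    mask = np.zeros((1, 2, 2, 1), bool)
    times[0, 0, 0, 0], mask[0, 0, 0, 0] = 1.4, True
    times[0, 0, 1, 0], mask[0, 0, 1, 0] = 1.55, True
    frame = SpikeFrame(times=times, mask=mask, t_min=1.0, t_max=3.0)
    layer = TTFSLayer(kind="maxpool", pool=2, stride=2)
    pooled = t.ttfs_maxpool(frame, layer)
    assert pooled.times[0, 0, 0, 0] == 1.4          # earliest spike wins
    assert pooled.mask[0, 0, 0, 0]
    silent = SpikeFrame(times=np.full((1, 2, 2, 1), 3.0),
                        mask=np.zeros((1, 2, 2, 1), bool), t_min=1.0, t_max=3.0)
    assert not t.ttfs_maxpool(silent, layer).mask.any()


def test_maxpool_equals_relu_maxpool():
    """Pooled-then-decoded activations equal max-pooled ReLU activations."""
    relu = t.init_conv_standard((8, 8, 1), channels=(3,), dense=(8,),
                                classes=2, seed=1)
    snn = t.forward_map_identity(relu)
    data = t.make_toy_images(n=12, seed=2)
    res = t.forward(snn, data.X, data.y)
    acts, _ = t.relu_forward(relu, data.X)
    for k, lay in enumerate(snn.layers):
        dev = np.abs(res.frames[k + 1].decoded(1.0) - acts[k + 1]).max()
        assert dev < 1e-9, f"layer {k} ({lay.kind})"
    assert np.abs(res.logits - acts[-1]).max() < 1e-9


# ---------------------------------------------------------------------------
# Sparsity and energy
# ---------------------------------------------------------------------------

def test_spike_sparsity_counts():
    _, snn = b1_pair([4, 4, 2], seed=0)
    res = t.forward(snn, np.zeros((2, 4)))
    assert t.spike_sparsity(res) == 0.0
    frames = res.frames
    frames[1].mask[:] = np.array([[True, True, True, False],
                                  [True, True, True, False]])
    assert t.spike_sparsity(res) == pytest.approx(0.75)
    frames[1].mask[:] = True
    assert t.spike_sparsity(res) == 1.0


def test_energy_formula_and_monotonicity():
    _, snn = b1_pair([4, 6, 2], seed=1)
    rng = np.random.default_rng(0)
    X = rng.random((8, 4))
    res = t.forward(snn, X)
    rep = t.energy_estimate(res, snn, T_r=2.0, C=1.0)
    assert 0.0 <= rep.spikes_per_neuron <= 1.0
    assert 0.0 <= rep.r_fraction <= 1.0
    # all-silent network with zero accumulated charge consumes no energy
    res0 = t.forward(snn, np.zeros((3, 4)))
    for fr, lay in zip(res0.frames[1:], snn.layers):
        delta = (fr.t_max - fr.t_min) / snn.tau_c
        fr.v_tmin[:] = -lay.B * delta  # makes V(t_max) = 0 exactly
    rep0 = t.energy_estimate(res0, snn, T_r=2.0, C=1.0)
    assert rep0.total_energy == pytest.approx(0.0)
    # flipping one silent neuron to spiking adds at least T_r
    frame = res.frames[1]
    silent_idx = np.argwhere(~frame.mask)
    if len(silent_idx):
        b, i = silent_idx[0]
        frame.mask[b, i] = True
        frame.times[b, i] = frame.t_min
        rep2 = t.energy_estimate(res, snn, T_r=2.0, C=1.0)
        assert rep2.total_energy >= rep.total_energy + 2.0 / X.shape[0] - 1e-9


def test_energy_all_spiking_closed_form():
    """S spikes at threshold theta with no silent charge cost
    S*(T_r + 0.5 theta^2 C)."""
    _, snn = b1_pair([2, 3, 2], seed=0)
    res = t.forward(snn, np.full((1, 2), 0.9))
    frame = res.frames[1]
    frame.mask[:] = True
    frame.v_tmin[:] = snn.layers[0].theta  # silent branch contributes 0
    theta = snn.layers[0].theta
    rep = t.energy_estimate(res, snn, T_r=1.5, C=2.0)
    expected = (1.5 + 0.5 * 2.0 * theta ** 2).sum()
    assert rep.total_energy == pytest.approx(expected)
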