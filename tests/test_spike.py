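"""Input scaling, Poisson rate coding, and integrate-and-fire dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikealpha.encoding import SpikeTrain, poisson_encode, scale_input
from spikealpha.ifneuron import (
    IFState,
    conv_time_same,
    if_backward_grads,
    if_conv_forward,
)


def _const_train(value, T=16, shape=(1, 1)):
    return SpikeTrain(np.full(shape + (T,), value, dtype=np.int8), T)


def scalar_if_oracle(drive, v_th, T):
    """Independent step-by-step simulation of one IF unit under constant drive."""
    v, n = 0.0, 0
    for _ in range(T):
        v += drive
        if v > v_th:
            n += 1
            v = 0.0
    return n, v


class TestScaleInput:
    def test_global_max_becomes_one(self, rng):
        x = np.clip(rng.normal(scale=20, size=(14, 128)), -45, 45)
        x[4, 7] = -50.0
        scaled = scale_input(x)
        assert np.abs(scaled).max() == pytest.approx(1.0)
        assert scaled[4, 7] == -1.0

    def test_all_zero_stays_zero(self):
        assert not scale_input(np.zeros((14, 128))).any()

    def test_proportional_with_sign(self):
        scaled = scale_input(np.array([[-50.0, 25.0]]))
        np.testing.assert_allclose(scaled, [[-1.0, 0.5]])

    def test_per_channel_option(self):
        x = np.array([[1.0, 2.0], [5.0, 10.0]])
        scaled = scale_input(x, per_channel=True)
        np.testing.assert_allclose(scaled, [[0.5, 1.0], [0.5, 1.0]])


class TestPoissonEncoder:
    def test_saturated_input_always_fires(self, rng):
        train = poisson_encode(np.ones((2, 3)), 16, rng)
        assert (train.values == 1).all()

    def test_zero_input_never_fires(self, rng):
        train = poisson_encode(np.zeros((2, 3)), 16, rng)
        assert not train.values.any()

    def test_firing_rate_binomial(self, rng):
        # |x| = 0.5 at T = 10,000: count within 3 binomial SDs of 5,000
        train = poisson_encode(np.array([[-0.5]]), 10_000, rng)
        count = np.abs(train.values).sum()
        assert (train.values <= 0).all()  # negative input -> -1 polarity only
        assert abs(count - 5000) <= 3 * np.sqrt(10_000 * 0.25)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_polarity_preservation(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(-1, 1, size=(4, 8))
        train = poisson_encode(x, 32, r)
        assert not ((x < 0)[..., None] & (train.values > 0)).any()
        assert not ((x > 0)[..., None] & (train.values < 0)).any()

    def test_rate_converges_to_magnitude(self):
        x = np.array([[0.13, -0.77, 0.4]])
        train = poisson_encode(x, 10_000, np.random.default_rng(0))
        sd = np.sqrt(np.abs(x) * (1 - np.abs(x)) / 10_000)
        assert (np.abs(train.firing_rate() - np.abs(x)) <= 3 * sd + 1e-12).all()

    def test_literal_unsigned_mode_silences_negatives(self, rng):
        x = np.array([[-0.9, 0.9]])
        train = poisson_encode(x, 1000, rng, signed=False)
        assert train.values[0, 0].sum() == 0
        assert train.values[0, 1].sum() > 0

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            poisson_encode(np.array([[1.5]]), 4, rng)

    def test_same_seed_bit_identical(self):
        x = np.random.default_rng(3).uniform(-1, 1, size=(14, 128))
        a = poisson_encode(x, 16, np.random.default_rng(42))
        b = poisson_encode(x, 16, np.random.default_rng(42))
        np.testing.assert_array_equal(a.values, b.values)


class TestIFDynamics:
    def test_zero_train_stays_silent(self):
        res = if_conv_forward(_const_train(0), np.array([[1.0]]), IFState(2.0, 16))
        assert not res.V.any()
        assert not res.output_spikes.any()

    @pytest.mark.parametrize("drive", [0.1, 0.5, 1.0, 1.3, 2.5])
    def test_constant_drive_matches_scalar_oracle(self, drive):
        # 1x1 kernel + all-ones spikes = constant per-step drive on one unit
        res = if_conv_forward(_const_train(1), np.array([[drive]]), IFState(2.0, 16))
        n_expect, v_expect = scalar_if_oracle(drive, 2.0, 16)
        assert res.output_spikes.item() == n_expect
        assert res.V.item() == pytest.approx(v_expect)

    def test_subthreshold_accumulation(self):
        res = if_conv_forward(_const_train(1), np.array([[0.1]]), IFState(2.0, 16))
        assert res.output_spikes.item() == 0
        assert res.V.item() == pytest.approx(1.6)

    def test_no_reset_equals_plain_convolution(self, rng):
        spikes = SpikeTrain(
            rng.integers(-1, 2, size=(4, 32, 16)).astype(np.int8), 16
        )
        w = rng.normal(size=(3, 5))
        res = if_conv_forward(spikes, w, IFState(1e9, 16), reset=False)
        linear = conv_time_same(spikes.values.sum(axis=-1).astype(float), w)
        np.testing.assert_allclose(res.V, linear, atol=1e-10)

    def test_t_mismatch_rejected(self):
        with pytest.raises(ValueError, match="T="):
            if_conv_forward(_const_train(1, T=8), np.array([[1.0]]), IFState(2.0, 16))

    def test_bad_weight_shape_named(self):
        with pytest.raises(ValueError, match="filters, kernel"):
            if_conv_forward(_const_train(1), np.ones(3), IFState(2.0, 16))

    def test_same_seed_identical_v(self, ):
        x = np.random.default_rng(5).uniform(-1, 1, size=(14, 128))
        w = np.random.default_rng(6).normal(size=(8, 64))
        outs = []
        for _ in range(2):
            train = poisson_encode(x, 16, np.random.default_rng(9))
            outs.append(if_conv_forward(train, w, IFState(2.0, 16)).V)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestIFBackward:
    def test_zero_upstream_gradient(self, rng):
        spikes = SpikeTrain(rng.integers(-1, 2, size=(2, 8, 16)).astype(np.int8), 16)
        res = if_conv_forward(spikes, rng.normal(size=(3, 5)), IFState(2.0, 16))
        g = if_backward_grads(np.zeros_like(res.V), res)
        assert not g.any()

    def test_inverse_vth_proportionality(self, rng):
        spikes = SpikeTrain(rng.integers(-1, 2, size=(2, 8, 16)).astype(np.int8), 16)
        w = rng.normal(size=(3, 5))
        gout = rng.normal(size=(3, 2, 8))
        res1 = if_conv_forward(spikes, w, IFState(2.0, 16))
        res2 = if_conv_forward(spikes, w, IFState(4.0, 16))
        # the accumulated input spikes are the same; only 1/V_th differs
        g1 = if_backward_grads(gout, res1)
        g2 = if_backward_grads(gout, res2)
        np.testing.assert_allclose(g2, g1 / 2.0, atol=1e-12)

    def test_scalar_toy_matches_finite_difference(self):
        # 1 input, 1 weight, T = 2, no reset, V_th = 1: the surrogate chain
        # is exact, so the gradient equals the central difference of the loss
        spikes = _const_train(1, T=2)
        state = IFState(1.0, 2)
        target = 5.0

        def loss(w):
            res = if_conv_forward(spikes, np.array([[w]]), state, reset=False)
            return 0.5 * (res.V.item() - target) ** 2, res

        w0, eps = 0.3, 1e-6
        val, res = loss(w0)
        gout = (res.V - target)  # dLoss/dV[T]
        grad = if_backward_grads(gout, res).item()
        fd = (loss(w0 + eps)[0] - loss(w0 - eps)[0]) / (2 * eps)
        assert grad == pytest.approx(fd, abs=1e-4)

    def test_backward_before_forward_rejected(self):
        from spikealpha.ifneuron import IFConvResult

        bare = IFConvResult(np.zeros((1, 1, 1)), np.zeros((1, 1, 1)),
                            np.zeros((1, 1)), 2.0, kernel_size=0)
        with pytest.raises(ValueError, match="forward"):
            if_backward_grads(np.zeros((1, 1, 1)), bare)
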