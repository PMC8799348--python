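"""Squash family, multilevel convolution, dynamic routing, margin loss."""

import math

import numpy as np
import pytest

from emgcaps import (
    CapsNet,
    CapsNetConfig,
    MarginLossConfig,
    MultilevelConv,
    MultilevelConvConfig,
    SQUASH_KINDS,
    apply_squash,
    dynamic_routing,
    margin_loss,
    predict,
    squash_length,
    to_primary_caps,
)
from emgcaps.nn import Tensor


# -- squash family -----------------------------------------------------------

def oracle_squash_vec(s, kind):
    """Independent evaluation: length law times unit direction."""
    x = math.sqrt(sum(v * v for v in s))
    if x == 0:
        return np.zeros(len(s))
    if kind == "squash":
        g = x**2 / (1 + x**2)
    elif kind == "hsquash":
        g = (x / 4) ** 2 / (1 + (x / 4) ** 2)
    elif kind == "strict_squash":
        g = 0.69 * x**2 * 2 ** (-0.6 * x - 1.115)
    elif kind == "squash_4":
        g = x**2 / (0.5 + x**2)
    elif kind == "e_squash":
        g = 1 - math.exp(-(x**2))
    return g * np.asarray(s) / x


class TestSquash:
    @pytest.mark.parametrize("kind", SQUASH_KINDS)
    def test_zero_vector_maps_to_zero(self, kind):
        np.testing.assert_array_equal(apply_squash(np.zeros(8), kind), np.zeros(8))

    @pytest.mark.parametrize(
        "kind,norm,expected",
        [
            ("e_squash", 1.0, 1 - math.exp(-1)),
            ("squash", 1.0, 0.5),
            ("squash_4", 1.0, 2 / 3),
            ("hsquash", 4.0, 0.5),
        ],
    )
    def test_lengths_at_reference_points(self, kind, norm, expected):
        v = apply_squash(np.array([norm, 0.0, 0.0]), kind)
        assert np.linalg.norm(v) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("kind", SQUASH_KINDS)
    def test_direction_preserved_and_matches_oracle(self, rng, kind):
        for _ in range(20):
            s = rng.standard_normal(8) * rng.uniform(0.01, 5)
            np.testing.assert_allclose(
                apply_squash(s, kind), oracle_squash_vec(s, kind), rtol=1e-9, atol=1e-12
            )

    def test_e_squash_dominates_original_on_dense_grid(self):
        x = np.linspace(0, 20, 4001)
        assert np.all(squash_length(x, "e_squash") >= squash_length(x, "squash") - 1e-15)

    @pytest.mark.parametrize("kind", ["squash", "hsquash", "squash_4", "e_squash"])
    def test_length_below_one_and_monotone(self, kind):
        # strictly below 1 wherever float64 can resolve the gap; never above
        x = np.linspace(0, 5.5, 2001)
        assert np.all(squash_length(x, kind) < 1.0)
        x_wide = np.linspace(0, 50, 2001)
        g = squash_length(x_wide, kind)
        assert np.all(g <= 1.0)
        assert np.all(np.diff(g) >= -1e-15)

    def test_unknown_kind_rejected(self):
        with pytest.raises(KeyError):
            squash_length(1.0, "not_a_squash")


# -- multilevel convolution and primary capsules -----------------------------

class TestMultilevelConv:
    def test_full_width_channel_counts(self, rng):
        ml = MultilevelConv(MultilevelConvConfig(channels=256), rng)
        x = Tensor(rng.random((1, 256, 7, 7)))
        out, stacked = ml.forward_parts(x)
        assert stacked.shape == (1, 768, 7, 7)
        assert out.shape == (1, 256, 7, 7)

    def test_zero_input_zero_biases_gives_zero(self, rng):
        ml = MultilevelConv(MultilevelConvConfig(channels=16), rng)
        out = ml(Tensor(np.zeros((1, 16, 7, 7))))
        np.testing.assert_array_equal(out.data, 0.0)


class TestPrimaryCaps:
    def test_full_width_capsule_count(self, rng):
        caps = to_primary_caps(rng.random((1, 256, 7, 7)), "squash")
        assert caps.shape == (1, 7 * 7 * 32, 8)
        assert caps.shape[1] == 1568

    def test_lengths_below_one(self, rng):
        caps = to_primary_caps(rng.random((2, 32, 7, 7)) * 10, "squash")
        assert np.all(np.linalg.norm(caps.data, axis=-1) < 1.0)

    def test_zero_map_gives_zero_capsules(self):
        caps = to_primary_caps(np.zeros((1, 32, 7, 7)), "e_squash")
        np.testing.assert_array_equal(caps.data, 0.0)

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            to_primary_caps(rng.random((1, 30, 7, 7)), "squash")


# -- dynamic routing ---------------------------------------------------------

def routing_oracle(u, W, iterations, kind):
    """Triple-loop transcription of the routing equations."""
    P, A, d_in, d_out = W.shape
    u_hat = np.zeros((P, A, d_out))
    for i in range(P):
        for j in range(A):
            u_hat[i, j] = u[i] @ W[i, j]
    b = np.zeros((P, A))
    c = np.zeros((P, A))
    v = np.zeros((A, d_out))
    for it in range(iterations):
        for i in range(P):
            ex = np.exp(b[i])
            c[i] = ex / ex.sum()
        s = np.zeros((A, d_out))
        for j in range(A):
            for i in range(P):
                s[j] += c[i, j] * u_hat[i, j]
        for j in range(A):
            v[j] = oracle_squash_vec(s[j], kind)
        if it < iterations - 1:
            for i in range(P):
                for j in range(A):
                    b[i, j] += u_hat[i, j] @ v[j]
    return v, c


class TestDynamicRouting:
    def test_uniform_couplings_at_initialization(self, rng):
        u = rng.standard_normal((6, 8))
        W = rng.standard_normal((6, 5, 8, 16)) * 0.05
        _, state = dynamic_routing(u, W, iterations=1, kind="squash")
        np.testing.assert_allclose(state.c, 0.2, atol=1e-12)

    def test_coupling_rows_sum_to_one_each_iteration(self, rng):
        u = rng.standard_normal((10, 8))
        W = rng.standard_normal((10, 5, 8, 16)) * 0.05
        for iters in (1, 2, 3, 5):
            _, state = dynamic_routing(u, W, iterations=iters, kind="e_squash")
            np.testing.assert_allclose(state.c.sum(axis=2), 1.0, atol=1e-9)

    @pytest.mark.parametrize("kind", ["squash", "e_squash"])
    def test_matches_triple_loop_oracle(self, kind):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            u = rng.standard_normal((4, 2))
            W = rng.standard_normal((4, 2, 2, 3)) * 0.5
            v, state = dynamic_routing(u, W, iterations=3, kind=kind)
            v_ref, c_ref = routing_oracle(u, W, 3, kind)
            np.testing.assert_allclose(v.data[0], v_ref, atol=1e-6)
            np.testing.assert_allclose(state.c[0], c_ref, atol=1e-6)

    def test_invariant_under_primary_permutation(self, rng):
        u = rng.standard_normal((7, 8))
        W = rng.standard_normal((7, 3, 8, 16)) * 0.1
        perm = rng.permutation(7)
        v1, _ = dynamic_routing(u, W, iterations=3, kind="e_squash")
        v2, _ = dynamic_routing(u[perm], W[perm], iterations=3, kind="e_squash")
        np.testing.assert_allclose(v1.data, v2.data, atol=1e-12)

    def test_rejects_zero_iterations(self, rng):
        with pytest.raises(ValueError):
            dynamic_routing(rng.standard_normal((3, 8)),
                            rng.standard_normal((3, 5, 8, 16)), iterations=0)


# -- margin loss and prediction ----------------------------------------------

class TestMarginLoss:
    @pytest.mark.parametrize(
        "lengths,label,expected",
        [
            ([0.95, 0.05, 0.05, 0.05, 0.05], 0, 0.0),
            ([0.0, 0.0, 0.0, 0.0, 0.0], 0, 0.81),
            ([0.95, 0.2, 0.2, 0.2, 0.2], 0, 0.02),
        ],
    )
    def test_hand_derived_values(self, lengths, label, expected):
        got = margin_loss(np.array(lengths), label, MarginLossConfig())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_batch_mean(self):
        lengths = np.array([[0.0] * 5, [0.95, 0.2, 0.2, 0.2, 0.2]])
        got = margin_loss(lengths, np.array([0, 0]))
        assert got == pytest.approx((0.81 + 0.02) / 2, abs=1e-12)


class TestPredict:
    def test_argmax_of_lengths(self):
        assert predict(np.array([0.1, 0.8, 0.2, 0.1, 0.1]))[0] == 1

    def test_tie_breaks_to_lowest_index(self):
        assert predict(np.full(5, 0.3))[0] == 0

    def test_permutation_equivariance(self, rng):
        lengths = rng.random(5)
        perm = rng.permutation(5)
        assert perm[predict(lengths[perm])[0]] == predict(lengths)[0]


class TestEndToEnd:
    def test_forward_lengths_in_unit_interval_and_deterministic(self, rng):
        model = CapsNet(CapsNetConfig(width_profile="test"), seed=7)
        fm = rng.random((2, 16, 15, 15))
        sm = rng.random((2, 16, 15, 20))
        l1, _ = model.forward(fm, sm)
        l2, _ = model.forward(fm, sm)
        assert l1.data.shape == (2, 5)
        assert np.all(l1.data >= 0) and np.all(l1.data < 1)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = CapsNet(CapsNetConfig(width_profile="test", squash_kind="hsquash"), seed=3)
        fm = rng.random((1, 16, 15, 15))
        sm = rng.random((1, 16, 15, 20))
        before, _ = model.forward(fm, sm)
        model.save(tmp_path / "model.npz")
        loaded = CapsNet.load(tmp_path / "model.npz")
        assert loaded.config.squash_kind == "hsquash"
        after, _ = loaded.forward(fm, sm)
        np.testing.assert_array_equal(before.data, after.data)
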