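"""Layer operations against independent scalar-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capstm.autodiff import Tensor
from capstm.layers import (
    BiLstmParams,
    CapsuleParams,
    HighwayParams,
    PredictHeadParams,
    aggregate,
    bilstm_encode,
    capsule_features,
    concat_representation,
    dynamic_routing,
    fuse,
    highway,
    interaction_attention,
    pool_capsules,
    predict_head,
    squash,
)
from oracles import (
    attention_ref,
    capsule_features_ref,
    highway_ref,
    lstm_cell_ref,
    routing_ref,
    squash_ref,
)


def make_highway_params(rng, E):
    return HighwayParams(
        w_f=Tensor(rng.normal(size=(E, E))),
        b_f=Tensor(rng.normal(size=E)),
        w_g=Tensor(rng.normal(size=(E, E))),
        b_g=Tensor(rng.normal(size=E)),
    )


class TestHighway:
    def test_gate_limit_zero_is_identity(self, rng):
        E = 3
        p = make_highway_params(rng, E)
        p.b_g = Tensor(np.full(E, -1e4))  # gate -> 0
        e = rng.normal(size=(4, E))
        np.testing.assert_allclose(highway(Tensor(e), p).data, e, atol=1e-6)

    def test_gate_limit_one_is_tanh_branch(self, rng):
        E = 3
        p = make_highway_params(rng, E)
        p.b_g = Tensor(np.full(E, 1e4))  # gate -> 1
        e = rng.normal(size=(4, E))
        expected = np.tanh(e @ p.w_f.data.T + p.b_f.data)
        np.testing.assert_allclose(highway(Tensor(e), p).data, expected, atol=1e-6)

    def test_matches_scalar_oracle(self, rng):
        E = 3
        for _ in range(20):
            p = make_highway_params(rng, E)
            e = rng.normal(size=(5, E))
            got = highway(Tensor(e), p).data
            want = highway_ref(e, p.w_f.data, p.b_f.data, p.w_g.data, p.b_g.data)
            assert np.abs(got - want).max() < 1e-10

    def test_dimension_mismatch_raises(self, rng):
        p = make_highway_params(rng, 3)
        with pytest.raises(ValueError):
            highway(Tensor(rng.normal(size=(4, 5))), p)


def make_bilstm_params(rng, D, H):
    return BiLstmParams(
        w_fwd=Tensor(rng.normal(size=(D, 4 * H)) * 0.3),
        u_fwd=Tensor(rng.normal(size=(H, 4 * H)) * 0.3),
        b_fwd=Tensor(rng.normal(size=4 * H) * 0.3),
        w_bwd=Tensor(rng.normal(size=(D, 4 * H)) * 0.3),
        u_bwd=Tensor(rng.normal(size=(H, 4 * H)) * 0.3),
        b_bwd=Tensor(rng.normal(size=4 * H) * 0.3),
    )


class TestBiLstm:
    def test_output_shape(self, rng):
        D, H, n = 3, 4, 5
        p = make_bilstm_params(rng, D, H)
        out = bilstm_encode(Tensor(rng.normal(size=(2, n, D))), np.ones((2, n)), p)
        assert out.shape == (2, n, 2 * H)

    def test_all_pad_input_gives_zeros(self, rng):
        p = make_bilstm_params(rng, 3, 4)
        out = bilstm_encode(Tensor(rng.normal(size=(1, 5, 3))), np.zeros((1, 5)), p)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_single_token_matches_hand_lstm_cell(self, rng):
        D, H = 2, 1
        p = make_bilstm_params(rng, D, H)
        x = rng.normal(size=(1, 1, D))
        out = bilstm_encode(Tensor(x), np.ones((1, 1)), p).data[0, 0]
        h_f, _ = lstm_cell_ref(x[0, 0], np.zeros(H), np.zeros(H), p.w_fwd.data, p.u_fwd.data, p.b_fwd.data)
        h_b, _ = lstm_cell_ref(x[0, 0], np.zeros(H), np.zeros(H), p.w_bwd.data, p.u_bwd.data, p.b_bwd.data)
        np.testing.assert_allclose(out, np.concatenate([h_f, h_b]), atol=1e-8)

    def test_multi_step_matches_sequential_oracle(self, rng):
        D, H, n = 3, 2, 4
        p = make_bilstm_params(rng, D, H)
        x = rng.normal(size=(1, n, D))
        out = bilstm_encode(Tensor(x), np.ones((1, n)), p).data[0]
        h = c = np.zeros(H)
        fwd = []
        for t in range(n):
            h, c = lstm_cell_ref(x[0, t], h, c, p.w_fwd.data, p.u_fwd.data, p.b_fwd.data)
            fwd.append(h)
        h = c = np.zeros(H)
        bwd = [None] * n
        for t in reversed(range(n)):
            h, c = lstm_cell_ref(x[0, t], h, c, p.w_bwd.data, p.u_bwd.data, p.b_bwd.data)
            bwd[t] = h
        want = np.concatenate([np.stack(fwd), np.stack(bwd)], axis=-1)
        np.testing.assert_allclose(out, want, atol=1e-8)

    def test_trailing_padding_does_not_change_valid_outputs(self, rng):
        D, H, n = 3, 2, 4
        p = make_bilstm_params(rng, D, H)
        x = rng.normal(size=(1, n, D))
        mask = np.array([[1.0, 1.0, 1.0, 0.0]])
        out_padded = bilstm_encode(Tensor(x), mask, p).data[0, :3]
        out_short = bilstm_encode(Tensor(x[:, :3]), np.ones((1, 3)), p).data[0]
        np.testing.assert_allclose(out_padded, out_short, atol=1e-12)

    def test_aggregate_is_bilstm_on_concatenated_sequence(self, rng):
        p = make_bilstm_params(rng, 5, 3)
        c_seq = Tensor(rng.normal(size=(1, 4, 5)))
        mask = np.ones((1, 4))
        np.testing.assert_array_equal(
            aggregate(c_seq, mask, p).data, bilstm_encode(c_seq, mask, p).data
        )


class TestAttention:
    def test_orthonormal_literal_worked_example(self):
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        res = interaction_attention(
            Tensor(u[None, :]), Tensor(np.stack([u, v])),
            np.ones(1), np.ones(2), norm_mode="literal",
        )
        np.testing.assert_allclose(res.sim.data, [[1.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(res.a_fwd.data, [[1.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(res.attended_a.data[0], u, atol=1e-12)

    def test_identical_rows_softmax_gives_uniform_weights(self):
        ea = np.ones((3, 2))
        eb = np.ones((4, 2))
        mask_b = np.array([1.0, 1.0, 1.0, 0.0])
        res = interaction_attention(Tensor(ea), Tensor(eb), np.ones(3), mask_b)
        np.testing.assert_allclose(res.a_fwd.data[:, :3], 1.0 / 3.0, atol=1e-9)
        np.testing.assert_array_equal(res.a_fwd.data[:, 3], 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            ea = rng.normal(size=(4, 3))
            eb = rng.normal(size=(4, 3))
            mask_a = np.array([1.0, 1.0, 1.0, 0.0])
            mask_b = np.array([1.0, 1.0, 0.0, 0.0])
            res = interaction_attention(Tensor(ea), Tensor(eb), mask_a, mask_b)
            sim, a_fwd, a_bwd, att_a, att_b = attention_ref(ea, eb, mask_a, mask_b)
            assert np.abs(res.sim.data - sim).max() < 1e-10
            assert np.abs(res.a_fwd.data - a_fwd).max() < 1e-10
            assert np.abs(res.a_bwd.data - a_bwd).max() < 1e-10
            assert np.abs(res.attended_a.data - att_a).max() < 1e-10
            assert np.abs(res.attended_b.data - att_b).max() < 1e-10

    def test_rows_sum_to_one_and_masked_columns_zero(self, rng):
        ea, eb = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        mask_a = np.array([1.0, 1, 1, 1, 0])
        mask_b = np.array([1.0, 1, 1, 0, 0])
        res = interaction_attention(Tensor(ea), Tensor(eb), mask_a, mask_b)
        np.testing.assert_allclose(res.a_fwd.data.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(res.a_fwd.data[:, mask_b == 0], 0.0)

    def test_literal_mode_rejects_nonpositive_row_sum(self):
        ea = np.array([[1.0, 0.0]])
        eb = np.array([[-1.0, 0.0]])
        with pytest.raises(ValueError, match="softmax"):
            interaction_attention(Tensor(ea), Tensor(eb), np.ones(1), np.ones(1), norm_mode="literal")


class TestConcat:
    def test_dims_and_order(self, rng):
        h = rng.normal(size=(3, 4))
        att = rng.normal(size=(3, 3))
        out = concat_representation(Tensor(h), Tensor(att)).data
        assert out.shape == (3, 7)
        np.testing.assert_array_equal(out[:, :4], h)
        np.testing.assert_array_equal(out[:, 4:], att)

    def test_zero_attended_block(self, rng):
        h = rng.normal(size=(3, 4))
        out = concat_representation(Tensor(h), Tensor(np.zeros((3, 2)))).data
        np.testing.assert_array_equal(out[:, 4:], 0.0)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            concat_representation(Tensor(rng.normal(size=(3, 4))), Tensor(rng.normal(size=(2, 4))))


def make_capsule_params(rng, F, width, I, C, J, d, zero_bias=False):
    return CapsuleParams(
        conv_w=Tensor(rng.normal(size=(width * F, I * C)) * 0.3),
        conv_b=Tensor(np.zeros(I * C) if zero_bias else rng.normal(size=I * C) * 0.3),
        caps_w=Tensor(rng.normal(size=(C, J * d)) * 0.3),
        caps_b=Tensor(np.zeros(d) if zero_bias else rng.normal(size=d) * 0.3),
        width=width,
        n_channels=I,
        n_capsules=J,
        capsule_dim=d,
    )


class TestCapsuleFeatures:
    def test_output_shape_published_sizes(self, rng):
        # 6 capsules of dimension 50, as in the published configuration
        I, J, d = 4, 6, 50
        p = make_capsule_params(rng, F=8, width=3, I=I, C=5, J=J, d=d)
        S = Tensor(rng.normal(size=(7, 8)))
        assert capsule_features(S, np.ones(7), p).shape == (I, J, d)

    def test_zero_input_zero_bias_gives_zero_predictions(self, rng):
        p = make_capsule_params(rng, F=4, width=3, I=2, C=3, J=2, d=3, zero_bias=True)
        out = capsule_features(Tensor(np.zeros((5, 4))), np.ones(5), p, activation="relu")
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(20):
            I, C, J, d = 2, 3, 2, 3
            p = make_capsule_params(rng, F=4, width=3, I=I, C=C, J=J, d=d)
            S = rng.normal(size=(6, 4))
            mask = np.array([1.0, 1, 1, 1, 0, 0])
            got = capsule_features(Tensor(S), mask, p).data
            want = capsule_features_ref(
                S, mask, p.conv_w.data, p.conv_b.data, p.caps_w.data, p.caps_b.data,
                width=3, I=I, J=J, d=d,
            )
            assert np.abs(got - want).max() < 1e-10

    def test_sequence_shorter_than_kernel_raises(self, rng):
        p = make_capsule_params(rng, F=4, width=3, I=2, C=3, J=2, d=3)
        with pytest.raises(ValueError):
            capsule_features(Tensor(np.zeros((2, 4))), np.ones(2), p)


class TestSquash:
    def test_printed_closed_form_three_four(self):
        out = squash(Tensor(np.array([3.0, 4.0])), variant="printed").data
        np.testing.assert_allclose(out, [0.5, 2.0 / 3.0], atol=1e-12)
        assert abs(np.linalg.norm(out) - 5.0 / 6.0) < 1e-12

    def test_zero_fixed_point_both_variants(self):
        for variant in ("printed", "standard"):
            np.testing.assert_array_equal(squash(Tensor(np.zeros(4)), variant).data, 0.0)

    def test_standard_variant_closed_form(self):
        s = np.array([3.0, 4.0])
        out = squash(Tensor(s), variant="standard").data
        np.testing.assert_allclose(out, s * 5.0 / 26.0, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6))
    def test_norm_below_one_and_direction_preserved(self, values):
        s = np.array(values)
        out = squash(Tensor(s), variant="printed").data
        assert np.linalg.norm(out) < 1.0
        norm = np.linalg.norm(s)
        np.testing.assert_allclose(out, squash_ref(s, "printed"), atol=1e-12)
        assert abs(np.linalg.norm(out) - norm / (1.0 + norm)) < 1e-9

    def test_norm_strictly_increasing_in_input_norm(self):
        norms = np.linspace(0.1, 20, 30)
        outs = [np.linalg.norm(squash(Tensor(np.array([r, 0.0]))).data) for r in norms]
        assert np.all(np.diff(outs) > 0)


class TestDynamicRouting:
    def test_single_iteration_closed_form(self, rng):
        I, J, d = 4, 3, 5
        u_hat = rng.normal(size=(I, J, d))
        d_out, couplings = dynamic_routing(Tensor(u_hat), T=1)
        np.testing.assert_allclose(couplings.data, 1.0 / J, atol=1e-12)
        expected = np.stack([squash_ref(u_hat[:, j, :].sum(axis=0) / J) for j in range(J)])
        np.testing.assert_allclose(d_out.data, expected, atol=1e-12)

    def test_degenerate_single_capsule(self, rng):
        u_hat = rng.normal(size=(1, 1, 4))
        d_out, couplings = dynamic_routing(Tensor(u_hat), T=3)
        np.testing.assert_allclose(couplings.data, 1.0, atol=1e-12)
        np.testing.assert_allclose(d_out.data[0], squash_ref(u_hat[0, 0]), atol=1e-12)

    def test_matches_scalar_oracle_20_instances(self, rng):
        for _ in range(20):
            u_hat = rng.normal(size=(4, 3, 5))
            d_out, couplings = dynamic_routing(Tensor(u_hat), T=3)
            want_d, want_c = routing_ref(u_hat, T=3)
            assert np.abs(d_out.data - want_d).max() < 1e-8
            assert np.abs(couplings.data - want_c).max() < 1e-8

    def test_coupling_conservation_every_iteration(self, rng):
        u_hat = rng.normal(size=(5, 4, 3)) * 2.0
        history: list = []
        dynamic_routing(Tensor(u_hat), T=4, coupling_history=history)
        assert len(history) == 4
        for c in history:
            np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-6)
            assert np.all((c > 0.0) & (c < 1.0))

    def test_output_norm_below_one(self, rng):
        d_out, _ = dynamic_routing(Tensor(rng.normal(size=(4, 3, 5)) * 10), T=3)
        assert np.all(np.linalg.norm(d_out.data, axis=-1) < 1.0)

    def test_deterministic_repeat(self, rng):
        u_hat = rng.normal(size=(4, 3, 5))
        a, _ = dynamic_routing(Tensor(u_hat), T=3)
        b, _ = dynamic_routing(Tensor(u_hat), T=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_iterations_raise(self, rng):
        with pytest.raises(ValueError):
            dynamic_routing(Tensor(rng.normal(size=(2, 2, 2))), T=0)


class TestPoolCapsules:
    def test_single_channel_equals_squash(self, rng):
        u_hat = rng.normal(size=(1, 3, 4))
        for mode in ("max", "mean"):
            out = pool_capsules(Tensor(u_hat), mode).data
            want = np.stack([squash_ref(u_hat[0, j]) for j in range(3)])
            np.testing.assert_allclose(out, want, atol=1e-12)

    def test_mean_of_opposite_predictions_is_zero(self, rng):
        u = rng.normal(size=(1, 2, 4))
        stacked = np.concatenate([u, -u], axis=0)
        np.testing.assert_allclose(pool_capsules(Tensor(stacked), "mean").data, 0.0, atol=1e-12)

    def test_max_matches_brute_force(self, rng):
        u_hat = rng.normal(size=(3, 2, 4))
        got = pool_capsules(Tensor(u_hat), "max").data
        want = np.stack([squash_ref(u_hat[:, j, :].max(axis=0)) for j in range(2)])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError):
            pool_capsules(Tensor(rng.normal(size=(2, 2, 2))), "median")


class TestFuse:
    def test_identity_case(self, rng):
        c = rng.normal(size=6)
        out = fuse(Tensor(c), Tensor(c)).data
        assert out.shape == (19,)
        np.testing.assert_array_equal(out[12:18], 0.0)
        assert abs(out[18] - 1.0) < 1e-9

    def test_orthogonal_gives_zero_cosine(self):
        c1 = np.array([1.0, 0.0])
        c2 = np.array([0.0, 1.0])
        assert abs(fuse(Tensor(c1), Tensor(c2)).data[-1]) < 1e-12

    def test_zero_vector_cosine_convention(self, rng):
        out = fuse(Tensor(np.zeros(4)), Tensor(rng.normal(size=4))).data
        assert out[-1] == 0.0

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fuse(Tensor(np.zeros(4)), Tensor(np.zeros(5)))


class TestPredictHead:
    def make_params(self, rng, in_dim, hidden):
        return PredictHeadParams(
            w1=Tensor(rng.normal(size=(in_dim, hidden))),
            b1=Tensor(np.zeros(hidden)),
            w2=Tensor(rng.normal(size=(hidden, 1))),
            b2=Tensor(np.zeros(1)),
        )

    def test_zero_logit_gives_half(self, rng):
        p = self.make_params(rng, 4, 3)
        p.w2 = Tensor(np.zeros((3, 1)))
        out = predict_head(Tensor(np.ones(4)), p)
        assert abs(out.data[0] - 0.5) < 1e-12

    def test_probability_increasing_in_logit(self, rng):
        p = self.make_params(rng, 2, 2)
        # make the hidden layer the identity-ish map so the logit is monotone in the input
        p.w1 = Tensor(np.eye(2))
        p.w2 = Tensor(np.ones((2, 1)))
        xs = [predict_head(Tensor(np.array([v, v])), p).data[0] for v in np.linspace(0.1, 3, 10)]
        assert np.all(np.diff(xs) > 0)
        assert all(0.0 < x < 1.0 for x in xs)


class TestRoutingGradients:
    def test_autodiff_matches_finite_differences_through_capsule_routing(self, rng):
        I, J, d = 3, 2, 4
        u0 = rng.normal(size=(I, J, d))
        weights = rng.normal(size=(J, d))

        def loss_value(u):
            d_out, _ = dynamic_routing(Tensor(u), T=3)
            return float((d_out.data * weights).sum())

        u = Tensor(u0.copy(), requires_grad=True)
        d_out, _ = dynamic_routing(u, T=3)
        (d_out * Tensor(weights)).sum().backward()

        numeric = np.zeros_like(u0)
        eps = 1e-6
        flat_n = numeric.reshape(-1)
        flat_u = u0.reshape(-1)
        for k in range(flat_u.size):
            orig = flat_u[k]
            flat_u[k] = orig + eps
            hi = loss_value(u0)
            flat_u[k] = orig - eps
            lo = loss_value(u0)
            flat_u[k] = orig
            flat_n[k] = (hi - lo) / (2 * eps)
        denom = max(np.abs(numeric).max(), 1e-12)
        assert np.abs(u.grad - numeric).max() / denom < 1e-4
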