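"""GRU cell semantics, stack composition, auto-encoder round trips,
layer-wise pretraining, and the cell-level gradient check."""

import numpy as np
import pytest

from dcra.gru import (GRULayer, GRULayerParams, GRUStack,
                      PretrainConfig, StackSpec, build_dra, decode,
                      default_encoder_spec, encode, gru_cell_step,
                      init_gru_layer, pretrain_layers, run_stack)
from dcra.nn import Tensor


def brute_force_gru_step(params, x, h_prev):
    """Scalar-by-scalar evaluation of the four gate equations.

    Independent of the vectorized implementation: every sum is an explicit
    python loop over matrix entries.
    """
    def col_dot(W, v, j):
        return sum(W[i, j] * v[i] for i in range(len(v)))

    u = params.W_xz.shape[1]
    z = np.empty(u)
    r = np.empty(u)
    g = np.empty(u)
    h = np.empty(u)
    Wd = {k: getattr(params, k).data for k in
          ("W_xz", "W_xr", "W_xg", "W_hz", "W_hr", "W_hg", "b_z", "b_r", "b_g")}
    for j in range(u):
        z[j] = 1 / (1 + np.exp(-(col_dot(Wd["W_xz"], x, j)
                                 + col_dot(Wd["W_hz"], h_prev, j) + Wd["b_z"][j])))
        r[j] = 1 / (1 + np.exp(-(col_dot(Wd["W_xr"], x, j)
                                 + col_dot(Wd["W_hr"], h_prev, j) + Wd["b_r"][j])))
    rh = r * h_prev
    for j in range(u):
        g[j] = np.tanh(col_dot(Wd["W_xg"], x, j) + col_dot(Wd["W_hg"], rh, j)
                       + Wd["b_g"][j])
        h[j] = z[j] * h_prev[j] + (1 - z[j]) * g[j]
    return h, (z, r, g)


def random_layer(rng, input_dim, units):
    return init_gru_layer(rng, input_dim, units)


class TestGRUCell:
    def test_zero_parameters_halve_previous_state(self, rng):
        p = init_gru_layer(rng, 3, 4)
        for t in p.tensors():
            t.data[...] = 0.0
        h0 = rng.normal(size=4)
        h, (z, r, g) = gru_cell_step(p, rng.normal(size=3), h0)
        assert np.allclose(z, 0.5) and np.allclose(r, 0.5) and np.allclose(g, 0.0)
        assert np.allclose(h, 0.5 * h0)

    def test_saturated_update_gate_carries_state_through(self, rng):
        p = init_gru_layer(rng, 3, 4)
        p.b_z.data[...] = 50.0  # z -> 1, so h ~ h_prev exactly
        h0 = rng.normal(size=4)
        h, _ = gru_cell_step(p, rng.normal(size=3), h0)
        assert np.allclose(h, h0, atol=1e-9)

    def test_matches_equation_by_equation_oracle(self, rng):
        """Vectorized cell equals the scalar brute-force oracle to 1e-12."""
        for _ in range(100):
            din = rng.integers(1, 5)
            u = rng.integers(1, 5)
            p = init_gru_layer(rng, din, u)
            for t in p.tensors():
                t.data[...] = rng.normal(size=t.data.shape)
            x = rng.normal(size=din)
            h0 = rng.normal(size=u)
            h, _ = gru_cell_step(p, x, h0)
            h_ref, _ = brute_force_gru_step(p, x, h0)
            assert np.allclose(h, h_ref, atol=1e-12)

    def test_gate_bounds_and_convex_combination(self, rng):
        p = init_gru_layer(rng, 4, 6)
        for _ in range(50):
            x = rng.normal(scale=3.0, size=4)
            h0 = rng.normal(scale=3.0, size=6)
            h, (z, r, g) = gru_cell_step(p, x, h0)
            assert ((z > 0) & (z < 1)).all() and ((r > 0) & (r < 1)).all()
            assert ((g > -1) & (g < 1)).all()
            lo, hi = np.minimum(h0, g), np.maximum(h0, g)
            assert ((h >= lo - 1e-12) & (h <= hi + 1e-12)).all()

    def test_shape_mismatch_raises(self, rng):
        p = init_gru_layer(rng, 3, 4)
        with pytest.raises(ValueError, match="dimension"):
            gru_cell_step(p, np.zeros(5), np.zeros(4))

    def test_gradient_check_two_unit_cell(self, rng):
        """Finite-difference gradient of a reconstruction-style loss matches
        backprop for every parameter of a 2-unit cell (rel err < 1e-4)."""
        p = init_gru_layer(rng, 2, 2)
        x = rng.normal(size=(3, 2))  # T=3 sequence
        target = rng.normal(size=2)

        def loss_value():
            h = np.zeros(2)
            for t in range(3):
                h, _ = gru_cell_step(p, x[t], h)
            return float(((h - target) ** 2).sum())

        h = Tensor(np.zeros(2))
        for t in range(3):
            h, _ = gru_cell_step(p, Tensor(x[t]), h)
        loss = ((h - Tensor(target)) ** 2).sum()
        loss.backward()

        eps = 1e-6
        for tensor in p.tensors():
            flat = tensor.data.reshape(-1)
            gflat = tensor.grad.reshape(-1)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                fp = loss_value()
                flat[i] = orig - eps
                fm = loss_value()
                flat[i] = orig
                num = (fp - fm) / (2 * eps)
                denom = max(abs(num), abs(gflat[i]), 1e-8)
                assert abs(num - gflat[i]) / denom < 1e-4


class TestRunStack:
    def test_single_layer_equals_direct_iteration(self, rng):
        p = init_gru_layer(rng, 3, 4)
        stack = GRUStack([GRULayer(params=p, activation="linear")])
        X = rng.normal(size=(5, 3))
        seqs, finals = run_stack(stack, X)
        h = np.zeros(4)
        for t in range(5):
            h, _ = gru_cell_step(p, X[t], h)
            assert np.allclose(seqs[0][t], h)
        assert np.allclose(finals[0], h)

    def test_two_layer_stack_matches_hand_unrolled_oracle(self, rng):
        p1 = init_gru_layer(rng, 2, 3)
        p2 = init_gru_layer(rng, 3, 2)
        stack = GRUStack([GRULayer(params=p1, activation="linear"),
                          GRULayer(params=p2, activation="linear")])
        X = rng.normal(size=(3, 2))
        seqs, _ = run_stack(stack, X)
        # oracle: full layer-1 sequence first, then layer 2 consumes it
        h1 = np.zeros(3)
        seq1 = []
        for t in range(3):
            h1, _ = gru_cell_step(p1, X[t], h1)
            seq1.append(h1)
        h2 = np.zeros(2)
        for t in range(3):
            h2, _ = gru_cell_step(p2, seq1[t], h2)
            assert np.allclose(seqs[1][t], h2, atol=1e-12)

    def test_empty_sequence_rejected(self, rng):
        stack = GRUStack([GRULayer(params=init_gru_layer(rng, 2, 2))])
        with pytest.raises(ValueError):
            run_stack(stack, np.zeros((0, 2)))

    def test_determinism(self, rng):
        stack = default_encoder_spec(4).build(4, rng)
        X = rng.normal(size=(6, 4))
        a = run_stack(stack, X)[1][-1]
        b = run_stack(stack, X)[1][-1]
        assert np.array_equal(a, b)


class TestAutoEncoder:
    def test_reconstruction_shape_matches_input(self, rng):
        dra = build_dra(7, rng, code_dim=3)
        for T in (1, 4, 9):
            X = rng.normal(size=(T, 7))
            code = encode(dra, X)
            assert code.shape == (3,)
            rec = decode(dra, code, T)
            assert rec.shape == (T, 7)

    def test_code_invariant_to_decoder_parameters(self, rng):
        dra = build_dra(5, rng, code_dim=2)
        X = rng.normal(size=(4, 5))
        c1 = encode(dra, X)
        for layer in dra.decoder.layers:
            for t in layer.params.tensors():
                t.data += rng.normal(size=t.data.shape)
        assert np.array_equal(c1, encode(dra, X))

    def test_decode_rejects_nonpositive_length(self, rng):
        dra = build_dra(3, rng, code_dim=2)
        with pytest.raises(ValueError):
            decode(dra, np.zeros(2), 0)

    def test_overfit_constant_sequence_round_trip(self, rng):
        """A tiny auto-encoder fitted to one constant sequence reproduces it."""
        from dcra.nn import Adam

        spec_e = StackSpec(units=(2,), activations=("linear",), batch_norm=(False,))
        spec_d = StackSpec(units=(2,), activations=("sigmoid",), batch_norm=(False,))
        dra = build_dra(2, rng, code_dim=1, encoder_spec=spec_e, decoder_spec=spec_d)
        X = np.full((1, 4, 2), 0.6)
        opt = Adam(dra.trainable(), lr=0.05)
        for _ in range(200):
            code = encode(dra, X, training=True, tape=True)
            rec = decode(dra, code, 4, training=True, tape=True)
            loss = ((rec - Tensor(X)) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        rec = decode(dra, encode(dra, X), 4)
        assert np.allclose(rec, X, atol=0.05)


class TestPretraining:
    def test_zero_steps_returns_initialization_unchanged(self, small_session):
        spec = default_encoder_spec(8)
        cfg = PretrainConfig(steps=0, seed=3)
        stack, traces = pretrain_layers(small_session.features_e, spec, cfg)
        ref, _ = pretrain_layers(small_session.features_e, spec, cfg)
        for la, lb in zip(stack.layers, ref.layers):
            for ta, tb in zip(la.params.tensors(), lb.params.tensors()):
                assert np.array_equal(ta.data, tb.data)
        assert all(len(t) == 0 for t in traces)

    def test_layer1_loss_decreases(self, small_session):
        spec = default_encoder_spec(8)
        _, traces = pretrain_layers(small_session.features_e, spec,
                                    PretrainConfig(steps=200, seed=3))
        t1 = traces[0]
        assert t1[-1] < t1[0]

    def test_stacking_dimensions_chain(self, small_session):
        spec = default_encoder_spec(8)
        stack, _ = pretrain_layers(small_session.features_e, spec,
                                   PretrainConfig(steps=2, seed=0))
        assert stack.layers[1].params.input_dim == stack.layers[0].params.units
        assert stack.layers[2].params.input_dim == stack.layers[1].params.units


def test_layer_params_shape_validation(rng):
    with pytest.raises(ValueError):
        GRULayerParams(
            W_xz=Tensor(np.zeros((3, 4))), W_xr=Tensor(np.zeros((3, 4))),
            W_xg=Tensor(np.zeros((3, 4))), W_hz=Tensor(np.zeros((4, 4))),
            W_hr=Tensor(np.zeros((4, 4))), W_hg=Tensor(np.zeros((4, 4))),
            b_z=Tensor(np.zeros(4)), b_r=Tensor(np.zeros(4)),
            b_g=Tensor(np.zeros(5)),
        )


def test_table_architecture_symmetry(rng):
    """Default stacks mirror each other: d -> 20 -> 16 -> [10] -> 16 -> 20 -> d."""
    dra = build_dra(36, rng, code_dim=10)
    enc_units = [l.params.units for l in dra.encoder.layers]
    dec_units = [l.params.units for l in dra.decoder.layers]
    assert enc_units == [36, 20, 16]
    assert dec_units == [16, 20, 36]
    assert dra.code_dim == 10
    assert dra.decoder.layers[-1].activation == "sigmoid"
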