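"""LSTM pathway (gate equations, BPTT) and the tiny transformer pathway."""

import math

import numpy as np
import pytest

import dualner as d
from dualner.encoders import (
    LstmParams,
    TinyTransformer,
    TransformerConfig,
    lstm_backward,
    lstm_forward,
)


def scalar_lstm_step(p: LstmParams, x, h_prev, c_prev):
    """Independent scalar-loop oracle for one LSTM step."""
    n = p.units
    h_out, c_out = np.zeros(n), np.zeros(n)
    for j in range(n):
        z = [0.0] * 4
        for gate in range(4):
            col = gate * n + j
            z[gate] = (
                sum(x[a] * p.w[a, col] for a in range(len(x)))
                + sum(h_prev[a] * p.u[a, col] for a in range(n))
                + p.b[col]
            )
        f = 1 / (1 + math.exp(-z[0]))
        i = 1 / (1 + math.exp(-z[1]))
        o = 1 / (1 + math.exp(-z[2]))
        g = math.tanh(z[3])
        c_out[j] = f * c_prev[j] + i * g
        h_out[j] = o * math.tanh(c_out[j])
    return h_out, c_out


class TestLstmStep:
    def test_zero_weights_closed_form(self, rng):
        p = LstmParams(np.zeros((3, 8)), np.zeros((2, 8)), np.zeros(8))
        c_prev = rng.normal(size=2)
        h, c = d.lstm_step(p, rng.normal(size=3), rng.normal(size=2), c_prev)
        # all gates sigmoid(0)=0.5, candidate tanh(0)=0
        assert np.allclose(c, 0.5 * c_prev)
        assert np.allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_zero_input_and_states(self):
        p = LstmParams(np.zeros((3, 8)), np.zeros((2, 8)), np.zeros(8))
        h, c = d.lstm_step(p, np.zeros(3), np.zeros(2), np.zeros(2))
        assert np.allclose(h, 0.0) and np.allclose(c, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = LstmParams.init(3, 4, rng)
        x, h0, c0 = rng.normal(size=3), rng.normal(size=4), rng.normal(size=4)
        h1, c1 = d.lstm_step(p, x, h0, c0)
        h2, c2 = scalar_lstm_step(p, x, h0, c0)
        assert np.allclose(h1, h2, atol=1e-6)
        assert np.allclose(c1, c2, atol=1e-6)

    def test_gates_strictly_bounded(self, rng):
        p = LstmParams.init(5, 6, rng)
        x = rng.normal(scale=10, size=5)
        z = x @ p.w + rng.normal(size=6) @ p.u + p.b
        from dualner.encoders import sigmoid

        gates = sigmoid(z)
        assert np.all(gates > 0) and np.all(gates < 1)

    def test_dimension_mismatch(self, rng):
        p = LstmParams.init(3, 4, rng)
        with pytest.raises(ValueError):
            d.lstm_step(p, np.zeros(5), np.zeros(4), np.zeros(4))


class TestLstmEncode:
    def test_length_one_equals_single_step(self, rng):
        p = LstmParams.init(3, 4, rng)
        x = rng.normal(size=(1, 3))
        out = d.lstm_encode(p, x, np.ones(1))
        h, _ = d.lstm_step(p, x[0], np.zeros(4), np.zeros(4))
        assert np.allclose(out[0], h)

    def test_matches_step_by_step_oracle(self, rng):
        p = LstmParams.init(3, 5, rng)
        x = rng.normal(size=(8, 3))
        out = d.lstm_encode(p, x, np.ones(8))
        h, c = np.zeros(5), np.zeros(5)
        for t in range(8):
            h, c = d.lstm_step(p, x[t], h, c)
            assert np.allclose(out[t], h, atol=1e-5)

    def test_fully_padded_mask_gives_zero_output(self, rng):
        p = LstmParams.init(3, 4, rng)
        out = d.lstm_encode(p, rng.normal(size=(5, 3)), np.zeros(5))
        assert np.allclose(out, 0.0)

    def test_backward_direction_mirrors_reversed_forward(self, rng):
        pf = LstmParams.init(3, 4, rng)
        pb = LstmParams.init(3, 4, rng)
        x = rng.normal(size=(6, 3))
        both = d.lstm_encode(pf, x, np.ones(6), params_bwd=pb)
        # the backward half equals running pb forward over the reversed input
        rev = d.lstm_encode(pb, x[::-1], np.ones(6))[::-1]
        assert np.allclose(both[:, 4:], rev, atol=1e-12)
        assert np.allclose(both[:, :4], d.lstm_encode(pf, x, np.ones(6)))

    def test_empty_sequence_rejected(self, rng):
        p = LstmParams.init(3, 4, rng)
        with pytest.raises(ValueError):
            d.lstm_encode(p, np.zeros((0, 3)), np.zeros(0))

    def test_bptt_matches_finite_differences(self, rng):
        p = LstmParams.init(3, 4, rng)
        x = rng.normal(size=(2, 5, 3))
        mask = np.ones((2, 5))
        mask[1, 3:] = 0.0
        d_h = rng.normal(size=(2, 5, 4))
        _, cache = lstm_forward(p, x, mask)
        grads, d_x = lstm_backward(p, cache, d_h)
        eps = 1e-6

        def objective(params, inp):
            h, _ = lstm_forward(params, inp, mask)
            return float((h * d_h).sum())

        for arr, g, idx in [
            (p.w, grads.w, (1, 2)),
            (p.u, grads.u, (0, 7)),
            (p.b, grads.b, (5,)),
        ]:
            orig = arr[idx]
            arr[idx] = orig + eps
            hi = objective(p, x)
            arr[idx] = orig - eps
            lo = objective(p, x)
            arr[idx] = orig
            assert abs((hi - lo) / (2 * eps) - g[idx]) < 1e-5
        x2 = x.copy()
        x2[0, 2, 1] += eps
        x3 = x.copy()
        x3[0, 2, 1] -= eps
        fd = (objective(p, x2) - objective(p, x3)) / (2 * eps)
        assert abs(fd - d_x[0, 2, 1]) < 1e-5

    def test_masked_steps_receive_no_gradient(self, rng):
        p = LstmParams.init(3, 4, rng)
        x = rng.normal(size=(1, 5, 3))
        mask = np.ones((1, 5))
        mask[0, 3:] = 0.0
        _, cache = lstm_forward(p, x, mask)
        _, d_x = lstm_backward(p, cache, np.ones((1, 5, 4)))
        assert np.allclose(d_x[0, 3:], 0.0)


class TestTinyTransformer:
    @pytest.fixture()
    def encoder(self):
        return TinyTransformer.from_charset(
            set("abcdefgh"), TransformerConfig(hidden=16, n_layers=2, n_heads=2, ffn=24, seed=9)
        )

    def test_deterministic_across_builds(self, encoder):
        other = TinyTransformer.from_charset(
            set("abcdefgh"), TransformerConfig(hidden=16, n_layers=2, n_heads=2, ffn=24, seed=9)
        )
        a = encoder.encode(list("abcd"))
        b = other.encode(list("abcd"))
        assert np.array_equal(a, b)

    def test_one_row_per_character_markers_stripped(self, encoder):
        for n in (1, 3, 7):
            assert encoder.encode(list("abcdefgh"[:n])).shape == (n, 16)

    def test_single_character_perturbation_changes_output(self, encoder):
        a = encoder.encode(list("abcd"))
        b = encoder.encode(list("abed"))
        assert not np.allclose(a, b)

    def test_unknown_character_uses_unk_not_exception(self, encoder):
        out = encoder.encode(["a", "字", "b"])
        assert out.shape == (3, 16)
        again = encoder.encode(["a", "另", "b"])  # any unknown char: same UNK row path
        assert np.allclose(out, again)

    def test_batch_padding_matches_single(self, encoder):
        batch = [list("abc"), list("fgh" * 2)]
        out, mask = encoder.encode_batch(batch)
        assert out.shape == (2, 6, 16)
        assert mask[0, :3].all() and not mask[0, 3:].any()
        single = encoder.encode(batch[0])
        assert np.allclose(out[0, :3], single, atol=1e-10)
        assert np.allclose(out[0, 3:], 0.0)

    def test_checkpoint_round_trip(self, encoder, tmp_path):
        encoder.save(tmp_path / "enc")
        again = TinyTransformer.load(tmp_path / "enc")
        assert np.array_equal(encoder.encode(list("abcd")), again.encode(list("abcd")))

    def test_pathway_shape_contract(self, encoder, rng):
        # both pathways must emit length x h_model for the same sequence
        chars = list("abcdef")
        table = d.EmbeddingTable(
            {"<PAD>": 0, "<UNK>": 1, **{c: i + 2 for i, c in enumerate("abcdef")}},
            rng.normal(size=(8, 5)),
        )
        pf = LstmParams.init(5, 3, rng)
        pb = LstmParams.init(5, 3, rng)
        h_cat = d.lstm_encode(pf, table.lookup(chars), np.ones(6), params_bwd=pb)
        proj = rng.normal(size=(6, 16))
        t_mat = h_cat @ proj
        b_mat = encoder.encode(chars)
        assert t_mat.shape == b_mat.shape == (6, 16)
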