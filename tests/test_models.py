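"""Equation-level oracles and training-loop contracts for the recurrent models.

Every attention/context/loss operation is checked against an independent
explicit-loop or hand-unrolled computation at tiny sizes.
"""

import numpy as np
import pytest

import tangle.models as models
from tangle._autograd import Tensor
from tangle.claims_io import build_vocabulary, encode_batch
from tangle.models import (
    ModelConfig,
    bce_loss,
    bilstm_encode,
    build_model,
    context_vector,
    embed_items,
    init_lstm_params,
    predict_head,
    standard_attention,
    tangle_attention,
    train,
)
from .conftest import make_sequence

rng = np.random.default_rng(2024)


def small_config(**kw):
    base = dict(E=8, H=4, U=4, dropout=0.0, max_epochs=4, patience=2,
                batch_size=16, learning_rate=1e-2, seed=1)
    base.update(kw)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# embedding lookup
# ---------------------------------------------------------------------------

class TestEmbedItems:
    def test_row_selection_and_pad(self):
        W = rng.normal(size=(5, 3))
        W[0] = 0.0
        out = embed_items(np.array([[0, 2, 4]]), W)
        assert np.array_equal(out[0, 0], np.zeros(3))
        assert np.array_equal(out[0, 1], W[2])
        assert np.array_equal(out[0, 2], W[4])

    def test_matches_gather_loop(self):
        W = rng.normal(size=(7, 4))
        idx = rng.integers(0, 7, size=(3, 5))
        out = embed_items(idx, W)
        for n in range(3):
            for t in range(5):
                assert np.array_equal(out[n, t], W[idx[n, t]])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(IndexError):
            embed_items(np.array([[9]]), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# BiLSTM encoder
# ---------------------------------------------------------------------------

def reference_lstm(x, W, R, b, H):
    """Scalar reference recurrence (fused gates ordered i, f, g, o)."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    h, c = np.zeros(H), np.zeros(H)
    out = []
    for t in range(x.shape[0]):
        z = x[t] @ W + h @ R + b
        i, f = sig(z[:H]), sig(z[H:2 * H])
        g, o = np.tanh(z[2 * H:3 * H]), sig(z[3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        out.append(h.copy())
    return np.array(out)


class TestBiLSTM:
    def test_output_width_is_2H(self):
        p = {"fw": init_lstm_params(3, 5, rng), "bw": init_lstm_params(3, 5, rng)}
        out = bilstm_encode(rng.normal(size=(2, 4, 3)), np.ones((2, 4), bool), p)
        assert out.shape == (2, 4, 10)

    def test_matches_reference_recurrence(self):
        H, T = 1, 2
        p = {"fw": init_lstm_params(2, H, rng), "bw": init_lstm_params(2, H, rng)}
        x = rng.normal(size=(1, T, 2))
        out = bilstm_encode(x, np.ones((1, T), bool), p)
        fw = reference_lstm(x[0], p["fw"]["W"].data, p["fw"]["R"].data,
                            p["fw"]["b"].data, H)
        bw = reference_lstm(x[0, ::-1], p["bw"]["W"].data, p["bw"]["R"].data,
                            p["bw"]["b"].data, H)[::-1]
        assert np.allclose(out[0, :, :H], fw, atol=1e-10)
        assert np.allclose(out[0, :, H:], bw, atol=1e-10)

    def test_masked_prefix_leaves_state_zero(self):
        p = {"fw": init_lstm_params(2, 3, rng), "bw": init_lstm_params(2, 3, rng)}
        mask = np.array([[False, False, True]])
        out = bilstm_encode(rng.normal(size=(1, 3, 2)), mask, p)
        assert np.allclose(out[0, :2, :3], 0.0)  # forward states at padded steps

    def test_shape_mismatch_rejected(self):
        p = {"fw": init_lstm_params(2, 3, rng), "bw": init_lstm_params(2, 3, rng)}
        with pytest.raises(ValueError):
            bilstm_encode(rng.normal(size=(1, 3, 2)), np.ones((2, 3), bool), p)


# ---------------------------------------------------------------------------
# time span-guided attention
# ---------------------------------------------------------------------------

def tangle_params(H, U, lam_raw=0.0, seed=5):
    r = np.random.default_rng(seed)
    t = lambda *s: Tensor(r.normal(size=s), requires_grad=True)
    return {"W_x": t(2 * H, U), "b_x": t(U), "W_tau": t(2 * H, U), "b_tau": t(U),
            "lam_raw": Tensor(float(lam_raw), requires_grad=True),
            "W_alpha": t(U, 2 * H)}


class TestTangleAttention:
    def test_single_unmasked_step_softmax_is_one(self):
        p = tangle_params(1, 1)
        Hx, Ht = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        mask = np.array([False, False, True])
        alpha, omega = tangle_attention(Hx, Ht, mask, p)
        assert np.allclose(alpha[2], 1.0)
        assert np.allclose(omega[2], Hx[2])
        assert np.all(alpha[:2] == 0.0) and np.all(omega[:2] == 0.0)

    def test_hand_unrolled_scalar_computation(self):
        # T=2, H=1, U=1: unroll the whole mechanism with plain floats
        p = tangle_params(1, 1, lam_raw=0.3)
        Hx, Ht = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        alpha, omega = tangle_attention(Hx, Ht, np.ones(2, bool), p)
        lam = 1 / (1 + np.exp(-0.3))
        Wx, bx = p["W_x"].data, p["b_x"].data
        Wt, bt = p["W_tau"].data, p["b_tau"].data
        Wa = p["W_alpha"].data
        v = [lam * np.tanh(Hx[t] @ Wx + bx) + (1 - lam) * np.tanh(Ht[t] @ Wt + bt)
             for t in range(2)]
        logits = np.array([v[t] @ Wa for t in range(2)])  # (2, 2H)
        for j in range(2):  # softmax over time, per hidden unit
            e = np.exp(logits[:, j] - logits[:, j].max())
            a = e / e.sum()
            assert np.allclose(alpha[:, j], a, atol=1e-10)
            assert np.allclose(omega[:, j], Hx[:, j] * a, atol=1e-10)

    def test_lambda_one_ignores_span_stream(self):
        p = tangle_params(2, 3, lam_raw=40.0)  # sigmoid(40) == 1 to fp precision
        Hx = rng.normal(size=(4, 4))
        a1, _ = tangle_attention(Hx, rng.normal(size=(4, 4)), np.ones(4, bool), p)
        a2, _ = tangle_attention(Hx, rng.normal(size=(4, 4)), np.ones(4, bool), p)
        assert np.allclose(a1, a2, atol=1e-10)

    def test_all_masked_raises(self):
        p = tangle_params(1, 1)
        with pytest.raises(ValueError):
            tangle_attention(np.zeros((2, 2)), np.zeros((2, 2)),
                             np.zeros(2, bool), p)

    def test_per_unit_normalization_over_time(self):
        p = tangle_params(3, 2)
        N, T = 5, 7
        mask = rng.random((N, T)) < 0.7
        mask[:, -1] = True
        alpha, _ = tangle_attention(rng.normal(size=(N, T, 6)),
                                    rng.normal(size=(N, T, 6)), mask, p)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-5)


class TestContextVector:
    def test_all_ones_gives_column_sums(self):
        X = rng.normal(size=(4, 3))
        assert np.allclose(context_vector(np.ones((4, 6)), X), X.sum(axis=0))

    def test_all_zeros_gives_zero(self):
        assert np.allclose(context_vector(np.zeros((4, 6)),
                                          rng.normal(size=(4, 3))), 0.0)

    def test_matches_triple_loop_oracle_on_100_instances(self):
        for k in range(100):
            r = np.random.default_rng(k)
            T, H2, E = r.integers(1, 6), 2 * r.integers(1, 3), r.integers(1, 4)
            omega, X = r.normal(size=(T, H2)), r.normal(size=(T, E))
            expected = np.zeros(E)
            for j in range(H2):
                for e in range(E):
                    for t in range(T):
                        expected[e] += omega[t, j] * X[t, e]
            expected /= H2
            assert np.abs(context_vector(omega, X) - expected).max() <= 1e-5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            context_vector(np.zeros((4, 6)), np.zeros((5, 3)))


class TestStandardAttention:
    @staticmethod
    def params(Hp, U, seed=6):
        r = np.random.default_rng(seed)
        return {"W_t": Tensor(r.normal(size=(Hp, U))),
                "b": Tensor(r.normal(size=U)),
                "w_alpha": Tensor(r.normal(size=U))}

    def test_single_step(self):
        p = self.params(3, 2)
        h = rng.normal(size=(1, 3))
        alpha, c = standard_attention(h, np.ones(1, bool), p)
        assert np.allclose(alpha, [1.0])
        assert np.allclose(c, h[0])

    def test_identical_steps_uniform_weights(self):
        p = self.params(3, 2)
        h = np.tile(rng.normal(size=(1, 3)), (4, 1))
        alpha, _ = standard_attention(h, np.ones(4, bool), p)
        assert np.allclose(alpha, 0.25)

    def test_hand_softmax_T3(self):
        p = self.params(1, 1)
        h = np.array([[0.3], [-1.2], [2.0]])
        alpha, c = standard_attention(h, np.ones(3, bool), p)
        u = np.tanh(h @ p["W_t"].data + p["b"].data)
        s = (u * p["w_alpha"].data).ravel()
        e = np.exp(s - s.max())
        expected = e / e.sum()
        assert np.allclose(alpha, expected, atol=1e-10)
        assert np.allclose(c, (expected[:, None] * h).sum(axis=0))


class TestHeadAndLoss:
    @staticmethod
    def head(W0, b0, W1, b1):
        return {"W_0": Tensor(W0), "b_0": Tensor(b0),
                "W_1": Tensor(W1), "b_1": Tensor(b1)}

    def test_zero_weights_give_half(self):
        p = self.head(np.zeros((3, 2)), np.zeros(2), np.zeros((2, 1)), np.zeros(1))
        assert predict_head(np.ones(3), p) == pytest.approx(0.5)

    def test_negative_preactivation_gives_sigmoid_of_bias(self):
        p = self.head(-np.ones((3, 2)), np.zeros(2), rng.normal(size=(2, 1)),
                      np.array([0.7]))
        got = predict_head(np.ones(3), p)
        assert got == pytest.approx(1 / (1 + np.exp(-0.7)))

    def test_hand_computation_tiny_dims(self):
        W0, b0 = np.array([[0.5], [-0.25]]), np.array([0.1])
        W1, b1 = np.array([[2.0]]), np.array([-0.3])
        c = np.array([0.4, 0.8])
        hidden = max(float((c @ W0 + b0)[0]), 0.0)
        expected = 1 / (1 + np.exp(-(hidden * 2.0 - 0.3)))
        assert predict_head(c, self.head(W0, b0, W1, b1)) == pytest.approx(expected)

    def test_bce_closed_forms(self):
        assert bce_loss([1], [0.5]) == pytest.approx(np.log(2), abs=1e-9)
        assert bce_loss([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-6)

    def test_bce_matches_per_sample_loop(self):
        y = rng.integers(0, 2, size=20)
        p = rng.uniform(0.01, 0.99, size=20)
        expected = np.mean([-(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
                            for yi, pi in zip(y, p)])
        assert bce_loss(y, p) == pytest.approx(expected, abs=1e-10)

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([1, 0], [0.5])


# ---------------------------------------------------------------------------
# model-level invariants
# ---------------------------------------------------------------------------

def separable_sequences(n=50, seed=0):
    """Label = presence of code 'sig' somewhere in the sequence."""
    r = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        L = int(r.integers(4, 9))
        items = list(r.choice(["a", "b", "c"], size=L))
        y = i % 2
        if y:
            items[int(r.integers(0, L))] = "sig"
        seqs.append(make_sequence(items, r.integers(0, 20, size=L), f"s{i}", y))
    return seqs


@pytest.fixture(scope="module")
def separable_batch():
    seqs = separable_sequences()
    vocab = build_vocabulary(seqs)
    return encode_batch(seqs, vocab, 8), vocab


class TestModelInvariants:
    def test_padding_amount_does_not_change_prediction(self, separable_batch):
        _, vocab = separable_batch
        seqs = separable_sequences(8)
        model = build_model("tangle", small_config(), vocab.size)
        p1 = model.predict_proba(encode_batch(seqs, vocab, 10))
        p2 = model.predict_proba(encode_batch(seqs, vocab, 17))
        assert np.abs(p1 - p2).max() < 1e-5

    def test_lambda_limit_makes_tau_stream_irrelevant(self, separable_batch):
        batch, vocab = separable_batch
        model = build_model("tangle", small_config(), vocab.size)
        model.params["attn"]["lam_raw"].data = np.asarray(40.0)
        r = np.random.default_rng(0)
        p1 = model.predict_proba(batch)
        shuffled = batch.spans.copy()
        for i in range(len(batch)):  # permute spans within the real events
            live = np.flatnonzero(batch.mask[i])
            shuffled[i, live] = shuffled[i, r.permutation(live)]
        p2 = model.forward(batch.item_indices, shuffled, batch.mask).data
        assert np.abs(p1 - p2).max() < 1e-5

    def test_constant_tau_permutation_invariant_in_limit(self, separable_batch):
        batch, vocab = separable_batch
        model = build_model("tangle", small_config(), vocab.size)
        model.params["attn"]["lam_raw"].data = np.asarray(10.0)
        const = np.where(batch.mask, 7.0, 0.0)
        p1 = model.forward(batch.item_indices, const, batch.mask).data
        p2 = model.forward(batch.item_indices, const[:, ::-1][:, :], batch.mask).data
        assert np.abs(p1 - p2).max() < 1e-4  # sigmoid(10) ~ 1 - 4.5e-5


class TestTraining:
    def test_loss_decreases_on_separable_data(self, separable_batch):
        batch, vocab = separable_batch
        cfg = small_config(max_epochs=3, batch_size=50, learning_rate=3e-2)
        _, hist = train("baseline", batch, batch, cfg, vocab_size=vocab.size)
        losses = hist["train_loss"].tolist()
        assert losses[0] > losses[1] > losses[2]

    def test_early_stopping_on_constant_validation_loss(self, separable_batch,
                                                        monkeypatch):
        batch, vocab = separable_batch
        monkeypatch.setattr(models, "_epoch_loss", lambda m, b: 1.0)
        cfg = small_config(max_epochs=20, patience=3)
        _, hist = train("baseline", batch, batch, cfg, vocab_size=vocab.size)
        assert len(hist) == cfg.patience + 1

    def test_training_is_deterministic(self, separable_batch):
        batch, vocab = separable_batch
        cfg = small_config(max_epochs=2)
        _, h1 = train("tangle", batch, batch, cfg, vocab_size=vocab.size)
        _, h2 = train("tangle", batch, batch, cfg, vocab_size=vocab.size)
        assert h1["val_loss"].tolist() == h2["val_loss"].tolist()

    def test_lambda_stays_in_unit_interval(self, separable_batch):
        batch, vocab = separable_batch
        cfg = small_config(max_epochs=3)
        model, _ = train("tangle", batch, batch, cfg, vocab_size=vocab.size)
        assert 0.0 < model.lam < 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("gru", small_config(), 5)


def test_save_load_roundtrip(tmp_path, separable_batch):
    batch, vocab = separable_batch
    model = build_model("tangle", small_config(), vocab.size)
    path = tmp_path / "m.npz"
    model.save(path)
    loaded = models.TangleModel.load(path)
    assert np.allclose(model.predict_proba(batch), loaded.predict_proba(batch))
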