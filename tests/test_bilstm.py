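"""Peephole LSTM unit, bidirectional encoder, end-to-end gradients, training."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cnerkit.bilstm import (
    LstmParams,
    NeuralConfig,
    bilstm_encode,
    build_inputs,
    init_model,
    load_bilstm,
    loss_and_gradients,
    lstm_step,
    neural_loss,
    predict_bilstm_crf,
    save_bilstm,
    train_bilstm_crf,
)
from cnerkit.corpus import TagScheme, bio_to_entities

SCHEME = TagScheme()


def scalar_lstm_step(x, h_prev, c_prev, p: LstmParams):
    """Independent element-by-element evaluation of the five gate equations."""
    H = p.hidden
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    h_out, c_out = [], []
    for r in range(H):
        a_i = sum(p.W_xi[r, m] * x[m] for m in range(len(x)))
        a_i += sum(p.W_hi[r, m] * h_prev[m] for m in range(H))
        a_i += p.w_ci[r] * c_prev[r] + p.b_i[r]
        i = sig(a_i)
        a_f = sum(p.W_xf[r, m] * x[m] for m in range(len(x)))
        a_f += sum(p.W_hf[r, m] * h_prev[m] for m in range(H))
        a_f += p.w_cf[r] * c_prev[r] + p.b_f[r]
        f = sig(a_f)
        a_g = sum(p.W_xc[r, m] * x[m] for m in range(len(x)))
        a_g += sum(p.W_hc[r, m] * h_prev[m] for m in range(H))
        a_g += p.b_c[r]
        c = f * c_prev[r] + i * math.tanh(a_g)
        a_o = sum(p.W_xo[r, m] * x[m] for m in range(len(x)))
        a_o += sum(p.W_ho[r, m] * h_prev[m] for m in range(H))
        a_o += p.w_co[r] * c + p.b_o[r]
        o = sig(a_o)
        c_out.append(c)
        h_out.append(o * math.tanh(c))
    return np.array(h_out), np.array(c_out)


def zero_params(d_in: int, hidden: int) -> LstmParams:
    ref = LstmParams.init(d_in, hidden, np.random.default_rng(0))
    return LstmParams(**{k: np.zeros_like(v) for k, v in ref.arrays().items()})


class TestLstmStep:
    def test_zero_params_zero_cell_give_zero_output(self):
        h, c = lstm_step(np.ones(3), np.zeros(2), np.zeros(2), zero_params(3, 2))
        assert np.array_equal(h, np.zeros(2))
        assert np.array_equal(c, np.zeros(2))

    def test_zero_params_halve_previous_cell(self):
        c_prev = np.array([0.6, -0.4])
        _, c = lstm_step(np.ones(3), np.zeros(2), c_prev, zero_params(3, 2))
        assert np.allclose(c, 0.5 * c_prev)  # forget gate sigmoid(0) = 0.5

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(17)
        p = LstmParams.init(3, 3, rng)
        x, h_prev, c_prev = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        h, c = lstm_step(x, h_prev, c_prev, p)
        h_ref, c_ref = scalar_lstm_step(x, h_prev, c_prev, p)
        assert np.allclose(h, h_ref, atol=1e-12)
        assert np.allclose(c, c_ref, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lstm_step(np.ones(4), np.zeros(2), np.zeros(2), zero_params(3, 2))


class TestBilstmEncode:
    def test_single_position(self):
        rng = np.random.default_rng(2)
        fwd, bwd = LstmParams.init(3, 2, rng), LstmParams.init(3, 2, rng)
        X = rng.normal(size=(1, 3))
        ctx = bilstm_encode(X, fwd, bwd)
        hf, _ = lstm_step(X[0], np.zeros(2), np.zeros(2), fwd)
        hb, _ = lstm_step(X[0], np.zeros(2), np.zeros(2), bwd)
        assert np.allclose(ctx[0], np.concatenate([hf, hb]))

    def test_zero_params_give_zero_matrix(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        ctx = bilstm_encode(X, zero_params(3, 2), zero_params(3, 2))
        assert np.array_equal(ctx, np.zeros((4, 4)))

    def test_palindrome_symmetry_with_tied_directions(self):
        rng = np.random.default_rng(3)
        p = LstmParams.init(4, 3, rng)
        half = rng.normal(size=(5, 4))
        X = np.vstack([half, half[::-1][1:]])  # palindromic sequence
        ctx = bilstm_encode(X, p, p)
        n = X.shape[0]
        for t in range(n):
            s = n - 1 - t
            assert np.allclose(ctx[t][:3], ctx[s][3:], atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            bilstm_encode(np.zeros((0, 3)), zero_params(3, 2), zero_params(3, 2))


class TestBuildInputs:
    @pytest.fixture(scope="class")
    def model(self):
        return init_model(list("心房颤"), SCHEME, NeuralConfig(embed_dim=6, hidden=2), seed=0)

    def test_segmentation_onehot_tail(self, model):
        X = build_inputs(model, "心", ["B"])
        assert X.shape == (1, 10)
        assert np.array_equal(X[0, 6:], [1, 0, 0, 0])

    def test_oov_character_uses_unk_row(self, model):
        X = build_inputs(model, "鑫", ["S"])
        assert np.array_equal(X[0, :6], model.embeddings[model.vocab["<UNK>"]])

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            build_inputs(model, "心房", ["B"])


class TestNeuralLoss:
    @pytest.fixture(scope="class")
    def tiny(self):
        model = init_model(list("abc"), SCHEME, NeuralConfig(embed_dim=3, hidden=2, dropout=0.0), seed=0)
        return model, "abca", ["B", "M", "E", "S"], ["B-symptom", "I-symptom", "O", "B-test"]

    def test_untrained_loss_positive_and_finite(self, tiny):
        model, chars, segs, gold = tiny
        loss = neural_loss(model, chars, segs, gold)
        assert 0 < loss < np.inf

    def test_deterministic_without_dropout(self, tiny):
        model, chars, segs, gold = tiny
        assert neural_loss(model, chars, segs, gold) == neural_loss(model, chars, segs, gold)

    def test_end_to_end_gradient_matches_finite_differences(self, tiny):
        model, chars, segs, gold = tiny
        _, grads = loss_and_gradients(model, chars, segs, gold)
        eps = 1e-4
        for name, arr in model.parameters():
            g = grads[name]
            for k in np.ndindex(arr.shape):
                orig = arr[k]
                arr[k] = orig + eps
                lp = neural_loss(model, chars, segs, gold)
                arr[k] = orig - eps
                lm = neural_loss(model, chars, segs, gold)
                arr[k] = orig
                numeric = (lp - lm) / (2 * eps)
                if abs(numeric) + abs(g[k]) < 1e-10:
                    continue
                rel = abs(numeric - g[k]) / max(abs(numeric) + abs(g[k]), 1e-8)
                assert rel < 1e-4, (name, k, numeric, g[k])


class TestTraining:
    def test_empty_corpus_rejected(self, seg_fn):
        with pytest.raises(ValueError):
            train_bilstm_crf([], seg_fn)

    def test_same_seed_reproduces_identical_weights(self, small_sentences, seg_fn):
        cfg = NeuralConfig(embed_dim=8, hidden=4, epochs=2)
        corpus = small_sentences[:12]
        a = train_bilstm_crf(corpus, seg_fn, cfg, seed=3)
        b = train_bilstm_crf(corpus, seg_fn, cfg, seed=3)
        for (name, pa), (_, pb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb), name
        assert [h["train_loss"] for h in a.training_history] == [
            h["train_loss"] for h in b.training_history
        ]

    def test_single_sentence_memorization(self, small_sentences, seg_fn):
        sent = min(
            (s for s in small_sentences if any(l.startswith("B-") for l in s.labels)),
            key=len,
        )
        cfg = NeuralConfig(embed_dim=10, hidden=6, dropout=0.0, lr=0.01, epochs=150)
        model = train_bilstm_crf([sent], seg_fn, cfg, seed=1)
        pred = predict_bilstm_crf(model, sent.chars, seg_fn(sent.chars), doc_offset=sent.doc_offset)
        assert pred == bio_to_entities(sent, SCHEME)

    def test_serialization_round_trip_is_bit_exact(self, small_sentences, seg_fn, tmp_path):
        cfg = NeuralConfig(embed_dim=8, hidden=4, epochs=1)
        model = train_bilstm_crf(small_sentences[:8], seg_fn, cfg, seed=2)
        path = tmp_path / "model.npz"
        save_bilstm(model, path)
        loaded = load_bilstm(path)
        assert loaded.vocab == model.vocab
        assert loaded.config == model.config
        for (name, pa), (_, pb) in zip(model.parameters(), loaded.parameters()):
            assert np.array_equal(pa, pb), name

    def test_prediction_is_legal_bio_everywhere(self, small_sentences, seg_fn):
        cfg = NeuralConfig(embed_dim=8, hidden=4, epochs=1)
        model = train_bilstm_crf(small_sentences[:8], seg_fn, cfg, seed=4)
        chars = "鑫鑫鑫，鑫鑫。"
        mentions = predict_bilstm_crf(model, chars, seg_fn(chars))
        for ent in mentions:
            assert chars[ent.pos_b : ent.pos_e + 1] == ent.mention
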