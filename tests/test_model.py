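"""Attention mathematics, model forward contracts, and checkpointing."""

import numpy as np
import pytest

from smirtd.attention import multi_head_attention, scaled_dot_attention
from smirtd.corpus import build_vocab, tokenize
from smirtd.model import CheckpointError, ElectraModel, ModelConfig


@pytest.fixture()
def tiny_model():
    vocab = build_vocab(["CCO", "CCN", "c1ccc(Cl)cc1", "CC(=O)O"])
    cfg = ModelConfig(
        vocab_size=len(vocab), d_model=16, n_heads=2, n_layers=2, d_ffn=32,
        max_len=32, generator_width_fraction=0.5, seed=3,
    )
    return ElectraModel(cfg, vocab)


class TestScaledDotAttention:
    def test_single_key_gets_all_weight(self):
        out, w = scaled_dot_attention(np.ones((3, 4)), np.ones((1, 4)), np.array([[5.0, 7.0]]))
        assert np.allclose(w, 1.0)
        assert np.allclose(out, [[5.0, 7.0]] * 3)

    def test_zero_queries_give_uniform_weights(self):
        V = np.arange(12.0).reshape(4, 3)
        out, w = scaled_dot_attention(np.zeros((2, 5)), np.random.default_rng(0).normal(size=(4, 5)), V)
        assert np.allclose(w, 0.25)
        assert np.allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_hand_evaluated_2x2(self):
        # softmax([[1,0],[0,1]] / sqrt(2)) and its product with V, by hand
        Q = K = np.eye(2)
        V = np.array([[2.0, 0.0], [0.0, 4.0]])
        out, w = scaled_dot_attention(Q, K, V)
        assert np.allclose(w, [[0.669762, 0.330238], [0.330238, 0.669762]], atol=1e-6)
        assert np.allclose(out, [[1.339523, 1.320954], [0.660477, 2.679046]], atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        _, w = scaled_dot_attention(rng.normal(size=(6, 8)), rng.normal(size=(5, 8)), rng.normal(size=(5, 3)))
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)))


class TestMultiHead:
    def test_single_identity_head_reduces_to_scaled_dot(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 4))
        params = {"Wq": np.eye(4)[None], "Wk": np.eye(4)[None], "Wv": np.eye(4)[None], "Wo": np.eye(4)}
        expected, _ = scaled_dot_attention(x, x, x)
        assert np.allclose(multi_head_attention(x, params), expected, atol=1e-6)

    def test_output_shape(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(7, 8))
        params = {
            "Wq": rng.normal(size=(4, 8, 2)), "Wk": rng.normal(size=(4, 8, 2)),
            "Wv": rng.normal(size=(4, 8, 2)), "Wo": rng.normal(size=(8, 8)),
        }
        assert multi_head_attention(x, params).shape == (7, 8)

    def test_matches_manual_per_head_computation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 6))
        params = {
            "Wq": rng.normal(size=(2, 6, 3)), "Wk": rng.normal(size=(2, 6, 3)),
            "Wv": rng.normal(size=(2, 6, 3)), "Wo": rng.normal(size=(6, 6)),
        }
        heads = []
        for i in range(2):  # brute-force per-head oracle
            out, _ = scaled_dot_attention(x @ params["Wq"][i], x @ params["Wk"][i], x @ params["Wv"][i])
            heads.append(out)
        expected = np.concatenate(heads, axis=-1) @ params["Wo"]
        assert np.allclose(multi_head_attention(x, params), expected, atol=1e-9)


class TestModelForward:
    def test_generator_rows_are_distributions(self, tiny_model):
        ids = tokenize("CCO", tiny_model.vocab).ids
        probs = tiny_model.generator_forward(ids, [0, 2])
        assert probs.shape == (2, len(tiny_model.vocab))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_generator_position_out_of_range(self, tiny_model):
        with pytest.raises(IndexError):
            tiny_model.generator_forward(tokenize("CCO", tiny_model.vocab).ids, [7])

    def test_discriminator_bounded_and_per_token(self, tiny_model):
        ids = tokenize("c1ccc(Cl)cc1", tiny_model.vocab).ids
        p = tiny_model.discriminator_forward(ids)
        assert p.shape == (len(ids),)
        assert ((p >= 0) & (p <= 1)).all()

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.discriminator_forward([])

    def test_eval_mode_deterministic(self, tiny_model):
        ids = tokenize("CC(=O)O", tiny_model.vocab).ids
        assert np.array_equal(tiny_model.discriminator_forward(ids), tiny_model.discriminator_forward(ids))
        assert np.array_equal(tiny_model.attention_maps(ids), tiny_model.attention_maps(ids))

    def test_attention_rows_stochastic_all_layers_heads(self, tiny_model):
        ids = tokenize("CCNCCO", tiny_model.vocab).ids
        maps = tiny_model.attention_maps(ids)
        assert maps.shape == (2, 2, len(ids), len(ids))
        assert np.allclose(maps.sum(axis=-1), 1.0, atol=1e-6)
        assert (maps >= 0).all()

    def test_first_layer_attention_matches_reference_math(self, tiny_model):
        """Parity: the autodiff encoder's first-layer weights equal
        softmax(QK^T/sqrt(d_k)) computed with plain NumPy from the same
        parameters."""
        ids = np.asarray(tokenize("CCOC", tiny_model.vocab).ids)
        p = {k: v.data for k, v in tiny_model.params.items()}
        x = p["tok_emb"][ids] + p["pos_emb"][: len(ids)]
        mu, var = x.mean(-1, keepdims=True), x.var(-1, keepdims=True)
        h = (x - mu) / np.sqrt(var + 1e-5) * p["disc.l0.ln1_g"] + p["disc.l0.ln1_b"]
        q = (h @ p["disc.l0.Wq"] + p["disc.l0.bq"]).reshape(len(ids), 2, 8).transpose(1, 0, 2)
        k = (h @ p["disc.l0.Wk"] + p["disc.l0.bk"]).reshape(len(ids), 2, 8).transpose(1, 0, 2)
        expected = np.stack([scaled_dot_attention(q[i], k[i], k[i])[1] for i in range(2)])
        got = tiny_model.attention_maps(ids)[0]
        assert np.allclose(got, expected, atol=1e-5)

    def test_truncation_warns(self, tiny_model):
        ids = [5] * 40  # beyond max_len=32
        with pytest.warns(UserWarning, match="truncated"):
            tiny_model.discriminator_forward(ids)


class TestConfig:
    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, d_model=30, n_heads=4)

    def test_dropout_range_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(vocab_size=10, dropout_ratio=1.5)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tiny_model, tmp_path):
        path = str(tmp_path / "model.npz")
        tiny_model.save(path)
        loaded = ElectraModel.load(path)
        ids = tokenize("CCO", tiny_model.vocab).ids
        assert np.allclose(loaded.discriminator_forward(ids), tiny_model.discriminator_forward(ids))
        assert loaded.vocab.token_to_id == tiny_model.vocab.token_to_id

    def test_missing_file_raises_checkpoint_error(self, tmp_path):
        with pytest.raises(CheckpointError):
            ElectraModel.load(str(tmp_path / "nope.npz"))
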