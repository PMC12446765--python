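"""The replaced-token-detection model: a transformer-encoder generator
(masked-language-model head) and discriminator (per-token original/replaced
head) with shared token and position embeddings.

The generator is a narrower copy of the discriminator encoder
(``generator_width_fraction``); both consume the same vocabulary.  All
parameters live in one flat dict of autodiff tensors so a single Adam instance
optimizes the joint objective.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from ._autograd import Tensor, softmax, gelu, layer_norm, dropout
from .corpus import Vocabulary, PAD

__all__ = ["ModelConfig", "ElectraModel", "CheckpointError"]

CHECKPOINT_VERSION = 1


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``d_model`` must be divisible by ``n_heads``; the generator width
    ``int(d_model * generator_width_fraction)`` must be too.  Dropout defaults
    to 0: the one-class scheme deliberately leverages tight fitting to the
    positive class, and regularization works against it.
    """

    vocab_size: int
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 4
    d_ffn: int = 256
    dropout_ratio: float = 0.0
    max_len: int = 256
    generator_width_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if not (0.0 <= self.dropout_ratio <= 1.0):
            raise ValueError("dropout_ratio must be in [0, 1]")
        if not (0.0 < self.generator_width_fraction <= 1.0):
            raise ValueError("generator_width_fraction must be in (0, 1]")
        if self.d_gen % self.n_heads:
            raise ValueError("generator width must be divisible by n_heads")

    @property
    def d_gen(self) -> int:
        return int(self.d_model * self.generator_width_fraction)

    @property
    def d_ffn_gen(self) -> int:
        return max(1, int(self.d_ffn * self.generator_width_fraction))


def _init(rng: np.random.Generator, *shape: int) -> Tensor:
    return Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)


def _zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape: int) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


def _encoder_params(rng: np.random.Generator, prefix: str, n_layers: int, d: int, d_ffn: int) -> dict[str, Tensor]:
    p: dict[str, Tensor] = {}
    for i in range(n_layers):
        k = f"{prefix}.l{i}"
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{k}.{name}"] = _init(rng, d, d)
            p[f"{k}.b{name[1:]}"] = _zeros(d)
        p[f"{k}.ln1_g"], p[f"{k}.ln1_b"] = _ones(d), _zeros(d)
        p[f"{k}.W1"], p[f"{k}.b1"] = _init(rng, d, d_ffn), _zeros(d_ffn)
        p[f"{k}.W2"], p[f"{k}.b2"] = _init(rng, d_ffn, d), _zeros(d)
        p[f"{k}.ln2_g"], p[f"{k}.ln2_b"] = _ones(d), _zeros(d)
    p[f"{prefix}.ln_f_g"], p[f"{prefix}.ln_f_b"] = _ones(d), _zeros(d)
    return p


class ElectraModel:
    """Generator + discriminator pair over a shared embedding table.

    Evaluation-mode entry points (``generator_forward``, ``discriminator_forward``,
    ``attention_maps``, ``embeddings``) take and return NumPy arrays and are
    deterministic; training-mode forwards build the autodiff graph.
    """

    def __init__(self, config: ModelConfig, vocab: Vocabulary):
        if config.vocab_size != len(vocab):
            raise ValueError("config.vocab_size must equal len(vocab)")
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        c = config
        p: dict[str, Tensor] = {
            "tok_emb": _init(rng, c.vocab_size, c.d_model),
            "pos_emb": _init(rng, c.max_len, c.d_model),
        }
        p.update(_encoder_params(rng, "disc", c.n_layers, c.d_model, c.d_ffn))
        p["disc.head_W1"], p["disc.head_b1"] = _init(rng, c.d_model, c.d_model), _zeros(c.d_model)
        p["disc.head_W2"], p["disc.head_b2"] = _init(rng, c.d_model, 1), _zeros(1)
        p.update(_encoder_params(rng, "gen", c.n_layers, c.d_gen, c.d_ffn_gen))
        if c.d_gen != c.d_model:
            p["gen.in_W"], p["gen.in_b"] = _init(rng, c.d_model, c.d_gen), _zeros(c.d_gen)
            p["gen.out_W"], p["gen.out_b"] = _init(rng, c.d_gen, c.d_model), _zeros(c.d_model)
        # MLM scores are taken against the shared embedding table (weight tying)
        p["gen.head_b"] = _zeros(c.vocab_size)
        self.params = p

    # ----- shared encoder ---------------------------------------------------

    def _embed(self, ids: np.ndarray) -> Tensor:
        L = ids.shape[-1]
        pos = self.params["pos_emb"].take_rows(np.arange(L))
        return self.params["tok_emb"].take_rows(ids) + pos

    def _encode(
        self,
        prefix: str,
        x: Tensor,
        pad_mask: np.ndarray,
        n_heads: int,
        train_rng: Optional[np.random.Generator] = None,
        collect_attention: bool = False,
    ) -> tuple[Tensor, list[np.ndarray]]:
        p = self.params
        d = x.data.shape[-1]
        dh = d // n_heads
        B, L = pad_mask.shape
        bias = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]
        drop = self.config.dropout_ratio if train_rng is not None else 0.0
        attn_maps: list[np.ndarray] = []
        n_layers = self.config.n_layers
        # pre-norm residual blocks: stable to train without a warmup schedule
        for i in range(n_layers):
            k = f"{prefix}.l{i}"

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, L, n_heads, dh).transpose(0, 2, 1, 3)

            h = layer_norm(x, p[f"{k}.ln1_g"], p[f"{k}.ln1_b"])
            q = heads(h @ p[f"{k}.Wq"] + p[f"{k}.bq"])
            kk = heads(h @ p[f"{k}.Wk"] + p[f"{k}.bk"])
            v = heads(h @ p[f"{k}.Wv"] + p[f"{k}.bv"])
            scores = q @ kk.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
            w = softmax(scores, bias=bias)
            if collect_attention:
                attn_maps.append(w.data.copy())
            ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
            ctx = ctx @ p[f"{k}.Wo"] + p[f"{k}.bo"]
            if drop > 0.0:
                ctx = dropout(ctx, drop, train_rng)
            x = x + ctx
            h = layer_norm(x, p[f"{k}.ln2_g"], p[f"{k}.ln2_b"])
            ff = gelu(h @ p[f"{k}.W1"] + p[f"{k}.b1"]) @ p[f"{k}.W2"] + p[f"{k}.b2"]
            if drop > 0.0:
                ff = dropout(ff, drop, train_rng)
            x = x + ff
        x = layer_norm(x, p[f"{prefix}.ln_f_g"], p[f"{prefix}.ln_f_b"])
        return x, attn_maps

    def gen_logits(self, ids: np.ndarray, pad_mask: np.ndarray, train_rng=None) -> Tensor:
        """Generator MLM logits, shape (B, L, vocab)."""
        x = self._embed(ids)
        if self.config.d_gen != self.config.d_model:
            x = x @ self.params["gen.in_W"] + self.params["gen.in_b"]
        h, _ = self._encode("gen", x, pad_mask, self.config.n_heads, train_rng)
        if self.config.d_gen != self.config.d_model:
            h = h @ self.params["gen.out_W"] + self.params["gen.out_b"]
        emb_t = self.params["tok_emb"].transpose(1, 0)
        return h @ emb_t + self.params["gen.head_b"]

    def disc_logits(
        self, ids: np.ndarray, pad_mask: np.ndarray, train_rng=None, collect_attention=False
    ) -> tuple[Tensor, list[np.ndarray]]:
        """Discriminator per-token replaced logits, shape (B, L)."""
        x = self._embed(ids)
        h, attn = self._encode(
            "disc", x, pad_mask, self.config.n_heads, train_rng, collect_attention
        )
        h1 = gelu(h @ self.params["disc.head_W1"] + self.params["disc.head_b1"])
        logits = h1 @ self.params["disc.head_W2"] + self.params["disc.head_b2"]
        B, L = pad_mask.shape
        return logits.reshape(B, L), attn

    def disc_hidden(self, ids: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        """Final discriminator encoder layer, (B, L, d_model), evaluation mode."""
        x = self._embed(ids)
        h, _ = self._encode("disc", x, pad_mask, self.config.n_heads)
        return h.data

    # ----- batching ---------------------------------------------------------

    def pad_batch(self, seqs: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
        """Pad id sequences to a (B, L) array plus a boolean real-token mask.
        Sequences beyond ``max_len`` are right-truncated with a warning."""
        max_len = self.config.max_len
        clipped = []
        for s in seqs:
            if len(s) > max_len:
                warnings.warn(f"sequence of length {len(s)} truncated to max_len={max_len}")
                s = list(s)[:max_len]
            clipped.append(list(s))
        L = max(len(s) for s in clipped)
        ids = np.full((len(clipped), L), PAD, dtype=np.int64)
        mask = np.zeros((len(clipped), L), dtype=bool)
        for i, s in enumerate(clipped):
            ids[i, : len(s)] = s
            mask[i, : len(s)] = True
        return ids, mask

    # ----- evaluation-mode API ----------------------------------------------

    def generator_forward(self, ids: Sequence[int], mask_positions: Sequence[int]) -> np.ndarray:
        """Probability distribution over the vocabulary at each masked position."""
        ids = list(ids)
        for pos in mask_positions:
            if not (0 <= pos < len(ids)):
                raise IndexError(f"mask position {pos} out of range for length {len(ids)}")
        arr, mask = self.pad_batch([ids])
        logits = self.gen_logits(arr, mask).data[0]
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=-1, keepdims=True)
        return probs[np.asarray(mask_positions, dtype=int)]

    def discriminator_forward(self, ids: Sequence[int]) -> np.ndarray:
        """Per-token replaced probability in [0, 1] for one sequence."""
        if len(ids) == 0:
            raise ValueError("empty sequence")
        arr, mask = self.pad_batch([list(ids)])
        logits, _ = self.disc_logits(arr, mask)
        return 1.0 / (1.0 + np.exp(-logits.data[0][: min(len(ids), self.config.max_len)]))

    def attention_maps(self, ids: Sequence[int]) -> np.ndarray:
        """All attention weights for one sequence: (n_layers, n_heads, L, L)."""
        if len(ids) == 0:
            raise ValueError("empty sequence")
        arr, mask = self.pad_batch([list(ids)])
        _, attn = self.disc_logits(arr, mask, collect_attention=True)
        return np.stack([a[0] for a in attn])

    def embeddings(self, seqs: Sequence[Sequence[int]]) -> np.ndarray:
        """Mean-pooled final discriminator layer, one row per molecule."""
        out = np.empty((len(seqs), self.config.d_model))
        for i, s in enumerate(seqs):
            arr, mask = self.pad_batch([list(s)])
            h = self.disc_hidden(arr, mask)[0]
            out[i] = h[mask[0]].mean(axis=0)
        return out

    # ----- checkpointing ----------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "vocab": json.loads(self.vocab.to_json()),
            "vocab_hash": self.vocab.content_hash(),
        }
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "ElectraModel":
        try:
            archive = np.load(path, allow_pickle=False)
        except FileNotFoundError:
            raise CheckpointError(f"checkpoint not found: {path}")
        if "_meta" not in archive:
            raise CheckpointError(f"not a model checkpoint: {path}")
        meta = json.loads(str(archive["_meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise CheckpointError(f"unsupported checkpoint version {meta.get('version')}")
        vocab = Vocabulary.from_json(json.dumps(meta["vocab"]))
        if vocab.content_hash() != meta["vocab_hash"]:
            raise CheckpointError("vocabulary hash mismatch in checkpoint")
        model = cls(ModelConfig(**meta["config"]), vocab)
        for k in model.params:
            model.params[k] = Tensor(archive[k.replace(".", "__")], requires_grad=True)
        return model
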