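"""One-class replaced-token-detection training.

The loop trains only on ADR-positive molecules: random token positions are
masked, the generator (a masked language model) proposes replacements by
temperature-1 sampling, and the discriminator learns to tell which tokens were
replaced.  The joint objective is ``L_MLM + lambda * L_disc``; after training
the discriminator is tightly fitted to the positive-class token distribution,
which is exactly what the downstream anomaly score exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._autograd import Tensor, cross_entropy, bce_with_logits
from .corpus import DrugRecord, Vocabulary, build_vocab, canonicalize, enumerate_smiles, tokenize, MASK
from .model import ElectraModel, ModelConfig

__all__ = ["MaskedBatch", "TrainConfig", "OneClassViolation", "mask_tokens", "corrupt_with_generator", "train"]


class OneClassViolation(ValueError):
    """Raised when a record without the ADR label reaches the training set."""


@dataclass
class MaskedBatch:
    """A sequence passing through the mask → generate → label pipeline."""

    original_ids: np.ndarray
    input_ids: np.ndarray          # original with <mask> at mask_positions
    mask_positions: np.ndarray     # sorted indices into the sequence
    corrupted_ids: Optional[np.ndarray] = None
    replaced_labels: Optional[np.ndarray] = None


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``masking_ratio`` defaults to 0.5: mid-range ratios give the discriminator
    both enough corrupted tokens to learn from and enough clean context to
    judge them against; very low or very high ratios starve one side or the
    other.  ``disc_loss_weight`` follows the standard replaced-token-detection
    weighting of the discriminator loss relative to the MLM loss.
    """

    masking_ratio: float = 0.5
    disc_loss_weight: float = 50.0
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 2e-4
    n_augment: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.masking_ratio < 1.0):
            raise ValueError("masking_ratio must be in (0, 1)")
        if self.disc_loss_weight <= 0:
            raise ValueError("disc_loss_weight must be > 0")


def mask_tokens(
    ids: Sequence[int],
    masking_ratio: float,
    seed: int | np.random.Generator,
    allow_degenerate: bool = False,
) -> MaskedBatch:
    """Mask exactly ``round(ratio * n_maskable)`` non-special positions,
    chosen uniformly without replacement; deterministic per seed."""
    if not allow_degenerate and not (0.0 < masking_ratio < 1.0):
        raise ValueError("masking_ratio must be in (0, 1)")
    if not (0.0 <= masking_ratio <= 1.0):
        raise ValueError("masking_ratio must be in [0, 1]")
    ids = np.asarray(ids, dtype=np.int64)
    maskable = np.flatnonzero(ids >= 5)  # special tokens occupy ids 0-4
    if maskable.size == 0:
        raise ValueError("sequence has no non-special tokens to mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_mask = int(round(masking_ratio * maskable.size))
    chosen = np.sort(rng.choice(maskable, size=n_mask, replace=False))
    masked = ids.copy()
    masked[chosen] = MASK
    return MaskedBatch(original_ids=ids, input_ids=masked, mask_positions=chosen)


def corrupt_with_generator(
    batch: MaskedBatch,
    model: ElectraModel,
    seed: int | np.random.Generator,
    gen_probs: Optional[np.ndarray] = None,
) -> MaskedBatch:
    """Fill each masked position by sampling the generator distribution and set
    per-token replaced labels (0 where the sample reproduces the original —
    the replaced-token-detection convention)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gen_probs is None:
        gen_probs = model.generator_forward(batch.input_ids, batch.mask_positions)
    corrupted = batch.original_ids.copy()
    labels = np.zeros_like(batch.original_ids)
    for row, pos in enumerate(batch.mask_positions):
        token = rng.choice(gen_probs.shape[1], p=gen_probs[row])
        corrupted[pos] = token
        labels[pos] = int(token != batch.original_ids[pos])
    batch.corrupted_ids = corrupted
    batch.replaced_labels = labels
    return batch


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _sample_batch_corruption(
    model: ElectraModel,
    ids: np.ndarray,
    pad_mask: np.ndarray,
    mask_sel: np.ndarray,
    rng: np.random.Generator,
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Generator forward on the masked batch; sample fills at masked positions.

    Returns (gen_logits tensor, corrupted_ids, replaced_labels)."""
    masked = ids.copy()
    masked[mask_sel] = MASK
    gen_logits = model.gen_logits(masked, pad_mask, train_rng=rng)
    z = gen_logits.data - gen_logits.data.max(axis=-1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=-1, keepdims=True)
    corrupted = ids.copy()
    labels = np.zeros_like(ids)
    rows, cols = np.nonzero(mask_sel)
    if rows.size:
        # vectorized categorical sampling via inverse CDF
        cdf = probs[rows, cols].cumsum(axis=-1)
        u = rng.random(rows.size)[:, None]
        samples = (u > cdf).sum(axis=-1)
        corrupted[rows, cols] = samples
        labels[rows, cols] = (samples != ids[rows, cols]).astype(np.int64)
    return gen_logits, corrupted, labels


@dataclass
class LossHistory:
    epochs: list[int] = field(default_factory=list)
    mlm: list[float] = field(default_factory=list)
    disc: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)


def train(
    records: Sequence[DrugRecord],
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    vocab: Optional[Vocabulary] = None,
    log: Optional[callable] = None,
) -> tuple[ElectraModel, LossHistory]:
    """Train the generator/discriminator pair on ADR-positive molecules only.

    Any record without label 1 raises :class:`OneClassViolation`.  SMILES
    enumeration (``n_augment`` variants per molecule, deduplicated) is applied
    once, up front, then training minimizes ``L_MLM + lambda * L_disc`` with
    Adam.  Deterministic for fixed seeds.
    """
    tc = train_config or TrainConfig()
    if not records:
        raise ValueError("empty training corpus")
    for r in records:
        if r.label != 1:
            raise OneClassViolation(
                f"record {r.drug_id!r} has label {r.label!r}; training is one-class (label 1 only)"
            )

    rng = np.random.default_rng(tc.seed)
    corpus: list[str] = []
    for r in records:
        can = canonicalize(r.smiles)
        corpus.append(can)
        if tc.n_augment > 1:
            variants = enumerate_smiles(can, tc.n_augment - 1, seed=int(rng.integers(2**31)))
            corpus.extend(v for v in variants if v != can)
    corpus = list(dict.fromkeys(corpus))

    if vocab is None:
        vocab = build_vocab(corpus)
    seqs = [tokenize(s, vocab).ids for s in corpus]

    mc = model_config or ModelConfig(vocab_size=len(vocab))
    if mc.vocab_size != len(vocab):
        # the vocabulary is derived from the (augmented) corpus; the config
        # follows it rather than the other way round
        from dataclasses import replace

        mc = replace(mc, vocab_size=len(vocab))
    model = ElectraModel(mc, vocab)
    opt = _Adam(model.params, tc.learning_rate)
    history = LossHistory()

    order = np.arange(len(seqs))
    for epoch in range(1, tc.epochs + 1):
        rng.shuffle(order)
        ep_mlm = ep_disc = 0.0
        n_batches = 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            ids, pad_mask = model.pad_batch([seqs[i] for i in idx])
            # choose exactly round(ratio * n_maskable) positions per sequence
            mask_sel = np.zeros_like(pad_mask)
            for b in range(ids.shape[0]):
                maskable = np.flatnonzero(pad_mask[b] & (ids[b] >= 5))
                n_mask = int(round(tc.masking_ratio * maskable.size))
                if n_mask:
                    mask_sel[b, rng.choice(maskable, size=n_mask, replace=False)] = True

            gen_logits, corrupted, labels = _sample_batch_corruption(model, ids, pad_mask, mask_sel, rng)
            assert not np.any(labels[~mask_sel]), "replaced labels outside masked positions"

            rows, cols = np.nonzero(mask_sel)
            V = mc.vocab_size
            flat = gen_logits.reshape(ids.shape[0] * ids.shape[1], V)
            sel = rows * ids.shape[1] + cols
            mlm_loss = _gather_ce(flat, sel, ids[rows, cols])

            disc_logits, _ = model.disc_logits(corrupted, pad_mask, train_rng=rng)
            disc_loss = bce_with_logits(disc_logits, labels.astype(float), pad_mask)

            total = mlm_loss + tc.disc_loss_weight * disc_loss
            opt.zero_grad()
            total.backward()
            opt.step()

            ep_mlm += float(mlm_loss.data)
            ep_disc += float(disc_loss.data)
            n_batches += 1
        history.epochs.append(epoch)
        history.mlm.append(ep_mlm / n_batches)
        history.disc.append(ep_disc / n_batches)
        history.total.append(history.mlm[-1] + tc.disc_loss_weight * history.disc[-1])
        if log is not None:
            log(
                f"epoch={epoch} L_MLM={history.mlm[-1]:.4f} "
                f"L_disc={history.disc[-1]:.4f} total={history.total[-1]:.4f}"
            )
    return model, history


def _gather_ce(flat_logits: Tensor, row_index: np.ndarray, targets: np.ndarray) -> Tensor:
    """Cross-entropy over a subset of rows of flattened (N, V) logits."""
    if row_index.size == 0:
        return Tensor(0.0)
    sub = _take_rows_2d(flat_logits, row_index)
    return cross_entropy(sub, targets)


def _take_rows_2d(x: Tensor, rows: np.ndarray) -> Tensor:
    out = Tensor(x.data[rows], _prev=(x,))

    def bw(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, rows, g)
            x._accum(acc)

    out._backward = bw
    return out
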