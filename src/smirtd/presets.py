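"""Shared configuration presets.

``small_model_config`` / ``small_train_config`` define the CPU-scale study
configuration used throughout the package's own experiments (tests, the
acceptance script, the examples): a 2-layer, 64-wide encoder with a
quarter-width generator, trained 60 epochs at masking ratio 0.5 with 6-fold
SMILES enumeration.  On a few hundred template-grammar molecules this reaches
the sharply-fitted discriminator regime the one-class score needs, in minutes
on one CPU core.
"""

from __future__ import annotations

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["small_model_config", "small_train_config"]


def small_model_config(vocab_size: int = 1, seed: int = 0) -> ModelConfig:
    return ModelConfig(
        vocab_size=vocab_size,
        d_model=64,
        n_heads=4,
        n_layers=2,
        d_ffn=128,
        max_len=96,
        generator_width_fraction=0.25,
        seed=seed,
    )


def small_train_config(masking_ratio: float = 0.5, seed: int = 0, epochs: int = 60) -> TrainConfig:
    return TrainConfig(
        masking_ratio=masking_ratio,
        disc_loss_weight=50.0,
        epochs=epochs,
        batch_size=32,
        learning_rate=5e-4,
        n_augment=6,
        seed=seed,
    )
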