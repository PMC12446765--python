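"""Drug-level risk scoring from the trained discriminator.

Each token of a molecule is flagged as "replaced" when the discriminator's
probability exceeds a token threshold (by default the training masking ratio).
The drug-level score is the replaced-token fraction

    probability = 100 * n_replaced / n_tokens  (percent)

which measures dissimilarity from the positive training class: a drug whose
tokens mostly look "original" to the one-class discriminator resembles the
ADR-positive distribution.  The classification cut on this score is calibrated
by maximizing Youden's J = sensitivity + specificity - 1 on labeled validation
scores; a drug is predicted positive (label 1) when its score falls BELOW the
chosen threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import TokenizedMolecule, tokenize
from .model import ElectraModel

__all__ = [
    "DrugScore",
    "ThresholdCalibration",
    "flag_tokens",
    "replaced_fraction",
    "score_drug",
    "score_drugs",
    "youden_threshold",
    "classify",
    "write_predictions",
]


@dataclass
class DrugScore:
    """Replaced-token summary for one drug.  ``n_tokens`` is the molecular
    length (token count excluding special tokens, the score denominator)."""

    drug_id: str
    n_tokens: int
    n_replaced: int
    probability: float  # percent in [0, 100]
    predicted_label: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_replaced <= self.n_tokens):
            raise ValueError("need 0 <= n_replaced <= n_tokens")


@dataclass(frozen=True)
class CalibrationRow:
    threshold: float
    sensitivity: float
    specificity: float
    J: float


@dataclass(frozen=True)
class ThresholdCalibration:
    rows: tuple[CalibrationRow, ...]
    chosen_threshold: float
    J_max: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "chosen_threshold": self.chosen_threshold,
                "J_max": self.J_max,
                "rows": [asdict(r) for r in self.rows],
            },
            indent=2,
        )


def flag_tokens(
    model: ElectraModel,
    tokenized: TokenizedMolecule,
    token_threshold: float,
) -> np.ndarray:
    """Per-token binary replaced flags: 1 where discriminator probability
    strictly exceeds ``token_threshold``."""
    if not (0.0 < token_threshold < 1.0):
        raise ValueError("token_threshold must be in (0, 1)")
    probs = model.discriminator_forward(tokenized.ids)
    return (probs > token_threshold).astype(int)


def replaced_fraction(flags: Sequence[int], n_tokens: int) -> float:
    """The drug-level score: 100 * (flagged tokens) / (molecular length)."""
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    return 100.0 * float(np.sum(flags)) / n_tokens


def score_drug(
    model: ElectraModel,
    drug_id: str,
    smiles: str,
    token_threshold: float,
) -> DrugScore:
    tok = tokenize(smiles, model.vocab)
    flags = flag_tokens(model, tok, token_threshold)
    n = min(len(tok), model.config.max_len)
    return DrugScore(drug_id, n, int(flags.sum()), replaced_fraction(flags, n))


def score_drugs(model, records, token_threshold: float) -> list[DrugScore]:
    return [score_drug(model, r.drug_id, r.smiles, token_threshold) for r in records]


def youden_threshold(
    scores: Sequence[DrugScore], labels: Sequence[int]
) -> ThresholdCalibration:
    """Scan candidate thresholds (midpoints of consecutive distinct sorted
    scores plus infinite sentinels) and return the one maximizing Youden's J.

    Prediction rule during the scan matches :func:`classify`: label 1 when the
    score is strictly below the threshold.  Ties in J resolve to the smallest
    maximizing threshold.
    """
    values = np.array([s.probability for s in scores], dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(values) != len(y):
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present to calibrate a threshold")

    distinct = np.unique(values)
    candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]))
    rows = []
    for t in candidates:
        pred = (values < t).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        rows.append(CalibrationRow(float(t), sens, spec, sens + spec - 1.0))
    j_max = max(r.J for r in rows)
    chosen = min(r.threshold for r in rows if r.J == j_max)
    return ThresholdCalibration(tuple(rows), chosen, j_max)


def classify(score: DrugScore, calibration: ThresholdCalibration) -> int:
    """Label 1 (same type as training, i.e. has the ADR) when the replaced
    fraction is below the calibrated threshold; label 0 at or above it."""
    return 1 if score.probability < calibration.chosen_threshold else 0


def write_predictions(scores: Sequence[DrugScore], path: str) -> None:
    pd.DataFrame(
        [
            (s.drug_id, s.n_tokens, s.n_replaced, s.probability, s.predicted_label)
            for s in scores
        ],
        columns=["drug_id", "n_tokens", "n_replaced", "probability", "predicted_label"],
    ).to_csv(path, sep="\t", index=False)
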