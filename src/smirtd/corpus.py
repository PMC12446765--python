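"""SMILES corpus handling: canonicalization, enumeration, tokenization, vocabulary,
and dataset partitioning for one-class training.

The tokenizer follows the standard SMILES lexical grammar: bracket atoms ``[...]``
are one token, the two-character elements ``Cl``/``Br`` are one token, ring-closure
digits and ``%nn`` labels are tokens, and every other bond/branch/charge character
is a single-character token.  Joining the tokens reproduces the input string
exactly, which is what lets per-token model outputs be mapped back onto atoms.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DrugRecord",
    "Vocabulary",
    "TokenizedMolecule",
    "SplitSpec",
    "DatasetSplit",
    "SmilesParseError",
    "TokenizationError",
    "canonicalize",
    "enumerate_smiles",
    "tokenize",
    "build_vocab",
    "split_dataset",
    "read_drug_table",
    "read_smi",
    "write_split_manifest",
]

SPECIAL_TOKENS = ("<pad>", "<unk>", "<bos>", "<eos>", "<mask>")
PAD, UNK, BOS, EOS, MASK = range(5)


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as a molecule."""


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be split by the lexical grammar."""


@dataclass(frozen=True)
class DrugRecord:
    """One drug: an opaque identifier, a SMILES string and an optional binary
    ADR label (1 = has the adverse reaction, 0 = does not)."""

    drug_id: str
    smiles: str
    label: Optional[int] = None


# Token pattern, longest-match first.  Bracket atoms, two-letter halogens, %nn
# ring closures, then organic-subset atoms, ring digits and structural symbols.
_TOKEN_RE = re.compile(
    r"\[[^\[\]]+\]"
    r"|Br|Cl"
    r"|%\d{2}"
    r"|[BCNOPSFI]"
    r"|[bcnops]"
    r"|\d"
    r"|[=#\-\+\(\)/\\\.:@\*\$~]"
)

# Tokens that carry an atom (everything the molecular graph counts as a node).
_ATOM_TOKEN_RE = re.compile(r"^(\[[^\[\]]+\]|Br|Cl|[BCNOPSFI]|[bcnops])$")


def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical SMILES.  Idempotent by construction."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def enumerate_smiles(smiles: str, n: int, seed: int = 0) -> list[str]:
    """Generate up to ``n`` distinct SMILES variants of one molecule by
    randomized atom-order traversal (data augmentation).

    Every variant canonicalizes back to ``canonicalize(smiles)``.  Deterministic
    for a fixed seed.  Small, symmetric molecules may admit fewer than ``n``
    distinct strings, in which case fewer are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"not a valid SMILES: {smiles!r}")
    rng = np.random.default_rng(seed)
    n_atoms = mol.GetNumAtoms()
    seen: dict[str, None] = {}
    attempts = max(100, 10 * n)
    for _ in range(attempts):
        order = rng.permutation(n_atoms).tolist()
        variant = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        seen.setdefault(variant, None)
        if len(seen) >= n:
            break
    return list(seen)[:n]


@dataclass(frozen=True)
class Vocabulary:
    """Token-string → contiguous-integer-id bijection with five leading special
    tokens (pad, unknown, sequence-start, sequence-end, mask) at ids 0–4."""

    token_to_id: dict[str, int]

    @property
    def special_tokens(self) -> tuple[str, ...]:
        return SPECIAL_TOKENS

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def encode(self, tokens: Sequence[str]) -> list[int]:
        get = self.token_to_id.get
        return [get(t, UNK) for t in tokens]

    def content_hash(self) -> str:
        payload = json.dumps(sorted(self.token_to_id.items())).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_json(self) -> str:
        return json.dumps({"tokens": sorted(self.token_to_id, key=self.token_to_id.get)})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        tokens = json.loads(text)["tokens"]
        return cls({t: i for i, t in enumerate(tokens)})

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "Vocabulary":
        ordered = list(SPECIAL_TOKENS) + sorted(set(tokens) - set(SPECIAL_TOKENS))
        return cls({t: i for i, t in enumerate(ordered)})


@dataclass(frozen=True)
class TokenizedMolecule:
    """A SMILES string with its token split, vocabulary ids and the per-token
    atom index (``None`` for structural tokens such as ring digits or bonds).

    ``"".join(tokens) == smiles`` always holds; atom-bearing tokens map to the
    atom order of the SMILES traversal, i.e. the RDKit atom indices of the
    molecule parsed from this exact string.
    """

    smiles: str
    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    atom_indices: tuple[Optional[int], ...]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_atoms(self) -> int:
        return sum(1 for a in self.atom_indices if a is not None)


def _split_tokens(smiles: str) -> list[str]:
    if not smiles:
        raise TokenizationError("empty SMILES string")
    depth = 0
    for pos, ch in enumerate(smiles):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise TokenizationError(f"unbalanced ']' at position {pos} in {smiles!r}")
    if depth != 0:
        raise TokenizationError(f"unbalanced '[' in {smiles!r}")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            # Unknown character: keep it as its own token so the join identity
            # holds; the id lookup maps it to <unk>.
            tokens.append(smiles[pos])
            pos += 1
        else:
            tokens.append(m.group())
            pos = m.end()
    return tokens


def tokenize(smiles: str, vocab: Optional[Vocabulary] = None) -> TokenizedMolecule:
    """Split a SMILES string by the lexical grammar and map tokens to ids.

    Without a vocabulary, ids are all ``<unk>`` placeholders (useful for corpus
    scans before the vocabulary exists).
    """
    tokens = _split_tokens(smiles)
    ids = vocab.encode(tokens) if vocab is not None else [UNK] * len(tokens)
    atom_indices: list[Optional[int]] = []
    atom = 0
    for t in tokens:
        if _ATOM_TOKEN_RE.match(t):
            atom_indices.append(atom)
            atom += 1
        else:
            atom_indices.append(None)
    return TokenizedMolecule(smiles, tuple(tokens), tuple(ids), tuple(atom_indices))


def build_vocab(corpus: Iterable[str]) -> Vocabulary:
    """Build a vocabulary from the token set of a SMILES corpus: the five
    special tokens followed by the sorted unique observed tokens."""
    observed: set[str] = set()
    n = 0
    for s in corpus:
        observed.update(_split_tokens(s))
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    return Vocabulary.from_tokens(observed)


@dataclass(frozen=True)
class SplitSpec:
    """How to partition a labeled drug table for one-class training.

    Positives go train/validation/test by the given fractions; negatives are
    never trained on, so they are split evenly between validation and test and
    then randomly down-sampled by ``negative_keep_fraction`` (floor rounding)
    to balance the evaluation classes.
    """

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    negative_val_frac: float = 0.5
    negative_keep_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("positive fractions must sum to 1")
        if not (0.0 < self.negative_keep_fraction <= 1.0):
            raise ValueError("negative_keep_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[DrugRecord, ...]
    validation: tuple[DrugRecord, ...]
    test: tuple[DrugRecord, ...]

    def __post_init__(self) -> None:
        if any(r.label == 0 for r in self.train):
            raise ValueError("train split must contain positives only")


def split_dataset(records: Sequence[DrugRecord], spec: SplitSpec) -> DatasetSplit:
    """Partition records per the one-class protocol; deterministic per seed.

    Positive counts use floor for validation/test with the remainder in train;
    negative down-sampling keeps ``floor(k * fraction)`` of each side.
    """
    positives = [r for r in records if r.label == 1]
    negatives = [r for r in records if r.label == 0]
    if len(positives) + len(negatives) != len(records):
        raise ValueError("all records must carry a 0/1 label")
    if len(positives) < 3:
        raise ValueError("need at least 3 positive records to split")
    ids = [r.drug_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("drug_id values must be unique")

    rng = np.random.default_rng(spec.seed)
    pos = [positives[i] for i in rng.permutation(len(positives))]
    neg = [negatives[i] for i in rng.permutation(len(negatives))]

    n_val = int(len(pos) * spec.val_frac)
    n_test = int(len(pos) * spec.test_frac)
    n_train = len(pos) - n_val - n_test
    train = pos[:n_train]
    val_pos = pos[n_train : n_train + n_val]
    test_pos = pos[n_train + n_val :]

    n_neg_val = int(round(len(neg) * spec.negative_val_frac))
    val_neg = neg[:n_neg_val]
    test_neg = neg[n_neg_val:]
    keep = spec.negative_keep_fraction
    val_neg = val_neg[: int(len(val_neg) * keep)]
    test_neg = test_neg[: int(len(test_neg) * keep)]

    return DatasetSplit(
        train=tuple(train),
        validation=tuple(val_pos + val_neg),
        test=tuple(test_pos + test_neg),
    )


def read_drug_table(path: str) -> list[DrugRecord]:
    """Read a CSV/TSV drug table with header columns drug_id, smiles[, label]."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"drug_id", "smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}; got {list(df.columns)}")
    has_label = "label" in df.columns
    out = []
    for row in df.itertuples(index=False):
        label = int(getattr(row, "label")) if has_label and pd.notna(getattr(row, "label")) else None
        out.append(DrugRecord(str(row.drug_id), str(row.smiles), label))
    return out


def read_smi(path: str, label: Optional[int] = None) -> list[DrugRecord]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            drug_id = parts[1] if len(parts) > 1 else f"mol{i}"
            out.append(DrugRecord(drug_id, parts[0], label))
    return out


def write_split_manifest(split: DatasetSplit, path: str) -> None:
    """Write an auditable drug_id → split-name manifest as TSV."""
    rows = [
        (r.drug_id, name)
        for name, part in (("train", split.train), ("validation", split.validation), ("test", split.test))
        for r in part
    ]
    pd.DataFrame(rows, columns=["drug_id", "split"]).to_csv(path, sep="\t", index=False)
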