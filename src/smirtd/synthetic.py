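"""Deterministic planted-motif SMILES datasets for one-class experiments.

Molecules are assembled from a congeneric-series template — an aromatic or
aliphatic head, one to three linker segments, and a tail — the way drugs in a
chemotype family share a scaffold and vary in decorations.  The two classes
are built from the same grammar but with class-characteristic linker
chemistry:

* positives always carry at least one structural-alert motif (by default a
  tertiary-amine linker or an aryl-halide head);
* negatives use motif-free linkers (secondary amines, ethers, esters) that
  form their own coherent chemotype.

Heads and tails overlap between the classes and the token vocabulary is
shared, so separating the classes requires modeling token context, not
spotting unique characters.  The low-entropy template grammar gives the
masked language model something learnable, mirroring the internal regularity
of real drug series.  Class purity (every positive matches >= 1 motif query,
no negative matches any) is verified by substructure matching on every
generated molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .corpus import DrugRecord, canonicalize

__all__ = [
    "Motif",
    "SyntheticSpec",
    "GenerationError",
    "generate",
    "motif_atoms",
    "write_smi",
    "write_manifest",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Motif:
    """A plantable fragment plus the substructure query that detects it."""

    name: str
    fragment: str  # chain-appendable SMILES piece
    smarts: str


DEFAULT_MOTIFS = (
    Motif("tertiary_amine", "CCN(C)C", "[NX3]([#6])([#6])[#6]"),
    Motif("aryl_halide", "c1ccc(Cl)cc1", "c[F,Cl,Br,I]"),
)

# Template grammar.  Every fragment is a valid SMILES chain continuation and
# closes its own rings, so plain concatenation stays parseable.
_POS_HEADS = ("c1ccc(Cl)cc1", "c1ccc(F)cc1", "c1ccccc1", "Cc1ccccc1")
_POS_LINKERS = ("CCN(C)C", "CN(C)CC", "CCN(CC)C", "OCCN(C)C")  # tertiary amines
_NEG_HEADS = ("c1ccccc1", "Cc1ccccc1", "C1CCCCC1", "CC(C)")
_NEG_LINKERS = ("CCNC", "COCC", "CC(=O)OC", "OCCOC")  # secondary amine / ether / ester
_TAILS = ("CCO", "CC", "CC(C)O", "C(=O)O")  # shared by both classes


def _heavy_atoms(fragment: str) -> int:
    mol = Chem.MolFromSmiles(fragment)
    return mol.GetNumAtoms() if mol is not None else 0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings: which motifs define the positive class, class
    sizes, heavy-atom bounds per molecule, and the seed."""

    motifs: tuple[Motif, ...] = DEFAULT_MOTIFS
    n_pos: int = 200
    n_neg: int = 60
    scaffold_size_range: tuple[int, int] = (12, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not self.motifs:
            raise ValueError("at least one motif is required")
        lo, hi = self.scaffold_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid scaffold_size_range")


def _assemble(
    rng: np.random.Generator,
    heads: Sequence[str],
    linkers: Sequence[str],
    lo: int,
    hi: int,
) -> str | None:
    """head + linkers + tail, linkers repeated until the heavy-atom target."""
    head = heads[rng.integers(len(heads))]
    tail = _TAILS[rng.integers(len(_TAILS))]
    parts = [head]
    total = _heavy_atoms(head) + _heavy_atoms(tail)
    target = int(rng.integers(lo, hi + 1))
    parts.append(linkers[rng.integers(len(linkers))])
    total += _heavy_atoms(parts[-1])
    while total < target:
        f = linkers[rng.integers(len(linkers))]
        parts.append(f)
        total += _heavy_atoms(f)
    parts.append(tail)
    smiles = "".join(parts)
    return smiles if Chem.MolFromSmiles(smiles) is not None else None


def _matches_any(mol: Chem.Mol, queries: Sequence[Chem.Mol]) -> bool:
    return any(mol.HasSubstructMatch(q) for q in queries)


def generate(spec: SyntheticSpec) -> tuple[list[DrugRecord], list[DrugRecord]]:
    """Generate (positives, negatives); every positive contains >= 1 motif,
    every negative contains none, verified by substructure matching.
    Deterministic per seed; canonical SMILES are unique within the dataset."""
    rng = np.random.default_rng(spec.seed)
    queries = [Chem.MolFromSmarts(m.smarts) for m in spec.motifs]
    lo, hi = spec.scaffold_size_range
    seen: set[str] = set()

    # positives draw their linkers from the motif fragments themselves (plus
    # the default tertiary-amine family when the caller supplies motifs whose
    # fragments are head-like, e.g. aryl halides)
    pos_linkers = tuple(m.fragment for m in spec.motifs if not m.fragment.startswith("c")) or _POS_LINKERS
    pos_linkers = tuple(dict.fromkeys(pos_linkers + _POS_LINKERS))

    def sample(want_motif: bool, count: int, prefix: str, label: int) -> list[DrugRecord]:
        heads = _POS_HEADS if want_motif else _NEG_HEADS
        linkers = pos_linkers if want_motif else _NEG_LINKERS
        out: list[DrugRecord] = []
        attempts = 0
        limit = 500 * count
        while len(out) < count:
            attempts += 1
            if attempts > limit:
                raise GenerationError(
                    f"could not generate {count} molecules within {limit} attempts; "
                    "motif may be unsatisfiable inside the size bounds"
                )
            smiles = _assemble(rng, heads, linkers, lo, hi)
            if smiles is None:
                continue
            mol = Chem.MolFromSmiles(smiles)
            if _matches_any(mol, queries) != want_motif:
                continue
            can = canonicalize(smiles)
            if can in seen:
                continue
            seen.add(can)
            out.append(DrugRecord(f"{prefix}{len(out):04d}", can, label))
        return out

    positives = sample(True, spec.n_pos, "POS", 1)
    negatives = sample(False, spec.n_neg, "NEG", 0)
    return positives, negatives


def motif_atoms(smiles: str, motifs: Sequence[Motif] = DEFAULT_MOTIFS) -> set[int]:
    """Atom indices covered by any motif match, in the molecule's own order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"not a valid SMILES: {smiles!r}")
    atoms: set[int] = set()
    for m in motifs:
        q = Chem.MolFromSmarts(m.smarts)
        for match in mol.GetSubstructMatches(q):
            atoms.update(match)
    return atoms


def write_smi(records: Sequence[DrugRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.drug_id}\n")


def write_manifest(spec: SyntheticSpec, path: str) -> None:
    payload = {
        "motifs": [{"name": m.name, "fragment": m.fragment, "smarts": m.smarts} for m in spec.motifs],
        "n_pos": spec.n_pos,
        "n_neg": spec.n_neg,
        "scaffold_size_range": list(spec.scaffold_size_range),
        "seed": spec.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
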