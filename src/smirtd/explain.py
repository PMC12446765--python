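"""Attention-based attribution: attention-map extraction, token-to-atom
salience, substructure highlighting, structural-alert prevalence tables, and
embedding export.

Salience of a token is the mean attention it receives (column mean of the
aggregated attention matrix).  Tokens that carry no atom — ring digits,
brackets, bond symbols — fold their salience into the nearest preceding atom
token, so that every unit of attention lands on an atom of the molecular
graph and highlighted regions can be drawn on the structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .corpus import TokenizedMolecule, tokenize
from .model import ElectraModel

__all__ = [
    "AtomAttribution",
    "SAPrevalence",
    "STRUCTURAL_ALERTS",
    "extract_attention",
    "aggregate_attention",
    "atom_salience",
    "sa_prevalence",
    "extract_embeddings",
    "attribution_json",
    "draw_attribution_svg",
]

# Structural alerts reported to differ between QT-prolonging and
# non-QT-prolonging drugs, as SMARTS queries.
STRUCTURAL_ALERTS: dict[str, str] = {
    "tertiary_amine": "[NX3]([#6])([#6])[#6]",
    "sp3_carbon": "[CX4]",
    "aryl_halide": "c[F,Cl,Br,I]",
}


@dataclass(frozen=True)
class AtomAttribution:
    drug_id: str
    smiles: str
    salience: tuple[float, ...]                   # one non-negative value per atom
    highlighted_atom_sets: tuple[tuple[int, ...], ...]  # ranked, most salient first


@dataclass(frozen=True)
class SAPrevalence:
    """Prevalence of one structural alert in each class, in percent, and the
    positive-minus-negative difference."""

    sa_name: str
    pattern: str
    proportion_pos: float
    proportion_neg: float

    @property
    def difference(self) -> float:
        return self.proportion_pos - self.proportion_neg


def extract_attention(model: ElectraModel, tokenized: TokenizedMolecule) -> np.ndarray:
    """Discriminator attention weights, shape (n_layers, n_heads, L, L),
    evaluation mode.  Rows are softmax-normalized."""
    return model.attention_maps(tokenized.ids)


def aggregate_attention(attention: np.ndarray, aggregation: str = "last_layer_mean") -> np.ndarray:
    """Collapse (layers, heads, L, L) to one L x L matrix.

    ``last_layer_mean`` (default): mean over heads of the final layer.
    ``rollout``: head-mean per layer, mixed with the identity, multiplied
    across layers to account for residual information flow.
    """
    per_layer = attention.mean(axis=1)  # (layers, L, L)
    if aggregation == "last_layer_mean":
        return per_layer[-1]
    if aggregation == "rollout":
        L = per_layer.shape[-1]
        rolled = np.eye(L)
        for a in per_layer:
            mixed = 0.5 * a + 0.5 * np.eye(L)
            mixed /= mixed.sum(axis=-1, keepdims=True)
            rolled = mixed @ rolled
        return rolled
    raise ValueError(f"unknown aggregation {aggregation!r}")


def atom_salience(
    attention: np.ndarray,
    tokenized: TokenizedMolecule,
    aggregation: str = "last_layer_mean",
    highlight_quantile: float = 0.75,
    drug_id: str = "",
) -> AtomAttribution:
    """Project token-level attention salience onto atoms and rank highlighted
    substructures (connected atom sets above the salience quantile)."""
    if tokenized.n_atoms == 0:
        raise ValueError("molecule has no atom tokens")
    mat = aggregate_attention(attention, aggregation)
    token_salience = mat.mean(axis=0)  # attention received per token
    L = min(len(tokenized), len(token_salience))

    n_atoms = tokenized.n_atoms
    atom_scores = np.zeros(n_atoms)
    current = None
    pending = 0.0
    for i in range(L):
        a = tokenized.atom_indices[i]
        if a is not None:
            current = a
            atom_scores[a] += token_salience[i] + pending
            pending = 0.0
        elif current is not None:
            atom_scores[current] += token_salience[i]
        else:
            pending += token_salience[i]  # leading non-atom tokens: first atom
    if pending and n_atoms:
        atom_scores[0] += pending

    mol = Chem.MolFromSmiles(tokenized.smiles)
    cutoff = np.quantile(atom_scores, highlight_quantile)
    hot = {i for i, s in enumerate(atom_scores) if s >= cutoff and i < (mol.GetNumAtoms() if mol else n_atoms)}
    groups = _connected_groups(mol, hot) if mol is not None else [tuple(sorted(hot))]
    groups.sort(key=lambda g: -float(np.mean([atom_scores[i] for i in g])))
    return AtomAttribution(
        drug_id=drug_id,
        smiles=tokenized.smiles,
        salience=tuple(float(s) for s in atom_scores),
        highlighted_atom_sets=tuple(tuple(g) for g in groups),
    )


def _connected_groups(mol: Chem.Mol, atoms: set[int]) -> list[tuple[int, ...]]:
    remaining = set(atoms)
    groups = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            a = frontier.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                j = nb.GetIdx()
                if j in remaining:
                    remaining.remove(j)
                    comp.add(j)
                    frontier.append(j)
        groups.append(tuple(sorted(comp)))
    return groups


def sa_prevalence(
    positives: Sequence[str],
    negatives: Sequence[str],
    pattern: str,
    sa_name: str = "",
) -> SAPrevalence:
    """Percent of molecules in each class containing at least one match of the
    substructure query; difference = positive - negative."""
    if not positives or not negatives:
        raise ValueError("both molecule sets must be non-empty")
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid substructure query: {pattern!r}")

    def prevalence(smiles_list: Sequence[str]) -> float:
        hits = 0
        for s in smiles_list:
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                raise ValueError(f"not a valid SMILES: {s!r}")
            if mol.HasSubstructMatch(query):
                hits += 1
        return 100.0 * hits / len(smiles_list)

    return SAPrevalence(sa_name or pattern, pattern, prevalence(positives), prevalence(negatives))


def extract_embeddings(model: ElectraModel, molecules: Sequence[str]) -> np.ndarray:
    """One d_model-wide row per molecule: the discriminator's final encoder
    layer mean-pooled over tokens.  Suitable for t-SNE/UMAP projection."""
    seqs = [tokenize(s, model.vocab).ids for s in molecules]
    return model.embeddings(seqs)


def attribution_json(attributions: Sequence[AtomAttribution]) -> str:
    return json.dumps(
        [
            {
                "drug_id": a.drug_id,
                "smiles": a.smiles,
                "atom_salience": list(a.salience),
                "highlighted_atom_sets": [list(g) for g in a.highlighted_atom_sets],
            }
            for a in attributions
        ],
        indent=2,
    )


def draw_attribution_svg(attribution: AtomAttribution, path: str) -> None:
    """Render the molecule with its top highlighted substructure as SVG."""
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = Chem.MolFromSmiles(attribution.smiles)
    drawer = rdMolDraw2D.MolDraw2DSVG(420, 320)
    highlight = [i for g in attribution.highlighted_atom_sets[:1] for i in g]
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol, highlightAtoms=highlight)
    drawer.FinishDrawing()
    with open(path, "w") as fh:
        fh.write(drawer.GetDrawingText())
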