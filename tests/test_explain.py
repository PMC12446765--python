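"""Attention extraction, atom salience projection, structural-alert
prevalence, and embedding export."""

import numpy as np
import pytest

from smirtd.corpus import build_vocab, tokenize
from smirtd.explain import (
    STRUCTURAL_ALERTS,
    aggregate_attention,
    atom_salience,
    extract_attention,
    extract_embeddings,
    sa_prevalence,
)
from smirtd.model import ElectraModel, ModelConfig


@pytest.fixture(scope="module")
def fixed_model():
    vocab = build_vocab(["CCOc1ccc(Cl)cc1CN(C)C", "CC(C)Cc1ccc(C)cc1C(C)C(=O)O"])
    cfg = ModelConfig(
        vocab_size=len(vocab), d_model=16, n_heads=2, n_layers=2, d_ffn=32,
        max_len=64, generator_width_fraction=0.5, seed=11,
    )
    return ElectraModel(cfg, vocab)


class TestExtractAttention:
    def test_shape_and_row_normalization(self, fixed_model):
        tok = tokenize("CCOc1ccccc1", fixed_model.vocab)
        attn = extract_attention(fixed_model, tok)
        L = len(tok)
        assert attn.shape == (2, 2, L, L)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert (attn >= 0).all()

    def test_deterministic(self, fixed_model):
        tok = tokenize("CCN(C)C", fixed_model.vocab)
        assert np.array_equal(extract_attention(fixed_model, tok), extract_attention(fixed_model, tok))

    def test_rollout_rows_stochastic(self, fixed_model):
        tok = tokenize("CCOCC", fixed_model.vocab)
        rolled = aggregate_attention(extract_attention(fixed_model, tok), "rollout")
        assert np.allclose(rolled.sum(axis=-1), 1.0, atol=1e-5)


class TestAtomSalience:
    def test_uniform_attention_gives_equal_salience_on_atom_only_molecule(self):
        tok = tokenize("CCCCO")
        attn = np.full((1, 1, 5, 5), 1 / 5)
        attr = atom_salience(attn, tok)
        assert np.allclose(attr.salience, attr.salience[0])

    def test_non_atom_tokens_fold_into_preceding_atom(self):
        tok = tokenize("CC(C)O")  # tokens C C ( C ) O; brackets fold into atoms 1 and 2
        attn = np.full((1, 1, 6, 6), 1 / 6)
        attr = atom_salience(attn, tok)
        assert len(attr.salience) == 4
        assert attr.salience[1] > attr.salience[0]  # second C absorbs '('
        assert sum(attr.salience) == pytest.approx(1.0, abs=1e-6)

    def test_salience_nonnegative_finite(self, fixed_model):
        tok = tokenize("CCOc1ccc(Cl)cc1", fixed_model.vocab)
        attr = atom_salience(extract_attention(fixed_model, tok), tok)
        sal = np.array(attr.salience)
        assert np.isfinite(sal).all() and (sal >= 0).all()
        assert len(sal) == tok.n_atoms

    def test_highlighted_sets_are_valid_connected_atoms(self, fixed_model):
        tok = tokenize("CCOc1ccc(Cl)cc1CN(C)C", fixed_model.vocab)
        attr = atom_salience(extract_attention(fixed_model, tok), tok)
        assert attr.highlighted_atom_sets
        all_atoms = set(range(tok.n_atoms))
        for group in attr.highlighted_atom_sets:
            assert set(group) <= all_atoms

    def test_shared_substructure_salience_stable_under_methyl_change(self, fixed_model):
        """Two molecules differing by one methyl (the ibufenac/ibuprofen
        pattern) get near-identical salience on their shared atoms."""
        a = "CC(C)Cc1ccc(CC(=O)O)cc1"        # ibufenac-like
        b = "CC(C)Cc1ccc(C(C)C(=O)O)cc1"     # extra methyl
        from rdkit import Chem

        ma, mb = Chem.MolFromSmiles(a), Chem.MolFromSmiles(b)
        match = mb.GetSubstructMatch(ma)  # shared-atom mapping a->b
        assert match
        tok_a, tok_b = tokenize(a, fixed_model.vocab), tokenize(b, fixed_model.vocab)
        sal_a = np.array(atom_salience(extract_attention(fixed_model, tok_a), tok_a).salience)
        sal_b = np.array(atom_salience(extract_attention(fixed_model, tok_b), tok_b).salience)
        shared_a = sal_a
        shared_b = sal_b[list(match)]
        rel = np.abs(shared_a - shared_b).mean() / shared_a.mean()
        assert rel < 0.5  # profiles agree on the shared scaffold

    def test_no_atoms_rejected(self):
        with pytest.raises(ValueError):
            tok = tokenize("CC")
            object.__setattr__(tok, "atom_indices", (None, None))
            atom_salience(np.full((1, 1, 2, 2), 0.5), tok)


class TestSAPrevalence:
    def test_published_qt_prevalence_difference(self):
        # tertiary amines: 61.1% in QT vs 12.6% in non-QT drugs
        from smirtd.explain import SAPrevalence

        row = SAPrevalence("tertiary_amine", STRUCTURAL_ALERTS["tertiary_amine"], 61.1, 12.6)
        assert row.difference == pytest.approx(48.5)

    def test_pattern_absent_in_both(self):
        row = sa_prevalence(["CCO"], ["CCC"], STRUCTURAL_ALERTS["aryl_halide"])
        assert (row.proportion_pos, row.proportion_neg, row.difference) == (0.0, 0.0, 0.0)

    def test_pattern_in_every_molecule(self):
        mols = ["c1ccc(Cl)cc1", "Cc1ccc(F)cc1"]
        row = sa_prevalence(mols, mols, STRUCTURAL_ALERTS["aryl_halide"])
        assert (row.proportion_pos, row.proportion_neg) == (100.0, 100.0)
        assert row.difference == 0.0

    def test_mixed_prevalence(self):
        row = sa_prevalence(["CN(C)C", "CCO"], ["CCO", "CCC", "CNC", "OCC"], STRUCTURAL_ALERTS["tertiary_amine"])
        assert row.proportion_pos == pytest.approx(50.0)
        assert row.proportion_neg == pytest.approx(0.0)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            sa_prevalence(["CCO"], ["CCC"], "not a smarts ((")

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sa_prevalence([], ["CCC"], "[CX4]")


class TestEmbeddings:
    def test_shape_and_determinism(self, fixed_model):
        mols = ["CCO", "CCN(C)C", "CCO"]
        emb = extract_embeddings(fixed_model, mols)
        assert emb.shape == (3, fixed_model.config.d_model)
        assert np.allclose(emb[0], emb[2])  # duplicate molecules identical

    def test_permutation_permutes_rows(self, fixed_model):
        mols = ["CCO", "CCN(C)C", "c1ccccc1"]
        emb = extract_embeddings(fixed_model, mols)
        emb_rev = extract_embeddings(fixed_model, mols[::-1])
        assert np.allclose(emb_rev, emb[::-1])
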