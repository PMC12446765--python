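"""SMILES canonicalization, enumeration, tokenization, vocabulary and
dataset-partitioning behavior."""

import numpy as np
import pytest

from smirtd.corpus import (
    DrugRecord,
    SmilesParseError,
    SplitSpec,
    TokenizationError,
    build_vocab,
    canonicalize,
    enumerate_smiles,
    read_drug_table,
    read_smi,
    split_dataset,
    tokenize,
    write_split_manifest,
)


class TestCanonicalize:
    @pytest.mark.parametrize("a,b", [("OCC", "CCO"), ("C1=CC=CC=C1", "c1ccccc1")])
    def test_equivalent_forms_collapse(self, a, b):
        assert canonicalize(a) == canonicalize(b)

    @pytest.mark.parametrize("s", ["CCO", "c1ccc(Cl)cc1CN(C)C", "CC(=O)Oc1ccccc1C(=O)O"])
    def test_idempotent(self, s):
        assert canonicalize(canonicalize(s)) == canonicalize(s)

    def test_parse_error_names_input(self):
        with pytest.raises(SmilesParseError, match="Cl9Q"):
            canonicalize("Cl9Q")


class TestEnumerate:
    def test_variants_share_canonical_form(self):
        variants = enumerate_smiles("CC(=O)Oc1ccccc1C(=O)O", 10, seed=3)
        assert 1 <= len(variants) <= 10
        assert {canonicalize(v) for v in variants} == {canonicalize("CC(=O)Oc1ccccc1C(=O)O")}

    def test_small_molecule_caps_at_distinct_traversals(self):
        variants = enumerate_smiles("CCO", 5, seed=0)
        assert len(variants) <= 5
        assert {canonicalize(v) for v in variants} == {"CCO"}

    def test_single_atom_has_one_traversal(self):
        assert enumerate_smiles("C", 5, seed=0) == ["C"]

    def test_deterministic_per_seed(self):
        s = "CC(C)Cc1ccc(C)cc1"
        assert enumerate_smiles(s, 8, seed=11) == enumerate_smiles(s, 8, seed=11)

    def test_invalid_smiles_raises(self):
        with pytest.raises(SmilesParseError):
            enumerate_smiles("notasmiles[", 3)


class TestTokenize:
    @pytest.mark.parametrize(
        "smiles,tokens",
        [
            ("CCO", ["C", "C", "O"]),
            ("CCl", ["C", "Cl"]),
            ("C1=CC=CC=C1", ["C", "1", "=", "C", "C", "=", "C", "C", "=", "C", "1"]),
            ("[NH3+]CBr", ["[NH3+]", "C", "Br"]),
            ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
        ],
    )
    def test_lexical_grammar(self, smiles, tokens):
        assert list(tokenize(smiles).tokens) == tokens

    def test_join_roundtrip(self):
        for s in ["CC(=O)Oc1ccccc1C(=O)O", "CN1CCC[C@H]1c1cccnc1", "O=[N+]([O-])c1ccccc1"]:
            assert "".join(tokenize(s).tokens) == s

    def test_atom_indices_increasing_and_distinct(self):
        tok = tokenize("CC(=O)Oc1ccccc1")
        atoms = [a for a in tok.atom_indices if a is not None]
        assert atoms == sorted(set(atoms)) == list(range(tok.n_atoms))

    def test_unbalanced_bracket_raises_with_position(self):
        with pytest.raises(TokenizationError, match="position"):
            tokenize("CC]O")

    def test_unknown_token_maps_to_unk(self):
        vocab = build_vocab(["CCO"])
        tok = tokenize("CCN", vocab)
        assert tok.ids[-1] == 1  # <unk>


class TestVocabulary:
    def test_small_corpus_size(self):
        assert len(build_vocab(["CCO"])) == 7  # 5 specials + {C, O}

    def test_specials_always_present(self):
        v = build_vocab(["c1ccncc1"])
        assert v.special_tokens == ("<pad>", "<unk>", "<bos>", "<eos>", "<mask>")
        assert [v.token_to_id[t] for t in v.special_tokens] == [0, 1, 2, 3, 4]

    def test_token_set_not_order_defines_vocab(self):
        assert build_vocab(["CCO", "OCC"]).token_to_id == build_vocab(["CCO"]).token_to_id

    def test_ids_contiguous(self):
        v = build_vocab(["CC(=O)NC1=CC=C(O)C=C1"])
        assert sorted(v.token_to_id.values()) == list(range(len(v)))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocab([])

    def test_json_roundtrip_preserves_hash(self):
        from smirtd.corpus import Vocabulary

        v = build_vocab(["CCOc1ccccc1"])
        assert Vocabulary.from_json(v.to_json()).content_hash() == v.content_hash()


def _records(n_pos, n_neg):
    recs = [DrugRecord(f"P{i}", "CCO", 1) for i in range(n_pos)]
    recs += [DrugRecord(f"N{i}", "CCC", 0) for i in range(n_neg)]
    return recs


class TestSplit:
    def test_exact_ratio(self):
        sp = split_dataset(_records(100, 0), SplitSpec(seed=0))
        assert (len(sp.train), len(sp.validation), len(sp.test)) == (80, 10, 10)

    def test_negatives_split_evenly_then_downsampled(self):
        sp = split_dataset(_records(10, 40), SplitSpec(seed=0))
        assert sum(r.label == 0 for r in sp.validation) == 20
        assert sum(r.label == 0 for r in sp.test) == 20
        sp3 = split_dataset(_records(10, 40), SplitSpec(seed=0, negative_keep_fraction=1 / 3))
        assert sum(r.label == 0 for r in sp3.validation) == 6  # floor(20/3)
        assert sum(r.label == 0 for r in sp3.test) == 6

    def test_train_contains_positives_only(self):
        sp = split_dataset(_records(20, 20), SplitSpec(seed=1))
        assert all(r.label == 1 for r in sp.train)

    def test_partition_disjoint_and_exhaustive(self):
        recs = _records(37, 23)
        sp = split_dataset(recs, SplitSpec(seed=5, negative_keep_fraction=1.0))
        ids = [r.drug_id for part in (sp.train, sp.validation, sp.test) for r in part]
        assert len(ids) == len(set(ids)) == len(recs)

    def test_deterministic_per_seed(self):
        recs = _records(30, 12)
        a = split_dataset(recs, SplitSpec(seed=9))
        b = split_dataset(recs, SplitSpec(seed=9))
        assert a == b

    def test_too_few_positives_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_records(2, 5), SplitSpec(seed=0))

    def test_bad_keep_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(negative_keep_fraction=0.0)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "drugs.csv"
        p.write_text("drug_id,smiles,label\nd1,CCO,1\nd2,CCC,0\n")
        recs = read_drug_table(str(p))
        assert recs == [DrugRecord("d1", "CCO", 1), DrugRecord("d2", "CCC", 0)]

    def test_smi_reader(self, tmp_path):
        p = tmp_path / "mols.smi"
        p.write_text("CCO drug_a\nCCC\n")
        recs = read_smi(str(p), label=1)
        assert recs[0] == DrugRecord("drug_a", "CCO", 1)
        assert recs[1].smiles == "CCC"

    def test_manifest_writer(self, tmp_path):
        sp = split_dataset(_records(10, 4), SplitSpec(seed=0))
        out = tmp_path / "manifest.tsv"
        write_split_manifest(sp, str(out))
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "drug_id\tsplit"
        assert len(lines) == 1 + 14
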