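"""Tokenize SMILES by the lexical grammar and build a corpus vocabulary.

Run:  python examples/01_tokenize_and_vocabulary.py
"""

from smirtd import build_vocab, canonicalize, enumerate_smiles, tokenize

aspirin = canonicalize("CC(=O)Oc1ccccc1C(=O)O")
tok = tokenize(aspirin)
print("canonical SMILES:", aspirin)
print("tokens:          ", " ".join(tok.tokens))
print("atom indices:    ", tok.atom_indices)
# Every token is either an atom (with its index in the molecular graph) or a
# structural symbol (ring digit, bond, branch) with index None; joining the
# tokens reproduces the SMILES exactly.
assert "".join(tok.tokens) == aspirin

variants = enumerate_smiles(aspirin, 5, seed=0)
print("\n5 enumerated variants (all the same molecule):")
for v in variants:
    print("  ", v)

vocab = build_vocab([aspirin] + variants)
print(f"\nvocabulary: {len(vocab)} tokens (5 specials + observed tokens)")
print("ids for tokens:", dict(list(vocab.token_to_id.items())[:10]), "...")
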