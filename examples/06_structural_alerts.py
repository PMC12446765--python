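"""Structural-alert prevalence differences and attention-based salience.

Run:  python examples/06_structural_alerts.py   (~5 min: trains the study model)
"""

import numpy as np

from smirtd import SyntheticSpec, generate, tokenize
from smirtd.explain import STRUCTURAL_ALERTS, SAPrevalence, atom_salience, extract_attention, sa_prevalence
from smirtd.presets import small_model_config, small_train_config
from smirtd.refdata import QT_SA_PREVALENCE
from smirtd.synthetic import motif_atoms
from smirtd.training import train

print("published structural-alert prevalences, QT vs non-QT drugs:")
for name, (p, n) in QT_SA_PREVALENCE.items():
    row = SAPrevalence(name, STRUCTURAL_ALERTS[name], p, n)
    print(f"  {name:12s} {p:5.1f}% vs {n:5.1f}%  difference {row.difference:+.1f} pp")

pos, neg = generate(SyntheticSpec(n_pos=230, n_neg=30, seed=7))
row = sa_prevalence(
    [r.smiles for r in pos], [r.smiles for r in neg], STRUCTURAL_ALERTS["tertiary_amine"], "tertiary_amine"
)
print(f"\nsynthetic dataset, tertiary amine: {row.proportion_pos:.1f}% vs {row.proportion_neg:.1f}%")

model, _ = train(pos[:200], small_model_config(seed=1), small_train_config(seed=1))
motif_vals, other_vals = [], []
for mol in pos[200:220]:
    tok = tokenize(mol.smiles, model.vocab)
    attr = atom_salience(extract_attention(model, tok), tok, drug_id=mol.drug_id)
    sal = np.array(attr.salience)
    hits = sorted(motif_atoms(mol.smiles))
    motif_vals.extend(sal[hits])
    other_vals.extend(sal[[i for i in range(len(sal)) if i not in hits]])
print(f"\nacross 20 held-out positives:")
print(f"mean salience on planted-motif atoms: {np.mean(motif_vals):.4f}")
print(f"mean salience on remaining atoms:     {np.mean(other_vals):.4f}")
print("\nIn aggregate, attention concentrates on the planted structural alerts,")
print("mirroring the substructure-highlighting analysis for real ADR drug")
print("families (per-molecule salience is noisier than the pooled comparison).")
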