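"""Bundled reference tables for worked examples.

Small published pharmacovigilance summaries used by the examples, tests and
the acceptance script, so that the ranked-recall and structural-alert-
prevalence computations can be exercised without any external download:

* ``TOP10_PRR``: for each ADR endpoint (QT prolongation, rhabdomyolysis,
  liver injury), the ten drugs with the highest proportional reporting
  ratios in spontaneous-report data, in descending PRR order, with a flag
  marking which of them a replaced-token-detection model predicted positive.
* ``QT_SA_PREVALENCE``: percent prevalence of three structural alerts in
  QT-prolonging vs non-QT-prolonging drug sets.
"""

from __future__ import annotations

__all__ = ["TOP10_PRR", "QT_SA_PREVALENCE"]

# (drug name, PRR, predicted positive by the model)
TOP10_PRR: dict[str, list[tuple[str, float, int]]] = {
    "qt_prolongation": [
        ("lactulose", 14.262, 0),
        ("aminocaproic acid", 12.526, 0),
        ("felbamate", 12.526, 1),
        ("ripretinib", 10.220, 1),
        ("imatinib", 10.214, 1),
        ("asciminib", 10.214, 1),
        ("omacetaxine mepesuccinate", 9.875, 0),
        ("edaravone", 9.122, 1),
        ("isocarboxazid", 6.699, 1),
        ("amphotericin b", 6.150, 1),
    ],
    "rhabdomyolysis": [
        ("betaine", 51.297, 1),
        ("maribavir", 17.265, 1),
        ("trifluoperazine", 11.266, 1),
        ("dexamethasone", 11.166, 0),
        ("valproic acid", 10.122, 1),
        ("pralatrexate", 9.855, 1),
        ("quazepam", 9.849, 1),
        ("sugammadex", 8.089, 0),
        ("ibuprofen", 8.089, 1),
        ("rocuronium", 8.089, 0),
    ],
    "liver_injury": [
        ("vancomycin", 6.188, 0),
        ("lacosamide", 6.188, 1),
        ("isosulfan blue", 4.763, 1),
        ("semaglutide", 4.442, 0),
        ("abrocitinib", 4.309, 1),
        ("maribavir", 3.807, 1),
        ("prednicarbate", 3.702, 1),
        ("crotamiton", 3.690, 1),
        ("desonide", 3.482, 1),
        ("sofosbuvir", 3.444, 1),
    ],
}

# alert name -> (% in QT-prolonging drugs, % in non-QT-prolonging drugs)
QT_SA_PREVALENCE: dict[str, tuple[float, float]] = {
    "tertiary_amine": (61.1, 12.6),
    "sp3_carbon": (81.3, 37.9),
    "aryl_halide": (37.5, 13.7),
}
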