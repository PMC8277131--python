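"""Compositional metrics for molecular formulas.

Parses a few formulas typical of environmental mixtures and prints the
metrics used to interpret them: monoisotopic/nominal mass, double bond
equivalents (DBE), elemental ratios, average carbon oxidation state
(OSc), aromaticity index (AI), and the composition class.
"""

from ntms import metrics, parse_formula

FORMULAS = ["C7H8O2", "C6H5NO4", "C16H26O3S", "C17H28O3S", "C14H16ClN3O2"]

print(f"{'formula':>14} {'MW':>9} {'nom':>4} {'DBE':>4} {'DBE/C':>6} "
      f"{'O/C':>5} {'H/C':>5} {'OSc':>6} {'AI':>5} class")
for text in FORMULAS:
    m = metrics(parse_formula(text))
    print(
        f"{text:>14} {m.mw_mono:9.4f} {m.mw_nominal:4d} {m.dbe:4.0f} "
        f"{m.dbe_c:6.2f} {m.oc:5.2f} {m.hc:5.2f} {m.osc:6.2f} {m.ai:5.2f} "
        f"{m.comp_class}"
    )

print()
print("DBE/C > 0.5 flags likely aromatic structures; OSc rises with")
print("atmospheric oxidation; the class (CHO/CHON/CHOS/...) groups")
print("compounds by heteroatom content for source comparison.")
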