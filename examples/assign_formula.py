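"""Molecular formula assignment for a measured accurate mass.

Enumerates every candidate formula within 3 ppm under the
particulate-matter element limits, verifies the observed isotopologue
pattern against theory (+/-30% relative), filters chemically implausible
candidates, and reports the assignment.
"""

from ntms.assign import ElementLimits, assign_feature, enumerate_candidates
from ntms.chem import ION_SPECIES, ion_mz, isotope_pattern, parse_formula

sp = ION_SPECIES["[M-H]-"]
true = parse_formula("C16H26O3S")
mz = ion_mz(true, sp)

print(f"measured m/z {mz:.4f} as {sp.label}")
print("candidates within 3 ppm:")
for f, err in enumerate_candidates(mz, sp, ElementLimits.negative_pm(), 3.0):
    print(f"  {str(f):>12}  {err:+6.2f} ppm")

pat = isotope_pattern(true, sp)
observed = {"A": 8e5, "A1": 8e5 * pat[1][1] * 1.05, "A2": 8e5 * pat[2][1] * 0.93}
a = assign_feature("demo", mz, sp, observed, limits=ElementLimits.negative_pm())
print()
print(f"assigned: {a.formula}  ({a.ppm_error:+.2f} ppm, status {a.status})")
print(f"isotope deviations: A+1 {a.isotope.dev_a1:+.1%}, A+2 {a.isotope.dev_a2:+.1%}")
print()
print("The +/-30% isotopologue tolerance is what separates candidates that")
print("are indistinguishable by exact mass alone (e.g. S vs O2 swaps).")
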