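"""Why accurate-mass extraction outperforms unit-mass extraction.

Builds a synthetic run containing one analyte plus an isobaric
interferent that falls inside the 1-Th unit-mass window but far outside
a 5 ppm accurate-mass window, then compares the chromatographic S/N of
the two extraction modes.
"""

from ntms.peaks import improvement_factor, sn_for_species
from ntms.synth import interference_fixture

run, truth, target_mz = interference_fixture(seed=3)

sn_unit = sn_for_species(run, target_mz, mode="unit")
sn_acc = sn_for_species(run, target_mz, mode="accurate")

print(f"analyte [M-H]- at m/z {target_mz:.4f}")
print(f"unit-mass window S/N     : {sn_unit:6.2f}")
print(f"accurate-mass window S/N : {sn_acc:6.2f}")
print(f"improvement factor       : {improvement_factor(sn_acc, sn_unit)}x")
print()
print("The interferent inflates the noise estimate of the unit window")
print("only; near-detection-limit compounds can therefore fall below an")
print("S/N gate under unit-mass extraction while remaining clearly")
print("detectable with accurate-mass windows.")
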