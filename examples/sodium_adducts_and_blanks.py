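"""Adduct grouping modes and blank subtraction.

Some compounds ionize exclusively as sodium adducts [M+Na]+.  A
protonated-first grouping strategy (``vendor_compat``, replicating a
documented limitation of a commercial framework) cannot detect them;
``independent`` grouping resolves each component on its own evidence.
The second half shows solvent-blank subtraction at the 3x area ratio.
"""

from ntms.artifacts import blank_subtract, group_adducts
from ntms.assign import ElementLimits
from ntms.features import Feature
from ntms.pipeline import find_features, fold_isotopologues
from ntms.synth import sodium_only_fixture

run, truth = sodium_only_fixture(seed=3)
feats, _ = fold_isotopologues(find_features(run))
limits = ElementLimits.positive()

for mode in ("independent", "vendor_compat"):
    comps = group_adducts(
        [Feature(f.feature_id, f.mz, f.rt, f.area, f.apex_intensity,
                 sample=f.sample, polarity=f.polarity, isotopes=dict(f.isotopes))
         for f in feats],
        mode=mode, limits=limits, detection_floor=3e4,
    )
    n_found = sum(
        any(abs(c.neutral_mass - (t.mz - 22.9892)) < 0.01 for c in comps)
        for t in truth.itertuples()
    )
    print(f"{mode:>14}: {n_found}/{len(truth)} sodium-only compounds detected")

print()
sample = [Feature("carryover", 200.05, 1.0, 2e5, 2e5),
          Feature("genuine", 250.10, 2.0, 9e5, 9e5)]
blank = [Feature("b1", 200.05, 1.0, 1e5, 1e5),
         Feature("b2", 250.10, 2.0, 1e5, 1e5)]
kept, log = blank_subtract(sample, blank, ratio_threshold=3)
print(f"blank subtraction kept {[f.feature_id for f in kept]}")
for entry in log:
    print(f"removed {entry['feature_id']}: sample/blank ratio "
          f"{entry['ratio']:.1f} < 3")
print()
print("A feature matching a blank survives only when its area exceeds 3x")
print("the blank area; survivors carry the ratio as an annotation.")
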