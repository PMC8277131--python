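"""Adduct grouping, artifact removal, and blank subtraction."""

from __future__ import annotations

import random

import pytest

from ntms.artifacts import (
    ArtifactTable,
    blank_subtract,
    group_adducts,
    remove_artifacts,
)
from ntms.assign import ElementLimits
from ntms.chem import ION_SPECIES, ion_mz, parse_formula
from ntms.features import Feature


def _feat(fid, mz, rt, area=1e5, polarity="positive", sample="s", formula=None, species=None):
    f = Feature(
        feature_id=fid, mz=mz, rt=rt, area=area, apex_intensity=area,
        sample=sample, polarity=polarity,
    )
    if formula is not None:
        # observed isotopologues as the generator would produce them
        from ntms.chem import isotope_pattern

        pat = isotope_pattern(formula, ION_SPECIES[species])
        f.isotopes = {"A": area, "A1": area * pat[1][1], "A2": area * pat[2][1]}
    return f


CAFFEINE = parse_formula("C8H10N4O2")
LEVOGLUCOSAN = parse_formula("C6H10O5")


class TestGroupAdducts:
    def test_proton_sodium_pair_merges(self):
        fh = _feat("h", ion_mz(CAFFEINE, ION_SPECIES["[M+H]+"]), 3.0, area=5e5)
        fna = _feat("na", ion_mz(CAFFEINE, ION_SPECIES["[M+Na]+"]), 3.02, area=2e5)
        comps = group_adducts([fh, fna])
        assert len(comps) == 1
        comp = comps[0]
        assert comp.preferred.feature_id == "h"
        assert {m.species_label for m in comp.members} == {"[M+H]+", "[M+Na]+"}
        assert comp.neutral_mass == pytest.approx(194.0804, abs=0.001)

    def test_rt_separation_blocks_merge(self):
        fh = _feat("h", ion_mz(CAFFEINE, ION_SPECIES["[M+H]+"]), 3.0)
        fna = _feat("na", ion_mz(CAFFEINE, ION_SPECIES["[M+Na]+"]), 5.0)
        assert len(group_adducts([fh, fna])) == 2

    def test_lone_sodiated_modes(self):
        """Na-only compounds: found in independent mode, lost in vendor_compat."""
        mz = ion_mz(LEVOGLUCOSAN, ION_SPECIES["[M+Na]+"])
        limits = ElementLimits.positive()
        f1 = _feat("solo", mz, 2.0, formula=LEVOGLUCOSAN, species="[M+Na]+")
        indep = group_adducts([f1], mode="independent", limits=limits)
        assert len(indep) == 1
        assert indep[0].preferred.species_label == "[M+Na]+"
        assert indep[0].neutral_mass == pytest.approx(162.0528, abs=0.001)

        f2 = _feat("solo", mz, 2.0, formula=LEVOGLUCOSAN, species="[M+Na]+")
        compat = group_adducts([f2], mode="vendor_compat", limits=limits)
        # vendor_compat treats the lone feature as [M+H]+: no component
        # carries the true neutral mass
        assert all(abs(c.neutral_mass - 162.0528) > 0.01 for c in compat)

    def test_independent_superset_of_vendor_compat(self):
        feats = []
        for i, f in enumerate(["C6H10O5", "C6H12O3", "C8H10N4O2"]):
            frm = parse_formula(f)
            feats.append(
                _feat(f"na{i}", ion_mz(frm, ION_SPECIES["[M+Na]+"]), 1.0 + i,
                      formula=frm, species="[M+Na]+")
            )
        frm = parse_formula("C8H10N4O2")
        feats.append(_feat("h3", ion_mz(frm, ION_SPECIES["[M+H]+"]), 3.0, area=9e5))
        limits = ElementLimits.positive()

        def truthy(comps):
            return {
                round(c.neutral_mass, 3)
                for c in comps
                if any(
                    abs(c.neutral_mass - m) < 0.01
                    for m in (162.053, 132.079, 194.080)
                )
            }

        indep = truthy(group_adducts([_copy(f) for f in feats], mode="independent", limits=limits))
        compat = truthy(group_adducts([_copy(f) for f in feats], mode="vendor_compat", limits=limits))
        assert compat <= indep
        assert len(indep) == 3  # all neutrals recovered
        assert len(compat) == 1  # only the protonated compound

    def test_permutation_invariance(self):
        fh = _feat("h", ion_mz(CAFFEINE, ION_SPECIES["[M+H]+"]), 3.0, area=5e5)
        fna = _feat("na", ion_mz(CAFFEINE, ION_SPECIES["[M+Na]+"]), 3.02, area=2e5)
        fx = _feat("x", 401.18, 7.0)
        base = group_adducts([_copy(f) for f in (fh, fna, fx)])
        for perm in ([fna, fx, fh], [fx, fna, fh]):
            comps = group_adducts([_copy(f) for f in perm])
            assert {
                frozenset(m.feature_id for m in c.members) for c in comps
            } == {frozenset(m.feature_id for m in c.members) for c in base}

    def test_mixed_polarity_rejected(self):
        f1 = _feat("a", 200.0, 1.0, polarity="positive")
        f2 = _feat("b", 222.0, 1.0, polarity="negative")
        with pytest.raises(ValueError):
            group_adducts([f1, f2])


def _copy(f: Feature) -> Feature:
    return Feature(
        feature_id=f.feature_id, mz=f.mz, rt=f.rt, area=f.area,
        apex_intensity=f.apex_intensity, sample=f.sample, polarity=f.polarity,
        isotopes=dict(f.isotopes),
    )


class TestRemoveArtifacts:
    def test_one_row_per_component(self):
        fh = _feat("h", ion_mz(CAFFEINE, ION_SPECIES["[M+H]+"]), 3.0, area=5e5)
        fna = _feat("na", ion_mz(CAFFEINE, ION_SPECIES["[M+Na]+"]), 3.02, area=2e5)
        fk = _feat("k", ion_mz(CAFFEINE, ION_SPECIES["[M+K]+"]), 3.01, area=1e5)
        comps = group_adducts([fh, fna, fk])
        kept, log = remove_artifacts(comps)
        assert len(kept) == 1
        assert kept[0].feature_id == "h"
        assert {r["feature_id"] for r in log} == {"na", "k"}

    def test_conservation(self):
        feats = [
            _feat("h", ion_mz(CAFFEINE, ION_SPECIES["[M+H]+"]), 3.0, area=5e5),
            _feat("na", ion_mz(CAFFEINE, ION_SPECIES["[M+Na]+"]), 3.02, area=2e5),
            _feat("lone", 355.1, 6.0),
        ]
        comps = group_adducts(feats)
        kept, log = remove_artifacts(comps)
        assert len(kept) + len(log) == len(feats)
        assert len(kept) == len(comps)


class TestBlankSubtract:
    def test_threshold_arithmetic(self):
        s = _feat("s1", 200.05, 1.0, area=1e6)
        b = _feat("b1", 200.05, 1.0, area=1e5)
        kept, log = blank_subtract([s], [b], ratio_threshold=3)
        assert kept == [s]
        assert s.annotations["solvent_blank_ratio"] == pytest.approx(10.0)

        s2 = _feat("s2", 200.05, 1.0, area=2e5)
        kept, log = blank_subtract([s2], [_copy(b)], ratio_threshold=3)
        assert kept == []
        assert log[0]["reason"] == "blank_artifact"
        assert log[0]["ratio"] == pytest.approx(2.0)

    def test_absent_from_blanks_retained(self):
        s = _feat("s", 321.01, 2.2, area=5e4)
        b = _feat("b", 119.02, 0.8, area=5e4)
        kept, _ = blank_subtract([s], [b], [])
        assert kept == [s]

    def test_subset_and_idempotent(self):
        sample = [
            _feat("a", 200.05, 1.0, area=1e6),
            _feat("b", 250.10, 2.0, area=2e5),
            _feat("c", 300.15, 3.0, area=9e4),
        ]
        blanks = [
            _feat("ba", 200.05, 1.0, area=1e5),
            _feat("bb", 250.10, 2.0, area=1e5),
        ]
        kept1, _ = blank_subtract(sample, blanks)
        assert set(f.feature_id for f in kept1) <= set(f.feature_id for f in sample)
        kept2, log2 = blank_subtract(kept1, blanks)
        assert [f.feature_id for f in kept2] == [f.feature_id for f in kept1]
        assert log2 == []

    def test_both_blanks_applied_sequentially(self):
        s = [
            _feat("a", 200.05, 1.0, area=1e5),
            _feat("b", 250.10, 2.0, area=1e5),
        ]
        solvent = [_feat("sb", 200.05, 1.0, area=9e4)]
        procedural = [_feat("pb", 250.10, 2.0, area=9e4)]
        kept, log = blank_subtract(s, solvent, procedural)
        assert kept == []
        assert {r["matched_blank"] for r in log} == {"solvent_blank", "procedural_blank"}
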