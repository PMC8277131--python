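"""Formula candidate enumeration, isotope verification, erroneous filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntms.assign import (
    ElementLimits,
    ErroneousRules,
    assign_feature,
    check_isotopes,
    enumerate_candidates,
    filter_erroneous,
)
from ntms.chem import ION_SPECIES, Formula, ion_mz, isotope_pattern, parse_formula

from oracles import brute_force_candidates

NEG = ION_SPECIES["[M-H]-"]
POS = ION_SPECIES["[M+H]+"]


class TestEnumerate:
    def test_contains_known_formula(self):
        cands = enumerate_candidates(123.0452, NEG, ElementLimits.negative_pm(), 3)
        assert parse_formula("C7H8O2") in {f for f, _ in cands}

    def test_sorted_by_abs_ppm(self):
        cands = enumerate_candidates(301.1, NEG, ElementLimits.negative_pm(), 3)
        errs = [abs(e) for _, e in cands]
        assert errs == sorted(errs)

    def test_shrinking_tolerance(self):
        f = parse_formula("C10H14O4")
        mz = ion_mz(f, NEG)
        for tol in (3, 1, 0.1, 0.001):
            cands = {g for g, _ in enumerate_candidates(mz, NEG, None, tol)}
            assert f in cands
        tight = enumerate_candidates(mz, NEG, None, 0.001)
        assert {g for g, _ in tight} == {f}

    def test_monotone_in_tolerance_and_limits(self):
        mz = 297.1530
        small = {f for f, _ in enumerate_candidates(mz, NEG, ElementLimits.negative_pm(), 1)}
        big = {f for f, _ in enumerate_candidates(mz, NEG, ElementLimits.negative_pm(), 3)}
        assert small <= big
        pm = {f for f, _ in enumerate_candidates(mz, NEG, ElementLimits.negative_pm(), 3)}
        water = {f for f, _ in enumerate_candidates(mz, NEG, ElementLimits.negative_water(), 3)}
        assert pm <= water

    @pytest.mark.parametrize("mode", ["negative_pm", "negative_water", "positive"])
    def test_oracle_equivalence_spot(self, mode):
        limits = {
            "negative_pm": ElementLimits.negative_pm(),
            "negative_water": ElementLimits.negative_water(),
            "positive": ElementLimits.positive(include_metals=True),
        }[mode]
        sp = POS if mode == "positive" else NEG
        rng = np.random.default_rng(hash(mode) % 2**31)
        for mz in rng.uniform(80, 450, 8):
            mine = {f for f, _ in enumerate_candidates(mz, sp, limits, 3)}
            assert mine == brute_force_candidates(mz, sp, limits, 3)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            enumerate_candidates(-5.0, NEG)
        with pytest.raises(ValueError):
            enumerate_candidates(123.0, NEG, tol_ppm=0)


class TestIsotopeCheck:
    def test_exact_match_passes(self):
        f = parse_formula("C16H26O3S")
        pat = isotope_pattern(f, NEG)
        obs = {"A": 1e6, "A1": 1e6 * pat[1][1], "A2": 1e6 * pat[2][1]}
        res = check_isotopes(f, NEG, obs)
        assert res.passed
        assert res.dev_a1 == pytest.approx(0.0, abs=1e-12)

    def test_over_tolerance_fails(self):
        f = parse_formula("C16H26O3S")
        pat = isotope_pattern(f, NEG)
        obs = {"A": 1e6, "A1": 1.31 * 1e6 * pat[1][1]}
        assert not check_isotopes(f, NEG, obs).passed

    def test_noisy_pattern_passes(self):
        f = parse_formula("C16H26O3S")
        pat = isotope_pattern(f, NEG)
        rng = np.random.default_rng(3)
        obs = {
            "A": 1e6,
            "A1": 1e6 * pat[1][1] * (1 + rng.uniform(-0.1, 0.1)),
            "A2": 1e6 * pat[2][1] * (1 + rng.uniform(-0.1, 0.1)),
        }
        assert check_isotopes(f, NEG, obs).passed

    def test_missing_below_floor_is_ok(self):
        f = parse_formula("C5H8O3")  # A+1 ~ 5.5% of A
        obs = {"A": 1e5}  # theoretical A1 ~ 5.5e3 < floor
        assert check_isotopes(f, NEG, obs, detection_floor=3e4).passed

    def test_missing_above_floor_fails(self):
        f = parse_formula("C30H50O2")  # A+1 ~ 33% of A
        obs = {"A": 1e6}  # theoretical A1 ~ 3.3e5 > floor
        assert not check_isotopes(f, NEG, obs, detection_floor=3e4).passed

    def test_requires_positive_a(self):
        with pytest.raises(ValueError):
            check_isotopes(parse_formula("C6H6"), NEG, {"A": 0.0})


class TestFilterErroneous:
    def test_plausible_retained(self):
        kept, rejected = filter_erroneous([parse_formula("C7H8O2")])
        assert kept == [parse_formula("C7H8O2")]
        assert rejected == []

    def test_implausible_rejected_with_one_rule(self):
        kept, rejected = filter_erroneous([Formula(C=2, H=9, O=1)])
        assert kept == []
        assert len(rejected) == 1
        _, rule = rejected[0]
        assert rule in ("non_integer_dbe", "negative_dbe", "hc_out_of_range")

    def test_union_is_input(self):
        cands = [f for f, _ in enumerate_candidates(201.9, NEG, None, 10)]
        kept, rejected = filter_erroneous(cands)
        assert len(kept) + len(rejected) == len(cands)
        assert set(kept) | {f for f, _ in rejected} == set(cands)

    def test_loose_rules_identity(self):
        loose = ErroneousRules(
            require_integer_dbe=False, dbe_min=-99, hc_min=0, hc_max=99, oc_max=99
        )
        cands = [Formula(C=2, H=9, O=1), parse_formula("C7H8O2")]
        kept, rejected = filter_erroneous(cands, loose)
        assert kept == cands and rejected == []


class TestAssignFeature:
    def test_round_trip_exact(self):
        f = parse_formula("C16H26O3S")
        pat = isotope_pattern(f, NEG)
        obs = {"A": 8e5, "A1": 8e5 * pat[1][1], "A2": 8e5 * pat[2][1]}
        a = assign_feature("f1", ion_mz(f, NEG), NEG, obs)
        assert a.status == "assigned"
        assert a.formula == f
        assert abs(a.ppm_error) < 1e-6

    def test_empty_window_unassigned(self):
        # a gap just below CH4's [M-H]- with sub-ppm tolerance
        a = assign_feature("f2", 14.5, NEG, tol_ppm=0.5)
        assert a.status == "unassigned"
        assert a.formula is None

    def test_ambiguity_reported(self):
        """Two legal survivors within 1 ppm are flagged, not silently picked."""
        f1 = parse_formula("C13H24O5S")  # vs C14H20N2O4 differ by ~1.6 mDa
        mz = ion_mz(f1, NEG)
        a = assign_feature("f3", mz, NEG, tol_ppm=8, ambiguity_ppm=8)
        assert a.n_candidates > 1
        assert a.status in ("ambiguous", "assigned")
        if a.status == "ambiguous":
            assert len(a.alternatives) >= 2

    @settings(max_examples=30)
    @given(
        st.fixed_dictionaries(
            dict(
                C=st.integers(4, 25),
                H=st.integers(4, 40),
                N=st.integers(0, 3),
                O=st.integers(1, 8),
                S=st.integers(0, 1),
            )
        ).filter(
            lambda d: d["H"] <= 2 * d["C"] + d["N"] + 2
            and (d["H"] + d["N"]) % 2 == 0
            and d["H"] >= 0.2 * d["C"]
            and 2 * (d["C"] - (d["H"] - d["N"]) / 2 + 1) >= 0
        )
    )
    def test_round_trip_noise_free_property(self, d):
        f = Formula(**d)
        a = assign_feature("p", ion_mz(f, NEG), NEG)
        assert a.formula == f

    def test_round_trip_with_jitter(self):
        """>= 95% of jittered (+/-2 ppm) ions with isotope evidence recover
        their formula; isotope verification prunes near-isobaric rivals."""
        rng = np.random.default_rng(23)
        wins = total = 0
        for _ in range(60):
            c = int(rng.integers(5, 20))
            h = int(rng.integers(max(4, c // 2), 2 * c + 1))
            if h % 2:
                h += 1
            o = int(rng.integers(1, 7))
            f = Formula(C=c, H=h, O=o)
            mz = ion_mz(f, NEG) * (1 + rng.uniform(-2, 2) * 1e-6)
            pat = isotope_pattern(f, NEG)
            obs = {"A": 5e5, "A1": 5e5 * pat[1][1], "A2": 5e5 * pat[2][1]}
            a = assign_feature("j", mz, NEG, obs, tol_ppm=3)
            total += 1
            wins += a.formula == f
        assert wins / total >= 0.95
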