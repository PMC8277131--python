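"""Molecular formula assignment: candidate enumeration, isotope check, filters.

Candidates are enumerated exhaustively within a ppm mass tolerance under
per-mode element limits: C, H, O effectively unlimited (capped only by the
neutral mass itself), N <= 5, S <= 2, Cl <= 3 in surface-water mode only,
and optionally Na <= 2 / K <= 1 as in-formula elements in positive mode.
A candidate is accepted only if the measured isotopologue intensities are
within a relative tolerance (default +/-30%) of theory, and erroneous
formulas (non-integer or negative DBE, implausible H/C or O/C) are
rejected with named rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .chem import (
    Formula,
    IonSpecies,
    dbe,
    ion_mz,
    isotope_pattern,
    neutral_mass_from_mz,
)
from .constants import MONOISOTOPIC_MASS

__all__ = [
    "ElementLimits",
    "ErroneousRules",
    "IsotopeCheck",
    "Assignment",
    "enumerate_candidates",
    "check_isotopes",
    "filter_erroneous",
    "assign_feature",
]

TOL_PPM = 3.0
ISOTOPE_TOL = 0.30


@dataclass(frozen=True)
class ElementLimits:
    """Min/max element counts for candidate enumeration.

    ``None`` maxima mean "unlimited", which is realised operationally as
    a cap by the neutral mass itself: C <= mass/12, O <= mass/15.99, and
    H <= 2C + N + 2 (no CHNO molecule can exceed this).  These caps are
    part of the enumeration contract — an exhaustive oracle must apply
    the same ones — and cannot exclude any chemically valid candidate
    within tolerance.
    """

    mode: str = "negative_pm"  # negative_pm | negative_water | positive
    c_max: int | None = None
    h_max: int | None = None
    n_max: int = 5
    o_max: int | None = None
    s_max: int = 2
    cl_max: int = 0
    na_max: int = 0
    k_max: int = 0

    @classmethod
    def negative_pm(cls) -> "ElementLimits":
        """Particulate-matter negative mode: CHNOS, no halogens or metals."""
        return cls(mode="negative_pm")

    @classmethod
    def negative_water(cls) -> "ElementLimits":
        """Surface-water negative mode: chlorine allowed up to 3."""
        return cls(mode="negative_water", cl_max=3)

    @classmethod
    def positive(cls, include_metals: bool = False) -> "ElementLimits":
        """Positive mode; ``include_metals`` opts in to in-formula Na/K.

        Metals default off: sodium/potassium normally enter as adduct
        species, and in-formula Na causes pathological candidate growth.
        """
        if include_metals:
            return cls(mode="positive", na_max=2, k_max=1)
        return cls(mode="positive")

    def caps(self, neutral_mass: float) -> dict[str, int]:
        """Effective per-element maxima at a given neutral mass."""
        c_cap = int(neutral_mass // MONOISOTOPIC_MASS["C"])
        o_cap = int(neutral_mass // MONOISOTOPIC_MASS["O"])
        return {
            "C": min(self.c_max, c_cap) if self.c_max is not None else c_cap,
            "N": self.n_max,
            "O": min(self.o_max, o_cap) if self.o_max is not None else o_cap,
            "S": self.s_max,
            "Cl": self.cl_max,
            "Na": self.na_max,
            "K": self.k_max,
        }

    def h_cap(self, c: int, n: int) -> int:
        base = 2 * c + n + 2
        return min(self.h_max, base) if self.h_max is not None else base


def enumerate_candidates(
    mz: float,
    sp: IonSpecies,
    limits: ElementLimits | None = None,
    tol_ppm: float = TOL_PPM,
) -> list[tuple[Formula, float]]:
    """All neutral formulas whose ion m/z is within ``tol_ppm`` of ``mz``.

    Enumerates heteroatoms lexicographically and solves the C/H inner
    loop in closed form against the residual mass window; sorted by
    absolute ppm error (ties by Hill string for determinism).
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    limits = limits or ElementLimits()
    m_neutral = neutral_mass_from_mz(mz, sp)
    tol_da = mz * tol_ppm * 1e-6 / sp.n_m
    lo, hi = m_neutral - tol_da, m_neutral + tol_da
    caps = limits.caps(hi)
    mH = MONOISOTOPIC_MASS["H"]
    out: list[tuple[Formula, float]] = []
    for n in range(caps["N"] + 1):
        m_n = n * MONOISOTOPIC_MASS["N"]
        if m_n > hi:
            break
        for s in range(caps["S"] + 1):
            m_s = m_n + s * MONOISOTOPIC_MASS["S"]
            if m_s > hi:
                break
            for cl in range(caps["Cl"] + 1):
                m_cl = m_s + cl * MONOISOTOPIC_MASS["Cl"]
                if m_cl > hi:
                    break
                for na in range(caps["Na"] + 1):
                    m_na = m_cl + na * MONOISOTOPIC_MASS["Na"]
                    if m_na > hi:
                        break
                    for k in range(caps["K"] + 1):
                        m_k = m_na + k * MONOISOTOPIC_MASS["K"]
                        if m_k > hi:
                            break
                        for o in range(caps["O"] + 1):
                            m_o = m_k + o * MONOISOTOPIC_MASS["O"]
                            if m_o > hi:
                                break
                            for c in range(caps["C"] + 1):
                                m_c = m_o + c * MONOISOTOPIC_MASS["C"]
                                if m_c > hi:
                                    break
                                # closed-form H range for the residual mass
                                h_lo = max(0, math.ceil((lo - m_c) / mH - 1e-12))
                                h_hi = min(
                                    limits.h_cap(c, n),
                                    math.floor((hi - m_c) / mH + 1e-12),
                                )
                                for h in range(h_lo, h_hi + 1):
                                    mass = m_c + h * mH
                                    if not (lo <= mass <= hi):
                                        continue
                                    counts = dict(
                                        C=c, H=h, N=n, O=o, S=s, Cl=cl, Na=na, K=k
                                    )
                                    if sum(counts.values()) == 0:
                                        continue
                                    f = Formula(**counts)
                                    err = (ion_mz(f, sp) - mz) / mz * 1e6
                                    out.append((f, err))
    out.sort(key=lambda t: (abs(t[1]), str(t[0])))
    return out


@dataclass(frozen=True)
class IsotopeCheck:
    """Result of comparing observed vs theoretical isotopologue intensities."""

    passed: bool
    dev_a1: float | None  # relative deviation (obs-theo)/theo, None if unobserved
    dev_a2: float | None


def check_isotopes(
    candidate: Formula,
    sp: IonSpecies,
    observed: dict[str, float],
    tol: float = ISOTOPE_TOL,
    detection_floor: float = 0.0,
) -> IsotopeCheck:
    """Verify observed A+1/A+2 relative intensities against theory.

    ``observed`` maps ``"A"``, ``"A1"``, ``"A2"`` to measured intensities
    (absolute counts; only ratios to A matter).  Passes iff every observed
    isotopologue is within ``tol`` *relative* of theory.  A missing A+1 or
    A+2 fails only when its theoretical intensity (scaled by the observed
    A) would exceed ``detection_floor`` — below the floor absence is
    uninformative.
    """
    a_obs = observed.get("A", 0.0)
    if a_obs <= 0:
        raise ValueError("observed A intensity must be positive")
    pattern = isotope_pattern(candidate, sp)
    theo = {"A1": pattern[1][1], "A2": pattern[2][1]}
    devs: dict[str, float | None] = {"A1": None, "A2": None}
    ok = True
    for key in ("A1", "A2"):
        th = theo[key]
        obs = observed.get(key)
        if obs is None or obs == 0.0:
            if th * a_obs > detection_floor and detection_floor > 0:
                ok = False
            continue
        rel = obs / a_obs
        dev = (rel - th) / th if th > 0 else math.inf
        devs[key] = dev
        if abs(dev) > tol:
            ok = False
    return IsotopeCheck(ok, devs["A1"], devs["A2"])


@dataclass(frozen=True)
class ErroneousRules:
    """Bounds defining a chemically implausible ('erroneous') formula."""

    require_integer_dbe: bool = True
    dbe_min: float = 0.0
    hc_min: float = 0.2
    hc_max: float = 3.1
    oc_max: float = 3.0


def filter_erroneous(
    candidates: list[Formula],
    rules: ErroneousRules | None = None,
) -> tuple[list[Formula], list[tuple[Formula, str]]]:
    """Split candidates into (surviving, rejected-with-rule-name).

    Rules checked in order: integer DBE (even-electron neutral), DBE >= 0,
    H/C within bounds, O/C below bound.  Each rejection carries exactly
    one rule name (the first that fired).  ``rules=None`` disables
    nothing; pass ``ErroneousRules()`` defaults explicitly to be clear.
    """
    rules = rules or ErroneousRules()
    kept: list[Formula] = []
    rejected: list[tuple[Formula, str]] = []
    for f in candidates:
        rule = _first_violation(f, rules)
        if rule is None:
            kept.append(f)
        else:
            rejected.append((f, rule))
    return kept, rejected


def _first_violation(f: Formula, rules: ErroneousRules) -> str | None:
    d = dbe(f)
    if rules.require_integer_dbe and d != int(d):
        return "non_integer_dbe"
    if d < rules.dbe_min:
        return "negative_dbe"
    if f.C > 0:
        hc = f.H / f.C
        if not (rules.hc_min <= hc <= rules.hc_max):
            return "hc_out_of_range"
        if f.O / f.C > rules.oc_max:
            return "oc_out_of_range"
    return None


@dataclass
class Assignment:
    """Outcome of formula assignment for one feature."""

    feature_id: str
    mz: float
    species: IonSpecies
    formula: Formula | None
    ppm_error: float | None
    isotope: IsotopeCheck | None
    n_candidates: int
    status: str  # assigned | ambiguous | unassigned | rejected_erroneous
    alternatives: list[tuple[Formula, float]] = field(default_factory=list)
    rejections: list[tuple[Formula, str]] = field(default_factory=list)


def assign_feature(
    feature_id: str,
    mz: float,
    sp: IonSpecies,
    observed_isotopes: dict[str, float] | None = None,
    limits: ElementLimits | None = None,
    tol_ppm: float = TOL_PPM,
    isotope_tol: float = ISOTOPE_TOL,
    rules: ErroneousRules | None = None,
    detection_floor: float = 0.0,
    ambiguity_ppm: float = 1.0,
) -> Assignment:
    """Enumerate -> isotope-check -> erroneous-filter -> choose lowest |ppm|.

    Status is ``ambiguous`` when more than one survivor lies within
    ``ambiguity_ppm`` of the best (both recorded in ``alternatives``),
    ``unassigned`` when nothing survives.
    """
    cands = enumerate_candidates(mz, sp, limits, tol_ppm)
    n_initial = len(cands)
    surviving, rejected = filter_erroneous([f for f, _ in cands], rules)
    ppm_of = dict((f, e) for f, e in cands)
    checked: list[tuple[Formula, float, IsotopeCheck | None]] = []
    for f in surviving:
        ic: IsotopeCheck | None = None
        if observed_isotopes is not None:
            ic = check_isotopes(f, sp, observed_isotopes, isotope_tol, detection_floor)
            if not ic.passed:
                rejected.append((f, "isotope_mismatch"))
                continue
        checked.append((f, ppm_of[f], ic))
    if not checked:
        return Assignment(
            feature_id, mz, sp, None, None, None, n_initial, "unassigned",
            rejections=rejected,
        )
    checked.sort(key=lambda t: (abs(t[1]), str(t[0])))
    best_f, best_ppm, best_ic = checked[0]
    close = [
        (f, e) for f, e, _ in checked[1:] if abs(abs(e) - abs(best_ppm)) <= ambiguity_ppm
    ]
    status = "ambiguous" if close else "assigned"
    return Assignment(
        feature_id, mz, sp, best_f, best_ppm, best_ic, n_initial, status,
        alternatives=[(best_f, best_ppm)] + close, rejections=rejected,
    )
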