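"""Molecular formulas, ion species arithmetic, and compositional metrics.

Everything downstream (peak assignment, artifact grouping, compositional
grouping) operates on neutral molecular formulas over the element set
C, H, N, O, S, Cl, Na, K, P.  P is accepted when parsing library hits
(e.g. organophosphate pesticides) but is never enumerated during formula
assignment.

The compositional metrics are the ones conventionally used to interpret
complex environmental mixtures: elemental ratios (O/C, H/C, ...), double
bond equivalents (DBE) and DBE per carbon, the average carbon oxidation
state OSc = 2*O/C - H/C, the aromaticity index, and CHO/CHON/CHOS/CHONS
composition classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .constants import (
    ELECTRON_MASS,
    ELEMENTS,
    ISOTOPE_ABUNDANCE,
    ISOTOPE_SPACING,
    MONOISOTOPIC_MASS,
    NOMINAL_MASS,
    PROTON_MASS,
)

__all__ = [
    "Formula",
    "IonSpecies",
    "MetricSet",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "ion_mz",
    "neutral_mass_from_mz",
    "dbe",
    "metrics",
    "composition_class",
    "isotope_pattern",
    "ION_SPECIES",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element -> count map for a neutral molecule.

    Counts are non-negative integers; at least one atom is required.
    Instances are immutable and hashable so they can key dictionaries
    and be compared set-wise in candidate enumeration.
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    Cl: int = 0
    Na: int = 0
    K: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"negative or non-integer count for {el}: {n!r}")
        if self.atom_count() == 0:
            raise ValueError("formula must contain at least one atom")

    def atom_count(self) -> int:
        return sum(getattr(self, el) for el in ELEMENTS)

    def counts(self) -> dict[str, int]:
        """Nonzero element counts."""
        return {el: getattr(self, el) for el in ELEMENTS if getattr(self, el)}

    def __add__(self, other: "Formula") -> "Formula":
        return Formula(**{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS})

    def __mul__(self, n: int) -> "Formula":
        return Formula(**{el: getattr(self, el) * n for el in ELEMENTS})

    __rmul__ = __mul__

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C17H28O3S"``.

    A count of one may omit the digit (``"C"`` is one carbon).  Raises
    ``ValueError`` on empty input, unknown element symbols, or text that
    is not a plain element/count sequence.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise ValueError(f"unknown element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return Formula(**counts)


def _hill_order(f: Formula) -> list[tuple[str, int]]:
    if f.C:
        order = ["C", "H"] + sorted(el for el in ELEMENTS if el not in ("C", "H"))
    else:
        order = sorted(ELEMENTS)
    return [(el, getattr(f, el)) for el in order if getattr(f, el)]


def format_formula(f: Formula) -> str:
    """Hill-order string: C, H first (when carbon present), then alphabetical."""
    return "".join(el if n == 1 else f"{el}{n}" for el, n in _hill_order(f))


def monoisotopic_mass(f: Formula) -> float:
    """Sum of most-abundant-isotope atomic masses, Da."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts().items())


def nominal_mass(f: Formula) -> int:
    """Sum of integer mass numbers of the most abundant isotopes."""
    return sum(NOMINAL_MASS[el] * n for el, n in f.counts().items())


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ion species: label, mass delta, charge sign.

    ``mz = n_m * M + delta`` where M is the neutral monoisotopic mass and
    ``n_m`` is 2 for dimer species ([2M-H]- etc.).  The delta includes the
    electron mass.
    """

    label: str
    delta: float
    charge: int  # +1 or -1
    n_m: int = 1

    def __post_init__(self) -> None:
        if self.charge not in (-1, 1):
            raise ValueError("only singly charged species are supported")
        if self.n_m not in (1, 2):
            raise ValueError("n_m must be 1 or 2")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


def _d(formula: str) -> float:
    return monoisotopic_mass(parse_formula(formula))


#: Built-in ion species registry.  Users may extend via ArtifactTable config.
ION_SPECIES: dict[str, IonSpecies] = {
    "[M-H]-": IonSpecies("[M-H]-", -PROTON_MASS, -1),
    "[M+H]+": IonSpecies("[M+H]+", +PROTON_MASS, +1),
    "[M+Na]+": IonSpecies("[M+Na]+", _d("Na") - ELECTRON_MASS, +1),
    "[M+K]+": IonSpecies("[M+K]+", _d("K") - ELECTRON_MASS, +1),
    "[M+NH4]+": IonSpecies("[M+NH4]+", _d("NH4") - ELECTRON_MASS, +1),
    "[M+Cl]-": IonSpecies("[M+Cl]-", _d("Cl") + ELECTRON_MASS, -1),
    "[M+HCOO]-": IonSpecies("[M+HCOO]-", _d("CHO2") + ELECTRON_MASS, -1),
    "[2M-H]-": IonSpecies("[2M-H]-", -PROTON_MASS, -1, n_m=2),
    "[2M+H]+": IonSpecies("[2M+H]+", +PROTON_MASS, +1, n_m=2),
    "[M-H-H2O]-": IonSpecies("[M-H-H2O]-", -PROTON_MASS - _d("H2O"), -1),
    "[M+H-H2O]+": IonSpecies("[M+H-H2O]+", +PROTON_MASS - _d("H2O"), +1),
}


def ion_mz(f: Formula, sp: IonSpecies) -> float:
    """m/z of the (singly charged) ion species for neutral formula ``f``."""
    return sp.n_m * monoisotopic_mass(f) + sp.delta


def neutral_mass_from_mz(mz: float, sp: IonSpecies) -> float:
    """Invert :func:`ion_mz` for the neutral monoisotopic mass."""
    return (mz - sp.delta) / sp.n_m


def dbe(f: Formula) -> float:
    """Double bond equivalents of the neutral molecule.

    DBE = C - (H + Cl + Na + K)/2 + (N + P)/2 + 1.  Halogens and the
    monovalent metals count as hydrogen; N and P count as trivalent,
    which keeps sodiated/potassiated neutrals on the integer-DBE grid
    used by the erroneous-formula filter.
    """
    return f.C - (f.H + f.Cl + f.Na + f.K) / 2 + (f.N + f.P) / 2 + 1


def composition_class(f: Formula) -> str:
    """CH / CHO / CHON / CHOS / CHONS / other, with a Cl suffix when Cl > 0."""
    n, o, s = f.N > 0, f.O > 0, f.S > 0
    if not (n or o or s):
        base = "CH"
    elif o and not n and not s:
        base = "CHO"
    elif o and n and not s:
        base = "CHON"
    elif o and s and not n:
        base = "CHOS"
    elif o and n and s:
        base = "CHONS"
    else:  # N and/or S without O
        base = "other"
    return base + "Cl" if f.Cl else base


@dataclass(frozen=True)
class MetricSet:
    """Per-formula compositional metrics for environmental interpretation."""

    formula: Formula
    mw_mono: float
    mw_nominal: int
    dbe: float
    dbe_c: float
    oc: float
    hc: float
    nc: float
    sc: float
    osc: float
    ai: float
    comp_class: str


def aromaticity_index(f: Formula, modified: bool = False) -> float:
    """Aromaticity index AI = (1 + C - O - S - H/2) / (C - O - S - N - P).

    Clamped to 0 when the numerator or denominator is <= 0.  With
    ``modified=True`` the oxygen term is halved (AImod), the common
    variant for partially carboxylated material.
    """
    o = 0.5 * f.O if modified else f.O
    num = 1 + f.C - o - f.S - 0.5 * f.H
    den = f.C - o - f.S - f.N - f.P
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


def metrics(f: Formula, modified_ai: bool = False) -> MetricSet:
    """All compositional metrics for a formula with at least one carbon."""
    if f.C < 1:
        raise ValueError("metrics require at least one carbon atom")
    d = dbe(f)
    oc = f.O / f.C
    hc = f.H / f.C
    return MetricSet(
        formula=f,
        mw_mono=monoisotopic_mass(f),
        mw_nominal=nominal_mass(f),
        dbe=d,
        dbe_c=d / f.C,
        oc=oc,
        hc=hc,
        nc=f.N / f.C,
        sc=f.S / f.C,
        osc=2 * oc - hc,
        ai=aromaticity_index(f, modified=modified_ai),
        comp_class=composition_class(f),
    )


def isotope_pattern(f: Formula, sp: IonSpecies | None = None) -> list[tuple[float, float]]:
    """Theoretical A, A+1, A+2 isotopologue pattern of the ion.

    Returns ``[(mz_A, 1.0), (mz_A1, rel1), (mz_A2, rel2)]`` with intensities
    relative to the monoisotopic (A) peak.  Intensities come from the exact
    polynomial expansion of natural isotope abundances, aggregated by
    nominal mass shift and truncated at A+2.  For dimer species the formula
    is doubled.  Isotopes of adduct atoms (H, Na, K, NH4) are neglected;
    their contribution is below 0.03% relative.
    """
    n_m = sp.n_m if sp is not None else 1
    # p[k] = probability the molecule is k nominal-mass units above A.
    p = [1.0, 0.0, 0.0]
    for el, n_atoms in f.counts().items():
        iso = ISOTOPE_ABUNDANCE[el]
        a0 = iso[0]
        # single-atom shift distribution, conditional probabilities
        single = [iso.get(0, 0.0), iso.get(1, 0.0), iso.get(2, 0.0)]
        total = sum(iso.values())
        single = [x / total for x in single]
        elem = [1.0, 0.0, 0.0]
        # n-fold self-convolution truncated at shift 2
        base = single[:]
        n = n_atoms * n_m
        while n:
            if n & 1:
                elem = _conv3(elem, base)
            n >>= 1
            if n:
                base = _conv3(base, base)
        p = _conv3(p, elem)
    if p[0] <= 0:
        raise ValueError("degenerate isotope distribution")
    if sp is not None:
        mz0 = ion_mz(f, sp)
    else:
        mz0 = monoisotopic_mass(f)
    return [
        (mz0, 1.0),
        (mz0 + ISOTOPE_SPACING, p[1] / p[0]),
        (mz0 + 2 * ISOTOPE_SPACING, p[2] / p[0]),
    ]


def _conv3(a: list[float], b: list[float]) -> list[float]:
    """Convolution of two length-3 shift distributions, truncated at 2."""
    return [
        a[0] * b[0],
        a[0] * b[1] + a[1] * b[0],
        a[0] * b[2] + a[1] * b[1] + a[2] * b[0],
    ]
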