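"""Physical constants and isotope data for the supported element set.

Monoisotopic masses are IUPAC/CODATA values to at least 6 decimal places.
Ion mass deltas account for the electron mass: at m/z 123 the electron is
~4.5 ppm, larger than the 3 ppm assignment tolerance, so it cannot be
neglected.
"""

from __future__ import annotations

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466621

#: Elements supported in formulas, in Hill order (C, H, then alphabetical).
ELEMENTS = ("C", "H", "Cl", "K", "N", "Na", "O", "P", "S")

#: Monoisotopic (most abundant isotope) atomic masses, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "P": 30.97376163,
}

#: Integer mass numbers of the most abundant isotopes.
NOMINAL_MASS = {
    "C": 12, "H": 1, "N": 14, "O": 16, "S": 32,
    "Cl": 35, "Na": 23, "K": 39, "P": 31,
}

#: Natural isotope abundances keyed by nominal mass shift from the
#: most abundant isotope (0 = A, 1 = A+1, 2 = A+2 ...).
ISOTOPE_ABUNDANCE = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    "Cl": {0: 0.7576, 2: 0.2424},
    "Na": {0: 1.0},
    "K": {0: 0.932581, 1: 0.000117, 2: 0.067302},
    "P": {0: 1.0},
}

#: Mean m/z spacing used to place A+k isotopologue centroids (the 13C-12C
#: mass difference; adequate at Orbitrap ppm scale for CHNOS molecules).
ISOTOPE_SPACING = 1.00335483507
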