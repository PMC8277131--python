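"""Independent brute-force oracles used only by the test suite.

These deliberately share no algorithmic structure with the package:
candidate enumeration walks the full element-count grid with plain
range loops (the C/H plane is evaluated as a dense numpy grid for
speed, with no closed-form solving), and the isotopologue oracle sums
multinomial substitution probabilities directly.
"""

from __future__ import annotations

import math

import numpy as np

from ntms.assign import ElementLimits
from ntms.chem import Formula, IonSpecies
from ntms.constants import ISOTOPE_ABUNDANCE, MONOISOTOPIC_MASS


def brute_force_candidates(
    mz: float, sp: IonSpecies, limits: ElementLimits, tol_ppm: float
) -> set[Formula]:
    """Exhaustive candidate set by scanning the entire element grid."""
    m_neutral = (mz - sp.delta) / sp.n_m
    tol_da = mz * tol_ppm * 1e-6 / sp.n_m
    lo, hi = m_neutral - tol_da, m_neutral + tol_da
    caps = limits.caps(hi)
    mC, mH = MONOISOTOPIC_MASS["C"], MONOISOTOPIC_MASS["H"]
    c_arr = np.arange(caps["C"] + 1)
    out: set[Formula] = set()
    for n in range(caps["N"] + 1):
        for s in range(caps["S"] + 1):
            for cl in range(caps["Cl"] + 1):
                for na in range(caps["Na"] + 1):
                    for k in range(caps["K"] + 1):
                        for o in range(caps["O"] + 1):
                            rest = (
                                n * MONOISOTOPIC_MASS["N"]
                                + s * MONOISOTOPIC_MASS["S"]
                                + cl * MONOISOTOPIC_MASS["Cl"]
                                + na * MONOISOTOPIC_MASS["Na"]
                                + k * MONOISOTOPIC_MASS["K"]
                                + o * MONOISOTOPIC_MASS["O"]
                            )
                            if rest > hi:
                                break
                            h_max = 2 * caps["C"] + n + 2
                            h_arr = np.arange(h_max + 1)
                            mass = rest + c_arr[:, None] * mC + h_arr[None, :] * mH
                            ok = (mass >= lo) & (mass <= hi)
                            # valence-style cap shared with the contract
                            ok &= h_arr[None, :] <= 2 * c_arr[:, None] + n + 2
                            for ci, hi_idx in zip(*np.nonzero(ok)):
                                counts = dict(
                                    C=int(c_arr[ci]), H=int(h_arr[hi_idx]),
                                    N=n, O=o, S=s, Cl=cl, Na=na, K=k,
                                )
                                if sum(counts.values()) == 0:
                                    continue
                                out.add(Formula(**counts))
    return out


def brute_force_isotope_pattern(f: Formula, max_shift: int = 2) -> list[float]:
    """A..A+max_shift relative intensities by direct multinomial summation."""
    shift_probs = [0.0] * (max_shift + 1)

    def element_dist(el: str, n: int) -> list[float]:
        iso = ISOTOPE_ABUNDANCE[el]
        total = sum(iso.values())
        shifts = sorted(iso)
        # enumerate substitution counts for each heavy isotope; the
        # multinomial coefficient is a product of binomials
        heavy = [s for s in shifts if s > 0]

        def rec2(idx: int, remaining: int, shift: int, ways: float, prob: float) -> None:
            if shift > max_shift:
                return
            if idx == len(heavy):
                dist[shift] += ways * prob * (iso[0] / total) ** remaining
                return
            s = heavy[idx]
            for kk in range(min(remaining, max_shift) + 1):
                if kk * s > max_shift:
                    break
                rec2(
                    idx + 1, remaining - kk, shift + kk * s,
                    ways * math.comb(remaining, kk), prob * (iso[s] / total) ** kk,
                )

        dist = [0.0] * (max_shift + 1)
        rec2(0, n, 0, 1.0, 1.0)
        return dist

    total_dist = [1.0] + [0.0] * max_shift
    for el, n in f.counts().items():
        ed = element_dist(el, n)
        new = [0.0] * (max_shift + 1)
        for i in range(max_shift + 1):
            for j in range(max_shift + 1 - i):
                new[i + j] += total_dist[i] * ed[j]
        total_dist = new
    return [d / total_dist[0] for d in total_dist]
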