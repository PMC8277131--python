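"""MS2 spectral library storage, similarity search, and confidence levels.

Identification follows the community 5-level confidence scale: exact mass
only (5), unambiguous molecular formula (4), formula plus recorded MS2
(3, tentative), probable structure through a spectral-library match (2),
and confirmed structure when the match is corroborated by the retention
time of an authentic standard (1).

The similarity score is a square-root-intensity cosine ("NIST-style"),
reported as a percentage.  Percent thresholds quoted for proprietary
scoring functions are *config values* here, not comparable across
scoring algorithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import ION_SPECIES, Formula, IonSpecies, ion_mz

__all__ = [
    "MS2Spectrum",
    "LibraryEntry",
    "MatchResult",
    "spectral_similarity",
    "search",
    "assign_confidence",
]

FRAG_TOL = 0.01  # Da
MIN_SCORE = 85.0
PRECURSOR_TOL_PPM = 10.0
RT_WINDOW = 0.3  # min


@dataclass
class MS2Spectrum:
    """A fragmentation spectrum with precursor information."""

    precursor_mz: float
    fragments: list[tuple[float, float]]  # (m/z, intensity), sorted by m/z
    species_label: str | None = None
    rt: float | None = None
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments, key=lambda t: t[0])
        if any(i < 0 for _, i in self.fragments):
            raise ValueError("negative fragment intensity")
        if self.fragments and self.fragments[-1][0] > self.precursor_mz + 0.5:
            raise ValueError("fragment m/z above precursor")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments])


@dataclass
class LibraryEntry:
    """A named reference compound with its spectrum and retention time."""

    name: str
    formula: Formula
    spectrum: MS2Spectrum
    rt: float | None = None

    def __post_init__(self) -> None:
        label = self.spectrum.species_label or "[M-H]-"
        theo = ion_mz(self.formula, ION_SPECIES[label])
        if abs(theo - self.spectrum.precursor_mz) > theo * 5e-6:
            raise ValueError(
                f"{self.name}: precursor {self.spectrum.precursor_mz:.4f} "
                f"inconsistent with {self.formula} as {label} ({theo:.4f})"
            )


@dataclass
class MatchResult:
    """A scored library hit for a query spectrum."""

    entry: LibraryEntry
    score: float  # percent, 0..100
    rt_deviation: float | None = None
    level: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 100.0 + 1e-9):
            raise ValueError("score must be a percentage in [0, 100]")


def _greedy_match(
    q: MS2Spectrum, r: MS2Spectrum, frag_tol: float
) -> list[tuple[int, int]]:
    """Greedy fragment pairing: highest summed intensity first, ties by dm/z."""
    qm, qi = q.mz_array, q.intensity_array
    rm, ri = r.mz_array, r.intensity_array
    cands: list[tuple[float, float, int, int]] = []
    for i in range(qm.size):
        for j in range(rm.size):
            d = abs(qm[i] - rm[j])
            if d <= frag_tol:
                cands.append((-(qi[i] + ri[j]), d, i, j))
    cands.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, i, j in cands:
        if i in used_q or j in used_r:
            continue
        pairs.append((i, j))
        used_q.add(i)
        used_r.add(j)
    return pairs


def spectral_similarity(
    query: MS2Spectrum, ref: MS2Spectrum, frag_tol: float = FRAG_TOL
) -> float:
    """Percent cosine similarity of square-root intensity vectors.

    Fragments are paired greedily within ``frag_tol``; unmatched
    fragments contribute to the vector norms only.  Symmetric, scale
    invariant, 100 iff the matched fragments are proportional with no
    unmatched intensity, 0 for disjoint fragment sets.
    """
    if not query.fragments or not ref.fragments:
        raise ValueError("both spectra must contain fragments")
    pairs = _greedy_match(query, ref, frag_tol)
    qs = np.sqrt(query.intensity_array)
    rs = np.sqrt(ref.intensity_array)
    dot = sum(qs[i] * rs[j] for i, j in pairs)
    nq = float(np.linalg.norm(qs))
    nr = float(np.linalg.norm(rs))
    if nq == 0 or nr == 0:
        return 0.0
    return 100.0 * dot / (nq * nr)


def search(
    query: MS2Spectrum,
    library: list[LibraryEntry],
    min_score: float = MIN_SCORE,
    precursor_tol_ppm: float = PRECURSOR_TOL_PPM,
    frag_tol: float = FRAG_TOL,
) -> list[MatchResult]:
    """Score the query against precursor-compatible entries, rank descending.

    Only entries whose precursor m/z lies within ``precursor_tol_ppm`` of
    the query precursor are scored; hits below ``min_score`` are dropped.
    Ranking ties break on entry name for determinism.
    """
    if not library:
        raise ValueError("empty spectral library")
    results: list[MatchResult] = []
    for entry in library:
        ref = entry.spectrum
        tol = query.precursor_mz * precursor_tol_ppm * 1e-6
        if abs(ref.precursor_mz - query.precursor_mz) > tol:
            continue
        score = spectral_similarity(query, ref, frag_tol)
        if score >= min_score:
            rt_dev = None
            if query.rt is not None and entry.rt is not None:
                rt_dev = query.rt - entry.rt
            results.append(MatchResult(entry, score, rt_dev))
    results.sort(key=lambda m: (-m.score, m.entry.name))
    return results


def assign_confidence(
    has_formula: bool,
    formula_unambiguous: bool = False,
    has_ms2: bool = False,
    match: MatchResult | None = None,
    rt_check: bool = False,
    rt_window: float = RT_WINDOW,
) -> int:
    """Identification confidence level 1 (best) to 5 (exact mass only).

    5: exact mass only; 4: unambiguous formula, no MS2; 3: formula plus
    recorded MS2 (tentative); 2: library spectral match at or above the
    score threshold; 1: level 2 plus retention-time agreement with an
    authentic standard (within ``rt_window`` minutes, requested via
    ``rt_check``).
    """
    if match is not None:
        if (
            rt_check
            and match.rt_deviation is not None
            and abs(match.rt_deviation) <= rt_window
        ):
            return 1
        return 2
    if has_formula and formula_unambiguous:
        return 3 if has_ms2 else 4
    return 5
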