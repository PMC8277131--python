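"""Calibration, quantification, and compositional grouping reports.

Calibration curves require at least five concentration levels with three
replicates each; quantification outside the fitted linear range is
flagged rather than reported.  Compositional reports aggregate assigned
features by (composition class, carbon-number bin), normalize peak areas
to the total sample area, and attach area-weighted mean O/C per group —
the standard presentation for comparing complex environmental mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem import Formula, metrics

__all__ = [
    "Calibration",
    "fit_calibration",
    "quantify",
    "normalized_abundance",
    "group_composition",
    "aromatic_fraction",
    "source_report",
    "DEFAULT_CARBON_BINS",
]

MIN_LEVELS = 5
MIN_REPLICATES = 3

#: (label, lo, hi) carbon-number bins, inclusive.
DEFAULT_CARBON_BINS: list[tuple[str, int, int]] = [
    ("C1-C5", 1, 5),
    ("C6-C8", 6, 8),
    ("C9-C12", 9, 12),
    ("C13-C15", 13, 15),
    ("C16-C20", 16, 20),
    ("C21+", 21, 10**9),
]


@dataclass
class Calibration:
    """Fitted linear response of peak area vs concentration."""

    compound: str
    species_label: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    level_rsd: dict[float, float] = field(default_factory=dict)
    residuals: list[float] = field(default_factory=list)

    def predict_area(self, conc: float) -> float:
        return self.slope * conc + self.intercept


def fit_calibration(
    points: list[tuple[float, list[float]]],
    compound: str = "",
    species_label: str = "",
) -> Calibration:
    """Ordinary least squares of mean replicate area against concentration.

    ``points`` is a list of ``(concentration, [replicate areas])``; at
    least five distinct concentrations with three replicates each are
    required.  Per-level relative standard deviations and fit residuals
    are stored as diagnostics.
    """
    concs = [c for c, _ in points]
    if len(set(concs)) < MIN_LEVELS:
        raise ValueError(f"need >= {MIN_LEVELS} distinct concentrations, got {len(set(concs))}")
    for c, reps in points:
        if len(reps) < MIN_REPLICATES:
            raise ValueError(f"need >= {MIN_REPLICATES} replicates at {c}, got {len(reps)}")
    x = np.array(concs, dtype=float)
    y = np.array([np.mean(reps) for _, reps in points])
    fit = stats.linregress(x, y)
    rsd = {
        c: float(np.std(reps, ddof=1) / np.mean(reps)) if np.mean(reps) > 0 else float("nan")
        for c, reps in points
    }
    resid = list(y - (fit.slope * x + fit.intercept))
    return Calibration(
        compound=compound,
        species_label=species_label,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(min(x)), float(max(x))),
        level_rsd=rsd,
        residuals=resid,
    )


def quantify(area: float, cal: Calibration) -> tuple[float | None, str]:
    """Invert the calibration: ``(concentration, flag)``.

    The flag is ``ok`` inside the calibrated range; outside it the
    concentration is *not* reported as a number (``None``) and the flag
    is ``below_range`` or ``above_range``.
    """
    if cal.slope == 0:
        raise ValueError("zero calibration slope")
    conc = (area - cal.intercept) / cal.slope
    lo, hi = cal.conc_range
    eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    if conc < lo - eps:
        return None, "below_range"
    if conc > hi + eps:
        return None, "above_range"
    return float(conc), "ok"


def normalized_abundance(areas: list[float]) -> list[float]:
    """Per-feature percent of total peak area; sums to 100."""
    a = np.asarray(areas, dtype=float)
    total = a.sum()
    if a.size == 0 or total <= 0:
        raise ValueError("need at least one feature with positive area")
    return list(a / total * 100.0)


def _carbon_bin(c: int, bins: list[tuple[str, int, int]]) -> str | None:
    for label, lo, hi in bins:
        if lo <= c <= hi:
            return label
    return None


def group_composition(
    rows: list[tuple[Formula, float]],
    sample: str = "sample",
    carbon_bins: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Aggregate assigned features into a (class, carbon-bin) table.

    ``rows`` are ``(formula, area)`` pairs for one sample.  Output columns:
    sample, comp_class, c_bin, area, pct (percent of total assigned area),
    oc_w (area-weighted mean O/C of the group) and oc_group (the group's
    area fraction itself, the literal 'group area over total area' ratio).
    Empty groups are absent, not zero rows.
    """
    bins = carbon_bins or DEFAULT_CARBON_BINS
    if not rows:
        raise ValueError("no assigned features to group")
    total = sum(a for _, a in rows)
    if total <= 0:
        raise ValueError("total area must be positive")
    agg: dict[tuple[str, str], dict[str, float]] = {}
    for f, area in rows:
        m = metrics(f)
        cb = _carbon_bin(f.C, bins)
        if cb is None:
            continue
        key = (m.comp_class, cb)
        d = agg.setdefault(key, {"area": 0.0, "oc_area": 0.0})
        d["area"] += area
        d["oc_area"] += area * m.oc
    records = []
    for (cls, cb), d in sorted(agg.items()):
        records.append(
            {
                "sample": sample,
                "comp_class": cls,
                "c_bin": cb,
                "area": d["area"],
                "pct": d["area"] / total * 100.0,
                "oc_w": d["oc_area"] / d["area"],
                "oc_group": d["area"] / total,
            }
        )
    return pd.DataFrame.from_records(records)


def aromatic_fraction(formulas: list[Formula], threshold: float = 0.5) -> float:
    """Percent of formulas (count, not area weighted) with DBE/C > threshold."""
    if not formulas:
        raise ValueError("empty group")
    n = sum(1 for f in formulas if metrics(f).dbe_c > threshold)
    return n / len(formulas) * 100.0


def source_report(
    compounds: list[tuple[str, float]],
    categories: dict[str, str],
    total_area: float | None = None,
    sample: str = "sample",
) -> pd.DataFrame:
    """Percent relative sample abundance by pollutant source category.

    ``compounds`` are identified ``(name, area)`` pairs; ``categories``
    maps compound name to a source label (uncategorized compounds fall
    into ``"other"``).  Abundance of each category is its summed area
    divided by the *total sample* peak area (defaults to the identified
    total) times 100.
    """
    if total_area is None:
        total_area = sum(a for _, a in compounds)
    if total_area <= 0:
        raise ValueError("total area must be positive")
    agg: dict[str, float] = {}
    for name, area in compounds:
        cat = categories.get(name, "other")
        agg[cat] = agg.get(cat, 0.0) + area
    records = [
        {"sample": sample, "category": cat, "area": a, "pct": a / total_area * 100.0}
        for cat, a in sorted(agg.items())
    ]
    return pd.DataFrame.from_records(records)
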