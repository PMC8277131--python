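"""Compound-level features: a detected chromatographic peak with its m/z.

A Feature is the unit passed between pipeline stages — adduct grouping,
blank subtraction, formula assignment, identification and reporting all
consume and produce feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Feature:
    """A chromatographic peak at a specific m/z in one run."""

    feature_id: str
    mz: float
    rt: float
    area: float
    apex_intensity: float = 0.0
    sn: float = 0.0
    n_scans: int = 1
    sample: str = "sample"
    polarity: str = "negative"
    species_label: str | None = None  # resolved ion species, e.g. "[M-H]-"
    isotopes: dict[str, float] = field(default_factory=dict)  # A/A1/A2 intensities
    annotations: dict[str, object] = field(default_factory=dict)

    def matches(self, other: "Feature", mz_tol_ppm: float, rt_tol: float) -> bool:
        """m/z within ppm tolerance and RT co-elution."""
        return (
            abs(self.mz - other.mz) <= self.mz * mz_tol_ppm * 1e-6
            and abs(self.rt - other.rt) <= rt_tol
        )
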