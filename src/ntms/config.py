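"""Pipeline configuration: one serializable object holding every threshold.

Defaults reproduce the standard screening parameters: S/N > 3, minimum
peak intensity 3e4, at least 3 consecutive scans, mass tolerance 3 ppm,
isotope intensity tolerance +/-30%, blank ratio 3.  The full config is
echoed into every run log so any deviation from defaults is auditable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .assign import ElementLimits, ErroneousRules
from .artifacts import ArtifactTable
from .quant import DEFAULT_CARBON_BINS

__all__ = ["PipelineConfig"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All module thresholds for one pipeline invocation."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    polarity: str = "negative"
    mode: str = "pm_negative"  # pm_negative | water_negative | positive
    min_sn: float = 3.0
    min_intensity: float = 3e4
    min_scans: int = 3
    tol_ppm: float = 3.0
    isotope_tol: float = 0.30
    blank_ratio: float = 3.0
    min_score: float = 85.0
    precursor_tol_ppm: float = 10.0
    frag_tol: float = 0.01
    rt_tol: float = 0.1
    mz_tol_ppm: float = 5.0
    eic_ppm: float = 5.0
    rt_id_window: float = 0.3
    ambiguity_ppm: float = 1.0
    grouping_mode: str = "independent"  # independent | vendor_compat
    include_metals: bool = False
    modified_ai: bool = False
    align: bool = False
    carbon_bins: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_CARBON_BINS)
    )
    source_categories: dict[str, str] = field(default_factory=dict)
    preferred_adducts: dict[str, str] = field(
        default_factory=lambda: {"negative": "[M-H]-", "positive": "[M+H]+"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.mode not in ("pm_negative", "water_negative", "positive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "positive" and self.polarity != "positive":
            raise ValueError("positive mode requires positive polarity")
        if self.mode != "positive" and self.polarity != "negative":
            raise ValueError(f"{self.mode} requires negative polarity")

    def element_limits(self) -> ElementLimits:
        if self.mode == "pm_negative":
            return ElementLimits.negative_pm()
        if self.mode == "water_negative":
            return ElementLimits.negative_water()
        return ElementLimits.positive(include_metals=self.include_metals)

    def erroneous_rules(self) -> ErroneousRules:
        return ErroneousRules()

    def artifact_table(self) -> ArtifactTable:
        return ArtifactTable(
            rt_tol=self.rt_tol,
            mz_tol_ppm=self.mz_tol_ppm,
            preferred=dict(self.preferred_adducts),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["carbon_bins"] = [list(b) for b in self.carbon_bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ver = d.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if ver != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {ver}")
        if "carbon_bins" in d:
            d["carbon_bins"] = [tuple(b) for b in d["carbon_bins"]]
        return cls(schema_version=ver, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
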