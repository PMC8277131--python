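"""Ground-truth-labelled synthetic centroided LC-MS runs.

The generator emulates centroided Orbitrap-style data at the level the
pipeline consumes: Gaussian chromatographic peaks, per-adduct ion series
with A/A+1/A+2 isotopologue envelopes at natural abundance, ppm-scale
mass jitter, a stochastic chemical background, and artifact species
shared between samples and blanks.  One centroid per isotopologue per
scan is produced (no profile shapes).  The background model — uniform
random m/z with exponentially distributed intensity — is deliberately
simple and non-physical; it exists to exercise S/N estimation and blank
logic, not to mimic real matrix chemistry.

Defaults mirror a standards-style acquisition: 0.05 min (3 s) Gaussian
peak sigma, 0.01 min scan interval, 1 ppm mass jitter, and analyte apex
intensities well above the 3e4 detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ION_SPECIES, Formula, ion_mz, isotope_pattern, parse_formula
from .peaks import Run, Scan

__all__ = [
    "AnalyteSpec",
    "NoiseSpec",
    "make_run",
    "make_blank",
    "make_calibration_series",
    "sodium_only_fixture",
    "interference_fixture",
]

PEAK_SIGMA = 0.05  # min
SCAN_INTERVAL = 0.01  # min
PPM_JITTER = 1.0
BACKGROUND_DENSITY = 0.02  # peaks per scan per Th
BACKGROUND_SCALE = 2e3  # exponential intensity scale
INTENSITY_FLOOR = 10.0  # centroids below this are not written


@dataclass
class AnalyteSpec:
    """One injected compound: formula, elution, intensity, adduct profile."""

    formula: Formula | str
    rt: float
    apex_intensity: float
    width: float = PEAK_SIGMA
    adducts: dict[str, float] = field(default_factory=lambda: {"[M-H]-": 1.0})
    ms2: list[tuple[float, float]] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.apex_intensity <= 0 or self.width <= 0:
            raise ValueError("intensity and width must be positive")
        total = sum(self.adducts.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"adduct fractions must sum to 1, got {total}")
        if not self.name:
            self.name = str(self.formula)


@dataclass
class NoiseSpec:
    """Stochastic components of a run; the seed fixes the run bit-exactly."""

    baseline_sigma: float = 0.0
    ppm_jitter: float = PPM_JITTER
    background_density: float = BACKGROUND_DENSITY
    background_scale: float = BACKGROUND_SCALE
    intensity_rsd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.baseline_sigma, self.ppm_jitter, self.background_density,
                  self.background_scale, self.intensity_rsd):
            if v < 0:
                raise ValueError("noise parameters must be non-negative")


def _polarity_of(adducts: dict[str, float]) -> str:
    pols = {ION_SPECIES[a].polarity for a in adducts}
    if len(pols) != 1:
        raise ValueError("analyte adduct profile mixes polarities")
    return pols.pop()


def make_run(
    analytes: list[AnalyteSpec],
    noise: NoiseSpec | None = None,
    rt_range: tuple[float, float] = (0.0, 10.0),
    scan_interval: float = SCAN_INTERVAL,
    mz_range: tuple[float, float] = (60.0, 900.0),
    sample: str = "sample",
    role: str = "sample",
) -> tuple[Run, pd.DataFrame]:
    """Simulate a centroided run; return it with its ground-truth table.

    Each analyte contributes, per adduct, a Gaussian-in-RT centroid
    series at the adduct's theoretical m/z (with seeded ppm jitter) plus
    A+1/A+2 isotopologue centroids scaled by the theoretical pattern.
    The ground truth lists every injected (analyte, adduct) peak with its
    m/z, RT and analytic area (apex * fraction * sigma * sqrt(2*pi), in
    intensity*minutes); peaks of identical m/z overlapping in RT are
    flagged.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    polarity = _polarity_of(analytes[0].adducts) if analytes else "negative"
    for a in analytes:
        if _polarity_of(a.adducts) != polarity:
            raise ValueError("all analytes in a run must share polarity")

    rts = np.arange(rt_range[0], rt_range[1] + 1e-12, scan_interval)
    # precompute per-(analyte, adduct) ion series
    series = []
    truth_rows = []
    for a in analytes:
        for label, frac in a.adducts.items():
            if frac <= 0:
                continue
            sp = ION_SPECIES[label]
            pattern = isotope_pattern(a.formula, sp)
            apex = a.apex_intensity * frac
            series.append((a, sp, pattern, apex))
            truth_rows.append(
                {
                    "analyte": a.name,
                    "formula": str(a.formula),
                    "species": label,
                    "mz": pattern[0][0],
                    "rt": a.rt,
                    "apex": apex,
                    "area": apex * a.width * np.sqrt(2 * np.pi),
                    "overlap": False,
                }
            )
    truth = pd.DataFrame.from_records(
        truth_rows,
        columns=["analyte", "formula", "species", "mz", "rt", "apex", "area", "overlap"],
    )
    # flag co-eluting identical-m/z peaks
    for i in range(len(truth)):
        for j in range(i + 1, len(truth)):
            if (
                abs(truth.at[i, "mz"] - truth.at[j, "mz"]) < truth.at[i, "mz"] * 5e-6
                and abs(truth.at[i, "rt"] - truth.at[j, "rt"]) < 0.3
            ):
                truth.at[i, "overlap"] = True
                truth.at[j, "overlap"] = True

    scans: list[Scan] = []
    span = mz_range[1] - mz_range[0]
    for t in rts:
        mzs: list[float] = []
        intens: list[float] = []
        for a, sp, pattern, apex in series:
            y = apex * np.exp(-0.5 * ((t - a.rt) / a.width) ** 2)
            if noise.intensity_rsd > 0:
                y *= max(0.0, 1.0 + rng.normal(0.0, noise.intensity_rsd))
            if y < INTENSITY_FLOOR:
                continue
            for mz0, rel in pattern:
                yy = y * rel
                if yy < INTENSITY_FLOOR:
                    continue
                mz = mz0 * (1.0 + rng.normal(0.0, noise.ppm_jitter) * 1e-6)
                mzs.append(mz)
                intens.append(yy)
        n_bg = rng.poisson(noise.background_density * span)
        if n_bg:
            bg_mz = rng.uniform(mz_range[0], mz_range[1], n_bg)
            bg_i = rng.exponential(noise.background_scale, n_bg)
            mzs.extend(bg_mz.tolist())
            intens.extend(bg_i.tolist())
        if noise.baseline_sigma > 0:
            # a diffuse noise floor: a few low-intensity centroids everywhere
            n_fl = rng.poisson(0.01 * span)
            if n_fl:
                mzs.extend(rng.uniform(mz_range[0], mz_range[1], n_fl).tolist())
                intens.extend(np.abs(rng.normal(0, noise.baseline_sigma, n_fl)).tolist())
        mzs_arr = np.array(mzs)
        intens_arr = np.array(intens)
        order = np.argsort(mzs_arr, kind="stable")
        mzs_arr, intens_arr = mzs_arr[order], intens_arr[order]
        # merge pathological exact-duplicate centroids
        if mzs_arr.size > 1:
            dup = np.diff(mzs_arr) <= 0
            while np.any(dup):
                i = int(np.argmax(dup)) + 1
                intens_arr[i - 1] += intens_arr[i]
                mzs_arr = np.delete(mzs_arr, i)
                intens_arr = np.delete(intens_arr, i)
                dup = np.diff(mzs_arr) <= 0 if mzs_arr.size > 1 else np.array([False])
        scans.append(Scan(rt=float(t), mz=mzs_arr, intensity=intens_arr, polarity=polarity))
    run = Run(scans=scans, sample=sample, role=role, polarity=polarity)
    return run, truth


def make_blank(
    shared_artifacts: list[AnalyteSpec],
    noise: NoiseSpec | None = None,
    rt_range: tuple[float, float] = (0.0, 10.0),
    scan_interval: float = SCAN_INTERVAL,
    mz_range: tuple[float, float] = (60.0, 900.0),
    sample: str = "blank",
    role: str = "solvent_blank",
) -> Run:
    """A blank run: only the shared artifact analytes plus noise."""
    run, _ = make_run(
        shared_artifacts, noise, rt_range, scan_interval, mz_range, sample, role
    )
    return run


def make_calibration_series(
    analyte: AnalyteSpec,
    concentrations: list[float],
    response_factor: float,
    noise: NoiseSpec | None = None,
    replicates: int = 3,
    rt_range: tuple[float, float] = (0.0, 4.0),
    scan_interval: float = SCAN_INTERVAL,
) -> list[tuple[float, int, Run]]:
    """Triplicate runs per level with apex proportional to concentration.

    Apex intensity is ``response_factor * concentration`` with seeded
    multiplicative noise of relative standard deviation
    ``noise.intensity_rsd``.  Requires at least five levels.  Levels low
    enough that the apex falls below the minimum-intensity threshold
    reproduce realistic low-concentration dropouts.
    """
    if len(set(concentrations)) < 5:
        raise ValueError("calibration needs at least 5 distinct concentrations")
    noise = noise or NoiseSpec()
    out = []
    k = 0
    for conc in concentrations:
        for rep in range(replicates):
            sub_seed = (noise.seed * 10007 + k) % (2**31)
            k += 1
            rng = np.random.default_rng(sub_seed)
            apex = response_factor * conc
            if noise.intensity_rsd > 0:
                apex *= max(0.0, 1.0 + rng.normal(0.0, noise.intensity_rsd))
            spec = AnalyteSpec(
                formula=analyte.formula,
                rt=analyte.rt,
                apex_intensity=max(apex, 1e-6),
                width=analyte.width,
                adducts=dict(analyte.adducts),
                name=analyte.name,
            )
            level_noise = NoiseSpec(
                baseline_sigma=noise.baseline_sigma,
                ppm_jitter=noise.ppm_jitter,
                background_density=noise.background_density,
                background_scale=noise.background_scale,
                intensity_rsd=0.0,  # level noise applied to apex above
                seed=sub_seed,
            )
            run, _ = make_run(
                [spec], level_noise, rt_range, scan_interval,
                sample=f"{analyte.name}_c{conc}_r{rep}",
            )
            out.append((conc, rep, run))
    return out


#: Compounds observed exclusively as sodium adducts in positive mode in
#: standards testing; their non-detection under protonated-first grouping
#: is the documented vendor limitation.
SODIUM_ONLY_COMPOUNDS = [
    ("levoglucosan", "C6H10O5"),
    ("2-hydroxyhexanoic acid", "C6H12O3"),
    ("2-hydroxy-3-methylbutanoic acid", "C5H10O3"),
    ("2,3-diacetyloxypropyl acetate", "C9H14O6"),
]


def sodium_only_fixture(
    seed: int = 0, include_protonated: bool = False
) -> tuple[Run, pd.DataFrame]:
    """Positive-mode run whose analytes ionize 100% as [M+Na]+.

    Demonstrates the grouping-mode difference: ``vendor_compat`` cannot
    form components for these compounds while ``independent`` detects
    them all.  With ``include_protonated`` two extra analytes carrying a
    normal [M+H]+/[M+Na]+ profile are added as positive controls.
    """
    analytes = [
        AnalyteSpec(
            formula=f, rt=1.0 + 0.8 * i, apex_intensity=5e5,
            adducts={"[M+Na]+": 1.0}, name=name,
        )
        for i, (name, f) in enumerate(SODIUM_ONLY_COMPOUNDS)
    ]
    if include_protonated:
        analytes += [
            AnalyteSpec("C8H10N4O2", rt=4.6, apex_intensity=8e5,
                        adducts={"[M+H]+": 0.7, "[M+Na]+": 0.3}, name="caffeine"),
            AnalyteSpec("C7H6O2", rt=5.4, apex_intensity=6e5,
                        adducts={"[M+H]+": 1.0}, name="benzoic acid"),
        ]
    noise = NoiseSpec(baseline_sigma=200.0, seed=seed)
    return make_run(analytes, noise, rt_range=(0.0, 6.5))


def interference_fixture(
    seed: int = 0, include_interferent: bool = True
) -> tuple[Run, pd.DataFrame, float]:
    """An analyte plus an isobaric interferent inside its unit-mass window.

    Returns (run, truth, analyte m/z).  The interferent elutes as a broad
    ragged hump across the run at ~0.6 Th above the analyte: inside the
    unit window [123, 124) but far outside a 5 ppm accurate window, so
    unit-mode S/N collapses while accurate-mode S/N is untouched — the
    mechanism behind low-concentration detection failures under unit-mass
    extraction.
    """
    rng = np.random.default_rng(seed)
    analyte = AnalyteSpec("C7H8O2", rt=2.0, apex_intensity=2e5,
                          adducts={"[M-H]-": 1.0}, name="3-methylbenzene-1,2-diol")
    noise = NoiseSpec(baseline_sigma=300.0, ppm_jitter=1.0, seed=seed)
    run, truth = make_run([analyte], noise, rt_range=(0.0, 4.0))
    target_mz = float(truth.iloc[0]["mz"])
    # inject the interferent (fluctuating centroids at ~123.62) plus a weak
    # chemical-noise centroid at the analyte m/z so both extraction modes
    # see a finite noise floor
    sources = [(123.62, 4e4), (target_mz, 1.5e3)]
    if not include_interferent:
        sources = sources[1:]
    for s in run.scans:
        for mz0, scale in sources:
            inten = rng.exponential(scale)
            mz = mz0 * (1.0 + rng.normal(0.0, 2.0) * 1e-6)
            i = int(np.searchsorted(s.mz, mz))
            s.mz = np.insert(s.mz, i, mz)
            s.intensity = np.insert(s.intensity, i, inten)
    return run, truth, target_mz
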