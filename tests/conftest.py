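from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

from ntms.chem import ION_SPECIES, ion_mz, parse_formula
from ntms.ms2 import LibraryEntry, MS2Spectrum
from ntms.synth import AnalyteSpec, NoiseSpec, make_run

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def simple_run():
    """One clean analyte (3-methylbenzene-1,2-diol-like) on a quiet baseline."""
    analyte = AnalyteSpec(
        "C7H8O2", rt=2.0, apex_intensity=5e5, name="methylcatechol"
    )
    run, truth = make_run(
        [analyte], NoiseSpec(baseline_sigma=200.0, seed=11), rt_range=(0.0, 4.0)
    )
    return run, truth


@pytest.fixture(scope="session")
def small_library():
    """Three-compound MS2 library with retention times."""

    def entry(name, formula, adduct, frags, rt):
        f = parse_formula(formula)
        return LibraryEntry(
            name, f,
            MS2Spectrum(ion_mz(f, ION_SPECIES[adduct]), frags, adduct, rt=rt),
            rt=rt,
        )

    return [
        entry("3-methylbenzene-1,2-diol", "C7H8O2", "[M-H]-",
              [(77.039, 100.0), (108.021, 55.0), (123.045, 30.0)], 2.0),
        entry("4-nitrocatechol", "C6H5NO4", "[M-H]-",
              [(108.021, 80.0), (124.016, 100.0), (154.014, 40.0)], 5.1),
        entry("4-dodecylbenzenesulfonic acid", "C18H30O3S", "[M-H]-",
              [(80.965, 60.0), (119.050, 100.0), (183.012, 90.0)], 22.4),
    ]
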