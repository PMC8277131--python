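"""The complete non-targeted workflow on a ground-truth synthetic sample.

Simulates a negative-mode run with eight analytes plus a shared
contamination artifact, a matching solvent blank, and an MS2 query for
one compound; runs detection -> isotopologue folding -> adduct grouping
-> blank subtraction -> formula assignment -> library screening ->
compositional grouping, then prints the per-stage counts and the final
compound table.
"""

from ntms.chem import ION_SPECIES, ion_mz, parse_formula
from ntms.config import PipelineConfig
from ntms.ms2 import LibraryEntry, MS2Spectrum
from ntms.pipeline import run_pipeline
from ntms.synth import AnalyteSpec, NoiseSpec, make_blank, make_run

analytes = [
    AnalyteSpec("C7H8O2", rt=1.0, apex_intensity=5e5, name="methylcatechol"),
    AnalyteSpec("C6H5NO4", rt=1.8, apex_intensity=4e5, name="nitrocatechol"),
    AnalyteSpec("C16H26O3S", rt=2.6, apex_intensity=8e5, name="LAS C16"),
    AnalyteSpec("C17H28O3S", rt=3.1, apex_intensity=7e5, name="LAS C17"),
    AnalyteSpec("C9H12O3", rt=3.8, apex_intensity=3e5, name="aromatic triol"),
    AnalyteSpec("C6H10O5", rt=4.4, apex_intensity=2.5e5, name="anhydrosugar"),
    AnalyteSpec("C8H8O4", rt=5.0, apex_intensity=6e5, name="methoxybenzoic"),
    AnalyteSpec("C10H16O2", rt=5.7, apex_intensity=4.5e5, name="terpenoid"),
]
artifact = AnalyteSpec("C8H18O3", rt=6.5, apex_intensity=3e5, name="plasticizer")

noise = NoiseSpec(baseline_sigma=250.0, background_density=0.02, seed=41)
run, truth = make_run(analytes + [artifact], noise, rt_range=(0.0, 7.5))
blank = make_blank([artifact], NoiseSpec(baseline_sigma=250.0, seed=42),
                   rt_range=(0.0, 7.5))

f = parse_formula("C7H8O2")
frags = [(77.039, 100.0), (108.021, 55.0)]
library = [LibraryEntry("3-methylbenzene-1,2-diol", f,
                        MS2Spectrum(ion_mz(f, ION_SPECIES["[M-H]-"]), frags,
                                    "[M-H]-", rt=1.0), rt=1.0)]
query = MS2Spectrum(float(truth.iloc[0]["mz"]), frags, "[M-H]-", rt=1.0)

res = run_pipeline([run], [blank], PipelineConfig(), library,
                   ms2_spectra={"sample": [query]})

for line in res.log_lines[1:]:
    print(line)
print()
cols = ["mz", "rt", "formula", "ppm_error", "comp_class", "compound", "level"]
print(res.table[cols].round(4).to_string(index=False))
print()
print(res.grouped[["comp_class", "c_bin", "pct", "oc_w"]].round(3).to_string(index=False))
print()
print("Every injected analyte returns with its correct formula; the")
print("plasticizer shared with the blank is removed; the library match")
print("with retention-time agreement reaches confidence level 1.")
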