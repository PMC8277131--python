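# ntms — non-targeted screening of LC–Orbitrap-MS data for environmental matrices

Air and water samples contain thousands of organic pollutants; targeted
methods measure a prescribed few and miss the rest. `ntms` is an open,
testable implementation of an automated non-targeted compositional-analysis
workflow for coupled liquid chromatography / ultrahigh-resolution mass
spectrometry (Orbitrap-style, centroided) data, aimed at environmental
chemists who need the full picture of a complex extract rather than a
target list.

The pipeline covers, in order:

1. **Chromatographic peak detection** — extracted ion chromatograms in
   unit-mass (`[⌊m/z⌋, ⌊m/z⌋+1)`) or accurate-mass (± ppm) windows, robust
   MAD-based noise estimation, and the screening gates S/N > 3, apex
   intensity ≥ 3×10⁴, ≥ 3 consecutive scans. Optional anchor-based
   retention-time alignment across runs.
2. **Molecular formula assignment** — exhaustive candidate enumeration
   within < 3 ppm under per-mode element limits (C, H, O unlimited; N ≤ 5;
   S ≤ 2; Cl ≤ 3 for surface-water mode; Na ≤ 2 / K ≤ 1 optional in
   positive mode), isotopologue verification against theory within ±30 %
   (relative), and rejection of chemically implausible formulas
   (non-integer or negative DBE, H/C outside [0.2, 3.1], O/C > 3).
3. **ESI artifact handling** — co-eluting adducts/dimers/water losses
   grouped into one component reported under the preferred adduct
   ([M−H]⁻ / [M+H]⁺), plus solvent- and procedural-blank subtraction
   (remove unless sample ≥ 3× blank area). An `independent` grouping mode
   detects compounds observed only as [M+Na]⁺; a `vendor_compat` mode
   replicates the protonated-first limitation of a commercial framework
   for comparison.
4. **MS² identification** — MSP/MGF spectral libraries, square-root
   intensity cosine similarity (percent), and the 5-level identification
   confidence scale (1 = structure confirmed by authentic-standard RT
   agreement … 5 = exact mass only).
5. **Quantification and reporting** — ≥ 5-level × 3-replicate linear
   calibrations with out-of-range flagging, and the compositional metrics
   and groupings used for environmental mixtures: DBE, DBE/C, O/C, H/C,
   OSc = 2·O/C − H/C, aromaticity index, CHO/CHON/CHOS/CHONS classes by
   carbon-number bin with area-normalized abundance and area-weighted O/C.
6. **Synthetic data** — a ground-truth-labelled generator of centroided
   runs (Gaussian peaks, isotopologue envelopes, ppm mass jitter, chemical
   background, shared blank artifacts) so every stage is testable without
   instrument data.

## Worked example

`examples/full_pipeline.py` simulates a negative-mode run with eight
analytes plus a plasticizer-like artifact shared with a solvent blank,
and one MS² query:

```
sample: detected 16, components 9, after blanks 8, assigned 8

      mz  rt   formula  ppm_error comp_class                 compound  level
123.0452 1.0    C7H8O2     0.0033        CHO 3-methylbenzene-1,2-diol      1
154.0146 1.8   C6H5NO4    -0.1792       CHON                               4
...
297.1528 2.6 C16H26O3S     0.6860       CHOS                               4
311.1687 3.1 C17H28O3S    -0.3174       CHOS                               4

comp_class   c_bin   pct  oc_w
       CHO   C6-C8 33.75 0.482
      CHON   C6-C8 10.00 0.667
      CHOS C16-C20 37.50 0.182
```

Sixteen raw features collapse to eight compounds: isotopologue features
fold into their parents, the blank-shared artifact is removed, every
analyte returns its correct formula within 3 ppm, and the compound with a
library match plus retention-time agreement reaches confidence level 1.
The grouped table gives each composition class's percent of total peak
area and its area-weighted O/C — the fingerprint used to compare samples
and attribute sources (e.g. C16–C20 CHOS with O/C ≈ 0.18 is the signature
of linear alkylbenzene sulfonate surfactants).

Other examples, one per capability: `formula_metrics.py`,
`unit_vs_accurate_sn.py` (why unit-mass extraction loses
near-detection-limit compounds), `assign_formula.py`,
`sodium_adducts_and_blanks.py`, `calibrate_and_quantify.py`.

A thin CLI mirrors the workflow (`ntms simulate | detect | assign |
screen | quantify | report | run-all`); the Python API is the primary
interface.

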