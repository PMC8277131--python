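# Methods

This note documents the models, conventions and numerical choices behind
`ntms`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the
synthetic-data tests do and do not demonstrate.

## Masses and ion species

Monoisotopic atomic masses are IUPAC/CODATA values hard-coded to ≥ 6
decimal places (`ntms.constants`). Ion m/z values include the electron
mass in the species delta: at m/z 123 the electron is ≈ 4.5 ppm, larger
than the 3 ppm assignment tolerance, so omitting it would bias every
assignment. Only singly charged species are supported; dimers ([2M−H]⁻,
[2M+H]⁺) double the neutral mass before applying the delta. Average
(isotope-weighted) molecular weights, multiply charged ions and radical
ions are out of scope.

Nominal (integer) molecular weight is the sum of the mass numbers of the
most abundant isotopes. For the compound classes handled here the printed
"MW" of a formula is identical whether read as nominal or rounded
monoisotopic mass; nominal is used for reporting.

## Compositional metrics

For a neutral formula with C ≥ 1:

- DBE = C − (H + Cl + Na + K)/2 + (N + P)/2 + 1. Halogens and the
  monovalent metals count as hydrogen, so sodiated neutrals stay on the
  integer-DBE grid and remain filterable; N and P are treated trivalent.
  DBE is always a multiple of ½ and is integer iff H+Cl+Na+K+N+P is even.
- Elemental ratios O/C, H/C, N/C, S/C; OSc = 2·O/C − H/C (heteroatoms
  ignored, the standard average-carbon-oxidation-state estimate).
- Aromaticity index AI = (1 + C − O − S − H/2)/(C − O − S − N − P),
  clamped to 0 when numerator or denominator ≤ 0. The modified variant
  (AImod, oxygen weighted ½) is available via `modified_ai`; both
  conventions are standard in ultrahigh-resolution environmental MS.
- Composition class from the presence pattern of N, O, S: CH, CHO, CHON,
  CHOS, CHONS; N or S without O fall into "other"; chlorine appends a
  "Cl" suffix (CHOCl, …) rather than folding into "other" because the
  surface-water element limits admit Cl.

Isotopologue patterns (A, A+1, A+2 relative to A) come from the exact
polynomial expansion of natural isotope abundances per element
(truncated convolution over nominal-mass shifts, exact up to A+2).
Isotopes of adduct atoms are neglected (< 0.03 % relative). A+k
centroids are placed at k × 1.0033548 Th above A — the ¹³C spacing,
adequate at ppm scale for CHNOS molecules.

## Peak detection

EICs sum centroid intensities per scan over half-open windows
[low, high). The unit-mass convention is [⌊m/z⌋, ⌊m/z⌋+1); the
accurate-mass default half-width is 5 ppm (configurable) — chosen to
contain ±2 ppm instrument jitter with margin while excluding isobaric
interferents ≥ ~0.01 Th away.

Noise is 1.4826 × the median absolute deviation of EIC intensities
outside the candidate peak's own RT extent (the 1.4826 factor makes the
estimator consistent with σ for Gaussian noise). The baseline is the
median of the same points. S/N = (apex − baseline)/noise; a noise-free
window reports S/N = ∞. This estimator is the package's own definition —
vendor S/N algorithms are undisclosed — so absolute S/N values are
comparable only within the package; *ratios* of S/N between extraction
modes are the meaningful quantity.

Detection keeps local maxima with apex ≥ 3×10⁴ counts, S/N > 3, and ≥ 3
consecutive scans above max(baseline + noise, 0.5 % of apex); the 0.5 %
floor handles noise-free synthetic data where baseline + noise is 0.
Peak bounds are the nearer of the flanking local minimum and the
baseline crossing; areas are trapezoidal over RT in intensity·minutes.
Detection counts are monotone non-increasing in each threshold, and the
output is invariant to uniform intensity scaling when thresholds scale
along.

Retention-time alignment (off by default, irrelevant for single runs)
matches the 50 most intense features between each run and a reference by
m/z (± 5 ppm) and RT (± 0.5 min), and fits a monotone piecewise-linear
warp through the matched pairs; monotonicity is enforced by
pool-adjacent-violators on the target RTs, and runs without anchors fall
back to the identity warp with a logged warning.

## Formula assignment

Candidates are enumerated lexicographically over heteroatoms (N, S, Cl,
Na, K, O) with the C/H plane solved in closed form against the residual
mass window. "Unlimited" C, H, O are realised as caps that cannot
exclude a valid candidate: C ≤ mass/12, O ≤ mass/15.99, H ≤ 2C + N + 2.
These caps are part of the enumeration contract; the test-suite oracle
(a naive full-grid scan) applies the same caps and must return exactly
the same set. In-formula Na/K are opt-in (`include_metals`) because
metal counts inflate the candidate space combinatorially while sodium
almost always enters as an adduct.

The isotope check compares observed A+1/A+2 *relative* intensities to
theory within ±30 % relative. A missing isotopologue fails the check
only when its theoretical absolute intensity would exceed the detection
floor (the minimum peak intensity); below the floor, absence is
uninformative. This check is what separates candidates that exact mass
cannot (e.g. S vs O₂ substitutions, which differ in A+2 by the 4.3 %
³⁴S signature).

Erroneous-formula rules (each rejection carries exactly one rule name):
non-integer DBE, DBE < 0, H/C outside [0.2, 3.1], O/C > 3. The winner is
the surviving candidate with the smallest |ppm error|; when a second
survivor lies within 1 ppm of the best, the assignment is reported
`ambiguous` with all close alternatives listed rather than silently
picking one.

## Artifact grouping and blanks

Features from one run and polarity that co-elute within 0.1 min and
whose m/z values are consistent with two ion species of the same neutral
mass (± 5 ppm) merge into a component; the consensus neutral mass is the
mean over members. The default artifact table is standard ESI chemistry
— negative: [M−H]⁻, [M+Cl]⁻, [M+HCOO]⁻, [2M−H]⁻, [M−H−H₂O]⁻; positive:
[M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺, [2M+H]⁺, [M+H−H₂O]⁺ — and fully
user-overridable. One preferred member ([M−H]⁻/[M+H]⁺ unless overridden,
highest area on ties) survives artifact removal; all drops are logged.

Singleton features default to the preferred adduct. In `independent`
mode, when element limits are supplied, the species is resolved by
assignability: the preferred adduct is tried first and the other table
species in order, keeping the first that yields an isotope-consistent
formula. This is what recovers compounds ionizing exclusively as
[M+Na]⁺. `vendor_compat` mode instead requires a protonated member
before sodiated members attach and treats lone features as protonated —
reproducing a documented commercial-software limitation so its cost can
be measured; it is not the recommended mode.

Blank subtraction removes a sample feature that matches a solvent- or
procedural-blank feature (± 5 ppm, ± 0.1 min) unless its area is ≥ 3×
the blank area (ratio configurable); matched survivors carry the ratio
as an annotation. Both blanks apply sequentially; the operation is
idempotent and its output is a subset of its input.

## MS² identification

Similarity is the cosine of square-root-intensity vectors after greedy
fragment pairing (highest summed intensity first, ties by smallest Δm/z)
within 0.01 Da, reported as a percent. It is symmetric, scale-invariant,
100 exactly for proportional matched spectra with no unmatched
intensity, and 0 for disjoint fragment sets. Percent thresholds quoted
for proprietary scoring functions are treated as configuration values
here — scores from different scoring algorithms are not comparable.
Library search gates candidates by precursor m/z (± 10 ppm) before
scoring and drops hits below the score threshold (default 85 %).

Confidence levels follow the community 5-point scale: 5 exact mass only;
4 unambiguous formula; 3 formula plus recorded MS²; 2 library match at
or above threshold; 1 level 2 plus retention-time agreement with an
authentic standard within ± 0.3 min. Adding evidence never worsens the
level.

## Quantification and grouping

Calibrations require ≥ 5 distinct concentrations with 3 replicates each;
the fit is unweighted ordinary least squares on replicate means, with
per-level RSDs and residuals stored as diagnostics. Quantification
inverts the line and *flags* (rather than reports) concentrations
outside the calibrated range. LOD/LOQ estimation and
ionization-efficiency correction are out of scope — normalized
abundances assume comparable ESI efficiencies, a known limitation of the
approach.

Compositional grouping aggregates assigned features by (class,
carbon-number bin); default bins C1–C5, C6–C8, C9–C12, C13–C15, C16–C20,
C21+. Two oxygen statistics are emitted per group: `oc_w`, the
area-weighted mean O/C of the group's members (always within the
members' O/C range), and `oc_group`, the group's area divided by total
sample area. The latter is literally a relative abundance, not an O/C;
both are reported because the two readings of "weighted O/C" coexist in
practice, and emitting both removes the ambiguity. The aromatic fraction
of a group is the *count* fraction (not area-weighted) of members with
DBE/C strictly > 0.5.

## Synthetic data

The generator emulates what the pipeline consumes, not instrument
physics: one centroid per isotopologue per scan (Gaussian-in-RT, σ
default 0.05 min, scan interval 0.01 min), ppm-scale Gaussian mass
jitter (σ 1 ppm, the accuracy class of a well-calibrated Orbitrap),
isotopologue envelopes from the exact pattern, and a chemical background
of uniform-random m/z centroids with exponential intensities —
deliberately non-physical, sufficient to exercise S/N estimation and
blank logic. No profile peak shapes, space-charge effects or RT drift
are modelled. Consequently, passing tests demonstrate the *logic* of the
pipeline (thresholding, grouping, assignment, conservation) under
realistic mass accuracy and intensity scales; they do not validate
behaviour against vendor centroiding, matrix suppression, or real
chromatographic tailing.

Calibration series scale apex intensity linearly with concentration
(multiplicative noise, default RSD 2 % where enabled); with a ppm-scale
response factor the sub-ppb levels fall below the 3×10⁴ intensity gate,
reproducing realistic low-concentration dropouts. All generators are
bit-exact under a fixed seed.

## Problem sizes and determinism

The test suite runs entirely on synthetic data: the largest fixtures are
a 50-analyte, 900-scan run for end-to-end formula recovery and 200
random masses per ionization mode for oracle set-equality — sizes chosen
so the full suite completes in about a minute on one core while still
exercising every code path at realistic m/z densities. Every stochastic
component is seeded; the pipeline is byte-deterministic for fixed inputs
and configuration.

## Known limitations

- Vendor .raw files are not read; inputs are centroided mzML or the CSV
  scan-table dialect. Profile-mode mzML is rejected explicitly.
- A single S/N gate is applied; instrument workflows that chain two
  gates (spectrum selection then compound detection) are not replicated.
- The default artifact table and the blank-ratio criterion are the
  package's documented choices of standard ESI chemistry; site-specific
  artifact lists should be supplied via configuration.
- In-source fragmentation beyond the listed neutral losses, charge
  states > 1, and fragment-informed formula scoring are not implemented.
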