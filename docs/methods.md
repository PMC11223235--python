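# Methods

## The measurement model

All processing assumes Beer–Lambert additivity on a uniform wavelength
grid: the absorbance of a two-component solution is

    A(λ) = c_ASC · ε_ASC(λ) + c_NIC · ε_NIC(λ) + baseline(λ) + noise(λ)

with concentrations in μg·mL⁻¹ and specific absorbances ε in
AU·mL·μg⁻¹ at 1 cm path. The default acquisition window is 200–400 nm at
1 nm resolution (201 points), the standard sweep for this analyte pair.

Differentiation with respect to wavelength is the core primitive. Two
operators are exposed:

* **central_diff** — three-point central differences (`numpy.gradient`),
  parameter-free, exact for polynomials of degree ≤ 2 on interior points;
  the two end points are one-sided estimates and are flagged. Higher
  orders are repeated applications of the first-order stencil, so
  "differentiate twice" and "ask for order 2" are identical by
  construction.
* **savitzky_golay** — local least-squares polynomial differentiation
  (`scipy.signal.savgol_filter`), the standard choice for noisy spectra.
  The `window // 2` points at each edge are flagged.

Flagged edge points are excluded from zero-crossing searches, which
removes spurious boundary crossings. Which operator a pipeline run uses is
an explicit config choice (`deriv_method`), since instrument software
rarely documents whether its built-in "differentiate" smooths first.

## Zero-crossing quantification

For a single symmetric band, dA/dλ vanishes exactly at the band maximum at
every concentration. The mixture derivative read at the interferent's
crossing therefore responds only to the analyte. `find_zero_crossing`
scans a window of interior integer-nm grid points, keeps those where every
spectrum in a pure-component concentration series shows a strict
derivative sign change (positive one side, negative the other), and
returns the point minimising the worst |dA/dλ| across the series; that
worst residual is reported as a quality metric. Ties are broken toward the
interferent's absorbance maximum. The estimate is reported on the integer
grid, matching the 1 nm instrument resolution — no sub-nm interpolation —
and is invariant under uniform scaling of the input spectra.

Calibration regresses the **signed** derivative amplitude on
concentration by OLS (statsmodels), preserving the conventional sign
behaviour of this pair: descending at 261 nm for ASC, ascending at 243 nm
for NIC. Reported diagnostics are slope, intercept, R², the slope's
standard error SD_a, residual SD, and the regression F statistic and
p-value. For numerically perfect fits, where the residual sum underflows
and the F statistic is non-finite, R² is reported as 1 and p as 0. A
fitted slope of exactly zero yields infinite detection limits rather than
an error, since such a curve is merely useless, not invalid.

Detection limits use the slope/standard-error closed form

    LOD = 3.3 · SD_a / |a|        LOQ = 10 · SD_a / |a|

The 3.3/10 multipliers are the ICH convention and are configurable. SD_a
is the standard error of the slope. The originating study's printed
LOD/LOQ pairs cannot be recomputed without its raw calibration data (and
its two printed pairs are mutually inconsistent with any single multiplier
convention), so the package pins the behaviour with closed-form property
tests instead of printed targets.

Quantification inverts the calibration line at each crossing,
c = (A′ − b)/a. Values at or below the LOQ, outside the calibrated range,
or negative (clamped to zero by default, raw value retained) are flagged,
never silently accepted. Recovery statistics follow pharmaceutical
validation practice: recovery = 100·found/theoretical; standard-addition
recovery = 100·(total − base)/added; precision is the mean and sample SD
(n − 1) of recovery percentages. The AOAC acceptance band for this
concentration range is 95–105 %.

## Cocrystal purity mass balance

Two assumptions, both supported by solid-state characterisation of this
system: (1) the cocrystal stoichiometry is fixed (1:1 ASC:NIC); (2) the
coformer NIC precipitates entirely as cocrystal, so only excess ASC
appears as homocrystals. Then, writing n_cc for mmol of cocrystal:

    n_cc     = m_NIC / MM_NIC
    m_cc     = n_cc · (R_s·MM_ASC + MM_NIC)
    purity   = 100 · m_cc / m_collected      (wt %)
    m_excess = m_ASC − n_cc · R_s·MM_ASC

with MM_ASC = 176.12, MM_NIC = 122.12 g·mol⁻¹, R_s = 1. The identity
m_cc + m_excess = m_ASC + m_NIC holds exactly and is asserted as a
property test. The formula set generalises to arbitrary R_s and to the
opposite limiting component via `StoichiometryModel`, though the defaults
replicate the 1:1 NIC-limited case. MM_NIC = 122.2 (a rounding variant
found in parts of the literature) is accepted through the same config
field.

Purity above 100 % is physically impossible but statistically routine
(both component totals carry measurement error); such values are reported
as computed with a warning, never clamped. Likewise a bulk molar ratio
below R_s contradicts assumption 2 and produces a warning plus a negative
excess mass, not an exception — excess coformer is normally lost to the
solvent phase during antisolvent processing rather than retained.

Against the bundled 16-cell reference batch table (8 batches × 2
measurement methods), recomputed purities agree with the independently
reported values within 0.41 percentage points for 15 cells. One cell
(GAS#13 by the derivative method) shows a 0.61 pp residual: its printed
NIC total (54.4 mg) and printed cocrystal mass (133.7 mg) are mutually
inconsistent by ~0.9 mg, indicating a rounding or transcription artefact
in the source table itself; the package reports the value implied by the
component totals.

## The synthetic-data generator

The generator exists so that every downstream stage has ground truth. It
emulates exactly the structure the analysis assumes — and nothing more:

* **Band shape**: one Gaussian band per component (ASC: centre 243 nm,
  σ 15 nm; NIC: centre 261 nm, σ 12 nm). Gaussian symmetry makes the
  zero-crossing-at-band-centre property exact and analytically checkable.
  Centres and widths sit inside the ranges reported for these analytes in
  acidic aqueous solution. Secondary shoulder bands can be added in
  config.
* **Amplitudes**: 0.056 (ASC) and 0.037 (NIC) AU·mL·μg⁻¹, the scale of
  literature specific absorptivities for these compounds at their band
  maxima (ε ≈ 1.0·10⁴ and 4.5·10³ M⁻¹cm⁻¹ respectively). A 24 μg·mL⁻¹ top
  standard then reads ≈ 1.3 AU, comfortably inside the photometric range.
  No absorptivities are printed for the reference system, so these
  defaults are honest placeholders at a realistic scale, exposed in
  config and recorded in every manifest.
* **Noise**: additive Gaussian, sd 0.002 AU per point, plus an optional
  linear baseline (zero by default). Identical seed and parameters
  reproduce identical spectra.
* **Calibration series**: twelve mixed standards, 2–24 μg·mL⁻¹, both
  analytes co-varying, matching the serial-dilution protocol of a mixed
  stock.
* **Cocrystal samples**: a collected mass is split into 1:1 cocrystal
  plus ASC homocrystal excess according to a true purity fraction,
  dissolved (default 10 mg in 10 mL, then 50× secondary dilution, landing
  near 20 μg·mL⁻¹ total) and scanned. The true component masses are
  returned for recovery testing; conservation (cocrystal + excess =
  collected) holds identically.

What the generator deliberately does **not** model: pH-dependent ASC
speciation and oxidation to dehydroascorbic acid (the assay's premise is
an effective stabiliser at pH 3), degradation-product spectra, stray
light, turbidity/scattering, or wavelength-registration error. Passing
tests on synthetic data therefore demonstrate the correctness of the
*algorithmic chain* under the stated noise model, not robustness to those
instrumental pathologies.

## Choice of the default smoothing window

The pipeline's default derivative operator is Savitzky–Golay with
polyorder 2 and window 31 (±15 nm). The window follows from a noise
propagation design rule rather than taste: a single-point derivative read
at the crossing has standard deviation σ_A·‖c‖₂/Δλ (filter coefficients
c), and dividing by the calibration slope converts it to concentration
error. With σ_A = 0.002 AU and the default bands, the requirement that
the 3σ concentration error stay within ±5 % at the *bottom* of the range
(2 μg·mL⁻¹, the worst case for a relative criterion) gives window 31 as
the smallest odd window satisfying it on both channels (3σ = 0.093
μg·mL⁻¹ vs the 0.100 bound; window 29 gives 0.101). Two facts make a
window of this size safe here: the derivative filter is antisymmetric, so
symmetric-band zero crossings are preserved *exactly*, and the whole chain
is linear in concentration, so smoothing attenuation cancels identically
between standards and samples — the universal rule that standards and
samples must share derivative settings. `differentiate` itself defaults
to plain central differences (window-free), which suits noise-free or
pre-smoothed data; the window matters only when reading noisy spectra at
a single wavelength.

## Numerical and reporting conventions

* Wavelengths are stored as floats, validated strictly ascending and
  uniformly spaced (relative tolerance 1e-8); integer-nm is enforced on
  ingestion only when a 1 nm resolution is declared.
* Spectrum CSVs round-trip bit-identically (shortest-round-trip float
  formatting); metadata travels as `# key: value` comment lines, and the
  one-sided-edge flag of derivative spectra survives I/O.
* Zero-crossing ties (equal residual amplitude) break toward the
  interferent's absorbance maximum.
* Report rounding: concentrations to 2 decimals, recoveries to 1 decimal,
  matching the conventions of the reference tables. Rounding is applied
  only at the report boundary, never inside computations.
* Pipeline stages draw noise from independent children of the master seed
  (`numpy.random.SeedSequence` spawn keys, reduced below 2³¹), so a stage
  is reproducible regardless of how many draws other stages consume.
* Simulation sizes in the default config (three pure levels per
  component, twelve calibration levels, ten validation mixtures, five
  interday replicates, three simulated bulk batches) mirror the scale of
  a realistic bench validation campaign; all are config fields.

## Known limitations

* Single-wavelength zero-crossing readout is noise-limited at the bottom
  of the range; multivariate calibration (CLS/PLS) would use the whole
  spectrum but is deliberately out of scope, as are ratio-spectra
  derivative methods.
* The zero-crossing wavelength is only exactly the band centre for
  symmetric bands; for skewed real bands the crossing is an empirical
  wavelength, which the search handles, but the synthetic tests do not
  exercise skewness.
* Derivative order selection is manual (orders 1–3 are supported as
  operators; the assay fixes order 1).
* The purity balance inherits both stoichiometric assumptions; for a
  system where the coformer also forms homocrystals the estimate becomes
  an upper bound, and only the molar-ratio diagnostic would reveal it.
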