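# fodspec

Zero-crossing **f**irst-**o**rder **d**erivative **spec**trophotometry for
the simultaneous UV determination of l-ascorbic acid (vitamin C, ASC) and
nicotinamide (vitamin B3 amide, NIC), and for estimating the purity of
their 1:1 cocrystal by stoichiometric mass balance.

ASC and NIC absorb in a narrow UV window (band maxima near 243–245 nm and
261–262 nm respectively), so direct absorbance readings of a mixture are
hopelessly entangled. The classical resolution is to work with the first
derivative of absorbance with respect to wavelength, dA/dλ. For each
component there is a wavelength — its *zero-crossing point* — where its own
derivative is zero at every concentration; the derivative amplitude of a
mixture read there depends only on the *other* component. Under acidic
conditions the crossing of NIC sits at 261 nm (quantifies ASC, descending
calibration) and the crossing of ASC at 243 nm (quantifies NIC, ascending
calibration):

```
A(λ)      = c_ASC·ε_ASC(λ) + c_NIC·ε_NIC(λ)            (Beer–Lambert additivity)
A′(261)   = c_ASC·ε′_ASC(261)        since ε′_NIC(261) = 0
A′(243)   = c_NIC·ε′_NIC(243)        since ε′_ASC(243) = 0
c         = (A′(λ_zc) − b) / a       from the OLS calibration A′ = a·c + b
```

Detection limits follow the ICH slope/standard-error form,
LOD = 3.3·SD_a/|a| and LOQ = 10·SD_a/|a|.

For a bulk cocrystal powder, assuming the 1:1 ASC:NIC stoichiometry and
that all NIC precipitates as cocrystal (only excess ASC forms
homocrystals), measured component totals m_ASC and m_NIC give

```
n_cc   = m_NIC / MM_NIC                     MM_ASC = 176.12 g·mol⁻¹
m_cc   = n_cc · (MM_ASC + MM_NIC)           MM_NIC = 122.12 g·mol⁻¹
purity = 100 · m_cc / m_collected  (wt %)
```

and the bulk molar ratio (m_ASC/MM_ASC)/(m_NIC/MM_NIC) > 1 diagnoses ASC
homocrystal impurities.

The package is aimed at analytical and formulation scientists who want the
whole chain — spectra in, purity out — as reusable, tested code: a spectrum
container with CSV I/O, central-difference and Savitzky–Golay derivative
operators, zero-crossing detection, calibration with full regression
diagnostics, mixture quantification with recovery/precision statistics, the
purity mass balance, and a synthetic-spectrum generator so every stage is
testable without an instrument.

## Worked example

```python
from fodspec import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(seed=1, outdir="demo_out")
rep = run_full_pipeline(cfg, write_outputs=False)

for k, zc in rep.crossings.items():
    print(f"{k} quantified at {zc.wavelength_nm} nm (crossing of {zc.interfering_component})")
for k, c in rep.curves.items():
    print(f"{k}: a = {c.slope_a:+.4e}, R^2 = {c.r_squared:.5f}, "
          f"LOD = {c.lod:.3f}, LOQ = {c.loq:.3f} ug/mL")
print(rep.purity.purity[["batch_id", "m_cocrystal_mg", "purity_wt_pct",
                         "molar_ratio_asc_nic"]].round(3).to_string(index=False))
```

prints

```
ASC quantified at 261 nm (crossing of NIC)
NIC quantified at 243 nm (crossing of ASC)
ASC: a = -1.8418e-03, R^2 = 0.99999, LOD = 0.002, LOQ = 0.007 ug/mL
NIC: a = +1.2912e-03, R^2 = 0.99999, LOD = 0.003, LOQ = 0.010 ug/mL
batch_id  m_cocrystal_mg  purity_wt_pct  molar_ratio_asc_nic
   SIM#1           9.965         99.649                1.006
   SIM#2           8.940         89.399                1.194
   SIM#3           6.019         60.188                2.123
```

The run simulated pure-component series, located both zero crossings on
the 1 nm grid, calibrated both channels over 2–24 μg·mL⁻¹ (negative slope
at 261 nm, positive at 243 nm, near-perfect linearity at 0.002 AU
photometric noise), then dissolved and quantified three simulated bulk
powders of true purity 100 %, 90 % and 60 % — recovering them to within a
fraction of a percentage point, with the molar ratio flagging the impure
batches (ratio ≫ 1 for the 60 % batch).

Quantifying a *measured* batch instead takes one call:

```python
from fodspec import BatchMeasurement, purity_mass_balance
r = purity_mass_balance(BatchMeasurement("GAS#9", 194.2, 114.2, 80.0, source="LC-MS"))
print(round(r.m_cocrystal_mg, 1), round(r.purity_wt_pct, 2))  # 195.4 100.61
```

## Command line

```bash
fodspec simulate  --config cfg.yaml --out spectra/      # synthetic spectra + manifest
fodspec derive    spectra/calib_2.csv --out derived/    # derivative CSV
fodspec calibrate --table amplitudes.csv --out cal/     # calibration.json
fodspec quantify  sample.csv --calibration cal/calibration.json --out q/
fodspec purity    --batches batches.csv --out purity/   # mass-balance report
fodspec validate  --recoveries recs.csv                 # precision summary
fodspec run-all   --config cfg.yaml --seed 1 --out run/ # everything + manifest
```

All tabular I/O is plain CSV; `run-all` writes a `manifest.json` with the
seed, a config hash and SHA-256 digests of every report, so a persisted
config re-runs byte-identically.

## Layout

```
src/fodspec/
  spectra.py    Spectrum/DerivativeSpectrum, CSV I/O, derivative operators
  synth.py      Gaussian-band Beer–Lambert spectrum generator + cocrystal samples
  calibration.py  zero-crossing search, OLS calibration, LOD/LOQ
  quantify.py   mixture quantification, recovery & precision statistics
  purity.py     stoichiometric mass balance and batch purity report
  datasets.py   published reference tables (validation mixtures, GAS batches)
  config.py     PipelineConfig (YAML-serializable, hashable)
  pipeline.py   run_full_pipeline orchestration + manifest
  cli.py        click CLI
docs/methods.md   model, parameter and design notes
```
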