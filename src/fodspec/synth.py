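"""Synthetic two-component UV absorption spectra.

Emulates the statistical structure the zero-crossing analysis relies on:
additive Beer–Lambert absorbance of two overlapping Gaussian bands —
ascorbic acid (ASC) with its principal band near 243 nm and nicotinamide
(NIC) near 261 nm — response linear in concentration over the working
2–24 μg·mL⁻¹ range, plus additive photometric noise and an optional
linear baseline.

Band shape is Gaussian so that the interference-free wavelength of each
component (where its first derivative vanishes) coincides exactly with the
band-centre grid point, which makes every zero-crossing property
analytically checkable. Default amplitudes follow literature-scale
specific absorptivities of the two vitamins in dilute aqueous solution
(ASC ≈ 0.056 and NIC ≈ 0.037 AU·mL·μg⁻¹·cm⁻¹ at their band maxima,
1 cm path), so a 24 μg·mL⁻¹ top standard reads ≈ 1.3 AU.

The cocrystal generator decomposes a collected bulk powder into 1:1
(ASC:NIC) cocrystal plus ASC homocrystal excess, dissolves it through the
stated two-step dilution and returns both the spectrum and the
ground-truth masses, so purity recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ParameterError
from .spectra import Spectrum

__all__ = [
    "GaussianBand",
    "ComponentModel",
    "NoiseModel",
    "CocrystalTruth",
    "default_grid",
    "default_asc_model",
    "default_nic_model",
    "DEFAULT_LEVELS",
    "gen_pure_spectrum",
    "gen_mixture_spectrum",
    "gen_calibration_set",
    "gen_cocrystal_sample",
]


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band.

    amplitude is the peak absorbance contributed per μg·mL⁻¹ of analyte
    (AU·mL·μg⁻¹, 1 cm path).
    """

    center_nm: float
    sigma_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise DomainError("band width sigma must be > 0")
        if self.amplitude < 0:
            raise DomainError("band amplitude must be >= 0")


@dataclass(frozen=True)
class ComponentModel:
    """A named analyte: its band set and molar mass."""

    name: str
    bands: tuple[GaussianBand, ...]
    molar_mass_g_mol: float

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ParameterError(f"component {self.name!r} needs at least one band")
        if self.molar_mass_g_mol <= 0:
            raise DomainError("molar mass must be > 0")

    @property
    def principal_center_nm(self) -> float:
        """Centre of the strongest band (the zero-crossing wavelength
        donated to the other analyte for symmetric bands)."""
        return max(self.bands, key=lambda b: b.amplitude).center_nm

    def absorptivity(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """AU per μg·mL⁻¹ at each wavelength (sum over bands)."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        out = np.zeros_like(lam)
        for b in self.bands:
            out += b.amplitude * np.exp(-((lam - b.center_nm) ** 2) / (2 * b.sigma_nm**2))
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument imperfections.

    additive_sd : AU
        Per-point Gaussian photometric noise (0.002 AU default).
    baseline_offset, baseline_slope : AU, AU·nm⁻¹
        Linear baseline drift, referenced to the first grid point.
    seed : int
        Reproducibility contract: identical seed + parameters give
        identical output.
    """

    additive_sd: float = 0.002
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise DomainError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


QUIET = NoiseModel(additive_sd=0.0)


def default_grid(start_nm: float = 200.0, stop_nm: float = 400.0, step_nm: float = 1.0) -> np.ndarray:
    """The default 200–400 nm sweep at 1 nm resolution (201 points)."""
    return np.arange(start_nm, stop_nm + step_nm / 2, step_nm)


def default_asc_model() -> ComponentModel:
    """l-ascorbic acid: single band at 243 nm, sigma 15 nm."""
    return ComponentModel(
        "ASC", (GaussianBand(243.0, 15.0, 0.056),), molar_mass_g_mol=176.12
    )


def default_nic_model() -> ComponentModel:
    """Nicotinamide: single band at 261 nm, sigma 12 nm."""
    return ComponentModel(
        "NIC", (GaussianBand(261.0, 12.0, 0.037),), molar_mass_g_mol=122.12
    )


#: Serial standards 2–24 μg·mL⁻¹, both analytes co-varying (stock mixture).
DEFAULT_LEVELS: tuple[float, ...] = tuple(float(c) for c in range(2, 25, 2))


def _baseline(noise: NoiseModel, grid: np.ndarray) -> np.ndarray:
    return noise.baseline_offset + noise.baseline_slope * (grid - grid[0])


def gen_pure_spectrum(
    component: ComponentModel,
    conc: float,
    noise: NoiseModel = QUIET,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Beer–Lambert spectrum of one pure component at ``conc`` μg·mL⁻¹."""
    if conc < 0:
        raise DomainError(f"concentration must be >= 0, got {conc}")
    if grid is None:
        grid = default_grid()
    if rng is None:
        rng = noise.rng()
    a = conc * component.absorptivity(grid) + _baseline(noise, grid)
    if noise.additive_sd > 0:
        a = a + rng.normal(0.0, noise.additive_sd, grid.size)
    return Spectrum(grid, a, meta={"component": component.name, "true_conc_ug_ml": conc})


def gen_mixture_spectrum(
    conc_asc: float,
    conc_nic: float,
    models: tuple[ComponentModel, ComponentModel] | None = None,
    noise: NoiseModel = QUIET,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Additive two-component mixture spectrum.

    The noise-free mixture equals the sum of the noise-free pure spectra
    (Beer–Lambert additivity); the baseline is added once.
    """
    if conc_asc < 0 or conc_nic < 0:
        raise DomainError("concentrations must be >= 0")
    if models is None:
        models = (default_asc_model(), default_nic_model())
    asc, nic = models
    if grid is None:
        grid = default_grid()
    if rng is None:
        rng = noise.rng()
    a = conc_asc * asc.absorptivity(grid) + conc_nic * nic.absorptivity(grid)
    a = a + _baseline(noise, grid)
    if noise.additive_sd > 0:
        a = a + rng.normal(0.0, noise.additive_sd, grid.size)
    return Spectrum(
        grid, a,
        meta={
            "true_conc_asc_ug_ml": conc_asc,
            "true_conc_nic_ug_ml": conc_nic,
        },
    )


def gen_calibration_set(
    levels=DEFAULT_LEVELS,
    models: tuple[ComponentModel, ComponentModel] | None = None,
    noise: NoiseModel = QUIET,
    grid: np.ndarray | None = None,
) -> list[Spectrum]:
    """One mixture spectrum per calibration level, both analytes at the
    same concentration (serial dilutions of a mixed stock).

    Deterministic under a fixed ``noise.seed``: two calls with identical
    arguments return identical spectra.
    """
    levels = [float(c) for c in levels]
    if not levels:
        raise ParameterError("calibration levels must be non-empty")
    if any(c < 0 for c in levels):
        raise DomainError("calibration levels must be >= 0")
    rng = noise.rng()
    out = []
    for i, c in enumerate(levels):
        sp = gen_mixture_spectrum(c, c, models=models, noise=noise, grid=grid, rng=rng)
        meta = dict(sp.meta)
        meta["level_index"] = i
        out.append(Spectrum(sp.wavelengths_nm, sp.absorbance, meta=meta))
    return out


@dataclass(frozen=True)
class CocrystalTruth:
    """Ground truth for one simulated bulk cocrystal sample (mg, μg·mL⁻¹)."""

    m_collected_mg: float
    m_cocrystal_mg: float
    m_excess_mg: float
    excess_component: str
    m_asc_total_mg: float
    m_nic_total_mg: float
    conc_asc_ug_ml: float
    conc_nic_ug_ml: float
    dilution_ml: float
    secondary_dilution_factor: float


def gen_cocrystal_sample(
    m_collected_mg: float = 10.0,
    true_purity_frac: float = 1.0,
    excess_component: str = "ASC",
    models: tuple[ComponentModel, ComponentModel] | None = None,
    dilution_ml: float = 10.0,
    secondary_dilution_factor: float = 50.0,
    noise: NoiseModel = QUIET,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Spectrum, CocrystalTruth]:
    """Simulate dissolving a bulk powder of 1:1 cocrystal plus homocrystal
    excess and scanning the resulting solution.

    The bulk is decomposed as ``true_purity_frac`` cocrystal (equimolar
    ASC:NIC) and the remainder pure excess-component homocrystals; the
    component masses always sum to ``m_collected_mg``. The powder is
    dissolved in ``dilution_ml`` mL and diluted again by
    ``secondary_dilution_factor`` to land inside the calibration range
    (about 10 mg / 10 mL / 50× → ~20 μg·mL⁻¹ total).
    """
    if not 0.0 < true_purity_frac <= 1.0:
        raise DomainError(f"purity fraction must be in (0, 1], got {true_purity_frac}")
    if m_collected_mg <= 0:
        raise DomainError("collected mass must be > 0")
    if excess_component not in ("ASC", "NIC"):
        raise ParameterError("excess_component must be 'ASC' or 'NIC'")
    if models is None:
        models = (default_asc_model(), default_nic_model())
    asc, nic = models

    m_cc = true_purity_frac * m_collected_mg
    m_excess = m_collected_mg - m_cc
    n_cc_mmol = m_cc / (asc.molar_mass_g_mol + nic.molar_mass_g_mol)
    m_asc = n_cc_mmol * asc.molar_mass_g_mol + (m_excess if excess_component == "ASC" else 0.0)
    m_nic = n_cc_mmol * nic.molar_mass_g_mol + (m_excess if excess_component == "NIC" else 0.0)

    # mg in dilution_ml mL, then /factor -> μg·mL⁻¹ in the scanned cuvette
    conc_asc = m_asc / dilution_ml * 1000.0 / secondary_dilution_factor
    conc_nic = m_nic / dilution_ml * 1000.0 / secondary_dilution_factor

    sp = gen_mixture_spectrum(conc_asc, conc_nic, models=models, noise=noise, grid=grid, rng=rng)
    meta = dict(sp.meta)
    meta.update(true_purity_frac=true_purity_frac, m_collected_mg=m_collected_mg)
    sp = Spectrum(sp.wavelengths_nm, sp.absorbance, meta=meta)
    truth = CocrystalTruth(
        m_collected_mg=m_collected_mg,
        m_cocrystal_mg=m_cc,
        m_excess_mg=m_excess,
        excess_component=excess_component,
        m_asc_total_mg=m_asc,
        m_nic_total_mg=m_nic,
        conc_asc_ug_ml=conc_asc,
        conc_nic_ug_ml=conc_nic,
        dilution_ml=dilution_ml,
        secondary_dilution_factor=secondary_dilution_factor,
    )
    return sp, truth
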