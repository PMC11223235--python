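"""Mixture quantification, recovery and precision statistics.

A mixture spectrum is differentiated once and read at the two
zero-crossing wavelengths; each signed amplitude is inverted through the
corresponding calibration line, conc = (amplitude − b)/a. Results below
the LOQ or outside the calibrated range are flagged rather than silently
trusted, and negative concentrations are clamped to zero (with the raw
value retained) unless clamping is disabled.

Recovery statistics follow the conventions of pharmaceutical method
validation: plain recovery 100·found/theoretical, standard-addition
recovery 100·(total − base)/added, and intraday/interday precision as the
mean and sample standard deviation (n − 1) of recovery percentages. The
AOAC acceptance band for this concentration range is 95–105 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import CalibrationCurve
from .exceptions import DomainError, ParameterError
from .spectra import DerivParams, Spectrum, differentiate_with

__all__ = [
    "QuantResult",
    "RecoveryRecord",
    "PrecisionSummary",
    "quantify_mixture",
    "recovery",
    "standard_addition_recovery",
    "precision_summary",
]


@dataclass(frozen=True)
class QuantResult:
    """Recovered concentrations from one mixture spectrum (μg·mL⁻¹)."""

    conc_asc: float
    conc_nic: float
    amplitude_asc: float  # derivative amplitude at the ASC wavelength (AU·nm⁻¹)
    amplitude_nic: float
    curves_used: tuple[str, str]
    flags: tuple[str, ...] = ()
    raw_conc_asc: float = float("nan")
    raw_conc_nic: float = float("nan")


@dataclass(frozen=True)
class RecoveryRecord:
    """One validation measurement: theoretical vs found concentration."""

    analyte: str
    theoretical_conc: float
    found_conc: float

    @property
    def recovery_pct(self) -> float:
        return recovery(self.theoretical_conc, self.found_conc)


@dataclass(frozen=True)
class PrecisionSummary:
    mode: str  # "intraday" or "interday"
    mean_recovery_pct: float
    sd_pct: float
    n: int


def _invert(amplitude: float, curve: CalibrationCurve, analyte: str,
            clamp_negative: bool, flags: list[str]) -> tuple[float, float]:
    raw = (amplitude - curve.intercept_b) / curve.slope_a
    conc = raw
    if raw < 0:
        if clamp_negative:
            conc = 0.0
            flags.append(f"{analyte}:negative-clamped")
        else:
            flags.append(f"{analyte}:negative")
    if conc <= curve.loq:
        flags.append(f"{analyte}:below-LOQ")
    lo, hi = curve.conc_range
    if conc > hi:
        flags.append(f"{analyte}:extrapolated-above-range")
    elif conc < lo:
        flags.append(f"{analyte}:below-range")
    return conc, raw


def quantify_mixture(
    spectrum: Spectrum,
    curve_asc: CalibrationCurve,
    curve_nic: CalibrationCurve,
    deriv: DerivParams = DerivParams(),
    clamp_negative: bool = True,
) -> QuantResult:
    """Quantify ASC and NIC in one mixture spectrum.

    The calibration wavelengths must lie on the spectrum grid
    (:class:`GridError` otherwise). The same derivative settings must be
    used here as were used to build the calibration amplitudes; a mismatch
    silently biases both channels.
    """
    d = differentiate_with(spectrum, deriv, order=1)
    amp_asc = float(d.values[d.index_of(curve_asc.wavelength_nm)])
    amp_nic = float(d.values[d.index_of(curve_nic.wavelength_nm)])
    flags: list[str] = []
    conc_asc, raw_asc = _invert(amp_asc, curve_asc, curve_asc.analyte, clamp_negative, flags)
    conc_nic, raw_nic = _invert(amp_nic, curve_nic, curve_nic.analyte, clamp_negative, flags)
    return QuantResult(
        conc_asc=conc_asc,
        conc_nic=conc_nic,
        amplitude_asc=amp_asc,
        amplitude_nic=amp_nic,
        curves_used=(
            f"{curve_asc.analyte}@{curve_asc.wavelength_nm:g}nm",
            f"{curve_nic.analyte}@{curve_nic.wavelength_nm:g}nm",
        ),
        flags=tuple(flags),
        raw_conc_asc=raw_asc,
        raw_conc_nic=raw_nic,
    )


def recovery(theoretical: float, found: float) -> float:
    """Recovery percentage, 100·found/theoretical (theoretical > 0)."""
    if theoretical <= 0:
        raise DomainError(f"theoretical concentration must be > 0, got {theoretical}")
    return 100.0 * found / theoretical


def standard_addition_recovery(base_found: float, total_found: float, added: float) -> float:
    """Recovery of a spiked standard, 100·(total − base)/added."""
    if added <= 0:
        raise DomainError(f"added amount must be > 0, got {added}")
    return 100.0 * (total_found - base_found) / added


def precision_summary(
    records: Sequence[RecoveryRecord] | Sequence[float],
    mode: str = "intraday",
) -> PrecisionSummary:
    """Mean and sample standard deviation (ddof=1) of recovery percentages.

    Accepts :class:`RecoveryRecord` objects or bare recovery percentages;
    at least two records are required.
    """
    if mode not in ("intraday", "interday"):
        raise ParameterError(f"mode must be 'intraday' or 'interday', got {mode!r}")
    vals = np.asarray(
        [r.recovery_pct if isinstance(r, RecoveryRecord) else float(r) for r in records],
        dtype=float,
    )
    if vals.size < 2:
        raise ParameterError("precision summary needs >= 2 records")
    return PrecisionSummary(
        mode=mode,
        mean_recovery_pct=float(vals.mean()),
        sd_pct=float(vals.std(ddof=1)),
        n=int(vals.size),
    )
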