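"""Zero-crossing detection and derivative-amplitude calibration.

The zero-crossing trick: in a two-component mixture the first-derivative
absorbance at a wavelength where the *other* component's derivative is
zero at every concentration depends only on the analyte of interest. For
the ASC/NIC pair under acidic conditions the crossings fall at 261 nm
(NIC derivative zero — quantifies ASC, descending calibration) and 243 nm
(ASC derivative zero — quantifies NIC, ascending calibration).

Calibration regresses the signed derivative amplitude at the fixed
wavelength on concentration by ordinary least squares and reports the
standard diagnostics (R², slope standard error, residual SD, regression F
and p). Detection and quantification limits follow the ICH slope/standard
error form LOD = 3.3·SDa/|a| and LOQ = 10·SDa/|a| (multipliers
configurable).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .exceptions import (
    DegenerateDesignError,
    DomainError,
    GridError,
    NoCrossingError,
    ParameterError,
)
from .spectra import DerivParams, Spectrum, differentiate_with

__all__ = [
    "ZeroCrossing",
    "CalibrationCurve",
    "find_zero_crossing",
    "fit_calibration",
    "compute_lod_loq",
]


@dataclass(frozen=True)
class ZeroCrossing:
    """A wavelength at which the interfering component's first derivative
    is zero across its whole concentration series."""

    interfering_component: str
    wavelength_nm: int
    analyte_quantified: str
    #: worst |first derivative| of the interferer at the crossing over the
    #: tested series (AU·nm⁻¹); a quality metric, 0 for ideal data.
    max_residual_amplitude: float


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of derivative amplitude vs concentration at one wavelength.

    Signed amplitudes are used throughout, so a descending response (e.g.
    ASC at 261 nm) has a negative slope.
    """

    analyte: str
    wavelength_nm: float
    slope_a: float
    intercept_b: float
    r_squared: float
    sd_slope: float
    residual_sd: float
    f_stat: float
    p_value: float
    conc_range: tuple[float, float]
    lod: float
    loq: float
    n_levels: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conc_range"] = list(self.conc_range)
        return d


def find_zero_crossing(
    pure_series: Sequence[Spectrum],
    search_window: tuple[float, float] | None = None,
    deriv: DerivParams = DerivParams(),
    interfering: str | None = None,
    analyte: str | None = None,
) -> ZeroCrossing:
    """Locate the zero-crossing wavelength of one pure component.

    Parameters
    ----------
    pure_series
        Spectra of the *same* pure component at >= 2 concentrations.
    search_window
        (min_nm, max_nm) to restrict the search; defaults to the full
        interior of the scan.
    deriv
        Derivative operator settings (first order is used).
    interfering, analyte
        Names recorded on the result; ``interfering`` defaults to the
        series' ``component`` metadata.

    Returns the integer-nm grid point that minimises the worst
    |first derivative| across the series, among points where every
    concentration shows a strict sign change (derivative positive on one
    side and negative on the other). Grid edges and one-sided estimates
    are excluded.
    """
    if len(pure_series) < 2:
        raise ParameterError("need pure spectra at >= 2 concentrations")
    grid = pure_series[0].wavelengths_nm
    for s in pure_series[1:]:
        if not np.array_equal(s.wavelengths_nm, grid):
            raise GridError("all spectra in the series must share one grid")
    if interfering is None:
        interfering = str(pure_series[0].meta.get("component", "unknown"))

    derivs = [differentiate_with(s, deriv, order=1) for s in pure_series]
    vals = np.vstack([d.values for d in derivs])
    edge = np.any(np.vstack([d.edge_mask for d in derivs]), axis=0)

    lo, hi = search_window if search_window is not None else (grid[0], grid[-1])
    if lo >= hi or lo < grid[0] or hi > grid[-1]:
        raise ParameterError(f"search window ({lo}, {hi}) outside scan range")

    candidate = np.zeros(grid.size, dtype=bool)
    interior = slice(1, grid.size - 1)
    sign_change = np.all(vals[:, :-2] * vals[:, 2:] < 0, axis=0)
    candidate[interior] = sign_change
    candidate &= ~edge
    candidate[1:-1] &= ~edge[:-2] & ~edge[2:]
    candidate &= (grid >= lo) & (grid <= hi)
    # strictly inside the scan window
    candidate[0] = candidate[-1] = False

    if not candidate.any():
        raise NoCrossingError(
            f"no consistent derivative sign change of {interfering} in ({lo}, {hi}) nm"
        )

    score = np.max(np.abs(vals), axis=0)
    cand_idx = np.flatnonzero(candidate)
    best = score[cand_idx].min()
    ties = cand_idx[np.isclose(score[cand_idx], best, rtol=1e-12, atol=0.0)]
    if ties.size > 1:
        # tie-break: nearest to the interferer's absorbance maximum
        mean_abs = np.mean([s.absorbance for s in pure_series], axis=0)
        peak = grid[int(np.argmax(mean_abs))]
        ties = ties[np.argsort(np.abs(grid[ties] - peak), kind="stable")]
    j = int(ties[0])
    return ZeroCrossing(
        interfering_component=interfering,
        wavelength_nm=int(round(grid[j])),
        analyte_quantified=analyte if analyte is not None else "",
        max_residual_amplitude=float(score[j]),
    )


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    analyte: str,
    wavelength_nm: float,
    lod_multiplier: float = 3.3,
    loq_multiplier: float = 10.0,
) -> CalibrationCurve:
    """OLS fit ``amplitude = a·conc + b`` with full diagnostics.

    ``levels`` is a sequence of (concentration μg·mL⁻¹, signed derivative
    amplitude AU·nm⁻¹) pairs; at least 3 pairs with at least 3 distinct
    concentrations are required. On an exactly linear input the slope and
    intercept are recovered to machine precision, R² is 1 and the
    regression p-value is 0.
    """
    conc = np.asarray([c for c, _ in levels], dtype=float)
    amp = np.asarray([a for _, a in levels], dtype=float)
    if conc.size < 3:
        raise ParameterError(f"need >= 3 calibration levels, got {conc.size}")
    if np.unique(conc).size < 3:
        if np.unique(conc).size == 1:
            raise DegenerateDesignError("all calibration concentrations are identical")
        raise ParameterError("need >= 3 distinct concentrations")

    with np.errstate(divide="ignore", invalid="ignore"):
        model = sm.OLS(amp, sm.add_constant(conc)).fit()
        b, a = model.params
        sd_a = float(model.bse[1])
        resid_sd = float(np.sqrt(model.mse_resid))
        r2 = float(model.rsquared)
        f_stat, p_value = float(model.fvalue), float(model.f_pvalue)
    # perfect fits: statsmodels yields inf/nan from a zero residual sum
    if not np.isfinite(f_stat):
        f_stat, p_value = np.inf, 0.0
        r2 = 1.0
    if a == 0:
        # zero sensitivity: nothing is detectable at this wavelength
        lod, loq = np.inf, np.inf
    else:
        lod, loq = compute_lod_loq(float(a), sd_a, lod_multiplier, loq_multiplier)
    return CalibrationCurve(
        analyte=analyte,
        wavelength_nm=float(wavelength_nm),
        slope_a=float(a),
        intercept_b=float(b),
        r_squared=r2,
        sd_slope=sd_a,
        residual_sd=resid_sd,
        f_stat=f_stat,
        p_value=p_value,
        conc_range=(float(conc.min()), float(conc.max())),
        lod=lod,
        loq=loq,
        n_levels=int(conc.size),
    )


def compute_lod_loq(
    slope_a: float | CalibrationCurve,
    sd_slope: float | None = None,
    lod_multiplier: float = 3.3,
    loq_multiplier: float = 10.0,
) -> tuple[float, float]:
    """Detection and quantification limits from slope and its standard
    error: LOD = k_d·SDa/|a|, LOQ = k_q·SDa/|a| (ICH defaults 3.3, 10, so
    LOQ/LOD = 10/3.3 whenever SDa > 0)."""
    if isinstance(slope_a, CalibrationCurve):
        curve = slope_a
        slope_a, sd_slope = curve.slope_a, curve.sd_slope
    if sd_slope is None:
        raise ParameterError("sd_slope is required when passing a bare slope")
    if slope_a == 0:
        raise DomainError("calibration slope is zero; LOD/LOQ undefined")
    if sd_slope < 0:
        raise DomainError("slope standard error must be >= 0")
    lod = lod_multiplier * sd_slope / abs(slope_a)
    loq = loq_multiplier * sd_slope / abs(slope_a)
    return float(lod), float(loq)
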