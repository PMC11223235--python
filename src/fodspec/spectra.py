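"""Spectrum data model, CSV I/O and wavelength-derivative operators.

A :class:`Spectrum` is a pair of arrays — a strictly ascending, uniformly
spaced wavelength grid (nm) and absorbance values (AU) — plus free-form
metadata. The default acquisition window is a 200–400 nm sweep on a 1 nm
grid, the usual setup for two-component UV work in the ASC/NIC region.

Derivatives with respect to wavelength are the core primitive of the
zero-crossing method: :func:`differentiate` supports plain central finite
differences (parameter-free, exact for polynomials of degree <= 2 on the
interior) and Savitzky–Golay convolution (least-squares polynomial
smoothing, the standard choice for noisy spectra). Grid endpoints are
estimated one-sidedly and flagged via ``edge_mask`` so downstream searches
can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import GridError, ParameterError, SpectrumFormatError

__all__ = [
    "Spectrum",
    "DerivativeSpectrum",
    "DerivParams",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_derivative_csv",
    "write_derivative_csv",
    "differentiate",
]

_GRID_RTOL = 1e-8


def _validate_grid(wavelengths: np.ndarray) -> float:
    """Check the grid contract and return the (uniform) spacing."""
    if wavelengths.ndim != 1 or wavelengths.size < 3:
        raise GridError("wavelength grid must be 1-D with at least 3 points")
    if not np.all(np.isfinite(wavelengths)):
        raise GridError("wavelength grid contains non-finite values")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise GridError("wavelengths must be strictly ascending")
    spacing = float(steps[0])
    if not np.allclose(steps, spacing, rtol=_GRID_RTOL, atol=spacing * _GRID_RTOL):
        raise GridError(
            "non-uniform wavelength grid (max step %.6g, min step %.6g)"
            % (steps.max(), steps.min())
        )
    return spacing


def _freeze(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float).copy()
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A zero-order absorbance spectrum on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly ascending, uniformly spaced wavelengths in nm (>= 3 points).
    absorbance : array-like
        Absorbance values (AU), same length as the grid, all finite.
    meta : dict
        Free-form provenance (sample id, true concentrations, ...).
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = _freeze(self.wavelengths_nm)
        a = _freeze(self.absorbance)
        _validate_grid(w)
        if a.shape != w.shape:
            raise SpectrumFormatError(
                f"wavelengths ({w.size}) and absorbance ({a.size}) differ in length"
            )
        if not np.all(np.isfinite(a)):
            raise SpectrumFormatError("absorbance contains non-finite values")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "absorbance", a)

    @property
    def spacing_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an on-grid wavelength; :class:`GridError` if off-grid."""
        idx = int(round((wavelength_nm - self.wavelengths_nm[0]) / self.spacing_nm))
        if idx < 0 or idx >= self.wavelengths_nm.size or not np.isclose(
            self.wavelengths_nm[idx], wavelength_nm, rtol=0, atol=1e-6
        ):
            raise GridError(f"wavelength {wavelength_nm} nm is not on the grid")
        return idx

    def __eq__(self, other) -> bool:  # value semantics, meta included
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.absorbance, other.absorbance)
            and self.meta == other.meta
        )


@dataclass(frozen=True)
class DerivativeSpectrum:
    """An order-n derivative of absorbance with respect to wavelength.

    ``values`` carries AU·nm^-order. ``edge_mask`` is True where the
    estimate used a one-sided or partial window (grid edges); such points
    are excluded from zero-crossing searches.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    order: int
    method: str
    edge_mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = _freeze(self.wavelengths_nm)
        v = _freeze(self.values)
        _validate_grid(w)
        if self.order < 1:
            raise ParameterError("derivative order must be >= 1")
        if v.shape != w.shape:
            raise SpectrumFormatError("wavelengths and values differ in length")
        if self.edge_mask is None:
            mask = np.zeros(w.size, dtype=bool)
        else:
            mask = np.asarray(self.edge_mask, dtype=bool).copy()
        mask.flags.writeable = False
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "edge_mask", mask)

    @property
    def spacing_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def index_of(self, wavelength_nm: float) -> int:
        return Spectrum.index_of(self, wavelength_nm)  # same grid contract

    def __eq__(self, other) -> bool:
        if not isinstance(other, DerivativeSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.values, other.values)
            and self.order == other.order
            and self.method == other.method
            and np.array_equal(self.edge_mask, other.edge_mask)
            and self.meta == other.meta
        )


@dataclass(frozen=True)
class DerivParams:
    """Derivative operator settings shared across pipeline stages.

    method : {"central_diff", "savitzky_golay"}
    window, polyorder : Savitzky–Golay settings (ignored by central_diff).
    """

    method: str = "central_diff"
    window: int = 5
    polyorder: int = 2


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _format_meta(meta: Mapping) -> list[str]:
    return [f"# {k}: {v}" for k, v in meta.items()]


def _parse_rows(path: Path):
    """Parse a comment-prefixed CSV into (meta, header-or-None, rows)."""
    meta: dict = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            cells = [c.strip() for c in s.split(",")]
            if header is None and rows == []:
                try:
                    float(cells[0])
                except ValueError:
                    header = cells
                    continue
            rows.append((lineno, cells))
    if not rows:
        raise SpectrumFormatError(f"{path}: no data rows found")
    return meta, header, rows


def read_spectrum_csv(
    path,
    wavelength_col: str = "wavelength_nm",
    absorbance_col: str = "absorbance",
    resolution_nm: float | None = None,
    resample: bool = False,
) -> Spectrum:
    """Read a spectrum from a ``wavelength_nm,absorbance`` CSV.

    ``#``-prefixed ``key: value`` lines are collected into ``meta``. A
    header row is optional; when present, ``wavelength_col`` and
    ``absorbance_col`` select the columns. Rows are sorted by wavelength;
    duplicate wavelengths are rejected. A non-uniform grid raises
    :class:`GridError` unless ``resample=True``, which linearly
    interpolates onto a uniform grid with the median spacing.

    When ``resolution_nm=1`` is declared, wavelengths are additionally
    validated to be integer nanometres.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, header, rows = _parse_rows(path)
    if header is not None:
        try:
            iw = header.index(wavelength_col)
            ia = header.index(absorbance_col)
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{path}: missing column {exc.args[0].split()[0]!r} in header {header}"
            ) from None
    else:
        iw, ia = 0, 1
    w, a = [], []
    for lineno, cells in rows:
        try:
            w.append(float(cells[iw]))
            a.append(float(cells[ia]))
        except (ValueError, IndexError):
            raise SpectrumFormatError(
                f"{path}: non-numeric or missing value at row {lineno}: {','.join(cells)}"
            ) from None
    w_arr = np.array(w)
    a_arr = np.array(a)
    order = np.argsort(w_arr, kind="stable")
    w_arr, a_arr = w_arr[order], a_arr[order]
    if np.any(np.diff(w_arr) == 0):
        dup = w_arr[np.flatnonzero(np.diff(w_arr) == 0)[0]]
        raise SpectrumFormatError(f"{path}: duplicate wavelength {dup} nm")
    if resample:
        spacing = float(np.min(np.diff(w_arr)))
        grid = np.arange(w_arr[0], w_arr[-1] + spacing / 2, spacing)
        a_arr = np.interp(grid, w_arr, a_arr)
        w_arr = grid
    if resolution_nm == 1 and not np.allclose(w_arr, np.round(w_arr), atol=1e-6):
        raise GridError(f"{path}: declared 1 nm resolution but wavelengths are not integer nm")
    return Spectrum(w_arr, a_arr, meta=meta)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as CSV with full float precision.

    Metadata is preserved as ``# key: value`` comment lines, so
    ``read(write(s))`` round-trips values bit-identically and meta as
    strings.
    """
    path = Path(path)
    lines = _format_meta(spectrum.meta)
    lines.append("wavelength_nm,absorbance")
    for w, a in zip(spectrum.wavelengths_nm, spectrum.absorbance):
        lines.append(f"{float(w)!r},{float(a)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_derivative_csv(deriv: DerivativeSpectrum, path) -> None:
    """Write a derivative spectrum; the one-sided edge flag is a column."""
    path = Path(path)
    meta = dict(deriv.meta)
    meta["derivative_order"] = deriv.order
    meta["derivative_method"] = deriv.method
    lines = _format_meta(meta)
    lines.append("wavelength_nm,derivative,edge")
    for w, v, e in zip(deriv.wavelengths_nm, deriv.values, deriv.edge_mask):
        lines.append(f"{float(w)!r},{float(v)!r},{int(e)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_derivative_csv(path) -> DerivativeSpectrum:
    path = Path(path)
    meta, header, rows = _parse_rows(path)
    order = int(meta.pop("derivative_order", 1))
    method = str(meta.pop("derivative_method", "unknown"))
    w, v, e = [], [], []
    for lineno, cells in rows:
        try:
            w.append(float(cells[0]))
            v.append(float(cells[1]))
            e.append(bool(int(cells[2])) if len(cells) > 2 else False)
        except (ValueError, IndexError):
            raise SpectrumFormatError(
                f"{path}: non-numeric or missing value at row {lineno}"
            ) from None
    return DerivativeSpectrum(
        np.array(w), np.array(v), order=order, method=method,
        edge_mask=np.array(e, dtype=bool), meta=meta,
    )


# ---------------------------------------------------------------------------
# Derivative operators
# ---------------------------------------------------------------------------

def differentiate(
    spectrum: Spectrum | DerivativeSpectrum,
    order: int = 1,
    method: str = "central_diff",
    window: int = 5,
    polyorder: int = 2,
) -> DerivativeSpectrum:
    """Differentiate a spectrum ``order`` times with respect to wavelength.

    Parameters
    ----------
    spectrum
        A :class:`Spectrum`, or a :class:`DerivativeSpectrum` to be
        differentiated further (orders accumulate).
    order : int
        Number of additional derivative orders to apply; total order must
        stay within 1–3.
    method : {"central_diff", "savitzky_golay"}
        ``central_diff`` applies the three-point central difference
        ``order`` times (one-sided at the two edges, which are flagged), so
        repeated order-1 calls and one order-n call agree identically.
        ``savitzky_golay`` performs local least-squares polynomial
        differentiation (``window`` odd, ``window > polyorder >= order``);
        the ``window // 2`` points at each edge use scipy's interpolating
        edge mode and are flagged.

    Returns
    -------
    DerivativeSpectrum in AU·nm^-order.
    """
    if isinstance(spectrum, DerivativeSpectrum):
        y = spectrum.values
        base_order = spectrum.order
        base_mask = spectrum.edge_mask.copy()
    else:
        y = spectrum.absorbance
        base_order = 0
        base_mask = np.zeros(y.size, dtype=bool)
    total_order = base_order + order
    if order < 1 or total_order > 3:
        raise ParameterError(f"total derivative order {total_order} outside 1–3")
    spacing = _validate_grid(np.asarray(spectrum.wavelengths_nm))

    if method == "central_diff":
        vals = np.asarray(y, dtype=float)
        for _ in range(order):
            vals = np.gradient(vals, spacing, edge_order=1)
        edge = order
    elif method in ("savitzky_golay", "savgol"):
        if window % 2 == 0:
            raise ParameterError(f"savitzky_golay window must be odd, got {window}")
        if not (window > polyorder >= order):
            raise ParameterError(
                f"require window > polyorder >= order, got {window}, {polyorder}, {order}"
            )
        if window > y.size:
            raise ParameterError("smoothing window exceeds spectrum length")
        vals = savgol_filter(
            np.asarray(y, dtype=float), window, polyorder, deriv=order,
            delta=spacing, mode="interp",
        )
        edge = window // 2
    else:
        raise ParameterError(f"unknown derivative method {method!r}")

    mask = base_mask
    mask[:edge] = True
    mask[-edge:] = True
    meta = dict(getattr(spectrum, "meta", {}))
    return DerivativeSpectrum(
        spectrum.wavelengths_nm, vals, order=total_order, method=method,
        edge_mask=mask, meta=meta,
    )


def differentiate_with(spectrum, params: DerivParams, order: int = 1) -> DerivativeSpectrum:
    """Convenience wrapper applying a :class:`DerivParams` bundle."""
    return differentiate(
        spectrum, order=order, method=params.method,
        window=params.window, polyorder=params.polyorder,
    )
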