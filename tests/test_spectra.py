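"""Spectrum container, CSV round trips and derivative operators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fodspec.exceptions import GridError, ParameterError, SpectrumFormatError
from fodspec.spectra import (
    DerivParams,
    Spectrum,
    differentiate,
    differentiate_with,
    read_derivative_csv,
    read_spectrum_csv,
    write_derivative_csv,
    write_spectrum_csv,
)


def make_spectrum(values, start=200.0, meta=None):
    w = start + np.arange(len(values), dtype=float)
    return Spectrum(w, np.asarray(values, dtype=float), meta=meta or {})


class TestSpectrumInvariants:
    def test_rejects_non_uniform_grid(self):
        with pytest.raises(GridError):
            Spectrum([200.0, 201.0, 203.0], [0.0, 0.0, 0.0])

    def test_rejects_descending_grid(self):
        with pytest.raises(GridError):
            Spectrum([203.0, 202.0, 201.0], [0.0, 0.0, 0.0])

    def test_rejects_length_mismatch_and_nonfinite(self):
        with pytest.raises(SpectrumFormatError):
            Spectrum([200.0, 201.0, 202.0], [0.0, 0.0])
        with pytest.raises(SpectrumFormatError):
            Spectrum([200.0, 201.0, 202.0], [0.0, np.nan, 0.0])

    def test_rejects_too_short(self):
        with pytest.raises(GridError):
            Spectrum([200.0, 201.0], [0.0, 0.0])

    def test_index_of_off_grid(self):
        s = make_spectrum(np.zeros(5))
        assert s.index_of(202.0) == 2
        with pytest.raises(GridError):
            s.index_of(202.5)


class TestCsvIO:
    def test_zero_spectrum_round_trip(self, tmp_path):
        s = make_spectrum(np.zeros(201))
        path = tmp_path / "zero.csv"
        write_spectrum_csv(s, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "wavelength_nm,absorbance"
        assert len(lines) == 202  # header + 201 data rows
        assert read_spectrum_csv(path) == s

    def test_round_trip_bit_identical_with_meta(self, tmp_path):
        rng = np.random.default_rng(3)
        s = make_spectrum(rng.normal(size=64) * 0.37, meta={"sample": "mix1"})
        path = tmp_path / "s.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path)
        assert np.array_equal(back.absorbance, s.absorbance)
        assert np.array_equal(back.wavelengths_nm, s.wavelengths_nm)
        assert back.meta == {"sample": "mix1"}

    def test_rows_sorted_and_headerless_accepted(self, tmp_path):
        path = tmp_path / "rev.csv"
        path.write_text("202,0.3\n200,0.1\n201,0.2\n")
        s = read_spectrum_csv(path)
        assert np.array_equal(s.wavelengths_nm, [200.0, 201.0, 202.0])
        assert np.array_equal(s.absorbance, [0.1, 0.2, 0.3])

    def test_non_uniform_file_raises_unless_resampled(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("wavelength_nm,absorbance\n200,0\n201,1\n203,3\n")
        with pytest.raises(GridError):
            read_spectrum_csv(path)
        s = read_spectrum_csv(path, resample=True)
        assert np.array_equal(s.wavelengths_nm, [200.0, 201.0, 202.0, 203.0])

    def test_bad_row_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,absorbance\n200,0.0\n201,oops\n")
        with pytest.raises(SpectrumFormatError, match="row 3"):
            read_spectrum_csv(path)

    def test_duplicate_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("200,0\n200,1\n201,0\n")
        with pytest.raises(SpectrumFormatError, match="duplicate"):
            read_spectrum_csv(path)

    def test_dialect_column_mapping(self, tmp_path):
        path = tmp_path / "alt.csv"
        path.write_text("lambda,extra,A\n200,9,0.1\n201,9,0.2\n202,9,0.3\n")
        s = read_spectrum_csv(path, wavelength_col="lambda", absorbance_col="A")
        assert np.array_equal(s.absorbance, [0.1, 0.2, 0.3])

    def test_integer_nm_validation(self, tmp_path):
        path = tmp_path / "frac.csv"
        path.write_text("200.5,0\n201.5,1\n202.5,2\n")
        read_spectrum_csv(path)  # fine without a declared resolution
        with pytest.raises(GridError):
            read_spectrum_csv(path, resolution_nm=1)

    def test_derivative_round_trip_preserves_edge_flags(self, tmp_path):
        s = make_spectrum(np.sin(np.linspace(0, 3, 31)))
        d = differentiate(s, method="savitzky_golay", window=7, polyorder=2)
        path = tmp_path / "d.csv"
        write_derivative_csv(d, path)
        back = read_derivative_csv(path)
        assert back.order == 1 and back.method == "savitzky_golay"
        assert np.array_equal(back.edge_mask, d.edge_mask)
        assert np.array_equal(back.values, d.values)


@pytest.mark.parametrize("method", ["central_diff", "savitzky_golay"])
class TestDifferentiate:
    def test_constant_spectrum_has_zero_derivative(self, method):
        s = make_spectrum(np.full(51, 0.5))
        d = differentiate(s, method=method)
        assert np.allclose(d.values, 0.0, atol=1e-14)

    def test_ramp_derivative_is_slope(self, method):
        w = np.arange(200.0, 401.0)
        s = Spectrum(w, 0.01 * (w - 200.0))
        d = differentiate(s, method=method)
        interior = ~d.edge_mask
        assert np.allclose(d.values[interior], 0.01, atol=1e-12)

    def test_gaussian_matches_closed_form(self, method):
        w = np.arange(200.0, 401.0)
        a = np.exp(-((w - 243.0) ** 2) / (2 * 9.0**2))
        s = Spectrum(w, a)
        d = differentiate(s, method=method, window=5, polyorder=3)
        expected = -((w - 243.0) / 81.0) * a
        interior = ~d.edge_mask
        assert np.max(np.abs(d.values[interior] - expected[interior])) < 1e-3

    def test_single_peak_sign_change_at_maximum(self, method):
        w = np.arange(200.0, 401.0)
        a = 0.8 * np.exp(-((w - 261.0) ** 2) / (2 * 12.0**2))
        d = differentiate(Spectrum(w, a), method=method)
        interior = np.flatnonzero(~d.edge_mask)
        vals = d.values[interior]
        # band symmetry puts a (numerical) zero on-grid at the maximum
        nz = np.flatnonzero(np.abs(vals) > 1e-12 * np.abs(vals).max())
        signs = np.sign(vals[nz])
        flips = np.flatnonzero(np.diff(signs) != 0)
        assert flips.size == 1
        # the sign change brackets the band maximum at 261 nm
        assert w[interior][nz[flips[0]]] == 260.0
        assert w[interior][nz[flips[0] + 1]] == 262.0


class TestDifferentiateContracts:
    def test_parameter_validation(self):
        s = make_spectrum(np.zeros(21))
        with pytest.raises(ParameterError):
            differentiate(s, method="savitzky_golay", window=6)
        with pytest.raises(ParameterError):
            differentiate(s, order=2, method="savitzky_golay", window=5, polyorder=1)
        with pytest.raises(ParameterError):
            differentiate(s, order=4)
        with pytest.raises(ParameterError):
            differentiate(s, method="no_such_operator")

    def test_repeated_first_order_equals_single_second_order(self):
        rng = np.random.default_rng(0)
        s = make_spectrum(rng.normal(size=41))
        twice = differentiate(differentiate(s))
        once = differentiate(s, order=2)
        assert twice.order == once.order == 2
        assert np.allclose(twice.values, once.values, atol=1e-12)

    def test_central_diff_exact_for_quadratics(self):
        w = np.arange(200.0, 241.0)
        s = Spectrum(w, 0.003 * w**2 - 1.1 * w + 4.0)
        d = differentiate(s, method="central_diff")
        interior = ~d.edge_mask
        assert np.allclose(d.values[interior], (0.006 * w - 1.1)[interior], atol=1e-9)

    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        seed=st.integers(0, 2**16),
        method=st.sampled_from(["central_diff", "savitzky_golay"]),
    )
    def test_linearity(self, a, b, seed, method):
        rng = np.random.default_rng(seed)
        y1, y2 = rng.normal(size=(2, 33))
        s1, s2 = make_spectrum(y1), make_spectrum(y2)
        combo = make_spectrum(a * y1 + b * y2)
        d = differentiate(combo, method=method)
        d1 = differentiate(s1, method=method)
        d2 = differentiate(s2, method=method)
        assert np.allclose(d.values, a * d1.values + b * d2.values,
                           rtol=1e-9, atol=1e-9)

    def test_units_metadata_carried(self):
        s = make_spectrum(np.zeros(11), meta={"sample": "x"})
        d = differentiate_with(s, DerivParams("savitzky_golay", 5, 2))
        assert d.meta["sample"] == "x"
        assert d.edge_mask[:2].all() and d.edge_mask[-2:].all()
        assert not d.edge_mask[2:-2].any()
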