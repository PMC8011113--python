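"""Spectra data model: CSV I/O, masking, derivatives, LWC formula."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatlwc import (
    BandMask,
    WavelengthGrid,
    apply_atmospheric_mask,
    first_derivative,
    lwc_from_mass,
    read_spectra_csv,
    write_spectra_csv,
)
from wheatlwc.errors import (
    DegenerateInputError,
    DomainError,
    MissingBandError,
    SpectraFormatError,
    SpectraValidationError,
)

from conftest import make_spectra


class TestCsvRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(0)
        s = make_spectra(rng.uniform(0, 1, (3, 5)), [400, 401, 402, 403, 404], lwc=[70, 75, 80])
        path = write_spectra_csv(s, tmp_path / "s.csv")
        back = read_spectra_csv(path)
        np.testing.assert_allclose(back.reflectance, s.reflectance, atol=1e-9)
        assert [m.sample_id for m in back.meta] == [m.sample_id for m in s.meta]
        assert [m.treatment for m in back.meta] == [m.treatment for m in s.meta]
        np.testing.assert_allclose(back.lwc, s.lwc)

    def test_percent_scale_converts_on_both_ends(self, tmp_path):
        s = make_spectra([[0.4345, 0.3227]], [820, 970], lwc=[80])
        path = write_spectra_csv(s, tmp_path / "pct.csv", reflectance_scale="percent")
        text = path.read_text()
        assert "43.45" in text and "32.27" in text
        back = read_spectra_csv(path, reflectance_scale="percent")
        np.testing.assert_allclose(back.reflectance, [[0.4345, 0.3227]], atol=1e-12)

    def test_shuffled_wavelength_columns_sort_on_read(self, tmp_path):
        s = make_spectra([[0.1, 0.2, 0.3]], [350, 351, 352], lwc=[80])
        path = write_spectra_csv(s, tmp_path / "a.csv")
        lines = path.read_text().splitlines()
        header = lines[0].split(",")
        row = lines[1].split(",")
        order = [0, 1, 2, 3, 4, 5, 8, 6, 7]  # move wl_352 before wl_350
        shuffled = tmp_path / "b.csv"
        shuffled.write_text(
            ",".join(header[i] for i in order) + "\n" + ",".join(row[i] for i in order) + "\n"
        )
        back = read_spectra_csv(shuffled)
        np.testing.assert_array_equal(back.grid.wavelengths, [350, 351, 352])
        np.testing.assert_allclose(back.reflectance, s.reflectance)

    def test_out_of_range_reflectance_names_the_cell(self, tmp_path):
        s = make_spectra([[0.5, 0.5]], [400, 401], lwc=[80])
        path = write_spectra_csv(s, tmp_path / "bad.csv")
        text = path.read_text().replace("0.5,0.5", "1.7,0.5")
        bad = tmp_path / "bad2.csv"
        bad.write_text(text)
        with pytest.raises(SpectraValidationError, match="wl_400"):
            read_spectra_csv(bad)

    def test_duplicated_column_is_a_format_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "sample_id,year,cultivar,treatment,date_index,lwc,wl_400,wl_400\n"
            "a,2018-2019,1,w0,1,80,0.5,0.5\n"
        )
        with pytest.raises(SpectraFormatError, match="duplicated"):
            read_spectra_csv(p)

    def test_missing_metadata_column_is_a_format_error(self, tmp_path):
        p = tmp_path / "miss.csv"
        p.write_text("sample_id,year,cultivar,treatment,date_index,wl_400\na,2018-2019,1,w0,1,0.5\n")
        with pytest.raises(SpectraFormatError, match="lwc"):
            read_spectra_csv(p)

    def test_empty_set_round_trips(self, tmp_path):
        s = make_spectra(np.empty((0, 2)), [400, 401])
        path = write_spectra_csv(s, tmp_path / "empty.csv")
        back = read_spectra_csv(path)
        assert back.n_samples == 0
        assert len(back.grid) == 2


class TestAtmosphericMask:
    def test_default_mask_retains_1901_bands(self):
        s = make_spectra(np.full((1, 2151), 0.5), WavelengthGrid.default().wavelengths)
        masked = apply_atmospheric_mask(s, BandMask.default())
        assert len(masked.grid) == 1901

    def test_mask_is_idempotent_and_preserves_values(self):
        rng = np.random.default_rng(1)
        s = make_spectra(rng.uniform(0, 1, (2, 2151)), WavelengthGrid.default().wavelengths)
        once = apply_atmospheric_mask(s)
        twice = apply_atmospheric_mask(once)
        np.testing.assert_array_equal(once.grid.wavelengths, twice.grid.wavelengths)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)
        for wl in (820, 1350, 1401, 2450):  # lower endpoints retained
            np.testing.assert_array_equal(once.band(wl), s.band(wl))

    def test_empty_mask_is_identity(self):
        s = make_spectra(np.full((1, 2151), 0.5), WavelengthGrid.default().wavelengths)
        masked = apply_atmospheric_mask(s, BandMask.empty())
        assert len(masked.grid) == 2151

    def test_mask_covering_everything_errors(self):
        s = make_spectra(np.full((1, 100), 0.5), np.arange(400, 500))
        with pytest.raises(DegenerateInputError):
            apply_atmospheric_mask(s, BandMask(((350, 2500),)))

    def test_original_object_is_unmodified(self):
        s = make_spectra(np.full((1, 2151), 0.5), WavelengthGrid.default().wavelengths)
        apply_atmospheric_mask(s)
        assert len(s.grid) == 2151


class TestLwcFromMass:
    @pytest.mark.parametrize(
        "fresh,dry,expected", [(5.00, 1.06, 78.8), (2.0, 0.5, 75.0), (3.0, 3.0, 0.0)]
    )
    def test_direct_formula(self, fresh, dry, expected):
        assert lwc_from_mass(fresh, dry) == pytest.approx(expected)

    @pytest.mark.parametrize("fresh,dry", [(1.0, 2.0), (0.0, 0.0), (-1.0, 0.5), (1.0, -0.5)])
    def test_domain_errors(self, fresh, dry):
        with pytest.raises(DomainError):
            lwc_from_mass(fresh, dry)

    @given(
        fresh=st.floats(0.1, 100),
        d1=st.floats(0.01, 1.0, exclude_max=True),
        d2=st.floats(0.01, 1.0, exclude_max=True),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_decreasing_in_dry_mass(self, fresh, d1, d2):
        lo, hi = sorted((d1 * fresh, d2 * fresh))
        if lo < hi:
            assert lwc_from_mass(fresh, lo) > lwc_from_mass(fresh, hi)


class TestFirstDerivative:
    def test_constant_spectrum_has_zero_derivative(self):
        s = make_spectra(np.full((2, 50), 0.4), np.arange(700, 750))
        d = first_derivative(s)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-15)

    def test_linear_ramp_recovers_slope(self):
        wl = np.arange(700, 760)
        a = 1e-3
        s = make_spectra((a * (wl - 700) + 0.1)[None, :], wl)
        d = first_derivative(s)
        np.testing.assert_allclose(d.values[0, 1:-1], a, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        wl = np.arange(350, 2501)
        r = 0.5 + 0.4 * np.sin(wl / 100.0)
        s = make_spectra(r[None, :], wl)
        d = first_derivative(s)
        analytic = 0.4 * np.cos(wl / 100.0) / 100.0
        assert np.nanmax(np.abs(d.values[0, 1:-1] - analytic[1:-1])) < 1e-4

    def test_masked_gap_breaks_segments(self):
        s = make_spectra(np.full((1, 2151), 0.5), WavelengthGrid.default().wavelengths)
        masked = apply_atmospheric_mask(s)
        d = first_derivative(masked)
        # the gap neighbours use one-sided differences within their own segment
        assert np.isfinite(d.band(1350)).all()
        with pytest.raises(MissingBandError):
            d.band(1380)  # inside the excluded window


class TestWavelengthGrid:
    def test_exact_lookup_only(self):
        g = WavelengthGrid(np.array([400, 402, 404]))
        assert g.index_of(402) == 1
        with pytest.raises(MissingBandError):
            g.index_of(403)

    def test_segments_split_at_mask_gaps(self):
        g = WavelengthGrid(np.array([400, 401, 402, 500, 501]))
        segs = g.segments()
        assert [(s.start, s.stop) for s in segs] == [(0, 3), (3, 5)]

    @pytest.mark.parametrize("wl", [[500, 500], [500, 499], [300, 400], [2400, 2501]])
    def test_invalid_grids_rejected(self, wl):
        with pytest.raises(DomainError):
            WavelengthGrid(np.array(wl))
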