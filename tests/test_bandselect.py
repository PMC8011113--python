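"""Characteristic-band screening: correlation extrema and PLS loading weights."""

import numpy as np
import pytest

from wheatlwc import (
    WavelengthGrid,
    correlation_curve,
    fit_pls_loadings,
    local_extrema,
    select_bands_ca,
    select_bands_xlw,
)
from wheatlwc.bandselect import CorrelationCurve, best_n_components
from wheatlwc.errors import DomainError, InsufficientDataError

from conftest import make_spectra


class TestCorrelationCurve:
    def test_affine_band_gives_unit_correlation(self):
        lwc = np.array([60.0, 70, 80, 90])
        refl = np.column_stack([0.002 * lwc + 0.1, -0.002 * lwc + 0.5, np.full(4, 0.3)])
        s = make_spectra(refl, [800, 900, 1000], lwc=lwc)
        curve = correlation_curve(s, lwc)
        assert curve.r[0] == pytest.approx(1.0)
        assert curve.r[1] == pytest.approx(-1.0)
        assert np.isnan(curve.r[2])  # zero-variance band is flagged missing

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(11)
        refl = rng.uniform(0.1, 0.9, (15, 4))
        lwc = rng.uniform(55, 90, 15)
        s = make_spectra(refl, [700, 800, 900, 1000], lwc=lwc)
        curve = correlation_curve(s, lwc)
        for j in range(4):
            expected = np.corrcoef(refl[:, j], lwc)[0, 1]
            assert curve.r[j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples(self):
        s = make_spectra([[0.1], [0.2]], [800], lwc=[70, 75])
        with pytest.raises(InsufficientDataError):
            correlation_curve(s, np.array([70.0, 75.0]))


class TestLocalExtrema:
    def test_canonical_peak(self):
        peaks, troughs = local_extrema(np.array([0.0, 1.0, 0.0]), window=1)
        assert peaks.tolist() == [1]
        assert troughs.tolist() == []

    def test_monotone_vector_has_no_interior_extrema(self):
        peaks, troughs = local_extrema(np.arange(10.0), window=2)
        assert peaks.size == 0 and troughs.size == 0

    def test_plateau_reports_leftmost_index(self):
        peaks, _ = local_extrema(np.array([0.0, 1.0, 1.0, 1.0, 0.0]), window=1)
        assert peaks.tolist() == [1]

    def test_two_gaussians_on_a_trend(self):
        x = np.linspace(0, 1, 300)
        f = (
            np.exp(-0.5 * ((x - 0.3) / 0.05) ** 2)
            + 0.8 * np.exp(-0.5 * ((x - 0.7) / 0.05) ** 2)
            + 0.1 * x
        )
        analytic = [int(np.argmin(np.abs(x - 0.3))), int(np.argmin(np.abs(x - 0.7)))]
        peaks, _ = local_extrema(f, window=10)
        assert len(peaks) == 2
        for found, want in zip(sorted(peaks), analytic):
            assert abs(found - want) <= 1

    def test_segments_are_independent(self):
        # a ramp up then down would peak at the junction; a segment break
        # there must suppress it
        v = np.concatenate([np.arange(5.0), np.arange(5.0)[::-1]])
        peaks, _ = local_extrema(v, window=2)
        assert 4 in peaks or 5 in peaks
        peaks_split, _ = local_extrema(v, window=2, segments=[slice(0, 5), slice(5, 10)])
        assert peaks_split.size == 0

    def test_shift_invariance_and_negation_duality(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=120)
        p1, t1 = local_extrema(v, window=4)
        p2, t2 = local_extrema(v + 17.0, window=4)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(t1, t2)
        p3, t3 = local_extrema(-v, window=4)
        np.testing.assert_array_equal(p1, t3)
        np.testing.assert_array_equal(t1, p3)


class TestSelectBandsCA:
    def test_exact_seed_count_returns_the_seeds(self):
        wl = np.arange(400, 700)
        r = (
            0.9 * np.exp(-0.5 * ((wl - 450) / 8.0) ** 2)
            - 0.8 * np.exp(-0.5 * ((wl - 550) / 8.0) ** 2)
            + 0.7 * np.exp(-0.5 * ((wl - 650) / 8.0) ** 2)
        )
        curve = CorrelationCurve(grid=WavelengthGrid(wl), r=r)
        sel = select_bands_ca(curve, n_target=3, window=10)
        assert sorted(sel.wavelengths.tolist()) == [450, 550, 650]

    def test_default_count_is_one_hundred(self, coarse_masked):
        spectra, _ = coarse_masked
        curve = correlation_curve(spectra, spectra.lwc)
        sel = select_bands_ca(curve)
        assert len(sel) == 100

    def test_top_bands_sit_near_water_features(self):
        # noise-free default data: the strongest correlations should sit in a
        # water-feature neighbourhood (+-60 nm of an absorption center)
        from wheatlwc import SyntheticConfig, apply_atmospheric_mask, simulate_dataset

        cfg = SyntheticConfig(noise_sd=0.0, residual_sd=0.0, cultivar_sd=0.0)
        spectra, truth = simulate_dataset(cfg)
        masked = apply_atmospheric_mask(spectra)
        curve = correlation_curve(masked, truth.true_lwc)
        sel = select_bands_ca(curve, n_target=100)
        order = np.argsort(-np.abs(sel.diagnostics["r"]))
        top5 = sel.wavelengths[order[:5]]
        centers = np.array(cfg.absorption_centers)
        for wl in top5:
            assert np.min(np.abs(centers - wl)) <= 60, f"{wl} nm far from water bands"

    def test_n_target_exceeding_bands_errors(self):
        wl = np.arange(500, 520)
        curve = CorrelationCurve(grid=WavelengthGrid(wl), r=np.linspace(-1, 1, 20))
        with pytest.raises(DomainError):
            select_bands_ca(curve, n_target=50)

    def test_selection_is_sorted_unique_and_deterministic(self, coarse_masked):
        spectra, _ = coarse_masked
        curve = correlation_curve(spectra, spectra.lwc)
        a = select_bands_ca(curve)
        b = select_bands_ca(curve)
        np.testing.assert_array_equal(a.wavelengths, b.wavelengths)
        assert np.all(np.diff(a.wavelengths) > 0)


class TestPlsLoadings:
    def test_rank_one_data_is_explained_by_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=20)
        direction = rng.normal(size=8)
        X = np.outer(t, direction)
        X = 0.5 + 0.05 * (X - X.mean(0))  # keep reflectance in [0, 1]
        y = 75 + 3 * t
        s = make_spectra(np.clip(X, 0, 1), np.arange(800, 808), lwc=y)
        loadings = fit_pls_loadings(s, y, max_components=3, cv="loo")
        assert loadings.rmsep_by_components[0] < 1e-6
        w = loadings.weights[0]
        cos = abs(w @ direction) / (np.linalg.norm(w) * np.linalg.norm(direction))
        assert cos > 0.999
        assert best_n_components(loadings) == 1

    def test_full_rank_limit_reproduces_ols_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 0.9, (40, 12))
        y = rng.uniform(55, 90, 40)
        s = make_spectra(X, np.arange(900, 912), lwc=y)
        loadings = fit_pls_loadings(s, y, max_components=12, cv="kfold")
        from sklearn.cross_decomposition import PLSRegression

        pls = PLSRegression(n_components=12, scale=False).fit(X, y)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(40), X]), y, rcond=None
        )
        ols_pred = np.column_stack([np.ones(40), X]) @ beta
        np.testing.assert_allclose(pls.predict(X).ravel(), ols_pred, atol=1e-8)
        # and the loading-weight bookkeeping spans the same fit
        assert loadings.n_components == 12

    def test_explained_variance_partition(self, coarse_masked):
        spectra, _ = coarse_masked
        loadings = fit_pls_loadings(spectra, spectra.lwc, max_components=5, cv="kfold")
        ev = loadings.explained_variance
        assert np.all(ev >= 0)
        assert ev.sum() <= 100.0 + 1e-9

    def test_insufficient_samples(self):
        rng = np.random.default_rng(2)
        s = make_spectra(rng.uniform(0, 1, (5, 10)), np.arange(800, 810), lwc=rng.uniform(60, 90, 5))
        with pytest.raises(InsufficientDataError):
            fit_pls_loadings(s, s.lwc, max_components=10)

    def test_sign_convention_largest_element_positive(self, coarse_masked):
        spectra, _ = coarse_masked
        loadings = fit_pls_loadings(spectra, spectra.lwc, max_components=3, cv="kfold")
        for k in range(loadings.n_components):
            w = loadings.weights[k]
            assert w[np.argmax(np.abs(w))] > 0


class TestSelectBandsXlw:
    def test_single_gaussian_bump_selects_its_apex(self):
        wl = np.arange(1000, 1200)
        rng = np.random.default_rng(0)
        # build data whose first PLS weight is a bump at 1100 nm
        t = rng.normal(size=30)
        bump = np.exp(-0.5 * ((wl - 1100) / 15.0) ** 2)
        X = 0.4 + 0.02 * np.outer(t, bump)
        y = 75 + 2 * t
        s = make_spectra(np.clip(X, 0, 1), wl, lwc=y)
        loadings = fit_pls_loadings(s, y, max_components=1, cv="kfold")
        sel = select_bands_xlw(loadings, n_components=1, window=10)
        assert len(sel) == 1
        assert abs(int(sel.wavelengths[0]) - 1100) <= 1

    def test_union_over_components_collapses_duplicates(self, coarse_masked):
        spectra, _ = coarse_masked
        loadings = fit_pls_loadings(spectra, spectra.lwc, max_components=3, cv="kfold")
        sel = select_bands_xlw(loadings, n_components=3)
        assert np.unique(sel.wavelengths).size == len(sel)
        assert np.all(np.diff(sel.wavelengths) > 0)
        grid = set(spectra.grid.wavelengths.tolist())
        assert set(sel.wavelengths.tolist()) <= grid

    def test_component_count_out_of_range(self, coarse_masked):
        spectra, _ = coarse_masked
        loadings = fit_pls_loadings(spectra, spectra.lwc, max_components=2, cv="kfold")
        with pytest.raises(DomainError):
            select_bands_xlw(loadings, n_components=5)

    def test_xlw_selects_fewer_bands_than_ca(self, coarse_masked):
        spectra, _ = coarse_masked
        curve = correlation_curve(spectra, spectra.lwc)
        ca = select_bands_ca(curve, n_target=100)
        loadings = fit_pls_loadings(spectra, spectra.lwc, max_components=3, cv="kfold")
        xlw = select_bands_xlw(loadings, n_components=3)
        assert len(xlw) < len(ca)
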