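import numpy as np
import pytest

from uvresolve import (
    DEFAULT_GRID,
    ETHANOL,
    AcmConfig,
    AnalyteModel,
    Band,
    CalibrationModel,
    DegenerateDivisorError,
    DegenerateSpectraError,
    IsoPointNotFoundError,
    MaskedWavelengthError,
    RatioConfig,
    Spectrum,
    StudyConfig,
    absorptivity_spectrum,
    acm_resolve,
    amplitude_at,
    build_method_suite,
    compute_fac,
    find_isoabsorptive_point,
    ism_resolve,
    ratio_derivative,
    ratio_spectrum,
    rdf_delta,
    resolve_all,
    simulate_measurement,
)


def gaussian_spectrum(grid, bands):
    """Spectrum from (center, fwhm, peak) triples."""
    model = AnalyteModel("test", [Band(*b) for b in bands])
    return absorptivity_spectrum(model, ETHANOL, grid)


class TestComputeFac:
    def test_definition_arithmetic(self, grid):
        s = gaussian_spectrum(grid, [(271.0, 15.0, 0.40), (361.0, 15.0, 0.80)])
        assert compute_fac(s, AcmConfig()) == pytest.approx(0.5, rel=1e-9)

    def test_concentration_independence(self, trim_model, grid):
        cfg = AcmConfig()
        s6 = simulate_measurement([(trim_model, 6.0)], ETHANOL, 0.0, 0, grid)
        s12 = simulate_measurement([(trim_model, 12.0)], ETHANOL, 0.0, 0, grid)
        assert compute_fac(s6, cfg) == pytest.approx(compute_fac(s12, cfg), abs=1e-12)

    def test_zero_free_wavelength_absorbance(self, hctz_unit):
        # HCTZ is silent at 361 nm, so it cannot define a correction factor
        with pytest.raises(DegenerateDivisorError):
            compute_fac(hctz_unit, AcmConfig())


class TestAcmResolve:
    @staticmethod
    def _engineered_system(grid):
        """Narrow-band system with exactly known unit absorptivities.

        a_H(271) = 0.069, a_T(361) = 0.0803, a_T(271) = 0.5*0.0803; the
        bands are narrow enough that all cross-terms vanish to round-off,
        so the closed-form algebra gives the exact concentrations.
        """
        h = AnalyteModel("HCTZ", [Band(271.0, 20.0, 0.069)])
        t = AnalyteModel(
            "TRIM", [Band(361.0, 20.0, 0.0803), Band(271.0, 20.0, 0.5 * 0.0803)]
        )
        calib_t = CalibrationModel(slope=0.0803, intercept=0.0, analyte="TRIM")
        calib_h = CalibrationModel(slope=0.069, intercept=0.0, analyte="HCTZ")
        return h, t, calib_t, calib_h

    def test_closed_form_recovery(self, grid):
        h, t, calib_t, calib_h = self._engineered_system(grid)
        mix = simulate_measurement([(h, 4.0), (t, 6.0)], ETHANOL, 0.0, 0, grid)
        cfg = AcmConfig(f_ac=compute_fac(absorptivity_spectrum(t, ETHANOL, grid), AcmConfig()))
        res = acm_resolve(mix, cfg, calib_t, calib_h)
        assert res.concentrations["HCTZ"] == pytest.approx(4.0, abs=1e-9)
        assert res.concentrations["TRIM"] == pytest.approx(6.0, abs=1e-9)

    def test_zero_interferent_leaves_raw_absorbance(self, grid):
        h, t, calib_t, calib_h = self._engineered_system(grid)
        mix = simulate_measurement([(h, 5.0)], ETHANOL, 0.0, 0, grid)
        res = acm_resolve(mix, AcmConfig(f_ac=0.5), calib_t, calib_h)
        assert res.intermediates["corrected_absorbance"] == pytest.approx(
            amplitude_at(mix, 271.0), abs=1e-12
        )
        assert res.concentrations["HCTZ"] == pytest.approx(5.0, abs=1e-9)

    def test_blank_gives_zero_estimates(self, grid):
        _, _, calib_t, calib_h = self._engineered_system(grid)
        blank = Spectrum(grid.wavelengths(), np.zeros(grid.n_points))
        res = acm_resolve(blank, AcmConfig(f_ac=0.5), calib_t, calib_h)
        assert res.concentrations["HCTZ"] == 0.0
        assert res.concentrations["TRIM"] == 0.0

    def test_strongly_negative_corrected_absorbance_is_flagged(self, grid):
        _, t, calib_t, calib_h = self._engineered_system(grid)
        # over-correction: F_ac far too large for a TRIM-only sample
        mix = simulate_measurement([(t, 10.0)], ETHANOL, 0.0, 0, grid)
        res = acm_resolve(mix, AcmConfig(f_ac=2.0), calib_t, calib_h)
        assert "corrected-absorbance-negative" in res.flags
        assert any(f.startswith("negative-estimate") for f in res.flags)


class TestIsoabsorptivePoint:
    def test_identical_spectra_degenerate(self, hctz_unit):
        with pytest.raises(DegenerateSpectraError):
            find_isoabsorptive_point(hctz_unit, hctz_unit.copy(), (260.0, 273.0))

    def test_symmetric_gaussians_cross_at_midpoint(self, grid):
        a = gaussian_spectrum(grid, [(260.0, 25.0, 0.1)])
        b = gaussian_spectrum(grid, [(280.0, 25.0, 0.1)])
        iso = find_isoabsorptive_point(a, b, (265.0, 275.0))
        assert iso.wavelength == pytest.approx(270.0, abs=1e-6)

    def test_presets_cross_where_fine_scan_says(self, hctz_unit, trim_unit):
        iso = find_isoabsorptive_point(hctz_unit, trim_unit, (260.0, 273.0))
        assert 265.0 <= iso.wavelength <= 268.5
        # oracle: exhaustive sign-change scan at 1 pm
        fine = np.arange(260.0, 273.0, 0.001)
        diff = np.interp(fine, hctz_unit.wavelengths, hctz_unit.absorbances) - np.interp(
            fine, trim_unit.wavelengths, trim_unit.absorbances
        )
        crossing = fine[np.where(np.diff(np.sign(diff)) != 0)[0][0]]
        assert iso.wavelength == pytest.approx(crossing, abs=0.005)

    def test_no_crossing_in_window(self, hctz_unit, trim_unit):
        with pytest.raises(IsoPointNotFoundError):
            find_isoabsorptive_point(hctz_unit, trim_unit, (268.0, 272.0))


class TestIsmResolve:
    @staticmethod
    def _calibs(hctz_unit, trim_unit, lam_iso):
        calib_iso = CalibrationModel(
            slope=amplitude_at(hctz_unit, lam_iso), analyte="HCTZ"
        )
        calib_free = CalibrationModel(
            slope=amplitude_at(trim_unit, 361.0), analyte="TRIM"
        )
        return calib_iso, calib_free

    def test_noiseless_mixture_within_one_percent(
        self, hctz_model, trim_model, hctz_unit, trim_unit, grid
    ):
        lam_iso = find_isoabsorptive_point(hctz_unit, trim_unit, (260.0, 273.0)).wavelength
        calib_iso, calib_free = self._calibs(hctz_unit, trim_unit, lam_iso)
        mix = simulate_measurement(
            [(hctz_model, 4.0), (trim_model, 6.0)], ETHANOL, 0.0, 0, grid
        )
        res = ism_resolve(mix, lam_iso, calib_iso, calib_free)
        assert res.intermediates["c_total"] == pytest.approx(10.0, rel=0.01)
        assert res.concentrations["HCTZ"] == pytest.approx(4.0, rel=0.01)
        assert res.concentrations["TRIM"] == pytest.approx(6.0, rel=0.01)
        # conservation is exact by construction
        assert res.concentrations["HCTZ"] + res.concentrations["TRIM"] == pytest.approx(
            res.intermediates["c_total"], abs=1e-12
        )

    def test_no_interferent_means_total_is_analyte(
        self, hctz_model, hctz_unit, trim_unit, grid
    ):
        lam_iso = find_isoabsorptive_point(hctz_unit, trim_unit, (260.0, 273.0)).wavelength
        calib_iso, calib_free = self._calibs(hctz_unit, trim_unit, lam_iso)
        mix = simulate_measurement([(hctz_model, 5.0)], ETHANOL, 0.0, 0, grid)
        res = ism_resolve(mix, lam_iso, calib_iso, calib_free)
        assert res.concentrations["HCTZ"] == pytest.approx(
            res.intermediates["c_total"], abs=1e-9
        )

    def test_interferent_only_mixture(self, trim_model, hctz_unit, trim_unit, grid):
        lam_iso = find_isoabsorptive_point(hctz_unit, trim_unit, (260.0, 273.0)).wavelength
        calib_iso, calib_free = self._calibs(hctz_unit, trim_unit, lam_iso)
        mix = simulate_measurement([(trim_model, 6.0)], ETHANOL, 0.0, 0, grid)
        res = ism_resolve(mix, lam_iso, calib_iso, calib_free)
        assert res.concentrations["HCTZ"] == pytest.approx(0.0, abs=0.05)
        if res.concentrations["HCTZ"] < 0:
            assert "negative-estimate:HCTZ" in res.flags


class TestRatioSpectrum:
    def test_self_division_is_unity(self, trim_unit):
        ratio = ratio_spectrum(trim_unit, trim_unit, 1.0, floor=1e-15)
        valid = ~ratio.mask if ratio.mask is not None else np.ones(len(ratio), bool)
        np.testing.assert_allclose(ratio.absorbances[valid], 1.0, rtol=1e-12)

    def test_pure_divisor_analyte_gives_constant(self, trim_model, trim_unit, grid):
        mix = simulate_measurement([(trim_model, 7.0)], ETHANOL, 0.0, 0, grid)
        ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=1e-6)
        valid = ~ratio.mask
        np.testing.assert_allclose(ratio.absorbances[valid], 0.7, rtol=1e-9)

    def test_smoothing_preserves_constant_ratio(self, trim_model, trim_unit, grid):
        mix = simulate_measurement([(trim_model, 7.0)], ETHANOL, 0.0, 0, grid)
        ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=1e-6, smooth_window=51)
        valid = ~ratio.mask
        np.testing.assert_allclose(ratio.absorbances[valid], 0.7, rtol=1e-9)

    def test_zero_divisor_region_is_masked_and_counted(self, hctz_unit, trim_unit):
        ratio = ratio_spectrum(hctz_unit, trim_unit, 10.0, floor=0.01)
        assert ratio.meta["n_masked"] == int(ratio.mask.sum()) > 0
        with pytest.raises(MaskedWavelengthError):
            amplitude_at(ratio, 430.0)  # far red: divisor below floor


class TestRdfDelta:
    def test_constant_ratio_cancels(self, trim_model, trim_unit, grid):
        mix = simulate_measurement([(trim_model, 7.0)], ETHANOL, 0.0, 0, grid)
        ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=1e-6)
        assert rdf_delta(ratio, 273.0, 293.0) == pytest.approx(0.0, abs=1e-12)

    def test_proportional_to_analyte_concentration(
        self, hctz_model, trim_unit, grid
    ):
        deltas = []
        concs = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
        for c in concs:
            mix = simulate_measurement([(hctz_model, c)], ETHANOL, 0.0, 0, grid)
            ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=0.01)
            deltas.append(rdf_delta(ratio, 273.0, 293.0))
        deltas = np.asarray(deltas)
        slopes = deltas / np.asarray(concs)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)

    def test_invariant_to_interferent(self, hctz_model, trim_model, trim_unit, grid):
        deltas = []
        for c_trim in [2.0, 6.0, 12.0]:
            mix = simulate_measurement(
                [(hctz_model, 6.0), (trim_model, c_trim)], ETHANOL, 0.0, 0, grid
            )
            ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=0.01)
            deltas.append(rdf_delta(ratio, 273.0, 293.0))
        assert max(deltas) - min(deltas) < 1e-3 * abs(np.mean(deltas))


class TestRatioDerivative:
    def test_constant_ratio_derivative_is_zero(self, trim_model, trim_unit, grid):
        mix = simulate_measurement([(trim_model, 7.0)], ETHANOL, 0.0, 0, grid)
        ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=1e-6)
        deriv = ratio_derivative(ratio, 9, 2)
        valid = ~deriv.mask if deriv.mask is not None else np.ones(len(deriv), bool)
        np.testing.assert_allclose(deriv.absorbances[valid], 0.0, atol=1e-9)

    def test_ramp_derivative(self, grid):
        w = grid.wavelengths()
        ramp = Spectrum(w, 0.05 * w)
        deriv = ratio_derivative(ramp, 9, 2)
        np.testing.assert_allclose(deriv.absorbances[10:-10], 0.05, rtol=1e-9)

    def test_invalid_window_rejected(self, grid):
        w = grid.wavelengths()
        s = Spectrum(w, np.ones_like(w))
        with pytest.raises(ValueError):
            ratio_derivative(s, 8, 2)
        with pytest.raises(ValueError):
            ratio_derivative(s, 3, 4)

    def test_amplitude_tracks_analyte_not_interferent(
        self, hctz_model, trim_model, trim_unit, grid
    ):
        cfg = RatioConfig()

        def amp(c_h, c_t):
            mix = simulate_measurement(
                [(hctz_model, c_h), (trim_model, c_t)], ETHANOL, 0.0, 0, grid
            )
            ratio = ratio_spectrum(mix, trim_unit, 10.0, floor=0.01)
            deriv = ratio_derivative(ratio, cfg.derivative_window, cfg.derivative_polyorder)
            return amplitude_at(deriv, 283.0)

        assert amp(8.0, 6.0) == pytest.approx(2 * amp(4.0, 6.0), rel=1e-9)
        assert amp(4.0, 12.0) == pytest.approx(amp(4.0, 2.0), rel=1e-3)


@pytest.fixture(scope="module")
def suite():
    cfg = StudyConfig(noise_sd=0.0, seed=0)
    return build_method_suite(cfg, np.random.default_rng(0))


class TestResolveAll:
    def test_noiseless_mixture_all_methods_within_one_percent(
        self, suite, hctz_model, trim_model, grid
    ):
        mix = simulate_measurement(
            [(hctz_model, 4.0), (trim_model, 6.0)], ETHANOL, 0.0, 0, grid
        )
        results = resolve_all(mix, suite.methods)
        assert len(results) == 5
        for res in results:
            assert not res.failed
            assert res.concentrations["HCTZ"] == pytest.approx(4.0, rel=0.01)
            assert res.concentrations["TRIM"] == pytest.approx(6.0, rel=0.01)

    def test_blank_gives_near_zero_estimates(self, suite, grid):
        blank = Spectrum(grid.wavelengths(), np.zeros(grid.n_points))
        for res in resolve_all(blank, suite.methods):
            assert not res.failed
            for conc in res.concentrations.values():
                assert conc == pytest.approx(0.0, abs=1e-6)

    def test_broken_method_reported_as_structured_failure(self, suite, hctz_model,
                                                          trim_model, grid):
        import dataclasses

        broken = dataclasses.replace(suite.methods[0], lambda_primary=1000.0)
        methods = [broken] + suite.methods[1:]
        mix = simulate_measurement(
            [(hctz_model, 4.0), (trim_model, 6.0)], ETHANOL, 0.0, 0, grid
        )
        results = resolve_all(mix, methods)
        assert sum(r.failed for r in results) == 1
        assert results[0].failed and results[0].flags[0].startswith("failed:")
        assert all(not r.failed for r in results[1:])
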