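"""Film calibration and Eq.-1 style densitometric conversion."""

import numpy as np
import pytest

from autoradq.calibration import (
    CalibrationError,
    DensityImage,
    FilmResponse,
    LigandParams,
    StandardMeasurement,
    density_to_radioactivity,
    fit_calibration,
    gray_to_radioactivity,
    quantify_image,
    radioactivity_to_density,
    specific_binding,
)


class TestDensityConversion:
    def test_zero_radioactivity_gives_zero_density(self, simple_ligand):
        assert radioactivity_to_density(0.0, simple_ligand) == 0.0

    def test_saturation_factor_two_when_kd_equals_l(self):
        lig = LigandParams(E=1, B=1, Wb=1, Sa=1, KD=3.0, L=3.0)
        for R in (1.0, 10.0, 123.4):
            assert radioactivity_to_density(R, lig) == pytest.approx(2 * R, rel=1e-12)

    def test_spot_value_matches_hand_evaluation(self, simple_ligand):
        # R/(E*B*Wb*Sa) * (KD+L)/L = 1000/4 * 3 = 750, computed independently
        assert radioactivity_to_density(1000.0, simple_ligand) == pytest.approx(
            750.0, rel=1e-12)

    def test_homogeneity_over_random_parameter_draws(self, rng):
        """C_b is linear in R and in (KD+L)/L; doubling Sa halves C_b."""
        for _ in range(50):
            E, B, Wb, Sa, KD, L = rng.uniform(0.1, 10.0, size=6)
            lig = LigandParams(E=E, B=B, Wb=Wb, Sa=Sa, KD=KD, L=L)
            R = rng.uniform(0.0, 1e4)
            c = radioactivity_to_density(R, lig)
            assert radioactivity_to_density(3.0 * R, lig) == pytest.approx(3 * c, rel=1e-10)
            lig2 = LigandParams(E=E, B=B, Wb=Wb, Sa=2 * Sa, KD=KD, L=L)
            assert radioactivity_to_density(R, lig2) == pytest.approx(c / 2, rel=1e-10)
            ratio = (KD + L) / L
            assert c == pytest.approx(R / (E * B * Wb * Sa) * ratio, rel=1e-10)

    def test_homogeneity_property(self):
        """Eq.-1 scaling laws hold for arbitrary valid parameter draws."""
        from hypothesis import given, settings, strategies as st

        pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)

        @settings(max_examples=100, derandomize=True, deadline=None)
        @given(E=pos, B=pos, Wb=pos, Sa=pos, KD=pos, L=pos,
               R=st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
               c=st.floats(min_value=1e-2, max_value=1e2, allow_nan=False))
        def check(E, B, Wb, Sa, KD, L, R, c):
            lig = LigandParams(E=E, B=B, Wb=Wb, Sa=Sa, KD=KD, L=L)
            base = radioactivity_to_density(R, lig)
            assert radioactivity_to_density(c * R, lig) == pytest.approx(
                c * base, rel=1e-9, abs=1e-12)
            halved = LigandParams(E=E, B=B, Wb=Wb, Sa=2 * Sa, KD=KD, L=L)
            assert radioactivity_to_density(R, halved) == pytest.approx(
                base / 2, rel=1e-9, abs=1e-12)

        check()

    def test_inverse_conversion_round_trips(self, simple_ligand, rng):
        Cb = rng.uniform(0, 2000, size=30)
        R = density_to_radioactivity(Cb, simple_ligand)
        np.testing.assert_allclose(radioactivity_to_density(R, simple_ligand), Cb,
                                   rtol=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(E=0.0), dict(B=-1.0), dict(L=0.0), dict(KD=0.0), dict(Sa=np.nan),
    ])
    def test_nonpositive_ligand_parameters_rejected(self, bad):
        params = dict(E=0.5, B=2.0, Wb=0.05, Sa=80.0, KD=1.4, L=0.7)
        params.update(bad)
        with pytest.raises(CalibrationError):
            LigandParams(**params)

    def test_negative_radioactivity_rejected(self, simple_ligand):
        with pytest.raises(CalibrationError):
            radioactivity_to_density(-1.0, simple_ligand)


def _exact_standards(film, levels):
    return [StandardMeasurement(r, float(film(r))) for r in levels]


class TestFitCalibration:
    film = FilmResponse(offset=2000.0, gmax=50000.0, rate=0.002)
    levels = np.array([0.0, 100.0, 250.0, 500.0, 800.0, 1200.0])

    def test_exact_model_recovered(self):
        cal = fit_calibration(_exact_standards(self.film, self.levels))
        assert np.max(np.abs(cal.residuals)) < 1e-6
        assert cal.film.offset == pytest.approx(self.film.offset, rel=1e-6)
        assert cal.film.gmax == pytest.approx(self.film.gmax, rel=1e-6)
        assert cal.film.rate == pytest.approx(self.film.rate, rel=1e-6)

    def test_noisy_standards_recover_radioactivity_within_2pct(self, rng):
        """Cross-checked against an independent grid-search least-squares fit."""
        standards = [StandardMeasurement(r, float(self.film(r)) + rng.normal(0, 0.5))
                     for r in self.levels]
        cal = fit_calibration(standards)
        for s in standards:
            if s.known_R == 0:
                continue
            rec = gray_to_radioactivity(cal, s.mean_gray)
            assert rec == pytest.approx(s.known_R, rel=0.02)

        # independent oracle: coarse grid search over the same family
        R = np.array([s.known_R for s in standards])
        G = np.array([s.mean_gray for s in standards])
        best, best_sse = None, np.inf
        for off in np.linspace(1990, 2010, 21):
            for gm in np.linspace(40000, 60000, 41):
                for rate in np.linspace(0.0015, 0.0025, 41):
                    sse = np.sum((G - (off + gm * (1 - np.exp(-rate * R)))) ** 2)
                    if sse < best_sse:
                        best, best_sse = (off, gm, rate), sse
        # the continuous optimum cannot be worse than the best grid point
        assert cal.rss <= best_sse + 1e-9
        oracle = FilmResponse(*best)
        for s in standards:
            if s.known_R == 0:
                continue
            assert float(oracle.inverse(s.mean_gray)) == pytest.approx(
                s.known_R, rel=0.05)

    def test_three_standards_is_insufficient(self):
        with pytest.raises(CalibrationError, match="insufficient"):
            fit_calibration(_exact_standards(self.film, [0.0, 100.0, 200.0]))

    def test_all_equal_grays_degenerate(self):
        standards = [StandardMeasurement(r, 500.0) for r in self.levels]
        with pytest.raises(CalibrationError):
            fit_calibration(standards)

    def test_polylog_family_fits_monotone_curve(self):
        cal = fit_calibration(_exact_standards(self.film, self.levels),
                              family="polylog")
        fitted = cal.film(self.levels)
        assert np.all(np.diff(fitted) > 0)
        assert np.max(np.abs(cal.residuals)) < 50.0  # model mismatch, still close


class TestGrayToRadioactivity:
    film = FilmResponse(offset=2000.0, gmax=50000.0, rate=0.002)
    levels = np.array([0.0, 150.0, 400.0, 700.0, 1000.0])

    @pytest.fixture()
    def cal(self):
        return fit_calibration(_exact_standards(self.film, self.levels))

    def test_standard_grays_map_to_known_radioactivity(self, cal):
        for s in cal.standards:
            assert gray_to_radioactivity(cal, s.mean_gray) == pytest.approx(
                s.known_R, abs=1e-6 * max(1.0, s.known_R))

    def test_monotone_in_gray(self, cal):
        grays = np.linspace(*cal.valid_gray_range, 64)
        R = gray_to_radioactivity(cal, grays)
        assert np.all(np.diff(R) > 0)

    def test_inverse_consistency_over_valid_range(self, cal):
        grays = np.linspace(*cal.valid_gray_range, 256)
        R = gray_to_radioactivity(cal, grays)
        np.testing.assert_allclose(cal.film(R), grays, rtol=0, atol=1e-6 * 50000)

    def test_out_of_range_masked_with_warning(self, cal):
        gray = np.array([1000.0, 3000.0, 60000.0])
        with pytest.warns(UserWarning, match="masked"):
            R = gray_to_radioactivity(cal, gray)
        assert np.isnan(R[0]) and np.isnan(R[2]) and np.isfinite(R[1])

    def test_nan_in_nan_out(self, cal):
        R = gray_to_radioactivity(cal, np.array([np.nan, 3000.0]))
        assert np.isnan(R[0]) and np.isfinite(R[1])


class TestSpecificBinding:
    def _img(self, values):
        return DensityImage(values=np.asarray(values, dtype=float))

    def test_zero_nonspecific_is_identity(self):
        total = self._img([[10.0, 5.0]])
        out = specific_binding(total, self._img([[0.0, 0.0]]))
        np.testing.assert_array_equal(out.values, total.values)

    def test_floor_rule_reports_count(self):
        out = specific_binding(self._img([10.0, 10.0]), self._img([3.0, 12.0]))
        np.testing.assert_array_equal(out.values, [7.0, 0.0])
        assert out.provenance["n_floored"] == 1

    def test_self_subtraction_all_zero(self):
        total = self._img([[4.0, 2.0], [1.0, 0.0]])
        out = specific_binding(total, total)
        assert np.all(out.values == 0.0)
        assert out.provenance["n_floored"] == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CalibrationError, match="shape"):
            specific_binding(self._img([1.0, 2.0]), self._img([[1.0], [2.0]]))


class TestQuantifyImage:
    def test_constant_gray_gives_constant_density(self, simple_ligand):
        film = FilmResponse(offset=2000.0, gmax=50000.0, rate=0.002)
        cal = fit_calibration(_exact_standards(film, [0.0, 100.0, 300.0, 600.0]))
        gray = np.full((8, 8), float(film(200.0)))
        dimg = quantify_image(gray, cal, simple_ligand)
        expected = radioactivity_to_density(200.0, simple_ligand)
        np.testing.assert_allclose(dimg.values, expected, rtol=1e-9)

    def test_saturated_pixels_masked(self, simple_ligand):
        film = FilmResponse(offset=2000.0, gmax=50000.0, rate=0.002)
        cal = fit_calibration(_exact_standards(film, [0.0, 100.0, 300.0, 600.0]))
        gray = np.array([[float(film(100.0)), 65000.0]])
        with pytest.warns(UserWarning):
            dimg = quantify_image(gray, cal, simple_ligand)
        assert np.isfinite(dimg.values[0, 0]) and np.isnan(dimg.values[0, 1])
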