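"""Lineal-energy spectrum functionals: y_F, y_D, y* and quality mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imkbnct.microdosimetry import (
    DomainGeometry,
    LinealEnergySpectrum,
    QualityComponents,
    calibrate_components,
    dose_density,
    dose_mean_lineal_energy,
    frequency_mean_lineal_energy,
    mix_quality,
    saturation_corrected_y_star,
)


def dirac(y: float) -> LinealEnergySpectrum:
    return LinealEnergySpectrum.from_point_masses([y], [1.0])


@st.composite
def discrete_spectra(draw):
    n = draw(st.integers(2, 8))
    y = np.sort(
        np.array(
            draw(
                st.lists(
                    st.floats(0.05, 500.0), min_size=n, max_size=n, unique=True
                )
            )
        )
    )
    w = np.array(draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n)))
    return LinealEnergySpectrum.from_point_masses(y, w)


class TestConstruction:
    def test_renormalises_and_records_factor(self):
        y = np.linspace(1.0, 3.0, 101)
        spec = LinealEnergySpectrum(y, np.full_like(y, 2.0))  # integrates to 4
        assert spec.norm_factor == pytest.approx(0.25)
        assert spec.integrate(np.ones_like(y)) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "y, f",
        [
            ([1.0, 0.5], [1.0, 1.0]),  # non-increasing grid
            ([-1.0, 2.0], [1.0, 1.0]),  # non-positive y
            ([1.0, 2.0], [1.0, -0.5]),  # negative density
            ([1.0, 2.0], [0.0, 0.0]),  # degenerate: zero mass
        ],
    )
    def test_invalid_spectra_rejected(self, y, f):
        with pytest.raises(ValueError):
            LinealEnergySpectrum(np.array(y), np.array(f))

    def test_large_renormalisation_logs_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="imkbnct.microdosimetry"):
            LinealEnergySpectrum.from_point_masses([1.0, 2.0], [1.0, 1.0])
        assert any("renormalised" in r.message for r in caplog.records)


class TestDoseDensity:
    def test_single_bin_is_fixed_point(self):
        d = dose_density(dirac(10.0))
        assert d.y_grid.tolist() == [10.0]
        assert d.density[0] == pytest.approx(1.0)

    def test_uniform_frequency_gives_linear_dose_density(self):
        # f uniform on [1,3] -> d(y) = y / ∫y dy = y/4
        y = np.linspace(1.0, 3.0, 2001)
        spec = LinealEnergySpectrum(y, np.full_like(y, 0.5))
        d = dose_density(spec)
        np.testing.assert_allclose(d.density, y / 4.0, rtol=1e-6)
        assert d.integrate(np.ones_like(y)) == pytest.approx(1.0, abs=1e-6)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            LinealEnergySpectrum(np.array([1.0, 2.0]), np.array([0.0, 0.0]))


class TestMoments:
    def test_dirac_means_collapse_to_the_line(self):
        spec = dirac(10.0)
        assert frequency_mean_lineal_energy(spec) == pytest.approx(10.0)
        assert dose_mean_lineal_energy(spec) == pytest.approx(10.0)

    def test_two_line_dose_mean_hand_value(self):
        spec = LinealEnergySpectrum.from_point_masses([1.0, 3.0], [0.5, 0.5])
        # y_D = (1 + 9)/(1 + 3)
        assert dose_mean_lineal_energy(spec) == pytest.approx(2.5)

    def test_dirac_y_star_closed_form(self, geom):
        # y* = y0^2 (1 - exp(-y^2/y0^2)) / y for a single line at y
        y, y0 = 10.0, geom.y0
        expected = y0**2 * -np.expm1(-(y / y0) ** 2) / y
        assert saturation_corrected_y_star(dirac(y), geom) == pytest.approx(
            expected, rel=1e-12
        )

    def test_y_star_approaches_y_d_without_saturation(self):
        spec = LinealEnergySpectrum.from_point_masses(
            [2.0, 30.0, 400.0], [0.5, 0.3, 0.2]
        )
        huge = DomainGeometry(y0=1e9)
        assert saturation_corrected_y_star(spec, huge) == pytest.approx(
            dose_mean_lineal_energy(spec), rel=1e-6
        )

    def test_overkill_limit_scales_as_y0_sq_over_y(self, geom):
        y = 1e5  # y >> y0
        assert saturation_corrected_y_star(dirac(y), geom) == pytest.approx(
            geom.y0**2 / y, rel=1e-6
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(discrete_spectra())
    def test_moment_ordering(self, spec):
        """y_F <= y_D and y* <= y_D for any spectrum."""
        y_f = frequency_mean_lineal_energy(spec)
        y_d = dose_mean_lineal_energy(spec)
        y_star = saturation_corrected_y_star(spec, DomainGeometry())
        assert y_f <= y_d * (1 + 1e-12)
        assert 0 < y_star <= y_d * (1 + 1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(discrete_spectra(), st.floats(5.0, 500.0), st.floats(1.05, 3.0))
    def test_saturation_monotone_in_y0(self, spec, y0, factor):
        low = saturation_corrected_y_star(spec, DomainGeometry(y0=y0))
        high = saturation_corrected_y_star(spec, DomainGeometry(y0=y0 * factor))
        assert low <= high * (1 + 1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(discrete_spectra(), discrete_spectra(), st.floats(0.05, 0.95))
    def test_mixture_linearity_against_merged_spectrum(self, s1, s2, w):
        """Dose-weighted y_D / y* mixing equals the merged-spectrum value.

        Merge the dose densities d = w·d1 + (1−w)·d2, rebuild f ∝ d/y, and
        compare its functionals with the dose-weighted component means.
        """
        geom = DomainGeometry()
        d1, d2 = dose_density(s1), dose_density(s2)
        y_all = np.unique(np.concatenate([s1.y_grid, s2.y_grid]))

        def mass_on(d, y_all):
            out = np.zeros_like(y_all)
            idx = np.searchsorted(y_all, d.y_grid)
            np.add.at(out, idx, d.density)
            return out

        d_mix = w * mass_on(d1, y_all) + (1 - w) * mass_on(d2, y_all)
        merged = LinealEnergySpectrum.from_point_masses(y_all, d_mix / y_all)
        y_d_mix = w * dose_mean_lineal_energy(s1) + (1 - w) * dose_mean_lineal_energy(s2)
        y_star_mix = w * saturation_corrected_y_star(s1, geom) + (
            1 - w
        ) * saturation_corrected_y_star(s2, geom)
        assert dose_mean_lineal_energy(merged) == pytest.approx(y_d_mix, rel=1e-10)
        assert saturation_corrected_y_star(merged, geom) == pytest.approx(
            y_star_mix, rel=1e-10
        )


class TestQualityMixing:
    def test_no_boron_returns_background(self):
        c = QualityComponents(40.0, 80.0, 1.0, 0.3)
        assert mix_quality(c, 0.0) == (1.0, 40.0)

    def test_hand_mixture(self):
        # components y*=40 at 1 Gy/min and y*=80 at 3 Gy/min -> 70 at 4 Gy/min
        c = QualityComponents(40.0, 80.0, 1.0, 3.0)
        rate, y_star = mix_quality(c, 1.0)
        assert rate == pytest.approx(4.0)
        assert y_star == pytest.approx(70.0)

    def test_negative_ppm_rejected(self):
        c = QualityComponents(40.0, 80.0, 1.0, 0.3)
        with pytest.raises(ValueError):
            mix_quality(c, -1.0)

    def test_monotone_in_ppm_when_boron_harder(self):
        c = QualityComponents(41.36, 78.37, 1.0, 0.275)
        ys = [mix_quality(c, p)[1] for p in np.linspace(0, 60, 30)]
        assert np.all(np.diff(ys) > 0)


class TestCalibration:
    def test_reference_calibration_hand_values(self):
        c = calibrate_components(1.0, 41.36, 3.75, 68.50, 10.0)
        assert c.boron_dose_rate_per_ppm == pytest.approx(0.275)
        assert c.boron_y_star == pytest.approx(
            (68.50 * 3.75 - 41.36 * 1.0) / 2.75, rel=1e-12
        )

    def test_identical_qualities_calibrate_to_identity(self):
        c = calibrate_components(1.0, 40.0, 2.0, 40.0, 10.0)
        assert c.boron_y_star == pytest.approx(40.0)

    def test_round_trip_reproduces_calibration_inputs(self):
        c = calibrate_components(1.0, 41.36, 3.75, 68.50, 10.0)
        rate, y_star = mix_quality(c, 10.0)
        assert rate == pytest.approx(3.75, abs=1e-12)
        assert y_star == pytest.approx(68.50, abs=1e-12)
        assert mix_quality(c, 0.0) == (1.0, 41.36)

    def test_no_boron_dose_rejected(self):
        with pytest.raises(ValueError):
            calibrate_components(1.0, 41.36, 0.9, 68.50, 10.0)
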