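"""Simulator tests: lineshape function, linear spectra, Fermi multiplet."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from azospec import (
    FFCFModel,
    ProbeThetaModel,
    TemperatureSeriesModel,
    fermi_multiplet_spectrum,
    generate_temperature_series,
    lineshape_function,
    linear_spectrum,
    peak_fwhm,
)
from azospec.errors import GridError, InvalidModelError
from azospec.lineshape import fermi_multiplet_fwhm
from azospec.models import TWO_PI_C

C_CM_PS = TWO_PI_C / (2.0 * np.pi)


class TestLineshapeFunction:
    def test_zero_fluctuation_gives_zero(self):
        t = np.linspace(0.0, 10.0, 101)
        g = lineshape_function(FFCFModel(), t)
        assert np.allclose(g, 0.0)

    def test_static_limit_closed_form(self):
        t = np.linspace(0.0, 10.0, 101)
        g = lineshape_function(FFCFModel(static_amplitude=4.0), t)
        expected = 0.5 * (TWO_PI_C * 4.0) ** 2 * t**2
        assert np.allclose(g.real, expected, rtol=1e-12)
        assert np.allclose(g.imag, 0.0)

    def test_exponential_component_matches_quadrature_oracle(self):
        """g(t) is the double time integral of C(t); check against
        numerical quadrature at Delta = 5 cm^-1, tau = 1 ps, t = 2 ps."""
        delta, tau, t_eval = 5.0, 1.0, 2.0
        dw2 = (TWO_PI_C * delta) ** 2

        def inner(tp):
            # integral of C over [0, tp]
            val, _ = quad(lambda s: dw2 * np.exp(-s / tau), 0.0, tp)
            return val

        oracle, _ = quad(inner, 0.0, t_eval, limit=200)
        t = np.linspace(0.0, 2.0, 401)
        g = lineshape_function(FFCFModel(components=((delta, tau),)), t)
        assert g[-1].real == pytest.approx(oracle, rel=1e-6)

    def test_invalid_models_rejected(self):
        with pytest.raises(InvalidModelError):
            FFCFModel(components=((-1.0, 1.0),))
        with pytest.raises(InvalidModelError):
            FFCFModel(components=((5.0, 0.0),))
        with pytest.raises(InvalidModelError):
            FFCFModel(pure_dephasing_time=-2.0)

    def test_time_axis_validation(self):
        with pytest.raises(GridError):
            lineshape_function(FFCFModel(), np.linspace(1.0, 2.0, 10))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        comps=st.lists(
            st.tuples(
                st.floats(0.0, 20.0), st.floats(0.05, 50.0)
            ),
            min_size=0,
            max_size=3,
        ),
        static=st.floats(0.0, 15.0),
    )
    def test_ffcf_is_non_increasing(self, comps, static):
        model = FFCFModel(components=tuple(comps), static_amplitude=static)
        t = np.linspace(0.0, 100.0, 2001)
        c = model.evaluate(t)
        assert np.all(np.diff(c) <= 1e-12)
        assert c[0] == pytest.approx(model.total_variance)


class TestLinearSpectrum:
    def test_lorentzian_limit(self):
        """Homogeneous-only band: FWHM = 1/(pi c T2) within 1 %."""
        t2 = 1.2
        spec = linear_spectrum(FFCFModel(pure_dephasing_time=t2), 2096.0)
        expected = 1.0 / (np.pi * C_CM_PS * t2)
        assert peak_fwhm(spec, smooth_window=1).fwhm == pytest.approx(expected, rel=0.01)

    def test_lifetime_contributes_to_dephasing(self):
        """1/T2 = 1/T2* + 1/(2 T1)."""
        spec = linear_spectrum(
            FFCFModel(pure_dephasing_time=2.0, lifetime=2.0), 2096.0
        )
        t2 = 1.0 / (1.0 / 2.0 + 1.0 / 4.0)
        expected = 1.0 / (np.pi * C_CM_PS * t2)
        assert peak_fwhm(spec, smooth_window=1).fwhm == pytest.approx(expected, rel=0.01)

    def test_gaussian_limit(self):
        """Static-inhomogeneity band: FWHM = 2 sqrt(2 ln 2) Delta0 within 1 %."""
        spec = linear_spectrum(FFCFModel(static_amplitude=10.0), 2096.0)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 10.0
        assert peak_fwhm(spec, smooth_window=1).fwhm == pytest.approx(expected, rel=0.01)

    def test_mixed_kubo_vs_bruteforce_ft_oracle(self):
        """Delta = 8 cm^-1, tau = 2 ps vs an independent fine-step FT."""
        delta, tau = 8.0, 2.0
        model = FFCFModel(components=((delta, tau),), pure_dephasing_time=5.0)
        spec = linear_spectrum(model, 2096.0)
        fwhm = peak_fwhm(spec, smooth_window=1).fwhm

        # oracle: 4x finer time step, direct cosine transform
        dt = 0.00125
        t = dt * np.arange(int(40.0 / dt))
        dw = TWO_PI_C * delta
        g = (dw * tau) ** 2 * (np.exp(-t / tau) + t / tau - 1.0)
        fid = np.exp(-g - t / 5.0)
        nu = np.linspace(-40.0, 40.0, 4001)
        cos_tf = (fid[None, :] * np.cos(TWO_PI_C * nu[:, None] * t[None, :])).sum(axis=1)
        half = 0.5 * cos_tf.max()
        above = np.where(cos_tf >= half)[0]
        oracle = nu[above[-1]] - nu[above[0]]
        assert fwhm == pytest.approx(oracle, rel=0.02)

    def test_narrow_grid_raises(self):
        with pytest.raises(GridError):
            linear_spectrum(
                FFCFModel(static_amplitude=10.0), 2096.0, grid=(2090.0, 2102.0, 0.2)
            )


class TestFermiMultiplet:
    def test_no_mixing_no_map_is_pure_lorentzian(self):
        probe = ProbeThetaModel(fermi_coupling=0.0, bright_slope=0.0)
        spec = fermi_multiplet_spectrum(probe)
        fwhm = peak_fwhm(spec, smooth_window=1).fwhm
        assert fwhm == pytest.approx(probe.homogeneous_fwhm, rel=0.02)

    def test_maximal_restriction_collapses_to_homogeneous(self):
        probe = ProbeThetaModel(restriction=0.01)
        assert fermi_multiplet_fwhm(probe) == pytest.approx(
            probe.homogeneous_fwhm, abs=0.15
        )

    def test_width_monotone_in_restriction(self):
        widths = [
            fermi_multiplet_fwhm(ProbeThetaModel(restriction=r))
            for r in (0.1, 0.25, 0.4, 0.55, 0.7, 0.85, 1.0)
        ]
        assert np.all(np.diff(widths) > 0)

    def test_restriction_width_factor(self):
        """Loose vs tight packing: the default model spans the
        experimental width range (factor >= 1.8 between rho 1 and 0.35)."""
        loose = fermi_multiplet_fwhm(ProbeThetaModel(restriction=1.0))
        tight = fermi_multiplet_fwhm(ProbeThetaModel(restriction=0.35))
        assert loose / tight >= 1.8

    def test_high_frequency_shoulder_when_unrestricted(self):
        spec = fermi_multiplet_spectrum(ProbeThetaModel(restriction=1.0))
        x, y = spec.wavenumbers, spec.absorbance
        mode = x[np.argmax(y)]
        mean = np.sum(x * y) / np.sum(y)
        assert mean > mode + 1.0  # intensity skewed to high frequency

    def test_observed_branch_anchored_at_base_frequency(self):
        spec = fermi_multiplet_spectrum(ProbeThetaModel(restriction=0.2))
        peak = spec.wavenumbers[np.argmax(spec.absorbance)]
        assert peak == pytest.approx(2096.0, abs=1.5)

    def test_invalid_restriction_rejected(self):
        with pytest.raises(InvalidModelError):
            ProbeThetaModel(restriction=0.0)

    def test_theta_distribution_span_matches_kt_range(self):
        """The harmonic theta potential reaches k_B T (weight 1/e) exactly
        half a span away from equilibrium at 298 K, unrestricted."""
        probe = ProbeThetaModel()
        h = probe.theta_kt_span / 2.0
        weight = np.exp(-((h / (probe.restriction * h)) ** 2) * (298.15 / 298.15))
        assert weight == pytest.approx(np.exp(-1.0), rel=1e-9)
        assert probe.theta_sigma(25.0) == pytest.approx(h / np.sqrt(2.0), rel=0.01)


class TestTemperatureSeries:
    def test_step_across_transition(self):
        model = TemperatureSeriesModel()
        probe = ProbeThetaModel()
        below, above = generate_temperature_series(model, probe, [35.0, 45.0])
        w_below = peak_fwhm(below, smooth_window=1).fwhm
        w_above = peak_fwhm(above, smooth_window=1).fwhm
        assert w_above > w_below + 5.0

    def test_seeded_generation_reproducible_and_seed_sensitive(self):
        model = TemperatureSeriesModel()
        probe = ProbeThetaModel()
        kw = dict(noise_sd=0.02, grid=(2040.0, 2140.0, 0.5))
        a = generate_temperature_series(model, probe, [30.0, 42.0], seed=7, **kw)
        b = generate_temperature_series(model, probe, [30.0, 42.0], seed=7, **kw)
        c = generate_temperature_series(model, probe, [30.0, 42.0], seed=8, **kw)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.absorbance, sb.absorbance)
        assert not np.array_equal(a[0].absorbance, c[0].absorbance)

    def test_noise_requires_seed(self):
        with pytest.raises(InvalidModelError):
            generate_temperature_series(
                TemperatureSeriesModel(), ProbeThetaModel(), [25.0], noise_sd=0.01
            )

    def test_empty_temperatures_rejected(self):
        with pytest.raises(InvalidModelError):
            generate_temperature_series(TemperatureSeriesModel(), ProbeThetaModel(), [])
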