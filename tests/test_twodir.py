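"""2DIR analysis tests: center line, ICLS, fits, width decomposition."""

import numpy as np
import pytest

from azospec import (
    CenterLine,
    FFCFModel,
    ICLSTrace,
    Spectrum2D,
    extract_center_line,
    fit_biexponential,
    icls_series,
    icls_value,
    simulate_2dir,
    width_decomposition,
)
from azospec.errors import (
    DuplicateTimeError,
    InsufficientBandError,
    UnstableSlopeError,
)


def _bivariate_gaussian_spectrum(corr, sigma=8.0, center=2096.0):
    """Negative-going 2D band from an explicit bivariate normal density."""
    axis = center + np.arange(-40.0, 40.01, 0.5)
    dx = axis - center
    xx, yy = np.meshgrid(dx, dx, indexing="ij")
    q = (xx**2 - 2.0 * corr * xx * yy + yy**2) / (
        2.0 * sigma**2 * (1.0 - corr**2)
    )
    return Spectrum2D(axis, axis.copy(), -np.exp(-q), waiting_time=1.0)


class TestExtractCenterLine:
    def test_slope_matches_bivariate_gaussian_correlation(self):
        """For a bivariate normal band the center line slope equals the
        correlation coefficient exactly."""
        for corr in (0.3, 0.6, 0.9):
            line = extract_center_line(_bivariate_gaussian_spectrum(corr))
            slope, _ = icls_value(line)
            assert slope == pytest.approx(corr, rel=0.05)

    def test_homogeneous_band_has_zero_slope(self):
        spec = simulate_2dir(FFCFModel(pure_dephasing_time=0.8), 1.0)
        slope, _ = icls_value(extract_center_line(spec))
        assert slope == pytest.approx(0.0, abs=0.02)

    def test_translation_invariance(self):
        a = _bivariate_gaussian_spectrum(0.6)
        b = Spectrum2D(
            a.omega_tau + 3.0, a.omega_t + 3.0, a.signal, waiting_time=1.0
        )
        sa, _ = icls_value(extract_center_line(a))
        sb, _ = icls_value(extract_center_line(b))
        assert sb == pytest.approx(sa, abs=1e-9)

    def test_scaling_invariance(self):
        a = _bivariate_gaussian_spectrum(0.6)
        b = Spectrum2D(a.omega_tau, a.omega_t, a.signal * 37.0, waiting_time=1.0)
        sa, _ = icls_value(extract_center_line(a))
        sb, _ = icls_value(extract_center_line(b))
        assert sb == pytest.approx(sa, abs=1e-12)

    def test_positive_band_rejected(self):
        a = _bivariate_gaussian_spectrum(0.5)
        flipped = Spectrum2D(a.omega_tau, a.omega_t, -a.signal, waiting_time=1.0)
        with pytest.raises(InsufficientBandError):
            extract_center_line(flipped)


class TestICLSValue:
    def test_perfect_diagonal_is_unity(self):
        x = np.linspace(2090.0, 2102.0, 9)
        slope, err = icls_value(CenterLine(x, x.copy()))
        assert slope == pytest.approx(1.0)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_flat_line_is_zero(self):
        x = np.linspace(2090.0, 2102.0, 9)
        slope, _ = icls_value(CenterLine(x, np.full(x.size, 2096.0)))
        assert slope == pytest.approx(0.0)

    def test_degenerate_spread_rejected(self):
        x = np.linspace(2095.0, 2097.0, 6)
        with pytest.raises(UnstableSlopeError):
            icls_value(CenterLine(x, x.copy()))


class TestICLSSeries:
    def test_static_inhomogeneity_gives_flat_trace(self):
        """A purely static FFCF has no spectral diffusion: ICLS is
        independent of waiting time at the variance-ratio level."""
        model = FFCFModel(static_amplitude=10.0, pure_dephasing_time=0.8)
        specs = [simulate_2dir(model, tw) for tw in (0.2, 2.0, 8.0)]
        trace = icls_series(specs)
        assert np.ptp(trace.icls) < 0.01
        assert np.all(trace.icls > 0.4)

    def test_decaying_ffcf_gives_decreasing_trace(self):
        model = FFCFModel(components=((10.0, 2.0),), pure_dephasing_time=0.8)
        specs = [simulate_2dir(model, tw) for tw in (0.2, 1.0, 3.0, 6.0, 10.0, 16.0)]
        trace = icls_series(specs)
        assert np.all(np.diff(trace.icls) < 0.0)
        assert np.all(trace.icls >= -0.02) and np.all(trace.icls <= 1.0)

    def test_duplicate_waiting_times_rejected(self):
        model = FFCFModel(components=((10.0, 2.0),), pure_dephasing_time=0.8)
        spec = simulate_2dir(model, 1.0)
        with pytest.raises(DuplicateTimeError):
            icls_series([spec, spec])

    def test_single_exponential_time_recovered(self):
        """CLS decay tracks the FFCF correlation time (tau = 4 ps)."""
        tau = 4.0
        model = FFCFModel(components=((10.0, tau),), pure_dephasing_time=0.8)
        tws = np.array([0.15, 0.3, 0.6, 1.0, 1.5, 2.5, 4.0, 6.0]) * tau
        trace = icls_series([simulate_2dir(model, tw) for tw in tws])
        fit = fit_biexponential(trace)
        recovered = fit.mean_time if fit.model_selected == "biexponential" else fit.tau1
        assert recovered == pytest.approx(tau, rel=0.15)


class TestFitBiexponential:
    def test_exact_samples_recovered_to_one_percent(self):
        t = np.array(
            [0.1, 0.2, 0.3, 0.45, 0.6, 0.8, 1.0, 1.4, 1.9, 2.6, 3.5, 5.0,
             7.0, 10.0, 14.0, 19.0, 25.0]
        )
        y = 0.4 * np.exp(-t / 0.5) + 0.4 * np.exp(-t / 3.8) + 0.1
        fit = fit_biexponential(ICLSTrace(t, y, np.full(t.size, 1e-3)))
        assert fit.model_selected == "biexponential"
        assert fit.a1 == pytest.approx(0.4, rel=0.01)
        assert fit.tau1 == pytest.approx(0.5, rel=0.01)
        assert fit.a2 == pytest.approx(0.4, rel=0.01)
        assert fit.tau2 == pytest.approx(3.8, rel=0.01)
        assert fit.offset == pytest.approx(0.1, rel=0.01)
        assert fit.mean_time == pytest.approx((0.4 * 0.5 + 0.4 * 3.8) / 0.8, rel=0.01)

    def test_constant_trace_degenerates_to_offset(self):
        t = np.linspace(0.2, 20.0, 10)
        fit = fit_biexponential(ICLSTrace(t, np.full(t.size, 0.37), np.full(t.size, 0.01)))
        assert fit.model_selected == "constant"
        assert fit.a1 == 0.0 and fit.a2 == 0.0
        assert fit.offset == pytest.approx(0.37)

    def test_single_exponential_data_selects_single_model(self):
        t = np.linspace(0.2, 20.0, 12)
        y = 0.5 * np.exp(-t / 3.0) + 0.05
        fit = fit_biexponential(ICLSTrace(t, y, np.full(t.size, 1e-3)))
        assert fit.model_selected == "exponential"
        assert fit.tau1 == pytest.approx(3.0, rel=0.02)


class TestWidthDecomposition:
    def test_homogeneous_band_is_round(self):
        spec = simulate_2dir(FFCFModel(pure_dephasing_time=0.8), 0.2, kind="rephasing")
        d = width_decomposition(spec)
        assert d.diagonal_fwhm / d.antidiagonal_fwhm == pytest.approx(1.0, abs=0.05)

    def test_static_inhomogeneity_recovered_from_diagonal(self):
        delta0 = 10.0
        spec = simulate_2dir(
            FFCFModel(static_amplitude=delta0, pure_dephasing_time=4.0),
            0.2,
            kind="rephasing",
        )
        d = width_decomposition(spec)
        gauss_fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * delta0
        assert d.diagonal_fwhm / d.antidiagonal_fwhm > 2.0
        assert d.inhomogeneous_estimate == pytest.approx(gauss_fwhm, rel=0.10)

    def test_antidiagonal_width_depth_independent(self):
        """Two 'depths' (inhomogeneity levels) share the homogeneous
        antidiagonal width while the diagonal width orders with Delta0."""
        decomps = [
            width_decomposition(
                simulate_2dir(
                    FFCFModel(static_amplitude=d0, pure_dephasing_time=4.0),
                    0.2,
                    kind="rephasing",
                )
            )
            for d0 in (6.0, 12.0)
        ]
        a0, a1 = (d.antidiagonal_fwhm for d in decomps)
        assert abs(a1 - a0) / a0 < 0.05
        assert decomps[1].diagonal_fwhm > decomps[0].diagonal_fwhm

    def test_consistent_with_linear_spectrum(self):
        """Diagonal width of the matched 2D model tracks the 1D FWHM."""
        from azospec import linear_spectrum, peak_fwhm

        model = FFCFModel(static_amplitude=9.0, pure_dephasing_time=4.0)
        one_d = peak_fwhm(linear_spectrum(model, 2096.0), smooth_window=1).fwhm
        d = width_decomposition(simulate_2dir(model, 0.2, kind="rephasing"))
        assert d.diagonal_fwhm == pytest.approx(one_d, rel=0.10)

    def test_rescaled_signal_gives_identical_widths(self):
        spec = simulate_2dir(
            FFCFModel(static_amplitude=8.0, pure_dephasing_time=3.0),
            0.2,
            kind="rephasing",
        )
        scaled = Spectrum2D(
            spec.omega_tau,
            spec.omega_t,
            spec.signal * 5.5,
            waiting_time=spec.waiting_time,
            kind=spec.kind,
            metadata=spec.metadata,
        )
        a = width_decomposition(spec)
        b = width_decomposition(scaled)
        assert b.diagonal_fwhm == pytest.approx(a.diagonal_fwhm, rel=1e-9)
        assert b.antidiagonal_fwhm == pytest.approx(a.antidiagonal_fwhm, rel=1e-9)


class TestSimulate2DIR:
    def test_absorptive_has_both_bands(self):
        spec = simulate_2dir(FFCFModel(static_amplitude=8.0, pure_dephasing_time=2.0), 0.5)
        assert spec.signal.min() == pytest.approx(-1.0)
        assert spec.signal.max() > 0.3

    def test_diagonal_symmetry_at_zero_waiting_time(self):
        """The 0->1 band is reflection-symmetric across the diagonal at
        T_w = 0 (anharmonicity pushed far away to isolate the band)."""
        spec = simulate_2dir(
            FFCFModel(static_amplitude=8.0, pure_dephasing_time=2.0),
            0.0,
            anharmonicity=60.0,
            grid=(2060.0, 2132.0, 0.5),
        )
        core = (spec.signal < -0.05) & (spec.signal.T < -0.05)
        asym = np.max(np.abs(spec.signal - spec.signal.T)[core])
        assert asym < 0.02

    def test_overlap_warning_recorded(self):
        spec = simulate_2dir(
            FFCFModel(static_amplitude=10.0, pure_dephasing_time=1.0),
            0.5,
            anharmonicity=8.0,
        )
        assert spec.metadata["warnings"]
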