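"""FTIR band analysis: background, width, phase transition, order parameter.

The nu_N3 band of the azido probe is non-Gaussian (high-frequency
shoulder), so the peak width is measured shape-free from the outermost
half-maximum crossings rather than by model fitting; a Voigt-fit width is
offered separately but is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import (
    AmbiguousPeakError,
    InvalidModelError,
    NoBaselineError,
    OutOfRangeError,
)
from .models import OrderParameterSpec, PeakReport, Spectrum1D, WidthSeries

__all__ = [
    "subtract_background",
    "peak_fwhm",
    "voigt_fwhm",
    "TransitionResult",
    "transition_temperature",
    "OrderParameterResult",
    "order_parameter",
    "width_series_from_spectra",
]


def subtract_background(
    spectrum: Spectrum1D,
    band_window: Tuple[float, float],
    poly_order: int = 1,
) -> Spectrum1D:
    """Remove a polynomial baseline fitted to the regions flanking the band.

    The polynomial (degree ``poly_order``) is fitted only to points outside
    ``band_window`` and subtracted everywhere.  Each flanking region must
    contain at least 10 points.
    """
    lo, hi = sorted(map(float, band_window))
    x = spectrum.wavenumbers
    if lo <= x[0] or hi >= x[-1]:
        raise NoBaselineError(
            "band_window must lie strictly inside the spectral axis"
        )
    mask = (x < lo) | (x > hi)
    if np.count_nonzero(x < lo) < 10 or np.count_nonzero(x > hi) < 10:
        raise NoBaselineError("each flanking baseline region needs >= 10 points")
    coeffs = np.polynomial.polynomial.polyfit(
        x[mask], spectrum.absorbance[mask], poly_order
    )
    baseline = np.polynomial.polynomial.polyval(x, coeffs)
    return Spectrum1D(
        x.copy(),
        spectrum.absorbance - baseline,
        temperature=spectrum.temperature,
        chain_length=spectrum.chain_length,
        label=spectrum.label,
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def peak_fwhm(spectrum: Spectrum1D, smooth_window: int = 5) -> PeakReport:
    """Shape-free center and FWHM of the dominant band.

    The center comes from parabolic interpolation through the maximum
    sample and its neighbours; the FWHM from linear interpolation of the
    two outermost half-maximum crossings (robust for shouldered bands).
    Light smoothing (moving average, ``smooth_window`` points) is applied
    only inside crossing detection, never to the stored data.  More than
    two crossings after smoothing raise :class:`AmbiguousPeakError`.
    """
    x = spectrum.wavenumbers
    y = spectrum.absorbance
    ys = _moving_average(y, smooth_window)

    i = int(np.argmax(ys))
    if i == 0 or i == y.size - 1:
        raise AmbiguousPeakError("band maximum sits on the axis edge", 0)
    # parabolic refinement of the apex on the raw data
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    center = x[i] + shift * spectrum.step
    height = y1 - 0.25 * (y0 - y2) * shift

    half = 0.5 * height
    above = ys >= half  # points exactly at half count as above
    sign_change = np.where(np.diff(above.astype(int)) != 0)[0]
    if sign_change.size < 2:
        raise AmbiguousPeakError(
            f"found {sign_change.size} half-maximum crossings", sign_change.size
        )
    if sign_change.size > 2:
        raise AmbiguousPeakError(
            f"found {sign_change.size} half-maximum crossings", sign_change.size
        )

    def _interp(j):
        return x[j] + (half - ys[j]) * (x[j + 1] - x[j]) / (ys[j + 1] - ys[j])

    left = _interp(sign_change[0])
    right = _interp(sign_change[-1])
    return PeakReport(center=float(center), fwhm=float(right - left),
                      peak_height=float(height))


def voigt_fwhm(spectrum: Spectrum1D) -> PeakReport:
    """Width from a Voigt profile fit (alternative to the crossing method).

    Provided for comparison only; the shouldered nu_N3 band is not Voigt
    shaped and the default analysis never uses this estimate.
    """
    from lmfit.models import VoigtModel

    x = spectrum.wavenumbers
    y = spectrum.absorbance
    model = VoigtModel()
    params = model.guess(y, x=x)
    params["gamma"].set(value=params["sigma"].value, vary=True, min=0)
    result = model.fit(y, params, x=x)
    fwhm = float(result.params["fwhm"].value)
    return PeakReport(
        center=float(result.params["center"].value),
        fwhm=fwhm,
        peak_height=float(result.eval(x=np.array([result.params["center"].value]))[0]),
        baseline_model="voigt-fit",
    )


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of a phase-transition search on a width series.

    ``temperature`` is None when no step is statistically distinguishable
    from zero at 95 % confidence (a no-transition result, not an error).
    """

    temperature: Optional[float]
    step_size: float
    step_stderr: float
    temperature_stderr: float = np.nan
    method: str = "sigmoid"
    significant: bool = True


def transition_temperature(series: WidthSeries) -> TransitionResult:
    """Locate the bilayer phase transition in a width-vs-temperature series.

    Fits width(T) = base + drift*(T - T_min) + A / (1 + exp(-(T - T0)/w))
    by least squares, initialized deterministically (midpoint at the
    maximum finite-difference temperature, amplitude from endpoint means).
    Falls back to the maximum finite-difference derivative when the fit
    fails, flagging ``method='derivative'``.
    """
    t = series.temperatures
    y = series.widths
    if t.size < 5:
        raise InvalidModelError("need >= 5 temperature points")

    d = np.diff(y) / np.diff(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    i_max = int(np.argmax(d))
    n_edge = max(2, t.size // 5)
    amp0 = float(np.mean(y[-n_edge:]) - np.mean(y[:n_edge]))
    base0 = float(np.mean(y[:n_edge]))
    p0 = [base0, 0.0, max(amp0, 1e-3), float(t_mid[i_max]), 1.0]

    from scipy.optimize import curve_fit

    def f(tt, base, drift, amplitude, midpoint, width):
        return (
            base
            + drift * (tt - t[0])
            + amplitude / (1.0 + np.exp(-(tt - midpoint) / width))
        )

    try:
        popt, pcov = curve_fit(
            f,
            t,
            y,
            p0=p0,
            bounds=(
                [-np.inf, -np.inf, 0.0, t[0] - 5.0, 0.1],
                [np.inf, np.inf, np.inf, t[-1] + 5.0, 0.5 * (t[-1] - t[0])],
            ),
            maxfev=20000,
        )
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        amplitude, midpoint = popt[2], popt[3]
        amp_err, mid_err = perr[2], perr[3]
        significant = bool(
            np.isfinite(amp_err) and amplitude - 1.96 * amp_err > 0.0
        )
        if not significant:
            return TransitionResult(
                temperature=None,
                step_size=float(amplitude),
                step_stderr=float(amp_err),
                significant=False,
            )
        return TransitionResult(
            temperature=float(midpoint),
            step_size=float(amplitude),
            step_stderr=float(amp_err),
            temperature_stderr=float(mid_err),
        )
    except RuntimeError:
        return TransitionResult(
            temperature=float(t_mid[i_max]),
            step_size=float(np.max(d) * (t[1] - t[0])),
            step_stderr=np.nan,
            method="derivative",
        )


@dataclass(frozen=True)
class OrderParameterResult:
    value: float
    clamped: bool = False


def order_parameter(
    width: float, spec: OrderParameterSpec = OrderParameterSpec()
) -> OrderParameterResult:
    """S_N3 = (width_max - width) / (width_max - width_min).

    Maps the nu_N3 band width onto [0, 1]: 1 at the narrowest band
    (most restricted probe environment), 0 at the broadest.  Widths within
    2 cm^-1 outside the endpoint interval are clamped with a flag; widths
    further out raise :class:`OutOfRangeError`.
    """
    tol = 2.0
    if not (spec.width_min - tol <= width <= spec.width_max + tol):
        raise OutOfRangeError(
            f"width {width} cm^-1 outside admissible band "
            f"[{spec.width_min - tol}, {spec.width_max + tol}]"
        )
    s = (spec.width_max - width) / (spec.width_max - spec.width_min)
    if 0.0 <= s <= 1.0:
        return OrderParameterResult(float(s))
    return OrderParameterResult(float(np.clip(s, 0.0, 1.0)), clamped=True)


def width_series_from_spectra(spectra, smooth_window: int = 5) -> WidthSeries:
    """Measure peak_fwhm on a list of Spectrum1D and sort by temperature."""
    temps, widths = [], []
    for s in spectra:
        if s.temperature is None:
            raise InvalidModelError("every spectrum needs a temperature")
        temps.append(s.temperature)
        widths.append(peak_fwhm(s, smooth_window=smooth_window).fwhm)
    order = np.argsort(temps)
    chain = spectra[0].chain_length if spectra else None
    return WidthSeries(
        np.asarray(temps)[order],
        np.asarray(widths)[order],
        chain_length=chain,
        label=spectra[0].label if spectra else "",
    )
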