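"""Domain types for depth-resolved vibrational-probe spectroscopy.

Unit conventions (used package-wide): wavenumbers in cm^-1, times in
picoseconds, temperatures in degrees Celsius unless a name says Kelvin,
angles in degrees, depths in Angstrom.  The angular-frequency conversion
2*pi*c (c in cm/ps) is applied only inside lineshape math, never in the
user-facing fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidModelError

#: speed of light in cm per ps
C_CM_PER_PS = 2.99792458e-2
#: cm^-1 -> rad/ps
TWO_PI_C = 2.0 * np.pi * C_CM_PER_PS
#: absolute zero in Celsius
ZERO_CELSIUS_K = 273.15
#: reference temperature for the theta potential calibration (25 C)
THETA_REF_K = 298.15


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidModelError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidModelError(f"{name} contains non-finite values")
    return arr


def _check_uniform_ascending(axis: np.ndarray, name: str, rtol: float = 1e-6) -> float:
    """Return the (constant) step of a strictly ascending uniform axis."""
    if axis.size < 2:
        raise InvalidModelError(f"{name} needs at least 2 points")
    steps = np.diff(axis)
    if np.any(steps <= 0):
        raise InvalidModelError(f"{name} must be strictly ascending")
    step = float(np.mean(steps))
    if np.max(np.abs(steps - step)) > rtol * max(step, 1.0):
        raise InvalidModelError(f"{name} must be uniformly spaced")
    return step


@dataclass(frozen=True)
class FFCFModel:
    """Frequency-frequency correlation function (FFCF) of a probe mode.

    C(t) = sum_i Delta_i^2 exp(-t/tau_i) + Delta_0^2   [cm^-2]

    The FFCF is the average probability that a frequency component of the
    inhomogeneous distribution retains its frequency after a delay t; its
    decay timescales are the spectral-diffusion timescales seen by 2DIR.

    Parameters
    ----------
    components
        Sequence of (Delta_i [cm^-1], tau_i [ps]) exponential terms.
    static_amplitude
        Delta_0 [cm^-1]; inhomogeneity that does not decay on the
        experimental window (plateau term).
    pure_dephasing_time
        T2* [ps], homogeneous pure dephasing. ``inf`` disables it.
    lifetime
        T1 [ps], vibrational population lifetime. ``inf`` disables it.
    """

    components: tuple = ()
    static_amplitude: float = 0.0
    pure_dephasing_time: float = np.inf
    lifetime: float = np.inf

    def __post_init__(self):
        comps = tuple((float(d), float(tau)) for d, tau in self.components)
        object.__setattr__(self, "components", comps)
        for d, tau in comps:
            if d < 0:
                raise InvalidModelError(f"negative FFCF amplitude {d}")
            if tau <= 0:
                raise InvalidModelError(f"non-positive correlation time {tau}")
        if self.static_amplitude < 0:
            raise InvalidModelError("negative static amplitude")
        if self.pure_dephasing_time <= 0:
            raise InvalidModelError("pure_dephasing_time must be positive")
        if self.lifetime <= 0:
            raise InvalidModelError("lifetime must be positive")

    def evaluate(self, t) -> np.ndarray:
        """C(t) in cm^-2 on an arbitrary array of times (ps)."""
        t = np.asarray(t, dtype=float)
        c = np.full(t.shape, self.static_amplitude**2)
        for d, tau in self.components:
            c = c + d**2 * np.exp(-t / tau)
        return c

    @property
    def total_variance(self) -> float:
        """C(0) = total inhomogeneous variance in cm^-2."""
        return float(sum(d**2 for d, _ in self.components) + self.static_amplitude**2)

    @property
    def total_dephasing_time(self) -> float:
        """T2 [ps] combining pure dephasing and lifetime: 1/T2 = 1/T2* + 1/(2 T1)."""
        rate = 0.0
        if np.isfinite(self.pure_dephasing_time):
            rate += 1.0 / self.pure_dephasing_time
        if np.isfinite(self.lifetime):
            rate += 1.0 / (2.0 * self.lifetime)
        return np.inf if rate == 0.0 else 1.0 / rate


@dataclass(frozen=True)
class ProbeThetaModel:
    """Internal-inhomogeneity model of the azido probe.

    The soft CNN bending angle theta carries most of the probe's intrinsic
    inhomogeneity: a bright nu_N3 fundamental and a Fermi-coupled dark
    combination state, both linear in theta, are mixed by a strong
    third-order coupling W, and theta is Boltzmann-distributed in a
    harmonic potential whose stiffness is scaled by 1/restriction^2 — a
    tightly packed environment (small ``restriction``) narrows the allowed
    theta range and hence the band.

    Parameters
    ----------
    base_frequency
        Position [cm^-1] of the observed (bright-dominant) Fermi branch at
        theta_equilibrium; the uncoupled states are placed so the mixed
        lower eigenstate lands here.
    dark_state_offset
        Dark-state frequency minus bright-state frequency at
        theta_equilibrium [cm^-1] (before mixing).
    theta_slope
        Dark-state frequency slope [cm^-1/deg] — the strong theta map.
    bright_slope
        Bright-state frequency slope [cm^-1/deg].
    fermi_coupling
        W [cm^-1], the 2x2 Fermi-resonance coupling.
    theta_equilibrium
        Potential minimum theta_0 [deg].
    theta_kt_span
        Full theta span [deg] for which the harmonic potential energy stays
        within k_B T at 298 K when unrestricted (restriction = 1).
    restriction
        rho in (0, 1]; 1 = unrestricted, smaller = tighter packing.
    homogeneous_fwhm
        Lorentzian FWHM [cm^-1] convolved onto the stick multiplet.
    """

    base_frequency: float = 2096.0
    dark_state_offset: float = 40.0
    theta_slope: float = 5.0
    bright_slope: float = 2.0
    fermi_coupling: float = 30.0
    theta_equilibrium: float = 116.0
    theta_kt_span: float = 11.0
    restriction: float = 1.0
    homogeneous_fwhm: float = 8.0

    def __post_init__(self):
        if self.theta_slope <= 0:
            raise InvalidModelError("theta_slope must be positive")
        if self.fermi_coupling < 0:
            raise InvalidModelError("fermi_coupling must be non-negative")
        if not (0.0 < self.restriction <= 1.0):
            raise InvalidModelError("restriction must lie in (0, 1]")
        if self.theta_kt_span <= 0:
            raise InvalidModelError("theta_kt_span must be positive")
        if self.homogeneous_fwhm <= 0:
            raise InvalidModelError("homogeneous_fwhm must be positive")

    def with_restriction(self, rho: float) -> "ProbeThetaModel":
        from dataclasses import replace

        return replace(self, restriction=rho)

    def theta_sigma(self, temperature_c: float = 25.0) -> float:
        """Std dev [deg] of the Boltzmann theta distribution.

        The harmonic stiffness is fixed so that at 298 K, restriction 1,
        the energy stays within k_B T over a span ``theta_kt_span``; the
        Boltzmann weight is then exp(-(dtheta / (rho h))^2 * 298/T) with
        h = theta_kt_span / 2, i.e. sigma = rho h sqrt(T/298) / sqrt(2).
        """
        t_k = temperature_c + ZERO_CELSIUS_K
        if t_k <= 0:
            raise InvalidModelError("temperature below absolute zero")
        h = self.theta_kt_span / 2.0
        return self.restriction * h * np.sqrt(t_k / THETA_REF_K) / np.sqrt(2.0)


@dataclass(frozen=True)
class TemperatureSeriesModel:
    """Width-versus-temperature behaviour across the Lbeta-Lalpha transition.

    The gel -> liquid-crystalline transition of DPPC (~41 C) releases the
    packing restriction on the probe's theta angle, stepping the nu_N3
    width from ``width_below`` to ``width_above``; the homogeneous
    component additionally scales as sqrt(T) in Kelvin.
    """

    transition_temperature: float = 41.0
    transition_width: float = 1.0
    width_below: float = 14.0
    width_above: float = 28.0
    homogeneous_ref_fwhm: float = 8.0
    reference_temperature: float = 25.0

    def __post_init__(self):
        if self.transition_width <= 0:
            raise InvalidModelError("transition_width must be positive")
        if not (self.width_below > 0 and self.width_above > 0):
            raise InvalidModelError("widths must be positive")
        if self.width_above < self.width_below:
            raise InvalidModelError(
                "width_above must be >= width_below (disorder grows through the transition)"
            )


@dataclass
class Spectrum1D:
    """A 1D absorption spectrum on a uniform ascending wavenumber axis."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    temperature: Optional[float] = None
    chain_length: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        self.wavenumbers = _as_1d(self.wavenumbers, "wavenumbers")
        self.absorbance = _as_1d(self.absorbance, "absorbance")
        if self.wavenumbers.size != self.absorbance.size:
            raise InvalidModelError("axis and absorbance lengths differ")
        self.step = _check_uniform_ascending(self.wavenumbers, "wavenumbers")

    def normalized(self) -> "Spectrum1D":
        peak = float(np.max(self.absorbance))
        if peak <= 0:
            raise InvalidModelError("cannot normalize a non-positive spectrum")
        return Spectrum1D(
            self.wavenumbers.copy(),
            self.absorbance / peak,
            temperature=self.temperature,
            chain_length=self.chain_length,
            label=self.label,
        )


@dataclass
class Spectrum2D:
    """A 2DIR spectrum: excitation axis omega_tau x detection axis omega_t.

    ``signal[i, j]`` corresponds to (omega_tau[i], omega_t[j]); the 0->1
    band is negative-going, the anharmonically shifted 1->2 band
    positive-going (absorptive kind).
    """

    omega_tau: np.ndarray
    omega_t: np.ndarray
    signal: np.ndarray
    waiting_time: float
    kind: str = "absorptive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.omega_tau = _as_1d(self.omega_tau, "omega_tau")
        self.omega_t = _as_1d(self.omega_t, "omega_t")
        _check_uniform_ascending(self.omega_tau, "omega_tau")
        _check_uniform_ascending(self.omega_t, "omega_t")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (self.omega_tau.size, self.omega_t.size):
            raise InvalidModelError(
                f"signal shape {self.signal.shape} does not match axes "
                f"({self.omega_tau.size}, {self.omega_t.size})"
            )
        if self.kind not in ("absorptive", "rephasing"):
            raise InvalidModelError(f"unknown spectrum kind {self.kind!r}")
        if self.waiting_time < 0:
            raise InvalidModelError("waiting_time must be >= 0")


@dataclass(frozen=True)
class PeakReport:
    """Result of a 1D peak-width measurement."""

    center: float
    fwhm: float
    peak_height: float
    baseline_model: str = "none"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise InvalidModelError("fwhm must be positive")


@dataclass(frozen=True)
class OrderParameterSpec:
    """Endpoints of the S_N3 order parameter.

    ``width_max`` is the broadest nu_N3 band among bilayer locations
    (probe near the carbonyl region), ``width_min`` the narrowest (probe
    mid-leaflet, gel phase, 22 C).
    """

    width_max: float = 31.0
    width_min: float = 14.0

    def __post_init__(self):
        if not (self.width_max > self.width_min > 0):
            raise InvalidModelError("require width_max > width_min > 0")


@dataclass
class WidthSeries:
    """nu_N3 peak width as a function of temperature for one compound."""

    temperatures: np.ndarray
    widths: np.ndarray
    chain_length: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        self.temperatures = _as_1d(self.temperatures, "temperatures")
        self.widths = _as_1d(self.widths, "widths")
        if self.temperatures.size != self.widths.size:
            raise InvalidModelError("temperatures and widths lengths differ")
        if np.any(np.diff(self.temperatures) <= 0):
            raise InvalidModelError("temperatures must be strictly ascending")


@dataclass
class CenterLine:
    """Locus of slice extrema of the 0->1 band of a 2DIR spectrum."""

    omega_tau: np.ndarray
    omega_t_star: np.ndarray
    band: str = "0->1"
    slice_range: tuple = ()

    def __post_init__(self):
        self.omega_tau = _as_1d(self.omega_tau, "omega_tau")
        self.omega_t_star = _as_1d(self.omega_t_star, "omega_t_star")
        if self.omega_tau.size != self.omega_t_star.size:
            raise InvalidModelError("center-line coordinate lengths differ")
        if self.omega_tau.size < 5:
            raise InvalidModelError("a center line needs at least 5 points")
        if np.any(np.diff(self.omega_tau) <= 0):
            raise InvalidModelError("omega_tau must be strictly ascending")


@dataclass
class ICLSTrace:
    """Inverse center line slope versus waiting time."""

    waiting_times: np.ndarray
    icls: np.ndarray
    stderr: np.ndarray

    def __post_init__(self):
        self.waiting_times = _as_1d(self.waiting_times, "waiting_times")
        self.icls = _as_1d(self.icls, "icls")
        self.stderr = _as_1d(self.stderr, "stderr")
        if not (self.waiting_times.size == self.icls.size == self.stderr.size):
            raise InvalidModelError("trace array lengths differ")
        if np.any(np.diff(self.waiting_times) <= 0):
            raise InvalidModelError("waiting times must be strictly ascending")
        if np.any(self.icls < -0.1) or np.any(self.icls > 1.1):
            raise InvalidModelError("ICLS values outside [-0.1, 1.1]")


@dataclass(frozen=True)
class BiexpFit:
    """Double-exponential + plateau fit of an ICLS trace.

    model: icls(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + C, tau1 < tau2.
    ``model_selected`` records which model won the AICc comparison
    ('biexponential', 'exponential' or 'constant'); for the simpler models
    unused parameters are zero.
    """

    a1: float
    tau1: float
    a2: float
    tau2: float
    offset: float
    stderr: dict
    model_selected: str = "biexponential"

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0 or self.offset < 0:
            raise InvalidModelError("amplitudes and offset must be >= 0")
        if self.a1 + self.a2 + self.offset > 1.1:
            raise InvalidModelError("total amplitude exceeds 1.1")

    @property
    def mean_time(self) -> float:
        """Amplitude-weighted mean decay time (A1 tau1 + A2 tau2)/(A1 + A2)."""
        denom = self.a1 + self.a2
        if denom == 0:
            return np.nan
        return (self.a1 * self.tau1 + self.a2 * self.tau2) / denom

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.offset)
        if self.a1 > 0 and self.tau1 > 0:
            out = out + self.a1 * np.exp(-t / self.tau1)
        if self.a2 > 0 and self.tau2 > 0:
            out = out + self.a2 * np.exp(-t / self.tau2)
        return out


@dataclass(frozen=True)
class WidthDecomposition:
    """Homogeneous/inhomogeneous split from a rephasing 2D band.

    Both profile widths are measured in detection-axis projection units so
    that the diagonal width of a statically inhomogeneous band equals the
    1D inhomogeneous FWHM.
    """

    diagonal_fwhm: float
    antidiagonal_fwhm: float
    inhomogeneous_estimate: float
    homogeneous_estimate: float

    def __post_init__(self):
        if self.diagonal_fwhm <= 0 or self.antidiagonal_fwhm <= 0:
            raise InvalidModelError("profile widths must be positive")
        if self.diagonal_fwhm < self.antidiagonal_fwhm * (1 - 0.05):
            raise InvalidModelError("diagonal width below antidiagonal width")


@dataclass(frozen=True)
class ChainGeometry:
    """All-anti alkyl chain geometry."""

    cc_bond_length: float = 1.54
    ccc_angle: float = 113.3

    def __post_init__(self):
        if not (1.0 < self.cc_bond_length < 2.0):
            raise InvalidModelError("cc_bond_length must lie in (1, 2) Angstrom")
        if not (90.0 < self.ccc_angle < 180.0):
            raise InvalidModelError("ccc_angle must lie in (90, 180) degrees")


@dataclass(frozen=True)
class DepthRecord:
    """Depth of the central azido nitrogen below the head-group region.

    z is measured from the plane separating the two leaflets; larger z is
    closer to the head groups.
    """

    chain_length: Optional[int]
    depth: float
    dispersion: float = 0.0
    temperature_label: str = ""
    midplane_crossing: bool = False

    def __post_init__(self):
        if self.depth < 0:
            raise InvalidModelError("depth must be >= 0")
        if self.chain_length is not None and (
            self.chain_length <= 0 or int(self.chain_length) != self.chain_length
        ):
            raise InvalidModelError("chain_length must be a positive integer")
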