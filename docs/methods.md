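# Methods

This note documents the models behind `azospec`, the defaults and why
they were chosen, the numerical machinery, and what the synthetic-data
tests do and do not demonstrate about real spectra.

## Units and conventions

Wavenumbers are cm⁻¹, times ps, temperatures °C (Kelvin only where a name
says so), angles degrees, depths Å. The angular-frequency conversion
2πc (c = 0.0299792458 cm/ps) is applied only inside lineshape math.
Absorptive 2DIR spectra are normalized so the 0→1 band extremum is −1;
the anharmonically red-shifted 1→2 band is positive. `signal[i, j]`
corresponds to (ω_τ[i], ω_t[j]).

## Kubo lineshape machinery

An `FFCFModel` holds C(t) = Σᵢ Δᵢ² exp(−t/τᵢ) + Δ₀² (cm⁻²) plus a pure
dephasing time T₂\* and a lifetime T₁. The line-broadening function uses
the closed forms

    g_exp(t)   = (2πc Δ)² τ² (e^{−t/τ} + t/τ − 1),
    g_static(t) = (2πc Δ₀)² t² / 2,

so no numerical double integration is ever needed (a quadrature oracle in
the tests confirms the closed form). The linear spectrum is the cosine
transform of exp(−g(t) − t/(2T₁) − t/T₂\*) on a 5 fs grid of 4096 points
(20.48 ps record), cosine-squared apodized over the final 5 % and
zero-padded to 2¹⁶ (0.10 cm⁻¹ sampling); this resolves 2–35 cm⁻¹ widths
without ringing, and the Lorentzian (FWHM = 1/(πcT₂)) and Gaussian
(FWHM = 2√(2 ln 2) Δ₀) limits are reproduced to ≲0.1 %.

The 2DIR simulator evaluates the third-order response in the
second-cumulant approximation with fully correlated fluctuations on both
transitions and harmonic dipole scaling:

    rephasing:     exp[−g(t₁)+g(t₂)−g(t₃)−g(t₁+t₂)−g(t₂+t₃)+g(t₁+t₂+t₃)]
    nonrephasing:  exp[−g(t₁)−g(t₂)−g(t₃)+g(t₁+t₂)+g(t₂+t₃)−g(t₁+t₂+t₃)]

on 128 × 128 coherence-time grids (60 fs step, 25 % cos² apodization,
half-weighted t = 0 points), with the 1→2 pathway carrying the opposite
sign and an e^{+i 2πc Δ_anh t₃} phase. The spectrum is obtained by
explicit DFT onto the requested frequency axes in the rotating frame of
the band center; absorptive = Re[rephasing + nonrephasing],
`kind="rephasing"` returns the negated magnitude of the echo-only signal
(the input to ellipticity/width analysis). Magnitude spectra carry 1/ω
tails, so the default rephasing window is much wider (±10 estimated
widths) than the absorptive one (±3). If the 1→2 wing displaces the
apparent 0→1 extremum by > 0.5 cm⁻¹ a note is recorded in
`metadata["warnings"]`.

The ν_N3 anharmonicity is not a measured input here; the default 25 cm⁻¹
(typical for azides) keeps the band pair resolvable and is configurable.

## The restricted θ-angle Fermi-multiplet band

`ProbeThetaModel` caricatures the probe's intrinsic inhomogeneity with
one bright fundamental and one dark combination state, both linear in the
CNN bend angle θ, mixed by a 2×2 Fermi coupling W:

* dark-state slope 5 cm⁻¹/deg (the θ-frequency map), bright slope
  2 cm⁻¹/deg;
* W = 30 cm⁻¹; dark state 40 cm⁻¹ above the bright state at θ₀
  (before mixing);
* harmonic θ potential whose energy reaches k_BT at 298 K over a full
  span of 11° when unrestricted; a restriction factor ρ ∈ (0, 1] scales
  the stiffness by 1/ρ², so the Boltzmann σ_θ = ρ·(span/2)·√(T/298)/√2;
* θ discretized at 0.05° over θ₀ ± 4 thermal half-ranges; both
  eigenstates deposited as sticks weighted by their bright-state
  character (intensity borrowing), then convolved with a homogeneous
  Lorentzian (default FWHM 8 cm⁻¹).

The uncoupled states are anchored so the *observed* (bright-dominant,
lower) branch sits at `base_frequency` (2096 cm⁻¹) at θ₀. With a 2×2
treatment the choice of the dark-state offset is constrained: for the
partner branch to stay below half maximum (so the band reads as a single
peak with a high-frequency shoulder rather than a resolved doublet) the
offset must exceed W/√2 ≈ 21 cm⁻¹. The default offset (40) and bright
slope (2) were fixed, before any closed-loop testing, by scanning the
model's FWHM(ρ) curve for a parameterization that (a) collapses to the
homogeneous width as ρ → 0, (b) keeps the partner branch below half
maximum at every ρ, and (c) spans the experimentally relevant 14–31 cm⁻¹
width range over ρ ∈ [0.35, 1]; the shipped defaults give 13.6 cm⁻¹ at
ρ = 0.35 and 28.6 cm⁻¹ at ρ = 1. The partner branch then sits ~72 cm⁻¹
above the main band at ~28 % relative intensity; the default working grid
(2040–2140 cm⁻¹) excludes it, mimicking an analysis window on real data
where that intensity is dispersed over many combination states instead.

What this model does *not* capture: the real multiplet involves many
CH₂-wagging/rocking combination states, polarity-dependent broadening,
and non-harmonic θ potentials. Passing the closed-loop tests shows the
*analysis* chain is faithful for bands of realistic shape and width, not
that the two-state caricature is spectroscopically complete.

## Temperature series and the phase transition

`TemperatureSeriesModel` maps temperature to restriction through a
logistic step centered at the transition temperature (default 41 °C,
width 1 °C): the restriction endpoints are obtained by inverting the
model's FWHM(ρ) curve at the target widths below/above the transition
(clamped to the attainable range), and the homogeneous Lorentzian scales
as √T (Kelvin) from its 25 °C reference. Gaussian noise (i.i.d. per
point on the normalized absorbance) requires a seed; generation is
bit-reproducible.

`transition_temperature` fits width(T) = base + drift·(T − T_min) +
A/(1 + exp(−(T − T₀)/w)) with deterministic initialization (midpoint at
the maximum finite difference, amplitude from endpoint means), falls back
to the maximum-derivative estimate if the fit fails (flagged), and
returns a no-transition result — not an exception — when the step
amplitude is indistinguishable from zero at 95 % confidence. The noisy
closed loop (SNR 20, 1 °C sampling, 22–45 °C) recovers 41 ± 1 °C in
≥ 95 % of replicates with a 7-point crossing-detection smoothing window.

## Peak widths and the order parameter

Because the band is shouldered and non-Gaussian, `peak_fwhm` is
shape-free: apex by parabolic interpolation through the maximum sample,
FWHM from the outermost half-maximum crossings by linear interpolation.
A moving-average smoothing (default 5 points) is used *only* inside
crossing detection; more than two crossings after smoothing raise an
ambiguous-peak error carrying the crossing count. A Voigt-fit width
(`voigt_fwhm`) is provided for comparison but never used by default.

S_N3 uses fixed endpoints (31, 14 cm⁻¹) regardless of temperature —
endpoint overrides are exposed, but the temperature dependence of
δν̄_min is deliberately not modelled. Widths within 2 cm⁻¹ outside the
endpoint interval are clamped to [0, 1] with a flag (the endpoints are
"circa" values); anything further out is an error.

## 2DIR analysis

The center line connects the minima of slices parallel to ω_t, using rows
whose extremum exceeds 50 % of the global 0→1 extremum (configurable);
the 1→2 band is excluded by searching only above the midpoint between
the band centers, and a sign flip at or above a slice minimum raises a
contamination error naming the rows. The ICLS is the OLS slope of ω_t*
against ω_τ — the [0, 1]-bounded quantity that equals the normalized FFCF
for Gaussian dynamics ("inverse" is kept in labels for continuity with
the experimental convention).

`fit_biexponential` does weighted least squares of
A₁e^{−t/τ₁} + A₂e^{−t/τ₂} + C under non-negativity bounds with a
deterministic multistart (8 τ-pair seeds spanning the sampled window and
the experimentally typical 0.5/3.8 ps scales), a soft wall keeping
A₁+A₂+C ≤ 1.1, and AICc selection against single-exponential and
constant models; `model="biexponential"` forces the double-exponential
(the protocol used on experimental traces). Flat traces short-circuit to
the constant model. Whether a plateau is a truly static FFCF term or
dynamics slower than the 25 ps window cannot be distinguished at this
record length; the simulator supports both (Δ₀ vs. a long-τ component)
and the fit reports only the offset.

`width_decomposition` interpolates the rephasing-magnitude signal along
the diagonal and antidiagonal through the refined band extremum, both
parameterized by their ω_t projection so that a statically inhomogeneous
band's diagonal FWHM equals the 1D Gaussian FWHM. Profile FWHMs walk
outward from the apex to the first half-maximum transit, which keeps the
antidiagonal measurement insensitive to the 1→2 ridge crossing that cut
at u = Δ_anh/2. Homogeneous estimate = antidiagonal FWHM; inhomogeneous
estimate = √(diag² − anti²) floored at 0. These are estimators in
magnitude-spectrum units: the homogeneous-only diagonal/antidiagonal
ratio is 1 by construction, and the inhomogeneous estimate recovers the
1D Gaussian width within ~7 % in the strongly inhomogeneous regime;
when homogeneous and inhomogeneous widths are comparable, magnitude-
spectrum interference biases both profiles and the decomposition is
only semi-quantitative (as with the experimental procedure).

## Depth calibration

For an all-anti alkyl chain the axial rise per methylene is
b·sin(α/2). The default C–C bond length is the standard 1.54 Å; the
default CCC angle 113.3° is reverse-engineered so that the rise equals
the 1.286 Å/CH₂ calibration slope (the source geometry behind that slope
is not stated; the tetrahedral angle would give 1.257 Å). `predict_depth`
is linear in n from a user-supplied anchor depth (the absolute COOH
anchoring depth is not published and must be provided), clipped at the
leaflet midplane with an intercalation flag. `depth_from_coordinates`
folds z-coordinates across the midplane (|z − z_mid|) and reports the
mean and population standard deviation.

## Fixtures

`make_fixtures` writes a deterministic demo set for n ∈ {6, 8, 11, 13, 15}:
FTIR series 22–45 °C (1 °C steps, 1 % noise) with per-compound width
endpoints mirroring the experimental ordering (narrowest at n = 11,
broad at n = 6 and 15, ~27–28.5 cm⁻¹ above the transition), and 2DIR
waiting-time series (0.2–25 ps) whose FFCFs use a ~4.5 ps correlation
time, 2.2 ps for n = 13 (fluid midplane region), and a 4 cm⁻¹ static
term for n = 15 (plateau, candidate intercalation into the opposing
leaflet). All files are plain text and regenerated at run time.

## Problem sizes

Defaults were sized for interactive use: 2DIR grids of 128² response
points (converged to < 0.5 % in the width decomposition against 256²),
25-point FWHM(ρ) inversion tables (cached), 100-replicate noise studies
for the transition and biexponential recovery. The full test suite and
the acceptance script each run in well under a minute on one CPU.

## Known limitations

* The Fermi-multiplet band is a two-state caricature (see above).
* CLS ≈ normalized FFCF is exact only in the inhomogeneous limit; for
  Δ·τ·2πc ≲ 1 the recovered timescales carry a few-percent bias (the
  τ = 1 ps case at Δ = 10 cm⁻¹ recovers within 1 % nonetheless because
  the amplitude, not the timescale, absorbs most of the deviation).
* The width decomposition assumes the 0→1 band dominates the rephasing
  magnitude near its extremum; heavily overlapped bands (anharmonicity
  below roughly the homogeneous width) are out of scope.
* No pulse-level processing (phasing, interferograms): inputs are
  assumed to be properly phased absorptive/rephasing spectra.
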