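# azospec

Depth-resolved analysis of lipid-bilayer interiors with azido vibrational
probes, by FTIR and two-dimensional infrared (2DIR) spectroscopy.

## The problem

The packing order and mobility of a lipid bilayer vary strongly with depth:
the acyl chains are crystalline-ordered in the middle of each leaflet (gel
phase, below the DPPC Lβ–Lα transition at ~41 °C) and disordered near the
head groups and at the midplane where the two leaflets meet. A family of
test compounds — an azido (N₃) group tethered by an *n*-carbon alkyl chain
to a polar anchor — places the ν_N3 asymmetric-stretch reporter
(~2096 cm⁻¹) at a depth that grows linearly with *n*, so its band shape and
spectral-diffusion dynamics read out the bilayer environment depth by
depth.

The ν_N3 band is intrinsically broad: the soft CNN bending angle θ spans
~11° within k_BT, the band position moves at ~5 cm⁻¹/deg, and a strong
(~30 cm⁻¹) Fermi resonance with a dark combination band redistributes the
intensity. A tightly packed environment restricts the accessible θ range
and *narrows* the band — from ~31 cm⁻¹ (unrestricted) down to ~14 cm⁻¹
(mid-leaflet, gel phase). That motivates a motional-restriction order
parameter

    S_N3 = (δν̄_max − δν̄_n) / (δν̄_max − δν̄_min),    δν̄_max = 31, δν̄_min = 14 cm⁻¹,

which is 1 where the probe is most constrained and 0 where it is freest.
Dynamics come from 2DIR: the inverse center line slope (ICLS) of the 0→1
diagonal peak as a function of waiting time T_w tracks the normalized
frequency–frequency correlation function (FFCF)

    C(t) = Σᵢ Δᵢ² exp(−t/τᵢ) + Δ₀²    [cm⁻²],

whose decay constants are the structural-randomization timescales of the
environment and whose static term Δ₀² appears as an ICLS plateau.

`azospec` implements the full chain as a tested, reusable pipeline:

* **`azospec.lineshape`** — synthetic-data generator: Kubo/cumulant linear
  and 2DIR lineshapes from an `FFCFModel`, the restricted θ-angle
  Fermi-multiplet band of the probe (`ProbeThetaModel`), and FTIR
  temperature series across the phase transition.
* **`azospec.ftir`** — background subtraction, shape-free peak FWHM,
  sigmoid phase-transition detection, and the S_N3 order parameter.
* **`azospec.twodir`** — center-line extraction, ICLS vs. T_w,
  double-exponential + plateau fitting with AICc model selection, and the
  diagonal/antidiagonal decomposition into inhomogeneous and homogeneous
  widths.
* **`azospec.depth`** — chain-length → depth calibration
  (1.286 Å per CH₂ for an all-anti chain) and depth from coordinate
  tables.
* **`azospec.io` / `azospec.cli`** — plain-text spectrum formats, a
  deterministic fixture generator, and the `azospec` command-line tool
  (`simulate-ftir`, `simulate-2dir`, `analyze-ftir`, `analyze-2dir`,
  `order-parameter`, `depth`, `fixtures`).

## Worked example

Simulate a noisy FTIR temperature series for a mid-leaflet probe
(width stepping 14 → 28 cm⁻¹ at the 41 °C transition), then recover the
widths, the order parameter and the transition temperature:

```python
import numpy as np
from azospec import (FFCFModel, ProbeThetaModel, TemperatureSeriesModel,
                     generate_temperature_series, width_series_from_spectra,
                     transition_temperature, order_parameter, simulate_2dir,
                     icls_series, fit_biexponential)

spectra = generate_temperature_series(
    TemperatureSeriesModel(width_below=14.0, width_above=28.0),
    ProbeThetaModel(), temperatures=np.arange(25.0, 45.1, 2.0),
    seed=7, noise_sd=0.01, grid=(2040.0, 2140.0, 0.5))
series = width_series_from_spectra(spectra, smooth_window=7)
res = transition_temperature(series)
for t, w in zip(series.temperatures, series.widths):
    print(f"{t:5.1f}  {w:12.2f}  {order_parameter(w).value:.3f}")
print(f"transition at {res.temperature:.2f} C, step {res.step_size:.1f} cm-1")
```

```
 25.0         14.06  0.996
 27.0         14.23  0.987
 ...
 39.0         16.20  0.871
 41.0         21.35  0.568
 43.0         26.56  0.261
 45.0         27.83  0.187
transition at 40.96 C, step 13.5 cm-1
```

The width sits at the gel-phase value (S_N3 ≈ 1, maximal restriction)
until just below the transition, steps up across 41 °C, and saturates near
the disordered-phase width (S_N3 ≈ 0.19). Spectral diffusion from the same
kind of environment, via 2DIR:

```python
ffcf = FFCFModel(components=((7.0, 4.5),), static_amplitude=4.0,
                 pure_dephasing_time=2.0, lifetime=3.0)
trace = icls_series([simulate_2dir(ffcf, tw)
                     for tw in (0.2, 0.5, 1, 2, 4, 7.5, 12, 18, 25)])
fit = fit_biexponential(trace)
print(f"fit: {fit.model_selected}, tau = {fit.tau1:.2f} ps, plateau C = {fit.offset:.3f}")
```

```
fit: exponential, tau = 4.44 ps, plateau C = 0.176
```

The ICLS decay time recovers the 4.5 ps FFCF correlation time within 2 %,
and the nonzero plateau reflects the static Δ₀ term (inhomogeneity that
does not randomize within the 25 ps window).

A complete demo data set (five compounds, FTIR temperature series + 2DIR
waiting-time series, with a manifest) is produced by
`azospec fixtures --seed 0 --out fixtures/`.

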