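"""Deterministic demo data emulating the depth-probe compound series.

Test compounds az{n} carry the azido label at the end of an n-carbon
alkyl chain: n = 6 sits near the lipid carbonyls (broad band), n = 10-11
mid-leaflet (narrowest, most ordered), n = 15 near the bilayer midplane
(broad again, with a slow/plateau spectral-diffusion component from
intercalation into the opposing leaflet).
"""

from __future__ import annotations

import json
import os

import numpy as np

from .io import write_spectrum1d, write_spectrum2d
from .lineshape import generate_temperature_series, simulate_2dir
from .models import FFCFModel, ProbeThetaModel, TemperatureSeriesModel

__all__ = ["make_fixtures", "COMPOUND_TABLE"]

# per-compound band widths [cm^-1] below/above the phase transition and
# FFCF timescales [ps]; values chosen to mirror the experimental ordering
# (narrowest mid-leaflet, broadest near the carbonyls and the midplane,
# fast mid-bilayer dynamics, plateau for the longest chain)
COMPOUND_TABLE = {
    6: dict(width_below=27.5, width_above=28.5, tau=4.5, static=0.0),
    8: dict(width_below=17.0, width_above=27.0, tau=4.5, static=0.0),
    11: dict(width_below=14.0, width_above=27.0, tau=4.5, static=0.0),
    13: dict(width_below=20.0, width_above=28.0, tau=2.2, static=0.0),
    15: dict(width_below=27.0, width_above=28.0, tau=5.0, static=4.0),
}

_WAITING_TIMES = (0.2, 0.5, 1.0, 2.0, 4.0, 7.5, 12.0, 18.0, 25.0)
_TEMPERATURES = tuple(np.arange(22.0, 45.1, 1.0))
_GRID_1D = (2040.0, 2140.0, 0.5)


def make_fixtures(
    seed: int,
    out_dir,
    noise_sd: float = 0.01,
    chain_lengths=None,
    temperatures=None,
    waiting_times=None,
) -> dict:
    """Generate the demo FTIR temperature series and 2DIR waiting-time sets.

    Writes, per chain length n in {6, 8, 11, 13, 15}, one FTIR temperature
    series (22-45 C) and one absorptive 2DIR waiting-time series, plus a
    ``manifest.json`` listing every file with its generating parameters.
    Deterministic for a fixed seed.  ``chain_lengths``, ``temperatures``
    and ``waiting_times`` may be narrowed for quick demo runs.
    """
    chain_lengths = sorted(chain_lengths or COMPOUND_TABLE)
    temperatures = list(temperatures) if temperatures is not None else list(_TEMPERATURES)
    waiting_times = list(waiting_times) if waiting_times is not None else list(_WAITING_TIMES)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"seed": seed, "compounds": {}}
    probe = ProbeThetaModel()

    for idx, n in enumerate(chain_lengths):
        pars = COMPOUND_TABLE[n]
        model = TemperatureSeriesModel(
            width_below=pars["width_below"], width_above=pars["width_above"]
        )
        sub_seed = seed * 1000 + idx
        spectra = generate_temperature_series(
            model,
            probe,
            temperatures,
            seed=sub_seed,
            noise_sd=noise_sd,
            grid=_GRID_1D,
        )
        ftir_files = []
        for spec in spectra:
            spec.chain_length = n
            spec.label = f"az{n}"
            fname = f"ftir_az{n}_T{spec.temperature:05.1f}C.csv"
            write_spectrum1d(spec, os.path.join(out_dir, fname))
            ftir_files.append(fname)

        # 2DIR: inhomogeneous amplitude from the room-temperature width
        hom = probe.homogeneous_fwhm
        width = pars["width_below"]
        sigma = max(np.sqrt(max(width**2 - hom**2, 1.0)) / 2.355, 1.0)
        d_exp = np.sqrt(max(sigma**2 - pars["static"] ** 2, 0.25))
        ffcf = FFCFModel(
            components=((float(d_exp), pars["tau"]),),
            static_amplitude=pars["static"],
            pure_dephasing_time=2.0,
            lifetime=3.0,
        )
        tdir_files = []
        for tw in waiting_times:
            spec2 = simulate_2dir(ffcf, tw)
            fname = f"tdir_az{n}_Tw{tw:05.2f}ps.csv"
            write_spectrum2d(spec2, os.path.join(out_dir, fname))
            tdir_files.append({"file": fname, "waiting_time_ps": tw})

        manifest["compounds"][str(n)] = {
            "label": f"az{n}",
            "temperature_series_model": {
                "transition_temperature": model.transition_temperature,
                "transition_width": model.transition_width,
                "width_below": model.width_below,
                "width_above": model.width_above,
            },
            "ffcf": {
                "components": [[float(d_exp), pars["tau"]]],
                "static_amplitude": pars["static"],
                "pure_dephasing_time": 2.0,
                "lifetime": 3.0,
            },
            "noise_sd": noise_sd,
            "seed": sub_seed,
            "ftir_files": ftir_files,
            "tdir_files": tdir_files,
        }

    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
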