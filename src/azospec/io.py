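"""Plain-text spectrum files.

Spectrum1D: two comma-separated columns (wavenumber, absorbance) with
``#``-prefixed ``key: value`` header lines for metadata.  Spectrum2D: a
comma-separated matrix whose first row is the omega_t axis and first
column the omega_tau axis (top-left cell empty), with waiting time and
kind in the header.  Floats are written with 17 significant digits so
write-then-read round-trips are value-exact.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .errors import FormatError
from .models import Spectrum1D, Spectrum2D

__all__ = [
    "read_spectrum1d",
    "write_spectrum1d",
    "read_spectrum2d",
    "write_spectrum2d",
]

_FMT = "%.17g"


def _read_header(path):
    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            rows.append((lineno, line))
    return meta, rows


def write_spectrum1d(spectrum: Spectrum1D, path) -> None:
    """Write a Spectrum1D as commented two-column CSV."""
    with open(path, "w") as fh:
        if spectrum.label:
            fh.write(f"# label: {spectrum.label}\n")
        if spectrum.temperature is not None:
            fh.write(f"# temperature_c: {_FMT % spectrum.temperature}\n")
        if spectrum.chain_length is not None:
            fh.write(f"# chain_length: {spectrum.chain_length}\n")
        fh.write("# columns: wavenumber_cm-1,absorbance\n")
        for x, y in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{_FMT % x},{_FMT % y}\n")


def read_spectrum1d(path) -> Spectrum1D:
    """Parse a two-column spectrum file; axis must be uniform ascending."""
    meta, rows = _read_header(path)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    xs, ys = [], []
    for lineno, line in rows:
        parts = line.split(",")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    x = np.asarray(xs)
    steps = np.diff(x)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0))
        raise FormatError(
            f"{path}: wavenumber axis not strictly ascending at data row {bad + 2} "
            f"({x[bad]} -> {x[bad + 1]})"
        )
    step = float(np.mean(steps))
    dev = np.abs(steps - step)
    if np.max(dev) > 1e-6 * max(step, 1.0):
        bad = int(np.argmax(dev))
        raise FormatError(
            f"{path}: wavenumber axis not uniform at data row {bad + 2}"
        )
    temperature = float(meta["temperature_c"]) if "temperature_c" in meta else None
    chain = int(meta["chain_length"]) if "chain_length" in meta else None
    return Spectrum1D(
        x,
        np.asarray(ys),
        temperature=temperature,
        chain_length=chain,
        label=meta.get("label", ""),
    )


def write_spectrum2d(spectrum: Spectrum2D, path) -> None:
    """Write a Spectrum2D as a commented CSV matrix (axes in row/column 0)."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        fh.write(f"# waiting_time_ps: {_FMT % spectrum.waiting_time}\n")
        center = spectrum.metadata.get("center")
        if center is not None:
            fh.write(f"# center_cm-1: {_FMT % center}\n")
        anh = spectrum.metadata.get("anharmonicity")
        if anh is not None:
            fh.write(f"# anharmonicity_cm-1: {_FMT % anh}\n")
        fh.write("# layout: first row = omega_t axis, first column = omega_tau axis\n")
        fh.write("," + ",".join(_FMT % v for v in spectrum.omega_t) + "\n")
        for wtau, row in zip(spectrum.omega_tau, spectrum.signal):
            fh.write(_FMT % wtau + "," + ",".join(_FMT % v for v in row) + "\n")


def read_spectrum2d(path, waiting_time: Optional[float] = None) -> Spectrum2D:
    """Parse a 2D spectrum matrix file.

    ``waiting_time`` overrides a missing ``waiting_time_ps`` header (as an
    analysis manifest would); with neither present a :class:`FormatError`
    is raised.
    """
    meta, rows = _read_header(path)
    if len(rows) < 3:
        raise FormatError(f"{path}: need an axis row and at least 2 data rows")
    first = rows[0][1].split(",")
    if first[0].strip() != "":
        raise FormatError(f"{path}: top-left cell of the axis row must be empty")
    try:
        omega_t = np.asarray([float(v) for v in first[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: bad omega_t axis: {exc}") from None
    omega_tau, data = [], []
    for lineno, line in rows[1:]:
        parts = line.split(",")
        if len(parts) != omega_t.size + 1:
            raise FormatError(
                f"{path}:{lineno}: row has {len(parts) - 1} values, "
                f"expected {omega_t.size}"
            )
        try:
            omega_tau.append(float(parts[0]))
            data.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    if "waiting_time_ps" in meta:
        tw = float(meta["waiting_time_ps"])
    elif waiting_time is not None:
        tw = float(waiting_time)
    else:
        raise FormatError(
            f"{path}: no waiting_time_ps header; supply the waiting time via "
            "the analysis manifest override"
        )
    metadata = {}
    if "center_cm-1" in meta:
        metadata["center"] = float(meta["center_cm-1"])
    if "anharmonicity_cm-1" in meta:
        metadata["anharmonicity"] = float(meta["anharmonicity_cm-1"])
    return Spectrum2D(
        np.asarray(omega_tau),
        omega_t,
        np.asarray(data),
        waiting_time=tw,
        kind=meta.get("kind", "absorptive"),
        metadata=metadata,
    )
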