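"""Chain-length -> probe-depth calibration in the bilayer.

The azido label rides at the end of an all-anti alkyl chain anchored (via
its COOH/CN head) at a roughly constant depth below the lipid head
groups; every extra methylene pushes the label deeper by the projection
of one C-C bond onto the chain axis.  Depth z is measured from the plane
separating the two leaflets (larger z = closer to the head groups).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import EmptyInputError
from .models import ChainGeometry, DepthRecord

__all__ = ["rise_per_methylene", "predict_depth", "depth_from_coordinates"]


def rise_per_methylene(geom: ChainGeometry = ChainGeometry()) -> float:
    """Axial rise per CH2 of an all-anti chain: b * sin(alpha / 2) [Angstrom].

    With the default geometry (b = 1.54 Angstrom, alpha = 113.3 deg) this
    evaluates to 1.286 Angstrom per methylene unit.
    """
    return float(geom.cc_bond_length * np.sin(np.radians(geom.ccc_angle) / 2.0))


def predict_depth(
    n: int,
    anchor_depth: float,
    geom: ChainGeometry = ChainGeometry(),
    n_ref: int = 1,
) -> DepthRecord:
    """Expected N3 depth for chain length ``n``, anchored at ``anchor_depth``.

    z(n) = anchor_depth - rise * (n - n_ref), clipped at the leaflet
    midplane (z = 0) with ``midplane_crossing=True`` when the probe would
    cross into the opposing leaflet (candidate intercalation).
    """
    if n < 1 or int(n) != n:
        raise ValueError("chain length n must be a positive integer")
    z = anchor_depth - rise_per_methylene(geom) * (n - n_ref)
    crossing = z < 0
    return DepthRecord(
        chain_length=int(n),
        depth=max(z, 0.0),
        midplane_crossing=bool(crossing),
    )


def depth_from_coordinates(
    z_coordinates: Sequence[float],
    midplane_z: float = 0.0,
    temperature_label: str = "",
    chain_length=None,
) -> DepthRecord:
    """Mean absolute distance of per-frame z coordinates from the midplane.

    Depths fold across the leaflet-separating plane (|z - midplane|);
    the dispersion is the population standard deviation.
    """
    z = np.asarray(list(z_coordinates), dtype=float)
    if z.size == 0:
        raise EmptyInputError("no coordinates supplied")
    d = np.abs(z - midplane_z)
    return DepthRecord(
        chain_length=chain_length,
        depth=float(np.mean(d)),
        dispersion=float(np.std(d)),
        temperature_label=temperature_label,
    )
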