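"""Measurement geometry: the four-layer 60-dipole transceiver array.

The default array surrounds a 0.24 m cubic domain of interest (DOI)
centered at the origin, operating at 300 MHz:

* layer 1: 32 dipoles, radius 0.12 m, z = -0.06 m, angular step 11.25 deg
* layer 2: 16 dipoles, radius 0.115 m, z = 0 m, step 22.5 deg
* layer 3:  8 dipoles, radius 0.10 m, z = 0.06 m, step 45 deg
* layer 4:  4 dipoles, radius 0.06 m, z = 0.10 m, step 90 deg

Every antenna acts as both transmitter and receiver (a transceiver); all
dipole axes point along z.  Angles start at 0 deg on the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_FREQUENCY_HZ = 300e6
DEFAULT_DOI_SIDE_M = 0.24

#: (count, radius_m, z_m) per layer of the default array.
DEFAULT_LAYERS: tuple[tuple[int, float, float], ...] = (
    (32, 0.12, -0.06),
    (16, 0.115, 0.0),
    (8, 0.10, 0.06),
    (4, 0.06, 0.10),
)


@dataclass(frozen=True)
class AntennaArray:
    """Positions and orientations of the transceiver dipoles."""

    positions_m: np.ndarray  # (n, 3)
    orientations: np.ndarray  # (n, 3) unit vectors
    frequency_hz: float = DEFAULT_FREQUENCY_HZ

    @property
    def n_antennas(self) -> int:
        return self.positions_m.shape[0]

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency_hz

    @property
    def k0(self) -> float:
        from .em import C0

        return self.omega / C0


def build_array(
    layers: tuple[tuple[int, float, float], ...] = DEFAULT_LAYERS,
    frequency_hz: float = DEFAULT_FREQUENCY_HZ,
    doi_side_m: float = DEFAULT_DOI_SIDE_M,
    brain_clearance_m: float = 0.012,
) -> AntennaArray:
    """Build a layered circular transceiver array.

    ``layers`` is a sequence of ``(count, radius_m, z_m)``; within each
    layer antennas are equally spaced starting at 0 deg on the +x axis.
    Dipole axes are along z.  Any antenna falling inside the DOI brain
    region (a centered ball of radius ``doi_side_m/2 - brain_clearance_m``
    intersected with the DOI cube) is rejected.
    """
    positions = []
    for count, radius, z in layers:
        if count < 1:
            raise ValueError("each layer needs at least one antenna")
        ang = 2.0 * np.pi * np.arange(count) / count
        for a in ang:
            positions.append((radius * np.cos(a), radius * np.sin(a), z))
    pos = np.asarray(positions, dtype=float)

    # reject antennas inside the imaging region proper (the centered ball
    # that can contain a phantom); antennas may sit inside the bounding cube
    # corners but never inside this ball.
    r_keepout = doi_side_m / 2.0 - brain_clearance_m
    inside = np.linalg.norm(pos, axis=1) < r_keepout
    if np.any(inside):
        bad = np.flatnonzero(inside)
        raise ValueError(
            f"antenna(s) {bad.tolist()} lie inside the imaging region "
            f"(|r| < {r_keepout:.3f} m); move them outside the DOI"
        )
    orient = np.tile(np.array([0.0, 0.0, 1.0]), (pos.shape[0], 1))
    return AntennaArray(positions_m=pos, orientations=orient, frequency_hz=frequency_hz)
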