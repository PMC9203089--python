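"""Adapter geometry, spectral grids and RGB channel passbands.

The adapter couples the phone's LED flash to the skin through a confined
illumination spot and images a rectangular field of view (FOV) at a lateral
offset from the spot.  All coordinates are millimetres in a frame whose
origin sits at the centre of the illumination spot's surface projection,
with +x pointing toward the FOV; the FOV rectangle spans
``[spot_radius + edge_offset, spot_radius + edge_offset + fov_width]`` in x
and ``[-fov_height/2, +fov_height/2]`` in y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, InvalidParameterError, UnsupportedBandError


@dataclass(frozen=True)
class AdapterGeometry:
    """Illumination/collection geometry of the snap-on adapter.

    Parameters
    ----------
    spot_radius : float
        Radius of the (top-hat) illumination spot at the skin, mm.
    edge_offset : float
        Gap between the proximal beam edge and the proximal FOV edge, mm.
        The two configurations of interest are 1.6 mm and 0.0 mm.
    fov : tuple of float
        (height, width) of the camera field of view, mm.  Default 9 x 12.
    acceptance_half_angle : float
        Half-angle of the collection cone, degrees.  Exit photons outside
        this cone are not counted as collected.
    incidence_angle : float
        Illumination beam angle from the surface normal, degrees.
    adapter_thickness : float
        Physical thickness of the adapter, mm (informational).
    """

    spot_radius: float = 1.5
    edge_offset: float = 1.6
    fov: tuple[float, float] = (9.0, 12.0)
    acceptance_half_angle: float = 21.0
    incidence_angle: float = 30.0
    adapter_thickness: float = 10.0

    def __post_init__(self) -> None:
        if self.spot_radius <= 0:
            raise GeometryError(f"spot_radius must be > 0, got {self.spot_radius}")
        if self.edge_offset < 0:
            raise GeometryError(f"edge_offset must be >= 0, got {self.edge_offset}")
        h, w = self.fov
        if h <= 0 or w <= 0:
            raise GeometryError(f"FOV dimensions must be > 0, got {self.fov}")
        if not 0 <= self.acceptance_half_angle < 90:
            raise GeometryError(
                f"acceptance_half_angle must be in [0, 90), got {self.acceptance_half_angle}"
            )
        if not 0 <= self.incidence_angle < 90:
            raise GeometryError(
                f"incidence_angle must be in [0, 90), got {self.incidence_angle}"
            )

    @property
    def fov_height(self) -> float:
        return self.fov[0]

    @property
    def fov_width(self) -> float:
        return self.fov[1]

    @property
    def fov_x0(self) -> float:
        """Proximal FOV edge, mm from the spot centre."""
        return self.spot_radius + self.edge_offset

    @property
    def fov_x1(self) -> float:
        return self.fov_x0 + self.fov_width

    def fov_bounds(self) -> tuple[float, float, float, float]:
        """(x0, x1, y0, y1) of the FOV rectangle in mm."""
        return (self.fov_x0, self.fov_x1, -self.fov_height / 2, self.fov_height / 2)


def center_offset(geometry: AdapterGeometry) -> float:
    """Distance from the centre of the illumination spot to the centre of the FOV, mm.

    ``spot_radius + edge_offset + fov_width / 2``; evaluates to 7.5 mm for the
    reduced-offset (0 mm) configuration and 9.1 mm for the original (1.6 mm)
    configuration with the default 1.5 mm spot and 12 mm wide FOV.
    """
    return geometry.spot_radius + geometry.edge_offset + geometry.fov_width / 2


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength samples in nm, within 400-700."""

    wavelengths: tuple[float, ...] = tuple(float(w) for w in range(400, 701, 10))

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.size == 0:
            raise InvalidParameterError("spectral grid must be non-empty")
        if np.any(np.diff(wl) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        if wl[0] < 400 or wl[-1] > 700:
            raise InvalidParameterError(
                f"wavelengths must lie within 400-700 nm, got [{wl[0]}, {wl[-1]}]"
            )
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in wl))

    def asarray(self) -> np.ndarray:
        return np.asarray(self.wavelengths, dtype=float)


@dataclass(frozen=True)
class Band:
    name: str
    center: float
    half_width: float


@dataclass(frozen=True)
class ChannelBank:
    """RGB filter passbands: (name, centre nm, half-width nm).

    Defaults follow the adapter's triple-band-pass filter: blue 474 +/- 10,
    green 554 +/- 10, red 635 +/- 10 nm.  Output order is always
    blue, green, red.
    """

    bands: tuple[Band, ...] = (
        Band("blue", 474.0, 10.0),
        Band("green", 554.0, 10.0),
        Band("red", 635.0, 10.0),
    )

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.center)
        for lo, hi in zip(ordered[:-1], ordered[1:]):
            if lo.center + lo.half_width > hi.center - hi.half_width:
                raise InvalidParameterError(
                    f"bands {lo.name} and {hi.name} overlap"
                )

    def validate_coverage(self, grid: SpectralGrid) -> None:
        wl = grid.asarray()
        for b in self.bands:
            in_band = (wl >= b.center - b.half_width) & (wl <= b.center + b.half_width)
            if not in_band.any():
                raise UnsupportedBandError(
                    f"band {b.name!r} [{b.center - b.half_width}, "
                    f"{b.center + b.half_width}] nm has no grid samples"
                )

    def band_indices(self, grid: SpectralGrid) -> dict[str, np.ndarray]:
        """Indices of grid samples inside each band, keyed by band name."""
        self.validate_coverage(grid)
        wl = grid.asarray()
        return {
            b.name: np.flatnonzero(
                (wl >= b.center - b.half_width) & (wl <= b.center + b.half_width)
            )
            for b in self.bands
        }
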