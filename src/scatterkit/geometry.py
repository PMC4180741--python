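"""Detector geometry: pixel coordinates to scattering coordinates.

Two geometries are supported:

* transmission SAXS/WAXS — each pixel maps to a momentum-transfer modulus
  ``q`` (nm^-1) and an azimuth ``chi`` (degrees),
* grazing incidence (GISAXS) — each pixel maps to in-plane ``q_y`` and
  out-of-plane ``q_z`` components (nm^-1).

Conventions, fixed once here and used everywhere else:

* pixel indexing is 0-based, image origin top-left, row-major; "up" on the
  detector is *decreasing* row index (matches TIFF/EDF display conventions);
* ``chi`` is measured counterclockwise from the +x detector axis (to the
  right, increasing column), in degrees in ``[0, 360)``;
* the detector is flat and orthogonal to the direct beam; tilt is not
  modeled;
* in grazing mode the beam center is the *direct-beam* spot, not the
  specular reflection;
* units: wavelength in nm, distances in mm, q in nm^-1, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["ExperimentGeometry", "QMap", "pixel_to_q", "pixel_to_gisaxs_q", "build_qmap"]


class GeometryError(ValueError):
    """Invalid experiment geometry configuration."""


@dataclass(frozen=True)
class ExperimentGeometry:
    """Experiment geometry defining the pixel -> q mapping.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in nm.
    distance : float
        Sample-to-detector distance in mm.
    beam_center : tuple of float
        Direct-beam position ``(x0, y0)`` in pixels; ``x0`` is the column
        coordinate, ``y0`` the row coordinate. Fractional values allowed.
    pixel_size : tuple of float
        ``(p_x, p_y)`` pixel pitch in mm/pixel.
    incidence : float
        Grazing-incidence angle alpha_i in degrees (grazing mode only).
    mode : {"transmission", "grazing"}
    """

    wavelength: float
    distance: float
    beam_center: tuple[float, float]
    pixel_size: tuple[float, float] = (0.172, 0.172)
    incidence: float = 0.0
    mode: Literal["transmission", "grazing"] = "transmission"

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise GeometryError(f"wavelength must be > 0 nm, got {self.wavelength}")
        if not (self.distance > 0):
            raise GeometryError(f"distance must be > 0 mm, got {self.distance}")
        if not (self.pixel_size[0] > 0 and self.pixel_size[1] > 0):
            raise GeometryError(f"pixel_size must be > 0 mm, got {self.pixel_size}")
        if self.mode not in ("transmission", "grazing"):
            raise GeometryError(f"unknown mode {self.mode!r}")
        if self.mode == "grazing" and self.incidence < 0:
            raise GeometryError("grazing mode requires incidence >= 0 degrees")


@dataclass
class QMap:
    """Per-pixel scattering-coordinate arrays for one detector shape.

    ``q`` and ``chi`` are always present; ``qy``/``qz`` only in grazing mode.
    """

    geometry: ExperimentGeometry
    q: np.ndarray
    chi: np.ndarray
    qy: np.ndarray | None = None
    qz: np.ndarray | None = None
    shape: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        self.shape = self.q.shape


def _pixel_offsets_mm(px: np.ndarray, py: np.ndarray, geom: ExperimentGeometry):
    """Signed detector-plane offsets (mm) of pixels from the beam center.

    dx points right (+column); dy points *up*, i.e. toward decreasing row.
    """
    x0, y0 = geom.beam_center
    dx = (np.asarray(px, dtype=float) - x0) * geom.pixel_size[0]
    dy = (y0 - np.asarray(py, dtype=float)) * geom.pixel_size[1]
    return dx, dy


def pixel_to_q(px, py, geom: ExperimentGeometry):
    """Map transmission-geometry pixel coordinates to (q, chi).

    Parameters
    ----------
    px, py : array_like
        Column and row pixel coordinates (0-based, fractional allowed).
    geom : ExperimentGeometry
        Must be in transmission mode.

    Returns
    -------
    q : ndarray
        Momentum transfer ``(4 pi / lambda) sin(theta)`` in nm^-1, where the
        scattering angle is ``2 theta = atan(r / D)`` with ``r`` the in-plane
        pixel distance from the beam center in mm.
    chi : ndarray
        Azimuth in degrees in ``[0, 360)``, counterclockwise from +x ("up"
        on the detector is 90 degrees). At the beam center chi is undefined
        and reported as 0.
    """
    if geom.mode != "transmission":
        raise GeometryError("pixel_to_q requires transmission mode")
    dx, dy = _pixel_offsets_mm(px, py, geom)
    r = np.hypot(dx, dy)
    two_theta = np.arctan2(r, geom.distance)
    q = (4.0 * np.pi / geom.wavelength) * np.sin(two_theta / 2.0)
    chi = np.degrees(np.arctan2(dy, dx)) % 360.0
    chi = np.where(r == 0.0, 0.0, chi)
    return q, chi


def pixel_to_gisaxs_q(px, py, geom: ExperimentGeometry):
    """Map grazing-incidence pixel coordinates to (q_y, q_z).

    With in-plane angle ``psi = atan(dx p_x / D)`` and exit angle
    ``alpha_f = atan(dy p_y / D) - alpha_i`` (``dy`` measured upward from the
    direct-beam spot):

    * ``q_y = (2 pi / lambda) sin(psi) cos(alpha_f)``
    * ``q_z = (2 pi / lambda) (sin(alpha_i) + sin(alpha_f))``

    ``q_x`` is neglected (small-angle approximation). ``q_z = 0`` at the
    direct-beam pixel; the specular position ``alpha_f = alpha_i`` maps to
    ``q_z = (4 pi / lambda) sin(alpha_i)``.
    """
    if geom.mode != "grazing":
        raise GeometryError("pixel_to_gisaxs_q requires grazing mode")
    dx, dy = _pixel_offsets_mm(px, py, geom)
    alpha_i = np.radians(geom.incidence)
    psi = np.arctan2(dx, geom.distance)
    alpha_f = np.arctan2(dy, geom.distance) - alpha_i
    if np.any(alpha_f < -alpha_i - np.pi / 2):
        raise GeometryError("exit angle below -alpha_i - 90 degrees: undefined geometry")
    k = 2.0 * np.pi / geom.wavelength
    qy = k * np.sin(psi) * np.cos(alpha_f)
    qz = k * (np.sin(alpha_i) + np.sin(alpha_f))
    return qy, qz


def build_qmap(shape: tuple[int, int], geom: ExperimentGeometry) -> QMap:
    """Build per-pixel q maps for a detector of ``shape`` (rows, cols).

    In transmission mode fills ``q``/``chi``; in grazing mode additionally
    ``qy``/``qz`` (with ``q = hypot(qy, qz)``). The result is cached per
    (shape, geometry) so repeated calls across a frame series are free.
    """
    return _build_qmap_cached(shape, geom)


def _build_qmap_uncached(shape: tuple[int, int], geom: ExperimentGeometry) -> QMap:
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise GeometryError(f"detector shape must be positive, got {shape}")
    py, px = np.mgrid[0:ny, 0:nx]
    if geom.mode == "transmission":
        q, chi = pixel_to_q(px, py, geom)
        return QMap(geometry=geom, q=q, chi=chi)
    qy, qz = pixel_to_gisaxs_q(px, py, geom)
    dx, dy = _pixel_offsets_mm(px, py, geom)
    chi = np.degrees(np.arctan2(dy, dx)) % 360.0
    return QMap(geometry=geom, q=np.hypot(qy, qz), chi=chi, qy=qy, qz=qz)


_QMAP_CACHE: dict[tuple, QMap] = {}


def _build_qmap_cached(shape: tuple[int, int], geom: ExperimentGeometry) -> QMap:
    key = (tuple(shape), geom.wavelength, geom.distance, tuple(geom.beam_center),
           tuple(geom.pixel_size), geom.incidence, geom.mode)
    hit = _QMAP_CACHE.get(key)
    if hit is None:
        hit = _build_qmap_uncached(tuple(shape), geom)
        if len(_QMAP_CACHE) > 16:  # bounded; frame series reuse one geometry
            _QMAP_CACHE.clear()
        _QMAP_CACHE[key] = hit
    return hit
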