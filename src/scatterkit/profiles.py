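"""Reduce 2-D frames to 1-D curves: radial/azimuthal integration, GISAXS cuts.

Binning is pixel-center histogramming ("simple box integration"): each
unmasked pixel contributes its full intensity to exactly one bin, the one
whose half-open interval ``[lo, hi)`` contains the pixel's coordinate (the
last bin is closed so the top edge is not lost). No pixel splitting is
performed. This makes the intensity-conservation identity exact:

    sum over bins of (mean_intensity * n_pix)  ==  sum of selected pixels.

Empty bins carry ``y = NaN`` (not zero) so downstream fits can drop them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corrections import _as_corrected
from .geometry import QMap

logger = logging.getLogger(__name__)

__all__ = ["Curve", "RoiStats", "radial_profile", "azimuthal_profile",
           "gisaxs_cut", "roi_stats"]


@dataclass
class Curve:
    """A 1-D reduced profile.

    ``x`` holds bin centers (q in nm^-1, q_y/q_z in nm^-1, or chi in
    degrees), strictly increasing. ``y`` is the *mean* intensity of the
    ``n_pix`` contributing pixels; ``sigma`` the propagated uncertainty of
    that mean.
    """

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    n_pix: np.ndarray
    kind: str = "radial"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.n_pix = np.asarray(self.n_pix)
        if not (len(self.x) == len(self.y) == len(self.sigma) == len(self.n_pix)):
            raise ValueError("curve arrays must have equal length")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("curve x must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)

    def dropna(self) -> "Curve":
        """Return the curve restricted to bins that received pixels."""
        keep = np.isfinite(self.y)
        return Curve(self.x[keep], self.y[keep], self.sigma[keep],
                     self.n_pix[keep], self.kind)


@dataclass(frozen=True)
class RoiStats:
    """Summary statistics of a rectangular detector region."""

    min: float
    max: float
    average: float
    sum: float
    n_pix: int


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bin assignment, last bin closed; -1 = out of range."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2  # close the last bin
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def _accumulate(values: np.ndarray, sigmas: np.ndarray, idx: np.ndarray,
                nbins: int, reduce: str = "mean"):
    """Per-bin mean (or median) with sigma = sqrt(sum sigma^2) / n."""
    sel = idx >= 0
    idx, values, sigmas = idx[sel], values[sel], sigmas[sel]
    n = np.bincount(idx, minlength=nbins).astype(float)
    var = np.bincount(idx, weights=sigmas ** 2, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        if reduce == "median":
            y = np.full(nbins, np.nan)
            for b in np.unique(idx):
                y[b] = np.median(values[idx == b])
            # first-order: sigma of the median ~ 1.2533 x sigma of the mean
            sigma = np.where(n > 0, 1.2533 * np.sqrt(var) / n, np.nan)
        else:
            total = np.bincount(idx, weights=values, minlength=nbins)
            y = np.where(n > 0, total / n, np.nan)
            sigma = np.where(n > 0, np.sqrt(var) / n, np.nan)
    return y, sigma, n.astype(int)


def _chi_selector(chi: np.ndarray, chi_range) -> np.ndarray:
    lo, hi = (c % 360.0 for c in chi_range)
    if lo <= hi:
        return (chi >= lo) & (chi < hi)
    return (chi >= lo) | (chi < hi)  # wrap-around sector


def _edges(bins, lo: float, hi: float) -> np.ndarray:
    if np.isscalar(bins):
        return np.linspace(lo, hi, int(bins) + 1)
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be a 1-D increasing array of length >= 2")
    return edges


def radial_profile(frame, qmap: QMap, q_bins, chi_range=None) -> Curve:
    """Azimuthally averaged I(q).

    Parameters
    ----------
    q_bins : int or array
        Bin count (spanning the detector's q range) or explicit bin edges
        in nm^-1.
    chi_range : (lo, hi) degrees, optional
        Restrict contributing pixels to an azimuthal sector; the range may
        wrap through 0 (e.g. ``(350, 10)``).
    """
    f = _as_corrected(frame)
    if f.data.shape != qmap.shape:
        raise ValueError(f"frame shape {f.data.shape} != qmap shape {qmap.shape}")
    q = qmap.q.ravel()
    good = (f.mask.ravel() == 0)
    if chi_range is not None:
        good &= _chi_selector(qmap.chi.ravel(), chi_range)
    edges = _edges(q_bins, q[good].min() if good.any() else 0.0,
                   q[good].max() if good.any() else 1.0)
    if not good.any():
        logger.warning("radial_profile: all pixels masked; returning all-NaN curve")
        nb = len(edges) - 1
        return Curve((edges[:-1] + edges[1:]) / 2, np.full(nb, np.nan),
                     np.full(nb, np.nan), np.zeros(nb, int), "radial")
    idx = np.where(good, _bin_index(q, edges), -1)
    y, sigma, n = _accumulate(f.data.ravel(), f.sigma.ravel(), idx, len(edges) - 1)
    return Curve((edges[:-1] + edges[1:]) / 2, y, sigma, n, "radial")


def azimuthal_profile(frame, qmap: QMap, q_range, chi_bins=180) -> Curve:
    """I(chi) averaged over an annulus ``q_range = (q_lo, q_hi)`` in nm^-1.

    ``chi_bins`` partitions [0, 360): an integer bin count or explicit
    edges. Raises if the annulus contains no unmasked pixels.
    """
    f = _as_corrected(frame)
    if f.data.shape != qmap.shape:
        raise ValueError(f"frame shape {f.data.shape} != qmap shape {qmap.shape}")
    q_lo, q_hi = q_range
    good = (f.mask.ravel() == 0) & (qmap.q.ravel() >= q_lo) & (qmap.q.ravel() < q_hi)
    if not good.any():
        raise ValueError(f"empty annulus: no unmasked pixels with q in [{q_lo}, {q_hi})")
    edges = _edges(chi_bins, 0.0, 360.0)
    idx = np.where(good, _bin_index(qmap.chi.ravel(), edges), -1)
    y, sigma, n = _accumulate(f.data.ravel(), f.sigma.ravel(), idx, len(edges) - 1)
    return Curve((edges[:-1] + edges[1:]) / 2, y, sigma, n, "azimuthal")


def gisaxs_cut(frame, qmap: QMap, direction="horizontal", at: float = 0.0,
               roi_width: float = 0.05, bins=None, reduce: str = "mean") -> Curve:
    """Line cut through a GISAXS pattern, averaged over an ROI band.

    * ``horizontal`` (out-of-plane cut): abscissa q_y, averaging pixels
      with ``|q_z - at| <= roi_width / 2``;
    * ``vertical`` (detector cut): abscissa q_z, band in q_y around ``at``;
    * a number (degrees from the q_y axis): cut along an arbitrary
      direction through the point ``(q_y, q_z) = (0, at)``; the abscissa is
      the signed distance along that direction.

    ``reduce="median"`` gives median instead of mean intensity profiles.
    """
    f = _as_corrected(frame)
    if qmap.qy is None or qmap.qz is None:
        raise ValueError("gisaxs_cut requires a grazing-mode qmap")
    if f.data.shape != qmap.shape:
        raise ValueError(f"frame shape {f.data.shape} != qmap shape {qmap.shape}")
    qy, qz = qmap.qy.ravel(), qmap.qz.ravel()
    if direction == "horizontal":
        axis, dist = qy, np.abs(qz - at)
    elif direction == "vertical":
        axis, dist = qz, np.abs(qy - at)
    else:
        phi = np.radians(float(direction))
        axis = qy * np.cos(phi) + (qz - at) * np.sin(phi)
        dist = np.abs(-qy * np.sin(phi) + (qz - at) * np.cos(phi))
    good = (f.mask.ravel() == 0) & (dist <= roi_width / 2.0)
    if not good.any():
        raise ValueError(f"cut ROI (at={at}, width={roi_width}) selects no pixels")
    if bins is None:
        # default resolution: one bin per detector column (horizontal) / row
        nrow, ncol = f.data.shape
        bins = ncol if direction == "horizontal" else nrow if direction == "vertical" \
            else max(int(np.sqrt(good.sum())), 8)
    if isinstance(bins, str) and bins == "pixel":
        # one bin per distinct pixel coordinate along the cut axis
        u = np.unique(np.round(axis[good], 12))
        if len(u) == 1:
            edges = np.array([u[0] - 0.5, u[0] + 0.5])
        else:
            mid = (u[:-1] + u[1:]) / 2
            edges = np.concatenate([[u[0] - (mid[0] - u[0])], mid,
                                    [u[-1] + (u[-1] - mid[-1])]])
    else:
        edges = _edges(bins, axis[good].min(), axis[good].max())
    idx = np.where(good, _bin_index(axis, edges), -1)
    y, sigma, n = _accumulate(f.data.ravel(), f.sigma.ravel(), idx,
                              len(edges) - 1, reduce=reduce)
    return Curve((edges[:-1] + edges[1:]) / 2, y, sigma, n, "cut")


def roi_stats(frame, x: int, y: int, width: int, height: int) -> RoiStats:
    """Min/max/average/sum intensity over a rectangular pixel region.

    The rectangle ``[x, x+width) x [y, y+height)`` is clipped to the image;
    masked pixels are excluded. Raises if nothing remains.
    """
    f = _as_corrected(frame)
    ny, nx = f.data.shape
    x0, x1 = max(int(x), 0), min(int(x) + int(width), nx)
    y0, y1 = max(int(y), 0), min(int(y) + int(height), ny)
    if x0 >= x1 or y0 >= y1:
        raise ValueError(f"ROI ({x},{y},{width},{height}) does not intersect "
                         f"a {ny}x{nx} image")
    patch = f.data[y0:y1, x0:x1]
    good = f.mask[y0:y1, x0:x1] == 0
    if not good.any():
        raise ValueError("ROI is fully masked")
    vals = patch[good]
    return RoiStats(min=float(vals.min()), max=float(vals.max()),
                    average=float(vals.mean()), sum=float(vals.sum()),
                    n_pix=int(good.sum()))
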