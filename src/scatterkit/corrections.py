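"""Pre-integration frame corrections with Poisson error propagation.

The error model is fixed once, here: a raw frame of counts ``N`` gets
``sigma = sqrt(max(N, 1))`` (Poisson, with the usual floor of 1 on empty
pixels so weighted fits never see zero weight), and every subsequent
correction propagates sigma to first order. Negative intensities after
background subtraction are *retained*, not clipped — clipping would bias
azimuthal/radial means upward in low-count regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import Frame

__all__ = ["CorrectedFrame", "from_frame", "subtract_background",
           "normalize_monitor", "bin_pixels"]


@dataclass
class CorrectedFrame:
    """Intensity + per-pixel uncertainty + mask, with correction provenance."""

    data: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray
    monitor: float = 1.0
    exposure: float = 1.0
    scan_pos: tuple[float, ...] | None = None
    source_path: str = ""
    provenance: list[str] = field(default_factory=list)
    binning: int = 1

    def __post_init__(self) -> None:
        if self.sigma.shape != self.data.shape or self.mask.shape != self.data.shape:
            raise ValueError("data/sigma/mask shape mismatch")
        if np.any(self.sigma < 0):
            raise ValueError("negative sigma")


def from_frame(frame: Frame) -> CorrectedFrame:
    """Wrap a raw frame, attaching sqrt(max(counts, 1)) Poisson uncertainties."""
    data = np.asarray(frame.data, dtype=float)
    sigma = np.sqrt(np.maximum(data, 1.0))
    return CorrectedFrame(data=data, sigma=sigma, mask=frame.mask.copy(),
                          monitor=frame.monitor, exposure=frame.exposure,
                          scan_pos=frame.scan_pos, source_path=frame.source_path,
                          provenance=["read"])


def _as_corrected(frame) -> CorrectedFrame:
    return frame if isinstance(frame, CorrectedFrame) else from_frame(frame)


def subtract_background(frame, bg_frame, scale: float = 1.0) -> CorrectedFrame:
    """Subtract ``scale * background`` pixel-wise.

    ``scale`` is the exposure/transmission ratio supplied by the caller.
    Under the Poisson model the variances add:
    ``sigma'^2 = sigma^2 + scale^2 * sigma_bg^2``. Masks are unioned.
    """
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    f = _as_corrected(frame)
    b = _as_corrected(bg_frame)
    if f.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: frame {f.data.shape} vs background {b.data.shape}")
    data = f.data - scale * b.data
    sigma = np.sqrt(f.sigma ** 2 + scale ** 2 * b.sigma ** 2)
    mask = ((f.mask != 0) | (b.mask != 0)).astype(np.uint8)
    return CorrectedFrame(data=data, sigma=sigma, mask=mask, monitor=f.monitor,
                          exposure=f.exposure, scan_pos=f.scan_pos,
                          source_path=f.source_path, binning=f.binning,
                          provenance=f.provenance + [f"subtract_background(scale={scale})"])


def normalize_monitor(frame, *, default_monitor: float | None = None) -> CorrectedFrame:
    """Divide intensities (and sigmas) by the monitor counts; reset monitor to 1.

    A frame without a monitor reading errors out unless ``default_monitor``
    provides the fallback policy.
    """
    f = _as_corrected(frame)
    monitor = f.monitor
    if monitor is None or not monitor > 0:
        if default_monitor is None:
            raise ValueError(f"frame has no usable monitor (got {monitor!r})")
        monitor = default_monitor
    return CorrectedFrame(data=f.data / monitor, sigma=f.sigma / monitor,
                          mask=f.mask.copy(), monitor=1.0, exposure=f.exposure,
                          scan_pos=f.scan_pos, source_path=f.source_path,
                          binning=f.binning,
                          provenance=f.provenance + [f"normalize_monitor({monitor})"])


def bin_pixels(frame, n: int, reduce: str = "sum") -> CorrectedFrame:
    """Reduce n x n pixel blocks by sum or mean.

    A binned pixel is masked iff *all* of its members are masked; partial
    blocks at the right/bottom edges are dropped. In sum mode
    ``sigma = sqrt(sum sigma^2)`` over unmasked members; mean mode divides
    by the unmasked member count. The result's ``binning`` factor is
    multiplied by ``n`` so downstream geometry can account for the coarser
    pixel pitch.
    """
    if n < 1:
        raise ValueError(f"bin factor must be >= 1, got {n}")
    if reduce not in ("sum", "mean"):
        raise ValueError(f"reduce must be 'sum' or 'mean', got {reduce!r}")
    f = _as_corrected(frame)
    ny, nx = f.data.shape
    if n > min(ny, nx):
        raise ValueError(f"bin factor {n} exceeds image dimensions {f.data.shape}")
    if n == 1:
        return f
    my, mx = ny // n, nx // n
    good = (f.mask[: my * n, : mx * n] == 0)

    def blocks(a):
        return a[: my * n, : mx * n].reshape(my, n, mx, n)

    cnt = blocks(good.astype(float)).sum(axis=(1, 3))
    dsum = blocks(np.where(good, f.data[: my * n, : mx * n], 0.0)).sum(axis=(1, 3))
    vsum = blocks(np.where(good, f.sigma[: my * n, : mx * n] ** 2, 0.0)).sum(axis=(1, 3))
    mask = (cnt == 0).astype(np.uint8)
    with np.errstate(invalid="ignore", divide="ignore"):
        if reduce == "sum":
            data = dsum
            sigma = np.sqrt(vsum)
        else:
            data = np.where(cnt > 0, dsum / cnt, 0.0)
            sigma = np.where(cnt > 0, np.sqrt(vsum) / cnt, 0.0)
    return CorrectedFrame(data=data, sigma=sigma, mask=mask, monitor=f.monitor,
                          exposure=f.exposure, scan_pos=f.scan_pos,
                          source_path=f.source_path, binning=f.binning * n,
                          provenance=f.provenance + [f"bin_pixels(n={n}, reduce={reduce})"])
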