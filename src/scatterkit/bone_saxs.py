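"""Bone-mineral nanostructure parameters from reduced SAXS curves.

Two stereological parameters summarize each scanning-SAXS frame of bone:

* **T parameter** (nm) — the mean mineral-platelet thickness, from Porod
  analysis of the radial profile. With the Porod constant ``P`` (the
  high-q limit ``I -> P / q^4 + B``) and the scattering invariant
  ``J = integral (I - B) q^2 dq``, the mean chord length of the minority
  phase in a dilute two-phase system is ``T = 4 J / (pi P)``. Both J and P
  scale linearly with intensity, so T needs no absolute calibration.

* **rho parameter** (dimensionless, [0, 1]) — the degree of platelet
  alignment, from the azimuthal profile I(chi) over a full turn. Oriented
  platelets produce two peaks separated by 180 degrees on an isotropic
  background; rho is the fraction of azimuthal intensity in the peaks,
  ``rho = A_peaks / (A_peaks + A_bg)``: 0 for a flat profile, 1 for peaks
  on zero background. The predominant platelet axis is perpendicular to
  the scattering streak, i.e. ``(chi0 + 90) mod 180``.

The azimuthal peak pair is modeled as equal-amplitude, equal-width
Gaussians wrapped at the 360-degree period (periodic replicas are included
in the fit so peaks near 0/360 are handled correctly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .peakfit import Background, Peak, PeakModel, fit_curve, peak_area
from .profiles import Curve

logger = logging.getLogger(__name__)

__all__ = ["PorodResult", "RhoResult", "porod_fit", "invariant",
           "t_parameter", "t_from_curve", "rho_parameter", "bone_map", "BoneMap"]

_GAUSS_AREA = np.sqrt(np.pi / (4.0 * np.log(2.0)))  # area = A * w * this


@dataclass
class PorodResult:
    """Porod analysis of one radial profile."""

    P: float            # Porod constant, intensity * nm^-4
    B: float            # fluctuation background, intensity
    q_range: tuple[float, float]
    J: float = float("nan")   # invariant, intensity * nm^-3
    T: float = float("nan")   # mean thickness, nm
    valid: bool = True


@dataclass
class RhoResult:
    """Azimuthal two-peak analysis of one frame."""

    rho: float          # oriented fraction in [0, 1] (NaN if fit failed)
    chi0: float         # first peak center, degrees in [0, 360)
    fwhm: float         # peak width, degrees
    orientation: float  # predominant particle axis, degrees mod 180
    converged: bool = True
    amplitude: float = float("nan")
    background: float = float("nan")


def porod_fit(curve: Curve, q_fit_range: tuple[float, float]) -> PorodResult:
    """Fit Porod's law ``I = P / q^4 + B`` on the high-q tail.

    Linearized as ``I q^4 = B q^4 + P``: ordinary regression of ``I q^4``
    against ``q^4`` gives slope B and intercept P exactly. A non-positive
    intercept means the pattern has no Porod tail in the chosen range; the
    result is flagged invalid rather than raised, since scanning maps
    routinely contain empty (non-Porod) positions.
    """
    lo, hi = q_fit_range
    sel = (curve.x >= lo) & (curve.x <= hi) & np.isfinite(curve.y)
    if sel.sum() < 5:
        raise ValueError(f"Porod fit needs >= 5 points in q range [{lo}, {hi}], "
                         f"got {int(sel.sum())}")
    q4 = curve.x[sel] ** 4
    iq4 = curve.y[sel] * q4
    slope, intercept = np.polyfit(q4, iq4, 1)
    valid = intercept > 0
    if not valid:
        logger.warning("Porod fit gave non-positive P=%.3g: pattern not Porod-like",
                       intercept)
    return PorodResult(P=float(intercept), B=float(slope), q_range=(lo, hi),
                       valid=valid)


def invariant(curve: Curve, P: float, B: float,
              extrapolation: str = "constant") -> float:
    """Scattering invariant ``J = integral_0^inf (I - B) q^2 dq``.

    Evaluated as the sum of three pieces:

    * trapezoid of ``(I - B) q^2`` over the measured ``[q_min, q_max]``
      (NaN bins dropped);
    * low-q extension below ``q_min`` — constant intensity ``I(q_min)``,
      contributing ``(I(q_min) - B) q_min^3 / 3`` (``extrapolation="none"``
      omits it; the constant extension is deliberately simpler than a
      Guinier model and biases J by at most that term);
    * analytic Porod tail ``integral_{q_max}^inf (P / q^4) q^2 dq = P / q_max``.
    """
    c = curve.dropna()
    if len(c) < 2:
        raise ValueError("invariant needs at least 2 finite bins")
    q, intensity = c.x, c.y
    integrand = (intensity - B) * q ** 2
    if integrand[-1] < 0:
        logger.warning("invariant: negative I - B at q_max; background overestimated?")
    j_measured = float(np.trapezoid(integrand, q))
    j_low = 0.0
    if extrapolation == "constant":
        j_low = max(float(intensity[0]) - B, 0.0) * q[0] ** 3 / 3.0
    elif extrapolation != "none":
        raise ValueError(f"unknown extrapolation {extrapolation!r}")
    j_tail = P / q[-1] if P > 0 else 0.0
    return j_measured + j_low + j_tail


def t_parameter(J: float, P: float) -> float:
    """Mean-thickness parameter ``T = 4 J / (pi P)`` (nm).

    This is the stereological mean chord length of the minority phase;
    for dilute spheres of radius R it equals 4R/3, and for a polydisperse
    ensemble (4/3) <R^3>/<R^2>. Intensity units cancel between J and P.
    """
    if not P > 0:
        raise ValueError(f"T parameter requires P > 0, got {P}")
    return 4.0 * J / (np.pi * P)


def t_from_curve(curve: Curve, q_fit_range: tuple[float, float],
                 extrapolation: str = "constant") -> PorodResult:
    """Full Porod analysis of a radial profile: P, B, J and T in one call."""
    res = porod_fit(curve, q_fit_range)
    if not res.valid:
        return res
    res.J = invariant(curve, res.P, res.B, extrapolation=extrapolation)
    res.T = t_parameter(res.J, res.P)
    return res


def _wrapped_pair_model(chi0: float, amplitude: float, fwhm: float,
                        bg: float) -> PeakModel:
    """Two equal Gaussians at chi0, chi0+180 with periodic replicas at +-360."""
    offsets = (-360.0, -180.0, 0.0, 180.0, 360.0)
    peaks = [Peak("gaussian", amplitude, chi0 + off, fwhm) for off in offsets]
    ties = {}
    ref = offsets.index(0.0)
    for j, off in enumerate(offsets):
        if j == ref:
            continue
        ties[f"p{j}_amplitude"] = f"p{ref}_amplitude"
        ties[f"p{j}_fwhm"] = f"p{ref}_fwhm"
        ties[f"p{j}_center"] = f"p{ref}_center + {off - 0.0:.1f}"
    return PeakModel(peaks=peaks, background=Background("constant", (bg,)),
                     constraints=ties)


def rho_parameter(curve: Curve, *, max_gap_fraction: float = 0.3,
                  denominator: str = "total") -> RhoResult:
    """Degree-of-alignment parameter from an azimuthal profile over [0, 360).

    Fits a constant background plus two Gaussian peaks constrained to equal
    amplitude and width with centers exactly 180 degrees apart (wrapped at
    the period). Then

    * ``A_peaks`` = combined closed-form area of the two peaks per period,
    * ``A_bg``   = background level x 360,
    * ``rho = A_peaks / (A_peaks + A_bg)`` (``denominator="total"``, in
      [0, 1]) or ``A_peaks / A_bg`` (``denominator="background"``, the
      unbounded peak-to-background ratio).

    A failed fit reports ``rho = NaN`` with ``converged=False`` — scanning
    pipelines must keep going.
    """
    finite = np.isfinite(curve.y)
    gap = 1.0 - finite.mean()
    if gap > max_gap_fraction:
        raise ValueError(f"azimuthal coverage gap {gap:.0%} exceeds "
                         f"{max_gap_fraction:.0%}")
    if denominator not in ("total", "background"):
        raise ValueError(f"unknown denominator {denominator!r}")
    x, y = curve.x[finite], curve.y[finite]
    bg0 = float(np.percentile(y, 10))
    amp0 = max(float(y.max() - bg0), 1e-12)
    chi0_init = float(x[np.argmax(y)]) % 180.0  # pair is 180-periodic
    model0 = _wrapped_pair_model(chi0_init, amp0, 40.0, bg0)
    bounds = {"p2_center": (chi0_init - 90.0, chi0_init + 90.0),
              "p2_fwhm": (1.0, 180.0),
              "bg_c0": (0.0, np.inf)}
    res = fit_curve(curve, model0, bounds=bounds)
    if not res.converged:
        return RhoResult(rho=float("nan"), chi0=float("nan"), fwhm=float("nan"),
                         orientation=float("nan"), converged=False)
    fitted = res.model.peaks[2]  # the k=0 replica carries the free parameters
    chi0 = fitted.center % 360.0
    a_peaks = 2.0 * peak_area(fitted)  # two peaks per period
    bg = res.model.background.coefficients[0]
    a_bg = bg * 360.0
    if denominator == "total":
        rho = a_peaks / (a_peaks + a_bg) if (a_peaks + a_bg) > 0 else float("nan")
    else:
        rho = a_peaks / a_bg if a_bg > 0 else float("inf")
    return RhoResult(rho=float(rho), chi0=float(chi0), fwhm=float(fitted.fwhm),
                     orientation=float((chi0 + 90.0) % 180.0), converged=True,
                     amplitude=float(fitted.amplitude), background=float(bg))


@dataclass
class BoneMap:
    """Dense scan-grid maps of per-frame parameters."""

    xs: np.ndarray                    # unique scan x positions, sorted
    ys: np.ndarray                    # unique scan y positions, sorted
    grids: dict[str, np.ndarray]      # name -> (len(ys), len(xs)) array, NaN = missing
    orientation_vectors: np.ndarray | None = None  # (len(ys), len(xs), 2) unit vectors


def bone_map(x, y, values: dict[str, np.ndarray]) -> BoneMap:
    """Arrange per-frame scalars onto the scan grid.

    ``x``/``y`` are per-frame motor positions; ``values`` maps parameter
    names (e.g. ``"T"``, ``"rho"``, ``"orientation"``) to per-frame arrays.
    Positions need not form a complete grid — missing cells are NaN.
    Duplicate positions resolve last-wins with a warning. When an
    ``"orientation"`` entry (degrees, mod 180) is present, unit vectors are
    attached for quiver-style plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or any(len(np.asarray(v)) != n for v in values.values()):
        raise ValueError("x, y and all value arrays must have equal length")
    xs = np.unique(x)
    ys = np.unique(y)
    ix = np.searchsorted(xs, x)
    iy = np.searchsorted(ys, y)
    seen = np.zeros((len(ys), len(xs)), dtype=bool)
    if seen[iy, ix].any() or len(np.unique(iy * len(xs) + ix)) < n:
        logger.warning("bone_map: duplicate scan positions; keeping last values")
    grids = {}
    for name, vals in values.items():
        g = np.full((len(ys), len(xs)), np.nan)
        g[iy, ix] = np.asarray(vals, dtype=float)  # last assignment wins
        grids[name] = g
    vectors = None
    if "orientation" in grids:
        ang = np.radians(grids["orientation"])
        vectors = np.dstack([np.cos(ang), np.sin(ang)])
    return BoneMap(xs=xs, ys=ys, grids=grids, orientation_vectors=vectors)
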