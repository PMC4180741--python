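"""Synthetic detector frames and frame series with known ground truth.

Every downstream stage (integration, cuts, Porod/rho analysis, series
fitting, the online watcher) is exercised against frames generated here,
so each generator writes a *truth record* holding the analytically known
quantities the analysis is supposed to recover.

Three pattern families:

* ``sphere_pattern`` — dilute polydisperse spheres: isotropic SAXS with a
  Porod ``q^-4`` tail. Intensity per pixel is the number-averaged
  ``c <V(R)^2 F^2(qR)>`` over a Schulz radius distribution plus a flat
  background, with ``F(x) = 3 (sin x - x cos x) / x^3`` the sphere form
  factor. The analytic Porod constant is ``P = 8 pi^2 c <R^2>``, the
  invariant ``J = 2 pi^2 c <V>``, hence ``T = (4/3) <R^3>/<R^2>`` exactly.
* ``anisotropic_pattern`` — centrosymmetric oriented scattering:
  ``I(q, chi) = S(q) [b + a g(chi; chi0, w) + a g(chi; chi0 + 180, w)]``
  with wrapped Gaussian azimuthal peaks; the truth record carries the
  analytically integrated peak/background areas and thus rho_true.
* ``gisaxs_series`` — grazing-incidence frames with symmetric side maxima
  at ``+- q_y*(k)`` drifting along a per-frame trajectory on a decaying
  diffuse background (cluster-growth style), written as numbered TIFFs
  plus a tab-separated truth manifest.

Counting noise is Poisson with an explicit seed; the noiseless expectation
is available for exact tests (``noise=False``). The Schulz distribution is
used for polydispersity because its moments are closed-form:
``<R^n> = R0^n Gamma(z + 1 + n) / (Gamma(z + 1) (z + 1)^n)`` with
``z = 1 / p^2 - 1`` for relative width ``p``. Default polydispersity is
10% — enough to damp form-factor oscillations so Porod fits are stable,
narrow enough to stay "monodisperse-like".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .geometry import ExperimentGeometry, build_qmap
from .image_io import Frame, write_frame

__all__ = ["SynthSpec", "schulz_moment", "sphere_pattern",
           "anisotropic_pattern", "gisaxs_series",
           "default_saxs_geometry", "default_gisaxs_geometry"]

_4LN2 = 4.0 * np.log(2.0)


def default_saxs_geometry(shape=(128, 128), wavelength=0.1, distance=500.0,
                          pixel_size=1.0) -> ExperimentGeometry:
    """Transmission geometry with the beam centered on the detector."""
    return ExperimentGeometry(wavelength=wavelength, distance=distance,
                              beam_center=((shape[1] - 1) / 2, (shape[0] - 1) / 2),
                              pixel_size=(pixel_size, pixel_size),
                              mode="transmission")


def default_gisaxs_geometry(shape=(128, 128), wavelength=0.096, distance=2750.0,
                            pixel_size=0.172, incidence=0.5) -> ExperimentGeometry:
    """Grazing geometry, direct beam at the bottom-center of the detector."""
    return ExperimentGeometry(wavelength=wavelength, distance=distance,
                              beam_center=((shape[1] - 1) / 2, shape[0] - 1),
                              pixel_size=(pixel_size, pixel_size),
                              incidence=incidence, mode="grazing")


@dataclass
class SynthSpec:
    """Recipe for one synthetic pattern or series.

    ``ground_truth`` is filled by the generator; the same seed and spec
    always reproduce bit-identical frames.
    """

    kind: str
    geometry: ExperimentGeometry
    shape: tuple[int, int] = (128, 128)
    seed: int = 0
    flux: float = 1.0e3
    background: float = 1.0
    noise: bool = True
    ground_truth: dict = field(default_factory=dict)


def schulz_moment(r_mean: float, poly: float, n: int) -> float:
    """n-th raw moment <R^n> of a Schulz distribution.

    ``r_mean`` is the mean radius, ``poly`` the relative width
    sigma_R / <R> (``poly = 0`` degenerates to monodisperse).
    """
    if poly <= 0:
        return r_mean ** n
    z = 1.0 / poly ** 2 - 1.0
    return r_mean ** n * np.exp(gammaln(z + 1 + n) - gammaln(z + 1)
                                - n * np.log(z + 1))


def _sphere_f2(x: np.ndarray) -> np.ndarray:
    """Squared sphere form factor, F(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 1e-8
    xs = x[nz]
    out[nz] = (3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3) ** 2
    return out


def _schulz_average_v2f2(q: np.ndarray, r_mean: float, poly: float,
                         n_quad: int = 101) -> np.ndarray:
    """<V(R)^2 F^2(qR)> over the Schulz distribution via Gauss quadrature.

    The Schulz law is a gamma distribution, so the average is done on a
    fixed probability grid (midpoint rule in probability space), which is
    deterministic and accurate to well below the Porod-fit tolerances.
    """
    v2 = lambda r: (4.0 * np.pi / 3.0) ** 2 * r ** 6
    if poly <= 0:
        return v2(r_mean) * _sphere_f2(np.outer(q, [r_mean]).ravel()).reshape(q.shape)
    z = 1.0 / poly ** 2 - 1.0
    dist = stats.gamma(a=z + 1.0, scale=r_mean / (z + 1.0))
    probs = (np.arange(n_quad) + 0.5) / n_quad
    radii = dist.ppf(probs)
    acc = np.zeros_like(q, dtype=float)
    for r in radii:
        acc += v2(r) * _sphere_f2(q * r)
    return acc / n_quad


def sphere_pattern(spec: SynthSpec, r_mean: float = 2.0,
                   poly: float = 0.1) -> tuple[Frame, dict]:
    """Isotropic dilute-sphere pattern with an analytic Porod tail.

    Returns the frame and a truth record with the analytic Porod constant
    ``P = 8 pi^2 c <R^2>`` (c = flux), the flat background, the exact
    invariant ``J = 2 pi^2 c <V>`` and ``T_true = (4/3) <R^3>/<R^2>``.
    """
    if r_mean <= 0:
        raise ValueError("sphere radius must be positive")
    qmap = build_qmap(spec.shape, spec.geometry)
    expect = spec.flux * _schulz_average_v2f2(qmap.q, r_mean, poly) + spec.background
    q_max = float(qmap.q.max())
    if q_max * r_mean < 8.0:
        import logging
        logging.getLogger(__name__).warning(
            "q coverage (q_max R = %.1f) too small for a clean Porod tail", q_max * r_mean)
    rng = np.random.default_rng(spec.seed)
    data = rng.poisson(expect).astype(np.float64) if spec.noise else expect
    m2, m3 = schulz_moment(r_mean, poly, 2), schulz_moment(r_mean, poly, 3)
    truth = {
        "kind": "isotropic_spheres", "r_mean": r_mean, "poly": poly,
        "flux": spec.flux, "background": spec.background,
        "porod_constant": spec.flux * 8.0 * np.pi ** 2 * m2,
        "invariant": spec.flux * 2.0 * np.pi ** 2 * (4.0 * np.pi / 3.0) * m3,
        "t_true": (4.0 / 3.0) * m3 / m2,
        "seed": spec.seed,
    }
    spec.ground_truth = truth
    frame = Frame(data=data, monitor=1.0, source_path="synthetic:spheres")
    return frame, truth


def _wrapped_gauss(chi_deg: np.ndarray, chi0: float, fwhm: float) -> np.ndarray:
    """Unit-height Gaussian in the angular distance to chi0, wrapped mod 360."""
    d = (np.asarray(chi_deg) - chi0 + 180.0) % 360.0 - 180.0
    return np.exp(-_4LN2 * d ** 2 / fwhm ** 2)


def anisotropic_pattern(spec: SynthSpec, chi0: float = 40.0, amplitude: float = 5.0,
                        fwhm: float = 40.0, q_peak: float = 1.0,
                        q_width: float = 0.6) -> tuple[Frame, dict]:
    """Centrosymmetric oriented pattern with known azimuthal peak areas.

    ``I(q, chi) = S(q) [b + a (g(chi; chi0) + g(chi; chi0 + 180))]`` with
    unit-height wrapped Gaussians ``g`` of width ``fwhm`` and a broad radial
    envelope ``S(q)`` centered at ``q_peak``. The truth record stores the
    per-period analytic areas

    * ``area_peaks = 2 a * integral_0^360 g  = 2 a w sqrt(pi/4ln2) * wrap``
      (computed by exact quadrature of the wrapped profile),
    * ``area_bg = 360 b``,

    and ``rho_true = area_peaks / (area_peaks + area_bg)``.
    """
    if amplitude < 0:
        raise ValueError("anisotropy amplitude must be >= 0")
    qmap = build_qmap(spec.shape, spec.geometry)
    s_q = np.exp(-((qmap.q - q_peak) / q_width) ** 2)  # radial envelope
    azim = (spec.background
            + amplitude * (_wrapped_gauss(qmap.chi, chi0, fwhm)
                           + _wrapped_gauss(qmap.chi, chi0 + 180.0, fwhm)))
    expect = spec.flux * s_q * azim
    rng = np.random.default_rng(spec.seed)
    data = rng.poisson(expect).astype(np.float64) if spec.noise else expect
    # exact per-period area of the wrapped pair on a fine deterministic grid
    grid = np.linspace(0.0, 360.0, 720001)
    pair = _wrapped_gauss(grid, chi0, fwhm) + _wrapped_gauss(grid, chi0 + 180.0, fwhm)
    area_peaks = amplitude * float(np.trapezoid(pair, grid))
    area_bg = 360.0 * spec.background
    truth = {
        "kind": "anisotropic", "chi0": chi0 % 360.0, "amplitude": amplitude,
        "fwhm": fwhm, "background": spec.background, "q_peak": q_peak,
        "area_peaks": area_peaks, "area_bg": area_bg,
        "rho_true": area_peaks / (area_peaks + area_bg),
        "orientation_true": (chi0 + 90.0) % 180.0,
        "seed": spec.seed,
    }
    spec.ground_truth = truth
    frame = Frame(data=data, monitor=1.0, source_path="synthetic:anisotropic")
    return frame, truth


def gisaxs_series(spec: SynthSpec, out_dir, n_frames: int = 50,
                  qy_start: float = 0.20, qy_end: float = 0.08,
                  peak_fwhm: float = 0.03, peak_height: float = 400.0,
                  qz_band: tuple[float, float] = (0.10, 0.30),
                  decay: float = 10.0) -> list[dict]:
    """Write a GISAXS growth series as numbered TIFFs plus a truth manifest.

    Frame ``k`` carries symmetric side maxima at ``q_y = +- q_y*(k)`` (the
    center moving linearly from ``qy_start`` to ``qy_end``, emulating
    cluster coarsening), Lorentzian in q_y with width ``peak_fwhm``,
    confined to the ``qz_band``, on an exponentially decaying diffuse
    background. Returns the manifest (one record per frame, with the
    planted center) also written to ``manifest.tsv`` / ``truth.json``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qmap = build_qmap(spec.shape, spec.geometry)
    qy, qz = qmap.qy, qmap.qz
    band = np.exp(-0.5 * ((qz - np.mean(qz_band)) / (np.ptp(qz_band) / 4.0)) ** 2)
    hw = peak_fwhm / 2.0
    rng = np.random.default_rng(spec.seed)
    centers = np.linspace(qy_start, qy_end, n_frames)
    manifest = []
    for k, qy_star in enumerate(centers):
        side = (hw ** 2 / ((qy - qy_star) ** 2 + hw ** 2)
                + hw ** 2 / ((qy + qy_star) ** 2 + hw ** 2))
        diffuse = spec.background + 20.0 * np.exp(-decay * np.abs(qy)) * band
        expect = peak_height * side * band + diffuse
        data = rng.poisson(expect) if spec.noise else expect
        name = f"frame_{k:05d}.tif"
        write_frame(out_dir / name, np.asarray(data, dtype=np.float32)
                    if not spec.noise else np.asarray(data, dtype=np.uint32))
        manifest.append({"frame": k, "file": name, "qy_center": float(qy_star),
                         "fwhm": peak_fwhm, "height": peak_height})
    with open(out_dir / "manifest.tsv", "w", encoding="utf-8") as fh:
        fh.write("frame\tfile\tqy_center\tfwhm\theight\n")
        for rec in manifest:
            fh.write(f"{rec['frame']}\t{rec['file']}\t{rec['qy_center']:.9g}"
                     f"\t{rec['fwhm']:.9g}\t{rec['height']:.9g}\n")
    truth = {"kind": "gisaxs_series", "n_frames": n_frames,
             "qy_start": qy_start, "qy_end": qy_end, "peak_fwhm": peak_fwhm,
             "qz_band": list(qz_band), "seed": spec.seed}
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    spec.ground_truth = truth
    return manifest
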