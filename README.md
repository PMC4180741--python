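# scatterkit

Plug-in based reduction and analysis of scanning SAXS/WAXS/GISAXS detector
data: calibrated integration and line-cutting of 2-D frames, composite peak
fitting across frame series, and bone-mineral T/ρ/orientation analysis —
runnable offline on file lists or online on a directory that is still being
filled by the acquisition, with all results accumulated in a typed table and
exportable as spreadsheets and scan-grid maps.

## Who this is for

Synchrotron users running scanning small-angle scattering (e.g. position-
resolved bone-tissue mapping) or in-situ grazing-incidence experiments
(e.g. metal sputter deposition on films) who need *fast, scriptable* data
reduction — per-frame scalars out of thousands of 2-D frames — rather than
full model fitting. Everything is a plain Python library plus a thin CLI;
the processing pipeline is assembled from small plug-ins wired into a tree,
so a beamline-specific step is one short `.py` file away.

## What it computes

**Geometry.** Each detector pixel maps to momentum transfer. In
transmission, q = (4π/λ)·sin θ with 2θ = atan(r/D) (r the in-plane distance
from the beam center, D the sample–detector distance) plus an azimuth χ.
In grazing incidence, with in-plane angle ψ = atan(Δx·p_x/D) and exit angle
α_f = atan(Δy·p_y/D) − α_i:

    q_y = (2π/λ) sin ψ cos α_f,   q_z = (2π/λ)(sin α_i + sin α_f).

**Reduction.** Radial profiles I(q), azimuthal profiles I(χ) over an
annulus, GISAXS out-of-plane/detector/arbitrary-direction line cuts
averaged over an ROI band, and rectangular ROI statistics — all by simple
box integration (pixel-center histogramming) with masks, Poisson error
propagation, background subtraction, monitor normalization and binning.

**Peak fitting.** Arbitrary sums of Gaussian, Lorentzian and pseudo-Voigt
peaks (height A, center x₀, FWHM w) on constant/linear/quadratic/power-law
backgrounds, with parameter ties and bounds; sequential fitting across a
frame series propagates each frame's result as the next frame's start, so
a drifting peak is tracked through 10⁴ frames without re-guessing.

**Bone-mineral parameters.** From the radial profile, Porod analysis
(I → P/q⁴ + B) and the scattering invariant J = ∫(I−B)q² dq give the mean
mineral-platelet thickness **T = 4J/(πP)**; from the azimuthal profile, a
constrained two-peak fit (equal Gaussians 180° apart on a constant
background) gives the degree of alignment **ρ = A_peaks/(A_peaks + A_bg)**
∈ [0, 1] and the predominant platelet orientation (χ₀ + 90°) mod 180°.
Per-frame values assemble into dense scan-grid maps.

**Synthetic ground truth.** A generator module produces dilute
polydisperse-sphere patterns (analytic Porod constant and T), oriented
patterns with known azimuthal peak areas (analytic ρ), and GISAXS series
with drifting side maxima — every analysis stage is testable without
beamline data.

## Worked example

```python
import numpy as np
from scatterkit import synthgen
from scatterkit.geometry import build_qmap
from scatterkit.profiles import radial_profile, azimuthal_profile
from scatterkit.bone_saxs import t_from_curve, rho_parameter

geom = synthgen.default_saxs_geometry((128, 128))
qmap = build_qmap((128, 128), geom)

# isotropic dilute spheres, R = 2 nm, 10% Schulz polydispersity
spec = synthgen.SynthSpec(kind="isotropic_spheres", geometry=geom,
                          shape=(128, 128), seed=1, flux=1e3)
frame, truth = synthgen.sphere_pattern(spec, r_mean=2.0, poly=0.1)
iq = radial_profile(frame, qmap, 200)
porod = t_from_curve(iq, (3.0, 11.0))
print(f"T = 4J/(pi P) = {porod.T:.3f} nm  (analytic {truth['t_true']:.3f} nm)")

# centrosymmetric oriented pattern
aspec = synthgen.SynthSpec(kind="anisotropic", geometry=geom,
                           shape=(128, 128), seed=1, flux=1e3)
aframe, atruth = synthgen.anisotropic_pattern(aspec, chi0=40.0, amplitude=5.0,
                                              fwhm=40.0, q_peak=3.0, q_width=1.5)
rho = rho_parameter(azimuthal_profile(aframe, qmap, (2.0, 4.0), 180))
print(f"rho = {rho.rho:.3f}  (analytic {atruth['rho_true']:.3f})")
print(f"orientation = {rho.orientation:.1f} deg")
```

prints

```
T = 4J/(pi P) = 2.705 nm  (analytic 2.720 nm)
rho = 0.542  (analytic 0.542)
orientation = 130.0 deg
```

The T estimate lands within 1% of the analytic mean chord length
(4/3)·⟨R³⟩/⟨R²⟩ of the planted sphere ensemble; ρ matches the planted
peak-area fraction, and the orientation is perpendicular to the planted
azimuthal maximum at χ₀ = 40°.

From the shell, the same chains run as `scatterkit synth`, `scatterkit
integrate`, `scatterkit cut`, `scatterkit fit-series`, `scatterkit
bone-map`, and `scatterkit run --config pipeline.cfg` for a full plug-in
pipeline (offline with `--offline`, or `--watch`ing a directory while
frames arrive; files are picked up once their size is stable across two
polls).

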