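# Methods

This note records the models, conventions and numerical choices behind
scatterkit, in the order data flows through the package.

## Detector geometry

Pixels are indexed 0-based with the image origin top-left (row-major), as
TIFF and EDF store them; "up" on the detector is *decreasing* row index.
The azimuth χ is measured counterclockwise from the +x detector axis
(increasing column) in degrees in [0, 360), so "up" is χ = 90°. Units are
fixed throughout: wavelength in nm, distances in mm, q in nm⁻¹, angles in
degrees; conversions happen only at the I/O boundary.

Transmission mapping: q = (4π/λ)·sin θ with 2θ = atan(r/D), exact at all
angles (no small-angle expansion). Grazing mapping: with ψ = atan(Δx·p_x/D)
and α_f = atan(Δy·p_y/D) − α_i,

    q_y = (2π/λ) sin ψ cos α_f,
    q_z = (2π/λ)(sin α_i + sin α_f).

The q_x component is neglected — the usual small-angle contract for
GISAXS detectors a few metres from the sample; at ψ, α_f ≲ 2° the neglected
term is below 10⁻³ of q_y. The beam center in grazing mode is the
*direct-beam* spot (α_f = −α_i there, hence q_z = 0), not the specular
reflection. The detector is modeled flat and orthogonal to the beam;
tilt/rotation calibration, refraction corrections below the critical
angle, and polarization/solid-angle corrections are out of scope. Q-maps
are cached per (shape, geometry), so frame series pay the trigonometry
once.

## Corrections and the error model

Raw counts N get σ = sqrt(max(N, 1)) — Poisson, with the conventional
floor of one count so weighted fits never receive infinite weight on empty
pixels. Every correction propagates σ to first order: background
subtraction adds variances (σ′² = σ² + s²σ_bg²), monitor normalization
divides both, n×n binning sums variances over unmasked members. Negative
intensities after background subtraction are retained, not clipped;
clipping would bias bin means upward exactly where statistics are worst.
A binned pixel is masked only when *all* members are masked; partial
blocks at the right/bottom edges are dropped.

## Integration ("simple box integration")

All 1-D reductions are pixel-center histogramming: each unmasked pixel
contributes its full intensity to the single bin whose half-open interval
[lo, hi) contains its coordinate (the last bin is closed). No pixel
splitting. This makes intensity conservation exact —
Σ_bins (mean·n_pix) = Σ selected pixels — which the tests assert to
1e-13, and makes a per-pixel loop a bit-exact oracle for the vectorized
path. Empty bins carry NaN (not zero) so downstream fits drop them.
Cuts accept mean (default) or median reduction; the median's σ uses the
asymptotic factor 1.2533·σ_mean.

## Peak fitting

Peaks are height-parameterized: Gaussian A·exp(−4 ln2 (x−x₀)²/w²),
Lorentzian A·(w/2)²/((x−x₀)²+(w/2)²), pseudo-Voigt η·L + (1−η)·G with
shared A, x₀, w — the common powder-diffraction form. Closed-form areas
(Gaussian A·w·sqrt(π/4ln2), Lorentzian A·w·π/2) are verified against
quadrature to 1e-6. Backgrounds: constant, linear, quadratic, power-law.
Optimization is deterministic Levenberg–Marquardt (via lmfit) with weights
1/σ²; parameter ties are algebraic expressions (e.g. center₂ = center₁ +
180). Amplitudes are bounded below by 0 and widths by 10⁻¹²
to keep the optimizer out of degenerate sign flips.

Non-convergence is data, not an exception: a failed frame yields
`converged=False` with the initial model echoed, and series processing
continues — mandatory when fitting 10⁴-frame in-situ series unattended.
With propagation enabled, frame k starts from frame k−1's converged
parameters and falls back to the configured initial model after a failure.

## Bone-mineral parameters

**T.** Porod's law is fitted linearly: regressing I·q⁴ on q⁴ gives
intercept P and slope B exactly, with no iteration. The invariant is
J = ∫₀^∞ (I−B) q² dq, assembled from (i) the trapezoid over the measured
range, (ii) a constant low-q extension contributing (I(q_min)−B)·q_min³/3
— deliberately simpler than a Guinier extrapolation; its bias is bounded
by that term and is < 1% in the test conditions — and (iii) the analytic
Porod tail P/q_max. Then T = 4J/(πP), the stereological mean chord length
of the minority phase: 4R/3 for dilute spheres of radius R,
(4/3)⟨R³⟩/⟨R²⟩ for a polydisperse ensemble. T is invariant under intensity
rescaling since J and P are both linear in I. For near-monodisperse
systems the Porod range must span several form-factor oscillation periods
(period π/R in q), otherwise the regression aliases the oscillation into
P; the end-to-end tests use q·R ≈ 6–22.

**ρ.** The azimuthal profile over [0, 360) is fitted with a constant
background plus two Gaussians constrained to equal amplitude and width
with centers exactly 180° apart. Wrapping at the period is handled by
fitting periodic replicas (centers χ₀ + k·180°, k = −2…2, all tied), so
peaks near 0°/360° are seamless. Then

    ρ = A_peaks / (A_peaks + A_bg),  A_peaks = 2·A·w·sqrt(π/4ln2),
                                     A_bg = background·360°.

ρ is 0 for a flat profile and → 1 for peaks on zero background. The
peak-to-background *ratio* A_peaks/A_bg is available via
`denominator="background"` for comparison with conventions that divide by
the background area only. The predominant particle orientation is
(χ₀ + 90°) mod 180° — platelet long axes lie perpendicular to the
azimuthal intensity maximum in the small-angle streak geometry. Profiles
with more than 30% empty azimuthal bins are rejected rather than fitted.

## Pipeline framework

Processing is strictly sequential, in input order — determinism over
throughput. A pipeline is a tree of plug-in instances rooted at a reader;
wiring is type-checked (scalar/curve/image/text) before any data flows.
Each frame appends exactly one row to the typed result table; a plug-in
failure on one frame produces NaN/empty cells plus an error note in that
row only. Images enter the table as file references, never pixels, so
tables stay in memory for 10⁴-row runs. Output columns are namespaced
`node.output` to make name collisions between plug-ins impossible.

The online runner polls a directory; a file is eligible only when its
size is unchanged across two successive polls (completeness heuristic —
acquisition systems write frames in one pass, so a stable size means a
finished file). Files that parse as truncated are held back until they
stop changing or the final drain; files that are simply unreadable are
retried once, then marked failed. Within a poll, new files are processed
in name-sorted order, so offline and online runs of the same file set
produce identical tables (asserted in the tests with frames dropped into
the watched directory mid-run). An overwritten file is not reprocessed:
the first complete version wins.

User plug-ins are plain `.py` files exposing a `DESCRIPTION` dict
(parameters, typed inputs/outputs) and a `get_data(params, inputs)`
function; malformed files are skipped with a diagnostic, never fatally.

## Synthetic data: what it emulates, and what not

The generator plants known ground truth so every chain is testable
end-to-end without beamline data. Defaults are chosen once to resemble
the instruments this kind of analysis runs on:

* **Spheres** — dilute, number-averaged I(q) = c·⟨V²F²(qR)⟩ over a Schulz
  radius distribution (closed-form moments; default 10% relative width,
  enough to damp form-factor oscillations, narrow enough to stay
  monodisperse-like), flat fluctuation background, Poisson noise. The
  truth record carries the analytic P = 8π²c⟨R²⟩, J = 2π²c⟨V⟩, and
  T = (4/3)⟨R³⟩/⟨R²⟩. The synthetic SAXS geometry (λ = 0.1 nm, D =
  500 mm, 1 mm pixels, 128² detector) covers q·R up to ≈ 22 so the Porod
  tail is well sampled.
* **Oriented patterns** — I(q,χ) = S(q)·[b + a·(wrapped Gaussian pair at
  χ₀, χ₀+180°)] with a broad radial envelope; the truth record stores the
  exactly integrated per-period peak and background areas, hence ρ_true.
* **GISAXS series** — symmetric side maxima at ±q_y\*(k), Lorentzian in
  q_y, drifting linearly (default 0.20 → 0.08 nm⁻¹, the coarsening
  direction of cluster growth) inside a q_z band on a decaying diffuse
  background; geometry matches a microfocus beamline (λ = 0.096 nm,
  D = 2750 mm, 172 µm pixels, α_i = 0.5°).

Not emulated: detector gaps and hot pixels beyond what masks express,
beam polarization and solid-angle effects, refraction/Yoneda enhancement
in the grazing patterns, inter-particle structure factors, and absolute
intensity units. Passing tests therefore demonstrate the correctness of
the *reduction and parameter extraction*, not of instrument-specific
corrections upstream of it.

## Problem sizes in the tests

The suite runs on 64²–128² synthetic detectors, 200-frame series and
50-file watcher runs — small enough to iterate quickly, large enough that
every statistical tolerance (T within 5%, ρ within 2%, series endpoints
within 2%) is dominated by the method, not the sample size.

## Known limitations

* EDF support covers single-image files with the common scalar header
  keys; multi-frame EDF and compressed TIFF variants are not read.
* The constant low-q extrapolation of J underestimates steeply rising
  low-q scattering (aggregates); use a smaller q_min or accept the
  documented bias.
* The ρ fit assumes a single orientation population; bimodal textures
  (two peak pairs) need a custom plug-in.
* The watcher's size-stability heuristic can mis-fire on writers that
  pause longer than one poll interval mid-file; such frames surface as
  parse errors and are retried.
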