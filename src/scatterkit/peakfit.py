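"""Composite peak fitting for 1-D curves, and sequential fitting of series.

Models are arbitrary sums of Gaussian, Lorentzian and pseudo-Voigt peaks on
top of a constant / linear / quadratic / power-law background. All peaks
are parameterized by *height* amplitude ``A``, center ``x0`` and full width
at half maximum ``w``:

* Gaussian:    ``A exp(-4 ln2 (x - x0)^2 / w^2)``
* Lorentzian:  ``A (w/2)^2 / ((x - x0)^2 + (w/2)^2)``
* pseudo-Voigt: ``eta * L + (1 - eta) * G`` with shared ``A, x0, w`` and
  mixing ``eta`` in [0, 1].

Closed-form areas (one peak, full line): Gaussian ``A w sqrt(pi / (4 ln2))``,
Lorentzian ``A w pi / 2``.

The optimizer is deterministic (Levenberg-Marquardt via lmfit, no
stochastic restarts) so repeated series runs are bit-reproducible.
Non-convergence on a frame is *data*, not an exception: ``fit_series``
records it and keeps going — essential when processing 10^4-frame series.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

__all__ = ["Peak", "Background", "PeakModel", "FitResult",
           "evaluate", "peak_area", "fit_curve", "fit_series",
           "gaussian", "lorentzian", "pseudo_voigt"]

_4LN2 = 4.0 * np.log(2.0)

PEAK_SHAPES = ("gaussian", "lorentzian", "pseudo_voigt")
BACKGROUND_KINDS = ("constant", "linear", "quadratic", "power_law", "none")


def gaussian(x, amplitude, center, fwhm):
    """Height-normalized Gaussian; value A at center, A/2 at center +- fwhm/2."""
    return amplitude * np.exp(-_4LN2 * (x - center) ** 2 / fwhm ** 2)


def lorentzian(x, amplitude, center, fwhm):
    """Height-normalized Lorentzian; value A at center, A/2 at center +- fwhm/2."""
    hw = fwhm / 2.0
    return amplitude * hw ** 2 / ((x - center) ** 2 + hw ** 2)


def pseudo_voigt(x, amplitude, center, fwhm, eta):
    """eta-weighted Lorentzian/Gaussian sum with shared amplitude and FWHM."""
    return (eta * lorentzian(x, amplitude, center, fwhm)
            + (1.0 - eta) * gaussian(x, amplitude, center, fwhm))


_SHAPE_FUNCS = {"gaussian": gaussian, "lorentzian": lorentzian,
                "pseudo_voigt": pseudo_voigt}


@dataclass
class Peak:
    """One peak component of a composite model."""

    shape: str = "gaussian"
    amplitude: float = 1.0
    center: float = 0.0
    fwhm: float = 1.0
    eta: float = 0.5  # pseudo-Voigt mixing; ignored by other shapes

    def __post_init__(self) -> None:
        if self.shape not in PEAK_SHAPES:
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")

    def __call__(self, x):
        if self.shape == "pseudo_voigt":
            return pseudo_voigt(x, self.amplitude, self.center, self.fwhm, self.eta)
        return _SHAPE_FUNCS[self.shape](x, self.amplitude, self.center, self.fwhm)


@dataclass
class Background:
    """Polynomial or power-law background.

    kinds: ``constant`` c0; ``linear`` c0 + c1 x; ``quadratic``
    c0 + c1 x + c2 x^2; ``power_law`` c0 x^c1 (requires x > 0);
    ``none`` — identically zero.
    """

    kind: str = "constant"
    coefficients: tuple[float, ...] = (0.0,)

    _NCOEF = {"none": 0, "constant": 1, "linear": 2, "quadratic": 3, "power_law": 2}

    def __post_init__(self) -> None:
        if self.kind not in BACKGROUND_KINDS:
            raise ValueError(f"unknown background kind {self.kind!r}")
        need = self._NCOEF[self.kind]
        coef = tuple(self.coefficients)
        if len(coef) < need:
            coef = coef + (0.0,) * (need - len(coef))
        self.coefficients = coef[:need] if need else ()

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.kind == "none":
            return np.zeros_like(x)
        if self.kind == "constant":
            return np.full_like(x, c[0])
        if self.kind == "linear":
            return c[0] + c[1] * x
        if self.kind == "quadratic":
            return c[0] + c[1] * x + c[2] * x ** 2
        return c[0] * np.power(x, c[1])  # power_law


@dataclass
class PeakModel:
    """Sum of peaks plus background, with optional parameter ties.

    ``constraints`` maps a parameter name (``p<i>_amplitude|center|fwhm|eta``
    or ``bg_c<j>``) to an algebraic expression in the other parameter names,
    e.g. ``{"p1_center": "p0_center + 180"}`` for centrosymmetric azimuthal
    peaks, or ``{"p1_amplitude": "p0_amplitude"}`` for equal heights.
    """

    peaks: list[Peak] = field(default_factory=list)
    background: Background = field(default_factory=Background)
    constraints: dict[str, str] = field(default_factory=dict)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        y = self.background(x)
        for p in self.peaks:
            y = y + p(x)
        return y

    def param_names(self) -> list[str]:
        names = []
        for i, p in enumerate(self.peaks):
            names += [f"p{i}_amplitude", f"p{i}_center", f"p{i}_fwhm"]
            if p.shape == "pseudo_voigt":
                names.append(f"p{i}_eta")
        names += [f"bg_c{j}" for j in range(len(self.background.coefficients))]
        return names


def evaluate(model: PeakModel, x) -> np.ndarray:
    """Evaluate a composite model on abscissa ``x``."""
    return model(x)


def peak_area(peak: Peak) -> float:
    """Closed-form area under one peak (over the full real line)."""
    g_area = peak.amplitude * peak.fwhm * np.sqrt(np.pi / _4LN2)
    l_area = peak.amplitude * peak.fwhm * np.pi / 2.0
    if peak.shape == "gaussian":
        return g_area
    if peak.shape == "lorentzian":
        return l_area
    return peak.eta * l_area + (1.0 - peak.eta) * g_area


@dataclass
class FitResult:
    """Outcome of one composite fit.

    ``converged=False`` results echo the initial model; they are ordinary
    rows in series processing, never exceptions.
    """

    model: PeakModel
    params: dict[str, float]
    stderr: dict[str, float]
    redchi: float
    converged: bool
    n_eval: int
    message: str = ""

    def peak(self, i: int) -> Peak:
        return self.model.peaks[i]


def _make_params(model: PeakModel, bounds: dict | None) -> lmfit.Parameters:
    bounds = bounds or {}
    params = lmfit.Parameters()
    for i, p in enumerate(model.peaks):
        init = {"amplitude": (p.amplitude, 0.0, np.inf),
                "center": (p.center, -np.inf, np.inf),
                "fwhm": (p.fwhm, 1e-12, np.inf)}
        if p.shape == "pseudo_voigt":
            init["eta"] = (p.eta, 0.0, 1.0)
        for suffix, (val, lo, hi) in init.items():
            name = f"p{i}_{suffix}"
            lo, hi = bounds.get(name, (lo, hi))
            if not lo <= val <= hi:
                raise ValueError(f"initial {name}={val} outside bounds [{lo}, {hi}]")
            params.add(name, value=val, min=lo, max=hi)
    for j, c in enumerate(model.background.coefficients):
        name = f"bg_c{j}"
        lo, hi = bounds.get(name, (-np.inf, np.inf))
        if not lo <= c <= hi:
            raise ValueError(f"initial {name}={c} outside bounds [{lo}, {hi}]")
        params.add(name, value=c, min=lo, max=hi)
    for name, expr in model.constraints.items():
        if name not in params:
            raise ValueError(f"constraint on unknown parameter {name!r}")
        params[name].set(expr=expr)
    return params


def _model_from_params(model: PeakModel, params) -> PeakModel:
    peaks = []
    for i, p in enumerate(model.peaks):
        peaks.append(replace(
            p,
            amplitude=float(params[f"p{i}_amplitude"].value),
            center=float(params[f"p{i}_center"].value),
            fwhm=float(params[f"p{i}_fwhm"].value),
            eta=float(params[f"p{i}_eta"].value) if p.shape == "pseudo_voigt" else p.eta,
        ))
    coef = tuple(float(params[f"bg_c{j}"].value)
                 for j in range(len(model.background.coefficients)))
    return PeakModel(peaks=peaks,
                     background=Background(model.background.kind, coef),
                     constraints=dict(model.constraints))


def fit_curve(curve, model0: PeakModel, bounds: dict | None = None,
              max_nfev: int | None = None) -> FitResult:
    """Weighted least-squares fit of a composite model to one curve.

    NaN bins are dropped. Weights are ``1 / sigma^2`` where finite positive
    sigmas exist, unit weights otherwise. Initial values outside bounds
    raise before any optimization. Non-convergence returns a
    ``FitResult(converged=False)`` echoing the initial model.
    """
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    sigma = np.asarray(getattr(curve, "sigma", np.ones_like(y)), dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y, sigma = x[keep], y[keep], sigma[keep]

    params = _make_params(model0, bounds)  # validates init vs bounds
    nfree = sum(1 for p in params.values() if p.vary and p.expr is None)
    if len(x) <= nfree:
        raise ValueError(f"{len(x)} finite points cannot constrain {nfree} free parameters")

    use_weights = np.all(np.isfinite(sigma)) and np.all(sigma > 0)
    weights = 1.0 / sigma if use_weights else None

    def residual(pars):
        m = _model_from_params(model0, pars)
        r = m(x) - y
        return r * weights if weights is not None else r

    try:
        out = lmfit.minimize(residual, params, method="leastsq",
                             max_nfev=max_nfev, nan_policy="raise")
    except Exception as exc:
        return FitResult(model=copy.deepcopy(model0),
                         params={n: float(params[n].value) for n in params},
                         stderr={n: float("nan") for n in params},
                         redchi=float("nan"), converged=False, n_eval=0,
                         message=f"optimizer raised: {exc}")

    fitted = _model_from_params(model0, out.params)
    values = {n: float(out.params[n].value) for n in out.params}
    stderr = {n: (float(out.params[n].stderr) if out.params[n].stderr is not None
                  else float("nan")) for n in out.params}
    return FitResult(model=fitted, params=values, stderr=stderr,
                     redchi=float(out.redchi), converged=bool(out.success),
                     n_eval=int(out.nfev), message=str(out.message))


def fit_series(curves, model0: PeakModel, propagate: bool = True,
               bounds: dict | None = None) -> list[FitResult]:
    """Fit an ordered series of curves, one FitResult per curve.

    With ``propagate`` (the online-analysis mode), frame k starts from
    frame k-1's converged parameters — drifting peaks are tracked without
    re-guessing. A non-converged frame falls back to ``model0`` for the
    next frame, and processing continues; the output order always equals
    the input order.
    """
    results: list[FitResult] = []
    init = copy.deepcopy(model0)
    for curve in curves:
        try:
            res = fit_curve(curve, init, bounds=bounds)
        except ValueError as exc:
            res = FitResult(model=copy.deepcopy(init), params={}, stderr={},
                            redchi=float("nan"), converged=False, n_eval=0,
                            message=str(exc))
        results.append(res)
        init = copy.deepcopy(res.model) if (propagate and res.converged) \
            else copy.deepcopy(model0)
    return results
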