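"""Built-in plug-ins wrapping the library behind the pipeline interface.

Each built-in is a :class:`~scatterkit.framework.Plugin` whose descriptor
follows the same contract as user plug-in files: declared parameters,
typed inputs and outputs, and a ``get_data(params, inputs)`` body. Frames
flow between plug-ins as ``image`` values, reduced profiles as ``curve``
values, fitted numbers as ``scalar`` columns.

Geometry-aware plug-ins expect the ``geometry`` parameter to hold an
:class:`~scatterkit.geometry.ExperimentGeometry`; the pipeline runner (or
CLI) injects it from the configuration's geometry block.
"""

from __future__ import annotations

import copy
import math

import numpy as np

from .. import bone_saxs, corrections, peakfit, profiles
from ..framework import Plugin, PluginDescriptor
from ..geometry import build_qmap
from ..image_io import read_frame, write_table

__all__ = ["builtin_registry"]


def _p(name, type_, default=None):
    return {"name": name, "type": type_, "default": default}


def _port(name, type_):
    return {"name": name, "type": type_}


# ------------------------------------------------------------------ readers

_READ = Plugin(
    PluginDescriptor(
        name="read_frame",
        parameters=(_p("format", "text", ""),),
        inputs=(_port("path", "text"),),
        outputs=(_port("image", "image"),),
    ),
    lambda params, inputs: {"image": read_frame(inputs["path"],
                                                params["format"] or None)},
)

_NORMALIZE = Plugin(
    PluginDescriptor(
        name="normalize_monitor",
        parameters=(_p("default_monitor", "scalar", None),),
        inputs=(_port("image", "image"),),
        outputs=(_port("image", "image"),),
    ),
    lambda params, inputs: {"image": corrections.normalize_monitor(
        inputs["image"], default_monitor=params["default_monitor"])},
)


# -------------------------------------------------------------- reductions

def _roi_stats(params, inputs):
    s = profiles.roi_stats(inputs["image"], params["x"], params["y"],
                           params["width"], params["height"])
    return {"min": s.min, "max": s.max, "average": s.average, "sum": s.sum}


_ROI = Plugin(
    PluginDescriptor(
        name="roi_stats",
        parameters=(_p("x", "scalar", 0), _p("y", "scalar", 0),
                    _p("width", "scalar", 10), _p("height", "scalar", 10)),
        inputs=(_port("image", "image"),),
        outputs=(_port("min", "scalar"), _port("max", "scalar"),
                 _port("average", "scalar"), _port("sum", "scalar")),
    ),
    _roi_stats,
)


def _radial(params, inputs):
    frame = inputs["image"]
    qmap = build_qmap(frame.data.shape, params["geometry"])
    chi_range = None
    if params["chi_min"] is not None and params["chi_max"] is not None:
        chi_range = (params["chi_min"], params["chi_max"])
    return {"curve": profiles.radial_profile(frame, qmap, int(params["q_bins"]),
                                             chi_range=chi_range)}


_RADIAL = Plugin(
    PluginDescriptor(
        name="radial_profile",
        parameters=(_p("geometry", "text"), _p("q_bins", "scalar", 100),
                    _p("chi_min", "scalar", None), _p("chi_max", "scalar", None)),
        inputs=(_port("image", "image"),),
        outputs=(_port("curve", "curve"),),
    ),
    _radial,
)


def _azimuthal(params, inputs):
    frame = inputs["image"]
    qmap = build_qmap(frame.data.shape, params["geometry"])
    return {"curve": profiles.azimuthal_profile(
        frame, qmap, (params["q_min"], params["q_max"]),
        int(params["chi_bins"]))}


_AZIMUTHAL = Plugin(
    PluginDescriptor(
        name="azimuthal_profile",
        parameters=(_p("geometry", "text"), _p("q_min", "scalar", 0.0),
                    _p("q_max", "scalar", 1.0), _p("chi_bins", "scalar", 180)),
        inputs=(_port("image", "image"),),
        outputs=(_port("curve", "curve"),),
    ),
    _azimuthal,
)


def _cut(params, inputs):
    frame = inputs["image"]
    qmap = build_qmap(frame.data.shape, params["geometry"])
    return {"curve": profiles.gisaxs_cut(
        frame, qmap, direction=params["direction"], at=params["at"],
        roi_width=params["roi_width"],
        bins=int(params["bins"]) if params["bins"] else None)}


_CUT = Plugin(
    PluginDescriptor(
        name="gisaxs_cut",
        parameters=(_p("geometry", "text"), _p("direction", "text", "horizontal"),
                    _p("at", "scalar", 0.0), _p("roi_width", "scalar", 0.05),
                    _p("bins", "scalar", None)),
        inputs=(_port("image", "image"),),
        outputs=(_port("curve", "curve"),),
    ),
    _cut,
)


# ---------------------------------------------------------------- analysis

def _porod(params, inputs):
    res = bone_saxs.t_from_curve(inputs["curve"],
                                 (params["q_fit_min"], params["q_fit_max"]))
    return {"T": res.T if res.valid else math.nan, "P": res.P, "B": res.B,
            "J": res.J}


_POROD = Plugin(
    PluginDescriptor(
        name="porod_t",
        parameters=(_p("q_fit_min", "scalar", 2.0), _p("q_fit_max", "scalar", 4.0)),
        inputs=(_port("curve", "curve"),),
        outputs=(_port("T", "scalar"), _port("P", "scalar"),
                 _port("B", "scalar"), _port("J", "scalar")),
    ),
    _porod,
)


def _rho(params, inputs):
    res = bone_saxs.rho_parameter(inputs["curve"])
    return {"rho": res.rho, "chi0": res.chi0, "orientation": res.orientation,
            "fwhm": res.fwhm}


_RHO = Plugin(
    PluginDescriptor(
        name="rho_parameter",
        parameters=(),
        inputs=(_port("curve", "curve"),),
        outputs=(_port("rho", "scalar"), _port("chi0", "scalar"),
                 _port("orientation", "scalar"), _port("fwhm", "scalar")),
    ),
    _rho,
)


# ------------------------------------------------------- series peak fitting

def _fit_peak(params, inputs, state):
    """Single-peak + constant-background fit with cross-frame propagation."""
    curve = inputs["curve"]
    if params["x_min"] is not None or params["x_max"] is not None:
        lo = -np.inf if params["x_min"] is None else params["x_min"]
        hi = np.inf if params["x_max"] is None else params["x_max"]
        keep = (curve.x >= lo) & (curve.x <= hi)
        curve = profiles.Curve(curve.x[keep], curve.y[keep], curve.sigma[keep],
                               curve.n_pix[keep], curve.kind)
    model0 = peakfit.PeakModel(
        peaks=[peakfit.Peak(params["shape"], params["amplitude"],
                            params["center"], params["fwhm"])],
        background=peakfit.Background("constant", (params["background"],)),
    )
    init = state.get("model")
    if not (params["propagate"] and init is not None):
        init = model0
    result = peakfit.fit_curve(curve, init)
    if not result.converged:  # fall back to the configured guess, keep going
        result = peakfit.fit_curve(curve, model0)
    state["model"] = copy.deepcopy(result.model) if result.converged else None
    peak = result.model.peaks[0]
    return {"center": peak.center, "fwhm": peak.fwhm, "amplitude": peak.amplitude,
            "redchi": result.redchi, "converged": float(result.converged)}


_FIT_PEAK = Plugin(
    PluginDescriptor(
        name="fit_peak",
        parameters=(_p("shape", "text", "lorentzian"), _p("amplitude", "scalar", 1.0),
                    _p("center", "scalar", 0.0), _p("fwhm", "scalar", 1.0),
                    _p("background", "scalar", 0.0), _p("propagate", "scalar", 1),
                    _p("x_min", "scalar", None), _p("x_max", "scalar", None)),
        inputs=(_port("curve", "curve"),),
        outputs=(_port("center", "scalar"), _port("fwhm", "scalar"),
                 _port("amplitude", "scalar"), _port("redchi", "scalar"),
                 _port("converged", "scalar")),
    ),
    _fit_peak,
    make_state=dict,
)


# ------------------------------------------------------------------ export

_EXPORT_TABLE = Plugin(
    PluginDescriptor(
        name="export_table",
        parameters=(_p("path", "text", "table.tsv"),),
        inputs=(_port("table", "text"),),  # receives the table object directly
        outputs=(),
        category="export",
    ),
    lambda params, inputs: write_table(inputs["table"], params["path"]) or {},
)


def builtin_registry() -> dict[str, Plugin]:
    """Registry of all built-in plug-ins, keyed by name."""
    plugins = (_READ, _NORMALIZE, _ROI, _RADIAL, _AZIMUTHAL, _CUT,
               _POROD, _RHO, _FIT_PEAK, _EXPORT_TABLE)
    return {p.descriptor.name: p for p in plugins}
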