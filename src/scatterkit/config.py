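"""Key-value pipeline configuration files.

INI-style text, e.g.::

    [geometry]
    mode = transmission
    wavelength_nm = 0.1
    distance_mm = 1000
    beam_center_px = 63.5 63.5
    pixel_size_mm = 0.5 0.5
    incidence_deg = 0.0

    [pipeline]
    nodes = reader radial porod

    [node:reader]
    plugin = read_frame
    wire.path = source.path

    [node:radial]
    plugin = radial_profile
    wire.image = reader.image
    q_bins = 120

    [node:porod]
    plugin = porod_t
    wire.curve = radial.curve
    q_fit_min = 2.0
    q_fit_max = 4.0

Plug-in parameters are plain keys in the node section; ``wire.<input>``
keys bind inputs to upstream ``node.output`` references. Nodes whose
plug-in declares a ``geometry`` parameter receive the parsed geometry
object automatically.
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .framework import PipelineGraph, PipelineNode, Plugin
from .geometry import ExperimentGeometry

__all__ = ["load_config", "parse_geometry"]


def _floats(text: str) -> tuple[float, ...]:
    return tuple(float(v) for v in text.replace(",", " ").split())


def parse_geometry(section) -> ExperimentGeometry:
    """Build an ExperimentGeometry from a config geometry block."""
    bc = _floats(section.get("beam_center_px", "0 0"))
    ps = _floats(section.get("pixel_size_mm", "0.172 0.172"))
    if len(ps) == 1:
        ps = (ps[0], ps[0])
    return ExperimentGeometry(
        wavelength=float(section.get("wavelength_nm", "0.1")),
        distance=float(section.get("distance_mm", "1000")),
        beam_center=(bc[0], bc[1]),
        pixel_size=(ps[0], ps[1]),
        incidence=float(section.get("incidence_deg", "0")),
        mode=section.get("mode", "transmission").strip(),
    )


def _coerce(text: str):
    text = text.strip()
    if text.lower() in ("none", ""):
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def load_config(path, registry: dict[str, Plugin] | None = None):
    """Parse a config file into (geometry, graph).

    When a ``registry`` is given, the geometry object is injected into the
    parameters of every node whose plug-in declares a ``geometry``
    parameter.
    """
    parser = configparser.ConfigParser()
    read = parser.read(Path(path))
    if not read:
        raise FileNotFoundError(f"config file {path} not found")
    geometry = parse_geometry(parser["geometry"]) if "geometry" in parser else None

    graph = PipelineGraph()
    if "pipeline" in parser:
        node_ids = parser["pipeline"].get("nodes", "").split()
        for node_id in node_ids:
            section_name = f"node:{node_id}"
            if section_name not in parser:
                raise ValueError(f"config missing section [{section_name}]")
            section = parser[section_name]
            plugin_name = section.get("plugin")
            if not plugin_name:
                raise ValueError(f"[{section_name}] has no 'plugin' key")
            params, wire = {}, {}
            for key, value in section.items():
                if key == "plugin":
                    continue
                if key.startswith("wire."):
                    wire[key[5:]] = value.strip()
                else:
                    params[key] = _coerce(value)
            if registry is not None and plugin_name in registry:
                declares_geom = any(p["name"] == "geometry" for p in
                                    registry[plugin_name].descriptor.parameters)
                if declares_geom and geometry is not None:
                    params["geometry"] = geometry
            graph.nodes.append(PipelineNode(id=node_id, plugin=plugin_name,
                                            params=params, wire=wire))
    return geometry, graph
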