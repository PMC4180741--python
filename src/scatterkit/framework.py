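"""Plug-in pipeline engine: typed result table, graph validation, runners.

The processing model: a *pipeline graph* wires plug-in instances into a
tree rooted at a reader. For each incoming data set (one detector frame),
the graph is processed in topological order and the union of all plug-in
outputs is appended to the result table as exactly one row. Processing is
strictly sequential — determinism over throughput — and a plug-in failure
on one frame yields NaN/empty cells plus an error note for that row only;
the series never aborts.

A plug-in is a descriptor (name, parameters, typed inputs/outputs,
category) plus a ``get_data(params, inputs)`` callable. User plug-ins are
plain ``.py`` files in a plug-in folder (see :func:`discover_plugins`);
built-ins wrapping the library live in :mod:`scatterkit.plugins`.

Cell types are ``scalar``, ``curve``, ``image`` and ``text``. Image cells
are stored in the table as *file references*, never pixel data — frame
series are large, result tables must stay in memory.
"""

from __future__ import annotations

import fnmatch
import importlib.util
import logging
import math
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .image_io import Frame, FrameReadError, IncompleteFileError, write_table
from .profiles import Curve

logger = logging.getLogger(__name__)

__all__ = ["PluginDescriptor", "Plugin", "DataTable", "PipelineNode",
           "PipelineGraph", "discover_plugins", "validate_graph",
           "process_dataset", "run_offline", "run_online", "export",
           "GraphError"]

CELL_TYPES = ("scalar", "curve", "image", "text")
_TYPE_ALIASES = {"image-ref": "image", "image_ref": "image", "number": "scalar"}


def _norm_type(t: str) -> str:
    t = _TYPE_ALIASES.get(str(t).lower(), str(t).lower())
    if t not in CELL_TYPES:
        raise ValueError(f"unknown cell type {t!r} (expected one of {CELL_TYPES})")
    return t


class GraphError(ValueError):
    """Pipeline graph failed validation."""


@dataclass(frozen=True)
class PluginDescriptor:
    """Declared interface of a plug-in: parameters, typed ports, category."""

    name: str
    parameters: tuple = ()   # of {"name", "type", "default"}
    inputs: tuple = ()       # of {"name", "type"}
    outputs: tuple = ()      # of {"name", "type"}
    category: str = "base"   # base | export

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("plug-in descriptor needs a non-empty name")
        if self.category not in ("base", "export"):
            raise ValueError(f"unknown plug-in category {self.category!r}")
        names = [o["name"] for o in self.outputs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate output names in plug-in {self.name!r}")
        for port in list(self.inputs) + list(self.outputs):
            _norm_type(port["type"])

    def output_type(self, name: str) -> str:
        for o in self.outputs:
            if o["name"] == name:
                return _norm_type(o["type"])
        raise KeyError(f"plug-in {self.name!r} has no output {name!r}")

    def default_params(self) -> dict:
        return {p["name"]: p.get("default") for p in self.parameters}


@dataclass
class Plugin:
    """A descriptor plus its implementation.

    ``func(params, inputs) -> dict`` returns one value per declared
    output. ``make_state()`` (optional) produces per-run mutable state
    passed as a third argument — used e.g. by the series peak fitter to
    propagate the previous frame's parameters.
    """

    descriptor: PluginDescriptor
    func: Callable[..., dict]
    make_state: Callable[[], Any] | None = None


def _load_plugin_file(path: Path) -> Plugin:
    spec = importlib.util.spec_from_file_location(f"scatterkit_plugin_{path.stem}", path)
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    desc_dict = getattr(module, "DESCRIPTION", None)
    get_data = getattr(module, "get_data", None)
    if not isinstance(desc_dict, dict) or not callable(get_data):
        raise ValueError(f"{path.name}: plug-in needs a DESCRIPTION dict and "
                         f"a get_data(params, inputs) function")
    desc = PluginDescriptor(
        name=desc_dict.get("name", path.stem),
        parameters=tuple(desc_dict.get("parameters", ())),
        inputs=tuple(desc_dict.get("inputs", ())),
        outputs=tuple(desc_dict.get("outputs", ())),
        category=desc_dict.get("category", "base"),
    )
    return Plugin(descriptor=desc, func=get_data)


def discover_plugins(directory, registry: dict[str, Plugin] | None = None
                     ) -> dict[str, Plugin]:
    """Load every conforming ``.py`` plug-in file from a folder.

    Malformed plug-ins are skipped with a logged diagnostic — a broken
    user file must never take the framework down. Duplicate names (within
    the folder or against an existing registry) raise.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"plug-in folder {directory} does not exist")
    registry = dict(registry) if registry else {}
    for path in sorted(directory.glob("*.py")):
        if path.name.startswith("_"):
            continue
        try:
            plugin = _load_plugin_file(path)
        except Exception as exc:
            logger.warning("skipping malformed plug-in %s: %s", path.name, exc)
            continue
        name = plugin.descriptor.name
        if name in registry:
            raise ValueError(f"duplicate plug-in name {name!r} (from {path.name})")
        registry[name] = plugin
        logger.info("registered plug-in %r from %s", name, path.name)
    return registry


# ----------------------------------------------------------------- DataTable

class DataTable:
    """Typed column store: one row per processed data set, in order.

    Columns are declared on first append (name -> cell type); every later
    cell must match. Image cells hold file references (strings). Access a
    column with ``table[name]``; convert with :meth:`to_dataframe`.
    """

    def __init__(self) -> None:
        self._types: dict[str, str] = {}
        self._columns: dict[str, list] = {}

    def __len__(self) -> int:
        return len(next(iter(self._columns.values()))) if self._columns else 0

    @property
    def columns(self) -> list[str]:
        return list(self._types)

    def column_type(self, name: str) -> str:
        return self._types[name]

    def __getitem__(self, name: str) -> list:
        return self._columns[name]

    @staticmethod
    def _check(value, ctype: str, name: str):
        if value is None:
            return None
        if ctype == "scalar":
            if isinstance(value, (int, float, np.integer, np.floating)):
                return float(value)
            raise TypeError(f"column {name!r} is scalar, got {type(value).__name__}")
        if ctype == "curve":
            if isinstance(value, Curve):
                return value
            raise TypeError(f"column {name!r} is curve, got {type(value).__name__}")
        if ctype == "image":
            if isinstance(value, Frame):
                return value.source_path or "<in-memory>"
            return str(value)
        return str(value)  # text

    def append_row(self, cells: dict[str, Any], types: dict[str, str]) -> None:
        """Append one row; new columns are back-filled with None."""
        for name, ctype in types.items():
            ctype = _norm_type(ctype)
            if name in self._types:
                if self._types[name] != ctype:
                    raise TypeError(f"column {name!r} redeclared as {ctype}, "
                                    f"was {self._types[name]}")
            else:
                self._types[name] = ctype
                self._columns[name] = [None] * len(self)
        n = len(self)
        for name in self._types:
            value = cells.get(name)
            self._columns[name].append(self._check(value, self._types[name], name))
        # keep rectangularity if cells missed a column
        for name, col in self._columns.items():
            if len(col) == n:
                col.append(None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({name: self._columns[name] for name in self._types})


# -------------------------------------------------------------------- graph

@dataclass
class PipelineNode:
    """One plug-in instance in the graph."""

    id: str
    plugin: str
    params: dict = field(default_factory=dict)
    wire: dict = field(default_factory=dict)  # input name -> "node_id.output"


@dataclass
class PipelineGraph:
    """Plug-in instances wired output -> input, rooted at the frame source.

    The implicit node ``source`` exposes one output, ``source.path``
    (text): the file currently being processed.
    """

    nodes: list[PipelineNode] = field(default_factory=list)

    def node(self, node_id: str) -> PipelineNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)


def _toposort(graph: PipelineGraph) -> list[PipelineNode]:
    ids = {n.id for n in graph.nodes}
    deps = {n.id: {ref.split(".", 1)[0] for ref in n.wire.values()} & ids
            for n in graph.nodes}
    order, done = [], set()
    pending = list(graph.nodes)
    while pending:
        progress = [n for n in pending if deps[n.id] <= done]
        if not progress:
            cycle = ", ".join(n.id for n in pending)
            raise GraphError(f"cycle in pipeline graph involving: {cycle}")
        for n in progress:
            order.append(n)
            done.add(n.id)
        pending = [n for n in pending if n.id not in done]
    return order


def validate_graph(graph: PipelineGraph, registry: dict[str, Plugin]) -> list[str]:
    """Type-check all wiring before any data flows. Returns a list of
    error strings; empty means the graph is runnable."""
    if registry is None:
        raise ValueError("a plug-in registry is required")
    errors: list[str] = []
    ids = [n.id for n in graph.nodes]
    if len(set(ids)) != len(ids):
        errors.append("duplicate node ids in graph")
    for node in graph.nodes:
        plugin = registry.get(node.plugin)
        if plugin is None:
            errors.append(f"node {node.id!r}: unknown plug-in {node.plugin!r}")
            continue
        desc = plugin.descriptor
        for port in desc.inputs:
            pname, ptype = port["name"], _norm_type(port["type"])
            ref = node.wire.get(pname)
            if ref is None:
                errors.append(f"node {node.id!r}: input {pname!r} not wired")
                continue
            src_id, _, src_port = ref.partition(".")
            if src_id == "source":
                src_type = "text" if src_port == "path" else None
            else:
                try:
                    src_node = graph.node(src_id)
                    src_type = registry[src_node.plugin].descriptor.output_type(src_port)
                except (KeyError, ValueError):
                    src_type = None
            if src_type is None:
                errors.append(f"node {node.id!r}: input {pname!r} wired to "
                              f"dangling output {ref!r}")
            elif src_type != ptype:
                errors.append(f"type mismatch: {ref!r} ({src_type}) -> "
                              f"{node.id}.{pname} ({ptype})")
    try:
        _toposort(graph)
    except GraphError as exc:
        errors.append(str(exc))
    return errors


# ------------------------------------------------------------------ running

def _nan_for(ctype: str):
    return math.nan if ctype == "scalar" else None


def process_dataset(graph: PipelineGraph, item, registry: dict[str, Plugin],
                    table: DataTable, states: dict[str, Any] | None = None):
    """Process one data set (file path) through the graph; append one row.

    Outputs are namespaced ``<node id>.<output>``. A failing plug-in
    contributes NaN/empty cells and an ``error`` note; downstream plug-ins
    whose inputs are missing fail the same soft way. A failing *reader*
    (no outputs at all produced, frame unreadable) skips the row and
    returns None.
    """
    states = states if states is not None else {}
    values: dict[str, Any] = {"source.path": str(item)}
    cells: dict[str, Any] = {"source": str(item)}
    types: dict[str, str] = {"source": "text"}
    errors: list[str] = []
    produced_any = False

    for node in _toposort(graph):
        plugin = registry[node.plugin]
        desc = plugin.descriptor
        params = {**desc.default_params(), **node.params}
        inputs, missing = {}, []
        for port in desc.inputs:
            ref = node.wire[port["name"]]
            if ref in values and values[ref] is not None:
                inputs[port["name"]] = values[ref]
            else:
                missing.append(ref)
        failure: str | None = None
        out: dict = {}
        if missing:
            failure = f"{node.id}: missing upstream data {missing}"
        else:
            try:
                if plugin.make_state is not None:
                    state = states.setdefault(node.id, plugin.make_state())
                    out = plugin.func(params, inputs, state)
                else:
                    out = plugin.func(params, inputs)
            except FrameReadError:
                raise  # reader-level failure: caller skips the row
            except Exception as exc:
                failure = f"{node.id}: {exc}"
                logger.warning("plug-in %s failed on %s: %s", node.id, item, exc)
        if failure:
            errors.append(failure)
            out = {}
        else:
            produced_any = True
        for port in desc.outputs:
            oname, otype = port["name"], _norm_type(port["type"])
            key = f"{node.id}.{oname}"
            value = out.get(oname, _nan_for(otype))
            values[key] = value
            cells[key] = value
            types[key] = otype
    if not produced_any and graph.nodes:
        raise FrameReadError(f"{item}: no plug-in produced data")
    cells["error"] = "; ".join(errors)
    types["error"] = "text"
    table.append_row(cells, types)
    return cells


def run_offline(graph: PipelineGraph, files, registry: dict[str, Plugin],
                table: DataTable | None = None) -> DataTable:
    """Sequentially process an explicit file list. Deterministic: same
    files, same table. Unreadable files are logged and skipped."""
    problems = validate_graph(graph, registry)
    if problems:
        raise GraphError("; ".join(problems))
    table = table if table is not None else DataTable()
    states: dict[str, Any] = {}
    for path in files:
        try:
            process_dataset(graph, path, registry, table, states)
        except FrameReadError as exc:
            logger.warning("skipping %s: %s", path, exc)
    return table


def run_online(graph: PipelineGraph, directory, pattern: str = "*.tif",
               poll_interval: float = 0.2, stop: threading.Event | None = None,
               registry: dict[str, Plugin] | None = None,
               table: DataTable | None = None,
               max_polls: int | None = None) -> DataTable:
    """Watch a directory and process files matching ``pattern`` exactly once.

    A file becomes eligible only when its size is unchanged across two
    successive polls — the completeness heuristic guarding against frames
    still being written by the acquisition. Within each poll, newly
    eligible files are processed in name-sorted order. When ``stop`` is
    set (or ``max_polls`` is exhausted) one final poll drains the queue,
    then the table is returned. Overwritten files are not reprocessed.
    Unreadable files are retried once on the next poll, then marked failed.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"watch directory {directory} does not exist")
    problems = validate_graph(graph, registry)
    if problems:
        raise GraphError("; ".join(problems))
    table = table if table is not None else DataTable()
    states: dict[str, Any] = {}
    sizes: dict[str, int] = {}
    done: set[str] = set()
    retries: dict[str, int] = {}
    stop = stop or threading.Event()
    polls = 0

    def poll(final: bool) -> None:
        batch = []
        for path in sorted(directory.iterdir()):
            if not path.is_file() or not fnmatch.fnmatch(path.name, pattern):
                continue
            key = str(path)
            if key in done:
                continue
            size = path.stat().st_size
            if final or (key in sizes and sizes[key] == size):
                batch.append(path)
            sizes[key] = size
        for path in batch:  # already name-sorted
            key = str(path)
            try:
                process_dataset(graph, path, registry, table, states)
                done.add(key)
            except IncompleteFileError as exc:
                # still being written: keep waiting, give up only at drain
                if final:
                    logger.warning("still incomplete at drain, giving up on %s: %s",
                                   path, exc)
                    done.add(key)
                else:
                    logger.info("waiting for %s to complete: %s", path, exc)
            except FrameReadError as exc:
                retries[key] = retries.get(key, 0) + 1
                if retries[key] > 1 or final:
                    logger.warning("giving up on %s: %s", path, exc)
                    done.add(key)
                else:
                    logger.info("retrying %s next poll: %s", path, exc)

    while not stop.is_set() and (max_polls is None or polls < max_polls):
        poll(final=False)
        polls += 1
        if stop.wait(poll_interval):
            break
    poll(final=True)  # drain: anything present now is assumed complete
    return table


def export(table: DataTable, path, exporter: Plugin | None = None) -> None:
    """Write a result table to disk.

    With no exporter plug-in, delegates to the spreadsheet writer
    (:func:`scatterkit.image_io.write_table`). An export-category plug-in
    receives ``({"path": path}, {"table": table})``.
    """
    if exporter is None:
        write_table(table, path)
        return
    if exporter.descriptor.category != "export":
        raise ValueError(f"plug-in {exporter.descriptor.name!r} is not an exporter")
    exporter.func({"path": str(path)}, {"table": table})
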