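"""Plug-in discovery, graph validation, sequential and online processing."""

import threading
import time

import numpy as np
import pytest

from scatterkit.framework import (DataTable, GraphError, PipelineGraph,
                                  PipelineNode, Plugin, PluginDescriptor,
                                  discover_plugins, export, process_dataset,
                                  run_offline, run_online, validate_graph)
from scatterkit.image_io import write_frame
from scatterkit.plugins import builtin_registry

ROI_PLUGIN_SOURCE = '''
import numpy as np

DESCRIPTION = {
    "name": "user_roi",
    "category": "base",
    "parameters": [
        {"name": "x", "type": "scalar", "default": 0},
        {"name": "y", "type": "scalar", "default": 0},
        {"name": "width", "type": "scalar", "default": 4},
        {"name": "height", "type": "scalar", "default": 4},
    ],
    "inputs": [{"name": "image", "type": "image"}],
    "outputs": [
        {"name": "min", "type": "scalar"},
        {"name": "max", "type": "scalar"},
        {"name": "average", "type": "scalar"},
        {"name": "sum", "type": "scalar"},
    ],
}

def get_data(params, inputs):
    frame = inputs["image"]
    x, y = int(params["x"]), int(params["y"])
    w, h = int(params["width"]), int(params["height"])
    patch = frame.data[y:y + h, x:x + w]
    return {"min": float(patch.min()), "max": float(patch.max()),
            "average": float(patch.mean()), "sum": float(patch.sum())}
'''


@pytest.fixture
def frames_dir(tmp_path, rng):
    d = tmp_path / "frames"
    d.mkdir()
    paths = []
    for k in range(8):
        p = d / f"f_{k:03d}.tif"
        write_frame(p, rng.integers(0, 100, (16, 16)).astype(np.uint16))
        paths.append(p)
    return d, paths


@pytest.fixture
def roi_graph():
    return PipelineGraph(nodes=[
        PipelineNode(id="reader", plugin="read_frame", wire={"path": "source.path"}),
        PipelineNode(id="roi", plugin="roi_stats",
                     params={"x": 1, "y": 1, "width": 5, "height": 5},
                     wire={"image": "reader.image"}),
    ])


# ----------------------------------------------------------------- discovery

def test_discover_roi_plugin_has_four_outputs(tmp_path):
    (tmp_path / "user_roi.py").write_text(ROI_PLUGIN_SOURCE)
    registry = discover_plugins(tmp_path)
    assert "user_roi" in registry
    outs = registry["user_roi"].descriptor.outputs
    assert [o["name"] for o in outs] == ["min", "max", "average", "sum"]


def test_discover_empty_folder(tmp_path):
    assert discover_plugins(tmp_path) == {}


def test_broken_plugin_skipped_others_load(tmp_path, caplog):
    (tmp_path / "user_roi.py").write_text(ROI_PLUGIN_SOURCE)
    (tmp_path / "broken.py").write_text("DESCRIPTION = 'not a dict'\n")
    (tmp_path / "syntax_err.py").write_text("def get_data(:\n")
    with caplog.at_level("WARNING"):
        registry = discover_plugins(tmp_path)
    assert set(registry) == {"user_roi"}
    assert sum("skipping malformed" in r.message for r in caplog.records) == 2


def test_duplicate_plugin_name_errors(tmp_path):
    (tmp_path / "user_roi.py").write_text(ROI_PLUGIN_SOURCE)
    (tmp_path / "user_roi2.py").write_text(ROI_PLUGIN_SOURCE)
    with pytest.raises(ValueError, match="duplicate plug-in name"):
        discover_plugins(tmp_path)


def test_descriptor_validation():
    with pytest.raises(ValueError, match="duplicate output"):
        PluginDescriptor(name="x", outputs=({"name": "a", "type": "scalar"},
                                            {"name": "a", "type": "scalar"}))
    with pytest.raises(ValueError, match="unknown cell type"):
        PluginDescriptor(name="x", outputs=({"name": "a", "type": "blob"},))


# ---------------------------------------------------------------- validation

def test_reader_roi_chain_validates(roi_graph):
    assert validate_graph(roi_graph, builtin_registry()) == []


def test_type_mismatch_names_both_ports():
    graph = PipelineGraph(nodes=[
        PipelineNode(id="reader", plugin="read_frame", wire={"path": "source.path"}),
        PipelineNode(id="fit", plugin="porod_t", wire={"curve": "reader.image"}),
    ])
    errors = validate_graph(graph, builtin_registry())
    assert len(errors) == 1
    assert "reader.image" in errors[0] and "fit.curve" in errors[0]


def test_self_loop_is_cycle_error():
    graph = PipelineGraph(nodes=[
        PipelineNode(id="a", plugin="porod_t", wire={"curve": "a.curve"}),
    ])
    errors = validate_graph(graph, builtin_registry())
    assert any("cycle" in e for e in errors)


def test_dangling_input_reported():
    graph = PipelineGraph(nodes=[
        PipelineNode(id="roi", plugin="roi_stats", wire={"image": "ghost.image"}),
    ])
    errors = validate_graph(graph, builtin_registry())
    assert any("dangling" in e for e in errors)


def test_unwired_input_reported():
    graph = PipelineGraph(nodes=[PipelineNode(id="roi", plugin="roi_stats")])
    errors = validate_graph(graph, builtin_registry())
    assert any("not wired" in e for e in errors)


# ---------------------------------------------------------------- processing

def test_single_frame_produces_roi_row(frames_dir, roi_graph):
    _, paths = frames_dir
    table = DataTable()
    process_dataset(roi_graph, paths[0], builtin_registry(), table)
    assert len(table) == 1
    for col in ("roi.min", "roi.max", "roi.average", "roi.sum"):
        assert col in table.columns
        assert np.isfinite(table[col][0])


def test_offline_rows_in_input_order(frames_dir, roi_graph):
    _, paths = frames_dir
    table = run_offline(roi_graph, paths, builtin_registry())
    assert len(table) == len(paths)
    assert table["source"] == [str(p) for p in paths]


def test_offline_rerun_identical(frames_dir, roi_graph):
    _, paths = frames_dir
    t1 = run_offline(roi_graph, paths, builtin_registry())
    t2 = run_offline(roi_graph, paths, builtin_registry())
    assert t1["roi.sum"] == t2["roi.sum"]


def test_midchain_failure_isolated_to_its_row(frames_dir):
    _, paths = frames_dir
    calls = {"n": 0}

    def flaky(params, inputs):
        calls["n"] += 1
        if calls["n"] == 3:
            raise RuntimeError("injected fault")
        return {"value": float(inputs["image"].data.sum())}

    registry = dict(builtin_registry())
    registry["flaky"] = Plugin(
        PluginDescriptor(name="flaky", inputs=({"name": "image", "type": "image"},),
                         outputs=({"name": "value", "type": "scalar"},)),
        flaky)
    graph = PipelineGraph(nodes=[
        PipelineNode(id="reader", plugin="read_frame", wire={"path": "source.path"}),
        PipelineNode(id="f", plugin="flaky", wire={"image": "reader.image"}),
    ])
    table = run_offline(graph, paths[:5], registry)
    assert len(table) == 5
    values = table["f.value"]
    assert np.isnan(values[2])
    assert all(np.isfinite(values[i]) for i in (0, 1, 3, 4))
    assert "injected fault" in table["error"][2]
    assert table["error"][1] == ""


def test_unreadable_file_skipped(frames_dir, roi_graph, tmp_path):
    _, paths = frames_dir
    bad = tmp_path / "frames" / "f_999.tif"
    bad.write_bytes(b"II*\x00garbage")
    table = run_offline(roi_graph, paths + [bad], builtin_registry())
    assert len(table) == len(paths)


def test_datatable_type_safety():
    table = DataTable()
    table.append_row({"a": 1.0}, {"a": "scalar"})
    with pytest.raises(TypeError, match="scalar"):
        table.append_row({"a": "oops"}, {"a": "scalar"})
    with pytest.raises(TypeError, match="redeclared"):
        table.append_row({"a": 2.0}, {"a": "text"})


def test_datatable_to_dataframe():
    table = DataTable()
    table.append_row({"a": 1.0, "s": "x"}, {"a": "scalar", "s": "text"})
    table.append_row({"a": 2.0, "s": "y"}, {"a": "scalar", "s": "text"})
    df = table.to_dataframe()
    assert list(df.columns) == ["a", "s"]
    assert df["a"].tolist() == [1.0, 2.0]


# -------------------------------------------------------------------- online

def test_online_matches_offline_on_dropped_files(tmp_path, rng, roi_graph):
    src = tmp_path / "src"
    src.mkdir()
    paths = []
    for k in range(12):
        p = src / f"g_{k:03d}.tif"
        write_frame(p, rng.integers(0, 100, (16, 16)).astype(np.uint16))
        paths.append(p)
    offline = run_offline(roi_graph, paths, builtin_registry())

    watch = tmp_path / "watch"
    watch.mkdir()
    stop = threading.Event()

    def dropper():
        for p in paths:
            (watch / p.name).write_bytes(p.read_bytes())
            time.sleep(0.03)
        time.sleep(0.3)
        stop.set()

    thread = threading.Thread(target=dropper)
    thread.start()
    online = run_online(roi_graph, watch, pattern="*.tif", poll_interval=0.05,
                        stop=stop, registry=builtin_registry())
    thread.join()
    assert len(online) == len(offline)
    assert online["roi.sum"] == offline["roi.sum"]
    assert [p.rsplit("/", 1)[-1] for p in online["source"]] == \
        [p.name for p in paths]


def test_online_overwritten_file_processed_once(tmp_path, rng, roi_graph):
    watch = tmp_path / "watch"
    watch.mkdir()
    data = rng.integers(0, 100, (16, 16)).astype(np.uint16)
    write_frame(watch / "a.tif", data)
    stop = threading.Event()

    processed_once = run_online(roi_graph, watch, pattern="*.tif",
                                poll_interval=0.02, stop=stop,
                                registry=builtin_registry(), max_polls=3)
    assert len(processed_once) == 1
    # overwrite: same name must not be reprocessed within one run
    table = DataTable()
    stop2 = threading.Event()

    def overwrite():
        time.sleep(0.1)
        write_frame(watch / "a.tif", data * 2)
        time.sleep(0.2)
        stop2.set()

    thread = threading.Thread(target=overwrite)
    thread.start()
    out = run_online(roi_graph, watch, pattern="*.tif", poll_interval=0.05,
                     stop=stop2, registry=builtin_registry(), table=table)
    thread.join()
    assert len(out) == 1


def test_online_empty_directory_clean_exit(tmp_path, roi_graph):
    stop = threading.Event()
    stop.set()
    table = run_online(roi_graph, tmp_path, pattern="*.tif", poll_interval=0.01,
                       stop=stop, registry=builtin_registry())
    assert len(table) == 0


def test_incomplete_file_retried(tmp_path, rng, roi_graph):
    watch = tmp_path / "watch"
    watch.mkdir()
    good = rng.integers(0, 100, (16, 16)).astype(np.uint16)
    write_frame(tmp_path / "full.tif", good)
    payload = (tmp_path / "full.tif").read_bytes()
    # drop a truncated file, complete it between polls
    (watch / "a.tif").write_bytes(payload[: len(payload) // 2])
    stop = threading.Event()

    def completer():
        time.sleep(0.15)
        (watch / "a.tif").write_bytes(payload)
        time.sleep(0.3)
        stop.set()

    thread = threading.Thread(target=completer)
    thread.start()
    table = run_online(roi_graph, watch, pattern="*.tif", poll_interval=0.05,
                       stop=stop, registry=builtin_registry())
    thread.join()
    assert len(table) == 1
    assert table["error"][0] == ""


# -------------------------------------------------------------------- export

def test_export_delegates_to_table_writer(tmp_path, frames_dir, roi_graph):
    _, paths = frames_dir
    table = run_offline(roi_graph, paths, builtin_registry())
    export(table, tmp_path / "out.tsv")
    lines = (tmp_path / "out.tsv").read_text().splitlines()
    assert len(lines) == len(paths) + 1
    assert "roi.sum" in lines[0].split("\t")


def test_export_rejects_non_exporter(tmp_path, frames_dir, roi_graph):
    _, paths = frames_dir
    registry = builtin_registry()
    table = run_offline(roi_graph, paths, registry)
    with pytest.raises(ValueError, match="not an exporter"):
        export(table, tmp_path / "x.tsv", exporter=registry["roi_stats"])


def test_run_offline_validates_first(frames_dir):
    _, paths = frames_dir
    bad = PipelineGraph(nodes=[PipelineNode(id="roi", plugin="roi_stats")])
    with pytest.raises(GraphError):
        run_offline(bad, paths, builtin_registry())
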