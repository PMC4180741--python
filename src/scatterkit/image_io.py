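"""Reading detector frames (TIFF, EDF) and writing curves, tables and maps.

Only two input dialects are supported, on purpose: plain grayscale TIFF
(8/16/32-bit, uncompressed or whatever :mod:`tifffile` handles) and the
ESRF data format (EDF) with a single image block. EDF is parsed natively —
the format is a fixed-size ASCII key-value header followed by raw binary —
because beamline EDF files carry monitor counts and exposure times in
header keys that we need to capture.

All tabular output is tab-separated UTF-8 text with ``.`` as the decimal
point; scalars are printed with 12 significant digits so a re-read is
loss-free at working precision.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "read_frame",
    "read_mask",
    "write_frame",
    "write_table",
    "write_curve",
    "read_curve",
    "write_map",
    "FrameReadError",
    "IncompleteFileError",
]

#: EDF header keys accepted (case-insensitively) as the monitor counter.
#: Facilities disagree on the key name; extend this list via read_frame().
MONITOR_KEYS = ("monitor", "mon", "mon1", "intensity0", "i0")
EXPOSURE_KEYS = ("exposuretime", "exposure_time", "count_time", "exposure")


class FrameReadError(IOError):
    """File exists but cannot be parsed as a detector frame."""


class IncompleteFileError(FrameReadError):
    """File is truncated — likely still being written by the acquisition."""


@dataclass
class Frame:
    """One detector frame: intensity array plus acquisition metadata.

    Attributes
    ----------
    data : ndarray
        2-D non-negative intensity array (counts).
    mask : ndarray
        2-D uint8 array of the same shape; 1 = pixel excluded.
    monitor : float
        Incident-flux proxy; defaults to 1.0 when the file carries none.
    exposure : float
        Exposure time in seconds; defaults to 1.0.
    scan_pos : tuple or None
        Motor coordinates of this frame within a scan grid.
    source_path : str
        Originating file, kept as a reference (images are never copied
        into result tables).
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    monitor: float = 1.0
    exposure: float = 1.0
    scan_pos: tuple[float, ...] | None = None
    source_path: str = ""
    header: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"frame data must be 2-D, got shape {self.data.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=np.uint8)
        else:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}")
            self.mask = (self.mask != 0).astype(np.uint8)
        if self.mask.all():
            raise ValueError("fully masked frame")
        if not (self.monitor > 0):
            raise ValueError(f"monitor must be > 0, got {self.monitor}")


# ---------------------------------------------------------------- EDF dialect

_EDF_DTYPES = {
    "unsignedbyte": np.uint8,
    "unsignedshort": np.uint16,
    "unsignedinteger": np.uint32,
    "unsignedlong": np.uint32,
    "signedbyte": np.int8,
    "signedshort": np.int16,
    "signedinteger": np.int32,
    "signedlong": np.int32,
    "floatvalue": np.float32,
    "float": np.float32,
    "doublevalue": np.float64,
}
_EDF_DTYPE_NAMES = {
    np.dtype(np.uint8): "UnsignedByte",
    np.dtype(np.uint16): "UnsignedShort",
    np.dtype(np.uint32): "UnsignedInteger",
    np.dtype(np.int8): "SignedByte",
    np.dtype(np.int16): "SignedShort",
    np.dtype(np.int32): "SignedInteger",
    np.dtype(np.float32): "FloatValue",
    np.dtype(np.float64): "DoubleValue",
}
_EDF_BLOCK = 512


def _read_edf(path: Path) -> tuple[np.ndarray, dict]:
    raw = path.read_bytes()
    if not raw.lstrip()[:1] == b"{":
        raise FrameReadError(f"{path}: not an EDF file (missing '{{' header)")
    end = raw.find(b"}")
    if end < 0:
        raise IncompleteFileError(f"{path}: EDF header never closed")
    # header is padded to a 512-byte boundary after the closing brace
    header_size = end + 1
    while header_size < len(raw) and raw[header_size:header_size + 1] in (b"\r", b"\n", b" "):
        header_size += 1
        if header_size % _EDF_BLOCK == 0:
            break
    text = raw[: end].decode("latin-1")
    header: dict[str, str] = {}
    for line in text.splitlines():
        m = re.match(r"\s*([^=;{]+?)\s*=\s*(.*?)\s*;?\s*$", line)
        if m and m.group(1):
            header[m.group(1)] = m.group(2)
    lower = {k.lower(): v for k, v in header.items()}
    try:
        dim1 = int(lower["dim_1"])
        dim2 = int(lower["dim_2"])
        dtype = _EDF_DTYPES[lower["datatype"].replace(" ", "").lower()]
    except KeyError as exc:
        raise FrameReadError(f"{path}: EDF header missing required key {exc}") from exc
    byteorder = lower.get("byteorder", "LowByteFirst").replace(" ", "").lower()
    dt = np.dtype(dtype).newbyteorder("<" if byteorder == "lowbytefirst" else ">")
    nbytes = dim1 * dim2 * dt.itemsize
    payload = raw[header_size: header_size + nbytes]
    if len(payload) < nbytes:
        raise IncompleteFileError(
            f"{path}: expected {nbytes} data bytes, found {len(payload)} (incomplete file)")
    data = np.frombuffer(payload, dtype=dt).reshape(dim2, dim1)
    return data.astype(data.dtype.newbyteorder("=")), header


def _write_edf(path: Path, data: np.ndarray, header: dict | None = None) -> None:
    data = np.ascontiguousarray(data)
    dtname = _EDF_DTYPE_NAMES.get(data.dtype)
    if dtname is None:
        data = data.astype(np.float64)
        dtname = "DoubleValue"
    data = data.astype(data.dtype.newbyteorder("<"))
    items = {
        "HeaderID": "EH:000001:000000:000000",
        "Image": "1",
        "ByteOrder": "LowByteFirst",
        "DataType": dtname,
        "Dim_1": str(data.shape[1]),
        "Dim_2": str(data.shape[0]),
        "Size": str(data.nbytes),
    }
    if header:
        items.update({str(k): str(v) for k, v in header.items()})
    body = "{\n" + "".join(f"{k} = {v} ;\n" for k, v in items.items())
    padded = (len(body) + 2 + _EDF_BLOCK - 1) // _EDF_BLOCK * _EDF_BLOCK
    body = body + " " * (padded - len(body) - 2) + "}\n"
    with open(path, "wb") as fh:
        fh.write(body.encode("latin-1"))
        fh.write(data.tobytes())


# ------------------------------------------------------------------- readers

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".edf":
        return "edf"
    head = path.read_bytes()[:4] if path.exists() else b""
    if head[:2] in (b"II", b"MM"):
        return "tiff"
    if head[:1] == b"{":
        return "edf"
    raise FrameReadError(f"{path}: unknown image format")


def _float_key(header: dict, keys: tuple[str, ...]) -> float | None:
    lower = {k.lower(): v for k, v in header.items()}
    for key in keys:
        if key in lower:
            try:
                return float(str(lower[key]).split()[0])
            except (ValueError, IndexError):
                continue
    return None


def read_frame(path, fmt: str | None = None, *, monitor_keys: tuple[str, ...] = MONITOR_KEYS,
               exposure_keys: tuple[str, ...] = EXPOSURE_KEYS) -> Frame:
    """Read a detector frame from a TIFF or EDF file.

    Integer intensities are preserved bit-exactly. Monitor counts and
    exposure time are taken from the EDF header when a recognized key is
    present (``monitor_keys`` is configurable because facilities disagree),
    otherwise they default to 1.0 with a logged notice.

    Raises
    ------
    FrameReadError
        Unknown format or unparseable file.
    IncompleteFileError
        Truncated file — the online watcher treats this as "try again",
        never as a silent partial read.
    """
    path = Path(path)
    if not path.exists():
        raise FrameReadError(f"{path}: no such file")
    fmt = fmt or _detect_format(path)
    header: dict = {}
    if fmt == "tiff":
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types on bad files
            msg = str(exc).lower()
            if ("corrupt" in msg or "truncat" in msg or "failed to read" in msg
                    or isinstance(exc, EOFError)):
                raise IncompleteFileError(f"{path}: incomplete TIFF ({exc})") from exc
            raise FrameReadError(f"{path}: cannot read TIFF ({exc})") from exc
        if data.ndim == 3 and data.shape[-1] in (3, 4):  # tolerate gray saved as RGB
            data = data[..., 0]
    elif fmt == "edf":
        data, header = _read_edf(path)
    else:
        raise FrameReadError(f"{path}: unsupported format {fmt!r}")
    if data.ndim != 2:
        raise FrameReadError(f"{path}: expected a single 2-D image, got shape {data.shape}")

    monitor = _float_key(header, monitor_keys)
    exposure = _float_key(header, exposure_keys)
    if monitor is None:
        logger.debug("%s: no monitor key in header, defaulting to 1.0", path)
        monitor = 1.0
    if exposure is None:
        exposure = 1.0
    return Frame(data=data, monitor=monitor, exposure=exposure,
                 source_path=str(path), header=header)


def read_mask(path) -> np.ndarray:
    """Read a mask image; nonzero pixels are excluded (coerced to 1).

    Non-binary inputs are accepted with a logged warning.
    """
    frame_data = read_frame(path).data
    uniq = np.unique(frame_data)
    if not np.isin(uniq, (0, 1)).all():
        logger.warning("mask %s is non-binary (values %s...); coercing nonzero -> 1",
                       path, uniq[:4])
    return (frame_data != 0).astype(np.uint8)


def write_frame(path, data: np.ndarray, header: dict | None = None) -> None:
    """Write an intensity array as TIFF or EDF (chosen by file suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(data))
    elif path.suffix.lower() == ".edf":
        _write_edf(path, data, header)
    else:
        raise ValueError(f"{path}: cannot infer output format from suffix")


# ------------------------------------------------------------------- writers

_FMT = "%.12g"


def write_curve(path, curve) -> None:
    """Write a 1-D curve as a 4-column TSV (x, y, sigma, n_pix)."""
    path = Path(path)
    cols = np.column_stack([curve.x, curve.y, curve.sigma, curve.n_pix])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind: {curve.kind}\n")
        fh.write("x\ty\tsigma\tn_pix\n")
        for row in cols:
            fh.write("\t".join(_FMT % v for v in row) + "\n")


def read_curve(path):
    """Re-read a curve written by :func:`write_curve`."""
    from .profiles import Curve

    path = Path(path)
    kind = "radial"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# kind:"):
            kind = first.split(":", 1)[1].strip()
    arr = np.loadtxt(path, skiprows=2 if kind else 1)
    arr = np.atleast_2d(arr)
    return Curve(x=arr[:, 0], y=arr[:, 1], sigma=arr[:, 2],
                 n_pix=arr[:, 3].astype(int), kind=kind)


def write_table(table, path) -> None:
    """Write a result table as tab-separated text.

    One header row of column names; scalar and text cells inline; curve
    cells are spilled to sidecar files (``<stem>_r<row>_<column>.dat``)
    next to the table, with the cell holding the sidecar file name.
    Image cells hold the source-path reference they already are.
    """
    path = Path(path)
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    names = list(table.columns)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(len(table)):
            cells = []
            for name in names:
                value = table[name][i]
                ctype = table.column_type(name)
                if ctype == "curve" and value is not None:
                    sidecar = f"{path.stem}_r{i:05d}_{name.replace('.', '_')}.dat"
                    write_curve(path.parent / sidecar, value)
                    cells.append(sidecar)
                elif ctype == "scalar":
                    cells.append("nan" if value is None else _FMT % value)
                else:
                    cells.append("" if value is None else str(value))
            fh.write("\t".join(cells) + "\n")


def write_map(path, xs: np.ndarray, ys: np.ndarray, grid: np.ndarray,
              value_name: str = "value") -> None:
    """Write a scan-grid map both as (x, y, value) triplets and a dense matrix.

    ``grid[j, i]`` is the value at ``(xs[i], ys[j])``; missing points are NaN.
    Two files result: ``<path>`` with one triplet per line and
    ``<path stem>_grid<suffix>`` with the dense matrix (rows = ys).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"x\ty\t{value_name}\n")
        for j, y in enumerate(ys):
            for i, x in enumerate(xs):
                fh.write(f"{_FMT % x}\t{_FMT % y}\t{_FMT % grid[j, i]}\n")
    dense = path.with_name(path.stem + "_grid" + (path.suffix or ".dat"))
    np.savetxt(dense, grid, fmt=_FMT, delimiter="\t")
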