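"""File formats: PLY/XYZ point clouds, trace CSV, MCFLIRT-style ``.par``,
respiration and sequence tables, scenario JSON.

All text outputs are comma-separated, ``.``-decimal, UTF-8, with a mandatory
header row; ``#`` comment lines are allowed and carry metadata. Floats are
written with 17 significant digits so round-trips are bit-exact. PLY supports
the ASCII and binary-little-endian dialects with float or double vertex
properties; an integer ``grid_index`` vertex property preserves the
depth-image raster ordering.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .registration import PointCloud
from .metrics import RespirationSignal
from .trace import MotionTrace, SequenceTable

__all__ = [
    "PLYError",
    "read_ply", "write_ply", "read_xyz", "write_xyz",
    "read_trace", "write_trace",
    "read_par", "write_par",
    "read_respiration", "write_respiration",
    "read_sequence_table", "write_sequence_table",
]

_FLOAT_FMT = "%.17g"

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


class PLYError(ValueError):
    """Malformed PLY input; the message names the byte offset."""


def _header_error(msg: str, offset: int) -> PLYError:
    return PLYError(f"{msg} (header byte offset {offset})")


def read_ply(path) -> PointCloud:
    """Read a point cloud from an ASCII or binary-little-endian PLY file.

    Requires float/double ``x``, ``y``, ``z`` vertex properties; an integer
    ``grid_index`` property is picked up when present, other properties are
    skipped. List properties and non-vertex elements are not supported.
    """
    raw = Path(path).read_bytes()
    offset = 0

    def next_line():
        nonlocal offset
        end = raw.find(b"\n", offset)
        if end < 0:
            raise _header_error("unterminated header", offset)
        line = raw[offset:end].decode("ascii", errors="replace").strip()
        offset = end + 1
        return line

    if next_line() != "ply":
        raise _header_error("missing 'ply' magic", 0)
    fmt = None
    n_vertex = None
    props = []  # (name, numpy dtype str) of the vertex element
    in_vertex = False
    while True:
        start = offset
        line = next_line()
        if line == "end_header":
            break
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if len(tok) < 2 or tok[1] not in ("ascii", "binary_little_endian"):
                raise _header_error(f"unsupported format {line!r}", start)
            fmt = tok[1]
        elif tok[0] == "element":
            if len(tok) != 3:
                raise _header_error(f"bad element line {line!r}", start)
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                try:
                    n_vertex = int(tok[2])
                except ValueError:
                    raise _header_error(f"bad vertex count {tok[2]!r}", start)
            elif int(tok[2]) != 0:
                raise _header_error(
                    f"unsupported non-empty element {tok[1]!r}", start)
        elif tok[0] == "property":
            if not in_vertex:
                continue
            if tok[1] == "list":
                raise _header_error("list properties unsupported", start)
            if len(tok) != 3 or tok[1] not in _PLY_DTYPES:
                raise _header_error(f"bad property line {line!r}", start)
            props.append((tok[2], _PLY_DTYPES[tok[1]]))
    if fmt is None:
        raise _header_error("missing format line", offset)
    if n_vertex is None:
        raise _header_error("missing vertex element", offset)
    names = [p[0] for p in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise _header_error(f"missing vertex property {axis!r}", offset)

    dtype = np.dtype([(n, "<" + d) for n, d in props])
    if fmt == "ascii":
        text = raw[offset:].decode("ascii")
        data = np.loadtxt(_io.StringIO(text), dtype=dtype, ndmin=1,
                          max_rows=n_vertex)
    else:
        data = np.frombuffer(raw, dtype=dtype, count=n_vertex, offset=offset)
    if data.shape[0] != n_vertex:
        raise PLYError(f"expected {n_vertex} vertices, got {data.shape[0]}")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    gidx = data["grid_index"].astype(int) if "grid_index" in names else None
    return PointCloud(pts, grid_index=gidx)


def write_ply(path, cloud: PointCloud, *, binary: bool = True,
              dtype: str = "double") -> None:
    """Write a point cloud as PLY (binary-little-endian by default, with
    ``double`` coordinates for lossless round-trips)."""
    if dtype not in ("float", "double"):
        raise ValueError("dtype must be 'float' or 'double'")
    np_dt = _PLY_DTYPES[dtype]
    fields = [("x", "<" + np_dt), ("y", "<" + np_dt), ("z", "<" + np_dt)]
    if cloud.grid_index is not None:
        fields.append(("grid_index", "<i4"))
    arr = np.empty(len(cloud), dtype=np.dtype(fields))
    arr["x"], arr["y"], arr["z"] = cloud.points.T
    if cloud.grid_index is not None:
        arr["grid_index"] = cloud.grid_index
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {dtype} {n}" for n in ("x", "y", "z")]
    if cloud.grid_index is not None:
        header.append("property int grid_index")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(arr.tobytes())
        else:
            cols = len(fields)
            fmt = " ".join([_FLOAT_FMT] * 3
                           + (["%d"] if cols == 4 else []))
            for row in arr:
                fh.write((fmt % tuple(row[n] for n, _ in fields) + "\n")
                         .encode("ascii"))


def read_xyz(path) -> PointCloud:
    """Whitespace-separated x y z, one point per line (mm)."""
    pts = np.loadtxt(path, ndmin=2)
    if pts.shape[1] < 3:
        raise ValueError(f"XYZ file needs >= 3 columns, got {pts.shape[1]}")
    return PointCloud(pts[:, :3])


def write_xyz(path, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.points, fmt=_FLOAT_FMT)


# ----------------------------------------------------------------------
# motion traces

_TRACE_COLUMNS = ["timestamp_s", "tx_mm", "ty_mm", "tz_mm",
                  "qw", "qx", "qy", "qz", "valid"]


def write_trace(path, trace: MotionTrace, extra_comments=()) -> None:
    """Trace CSV: one row per sample, scalar-first unit quaternion,
    ``# space_label`` / ``# reference_note`` comments."""
    q = trace.quaternions()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# space_label: {trace.space_label}\n")
        fh.write(f"# reference_note: {trace.reference_note}\n")
        for line in extra_comments:
            fh.write(f"# {line}\n")
        fh.write(",".join(_TRACE_COLUMNS) + "\n")
        for i in range(len(trace)):
            vals = [trace.times[i], *trace.translations[i], *q[i]]
            fh.write(",".join(_FLOAT_FMT % v for v in vals)
                     + f",{int(trace.valid[i])}\n")


def read_trace(path) -> MotionTrace:
    space_label, reference_note = "camera", ""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        s = line.strip()
        if s.startswith("#"):
            c = s[1:].strip()
            if c.startswith("space_label:"):
                space_label = c.split(":", 1)[1].strip()
            elif c.startswith("reference_note:"):
                reference_note = c.split(":", 1)[1].strip()
            continue
        if s:
            body.append(s)
    if not body or body[0].split(",") != _TRACE_COLUMNS:
        raise ValueError(f"{path}: not a trace CSV (bad or missing header)")
    data = np.array([[float(x) for x in row.split(",")] for row in body[1:]])
    if data.size == 0:
        raise ValueError(f"{path}: empty trace")
    times = data[:, 0]
    t_mm = data[:, 1:4]
    q = data[:, 4:8]
    valid = data[:, 8].astype(bool)
    norms = np.linalg.norm(q, axis=1)
    ok = valid & (norms > 1e-12)
    R = np.tile(np.eye(3), (len(times), 1, 1))
    if ok.any():
        qs = q[ok] / norms[ok, None]
        R[ok] = Rotation.from_quat(
            np.column_stack([qs[:, 1:], qs[:, 0]])).as_matrix()
    return MotionTrace(times, R, t_mm, valid, space_label, reference_note)


def read_par(path, frame_duration: float, t0: float = 0.0) -> MotionTrace:
    """MCFLIRT-style realignment parameters: 6 whitespace columns per frame,
    3 rotations (radians, extrinsic about x, then y, then z) then 3
    translations (mm). Timestamps are the frame midpoints
    ``t0 + (k + ½)·frame_duration``.
    """
    if frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {data.shape[1]}")
    n = data.shape[0]
    times = t0 + (np.arange(n) + 0.5) * frame_duration
    R = Rotation.from_euler("xyz", data[:, :3]).as_matrix()
    return MotionTrace(times, R, data[:, 3:6],
                       space_label="anatomical",
                       reference_note="fMRI realignment parameters")


def write_par(path, trace: MotionTrace) -> None:
    """Write the ``.par`` dialect read by :func:`read_par` (valid samples
    only; frame timing is carried externally)."""
    v = trace.valid_only()
    ang = Rotation.from_matrix(v.rotations).as_euler("xyz")
    np.savetxt(path, np.hstack([ang, v.translations]), fmt=_FLOAT_FMT)


# ----------------------------------------------------------------------
# scalar tables


def write_respiration(path, resp: RespirationSignal) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp_s,value\n")
        for t, x in zip(resp.timestamps, resp.values):
            fh.write(f"{_FLOAT_FMT % t},{_FLOAT_FMT % x}\n")


def read_respiration(path) -> RespirationSignal:
    """Read ``timestamp_s,value`` CSV, or the constant-rate variant with a
    ``# rate_hz: <Hz>`` comment and a single ``value`` column."""
    rate = None
    t0 = 0.0
    rows = []
    header = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                c = s[1:].strip()
                if c.startswith("rate_hz:"):
                    rate = float(c.split(":", 1)[1])
                elif c.startswith("t0_s:"):
                    t0 = float(c.split(":", 1)[1])
                continue
            if header is None:
                header = s.split(",")
                continue
            rows.append([float(x) for x in s.split(",")])
    data = np.asarray(rows, float)
    if header == ["timestamp_s", "value"]:
        return RespirationSignal(data[:, 0], data[:, 1])
    if header == ["value"]:
        if rate is None:
            raise ValueError(f"{path}: single-column variant needs a "
                             "'# rate_hz:' comment")
        t = t0 + np.arange(data.shape[0]) / rate
        return RespirationSignal(t, data[:, 0])
    raise ValueError(f"{path}: unrecognized respiration header {header}")


def write_sequence_table(path, table: SequenceTable) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sequence,start_s,end_s\n")
        for name, start, end in table.rows():
            fh.write(f"{name},{_FLOAT_FMT % start},{_FLOAT_FMT % end}\n")


def read_sequence_table(path) -> SequenceTable:
    df = pd.read_csv(path, comment="#")
    expected = ["sequence", "start_s", "end_s"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, "
                         f"got {list(df.columns)}")
    return SequenceTable(df["sequence"].astype(str).tolist(),
                         df["start_s"].to_numpy(float),
                         df["end_s"].to_numpy(float))
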