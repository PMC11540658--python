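"""Point-cloud file I/O: PLY (ASCII / binary little-endian) and XYZ text.

The PLY writer emits float64 coordinates so a write→read round-trip is
the identity to full float precision.  Colors default to float64
properties for the same reason; pass ``color_dtype="uchar"`` for the
8-bit convention most viewers expect.  A JSON sidecar
(``<path>.meta.json``) records ``is_metric`` and, when known, the scale
factor, so metric status survives the round-trip.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .cloud import PointCloud, TriangleMesh

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "write_mesh",
    "PointCloudParseError",
]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class PointCloudParseError(ValueError):
    """Malformed point-cloud file; message names the offending line/element."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _detect_format(path: Path) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(3)
    return "ply" if magic == b"ply" else "xyz"


def read_point_cloud(path, format: str = "auto") -> PointCloud:
    """Read a PLY or whitespace XYZ[RGB] file into a :class:`PointCloud`.

    ``is_metric`` is taken from the JSON sidecar when present, else False.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point-cloud file not found: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format == "ply":
        points, colors = _read_ply(path)
    elif format == "xyz":
        points, colors = _read_xyz(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected ply, xyz or auto")

    is_metric = False
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            is_metric = bool(json.loads(sidecar.read_text()).get("is_metric", False))
        except (json.JSONDecodeError, AttributeError) as exc:
            raise PointCloudParseError(f"malformed sidecar {sidecar}: {exc}") from exc
    return PointCloud(points, colors, is_metric)


def write_point_cloud(
    cloud: PointCloud,
    path,
    format: str = "ply",
    *,
    binary: bool = True,
    color_dtype: str = "double",
    scale_factor: float | None = None,
) -> None:
    """Write a cloud as PLY (binary little-endian by default) or XYZ text.

    Also writes the ``is_metric`` sidecar so metric status round-trips.
    """
    path = Path(path)
    if format == "ply":
        _write_ply(cloud, path, binary=binary, color_dtype=color_dtype)
    elif format == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected ply or xyz")
    meta = {"is_metric": cloud.is_metric}
    if scale_factor is not None:
        meta["scale_factor"] = float(scale_factor)
    _sidecar_path(path).write_text(json.dumps(meta))


# ---------------------------------------------------------------- PLY reading

def _read_ply(path: Path):
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise PointCloudParseError(f"{path}: missing 'ply' magic")
        fmt = None
        elements = []  # (name, count, [(prop_name, dtype_str or list-marker)])
        current = None
        while True:
            raw = fh.readline()
            if not raw:
                raise PointCloudParseError(f"{path}: header ended without end_header")
            tokens = raw.decode("ascii", "replace").strip().split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                current = (tokens[1], int(tokens[2]), [])
                elements.append(current)
            elif tokens[0] == "property":
                if current is None:
                    raise PointCloudParseError(f"{path}: property before element")
                if tokens[1] == "list":
                    current[2].append((tokens[4], ("list", tokens[2], tokens[3])))
                else:
                    if tokens[1] not in _PLY_DTYPES:
                        raise PointCloudParseError(
                            f"{path}: unsupported property type {tokens[1]!r}")
                    current[2].append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudParseError(f"{path}: unsupported PLY format {fmt!r}")

        vertex_data = None
        for name, count, props in elements:
            data = _read_ply_element(fh, fmt, count, props, path)
            if name == "vertex":
                vertex_data = (props, data)
        if vertex_data is None:
            raise PointCloudParseError(f"{path}: no vertex element")

    props, data = vertex_data
    names = [p[0] for p in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PointCloudParseError(f"{path}: vertex element lacks {axis!r}")
    points = np.column_stack([data["x"], data["y"], data["z"]])
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack([data["red"], data["green"], data["blue"]])
        # uchar convention is 0..255; float colors are already 0..1
        dtypes = {p[0]: p[1] for p in props}
        if dtypes["red"] == "u1":
            colors = colors / 255.0
    return points, colors


def _read_ply_element(fh, fmt, count, props, path):
    has_list = any(isinstance(p[1], tuple) for p in props)
    if fmt == "binary_little_endian" and not has_list:
        dtype = np.dtype([(name, "<" + code) for name, code in props])
        buf = fh.read(dtype.itemsize * count)
        if len(buf) != dtype.itemsize * count:
            raise PointCloudParseError(f"{path}: truncated binary payload")
        rec = np.frombuffer(buf, dtype=dtype, count=count)
        return {name: rec[name].astype(np.float64) for name, _ in props}
    if fmt == "binary_little_endian":
        return _read_ply_binary_lists(fh, count, props, path)
    # ASCII
    out = {name: [] for name, code in props if not isinstance(code, tuple)}
    for i in range(count):
        raw = fh.readline()
        if not raw:
            raise PointCloudParseError(f"{path}: element row {i} missing")
        fields = raw.split()
        pos = 0
        for name, code in props:
            if isinstance(code, tuple):
                n = int(fields[pos]); pos += 1 + n
                continue
            try:
                val = float(fields[pos])
            except (ValueError, IndexError):
                raise PointCloudParseError(
                    f"{path}: non-numeric or missing value for {name!r} in "
                    f"element row {i}") from None
            out[name].append(val)
            pos += 1
    return {k: np.asarray(v, dtype=np.float64) for k, v in out.items()}


def _read_ply_binary_lists(fh, count, props, path):
    out = {name: [] for name, code in props if not isinstance(code, tuple)}
    for i in range(count):
        for name, code in props:
            if isinstance(code, tuple):
                _, count_t, item_t = code
                cdt = np.dtype("<" + _PLY_DTYPES[count_t])
                n = int(np.frombuffer(fh.read(cdt.itemsize), cdt)[0])
                idt = np.dtype("<" + _PLY_DTYPES[item_t])
                fh.read(idt.itemsize * n)
            else:
                dt = np.dtype("<" + code)
                buf = fh.read(dt.itemsize)
                if len(buf) != dt.itemsize:
                    raise PointCloudParseError(f"{path}: truncated row {i}")
                out[name].append(float(np.frombuffer(buf, dt)[0]))
    return {k: np.asarray(v, dtype=np.float64) for k, v in out.items()}


# ---------------------------------------------------------------- PLY writing

def _write_ply(cloud: PointCloud, path: Path, *, binary: bool, color_dtype: str):
    if color_dtype not in ("double", "float", "uchar"):
        raise ValueError("color_dtype must be double, float or uchar")
    n = len(cloud)
    has_colors = cloud.colors is not None
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += [f"property double {ax}" for ax in "xyz"]
    if has_colors:
        header += [f"property {color_dtype} {c}" for c in ("red", "green", "blue")]
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if n == 0:
            return
        if has_colors:
            if color_dtype == "uchar":
                cols = np.rint(cloud.colors * 255).astype("u1")
            else:
                cols = cloud.colors.astype("f4" if color_dtype == "float" else "f8")
        if binary:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
            if has_colors:
                cc = {"double": "<f8", "float": "<f4", "uchar": "u1"}[color_dtype]
                fields += [("red", cc), ("green", cc), ("blue", cc)]
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = cloud.points.T
            if has_colors:
                rec["red"], rec["green"], rec["blue"] = cols.T
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                row = [f"{v:.17g}" for v in cloud.points[i]]
                if has_colors:
                    if color_dtype == "uchar":
                        row += [str(int(v)) for v in cols[i]]
                    else:
                        row += [f"{v:.17g}" for v in cols[i]]
                fh.write((" ".join(row) + "\n").encode("ascii"))


# ------------------------------------------------------------------ XYZ text

def _read_xyz(path: Path):
    points, colors = [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) not in (3, 6):
                raise PointCloudParseError(
                    f"{path}: line {lineno} has {len(fields)} columns; "
                    "expected 3 (xyz) or 6 (xyzrgb)")
            try:
                vals = [float(f) for f in fields]
            except ValueError as exc:
                raise PointCloudParseError(
                    f"{path}: non-numeric value on line {lineno}: {exc}") from None
            points.append(vals[:3])
            if len(vals) == 6:
                colors.append(vals[3:])
    if colors and len(colors) != len(points):
        raise PointCloudParseError(f"{path}: mixed 3- and 6-column rows")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    cols = np.asarray(colors, dtype=np.float64).reshape(-1, 3) if colors else None
    return pts, cols


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(cloud)):
            row = [f"{v:.17g}" for v in cloud.points[i]]
            if cloud.colors is not None:
                row += [f"{v:.17g}" for v in cloud.colors[i]]
            fh.write(" ".join(row) + "\n")


# --------------------------------------------------------------- mesh export

def write_mesh(mesh: TriangleMesh, path) -> None:
    """Export a triangle mesh as PLY or OBJ (by extension) via trimesh."""
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)
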