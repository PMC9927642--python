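"""Point-cloud container and readers/writers for PLY, PCD and xyz text.

Only the channels the pipeline touches are supported: x/y/z coordinates and an
optional integer per-point instance label. The xyz dialect is
whitespace-delimited, one point per line, optional integer 4th column = label,
``#`` lines are comments.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["PointCloud", "read_cloud", "write_cloud"]


@dataclass
class PointCloud:
    """An ordered set of 3-D points with optional per-point instance labels."""

    points: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (n, 3), got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise ValidationError("a point cloud needs at least one point")
        if not np.all(np.isfinite(pts)):
            bad = int(np.argwhere(~np.isfinite(pts).all(axis=1))[0, 0])
            raise ValidationError(f"non-finite coordinate at point index {bad}")
        self.points = pts
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != (pts.shape[0],):
                raise ValidationError(
                    f"labels length {lab.shape} does not match n={pts.shape[0]}"
                )
            self.labels = lab.astype(np.int64)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def bounding_box_diagonal(self) -> float:
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(span))

    def select(self, indices: Sequence[int]) -> "PointCloud":
        """Sub-cloud at the given indices (labels carried through)."""
        idx = np.asarray(indices, dtype=np.int64)
        lab = self.labels[idx] if self.labels is not None else None
        return PointCloud(self.points[idx], lab)

    def with_labels(self, labels: Sequence[int]) -> "PointCloud":
        return PointCloud(self.points.copy(), np.asarray(labels, dtype=np.int64))


# ---------------------------------------------------------------------------
# xyz text
# ---------------------------------------------------------------------------

def _read_xyz(path: str) -> PointCloud:
    rows = []
    labels = []
    ncols = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValidationError(
                    f"{path}:{lineno}: inconsistent column count"
                )
            try:
                xyz = [float(v) for v in parts[:3]]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if not all(np.isfinite(xyz)):
                raise ValidationError(f"{path}:{lineno}: non-finite coordinate")
            rows.append(xyz)
            if ncols == 4:
                labels.append(int(float(parts[3])))
    if not rows:
        raise ValidationError(f"{path}: no points")
    return PointCloud(np.array(rows), np.array(labels) if labels else None)


def _write_xyz(cloud: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        for i in range(cloud.n):
            x, y, z = cloud.points[i]
            if cloud.labels is not None:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {int(cloud.labels[i])}\n")
            else:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# PLY (ascii + binary_little_endian); label property "label" (int32),
# "scalar_label" also accepted on read (CloudCompare convention).
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_LABEL_NAMES = ("label", "scalar_label")


def _read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValidationError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValidationError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValidationError(f"{path}: list vertex properties unsupported")
                props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValidationError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise ValidationError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValidationError(f"{path}: missing vertex property {axis!r}")
        if fmt == "ascii":
            data = np.loadtxt(fh, dtype=np.float64, max_rows=n_vertex, ndmin=2)
            if data.shape != (n_vertex, len(props)):
                raise ValidationError(f"{path}: vertex data shape mismatch")
            cols = {name: data[:, i] for i, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, "<" + t) for name, t in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) < dtype.itemsize * n_vertex:
                raise ValidationError(f"{path}: truncated PLY body")
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            cols = {name: rec[name].astype(np.float64) for name, _ in props}
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = None
    for cand in _LABEL_NAMES:
        if cand in cols:
            labels = np.rint(cols[cand]).astype(np.int64)
            break
    if not np.all(np.isfinite(pts)):
        bad = int(np.argwhere(~np.isfinite(pts).all(axis=1))[0, 0])
        raise ValidationError(f"{path}: non-finite coordinate at vertex {bad}")
    return PointCloud(pts, labels)


def _write_ply(cloud: PointCloud, path: str, binary: bool = False) -> None:
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {cloud.n}")
    header += ["property double x", "property double y", "property double z"]
    if cloud.labels is not None:
        header.append("property int32 label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            for i in range(cloud.n):
                fh.write(struct.pack("<3d", *cloud.points[i]))
                if cloud.labels is not None:
                    fh.write(struct.pack("<i", int(cloud.labels[i])))
        else:
            for i in range(cloud.n):
                x, y, z = cloud.points[i]
                row = f"{x:.17g} {y:.17g} {z:.17g}"
                if cloud.labels is not None:
                    row += f" {int(cloud.labels[i])}"
                fh.write((row + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# PCD (ascii only)
# ---------------------------------------------------------------------------

def _read_pcd(path: str) -> PointCloud:
    fields: list[str] = []
    n_points = None
    data_mode = None
    body_start = 0
    with open(path, "r") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise ValidationError(f"{path}: truncated PCD header")
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            key = tokens[0].upper()
            if key == "FIELDS":
                fields = tokens[1:]
            elif key == "POINTS":
                n_points = int(tokens[1])
            elif key == "DATA":
                data_mode = tokens[1]
                body_start = fh.tell()
                break
        if data_mode != "ascii":
            raise ValidationError(f"{path}: only DATA ascii PCD supported")
        if n_points is None or not fields:
            raise ValidationError(f"{path}: incomplete PCD header")
        fh.seek(body_start)
        data = np.loadtxt(fh, dtype=np.float64, max_rows=n_points, ndmin=2)
    if data.shape != (n_points, len(fields)):
        raise ValidationError(f"{path}: PCD body shape mismatch")
    cols = {name: data[:, i] for i, name in enumerate(fields)}
    for axis in ("x", "y", "z"):
        if axis not in cols:
            raise ValidationError(f"{path}: missing PCD field {axis!r}")
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = None
    for cand in _LABEL_NAMES:
        if cand in cols:
            labels = np.rint(cols[cand]).astype(np.int64)
            break
    if not np.all(np.isfinite(pts)):
        bad = int(np.argwhere(~np.isfinite(pts).all(axis=1))[0, 0])
        raise ValidationError(f"{path}: non-finite coordinate at point {bad}")
    return PointCloud(pts, labels)


def _write_pcd(cloud: PointCloud, path: str) -> None:
    fields = ["x", "y", "z"] + (["label"] if cloud.labels is not None else [])
    sizes = ["8"] * 3 + (["4"] if cloud.labels is not None else [])
    types = ["F"] * 3 + (["I"] if cloud.labels is not None else [])
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\n")
        fh.write(f"FIELDS {' '.join(fields)}\n")
        fh.write(f"SIZE {' '.join(sizes)}\n")
        fh.write(f"TYPE {' '.join(types)}\n")
        fh.write(f"COUNT {' '.join(['1'] * len(fields))}\n")
        fh.write(f"WIDTH {cloud.n}\nHEIGHT 1\n")
        fh.write("VIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {cloud.n}\nDATA ascii\n")
        for i in range(cloud.n):
            x, y, z = cloud.points[i]
            row = f"{x:.17g} {y:.17g} {z:.17g}"
            if cloud.labels is not None:
                row += f" {int(cloud.labels[i])}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_EXT_MAP = {".ply": "ply", ".pcd": "pcd", ".xyz": "xyz", ".txt": "xyz", ".asc": "xyz"}


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in _EXT_MAP:
        return _EXT_MAP[ext]
    with open(path, "rb") as fh:
        head = fh.read(4)
    return "ply" if head.startswith(b"ply") else "xyz"


def read_cloud(path: str, format: str = "auto") -> PointCloud:
    """Read a point cloud; a 4th xyz column or a ``label`` property becomes labels."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    raise ValidationError(f"unknown format {format!r}")


def write_cloud(cloud: PointCloud, path: str, format: str = "auto",
                binary: bool = False) -> None:
    """Write a point cloud; labels are serialized whenever present."""
    fmt = _sniff_format_for_write(path) if format == "auto" else format
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    else:
        raise ValidationError(f"unknown format {format!r}")


def _sniff_format_for_write(path: str) -> str:
    return _EXT_MAP.get(os.path.splitext(path)[1].lower(), "xyz")
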