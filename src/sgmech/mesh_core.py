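"""Shared geometric types and I/O.

Units are fixed package-wide: millimetres for length, Newtons for force and
MPa for stress (1 N/mm^2 = 1 MPa).  No unit inference is performed anywhere.

The two central containers are :class:`TriMesh` (vessel walls and graft
membranes, with optional named per-node / per-element data arrays) and
:class:`Centerline` (an ordered polyline with cumulative arc length, used to
bin surfaces into axial sections and regions).  Nodal force / stress fields
read from CSV live in :class:`FieldTable`.

Supported interchange formats: STL (binary + ASCII read, ASCII write),
VTK legacy ASCII polydata (POINTS/POLYGONS with named POINT_DATA/CELL_DATA
arrays), and a CSV pair (``nodes.csv``: id,x,y,z; ``elements.csv``:
id,n0,n1[,n2]).  Indices are 0-based everywhere, including on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .errors import MeshFormatError, ParameterError

__all__ = [
    "TriMesh",
    "Centerline",
    "FieldTable",
    "read_mesh",
    "write_mesh",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_field_csv",
    "write_field_csv",
    "resample_centerline",
    "merge_duplicate_nodes",
]

#: vertices closer than this (mm) are welded on STL import
WELD_TOL = 1e-6

#: triangles with area below this (mm^2) trigger a degeneracy warning
DEGENERATE_AREA_TOL = 1e-9


@dataclass
class TriMesh:
    """Triangle surface mesh with optional named data arrays.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in mm.
    triangles : (M, 3) int array
        Node index triplets, 0-based.
    node_fields, element_fields : dict of str -> array
        Named per-node / per-element scalar or vector arrays; first axis
        must match the node / element count.
    thickness : float, optional
        Shell thickness in mm (carried as metadata).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    node_fields: dict = field(default_factory=dict)
    element_fields: dict = field(default_factory=dict)
    thickness: float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.nodes)
        ):
            raise MeshFormatError("triangle indices out of node range")
        for name, arr in self.node_fields.items():
            if len(arr) != len(self.nodes):
                raise MeshFormatError(
                    f"node field {name!r} length {len(arr)} != node count {len(self.nodes)}"
                )
        for name, arr in self.element_fields.items():
            if len(arr) != len(self.triangles):
                raise MeshFormatError(
                    f"element field {name!r} length {len(arr)} != element count "
                    f"{len(self.triangles)}"
                )
        if self.triangles.size:
            bad = int((self.element_areas() <= DEGENERATE_AREA_TOL).sum())
            if bad:
                warnings.warn(
                    f"{bad} degenerate (near zero-area) triangles retained",
                    stacklevel=2,
                )

    # -- derived quantities --------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def triangle_coords(self) -> np.ndarray:
        """(M, 3, 3) coordinates of each triangle's corners."""
        return self.nodes[self.triangles]

    def element_areas(self) -> np.ndarray:
        t = self.triangle_coords()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def element_centroids(self) -> np.ndarray:
        return self.triangle_coords().mean(axis=1)

    def area(self) -> float:
        return float(self.element_areas().sum())

    def nodal_areas(self) -> np.ndarray:
        """Lumped nodal areas: one third of each incident triangle's area."""
        areas = np.zeros(self.n_nodes)
        third = self.element_areas() / 3.0
        for k in range(3):
            np.add.at(areas, self.triangles[:, k], third)
        return areas


@dataclass
class Centerline:
    """Ordered 3D polyline with cumulative arc length (mm).

    ``arc_length`` is recomputed from the points if not supplied; it must be
    strictly increasing and start at zero.
    """

    points: np.ndarray
    arc_length: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ParameterError("centerline needs at least 2 points")
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=float)
        if len(self.arc_length) != len(self.points):
            raise ParameterError("arc_length length mismatch")
        if self.arc_length[0] != 0.0 or np.any(np.diff(self.arc_length) <= 0):
            raise ParameterError("arc_length must start at 0 and strictly increase")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of position at arc length ``s``."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length)
        out = np.column_stack(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)]
        )
        return out if out.shape[0] > 1 else out[0]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Arc length of the nearest point on the polyline for each query.

        Exact per-segment projection (no spatial pruning): robust and fast
        enough for the mesh sizes this package handles.
        """
        q = np.asarray(points, dtype=float).reshape(-1, 3)
        a = self.points[:-1]  # (S,3)
        d = self.points[1:] - a
        seg_len2 = np.einsum("ij,ij->i", d, d)
        seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
        s_out = np.empty(len(q))
        # chunk queries to bound memory at (chunk x segments)
        chunk = max(1, int(2e6 // max(len(a), 1)))
        for lo in range(0, len(q), chunk):
            qq = q[lo : lo + chunk]  # (Q,3)
            w = qq[:, None, :] - a[None, :, :]  # (Q,S,3)
            t = np.clip(np.einsum("qsj,sj->qs", w, d) / seg_len2, 0.0, 1.0)
            closest = a[None] + t[..., None] * d[None]
            dist2 = np.einsum("qsj->qs", (qq[:, None, :] - closest) ** 2)
            idx = np.argmin(dist2, axis=1)
            tt = t[np.arange(len(qq)), idx]
            s_out[lo : lo + chunk] = self.arc_length[idx] + tt * np.sqrt(
                seg_len2[idx]
            )
        return s_out


@dataclass
class FieldTable:
    """Nodal field: 3D force vectors (N) or scalar stresses (MPa).

    ``values`` has shape (n,) for scalars or (n, k) for vectors/components;
    ``node_index`` maps each row to a mesh node.
    """

    node_index: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.node_index = np.asarray(self.node_index, dtype=np.int64).ravel()
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.node_index):
            raise ParameterError("field rows must match node_index length")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("field contains non-finite values")

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 2

    def magnitudes(self) -> np.ndarray:
        if self.is_vector:
            return np.linalg.norm(self.values, axis=1)
        return np.abs(self.values)

    def check_bounds(self, n_nodes: int) -> None:
        if self.node_index.size and (
            self.node_index.min() < 0 or self.node_index.max() >= n_nodes
        ):
            raise ParameterError("field node indices out of mesh bounds")

    def dense(self, n_nodes: int) -> np.ndarray:
        """Scatter to a dense per-node array (zeros where absent)."""
        self.check_bounds(n_nodes)
        shape = (n_nodes,) if not self.is_vector else (n_nodes, self.values.shape[1])
        out = np.zeros(shape)
        out[self.node_index] = self.values
        return out


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def merge_duplicate_nodes(nodes: np.ndarray, triangles: np.ndarray,
                          tol: float = WELD_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Weld vertices closer than ``tol`` (STL stores facets unshared)."""
    if len(nodes) == 0:
        return nodes, triangles
    # quantise on a grid of size tol; tol is far below any feature size here
    key = np.round(nodes / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    return nodes[first], inverse[triangles]


def read_mesh(path, format: str) -> TriMesh:
    """Read a triangle mesh in one of the supported dialects.

    format is one of ``stl``, ``vtk_legacy``, ``csv_pair``.  For
    ``csv_pair``, ``path`` is the nodes CSV; the elements CSV is found by
    replacing ``nodes`` with ``elements`` in the file name.
    """
    path = Path(path)
    if format == "stl":
        return _read_stl(path)
    if format == "vtk_legacy":
        return _read_vtk_legacy(path)
    if format == "csv_pair":
        return _read_csv_pair(path)
    raise ParameterError(f"unknown mesh format {format!r}")


def write_mesh(mesh: TriMesh, path, format: str) -> None:
    path = Path(path)
    if format == "stl":
        _write_stl_ascii(mesh, path)
    elif format == "vtk_legacy":
        _write_vtk_legacy(mesh, path)
    elif format == "csv_pair":
        _write_csv_pair(mesh, path)
    else:
        raise ParameterError(f"unknown mesh format {format!r}")


def _read_stl(path: Path) -> TriMesh:
    import trimesh as _trimesh

    try:
        tm = _trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise MeshFormatError(f"{path}: STL parse failed: {exc}") from exc
    nodes, tris = merge_duplicate_nodes(
        np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64)
    )
    return TriMesh(nodes, tris)


def _write_stl_ascii(mesh: TriMesh, path: Path) -> None:
    t = mesh.triangle_coords()
    cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    nrm = np.linalg.norm(cross, axis=1)
    normals = cross / np.where(nrm == 0, 1.0, nrm)[:, None]
    with open(path, "w") as fh:
        fh.write("solid sgmech\n")
        for k in range(len(t)):
            fh.write(f" facet normal {normals[k,0]:.9e} {normals[k,1]:.9e} "
                     f"{normals[k,2]:.9e}\n  outer loop\n")
            for v in t[k]:
                fh.write(f"   vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            fh.write("  endloop\n endfacet\n")
        fh.write("endsolid sgmech\n")


def _read_vtk_legacy(path: Path) -> TriMesh:
    """Minimal VTK legacy ASCII POLYDATA reader (the dialect we write)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    tok: list[tuple[int, str]] = []  # (line number, token line)
    for i, ln in enumerate(lines):
        if ln.strip():
            tok.append((i + 1, ln.strip()))

    def fail(lineno: int, msg: str) -> MeshFormatError:
        return MeshFormatError(f"{path}:{lineno}: {msg}")

    i = 0
    try:
        if not tok[0][1].startswith("# vtk DataFile"):
            raise fail(tok[0][0], "missing '# vtk DataFile' header")
        if tok[2][1].upper() != "ASCII":
            raise fail(tok[2][0], "only ASCII VTK legacy files supported")
        if "POLYDATA" not in tok[3][1].upper():
            raise fail(tok[3][0], "only DATASET POLYDATA supported")
        i = 4
    except IndexError as exc:
        raise MeshFormatError(f"{path}: truncated VTK header") from exc

    nodes = None
    tris = None
    node_fields: dict[str, np.ndarray] = {}
    element_fields: dict[str, np.ndarray] = {}
    target = None  # which dict data sections fill

    def read_numbers(count: int, start: int) -> tuple[np.ndarray, int]:
        vals: list[float] = []
        j = start
        while len(vals) < count:
            if j >= len(tok):
                raise fail(tok[start - 1][0], f"expected {count} numbers")
            vals.extend(float(x) for x in tok[j][1].split())
            j += 1
        if len(vals) != count:
            raise fail(tok[j - 1][0], "unexpected extra numbers")
        return np.array(vals), j

    while i < len(tok):
        lineno, line = tok[i]
        parts = line.split()
        kw = parts[0].upper()
        if kw == "POINTS":
            n = int(parts[1])
            flat, i = read_numbers(3 * n, i + 1)
            nodes = flat.reshape(n, 3)
        elif kw == "POLYGONS":
            n = int(parts[1])
            total = int(parts[2])
            flat, i = read_numbers(total, i + 1)
            out = []
            p = 0
            while p < len(flat):
                sz = int(flat[p])
                if sz != 3:
                    raise fail(lineno, "only triangle POLYGONS supported")
                out.append(flat[p + 1 : p + 4].astype(np.int64))
                p += sz + 1
            if len(out) != n:
                raise fail(lineno, "POLYGONS count mismatch")
            tris = np.array(out, dtype=np.int64)
        elif kw == "POINT_DATA":
            target = ("node", int(parts[1]))
            i += 1
        elif kw == "CELL_DATA":
            target = ("cell", int(parts[1]))
            i += 1
        elif kw in ("SCALARS", "VECTORS"):
            if target is None:
                raise fail(lineno, f"{kw} before POINT_DATA/CELL_DATA")
            name = parts[1]
            kind, count = target
            ncomp = 3 if kw == "VECTORS" else 1
            i += 1
            if kw == "SCALARS":
                if i < len(tok) and tok[i][1].upper().startswith("LOOKUP_TABLE"):
                    i += 1
            flat, i = read_numbers(ncomp * count, i)
            arr = flat.reshape(count, 3) if ncomp == 3 else flat
            (node_fields if kind == "node" else element_fields)[name] = arr
        elif kw == "LOOKUP_TABLE":
            i += 1
        else:
            raise fail(lineno, f"unsupported VTK keyword {parts[0]!r}")
    if nodes is None or tris is None:
        raise MeshFormatError(f"{path}: missing POINTS or POLYGONS section")
    return TriMesh(nodes, tris, node_fields=node_fields,
                   element_fields=element_fields)


def _write_vtk_legacy(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsgmech surface\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"POLYGONS {mesh.n_elements} {4 * mesh.n_elements}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        _write_vtk_data(fh, "POINT_DATA", mesh.n_nodes, mesh.node_fields)
        _write_vtk_data(fh, "CELL_DATA", mesh.n_elements, mesh.element_fields)


def _write_vtk_data(fh, section: str, count: int, fields: dict) -> None:
    if not fields:
        return
    fh.write(f"{section} {count}\n")
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} float\n")
            for v in arr:
                fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
        else:
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in arr.ravel():
                fh.write(f"{v:.9e}\n")


def _csv_pair_paths(path: Path) -> tuple[Path, Path]:
    if "nodes" not in path.name:
        raise ParameterError(
            "csv_pair path must be the nodes CSV (name containing 'nodes')"
        )
    return path, path.with_name(path.name.replace("nodes", "elements"))


def _read_csv_pair(path: Path) -> TriMesh:
    nodes_path, elems_path = _csv_pair_paths(path)
    try:
        nodes = np.loadtxt(nodes_path, delimiter=",", skiprows=1, ndmin=2)
        elems = np.loadtxt(elems_path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise MeshFormatError(f"{path}: CSV pair parse failed: {exc}") from exc
    if nodes.shape[1] != 4:
        raise MeshFormatError(f"{nodes_path}: expected columns id,x,y,z")
    if elems.shape[1] != 4:
        raise MeshFormatError(f"{elems_path}: expected columns id,n0,n1,n2")
    order = np.argsort(nodes[:, 0])
    return TriMesh(nodes[order, 1:4], elems[:, 1:4].astype(np.int64))


def _write_csv_pair(mesh: TriMesh, path: Path) -> None:
    nodes_path, elems_path = _csv_pair_paths(Path(path))
    with open(nodes_path, "w") as fh:
        fh.write("id,x,y,z\n")  # ids 0-based
        for i, p in enumerate(mesh.nodes):
            fh.write(f"{i},{p[0]:.9e},{p[1]:.9e},{p[2]:.9e}\n")
    with open(elems_path, "w") as fh:
        fh.write("id,n0,n1,n2\n")
        for i, t in enumerate(mesh.triangles):
            fh.write(f"{i},{t[0]},{t[1]},{t[2]}\n")


# ---------------------------------------------------------------------------
# centerline / field I/O
# ---------------------------------------------------------------------------

def read_centerline_csv(path) -> Centerline:
    try:
        pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise MeshFormatError(f"{path}: centerline CSV parse failed: {exc}") from exc
    if pts.shape[1] != 3:
        raise MeshFormatError(f"{path}: expected columns x,y,z")
    return Centerline(pts)


def write_centerline_csv(c: Centerline, path) -> None:
    with open(path, "w") as fh:
        fh.write("x,y,z\n")
        for p in c.points:
            fh.write(f"{p[0]:.9e},{p[1]:.9e},{p[2]:.9e}\n")


def read_field_csv(path) -> FieldTable:
    """Read ``node_id,fx,fy,fz`` (vector) or ``node_id,value`` (scalar)."""
    try:
        raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise MeshFormatError(f"{path}: field CSV parse failed: {exc}") from exc
    if raw.shape[1] == 2:
        return FieldTable(raw[:, 0].astype(np.int64), raw[:, 1])
    if raw.shape[1] == 4:
        return FieldTable(raw[:, 0].astype(np.int64), raw[:, 1:4])
    raise MeshFormatError(f"{path}: expected 2 or 4 columns")


def write_field_csv(f: FieldTable, path) -> None:
    with open(path, "w") as fh:
        if f.is_vector:
            fh.write("node_id,fx,fy,fz\n")
            for i, v in zip(f.node_index, f.values):
                fh.write(f"{i},{v[0]:.9e},{v[1]:.9e},{v[2]:.9e}\n")
        else:
            fh.write("node_id,value\n")
            for i, v in zip(f.node_index, f.values):
                fh.write(f"{i},{v:.9e}\n")


# ---------------------------------------------------------------------------
# centerline resampling
# ---------------------------------------------------------------------------

def resample_centerline(c: Centerline, spacing: float) -> Centerline:
    """Resample at uniform arc-length spacing.

    Consecutive gaps equal ``spacing`` except the final one, which is at most
    ``spacing`` so that both endpoints are preserved exactly.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    total = c.length
    if spacing >= total:
        warnings.warn("spacing >= centerline length; returning endpoints only",
                      stacklevel=2)
        s = np.array([0.0, total])
    else:
        s = np.arange(0.0, total, spacing)
        if total - s[-1] > 1e-12 * max(total, 1.0):
            s = np.append(s, total)
        else:
            s[-1] = total
    pts = np.column_stack(
        [np.interp(s, c.arc_length, c.points[:, k]) for k in range(3)]
    )
    pts[0] = c.points[0]
    pts[-1] = c.points[-1]
    return Centerline(pts, s.copy())
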