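"""STL surface-model I/O and deterministic surface sampling.

All coordinates are millimetres. STL carries no unit metadata, so values are
taken verbatim as mm (the convention of CT/CBCT-derived segmentations).
"""

from __future__ import annotations

import os
import re
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriMesh",
    "PointCloud",
    "MeshFormatError",
    "EmptyMeshError",
    "read_stl",
    "write_stl",
    "sample_surface",
]

_FACET_RECORD = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


class MeshFormatError(ValueError):
    """Raised when an STL file cannot be parsed."""


class EmptyMeshError(ValueError):
    """Raised for a mesh (or file) with zero triangles."""


@dataclass
class TriMesh:
    """Triangle surface mesh in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : free-text label
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if len(self.faces) < 1:
            raise EmptyMeshError("mesh has no triangles")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices contain non-finite coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(norm > 0, n / norm, 0.0)
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (zero for isolated vertices)."""
        tri = self.triangles
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vn = np.where(norm > 0, vn / norm, 0.0)
        return vn


@dataclass(frozen=True)
class PointCloud:
    """Dense surface samples in mm.

    ``spacing_mm`` is the maximum nearest-sample spacing guaranteed by the
    sampler (every surface point of the source mesh lies within this distance
    of some sample).
    """

    points: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
            raise ValueError("points must be a nonempty (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be > 0")

    def __len__(self) -> int:
        return len(self.points)


def _weld(raw_vertices: np.ndarray, name: str) -> TriMesh:
    """Merge exactly-duplicated corner vertices into an indexed mesh."""
    uniq, inverse = np.unique(raw_vertices, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriMesh(vertices=uniq, faces=faces, name=name)


_ASCII_VERTEX_RE = re.compile(
    rb"vertex\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)"
)


def _read_ascii(data: bytes, path: str) -> TriMesh:
    coords = _ASCII_VERTEX_RE.findall(data)
    if not coords:
        raise EmptyMeshError(f"{path}: ASCII STL contains no facets")
    if len(coords) % 3 != 0:
        raise MeshFormatError(
            f"{path}: ASCII STL vertex count {len(coords)} not a multiple of 3"
        )
    try:
        verts = np.array(coords, dtype=np.float64)
    except ValueError as exc:  # pragma: no cover - regex restricts charset
        raise MeshFormatError(f"{path}: unparsable vertex coordinate") from exc
    name = ""
    first = data.split(b"\n", 1)[0].strip()
    if first.startswith(b"solid"):
        name = first[5:].strip().decode("ascii", "replace")
    return _weld(verts, name)


def _read_binary(data: bytes, path: str) -> TriMesh:
    if len(data) < 84:
        raise MeshFormatError(
            f"{path}: binary STL truncated at byte offset {len(data)} "
            "(header + count need 84 bytes)"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    if count == 0:
        raise EmptyMeshError(f"{path}: binary STL declares 0 facets")
    expected = 84 + 50 * count
    if len(data) < expected:
        raise MeshFormatError(
            f"{path}: binary STL declares {count} facets ({expected} bytes) but "
            f"file ends at byte offset {len(data)}"
        )
    rec = np.frombuffer(data, dtype=_FACET_RECORD, count=count, offset=84)
    verts = rec["vertices"].reshape(-1, 3).astype(np.float64)
    if not np.all(np.isfinite(verts)):
        raise MeshFormatError(f"{path}: binary STL contains non-finite vertices")
    name = data[:80].split(b"\x00", 1)[0].decode("ascii", "replace").strip()
    return _weld(verts, name)


def read_stl(path: str | os.PathLike) -> TriMesh:
    """Read a binary or ASCII STL file into a :class:`TriMesh`.

    Exact duplicate corner vertices are welded into shared indices; geometry
    is otherwise taken verbatim (units assumed mm).
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) >= 84:
        (count,) = struct.unpack_from("<I", data, 80)
        if len(data) == 84 + 50 * count and count > 0:
            return _read_binary(data, str(path))
    head = data[:512].lstrip()
    if head.startswith(b"solid") and b"facet" in data:
        return _read_ascii(data, str(path))
    return _read_binary(data, str(path))


def write_stl(mesh: TriMesh, path: str | os.PathLike, dialect: str = "binary") -> None:
    """Write ``mesh`` to ``path`` as binary (default) or ASCII STL."""
    if not isinstance(mesh, TriMesh):
        raise TypeError("mesh must be a TriMesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError("dialect must be 'binary' or 'ascii'")
    path = Path(path)
    tri = mesh.triangles
    normals = mesh.face_normals()
    if dialect == "binary":
        rec = np.zeros(mesh.n_faces, dtype=_FACET_RECORD)
        rec["normal"] = normals.astype(np.float32)
        rec["vertices"] = tri.astype(np.float32)
        header = mesh.name.encode("ascii", "replace")[:80].ljust(80, b"\x00")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(rec.tobytes())
    else:
        name = mesh.name or "mesh"
        lines = [f"solid {name}"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {name}\n")
        path.write_text("\n".join(lines))


def sample_surface(mesh: TriMesh, max_spacing_mm: float) -> PointCloud:
    """Deterministically sample the mesh surface on a barycentric grid.

    Each triangle is subdivided so no sub-edge exceeds ``max_spacing_mm``;
    every surface point then lies within ``max_spacing_mm`` of a sample.
    The result is bitwise reproducible for identical inputs (no randomness).
    Zero-area triangles are skipped with a warning.
    """
    if not max_spacing_mm > 0:
        raise ValueError("max_spacing_mm must be > 0")
    tri = mesh.triangles
    edges = np.stack(
        [
            np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
        ],
        axis=1,
    )
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    good = areas > 1e-12
    if not good.any():
        raise ValueError("all triangles are degenerate (zero area)")
    if not good.all():
        warnings.warn(
            f"skipping {int((~good).sum())} zero-area triangle(s) during sampling",
            stacklevel=2,
        )
    tri = tri[good]
    longest = edges[good].max(axis=1)
    # tiny slack so mathematically-equal meshes (e.g. rigidly moved copies)
    # pick identical subdivision counts despite float rounding of edge lengths
    n_sub = np.maximum(1, np.ceil(longest / max_spacing_mm - 1e-9).astype(np.int64))
    achieved = float((longest / n_sub).max())

    chunks: list[np.ndarray] = []
    for n in np.unique(n_sub):
        sel = tri[n_sub == n]
        ii, jj = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = (ii + jj) <= n
        a = (ii[keep] / n).astype(np.float64)
        b = (jj[keep] / n).astype(np.float64)
        # p = A + a*(B-A) + b*(C-A), one grid per triangle in this bucket
        pts = (
            sel[:, None, 0, :]
            + a[None, :, None] * (sel[:, None, 1, :] - sel[:, None, 0, :])
            + b[None, :, None] * (sel[:, None, 2, :] - sel[:, None, 0, :])
        )
        chunks.append(pts.reshape(-1, 3))
    points = np.concatenate(chunks, axis=0)
    return PointCloud(points=points, spacing_mm=achieved)
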