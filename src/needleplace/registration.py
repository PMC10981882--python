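"""Rigid alignment: closed-form landmark fit, point-to-point ICP, transforms.

Reflections are never produced: anatomy cannot mirror, so every fitted
rotation is constrained to determinant +1.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import PointCloud, TriMesh

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "RegistrationReport",
    "PairingError",
    "DegenerateConfigurationError",
    "LANDMARK_NAMES",
    "procrustes_rigid",
    "icp_rigid",
    "apply_transform",
    "compose",
    "inverse",
]

#: Canonical pelvic landmark names used for Procrustes alignment.
LANDMARK_NAMES = (
    "left_ischial_tuberosity",
    "right_ischial_tuberosity",
    "left_midpoint_lateral_border_sacrum",
    "right_midpoint_lateral_border_sacrum",
    "left_greater_trochanter",
    "right_greater_trochanter",
)


class PairingError(ValueError):
    """Landmark names of the two sets cannot be put in correspondence."""


class DegenerateConfigurationError(ValueError):
    """Landmark geometry (collinear/coincident) does not pin down a rotation."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R @ p + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self) -> str:
        return json.dumps(self.matrix.tolist())

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(np.array(json.loads(text)))


@dataclass
class LandmarkSet:
    """Ordered, named landmark coordinates (mm)."""

    landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.landmarks.items():
            arr = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            clean[str(name)] = arr
        if len(clean) != len(self.landmarks):
            raise ValueError("landmark names must be distinct")
        self.landmarks = clean

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.landmarks)

    def points(self, order: Iterable[str] | None = None) -> np.ndarray:
        names = tuple(order) if order is not None else self.names
        return np.array([self.landmarks[n] for n in names])

    def __len__(self) -> int:
        return len(self.landmarks)

    def to_csv(self, path: str | os.PathLike) -> None:
        lines = ["name,x,y,z"]
        for name, p in self.landmarks.items():
            lines.append(f"{name},{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "LandmarkSet":
        marks: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("name"):
                raise ValueError(f"{path}: expected 'name,x,y,z' header")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                name, x, y, z = line.split(",")
                marks[name] = np.array([float(x), float(y), float(z)])
        return cls(marks)


@dataclass
class RegistrationReport:
    transform: RigidTransform
    rms_mm: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def _as_points(cloud: PointCloud | np.ndarray) -> np.ndarray:
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("expected a nonempty (n, 3) point array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point cloud contains non-finite coordinates")
    return pts


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form proper rigid fit minimizing sum ||R s + t - m||^2."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, tc - R @ sc)


def procrustes_rigid(source: LandmarkSet, target: LandmarkSet) -> RegistrationReport:
    """Closed-form rigid (no-scale) fit between two named landmark sets.

    Points are paired by name; the returned rotation always has det +1.
    """
    if set(source.names) != set(target.names):
        raise PairingError(
            f"landmark names differ: {sorted(source.names)} vs {sorted(target.names)}"
        )
    order = source.names
    src = source.points(order)
    tgt = target.points(order)
    for pts, label in ((src, "source"), (tgt, "target")):
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[0] < 1e-9 or s[1] < 1e-9 * max(s[0], 1.0):
            raise DegenerateConfigurationError(
                f"{label} landmarks are collinear or coincident"
            )
    transform = _kabsch(src, tgt)
    resid = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationReport(transform=transform, rms_mm=rms, iterations=0, converged=True)


def icp_rigid(
    source: PointCloud | np.ndarray,
    target: PointCloud | np.ndarray,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol_mm: float = 1e-6,
    max_correspondence_points: int | None = 20000,
) -> RegistrationReport:
    """Point-to-point ICP of ``source`` onto ``target``.

    Each iteration pairs every (subsampled) source point with its nearest
    target point and solves the closed-form rigid fit on those pairs. The RMS
    of matched pairs is non-increasing; iteration stops when the improvement
    drops below ``tol_mm`` (or RMS itself falls below ``tol_mm``).

    ``max_correspondence_points`` caps the number of source points used for
    correspondence search (deterministic stride subsampling); the returned
    transform still applies to the full cloud.
    """
    src_all = _as_points(source)
    tgt = _as_points(target)
    if not tol_mm > 0:
        raise ValueError("tol_mm must be > 0")
    src = src_all
    if max_correspondence_points is not None and len(src) > max_correspondence_points:
        stride = int(np.ceil(len(src) / max_correspondence_points))
        src = src[::stride]
    tree = cKDTree(tgt)
    cur = init if init is not None else RigidTransform.identity()
    history: list[float] = []
    rms_prev = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        moved = cur.apply(src)
        dist, idx = tree.query(moved, workers=-1)
        rms = float(np.sqrt(np.mean(dist**2)))
        history.append(rms)
        if rms <= tol_mm or rms_prev - rms < tol_mm:
            converged = True
            break
        rms_prev = rms
        cur = _kabsch(src, tgt[idx])
    return RegistrationReport(
        transform=cur,
        rms_mm=history[-1],
        iterations=iterations,
        converged=converged,
        rms_history=history,
    )


def apply_transform(t: RigidTransform, obj):
    """Apply a rigid transform to a PointCloud, TriMesh, LandmarkSet or array."""
    if isinstance(obj, PointCloud):
        return PointCloud(points=t.apply(obj.points), spacing_mm=obj.spacing_mm)
    if isinstance(obj, TriMesh):
        return TriMesh(vertices=t.apply(obj.vertices), faces=obj.faces.copy(), name=obj.name)
    if isinstance(obj, LandmarkSet):
        return LandmarkSet({n: t.apply(p) for n, p in obj.landmarks.items()})
    return t.apply(np.asarray(obj, dtype=np.float64))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """a ∘ b (apply b first)."""
    return a.compose(b)


def inverse(t: RigidTransform) -> RigidTransform:
    return t.inverse()
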