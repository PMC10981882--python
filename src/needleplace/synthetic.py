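"""Synthetic nerve/needle trial generator with exact ground truth.

Builds a curved nerve tube (default 75 mm x 2 mm, mimicking the phantom's
wire nerve) and a straight cylindrical needle whose axis is placed at exact,
configurable lateral/depth offsets from the nerve centerline. Every trial can
be perturbed by a random rigid pose and surface noise, with the noiseless
truth recorded, so the full registration + metrics pipeline is verifiable
without any scanned data.

Sign conventions of the ground truth:

* ``true_lateral_mm`` > 0 places the needle on the +``lateral_ref`` side of
  the nerve ("subject's right" by convention).
* ``true_depth_mm`` > 0 stops the tip short of the closest-approach point
  (undershoot); negative drives it past (deeper than target).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh_io import PointCloud, TriMesh, sample_surface, write_stl
from .registration import LANDMARK_NAMES, LandmarkSet, RigidTransform

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "TrialRecord",
    "generate_nerve",
    "generate_needle",
    "generate_trial",
    "generate_cohort",
    "write_cohort",
    "surface_truth",
    "distance_to_polyline",
]

# Fixed frame of six pelvic-style landmarks (mm) surrounding the nerve.
_LANDMARK_BASE = {
    "left_ischial_tuberosity": np.array([-45.0, -40.0, -30.0]),
    "right_ischial_tuberosity": np.array([45.0, -40.0, -30.0]),
    "left_midpoint_lateral_border_sacrum": np.array([-35.0, 60.0, 20.0]),
    "right_midpoint_lateral_border_sacrum": np.array([35.0, 60.0, 20.0]),
    "left_greater_trochanter": np.array([-90.0, 0.0, 10.0]),
    "right_greater_trochanter": np.array([90.0, 0.0, 10.0]),
}
assert set(_LANDMARK_BASE) == set(LANDMARK_NAMES)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic trial family; ``seed`` fixes all randomness."""

    nerve_length_mm: float = 75.0
    nerve_diameter_mm: float = 2.0
    nerve_curvature_mm: float = 5.0  # max centerline deflection from the chord
    needle_length_mm: float = 100.0
    needle_diameter_mm: float = 1.0
    true_lateral_mm: float = 3.0
    true_depth_mm: float = 4.0
    # Angle between needle and nerve tangent. At 90 deg (perpendicular
    # approach) the configured offsets satisfy euclidean^2 = lat^2 + depth^2
    # exactly; oblique approaches shrink the measured euclidean below that.
    approach_polar_deg: float = 90.0
    approach_azimuth_deg: float = 0.0
    surface_noise_sd_mm: float = 0.0
    pose_jitter_rot_deg: float = 0.0
    pose_jitter_trans_mm: float = 0.0
    landmark_noise_sd_mm: float = 0.0
    # optional per-trial offset draws for cohorts (0 = keep fixed offsets)
    lateral_sd_mm: float = 0.0
    depth_sd_mm: float = 0.0
    seed: int = 0
    n_axial: int = 150
    n_circumference: int = 24
    centerline_spacing_mm: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "nerve_length_mm",
            "nerve_diameter_mm",
            "needle_length_mm",
            "needle_diameter_mm",
            "centerline_spacing_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.nerve_curvature_mm < 0:
            raise ValueError("nerve_curvature_mm must be >= 0")
        if self.nerve_curvature_mm > 0.3 * self.nerve_length_mm:
            raise ValueError("nerve_curvature_mm too large for the given length")
        if self.nerve_curvature_mm > 0:
            theta = _arc_angle(self.nerve_length_mm, self.nerve_curvature_mm)
            if self.nerve_length_mm / theta <= self.nerve_diameter_mm:
                raise ValueError("curvature so high the nerve tube self-intersects")
        if not (5.0 <= self.approach_polar_deg <= 175.0):
            raise ValueError(
                "approach_polar_deg must keep the needle at least 5 deg off the nerve tangent"
            )


@dataclass
class GroundTruth:
    """Noiseless placement truth recorded alongside each synthetic trial."""

    true_lateral_mm: float
    true_depth_mm: float
    true_euclidean_mm: float
    nerve_centerline: np.ndarray  # (k, 3), in the trial's (posed) frame
    applied_pose: RigidTransform
    landmark_truth: LandmarkSet
    tip_point: np.ndarray
    needle_direction: np.ndarray  # unit, hub -> tip, posed frame
    lateral_ref: np.ndarray  # unit "subject right" direction, posed frame
    surface_euclidean_mm: float | None = None

    def __post_init__(self) -> None:
        expect = float(np.hypot(self.true_lateral_mm, self.true_depth_mm))
        if abs(self.true_euclidean_mm - expect) > 1e-9:
            raise ValueError("true_euclidean_mm violates the Pythagorean identity")


@dataclass
class TrialRecord:
    trial_id: str
    nerve: TriMesh
    needle: TriMesh
    landmarks: LandmarkSet | None = None
    truth: GroundTruth | None = None


def _arc_angle(length: float, deflection: float) -> float:
    """Subtended angle of a circular arc with given arclength and sagitta."""

    def f(theta: float) -> float:
        return (length / theta) * (1.0 - np.cos(theta / 2.0)) - deflection

    return float(brentq(f, 1e-9, 2.0 * np.pi - 1e-9, xtol=1e-13))


def _centerline(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Arclength-parametrized centerline points and unit tangents.

    The arc lies in the xy-plane, midpoint at the origin, mid-tangent +x,
    bending toward +y. Vertex spacing <= config.centerline_spacing_mm.
    """
    L = config.nerve_length_mm
    k = int(np.ceil(L / config.centerline_spacing_mm)) + 1
    s = np.linspace(0.0, L, k)
    if config.nerve_curvature_mm <= 0:
        pts = np.column_stack([s - L / 2.0, np.zeros(k), np.zeros(k)])
        tangents = np.tile([1.0, 0.0, 0.0], (k, 1))
        return pts, tangents
    theta = _arc_angle(L, config.nerve_curvature_mm)
    R = L / theta
    phi = (s - L / 2.0) / R
    pts = np.column_stack([R * np.sin(phi), R * (1.0 - np.cos(phi)), np.zeros(k)])
    tangents = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(k)])
    return pts, tangents


def _tube_mesh(
    centers: np.ndarray,
    tangents: np.ndarray,
    radius: float,
    n_circ: int,
    name: str,
) -> TriMesh:
    """Capped tube around a polyline with per-station orthonormal frames."""
    n_st = len(centers)
    # frames: normal/binormal perpendicular to tangent, propagated stably
    normals = np.empty_like(tangents)
    binormals = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    for i, t in enumerate(tangents):
        b = np.cross(t, ref) if abs(t @ ref) < 0.99 else np.cross(t, [0.0, 1.0, 0.0])
        b /= np.linalg.norm(b)
        normals[i] = np.cross(b, t)
        binormals[i] = b
    psi = 2.0 * np.pi * np.arange(n_circ) / n_circ
    ring = (
        centers[:, None, :]
        + radius * np.cos(psi)[None, :, None] * normals[:, None, :]
        + radius * np.sin(psi)[None, :, None] * binormals[:, None, :]
    ).reshape(-1, 3)
    verts = np.vstack([ring, centers[0], centers[-1]])
    i_start_cap = len(ring)
    i_end_cap = len(ring) + 1

    faces = []
    for i in range(n_st - 1):
        base0 = i * n_circ
        base1 = (i + 1) * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([base0 + j, base1 + j, base1 + j1])
            faces.append([base0 + j, base1 + j1, base0 + j1])
    for j in range(n_circ):  # caps
        j1 = (j + 1) % n_circ
        faces.append([i_start_cap, j1, j])
        last = (n_st - 1) * n_circ
        faces.append([i_end_cap, last + j, last + j1])
    return TriMesh(vertices=verts, faces=np.array(faces), name=name)


def generate_nerve(config: SynthConfig) -> tuple[TriMesh, np.ndarray]:
    """Capped nerve tube mesh plus its densely sampled centerline polyline."""
    centers, tangents = _centerline(config)
    # stations for the mesh (coarser than the returned centerline)
    idx = np.unique(
        np.round(np.linspace(0, len(centers) - 1, config.n_axial + 1)).astype(int)
    )
    mesh = _tube_mesh(
        centers[idx],
        tangents[idx],
        config.nerve_diameter_mm / 2.0,
        config.n_circumference,
        "nerve",
    )
    return mesh, centers


def _mid_frame(config: SynthConfig, centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mid = len(centerline) // 2
    C = centerline[mid]
    T = centerline[min(mid + 1, len(centerline) - 1)] - centerline[max(mid - 1, 0)]
    T = T / np.linalg.norm(T)
    B = np.array([0.0, 0.0, 1.0])
    N = np.cross(B, T)
    N /= np.linalg.norm(N)
    return C, T, N, np.cross(T, N)


def generate_needle(
    config: SynthConfig, nerve_centerline: np.ndarray
) -> tuple[TriMesh, np.ndarray, np.ndarray, np.ndarray]:
    """Straight cylindrical needle realizing the configured offsets.

    Returns ``(mesh, tip_point, direction, lateral_ref)`` where ``direction``
    is the unit insertion direction (hub -> tip) and ``lateral_ref`` the unit
    vector along which a positive lateral offset moves the needle.

    The needle axis passes at exact perpendicular distance
    ``|true_lateral_mm|`` from the centerline's mid-region closest-approach
    point, and the tip stops ``true_depth_mm`` short of (positive) or past
    (negative) the foot of that perpendicular.
    """
    C, T, N, B = _mid_frame(config, nerve_centerline)
    pol = np.deg2rad(config.approach_polar_deg)
    az = np.deg2rad(config.approach_azimuth_deg)
    d = np.cos(pol) * T + np.sin(pol) * (np.cos(az) * N + np.sin(az) * B)
    d /= np.linalg.norm(d)
    u = np.cross(d, T)
    nu = np.linalg.norm(u)
    if nu < np.sin(np.deg2rad(5.0)):
        raise ValueError("needle direction is (nearly) parallel to the nerve tangent")
    u /= nu
    # u is perpendicular to both d and T, so offsetting the axis along u keeps
    # C the stationary closest-approach point of the centerline to the axis.
    lateral_ref = -u  # needle at +lateral means nerve sits on the -u side
    foot = C + config.true_lateral_mm * u
    tip = foot - config.true_depth_mm * d
    hub = tip - config.needle_length_mm * d
    n_ax = max(2, int(round(config.n_axial * config.needle_length_mm / config.nerve_length_mm)))
    stations = hub + np.linspace(0.0, 1.0, n_ax + 1)[:, None] * (tip - hub)
    tangents = np.tile(d, (n_ax + 1, 1))
    mesh = _tube_mesh(
        stations, tangents, config.needle_diameter_mm / 2.0, config.n_circumference, "needle"
    )
    return mesh, tip, d, lateral_ref


def _trial_rng(config_seed: int, trial_id: str, seed: int | None) -> np.random.Generator:
    entropy = seed if seed is not None else config_seed
    return np.random.default_rng(
        np.random.SeedSequence([int(entropy) & 0xFFFFFFFF, zlib.crc32(trial_id.encode())])
    )


def _random_pose(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rot_deg)) if max_rot_deg > 0 else 0.0
    trans = rng.uniform(-max_trans_mm, max_trans_mm, 3) if max_trans_mm > 0 else np.zeros(3)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    return RigidTransform(R, trans)


def _noisy(mesh: TriMesh, sd: float, rng: np.random.Generator) -> TriMesh:
    if sd <= 0:
        return mesh
    disp = sd * rng.standard_normal((len(mesh.vertices), 1)) * mesh.vertex_normals()
    return TriMesh(vertices=mesh.vertices + disp, faces=mesh.faces.copy(), name=mesh.name)


def generate_trial(config: SynthConfig, trial_id: str, seed: int | None = None) -> TrialRecord:
    """One synthetic trial: posed, optionally noisy meshes plus ground truth.

    The per-trial rigid pose simulates the per-scan coordinate frame; surface
    noise is applied after posing, along vertex normals. Identical
    ``(config, trial_id, seed)`` yield a bitwise-identical record.
    """
    rng = _trial_rng(config.seed, trial_id, seed)
    nerve, centerline = generate_nerve(config)
    needle, tip, d, lateral_ref = generate_needle(config, centerline)

    pose = _random_pose(rng, config.pose_jitter_rot_deg, config.pose_jitter_trans_mm)
    nerve = TriMesh(pose.apply(nerve.vertices), nerve.faces, nerve.name)
    needle = TriMesh(pose.apply(needle.vertices), needle.faces, needle.name)
    centerline = pose.apply(centerline)
    tip = pose.apply(tip)
    d = pose.rotation @ d
    lateral_ref = pose.rotation @ lateral_ref

    marks_true = LandmarkSet({n: pose.apply(p) for n, p in _LANDMARK_BASE.items()})
    if config.landmark_noise_sd_mm > 0:
        marks = LandmarkSet(
            {
                n: p + config.landmark_noise_sd_mm * rng.standard_normal(3)
                for n, p in marks_true.landmarks.items()
            }
        )
    else:
        marks = LandmarkSet(dict(marks_true.landmarks))

    nerve = _noisy(nerve, config.surface_noise_sd_mm, rng)
    needle = _noisy(needle, config.surface_noise_sd_mm, rng)

    truth = GroundTruth(
        true_lateral_mm=config.true_lateral_mm,
        true_depth_mm=config.true_depth_mm,
        true_euclidean_mm=float(np.hypot(config.true_lateral_mm, config.true_depth_mm)),
        nerve_centerline=centerline,
        applied_pose=pose,
        landmark_truth=marks_true,
        tip_point=tip,
        needle_direction=d,
        lateral_ref=lateral_ref,
    )
    return TrialRecord(trial_id=trial_id, nerve=nerve, needle=needle, landmarks=marks, truth=truth)


def generate_cohort(config: SynthConfig, n_trials: int, seed: int | None = None) -> list[TrialRecord]:
    """Independent trials; offsets fixed, or drawn per trial when the
    ``lateral_sd_mm`` / ``depth_sd_mm`` fields are positive."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base_seed = seed if seed is not None else config.seed
    offset_rng = np.random.default_rng(
        np.random.SeedSequence([int(base_seed) & 0xFFFFFFFF, 0xC0FFEE])
    )
    records = []
    for i in range(n_trials):
        cfg = config
        if config.lateral_sd_mm > 0 or config.depth_sd_mm > 0:
            lat = config.true_lateral_mm + config.lateral_sd_mm * offset_rng.standard_normal()
            dep = config.true_depth_mm + config.depth_sd_mm * offset_rng.standard_normal()
            cfg = replace(config, true_lateral_mm=float(lat), true_depth_mm=float(dep))
        records.append(generate_trial(cfg, f"trial_{i:03d}", seed=base_seed))
    return records


def write_cohort(records: Sequence[TrialRecord], outdir) -> None:
    """Write STL pairs, per-trial landmark CSVs and a ground-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["trial_id,true_lateral_mm,true_depth_mm,true_euclidean_mm"]
    for rec in records:
        write_stl(rec.nerve, outdir / f"{rec.trial_id}_nerve.stl")
        write_stl(rec.needle, outdir / f"{rec.trial_id}_needle.stl")
        if rec.landmarks is not None:
            rec.landmarks.to_csv(outdir / f"{rec.trial_id}_landmarks.csv")
        if rec.truth is not None:
            t = rec.truth
            rows.append(
                f"{rec.trial_id},{t.true_lateral_mm!r},{t.true_depth_mm!r},{t.true_euclidean_mm!r}"
            )
    if len(rows) > 1:
        (outdir / "ground_truth.csv").write_text("\n".join(rows) + "\n")


def distance_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (segments, not vertices)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a = polyline[:-1]
    ab = polyline[1:] - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    # prefilter with vertex KD-tree: nearest segment is near the nearest vertex
    tree = cKDTree(polyline)
    d_vert, idx = tree.query(points, workers=-1)
    out = np.empty(len(points))
    n_seg = len(a)
    for k, (p, i0) in enumerate(zip(points, idx)):
        lo = max(0, i0 - 2)
        hi = min(n_seg, i0 + 2)
        seg = slice(lo, hi)
        ap = p - a[seg]
        t = np.clip(np.einsum("ij,ij->i", ap, ab[seg]) / ab2[seg], 0.0, 1.0)
        proj = a[seg] + t[:, None] * ab[seg]
        out[k] = min(float(np.linalg.norm(p - proj, axis=1).min()), float(d_vert[k]))
    return out


def surface_truth(config: SynthConfig, spacing_mm: float = 0.05) -> float:
    """Brute-force surface-referenced oracle for the minimal tip-to-nerve
    distance: noiseless, unposed meshes, exhaustive nearest-neighbor minimum
    between the needle's outermost active-tip samples and the nerve surface.

    Independent of the metrics module (KD-tree nearest neighbor only).
    """
    cfg = replace(
        config,
        surface_noise_sd_mm=0.0,
        pose_jitter_rot_deg=0.0,
        pose_jitter_trans_mm=0.0,
    )
    nerve, centerline = generate_nerve(cfg)
    needle, tip, d, _ = generate_needle(cfg, centerline)
    nerve_pts = sample_surface(nerve, spacing_mm).points
    needle_pts = sample_surface(needle, spacing_mm).points
    s = (needle_pts - tip) @ d  # axial coordinate, 0 at the tip, negative behind
    tip_pts = needle_pts[s >= s.max() - 5.0]
    dist, _ = cKDTree(nerve_pts).query(tip_pts, workers=-1)
    return float(dist.min())
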