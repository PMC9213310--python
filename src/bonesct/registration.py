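"""Rigid initialization of CT-to-MR alignment from bone surfaces.

Bone masks are turned into surface point clouds in physical (mm) space and
aligned by iterative closest point (ICP): alternate nearest-neighbour
correspondence with a closed-form least-squares rigid fit (cross-covariance
SVD with a reflection guard).  Volumes are then resampled onto the fixed
grid with cubic B-spline interpolation (nearest-neighbour for masks).

Only this rigid initialization is implemented; a subsequent deformable
stage can be plugged in externally between registration and evaluation.
All geometry is computed in mm so anisotropic voxels never bias distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform",
    "SurfaceCloud",
    "mask_to_surface",
    "icp_rigid",
    "resample",
    "registration_residual",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation in physical mm space, moving -> fixed.

    ``apply`` maps moving-space points into fixed space:
    ``x_fixed = R @ x_moving + t``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper rotation (det = +1)")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(cls, angles_deg=(0.0, 0.0, 0.0), translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from extrinsic x-y-z Euler angles in degrees and a mm shift."""
        ax, ay, az = np.deg2rad(angles_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.as_matrix().tolist(), "direction": "moving->fixed"}, fh)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_matrix(np.array(json.load(fh)["matrix"]))


@dataclass(frozen=True)
class SurfaceCloud:
    """Surface points in physical mm coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if p.size == 0:
            raise ValueError("empty surface cloud")
        if not np.isfinite(p).all():
            raise ValueError("surface cloud contains non-finite coordinates")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return len(self.points)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def mask_to_surface(mask: np.ndarray, spacing) -> SurfaceCloud:
    """Boundary voxel centers of a binary mask, in mm.

    A voxel is boundary if at least one of its 6 face neighbours is
    outside the mask (voxels on the array border count as boundary).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    interior = ndimage.binary_erosion(mask, _FACE_STRUCT, border_value=0)
    idx = np.argwhere(mask & ~interior)
    return SurfaceCloud(idx * np.asarray(spacing, dtype=float))


def _fit_rigid(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit moving -> fixed (Kabsch, reflection-guarded)."""
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cf - r @ cm)


def _check_nondegenerate(cloud: SurfaceCloud, name: str) -> None:
    p = cloud.points
    if len(p) < 3:
        raise ValueError(f"{name} cloud has fewer than 3 points")
    centered = p - p.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError(f"{name} cloud is collinear/degenerate")


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _icp_once(moving_pts, fixed_pts, tree, init: RigidTransform,
              max_iter: int, tol_mm: float):
    transform = init
    rms_history: list[float] = []
    converged = False
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = transform.apply(moving_pts)
        _, nn = tree.query(moved, k=1)
        transform = _fit_rigid(moving_pts, fixed_pts[nn])
        moved = transform.apply(moving_pts)
        rms = float(np.sqrt(np.mean(np.sum((moved - fixed_pts[nn]) ** 2, axis=1))))
        rms_history.append(rms)
        if abs(prev_rms - rms) < tol_mm:
            converged = True
            break
        prev_rms = rms
    return transform, rms_history, converged


DEFAULT_START_ANGLES = (0.0, -10.0, 10.0, -20.0, 20.0, -30.0, 30.0)


def icp_rigid(
    moving: SurfaceCloud,
    fixed: SurfaceCloud,
    max_iter: int = 100,
    tol_mm: float = 1e-3,
    start_angles_deg=DEFAULT_START_ANGLES,
) -> tuple[RigidTransform, dict]:
    """Iterative closest point: rigidly align ``moving`` onto ``fixed``.

    Each iteration matches every (transformed) moving point to its
    nearest fixed point and refits the full transform in closed form
    (Kabsch); iteration stops when the RMS correspondence distance
    changes by less than ``tol_mm``.

    Initialization matters for tubular bone surfaces: the translation is
    seeded by centroid alignment, and because residual rotation about the
    bone's long axis is the classic shallow local minimum, ICP is
    restarted from a small set of rotations (``start_angles_deg``) about
    the fixed cloud's principal axis and the start with the lowest final
    RMS wins.  Ties in nearest neighbours are broken towards the lowest
    fixed-point index, so runs are fully deterministic.

    Returns the transform and an info dict with the winning start's
    per-iteration RMS history, final RMS and a convergence flag.
    """
    _check_nondegenerate(moving, "moving")
    _check_nondegenerate(fixed, "fixed")
    tree = cKDTree(fixed.points)
    cf = fixed.points.mean(axis=0)
    cm = moving.points.mean(axis=0)
    centered = fixed.points - cf
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    principal = vt[0]
    best = None
    for angle in start_angles_deg:
        r0 = _axis_rotation(principal, angle)
        init = RigidTransform(r0, cf - r0 @ cm)
        candidate = _icp_once(moving.points, fixed.points, tree, init,
                              max_iter, tol_mm)
        if best is None or candidate[1][-1] < best[1][-1]:
            best = candidate
    transform, rms_history, converged = best
    if not converged:
        warnings.warn("ICP reached max_iter without converging; returning best transform",
                      stacklevel=2)
    return transform, {"rms_history": rms_history,
                       "rms": rms_history[-1] if rms_history else 0.0,
                       "converged": converged,
                       "n_iter": len(rms_history)}


def resample(
    volume: np.ndarray,
    transform: RigidTransform,
    moving_spacing,
    target_shape,
    target_spacing,
    interpolation: str = "bspline",
    background: float = 0.0,
) -> np.ndarray:
    """Resample a moving-space volume onto a fixed (target) grid.

    ``transform`` maps moving coordinates to fixed coordinates, so the
    value at fixed-grid point x is sampled from the moving volume at
    T^{-1}(x).  Images use cubic B-spline interpolation; masks should use
    ``interpolation='nearest'``.  Out-of-field voxels are filled with
    ``background`` (use -1024 for CT, 0 for MR and masks).
    """
    orders = {"bspline": 3, "linear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    inv = transform.inverse()
    sp_m = np.asarray(moving_spacing, dtype=float)
    sp_f = np.asarray(target_spacing, dtype=float)
    # index_moving = diag(1/sp_m) (R_inv diag(sp_f) index_fixed + t_inv)
    matrix = (inv.rotation * sp_f[np.newaxis, :]) / sp_m[:, np.newaxis]
    offset = inv.translation / sp_m
    return ndimage.affine_transform(
        np.asarray(volume, dtype=float),
        matrix,
        offset=offset,
        output_shape=tuple(target_shape),
        order=orders[interpolation],
        mode="grid-constant",
        cval=background,
    )


def registration_residual(transform: RigidTransform, moving: SurfaceCloud,
                          fixed: SurfaceCloud) -> float:
    """RMS nearest-neighbour distance (mm) after applying ``transform``."""
    tree = cKDTree(fixed.points)
    dists, _ = tree.query(transform.apply(moving.points), k=1)
    return float(np.sqrt(np.mean(dists**2)))
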