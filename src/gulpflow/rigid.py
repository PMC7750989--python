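"""Rigid-body kinematics in a skull-fixed anatomical frame.

The braincase (neurocranium) serves as the reference body: all cranial
motion and the food marker are re-expressed relative to it, in an
anatomical coordinate system whose origin is the rostral-most midline tip
of the neurocranium and whose axes are rostrocaudal (positive caudal),
dorsoventral and mediolateral. Axis order everywhere is (rc, dv, ml).

Rigid transforms map reference-configuration coordinates to current
coordinates: ``x_cur = R @ x_ref + t``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    InsufficientMarkersError,
    NoIntersectionError,
    ValidationError,
)
from .io import MarkerTrackSet

_ORTHO_TOL = 1e-9
_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform (rotation + translation, mm)."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValidationError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation is improper (det < 0)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])


class RigidMotionSeries:
    """Per-frame rigid transforms for one body, with explicit gap frames.

    Stored as stacked arrays ``R (n,3,3)``, ``t (n,3)`` plus a validity
    mask; a gap frame means fewer than three of the body's markers were
    visible that frame (or a gap propagated from the reference body).
    """

    def __init__(self, body_id: str, R: np.ndarray, t: np.ndarray,
                 valid: np.ndarray, reference: str = "world"):
        self.body_id = body_id
        self.R = np.asarray(R, dtype=float)
        self.t = np.asarray(t, dtype=float)
        self.valid = np.asarray(valid, dtype=bool)
        self.reference = reference
        n = len(self.valid)
        if self.R.shape != (n, 3, 3) or self.t.shape != (n, 3):
            raise ValidationError("inconsistent series shapes")

    def __len__(self) -> int:
        return len(self.valid)

    def transform(self, frame: int) -> RigidTransform:
        if not self.valid[frame]:
            raise ValidationError(f"frame {frame} is a gap for body {self.body_id!r}")
        return RigidTransform(self.R[frame], self.t[frame])

    @classmethod
    def identity(cls, body_id: str, n: int, reference: str = "world") -> "RigidMotionSeries":
        return cls(body_id, np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
                   np.zeros((n, 3)), np.ones(n, dtype=bool), reference)


def fit_rigid_transform(ref_points: np.ndarray, cur_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of matched 3D point sets.

    Orthogonal-Procrustes (Kabsch) solution via SVD of the cross-covariance
    with reflection correction: the returned rotation is proper and
    minimizes ``sum ||R @ ref + t - cur||^2``. Pairs where either point is
    missing (NaN) are dropped; at least three non-collinear pairs must
    remain.
    """
    ref = np.asarray(ref_points, dtype=float)
    cur = np.asarray(cur_points, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValidationError("ref and cur must be matched (n, 3) arrays")
    ok = ~(np.isnan(ref).any(axis=1) | np.isnan(cur).any(axis=1))
    ref, cur = ref[ok], cur[ok]
    if len(ref) < 3:
        raise InsufficientMarkersError(f"only {len(ref)} usable point pairs (need >= 3)")

    ref_c = ref.mean(axis=0)
    cur_c = cur.mean(axis=0)
    A = ref - ref_c
    B = cur - cur_c
    H = A.T @ B  # cross-covariance
    U, s, Vt = np.linalg.svd(H)
    # collinearity: the two largest singular values must both carry spread
    scale = max(s[0], 1.0)
    if s[1] / scale < _COLLINEAR_TOL:
        raise DegenerateGeometryError("marker configuration is collinear (rank < 2)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cur_c - R @ ref_c
    return RigidTransform(R, t)


def body_motion_from_markers(
    tracks: MarkerTrackSet,
    body_def: Mapping[str, list[str]],
    ref_frame: int = None,
) -> dict[str, RigidMotionSeries]:
    """Estimate per-frame world motion for each body from its markers.

    ``body_def`` maps body name -> marker names (>= 3 each). The reference
    configuration is the marker layout at ``ref_frame`` (default: the first
    frame where every marker of the body is visible). Frames with fewer
    than three visible markers become gaps.
    """
    out = {}
    n = tracks.n_frames
    for body, markers in body_def.items():
        if len(markers) < 3:
            raise ValidationError(f"body {body!r} has {len(markers)} markers (need >= 3)")
        for m in markers:
            if m not in tracks:
                raise ValidationError(f"body {body!r} references unknown marker {m!r}")
        pts = np.stack([tracks.get(m) for m in markers], axis=1)  # (n, k, 3)
        vis = ~np.isnan(pts).any(axis=2)  # (n, k)
        if ref_frame is None:
            full = np.nonzero(vis.all(axis=1))[0]
            if len(full) == 0:
                raise InsufficientMarkersError(
                    f"body {body!r}: no frame with all markers visible"
                )
            rf = int(full[0])
        else:
            rf = int(ref_frame)
            if not vis[rf].all():
                raise InsufficientMarkersError(
                    f"body {body!r}: reference frame {rf} has missing markers"
                )
        ref = pts[rf]
        R = np.full((n, 3, 3), np.nan)
        t = np.full((n, 3), np.nan)
        valid = np.zeros(n, dtype=bool)
        for f in range(n):
            if vis[f].sum() < 3:
                continue
            tr = fit_rigid_transform(ref[vis[f]], pts[f][vis[f]])
            R[f], t[f] = tr.rotation, tr.translation
            valid[f] = True
        out[body] = RigidMotionSeries(body, R, t, valid, reference="world")
    return out


def express_relative(body: RigidMotionSeries, reference: RigidMotionSeries) -> RigidMotionSeries:
    """Re-express a body's motion relative to a reference body.

    Per frame: ``T_rel = T_ref^-1 ∘ T_body``. Gaps in either series
    propagate. A body expressed relative to itself is the identity at every
    valid frame.
    """
    if len(body) != len(reference):
        raise AlignmentError(
            f"length mismatch: body {len(body)} vs reference {len(reference)}"
        )
    n = len(body)
    valid = body.valid & reference.valid
    R = np.full((n, 3, 3), np.nan)
    t = np.full((n, 3), np.nan)
    Rr = reference.R
    # R_rel = R_ref^T R_body ; t_rel = R_ref^T (t_body - t_ref)
    RrT = np.swapaxes(Rr, 1, 2)
    R[valid] = np.einsum("nij,njk->nik", RrT[valid], body.R[valid])
    t[valid] = np.einsum("nij,nj->ni", RrT[valid], body.t[valid] - reference.t[valid])
    return RigidMotionSeries(body.body_id, R, t, valid, reference=reference.body_id)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Skull-fixed anatomical coordinate system of one individual.

    ``origin`` is the rostral-most midline tip of the neurocranium in the
    neurocranium's reference configuration (mm); ``axes`` holds the unit
    rostrocaudal (positive caudal), dorsoventral and mediolateral direction
    vectors as columns.
    """

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3), columns = (rc, dv, ml)

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        A = np.asarray(self.axes, dtype=float)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)
        if A.shape != (3, 3) or not np.allclose(A.T @ A, np.eye(3), atol=1e-6):
            raise ValidationError("axes must be a 3x3 orthonormal triad (columns)")

    @classmethod
    def canonical(cls) -> "AnatomicalFrame":
        """Origin at zero, axes aligned with the coordinate axes."""
        return cls(np.zeros(3), np.eye(3))

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map points from reference-configuration coords to anatomical coords."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.axes.T + self.origin


def food_in_anatomical_frame(
    food_world: np.ndarray,
    neuro_motion: RigidMotionSeries,
    frame_def: AnatomicalFrame,
) -> np.ndarray:
    """Map a world-space food point series into the anatomical frame.

    Removes the neurocranium's world motion (``x_ref = R^T (x - t)``) and
    then applies the anatomical origin/axes. Gaps in either input become
    NaN rows; invariant under any common rigid transform applied to both
    the food and the neurocranium series.
    """
    food = np.asarray(food_world, dtype=float)
    if len(food) != len(neuro_motion):
        raise AlignmentError(
            f"length mismatch: food {len(food)} vs neurocranium {len(neuro_motion)}"
        )
    n = len(food)
    out = np.full((n, 3), np.nan)
    ok = neuro_motion.valid & ~np.isnan(food).any(axis=1)
    RT = np.swapaxes(neuro_motion.R, 1, 2)
    ref_coords = np.einsum("nij,nj->ni", RT[ok], food[ok] - neuro_motion.t[ok])
    out[ok] = frame_def.to_frame(ref_coords)
    return out


@dataclass(frozen=True)
class EsophagusPlane:
    """Best-fit plane through esophageal-sphincter landmarks.

    Plane equation: ``normal . x = offset`` (mm). ``rostrocaudal_distance``
    is filled by :func:`esophagus_threshold`.
    """

    normal: np.ndarray  # (3,), unit
    offset: float
    rostrocaudal_distance: float | None = None
    rms_residual: float = 0.0

    def __post_init__(self):
        nrm = np.asarray(self.normal, dtype=float).reshape(3)
        object.__setattr__(self, "normal", nrm)
        if not np.isclose(np.linalg.norm(nrm), 1.0, atol=1e-9):
            raise ValidationError("plane normal must be unit length")

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Signed perpendicular distances (mm)."""
        return np.asarray(points) @ self.normal - self.offset


def fit_plane(points: np.ndarray) -> EsophagusPlane:
    """Total-least-squares plane through >= 3 non-collinear 3D points.

    Minimizes perpendicular distances (SVD of the centered point cloud).
    The normal is oriented so its rostrocaudal (first-axis) component is
    non-negative; with a zero rc component, dorsoventral then mediolateral
    components break the tie.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[~np.isnan(pts).any(axis=1)]
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 finite 3D points")
    c = pts.mean(axis=0)
    X = pts - c
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < _COLLINEAR_TOL:
        raise DegenerateGeometryError("landmarks are collinear; plane is undetermined")
    normal = Vt[2]
    for comp in normal:  # orient deterministically, rc component first
        if abs(comp) > 1e-12:
            if comp < 0:
                normal = -normal
            break
    offset = float(normal @ c)
    rms = float(np.sqrt(np.mean((X @ normal) ** 2)))
    return EsophagusPlane(normal / np.linalg.norm(normal), offset, None, rms)


def esophagus_threshold(
    plane: EsophagusPlane,
    frame_def: AnatomicalFrame,
    mode: str = "along_axis",
) -> float:
    """Rostrocaudal location of the esophageal sphincter (mm).

    ``along_axis`` (default): distance from the anatomical origin to the
    point where the midline rostrocaudal axis ray pierces the plane —
    consistent with normalizing food position to 0 at the jaws and 1 at
    the esophagus along that axis. ``perpendicular``: unsigned
    point-to-plane distance from the origin.
    """
    rc_axis = frame_def.axes[:, 0]
    if mode == "perpendicular":
        return float(abs(plane.distance(frame_def.origin[None, :])[0]))
    if mode != "along_axis":
        raise ValidationError(f"unknown mode {mode!r}")
    denom = float(plane.normal @ rc_axis)
    if abs(denom) < 1e-9:
        raise NoIntersectionError("plane is parallel to the rostrocaudal axis")
    tval = (plane.offset - float(plane.normal @ frame_def.origin)) / denom
    if tval <= 0:
        raise NoIntersectionError(
            "plane pierces the rostrocaudal axis rostral of the origin"
        )
    return float(tval)
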