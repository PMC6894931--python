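"""Manipulator/microscope coordinate registration and pipette positioning.

Conventions: right-handed coordinates, z up, micrometres, with the
microscope/stage frame canonical.  Each manipulator frame is related to it
by a proper rigid transform estimated from >=3 matched reference points
(Kabsch / orthogonal Procrustes with the reflection excluded).  Pipettes
approach the tissue along their longitudinal axis, which is defined by an
azimuth (horizontal bearing toward the chamber centre) and an approach
angle above the horizontal; 27 degrees is a good compromise between x-range
and the ability to clear the recording-well wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InvalidArgumentError, InvalidPoseError, PathInfeasibleError

__all__ = [
    "RigidTransform",
    "PipettePose",
    "WellGeometry",
    "TargetPlan",
    "fit_rigid_transform",
    "plan_targets",
    "approach_path",
    "reachability",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map p -> R @ p + t from manipulator to microscope frame."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), um
    residual_rms: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise InvalidArgumentError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidArgumentError("reflections are not valid rig transforms")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_scope(self, p_manip) -> np.ndarray:
        """Map manipulator-frame point(s) into the microscope frame."""
        p = np.asarray(p_manip, dtype=float)
        return p @ self.rotation.T + self.translation

    def to_manip(self, p_scope) -> np.ndarray:
        """Inverse map, microscope frame back to the manipulator frame."""
        p = np.asarray(p_scope, dtype=float)
        return (p - self.translation) @ self.rotation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def fit_rigid_transform(manip_points, scope_points) -> RigidTransform:
    """Least-squares proper rigid transform mapping manipulator points onto scope points.

    Kabsch algorithm: SVD of the cross-covariance of the centred point sets
    with the determinant sign corrected so a reflection is never returned.
    Requires >=3 non-collinear correspondences.
    """
    P = np.atleast_2d(np.asarray(manip_points, dtype=float))
    Q = np.atleast_2d(np.asarray(scope_points, dtype=float))
    if P.shape != Q.shape or P.shape[1] != 3:
        raise InvalidArgumentError(f"point sets must both be (N, 3), got {P.shape} and {Q.shape}")
    if P.shape[0] < 3:
        raise InvalidArgumentError("at least 3 point correspondences are required")
    p_mean = P.mean(axis=0)
    q_mean = Q.mean(axis=0)
    Pc = P - p_mean
    Qc = Q - q_mean
    # collinear points leave the rotation about the line unconstrained
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, float(np.abs(Pc).max()))) < 2:
        raise DegenerateGeometryError("manipulator reference points are collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    resid = Q - (P @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(R, t, residual_rms=rms)


@dataclass(frozen=True)
class PipettePose:
    """Home pose of one pipette: tip position plus axis orientation.

    ``azimuth_deg`` is the horizontal bearing of forward (advancing) tip
    motion, i.e. pointing from the pipette toward the chamber centre;
    ``approach_deg`` the angle of the axis above horizontal (advancing
    lowers the tip).
    """

    id: int
    tip: np.ndarray  # um, microscope frame
    azimuth_deg: float
    approach_deg: float = 27.0

    def __post_init__(self):
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float).reshape(3))
        if not 0.0 < self.approach_deg < 90.0:
            raise InvalidPoseError(
                f"approach angle must be in (0, 90) deg, got {self.approach_deg}"
            )

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of forward tip motion (descending along the pipette)."""
        az = math.radians(self.azimuth_deg)
        al = math.radians(self.approach_deg)
        return np.array(
            [math.cos(az) * math.cos(al), math.sin(az) * math.cos(al), -math.sin(al)]
        )


@dataclass(frozen=True)
class WellGeometry:
    """Recording chamber: inner recording well ringed by the cleaning well."""

    inner_radius_um: float
    wall_height_um: float  # wall top above the slice surface
    outer_ring_inner_um: float
    outer_ring_outer_um: float
    slice_surface_z_um: float = 0.0
    center: tuple = (0.0, 0.0)

    def __post_init__(self):
        if not (0 < self.inner_radius_um <= self.outer_ring_inner_um < self.outer_ring_outer_um):
            raise InvalidArgumentError("outer cleaning ring must enclose the inner well")
        if self.wall_height_um < 0:
            raise InvalidArgumentError("wall height must be >= 0")


@dataclass
class TargetPlan:
    targets: dict  # pipette id -> (3,) target, um
    min_pairwise_um: float
    clearance_um: float
    collision: bool
    order: list = field(default_factory=list)  # pipette ids by assigned sector


def plan_targets(
    n_pipettes: int,
    roi_center,
    spread_radius_um: float,
    poses,
    stage_height_um: float = 200.0,
    slice_surface_z_um: float = 0.0,
    clearance_um: float = 20.0,
) -> TargetPlan:
    """Assign staging targets on a circle around the region of interest.

    Targets sit ``stage_height_um`` above the slice surface (default 200 um)
    on a circle of ``spread_radius_um`` around ``roi_center``; each pipette
    takes the angular sector nearest its home azimuth (ties broken by id),
    so the assignment is independent of input ordering.  A collision flag is
    raised when any pairwise target distance falls below ``clearance_um``.
    """
    if spread_radius_um < 0:
        raise InvalidArgumentError("spread_radius_um must be >= 0")
    poses = sorted(poses, key=lambda p: (p.azimuth_deg % 360.0, p.id))[:n_pipettes]
    if len(poses) < n_pipettes:
        raise InvalidArgumentError(f"need {n_pipettes} poses, got {len(poses)}")
    azimuths = [p.azimuth_deg % 360.0 for p in poses]
    if len(set(azimuths)) != len(azimuths):
        raise InvalidPoseError("pipette azimuths must be pairwise distinct")
    roi = np.asarray(roi_center, dtype=float).reshape(3)
    z = slice_surface_z_um + stage_height_um
    n = n_pipettes
    # evenly spaced sectors phased to the first (smallest) azimuth: for
    # evenly distributed home azimuths every pipette gets exactly its own
    phase = azimuths[0]
    targets = {}
    order = []
    for i, pose in enumerate(poses):
        ang = math.radians(phase + 360.0 * i / n)
        targets[pose.id] = roi + np.array(
            [spread_radius_um * math.cos(ang), spread_radius_um * math.sin(ang), z - roi[2]]
        )
        order.append(pose.id)
    pts = np.array([targets[i] for i in order])
    if n >= 2:
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        min_d = float(d[np.triu_indices(n, k=1)].min())
    else:
        min_d = math.inf
    return TargetPlan(
        targets=targets,
        min_pairwise_um=min_d,
        clearance_um=clearance_um,
        collision=min_d < clearance_um,
        order=order,
    )


def approach_path(pose: PipettePose, target) -> list:
    """Waypoints from the pose's tip to ``target``, ending axis-parallel.

    The final segment runs along the pipette's longitudinal axis so the tip
    enters the tissue without lateral shear; any preceding motion happens at
    the starting z (free space above the slice).  Raises
    :class:`PathInfeasibleError` when the target is not below the tip.
    """
    target = np.asarray(target, dtype=float).reshape(3)
    tip = pose.tip
    dz = tip[2] - target[2]
    if dz <= 0:
        raise PathInfeasibleError("target must lie below the current tip position")
    axis = pose.axis
    # entry point: on the approach line through the target, at the tip's z
    s = dz / -axis[2]
    entry = target - axis * s
    if np.linalg.norm(entry - tip) < 1e-9:
        return [tip.copy(), target.copy()]
    return [tip.copy(), entry, target.copy()]


@dataclass
class Reachability:
    reachable: bool
    limiting_constraint: str | None
    standoff_um: float  # horizontal distance from wall to target along approach
    required_um: float  # wall clearance needed at this approach angle

    def __bool__(self) -> bool:
        return self.reachable


def reachability(pose: PipettePose, well: WellGeometry, target) -> Reachability:
    """Can a straight axis-aligned descent clear the well wall and hit ``target``?

    The pipette crosses the wall top edge and then descends at the approach
    angle; the target is reachable iff its horizontal distance from the wall
    (along the approach direction) is at least
    ``(wall_top_z - target_z) / tan(approach_angle)``.
    """
    target = np.asarray(target, dtype=float).reshape(3)
    cx, cy = well.center
    rel = target[:2] - np.array([cx, cy])
    if np.linalg.norm(rel) >= well.inner_radius_um:
        raise InvalidArgumentError("target must lie inside the inner well")
    # horizontal ray from the target back toward the pipette home
    u = -pose.axis[:2]
    nu = np.linalg.norm(u)
    u = u / nu if nu > 0 else np.array([1.0, 0.0])
    # solve |rel + t*u| = inner_radius for t > 0
    b = float(rel @ u)
    c = float(rel @ rel) - well.inner_radius_um**2
    t = -b + math.sqrt(b * b - c)
    standoff = t
    drop = (well.slice_surface_z_um + well.wall_height_um) - target[2]
    if drop <= 0:
        return Reachability(True, None, standoff, 0.0)
    required = drop / math.tan(math.radians(pose.approach_deg))
    if standoff >= required:
        return Reachability(True, None, standoff, required)
    return Reachability(False, "wall clearance", standoff, required)
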