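"""Tibiofemoral pose representation and rigid-body transforms.

Frame convention (right knee, used everywhere in this package):

* ``x`` — anterior (+)
* ``y`` — superior (+)
* ``z`` — lateral (+); medial structures therefore have negative ``z``

Both the tibial and the femoral body frame share this axis convention; the
tibial frame is the ground frame and its origin is the knee center on the
tibial joint line.  A :class:`JointPose` describes the femoral frame relative
to the tibial frame with six degrees of freedom: a prescribed flexion angle,
two secondary rotations (varus/valgus, internal/external) and three
translations.

Rotation decomposition
----------------------
The femoral orientation is composed intrinsically as

    R = Rz(flexion) @ Rx(-varus_valgus) @ Ry(-internal_external)

(angles in degrees in the dataclass, radians internally).  Signs are chosen
so that

* positive flexion tilts the femoral shaft posteriorly,
* positive varus_valgus (varus) lowers the medial femoral condyle,
  closing the medial compartment gap,
* positive internal_external means tibial internal rotation (equivalently
  femoral external rotation for this right knee).

The translation maps the femoral origin into the tibial frame:
``t = (ap_translation, si_translation, -ml_translation)`` — anterior,
superior and medial femoral translation are positive.

The decomposition is a fixed Z-X-Y Euler sequence and is invertible
(`pose_from_transform`) away from the gimbal singularity at
varus_valgus = +/-90 deg, far outside the physiologic range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "JointPose",
    "pose_transform",
    "pose_from_transform",
    "transform_points",
    "mirror_pose",
]


@dataclass(frozen=True)
class JointPose:
    """6-DOF femoral pose relative to the tibia (degrees / mm)."""

    flexion: float = 0.0
    varus_valgus: float = 0.0
    internal_external: float = 0.0
    ap_translation: float = 0.0
    ml_translation: float = 0.0
    si_translation: float = 0.0

    def secondary_dofs(self) -> np.ndarray:
        """The five solved DOFs as (ap, ml, si, vv, ie)."""
        return np.array(
            [
                self.ap_translation,
                self.ml_translation,
                self.si_translation,
                self.varus_valgus,
                self.internal_external,
            ]
        )

    def with_secondary(self, dofs: np.ndarray) -> "JointPose":
        ap, ml, si, vv, ie = (float(v) for v in dofs)
        return replace(
            self,
            ap_translation=ap,
            ml_translation=ml,
            si_translation=si,
            varus_valgus=vv,
            internal_external=ie,
        )

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.secondary_dofs())) and np.isfinite(self.flexion))


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def pose_transform(pose: JointPose) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation of the femoral frame in the tibial frame."""
    f = np.deg2rad(pose.flexion)
    v = np.deg2rad(pose.varus_valgus)
    e = np.deg2rad(pose.internal_external)
    R = _rz(f) @ _rx(-v) @ _ry(-e)
    t = np.array([pose.ap_translation, pose.si_translation, -pose.ml_translation])
    return R, t


def pose_from_transform(R: np.ndarray, t: np.ndarray) -> JointPose:
    """Invert :func:`pose_transform` (Z-X-Y intrinsic Euler extraction)."""
    b = np.arcsin(np.clip(R[2, 1], -1.0, 1.0))
    a = np.arctan2(-R[0, 1], R[1, 1])
    c = np.arctan2(-R[2, 0], R[2, 2])
    return JointPose(
        flexion=float(np.rad2deg(a)),
        varus_valgus=float(-np.rad2deg(b)),
        internal_external=float(-np.rad2deg(c)),
        ap_translation=float(t[0]),
        si_translation=float(t[1]),
        ml_translation=float(-t[2]),
    )


def transform_points(points: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Map points (n, 3) or (3,) through a rigid transform."""
    return np.asarray(points) @ R.T + t


def mirror_pose(pose: JointPose) -> JointPose:
    """Pose of the left-right mirrored joint (z -> -z reflection).

    Translations along z and rotations about x and y flip sign; flexion,
    AP and SI components are invariant.
    """
    return replace(
        pose,
        varus_valgus=-pose.varus_valgus,
        internal_external=-pose.internal_external,
        ml_translation=-pose.ml_translation,
    )
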