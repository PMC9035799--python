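"""Two-compartment implant articulation and elastic contact forces.

The articulating surfaces of the cruciate-retaining implant are replaced by
a documented parametric stand-in: each femoral condyle is a sphere of radius
``R_f`` whose center rides on the femoral flexion axis, articulating inside
a dished tibial insert pocket of radius ``R_i > R_f`` (socket center on the
joint line).  This is classical internal sphere-in-socket contact: the
condyle floats freely while its center stays within the radial clearance
``R_i - R_f`` of the pocket center, and once the offset exceeds the
clearance the surfaces overlap elastically,

    depth = max(0, |condyle center - pocket center| - (R_i - R_f))
    F     = K_c * depth**exponent,

with the force on the femur directed from the condyle center back toward
the pocket center (restoring toward concentricity; equal and opposite on
the tibia).  The dish is the lower half of the socket, so contact requires
the condyle center to sit below the pocket center along the tray normal —
under compressive load the condyle center rides ~``R_i - R_f`` below the
pocket center and the contact force points up the tray normal.  The law is
continuous, has no fall-through, and resists tilt and tangential shift the
way a dished insert does.  With the default stiffness (5000 N/mm) operating
overlaps stay below ~0.5 mm at 3 body weights, so the stand-in behaves like
a stiff, frictionless, low-conformity condylar contact.

Compartment forces and their moments about the knee center yield the medial
(MCF) and lateral (LCF) contact forces; the total contact force is their sum
(TCF = MCF + LCF) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import JointPose, pose_transform

__all__ = [
    "ImplantGeometry",
    "ContactParams",
    "ContactResult",
    "penetration",
    "compartment_force",
    "contact_wrench",
    "mirror_model",
]

_MIRROR = np.array([1.0, 1.0, -1.0])


@dataclass(frozen=True)
class ImplantGeometry:
    """Parametric two-compartment articulation (mm, right-knee frame).

    ``condyle_centers`` and ``pocket_centers`` are stacked (medial, lateral)
    rows in the femoral and tibial frames respectively;
    ``compartment_half_spacing`` is the lateral offset of each compartment
    from the sagittal midplane in the default symmetric geometry.
    """

    condyle_radius: float = 24.0
    pocket_radius: float = 26.0
    compartment_half_spacing: float = 22.0
    condyle_centers: np.ndarray = field(default=None)  # type: ignore[assignment]
    pocket_centers: np.ndarray = field(default=None)   # type: ignore[assignment]
    tray_normal: np.ndarray = field(default=None)      # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.pocket_radius > self.condyle_radius > 0:
            raise ValueError(
                f"require pocket_radius > condyle_radius > 0, got "
                f"{self.pocket_radius}, {self.condyle_radius}"
            )
        c = self.compartment_half_spacing
        if self.condyle_centers is None:
            object.__setattr__(
                self, "condyle_centers", np.array([[0.0, 0.0, -c], [0.0, 0.0, c]])
            )
        else:
            object.__setattr__(self, "condyle_centers", np.asarray(self.condyle_centers, float))
        if self.pocket_centers is None:
            object.__setattr__(
                self, "pocket_centers", np.array([[0.0, 0.0, -c], [0.0, 0.0, c]])
            )
        else:
            object.__setattr__(self, "pocket_centers", np.asarray(self.pocket_centers, float))
        if self.tray_normal is None:
            object.__setattr__(self, "tray_normal", np.array([0.0, 1.0, 0.0]))
        else:
            n = np.asarray(self.tray_normal, float)
            object.__setattr__(self, "tray_normal", n / np.linalg.norm(n))

    @property
    def clearance(self) -> float:
        """Radial clearance R_i - R_f [mm]."""
        return self.pocket_radius - self.condyle_radius


@dataclass(frozen=True)
class ContactParams:
    """Pressure-overclosure law: F = stiffness * depth**exponent."""

    stiffness: float = 5000.0   # N/mm
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError(f"contact stiffness must be > 0, got {self.stiffness}")
        if self.exponent < 1:
            raise ValueError(f"contact exponent must be >= 1, got {self.exponent}")


@dataclass(frozen=True)
class ContactResult:
    """Per-compartment contact forces [N]; tcf = mcf + lcf exactly."""

    mcf: float
    lcf: float
    contact_points: np.ndarray   # (2, 3), tibial frame, mm
    penetrations: np.ndarray     # (2,), mm

    @property
    def tcf(self) -> float:
        return self.mcf + self.lcf


_SIDES = {"medial": 0, "lateral": 1}


def _depth_and_normal(
    u: np.ndarray, geometry: ImplantGeometry
) -> tuple[float, np.ndarray]:
    """Elastic overlap depth and contact normal from a center offset vector.

    ``u`` is condyle center minus pocket center in the tibial frame.  The
    surfaces overlap by ``|u| - clearance`` once the offset exceeds the
    radial clearance, provided the condyle center lies in the dished (lower)
    half of the socket; the normal — the direction of the force on the femur
    — points from the condyle center toward the pocket center, i.e. the dish
    pushes the condyle back toward concentricity.
    """
    h = float(u @ geometry.tray_normal)
    if h >= 0.0:
        return 0.0, geometry.tray_normal
    d = float(np.linalg.norm(u))
    depth = max(0.0, d - geometry.clearance)
    if depth == 0.0:
        return 0.0, geometry.tray_normal
    return depth, -u / d


def penetration(
    pose: JointPose, geometry: ImplantGeometry, compartment: str
) -> float:
    """Elastic overlap depth [mm] of one compartment at a pose."""
    i = _SIDES[compartment]
    R, t = pose_transform(pose)
    cc = R @ geometry.condyle_centers[i] + t
    depth, _ = _depth_and_normal(cc - geometry.pocket_centers[i], geometry)
    return float(depth)


def compartment_force(
    depth: float, params: ContactParams, normal: np.ndarray
) -> np.ndarray:
    """Contact force vector [N] on the femur for one compartment."""
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if depth == 0.0:
        return np.zeros(3)
    return params.stiffness * depth**params.exponent * np.asarray(normal, float)


def contact_wrench(
    pose: JointPose, geometry: ImplantGeometry, params: ContactParams
) -> tuple[ContactResult, np.ndarray, np.ndarray]:
    """Contact result plus net force and moment on the femur.

    The moment [N mm] is taken about the knee center (tibial origin).  The
    contact normal of each engaged compartment is the unit vector from the
    condyle center toward the pocket center; the contact point is reported
    halfway between the two centers (the force line of action passes through
    both, so the moment does not depend on this choice).
    """
    R, t = pose_transform(pose)
    cc = geometry.condyle_centers @ R.T + t      # (2, 3) in tibial frame
    pc = geometry.pocket_centers
    force = np.zeros(3)
    moment = np.zeros(3)
    mags = np.zeros(2)
    depths = np.zeros(2)
    points = (cc + pc) / 2.0
    for i in range(2):
        depth, n = _depth_and_normal(cc[i] - pc[i], geometry)
        depths[i] = depth
        if depth == 0.0:
            continue
        f = params.stiffness * depth**params.exponent * n
        mags[i] = float(np.linalg.norm(f))
        force += f
        moment += np.cross(points[i], f)
    result = ContactResult(
        mcf=float(mags[0]), lcf=float(mags[1]), contact_points=points, penetrations=depths
    )
    return result, force, moment


def mirror_model(model):
    """Left-right mirror of a whole knee model (involution).

    Negates the lateral (z) coordinate of every geometric quantity and swaps
    the medial/lateral roles: condyle/pocket rows are exchanged so that row 0
    remains the medial compartment, and bundle side tags swap
    medial <-> lateral.  Imported here to keep the medial/lateral bookkeeping
    in one place; works on :class:`kneesim.model.KneeModel`.
    """
    from .kinematics import mirror_pose
    from .ligaments import mirror_bundle

    geom = model.geometry
    new_geom = replace(
        geom,
        condyle_centers=(geom.condyle_centers * _MIRROR)[::-1].copy(),
        pocket_centers=(geom.pocket_centers * _MIRROR)[::-1].copy(),
        tray_normal=geom.tray_normal * _MIRROR,
    )
    new_bundles = [mirror_bundle(b) for b in model.bundles]
    swap_side = {"medial": "lateral", "lateral": "medial", None: None}
    return replace(
        model,
        geometry=new_geom,
        bundles=new_bundles,
        femoral_vv=-model.femoral_vv,
        tibial_vv=-model.tibial_vv,
        calibration_vv=None if model.calibration_vv is None else -model.calibration_vv,
        calibration_pose=None if model.calibration_pose is None
        else mirror_pose(model.calibration_pose),
        laxity_side=swap_side[model.laxity_side],
        neutral_calibration_pose=None if model.neutral_calibration_pose is None
        else mirror_pose(model.neutral_calibration_pose),
    )
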