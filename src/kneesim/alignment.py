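"""Component coronal alignment and the A-G laxity/alignment variants.

Seven model configurations span the clinically debated 2-degree window of
coronal alignment and gap balance after cruciate-retaining TKA:

=====  ==================  ================  ==========================
label  femoral/tibial vv   calibration vv    meaning
=====  ==================  ================  ==========================
A      0 / 0               0                 neutral, balanced
B      0 / -2              -2                tibial valgus, balanced
C      -2 / 0              -2                femoral valgus, balanced
D      0 / 0               -2                neutral, 2 deg medial laxity
E      0 / +2              +2                tibial varus, balanced
F      +2 / 0              +2                femoral varus, balanced
G      0 / 0               +2                neutral, 2 deg lateral laxity
=====  ==================  ================  ==========================

(varus positive).  Component alignment rotates the *implant geometry* about
the anterior-posterior axis through the component origin (midpoint of the
compartment centers on the joint line); bone-fixed ligament attachments do
not move — re-orienting the bone cut moves the implant, not the ligament
footprints.  Ligament balancing then calibrates all slack lengths at a
seated extension pose of the configured coronal angle: calibrating at 2 deg
valgus and returning the knee to neutral leaves the medial structures slack
(model D), and symmetrically for lateral laxity (model G), reproducing the
leave-2-degrees-of-gap-difference construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinematics import JointPose
from .ligaments import calibrate
from .model import KneeModel
from .solver import seat_extension

__all__ = [
    "AlignmentConfig",
    "VARIANTS",
    "apply_component_alignment",
    "coronal_extension_pose",
    "build_model_variant",
]


@dataclass(frozen=True)
class AlignmentConfig:
    """Component rotations plus the coronal angle of the balancing pose."""

    label: str
    femoral_vv: float
    tibial_vv: float
    calibration_vv: float


#: The seven preset configurations (angles in degrees, varus positive).
VARIANTS: dict[str, AlignmentConfig] = {
    "A": AlignmentConfig("A", 0.0, 0.0, 0.0),
    "B": AlignmentConfig("B", 0.0, -2.0, -2.0),
    "C": AlignmentConfig("C", -2.0, 0.0, -2.0),
    "D": AlignmentConfig("D", 0.0, 0.0, -2.0),
    "E": AlignmentConfig("E", 0.0, 2.0, 2.0),
    "F": AlignmentConfig("F", 2.0, 0.0, 2.0),
    "G": AlignmentConfig("G", 0.0, 0.0, 2.0),
}


def _coronal_rotation(vv_deg: float) -> np.ndarray:
    """Rotation about the AP (x) axis matching the pose varus convention."""
    a = -np.deg2rad(vv_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def apply_component_alignment(model: KneeModel, component: str, vv_deg: float) -> KneeModel:
    """Rotate one component's implant geometry into varus/valgus.

    A varus tibial cut tilts the insert pockets medial-side-down in the
    tibial frame (same sense as the pose varus rotation); a varus femoral
    cut resects more medial distal bone, so the condyle geometry rotates by
    the *inverse* sense in the femoral frame — either way the seated knee
    ends up in ``vv_deg`` of bony varus.  Ligament attachments are bone
    fixed and do not move.
    """
    if abs(vv_deg) > 10:
        raise ValueError(f"|vv_deg| must be <= 10, got {vv_deg}")
    geom = model.geometry
    if component == "tibial":
        rot = _coronal_rotation(vv_deg)
        pivot = geom.pocket_centers.mean(axis=0)
        new_geom = replace(
            geom,
            pocket_centers=(geom.pocket_centers - pivot) @ rot.T + pivot,
            tray_normal=rot @ geom.tray_normal,
        )
        return replace(model, geometry=new_geom, tibial_vv=model.tibial_vv + vv_deg)
    if component == "femoral":
        rot = _coronal_rotation(vv_deg).T   # inverse sense
        pivot = geom.condyle_centers.mean(axis=0)
        new_geom = replace(
            geom, condyle_centers=(geom.condyle_centers - pivot) @ rot.T + pivot
        )
        return replace(model, geometry=new_geom, femoral_vv=model.femoral_vv + vv_deg)
    raise ValueError(f"unknown component {component!r} (expected 'femoral' or 'tibial')")


def coronal_extension_pose(vv_deg: float, model: KneeModel, preload: float = 100.0) -> JointPose:
    """Seated extension pose at a fixed coronal angle (ligaments disabled)."""
    return seat_extension(model, vv_deg, preload=preload)


def build_model_variant(label: str, base_model: KneeModel) -> KneeModel:
    """Apply one A-G preset: align components, then balance ligaments.

    Every bundle is balanced (set to its reference strain) at the seated
    extension pose of the configured coronal angle.  For the aligned
    variants (B, C, E, F) that pose matches the component alignment, so the
    joint operates around it with no residual tightness.  For the
    neutral-alignment laxity variants (D, G) the balancing pose is tilted
    while the components stay neutral: rotating the joint back to neutral
    slackens the bundles on the side the tilt had opened (medial for a
    valgus balancing pose, model D; lateral for a varus pose, model G) and
    pre-tensions the opposite side — the leave-a-2-degree-gap-difference
    construction.

    The returned model carries calibrated slack lengths, the alignment
    metadata and the calibration pose; model A is the base model with
    calibration only.  Laxity variants additionally record the neutral
    seated pose (their operating region) and which side is lax.
    """
    if label not in VARIANTS:
        raise ValueError(f"unknown variant {label!r} (expected one of A-G)")
    cfg = VARIANTS[label]
    m = base_model
    if cfg.femoral_vv != 0.0:
        m = apply_component_alignment(m, "femoral", cfg.femoral_vv)
    if cfg.tibial_vv != 0.0:
        m = apply_component_alignment(m, "tibial", cfg.tibial_vv)
    cal_pose = coronal_extension_pose(cfg.calibration_vv, m)
    bundles = calibrate(m.bundles, cal_pose)
    aligned = cfg.femoral_vv != 0.0 or cfg.tibial_vv != 0.0
    if aligned or cfg.calibration_vv == 0.0:
        laxity_side = None
        neutral_pose = None
    else:
        laxity_side = "medial" if cfg.calibration_vv < 0 else "lateral"
        neutral_pose = coronal_extension_pose(0.0, m)
    return replace(
        m,
        bundles=bundles,
        label=label,
        calibration_vv=cfg.calibration_vv,
        calibration_pose=cal_pose,
        laxity_side=laxity_side,
        neutral_calibration_pose=neutral_pose,
    )
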