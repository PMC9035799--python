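"""The assembled knee model: ligament apparatus + implant articulation.

A :class:`KneeModel` bundles the 21 ligament bundles, the parametric implant
geometry, the contact law and subject parameters, and can be serialized to a
plain YAML document (including calibrated slack lengths and alignment
metadata) for fully reproducible variant files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .contact import ContactParams, ImplantGeometry
from .kinematics import JointPose
from .ligaments import (
    LigamentBundle,
    LigamentParams,
    build_default_bundles,
    load_attachments,
    load_param_table,
)

__all__ = ["KneeModel", "default_model"]

DEFAULT_BODY_MASS_KG = 66.7
GRAVITY = 9.81


@dataclass(frozen=True)
class KneeModel:
    """Ligaments + implant of one (possibly aligned and calibrated) knee."""

    bundles: list[LigamentBundle]
    geometry: ImplantGeometry
    contact: ContactParams
    body_mass: float = DEFAULT_BODY_MASS_KG
    label: str | None = None
    femoral_vv: float = 0.0
    tibial_vv: float = 0.0
    calibration_vv: float | None = None
    calibration_pose: JointPose | None = None
    #: For the neutral-alignment laxity variants: the side left slack at
    #: neutral extension by the tilted balancing pose, plus the neutral
    #: seated pose itself (the variant's operating region, used to seed the
    #: equilibrium solver).
    laxity_side: str | None = None
    neutral_calibration_pose: JointPose | None = None

    @property
    def tibiofemoral_bundles(self) -> list[LigamentBundle]:
        return [b for b in self.bundles if b.is_tibiofemoral]

    @property
    def bundle_names(self) -> list[str]:
        return [b.name for b in self.bundles]

    @property
    def body_weight(self) -> float:
        """Body weight [N]."""
        return self.body_mass * GRAVITY

    def is_calibrated(self) -> bool:
        return all(b.slack_length is not None for b in self.bundles)


    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "body_mass_kg": self.body_mass,
            "label": self.label,
            "alignment": {
                "femoral_vv_deg": self.femoral_vv,
                "tibial_vv_deg": self.tibial_vv,
                "calibration_vv_deg": self.calibration_vv,
            },
            "geometry": {
                "condyle_radius_mm": self.geometry.condyle_radius,
                "pocket_radius_mm": self.geometry.pocket_radius,
                "compartment_half_spacing_mm": self.geometry.compartment_half_spacing,
                "condyle_centers_mm": self.geometry.condyle_centers.tolist(),
                "pocket_centers_mm": self.geometry.pocket_centers.tolist(),
                "tray_normal": self.geometry.tray_normal.tolist(),
            },
            "contact": {
                "stiffness_N_per_mm": self.contact.stiffness,
                "exponent": self.contact.exponent,
            },
            "bundles": {
                b.name: {
                    "side": b.side_tag,
                    "origin": b.origin.tolist(),
                    "insertion": b.insertion.tolist(),
                    "reference_strain": b.params.reference_strain,
                    "stiffness_N": b.params.stiffness,
                    "linear_limit_strain": b.params.linear_limit_strain,
                    "slack_length_mm": None if b.slack_length is None
                    else float(b.slack_length),
                }
                for b in self.bundles
            },
        }
        if self.laxity_side is not None:
            d["laxity_side"] = self.laxity_side
        for key, pose in (
            ("calibration_pose", self.calibration_pose),
            ("neutral_calibration_pose", self.neutral_calibration_pose),
        ):
            if pose is not None:
                d[key] = {
                    "flexion": pose.flexion,
                    "varus_valgus": pose.varus_valgus,
                    "internal_external": pose.internal_external,
                    "ap_translation": pose.ap_translation,
                    "ml_translation": pose.ml_translation,
                    "si_translation": pose.si_translation,
                }
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "KneeModel":
        g = d["geometry"]
        geometry = ImplantGeometry(
            condyle_radius=float(g["condyle_radius_mm"]),
            pocket_radius=float(g["pocket_radius_mm"]),
            compartment_half_spacing=float(g["compartment_half_spacing_mm"]),
            condyle_centers=np.asarray(g["condyle_centers_mm"], float),
            pocket_centers=np.asarray(g["pocket_centers_mm"], float),
            tray_normal=np.asarray(g["tray_normal"], float),
        )
        c = d["contact"]
        contact = ContactParams(
            stiffness=float(c["stiffness_N_per_mm"]), exponent=float(c["exponent"])
        )
        bundles = []
        for name, row in d["bundles"].items():
            params = LigamentParams(
                name="PC" if name.startswith("PC") else name,
                reference_strain=float(row["reference_strain"]),
                stiffness=float(row["stiffness_N"]),
                linear_limit_strain=float(row["linear_limit_strain"]),
            )
            slack = row.get("slack_length_mm")
            bundles.append(
                LigamentBundle(
                    name=name,
                    params=params,
                    origin=np.asarray(row["origin"], float),
                    insertion=np.asarray(row["insertion"], float),
                    side_tag=row["side"],
                    slack_length=None if slack is None else float(slack),
                )
            )
        al = d.get("alignment", {})
        poses = {
            key: JointPose(**d[key]) if key in d else None
            for key in ("calibration_pose", "neutral_calibration_pose")
        }
        return cls(
            bundles=bundles,
            geometry=geometry,
            contact=contact,
            body_mass=float(d.get("body_mass_kg", DEFAULT_BODY_MASS_KG)),
            label=d.get("label"),
            femoral_vv=float(al.get("femoral_vv_deg", 0.0)),
            tibial_vv=float(al.get("tibial_vv_deg", 0.0)),
            calibration_vv=al.get("calibration_vv_deg"),
            calibration_pose=poses["calibration_pose"],
            laxity_side=d.get("laxity_side"),
            neutral_calibration_pose=poses["neutral_calibration_pose"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KneeModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_model(
    body_mass: float = DEFAULT_BODY_MASS_KG,
    param_table=None,
    attachments=None,
    geometry: ImplantGeometry | None = None,
    contact: ContactParams | None = None,
) -> KneeModel:
    """The uncalibrated neutral generic right-knee model with packaged defaults."""
    bundles = build_default_bundles(
        param_table=load_param_table(param_table) if param_table is not None else None,
        attachments=load_attachments(attachments) if attachments is not None else None,
    )
    return KneeModel(
        bundles=bundles,
        geometry=geometry if geometry is not None else ImplantGeometry(),
        contact=contact if contact is not None else ContactParams(),
        body_mass=body_mass,
    )
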