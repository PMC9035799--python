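"""Nonlinear ligament bundles of the cruciate-retaining TKA knee model.

The knee capsule is represented by 21 ligament bundles, each a tension-only
nonlinear spring acting along the straight line between a femoral origin and
a tibial (or patellar-surrogate) insertion.  The constitutive law is the
standard piecewise quadratic/linear force-strain relation

    f(eps) = k * eps^2 / (4 * eps1)   for 0 <= eps <= 2*eps1   (toe region)
           = k * (eps - eps1)         for eps > 2*eps1          (linear region)
           = 0                        for eps < 0               (slack)

with stiffness ``k`` (N per unit strain) and linear-limit strain ``eps1``.
The law is continuous and once-differentiable at both breakpoints.

Strain is engineering strain relative to the slack length,
``eps = (l - l0) / l0``.  The slack length of each bundle is not a free
parameter: it is *calibrated* from the bundle length at a reference
(extended) pose together with a tabulated reference strain,
``l0 = l_ref / (1 + eps_ref)``, so that evaluating the bundle at the
calibration pose returns exactly its reference strain.  A negative reference
strain (the posterior cruciate bundles) means the bundle is slack at
extension and engages only in flexion.

Bundle classes, reference strains and stiffnesses are packaged in
``data/ligament_parameters.yaml``; attachment coordinates of the generic
right-knee geometry in ``data/attachments.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .kinematics import JointPose, pose_transform

__all__ = [
    "ACTIVATION_THRESHOLD_N",
    "BUNDLE_CLASSES",
    "BUNDLE_NAMES",
    "TIBIOFEMORAL_BUNDLES",
    "GROUPS",
    "ConfigError",
    "LigamentParams",
    "LigamentBundle",
    "LigamentState",
    "ligament_force",
    "strain_of",
    "slack_length_from_reference",
    "bundle_length",
    "bundle_lengths",
    "calibrate",
    "load_param_table",
    "load_attachments",
    "build_default_bundles",
    "mirror_bundle",
]

#: A bundle is "active" (tight) when its tension exceeds this threshold [N].
ACTIVATION_THRESHOLD_N = 1.0

#: The 18 parameter classes of the registry, in canonical order.
BUNDLE_CLASSES = (
    "aALL", "pALL", "aLCL", "pLCL", "aMCL", "cMCL", "pMCL", "aDM", "pDM",
    "aPCL", "pPCL", "PC", "sMPFL", "cMPFL", "iMPFL", "sLPFL", "cLPFL", "iLPFL",
)

#: The 21 bundle instances (the PC class expands into PC1-PC4).
BUNDLE_NAMES = (
    "aALL", "pALL", "aLCL", "pLCL", "aMCL", "cMCL", "pMCL", "aDM", "pDM",
    "aPCL", "pPCL", "PC1", "PC2", "PC3", "PC4",
    "sMPFL", "cMPFL", "iMPFL", "sLPFL", "cLPFL", "iLPFL",
)

#: The 15 bundles participating in the tibiofemoral force balance (the six
#: patellofemoral bundles are registered but the patellofemoral joint is not
#: solved).
TIBIOFEMORAL_BUNDLES = BUNDLE_NAMES[:15]

#: Reporting groups for peak-tension and activation summaries.
GROUPS: Mapping[str, tuple[str, ...]] = {
    "ALL": ("aALL", "pALL"),
    "LCL": ("aLCL", "pLCL"),
    "MCL": ("aMCL", "cMCL", "pMCL", "aDM", "pDM"),
    "PCL": ("aPCL", "pPCL"),
}

_SIDE_OF_CLASS = {
    "aALL": "lateral", "pALL": "lateral", "aLCL": "lateral", "pLCL": "lateral",
    "aMCL": "medial", "cMCL": "medial", "pMCL": "medial",
    "aDM": "medial", "pDM": "medial",
    "aPCL": "cruciate", "pPCL": "cruciate", "PC": "posterior",
    "sMPFL": "patellofemoral-medial", "cMPFL": "patellofemoral-medial",
    "iMPFL": "patellofemoral-medial",
    "sLPFL": "patellofemoral-lateral", "cLPFL": "patellofemoral-lateral",
    "iLPFL": "patellofemoral-lateral",
}

_MIRRORED_SIDE = {
    "medial": "lateral",
    "lateral": "medial",
    "posterior": "posterior",
    "cruciate": "cruciate",
    "patellofemoral-medial": "patellofemoral-lateral",
    "patellofemoral-lateral": "patellofemoral-medial",
}


class ConfigError(ValueError):
    """Invalid model configuration (missing bundle, bad parameter, ...)."""


@dataclass(frozen=True)
class LigamentParams:
    """Constitutive parameters of one bundle class."""

    name: str
    reference_strain: float
    stiffness: float          # N per unit strain
    linear_limit_strain: float = 0.03

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ConfigError(f"{self.name}: stiffness must be > 0, got {self.stiffness}")
        if self.linear_limit_strain <= 0:
            raise ConfigError(
                f"{self.name}: linear_limit_strain must be > 0, got {self.linear_limit_strain}"
            )
        if not -0.2 <= self.reference_strain <= 0.2:
            raise ConfigError(
                f"{self.name}: reference_strain outside [-0.2, 0.2]: {self.reference_strain}"
            )


@dataclass(frozen=True)
class LigamentBundle:
    """One bundle: parameters, attachments, side tag and calibrated slack length."""

    name: str
    params: LigamentParams
    origin: np.ndarray       # femoral frame, mm
    insertion: np.ndarray    # tibial (or patellar-surrogate) frame, mm
    side_tag: str
    slack_length: float | None = None   # mm, set by calibrate()

    @property
    def is_tibiofemoral(self) -> bool:
        return not self.side_tag.startswith("patellofemoral")


@dataclass(frozen=True)
class LigamentState:
    """Evaluated state of one bundle at a pose."""

    name: str
    length: float    # mm
    strain: float
    tension: float   # N
    active: bool


def ligament_force(
    strain: float | np.ndarray, params: LigamentParams
) -> float | np.ndarray:
    """Tension [N] of the piecewise quadratic/linear spring law at a strain.

    Total function of real strain: zero below zero strain, quadratic toe up
    to twice the linear-limit strain, linear beyond.
    """
    eps = np.asarray(strain, dtype=float)
    k, e1 = params.stiffness, params.linear_limit_strain
    quad = k * eps**2 / (4.0 * e1)
    lin = k * (eps - e1)
    out = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * e1, quad, lin))
    if np.isscalar(strain) or np.ndim(strain) == 0:
        return float(out)
    return out


def strain_of(length: float | np.ndarray, slack_length: float) -> float | np.ndarray:
    """Engineering strain (l - l0) / l0."""
    if slack_length <= 0:
        raise ConfigError(f"slack_length must be > 0, got {slack_length}")
    return (length - slack_length) / slack_length


def slack_length_from_reference(reference_length: float, reference_strain: float) -> float:
    """Slack length from a reference length carrying a known strain.

    Defined so that ``strain_of(reference_length, result) == reference_strain``
    to machine precision: ``l0 = l_ref / (1 + eps_ref)``.
    """
    if reference_length <= 0:
        raise ConfigError(f"reference_length must be > 0, got {reference_length}")
    if 1.0 + reference_strain <= 0:
        raise ConfigError(f"1 + reference_strain must be > 0, got {reference_strain}")
    return reference_length / (1.0 + reference_strain)


def bundle_length(bundle: LigamentBundle, pose: JointPose) -> float:
    """Straight-line bundle length [mm] at a pose.

    The femoral origin is mapped into the tibial frame; the insertion is
    already tibia-fixed (the patellar surrogate frame is rigid with the
    tibia).  No wrapping is modeled.
    """
    R, t = pose_transform(pose)
    return float(np.linalg.norm(R @ bundle.origin + t - bundle.insertion))


def bundle_lengths(bundles: Sequence[LigamentBundle], pose: JointPose) -> np.ndarray:
    """Vectorized straight-line lengths of many bundles at one pose."""
    if not bundles:
        return np.zeros(0)
    R, t = pose_transform(pose)
    origins = np.array([b.origin for b in bundles])
    insertions = np.array([b.insertion for b in bundles])
    return np.linalg.norm(origins @ R.T + t - insertions, axis=1)


def calibrate(
    bundles: Sequence[LigamentBundle], calibration_pose: JointPose
) -> list[LigamentBundle]:
    """Set every bundle's slack length from its length at the calibration pose.

    After calibration each bundle's strain evaluated at ``calibration_pose``
    equals its tabulated reference strain exactly.
    """
    lengths = bundle_lengths(bundles, calibration_pose)
    out = []
    for b, l_ref in zip(bundles, lengths):
        if l_ref < 1e-9:
            raise ConfigError(f"{b.name}: zero-length bundle at calibration pose")
        out.append(
            replace(
                b,
                slack_length=float(
                    slack_length_from_reference(l_ref, b.params.reference_strain)
                ),
            )
        )
    return out


def evaluate_bundles(
    bundles: Sequence[LigamentBundle],
    pose: JointPose,
    threshold: float = ACTIVATION_THRESHOLD_N,
) -> list[LigamentState]:
    """Length, strain, tension and activation of each calibrated bundle."""
    lengths = bundle_lengths(bundles, pose)
    states = []
    for b, l in zip(bundles, lengths):
        if b.slack_length is None:
            raise ConfigError(f"{b.name}: bundle not calibrated")
        eps = float(strain_of(l, b.slack_length))
        f = float(ligament_force(eps, b.params))
        states.append(LigamentState(b.name, float(l), eps, f, f > threshold))
    return states


def _read_yaml(source: str | Path | Mapping) -> Mapping:
    if isinstance(source, Mapping):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def load_param_table(source: str | Path | Mapping | None = None) -> list[LigamentParams]:
    """Load the 18-class parameter registry (packaged defaults if no source).

    Accepts a YAML path or an already-parsed mapping with a ``bundles`` list
    of rows ``{name, reference_strain, stiffness_N, linear_limit_strain}``.
    Every class in :data:`BUNDLE_CLASSES` must be present.
    """
    if source is None:
        ref = importlib.resources.files("kneesim.data") / "ligament_parameters.yaml"
        data = yaml.safe_load(ref.read_text())
    else:
        data = _read_yaml(source)
    rows = {row["name"]: row for row in data["bundles"]}
    missing = [c for c in BUNDLE_CLASSES if c not in rows]
    if missing:
        raise ConfigError(f"parameter table missing bundle class(es): {', '.join(missing)}")
    params = []
    for cls in BUNDLE_CLASSES:
        row = rows[cls]
        params.append(
            LigamentParams(
                name=cls,
                reference_strain=float(row["reference_strain"]),
                stiffness=float(row["stiffness_N"]),
                linear_limit_strain=float(row.get("linear_limit_strain", 0.03)),
            )
        )
    return params


def load_attachments(source: str | Path | Mapping | None = None) -> dict[str, dict]:
    """Load per-bundle attachment coordinates (packaged defaults if no source)."""
    if source is None:
        ref = importlib.resources.files("kneesim.data") / "attachments.yaml"
        data = yaml.safe_load(ref.read_text())
    else:
        data = _read_yaml(source)
    return dict(data["bundles"])


def build_default_bundles(
    param_table: Iterable[LigamentParams] | None = None,
    attachments: Mapping[str, Mapping] | None = None,
) -> list[LigamentBundle]:
    """Construct the 21 uncalibrated bundles of the knee apparatus.

    Counts per class: 2 ALL, 2 LCL, 5 MCL-group, 2 PCL, 4 posterior-capsule,
    3 MPFL, 3 LPFL.  Side tags follow the attachment file but are validated
    against the canonical class sides for the default names.
    """
    params = {p.name: p for p in (param_table if param_table is not None else load_param_table())}
    attach = attachments if attachments is not None else load_attachments()
    bundles = []
    for name in BUNDLE_NAMES:
        cls = "PC" if name.startswith("PC") else name
        if name not in attach:
            raise ConfigError(f"attachment coordinates missing for bundle {name}")
        entry = attach[name]
        for key in ("origin", "insertion"):
            if key not in entry:
                raise ConfigError(f"bundle {name}: missing {key} coordinates")
        side = entry.get("side", _SIDE_OF_CLASS[cls])
        origin = np.asarray(entry["origin"], dtype=float)
        insertion = np.asarray(entry["insertion"], dtype=float)
        if origin.shape != (3,) or insertion.shape != (3,):
            raise ConfigError(f"bundle {name}: attachment coordinates must be 3-vectors")
        bundles.append(LigamentBundle(name, params[cls], origin, insertion, side))
    return bundles


def mirror_bundle(bundle: LigamentBundle) -> LigamentBundle:
    """Left-right mirror of one bundle (z -> -z; medial/lateral tags swap)."""
    return replace(
        bundle,
        origin=bundle.origin * np.array([1.0, 1.0, -1.0]),
        insertion=bundle.insertion * np.array([1.0, 1.0, -1.0]),
        side_tag=_MIRRORED_SIDE[bundle.side_tag],
    )
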