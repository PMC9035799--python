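"""Independently coded oracles used by the solver and acceptance tests.

These deliberately re-derive quantities with their own code path (explicit
per-bundle loops, scipy-free transforms written out by hand) so they can
serve as cross-checks of the package implementation.
"""

from __future__ import annotations

import numpy as np

from kneesim.kinematics import JointPose, pose_transform
from kneesim.ligaments import ligament_force, strain_of
from kneesim.solver import LoadStep


def independent_wrench(model, pose: JointPose, loads: LoadStep):
    """Net force [N] / moment [N mm] on the femur: explicit sums of F, r x F."""
    R, t = pose_transform(pose)
    force = np.zeros(3)
    moment = np.zeros(3)
    for b in model.tibiofemoral_bundles:
        p = R @ b.origin + t
        d = b.insertion - p
        length = np.linalg.norm(d)
        tension = ligament_force(strain_of(length, b.slack_length), b.params)
        if tension > 0:
            f = tension * d / length
            force += f
            moment += np.cross(p, f)
    g = model.geometry
    for i in range(2):
        cc = R @ g.condyle_centers[i] + t
        u = cc - g.pocket_centers[i]
        if u @ g.tray_normal >= 0:
            continue
        overlap = np.linalg.norm(u) - g.clearance
        if overlap <= 0:
            continue
        f = model.contact.stiffness * overlap ** model.contact.exponent
        f = f * (-u / np.linalg.norm(u))
        force += f
        moment += np.cross((cc + g.pocket_centers[i]) / 2, f)
    fx, fy, fz = loads.external_force
    force += np.array([fx, -fz, -fy])
    moment += np.array([-loads.external_moment[0] * 1e3,
                        -loads.external_moment[1] * 1e3, 0.0])
    return force, moment
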