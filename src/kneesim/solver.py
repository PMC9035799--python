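"""Quasi-static force-dependent-kinematics solver.

At each gait sample the knee flexion angle is prescribed and the five
secondary tibiofemoral degrees of freedom — anterior/posterior, medial/
lateral and superior/inferior translation plus varus/valgus and internal/
external rotation — are found by driving the net force and moment on the
femur to zero.  The wrench balance collects

* the 15 tibiofemoral ligament bundle tensions (straight-line lines of
  action; the six patellofemoral bundles are evaluated for reporting but do
  not enter the balance),
* the two compartmental contact forces, and
* the external intersegmental load (3 force components and the coronal and
  axial moment components; the flexion moment is reacted by the prescribed
  flexion DOF).

Sign conventions for external loads (right knee, tibial frame): the axial
force component is compressive (>= 0 pushes the femur inferiorly), a
positive medial-lateral force pushes the femur medially, a positive AP force
pushes it anteriorly; a positive varus/adduction moment loads the medial
compartment and a positive axial moment is tibial internal rotation.

The root solve is a damped-Newton/dogleg trust-region iteration with a
finite-difference Jacobian (MINPACK ``hybr``), with a Levenberg-Marquardt
retry and a cold restart from the seated extension pose as fallbacks.
Moments are scaled by a 50 mm lever arm to commensurate N units inside the
residual norm; convergence is declared per component (|F| < 0.1 N,
|M| < 0.01 N m), re-checked independently of the optimizer's own exit
status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares as _scipy_lsq
from scipy.optimize import root as _scipy_root

from .contact import ContactResult, contact_wrench
from .kinematics import JointPose
from .ligaments import (
    ACTIVATION_THRESHOLD_N,
    LigamentState,
    evaluate_bundles,
    ligament_force,
    strain_of,
)
from .model import KneeModel

__all__ = [
    "FORCE_TOL_N",
    "MOMENT_TOL_NM",
    "MOMENT_LEVER_M",
    "LoadStep",
    "StepResult",
    "GaitResult",
    "SolverError",
    "residual",
    "solve_step",
    "simulate_gait",
    "seat_extension",
]

FORCE_TOL_N = 0.1      # per force component
MOMENT_TOL_NM = 0.01   # per moment component
MOMENT_LEVER_M = 0.05  # scales N m to commensurate N in the mixed residual norm


class SolverError(RuntimeError):
    """Equilibrium solve failed to converge."""


@dataclass(frozen=True)
class LoadStep:
    """One gait sample: prescribed flexion plus intersegmental loads.

    ``external_force`` is (AP, ML, axial-compressive) in N;
    ``external_moment`` is (varus/adduction, internal/external) in N m.
    """

    time: float
    flexion: float
    external_force: np.ndarray
    external_moment: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "external_force", np.asarray(self.external_force, float))
        object.__setattr__(self, "external_moment", np.asarray(self.external_moment, float))


@dataclass(frozen=True)
class StepResult:
    """Equilibrium state at one gait sample."""

    time: float
    pose: JointPose
    contact: ContactResult
    bundle_states: list[LigamentState]
    residual_norm: float   # norm of the lever-scaled mixed-unit residual [N]
    converged: bool
    iterations: int = 0

    @property
    def tensions(self) -> np.ndarray:
        return np.array([s.tension for s in self.bundle_states])


@dataclass
class GaitResult:
    """Ordered equilibrium states over one gait cycle."""

    steps: list[StepResult]
    model_label: str | None = None
    bundle_names: list[str] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.steps])

    @property
    def percent_cycle(self) -> np.ndarray:
        t = self.times
        span = t[-1] - t[0]
        return 100.0 * (t - t[0]) / span if span > 0 else np.zeros_like(t)

    def trace(self, name: str) -> np.ndarray:
        """Named scalar trace: mcf, lcf, tcf, or any JointPose field."""
        if name in ("mcf", "lcf", "tcf"):
            return np.array([getattr(s.contact, name) for s in self.steps])
        return np.array([getattr(s.pose, name) for s in self.steps])

    def tension_matrix(self) -> np.ndarray:
        """(n_steps, n_bundles) bundle tensions [N]."""
        return np.array([s.tensions for s in self.steps])


def _external_wrench(loads: LoadStep) -> tuple[np.ndarray, np.ndarray]:
    """Applied force [N] and moment [N mm] on the femur at the knee center."""
    fx_ap, fy_ml, fz_axial = loads.external_force
    m_vv, m_ie = loads.external_moment
    force = np.array([fx_ap, -fz_axial, -fy_ml])
    moment = np.array([-m_vv * 1000.0, -m_ie * 1000.0, 0.0])
    return force, moment


def _ligament_wrench(model: KneeModel, pose: JointPose) -> tuple[np.ndarray, np.ndarray]:
    """Net tibiofemoral ligament force [N] / moment [N mm] on the femur."""
    from .kinematics import pose_transform

    bundles = model.tibiofemoral_bundles
    if not bundles:
        return np.zeros(3), np.zeros(3)
    R, t = pose_transform(pose)
    origins = np.array([b.origin for b in bundles])
    insertions = np.array([b.insertion for b in bundles])
    p = origins @ R.T + t                      # femoral attachment, tibial frame
    d = insertions - p
    lengths = np.linalg.norm(d, axis=1)
    tensions = np.empty(len(bundles))
    for i, b in enumerate(bundles):
        if b.slack_length is None:
            raise SolverError(f"{b.name}: model not calibrated")
        tensions[i] = ligament_force(strain_of(lengths[i], b.slack_length), b.params)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(lengths[:, None] > 1e-12, d / lengths[:, None], 0.0)
    forces = tensions[:, None] * unit
    return forces.sum(axis=0), np.cross(p, forces).sum(axis=0)


def residual(
    secondary_dofs: np.ndarray,
    flexion: float,
    loads: LoadStep,
    model: KneeModel,
    include_ligaments: bool = True,
) -> np.ndarray:
    """Net wrench on the femur projected on the five secondary DOFs.

    Returns (Fx, Fy, Fz) in N and (Mx_vv, My_ie) in N m about the knee
    center.  The flexion (z) moment is the reaction of the prescribed DOF
    and is excluded.
    """
    dofs = np.asarray(secondary_dofs, float)
    if not np.all(np.isfinite(dofs)) or not np.isfinite(flexion):
        raise ValueError("non-finite pose input to residual")
    pose = JointPose(flexion=flexion).with_secondary(dofs)
    _, f_con, m_con = contact_wrench(pose, model.geometry, model.contact)
    f_ext, m_ext = _external_wrench(loads)
    force = f_con + f_ext
    moment = m_con + m_ext
    if include_ligaments:
        f_lig, m_lig = _ligament_wrench(model, pose)
        force = force + f_lig
        moment = moment + m_lig
    return np.array([force[0], force[1], force[2], moment[0] / 1000.0, moment[1] / 1000.0])


def _scaled(res: np.ndarray) -> np.ndarray:
    out = res.copy()
    out[3:] /= MOMENT_LEVER_M   # N m -> commensurate N
    return out


def _converged(res: np.ndarray) -> bool:
    return bool(np.all(np.abs(res[:3]) < FORCE_TOL_N) and np.all(np.abs(res[3:]) < MOMENT_TOL_NM))


def solve_step(
    flexion: float,
    loads: LoadStep,
    model: KneeModel,
    initial_guess: np.ndarray | Sequence[float] | None = None,
) -> StepResult:
    """Solve the five secondary DOFs at one prescribed flexion angle."""
    x0 = (
        np.asarray(initial_guess, float)
        if initial_guess is not None
        else _default_guess(model)
    )
    if not np.all(np.isfinite(x0)):
        raise ValueError("non-finite initial guess")

    def fun(x: np.ndarray) -> np.ndarray:
        return _scaled(residual(x, flexion, loads, model))

    nfev = 0
    best = None

    def _try(x_start: np.ndarray, how: str) -> tuple[np.ndarray, np.ndarray]:
        nonlocal nfev
        if how == "lsq":
            sol = _scipy_lsq(
                fun, x_start, x_scale=_DOF_SCALE, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        else:
            sol = _scipy_root(
                fun, x_start, method=how,
                options={"xtol": 1e-12, "maxfev": 4000} if how == "hybr"
                else {"xtol": 1e-12, "maxiter": 4000},
            )
        nfev += sol.nfev
        return sol.x, residual(sol.x, flexion, loads, model)

    # Primary: damped trust-region descent with the physical DOF scaling
    # (superior-inferior is ~100x stiffer than the in-plane DOFs), which
    # stays in the local basin; Newton variants polish or take over if it
    # stalls, and a deterministic fan of restarts is the last resort.
    attempts: list[tuple[np.ndarray, str]] = [(x0, "lsq"), (x0, "hybr"), (x0, "lm")]
    for start, how in attempts:
        x, res = _try(start, how)
        if best is None or np.linalg.norm(_scaled(res)) < np.linalg.norm(_scaled(best[1])):
            best = (x, res)
        if _converged(res):
            break
    if not _converged(best[1]):
        for dx in _MULTISTART_OFFSETS:
            x, res = _try(best[0] + dx, "lsq")
            if np.linalg.norm(_scaled(res)) < np.linalg.norm(_scaled(best[1])):
                best = (x, res)
            if _converged(res):
                break
    x, res = best
    pose = JointPose(flexion=flexion).with_secondary(x)
    cres, _, _ = contact_wrench(pose, model.geometry, model.contact)
    states = evaluate_bundles(model.bundles, pose, ACTIVATION_THRESHOLD_N)
    return StepResult(
        time=loads.time,
        pose=pose,
        contact=cres,
        bundle_states=states,
        residual_norm=float(np.linalg.norm(_scaled(res))),
        converged=_converged(res),
        iterations=nfev,
    )


# Trust-region scaling of the DOF vector (ap, ml, si, vv, ie): the SI
# translation rides on the contact stiffness and is ~100x stiffer than the
# ligament-governed in-plane DOFs.
_DOF_SCALE = np.array([1.0, 1.0, 0.05, 1.0, 2.0])

# Fixed fan of fallback perturbations (mm / deg), same order as the DOF
# vector (ap, ml, si, vv, ie); frozen so the solver stays deterministic.
_MULTISTART_OFFSETS = np.array(
    [
        [0.0, 0.0, -0.3, 0.0, 0.0],
        [0.0, 0.0, 0.3, 0.0, 0.0],
        [-0.5, 0.0, -0.2, 0.5, -2.0],
        [0.5, 0.0, -0.2, -0.5, 2.0],
        [-1.0, -0.2, -0.4, 0.5, -3.0],
        [1.0, 0.2, -0.4, -0.5, 3.0],
        [-0.5, 0.5, 0.0, 1.0, 1.0],
        [0.5, -0.5, 0.0, -1.0, -1.0],
        [-1.5, 0.0, -0.6, 0.0, -4.0],
        [1.5, 0.0, -0.6, 0.0, 4.0],
        [0.0, -1.0, -0.2, 2.0, 0.0],
        [0.0, 1.0, -0.2, -2.0, 0.0],
    ]
)


def _default_guess(model: KneeModel) -> np.ndarray:
    """Starting point on the physical equilibrium branch.

    The calibration pose (when the model has been balanced) is the natural
    seed: the joint is seated and every bundle is at its reference strain
    there, so the damped Newton iteration tracks the physiologic branch
    rather than a self-stressed jammed configuration.
    """
    if model.neutral_calibration_pose is not None:
        # Laxity variants have neutral components; they operate near the
        # neutral seated pose, not the tilted balancing pose.
        return model.neutral_calibration_pose.secondary_dofs()
    if model.calibration_pose is not None:
        return model.calibration_pose.secondary_dofs()
    si0 = -(model.geometry.clearance + 0.05)
    return np.array([0.0, 0.0, si0, 0.0, 0.0])


def simulate_gait(
    model: KneeModel,
    profile: Sequence[LoadStep],
    initial_guess: np.ndarray | None = None,
    warm_start: bool = True,
    raise_on_failure: bool = True,
) -> GaitResult:
    """Sequential equilibrium solve over a load profile with warm starting."""
    if len(profile) == 0:
        raise ValueError("empty load profile")
    times = [s.time for s in profile]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("load profile times must be strictly increasing")
    steps: list[StepResult] = []
    guess = initial_guess
    for i, ls in enumerate(profile):
        step = solve_step(ls.flexion, ls, model, initial_guess=guess)
        if not step.converged and raise_on_failure:
            raise SolverError(
                f"step {i} (t={ls.time:.3f}s, flexion={ls.flexion:.1f} deg) did not "
                f"converge: residual_norm={step.residual_norm:.3g} N"
            )
        steps.append(step)
        if warm_start:
            guess = step.pose.secondary_dofs()
    return GaitResult(steps=steps, model_label=model.label, bundle_names=model.bundle_names)


def seat_extension(model: KneeModel, vv_deg: float, preload: float = 100.0) -> JointPose:
    """Seat the femur at an extended pose of fixed coronal angle.

    Translations are solved from a contact-only (ligaments disabled) force
    balance under a nominal axial preload, with flexion, IE rotation fixed
    at zero and varus/valgus fixed at ``vv_deg``.  Used to construct the
    ligament calibration pose at a chosen coronal alignment.
    """
    if abs(vv_deg) > 10:
        raise ValueError(f"|vv_deg| must be <= 10, got {vv_deg}")
    loads = LoadStep(
        time=0.0, flexion=0.0, external_force=np.array([0.0, 0.0, preload]),
        external_moment=np.zeros(2),
    )

    def fun(xyz: np.ndarray) -> np.ndarray:
        dofs = np.array([xyz[0], xyz[1], xyz[2], vv_deg, 0.0])
        return residual(dofs, 0.0, loads, model, include_ligaments=False)[:3]

    x0 = np.array([0.0, 0.0, -(model.geometry.clearance + 0.05)])
    sol = _scipy_root(fun, x0, method="hybr", options={"xtol": 1e-13, "maxfev": 4000})
    res = fun(sol.x)
    if not np.all(np.abs(res) < FORCE_TOL_N):
        raise SolverError(
            f"seating at vv={vv_deg} deg failed: residual force {np.abs(res).max():.3g} N"
        )
    return JointPose(
        flexion=0.0,
        varus_valgus=vv_deg,
        internal_external=0.0,
        ap_translation=float(sol.x[0]),
        ml_translation=float(sol.x[1]),
        si_translation=float(sol.x[2]),
    )
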