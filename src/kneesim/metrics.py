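"""Validation metrics, cross-model comparisons and result export.

Covers the post-processing a contact-force prediction study reports:
root-mean-squared error and Pearson correlation against measured compartment
forces, peak contact forces and ligament-group tensions of the A-G variants
with percent changes relative to the neutral balanced model, ligament
activation timing (fraction of the gait cycle a group is tight, with
activation/deactivation crossings), kinematic extremes per degree of
freedom, and the cycle-average medial load share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contact import ContactResult
from .kinematics import JointPose
from .ligaments import ACTIVATION_THRESHOLD_N, GROUPS, LigamentState
from .model import GRAVITY
from .solver import GaitResult, StepResult

__all__ = [
    "rmse",
    "pearson_r",
    "peak",
    "percent_change",
    "activation_stats",
    "ligament_group_tension",
    "medial_share",
    "compare_models",
    "validate",
    "ComparisonSummary",
    "ValidationReport",
    "result_to_frame",
    "write_result_csv",
    "result_from_csv",
]

POSE_DOFS = (
    "flexion", "varus_valgus", "internal_external",
    "ap_translation", "ml_translation", "si_translation",
)


def rmse(a: Sequence[float], b: Sequence[float]) -> float:
    """Root-mean-squared difference of two equal-length series."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError(f"series must have equal nonzero length, got {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    am, bm = a - a.mean(), b - b.mean()
    return float(np.dot(am, bm) / np.sqrt(np.dot(am, am) * np.dot(bm, bm)))


def peak(series: Sequence[float]) -> float:
    """Maximum of a non-empty series."""
    s = np.asarray(series, float)
    if s.size == 0:
        raise ValueError("peak of empty series")
    return float(s.max())


def percent_change(peak_model: float, peak_ref: float) -> float:
    """Signed percent change relative to a positive reference."""
    if peak_ref <= 0:
        raise ValueError(f"reference peak must be > 0, got {peak_ref}")
    return 100.0 * (peak_model - peak_ref) / peak_ref


def activation_stats(
    tension: Sequence[float],
    threshold: float = ACTIVATION_THRESHOLD_N,
    percent_cycle: np.ndarray | None = None,
) -> tuple[float, list[float], list[float]]:
    """Activation fraction [%] and crossing points of a tension trace.

    A sample is active when tension exceeds the threshold.  The fraction is
    the percentage of active samples; activation (off->on) and deactivation
    (on->off) points are reported at the percent-cycle position of the first
    sample of the new state.
    """
    t = np.asarray(tension, float)
    if t.size == 0:
        raise ValueError("empty tension series")
    pc = (
        np.asarray(percent_cycle, float)
        if percent_cycle is not None
        else np.linspace(0.0, 100.0, t.size)
    )
    active = t > threshold
    fraction = 100.0 * active.mean()
    d = np.diff(active.astype(int))
    on = [float(pc[i + 1]) for i in np.flatnonzero(d == 1)]
    off = [float(pc[i + 1]) for i in np.flatnonzero(d == -1)]
    return float(fraction), on, off


def ligament_group_tension(result: GaitResult, group: str) -> np.ndarray:
    """Per-step summed tension [N] of one reporting group (ALL/LCL/MCL/PCL)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r} (expected one of {sorted(GROUPS)})")
    names = result.bundle_names
    idx = [names.index(n) for n in GROUPS[group]]
    return result.tension_matrix()[:, idx].sum(axis=1)


def medial_share(result: GaitResult) -> float:
    """Cycle-average medial share of the total contact force [%]."""
    mcf = result.trace("mcf")
    tcf = result.trace("tcf")
    total = tcf.sum()
    if total <= 0:
        raise ValueError("no contact force in result")
    return float(100.0 * mcf.sum() / total)


@dataclass(frozen=True)
class ComparisonSummary:
    """Cross-model peaks, percent changes, activation and kinematics."""

    table: pd.DataFrame          # one row per model
    reference_label: str = "A"

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"reference": self.reference_label,
                 "models": self.table.to_dict(orient="records")},
                fh, indent=1, default=float,
            )


@dataclass(frozen=True)
class ValidationReport:
    """Agreement of a simulated result with measured compartment forces."""

    rmse_tcf: float
    rmse_mcf: float
    rmse_lcf: float
    rmse_tcf_pct_bw: float
    rmse_mcf_pct_bw: float
    rmse_lcf_pct_bw: float
    pearson_tcf: float | None
    pearson_mcf: float | None
    pearson_lcf: float | None
    medial_share: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=float)


def compare_models(results: Mapping[str, GaitResult], reference: str = "A") -> ComparisonSummary:
    """Summarize peak forces/tensions, activation and kinematics across models."""
    if reference not in results:
        raise ValueError(f"reference model {reference!r} missing from results")
    ref = results[reference]
    ref_peaks = {
        "tcf": peak(ref.trace("tcf")),
        "mcf": peak(ref.trace("mcf")),
        "lcf": peak(ref.trace("lcf")),
        **{g: peak(ligament_group_tension(ref, g)) for g in GROUPS},
    }
    rows = []
    for label in sorted(results):
        r = results[label]
        pc = r.percent_cycle
        row: dict = {"model": label}
        for name in ("tcf", "mcf", "lcf"):
            pk = peak(r.trace(name))
            row[f"peak_{name}_N"] = pk
            row[f"pct_change_{name}"] = percent_change(pk, ref_peaks[name])
        for g in GROUPS:
            series = ligament_group_tension(r, g)
            pk = peak(series)
            row[f"peak_{g}_N"] = pk
            row[f"pct_change_{g}"] = (
                percent_change(pk, ref_peaks[g]) if ref_peaks[g] > 0 else np.nan
            )
            frac, on, off = activation_stats(series, percent_cycle=pc)
            row[f"activation_{g}_pct"] = frac
            row[f"activation_{g}_on"] = ";".join(f"{v:.1f}" for v in on)
            row[f"activation_{g}_off"] = ";".join(f"{v:.1f}" for v in off)
        for dof in POSE_DOFS:
            trace = r.trace(dof)
            row[f"min_{dof}"] = float(trace.min())
            row[f"max_{dof}"] = float(trace.max())
        row["medial_share_pct"] = medial_share(r)
        rows.append(row)
    return ComparisonSummary(table=pd.DataFrame(rows), reference_label=reference)


def validate(
    result: GaitResult,
    measured_mcf: Sequence[float],
    measured_lcf: Sequence[float],
    body_mass: float | None = None,
) -> ValidationReport:
    """RMSE / Pearson r of simulated vs measured compartment forces.

    The measured series must already be on the result's sample grid (use
    :func:`kneesim.gait.read_measured_forces_csv` with the result's percent
    grid).  Percent-body-weight RMSEs use the model body mass unless given.
    """
    mcf_m = np.asarray(measured_mcf, float)
    lcf_m = np.asarray(measured_lcf, float)
    mcf_s = result.trace("mcf")
    lcf_s = result.trace("lcf")
    if mcf_m.shape != mcf_s.shape or lcf_m.shape != lcf_s.shape:
        raise ValueError("measured series must match the result grid")
    tcf_m = mcf_m + lcf_m
    tcf_s = result.trace("tcf")
    bw = (body_mass if body_mass is not None else 66.7) * GRAVITY

    def _r(a, b):
        try:
            return pearson_r(a, b)
        except ValueError:
            return None

    return ValidationReport(
        rmse_tcf=rmse(tcf_s, tcf_m),
        rmse_mcf=rmse(mcf_s, mcf_m),
        rmse_lcf=rmse(lcf_s, lcf_m),
        rmse_tcf_pct_bw=100.0 * rmse(tcf_s, tcf_m) / bw,
        rmse_mcf_pct_bw=100.0 * rmse(mcf_s, mcf_m) / bw,
        rmse_lcf_pct_bw=100.0 * rmse(lcf_s, lcf_m) / bw,
        pearson_tcf=_r(tcf_s, tcf_m),
        pearson_mcf=_r(mcf_s, mcf_m),
        pearson_lcf=_r(lcf_s, lcf_m),
        medial_share=medial_share(result),
    )


def result_to_frame(result: GaitResult) -> pd.DataFrame:
    """Flatten a GaitResult to a tidy per-step table."""
    rows = []
    pc = result.percent_cycle
    for i, s in enumerate(result.steps):
        row = {
            "time_s": s.time,
            "percent_cycle": pc[i],
            **{dof: getattr(s.pose, dof) for dof in POSE_DOFS},
            "mcf_N": s.contact.mcf,
            "lcf_N": s.contact.lcf,
            "tcf_N": s.contact.tcf,
            "residual_norm": s.residual_norm,
            "converged": s.converged,
        }
        for name, st in zip(result.bundle_names, s.bundle_states):
            row[f"tension_{name}_N"] = st.tension
        rows.append(row)
    return pd.DataFrame(rows)


def write_result_csv(result: GaitResult, path: str | Path) -> None:
    result_to_frame(result).to_csv(path, index=False, float_format="%.8g")


def result_from_csv(path: str | Path, label: str | None = None) -> GaitResult:
    """Rebuild a GaitResult from a per-step result CSV.

    Bundle lengths/strains are not stored in the CSV, so the reconstructed
    ligament states carry tension and activation only (length and strain are
    NaN); that is sufficient for :func:`compare_models` and :func:`validate`.
    """
    df = pd.read_csv(path)
    required = {"time_s", "mcf_N", "lcf_N", *POSE_DOFS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    names = [c[len("tension_"):-len("_N")] for c in df.columns if c.startswith("tension_")]
    steps = []
    for _, row in df.iterrows():
        pose = JointPose(**{dof: float(row[dof]) for dof in POSE_DOFS})
        contact = ContactResult(
            mcf=float(row["mcf_N"]), lcf=float(row["lcf_N"]),
            contact_points=np.full((2, 3), np.nan), penetrations=np.full(2, np.nan),
        )
        states = [
            LigamentState(
                name=n, length=np.nan, strain=np.nan,
                tension=float(row[f"tension_{n}_N"]),
                active=float(row[f"tension_{n}_N"]) > ACTIVATION_THRESHOLD_N,
            )
            for n in names
        ]
        steps.append(
            StepResult(
                time=float(row["time_s"]), pose=pose, contact=contact,
                bundle_states=states,
                residual_norm=float(row.get("residual_norm", np.nan)),
                converged=bool(row.get("converged", True)),
            )
        )
    return GaitResult(steps=steps, model_label=label, bundle_names=names)
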