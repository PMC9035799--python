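"""Equilibrium residual, single-step solve and gait-cycle simulation."""

import dataclasses

import numpy as np
import pytest

from kneesim.kinematics import JointPose
from kneesim.solver import (
    FORCE_TOL_N,
    MOMENT_TOL_NM,
    LoadStep,
    residual,
    simulate_gait,
    solve_step,
)


from .oracles import independent_wrench


def axial_step(force_n: float, m_add: float = 0.0, flexion: float = 0.0) -> LoadStep:
    return LoadStep(time=0.0, flexion=flexion,
                    external_force=np.array([0.0, 0.0, force_n]),
                    external_moment=np.array([m_add, 0.0]))


class TestResidual:
    def test_empty_system_zero_residual(self, variants):
        empty = dataclasses.replace(variants["A"], bundles=[])
        loads = axial_step(0.0)
        # femur floated above the dish: no contact either
        r = residual(np.array([0.0, 0.0, 5.0, 0.0, 0.0]), 0.0, loads, empty)
        assert np.allclose(r, 0.0)

    def test_symmetric_configuration_zero_lateral_components(self, variants):
        # mirror-symmetric system (contact only; the ligament apparatus is
        # intentionally medially dominant) under a pure axial load
        symmetric = dataclasses.replace(variants["A"], bundles=[])
        r = residual(np.array([0.0, 0.0, -2.2, 0.0, 0.0]), 0.0,
                     axial_step(500.0), symmetric)
        assert r[2] == pytest.approx(0.0, abs=1e-9)   # ML force
        assert r[3] == pytest.approx(0.0, abs=1e-9)   # VV moment

    def test_matches_independent_wrench_oracle(self, variants, rng):
        model = variants["A"]
        for _ in range(50):
            dofs = np.concatenate([rng.uniform(-2, 2, 2), rng.uniform(-2.6, -1.6, 1),
                                   rng.uniform(-2, 2, 2)])
            dofs = dofs[[0, 1, 2, 3, 4]]
            flexion = rng.uniform(0, 60)
            loads = LoadStep(time=0.0, flexion=flexion,
                             external_force=rng.uniform(-100, 800, 3),
                             external_moment=rng.uniform(-10, 10, 2))
            r = residual(dofs, flexion, loads, model)
            force, moment = independent_wrench(
                model, JointPose(flexion=flexion).with_secondary(dofs), loads
            )
            assert np.allclose(r[:3], force, atol=1e-9)
            assert np.allclose(r[3:], moment[:2] / 1e3, atol=1e-9)

    def test_nan_input_rejected(self, variants):
        with pytest.raises(ValueError):
            residual(np.array([np.nan, 0, 0, 0, 0]), 0.0, axial_step(100.0),
                     variants["A"])


class TestSolveStep:
    def test_two_point_statics_oracle(self, variants):
        """Ligaments off: mcf = F/2 + M/(2c), lcf = F/2 - M/(2c) to 0.1%."""
        empty = dataclasses.replace(variants["A"], bundles=[])
        step = solve_step(0.0, axial_step(1000.0, m_add=11.0), empty)
        assert step.converged
        c = empty.geometry.compartment_half_spacing / 1000.0   # m
        mcf_exp = 1000.0 / 2 + 11.0 / (2 * c)
        lcf_exp = 1000.0 / 2 - 11.0 / (2 * c)
        assert step.contact.mcf == pytest.approx(mcf_exp, rel=1e-3)
        assert step.contact.lcf == pytest.approx(lcf_exp, rel=1e-3)
        assert lcf_exp > 0

    def test_symmetric_axial_splits_evenly(self, variants):
        empty = dataclasses.replace(variants["A"], bundles=[])
        step = solve_step(0.0, axial_step(1000.0), empty)
        assert step.converged
        assert step.contact.mcf == pytest.approx(500.0, abs=0.5)
        assert step.contact.lcf == pytest.approx(500.0, abs=0.5)
        assert step.pose.ml_translation == pytest.approx(0.0, abs=1e-6)

    def test_solution_invariant_to_initial_guess_perturbation(self, variants):
        model = variants["A"]
        loads = axial_step(800.0, m_add=5.0, flexion=10.0)
        ref = solve_step(10.0, loads, model)
        assert ref.converged
        base = ref.pose.secondary_dofs()
        for delta in ([0.5, 0, 0, 0.5, 0], [-0.5, 0.3, 0.2, -0.5, 0.5],
                      [0, -0.5, -0.3, 0, -0.5]):
            step = solve_step(10.0, loads, model, initial_guess=base + np.array(delta))
            assert step.converged
            assert np.allclose(step.pose.secondary_dofs(), base, atol=1e-6)

    def test_converged_step_meets_component_tolerances(self, variants):
        step = solve_step(15.0, axial_step(1500.0, m_add=15.0, flexion=15.0),
                          variants["A"])
        assert step.converged
        r = residual(step.pose.secondary_dofs(), 15.0,
                     axial_step(1500.0, m_add=15.0, flexion=15.0), variants["A"])
        assert np.all(np.abs(r[:3]) < FORCE_TOL_N)
        assert np.all(np.abs(r[3:]) < MOMENT_TOL_NM)


class TestSimulateGait:
    def test_constant_profile_reaches_steady_state(self, variants):
        steps = [LoadStep(time=0.1 * i, flexion=5.0,
                          external_force=np.array([10.0, 5.0, 700.0]),
                          external_moment=np.array([8.0, 1.0]))
                 for i in range(8)]
        result = simulate_gait(variants["A"], steps)
        first = result.steps[1].pose.secondary_dofs()
        for s in result.steps[2:]:
            assert np.allclose(s.pose.secondary_dofs(), first, atol=1e-8)

    def test_default_profile_tcf_has_two_stance_peaks(self, gait_results):
        tcf = gait_results["A"].trace("tcf")
        pc = gait_results["A"].percent_cycle
        interior = (tcf[1:-1] > tcf[:-2]) & (tcf[1:-1] > tcf[2:])
        peaks = pc[1:-1][interior]
        # a local maximum in each stance window, and the global peak in stance
        assert any(0 < p < 50 for p in peaks)
        assert any(40 < p < 60 for p in peaks)
        assert pc[np.argmax(tcf)] < 60

    def test_warm_vs_cold_start_path_independence(self, variants, default_profile):
        model = variants["A"]
        warm = simulate_gait(model, default_profile, warm_start=True)
        cold = simulate_gait(model, default_profile, warm_start=False)
        for sw, sc in zip(warm.steps, cold.steps):
            assert np.allclose(sw.pose.secondary_dofs(), sc.pose.secondary_dofs(),
                               atol=1e-4)

    def test_empty_and_nonmonotone_profiles_rejected(self, variants):
        with pytest.raises(ValueError):
            simulate_gait(variants["A"], [])
        steps = [axial_step(100.0), axial_step(100.0)]
        with pytest.raises(ValueError, match="increasing"):
            simulate_gait(variants["A"], steps)

    def test_mirrored_model_under_mirrored_loads_swaps_traces(self, variants,
                                                              default_profile):
        from kneesim.contact import mirror_model

        model = variants["A"]
        mirrored = mirror_model(model)
        flipped = [LoadStep(time=s.time, flexion=s.flexion,
                            external_force=s.external_force * np.array([1, -1, 1]),
                            external_moment=-s.external_moment)
                   for s in default_profile]
        # short sub-cycle is enough to exercise stance loading
        r = simulate_gait(model, default_profile[:35])
        rm = simulate_gait(mirrored, flipped[:35])
        assert np.allclose(r.trace("mcf"), rm.trace("lcf"), atol=1e-6)
        assert np.allclose(r.trace("lcf"), rm.trace("mcf"), atol=1e-6)
        assert np.allclose(r.trace("ml_translation"),
                           -rm.trace("ml_translation"), atol=1e-9)
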