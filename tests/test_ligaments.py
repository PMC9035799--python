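"""Ligament constitutive law, parameter registry, apparatus and calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kneesim.kinematics import JointPose
from kneesim.ligaments import (
    BUNDLE_CLASSES,
    BUNDLE_NAMES,
    ConfigError,
    LigamentParams,
    build_default_bundles,
    bundle_length,
    bundle_lengths,
    calibrate,
    ligament_force,
    load_param_table,
    mirror_bundle,
    slack_length_from_reference,
    strain_of,
)

# ---------------------------------------------------------------- force law


@pytest.mark.parametrize(
    "eps, k, e1, expected",
    [
        (-0.05, 2000.0, 0.03, 0.0),       # slack branch
        (0.06, 2750.0, 0.03, 82.5),       # toe/linear junction: k * e1
        (0.03, 2000.0, 0.03, 15.0),       # toe: k * eps^2 / (4 e1)
        (0.10, 9000.0, 0.03, 630.0),      # linear: k * (eps - e1)
        (0.0, 5000.0, 0.03, 0.0),
    ],
)
def test_force_law_hand_values(eps, k, e1, expected):
    p = LigamentParams("x", 0.0, k, e1)
    assert ligament_force(eps, p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("params", load_param_table(), ids=lambda p: p.name)
def test_force_law_c1_continuity_every_class(params):
    """Both branches agree in value and slope at eps = 2*eps1."""
    k, e1 = params.stiffness, params.linear_limit_strain
    x = 2.0 * e1
    quad = k * x**2 / (4 * e1)
    lin = k * (x - e1)
    assert abs(quad - lin) < 1e-9 * k
    h = 1e-6
    slope_lo = (ligament_force(x, params) - ligament_force(x - h, params)) / h
    slope_hi = (ligament_force(x + h, params) - ligament_force(x, params)) / h
    assert abs(slope_hi - slope_lo) < 1e-3 * k


@pytest.mark.parametrize("params", load_param_table(), ids=lambda p: p.name)
def test_force_law_nonnegative_and_monotone(params):
    grid = np.linspace(-0.5, 0.5, 2001)
    f = ligament_force(grid, params)
    assert np.all(f >= 0)
    assert np.all(np.diff(f) >= -1e-12)
    assert np.all(f[grid <= 0] == 0)


@given(
    eps=st.floats(-0.5, 0.5),
    k=st.floats(100.0, 20000.0),
    e1=st.floats(0.005, 0.1),
)
def test_force_law_branches_property(eps, k, e1):
    p = LigamentParams("x", 0.0, k, e1)
    f = ligament_force(eps, p)
    if eps <= 0:
        assert f == 0.0
    elif eps <= 2 * e1:
        assert f == pytest.approx(k * eps**2 / (4 * e1))
    else:
        assert f == pytest.approx(k * (eps - e1))


# ------------------------------------------------------- strain and slack


def test_strain_hand_values():
    assert strain_of(104.0, 104.0) == 0.0
    assert strain_of(104.0, 100.0) == pytest.approx(0.04)
    assert strain_of(95.0, 100.0) == pytest.approx(-0.05)
    with pytest.raises(ConfigError):
        strain_of(100.0, 0.0)


def test_slack_length_round_trips_reference_strain():
    assert slack_length_from_reference(50.0, 0.0) == 50.0
    l0 = slack_length_from_reference(100.0, 0.04)
    assert l0 == pytest.approx(96.1538, abs=1e-4)
    assert strain_of(100.0, l0) == pytest.approx(0.04, abs=1e-15)
    # negative reference strain (slack at reference) gives l0 > l_ref
    l0 = slack_length_from_reference(100.0, -0.10)
    assert l0 == pytest.approx(111.1111, abs=1e-4)
    assert strain_of(100.0, l0) == pytest.approx(-0.10, abs=1e-15)
    with pytest.raises(ConfigError):
        slack_length_from_reference(100.0, -1.0)


# ------------------------------------------------------------ bundle length


def test_bundle_length_axis_aligned_cases(base_model):
    b = base_model.bundles[0]
    b = type(b)(
        name="t", params=b.params, origin=np.zeros(3),
        insertion=np.array([0.0, -30.0, 0.0]), side_tag="medial",
    )
    assert bundle_length(b, JointPose()) == pytest.approx(30.0)
    # femur moved 10 mm superior == tibia 10 mm inferior: collinear stretch
    assert bundle_length(b, JointPose(si_translation=10.0)) == pytest.approx(40.0)


def test_bundle_length_matches_independent_transform_oracle(base_model, rng):
    from scipy.spatial.transform import Rotation

    bundles = base_model.bundles
    for _ in range(100):
        pose = JointPose(*rng.uniform(-30, 30, size=3), *rng.uniform(-10, 10, size=3))
        R = Rotation.from_euler(
            "ZXY",
            [pose.flexion, -pose.varus_valgus, -pose.internal_external],
            degrees=True,
        ).as_matrix()
        t = np.array([pose.ap_translation, pose.si_translation, -pose.ml_translation])
        b = bundles[rng.integers(len(bundles))]
        expected = np.linalg.norm(R @ b.origin + t - b.insertion)
        assert bundle_length(b, pose) == pytest.approx(expected, abs=1e-9)


# -------------------------------------------------------------- calibration


def test_calibration_recovers_reference_strain_at_random_poses(base_model, rng):
    for _ in range(20):
        pose = JointPose(
            flexion=rng.uniform(-5, 5),
            varus_valgus=rng.uniform(-3, 3),
            internal_external=rng.uniform(-3, 3),
            ap_translation=rng.uniform(-3, 3),
            ml_translation=rng.uniform(-3, 3),
            si_translation=rng.uniform(-3, 3),
        )
        calibrated = calibrate(base_model.bundles, pose)
        lengths = bundle_lengths(calibrated, pose)
        for b, l in zip(calibrated, lengths):
            assert strain_of(l, b.slack_length) == pytest.approx(
                b.params.reference_strain, abs=1e-12
            )


def test_calibrated_tension_composes_hand_values(base_model):
    pose = JointPose()
    calibrated = {b.name: b for b in calibrate(base_model.bundles, pose)}
    # aMCL carries its reference-strain tension: k=2750, eps=0.04 > 2*0.03 is
    # false (0.04 < 0.06) -> toe branch 2750*0.04^2/(4*0.03)
    b = calibrated["aMCL"]
    eps = strain_of(bundle_length(b, pose), b.slack_length)
    assert ligament_force(eps, b.params) == pytest.approx(2750 * 0.04**2 / 0.12)
    # aPCL has negative reference strain: slack, zero tension at calibration
    b = calibrated["aPCL"]
    eps = strain_of(bundle_length(b, pose), b.slack_length)
    assert eps == pytest.approx(-0.10, abs=1e-12)
    assert ligament_force(eps, b.params) == 0.0


def test_negative_reference_strain_engages_only_after_relative_elongation():
    p = LigamentParams("aPCL", -0.10, 9000.0)
    l_ref = 30.0
    l0 = slack_length_from_reference(l_ref, p.reference_strain)
    # engagement exactly when length reaches l0, i.e. after |eps_r|/(1+eps_r)
    # relative elongation from the reference length
    needed = abs(p.reference_strain) / (1 + p.reference_strain)
    assert ligament_force(strain_of(l_ref * (1 + needed * 0.999), l0), p) == 0.0
    assert ligament_force(strain_of(l_ref * (1 + needed * 1.001), l0), p) > 0.0


def test_zero_length_bundle_at_calibration_errors(base_model):
    b0 = base_model.bundles[0]
    degenerate = type(b0)(
        name="bad", params=b0.params, origin=np.zeros(3),
        insertion=np.zeros(3), side_tag="medial",
    )
    with pytest.raises(ConfigError, match="zero-length"):
        calibrate([degenerate], JointPose())


# ---------------------------------------------------- registry and apparatus


def test_param_table_defaults():
    table = load_param_table()
    assert len(table) == len(BUNDLE_CLASSES) == 18
    by_name = {p.name: p for p in table}
    assert by_name["aMCL"].reference_strain == 0.04
    assert by_name["aMCL"].stiffness == 2750.0
    assert by_name["aPCL"].reference_strain == -0.10
    assert by_name["pPCL"].reference_strain == -0.05
    assert by_name["PC"].stiffness == 1000.0


def test_param_table_missing_class_errors():
    rows = [
        {"name": p.name, "reference_strain": p.reference_strain,
         "stiffness_N": p.stiffness, "linear_limit_strain": p.linear_limit_strain}
        for p in load_param_table() if p.name != "cMCL"
    ]
    with pytest.raises(ConfigError, match="cMCL"):
        load_param_table({"bundles": rows})


def test_invalid_params_rejected():
    with pytest.raises(ConfigError):
        LigamentParams("x", 0.0, -1.0)
    with pytest.raises(ConfigError):
        LigamentParams("x", 0.5, 1000.0)


def test_apparatus_counts_and_sides():
    bundles = build_default_bundles()
    assert len(bundles) == 21
    assert [b.name for b in bundles] == list(BUNDLE_NAMES)
    by_side = {}
    for b in bundles:
        by_side.setdefault(b.side_tag, []).append(b.name)
    assert sorted(by_side["medial"]) == ["aDM", "aMCL", "cMCL", "pDM", "pMCL"]
    assert sorted(by_side["lateral"]) == ["aALL", "aLCL", "pALL", "pLCL"]
    assert sorted(by_side["posterior"]) == ["PC1", "PC2", "PC3", "PC4"]
    assert sorted(by_side["cruciate"]) == ["aPCL", "pPCL"]
    # medial insertions sit at negative z, lateral at positive z
    for b in bundles:
        if b.side_tag == "medial":
            assert b.insertion[2] < 0
        if b.side_tag == "lateral":
            assert b.insertion[2] > 0
    # the four posterior-capsule bundles share the single PC parameter row
    pc = [b for b in bundles if b.name.startswith("PC")]
    assert all(b.params.stiffness == 1000.0 and b.params.reference_strain == 0.07
               for b in pc)


def test_apparatus_missing_attachment_errors():
    from kneesim.ligaments import load_attachments

    attach = load_attachments()
    del attach["cMCL"]
    with pytest.raises(ConfigError, match="cMCL"):
        build_default_bundles(attachments=attach)


def test_mirror_bundle_swaps_sides_and_is_involution(base_model):
    for b in base_model.bundles:
        m = mirror_bundle(b)
        assert np.allclose(m.origin * [1, 1, -1], b.origin)
        if b.side_tag == "medial":
            assert m.side_tag == "lateral"
        mm = mirror_bundle(m)
        assert np.allclose(mm.origin, b.origin)
        assert mm.side_tag == b.side_tag
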