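"""Shared fixtures: the default knee model, the A-G variants and one full
simulated gait cycle per variant (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kneesim as ks

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

LABELS = tuple("ABCDEFG")


@pytest.fixture(scope="session")
def base_model() -> ks.KneeModel:
    return ks.default_model()


@pytest.fixture(scope="session")
def variants(base_model) -> dict[str, ks.KneeModel]:
    return {label: ks.build_model_variant(label, base_model) for label in LABELS}


@pytest.fixture(scope="session")
def default_profile() -> list[ks.LoadStep]:
    return ks.generate_profile(ks.GaitGenParams(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def gait_results(variants, default_profile) -> dict[str, ks.GaitResult]:
    """One simulated gait cycle per A-G variant on the default profile."""
    return {
        label: ks.simulate_gait(model, default_profile)
        for label, model in variants.items()
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
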