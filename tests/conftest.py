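"""Shared fixtures: tiny hand-built datasets, preset model objects, and
session-scoped simulation sweeps reused by several tests."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from bivlmm import (
    BLMMFit,
    ErrorCov,
    FixedEffects,
    LongitudinalDataset,
    RandomEffectsCov,
    glaucoma_presets,
    run_scenario,
    simulate_dataset,
)

PRESET_SIGMA = np.array([
    [1.65, 1.13, -0.11, 0.13],
    [1.13, 36.5, 0.40, -1.13],
    [-0.11, 0.40, 0.09, 0.03],
    [0.13, -1.13, 0.03, 0.81],
])


def make_fit(Sigma=None, s1sq=2.0, s2sq=19.0, s12=0.0, error_model="independent",
             fixed=None) -> BLMMFit:
    """A BLMMFit built directly from parameters (no fitting), for plug-in summaries."""
    if Sigma is None:
        Sigma = PRESET_SIGMA
    if fixed is None:
        fixed = FixedEffects(alpha0=-2.0, alpha1=-0.2, beta0=53.0, beta1=-0.4)
    return BLMMFit(
        fixed=fixed,
        re_cov=RandomEffectsCov(np.asarray(Sigma, dtype=float)),
        err=ErrorCov(sigma1_sq=s1sq, sigma2_sq=s2sq, sigma12=s12),
        loglik=0.0,
        n_subjects=300,
        error_model=error_model,
        converged=True,
    )


@pytest.fixture
def preset_fit():
    return make_fit()


@pytest.fixture
def toy_dataset():
    """One subject, both outcomes at times 0 and 0.5."""
    obs = pd.DataFrame({
        "subject_id": ["s1"] * 4,
        "outcome": ["MD", "MD", "VA", "VA"],
        "time": [0.0, 0.5, 0.0, 0.5],
        "value": [-2.0, -2.1, 52.0, 51.0],
    })
    return LongitudinalDataset.from_frames(obs, "MD", "VA")


@pytest.fixture
def small_homogeneous():
    """60 stable-class subjects on the preset grid (fast to fit)."""
    spec = replace(glaucoma_presets(), n_subjects=60, p_progressive=0.0)
    data, _ = simulate_dataset(spec, seed=2024)
    return data


@pytest.fixture(scope="session")
def scenario_a_sweep():
    """Scenario A at 5/10/20% progressive, 100 replicates per level."""
    return run_scenario("A", levels=[0.05, 0.10, 0.20], n_replicates=100, seed=20_170_817)


@pytest.fixture(scope="session")
def scenario_b50():
    return run_scenario("B", levels=[0.5], n_replicates=100, seed=50)


@pytest.fixture(scope="session")
def scenario_c08():
    return run_scenario("C", levels=[0.8], n_replicates=100, seed=80)
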