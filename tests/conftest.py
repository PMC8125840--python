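import numpy as np
import pytest

from stsfrail import CohortSpec, SubjectProfile, planted_effects

#: The eight features significantly different between groups in the
#: reference cohort -- the canonical RFE candidate set.
CANDIDATES_8 = [
    "duration_s",
    "mean_hip_angular_velocity_range",
    "mean_hip_power_range",
    "mean_knee_angular_velocity_range",
    "mean_vertical_power_range",
    "cv_hip_angular_velocity_range",
    "cv_vertical_velocity_range",
    "cv_vertical_power_range",
]

#: The published optimal trio: slowness, weakness, exhaustion indicators.
OPTIMAL_TRIO = [
    "mean_hip_angular_velocity_range",
    "mean_vertical_power_range",
    "cv_vertical_power_range",
]


@pytest.fixture
def noiseless_profile():
    """Deterministic subject profile with grid-aligned cycles and no noise."""
    return SubjectProfile(
        group=0,
        mass=70.0,
        height=1.65,
        cycle_duration=1.2,
        pause_duration=0.3,
        thigh_amplitude=1.30,
        trunk_lean=0.35,
        vertical_rise=0.45,
        cycle_cv=0.0,
        noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def null_spec(seed: int, n_robust: int = 42, n_frail: int = 60) -> CohortSpec:
    """Cohort spec with zero group effect on every feature."""
    return CohortSpec(
        n_robust=n_robust, n_frail=n_frail, seed=seed, feature_effects={}
    )


def planted_spec(seed: int, d: float = 1.5, features=None) -> CohortSpec:
    """Cohort spec planting a standardized shift d on the optimal trio only."""
    return CohortSpec(
        seed=seed, feature_effects=planted_effects(features or OPTIMAL_TRIO, d)
    )
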