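"""Synthetic 5xSTS cohorts with known group structure.

Two generation paths are provided:

* a waveform path (:func:`generate_recording`) that synthesises segment pitch
  and vertical displacement time series for five stand-sit cycles, so the
  whole extraction pipeline can be exercised against closed-form ground
  truth; and
* a fast table path (:func:`generate_feature_table`) that draws the 17
  sensor-derived features directly from parametric distributions with
  configurable standardized group shifts, for statistical unit tests of the
  screening/selection stages.

The default cohort mirrors the reference study conditions: 42 robust and 60
pre-frail/frail subjects sampled at 100 Hz, with the frail group slower
(longer cycles, hence lower angular velocities), weaker (lower vertical rise,
hence lower powers) and more variable cycle-to-cycle (higher CVs).
Demographics (mass, height) follow the published group means and SDs.

Waveform family: within one cycle of duration ``d`` the thigh pitch moves
seated -> standing -> seated along a raised cosine, which makes the whole
cycle a pure cosine ``theta_s - (A/2)(1 - cos(2*pi*t/d))``; the trunk lean and
shank modulation are raised-cosine pulses on the same phase, and the vertical
displacement rises by a cubic smoothstep and mirrors back.  All waveforms are
twice differentiable with closed-form derivatives (see
:func:`closed_form_ranges`), which downstream recovery tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, STSRecording, moment_of_inertia

__all__ = [
    "SubjectProfile",
    "CohortSpec",
    "DEFAULT_PROFILE_EFFECTS",
    "DEFAULT_FEATURE_EFFECTS",
    "FEATURE_BASELINES",
    "draw_subject_profile",
    "generate_recording",
    "generate_cohort_recordings",
    "generate_feature_table",
    "closed_form_ranges",
    "planted_effects",
]

# seated/standing pitch conventions (rad, from vertical); fixtures, not claims
THIGH_SEATED = 1.40
SHANK_BASE = 0.35
LEAD_IN_S = 1.0
LEAD_OUT_S = 1.0

#: Robust-group base distributions for the generator parameters:
#: name -> (mean, SD, lower truncation).  Units: kg, m, s, rad, dimensionless.
_PROFILE_BASELINES = {
    "cycle_duration": (1.20, 0.15, 0.50),
    "pause_duration": (0.30, 0.05, 0.10),
    "thigh_amplitude": (1.30, 0.10, 0.60),
    "trunk_lean": (0.35, 0.05, 0.10),
    "shank_amplitude": (0.10, 0.02, 0.02),
    "vertical_rise": (0.45, 0.05, 0.15),
    "cycle_cv": (0.08, 0.03, 0.0),
}

#: Published demographics: group -> {param: (mean, SD, lower truncation)}.
_DEMOGRAPHICS = {
    0: {"mass": (66.77, 12.21, 35.0), "height": (1.6209, 0.0734, 1.30)},
    1: {"mass": (78.61, 19.95, 35.0), "height": (1.6490, 0.1077, 1.30)},
}

#: Default standardized shifts applied to frail-group generator parameters:
#: slower cycles, reduced vertical rise, higher cycle-to-cycle variability.
DEFAULT_PROFILE_EFFECTS: Mapping[str, float] = {
    "cycle_duration": 1.2,
    "vertical_rise": -0.6,
    "cycle_cv": 0.8,
}

#: Feature baselines for the direct table path: name -> (mean, SD).
#: Magnitudes chosen to be physiologically plausible for the waveform
#: defaults (rad, rad/s, W, m/s, s; CVs dimensionless).
FEATURE_BASELINES: Mapping[str, tuple[float, float]] = {
    "duration_s": (10.0, 2.0),
    "mean_hip_angle_range": (1.65, 0.15),
    "cv_hip_angle_range": (0.12, 0.04),
    "mean_hip_angular_velocity_range": (8.6, 1.2),
    "cv_hip_angular_velocity_range": (0.12, 0.04),
    "mean_hip_power_range": (95.0, 25.0),
    "cv_hip_power_range": (0.15, 0.05),
    "mean_knee_angle_range": (1.40, 0.15),
    "cv_knee_angle_range": (0.12, 0.04),
    "mean_knee_angular_velocity_range": (7.3, 1.1),
    "cv_knee_angular_velocity_range": (0.12, 0.04),
    "mean_knee_power_range": (12.0, 3.5),
    "cv_knee_power_range": (0.15, 0.05),
    "mean_vertical_velocity_range": (2.25, 0.30),
    "cv_vertical_velocity_range": (0.12, 0.04),
    "mean_vertical_power_range": (450.0, 120.0),
    "cv_vertical_power_range": (0.15, 0.05),
}

#: Default standardized group shifts for the direct table path, planted on
#: the eight features significant in the reference cohort, with the reported
#: directions (frail: longer duration, slower velocities, lower powers,
#: higher CVs); the remaining nine features are exchangeable between groups.
DEFAULT_FEATURE_EFFECTS: Mapping[str, float] = {
    "duration_s": 1.0,
    "mean_hip_angular_velocity_range": -1.0,
    "mean_knee_angular_velocity_range": -0.9,
    "mean_hip_power_range": -0.6,
    "mean_vertical_power_range": -0.7,
    "cv_hip_angular_velocity_range": 0.6,
    "cv_vertical_velocity_range": 0.6,
    "cv_vertical_power_range": 0.7,
}


@dataclass(frozen=True)
class SubjectProfile:
    """Generator parameters for one subject's 5xSTS trial."""

    group: int
    mass: float
    height: float
    cycle_duration: float
    pause_duration: float
    thigh_amplitude: float
    trunk_lean: float
    vertical_rise: float
    cycle_cv: float
    noise_sd: float
    shank_amplitude: float = 0.10

    def __post_init__(self):
        if self.group not in (0, 1):
            raise ValueError(f"group must be 0 or 1, got {self.group}")
        if self.mass <= 0 or self.height <= 0:
            raise ValueError("mass and height must be positive")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        if not 0 <= self.cycle_cv < 1:
            raise ValueError("cycle_cv must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-group cohort.

    Effects are standardized shifts (in baseline-SD units) applied to the
    frail group: ``profile_effects`` act on generator parameters for the
    waveform path, ``feature_effects`` act directly on feature distributions
    for the table path.  Identical specs (including seed) yield bit-identical
    cohorts.
    """

    n_robust: int = 42
    n_frail: int = 60
    seed: int = 0
    sampling_rate: float = 100.0
    noise_sd: float = 0.01
    profile_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_EFFECTS)
    )
    feature_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS)
    )

    def __post_init__(self):
        if self.n_robust + self.n_frail < 4:
            raise ValueError("cohort must have at least 4 subjects")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        unknown = set(self.profile_effects) - set(_PROFILE_BASELINES)
        if unknown:
            raise ValueError(f"unknown profile-effect parameters: {sorted(unknown)}")
        unknown = set(self.feature_effects) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature-effect names: {sorted(unknown)}")


def planted_effects(features: Mapping[str, float] | list[str], d: float = 1.5) -> dict[str, float]:
    """Effect map planting a standardized shift ``d`` on the given features.

    A list plants ``+d`` on every listed feature; a mapping gives per-feature
    signed shifts.  Everything else is left at zero effect.
    """
    if isinstance(features, Mapping):
        return dict(features)
    return {name: d for name in features}


def _draw_trunc(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    """Normal draw truncated below by redrawing (bounded attempts)."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return float(lower)


def draw_subject_profile(
    spec: CohortSpec, group: int, rng: np.random.Generator
) -> SubjectProfile:
    """Draw one subject's generator parameters for the given group.

    Frail-group (``group=1``) parameter means are shifted by
    ``spec.profile_effects[param] * baseline SD``; demographics follow the
    published group distributions.
    """
    if group not in (0, 1):
        raise ValueError(f"group must be 0 or 1, got {group}")
    params = {}
    for name, (mean, sd, lower) in _PROFILE_BASELINES.items():
        shift = spec.profile_effects.get(name, 0.0) if group == 1 else 0.0
        params[name] = _draw_trunc(rng, mean + shift * sd, sd, lower)
    params["cycle_cv"] = min(params["cycle_cv"], 0.4)
    demo = _DEMOGRAPHICS[group]
    mass = _draw_trunc(rng, *demo["mass"])
    height = _draw_trunc(rng, *demo["height"])
    return SubjectProfile(
        group=group, mass=mass, height=height, noise_sd=spec.noise_sd, **params
    )


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _raised_cosine(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _smoothstep(w: np.ndarray) -> np.ndarray:
    w = np.clip(w, 0.0, 1.0)
    return w * w * (3.0 - 2.0 * w)


def generate_recording(
    profile: SubjectProfile,
    rng: np.random.Generator,
    sampling_rate: float = 100.0,
    return_cycles: bool = False,
):
    """Synthesise one noisy 5xSTS recording from a subject profile.

    Exactly five stand-sit cycles separated by seated pauses, with seated
    lead-in/lead-out; per-cycle durations and amplitudes are jittered with
    relative SD ``cycle_cv``, and white noise of SD ``noise_sd`` is added to
    the three angle channels.  With ``return_cycles=True`` the realized
    per-cycle ground truth (duration in samples, amplitudes) is returned
    alongside the recording, for recovery tests.
    """
    fs = sampling_rate
    jitter = lambda: 1.0 + profile.cycle_cv * float(rng.standard_normal())  # noqa: E731
    cycles = []
    for _ in range(5):
        # cycle extent realized on the sample grid (nearest sample) so that
        # identical parameters yield bit-identical per-cycle waveforms
        d = max(profile.cycle_duration * jitter(), 0.3 * profile.cycle_duration)
        cycles.append(
            {
                "n": max(int(round(d * fs)), 4),
                "amp": max(profile.thigh_amplitude * jitter(), 0.1),
                "lean": max(profile.trunk_lean * jitter(), 0.0),
                "sh": max(profile.shank_amplitude * jitter(), 0.0),
                "rise": max(profile.vertical_rise * jitter(), 0.05),
            }
        )

    n_lead = int(round(LEAD_IN_S * fs))
    n_pause = int(round(profile.pause_duration * fs))
    n_out = int(round(LEAD_OUT_S * fs))
    n = n_lead + sum(c["n"] for c in cycles) + 4 * n_pause + n_out + 1

    trunk = np.zeros(n)
    thigh = np.full(n, THIGH_SEATED)
    shank = np.full(n, SHANK_BASE)
    vert = np.zeros(n)

    i0 = n_lead
    for c in cycles:
        nc = c["n"]
        u = np.arange(nc + 1) / nc
        sl = slice(i0, i0 + nc + 1)
        rc = _raised_cosine(u)
        thigh[sl] = THIGH_SEATED - c["amp"] * rc
        trunk[sl] = c["lean"] * rc
        shank[sl] = SHANK_BASE + c["sh"] * rc
        vert[sl] = c["rise"] * np.where(
            u <= 0.5, _smoothstep(2.0 * u), _smoothstep(2.0 * (1.0 - u))
        )
        i0 += nc + n_pause

    if profile.noise_sd > 0:
        trunk = trunk + rng.normal(0.0, profile.noise_sd, n)
        thigh = thigh + rng.normal(0.0, profile.noise_sd, n)
        shank = shank + rng.normal(0.0, profile.noise_sd, n)

    rec = STSRecording(
        sampling_rate=fs,
        trunk_pitch=trunk,
        thigh_pitch=thigh,
        shank_pitch=shank,
        vert_disp=vert,
        mass=profile.mass,
        height=profile.height,
    )
    return (rec, cycles) if return_cycles else rec


def closed_form_ranges(profile: SubjectProfile) -> dict[str, float]:
    """Exact per-cycle range values implied by the noiseless waveforms.

    Valid for ``cycle_cv = 0`` and ``noise_sd = 0``.  With cycle duration
    ``d``, joint amplitudes ``A_hip = trunk_lean + thigh_amplitude`` and
    ``A_knee = thigh_amplitude + shank_amplitude``, and vertical rise ``r``:

    * angle range = ``A``
    * angular-velocity range = ``2*pi*A/d``
    * angular-power range = ``2*I*A^2*pi^3/d^3``
    * vertical-velocity range = ``6*r/d``
    * vertical-power range = ``32*sqrt(3)*m*r^2/d^3``

    plus ``duration_s = 5*d + 4*pause``.
    """
    d = profile.cycle_duration
    a_hip = profile.trunk_lean + profile.thigh_amplitude
    a_knee = profile.thigh_amplitude + profile.shank_amplitude
    r = profile.vertical_rise
    I_hip = moment_of_inertia("trunk", profile.mass, profile.height)
    I_knee = moment_of_inertia("shank", profile.mass, profile.height)
    pi = math.pi
    return {
        "duration_s": 5 * d + 4 * profile.pause_duration,
        "hip_angle_range": a_hip,
        "hip_angular_velocity_range": 2 * pi * a_hip / d,
        "hip_power_range": 2 * I_hip * a_hip ** 2 * pi ** 3 / d ** 3,
        "knee_angle_range": a_knee,
        "knee_angular_velocity_range": 2 * pi * a_knee / d,
        "knee_power_range": 2 * I_knee * a_knee ** 2 * pi ** 3 / d ** 3,
        "vertical_velocity_range": 6 * r / d,
        "vertical_power_range": 32 * math.sqrt(3) * profile.mass * r ** 2 / d ** 3,
    }


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_streams(spec: CohortSpec) -> tuple[list, list]:
    """Independent per-subject random streams, split per group by counter so
    adding subjects to either group never perturbs earlier ones."""
    root = np.random.SeedSequence(spec.seed)
    ss_robust, ss_frail = root.spawn(2)
    return ss_robust.spawn(spec.n_robust), ss_frail.spawn(spec.n_frail)


def generate_cohort_recordings(
    spec: CohortSpec,
) -> list[tuple[str, int, SubjectProfile, STSRecording]]:
    """Generate the full cohort of synthetic recordings.

    Returns ``(subject_id, status, profile, recording)`` tuples, robust
    subjects first.  Deterministic in ``spec`` (including the seed).
    """
    robust_ss, frail_ss = _subject_streams(spec)
    out = []
    for group, streams, tag in ((0, robust_ss, "R"), (1, frail_ss, "F")):
        for i, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            profile = draw_subject_profile(spec, group, rng)
            rec = generate_recording(profile, rng, spec.sampling_rate)
            out.append((f"{tag}{i + 1:03d}", group, profile, rec))
    return out


def generate_feature_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subjects x features table directly from parametric distributions.

    Each feature is normal with the baseline mean and SD; frail-group means
    are shifted by ``spec.feature_effects[name] * SD``.  Features are mutually
    independent, so unshifted features are exchangeable between the groups.
    Columns: ``subject_id``, the 17 canonical features, ``status``.
    """
    if spec.n_robust < 2 or spec.n_frail < 2:
        raise ValueError("need at least 2 subjects per group")
    robust_ss, frail_ss = _subject_streams(spec)
    rows = []
    for group, streams, tag in ((0, robust_ss, "R"), (1, frail_ss, "F")):
        for i, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            row = {"subject_id": f"{tag}{i + 1:03d}"}
            for name in FEATURE_NAMES:
                mean, sd = FEATURE_BASELINES[name]
                shift = spec.feature_effects.get(name, 0.0) if group == 1 else 0.0
                row[name] = rng.normal(mean + shift * sd, sd)
            row["status"] = group
            rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *FEATURE_NAMES, "status"])


def cohort_feature_table(spec: CohortSpec) -> tuple[pd.DataFrame, list[str]]:
    """Extract the feature table from synthetic waveform recordings.

    Runs the full extraction pipeline on every generated recording; trials
    that do not segment into five cycles are excluded and their subject ids
    returned alongside the table.
    """
    from .features import InvalidTrialError, extract_features

    rows, invalid = [], []
    for sid, status, _profile, rec in generate_cohort_recordings(spec):
        try:
            fv = extract_features(rec)
        except InvalidTrialError:
            invalid.append(sid)
            continue
        rows.append({"subject_id": sid, **fv.values, "status": status})
    return pd.DataFrame(rows, columns=["subject_id", *FEATURE_NAMES, "status"]), invalid
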