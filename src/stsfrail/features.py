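"""Biomechanical feature extraction from five-times-sit-to-stand (5xSTS) recordings.

A 5xSTS trial is recorded as sagittal pitch angles of the trunk, thigh and
shank segments plus the vertical trunk displacement, sampled at a common rate
(100 Hz in the reference protocol).  This module segments the trial into its
five stand--sit cycles and computes the 17 sensor-derived features used for
frailty phenotyping: the sensor-based 5xSTS duration plus, for each of eight
primary per-cycle range signals (hip/knee angle, hip/knee angular velocity,
hip/knee angular power, vertical velocity, vertical power), the mean and the
coefficient of variation (CV = sample SD / mean) across the five cycles.

Angular power follows the rigid-segment relation ``P = I * alpha * omega``
(torque ``I*alpha`` times angular velocity); vertical power is
``m * v * a``.  Segment moments of inertia come from the adjusted
Zatsiorsky-Seluyanov (de Leva) body-segment inertia parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "G",
    "FEATURE_NAMES",
    "PRIMARY_SIGNALS",
    "PHENOTYPE_MAP",
    "SEGMENT_INERTIA_PARAMS",
    "STSRecording",
    "CycleBounds",
    "FeatureVector",
    "InvalidTrialError",
    "smooth",
    "differentiate",
    "joint_angles",
    "segment_cycles",
    "angular_power",
    "vertical_power",
    "scaled_vertical_power",
    "moment_of_inertia",
    "extract_features",
]

#: Gravitational acceleration (m/s^2).
G = 9.81

#: The eight primary per-cycle range signals, in canonical order.
PRIMARY_SIGNALS = (
    "hip_angle_range",
    "hip_angular_velocity_range",
    "hip_power_range",
    "knee_angle_range",
    "knee_angular_velocity_range",
    "knee_power_range",
    "vertical_velocity_range",
    "vertical_power_range",
)

#: Canonical names of the 17 sensor-derived features, in canonical order:
#: the 5xSTS duration, then mean and CV of each primary range signal.
FEATURE_NAMES = ("duration_s",) + tuple(
    f"{kind}_{sig}" for sig in PRIMARY_SIGNALS for kind in ("mean", "cv")
)

#: Frailty-phenotype proxied by each feature: angular/vertical velocity means
#: and the overall duration indicate slowness, angle and power means indicate
#: weakness, and every cycle-to-cycle CV indicates exhaustion.
PHENOTYPE_MAP = {
    "duration_s": "slowness",
    "mean_hip_angle_range": "weakness",
    "mean_hip_angular_velocity_range": "slowness",
    "mean_hip_power_range": "weakness",
    "mean_knee_angle_range": "weakness",
    "mean_knee_angular_velocity_range": "slowness",
    "mean_knee_power_range": "weakness",
    "mean_vertical_velocity_range": "slowness",
    "mean_vertical_power_range": "weakness",
    **{f"cv_{sig}": "exhaustion" for sig in PRIMARY_SIGNALS},
}

#: Adjusted Zatsiorsky-Seluyanov (de Leva) segment inertia parameters:
#: (mass fraction of body mass, segment length as fraction of stature,
#: sagittal radius of gyration as fraction of segment length).
#: Implementation constants; male table values.
SEGMENT_INERTIA_PARAMS = {
    "trunk": (0.4346, 0.3056, 0.372),
    "thigh": (0.1416, 0.2425, 0.329),
    "shank": (0.0433, 0.2464, 0.255),
}

#: Default zero-phase smoothing: Savitzky-Golay window length in seconds and
#: polynomial order.  At 100 Hz the window spans 25 samples, an equivalent
#: low-pass cutoff near 5 Hz -- standard for human sit-to-stand kinematics.
SMOOTH_WINDOW_S = 0.25
SMOOTH_POLYORDER = 3

#: Minimum thigh-pitch excursion (rad) for a trial to count as movement.
_MIN_AMPLITUDE = 0.2

#: |mean| below this (in feature units) makes a CV undefined rather than huge.
_CV_MEAN_TOL = 1e-9


class InvalidTrialError(ValueError):
    """A recording does not contain exactly five detectable stand-sit cycles."""

    def __init__(self, n_cycles: int, message: str | None = None):
        self.n_cycles = n_cycles
        super().__init__(
            message or f"expected 5 stand-sit cycles, detected {n_cycles}"
        )


@dataclass(frozen=True)
class STSRecording:
    """One subject's 5xSTS trial.

    Angle series are sagittal pitch relative to vertical, in radians;
    vertical displacement is in metres.  All series share ``sampling_rate``.
    """

    sampling_rate: float
    trunk_pitch: np.ndarray
    thigh_pitch: np.ndarray
    shank_pitch: np.ndarray
    vert_disp: np.ndarray
    mass: float
    height: float

    def __post_init__(self):
        object.__setattr__(self, "trunk_pitch", np.asarray(self.trunk_pitch, float))
        object.__setattr__(self, "thigh_pitch", np.asarray(self.thigh_pitch, float))
        object.__setattr__(self, "shank_pitch", np.asarray(self.shank_pitch, float))
        object.__setattr__(self, "vert_disp", np.asarray(self.vert_disp, float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mass <= 0 or self.height <= 0:
            raise ValueError("body mass and height must be positive")
        n = len(self.trunk_pitch)
        if n < 2:
            raise ValueError("series must have length >= 2")
        for name in ("thigh_pitch", "shank_pitch", "vert_disp"):
            if len(getattr(self, name)) != n:
                raise ValueError("all series must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.trunk_pitch)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class CycleBounds:
    """Sample-index intervals of the five stand-sit cycles of one trial.

    ``intervals`` are half-open ``[start, stop)`` index pairs in increasing
    order.  ``onset`` / ``offset`` are the movement start / final
    return-to-sit, in seconds from the start of the recording, located with
    sub-sample precision by linear interpolation of the threshold crossings.
    """

    intervals: tuple[tuple[int, int], ...]
    onset: float
    offset: float
    cycle_times: tuple[tuple[float, float], ...] = field(default=())

    @property
    def n_cycles(self) -> int:
        return len(self.intervals)

    def durations(self) -> np.ndarray:
        """Per-cycle durations in seconds (sub-sample crossing times)."""
        return np.array([t1 - t0 for t0, t1 in self.cycle_times])


@dataclass(frozen=True)
class FeatureVector:
    """The 17 named sensor-derived features of one 5xSTS trial.

    Undefined CVs (|mean| below tolerance) are stored as NaN.
    """

    values: dict[str, float]

    def __post_init__(self):
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing or len(self.values) != len(FEATURE_NAMES):
            raise ValueError(f"feature vector must have exactly the 17 canonical entries; missing {missing}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# signal processing
# ---------------------------------------------------------------------------

def _window_length(sampling_rate: float) -> int:
    w = int(round(SMOOTH_WINDOW_S * sampling_rate))
    w = max(w, SMOOTH_POLYORDER + 2)
    return w + 1 if w % 2 == 0 else w


def smooth(series: Sequence[float], sampling_rate: float) -> np.ndarray:
    """Zero-phase low-pass smoothing (Savitzky-Golay, ~5 Hz at 100 Hz).

    The finite symmetric kernel introduces no phase shift and reproduces
    polynomials up to the fitting order exactly, so linear trends and slow
    transitions pass through unchanged.
    """
    x = np.asarray(series, float)
    w = _window_length(sampling_rate)
    if len(x) <= w:
        return x.copy()
    return savgol_filter(x, w, SMOOTH_POLYORDER, mode="interp")


def differentiate(
    series: Sequence[float], sampling_rate: float, presmooth: bool = True
) -> np.ndarray:
    """Time derivative by central differences (one-sided at the endpoints).

    By default the series is low-pass smoothed first; pass
    ``presmooth=False`` for already-smoothed input.
    """
    x = np.asarray(series, float)
    if len(x) < 3:
        raise ValueError("series must have length >= 3 to differentiate")
    if presmooth:
        x = smooth(x, sampling_rate)
    return np.gradient(x, 1.0 / sampling_rate)


def joint_angles(recording: STSRecording) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal hip and knee joint angles from segment pitch.

    hip = trunk pitch - thigh pitch; knee = thigh pitch - shank pitch.
    """
    hip = recording.trunk_pitch - recording.thigh_pitch
    knee = recording.thigh_pitch - recording.shank_pitch
    return hip, knee


# ---------------------------------------------------------------------------
# cycle segmentation
# ---------------------------------------------------------------------------

def _crossing_time(x: np.ndarray, i: int, level: float, fs: float) -> float:
    """Linear-interpolated time at which x crosses `level` between i-1 and i."""
    if i == 0:
        return 0.0
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return i / fs
    frac = (level - x0) / (x1 - x0)
    return (i - 1 + frac) / fs


def _detect_cycles(thigh_smooth: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Detect stand-sit cycles on the smoothed thigh pitch.

    The thigh pitch is high when seated and low when standing.  Candidate
    stands are runs below the 50 % amplitude level, validated by hysteresis:
    a run must reach below the 40 % level, and consecutive runs must be
    separated by a return above the 60 % level (otherwise they are merged).
    The half-amplitude crossings bracket the middle half of a symmetric
    stand-sit transition, so each cycle's full extent is estimated by
    extending the crossing pair symmetrically by half its width.
    """
    lo_v, hi_v = float(np.min(thigh_smooth)), float(np.max(thigh_smooth))
    amp = hi_v - lo_v
    if amp < _MIN_AMPLITUDE:
        return []
    mid = lo_v + 0.5 * amp
    lower = lo_v + 0.4 * amp
    upper = lo_v + 0.6 * amp

    below = thigh_smooth < mid
    # contiguous runs of samples below the mid level
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = [0] if below[0] else []
    starts += [int(i) + 1 for i in edges if not below[i]]
    stops = [int(i) + 1 for i in edges if below[i]]
    if below[-1]:
        stops.append(len(below))
    runs = list(zip(starts, stops))

    # hysteresis: merge runs not separated by an excursion above the upper band
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and np.max(thigh_smooth[merged[-1][1]:s]) < upper:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # keep runs that actually reach the lower band (true stands, not noise)
    stands = [(s, e) for s, e in merged if np.min(thigh_smooth[s:e]) < lower]

    cycles = []
    for s, e in stands:
        t_down = _crossing_time(thigh_smooth, s, mid, fs)
        t_up = _crossing_time(thigh_smooth, e, mid, fs) if e < len(below) else (e - 1) / fs
        half = 0.5 * (t_up - t_down)
        cycles.append((t_down - half, t_up + half))
    return cycles


def segment_cycles(recording: STSRecording) -> CycleBounds:
    """Segment a 5xSTS recording into its five stand-sit cycles.

    Raises :class:`InvalidTrialError` (carrying the detected count) when the
    trial does not contain exactly five cycles.
    """
    fs = recording.sampling_rate
    thigh = smooth(recording.thigh_pitch, fs)
    cycles = _detect_cycles(thigh, fs)
    if len(cycles) != 5:
        raise InvalidTrialError(len(cycles))

    n = recording.n_samples
    intervals = []
    for t0, t1 in cycles:
        i0 = max(0, int(round(t0 * fs)))
        i1 = min(n, int(round(t1 * fs)) + 1)
        intervals.append((i0, i1))
    for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
        if b0 < a1 - 1:
            raise InvalidTrialError(5, "detected cycles overlap")
    return CycleBounds(
        intervals=tuple(intervals),
        onset=max(0.0, cycles[0][0]),
        offset=min((n - 1) / fs, cycles[-1][1]),
        cycle_times=tuple(cycles),
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def angular_power(I: float, alpha, omega):
    """Angular power ``P = I * alpha * omega`` (= torque times angular velocity), in W."""
    if I < 0:
        raise ValueError("moment of inertia must be non-negative")
    return I * np.asarray(alpha, float) * np.asarray(omega, float)


def vertical_power(m: float, v, a):
    """Vertical power ``P = m * v * a``, in W."""
    if m <= 0:
        raise ValueError("body mass must be positive")
    return m * np.asarray(v, float) * np.asarray(a, float)


def scaled_vertical_power(P, m: float, h: float, convention: str = "printed"):
    """Dimensionless body-size-scaled vertical power.

    ``convention="printed"`` divides by ``m * g^2 * h``; the conventional
    dynamic similarity scaling ``m * g * sqrt(g*h)`` is available as
    ``convention="dynamic"``.
    """
    if m <= 0 or h <= 0:
        raise ValueError("body mass and height must be positive")
    if convention == "printed":
        denom = m * G * G * h
    elif convention == "dynamic":
        denom = m * G * np.sqrt(G * h)
    else:
        raise ValueError(f"unknown scaling convention {convention!r}")
    return np.asarray(P, float) / denom


def moment_of_inertia(segment: str, mass: float, height: float) -> float:
    """Segment moment of inertia from body mass (kg) and stature (m).

    ``I = m_seg * r_gyr^2`` with the segment mass and sagittal radius of
    gyration taken from the adjusted Zatsiorsky-Seluyanov (de Leva) table.
    """
    if segment not in SEGMENT_INERTIA_PARAMS:
        raise KeyError(f"unknown segment {segment!r}")
    if mass <= 0 or height <= 0:
        raise ValueError("body mass and height must be positive")
    m_frac, len_frac, r_frac = SEGMENT_INERTIA_PARAMS[segment]
    r_gyr = r_frac * len_frac * height
    return m_frac * mass * r_gyr ** 2


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _mean_cv(per_cycle: np.ndarray) -> tuple[float, float]:
    """Mean and CV (sample SD / mean, ddof=1) of per-cycle values."""
    mean = float(np.mean(per_cycle))
    # identical cycles must give an exactly zero SD (mean rounding would
    # otherwise leave an O(ulp) residue)
    sd = 0.0 if np.ptp(per_cycle) == 0 else float(np.std(per_cycle, ddof=1))
    if abs(mean) < _CV_MEAN_TOL:
        return mean, (0.0 if sd == 0.0 else float("nan"))
    return mean, sd / mean


def extract_features(
    recording: STSRecording, bounds: CycleBounds | None = None
) -> FeatureVector:
    """Compute the 17 sensor-derived features of one 5xSTS trial.

    For each of the eight primary signals the per-cycle range (max - min
    within each cycle interval) is computed, then its mean and CV across the
    five cycles; ``duration_s`` is the movement onset to final return-to-sit.
    """
    if bounds is None:
        bounds = segment_cycles(recording)
    fs = recording.sampling_rate

    trunk = smooth(recording.trunk_pitch, fs)
    thigh = smooth(recording.thigh_pitch, fs)
    shank = smooth(recording.shank_pitch, fs)
    vert = smooth(recording.vert_disp, fs)

    hip = trunk - thigh
    knee = thigh - shank
    hip_vel = differentiate(hip, fs, presmooth=False)
    knee_vel = differentiate(knee, fs, presmooth=False)
    hip_acc = differentiate(hip_vel, fs)
    knee_acc = differentiate(knee_vel, fs)

    # trunk rotates about the hip, shank about the knee
    I_hip = moment_of_inertia("trunk", recording.mass, recording.height)
    I_knee = moment_of_inertia("shank", recording.mass, recording.height)

    v_vel = differentiate(vert, fs, presmooth=False)
    v_acc = differentiate(v_vel, fs)

    signals = {
        "hip_angle_range": hip,
        "hip_angular_velocity_range": hip_vel,
        "hip_power_range": angular_power(I_hip, hip_acc, hip_vel),
        "knee_angle_range": knee,
        "knee_angular_velocity_range": knee_vel,
        "knee_power_range": angular_power(I_knee, knee_acc, knee_vel),
        "vertical_velocity_range": v_vel,
        "vertical_power_range": vertical_power(recording.mass, v_vel, v_acc),
    }

    values = {"duration_s": bounds.offset - bounds.onset}
    for name, sig in signals.items():
        ranges = np.array(
            [np.max(sig[i0:i1]) - np.min(sig[i0:i1]) for i0, i1 in bounds.intervals]
        )
        mean, cv = _mean_cv(ranges)
        values[f"mean_{name}"] = mean
        values[f"cv_{name}"] = cv
    return FeatureVector(values=values)
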