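"""Locomotor metrics from pose-tracked landmark trajectories.

The chain mirrors standard free-swimming analysis of larval amphibians:
per-frame swim speed and cumulative distance from the body centre of
mass, tail deflection angle/velocity from the body axis, head yaw from
the inter-eye line (differentiated twice for angular acceleration),
Savitzky-Golay smoothing (window 15, order 3), dual-threshold bout
detection (speed > 3 mm/s AND tail-deflection speed > 3 deg/s), and
duration-weighted bout statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import ks_2samp

from .io_formats import LandmarkTrajectory

SAVGOL_WINDOW = 15
SAVGOL_ORDER = 3


class InputError(ValueError):
    pass


@dataclasses.dataclass
class KinematicsSeries:
    """Per-frame locomotor quantities derived from one trajectory."""

    time: np.ndarray  # s
    position_com: np.ndarray  # (n, 2) mm
    swim_speed: np.ndarray  # mm/s, smoothed
    cumulative_distance: np.ndarray  # mm
    tail_angle: np.ndarray  # degrees
    tail_velocity: np.ndarray  # deg/s, smoothed (signed)
    tail_activity: np.ndarray  # deg/s, smoothed |velocity| envelope
    head_angle: np.ndarray  # degrees vs image horizontal
    head_ang_accel: np.ndarray  # deg/s^2
    frame_rate: float

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in (
            "swim_speed",
            "cumulative_distance",
            "tail_angle",
            "tail_velocity",
            "tail_activity",
            "head_angle",
            "head_ang_accel",
        ):
            if len(getattr(self, name)) != n:
                raise InputError(f"{name} length mismatch")
        if np.any(np.diff(self.cumulative_distance) < -1e-9):
            raise InputError("cumulative_distance must be non-decreasing")


@dataclasses.dataclass(frozen=True)
class SwimBout:
    """One continuous, uninterrupted locomotor event."""

    start: float  # s
    end: float  # s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("bout end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclasses.dataclass
class BoutSummary:
    n_bouts: int
    total_swim_time: float  # s
    percent_time_swimming: float  # %
    bin_edges: np.ndarray  # s
    weighted_density: np.ndarray  # probability density over durations


def _unwrap_deg(angle: np.ndarray) -> np.ndarray:
    return np.rad2deg(np.unwrap(np.deg2rad(angle)))


def _second_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central second difference (second-order at the ends).

    The plain twice-applied central difference attenuates a 2 Hz yaw
    sampled at 30 frames/s by ~6%; the five-point stencil keeps the error
    well under 1% across the behavioral band.
    """
    n = len(y)
    d2 = np.empty(n)
    if n >= 5:
        d2[2:-2] = (-y[:-4] + 16 * y[1:-3] - 30 * y[2:-2] + 16 * y[3:-1] - y[4:]) / (
            12 * dt**2
        )
    edge = slice(0, min(2, n))
    d2[:2] = np.gradient(np.gradient(y, dt), dt)[edge]
    d2[-2:] = np.gradient(np.gradient(y, dt), dt)[-2:]
    return d2


def compute_kinematics(
    traj: LandmarkTrajectory, tail_point: str = "tail1"
) -> KinematicsSeries:
    """Derive the per-frame kinematic series from a landmark trajectory.

    Swim speed is the per-frame centre-of-mass displacement scaled to
    mm/s; the tail angle is the angle between the skull-to-centre-of-mass
    axis and the centre-of-mass-to-tail axis; the head angle is the
    orientation of the inter-eye line against the image horizontal. Speed
    and tail-velocity traces are Savitzky-Golay smoothed (window 15,
    order 3). ``tail_activity`` is the same smoothing applied to the
    rectified tail velocity: a magnitude envelope that does not dip to
    zero at every beat reversal, which is what the bout detector
    thresholds.
    """
    if traj.n_frames < SAVGOL_WINDOW:
        raise InputError(
            f"trajectory shorter than the smoothing window ({SAVGOL_WINDOW} frames)"
        )
    missing = [n for n in ("left_eye", "right_eye", "skull_center", "body_com", tail_point)
               if n not in traj.landmarks]
    if missing:
        raise InputError(f"missing landmarks: {missing}")
    fps = traj.frame_rate
    dt = 1.0 / fps
    mm = traj.pixel_scale

    com = traj.landmarks["body_com"] * mm
    disp = np.linalg.norm(np.diff(com, axis=0), axis=1)
    speed_raw = np.concatenate([[disp[0] if len(disp) else 0.0], disp]) * fps
    swim_speed = savgol_filter(speed_raw, SAVGOL_WINDOW, SAVGOL_ORDER)
    cumdist = np.concatenate([[0.0], np.cumsum(disp)])

    skull = traj.landmarks["skull_center"] * mm
    tail = traj.landmarks[tail_point] * mm
    body_axis = com - skull  # points backward along the body
    tail_axis = tail - com
    ang_body = np.degrees(np.arctan2(body_axis[:, 1], body_axis[:, 0]))
    ang_tail = np.degrees(np.arctan2(tail_axis[:, 1], tail_axis[:, 0]))
    tail_angle = (ang_tail - ang_body + 180.0) % 360.0 - 180.0
    tail_vel_raw = np.gradient(_unwrap_deg(tail_angle), dt)
    tail_velocity = savgol_filter(tail_vel_raw, SAVGOL_WINDOW, SAVGOL_ORDER)
    tail_activity = savgol_filter(np.abs(tail_vel_raw), SAVGOL_WINDOW, SAVGOL_ORDER)

    le, re = traj.landmarks["left_eye"] * mm, traj.landmarks["right_eye"] * mm
    eye_line = re - le
    head_angle = _unwrap_deg(np.degrees(np.arctan2(eye_line[:, 1], eye_line[:, 0])))
    head_ang_accel = _second_derivative(head_angle, dt)

    return KinematicsSeries(
        time=traj.time,
        position_com=com,
        swim_speed=swim_speed,
        cumulative_distance=cumdist,
        tail_angle=tail_angle,
        tail_velocity=tail_velocity,
        tail_activity=tail_activity,
        head_angle=head_angle,
        head_ang_accel=head_ang_accel,
        frame_rate=fps,
    )


def detect_bouts(
    kin: KinematicsSeries,
    v_thresh: float = 3.0,
    tail_thresh: float = 3.0,
    max_bridge: int = 2,
) -> list[SwimBout]:
    """Dual-threshold bout detection on the smoothed traces.

    A frame is active when the smoothed swim speed strictly exceeds
    ``v_thresh`` (mm/s) AND the smoothed tail-deflection speed envelope
    strictly exceeds ``tail_thresh`` (deg/s) — the conjunction discards
    both tail beating without translation and passive drift. Sub-threshold
    gaps of at most ``max_bridge`` frames (single-frame dips where a tail
    beat reverses) are bridged; maximal active runs become bouts.
    """
    if v_thresh <= 0 or tail_thresh <= 0:
        raise InputError("thresholds must be positive")
    active = (kin.swim_speed > v_thresh) & (kin.tail_activity > tail_thresh)
    if max_bridge > 0 and active.any():
        idx = np.flatnonzero(active)
        gaps = np.diff(idx)
        for i, g in enumerate(gaps):
            if 1 < g <= max_bridge + 1:
                active[idx[i] : idx[i + 1]] = True
    bouts: list[SwimBout] = []
    dt = 1.0 / kin.frame_rate
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return bouts
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        bouts.append(SwimBout(run[0] * dt, (run[-1] + 1) * dt))
    return bouts


def summarize_bouts(
    bouts: list[SwimBout], recording_length: float, bin_width: float = 0.5
) -> BoutSummary:
    """Duration-weighted bout statistics.

    Each bout contributes to the duration histogram with multiplicity
    proportional to its own duration (a 30 s bout counts 30x a 1 s bout),
    and the weighted histogram is normalized to unit integral.
    """
    durations = np.array([b.duration for b in bouts])
    if len(bouts) and recording_length < max(b.end for b in bouts):
        raise InputError("recording_length shorter than the last bout")
    total = float(durations.sum())
    if len(durations) == 0:
        return BoutSummary(0, 0.0, 0.0, np.array([0.0]), np.array([]))
    edges = np.arange(0.0, durations.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    density, edges = np.histogram(durations, bins=edges, weights=durations, density=True)
    return BoutSummary(
        n_bouts=len(bouts),
        total_swim_time=total,
        percent_time_swimming=100.0 * total / recording_length,
        bin_edges=edges,
        weighted_density=density,
    )


def compare_distributions(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison.

    Returns the supremum absolute difference between the two empirical
    CDFs and the two-sided asymptotic p-value.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
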