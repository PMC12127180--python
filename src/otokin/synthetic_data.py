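"""Synthetic generators with analytic ground truth.

Every downstream stage of the pipeline is exercised against data produced
here: burst-and-glide vs continuous swimming as landmark trajectories,
sinusoidal stimulus-locked eye responses with controlled gain/phase/noise
and optional fast-phase resets, paired eye-tail traces with a programmed
coupling fraction, voxelized elliptic-torus canal phantoms with ampulla
bulge, out-of-plane tilt and optional pre-ampullary stenosis, and
two-species morpho-behavioral feature cohorts with missing entries.

Generators are pure functions of their configuration and seed (fixed seed
implies bit-identical output) and always return the analytic ground truth
alongside the generated object; they never import downstream analysis
modules.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import CanalVolume, LandmarkTrajectory, MotionTrace
from .presets import get_preset


class ConfigError(ValueError):
    pass


class ResolutionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# free swimming


@dataclasses.dataclass
class SwimSimConfig:
    """Free-swimming landmark-trajectory generator settings.

    ``bout_schedule`` is a list of (start s, duration s) tuples; bouts must
    fit inside the recording and not overlap. During a bout the body
    centre of mass advances at ``swim_speed`` while the tail points beat
    sinusoidally at ``tail_beat_freq`` with half-amplitude
    ``tail_amplitude`` and the eye line yaws with the tail rhythm. With
    ``glide`` enabled the forward speed decays exponentially (time
    constant ``glide_tau``) after each bout instead of stopping abruptly,
    while the tail is still — emulating the passive glide of
    thrust-and-glide swimmers.
    """

    duration: float = 60.0
    frame_rate: float = 30.0
    pixel_scale: float = 0.1  # mm/pixel
    bout_schedule: Sequence[tuple[float, float]] = ()
    swim_speed: float = 5.0  # mm/s
    glide: bool = False
    glide_tau: float = 0.05  # s
    tail_beat_freq: float = 4.0  # Hz
    tail_amplitude: float = 15.0  # degrees, half-amplitude of tail deflection
    head_yaw_amplitude: float = 5.0  # degrees
    noise_sd: float = 0.003  # mm of landmark jitter
    noise_corr_frames: float = 4.0  # temporal correlation of the jitter
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("duration", "frame_rate", "pixel_scale", "tail_beat_freq"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        bouts = sorted((float(s), float(d)) for s, d in self.bout_schedule)
        prev_end = 0.0
        for start, dur in bouts:
            if dur <= 0:
                raise ConfigError("bout durations must be positive")
            if start < 0 or start + dur > self.duration:
                raise ConfigError("bout outside the recording window")
            if start < prev_end:
                raise ConfigError("bouts overlap")
            prev_end = start + dur
        self.bout_schedule = bouts


@dataclasses.dataclass
class SwimSimResult:
    trajectory: LandmarkTrajectory
    bouts: list[tuple[float, float]]  # ground-truth (start, end) seconds
    config: SwimSimConfig

    @property
    def total_swim_time(self) -> float:
        return float(sum(e - s for s, e in self.bouts))


def _rot(vec: np.ndarray, deg: np.ndarray) -> np.ndarray:
    """Rotate 2D vectors by per-frame angles in degrees."""
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    x, y = vec[..., 0], vec[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def simulate_swim(config: SwimSimConfig) -> SwimSimResult:
    """Generate a six-landmark trajectory with known bout intervals.

    The animal heads along +x. Between bouts all landmark velocities stay
    below the bout-detection floor (only tracker jitter remains); the
    returned ground-truth intervals are exactly the scheduled bouts
    (glides are not part of a bout).
    """
    cfg = config
    n = int(round(cfg.duration * cfg.frame_rate))
    t = np.arange(n) / cfg.frame_rate
    dt = 1.0 / cfg.frame_rate

    speed = np.zeros(n)  # mm/s
    tail_phase = np.zeros(n)
    active = np.zeros(n, dtype=bool)
    for start, dur in cfg.bout_schedule:
        inb = (t >= start) & (t < start + dur)
        active |= inb
        speed[inb] = cfg.swim_speed
        tail_phase[inb] = 2 * np.pi * cfg.tail_beat_freq * (t[inb] - start)
        if cfg.glide:
            post = t >= start + dur
            decay = np.exp(-np.clip(t[post] - (start + dur), 0, None) / cfg.glide_tau)
            speed[post] = np.maximum(speed[post], cfg.swim_speed * decay)

    x_mm = np.cumsum(speed) * dt
    com = np.stack([x_mm, np.full(n, 0.0)], axis=1) / cfg.pixel_scale  # px

    tail_angle = np.where(active, cfg.tail_amplitude * np.sin(tail_phase), 0.0)
    yaw = np.where(active, cfg.head_yaw_amplitude * np.sin(tail_phase), 0.0)

    # body geometry in mm, converted to px
    u = np.array([1.0, 0.0])  # heading
    head_len, eye_fwd, eye_half = 4.0, 1.0, 0.8
    tail1_len, tail2_len = 4.0, 8.0
    px = cfg.pixel_scale

    skull = com + (head_len / px) * u
    eye_mid = skull + (eye_fwd / px) * u
    eye_arm = np.array([0.0, eye_half / px])
    left_eye = eye_mid + _rot(np.broadcast_to(eye_arm, (n, 2)), yaw)
    right_eye = eye_mid - _rot(np.broadcast_to(eye_arm, (n, 2)), yaw)
    back = np.broadcast_to(-u, (n, 2))
    tail1 = com + (tail1_len / px) * _rot(back, tail_angle)
    tail2 = com + (tail2_len / px) * _rot(back, 1.5 * tail_angle)

    landmarks = {
        "left_eye": left_eye,
        "right_eye": right_eye,
        "skull_center": skull,
        "body_com": com,
        "tail1": tail1,
        "tail2": tail2,
    }
    if cfg.noise_sd > 0 and cfg.seed is not None:
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(cfg.seed)
        for name in landmarks:
            # tracker jitter is temporally correlated: a marker on a still
            # animal wanders slowly rather than flickering frame to frame
            raw = rng.normal(0.0, 1.0, size=(n, 2))
            corr = gaussian_filter1d(raw, cfg.noise_corr_frames, axis=0)
            corr *= cfg.noise_sd / px / corr.std()
            landmarks[name] = landmarks[name] + corr
    traj = LandmarkTrajectory(cfg.frame_rate, cfg.pixel_scale, landmarks)
    bouts = [(s, s + d) for s, d in cfg.bout_schedule]
    return SwimSimResult(traj, bouts, cfg)


def even_schedule(
    duration: float, n_bouts: int, bout_duration: float
) -> list[tuple[float, float]]:
    """Evenly spaced non-overlapping bouts of equal duration."""
    total = n_bouts * bout_duration
    if total >= duration:
        raise ConfigError("bouts do not fit in the recording")
    gap = (duration - total) / (n_bouts + 1)
    return [(gap + i * (bout_duration + gap), bout_duration) for i in range(n_bouts)]


def random_schedule(
    duration: float,
    mean_bout: float,
    mean_gap: float,
    seed: int = 0,
    min_bout: float = 0.2,
) -> list[tuple[float, float]]:
    """Exponential bout-duration / inter-bout-gap stochastic schedule."""
    rng = np.random.default_rng(seed)
    sched: list[tuple[float, float]] = []
    t = rng.exponential(mean_gap)
    while True:
        dur = max(min_bout, rng.exponential(mean_bout))
        if t + dur >= duration:
            break
        sched.append((t, dur))
        t += dur + max(min_bout, rng.exponential(mean_gap))
    return sched


def swim_preset(name: str, seed: int = 0, duration: float = 60.0) -> SwimSimConfig:
    """Species preset with scripted bouts matching the published means.

    The schedule is scripted (not stochastic): equal-duration bouts whose
    total equals the published mean time-spent-swimming per 60 s, at bout
    durations near the published species mean.
    """
    p = get_preset(name)
    scale = duration / 60.0
    total = p["time_swimming_per_60s"] * scale
    n_bouts = max(1, int(round(total / p["mean_bout_duration"])))
    bout_dur = total / n_bouts
    return SwimSimConfig(
        duration=duration,
        bout_schedule=even_schedule(duration, n_bouts, bout_dur),
        swim_speed=p["swim_speed"],
        glide=p["glide"],
        tail_beat_freq=p["tail_beat_freq"],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stimulus-locked eye responses


@dataclasses.dataclass
class EyeSimConfig:
    """Sinusoidal stimulus / eye-response generator settings.

    ``phase`` is in degrees relative to peak stimulus position with the
    compensatory sign convention: negative = the (reflected, for
    vestibular conditions) eye response peaks before the stimulus (phase
    lead). ``fast_phase_rate`` inserts resetting quick phases as 100 ms
    linear position offsets opposite to the ongoing slow-phase direction.
    """

    gain: float = 0.29
    phase: float = 0.0  # degrees, negative = lead
    stimulus_kind: str = "vestibular_dark"
    stimulus_freq: float = 0.5  # Hz
    stimulus_amplitude: float = 10.0  # degrees half-excursion
    n_cycles: int = 20
    sample_rate: float = 200.0
    noise_sd: float = 0.0  # degrees
    fast_phase_rate: float = 0.0  # events/min
    fast_phase_amplitude: float | None = None  # degrees; default 2x eye excursion
    n_eyes: int = 2
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ConfigError("gain must be >= 0")
        if not (-180.0 < self.phase <= 180.0):
            raise ConfigError("phase must lie in (-180, 180]")
        if self.stimulus_freq <= 0 or self.sample_rate <= 0:
            raise ConfigError("rates must be positive")


@dataclasses.dataclass
class EyeSimResult:
    trace: MotionTrace
    gain: float
    phase: float
    fast_phase_times: np.ndarray


def simulate_eyes(config: EyeSimConfig) -> EyeSimResult:
    """Generate a stimulus/eye trace with known gain and phase.

    The stimulus is ``A sin(2 pi f t)``. The slow-phase eye response is
    ``gain * A * sin(2 pi f t - phase_rad)`` so that a negative configured
    phase places the response peak before the stimulus peak (a lead); for
    vestibular conditions the trace is negated because the compensatory
    response moves against the stimulus.
    """
    cfg = config
    fs = cfg.sample_rate
    n = int(round(cfg.n_cycles / cfg.stimulus_freq * fs)) + 1
    t = np.arange(n) / fs
    omega = 2 * np.pi * cfg.stimulus_freq
    stim = cfg.stimulus_amplitude * np.sin(omega * t)
    slow = cfg.gain * cfg.stimulus_amplitude * np.sin(omega * t - np.deg2rad(cfg.phase))
    if cfg.stimulus_kind.startswith("vestibular"):
        slow = -slow

    rng = np.random.default_rng(cfg.seed)
    fp_times = np.array([])
    fp_offset = np.zeros(n)
    if cfg.fast_phase_rate > 0:
        duration = t[-1]
        n_events = rng.poisson(cfg.fast_phase_rate * duration / 60.0)
        # keep resets away from the trace edges
        fp_times = np.sort(rng.uniform(0.05 * duration, 0.95 * duration, n_events))
        amp = cfg.fast_phase_amplitude
        if amp is None:
            amp = max(4.0 * cfg.gain * cfg.stimulus_amplitude, 5.0)
        vel = np.gradient(slow, t)
        for t0 in fp_times:
            i0 = int(t0 * fs)
            direction = -np.sign(vel[i0]) if vel[i0] != 0 else 1.0
            ramp = np.clip((t - t0) / 0.1, 0.0, 1.0)  # 100 ms linear ramp
            fp_offset += direction * amp * ramp

    eyes = []
    for _ in range(cfg.n_eyes):
        noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
        eyes.append(slow + fp_offset + noise)
    trace = MotionTrace(
        sample_rate=fs,
        stimulus=stim,
        eyes=eyes,
        stimulus_kind=cfg.stimulus_kind,
        stimulus_freq=cfg.stimulus_freq,
        stimulus_amplitude=cfg.stimulus_amplitude,
    )
    return EyeSimResult(trace, cfg.gain, cfg.phase, fp_times)


def eye_preset(
    name: str,
    condition: str = "vor_dark",
    seed: int = 0,
    noise_sd: float = 0.0,
    **overrides,
) -> EyeSimConfig:
    """Eye-trace generator config at the published species means.

    ``condition`` is one of ``vor_dark``, ``vor_light``, ``okr``. VOR
    conditions use the 0.5 Hz +/-10 deg rotation protocol; OKR uses the
    0.1 Hz +/-10 deg pattern motion protocol.
    """
    p = get_preset(name)
    gp = p[condition]
    kind = {"vor_dark": "vestibular_dark", "vor_light": "vestibular_light", "okr": "visual"}[
        condition
    ]
    defaults = dict(
        gain=gp["gain"],
        phase=gp["phase"],
        stimulus_kind=kind,
        stimulus_freq=0.1 if condition == "okr" else 0.5,
        stimulus_amplitude=10.0,
        n_cycles=10 if condition == "okr" else 20,
        noise_sd=noise_sd,
        seed=seed,
    )
    defaults.update(overrides)
    return EyeSimConfig(**defaults)


# ---------------------------------------------------------------------------
# paired eye-tail traces (spino-ocular coupling)


@dataclasses.dataclass
class EyeTailSimResult:
    time: np.ndarray
    tail: np.ndarray  # degrees
    eye: np.ndarray  # degrees
    sample_rate: float
    coupled_mask: np.ndarray  # per tail cycle
    cycle_bounds: np.ndarray  # (n_cycles, 2) start/end seconds
    tail_amplitudes: np.ndarray  # per-cycle peak-to-peak, degrees
    gains: np.ndarray  # per-cycle programmed eye/tail gain

    @property
    def coupled_fraction(self) -> float:
        return float(np.mean(self.coupled_mask))


def simulate_eye_tail(
    n_cycles: int,
    coupled_fraction: float,
    tail_amplitude: float = 20.0,
    gain: float = 0.3,
    seed: int = 0,
    tail_freq: float = 2.5,
    sample_rate: float = 250.0,
    amplitude_jitter: float = 0.0,
    gain_slope: float = 0.0,
    eye_noise_sd: float = 0.02,
) -> EyeTailSimResult:
    """Tail oscillation with a programmed fraction of coupled eye cycles.

    Exactly ``round(coupled_fraction * n_cycles)`` randomly chosen tail
    cycles carry an anti-phase eye oscillation scaled by the per-cycle
    gain; the rest leave the eye at noise level. ``tail_amplitude`` is
    peak-to-peak. ``gain_slope`` (per degree of peak-to-peak tail
    amplitude) programs a linear amplitude dependence of the gain for
    slope-recovery tests; ``amplitude_jitter`` draws per-cycle amplitudes
    uniformly within +/- that fraction of the nominal.
    """
    if not 0.0 <= coupled_fraction <= 1.0:
        raise ConfigError("coupled_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    period = 1.0 / tail_freq
    dt = 1.0 / sample_rate
    # two-sample lead-in/out so cycle boundaries at 0 and n_cycles*T are
    # recoverable as upward zero crossings
    t = np.arange(-2 * dt, n_cycles * period + 2.5 * dt, dt)
    n = len(t)

    n_coupled = int(round(coupled_fraction * n_cycles))
    coupled_idx = rng.choice(n_cycles, size=n_coupled, replace=False)
    coupled = np.zeros(n_cycles, dtype=bool)
    coupled[coupled_idx] = True

    half = tail_amplitude / 2.0
    amps = np.full(n_cycles, half)
    if amplitude_jitter > 0:
        amps *= 1.0 + amplitude_jitter * rng.uniform(-1, 1, n_cycles)
    gains = np.clip(gain + gain_slope * (2 * amps - tail_amplitude), 0.0, None)

    tail = np.zeros(n)
    eye = np.zeros(n)
    bounds = np.empty((n_cycles, 2))
    for k in range(n_cycles):
        t0, t1 = k * period, (k + 1) * period
        bounds[k] = (t0, t1)
        sel = (t >= t0) & (t < t1) if k < n_cycles - 1 else (t >= t0)
        phase = 2 * np.pi * tail_freq * (t[sel] - t0)
        tail[sel] = amps[k] * np.sin(phase)
        if coupled[k]:
            eye[sel] = -gains[k] * amps[k] * np.sin(phase)
    # lead-in continues the first cycle's sine so the t=0 crossing exists
    lead = t < 0
    tail[lead] = amps[0] * np.sin(2 * np.pi * tail_freq * t[lead])
    if eye_noise_sd > 0:
        eye = eye + rng.normal(0.0, eye_noise_sd, n)
    return EyeTailSimResult(
        time=t,
        tail=tail,
        eye=eye,
        sample_rate=sample_rate,
        coupled_mask=coupled,
        cycle_bounds=bounds,
        tail_amplitudes=2 * amps,
        gains=gains,
    )


# ---------------------------------------------------------------------------
# canal phantoms


@dataclasses.dataclass
class CanalPhantomConfig:
    """Voxelized elliptic-torus canal phantom settings.

    The duct centerline is an elliptic arc with semi-axes ``(a, b)`` in
    the canal plane, swept over ``arc_span`` degrees, optionally tilted
    out of plane. The tube radius is constant (``tube_radius``) apart from
    an optional Gaussian ampulla bulge at the arc end (factor
    ``ampulla_scale`` over ~15% of arc) and an optional Gaussian stenosis
    (``stenosis`` = (normalized arclength position, radial constriction
    factor in (0, 1))).
    """

    semi_axes: tuple[float, float] = (600.0, 600.0)  # μm
    tube_radius: float = 66.0  # μm
    arc_span: float = 360.0  # degrees
    out_of_plane_tilt: float = 0.0  # degrees
    ampulla_scale: float = 1.0
    stenosis: tuple[float, float] | None = None  # (position in [0,1], factor)
    voxel_size: float | tuple[float, float, float] = 3.0  # μm
    grayscale: bool = False
    blur_sigma: float = 1.0  # voxels, grayscale mode only
    noise_sd: float = 0.0  # fraction of signal, grayscale mode only
    pad: int = 4  # voxels of empty margin
    seed: int | None = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > self.tube_radius > 0):
            raise ConfigError("require semi-axes a >= b > tube_radius > 0")
        if self.stenosis is not None:
            pos, factor = self.stenosis
            if not (0.0 <= pos <= 1.0 and 0.0 < factor < 1.0):
                raise ConfigError("stenosis = (position in [0,1], factor in (0,1))")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        if self.tube_radius < 2 * max(self.voxel_size):
            raise ResolutionError("tube thinner than 2 voxels; reduce voxel size")


@dataclasses.dataclass
class CanalTruth:
    """Analytic ground truth of a canal phantom."""

    centerline: np.ndarray  # (n, 3) μm, (x, y, z)
    arc_length: float  # μm
    s_norm: np.ndarray  # normalized arclength of centerline samples
    radius_profile: np.ndarray  # tube radius r(s), μm
    cs_area_profile: np.ndarray  # pi r(s)^2, μm^2
    semi_axes: tuple[float, float, float]  # (a, b, tube radius)

    @property
    def cs_mean(self) -> float:
        return float(np.trapezoid(self.cs_area_profile, self.s_norm))

    @property
    def cs_min(self) -> float:
        return float(self.cs_area_profile.min())

    @property
    def stenosis_ratio(self) -> float:
        return self.cs_min / self.cs_mean

    @property
    def stenosis_position(self) -> float:
        return float(self.s_norm[np.argmin(self.cs_area_profile)])

    @property
    def elongation(self) -> float:
        return self.semi_axes[0] / self.semi_axes[1]


@dataclasses.dataclass
class CanalPhantomResult:
    volume: CanalVolume
    truth: CanalTruth
    config: CanalPhantomConfig


def _centerline(cfg: CanalPhantomConfig, n: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    """Dense analytic centerline (μm) and cumulative arclength."""
    a, b = cfg.semi_axes
    theta = np.linspace(0.0, np.deg2rad(cfg.arc_span), n)
    pts = np.stack([a * np.cos(theta), b * np.sin(theta), np.zeros(n)], axis=1)
    if cfg.out_of_plane_tilt:
        tlt = np.deg2rad(cfg.out_of_plane_tilt)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(tlt), -np.sin(tlt)], [0, np.sin(tlt), np.cos(tlt)]]
        )
        pts = pts @ rot.T
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def _radius_profile(cfg: CanalPhantomConfig, s_norm: np.ndarray) -> np.ndarray:
    r = np.full_like(s_norm, cfg.tube_radius)
    if cfg.ampulla_scale != 1.0:
        sigma = 0.075  # bulge spans ~15% of arc at the far end
        r *= 1.0 + (cfg.ampulla_scale - 1.0) * np.exp(-(((s_norm - 1.0) / sigma) ** 2))
    if cfg.stenosis is not None:
        pos, factor = cfg.stenosis
        sigma = 0.03
        r *= 1.0 - (1.0 - factor) * np.exp(-(((s_norm - pos) / sigma) ** 2))
    return r


def arc_span_for_length(semi_axes: tuple[float, float], length: float) -> float:
    """Arc span (degrees) of an elliptic arc with the given arclength."""
    a, b = semi_axes
    theta = np.linspace(0.0, 2 * np.pi, 20000)
    seg = np.hypot(-a * np.sin(theta), b * np.cos(theta))
    s = np.concatenate([[0.0], np.cumsum((seg[1:] + seg[:-1]) / 2 * np.diff(theta))])
    if length > s[-1]:
        raise ConfigError("requested length exceeds the full circuit")
    return float(np.rad2deg(np.interp(length, s, theta)))


def simulate_canal(config: CanalPhantomConfig) -> CanalPhantomResult:
    """Voxelize an elliptic-torus canal segment with analytic ground truth.

    A voxel is foreground when its centre lies within the local tube
    radius of the nearest centerline sample. Grayscale mode blurs the
    binary mask and adds Gaussian noise to emulate a fluorescence stack.
    """
    cfg = config
    pts, s = _centerline(cfg)
    length = s[-1]
    s_norm = s / length
    radius = _radius_profile(cfg, s_norm)
    r_max = radius.max()

    dz, dy, dx = cfg.voxel_size
    lo = pts.min(axis=0) - r_max
    hi = pts.max(axis=0) + r_max
    # voxel (z, y, x) grid; world x -> axis 2, y -> axis 1, z -> axis 0
    nx = int(np.ceil((hi[0] - lo[0]) / dx)) + 2 * cfg.pad
    ny = int(np.ceil((hi[1] - lo[1]) / dy)) + 2 * cfg.pad
    nz = int(np.ceil((hi[2] - lo[2]) / dz)) + 2 * cfg.pad
    origin = lo - cfg.pad * np.array([dx, dy, dz])

    zz = origin[2] + (np.arange(nz) + 0.5) * dz
    yy = origin[1] + (np.arange(ny) + 0.5) * dy
    xx = origin[0] + (np.arange(nx) + 0.5) * dx

    # cheap prefilter in the (untilted) canal frame: keep voxels within a
    # shell around the elliptic annulus, then exact nearest-centerline test
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    if cfg.out_of_plane_tilt:
        tlt = np.deg2rad(cfg.out_of_plane_tilt)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(tlt), -np.sin(tlt)], [0, np.sin(tlt), np.cos(tlt)]]
        )
        frame = coords @ rot  # inverse rotation (rot is orthonormal)
    else:
        frame = coords
    a, b = cfg.semi_axes
    margin = r_max * 1.2 + max(cfg.voxel_size)
    near_plane = np.abs(frame[:, 2]) <= margin
    rad = np.hypot(frame[:, 0] / a, frame[:, 1] / b)
    shell = (rad >= 1.0 - margin / b) & (rad <= 1.0 + margin / b)
    cand = np.flatnonzero(near_plane & shell)

    voxels = np.zeros(nz * ny * nx, dtype=np.uint8)
    if cand.size:
        tree = cKDTree(pts)
        dist, idx = tree.query(coords[cand], workers=-1)
        keep = dist <= radius[idx]
        if cfg.arc_span < 360.0:
            # flat end caps: drop the hemispherical bulge past each arc end
            for end_i, inner_i in ((0, 1), (len(pts) - 1, len(pts) - 2)):
                outward = pts[end_i] - pts[inner_i]
                outward = outward / np.linalg.norm(outward)
                at_end = idx == end_i
                if at_end.any():
                    proj = (coords[cand[at_end]] - pts[end_i]) @ outward
                    sel = np.flatnonzero(at_end)
                    keep[sel[proj > 0]] = False
        voxels[cand[keep]] = 1
    voxels = voxels.reshape(nz, ny, nx)
    if not voxels.any():
        raise ResolutionError("phantom produced an empty volume")

    if cfg.grayscale:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(voxels.astype(float), cfg.blur_sigma)
        if cfg.noise_sd > 0:
            rng = np.random.default_rng(cfg.seed)
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        vol = CanalVolume(img, (dz, dy, dx), is_binary=False)
    else:
        vol = CanalVolume(voxels, (dz, dy, dx), is_binary=True)

    truth = CanalTruth(
        centerline=pts,
        arc_length=float(length),
        s_norm=s_norm,
        radius_profile=radius,
        cs_area_profile=np.pi * radius**2,
        semi_axes=(a, b, cfg.tube_radius),
    )
    return CanalPhantomResult(vol, truth, cfg)


def canal_preset(
    name: str, voxel_size: float = 3.0, arc_span: float | None = None, **overrides
) -> CanalPhantomConfig:
    """Circular-circuit phantom at the published species radii.

    By default the arc span is solved so the analytic centerline length
    equals the published duct length; pass ``arc_span`` to override.
    """
    p = get_preset(name)
    R, r = p["circuit_radius"], p["lumen_radius"]
    if arc_span is None:
        arc_span = arc_span_for_length((R, R), p["duct_length_mm"] * 1000.0)
    defaults = dict(
        semi_axes=(R, R), tube_radius=r, arc_span=arc_span, voxel_size=voxel_size
    )
    defaults.update(overrides)
    return CanalPhantomConfig(**defaults)


# ---------------------------------------------------------------------------
# morpho-behavioral cohorts


def simulate_cohort(
    n_per_species: int = 8,
    n_vars: int = 18,
    n_affected: int = 5,
    effect_size: float = 3.0,
    secondary_effect: float = 0.6,
    missing_fraction: float = 0.2,
    seed: int = 0,
    var_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-species feature cohort with a programmed species offset.

    ``n_affected`` variables differ between species; the first affected
    variable carries the full ``effect_size`` (in units of the
    within-species SD, which is 1) and the remaining affected ones
    ``secondary_effect`` times it, so the programmed dominant species
    marker is identifiable in the loadings; the rest share one
    distribution. Note that per-variable z-scoring bounds the achievable
    separation (a two-point mixture with gap d has z-space separation
    d/sqrt(1 + d^2/4) < 2), so dominance in the loadings requires a clear
    gap between primary and secondary effects. A ``missing_fraction`` of cells is blanked at random
    (never leaving a variable unobserved within a species). Returns the
    cohort table (``animal_id``, ``species`` + variable columns) and a
    ground-truth dict with the affected variable names.
    """
    rng = np.random.default_rng(seed)
    if var_names is None:
        var_names = [f"var_{i:02d}" for i in range(n_vars)]
    var_names = list(var_names)
    affected = var_names[:n_affected]
    rows = []
    for sp_i, species in enumerate(("xenopus", "axolotl")):
        sign = 1.0 if sp_i == 0 else -1.0
        effects = effect_size * np.r_[
            1.0, np.full(max(n_affected - 1, 0), secondary_effect)
        ]
        for k in range(n_per_species):
            vals = rng.normal(0.0, 1.0, len(var_names))
            vals[:n_affected] += sign * effects / 2.0
            rows.append(
                {"animal_id": f"{species}_{k}", "species": species}
                | dict(zip(var_names, vals))
            )
    df = pd.DataFrame(rows)
    if missing_fraction > 0:
        for var in var_names:
            for species in ("xenopus", "axolotl"):
                sel = np.flatnonzero((df["species"] == species).to_numpy())
                n_miss = int(missing_fraction * len(sel))
                n_miss = min(n_miss, len(sel) - 1)  # keep >= 1 observed
                if n_miss > 0:
                    miss = rng.choice(sel, size=n_miss, replace=False)
                    df.loc[miss, var] = np.nan
    truth = {"affected": affected, "effect_size": effect_size}
    return df, truth
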