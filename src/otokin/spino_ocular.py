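"""Locomotor-induced (efference-copy) eye movements from eye/tail traces.

During undulatory swimming, spinal central pattern generators drive
conjugate eye oscillations anti-phase to the tail, even without any
visual or vestibular input. This module quantifies that coupling: tail
cycles are delimited by successive upward zero crossings of the
mean-subtracted tail angle, each cycle is tested for an opposite-
direction eye excursion, and the eye/tail cycle ratio (percentage of tail
cycles with a matched eye cycle) and the amplitude dependence of the
per-cycle gain are reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class InputError(ValueError):
    pass


@dataclasses.dataclass
class TailCycle:
    start: float  # s
    end: float  # s
    amplitude: float  # degrees, peak-to-peak
    matched_eye: bool = False
    eye_amplitude: float | None = None  # degrees, peak-to-peak if matched

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("cycle end must exceed start")
        if self.amplitude < 0:
            raise InputError("amplitude must be >= 0")


def _upward_crossings(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Interpolated times of negative-to-positive zero crossings."""
    rising = ((v[:-1] <= 0) & (v[1:] > 0)) | ((v[:-1] < 0) & (v[1:] >= 0))
    idx = np.flatnonzero(rising)
    if idx.size == 0:
        return np.array([])
    denom = v[idx + 1] - v[idx]
    frac = np.where(denom != 0, -v[idx] / denom, 0.0)
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    # collapse duplicates from exact-zero samples
    keep = np.concatenate([[True], np.diff(times) > 2 * np.median(np.diff(t))])
    return times[keep]


def detect_tail_cycles(
    time: np.ndarray, tail: np.ndarray, min_amplitude: float = 2.0
) -> list[TailCycle]:
    """Delimit tail cycles at successive upward zero crossings.

    The tail trace is mean-subtracted first; cycles whose peak-to-peak
    deflection stays under ``min_amplitude`` (noise floor, degrees) are
    ignored. A flat trace yields no cycles.
    """
    t = np.asarray(time, float)
    v = np.asarray(tail, float) - np.mean(tail)
    if len(t) != len(v):
        raise InputError("time and tail lengths differ")
    crossings = _upward_crossings(t, v)
    if crossings.size >= 2:
        # the trace edges close a cycle when they sit a full period away
        period = float(np.median(np.diff(crossings)))
        if crossings[0] - t[0] >= 0.9 * period:
            crossings = np.concatenate([[t[0]], crossings])
        if t[-1] - crossings[-1] >= 0.9 * period:
            crossings = np.concatenate([crossings, [t[-1]]])
    cycles = []
    for t0, t1 in zip(crossings[:-1], crossings[1:]):
        sel = (t >= t0) & (t <= t1)
        if sel.sum() < 3:
            continue
        amp = float(np.ptp(v[sel]))
        if amp >= min_amplitude:
            cycles.append(TailCycle(start=float(t0), end=float(t1), amplitude=amp))
    return cycles


def match_eye_cycles(
    cycles: list[TailCycle],
    time: np.ndarray,
    tail: np.ndarray,
    eye: np.ndarray,
    min_eye_amplitude: float = 0.5,
) -> list[TailCycle]:
    """Flag tail cycles that carry an opposite-direction eye excursion.

    Within each cycle span the eye must (a) exceed ``min_eye_amplitude``
    peak-to-peak and (b) co-vary negatively with the tail (covariance
    sign test for "opposite direction"). Matched cycles record the eye
    peak-to-peak amplitude.
    """
    t = np.asarray(time, float)
    tl = np.asarray(tail, float)
    ey = np.asarray(eye, float)
    if not (len(t) == len(tl) == len(ey)):
        raise InputError("misaligned trace lengths")
    out = []
    for c in cycles:
        sel = (t >= c.start) & (t <= c.end)
        e, w = ey[sel], tl[sel]
        amp = float(np.ptp(e))
        cov = float(np.mean((e - e.mean()) * (w - w.mean())))
        matched = (amp >= min_eye_amplitude) and (cov < 0)
        out.append(
            TailCycle(
                start=c.start,
                end=c.end,
                amplitude=c.amplitude,
                matched_eye=matched,
                eye_amplitude=amp if matched else None,
            )
        )
    return out


def cycle_ratio(cycles: list[TailCycle]) -> float:
    """Eye/tail cycle ratio: percentage of tail cycles with a matched eye."""
    if not cycles:
        raise InputError("no tail cycles")
    matched = sum(c.matched_eye for c in cycles)
    return 100.0 * matched / len(cycles)


def gain_vs_amplitude(
    cycles: list[TailCycle], bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cycle spino-ocular gain against tail amplitude.

    Gain is eye amplitude / tail amplitude per matched cycle. Cycles are
    binned by tail amplitude (``bin_width`` degrees peak-to-peak) and an
    ordinary least-squares line is fitted through the bin means; the
    returned slope is in gain units per degree. Requires at least two
    matched cycles in at least two bins.
    """
    amps = np.array([c.amplitude for c in cycles if c.matched_eye])
    gains = np.array(
        [c.eye_amplitude / c.amplitude for c in cycles if c.matched_eye]
    )
    if amps.size < 2:
        raise InputError("need at least two matched cycles for a fit")
    edges = np.arange(amps.min(), amps.max() + bin_width, bin_width)
    if len(edges) < 3:
        centers, means = amps, gains
    else:
        which = np.digitize(amps, edges) - 1
        centers, means = [], []
        for k in range(len(edges) - 1):
            sel = which == k
            if sel.any():
                centers.append(amps[sel].mean())
                means.append(gains[sel].mean())
        centers, means = np.array(centers), np.array(means)
    if len(centers) < 2:
        raise InputError("need at least two amplitude bins for a fit")
    slope = float(np.polyfit(centers, means, 1)[0])
    return centers, means, slope
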