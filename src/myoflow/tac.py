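"""Frame schedules, time-activity curves and the numerics built on them.

A dynamic cardiac acquisition is rebinned into contiguous frames; every
region (blood pool or myocardium) is summarized as one frame-averaged
activity concentration per frame — a time-activity curve (TAC).  TAC values
are attached to frame midtimes and all integration is performed on the
piecewise-linear interpolant through those (midtime, value) points, extended
flat to the acquisition boundaries.  That interpolant is exact for signals
that are linear within frames and is the conventional treatment of
frame-binned dynamic data.

Times are stored in seconds; integrals are reported in kBq/mL·min because
flow is expressed in mL/min/g downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Region labels used throughout: blood-pool input plus the global LV and
#: the three coronary territories.
BLOOD = "BLOOD"
GLOBAL = "GLOBAL"
TERRITORIES = ("LAD", "LCX", "RCA")
REGIONS = (BLOOD, GLOBAL) + TERRITORIES
MYO_REGIONS = (GLOBAL,) + TERRITORIES


@dataclass(frozen=True)
class FrameSchedule:
    """Temporal binning of a dynamic acquisition.

    Frames are contiguous and non-overlapping:
    ``start[i+1] == start[i] + duration[i]``.
    """

    frame_start: np.ndarray  # seconds, shape (n,)
    frame_duration: np.ndarray  # seconds, shape (n,)

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise ValueError("schedule times must be finite")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if start.size > 1 and not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous: start[i+1] == start[i] + duration[i]")

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(list(durations), dtype=float)
        if dur.size == 0:
            raise ValueError("schedule must contain at least one frame")
        start = t0 + np.concatenate(([0.0], np.cumsum(dur[:-1])))
        return cls(start, dur)

    @classmethod
    def spect_32frame(cls) -> "FrameSchedule":
        """The dynamic CZT-SPECT rebinning: 21x3, 1x9, 1x15, 1x21, 1x27, 7x30 s."""
        return cls.from_durations([3.0] * 21 + [9.0, 15.0, 21.0, 27.0] + [30.0] * 7)

    @classmethod
    def pet_24frame(cls) -> "FrameSchedule":
        """The dynamic water-PET binning: 14x5, 3x10, 3x20, 4x30 s."""
        return cls.from_durations([5.0] * 14 + [10.0] * 3 + [20.0] * 3 + [30.0] * 4)

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Midtime of each frame in seconds (strictly increasing)."""
    return schedule.frame_start + schedule.frame_duration / 2.0


def total_duration(schedule: FrameSchedule) -> float:
    """Total acquisition length in seconds."""
    return float(np.sum(schedule.frame_duration))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/mL) for one region.

    Negative inputs (possible after noise) are clamped to zero; non-finite
    values are rejected.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = field(default=GLOBAL)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.schedule.frame_start.shape:
            raise ValueError("need exactly one value per frame")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    @property
    def midtimes(self) -> np.ndarray:
        return frame_midtimes(self.schedule)


def _interp_knots(schedule: FrameSchedule, values: np.ndarray):
    """Knots of the piecewise-linear interpolant, flat-extended to [0, T]."""
    mid = frame_midtimes(schedule)
    t_end = schedule.frame_start[0] + total_duration(schedule)
    knots = np.concatenate(([schedule.frame_start[0]], mid, [t_end]))
    vals = np.concatenate(([values[0]], values, [values[-1]]))
    return knots, vals


def _integrate_values(schedule: FrameSchedule, values: np.ndarray,
                      t_lo: float, t_hi: float) -> float:
    """Trapezoidal integral of the interpolant over [t_lo, t_hi], kBq/mL·min.

    Unlike :func:`integrate_tac` this works on a raw value array so that
    signed combinations (e.g. P - sm*Ca) can be integrated without the TAC
    nonnegativity clamp.
    """
    t0 = float(schedule.frame_start[0])
    t_end = t0 + total_duration(schedule)
    if not (np.isfinite(t_lo) and np.isfinite(t_hi)):
        raise ValueError("integration limits must be finite")
    if t_lo >= t_hi:
        raise ValueError(f"need t_lo < t_hi, got [{t_lo}, {t_hi}]")
    if t_lo < t0 - 1e-9 or t_hi > t_end + 1e-9:
        raise ValueError(
            f"integration limits [{t_lo}, {t_hi}] s outside acquisition window "
            f"[{t0}, {t_end}] s")
    knots, vals = _interp_knots(schedule, np.asarray(values, dtype=float))
    inner = (knots > t_lo) & (knots < t_hi)
    tt = np.concatenate(([t_lo], knots[inner], [t_hi]))
    vv = np.concatenate(([np.interp(t_lo, knots, vals)],
                         vals[inner],
                         [np.interp(t_hi, knots, vals)]))
    return float(np.trapezoid(vv, tt)) / 60.0


def integrate_tac(tac: TimeActivityCurve, t_lo: float, t_hi: float) -> float:
    """Definite integral of a TAC over [t_lo, t_hi] seconds, in kBq/mL·min."""
    return _integrate_values(tac.schedule, tac.values, t_lo, t_hi)


def detect_bolus_landmarks(blood: TimeActivityCurve,
                           arrival_fraction: float = 0.10) -> tuple[float, float]:
    """Locate bolus arrival and peak on a blood-pool TAC.

    Returns ``(t_arrival, t_peak)`` in seconds: the peak is the midtime of
    the maximal frame and the arrival is the midtime of the first frame
    exceeding ``arrival_fraction`` of that maximum (default 10%, a level
    robust to baseline noise).
    """
    v = blood.values
    vmax = float(np.max(v))
    if vmax <= 0:
        raise ValueError("blood TAC has no positive values; cannot locate bolus")
    mid = blood.midtimes
    i_peak = int(np.argmax(v))
    i_arr = int(np.argmax(v > arrival_fraction * vmax))
    t_arrival, t_peak = float(mid[i_arr]), float(mid[i_peak])
    assert t_arrival <= t_peak
    return t_arrival, t_peak
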