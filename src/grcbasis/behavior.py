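"""Behavioral event detection: reach kinematics, trial assembly, licking.

Reaches are detected from the 200 Hz manipulandum y-position: reach "end"
is the first time the position comes within 0.5 mm of its maximum, "mid"
the first crossing of 4 mm, and "start" the latest time before mid at which
the 100-ms-smoothed speed falls below 15 mm/s.  Only reaches extending
beyond 7 mm count as stereotyped trials.  Lick analysis excludes trials in
which the capacitive sensor is stuck high (>90% of any continuous 1.5-s
block) and summarizes lick timing with the late/early preference index and
the post-reward lick off-time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReachEvent",
    "detect_reaches",
    "build_trial_table",
    "lick_validity_mask",
    "lick_rate_trace",
    "lick_preference",
    "lick_offtime",
]

MIN_EXTENT_MM = 7.0
MID_MM = 4.0
END_TOL_MM = 0.5
SPEED_THRESH = 15.0  # mm/s
SPEED_SMOOTH_S = 0.1


@dataclass(frozen=True)
class ReachEvent:
    start_s: float
    mid_s: float
    end_s: float
    max_extent_mm: float

    @property
    def included(self) -> bool:
        return self.max_extent_mm > MIN_EXTENT_MM

    def __post_init__(self) -> None:
        if not self.start_s < self.mid_s <= self.end_s:
            raise ValueError("reach times must be ordered start < mid <= end")
        if self.max_extent_mm < 0:
            raise ValueError("extent must be non-negative")


def _smoothed_speed(y: np.ndarray, fs: float) -> np.ndarray:
    v = np.gradient(y) * fs
    w = max(1, int(round(SPEED_SMOOTH_S * fs)))
    kernel = np.ones(w) / w
    return np.convolve(np.abs(v), kernel, mode="same")


def detect_reaches(t: np.ndarray, y: np.ndarray) -> list[ReachEvent]:
    """Detect forward pushes from uniformly sampled y position (mm, 200 Hz).

    Pushes never exceeding 4 mm are rejected.  Returns one ReachEvent per
    push; callers filter on ``included`` (extent > 7 mm) for analysis.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        return []
    fs = 1.0 / float(np.median(np.diff(t)))
    speed = _smoothed_speed(y, fs)

    above = y > MID_MM
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    events: list[ReachEvent] = []
    for mid_idx in rises:
        # push segment: until y falls back below mid threshold
        after = np.flatnonzero(y[mid_idx:] < MID_MM)
        seg_end = mid_idx + (after[0] if after.size else y.size - mid_idx)
        seg = y[mid_idx:seg_end]
        if seg.size == 0:
            continue
        ymax = float(seg.max())
        end_idx = mid_idx + int(np.flatnonzero(seg >= ymax - END_TOL_MM)[0])
        # start: latest sub-threshold-speed sample before the midpoint
        before = np.flatnonzero(speed[:mid_idx] < SPEED_THRESH)
        if before.size == 0:
            continue
        start_idx = int(before[-1])
        if start_idx >= mid_idx:
            continue
        events.append(ReachEvent(start_s=float(t[start_idx]),
                                 mid_s=float(t[mid_idx]),
                                 end_s=float(t[end_idx]),
                                 max_extent_mm=ymax))
    return events


def build_trial_table(reaches: list[ReachEvent], reward_pulse_times: np.ndarray,
                      delay_s: float, match_tol_s: float = 0.3) -> pd.DataFrame:
    """Assemble the trial table from included reaches and solenoid pulses.

    Each included reach is matched to the first reward pulse within
    ``delay_s ± match_tol_s`` of its end; unmatched reaches are omission
    trials with reward_s set to the expected time (end + delay).  Reward
    pulses with no matching reach are logged as orphans.
    """
    pulses = np.sort(np.asarray(reward_pulse_times, dtype=float))
    used = np.zeros(pulses.size, dtype=bool)
    rows = []
    for reach in reaches:
        if not reach.included:
            continue
        expected = reach.end_s + delay_s
        j = np.searchsorted(pulses, expected - match_tol_s)
        matched = None
        while j < pulses.size and pulses[j] <= expected + match_tol_s:
            if not used[j]:
                matched = j
                break
            j += 1
        if matched is not None:
            used[matched] = True
            reward_s, omitted = float(pulses[matched]), False
        else:
            reward_s, omitted = expected, True
        rows.append((reach.start_s, reach.mid_s, reach.end_s,
                     reach.max_extent_mm, reward_s, omitted))
    for p in pulses[~used]:
        logger.warning("orphan reward pulse at t=%.3f s (no matching reach)", p)
    table = pd.DataFrame(rows, columns=["start_s", "mid_s", "end_s",
                                        "max_extent_mm", "reward_s", "omitted"])
    table.insert(0, "trial", np.arange(len(table)))
    table["valid"] = True
    return table


def lick_validity_mask(t: np.ndarray, lick: np.ndarray, trials: pd.DataFrame,
                       block_s: float = 1.5, duty: float = 0.9,
                       post_reward_s: float = 2.0) -> np.ndarray:
    """Flag trials in which the lick sensor was stuck on.

    A trial is invalid iff the sensor is high for more than ``duty`` of any
    continuous ``block_s`` window inside the trial span (reach start to
    reward + 2 s).
    """
    t = np.asarray(t, dtype=float)
    lick = np.asarray(lick, dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    w = int(round(block_s * fs))
    csum = np.concatenate([[0.0], np.cumsum(lick)])
    frac = (csum[w:] - csum[:-w]) / w  # window starting at each index
    valid = np.ones(len(trials), dtype=bool)
    for i, row in trials.iterrows():
        lo = int(np.searchsorted(t, row["start_s"]))
        hi = int(np.searchsorted(t, row["reward_s"] + post_reward_s))
        hi_start = hi - w  # last window fully inside the span
        if hi_start > lo and np.any(frac[lo:hi_start] > duty):
            valid[i] = False
    return valid


def lick_rate_trace(t: np.ndarray, lick: np.ndarray,
                    kernel_fwhm_s: float = 0.15) -> np.ndarray:
    """Smooth lick onsets (0->1 sensor transitions) into a rate (licks/s)."""
    lick = np.asarray(lick, dtype=float) > 0.5
    fs = 1.0 / float(np.median(np.diff(np.asarray(t, dtype=float))))
    onsets = np.zeros(lick.size)
    idx = np.flatnonzero(~lick[:-1] & lick[1:]) + 1
    if lick[0]:
        idx = np.concatenate([[0], idx])
    onsets[idx] = fs
    sd = kernel_fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0))) * fs
    half = int(np.ceil(4 * sd))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    k /= k.sum()
    return np.convolve(onsets, k, mode="same")


def lick_preference(time_axis: np.ndarray, rate: np.ndarray,
                    early: tuple[float, float] = (-0.8, -0.6),
                    late: tuple[float, float] = (-0.2, 0.0)) -> float:
    """Late/early lick preference (late - early)/(late + early), in [-1, 1].

    ``rate`` is a reward-aligned lick rate (single trial or trial-average)
    on ``time_axis`` seconds relative to reward.  NaN if neither window
    contains licking.
    """
    time_axis = np.asarray(time_axis, dtype=float)
    rate = np.asarray(rate, dtype=float)
    e = rate[(time_axis >= early[0]) & (time_axis <= early[1])].mean()
    l = rate[(time_axis >= late[0]) & (time_axis <= late[1])].mean()
    if e + l == 0:
        return float("nan")
    return float((l - e) / (l + e))


def lick_offtime(time_axis: np.ndarray, rate: np.ndarray,
                 peak_window: tuple[float, float] = (-0.25, 0.5),
                 max_s: float = 2.0) -> float:
    """Post-reward lick off-time: last time (max 2 s) the rate exceeds 70%
    of the peak over [-0.25, 0.5] s; 0 if licking never falls below 50% of
    that peak.  NaN if there is no licking in the peak window.
    """
    time_axis = np.asarray(time_axis, dtype=float)
    rate = np.asarray(rate, dtype=float)
    in_peak = (time_axis >= peak_window[0]) & (time_axis <= peak_window[1])
    if not in_peak.any() or np.nanmax(rate[in_peak]) <= 0:
        return float("nan")
    peak = float(np.nanmax(rate[in_peak]))
    peak_t = float(time_axis[in_peak][np.nanargmax(rate[in_peak])])
    tail = (time_axis >= peak_t) & (time_axis <= max_s)
    if np.nanmin(rate[tail]) >= 0.5 * peak:
        return 0.0
    above = tail & (rate > 0.7 * peak)
    if not above.any():
        return float(max(peak_t, 0.0))
    return float(time_axis[above][-1])
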