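"""Trial alignment and window-based response classification.

Builds cells x time x trials tensors aligned to reward or movement (or a
concatenation of both, with the movement midpoint pinned at -delay relative
to reward), then applies window-threshold rules to identify anticipatory
GrCs and reward-responsive CFs, and computes the per-cell timing metrics:
anticipation off-time, CF onset time, anticipatory center time, and the
duration of elevated activity after movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedTensor",
    "align_to_trials",
    "standardize_rates",
    "zscore_rate_tensor",
    "classify_modulated",
    "classify_anticipatory_grcs",
    "classify_reward_cfs",
    "anticipation_offtime",
    "cf_onset_time",
    "anticipatory_center_time",
    "elevated_duration",
]


@dataclass
class AlignedTensor:
    """cells x time x trials array on a uniform relative-time axis."""

    values: np.ndarray
    time: np.ndarray
    alignment: str                      # reward | movement | concatenated
    trial_index: np.ndarray             # rows of the source trial table

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.time.size:
            raise ValueError("time axis mismatch")
        steps = np.diff(self.time)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("time axis must be strictly increasing, uniform")

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    def trial_average(self) -> np.ndarray:
        return self.values.mean(axis=2)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.time >= window[0]) & (self.time <= window[1])


def _event_times(trials: pd.DataFrame, alignment: str) -> np.ndarray:
    col = {"reward": "reward_s", "movement": "mid_s"}[alignment]
    return trials[col].to_numpy(dtype=float)


def align_to_trials(traces: np.ndarray, frame_times: np.ndarray,
                    trials: pd.DataFrame, alignment: str = "reward",
                    window: tuple[float, float] = (-1.5, 0.5),
                    delay_s: float | None = None,
                    subset: str = "all") -> AlignedTensor:
    """Sample traces onto a relative time grid around each trial's event.

    ``alignment='reward'`` or ``'movement'`` uses a single event;
    ``'concatenated'`` joins a movement-aligned segment and a reward-aligned
    segment such that the movement midpoint sits at ``-delay_s`` on the
    reward-relative axis (requires ``delay_s``).  ``subset`` selects
    ``'all'``, ``'rewarded'`` or ``'omission'`` trials.  Trials whose window
    exceeds the session bounds are dropped with a log entry.  Sampling is
    nearest-frame.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    frame_times = np.asarray(frame_times, dtype=float)
    fs = 1.0 / float(np.median(np.diff(frame_times)))

    if subset == "rewarded":
        trials = trials[~trials["omitted"].astype(bool)]
    elif subset == "omission":
        trials = trials[trials["omitted"].astype(bool)]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")

    rel = np.arange(np.ceil(window[0] * fs), np.floor(window[1] * fs) + 1) / fs

    if alignment == "concatenated":
        if delay_s is None:
            raise ValueError("concatenated alignment requires delay_s")
        split = -delay_s / 2.0
        mov_part = rel[rel < split]
        rew_part = rel[rel >= split]
        events_m = _event_times(trials, "movement")
        events_r = _event_times(trials, "reward")
        # movement segment times are relative to the midpoint, shifted so the
        # midpoint lands at -delay_s on the reward-relative axis
        offs_m = events_m[:, None] + (mov_part[None, :] + delay_s)
        offs_r = events_r[:, None] + rew_part[None, :]
        abs_times = np.concatenate([offs_m, offs_r], axis=1)
    elif alignment in ("reward", "movement"):
        events = _event_times(trials, alignment)
        abs_times = events[:, None] + rel[None, :]
    else:
        raise ValueError(f"unknown alignment {alignment!r}")

    idx = np.round(abs_times * fs).astype(int)
    ok = (idx.min(axis=1) >= 0) & (idx.max(axis=1) < frame_times.size)
    if not np.all(ok):
        logger.info("dropping %d trials whose window exceeds session bounds",
                    int((~ok).sum()))
    idx = idx[ok]
    values = traces[:, idx]  # cells x kept-trials x time
    values = np.moveaxis(values, 1, 2)
    return AlignedTensor(values=values, time=rel, alignment=alignment,
                         trial_index=trials.index.to_numpy()[ok])


def standardize_rates(rates: np.ndarray) -> np.ndarray:
    """Standardize rate traces per cell over the whole session.

    Rates are non-negative, so the sub-zero fluorescence normalization does
    not apply; session-wide mean/s.d. scaling puts the 0.1-zsc
    classification margins on a comparable footing across cells.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    mu = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (rates - mu) / sd


def zscore_rate_tensor(tensor: AlignedTensor,
                       baseline_window: tuple[float, float] = (-1.0, -0.5)
                       ) -> AlignedTensor:
    """Standardize a rate tensor per cell against its pre-event baseline.

    Rates are non-negative so the sub-zero noise normalization used for
    fluorescence does not apply; instead each cell's rates are centered and
    scaled by the mean and s.d. of all (trial, frame) baseline samples.
    """
    m = tensor.window_mask(baseline_window)
    base = tensor.values[:, m, :].reshape(tensor.values.shape[0], -1)
    mu = base.mean(axis=1)[:, None, None]
    sd = base.std(axis=1)[:, None, None]
    sd = np.where(sd > 0, sd, 1.0)
    return AlignedTensor(values=(tensor.values - mu) / sd, time=tensor.time,
                         alignment=tensor.alignment,
                         trial_index=tensor.trial_index)


def classify_modulated(tensor: AlignedTensor, window: tuple[float, float],
                       baseline_window: tuple[float, float],
                       alpha: float = 0.05, magnitude: float = 0.2
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-trial modulation test: flag cells with p < alpha (two-sided
    paired signed-rank on per-trial window means) AND |mean difference|
    exceeding ``magnitude`` z-scores.

    Returns ``(flags, p_values, mean_differences)``.
    """
    if tensor.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if tensor.n_trials < 10:
        logger.warning("classify_modulated with <10 trials is underpowered")
    wm = tensor.window_mask(window)
    bm = tensor.window_mask(baseline_window)
    win = tensor.values[:, wm, :].mean(axis=1)   # cells x trials
    base = tensor.values[:, bm, :].mean(axis=1)
    diffs = win - base
    mean_diff = diffs.mean(axis=1)
    pvals = np.ones(diffs.shape[0])
    for i in range(diffs.shape[0]):
        d = diffs[i]
        if np.allclose(d, 0):
            continue
        pvals[i] = stats.wilcoxon(d, zero_method="wilcox").pvalue
    flags = (pvals < alpha) & (np.abs(mean_diff) > magnitude)
    return flags, pvals, mean_diff


def classify_anticipatory_grcs(tensor: AlignedTensor, margin: float = 0.1,
                               pre_reward: tuple[float, float] = (-0.3, -0.03),
                               early: tuple[float, float] = (-1.3, -1.0),
                               post: tuple[float, float] = (0.3, 0.5)
                               ) -> np.ndarray:
    """Anticipatory GrCs: trial-average activity just before reward exceeds
    both the early-delay flank and the post-reward flank by > 0.1 z-scores.

    Requires a reward-aligned tensor spanning at least [-1.3, 0.5] s.
    """
    for w in (pre_reward, early, post):
        if not tensor.window_mask(w).any():
            raise ValueError(f"tensor does not span window {w}")
    avg = tensor.trial_average()
    pre = avg[:, tensor.window_mask(pre_reward)].mean(axis=1)
    e = avg[:, tensor.window_mask(early)].mean(axis=1)
    p = avg[:, tensor.window_mask(post)].mean(axis=1)
    return (pre > e + margin) & (pre > p + margin)


def classify_reward_cfs(rate_tensor: AlignedTensor, margin: float = 0.1,
                        reward_window: tuple[float, float] = (0.0, 0.2),
                        pre_window: tuple[float, float] = (-0.3, -0.03)
                        ) -> np.ndarray:
    """Reward CFs: z-scored spike rate in [0, 0.2] s after reward exceeds
    0.1 and exceeds the pre-reward rate by 0.1.  Expects a standardized
    (z-scored) reward-aligned rate tensor.
    """
    for w in (reward_window, pre_window):
        if not rate_tensor.window_mask(w).any():
            raise ValueError(f"tensor does not span window {w}")
    avg = rate_tensor.trial_average()
    rw = avg[:, rate_tensor.window_mask(reward_window)].mean(axis=1)
    pre = avg[:, rate_tensor.window_mask(pre_window)].mean(axis=1)
    return (rw > margin) & (rw > pre + margin)


def anticipation_offtime(time_axis: np.ndarray, trace: np.ndarray,
                         peak_window: tuple[float, float] = (-0.5, 0.0)
                         ) -> float:
    """Time after reward at which anticipation terminates: first post-reward
    time the trace falls below 50% of its pre-reward peak.  NaN if the peak
    is not positive or the trace never falls below half-peak."""
    time_axis = np.asarray(time_axis, dtype=float)
    trace = np.asarray(trace, dtype=float)
    pm = (time_axis >= peak_window[0]) & (time_axis <= peak_window[1])
    if not pm.any():
        raise ValueError("time axis does not span the peak window")
    peak = float(trace[pm].max())
    if peak <= 0:
        return float("nan")
    post = time_axis >= 0
    below = post & (trace < 0.5 * peak)
    if not below.any():
        return float("nan")
    return float(time_axis[below][0])


def cf_onset_time(time_axis: np.ndarray, mean_rate: np.ndarray,
                  response_window: tuple[float, float] = (0.0, 0.2),
                  percentile: float = 20.0,
                  threshold: float | None = None) -> float:
    """Time after reward when population CF spiking rises: first post-reward
    time the across-cell average exceeds the 20th percentile of the reward
    response ([0, 0.2] s).  For omission trials pass ``threshold`` computed
    from the rewarded-trial response (the reward response defines the
    threshold; omission traces are compared against it).  NaN if the
    response window is silent."""
    time_axis = np.asarray(time_axis, dtype=float)
    mean_rate = np.asarray(mean_rate, dtype=float)
    if threshold is None:
        rm = ((time_axis >= response_window[0])
              & (time_axis <= response_window[1]))
        if not rm.any():
            raise ValueError("time axis does not span the response window")
        if mean_rate[rm].max() <= 0:
            return float("nan")
        threshold = float(np.percentile(mean_rate[rm], percentile))
    post = time_axis >= 0
    above = post & (mean_rate > threshold)
    if not above.any():
        return float("nan")
    return float(time_axis[above][0])


def anticipatory_center_time(time_axis: np.ndarray, trace: np.ndarray,
                             window: tuple[float, float],
                             mode: str = "rectified") -> float:
    """Center of a cell's delay activity, seconds relative to reward.

    ``mode='rectified'`` (default): activity-weighted centroid of the
    positive-rectified trial-average within the delay window.
    ``mode='elevated'``: unweighted center of timepoints whose activity
    exceeds 0.1 z-scores.  NaN if there is no positive activity.
    """
    time_axis = np.asarray(time_axis, dtype=float)
    trace = np.asarray(trace, dtype=float)
    m = (time_axis >= window[0]) & (time_axis <= window[1])
    tw, xw = time_axis[m], trace[m]
    if mode == "rectified":
        w = np.maximum(xw, 0.0)
        if w.sum() <= 0:
            return float("nan")
        return float((tw * w).sum() / w.sum())
    if mode == "elevated":
        el = xw > 0.1
        if not el.any():
            return float("nan")
        return float(tw[el].mean())
    raise ValueError(f"unknown mode {mode!r}")


def elevated_duration(time_axis: np.ndarray, trace: np.ndarray,
                      window: tuple[float, float] = (0.0, 2.0),
                      baseline_window: tuple[float, float] = (-1.0, 0.0),
                      margin: float = 0.1) -> float:
    """Total time within ``window`` (movement-aligned) that activity exceeds
    the pre-movement baseline mean by ``margin`` z-scores."""
    time_axis = np.asarray(time_axis, dtype=float)
    trace = np.asarray(trace, dtype=float)
    bm = (time_axis >= baseline_window[0]) & (time_axis <= baseline_window[1])
    wm = (time_axis >= window[0]) & (time_axis <= window[1])
    if not bm.any() or not wm.any():
        raise ValueError("time axis does not span the required windows")
    base = float(trace[bm].mean())
    dt = float(np.median(np.diff(time_axis)))
    return float((trace[wm] > base + margin).sum() * dt)
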