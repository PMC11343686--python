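"""CF-driven GrC→PkC plasticity rules: LTD from reward-evoked CF spikes,
the LTP extension, and null controls.

For each Purkinje cell (proxied by its imaged dendrite / CF input, assuming
all-to-all GrC connectivity within the field of view) and each reward-evoked
CF spike (within [0, 0.25] s of reward), a GrC's depression event magnitude
is its mean activity in the eligibility window [-150, -25] ms before the
spike, rectified at baseline and bounded to (0, 1) by a logistic
``1/(1 + exp(-F/s))`` with per-cell scale ``s`` set to the cell's 95th
percentile fluorescence.  Event magnitudes are averaged over all spikes,
giving one GrC weight vector per PkC, which is normalized to unit sum,
mean-subtracted, averaged across PkCs, and negated (the sign of depression)
to yield the session weight vector used for readout.

The LTP variant adds opposing potentiation events at timepoints in the
bottom 0.5% of a CF's firing-rate distribution.  Controls: LTD on
time-shuffled GrC data, random reordering of the true weight vector, and a
uniform (simple-average) readout.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import AlignedTensor

logger = logging.getLogger(__name__)

__all__ = [
    "PlasticityParams",
    "WeightSet",
    "select_included_cfs",
    "reward_spike_events",
    "plasticity_event_magnitude",
    "compute_session_weights",
    "compute_ltp_adjusted_weights",
    "control_weights",
]


@dataclass(frozen=True)
class PlasticityParams:
    reward_spike_window_s: tuple[float, float] = (0.0, 0.25)
    eligibility_window_s: tuple[float, float] = (-0.150, -0.025)
    cf_post_window_s: tuple[float, float] = (0.0, 0.25)
    cf_pre_window_s: tuple[float, float] = (-0.3, -0.025)
    logistic_scale_percentile: float = 95.0
    rectify: bool = True
    ltp_rate_percentile: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.eligibility_window_s
        if not lo < hi <= 0:
            raise ValueError("eligibility window must be strictly pre-spike")
        if not 0 < self.logistic_scale_percentile < 100:
            raise ValueError("percentile outside (0,100)")
        if not 0 < self.ltp_rate_percentile < 100:
            raise ValueError("percentile outside (0,100)")


@dataclass
class WeightSet:
    """Per-PkC and session-level GrC weight vectors.

    ``per_pkc`` rows are unit-sum normalized; ``session_vector`` is the
    negated mean of the mean-subtracted rows (zero mean).  ``raw_ltd`` is
    the pre-normalization mean event magnitude per GrC averaged across PkCs
    (the "predicted LTD magnitude").  ``readout_vector`` is what a weighted
    readout should use: the session vector, except for the uniform control
    where it is the pre-subtraction simple average.
    """

    per_pkc: np.ndarray
    session_vector: np.ndarray
    provenance: str
    params: PlasticityParams
    raw_ltd: np.ndarray | None = None

    @property
    def n_grc(self) -> int:
        return self.session_vector.size

    @property
    def readout_vector(self) -> np.ndarray:
        if self.provenance == "uniform":
            return np.full(self.n_grc, 1.0 / self.n_grc)
        return self.session_vector

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grc_id": np.arange(self.n_grc),
            "weight": self.session_vector,
            "provenance": self.provenance,
        })


def select_included_cfs(rate_tensor: AlignedTensor,
                        params: PlasticityParams = PlasticityParams()
                        ) -> np.ndarray:
    """CFs with detectable reward-evoked spiking: trial-averaged rate over
    [0, 0.25] s exceeds the pre-reward [-0.3, -0.025] s average."""
    avg = rate_tensor.trial_average()
    post = avg[:, rate_tensor.window_mask(params.cf_post_window_s)].mean(axis=1)
    pre = avg[:, rate_tensor.window_mask(params.cf_pre_window_s)].mean(axis=1)
    return post > pre


def reward_spike_events(trains: list[np.ndarray], reward_times: np.ndarray,
                        params: PlasticityParams = PlasticityParams()
                        ) -> list[np.ndarray]:
    """Keep, per CF, only spikes within the reward window of some reward.

    ``reward_times`` should be delivery times of rewarded trials (omission
    trials deliver nothing and so contribute no teaching events).
    """
    lo, hi = params.reward_spike_window_s
    reward_times = np.sort(np.asarray(reward_times, dtype=float))
    out = []
    for train in trains:
        train = np.asarray(train, dtype=float)
        if train.size == 0 or reward_times.size == 0:
            out.append(np.empty(0))
            continue
        j = np.searchsorted(reward_times, train) - 1
        ok = np.zeros(train.size, dtype=bool)
        for off in (0, 1):
            jj = np.clip(j + off, 0, reward_times.size - 1)
            dt = train - reward_times[jj]
            ok |= (dt >= lo) & (dt <= hi)
        out.append(train[ok])
    return out


def logistic_scales(grc_z: np.ndarray,
                    params: PlasticityParams = PlasticityParams()) -> np.ndarray:
    """Per-cell logistic scale s: the 95th-percentile of the full z trace."""
    return np.percentile(grc_z, params.logistic_scale_percentile, axis=1)


def plasticity_event_magnitude(f: np.ndarray | float, s: np.ndarray | float,
                               rectify: bool = True) -> np.ndarray:
    """Bounded event magnitude 1/(1 + exp(-F/s)) in (0, 1).

    ``f`` is the mean eligibility-window activity, rectified at zero by
    default so only activity above baseline drives depression; the logistic
    midpoint 0.5 is therefore the no-activity floor.  Monotone
    non-decreasing in ``f``.
    """
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    if rectify:
        f = np.maximum(f, 0.0)
    return 1.0 / (1.0 + np.exp(-f / s))


def _eligibility_means(grc_z: np.ndarray, frame_times: np.ndarray,
                       event_times: np.ndarray,
                       window: tuple[float, float]) -> np.ndarray:
    """Mean GrC activity in the pre-event eligibility window.

    Returns an (events x cells) matrix.  Uses the frames whose times fall in
    [t + lo, t + hi]; events whose window contains no frame or leaves the
    session are dropped (rows of NaN filtered by callers).
    """
    lo, hi = window
    out = np.full((event_times.size, grc_z.shape[0]), np.nan)
    for k, t in enumerate(np.asarray(event_times, dtype=float)):
        i0 = int(np.searchsorted(frame_times, t + lo))
        i1 = int(np.searchsorted(frame_times, t + hi, side="right"))
        if i1 > i0 and i0 >= 0 and i1 <= grc_z.shape[1]:
            out[k] = grc_z[:, i0:i1].mean(axis=1)
    return out


def _normalize_chain(per_pkc_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """unit-sum -> mean-subtract -> average across PkCs -> negate."""
    sums = per_pkc_raw.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("per-PkC weight vector with non-positive sum")
    unit = per_pkc_raw / sums
    centered = unit - unit.mean(axis=1, keepdims=True)
    session = -centered.mean(axis=0)
    return unit, session


def compute_session_weights(grc_z: np.ndarray, frame_times: np.ndarray,
                            cf_reward_spikes: list[np.ndarray],
                            params: PlasticityParams = PlasticityParams(),
                            provenance: str = "true") -> WeightSet:
    """Predicted GrC→PkC weights from reward-evoked CF spikes.

    ``cf_reward_spikes`` holds, per included CF, the reward-window spike
    times (see :func:`reward_spike_events`).  CFs without any reward spike
    are skipped.  Raises if no CF provides a teaching signal.
    """
    grc_z = np.atleast_2d(np.asarray(grc_z, dtype=float))
    s = logistic_scales(grc_z, params)
    degenerate = s <= 0
    if degenerate.any():
        logger.warning("%d GrCs with non-positive logistic scale; "
                       "assigned neutral magnitude 0.5", int(degenerate.sum()))
        s = np.where(degenerate, 1.0, s)

    rows = []
    raw_rows = []
    for spikes in cf_reward_spikes:
        spikes = np.asarray(spikes, dtype=float)
        if spikes.size == 0:
            continue
        f = _eligibility_means(grc_z, frame_times, spikes,
                               params.eligibility_window_s)
        f = f[~np.isnan(f).any(axis=1)]
        if f.shape[0] == 0:
            continue
        m = plasticity_event_magnitude(f, s[None, :], params.rectify)
        if degenerate.any():
            m[:, degenerate] = 0.5
        raw = m.mean(axis=0)  # mean LTD over all (trial, spike) events pooled
        raw_rows.append(raw)
        rows.append(raw)
    if not rows:
        raise ValueError("no teaching signal: no included CF has reward spikes")
    per_pkc_raw = np.stack(rows)
    unit, session = _normalize_chain(per_pkc_raw)
    return WeightSet(per_pkc=unit, session_vector=session,
                     provenance=provenance, params=params,
                     raw_ltd=np.stack(raw_rows).mean(axis=0))


def _trial_frame_slices(frame_times: np.ndarray, trials: pd.DataFrame,
                        pad_post_s: float = 1.0) -> list[slice]:
    out = []
    for _, row in trials.iterrows():
        i0 = int(np.searchsorted(frame_times, row["start_s"]))
        i1 = int(np.searchsorted(frame_times, row["reward_s"] + pad_post_s))
        out.append(slice(i0, min(i1, frame_times.size)))
    return out


def compute_ltp_adjusted_weights(grc_z: np.ndarray, frame_times: np.ndarray,
                                 cf_reward_spikes: list[np.ndarray],
                                 cf_rates: np.ndarray, trials: pd.DataFrame,
                                 params: PlasticityParams = PlasticityParams(),
                                 seed: int = 0) -> WeightSet:
    """LTD weights opposed by LTP at low-CF-rate timepoints.

    Per CF, LTP events are the bottom ``ltp_rate_percentile`` % of trial
    timepoints ranked by that CF's firing rate (a count, not a threshold:
    smoothed CF rates are zero at most frames, so the low-rate tail is one
    large tie broken with a seeded shuffle); their magnitudes use the same
    eligibility window and logistic bound.  The net depression per
    (CF, GrC) is (sum of LTD magnitudes) − (sum of LTP magnitudes), then
    the usual normalization chain.  A CF with no selected timepoints
    reduces to pure LTD.
    """
    grc_z = np.atleast_2d(np.asarray(grc_z, dtype=float))
    s = logistic_scales(grc_z, params)
    degenerate = s <= 0
    if degenerate.any():
        logger.warning("%d GrCs with non-positive logistic scale; "
                       "assigned neutral magnitude 0.5", int(degenerate.sum()))
        s = np.where(degenerate, 1.0, s)
    slices = _trial_frame_slices(frame_times, trials)
    trial_idx = np.concatenate([np.arange(sl.start, sl.stop) for sl in slices])

    rows = []
    for j, spikes in enumerate(cf_reward_spikes):
        spikes = np.asarray(spikes, dtype=float)
        if spikes.size == 0:
            continue
        f_ltd = _eligibility_means(grc_z, frame_times, spikes,
                                   params.eligibility_window_s)
        f_ltd = f_ltd[~np.isnan(f_ltd).any(axis=1)]
        if f_ltd.shape[0] == 0:
            continue
        m_ltd = plasticity_event_magnitude(f_ltd, s[None, :], params.rectify)

        rate_vals = cf_rates[j, trial_idx]
        k = int(round(params.ltp_rate_percentile / 100.0 * rate_vals.size))
        rng = np.random.default_rng(np.random.SeedSequence([seed, j]))
        shuffle = rng.permutation(rate_vals.size)
        order = shuffle[np.argsort(rate_vals[shuffle], kind="stable")]
        ltp_times = frame_times[trial_idx[order[:k]]]
        n_ltp = 0
        m_ltp_sum = np.zeros(grc_z.shape[0])
        if ltp_times.size:
            f_ltp = _eligibility_means(grc_z, frame_times, ltp_times,
                                       params.eligibility_window_s)
            f_ltp = f_ltp[~np.isnan(f_ltp).any(axis=1)]
            n_ltp = f_ltp.shape[0]
            if n_ltp:
                m_ltp_sum = plasticity_event_magnitude(
                    f_ltp, s[None, :], params.rectify).sum(axis=0)
        net = m_ltd.sum(axis=0) - m_ltp_sum
        if degenerate.any():
            net[degenerate] = 0.5 * (m_ltd.shape[0] - n_ltp)
        if net.sum() <= 0:
            logger.warning("CF %d: non-positive net depression sum; skipped", j)
            continue
        rows.append(net)
    if not rows:
        raise ValueError("no teaching signal for LTP-adjusted weights")
    unit, session = _normalize_chain(np.stack(rows))
    return WeightSet(per_pkc=unit, session_vector=session,
                     provenance="ltp_adjusted", params=params)


def control_weights(grc_z: np.ndarray, frame_times: np.ndarray,
                    cf_reward_spikes: list[np.ndarray], trials: pd.DataFrame,
                    mode: str, seed: int = 0,
                    params: PlasticityParams = PlasticityParams(),
                    true_weights: WeightSet | None = None) -> WeightSet:
    """Null-control weight vectors.

    ``time_shuffled``: permute each GrC's timepoints within every trial,
    then run the full LTD pipeline (each GrC keeps its per-trial value
    distribution but loses its timing).  ``reordered``: randomly permute the
    true session vector across GrCs (the multiset of weights is preserved).
    ``uniform``: simple GrC average (mean subtraction makes the session
    vector exactly zero; the readout uses the uniform pre-subtraction
    average).
    """
    rng = np.random.default_rng(seed)
    grc_z = np.atleast_2d(np.asarray(grc_z, dtype=float))
    n = grc_z.shape[0]
    if mode == "time_shuffled":
        shuffled = grc_z.copy()
        for sl in _trial_frame_slices(frame_times, trials):
            width = sl.stop - sl.start
            for i in range(n):
                shuffled[i, sl] = shuffled[i, sl][rng.permutation(width)]
        ws = compute_session_weights(shuffled, frame_times, cf_reward_spikes,
                                     params, provenance="time_shuffled")
        return ws
    if mode == "reordered":
        if true_weights is None:
            true_weights = compute_session_weights(grc_z, frame_times,
                                                   cf_reward_spikes, params)
        perm = rng.permutation(n)
        return WeightSet(per_pkc=true_weights.per_pkc[:, perm],
                         session_vector=true_weights.session_vector[perm],
                         provenance="reordered", params=params)
    if mode == "uniform":
        unit = np.full((1, n), 1.0 / n)
        return WeightSet(per_pkc=unit, session_vector=np.zeros(n),
                         provenance="uniform", params=params)
    raise ValueError(f"unknown control mode {mode!r}")
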