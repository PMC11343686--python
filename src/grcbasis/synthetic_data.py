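"""Synthetic delayed-reward conditioning sessions with ground truth.

Generates complete sessions — 200 Hz behavior streams (manipulandum
position, reward solenoid, capacitive lick sensor), granule-cell (GrC)
fluorescence, climbing-fiber (CF, i.e. Purkinje-dendrite) fluorescence —
with the statistical structure of dual-color two-photon recordings during
forelimb operant conditioning: mice push a manipulandum ~8 mm, wait a fixed
delay (1, 1.1 or 2 s), and receive a water reward that is withheld on a
random subset of trials.

Expert sessions contain a population of anticipatory GrCs whose activity
ramps up and down at heterogeneous rates spanning movement-to-reward (the
"delay-spanning basis"), truncated shortly after reward and prolonged after
reward omission; reward-responsive CFs spike time-locked to reward on a
~1 Hz Poisson background and shift to a late omission-recognition spike on
omitted trials. Novice sessions instead carry brief movement-locked
anticipatory transients and early, poorly-timed licking.

Every cell's generative parameters are returned as ground truth so that
each downstream stage (event detection, classification, plasticity, and
decoding) can be scored against the simulator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "SynthConfig",
    "Session",
    "simulate_trials",
    "simulate_grc_population",
    "simulate_cf_population",
    "simulate_session",
    "save_session",
    "load_session",
]

# nominal reach kinematics (seconds, mm)
_REACH_MM = 8.0
_POST_REWARD_TRUNC_S = 0.2  # anticipation falls to zero this long after reward


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic session.

    Defaults are the recorded-data conditions: ~143 GrCs and ~55 PkC
    dendrites per session, ~110 trials, a 1.1-s delay with 20% reward
    omissions, 30 Hz imaging, 200 Hz behavior, 34% anticipatory GrCs, 50%
    reward-responsive CFs on a 1 Hz spontaneous background, and a 150 ms
    indicator decay constant.
    """

    n_grc: int = 143
    n_cf: int = 55
    n_trials: int = 110
    delay_s: float = 1.1
    omission_frac: float = 0.2
    frame_rate_hz: float = 30.0
    behav_rate_hz: float = 200.0
    frac_anticipatory: float = 0.34
    frac_cf_reward: float = 0.5
    cf_baseline_hz: float = 1.0
    ca_tau_s: float = 0.15
    noise_sigma: float = 1.0
    bleach_amps: tuple[float, float] = (0.25, 0.08)
    bleach_taus_s: tuple[float, float] = (400.0, 60.0)
    expertise: str = "expert"
    seed: int = 0
    # basis_delay_s: delay the GrC temporal basis is matched to.  Defaults to
    # delay_s; set shorter than delay_s to emulate animals freshly switched to
    # a longer delay whose basis still spans only the previously learned one.
    basis_delay_s: float | None = None
    frac_movement: float = 0.15
    frac_reward: float = 0.10
    cf_spike_amp: float = 5.0
    # noise composition: white (shot-noise-like) plus AR(1) correlated
    # (neuropil / motion-residual-like) parts, total variance noise_sigma^2
    noise_white_frac: float = 0.5
    noise_corr_tau_s: float = 0.3
    drift_amp_frac: float = 0.3
    baseline_f: float = 50.0
    gain: float = 10.0
    # spontaneous background transients present in every GrC (Hz per cell)
    grc_background_hz: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.omission_frac < 1.0:
            raise ValueError(f"omission_frac={self.omission_frac} outside [0,1)")
        for name in ("frac_anticipatory", "frac_cf_reward", "frac_movement",
                     "frac_reward", "noise_white_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.delay_s <= 0:
            raise ValueError("delay_s must be positive")
        if self.frame_rate_hz <= 0 or self.behav_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.cf_baseline_hz < 0:
            raise ValueError("cf_baseline_hz must be non-negative")
        if self.ca_tau_s <= 0:
            raise ValueError("ca_tau_s must be positive")

    @property
    def basis_delay(self) -> float:
        return self.delay_s if self.basis_delay_s is None else self.basis_delay_s

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        d = json.loads(text)
        for key in ("bleach_amps", "bleach_taus_s"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Session:
    """One synthetic session: behavior, fluorescence, and ground truth."""

    config: SynthConfig
    behav: pd.DataFrame          # 200 Hz: t, x, y, reward, lick
    trials: pd.DataFrame         # per-trial ground truth timing
    frame_times: np.ndarray      # imaging frame clock (s)
    grc_raw: np.ndarray          # cells x frames, raw fluorescence (a.u.)
    grc_clean: np.ndarray        # cells x frames, noiseless z-scale signal
    grc_truth: pd.DataFrame      # per-cell generative parameters
    cf_raw: np.ndarray
    cf_clean: np.ndarray
    cf_truth: pd.DataFrame
    cf_spikes: list[np.ndarray]  # per-cell sorted true spike times (s)

    @property
    def duration_s(self) -> float:
        return float(self.frame_times[-1] + 1.0 / self.config.frame_rate_hz)


def _minjerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def simulate_trials(config: SynthConfig, rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate self-initiated reaches and the 200 Hz behavior streams.

    Returns ``(trials, behav)``: a per-trial table with reach start/mid/end
    times, reward time (delivery time, or expected time on omission trials),
    and the omission flag; and a DataFrame of the 200 Hz streams
    (t, x, y, reward, lick).

    The reward solenoid fires exactly ``delay_s`` after reach end on
    non-omission trials.  Licking follows the configured expertise: novices
    lick mostly early in the delay; experts ramp licking toward reward, emit
    a consummatory burst after delivery, and truncate licking after omission.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.omission_frac >= 1.0:
        raise ValueError("omission_frac must be < 1")

    n = config.n_trials
    # experts reach faster and more stereotypically than novices
    if config.expertise == "expert":
        reach_dur = rng.uniform(0.3, 0.45, n)
    else:
        reach_dur = rng.uniform(0.25, 0.65, n)
    iti = rng.uniform(2.0, 3.5, n)
    omitted = rng.random(n) < config.omission_frac

    starts = np.empty(n)
    t_cursor = 3.0
    for i in range(n):
        starts[i] = t_cursor
        # start -> reach -> delay -> reward -> 1.5 s consumption -> ITI
        t_cursor += reach_dur[i] + config.delay_s + 1.5 + iti[i]
    ends = starts + reach_dur
    rewards = ends + config.delay_s

    duration = rewards[-1] + 4.0
    fs = config.behav_rate_hz
    t = np.arange(int(round(duration * fs))) / fs
    y = rng.normal(0.0, 0.05, t.size)
    x = rng.normal(0.0, 0.05, t.size)
    reward_stream = np.zeros(t.size)
    lick = np.zeros(t.size, dtype=np.int8)

    def _seg(t0: float, t1: float) -> slice:
        return slice(int(round(t0 * fs)), min(int(round(t1 * fs)), t.size))

    mids = np.empty(n)
    for i in range(n):
        s, e = starts[i], ends[i]
        sl = _seg(s, e)
        y[sl] += _REACH_MM * _minjerk((t[sl] - s) / reach_dur[i])
        hold_end = rewards[i] + 0.7
        y[_seg(e, hold_end)] += _REACH_MM
        ret = _seg(hold_end, hold_end + 0.5)
        y[ret] += _REACH_MM * (1.0 - _minjerk((t[ret] - hold_end) / 0.5))
        # analytic midpoint: y = 4 mm at minjerk fraction 0.5
        mids[i] = s + 0.5 * reach_dur[i]
        if not omitted[i]:
            reward_stream[_seg(rewards[i], rewards[i] + 0.03)] = 1.0

    # licking: inhomogeneous Poisson lick onsets from a per-expertise template
    rate = np.full(t.size, 0.3)
    for i in range(n):
        s, r = starts[i], rewards[i]
        delay_sl = _seg(s, r)
        u = (t[delay_sl] - s) / (r - s)
        if config.expertise == "expert":
            rate[delay_sl] = 0.5 + 6.5 * u**2
        else:
            rate[delay_sl] = 0.8 + 5.2 * np.exp(-(t[delay_sl] - s) / 0.25)
        if not omitted[i]:
            burst = _seg(r, r + 1.2)
            rate[burst] = 8.0 * np.exp(-(t[burst] - r) / 0.6)
        else:
            tail = _seg(r, r + 0.5)
            rate[tail] = rate[int(round(r * fs)) - 1] * np.exp(-(t[tail] - r) / 0.15)
    onsets = rng.random(t.size) < rate / fs
    contact = int(round(0.04 * fs))
    onset_idx = np.flatnonzero(onsets)
    for j in onset_idx:
        lick[j:j + contact] = 1

    trials = pd.DataFrame({
        "trial": np.arange(n),
        "start_s": starts,
        "mid_s": mids,
        "end_s": ends,
        "reward_s": rewards,
        "omitted": omitted,
        "valid": np.ones(n, dtype=bool),
    })
    behav = pd.DataFrame({"t": t, "x": x, "y": y,
                          "reward": reward_stream, "lick": lick.astype(float)})
    return trials, behav


def _calcium_filter(rates: np.ndarray, tau_s: float, fs: float,
                    unit_gain: bool = True) -> np.ndarray:
    """Causal single-exponential indicator kernel along the last axis."""
    a = np.exp(-1.0 / (fs * tau_s))
    b = [1.0 - a] if unit_gain else [1.0]
    return lfilter(b, [1.0, -a], rates, axis=-1)


def _session_noise(rng: np.random.Generator, shape: tuple[int, int],
                   config: SynthConfig) -> np.ndarray:
    """White + AR(1)-correlated noise mix with total s.d. noise_sigma."""
    if config.noise_sigma == 0:
        return np.zeros(shape)
    fs = config.frame_rate_hz
    phi = np.exp(-1.0 / (fs * config.noise_corr_tau_s))
    white = rng.normal(0.0, 1.0, shape)
    corr = lfilter([np.sqrt(1.0 - phi**2)], [1.0, -phi],
                   rng.normal(0.0, 1.0, shape), axis=-1)
    w = config.noise_white_frac
    return config.noise_sigma * (np.sqrt(w) * white + np.sqrt(1.0 - w) * corr)


def _bleach(t: np.ndarray, config: SynthConfig) -> np.ndarray:
    a1, a2 = config.bleach_amps
    t1, t2 = config.bleach_taus_s
    return 1.0 + a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)


def _raw_from_clean(clean: np.ndarray, frame_times: np.ndarray,
                    rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    sig = clean + _session_noise(rng, clean.shape, config)
    if config.drift_amp_frac > 0 and config.noise_sigma > 0:
        amp = config.drift_amp_frac * config.noise_sigma
        ph = rng.uniform(0, 2 * np.pi, (clean.shape[0], 2))
        drift = (amp * np.sin(2 * np.pi * frame_times / 97.0 + ph[:, :1])
                 + amp * np.sin(2 * np.pi * frame_times / 211.0 + ph[:, 1:2]))
        sig = sig + drift
    return (config.baseline_f + config.gain * sig) * _bleach(frame_times, config)


def _anticipatory_profile(tq: np.ndarray, onset: float, peak_t: float,
                          amp: float, reward: float, residual: float,
                          decay_w: float, fall_end: float) -> np.ndarray:
    """Piecewise-linear delay-spanning ramp evaluated at times tq.

    Rises linearly onset->peak, decays over ``decay_w`` seconds to a
    sustained absolute residual level ``residual`` (z-score units) held
    until reward (the residual encodes the cell's timing: later-peaking
    cells keep more activity at reward, so near-reward activity is a
    snapshot of a cell's earlier profile).  Cells whose nominal peak falls
    after reward are
    still on their rising limb at reward.  At reward the profile falls
    linearly to zero at ``fall_end`` (0.2 s post reward, later on omission
    trials).
    """
    out = np.zeros_like(tq)
    res = min(residual, 0.8 * amp)  # absolute sustained level (z-score units)
    rise_end = min(peak_t, reward)
    rise = (tq >= onset) & (tq < rise_end)
    out[rise] = amp * (tq[rise] - onset) / max(peak_t - onset, 1e-6)
    if peak_t < reward:
        decay = (tq >= peak_t) & (tq <= reward)
        out[decay] = np.maximum(
            amp - (amp - res) * (tq[decay] - peak_t) / max(decay_w, 1e-6),
            res)
        v_r = max(amp - (amp - res) * (reward - peak_t) / max(decay_w, 1e-6),
                  res)
    else:
        v_r = amp * (reward - onset) / max(peak_t - onset, 1e-6)
    post = (tq > reward) & (tq < fall_end)
    out[post] = v_r * (fall_end - tq[post]) / max(fall_end - reward, 1e-6)
    return out


def simulate_grc_population(config: SynthConfig, trials: pd.DataFrame,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate the GrC population given a trial table.

    Returns ``(raw, clean, frame_times, truth)`` where ``clean`` is the
    noiseless indicator-convolved signal in z-score units and ``raw`` adds
    noise, drift, baseline/gain, and multiplicative double-exponential
    bleaching.

    Cell classes: ``anticipatory`` (delay-spanning ramps; brief
    movement-locked transients for novices), ``movement_transient``,
    ``reward_transient`` (latency-jittered consummatory responses, absent on
    omission), and ``silent``.
    """
    if not 0.0 <= config.frac_anticipatory <= 1.0:
        raise ValueError("frac_anticipatory outside [0,1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fs = config.frame_rate_hz
    duration = trials["reward_s"].iloc[-1] + 4.0
    frame_times = np.arange(int(round(duration * fs))) / fs
    n = config.n_grc

    n_ant = int(round(config.frac_anticipatory * n))
    n_mov = int(round(config.frac_movement * n))
    n_rew = int(round(config.frac_reward * n))
    n_mov = min(n_mov, n - n_ant)
    n_rew = min(n_rew, n - n_ant - n_mov)
    classes = np.array(["anticipatory"] * n_ant + ["movement_transient"] * n_mov
                       + ["reward_transient"] * n_rew
                       + ["silent"] * (n - n_ant - n_mov - n_rew))

    # anticipatory profile layout in delay coordinates: onset and peak are
    # seconds after movement end (delay start); peaks fall uniformly across
    # the delay and up to 0.3 s past the nominal reward, emulating cells
    # still rising when reward arrives and truncates them.  Early-peaking
    # cells decay to a small residual ordered by their timing (the
    # "snapshot" structure that lets near-reward plasticity grade them).
    B = config.basis_delay
    amp = rng.uniform(1.0, 3.0, n)
    onset = np.zeros(n)
    peak_t = np.zeros(n)
    residual = np.zeros(n)
    decay_w = np.full(n, 0.1)
    prolong = rng.uniform(0.2, 0.6, n)
    expert = config.expertise == "expert"
    tg_unit = np.linspace(0.0, B, 200)
    for i in range(n):
        if classes[i] != "anticipatory":
            continue
        if expert:
            # mixture of early-peaking cells that ramp down across the delay
            # and later-peaking cells that ramp up toward reward ("ramping up
            # and down at differing rates")
            if rng.random() < 0.35:
                peak_t[i] = rng.uniform(0.02 * B, 0.3 * B)
                decay_w[i] = (B - peak_t[i]) * rng.uniform(0.3, 0.7)
            else:
                peak_t[i] = rng.uniform(0.3 * B, B + 0.3)
                decay_w[i] = (B + _POST_REWARD_TRUNC_S
                              - min(peak_t[i], B)) * rng.uniform(0.5, 1.0)
            onset[i] = rng.uniform(0.0, min(max(peak_t[i] - 0.1, 0.02), 0.7 * B))
            residual[i] = 0.08 + 0.5 * min(peak_t[i], B) / B
            # scale amplitude so the cell's within-trial activity integral
            # (delay plus post-reward truncation) is independent of its
            # timing (keeps the time-shuffled null unbiased)
            tg_full = np.linspace(0.0, B + _POST_REWARD_TRUNC_S, 220)
            unit = _anticipatory_profile(tg_full, onset[i], peak_t[i], 1.0, B,
                                         residual[i], decay_w[i],
                                         B + _POST_REWARD_TRUNC_S)
            integral = unit.sum() * (tg_full[1] - tg_full[0])
            amp[i] *= 0.45 * B / max(integral, 0.05 * B)
        else:
            onset[i] = rng.uniform(0.0, 0.3 * B)
            peak_t[i] = onset[i] + rng.uniform(0.1, 0.3)

    clean = np.zeros((n, frame_times.size))
    t_starts = trials["start_s"].to_numpy()
    t_mids = trials["mid_s"].to_numpy()
    t_ends = trials["end_s"].to_numpy()
    t_rewards = trials["reward_s"].to_numpy()
    omitted = trials["omitted"].to_numpy()

    for i in range(n):
        cls = classes[i]
        if cls == "silent":
            continue
        for k in range(len(trials)):
            s, e, r = t_starts[k], t_ends[k], t_rewards[k]
            lo = int(np.searchsorted(frame_times, s - 0.5))
            hi = int(np.searchsorted(frame_times, r + 1.5))
            tq = frame_times[lo:hi]
            if cls == "anticipatory":
                if expert:
                    on, pk = e + onset[i], e + peak_t[i]
                    # anticipation terminates after reward with behavioral jitter
                    fall = (r + (prolong[i] if omitted[k] else 0.0)
                            + max(0.05, _POST_REWARD_TRUNC_S + rng.normal(0.0, 0.1)))
                    # trial-to-trial response gain variability
                    a_k = amp[i] * rng.lognormal(0.0, 0.4)
                    prof = _anticipatory_profile(tq, on, pk, a_k, r,
                                                 residual[i], decay_w[i], fall)
                else:
                    # brief movement-locked transient; novice responses are
                    # unreliable in both timing and size trial-to-trial
                    jit = rng.normal(0.0, 0.25)
                    a_k = amp[i] * rng.lognormal(0.0, 0.5)
                    on, pk = e + onset[i] + jit, e + peak_t[i] + jit
                    end = pk + rng.uniform(0.2, 0.4)
                    prof = np.interp(tq, [on, pk, end], [0, a_k, 0],
                                     left=0.0, right=0.0)
                clean[i, lo:hi] += prof
            elif cls == "movement_transient":
                m = t_mids[k] + rng.normal(0.0, 0.08)
                a_k = amp[i] * rng.lognormal(0.0, 0.5)
                clean[i, lo:hi] += a_k * np.exp(-0.5 * ((tq - m) / 0.15) ** 2)
            elif cls == "reward_transient":
                if omitted[k]:
                    continue
                # consummatory response: causal alpha function after reward,
                # with trial-varying latency, width and size
                lat = r + max(0.05, rng.normal(0.2, 0.25))
                a_k = amp[i] * rng.lognormal(0.0, 0.5)
                width = rng.uniform(0.1, 0.2)
                u = np.maximum(tq - lat, 0.0) / width
                clean[i, lo:hi] += a_k * u * np.exp(1.0 - u)

    # spontaneous background transients in every cell, at random times
    if config.grc_background_hz > 0:
        gain_inv = 1.0 / (1.0 - np.exp(-1.0 / (fs * config.ca_tau_s)))
        for i in range(n):
            n_ev = rng.poisson(config.grc_background_hz * duration)
            if n_ev == 0:
                continue
            ev_idx = rng.integers(0, frame_times.size, n_ev)
            ev_amp = amp[i] * rng.uniform(0.5, 1.0, n_ev) * gain_inv
            np.add.at(clean[i], ev_idx, ev_amp)

    clean = _calcium_filter(clean, config.ca_tau_s, fs)

    # ground-truth anticipatory center time: rectified centroid of the
    # nominal rewarded-trial profile over [-delay, 0] s relative to reward
    center = np.full(n, np.nan)
    rise_rate = np.full(n, np.nan)
    if expert:
        # nominal rewarded-trial profile in reward-relative coordinates
        # (delay start at -delay_s, reward at 0)
        tg = np.linspace(-config.delay_s, 0.0, 200)
        for i in np.flatnonzero(classes == "anticipatory"):
            d0 = -config.delay_s
            prof = _anticipatory_profile(
                tg, d0 + onset[i], d0 + peak_t[i], amp[i], 0.0,
                residual[i], decay_w[i], _POST_REWARD_TRUNC_S)
            w = np.maximum(prof, 0.0)
            if w.sum() > 0:
                center[i] = float((tg * w).sum() / w.sum())
            rise_rate[i] = amp[i] / max(peak_t[i] - onset[i], 1e-6)

    truth = pd.DataFrame({
        "cell": np.arange(n),
        "class": classes,
        "onset_s": np.where(classes == "anticipatory", onset, np.nan),
        "peak_time_s": np.where(classes == "anticipatory", peak_t, np.nan),
        "rise_rate": rise_rate,
        "amplitude_zsc": amp,
        "center_time_s": center,
        "omission_prolongation_s": np.where(classes == "anticipatory",
                                            prolong, np.nan),
    })
    raw = _raw_from_clean(clean, frame_times, rng, config)
    return raw, clean, frame_times, truth


def simulate_cf_population(config: SynthConfig, trials: pd.DataFrame,
                           rng: np.random.Generator | None = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                      list[np.ndarray], pd.DataFrame]:
    """Simulate CF (PkC-dendrite) spiking and dendritic fluorescence.

    Baseline Poisson spiking at ``cf_baseline_hz``; reward-responsive cells
    emit a spike with per-cell probability within [0, 0.2] s of reward; on
    omission trials the reward spike is replaced by a late spike near the
    time anticipation terminates.  Returns
    ``(raw, clean, frame_times, spike_trains, truth)``.
    """
    if config.cf_baseline_hz < 0:
        raise ValueError("cf_baseline_hz must be non-negative")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    fs = config.frame_rate_hz
    duration = trials["reward_s"].iloc[-1] + 4.0
    frame_times = np.arange(int(round(duration * fs))) / fs
    n = config.n_cf

    n_rew = int(round(config.frac_cf_reward * n))
    reward_responsive = np.zeros(n, dtype=bool)
    reward_responsive[:n_rew] = True
    p_spike = np.where(reward_responsive, rng.uniform(0.65, 0.95, n), 0.0)
    movement_responsive = rng.random(n) < 0.2
    suppressed = rng.random(n) < 0.15

    t_rewards = trials["reward_s"].to_numpy()
    t_mids = trials["mid_s"].to_numpy()
    t_starts = trials["start_s"].to_numpy()
    omitted = trials["omitted"].to_numpy()

    spike_trains: list[np.ndarray] = []
    for i in range(n):
        spikes = []
        if config.cf_baseline_hz > 0:
            n_base = rng.poisson(config.cf_baseline_hz * duration)
            base = rng.uniform(0.0, duration, n_base)
            if suppressed[i]:
                # thin background during the delay period
                keep = np.ones(base.size, dtype=bool)
                for k in range(len(trials)):
                    in_delay = (base > t_starts[k]) & (base < t_rewards[k])
                    keep &= ~in_delay | (rng.random(base.size) > 0.6)
                base = base[keep]
            spikes.append(base)
        if reward_responsive[i]:
            for k in range(len(trials)):
                if rng.random() >= p_spike[i]:
                    continue
                if not omitted[k]:
                    spikes.append(np.array([t_rewards[k] + rng.uniform(0.02, 0.18)]))
                else:
                    # late spike near the (delayed) anticipation off-time
                    spikes.append(np.array([t_rewards[k] + 0.35 + rng.uniform(0.0, 0.2)]))
        if movement_responsive[i]:
            for k in range(len(trials)):
                if rng.random() < 0.3:
                    spikes.append(np.array([t_mids[k] + rng.normal(0.0, 0.05)]))
        st = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        st = st[(st >= 0) & (st < duration - 1.0 / fs)]
        # enforce strictly increasing times (merge sub-sample coincidences)
        if st.size > 1:
            st = st[np.insert(np.diff(st) > 1e-6, 0, True)]
        spike_trains.append(st)

    impulses = np.zeros((n, frame_times.size))
    for i, st in enumerate(spike_trains):
        idx = np.round(st * fs).astype(int)
        np.add.at(impulses[i], idx, config.cf_spike_amp)
    clean = _calcium_filter(impulses, config.ca_tau_s, fs, unit_gain=False)

    truth = pd.DataFrame({
        "cell": np.arange(n),
        "reward_responsive": reward_responsive,
        "p_reward_spike": p_spike,
        "movement_responsive": movement_responsive,
        "suppressed_during_delay": suppressed,
        "n_spikes": [len(s) for s in spike_trains],
    })
    raw = _raw_from_clean(clean, frame_times, rng, config)
    return raw, clean, frame_times, spike_trains, truth


def simulate_session(config: SynthConfig) -> Session:
    """Generate a full session; identical configs give identical sessions."""
    rng_t = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    trials, behav = simulate_trials(config, rng_t)
    grc_raw, grc_clean, ft, grc_truth = simulate_grc_population(config, trials)
    cf_raw, cf_clean, _, cf_spikes, cf_truth = simulate_cf_population(config, trials)
    return Session(config=config, behav=behav, trials=trials, frame_times=ft,
                   grc_raw=grc_raw, grc_clean=grc_clean, grc_truth=grc_truth,
                   cf_raw=cf_raw, cf_clean=cf_clean, cf_truth=cf_truth,
                   cf_spikes=cf_spikes)


def save_session(session: Session, outdir: str | Path) -> Path:
    """Write a session to ``outdir``: HDF5 arrays + CSV tables + JSON config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "session.h5", "w") as f:
        f.create_dataset("grc/F", data=session.grc_raw, compression="gzip")
        f.create_dataset("grc/F_clean", data=session.grc_clean, compression="gzip")
        f.create_dataset("cf/F", data=session.cf_raw, compression="gzip")
        f.create_dataset("cf/F_clean", data=session.cf_clean, compression="gzip")
        f.create_dataset("frame_times", data=session.frame_times)
        g = f.create_group("cf/spikes")
        for i, st in enumerate(session.cf_spikes):
            g.create_dataset(str(i), data=st)
    session.behav.to_csv(outdir / "behavior.csv", index=False)
    session.trials.to_csv(outdir / "trials.csv", index=False)
    session.grc_truth.to_csv(outdir / "grc_truth.csv", index=False)
    session.cf_truth.to_csv(outdir / "cf_truth.csv", index=False)
    (outdir / "config.json").write_text(session.config.to_json())
    return outdir


def load_session(indir: str | Path) -> Session:
    indir = Path(indir)
    config = SynthConfig.from_json((indir / "config.json").read_text())
    with h5py.File(indir / "session.h5", "r") as f:
        grc_raw = f["grc/F"][()]
        grc_clean = f["grc/F_clean"][()]
        cf_raw = f["cf/F"][()]
        cf_clean = f["cf/F_clean"][()]
        frame_times = f["frame_times"][()]
        spikes = [f["cf/spikes"][str(i)][()] for i in range(cf_raw.shape[0])]
    return Session(
        config=config,
        behav=pd.read_csv(indir / "behavior.csv"),
        trials=pd.read_csv(indir / "trials.csv"),
        frame_times=frame_times,
        grc_raw=grc_raw, grc_clean=grc_clean,
        grc_truth=pd.read_csv(indir / "grc_truth.csv"),
        cf_raw=cf_raw, cf_clean=cf_clean,
        cf_truth=pd.read_csv(indir / "cf_truth.csv"),
        cf_spikes=spikes,
    )
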