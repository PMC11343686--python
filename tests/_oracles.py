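"""Independent brute-force oracles for the plasticity rules.

Pure-Python triple loops over (CFs, spikes, GrCs), kept deliberately
separate from the vectorized implementation they check.
"""

import math

import numpy as np


def _percentile(values, q):
    return float(np.percentile(np.asarray(values, dtype=float), q))


def _elig_mean(trace, frame_times, t, lo, hi):
    vals = [trace[i] for i in range(len(frame_times))
            if t + lo <= frame_times[i] <= t + hi]
    if not vals:
        return None
    return sum(vals) / len(vals)


def _magnitude(f, s, rectify):
    if rectify and f < 0:
        f = 0.0
    return 1.0 / (1.0 + math.exp(-f / s))


def brute_force_session_weights(grc_z, frame_times, cf_spikes,
                                elig=(-0.150, -0.025), pct=95.0,
                                rectify=True):
    """Triple-loop LTD weights: per-CF mean event magnitude, unit-sum,
    mean-subtract, average across CFs, negate."""
    grc_z = np.asarray(grc_z, dtype=float)
    n_grc = grc_z.shape[0]
    scales = [_percentile(grc_z[i], pct) for i in range(n_grc)]
    per_pkc = []
    for spikes in cf_spikes:
        if len(spikes) == 0:
            continue
        w = []
        for i in range(n_grc):
            mags = []
            for t in spikes:
                f = _elig_mean(grc_z[i], frame_times, t, elig[0], elig[1])
                if f is None:
                    continue
                mags.append(_magnitude(f, scales[i], rectify))
            w.append(sum(mags) / len(mags))
        per_pkc.append(w)
    if not per_pkc:
        raise ValueError("no spikes")
    unit = []
    for w in per_pkc:
        tot = sum(w)
        unit.append([x / tot for x in w])
    centered = []
    for w in unit:
        mu = sum(w) / len(w)
        centered.append([x - mu for x in w])
    session = [-sum(centered[j][i] for j in range(len(centered))) / len(centered)
               for i in range(n_grc)]
    return np.array(unit), np.array(session)


def brute_force_ltp_weights(grc_z, frame_times, cf_spikes, cf_rates,
                            trial_spans, elig=(-0.150, -0.025), pct=95.0,
                            rectify=True, ltp_pct=0.5):
    """Triple-loop LTP-adjusted weights for toy sessions with strictly
    distinct CF rate values (no tie ambiguity in the bottom-percentile
    selection)."""
    grc_z = np.asarray(grc_z, dtype=float)
    n_grc = grc_z.shape[0]
    scales = [_percentile(grc_z[i], pct) for i in range(n_grc)]

    trial_frames = []
    for lo_t, hi_t in trial_spans:
        for i in range(len(frame_times)):
            if lo_t <= frame_times[i] < hi_t:
                trial_frames.append(i)

    per_pkc = []
    for j, spikes in enumerate(cf_spikes):
        if len(spikes) == 0:
            continue
        rate_vals = [cf_rates[j][i] for i in trial_frames]
        k = int(round(ltp_pct / 100.0 * len(rate_vals)))
        order = sorted(range(len(rate_vals)), key=lambda q: rate_vals[q])
        ltp_times = [frame_times[trial_frames[q]] for q in order[:k]]
        w = []
        for i in range(n_grc):
            ltd = 0.0
            for t in spikes:
                f = _elig_mean(grc_z[i], frame_times, t, elig[0], elig[1])
                if f is not None:
                    ltd += _magnitude(f, scales[i], rectify)
            ltp = 0.0
            for t in ltp_times:
                f = _elig_mean(grc_z[i], frame_times, t, elig[0], elig[1])
                if f is not None:
                    ltp += _magnitude(f, scales[i], rectify)
            w.append(ltd - ltp)
        per_pkc.append(w)
    if not per_pkc:
        raise ValueError("no spikes")
    unit = []
    for w in per_pkc:
        tot = sum(w)
        unit.append([x / tot for x in w])
    centered = []
    for w in unit:
        mu = sum(w) / len(w)
        centered.append([x - mu for x in w])
    session = [-sum(centered[j][i] for j in range(len(centered))) / len(centered)
               for i in range(n_grc)]
    return np.array(unit), np.array(session)
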