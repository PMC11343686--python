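"""Trial alignment, window classifiers, and timing metrics."""

import numpy as np
import pandas as pd
import pytest

import grcbasis as g
from grcbasis import classification as cl

FS = 30.0


def _trials(rewards, mids=None, omitted=None):
    rewards = np.asarray(rewards, dtype=float)
    mids = rewards - 1.5 if mids is None else np.asarray(mids, dtype=float)
    return pd.DataFrame({
        "start_s": mids - 0.2, "mid_s": mids, "end_s": mids + 0.2,
        "reward_s": rewards,
        "omitted": np.zeros(rewards.size, bool) if omitted is None else omitted,
        "valid": np.ones(rewards.size, bool),
    })


class TestAlignment:
    def test_delta_at_reward_lands_at_time_zero(self):
        ft = np.arange(3000) / FS
        rewards = np.array([20.0, 40.0, 60.0])
        trace = np.zeros(ft.size)
        trace[(rewards * FS).astype(int)] = 1.0
        tens = cl.align_to_trials(trace, ft, _trials(rewards), "reward",
                                  (-1.0, 1.0))
        nz = np.nonzero(tens.values[0])
        assert set(nz[0]) == {int(np.flatnonzero(tens.time == 0.0)[0])}
        assert tens.values[0, tens.time == 0.0, :].sum() == 3.0

    def test_concatenated_midpoint_at_minus_delay(self):
        ft = np.arange(3000) / FS
        rewards = np.array([30.0, 60.0])
        mids = rewards - 1.1  # movement midpoint exactly delay before reward
        trace = np.zeros(ft.size)
        trace[np.round(mids * FS).astype(int)] = 1.0
        tens = cl.align_to_trials(trace, ft, _trials(rewards, mids),
                                  "concatenated", (-1.5, 0.5), delay_s=1.1)
        col = np.flatnonzero(np.isclose(tens.time, -1.1))
        assert tens.values[0, col, :].sum() == 2.0

    def test_out_of_bounds_trials_dropped(self):
        ft = np.arange(300) / FS
        tens = cl.align_to_trials(np.zeros(ft.size), ft,
                                  _trials([0.5, 5.0]), "reward", (-1.0, 1.0))
        assert tens.n_trials == 1

    def test_alignment_recovers_generated_profiles(self, small_expert):
        session, _ = small_expert
        cfg = session.config
        ant = (session.grc_truth["class"] == "anticipatory").to_numpy()
        tens = cl.align_to_trials(session.grc_clean[ant], session.frame_times,
                                  session.trials, "reward",
                                  (-cfg.delay_s, 0.0), subset="rewarded")
        # trial-average peak activity of each aligned cell approximates its
        # per-trial profile level (interpolation error only)
        avg = tens.trial_average()
        assert avg.max() > 0.5
        assert tens.time[0] == pytest.approx(-cfg.delay_s, abs=1 / FS)


class TestClassifyModulated:
    def _tensor(self, elevation, n_trials=50, seed=0):
        rng = np.random.default_rng(seed)
        time = np.arange(-30, 16) / FS
        vals = rng.normal(0, 1.0, (3, time.size, n_trials))
        vals[:, time >= 0, :] += elevation
        return cl.AlignedTensor(vals, time, "reward", np.arange(n_trials))

    def test_identical_windows_not_flagged(self):
        tens = self._tensor(0.0)
        flags, _, _ = cl.classify_modulated(tens, (0.0, 0.5), (-1.0, -0.5))
        assert not flags.any()

    def test_half_zscore_elevation_flagged(self):
        tens = self._tensor(0.5)
        flags, p, d = cl.classify_modulated(tens, (0.0, 0.5), (-1.0, -0.5))
        assert flags.all()
        assert (p < 0.05).all() and (d > 0.2).all()

    def test_small_elevation_blocked_by_magnitude_rule(self):
        # 0.1 zsc with many trials: significant p but below the 0.2 magnitude
        tens = self._tensor(0.1, n_trials=500)
        flags, p, d = cl.classify_modulated(tens, (0.0, 0.5), (-1.0, -0.5))
        assert (p < 0.05).any()
        assert not flags.any()

    def test_too_few_trials_rejected(self):
        tens = self._tensor(0.5, n_trials=1)
        with pytest.raises(ValueError):
            cl.classify_modulated(tens, (0.0, 0.5), (-1.0, -0.5))

    def test_labels_invariant_to_trial_order(self):
        tens = self._tensor(0.5)
        perm = np.random.default_rng(1).permutation(tens.n_trials)
        tens2 = cl.AlignedTensor(tens.values[:, :, perm], tens.time,
                                 tens.alignment, tens.trial_index[perm])
        f1, _, _ = cl.classify_modulated(tens, (0.0, 0.5), (-1.0, -0.5))
        f2, _, _ = cl.classify_modulated(tens2, (0.0, 0.5), (-1.0, -0.5))
        np.testing.assert_array_equal(f1, f2)


class TestAnticipatoryClassifier:
    def _tensor_from_profiles(self, profiles):
        time = np.arange(-45, 16) / FS
        vals = np.repeat(profiles(time)[:, :, None], 12, axis=2)
        return cl.AlignedTensor(vals, time, "reward", np.arange(12))

    def test_pre_reward_trapezoid_flagged(self):
        def profiles(t):
            ramp = np.clip(1.5 * (t + 1.0) / 1.0, 0, 1.5)
            ramp[t > 0.1] = 0.0
            return ramp[None, :]
        assert cl.classify_anticipatory_grcs(
            self._tensor_from_profiles(profiles)).all()

    def test_reward_consumption_transient_not_flagged(self):
        def profiles(t):
            return (2.0 * np.exp(-0.5 * ((t - 0.35) / 0.1) ** 2))[None, :]
        assert not cl.classify_anticipatory_grcs(
            self._tensor_from_profiles(profiles)).any()

    def test_insufficient_span_rejected(self):
        time = np.arange(-10, 5) / FS
        tens = cl.AlignedTensor(np.zeros((1, time.size, 3)), time, "reward",
                                np.arange(3))
        with pytest.raises(ValueError):
            cl.classify_anticipatory_grcs(tens)

    def test_recovery_on_synthetic_population(self, big_expert):
        session, report = big_expert
        truth = (session.grc_truth["class"] == "anticipatory").to_numpy()
        frac = report["classification"]["frac_anticipatory_grc"]
        # realized fraction within binomial error of configured 0.4
        assert abs(frac - truth.mean()) < 4 * np.sqrt(0.4 * 0.6 / truth.size)


class TestRewardCfClassifier:
    def test_recovery_on_synthetic_population(self, big_expert):
        session, report = big_expert
        truth = session.cf_truth["reward_responsive"].to_numpy()
        frac = report["classification"]["frac_reward_cf"]
        assert abs(frac - truth.mean()) < 0.15

    def test_tonic_cf_not_flagged(self):
        time = np.arange(-30, 16) / FS
        vals = np.zeros((1, time.size, 15))
        tens = cl.AlignedTensor(vals, time, "reward", np.arange(15))
        assert not cl.classify_reward_cfs(tens).any()


class TestTimingMetrics:
    def test_offtime_step_down(self):
        t = np.arange(-30, 31) / FS
        trace = np.where(t < 0.3, 1.0, 0.0)
        assert cl.anticipation_offtime(t, trace) == pytest.approx(0.3, abs=1 / FS)

    def test_offtime_flat_trace_undefined(self):
        t = np.arange(-30, 31) / FS
        assert np.isnan(cl.anticipation_offtime(t, np.zeros(t.size)))

    def test_offtime_later_on_omission_trials(self, small_expert):
        session, _ = small_expert
        ant = (session.grc_truth["class"] == "anticipatory").to_numpy()
        offs = {}
        for subset in ("rewarded", "omission"):
            tens = cl.align_to_trials(session.grc_clean[ant],
                                      session.frame_times, session.trials,
                                      "reward", (-1.0, 1.2), subset=subset)
            avg = tens.trial_average().mean(axis=0)
            offs[subset] = cl.anticipation_offtime(tens.time, avg)
        assert offs["omission"] > offs["rewarded"]

    def test_cf_onset_immediate_spike(self):
        t = np.arange(-15, 16) / FS
        rate = np.where((t >= 0.0) & (t <= 0.15), 5.0, 0.0)
        assert cl.cf_onset_time(t, rate) <= 0.05

    def test_cf_onset_no_spikes_undefined(self):
        t = np.arange(-15, 16) / FS
        assert np.isnan(cl.cf_onset_time(t, np.zeros(t.size)))

    def test_cf_onset_later_on_omission(self, small_expert):
        session, report = small_expert
        inter = report["_intermediates"]
        rates = inter["cf_rates"][inter["reward_cf"]]
        means = {}
        for subset in ("rewarded", "omission"):
            tens = cl.align_to_trials(rates, session.frame_times,
                                      inter["trials"], "reward", (-0.5, 1.0),
                                      subset=subset)
            means[subset] = tens.trial_average().mean(axis=0)
        on_rew = cl.cf_onset_time(tens.time, means["rewarded"])
        resp = means["rewarded"][(tens.time >= 0) & (tens.time <= 0.2)]
        thr = float(np.percentile(resp, 20.0))
        on_omi = cl.cf_onset_time(tens.time, means["omission"], threshold=thr)
        assert on_omi > on_rew

    def test_center_time_symmetric_bump(self):
        t = np.arange(-33, 1) / FS
        trace = np.exp(-0.5 * ((t + 0.5) / 0.1) ** 2)
        assert cl.anticipatory_center_time(t, trace, (-1.1, 0.0)) == \
            pytest.approx(-0.5, abs=0.02)

    def test_center_time_uniform_elevation(self):
        t = np.arange(-33, 1) / FS
        c = cl.anticipatory_center_time(t, np.ones(t.size), (-1.1, 0.0))
        assert c == pytest.approx(t[(t >= -1.1)].mean(), abs=0.02)

    def test_center_time_recovery(self, big_expert):
        """Estimated centers match ground truth within 0.1 s at noise
        sigma 1 and 100 trials."""
        session, report = big_expert
        inter = report["_intermediates"]
        truth = session.grc_truth
        ant = (truth["class"] == "anticipatory").to_numpy()
        err = np.abs(inter["centers"][ant] -
                     truth["center_time_s"].to_numpy()[ant])
        assert np.nanmedian(err) < 0.1

    def test_elevated_duration_trapezoid(self):
        t = np.arange(-30, 61) / FS
        trace = np.where((t >= 0.4) & (t <= 1.4), 1.0, 0.0)
        d = cl.elevated_duration(t, trace)
        assert d == pytest.approx(1.0, abs=0.1)

    def test_elevated_duration_flat_zero(self):
        t = np.arange(-30, 61) / FS
        assert cl.elevated_duration(t, np.zeros(t.size)) == 0.0

    def test_longer_delay_lengthens_elevated_durations(self):
        """2-s-expert populations sustain activity longer than 1-s experts."""
        durs = {}
        for delay in (1.0, 2.0):
            cfg = g.SynthConfig(n_grc=60, n_cf=4, n_trials=30, delay_s=delay,
                                frac_anticipatory=0.5, seed=14,
                                noise_sigma=0.0, bleach_amps=(0.0, 0.0),
                                drift_amp_frac=0.0, baseline_f=0.0, gain=1.0,
                                grc_background_hz=0.0)
            s = g.simulate_session(cfg)
            ant = (s.grc_truth["class"] == "anticipatory").to_numpy()
            tens = cl.align_to_trials(s.grc_clean[ant], s.frame_times,
                                      s.trials, "movement", (-1.0, 2.0),
                                      subset="rewarded")
            avg = tens.trial_average()
            durs[delay] = np.median([
                cl.elevated_duration(tens.time, avg[i])
                for i in range(avg.shape[0])])
        assert durs[2.0] > durs[1.0]
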