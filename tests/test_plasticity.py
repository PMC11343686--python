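"""Plasticity rules: logistic magnitudes, weight normalization, controls,
and exact agreement with an independent brute-force implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

import grcbasis as g
from grcbasis import classification as cl
from grcbasis import plasticity as pl
from _oracles import brute_force_ltp_weights, brute_force_session_weights

FS = 30.0


def _toy_session(n_grc=8, n_cf=3, n_trials=30, seed=0):
    """Handcrafted GrC traces + CF reward spikes on a regular trial grid."""
    rng = np.random.default_rng(seed)
    trial_period = 4.0
    dur = n_trials * trial_period + 4.0
    ft = np.arange(int(dur * FS)) / FS
    rewards = 2.0 + trial_period * np.arange(n_trials)
    grc = rng.normal(0, 1.0, (n_grc, ft.size))
    # structured pre-reward activity with cell-specific levels
    for i in range(n_grc):
        level = 0.5 + 0.4 * i
        for r in rewards:
            m = (ft >= r - 0.6) & (ft <= r)
            grc[i, m] += level * (ft[m] - (r - 0.6)) / 0.6
    spikes = []
    for j in range(n_cf):
        s = rewards + rng.uniform(0.02, 0.2, n_trials)
        spikes.append(np.sort(s[rng.random(n_trials) < 0.8]))
    trials = pd.DataFrame({
        "start_s": rewards - 1.5, "mid_s": rewards - 1.3,
        "end_s": rewards - 1.1, "reward_s": rewards,
        "omitted": np.zeros(n_trials, bool), "valid": np.ones(n_trials, bool),
    })
    return grc, ft, spikes, trials, rewards


class TestEventMagnitude:
    def test_logistic_midpoint_at_zero(self):
        assert pl.plasticity_event_magnitude(0.0, 2.0) == pytest.approx(0.5)

    def test_logistic_at_scale(self):
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert pl.plasticity_event_magnitude(2.0, 2.0) == pytest.approx(expected)

    def test_monotone_in_activity(self):
        f = np.linspace(-3, 5, 100)
        m = pl.plasticity_event_magnitude(f, 1.5)
        assert np.all(np.diff(m) >= 0)

    def test_rectification_floors_at_half(self):
        assert pl.plasticity_event_magnitude(-2.0, 1.0, rectify=True) == 0.5
        assert pl.plasticity_event_magnitude(-2.0, 1.0, rectify=False) < 0.5


class TestRewardSpikeEvents:
    def test_kept_and_dropped(self):
        trains = [np.array([5.1, 5.3, 9.0])]
        out = pl.reward_spike_events(trains, np.array([5.0]))
        np.testing.assert_allclose(out[0], [5.1])

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(3)
        rewards = np.sort(rng.uniform(0, 100, 20))
        train = np.sort(rng.uniform(0, 100, 300))
        out = pl.reward_spike_events([train], rewards)[0]
        brute = [t for t in train
                 if any(0.0 <= t - r <= 0.25 for r in rewards)]
        np.testing.assert_allclose(out, brute)


class TestSelectIncludedCfs:
    def test_reward_spiking_included_pre_spiking_excluded(self):
        time = np.arange(-15, 16) / FS
        vals = np.zeros((2, time.size, 10))
        vals[0, (time >= 0) & (time <= 0.2), :] = 5.0   # post-reward spiker
        vals[1, (time >= -0.25) & (time <= -0.05), :] = 5.0  # pre-reward only
        tens = cl.AlignedTensor(vals, time, "reward", np.arange(10))
        inc = pl.select_included_cfs(tens)
        assert inc[0] and not inc[1]

    def test_recovery_on_synthetic_session(self, big_expert):
        session, report = big_expert
        inter = report["_intermediates"]
        truth = session.cf_truth["reward_responsive"].to_numpy()
        sens = inter["included_cf"][truth].mean()
        assert sens >= 0.95


class TestSessionWeights:
    def test_matches_brute_force(self):
        grc, ft, spikes, trials, _ = _toy_session()
        ws = pl.compute_session_weights(grc, ft, spikes)
        unit, session = brute_force_session_weights(grc, ft, spikes)
        np.testing.assert_allclose(ws.per_pkc, unit, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(ws.session_vector, session,
                                   rtol=1e-10, atol=1e-12)

    def test_identical_grcs_give_zero_vector(self):
        grc, ft, spikes, trials, _ = _toy_session(n_grc=1)
        grc = np.repeat(grc, 5, axis=0)
        ws = pl.compute_session_weights(grc, ft, spikes)
        np.testing.assert_allclose(ws.session_vector, 0.0, atol=1e-12)

    def test_no_teaching_signal_raises(self):
        grc, ft, _, _, _ = _toy_session(n_cf=1)
        with pytest.raises(ValueError, match="no teaching signal"):
            pl.compute_session_weights(grc, ft, [np.empty(0)])

    def test_permutation_equivariance(self):
        grc, ft, spikes, trials, _ = _toy_session()
        ws = pl.compute_session_weights(grc, ft, spikes)
        perm = np.random.default_rng(5).permutation(grc.shape[0])
        ws_p = pl.compute_session_weights(grc[perm], ft, spikes)
        np.testing.assert_allclose(ws_p.session_vector,
                                   ws.session_vector[perm], rtol=1e-10)

    def test_monotonicity_in_eligibility_activity(self):
        """Raising one GrC's pre-reward activity never decreases its
        pre-negation LTD magnitude."""
        grc, ft, spikes, trials, rewards = _toy_session()
        ws0 = pl.compute_session_weights(grc, ft, spikes)
        boosted = grc.copy()
        for r in rewards:
            m = (ft >= r - 0.2) & (ft <= r)
            boosted[2, m] += 1.0
        ws1 = pl.compute_session_weights(boosted, ft, spikes)
        assert ws1.raw_ltd[2] >= ws0.raw_ltd[2]


class TestNormalizationInvariants:
    def test_all_provenances(self, small_expert):
        _, report = small_expert
        for name, ws in report["_intermediates"]["weights"].items():
            np.testing.assert_allclose(ws.per_pkc.sum(axis=1), 1.0,
                                       atol=1e-9, err_msg=name)
            centered = ws.per_pkc - ws.per_pkc.mean(axis=1, keepdims=True)
            np.testing.assert_allclose(centered.sum(axis=1), 0.0,
                                       atol=1e-9, err_msg=name)
            assert abs(ws.session_vector.mean()) < 1e-9, name


class TestLtpAdjusted:
    def test_matches_brute_force_toy(self):
        grc, ft, spikes, trials, rewards = _toy_session(n_grc=3, n_cf=2,
                                                        n_trials=20)
        rng = np.random.default_rng(9)
        # strictly distinct rates: unambiguous bottom-percentile selection
        rates = rng.uniform(0.1, 5.0, (2, ft.size))
        params = pl.PlasticityParams(ltp_rate_percentile=0.5)
        ws = pl.compute_ltp_adjusted_weights(grc, ft, spikes, rates, trials,
                                             params)
        spans = [(row["start_s"], row["reward_s"] + 1.0)
                 for _, row in trials.iterrows()]
        unit, session = brute_force_ltp_weights(grc, ft, spikes, rates, spans,
                                                ltp_pct=0.5)
        np.testing.assert_allclose(ws.session_vector, session,
                                   rtol=1e-9, atol=1e-12)

    def test_no_ltp_timepoints_reduces_to_pure_ltd(self):
        grc, ft, spikes, trials, _ = _toy_session(n_grc=4, n_cf=2,
                                                  n_trials=10)
        rates = np.ones((2, ft.size))
        # percentile small enough that the selected count rounds to zero
        params = pl.PlasticityParams(ltp_rate_percentile=0.01)
        ws = pl.compute_ltp_adjusted_weights(grc, ft, spikes, rates, trials,
                                             params)
        pure = pl.compute_session_weights(grc, ft, spikes, params)
        np.testing.assert_allclose(ws.session_vector, pure.session_vector,
                                   rtol=1e-9, atol=1e-12)


class TestControls:
    def test_reordered_preserves_weight_multiset(self):
        grc, ft, spikes, trials, _ = _toy_session()
        true = pl.compute_session_weights(grc, ft, spikes)
        re = pl.control_weights(grc, ft, spikes, trials, "reordered", seed=3,
                                true_weights=true)
        np.testing.assert_allclose(np.sort(re.session_vector),
                                   np.sort(true.session_vector))
        assert not np.allclose(re.session_vector, true.session_vector)

    def test_time_shuffle_preserves_per_trial_distributions(self):
        grc, ft, spikes, trials, _ = _toy_session(n_grc=3, n_trials=5)
        rng_check = np.random.default_rng(0)
        shuffled = grc.copy()
        for sl in pl._trial_frame_slices(ft, trials):
            for i in range(3):
                shuffled[i, sl] = shuffled[i, sl][
                    rng_check.permutation(sl.stop - sl.start)]
        for sl in pl._trial_frame_slices(ft, trials):
            np.testing.assert_allclose(np.sort(shuffled[0, sl]),
                                       np.sort(grc[0, sl]))

    def test_uniform_control_vectors(self):
        grc, ft, spikes, trials, _ = _toy_session()
        uni = pl.control_weights(grc, ft, spikes, trials, "uniform", seed=0)
        np.testing.assert_allclose(uni.session_vector, 0.0)
        np.testing.assert_allclose(uni.readout_vector, 1.0 / grc.shape[0])

    def test_unknown_mode_rejected(self):
        grc, ft, spikes, trials, _ = _toy_session()
        with pytest.raises(ValueError):
            pl.control_weights(grc, ft, spikes, trials, "bogus", seed=0)


def test_params_validation():
    with pytest.raises(ValueError):
        pl.PlasticityParams(eligibility_window_s=(-0.025, -0.150))
    with pytest.raises(ValueError):
        pl.PlasticityParams(logistic_scale_percentile=101)
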