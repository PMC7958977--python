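"""Generator tests: Markov chain law, EEG emission, cohort design."""

import numpy as np
import pytest

from alphastates import (
    CohortSpec,
    EmissionParams,
    MarkovParams,
    alpha_power,
    fractional_occupancy,
    power_pipeline,
    segment_epochs,
    simulate_cohort,
    simulate_state_sequence,
    symbolize,
    synthesize_eeg,
)


class TestMarkovParams:
    @pytest.mark.parametrize("p_lh,p_hl", [(-0.1, 0.5), (0.5, 1.2), (2.0, 2.0)])
    def test_invalid_probabilities_rejected(self, p_lh, p_hl):
        with pytest.raises(ValueError):
            MarkovParams(p_lh, p_hl)

    def test_stationary_draw_needs_nondegenerate_chain(self):
        with pytest.raises(ValueError):
            MarkovParams(0.0, 0.0, initial_state="stationary")


class TestSimulateStateSequence:
    def test_absorbing_low_state_stays_low(self):
        seq = simulate_state_sequence(MarkovParams(0.0, 0.5, "low"), 100, seed=0)
        assert (seq == 0).all()

    def test_forced_alternation(self):
        seq = simulate_state_sequence(MarkovParams(1.0, 1.0, "low"), 4, seed=0)
        assert seq.tolist() == [0, 1, 0, 1]

    def test_reproducible_given_seed(self, healthy_s1_params):
        a = simulate_state_sequence(healthy_s1_params, 500, seed=7)
        b = simulate_state_sequence(healthy_s1_params, 500, seed=7)
        assert (a == b).all()
        assert set(np.unique(a)) <= {0, 1}

    def test_occupancy_converges_to_stationary_value(self, healthy_s1_params):
        # pi_high = 0.53 / (0.53 + 0.25) = 0.679...
        seq = simulate_state_sequence(healthy_s1_params, 1_000_000, seed=11)
        assert fractional_occupancy(seq) == pytest.approx(0.68, abs=0.01)

    def test_empirical_transition_frequencies_converge(self):
        """|p_hat - p| <= 3*sqrt(p(1-p)/n_from) in >= 95% of seeded runs."""
        p_lh, p_hl = 0.4, 0.3
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            seq = simulate_state_sequence(MarkovParams(p_lh, p_hl), 4000, seed=seed)
            pairs_from_low = np.sum(seq[:-1] == 0)
            pairs_from_high = np.sum(seq[:-1] == 1)
            lh = np.sum((seq[:-1] == 0) & (seq[1:] == 1)) / pairs_from_low
            hl = np.sum((seq[:-1] == 1) & (seq[1:] == 0)) / pairs_from_high
            ok_lh = abs(lh - p_lh) <= 3 * np.sqrt(p_lh * (1 - p_lh) / pairs_from_low)
            ok_hl = abs(hl - p_hl) <= 3 * np.sqrt(p_hl * (1 - p_hl) / pairs_from_high)
            hits += ok_lh and ok_hl
        assert hits / n_runs >= 0.95

    def test_requires_at_least_one_epoch(self, healthy_s1_params):
        with pytest.raises(ValueError):
            simulate_state_sequence(healthy_s1_params, 0, seed=0)


class TestSynthesizeEEG:
    def test_sample_count_and_determinism(self, quiet_emission):
        states = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        a = synthesize_eeg(states, quiet_emission, seed=3)
        b = synthesize_eeg(states, quiet_emission, seed=3)
        assert a.n_samples == states.size * quiet_emission.sampling_rate
        assert a.channel_labels == ["AF3", "AF4"]
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_noiseless_power_ratio_is_amplitude_ratio_squared(self):
        em = EmissionParams(amp_high=20, amp_low=5, pink_noise_sd=0, white_noise_sd=0,
                            sampling_rate=1000)
        states = np.array([0, 1] * 10)
        raw = synthesize_eeg(states, em, seed=0)
        epochs = segment_epochs(raw)
        power = alpha_power(epochs, raw.sampling_rate).values
        ratio = power[states == 1].mean() / power[states == 0].mean()
        assert ratio == pytest.approx(16.0, rel=1e-6)  # (20/5)^2, sinusoid power a^2/2

    def test_equal_amplitudes_give_indistinguishable_states(self):
        em = EmissionParams(amp_high=10, amp_low=10, pink_noise_sd=0, white_noise_sd=0,
                            sampling_rate=500)
        states = np.array([0, 1, 0, 1, 1])
        raw = synthesize_eeg(states, em, seed=0)
        power = alpha_power(segment_epochs(raw), raw.sampling_rate).values
        assert np.ptp(power) / power.mean() < 1e-6

    def test_full_pipeline_recovers_generator_states(self, healthy_s1_params, quiet_emission):
        """Downsample -> epoch -> band power -> midpoint threshold matches ground truth >= 99%."""
        states = simulate_state_sequence(healthy_s1_params, 300, seed=21)
        raw = synthesize_eeg(states, quiet_emission, seed=22)
        ps = power_pipeline(raw)
        midpoint = (quiet_emission.amp_high**2 + quiet_emission.amp_low**2) / 2 / 2 / 6
        recovered = symbolize(ps, midpoint)
        assert np.mean(recovered == states) >= 0.99

    def test_rejects_invalid_emission(self):
        with pytest.raises(ValueError):
            EmissionParams(amp_high=5, amp_low=10)
        with pytest.raises(ValueError):
            EmissionParams(alpha_freq=10, sampling_rate=15)
        with pytest.raises(ValueError):
            synthesize_eeg(np.array([]), seed=0)
        with pytest.raises(ValueError):
            synthesize_eeg(np.array([0, 2, 1]), seed=0)


class TestSimulateCohort:
    def _small_spec(self, **kw):
        defaults = dict(n_per_group=2, n_sessions=3, resting_epochs=20, nfb_epochs=60, seed=9)
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_record_count(self):
        cohort = simulate_cohort(CohortSpec(n_per_group=4, n_sessions=5,
                                            resting_epochs=8, nfb_epochs=8, seed=0))
        assert len(cohort) == 4 * 5 * 2  # participants x sessions x groups

    def test_vas_within_scale_and_block_size(self):
        cohort = simulate_cohort(self._small_spec(vas_noise_sd=4.0))
        for rec in cohort.records:
            for block in (rec.vas_pre, rec.vas_post):
                assert block.size == 6
                assert (block >= 0).all() and (block <= 10).all()

    def test_zero_slope_gives_no_planted_dependence(self):
        """With effect_slope=0 the occupancy/pain-change correlation has no planted sign."""
        rs = []
        for seed in range(30):
            cohort = simulate_cohort(self._small_spec(effect_slope=0.0, seed=seed))
            gt = cohort.ground_truth_frame()
            base = gt[gt.session == 1].set_index("participant")["vas_pre_mean"]
            change = gt["vas_post_mean"].to_numpy() - base.loc[gt["participant"]].to_numpy()
            rs.append(np.corrcoef(gt["true_nfb_occupancy"], change)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_planted_negative_effect_recovers_sign(self):
        """Pearson r between occupancy and pain change is negative across seeded replicates."""
        neg = 0
        for seed in range(20):
            cohort = simulate_cohort(self._small_spec(effect_slope=5.0, vas_noise_sd=0.3,
                                                      seed=seed))
            gt = cohort.ground_truth_frame()
            base = gt[gt.session == 1].set_index("participant")["vas_pre_mean"]
            change = gt["vas_post_mean"].to_numpy() - base.loc[gt["participant"]].to_numpy()
            neg += np.corrcoef(gt["true_nfb_occupancy"], change)[0, 1] < 0
        assert neg == 20

    def test_session_drift_is_clipped_to_unit_interval(self):
        spec = self._small_spec(n_sessions=5, drift_patient=(0.3, -0.3))
        for s in range(1, 6):
            p = spec.session_params("patient", s)
            assert 0.0 <= p.p_low_to_high <= 1.0
            assert 0.0 <= p.p_high_to_low <= 1.0
        assert spec.session_params("patient", 5).p_low_to_high == 1.0

    def test_determinism(self):
        a = simulate_cohort(self._small_spec())
        b = simulate_cohort(self._small_spec())
        np.testing.assert_array_equal(a.records[5].nfb_states, b.records[5].nfb_states)
        np.testing.assert_array_equal(a.records[5].vas_post, b.records[5].vas_post)
        np.testing.assert_array_equal(a.records[3].nfb_eeg().samples,
                                      b.records[3].nfb_eeg().samples)
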