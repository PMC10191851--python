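"""Channel screening, trial selection, epoching, HGp and ERSP extraction."""

import numpy as np
import pytest
from scipy import stats as sstats

from gliocircuit.ecog import (
    EpochSet,
    compute_ersp,
    compute_hgp,
    epoch_speech_locked,
    label_electrodes,
    make_trial_table,
    reject_noisy_channels,
    select_trials,
)

from conftest import make_recording, sinusoid_epochs


class TestLabelElectrodes:
    @pytest.mark.parametrize(
        "distance, expected",
        [(8.0, "tumour"), (12.0, "non_tumour"), (10.0, "tumour")],
    )
    def test_distance_rule_inclusive_at_radius(self, distance, expected):
        core = np.array([[0.0, 0.0, 0.0]])
        labels, dmin = label_electrodes(np.array([[distance, 0, 0]]), core)
        assert labels == [expected]
        assert dmin[0] == pytest.approx(distance)

    def test_minimum_distance_over_core_points(self):
        core = np.array([[0, 0, 0], [30, 0, 0]])
        labels, dmin = label_electrodes(np.array([[25.0, 0, 0]]), core)
        assert labels == ["tumour"] and dmin[0] == pytest.approx(5.0)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            label_electrodes(np.zeros((1, 3)), np.zeros((0, 3)))


class TestChannelScreen:
    def test_gaussian_retained_laplace_removed(self, rng):
        n = 100_000
        gauss = rng.standard_normal(n)
        laplace = rng.laplace(size=n)  # population kurtosis 6
        rec = make_recording(np.stack([gauss, laplace]))
        screened, report = reject_noisy_channels(rec)
        assert screened.channel_ids == ["ch0"]
        # oracle: direct moment computation matches the logged values
        for i, x in enumerate((gauss, laplace)):
            k = np.mean((x - x.mean()) ** 4) / np.var(x) ** 2
            assert report["kurtosis"].iloc[i] == pytest.approx(k)
        assert report["status"].tolist() == ["retained", "kurtosis"]

    def test_constant_channel_degenerate(self, rng):
        rec = make_recording(np.stack([rng.standard_normal(1000), np.ones(1000)]))
        screened, report = reject_noisy_channels(rec)
        assert report["status"].tolist() == ["retained", "degenerate"]

    def test_all_rejected_raises(self, rng):
        rec = make_recording(np.ones((2, 1000)))
        with pytest.raises(ValueError, match="all channels rejected"):
            reject_noisy_channels(rec)


class TestSelectTrials:
    def test_hand_trace_of_both_rules(self):
        trials = make_trial_table(
            onset_s=[1, 2, 3, 4, 5],
            condition=["low_freq_word"] * 5,
            correct=[True, True, False, True, True],
            latency_s=[0.8, 2.5, 1.0, 2.0, 1.1],
        )
        kept, counts = select_trials(trials)
        assert kept["onset_s"].tolist() == [1, 4, 5]
        assert counts == {"kept": 3, "incorrect": 1, "slow_response": 1}

    def test_latency_exactly_two_seconds_kept(self):
        trials = make_trial_table([1.0], ["other"], [True], [2.0])
        kept, _ = select_trials(trials)
        assert len(kept) == 1

    def test_all_good_all_kept(self):
        trials = make_trial_table([1, 2], ["other"] * 2, [True] * 2, [0.5, 1.0])
        kept, _ = select_trials(trials)
        assert len(kept) == 2


class TestEpoching:
    def test_window_arithmetic_and_impulse_position(self):
        fs = 1200.0
        sig = np.zeros((1, int(10 * fs)))
        onset = 5.0
        sig[0, int(onset * fs)] = 1.0
        rec = make_recording(sig, fs=fs)
        trials = make_trial_table([onset], ["other"], [True], [1.0])
        epochs = epoch_speech_locked(rec, trials)
        assert epochs.data.shape[2] == 4800
        assert epochs.onset_index == 2400
        assert epochs.data[0, 0, 2400] == 1.0
        assert epochs.data[0, 0].sum() == 1.0

    def test_edge_trial_dropped(self):
        fs = 100.0
        rec = make_recording(np.zeros((1, int(10 * fs))), fs=fs)
        trials = make_trial_table([1.0, 5.0], ["other"] * 2, [True] * 2, [1, 1])
        epochs = epoch_speech_locked(rec, trials)
        assert len(epochs.trials) == 1
        assert epochs.trials["onset_s"].iloc[0] == 5.0

    def test_no_surviving_trials_is_an_error(self):
        rec = make_recording(np.zeros((1, 300)), fs=100.0)
        trials = make_trial_table([1.0], ["other"], [True], [1.0])
        with pytest.raises(ValueError, match="no trials"):
            epoch_speech_locked(rec, trials)


class TestHgp:
    def test_in_band_unit_sinusoid_unit_power(self):
        hgp = compute_hgp(sinusoid_epochs(90.0))
        t = hgp.window_s[0] + np.arange(hgp.values.shape[2]) / hgp.fs
        steady = (t > -1.75) & (t < 1.75)  # exclude 0.25 s edges
        assert np.abs(hgp.values[0, 0, steady] - 1.0).max() < 0.02

    def test_out_of_band_rejected(self):
        in_band = compute_hgp(sinusoid_epochs(90.0))
        out_band = compute_hgp(sinusoid_epochs(20.0))
        assert out_band.values.mean() < 0.01 * in_band.values.mean()

    def test_zero_input_zero_power_and_nonnegativity(self, rng):
        fs = 1200.0
        zeros = EpochSet(data=np.zeros((1, 2, int(4 * fs))), fs=fs)
        assert compute_hgp(zeros).values.max() == 0.0
        noise = EpochSet(data=rng.standard_normal((2, 3, int(4 * fs))), fs=fs)
        assert (compute_hgp(noise).values >= 0).all()

    def test_band_edge_at_nyquist_rejected(self):
        fs = 200.0
        ep = EpochSet(data=np.zeros((1, 2, int(4 * fs))), fs=fs)
        with pytest.raises(ValueError, match="Nyquist"):
            compute_hgp(ep, band=(70.0, 110.0))

    def test_shift_covariance_of_filter_chain(self):
        # zero-phase chain: delaying the impulse delays the envelope
        fs = 1200.0
        n = int(4 * fs)
        d = 180
        base = np.zeros((1, 2, n))
        base[0, :, 1000] = [1.0, -1.0]
        shifted = np.zeros((1, 2, n))
        shifted[0, :, 1000 + d] = [1.0, -1.0]
        h1 = compute_hgp(EpochSet(data=base, fs=fs)).values[0, 0]
        h2 = compute_hgp(EpochSet(data=shifted, fs=fs)).values[0, 0]
        assert np.argmax(h1) + d == np.argmax(h2)
        np.testing.assert_allclose(h1[500:3000], h2[500 + d : 3000 + d], atol=1e-12)


class TestErsp:
    def _recording_with_burst(self, rng, burst_freq=120.0, burst_window=(0.0, 0.3)):
        fs = 1200.0
        dur = 20.0
        sig = 0.1 * rng.standard_normal((2, int(dur * fs)))
        onset = 10.0
        i0 = int((onset + burst_window[0]) * fs)
        i1 = int((onset + burst_window[1]) * fs)
        tt = np.arange(i1 - i0) / fs
        sig[0, i0:i1] += 2 * np.sin(2 * np.pi * burst_freq * tt)
        rec = make_recording(sig, fs=fs)
        trials = make_trial_table([onset], ["low_freq_word"], [True], [1.0])
        return rec, trials

    def test_per_trial_normalization_exact_and_rate(self, rng):
        rec, trials = self._recording_with_burst(rng)
        epochs, degenerate = compute_ersp(rec, trials)
        assert epochs.fs == 100.0
        assert epochs.data.shape[2] == 400
        assert not degenerate.any()
        for c in range(2):
            assert abs(epochs.data[0, c].mean()) < 1e-9
            assert abs(epochs.data[0, c].std() - 1.0) < 1e-9

    def test_injected_burst_peaks_in_its_window(self, rng):
        rec, trials = self._recording_with_burst(rng)
        epochs, _ = compute_ersp(rec, trials)
        t_peak = epochs.times[np.argmax(epochs.data[0, 0])]
        assert 0.0 <= t_peak <= 0.3

    def test_zero_variance_trial_flagged(self):
        fs = 1200.0
        rec = make_recording(np.zeros((2, int(20 * fs))), fs=fs)
        trials = make_trial_table([10.0], ["other"], [True], [1.0])
        _, degenerate = compute_ersp(rec, trials)
        assert degenerate.all()


class TestTissueContrastEndToEnd:
    def test_tumour_channels_have_higher_hgp(self):
        # amplitude ratio 2 must push every tumour channel above the
        # non-tumour median in nearly all channel comparisons
        from gliocircuit.synthdata import EcogSimSpec, generate_ecog_dataset

        wins = total = 0
        for seed in range(3):
            spec = EcogSimSpec(
                n_participants=2,
                n_channels=8,
                n_trials_per_condition=5,
                tumour_amplitude_ratio=2.0,
                seed=seed,
            )
            recs, trials, _ = generate_ecog_dataset(spec)
            for rec, tt in zip(recs, trials):
                epochs = epoch_speech_locked(rec, tt)
                hgp = compute_hgp(epochs)
                means = hgp.channel_task_mean((0.0, 0.4))
                tum = means[[t == "tumour" for t in rec.tissue_label]]
                non = means[[t == "non_tumour" for t in rec.tissue_label]]
                wins += (tum[:, None] > non[None, :]).sum()
                total += tum.size * non.size
        assert wins / total >= 0.95
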