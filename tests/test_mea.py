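"""MEA spike, burst, network-burst detection and synchrony metrics."""

import numpy as np
import pandas as pd
import pytest

from gliocircuit.mea import (
    SpikeTrainSet,
    compute_auncc,
    detect_bursts,
    detect_network_bursts,
    detect_spikes,
    summarize_firing,
)
from gliocircuit.synthdata import RasterSimSpec, generate_spike_data


def brute_force_bursts(train, min_spikes=5, max_isi=0.1):
    """Exhaustive run-scan oracle for the ISI burst rule."""
    out = []
    i = 0
    t = list(train)
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] - t[j] <= max_isi:
            j += 1
        if j - i + 1 >= min_spikes:
            out.append((t[i], t[j], j - i + 1))
        i = j + 1
    return out


class TestBurstDetection:
    def test_six_spikes_all_short_isis_one_burst(self):
        bursts = detect_bursts(np.arange(6) * 0.05)
        assert len(bursts) == 1
        assert bursts.iloc[0].to_dict() == {"start_s": 0.0, "end_s": 0.25, "n_spikes": 6}

    def test_below_minimum_count_no_burst(self):
        assert len(detect_bursts(np.arange(4) * 0.05)) == 0

    def test_gap_splits_into_two_bursts(self):
        train = np.r_[np.arange(5) * 0.05, 0.5 + np.arange(5) * 0.05]
        bursts = detect_bursts(train)
        assert len(bursts) == 2
        assert (bursts["n_spikes"] == 5).all()

    def test_isi_exactly_at_threshold_joins_run(self):
        train = np.arange(5) * 0.1
        threshold = float(np.diff(train).max())  # inclusive boundary
        assert len(detect_bursts(train, max_isi_s=threshold)) == 1

    def test_matches_brute_force_oracle_on_random_trains(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = rng.integers(0, 40)
            train = np.sort(rng.uniform(0, 5.0, size=n))
            train = np.unique(train)
            got = detect_bursts(train)
            expected = brute_force_bursts(train)
            assert len(got) == len(expected)
            for row, exp in zip(got.itertuples(index=False), expected):
                assert (row.start_s, row.end_s, row.n_spikes) == exp


class TestNetworkBursts:
    @staticmethod
    def _well(n_burst_elec, total_spikes, n_active=16):
        trains = {}
        per = total_spikes // n_burst_elec
        for e in range(n_burst_elec):
            trains[e] = 10.0 + np.arange(per) * 0.01 + e * 1e-4
        for e in range(n_burst_elec, n_active):
            trains[e] = np.linspace(100, 1700, 160)  # active but not bursting
        return trains

    @pytest.mark.parametrize(
        "n_elec, total, expected",
        [(6, 60, 1), (5, 60, 0), (6, 40, 0)],
    )
    def test_threshold_hand_cases(self, n_elec, total, expected):
        trains = self._well(n_elec, total)
        nb = detect_network_bursts(trains, active_electrodes=list(range(16)))
        assert len(nb) == expected

    def test_no_active_electrodes_rejected(self):
        with pytest.raises(ValueError, match="active"):
            detect_network_bursts({}, active_electrodes=[])

    def test_scheduled_bursts_recovered_end_to_end(self):
        schedule = tuple((30.0 + 25.0 * i, 0.5, 80) for i in range(10))
        spec = RasterSimSpec(
            duration=300.0,
            background_rate=0.5,
            network_burst_schedule=schedule,
            seed=21,
        )
        sts, _, truth = generate_spike_data(spec)
        trains = sts.well_trains(0)
        summary = summarize_firing(trains, duration=300.0)
        active = [e for e, a in summary["active"].items() if a]
        nb = detect_network_bursts(trains, active_electrodes=active)
        assert len(nb) == 10


class TestSpikeDetection:
    def test_zero_trace_no_spikes(self):
        assert detect_spikes(np.zeros(12500)).size == 0

    def test_false_positive_rate_on_gaussian_noise(self):
        rng = np.random.default_rng(5)
        fp = detect_spikes(rng.standard_normal(int(60 * 12500)))
        assert len(fp) / 60.0 <= 0.05

    def test_injected_spikes_recovered(self):
        spec = RasterSimSpec(
            n_wells=1,
            n_electrodes_per_well=2,
            duration=60.0,
            background_rate=2.0,
            emit_voltage=True,
            spike_snr=10.0,
            seed=3,
        )
        sts, volt, _ = generate_spike_data(spec)
        detected = detect_spikes(volt[0][0])
        true_times = sts.spikes[(0, 0)]
        hits = sum(np.min(np.abs(detected - t)) <= 0.001 for t in true_times)
        assert hits / len(true_times) >= 0.99


class TestFiringSummary:
    def test_mfr_arithmetic(self):
        trains = {0: np.linspace(0, 1799.5, 3600)}
        s = summarize_firing(trains)
        assert s["mfr"][0] == pytest.approx(2.0)

    def test_active_rule_five_per_minute(self):
        t100 = np.linspace(0, 1799, 100)
        t200 = np.linspace(0, 1799, 200)
        s = summarize_firing({0: t100, 1: t200})
        assert s["active"] == {0: False, 1: True}

    def test_wmfr_mean_over_active(self):
        trains = {
            0: np.linspace(0, 1799.9, 3600),  # 2 Hz
            1: np.linspace(0, 1799.9, 7200),  # 4 Hz
            2: np.array([1.0]),  # silent-ish, inactive
        }
        s = summarize_firing(trains)
        assert s["wmfr"] == pytest.approx(3.0)
        lit = summarize_firing(trains, wmfr_mode="literal")
        assert lit["wmfr"] == pytest.approx((10801 / 1800.0) * 2)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            summarize_firing({0: np.array([1.0])}, duration=0.0)


class TestAuncc:
    def test_identical_trains_unit_zero_lag(self):
        rng = np.random.default_rng(7)
        base = np.sort(rng.uniform(0, 300, 300))
        trains = {e: base for e in range(3)}
        _, rho = compute_auncc(trains, 300.0)
        centre = rho.shape[1] // 2
        np.testing.assert_allclose(rho[:, centre], 1.0)

    def test_rho_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        trains = {e: np.sort(rng.uniform(0, 120, rng.integers(20, 200))) for e in range(5)}
        _, rho = compute_auncc(trains, 120.0)
        assert rho.min() >= 0.0 and rho.max() <= 1.0 + 1e-12

    def test_monotone_in_jitter(self):
        rng = np.random.default_rng(7)
        base = np.sort(rng.uniform(0, 600, 600))

        def jittered(sd):
            x = np.unique(np.sort(base + rng.normal(0, sd, base.size)))
            return x[(x >= 0) & (x < 600)]

        a_id, _ = compute_auncc({0: base, 1: base, 2: base}, 600.0)
        a_5, _ = compute_auncc({0: base, 1: jittered(0.005), 2: jittered(0.005)}, 600.0)
        a_20, _ = compute_auncc({0: base, 1: jittered(0.020), 2: jittered(0.020)}, 600.0)
        indep = {e: np.sort(rng.uniform(0, 600, 600)) for e in range(3)}
        a_ind, _ = compute_auncc(indep, 600.0)
        assert a_id > a_5 > a_20 > a_ind

    def test_independent_poisson_much_lower_than_identical(self):
        rng = np.random.default_rng(13)
        base = np.sort(rng.uniform(0, 600, 600))
        a_id, _ = compute_auncc({0: base, 1: base}, 600.0)
        indep = {e: np.sort(rng.uniform(0, 600, 600)) for e in range(2)}
        a_ind, _ = compute_auncc(indep, 600.0)
        assert a_ind <= 0.1 * a_id

    def test_fewer_than_two_electrodes_rejected(self):
        with pytest.raises(ValueError):
            compute_auncc({0: np.array([1.0])}, 10.0)


class TestSpikeTrainSet:
    def test_frame_roundtrip(self):
        spikes = {(0, 0): np.array([0.1, 0.5]), (0, 1): np.array([0.2]), (1, 0): np.array([])}
        sts = SpikeTrainSet(spikes=spikes, duration=10.0)
        df = sts.to_frame()
        back = SpikeTrainSet.from_frame(df, duration=10.0)
        for key, t in spikes.items():
            if t.size:
                np.testing.assert_array_equal(back.spikes[key], t)

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SpikeTrainSet(spikes={(0, 0): np.array([-1.0])}, duration=10.0)
        with pytest.raises(ValueError, match="increasing"):
            SpikeTrainSet(spikes={(0, 0): np.array([2.0, 1.0])}, duration=10.0)
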