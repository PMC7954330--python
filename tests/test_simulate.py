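"""Generator: determinism, renewal calibration, coupling, block model,
intracellular driving-force scaling."""

import numpy as np
import pytest

import fieldsync as fs
from fieldsync._util import derive_seed, truncated_normal_moments
from fieldsync.simulate import measure_current_peaks


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self, syn_spec):
        a, ta = fs.simulate_recording(syn_spec, 60.0, seed=1, sampling_rate=2000.0)
        b, tb = fs.simulate_recording(syn_spec, 60.0, seed=1, sampling_rate=2000.0)
        assert np.array_equal(a.ca3, b.ca3)
        assert np.array_equal(a.ca1, b.ca1)
        assert ta.events.df.equals(tb.events.df)
        assert ta.bursting == tb.bursting

    def test_different_seeds_differ(self, syn_spec):
        a, _ = fs.simulate_recording(syn_spec, 60.0, seed=1, sampling_rate=2000.0)
        b, _ = fs.simulate_recording(syn_spec, 60.0, seed=2, sampling_rate=2000.0)
        assert not np.array_equal(a.ca3, b.ca3)

    def test_population_reproducible_and_distinct(self, syn_spec):
        pop1 = fs.simulate_population(syn_spec, 3, 30.0, seed=7, sampling_rate=1000.0)
        pop2 = fs.simulate_population(syn_spec, 3, 30.0, seed=7, sampling_rate=1000.0)
        for (r1, _), (r2, _) in zip(pop1, pop2):
            assert np.array_equal(r1.ca3, r2.ca3)
        assert not np.array_equal(pop1[0][0].ca3, pop1[1][0].ca3)

    def test_invalid_arguments(self, syn_spec):
        with pytest.raises(ValueError):
            fs.simulate_recording(syn_spec, -5.0, seed=1)
        with pytest.raises(ValueError):
            fs.simulate_recording(syn_spec, 60.0, seed=None)
        with pytest.raises(ValueError):
            fs.simulate_population(syn_spec, 0, 60.0, seed=1)


class TestRenewalProcess:
    def test_event_count_matches_rate(self, syn_spec):
        """Renewal expectation: ~rate*duration events per slice, checked by
        Monte Carlo over 200 seeds (no bursts, no coupling complications)."""
        spec = syn_spec.replace(burst_probability=0.0, coupling_failure_prob=1.0,
                                popspike_rate_ca1=0.0, noise_sd=0.0)
        counts = []
        for i in range(200):
            _, truth = fs.simulate_recording(spec, 600.0, derive_seed(17, i),
                                             sampling_rate=200.0)
            counts.append(len(truth.events.channel("CA3")))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 23.6) < max(3 * se, 1.0)

    def test_ground_truth_calibration(self, syn_spec):
        """Drawn durations and burst statistics match the condition spec
        within 3 standard errors (n = 200 slices, reduced sampling rate)."""
        durs, bdurs, bfreqs = [], [], []
        bursting = 0
        for i in range(200):
            _, truth = fs.simulate_recording(syn_spec, 600.0, derive_seed(23, i),
                                             sampling_rate=500.0)
            g = truth.events.channel("CA3")
            d = g[g["kind"] == "discharge"]
            singles = d[d["burst_id"].isna()]
            durs += list(singles["offset_s"] - singles["onset_s"])
            if truth.bursting:
                bursting += 1
            for _, grp in d[d["burst_id"].notna()].groupby("burst_id"):
                dur = grp["offset_s"].max() - grp["onset_s"].min()
                bdurs.append(dur)
                bfreqs.append((len(grp) - 1) / dur)
        durs = np.asarray(durs)
        assert abs(durs.mean() - 1.07) < 3 * durs.std() / np.sqrt(len(durs))
        bdurs = np.asarray(bdurs)
        assert abs(bdurs.mean() - 35.61) < 3 * bdurs.std() / np.sqrt(len(bdurs))
        bfreqs = np.asarray(bfreqs)
        assert abs(bfreqs.mean() - 0.52) < 3 * bfreqs.std() / np.sqrt(len(bfreqs))
        p = bursting / 200
        assert abs(p - 0.48) < 3 * np.sqrt(0.48 * 0.52 / 200)

    def test_truncated_normal_calibration(self):
        """Calibrated truncated draws reproduce the target moments."""
        for mean, sd, lo in [(1.07, 0.34, 0.3), (4.09, 2.60, 0.0),
                             (35.61, 12.67, 10.0), (51.60, 22.71, 0.0)]:
            m, s = truncated_normal_moments(mean, sd, lo)
            assert m == pytest.approx(mean, abs=1e-6)
            assert s == pytest.approx(sd, abs=1e-4)


class TestCoupling:
    @pytest.mark.parametrize("failure", [0.0, 0.5, 1.0])
    def test_ca1_fraction_tracks_failure_prob(self, syn_spec, failure):
        spec = syn_spec.replace(coupling_failure_prob=failure,
                                burst_probability=0.0, popspike_rate_ca1=0.0)
        n3 = n1 = 0
        for i in range(50):
            _, truth = fs.simulate_recording(spec, 600.0, derive_seed(29, i),
                                             sampling_rate=200.0)
            n3 += len(truth.events.channel("CA3"))
            n1 += len(truth.events.channel("CA1"))
        ratio = n1 / max(n3, 1)
        assert ratio == pytest.approx(1.0 - failure, abs=0.05)

    def test_ca1_events_delayed(self, syn_spec):
        spec = syn_spec.replace(coupling_failure_prob=0.0,
                                coupling_jitter_sd=0.0, burst_probability=0.0,
                                popspike_rate_ca1=0.0)
        _, truth = fs.simulate_recording(spec, 600.0, seed=4, sampling_rate=500.0)
        on3 = truth.events.channel("CA3")["onset_s"].to_numpy()
        on1 = truth.events.channel("CA1")["onset_s"].to_numpy()
        assert len(on3) == len(on1)
        assert np.allclose(on1 - on3, spec.coupling_delay)


class TestBlockModel:
    def test_block_fractions_and_delay(self):
        spec = fs.make_condition("cd2_15um")
        onsets = []
        for i in range(200):
            _, truth = fs.simulate_recording(spec, 600.0, derive_seed(31, i),
                                             sampling_rate=200.0)
            onsets.append(truth.block_onset)
        onsets = np.asarray(onsets, float)
        assert np.all(np.isfinite(onsets))
        frac_immediate = (onsets == 0).mean()
        assert abs(frac_immediate - 0.455) < 3 * np.sqrt(0.455 * 0.545 / 200)
        delays_min = onsets[onsets > 0] / 60.0
        se = delays_min.std() / np.sqrt(len(delays_min))
        assert abs(delays_min.mean() - 4.09) < 3 * se

    def test_no_events_after_block(self):
        spec = fs.make_condition("cd2_15um").replace(popspike_rate_ca3=0.0,
                                                     popspike_rate_ca1=0.0)
        for i in range(10):
            _, truth = fs.simulate_recording(spec, 600.0, derive_seed(37, i),
                                             sampling_rate=200.0)
            if len(truth.events):
                assert truth.events.df["onset_s"].max() < truth.block_onset

    def test_mec_preset_abolishes_discharges(self):
        spec = fs.make_condition("mec_50um")
        _, truth = fs.simulate_recording(spec, 300.0, seed=2, sampling_rate=500.0)
        assert truth.block_onset == 0.0
        assert (truth.events.df["kind"] != "discharge").all()


class TestIntracellular:
    def test_zero_driving_force_gives_zero(self, short_recording, syn_spec):
        rec, truth = short_recording
        it = fs.simulate_intracellular(syn_spec, rec, truth, 0.0, seed=1,
                                       noise_sd=0.0)
        assert np.allclose(it.current, 0.0)
        assert np.allclose(it.peak_amplitudes, 0.0)

    def test_driving_force_linearity(self, short_recording, syn_spec):
        rec, truth = short_recording
        it70 = fs.simulate_intracellular(syn_spec, rec, truth, -70.0, seed=1,
                                         noise_sd=0.0)
        it35 = fs.simulate_intracellular(syn_spec, rec, truth, -35.0, seed=1,
                                         noise_sd=0.0)
        assert np.allclose(2.0 * it35.peak_amplitudes, it70.peak_amplitudes)
        assert np.allclose(2.0 * it35.current, it70.current)

    def test_transient_per_ca1_event_and_sign(self, short_recording, syn_spec):
        rec, truth = short_recording
        it = fs.simulate_intracellular(syn_spec, rec, truth, -70.0, seed=1,
                                       noise_sd=0.0)
        n_ca1 = (truth.events.channel("CA1")["kind"] == "discharge").sum()
        assert len(it.peak_amplitudes) == n_ca1
        assert np.all(it.peak_amplitudes < 0)  # inward current at -70 mV

    def test_peak_amplitude_distribution(self, syn_spec):
        peaks = []
        i = 0
        while len(peaks) < 200:
            rec, truth = fs.simulate_recording(syn_spec, 600.0, derive_seed(41, i),
                                               sampling_rate=1000.0)
            it = fs.simulate_intracellular(syn_spec, rec, truth, -70.0,
                                           seed=derive_seed(41, i, 1))
            peaks += list(np.abs(measure_current_peaks(it)))
            i += 1
        peaks = np.asarray(peaks)
        se = peaks.std() / np.sqrt(len(peaks))
        assert abs(peaks.mean() - 51.60) < 3 * se


class TestGroundTruthIntegrity:
    def test_tables_sorted_nonoverlapping(self, full_recording):
        _, truth = full_recording
        df = truth.events.df
        for ch, sub in df.groupby("channel"):
            on = sub["onset_s"].to_numpy()
            off = sub["offset_s"].to_numpy()
            assert np.all(np.diff(on) > 0)
            assert np.all(off[:-1] <= on[1:] + 1e-9)
            assert np.all(off > on)

    def test_slice_effects_shared(self, syn_spec):
        eff = {"bursting": True, "amplitude_factor": 1.3}
        _, t1 = fs.simulate_recording(syn_spec, 200.0, seed=9,
                                      sampling_rate=500.0, slice_effects=eff)
        assert t1.bursting
        _, t2 = fs.simulate_recording(syn_spec, 200.0, seed=9,
                                      sampling_rate=500.0,
                                      slice_effects={"bursting": False})
        assert not t2.bursting
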