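"""Event detection: recovery against ground truth, burst grouping,
summaries, and detector invariances."""

import numpy as np
import pandas as pd
import pytest

import fieldsync as fs
from fieldsync._util import derive_seed
from fieldsync.detect import DetectionParams, EventTable
from fieldsync.templates import discharge_waveform

from conftest import match_events


def _render(events, duration, fs_hz, noise_sd=0.002, seed=0, floor_mv=None):
    """Trace with discharge templates at given (onset, duration, amplitude)."""
    n = int(duration * fs_hz)
    x = np.zeros(n)
    for t0, d, a in events:
        off_s, w = (discharge_waveform(d, a, fs_hz) if floor_mv is None else
                    discharge_waveform(d, a, fs_hz, floor_mv=floor_mv))
        i0 = int(round((t0 + off_s) * fs_hz))
        j0, j1 = max(i0, 0), min(i0 + len(w), n)
        x[j0:j1] -= w[j0 - i0: j1 - i0]
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return x


class TestDetectEvents:
    def test_flat_noise_trace_empty(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 60_000)
        table = fs.detect_events(x, 1000.0, channel="CA3")
        assert len(table) == 0

    def test_constant_trace_empty_not_error(self):
        table = fs.detect_events(np.zeros(60_000), 1000.0)
        assert len(table) == 0

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="10 s"):
            fs.detect_events(np.zeros(1000), 1000.0)

    def test_noiseless_templates_recovered_exactly(self):
        """Three embedded templates: perfect recall/precision, onsets within
        two analysis samples, durations within one sample."""
        fs_hz = 1000.0
        events = [(20.0, 1.0, 2.5), (40.0, 0.8, 1.8), (60.0, 1.4, 3.0)]
        noise = 0.002
        x = _render(events, 80.0, fs_hz, noise_sd=noise, floor_mv=0.67 * noise)
        table = fs.detect_events(x, fs_hz, channel="CA3")
        disc = table.df[table.df["kind"] == "discharge"]
        assert len(disc) == 3
        for (t0, d, _), (_, row) in zip(events, disc.iterrows()):
            assert row["onset_s"] == pytest.approx(t0, abs=2e-3)
            assert (row["offset_s"] - row["onset_s"]) == pytest.approx(d, abs=5e-3)

    def test_default_snr_f1(self, syn_spec):
        """Detected-vs-truth F1 at default SNR over 10 slices."""
        f1s = []
        for i in range(10):
            rec, truth = fs.simulate_recording(syn_spec, 600.0, derive_seed(53, i))
            table = fs.detect_events(rec.ca3, rec.sampling_rate, channel="CA3")
            gt = truth.events.channel("CA3")
            tp, ndet, ngt, _ = match_events(
                table.df[table.df["kind"] == "discharge"],
                gt[gt["kind"] == "discharge"])
            f1s.append(2 * tp / (ndet + ngt))
        assert np.mean(f1s) >= 0.95

    def test_amplitude_monotonicity(self, short_recording):
        """Scaling the trace by c scales every detected peak by exactly c."""
        rec, _ = short_recording
        t1 = fs.detect_events(rec.ca3, rec.sampling_rate, channel="CA3")
        t2 = fs.detect_events(3.0 * rec.ca3, rec.sampling_rate, channel="CA3")
        assert len(t1) == len(t2)
        assert np.allclose(3.0 * t1.df["peak_mv"], t2.df["peak_mv"])
        assert np.allclose(t1.df["onset_s"], t2.df["onset_s"], atol=1e-9)

    def test_detection_idempotent_under_reconstruction(self):
        """detect -> re-render templates from the detections -> detect
        reproduces the same event table (boundaries within a few samples)."""
        fs_hz = 1000.0
        events = [(15.0, 0.9, 2.0), (45.0, 1.2, 2.6), (75.0, 0.6, 1.5)]
        noise = 0.002
        x = _render(events, 100.0, fs_hz, noise_sd=noise, floor_mv=0.67 * noise)
        t1 = fs.detect_events(x, fs_hz, channel="CA3")
        recon = _render([(r["onset_s"], r["offset_s"] - r["onset_s"], r["peak_mv"])
                         for _, r in t1.df.iterrows()],
                        100.0, fs_hz, noise_sd=noise, seed=1,
                        floor_mv=0.67 * noise)
        t2 = fs.detect_events(recon, fs_hz, channel="CA3")
        assert len(t1) == len(t2)
        assert np.allclose(t1.df["onset_s"], t2.df["onset_s"], atol=0.01)
        assert np.allclose(t1.df["offset_s"], t2.df["offset_s"], atol=0.01)

    def test_popspike_classification(self, syn_spec):
        """Large population spikes (50 ms) are detected and classified
        separately from discharges.  (The detector is matched to ~1 s
        discharges, so small spikes are attenuated below threshold by the
        pre-smoothing; only clearly supra-threshold spikes are recovered.)"""
        spec = syn_spec.replace(popspike_rate_ca1=20.0, burst_probability=0.0,
                                popspike_amplitude_mean=4.0,
                                popspike_amplitude_sd=1.0)
        rec, truth = fs.simulate_recording(spec, 300.0, seed=11)
        table = fs.detect_events(rec.ca1, rec.sampling_rate, channel="CA1")
        kinds = table.df["kind"].value_counts()
        n_ps_truth = (truth.events.channel("CA1")["kind"] == "population_spike").sum()
        assert kinds.get("population_spike", 0) >= 0.6 * n_ps_truth
        ps = table.df[table.df["kind"] == "population_spike"]
        assert ((ps["offset_s"] - ps["onset_s"]) < 0.1).all()


class TestGroupBursts:
    def test_train_arithmetic(self):
        """15 discharges at exact 2 s spacing form one burst at 0.5 Hz."""
        rows = [("CA3", 10.0 + 2.0 * i, 10.0 + 2.0 * i + 1.0, 2.0, "discharge", pd.NA)
                for i in range(15)]
        table = EventTable(pd.DataFrame(rows, columns=EventTable(None).df.columns))
        out = fs.group_bursts(table)
        ids = out.df["burst_id"]
        assert ids.notna().all()
        assert ids.nunique() == 1
        summary = fs.summarize_events(out, 60.0, channel="CA3")
        assert summary.n_bursts == 1
        assert summary.burst_duration_mean == pytest.approx(29.0)  # 28 s + last event
        assert summary.intraburst_frequency_mean == pytest.approx(14 / 29.0)

    def test_isolated_events_not_bursts(self):
        rows = [("CA3", 10.0 * i, 10.0 * i + 1.0, 2.0, "discharge", pd.NA)
                for i in range(1, 8)]
        table = EventTable(pd.DataFrame(rows, columns=EventTable(None).df.columns))
        out = fs.group_bursts(table)
        assert out.df["burst_id"].isna().all()

    def test_empty_table_unchanged(self):
        out = fs.group_bursts(EventTable(None))
        assert len(out) == 0

    def test_matches_brute_force_scan(self):
        """Burst assignment equals a brute-force run scan on random tables."""
        rng = np.random.default_rng(3)
        params = DetectionParams()
        for _ in range(20):
            n = rng.integers(5, 60)
            gaps = rng.exponential(3.0, n)
            onsets = np.cumsum(1.0 + gaps)
            rows = [("CA3", float(t), float(t + 0.5), 1.0, "discharge", pd.NA)
                    for t in onsets]
            table = EventTable(pd.DataFrame(rows, columns=EventTable(None).df.columns))
            out = fs.group_bursts(table, params)
            # brute force: split where onset gap >= burst_max_gap
            runs, cur = [], [0]
            for i in range(1, n):
                if onsets[i] - onsets[i - 1] < params.burst_max_gap:
                    cur.append(i)
                else:
                    runs.append(cur)
                    cur = [i]
            runs.append(cur)
            expect = [len(r) >= params.burst_min_events for r in runs for _ in r]
            assert list(out.df["burst_id"].notna()) == expect

    def test_detected_burst_count_matches_truth(self, syn_spec):
        hits = total = 0
        for i in range(12):
            rec, truth = fs.simulate_recording(syn_spec, 600.0, derive_seed(59, i),
                                               sampling_rate=10_000.0)
            if not truth.bursting:
                continue
            table = fs.group_bursts(
                fs.detect_events(rec.ca3, rec.sampling_rate, channel="CA3"))
            n_true = truth.events.channel("CA3")["burst_id"].nunique()
            n_det = table.channel("CA3")["burst_id"].nunique()
            total += 1
            hits += (n_det == n_true)
        assert total > 0
        assert hits >= 0.7 * total


class TestSummaries:
    def test_two_event_arithmetic(self):
        rows = [("CA3", 5.0, 6.0, 2.0, "discharge", pd.NA),
                ("CA3", 30.0, 31.2, 3.0, "discharge", pd.NA)]
        table = EventTable(pd.DataFrame(rows, columns=EventTable(None).df.columns))
        s = fs.summarize_events(table, 60.0, channel="CA3")
        assert s.mean_duration == pytest.approx(1.1)
        assert s.rate == pytest.approx(2.0)
        assert s.n_events == 2
        assert s.mean_amplitude == pytest.approx(2.5)

    def test_empty_summary_zeroed(self):
        s = fs.summarize_events(EventTable(None), 60.0)
        assert s.n_events == 0 and s.rate == 0.0 and s.n_bursts == 0

    def test_sla_mode_modal_frequency(self):
        onsets = 5.0 + np.arange(100) * 2.5   # 0.4 Hz regular train
        rows = [("CA3", float(t), float(t + 0.4), 2.0, "discharge", pd.NA)
                for t in onsets]
        table = EventTable(pd.DataFrame(rows, columns=EventTable(None).df.columns))
        s = fs.summarize_events(table, 300.0, channel="CA3", sla=True)
        assert s.sla_frequency == pytest.approx(0.4)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            fs.summarize_events(EventTable(None), 0.0)


class TestDetectionParamsValidation:
    def test_popspike_boundary_ordering_enforced(self):
        with pytest.raises(ValueError):
            DetectionParams(popspike_max_duration=0.3, min_duration=0.2)

    def test_positive_fields(self):
        with pytest.raises(ValueError):
            DetectionParams(threshold_k=0.0)


class TestEventTableIO:
    def test_csv_round_trip(self, tmp_path, full_recording):
        _, truth = full_recording
        p = tmp_path / "events.csv"
        truth.events.to_csv(p)
        back = EventTable.from_csv(p)
        pd.testing.assert_frame_equal(truth.events.df, back.df)

    def test_overlap_rejected(self):
        rows = [("CA3", 1.0, 3.0, 2.0, "discharge", pd.NA),
                ("CA3", 2.0, 4.0, 2.0, "discharge", pd.NA)]
        with pytest.raises(ValueError, match="overlap"):
            EventTable(pd.DataFrame(rows, columns=EventTable(None).df.columns))
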