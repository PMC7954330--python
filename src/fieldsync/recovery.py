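"""Parameter-recovery experiments.

Each function simulates a cohort under a condition preset, runs the
detection/summary pipeline on it, and returns the recovered summary
statistics — the quantities the generator encodes (single-discharge
duration and rate, burst structure, block latency, synaptic-current
amplitude, SLA frequency).  They are the package's end-to-end consistency
checks: generator and detector agree on what an "event" is.
"""

from __future__ import annotations

import numpy as np

from ._util import derive_seed
from .conditions import make_condition
from .detect import DetectionParams, detect_events, group_bursts, summarize_events
from .simulate import (iter_population, measure_current_peaks,
                       simulate_intracellular, simulate_recording)


def recover_discharge_statistics(n_slices: int = 200, duration: float = 600.0,
                                 seed: int = 0, condition: str = "synaptic_blockers",
                                 sampling_rate: float = 10_000.0,
                                 channel: str = "CA3",
                                 params: DetectionParams | None = None) -> dict:
    """Detector-recovered event statistics over a simulated cohort.

    Returns a dict with pooled single-discharge ``durations`` (s), per-slice
    ``rates`` (min^-1), detected ``burst_durations`` (s) and
    ``intraburst_frequencies`` (Hz), and the fraction of slices with at
    least one detected burst (``bursting_fraction``).
    """
    spec = make_condition(condition)
    params = params or DetectionParams()
    durations, rates, bdur, bfreq = [], [], [], []
    n_bursting = 0
    for rec, _ in iter_population(spec, n_slices, duration, seed, sampling_rate):
        trace = rec.ca3 if channel == "CA3" else rec.ca1
        table = group_bursts(detect_events(trace, rec.sampling_rate, params,
                                           channel=channel), params)
        summary = summarize_events(table, duration, channel=channel)
        rates.append(summary.rate)
        df = table.channel(channel)
        singles = df[(df["kind"] == "discharge") & df["burst_id"].isna()]
        durations += list(singles["offset_s"] - singles["onset_s"])
        bursts = df[df["burst_id"].notna()]
        if len(bursts):
            n_bursting += 1
            for _, grp in bursts.groupby("burst_id"):
                d = float(grp["offset_s"].max() - grp["onset_s"].min())
                bdur.append(d)
                if len(grp) > 1 and d > 0:
                    bfreq.append((len(grp) - 1) / d)
    return {
        "durations": np.asarray(durations),
        "rates": np.asarray(rates),
        "burst_durations": np.asarray(bdur),
        "intraburst_frequencies": np.asarray(bfreq),
        "bursting_fraction": n_bursting / n_slices,
        "n_slices": n_slices,
    }


def recover_block_statistics(n_runs: int = 200, duration: float = 1200.0,
                             seed: int = 0, condition: str = "cd2_15um",
                             sampling_rate: float = 1000.0) -> dict:
    """Ground-truth block onsets over repeated applications of a blocking
    condition: fraction with immediate block and mean nonzero latency."""
    spec = make_condition(condition)
    onsets = []
    for _, truth in iter_population(spec, n_runs, duration, seed, sampling_rate):
        onsets.append(truth.block_onset)
    onsets = np.asarray(onsets, float)
    delayed = onsets[onsets > 0] / 60.0
    return {
        "immediate_fraction": float((onsets == 0.0).mean()),
        "delay_mean_min": float(delayed.mean()) if len(delayed) else np.nan,
        "delays_min": delayed,
        "n_runs": n_runs,
    }


def recover_synaptic_current_amplitude(min_events: int = 200,
                                       holding_potential: float = -70.0,
                                       seed: int = 0, duration: float = 600.0,
                                       sampling_rate: float = 2000.0) -> dict:
    """Mean measured synaptic-current peak amplitude at a holding potential.

    Simulates synaptic-blockers recordings with a companion whole-cell
    trace until at least ``min_events`` CA1 events are collected, and reads
    the current at each transient's peak time.
    """
    spec = make_condition("synaptic_blockers")
    peaks = []
    i = 0
    while len(peaks) < min_events:
        rec, truth = simulate_recording(spec, duration, derive_seed(seed, i),
                                        sampling_rate=sampling_rate)
        it = simulate_intracellular(spec, rec, truth, holding_potential,
                                    seed=derive_seed(seed, i, 1))
        peaks += list(np.abs(measure_current_peaks(it)))
        i += 1
    peaks = np.asarray(peaks)
    return {"mean_peak_pa": float(peaks.mean()), "peaks_pa": peaks,
            "n_events": len(peaks)}


def recover_sla_frequency(n_slices: int = 20, duration: float = 600.0,
                          seed: int = 0, condition: str = "4ap",
                          sampling_rate: float = 10_000.0) -> dict:
    """Detector-recovered SLA event frequency per slice (Hz)."""
    spec = make_condition(condition)
    freqs = []
    for rec, _ in iter_population(spec, n_slices, duration, seed, sampling_rate):
        table = detect_events(rec.ca3, rec.sampling_rate, channel="CA3")
        summary = summarize_events(table, duration, channel="CA3", sla=True)
        freqs.append(summary.sla_frequency)
    freqs = np.asarray(freqs)
    return {"mean_hz": float(freqs.mean()), "freqs_hz": freqs,
            "n_slices": n_slices}
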