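"""Seeded synthetic paired CA3/CA1 field-potential recordings.

The generator emits, per simulated slice:

* a CA3 event train — single discharges as a renewal process (exponential
  inter-event intervals above a refractory floor), plus, in bursting slices,
  trains of discharges lasting tens of seconds that start with a
  large-amplitude leader event;
* CA1 copies of every CA3 discharge with a short conduction delay, Gaussian
  jitter and a per-event failure probability (CA3 is the generating site);
* independent nonsynaptic population spikes per channel;
* an optional discharge-block model (immediate with some probability,
  otherwise after a truncated-normal latency) after which discharges cease;
* band-limited Gaussian noise (low-pass 100 Hz), independent per channel.

Regular seizure-like activity (SLA) conditions replace the renewal process
with a near-periodic train at a per-slice frequency.

Every draw is routed through a single ``numpy`` generator seeded from the
``seed`` argument, so ``(spec, duration, seed)`` fully determines every
sample.  Ground truth records every emitted event (post-block truncation)
with the same schema the detector produces, so detections can be diffed
against truth directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from ._util import REFRACTORY_S, derive_seed, lognormal, rng_from, truncated_normal
from .conditions import ConditionSpec
from .detect import EVENT_COLUMNS, EventTable
from .templates import (
    FLOOR_PER_NOISE_SD,
    discharge_waveform,
    popspike_waveform,
    synaptic_current_kernel,
)

#: guard interval separating bursts from background activity, s
BURST_GUARD_S = 8.0
#: support of the drawn intraburst frequency, Hz (keeps every emitted train
#: groupable at the default burst_max_gap and resolvable at ~1 s durations)
INTRABURST_F_RANGE = (0.23, 1.2)
#: relative SD of the per-event CA3->CA1 amplitude transfer factor
COUPLING_AMP_REL_SD = 0.15
#: lower bound (mV) of the intraburst discharge amplitude distribution
INTRABURST_AMP_FLOOR_MV = 1.0
#: noise band limit, Hz
NOISE_CUTOFF_HZ = 100.0
#: default intracellular recording noise, pA (the observed baseline scatter
#: of synaptic-current amplitudes at the 0 mV reversal potential)
INTRACELLULAR_NOISE_PA = 14.89
#: mean and SD of synaptic-current peak amplitude at -70 mV holding, pA
SYNAPTIC_PEAK_MEAN_PA = 51.60
SYNAPTIC_PEAK_SD_PA = 22.71
#: driving-force reference used to convert amplitude to conductance, mV
_CALIBRATION_VHOLD_MV = -70.0


@dataclass
class Recording:
    """Paired CA3/CA1 extracellular voltage traces (mV)."""

    sampling_rate: float
    duration: float
    ca3: np.ndarray
    ca1: np.ndarray
    condition: str = ""
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        n = int(round(self.duration * self.sampling_rate))
        if len(self.ca3) != n or len(self.ca1) != n:
            raise ValueError(
                f"channel length mismatch: expected {n} samples for "
                f"{self.duration} s at {self.sampling_rate} Hz, got "
                f"ca3={len(self.ca3)}, ca1={len(self.ca1)}")
        if not (np.isfinite(self.ca3).all() and np.isfinite(self.ca1).all()):
            raise ValueError("non-finite samples in recording")


@dataclass
class GroundTruth:
    """Emitted events plus per-slice flags."""

    events: EventTable
    bursting: bool = False
    block_onset: float | None = None   # s; 0.0 = immediate block; None = no block


@dataclass
class IntracellularTrace:
    """Whole-cell current trace (pA) companion to a :class:`Recording`."""

    sampling_rate: float
    current: np.ndarray
    holding_potential: float           # mV
    reversal_potential: float = 0.0    # mV
    peak_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    peak_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))


# --------------------------------------------------------------------------
# event-train construction


def _single_discharge_onsets(rng, rate_per_min: float, duration: float):
    """Renewal process: refractory floor plus exponential inter-event time,
    with the exponential mean set so the realized rate equals the target."""
    if rate_per_min <= 0:
        return np.zeros(0)
    mean_iei = 60.0 / rate_per_min
    refr = min(REFRACTORY_S, 0.5 * mean_iei)
    exp_mean = mean_iei - refr
    onsets = []
    t = rng.exponential(mean_iei)
    while t < duration - 3.0:
        onsets.append(t)
        t += refr + rng.exponential(exp_mean)
    return np.asarray(onsets)


def _draw_bursts(rng, spec: ConditionSpec, duration: float):
    """Burst windows and their event trains for a bursting slice.

    Returns a list of dicts with keys onsets, durations, amplitudes_scale
    (leader factor per event) and the window (start, end).
    """
    lam = spec.burst_rate * duration / 60.0
    n_bursts = 0
    for _ in range(200):  # condition on at least one burst
        n_bursts = rng.poisson(lam)
        if n_bursts >= 1:
            break
    n_bursts = max(n_bursts, 1)

    windows = []
    for _ in range(n_bursts):
        b = float(truncated_normal(rng, spec.burst_duration_mean,
                                   spec.burst_duration_sd, (), lower=10.0))
        placed = None
        lo, hi = BURST_GUARD_S + 2.0, duration - b - BURST_GUARD_S - 2.0
        if hi <= lo:
            continue
        for _ in range(200):
            start = rng.uniform(lo, hi)
            if all(start > e + BURST_GUARD_S or start + b < s - BURST_GUARD_S
                   for s, e in windows):
                placed = start
                break
        if placed is not None:
            windows.append((placed, placed + b))

    bursts = []
    for start, end in sorted(windows):
        b = end - start
        f = float(truncated_normal(rng, spec.intraburst_frequency_mean,
                                   spec.intraburst_frequency_sd, (),
                                   lower=INTRABURST_F_RANGE[0],
                                   upper=INTRABURST_F_RANGE[1]))
        n_ev = max(4, int(round(f * b)) + 1)
        s0 = b / (n_ev - 1)
        durs = truncated_normal(rng, spec.discharge_duration_mean,
                                spec.discharge_duration_sd, n_ev, lower=0.3)
        durs = np.minimum(durs, 0.7 * s0)
        spacing = (b - durs[-1]) / (n_ev - 1)
        onsets = start + np.arange(n_ev) * spacing
        leader = np.ones(n_ev)
        leader[0] = spec.burst_leader_amplitude_factor
        bursts.append({"onsets": onsets, "durations": durs,
                       "leader": leader, "window": (start, end)})
    return bursts


def _sla_train(rng, spec: ConditionSpec, duration: float):
    """Near-periodic SLA train: per-slice frequency, 5% interval jitter."""
    f = float(truncated_normal(rng, spec.sla_frequency, spec.sla_frequency_sd,
                               (), lower=max(0.02, spec.sla_frequency / 4)))
    period = 1.0 / f
    onsets = []
    t = 5.0 + rng.uniform(0, period)
    while t < duration - 3.0:
        onsets.append(t)
        t += period * max(0.3, 1.0 + 0.05 * rng.standard_normal())
    onsets = np.asarray(onsets)
    durs = truncated_normal(rng, spec.discharge_duration_mean,
                            spec.discharge_duration_sd, len(onsets), lower=0.2)
    durs = np.minimum(durs, 0.6 * period)
    return onsets, durs, f


def _popspike_onsets(rng, rate_per_min: float, t_lo: float, t_hi: float,
                     keepout: np.ndarray, keepout_pad: float = 0.5):
    """Poisson population-spike times avoiding discharge extents."""
    if rate_per_min <= 0 or t_hi <= t_lo:
        return np.zeros(0)
    n = rng.poisson(rate_per_min * (t_hi - t_lo) / 60.0)
    times = np.sort(rng.uniform(t_lo, t_hi, n))
    if keepout.size:
        ok = np.ones(len(times), bool)
        for s, e in keepout:
            ok &= ~((times > s - keepout_pad) & (times < e + keepout_pad))
        times = times[ok]
    if len(times) > 1:   # keep popspikes themselves resolvable
        keep = np.r_[True, np.diff(times) > 0.3]
        times = times[keep]
    return times


def _bandlimited_noise(rng, n: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian noise low-pass filtered at NOISE_CUTOFF_HZ with exact SD."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    cutoff = min(NOISE_CUTOFF_HZ, 0.45 * fs)   # stay below Nyquist at low rates
    sos = signal.butter(4, cutoff, fs=fs, output="sos")
    white = rng.standard_normal(n)
    out = signal.sosfilt(sos, white)
    # analytic variance gain of the filter on white noise
    w, h = signal.sosfreqz(sos, worN=4096, fs=fs)
    gain = np.sqrt(np.trapezoid(np.abs(h) ** 2, w) / (fs / 2.0))
    return out * (sd / gain)


# --------------------------------------------------------------------------
# public API


def simulate_recording(spec: ConditionSpec, duration: float, seed: int,
                       sampling_rate: float = 10_000.0,
                       slice_effects: dict | None = None):
    """Simulate one paired CA3/CA1 recording.

    Returns ``(Recording, GroundTruth)``.  Identical ``(spec, duration,
    seed)`` yield bit-identical output.  ``slice_effects`` optionally fixes
    slice-level latent traits shared between consecutive segments of the
    same slice (keys ``bursting`` and ``amplitude_factor``); the pipeline
    uses this to model within-slice drug application.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    fs = float(sampling_rate)
    n = int(round(duration * fs))
    rng = rng_from(seed)
    effects = slice_effects or {}

    # --- slice-level traits (drawn first so downstream draws are stable) --
    bursting_draw = bool(rng.random() < spec.burst_probability)
    amp_factor_draw = float(lognormal(rng, 1.0, 0.2, ()))
    bursting = bool(effects.get("bursting", bursting_draw)) and spec.burst_probability > 0
    amp_factor = float(effects.get("amplitude_factor", amp_factor_draw))

    # --- block model -----------------------------------------------------
    block_onset = None
    if spec.has_block:
        if rng.random() < spec.block_immediate_prob:
            block_onset = 0.0
        else:
            block_onset = 60.0 * float(truncated_normal(
                rng, spec.block_delay_mean_min, spec.block_delay_sd_min, (),
                lower=0.0))

    # --- CA3 discharge train ---------------------------------------------
    rows = []  # (channel, onset, duration, amplitude, kind, burst_id)
    if spec.is_sla:
        onsets, durs, _ = _sla_train(rng, spec, duration)
        amps = lognormal(rng, spec.discharge_amplitude_mean_ca3,
                         spec.discharge_amplitude_sd_ca3, len(onsets))
        for t0, d, a in zip(onsets, durs, amps):
            rows.append(["CA3", t0, d, a, "discharge", pd.NA])
    else:
        singles = _single_discharge_onsets(rng, spec.discharge_rate, duration)
        burst_windows = []
        burst_list = _draw_bursts(rng, spec, duration) if bursting else []
        for burst in burst_list:
            burst_windows.append(burst["window"])
        if burst_windows:
            keep = np.ones(len(singles), bool)
            for s, e in burst_windows:
                keep &= ~((singles > s - BURST_GUARD_S - 2.0)
                          & (singles < e + BURST_GUARD_S))
            singles = singles[keep]
        sdur = truncated_normal(rng, spec.discharge_duration_mean,
                                spec.discharge_duration_sd, len(singles),
                                lower=0.3)
        if len(singles) > 1:
            # keep successive events resolvable (cap at 80% of the gap)
            gaps = np.diff(singles)
            sdur[:-1] = np.minimum(sdur[:-1], 0.8 * gaps)
        samp = lognormal(rng, spec.discharge_amplitude_mean_ca3,
                         spec.discharge_amplitude_sd_ca3, len(singles))
        for t0, d, a in zip(singles, sdur, samp):
            rows.append(["CA3", t0, d, a, "discharge", pd.NA])
        for bid, burst in enumerate(burst_list):
            # intraburst events ride the hypersynchronous state: same
            # amplitude law conditioned on clear detectability, so a train's
            # event count (hence its frequency) is a recoverable quantity
            amps = lognormal(rng, spec.discharge_amplitude_mean_ca3,
                             spec.discharge_amplitude_sd_ca3,
                             len(burst["onsets"]),
                             lower=INTRABURST_AMP_FLOOR_MV) * burst["leader"]
            for t0, d, a in zip(burst["onsets"], burst["durations"], amps):
                rows.append(["CA3", t0, d, a, "discharge", bid])

    # --- CA3 -> CA1 coupling ---------------------------------------------
    ratio = (spec.discharge_amplitude_mean_ca1
             / max(spec.discharge_amplitude_mean_ca3, 1e-12))
    ca1_rows = []
    for ch, t0, d, a, kind, bid in rows:
        if rng.random() < spec.coupling_failure_prob:
            continue
        t1 = t0 + spec.coupling_delay + spec.coupling_jitter_sd * rng.standard_normal()
        a1 = a * ratio * float(lognormal(rng, 1.0, COUPLING_AMP_REL_SD, ()))
        ca1_rows.append(["CA1", t1, d, a1, kind, bid])
    rows.extend(ca1_rows)

    # --- block truncation -------------------------------------------------
    if block_onset is not None:
        rows = [r for r in rows if r[1] < block_onset]

    # --- population spikes (independent per channel) ----------------------
    ps_t0 = block_onset if (spec.has_block and block_onset is not None) else 0.0
    for ch, rate in (("CA3", spec.popspike_rate_ca3), ("CA1", spec.popspike_rate_ca1)):
        keepout = np.array([(r[1] - 0.3, r[1] + r[2] + 0.3)
                            for r in rows if r[0] == ch], float).reshape(-1, 2)
        times = _popspike_onsets(rng, rate, max(ps_t0, 3.0), duration - 3.0, keepout)
        amps = lognormal(rng, spec.popspike_amplitude_mean,
                         spec.popspike_amplitude_sd, len(times))
        for t0, a in zip(times, amps):
            rows.append([ch, t0, spec.popspike_duration, a, "population_spike", pd.NA])

    # --- render ------------------------------------------------------------
    scale = {"CA3": spec.amplitude_scale_ca3 * amp_factor,
             "CA1": spec.amplitude_scale_ca1 * amp_factor}
    floor_mv = FLOOR_PER_NOISE_SD * spec.noise_sd
    traces = {"CA3": np.zeros(n), "CA1": np.zeros(n)}
    gt_rows = []
    for ch, t0, d, a, kind, bid in rows:
        amp = a * scale[ch]
        if kind == "discharge":
            off_s, w = discharge_waveform(d, amp, fs, floor_mv=floor_mv)
        else:
            off_s, w = popspike_waveform(d, amp, fs)
        i0 = int(round((t0 + off_s) * fs))
        j0, j1 = max(i0, 0), min(i0 + len(w), n)
        if j1 > j0:
            traces[ch][j0:j1] -= w[j0 - i0: j1 - i0]   # negative-going events
        gt_rows.append((ch, t0, t0 + d, amp, kind, bid))

    traces["CA3"] += _bandlimited_noise(rng, n, fs, spec.noise_sd)
    traces["CA1"] += _bandlimited_noise(rng, n, fs, spec.noise_sd)

    gt_df = pd.DataFrame(gt_rows, columns=EVENT_COLUMNS[:3] + ["peak_mv", "kind", "burst_id"])
    gt_df.columns = EVENT_COLUMNS
    truth = GroundTruth(
        events=EventTable(gt_df, metadata={"condition": spec.name, "seed": seed,
                                           "sampling_rate": fs}),
        bursting=bursting if not spec.is_sla else False,
        block_onset=block_onset,
    )
    rec = Recording(sampling_rate=fs, duration=float(duration),
                    ca3=traces["CA3"], ca1=traces["CA1"],
                    condition=spec.name, seed=int(seed),
                    metadata={"amplitude_factor": amp_factor})
    return rec, truth


def simulate_population(spec: ConditionSpec, n_slices: int, duration: float,
                        seed: int, sampling_rate: float = 10_000.0):
    """Independent slices from child seeds derived deterministically.

    Child seed protocol: ``derive_seed(seed, i)`` = first 32-bit word of
    ``numpy.random.SeedSequence(entropy=seed, spawn_key=(i,))`` — stable
    across runs and versions.  Returns a list of ``(Recording,
    GroundTruth)``; prefer iterating :func:`iter_population` for large
    cohorts.
    """
    return list(iter_population(spec, n_slices, duration, seed, sampling_rate))


def iter_population(spec: ConditionSpec, n_slices: int, duration: float,
                    seed: int, sampling_rate: float = 10_000.0):
    """Generator form of :func:`simulate_population` (constant memory)."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    for i in range(int(n_slices)):
        yield simulate_recording(spec, duration, derive_seed(seed, i),
                                 sampling_rate=sampling_rate)


def simulate_intracellular(spec: ConditionSpec, recording: Recording,
                           truth: GroundTruth, holding_potential: float,
                           seed: int, reversal_potential: float = 0.0,
                           noise_sd: float = INTRACELLULAR_NOISE_PA) -> IntracellularTrace:
    """Whole-cell synaptic current trace for a CA1 neuron.

    One biexponential current transient per CA1 ground-truth discharge,
    aligned within the coupling jitter.  Each event's peak conductance is
    drawn so that at a holding potential of -70 mV (reversal 0 mV) the peak
    amplitude distribution has mean 51.60 and SD 22.71 pA; the current
    scales exactly linearly with the driving force
    ``holding_potential - reversal_potential`` before noise.
    """
    if not np.isfinite(holding_potential):
        raise ValueError("holding_potential must be finite")
    fs_truth = truth.events.metadata.get("sampling_rate", recording.sampling_rate)
    if fs_truth != recording.sampling_rate:
        raise ValueError("mismatched sampling rates between recording and truth")
    fs = recording.sampling_rate
    n = int(round(recording.duration * fs))
    rng = rng_from(seed)

    events = truth.events.channel("CA1")
    events = events[events["kind"] == "discharge"]
    onsets = events["onset_s"].to_numpy()
    m = len(onsets)

    peak_at_ref = truncated_normal(rng, SYNAPTIC_PEAK_MEAN_PA,
                                   SYNAPTIC_PEAK_SD_PA, m, lower=0.0)
    g_peak = peak_at_ref / abs(_CALIBRATION_VHOLD_MV - 0.0)   # nS == pA/mV
    jitter = spec.coupling_jitter_sd * rng.standard_normal(m)

    drive = holding_potential - reversal_potential
    t_peak_k, kernel = synaptic_current_kernel(fs)
    current = np.zeros(n)
    peak_times = np.empty(m)
    peak_amps = np.empty(m)
    for i in range(m):
        t0 = onsets[i] + jitter[i]
        i0 = int(round(t0 * fs))
        j0, j1 = max(i0, 0), min(i0 + len(kernel), n)
        amp = g_peak[i] * drive
        if j1 > j0:
            current[j0:j1] += amp * kernel[j0 - i0: j1 - i0]
        peak_times[i] = t0 + t_peak_k
        peak_amps[i] = amp

    if noise_sd > 0:
        current = current + _bandlimited_noise(rng, n, fs, noise_sd)

    return IntracellularTrace(sampling_rate=fs, current=current,
                              holding_potential=float(holding_potential),
                              reversal_potential=float(reversal_potential),
                              peak_times=peak_times, peak_amplitudes=peak_amps)


def measure_current_peaks(itrace: IntracellularTrace) -> np.ndarray:
    """Measured current at each transient's peak time (pA, signed).

    Samples the noisy trace at the known peak times, the same way coincident
    synaptic currents are read off against the field-event markers.
    """
    idx = np.clip((itrace.peak_times * itrace.sampling_rate).round().astype(int),
                  0, len(itrace.current) - 1)
    if idx.size == 0:
        return np.zeros(0)
    return itrace.current[idx]
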