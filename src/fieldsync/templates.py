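"""Event waveform templates.

A field discharge is rendered as a sharp biphasic deflection: a fast
biexponential body (rise time constant ~5 ms) carrying the drawn peak
amplitude, flanked by linear onset/offset skirts with a fixed absolute
slope.  The skirts are anchored so that the waveform crosses the nominal
detectability floor (``HALF_THRESHOLD_MV``, the half-threshold of the
default detector at the default noise level) exactly at the nominal onset
and at ``onset + duration`` — for every drawn amplitude.  Ground-truth
onset/offset therefore delimit the interval over which the event is
nominally detectable, and the drawn "duration" is exactly the quantity the
detector's half-threshold boundaries estimate.

Population spikes use a plain biexponential at a fixed 50 ms scale;
synaptic currents use a fast-rise/slow-decay conductance kernel.
"""

from __future__ import annotations

import numpy as np

#: detectability floor per unit of generator noise SD, dimensionless.
#: Equals threshold_k/2 times the ratio of smoothed-noise sigma to raw
#: noise SD under the default detector (10 Hz Gaussian smoothing at
#: 1 kHz): 2.5 * 0.268 ~= 0.67.  The skirts of a rendered discharge cross
#: ``FLOOR_PER_NOISE_SD * noise_sd`` exactly at the nominal onset/offset,
#: so the drawn duration is what the default detector's half-threshold
#: boundaries estimate, at any preset noise level.
FLOOR_PER_NOISE_SD = 0.67
#: default floor (mV) when no noise level is supplied (default preset noise)
HALF_THRESHOLD_MV = 0.235
#: absolute slope of the onset/offset skirts, mV/s
SKIRT_SLOPE = 4.0
#: skirt top level for large events, mV
SKIRT_TOP_MV = 0.7
#: body rise time constant, s (time to peak ~20 ms)
RISE_TAU_S = 0.005
#: small opposite-polarity lobe amplitude cap, mV (kept below the
#: detectability floor so it never triggers the detector)
BIPHASIC_LOBE_MV = 0.15


def discharge_waveform(duration: float, amplitude: float, sampling_rate: float,
                       floor_mv: float = HALF_THRESHOLD_MV):
    """Render one discharge.

    Returns ``(start_offset_s, samples)``: the waveform samples and the time
    of the first sample relative to the nominal event onset.  The waveform is
    positive; callers apply polarity.  ``floor_mv`` is the detectability
    floor the skirts are anchored to (``FLOOR_PER_NOISE_SD`` times the
    recording noise SD).  For amplitudes at or below the floor a plain
    biexponential is used (such events are sub-threshold by construction).
    """
    fs = float(sampling_rate)
    a = float(amplitude)
    d = float(duration)
    floor = max(float(floor_mv), 1e-6)
    if a <= 0 or d <= 0:
        return 0.0, np.zeros(0)

    v_top = min(SKIRT_TOP_MV, 0.55 * a)
    if v_top <= floor + 0.02:
        # sub-threshold event: simple biexponential, no skirt calibration
        t = np.arange(0.0, d + 0.2, 1.0 / fs)
        tau_d = max(d / 3.0, 0.02)
        w = np.exp(-t / tau_d) - np.exp(-t / RISE_TAU_S)
        peak = w.max()
        return 0.0, (a / peak) * w if peak > 0 else np.zeros(0)

    # skirt geometry: onset skirt crosses the floor level at t = 0,
    # offset skirt crosses it at t = d, both with slope SKIRT_SLOPE.
    t_start = -floor / SKIRT_SLOPE
    t_end = d + floor / SKIRT_SLOPE
    t = np.arange(np.floor(t_start * fs), np.ceil(t_end * fs) + 1) / fs

    on_skirt = np.clip(floor + SKIRT_SLOPE * t, 0.0, v_top)
    off_skirt = np.clip(floor - SKIRT_SLOPE * (t - d), 0.0, v_top)

    # body: fast rise from the skirt top toward the peak, exponential decay
    # back to the skirt top; active between the two skirt tops
    t_b = (v_top - floor) / SKIRT_SLOPE   # onset skirt reaches top
    t_c = d - t_b                         # offset skirt leaves top
    body = np.zeros_like(t)
    if t_c > t_b + 0.05 and a > v_top:
        u = t - t_b
        rise = 1.0 - np.exp(-np.clip(u, 0.0, None) / RISE_TAU_S)
        t_peak = t_b + 4.0 * RISE_TAU_S
        # decay constant: body falls to within 0.1 mV of the skirt top
        # before the offset skirt takes over
        tau_d = (t_c - t_peak) / np.log(max((a - v_top) / 0.1, 2.0))
        decay = np.exp(-np.clip(t - t_peak, 0.0, None) / tau_d)
        body = (a - v_top) * rise * decay
        body[(t < t_b) | (t > t_c)] = 0.0

    w = np.maximum(np.minimum(on_skirt, off_skirt) + body, 0.0)

    # small opposite-polarity rebound after the main lobe (biphasic
    # character); kept below the detectability floor so it never triggers
    # the detector, and centred well inside the event so the calibrated
    # skirt crossings are untouched
    lobe = min(BIPHASIC_LOBE_MV, 0.08 * a)
    if t_c > t_b + 0.2:
        centre = t_b + 4.0 * RISE_TAU_S + 0.08
        w = w - lobe * np.exp(-0.5 * ((t - centre) / 0.015) ** 2)
    return float(t[0]), w


def popspike_waveform(duration: float, amplitude: float, sampling_rate: float):
    """A brief biexponential population-spike deflection (unit polarity)."""
    fs = float(sampling_rate)
    tau_r = duration / 16.0
    tau_d = duration / 4.0
    t = np.arange(0.0, duration * 1.8, 1.0 / fs)
    w = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = w.max()
    if peak <= 0:
        return 0.0, np.zeros(0)
    return 0.0, (amplitude / peak) * w


def synaptic_current_kernel(sampling_rate: float, rise_s: float = 0.002,
                            decay_s: float = 0.020):
    """Unit-peak biexponential conductance time course for synaptic currents.

    Returns ``(peak_time_s, samples)`` so callers can locate the peak.
    """
    fs = float(sampling_rate)
    t = np.arange(0.0, decay_s * 8.0, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak_idx = int(np.argmax(k))
    peak = k[peak_idx]
    return peak_idx / fs, k / peak
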