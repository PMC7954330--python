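"""Detection of epileptiform discharges and population spikes.

The detector works on a decimated (default 1 kHz) and lightly smoothed copy
of a single-channel field trace:

1. baseline: block-wise running median (robust to dense bursting);
2. threshold: ``threshold_k`` times the MAD-based sigma of the deviation
   from baseline (the median absolute deviation is insensitive to the small
   duty cycle of events);
3. supra-threshold excursions of ``|trace - baseline|`` are merged across
   gaps shorter than ``merge_gap``;
4. event boundaries are placed at the half-threshold crossings, refined by
   a local least-squares line fit so crossing-time errors are symmetric in
   the noise;
5. classification by duration: below 20 ms discarded as artefact, below
   ``popspike_max_duration`` a population spike, at or above
   ``min_duration`` a discharge (the gap in between is discarded as
   unclassifiable).

Bursts are trains of at least ``burst_min_events`` discharges whose
consecutive onsets are separated by less than ``burst_max_gap``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

EVENT_COLUMNS = ["channel", "onset_s", "offset_s", "peak_mv", "kind", "burst_id"]

_MAD_TO_SIGMA = 1.4826

#: quiet margin around each burst (s) excluded from the observation time
#: when computing the single-discharge rate: background activity is
#: suppressed for several seconds around a burst, so counting that stretch
#: as observation time would understate the single-event rate
BURST_MARGIN_S = 18.0


@dataclass
class DetectionParams:
    """Detector configuration.

    ``threshold_k`` is in multiples of the robust (MAD-based) deviation of
    the smoothed trace from baseline.  Durations are seconds.
    """

    threshold_k: float = 5.0
    merge_gap: float = 0.2
    min_duration: float = 0.2
    popspike_max_duration: float = 0.1
    burst_min_events: int = 4
    burst_max_gap: float = 4.5
    analysis_rate: float = 1000.0   # Hz, detection decimation target
    smooth_cutoff: float = 10.0     # Hz, Gaussian pre-smoothing for thresholding
    baseline_window: float = 5.0    # s, running-median window

    def __post_init__(self):
        for f in ("threshold_k", "merge_gap", "min_duration",
                  "popspike_max_duration", "burst_max_gap", "analysis_rate",
                  "smooth_cutoff", "baseline_window"):
            if getattr(self, f) <= 0:
                raise ValueError(f"DetectionParams.{f} must be > 0")
        if self.burst_min_events < 1:
            raise ValueError("burst_min_events must be >= 1")
        if self.popspike_max_duration >= self.min_duration:
            raise ValueError("popspike_max_duration must be < min_duration")


class EventTable:
    """Ordered table of detected or ground-truth events.

    Wraps a :class:`pandas.DataFrame` with columns
    ``channel, onset_s, offset_s, peak_mv, kind, burst_id`` (``burst_id`` is
    nullable).  Events are kept sorted by onset within channel and may not
    overlap within a channel.
    """

    def __init__(self, df: pd.DataFrame | None = None, metadata: dict | None = None):
        if df is None:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        df = df[EVENT_COLUMNS].copy()
        df["burst_id"] = df["burst_id"].astype("Int64")
        df = df.sort_values(["channel", "onset_s"], kind="stable").reset_index(drop=True)
        for ch, sub in df.groupby("channel"):
            if (sub["onset_s"].to_numpy() >= sub["offset_s"].to_numpy()).any():
                raise ValueError(f"channel {ch}: event with onset >= offset")
            if (sub["onset_s"].to_numpy()[1:] < sub["offset_s"].to_numpy()[:-1] - 1e-9).any():
                raise ValueError(f"channel {ch}: overlapping events")
        self.df = df
        self.metadata = dict(metadata or {})

    def __len__(self):
        return len(self.df)

    def channel(self, name: str) -> pd.DataFrame:
        return self.df[self.df["channel"] == name]

    @property
    def durations(self) -> np.ndarray:
        return (self.df["offset_s"] - self.df["onset_s"]).to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(df)


@dataclass
class EventSummary:
    """Mean ± SD summaries of an event table (single discharges, bursts,
    population spikes; optionally the regular-SLA train frequency)."""

    n_events: int = 0
    mean_duration: float = 0.0
    sd_duration: float = 0.0
    rate: float = 0.0                   # single discharges per minute
    mean_amplitude: float = 0.0
    sd_amplitude: float = 0.0
    n_bursts: int = 0
    burst_duration_mean: float = 0.0
    burst_duration_sd: float = 0.0
    intraburst_frequency_mean: float = 0.0
    intraburst_frequency_sd: float = 0.0
    n_popspikes: int = 0
    sla_frequency: float = 0.0          # Hz; only set in SLA mode

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _decimate(trace: np.ndarray, fs: float, target: float):
    """Polyphase anti-aliased decimation to ``target`` Hz (or no-op)."""
    if target >= fs:
        return np.asarray(trace, float), fs
    from fractions import Fraction

    frac = Fraction(target / fs).limit_denominator(1000)
    out = signal.resample_poly(np.asarray(trace, float), frac.numerator, frac.denominator)
    return out, fs * frac.numerator / frac.denominator


def _running_median(x: np.ndarray, fs: float, window_s: float,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Block-wise running median, linearly interpolated to full resolution.

    Samples where ``mask`` is True (event regions) are excluded so the
    baseline does not track dense bursting; fully masked blocks are filled
    by interpolation from neighbouring quiet blocks.
    """
    block = max(int(round(0.5 * fs)), 1)
    nblk = len(x) // block
    if nblk < 3:
        return np.full_like(x, np.median(x))
    xb = x[: nblk * block].astype(float).reshape(nblk, block)
    if mask is not None:
        xb = np.where(mask[: nblk * block].reshape(nblk, block), np.nan, xb)
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(xb, axis=1)
    good = np.isfinite(med)
    if not good.any():
        return np.full_like(x, np.median(x))
    if not good.all():
        med = np.interp(np.arange(nblk), np.flatnonzero(good), med[good])
    size = max(int(round(window_s / 0.5)), 1)
    med = ndimage.median_filter(med, size=size, mode="nearest")
    centers = (np.arange(nblk) + 0.5) * block
    return np.interp(np.arange(len(x)), centers, med)


def _initial_baseline(xs: np.ndarray, fs: float, window_s: float = 60.0) -> np.ndarray:
    """Polarity-adaptive first-pass baseline for event masking.

    Field events are one-sided excursions, so inside dense bursts the
    running median tracks the events rather than the quiet level.  This
    estimate instead follows the event-free side of the amplitude
    distribution: an within-block quantile on the quiet side, then a
    running quantile across blocks.  It is slightly offset into the noise
    (fraction of a noise SD), which is harmless for masking; the final
    baseline is the masked running median.
    """
    med = float(np.median(xs))
    lo, hi = np.quantile(xs, [0.01, 0.99])
    negative_events = (med - lo) > (hi - med)
    q = 0.8 if negative_events else 0.2
    block = max(int(round(0.5 * fs)), 1)
    nblk = len(xs) // block
    if nblk < 3:
        return np.full_like(xs, med)
    bq = np.quantile(xs[: nblk * block].reshape(nblk, block), q, axis=1)
    size = max(int(round(window_s / 0.5)), 1)
    bq = ndimage.percentile_filter(bq, 80 if negative_events else 20,
                                   size=size, mode="nearest")
    centers = (np.arange(nblk) + 0.5) * block
    return np.interp(np.arange(len(xs)), centers, bq)


def _fit_crossing(signed_raw, lo, hi, level, rising):
    """Least-squares line through samples [lo, hi); crossing of ``level``."""
    t = np.arange(lo, hi, dtype=float)
    y = signed_raw[lo:hi]
    b, a = np.polyfit(t, y, 1)
    slope_ok = b > 1e-12 if rising else b < -1e-12
    if not slope_ok:
        return None, b
    return (level - a) / b, b


def _refine_crossing(signed_raw: np.ndarray, idx: int, level: float, fs: float,
                     rising: bool, half_window_s: float = 0.04) -> float:
    """Sub-sample crossing time of a noisy event edge through ``level``.

    Symmetric least-squares line fit on the raw (unsmoothed,
    polarity-corrected) trace around the coarse crossing: noise enters
    symmetrically, so the estimate is unbiased on the linear edge ramp of
    the event (the ramp extends well past the fit window on both sides at
    the SNR this branch is used for).
    """
    n = len(signed_raw)
    h = max(int(round(half_window_s * fs)), 2)
    lo, hi = max(idx - h, 0), min(idx + h + 1, n)
    t_cross, _ = _fit_crossing(signed_raw, lo, hi, level, rising)
    if t_cross is None:
        return idx / fs
    return float(np.clip(t_cross, lo, hi - 1)) / fs


def _walk_crossing(signed_raw: np.ndarray, peak_idx: int, level: float,
                   fs: float, rising: bool, max_reach: int) -> float:
    """Crossing time for a high-SNR event edge: walk outward from the peak
    on the raw trace to the first sample below ``level`` and interpolate
    between the straddling samples.  Exact at vanishing noise."""
    n = len(signed_raw)
    step = -1 if rising else 1
    i = peak_idx
    stop = max(peak_idx - max_reach, 0) if rising else min(peak_idx + max_reach, n - 1)
    while i != stop and signed_raw[i + step] >= level:
        i += step
    j = i + step
    if not 0 <= j < n or signed_raw[j] >= level:
        return i / fs
    # refine with a short line fit on the interior (ramp) side, which
    # averages the noise without touching the flat region past the edge
    if rising:
        lo, hi = i, min(i + 9, n)
    else:
        lo, hi = max(i - 8, 0), i + 1
    if hi - lo >= 4:
        t_fit, _ = _fit_crossing(signed_raw, lo, hi, level, rising)
        if t_fit is not None and abs(t_fit - i) <= 10:
            return float(t_fit) / fs
    y_in, y_out = signed_raw[i], signed_raw[j]
    frac = (y_in - level) / (y_in - y_out) if y_in != y_out else 0.0
    return (i + step * frac) / fs


def detect_events(trace, sampling_rate: float, params: DetectionParams | None = None,
                  channel: str = "CA3") -> EventTable:
    """Detect discharges and population spikes in one field-potential trace.

    Returns an :class:`EventTable` (``burst_id`` unset; see
    :func:`group_bursts`).  A constant trace yields an empty table.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, float)
    fs = float(sampling_rate)
    if len(trace) < 10 * fs:
        raise ValueError("trace shorter than 10 s; too short for detection")

    x, fs_a = _decimate(trace, fs, params.analysis_rate)
    from .sync import gaussian_lowpass

    if params.smooth_cutoff < fs_a / 2:
        xs = gaussian_lowpass(x, fs_a, params.smooth_cutoff)
    else:
        xs = x
    # two-pass baseline and noise estimate: a first running median flags
    # candidate event regions; the baseline and the MAD-based sigma are then
    # recomputed on the discharge-free remainder so dense bursting neither
    # drags the baseline nor inflates the threshold
    base0 = _initial_baseline(xs, fs_a)
    dev0 = np.abs(xs - base0)
    sigma0 = _MAD_TO_SIGMA * np.median(dev0)
    if sigma0 <= 0:
        return EventTable(metadata={"channel": channel, "threshold_mv": 0.0})
    mask = dev0 > 2.5 * sigma0
    mask = ndimage.binary_dilation(mask, np.ones(2 * int(0.1 * fs_a) + 1, bool))
    if mask.mean() < 0.95:
        baseline = _running_median(xs, fs_a, params.baseline_window, mask=mask)
        quiet = np.abs(xs - baseline)[~mask]
        sigma = _MAD_TO_SIGMA * np.median(quiet) if quiet.size else sigma0
    else:
        baseline, sigma = base0, sigma0
    if sigma <= 0:
        return EventTable(metadata={"channel": channel, "threshold_mv": 0.0})
    absdev = np.abs(xs - baseline)
    raw_signed = x - baseline
    quiet_raw = np.abs(raw_signed)[~mask]
    sigma_raw = _MAD_TO_SIGMA * np.median(quiet_raw) if quiet_raw.size else sigma
    threshold = params.threshold_k * sigma
    half = threshold / 2.0

    supra = absdev > threshold
    if not supra.any():
        return EventTable(metadata={"channel": channel, "threshold_mv": threshold})

    # supra-threshold runs
    edges = np.diff(supra.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if supra[0]:
        starts = np.r_[0, starts]
    if supra[-1]:
        ends = np.r_[ends, len(supra)]

    # merge across short gaps
    gap = int(round(params.merge_gap * fs_a))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    max_reach = int(round(2.0 * fs_a))
    raw_dev = np.abs(raw_signed)
    rows = []
    prev_offset = -np.inf
    neg_signed = None
    for s, e in merged:
        # polarity of this event (events are one-sided deflections)
        peak_idx = s + int(np.argmax(absdev[s:e]))
        if xs[peak_idx] - baseline[peak_idx] >= 0:
            signed = raw_signed
        else:
            if neg_signed is None:
                neg_signed = -raw_signed
            signed = neg_signed
        peak_raw = signed[max(s - 5, 0): e + 5].max()

        brief = (e - s) < 2.0 * params.popspike_max_duration * fs_a
        if peak_raw > 20.0 * sigma_raw or brief:
            # high-SNR or brief event: the raw trace crosses the level over
            # a span too short for a line fit; walk out from the peak
            onset = _walk_crossing(signed, peak_idx, half, fs_a, True, max_reach)
            offset = _walk_crossing(signed, peak_idx, half, fs_a, False, max_reach)
        else:
            # noisy edge: coarse crossing on the smoothed deviation, then an
            # unbiased symmetric line fit on the raw trace
            i = s
            lo_stop = max(s - max_reach, 0)
            while i > lo_stop and absdev[i - 1] >= half:
                i -= 1
            onset = _refine_crossing(signed, i, half, fs_a, rising=True)
            j = e - 1
            hi_stop = min(e - 1 + max_reach, len(absdev) - 1)
            while j < hi_stop and absdev[j + 1] >= half:
                j += 1
            offset = _refine_crossing(signed, j + 1 if j + 1 < len(absdev) else j,
                                      half, fs_a, rising=False)
        if offset <= onset:
            continue
        if onset < prev_offset:  # keep events non-overlapping
            onset = prev_offset + 1.0 / fs_a
            if offset <= onset:
                continue
        duration = offset - onset
        if duration < 0.02:
            continue
        if duration < params.popspike_max_duration:
            kind = "population_spike"
        elif duration >= params.min_duration:
            kind = "discharge"
        else:
            continue
        i0, i1 = int(onset * fs_a), min(int(np.ceil(offset * fs_a)) + 1, len(x))
        peak = float(raw_dev[i0:i1].max()) if i1 > i0 else 0.0
        rows.append((channel, onset, offset, peak, kind, pd.NA))
        prev_offset = offset

    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventTable(df, metadata={"channel": channel, "threshold_mv": threshold,
                                    "analysis_rate": fs_a})


def group_bursts(table: EventTable, params: DetectionParams | None = None) -> EventTable:
    """Assign ``burst_id`` to maximal trains of discharges.

    A burst is a maximal run of at least ``burst_min_events`` discharges
    whose consecutive onsets are separated by less than ``burst_max_gap``.
    Population spikes are ignored.  Returns a new table.
    """
    params = params or DetectionParams()
    df = table.df.copy()
    df["burst_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    next_id = 0
    for ch in df["channel"].unique():
        mask = (df["channel"] == ch) & (df["kind"] == "discharge")
        idx = df.index[mask]
        if len(idx) == 0:
            continue
        onsets = df.loc[idx, "onset_s"].to_numpy()
        new_run = np.r_[True, np.diff(onsets) >= params.burst_max_gap]
        run_ids = np.cumsum(new_run)
        for rid in np.unique(run_ids):
            members = idx[run_ids == rid]
            if len(members) >= params.burst_min_events:
                df.loc[members, "burst_id"] = next_id
                next_id += 1
    return EventTable(df, metadata=dict(table.metadata))


def summarize_events(table: EventTable, duration: float,
                     channel: str | None = "CA3", sla: bool = False) -> EventSummary:
    """Summary statistics of an event table over a recording of ``duration`` s.

    Statistics are over *single* discharges (``burst_id`` unset); bursts and
    population spikes are summarized separately.  Run :func:`group_bursts`
    first if burst membership should be excluded from the single-event
    statistics.  With ``sla=True`` the regular-SLA train frequency is
    reported as the inverse median inter-onset interval of all discharges.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    df = table.df
    if channel is not None:
        df = df[df["channel"] == channel]
    disc = df[df["kind"] == "discharge"]
    singles = disc[disc["burst_id"].isna()]
    out = EventSummary()
    out.n_popspikes = int((df["kind"] == "population_spike").sum())

    # observation time for the single-discharge rate excludes burst spans
    # (plus a quiet margin) where background activity is suppressed
    burst_time = 0.0
    if disc["burst_id"].notna().any():
        for _, grp in disc[disc["burst_id"].notna()].groupby("burst_id"):
            burst_time += float(grp["offset_s"].max() - grp["onset_s"].min()) + BURST_MARGIN_S
    obs_time = max(duration - burst_time, duration * 0.1)

    if len(singles):
        d = (singles["offset_s"] - singles["onset_s"]).to_numpy()
        a = singles["peak_mv"].to_numpy()
        out.n_events = len(singles)
        out.mean_duration = float(d.mean())
        out.sd_duration = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        out.mean_amplitude = float(a.mean())
        out.sd_amplitude = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        out.rate = len(singles) / obs_time * 60.0
    if disc["burst_id"].notna().any():
        bursts = disc[disc["burst_id"].notna()].groupby("burst_id")
        bd, bf = [], []
        for _, grp in bursts:
            dur = float(grp["offset_s"].max() - grp["onset_s"].min())
            bd.append(dur)
            if len(grp) > 1 and dur > 0:
                bf.append((len(grp) - 1) / dur)
        out.n_bursts = len(bd)
        out.burst_duration_mean = float(np.mean(bd))
        out.burst_duration_sd = float(np.std(bd, ddof=1)) if len(bd) > 1 else 0.0
        if bf:
            out.intraburst_frequency_mean = float(np.mean(bf))
            out.intraburst_frequency_sd = float(np.std(bf, ddof=1)) if len(bf) > 1 else 0.0
    if sla and len(disc) > 2:
        ioi = np.diff(np.sort(disc["onset_s"].to_numpy()))
        med = float(np.median(ioi))
        if med > 0:
            out.sla_frequency = 1.0 / med
    return out
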