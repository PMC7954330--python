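"""CA3-CA1 synchronization statistic.

The synchronization level of a paired field-potential recording is the
first maximum of the smoothed cross-correlation function:

1. both channels are decimated to ``analysis_rate`` (polyphase,
   anti-aliased) and low-pass filtered with a zero-phase Gaussian kernel
   whose gain is 0.5 at ``cutoff`` (default 50 Hz);
2. the Pearson-normalized cross-correlation function is computed for lags
   within ``±max_lag``;
3. the CCF is smoothed with a Lowess smoother (tricube weights, one
   robustness iteration, span a fraction of the number of lag points);
4. the score is the maximum of the smoothed CCF inside ``±max_lag``, ties
   broken toward the smallest ``|lag|``.

The Gaussian kernel has the closed form gain(f) = exp(-2 pi^2 sigma^2 f^2),
so gain(cutoff) = 0.5 gives sigma = sqrt(ln 2 / 2) / (pi * cutoff) seconds.

Sign convention: a positive ``score_lag`` means the second channel (CA1)
lags the first (CA3).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, signal


@dataclass
class SyncParams:
    cutoff: float = 50.0        # Hz, Gaussian low-pass (gain 0.5 at cutoff)
    lowess_span: float = 0.01   # fraction of lag points in the smoother window
    max_lag: float = 1.0        # s
    min_duration: float = 300.0  # s, minimum usable recording
    analysis_rate: float = 1000.0  # Hz, decimation target (set to the
                                   # sampling rate to disable decimation)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess_span must be in (0, 1]")
        if self.max_lag <= 0 or self.min_duration <= 0 or self.analysis_rate <= 0:
            raise ValueError("max_lag, min_duration, analysis_rate must be > 0")


@dataclass
class SyncResult:
    """Cross-correlation function, its smoothed form and the extracted
    synchronization score (the smoothed CCF's first maximum)."""

    lags: np.ndarray
    ccf: np.ndarray
    ccf_smoothed: np.ndarray
    score: float
    score_lag: float
    params: SyncParams = field(default_factory=SyncParams)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "ccf": self.ccf,
                             "ccf_smoothed": self.ccf_smoothed})

    def summary(self) -> dict:
        return {"score": self.score, "score_lag_s": self.score_lag,
                "cutoff_hz": self.params.cutoff,
                "lowess_span": self.params.lowess_span,
                "max_lag_s": self.params.max_lag,
                "analysis_rate_hz": self.params.analysis_rate}


def write_sync_result(result: SyncResult, csv_path, summary_path=None) -> None:
    """Write ``lag_s,ccf,ccf_smoothed`` CSV plus a one-line JSON summary."""
    result.to_frame().to_csv(csv_path, index=False)
    if summary_path is None:
        summary_path = str(csv_path) + ".summary.json"
    with open(summary_path, "w") as fh:
        fh.write(json.dumps(result.summary()) + "\n")


def gaussian_lowpass(trace, sampling_rate: float, cutoff: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass filter with gain 0.5 at ``cutoff``.

    The kernel standard deviation follows from the Gaussian's frequency
    response gain(f) = exp(-2 pi^2 sigma^2 f^2):
    sigma = sqrt(ln 2 / (2 pi^2 cutoff^2)).  The kernel is truncated at
    4 sigma, normalized to unit sum, and edges are handled by reflection.
    """
    trace = np.asarray(trace, float)
    if trace.size == 0:
        raise ValueError("empty trace")
    fs = float(sampling_rate)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist "
                         f"frequency {fs / 2} Hz")
    sigma_s = np.sqrt(np.log(2.0) / 2.0) / (np.pi * cutoff)
    return ndimage.gaussian_filter1d(trace, sigma_s * fs, mode="reflect",
                                     truncate=4.0)


def cross_correlation(x, y, sampling_rate: float, max_lag: float):
    """Pearson-normalized cross-correlation restricted to ``|lag| <= max_lag``.

    Each lag's value is the Pearson correlation of the two overlapping
    segments (means and variances taken per overlap), so ``|ccf| <= 1``
    everywhere by Cauchy-Schwarz and ``ccf(0) == 1`` when ``x is y``.
    Positive lag means ``y`` lags ``x``.  Returns ``(lags_s, ccf)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    fs = float(sampling_rate)
    L = int(round(max_lag * fs))
    n = len(x)
    if n <= 2 * L:
        raise ValueError("traces must be longer than 2 * max_lag")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant trace: cross-correlation undefined")

    # raw lagged products via FFT: full[n - 1 + k] = sum_t x[t] * y[t + k]
    full = signal.correlate(y, x, mode="full", method="fft")
    k = np.arange(-L, L + 1)
    s_xy = full[n - 1 + k]
    m = (n - np.abs(k)).astype(float)

    # per-lag segment sums from prefix sums: for k >= 0 the overlap is
    # x[0:n-k] against y[k:n]; for k < 0 it is x[-k:] against y[0:n+k]
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    kp = np.clip(k, 0, None)          # shift of y
    kn = np.clip(-k, 0, None)         # shift of x
    s_x = cx[n - kp] - cx[kn]
    s_y = cy[n - kn] - cy[kp]
    s_xx = cxx[n - kp] - cxx[kn]
    s_yy = cyy[n - kn] - cyy[kp]

    cov = s_xy - s_x * s_y / m
    var_x = np.maximum(s_xx - s_x ** 2 / m, 0.0)
    var_y = np.maximum(s_yy - s_y ** 2 / m, 0.0)
    denom = np.sqrt(var_x * var_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        ccf = np.where(denom > 0, cov / denom, 0.0)
    return k / fs, ccf


def _lowess_pass(lags, ccf, k, robust_w):
    """One locally weighted linear-regression pass over all points."""
    n = len(lags)
    out = np.empty(n)
    half = k // 2
    for i in range(n):
        lo = min(max(i - half, 0), n - k)
        hi = lo + k
        x = lags[lo:hi]
        y = ccf[lo:hi]
        d = np.abs(x - lags[i])
        dmax = d.max()
        w = (1.0 - np.minimum(d / dmax, 1.0) ** 3) ** 3 if dmax > 0 else np.ones(k)
        w = w * robust_w[lo:hi]
        sw = w.sum()
        if sw <= 0:
            out[i] = y[d.argmin()]
            continue
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx > 0:
            b = (w * (x - xm) * (y - ym)).sum() / sxx
            out[i] = ym + b * (lags[i] - xm)
        else:
            out[i] = ym
    return out


def lowess_smooth(lags, ccf, span: float = 0.01) -> np.ndarray:
    """Lowess smoothing of the CCF over the lag axis.

    Locally weighted linear regression with tricube distance weights and
    one bisquare robustness iteration; the window holds ``span`` times the
    number of lag points (nearest neighbours).  Output has the same length
    as the input.
    """
    lags = np.asarray(lags, float)
    ccf = np.asarray(ccf, float)
    n = len(lags)
    if span * n < 3:
        raise ValueError(
            f"lowess window spans fewer than 3 of the {n} lag points; "
            f"use span >= {3.0 / n:.4g}")
    k = min(max(int(round(span * n)), 3), n)
    ones = np.ones(n)
    fit = _lowess_pass(lags, ccf, k, ones)
    resid = ccf - fit
    s = np.median(np.abs(resid))
    if s > 0:
        rw = np.clip(resid / (6.0 * s), -1.0, 1.0)
        rw = (1.0 - rw ** 2) ** 2
        fit = _lowess_pass(lags, ccf, k, rw)
    return fit


def sync_score(recording, params: SyncParams | None = None,
               allow_short: bool = False) -> SyncResult:
    """Full synchronization pipeline on a paired :class:`Recording`.

    Decimation -> Gaussian low-pass -> cross-correlation -> Lowess ->
    first maximum.  Recordings shorter than ``params.min_duration`` raise
    unless ``allow_short`` (then a warning is issued).
    """
    params = params or SyncParams()
    if recording.duration < params.min_duration:
        msg = (f"recording duration {recording.duration:.1f} s is below the "
               f"minimum usable duration {params.min_duration:.0f} s")
        if not allow_short:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    fs = recording.sampling_rate
    ca3, ca1 = recording.ca3, recording.ca1
    fs_a = fs
    if params.analysis_rate < fs:
        frac = Fraction(params.analysis_rate / fs).limit_denominator(1000)
        ca3 = signal.resample_poly(ca3, frac.numerator, frac.denominator)
        ca1 = signal.resample_poly(ca1, frac.numerator, frac.denominator)
        fs_a = fs * frac.numerator / frac.denominator

    ca3 = gaussian_lowpass(ca3, fs_a, params.cutoff)
    ca1 = gaussian_lowpass(ca1, fs_a, params.cutoff)
    lags, ccf = cross_correlation(ca3, ca1, fs_a, params.max_lag)
    smoothed = lowess_smooth(lags, ccf, params.lowess_span)

    peak = smoothed.max()
    candidates = np.flatnonzero(smoothed >= peak - 1e-15)
    best = candidates[np.argmin(np.abs(lags[candidates]))]
    return SyncResult(lags=lags, ccf=ccf, ccf_smoothed=smoothed,
                      score=float(smoothed[best]), score_lag=float(lags[best]),
                      params=params)
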