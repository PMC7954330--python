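# Methods

`fieldsync` simulates paired CA3/CA1 extracellular field-potential
recordings with controlled event statistics, detects epileptiform events in
them, measures CA3–CA1 synchronization as the first maximum of the smoothed
cross-correlation function, and compares conditions with a normality-gated
statistical protocol.  This note records the models, the defaults that
matter, the numerical choices, and what the synthetic data do and do not
represent.

## The recording model

A simulated slice is a pair of voltage traces (mV, default 10 kHz) built
from four ingredients.

**Single epileptiform discharges.**  CA3 discharge onsets follow a renewal
process: a 2 s refractory floor plus an exponential inter-event interval
whose mean is set so the realized rate equals the condition's
`discharge_rate` (default 2.36 min⁻¹).  Durations are drawn from a
truncated normal calibrated so the *post-truncation* mean and SD equal the
nominal 1.07 ± 0.34 s (support ≥ 0.3 s); durations are additionally capped
at 80% of the gap to the next event so successive events stay resolvable.
Peak amplitudes are log-normal (CA3 mean 2.0, SD 1.0 mV — a free parameter;
the source experiments quote no field-discharge amplitude for this
condition).

**Bursts.**  Each slice is a burster with probability `burst_probability`
(0.48).  A bursting slice receives a zero-truncated Poisson number of burst
windows (rate 0.375 min⁻¹, implied by ~45 bursts over 12 bursting slices of
~10 min), each with a calibrated truncated-normal duration (35.61 ±
12.67 s, ≥ 10 s) and an intraburst frequency drawn on [0.23, 1.2] Hz with
calibrated mean 0.52 Hz.  The SD of 0.28 Hz is infeasible on that support
(a uniform distribution there has SD 0.28), so the realized SD is ~0.20 Hz;
the support is what keeps every emitted train groupable by the default
burst detector.  A burst holds `1 + round(f·B)` equally spaced discharges,
the first scaled by the leader factor (2.0) — bursts start with a
large-amplitude field event.  Bursts are set off from background singles by
an 8 s guard interval, and the background renewal process is suspended
inside it.

**CA3→CA1 coupling.**  Every CA3 discharge is copied to CA1 with
probability `1 − coupling_failure_prob` (default failure 0.05), delayed by
5 ms with 2 ms Gaussian jitter (monosynaptic scale; free parameters).  The
CA1 amplitude is the CA3 amplitude times the channel ratio (1.5/2.0) times
a per-event log-normal transfer factor (SD 15%): amplitudes are *shared*
across channels up to this factor, which is what lets near-ideal coupling
reach cross-correlations above 0.9.

**Population spikes and noise.**  Nonsynaptic population spikes (50 ms
biexponential deflections) occur as independent Poisson trains per channel,
placed in quiet stretches.  Each channel receives independent Gaussian
noise low-pass filtered at 100 Hz with SD `noise_sd`.

## Waveforms and the meaning of "duration"

A discharge is rendered as a fast biexponential body (5 ms rise constant,
decay filling the drawn duration) flanked by linear onset/offset skirts of
fixed slope (4 mV/s) plus a small opposite-going rebound lobe.  The skirts
are anchored so the waveform crosses the *detectability floor* —
`0.67 × noise_sd`, which equals half of the default detector's 5×MAD
threshold at that noise level — exactly at the nominal onset and at
`onset + duration`, for every amplitude.  Ground-truth onset/offset are
defined as these crossings.  This makes the drawn duration exactly the
quantity the detector's half-threshold boundaries estimate; without the
anchoring, half-threshold crossing times depend logarithmically on
amplitude and pooled duration recovery is biased by 5–10%.

## Event detection

Detection operates per channel on a polyphase-decimated copy (1 kHz) of the
trace:

1. smoothing with a 10 Hz Gaussian (gain 0.5 at cutoff) — matched to the
   ~1 s discharge scale, it reduces the band-limited noise ~3.7× so the
   5×MAD threshold sits well below the event amplitudes;
2. baseline: a polarity-adaptive running quantile flags candidate event
   samples, then the baseline is a 5 s running median over the
   discharge-free remainder (so dense bursting neither drags the baseline
   nor inflates the threshold), and sigma is the MAD-based deviation of
   that remainder;
3. supra-threshold excursions of |trace − baseline| are merged across gaps
   < 0.2 s; boundaries are placed at the half-threshold crossings.
   Brief or very-high-SNR events use a peak-outward walk on the raw trace
   with an interior-side line refit (exact in the noiseless limit); noisy
   discharges use a symmetric least-squares crossing fit on the raw trace,
   which is unbiased because the template edge is locally linear;
4. classification by duration: < 20 ms discarded, < 0.1 s population
   spike, ≥ 0.2 s discharge, the band in between discarded as
   unclassifiable.

Because the smoothing is matched to discharges, 50 ms population spikes are
attenuated ~3× and only clearly supra-threshold spikes are recovered; no
summary statistic in the package depends on popspike counts.

Bursts are maximal runs of ≥ 4 discharges with consecutive onsets closer
than 4.5 s.  At the default background rate (2.36 min⁻¹ over a 2 s
refractory floor) these values keep the false-burst rate in non-bursting
slices near 2% while grouping trains down to 0.23 Hz; a (3, 4 s) rule would
misclassify ~14% of non-bursting slices as bursting.

The single-discharge rate reported by `summarize_events` divides by the
burst-free observation time (recording duration minus each burst span plus
an 18 s margin, mirroring the generator's guard interval): background
activity is suppressed around bursts, so counting that time would
understate the background rate by ~30% in bursting slices.

## Synchronization score

The pipeline decimates both channels to 1 kHz (polyphase, anti-aliased;
disabled when `analysis_rate` equals the sampling rate), low-pass filters
with a zero-phase Gaussian whose gain is 0.5 at 50 Hz (kernel sigma
`sqrt(ln 2 / 2) / (pi * cutoff)` seconds, truncated at 4 sigma, reflected
edges), computes the cross-correlation function for lags within ±1 s,
smooths it with a Lowess smoother (span 0.01 of the lag points), and
reports the maximum of the smoothed CCF with ties broken toward zero lag.
Recordings shorter than 300 s are rejected unless explicitly allowed.

Two definitions were genuinely open:

* **Normalization** is per-lag Pearson: each lag's value is the Pearson
  correlation of the two overlapping segments.  This bounds the CCF by 1
  (Cauchy–Schwarz), makes it scale-invariant, and gives exactly 1 at zero
  lag for identical channels.  A global-SD normalization can exceed 1 for
  narrow-band inputs.
* **"First maximum"** is read as the global maximum of the smoothed CCF
  inside the lag window, ties toward the smallest |lag|; on unimodal CCFs
  this coincides with the first local peak from zero lag.

The Lowess smoother is implemented in the package (tricube weights, local
linear fit over the span-fraction nearest neighbours, one bisquare
robustness iteration guarded against a zero residual MAD); it matches
statsmodels to machine precision on non-degenerate inputs, while handling
the degenerate all-zero-residual case that makes statsmodels return an
isolated spike unsmoothed.

The whole CCF is computed on the full record (no windowing), matching the
reported usage of ~600 s records.

**Calibration.**  With all other defaults fixed, the default noise SD was
calibrated once so that the 25-slice mean synchronization score of the
synchronized preset falls at the observed level: `noise_sd = 0.45 mV`
yields a mean score of ~0.48 (observed 0.47 ± 0.17) while detection F1
stays ≈ 0.99.  This is a statement about the synthetic preset, not about
biology: the score's absolute level in real slices reflects waveform
variability and background activity the generator does not model.

## Condition presets

`synaptic_blockers` encodes the spontaneous-discharge statistics above.
`low_ca` has no coupled discharges — only independent population-spike
trains per channel (20 min⁻¹, 1.0 mV; free parameters, unquantified in the
source) — and reproduces the desynchronized regime (scores ≈ 0.01–0.05).
`cd2_15um` adds the blockade model: immediate block with probability
0.455, otherwise a latency drawn from a calibrated truncated normal with
mean 4.09 and SD 2.60 min; discharges cease at the block onset and
nonsynaptic population spikes develop afterwards.  `mec_50um` and
`d_tubocurarine_50um` model the application-period steady state as an
immediate block (the latency is only quantified for Cd²⁺).
`surgical_cut` keeps CA3 discharges and abolishes all CA1 coupling.
`atropine_10um`, `mla_100nm` and `dhbe_10um` are no-effect presets
(identical parameters to `synaptic_blockers`).  `bicuculline` and `4ap`
(and their mecamylamine counterparts) are regular-SLA presets: a
near-periodic train at a per-slice frequency (calibrated truncated normal;
0.13 ± 0.07 and 0.36 ± 0.06 Hz) with ~0.5 s events at the quoted per-channel
amplitudes.

The intracellular channel emits one biexponential current transient (2 ms
rise, 20 ms decay) per CA1 discharge, aligned within the coupling jitter.
Peak conductance is drawn so the peak-amplitude distribution at −70 mV
holding (reversal 0 mV) has mean 51.60 and SD 22.71 pA; the current scales
exactly linearly with the driving force and is zero at the reversal
potential before noise.  Recording noise defaults to 14.89 pA — the
observed baseline scatter of amplitudes measured at the reversal potential.

## Statistical protocol

Paired samples: Shapiro–Wilk on the paired differences at alpha 0.05; pass
→ paired t, fail → exact Wilcoxon signed-rank.  Unpaired: both samples
normal → Welch t, otherwise two-sample Kolmogorov–Smirnov (exact when
`n_a·n_b ≤ 10⁴`).  Zero differences are dropped before ranking (count
logged); identical paired samples return a flagged degenerate result with
p = 1.  The exact Wilcoxon null distribution is built by dynamic-programming
convolution over the doubled mid-ranks — identical to enumerating all 2ⁿ
sign assignments, exact under ties — for n ≤ 25, with a continuity- and
tie-corrected normal approximation above.  Alpha is 0.05 throughout,
configurable.

## Experiments and determinism

`run_experiment` models within-slice drug application: each slice is two
consecutive segments (control preset, application preset) sharing
slice-level latent traits (bursting propensity and an overall amplitude
factor), scored and compared pairwise.  Every random draw descends from a
single integer seed through `numpy.random.SeedSequence` with the slice
index as spawn key, so identical configurations reproduce every sample
bit-for-bit; the provenance block written with each report suffices to
regenerate it.

## Problem sizes

The package's consistency checks use: 200 slices × 10 min for
discharge-statistic recovery (pooling ~4,000 events and ~360 bursts;
acceptance within three standard errors of the recovered estimate), 200
simulated Cd²⁺ applications for the block model, ≥ 200 events for the
synaptic-current amplitude, 20 slices for the SLA frequency, 50 seeds per
level for coupling-monotonicity checks, and 2,000 null replicates for the
5%-level calibration of the gated paired test.  Property checks that are
analytically exact (CCF oracle equivalence, filter gains, signed-rank
enumeration) run at small sizes.

## Known limitations

* The generator emulates event statistics, not biophysics: no field
  morphology variability beyond amplitude/duration draws, no drift or line
  noise, no inter-channel noise correlation, no receptor kinetics.  Passing
  recovery tests show generator/detector consistency, not detector
  performance on real recordings.
* The absolute synchronization level is calibrated through the noise term;
  in real data the sub-unity score has different (structured) sources.
* Population-spike detection is deliberately insensitive (see above).
* Whether the 48% bursting fraction is a fixed per-slice trait or a
  time-varying state is unknown; it is modelled as a fixed trait.
* The Shapiro–Wilk gate alpha (0.05) and the exactness of small-n
  signed-rank p-values are conventional choices where the source protocol
  is silent.
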