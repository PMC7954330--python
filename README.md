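# fieldsync

Simulation and synchronization analysis of paired CA3/CA1 hippocampal
field-potential recordings.

In hippocampal slices perfused with AMPA, NMDA and GABA-A receptor
antagonists, spontaneous epileptiform discharges still appear — and appear
*synchronously* — in areas CA3 and CA1, a synchrony attributable to
nicotinic cholinergic transmission.  Quantifying that observation takes
three ingredients: detection of discharges, bursts and population spikes in
noisy extracellular traces; a synchronization statistic between the paired
channels; and a small-sample statistical protocol for drug
control-vs-application comparisons.  `fieldsync` implements all three as a
reusable, fully seeded pipeline, together with a synthetic dual-channel
recording generator whose condition presets encode the measured event
statistics of each pharmacological condition (synaptic-blockers aCSF,
low-Ca²⁺, Cd²⁺, surgical CA3/CA1 separation, cholinergic antagonists,
bicuculline- and 4-AP-induced seizure-like activity).  It is written for
slice electrophysiologists and methods developers who want a
ground-truth-annotated testbed for epileptiform event detection and
synchronization measurement.

## The statistic at the core

For a paired recording (x = CA3, y = CA1), both channels are filtered with
a zero-phase Gaussian low-pass with gain ½ at f_c = 50 Hz,

  G(f) = exp(−2π²σ²f²),  σ = √(ln 2 / 2) / (π f_c),

then the per-lag Pearson cross-correlation function is computed for lags
|τ| ≤ 1 s,

  r(τ) = corr( x(t), y(t + τ) )  over the overlapping samples,

smoothed with a Lowess smoother (tricube local linear regression, span
0.01, one robustness iteration), and the synchronization score is the
first maximum of the smoothed CCF:

  CC = max_τ r̃(τ),  with ties broken toward the smallest |τ|.

Identical channels give CC = 1 at τ = 0; independent channels give CC ≈ 0.
Condition comparisons use mean ± SD summaries with a normality-gated test:
Shapiro–Wilk on the paired differences, then a paired t-test if normal,
otherwise an exact Wilcoxon signed-rank test (full sign-assignment null
distribution for n ≤ 25); unpaired comparisons use Welch's t or the
two-sample Kolmogorov–Smirnov test.  p < 0.05 is considered significant.

## Worked example

Simulate one slice under synaptic-blockers aCSF, detect its events, and
score CA3–CA1 synchronization:

```python
import fieldsync as fs

spec = fs.make_condition("synaptic_blockers")
rec, truth = fs.simulate_recording(spec, duration=600.0, seed=42)

table = fs.group_bursts(fs.detect_events(rec.ca3, rec.sampling_rate,
                                         channel="CA3"))
summary = fs.summarize_events(table, rec.duration, channel="CA3")
print(f"singles: n={summary.n_events}, duration "
      f"{summary.mean_duration:.2f} ± {summary.sd_duration:.2f} s, "
      f"rate {summary.rate:.2f}/min, bursts={summary.n_bursts}")

result = fs.sync_score(rec)
print(f"sync score {result.score:.2f} at lag {result.score_lag*1000:.0f} ms")
```

```
singles: n=26, duration 1.08 ± 0.26 s, rate 2.60/min, bursts=0
sync score 0.28 at lag 11 ms
```

This slice drew no bursts; its 26 single discharges average 1.08 s — the
generator encodes 1.07 ± 0.34 s — and the synchronization score of 0.28
sits at the low end of the spread observed for the synchronized condition
(0.47 ± 0.17 across slices), with the CCF peaking within ~10 ms of the
CA3→CA1 conduction delay.  A full drug experiment
(paired control/application cohorts, Table-style report) runs via

```sh
fieldsync run --config experiment.yaml
```

and single stages via `fieldsync simulate | detect | sync | compare`
(see `fieldsync --help`).

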