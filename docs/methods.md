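# Methods

## Signal model

Each simulated channel is

```
x_i(t) = b_i(t) · e_i(t) + s_i(t) + z_i(t)
```

passed through a causal model of the acquisition chain, where `b_i` is
background activity, `e_i` a multiplicative depression envelope, `s_i` the
sum of slow-potential templates, and `z_i` seizure spike trains.

**Background.** Band-limited 1/f^α noise (α = 1, band 0.5–45 Hz),
normalized to a time-domain RMS of 0.05 mV per channel. No background
spectrum or amplitude is reported for the original recordings, so these are
conventions: only *relative* depression of activity matters to every
downstream computation, and the detection thresholds are expressed relative
to the pre-impact baseline. An optional anesthesia-emergence ramp
(amplitude gain decaying linearly to 1, default off except in the sham
scenario) emulates the high-amplitude activity seen on recovery from
anesthesia.

**SD slow potential.** A raised-cosine fall (10 s), a plateau at
−A, and a raised-cosine recovery, parameterized so the full width at half
recovery equals `duration_s` (default 60 s). Terminal SDs hold the plateau
to the end of the record. The template is phenomenological by design; no
ionic or reaction–diffusion model is attempted.

**Propagation.** Electrode coordinates are planar mm relative to bregma
(x lateral, right positive; y anterior positive); the standard layout puts
one screw per parietal bone at (±3, −2) and brainstem wires at (±3, −12),
a planar proxy for their 9 mm-deep insertion. The SD wavefront expands
radially from its origin at `velocity_mm_per_min` (default 4), so channel
onsets lag by Euclidean distance / velocity. Amplitude is constant along
the path (no decay is reported). Cortical geodesics are unknown; planar
Euclidean distance is the documented simplification.

**Amplitude calibration.** The acquisition chain (first-order 0.02 Hz
Butterworth high-pass, 4th-order 100 Hz low-pass, 60 Hz notch with Q = 30,
all causal) distorts slow potentials: a 60 s plateau droops with the ~8 s
high-pass time constant. Reported SD amplitudes are measured on such
filtered traces, so the generator calibrates the injected template
amplitude such that the *post-amplifier* peak negative deflection equals
the requested `amplitude_mv` (the linear chain makes this an exact
per-event scale factor). Defaults: 1.5 mV for impact-induced SDs, 0.26 mV
for electrically triggered SDs.

**Depression.** During a depression interval, the background is multiplied
by `depression_fraction` (default 0.2 for SD-associated spreading
depression, 0.1 for NSD) with 1 s raised-cosine edges. For SD events the
interval starts at each channel's own wave-arrival time and lasts
`depression_duration_s` (default 300 s); for NSD it is identical across all
affected channels. Terminal episodes never restore the background.

**Seizures.** Periodic biphasic spikes (one sine period, 50 ms wide,
default 0.5 mV at 5 Hz). Real post-traumatic seizure morphology is richer;
the events are rare in this setting and only occurrence is analyzed.

**Latency distributions.** The study conditions are summary statistics of
*observed, positive* latencies (SD onset 124 ± 48 s mild / 149 ± 43 s
severe / 104 ± 85 s triggered; NSD onset 47 ± 40 s; NSD→terminal-SD delay
125 ± 77 s). Draws therefore come from a zero-truncated normal whose parent
(μ, σ) are solved numerically so that the **truncated** distribution has
the reported mean and SD; naive truncation of N(47, 40²) at zero would
inflate the mean to ~56 s. Cohort draws are stratified by default (one
inverse-CDF draw per equal-probability bin, jittered and shuffled) so that
a 9–37 recording cohort is representative of the distribution it is meant
to embody; `sampling="iid"` restores independent draws.

## Derived traces and detection

Analysis filtering is zero-phase (forward–backward), unlike the causal
acquisition model, so onset timing carries no filter delay. The derived
traces are the 0.5–45 Hz band-pass (4th-order Butterworth), the power
envelope (squared AC trace, 1 s moving average — the smoothing window is a
convention), and the DC trend (4th-order 0.1 Hz low-pass).

Baselines are taken from the pre-marker segment (the protocol records a
baseline period before impact; the scaled scenarios use 60 s of it).

* **DC shifts:** event where the DC trend stays below
  `baseline − max(k·σ_baseline, 0.1 mV)` for ≥ 10 s (k = 5); onset refined
  back to the last sample within `baseline − max(2σ, 0.02 mV)`; peak
  measured against the baseline mean on a 1 s moving average of the
  *recorded* trace (the 0.1 Hz trend used for thresholding attenuates the
  peak by a few percent); duration from onset to recovery to half peak;
  deflections that never recover are flagged. Only negative deflections are
  considered (SD polarity), and the whole post-marker record is searched —
  late events are not excluded by any latency cutoff.
* **Depressions:** power below `f·P_baseline` (f = 0.25) for ≥ 30 s; the
  interval ends at the first 10 s stretch sustained above `0.5·P_baseline`,
  otherwise it is unrecovered. The residual depth is the median
  √(P/P_baseline) over the interval. The original events were identified by
  visual inspection; these numerical criteria are conventions, exposed as
  parameters.
* **Seizures:** windowed line length (mean |Δx|/Δt over 1 s) above
  3× its baseline for ≥ 10 s, with an absolute floor of 0.2 mV/s so a
  near-silent baseline cannot flag everything.

## Classification

* **NSD** — depressions present on *all* monitored channels with pairwise
  onset lags ≤ θ_sim = 5 s and no DC shift at or before the depression
  onset. θ_sim = 5 s cleanly separates simultaneity from propagation: at
  ≥ 4 mm electrode separation and ≤ 20 mm/min wave speed the minimum
  spreading lag is 12 s. A DC shift counts as "preceding" up to 2 s after
  the depression onset — in an SD the depression trails the slow potential
  change, so the two detected onsets coincide within jitter, whereas a
  terminal SD after NSD starts clearly later.
* **SD** — DC shifts across channels grouped into one wave when their lags
  are compatible with a physiological speed (≥ 2 mm/min over the layout
  diameter); spread is "spreading" when the maximum pairwise lag exceeds
  θ_sim, else "simultaneous" (near-zero bilateral lags are reported as one
  event with per-channel onsets; whether they reflect one wave or multisite
  initiation is left open, as it must be with two electrodes).
* **Terminal SD / outcome** — a DC-shift wave after an unrecovered NSD,
  with activity never returning to ≥ 50% of baseline power by the end of
  the record, is terminal, and the recording is labelled died (cause
  NSD → terminal SD). The acquisition high-pass makes even a terminal DC
  plateau droop back to baseline, so terminality is judged by activity,
  not by the DC trace. The death label is derived solely from the
  electrographic pattern; respiratory data are out of scope.
* **Velocity** — least squares of pairwise distance = v·|lag| through the
  origin (separation/lag for two channels); an optional anchor at a known
  stimulation site with its onset time serves triggered scenarios. All
  onsets equal raises a simultaneity error rather than dividing by zero.

## Statistics

`chi_squared_2x2` implements the Pearson statistic with df = 1 and optional
Yates correction (off by default; both variants clear the p < 0.001 bound
on the brainstem-vs-cortex prevalence table). `fisher_exact_2x2` sums
hypergeometric probabilities ≤ the observed table's over the fixed-margin
support; degenerate margins return p = 1. Both are cross-checked in the
test suite against scipy and, for Fisher, a brute-force enumeration oracle.
t-tests/ANOVA for the assay endpoints are deliberately not re-implemented —
they are standard library calls, not part of this package's contribution.

## Oxidative-stress scoring

* **MitoSOX:** threshold `median + (median − 5th percentile)` with
  percentiles by linear interpolation between order statistics (the rule's
  percentile method is otherwise unspecified; the convention is tested
  against an independent implementation). The comparison is ≥, so an
  all-equal intensity distribution scores every cell high-ROS — a
  documented degenerate case. The threshold scope defaults to per region
  (pooled-per-animal is available); fractions divide by the region's DAPI
  total, and an animal's value is the unweighted mean over its regions
  (the aggregation is not specified in the source protocol; it is exposed
  as a parameter). Fewer than 20 cells triggers a warning, not an error.
* **Antioxidant capacity:** the lag is the linearly interpolated time at
  which absorbance first rises 10% of its total dynamic range above the
  initial plateau (the shift criterion Δ is a convention, exposed as
  `delta_frac`); the standard line is an ordinary least-squares fit and a
  non-positive slope is rejected; sample lags outside the standard range
  are flagged as extrapolation, not errors.
* **2^−ΔΔCT:** ΔCT per sample against the reference gene, ΔΔCT against the
  control-group mean ΔCT, fold = 2^−ΔΔCT; the control group's mean ΔΔCT is
  0 (geometric-mean fold 1) by construction, and any per-sample constant
  CT offset cancels. The underlying CT values of the original assays are
  not published, so their test statistics are not reproducible; only the
  method is implemented, validated on generators with known fold changes.

## Problem sizes and determinism

Scenario defaults use 250 Hz sampling, a 60 s pre-impact baseline and a
600 s post-impact window (extended automatically to cover late events) —
scaled from the full experimental protocol (1 kHz, 1 h baseline, 2 h
follow-up), which remains a configuration away. All randomness flows from
`numpy.random.default_rng(seed)`; a fixed seed gives bit-identical traces,
logs and pipeline reports (the report embeds a config hash, the seed, the
package version and all thresholds).

## What passing tests do and do not show

The generator reproduces the *statistical structure* of the recordings —
event timing, amplitudes on the recorded trace, propagation geometry,
depression depth and recovery, prevalence — on a clean, artifact-free
background. It does not model electrode pops, movement artifact,
non-stationary anesthesia depth, amplitude decay along the propagation
path, negative ultraslow potentials (which require full-band DC
recording), or realistic seizure morphology. Detection results on this
synthetic data therefore demonstrate correctness of the measurement
conventions and classification logic, not robustness to real-world
artifact; the thresholds are exposed precisely so they can be retuned on
real recordings.

Known limitations: EDF files can be read (through mne) but not written —
the lossless interchange format is CSV with a YAML sidecar; depression
interval ends lag true recovery by a few seconds by construction of the
sustained-recovery rule; and the NSD/SD discrimination assumes at least
two recording sites.
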