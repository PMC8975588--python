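# Methods

This note documents the models and procedures implemented in `ehgkit`, the
assumptions behind them, the tunable parameters with their defaults, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the underlying method leaves the design open.

## Signal model and scope

The input is a multichannel surface electrohysterogram: seven monopolar
abdominal electrodes (labelled `E1`..`E7`, electrode *k* addressed by label
`Ek` unless an explicit electrode map is supplied), sampled at a common rate
`fs`, amplitudes in microvolts. Recordings are assumed to be resting-position
intrapartum captures of roughly 30 minutes containing a handful of contraction
bursts — transient, tens-of-seconds episodes of coordinated myometrial
electrical activity — over a quiescent baseline with possible slow wander.
The package does not model or remove maternal ECG, fetal ECG, or motion
artifacts; inputs are expected to be reasonably clean or pre-cleaned.

Time is measured in seconds; intervals are half-open `[start, end)` and sample
`i` covers `[i/fs, (i+1)/fs)`, so boundaries are never double-counted.

## Contraction detection

Per channel, the chain is:

1. **Running mean** over a centered window (default 0.5 s, edge windows
   truncated) to suppress sample-scale noise.
2. **Linear detrend** (least-squares line removal) for baseline wander of
   order one.
3. **Teager–Kaiser energy** `y_t = x_t² − x_{t−i}·x_{t+i}` with lag `i`
   configurable, default 1 (the classical operator). Edge samples replicate
   the nearest computed value so lengths are preserved.
4. **Baseline z-score** `z = (y − μ)/σ` with μ, σ taken over an estimated
   quiescent (non-contraction) period. Because true quiescence is unknown
   before detection, the default estimate marks the samples whose smoothed
   energy lies at or below the 0.5 quantile — consistent with bursts occupying
   less than half of a typical recording. The mask is exposed so a caller with
   a known quiet segment can supply it directly.
5. **Gaussian smoothing** with a unit-area kernel, σ = 3.0 s by default
   (reflected boundaries). Bursts last tens of seconds, so seconds-scale
   smoothing preserves them while removing spike noise; 3 s (rather than a
   smaller value) also lets the supra-threshold core of a detection cover most
   of a burst's extent, which matters when detections are compared with
   full-burst annotations by intersection-over-union.
6. **Envelope** as the analytic-signal (Hilbert) modulus.

Channel envelopes are combined into a single per-sample RMS trace, which is
segmented window by window: a four-minute window slides in one-minute steps
(a shorter record forms a single window; a non-aligned tail gets one final
window flush with the end), and within each window

    threshold = 1.2 · (basal tone + 0.25 · range)

with basal tone the mean of the lowest 10% of window values and range their
max − min. Runs of strictly supra-threshold samples lasting strictly more than
10 s (both comparisons strict) become contractions; detections from
overlapping windows are merged by interval union, and each interval is scored
by the peak combined value inside it. An all-equal window degenerates to
`1.2 · basal` without error, which no sample strictly exceeds — a flat trace
yields no detections.

A Hanning taper of the window values during threshold estimation is available
(`DetectionConfig.taper="hann"`) but off by default: multiplying a window that
is quiet throughout drives the basal-tone estimate toward zero and fires on
the entire window.

Because the z-score removes the amplitude scale and the threshold is
homogeneous of degree one, detection is invariant to rescaling the raw record.

**Known limitation — activity-free signal.** On a window containing no burst,
basal tone and range are both statistics of the noise floor, so the threshold
necessarily sits inside the floor's distribution and the >10 s duration rule
is the only guard. With seconds-scale smoothing, occasional noise ridges
outlast 10 s and are flagged; their scores stay far below burst scores
(roughly an order of magnitude or more), so downstream users of sparse or
activity-free recordings should filter on score. On burst-bearing recordings
— the intended regime — window ranges are burst-dominated and false positives
are rare; the acceptance script measures both the recovery rate and the
false-positive rate on a 30-record synthetic cohort.

## Contraction consistency

For each subject the first contraction is the reference; every contraction
(the reference itself included, scoring 1) receives a similarity coefficient:
the Pearson correlation of the two segments maximized over alignment lags,
where a lag is admissible if the overlap covers at least half of the shorter
segment, the lag with the largest correlation magnitude wins, and ties go to
the smaller |lag|. The signed coefficient at that lag is returned, so an
anti-phase match is reported as negative. Plain zero-lag correlation and
envelope-domain correlation are available as options; raw segments from the
mid-abdomen channel `E3` are the default input — a channel away from the
bipolar electrodes 1, 2, 5, 7 so dominance gain does not leak into the
similarity measure (configurable).

Per-subject coefficients are min–max normalized to [0, 1] (an all-equal list
maps to 1 by convention) and discretized into five equal-width states with
half-open bins and a closed top bin; a coefficient exactly on a bin edge goes
to the higher bin. Consecutive-pair counts pooled over subjects, column-
normalized, give the transition matrix; columns are the source state, so every
observed column sums to 1 (within 1e−12) and unobserved source columns are
zero and flagged.

**Note on normalization.** Min–max normalization is location- and scale-free
within a subject: it makes subjects comparable but erases the absolute
similarity level, so the *state distribution* of a subject with uniformly high
raw correlations can resemble that of a subject with uniformly low ones. The
generator-facing tests therefore check the effect of the consistency knob on
*raw* coefficients, and in the combined risk rule the consistency criterion is
the weaker of the two (see below).

## Fundal dominance

Computed on the *unprocessed* monopolar signals in a differential
configuration: BPU = e1 − e2 localizes upper-segment activity, BPL = e5 − e7
lower-segment activity. Per contraction, both bipolar segments are enveloped
by Hilbert transform (with 5% reflected padding against edge artifacts,
configurable; RMS on the raw bipolar signal is available as an option), the
contraction is split into five equi-temporal regions (remainder samples
handed out one per region starting at region 1, so lengths differ by at most
one sample and the regions exactly partition the interval), and the
low-intensity first and last regions are discarded. For k ∈ {2, 3, 4}:

    D_k = RMS-u_k − RMS-l_k

D_k > 0 labels region k upper-dominant, D_k < 0 lower-dominant; an exact tie
labels it `tie` and is excluded from the majority. The contraction's overall
label is the majority of the three regions; a contraction with no non-tie
region defaults to `lower` (the modal label of normally progressing labor) and
is marked `all_tie`. Dominance is antisymmetric under swapping the two bipolar
series and invariant to common rescaling.

## Risk rule and evaluation

Per subject, two binary criteria (both strict `> 0.5`):

* **consistency flag** — fraction of state transitions whose *destination*
  state is 4 or 5 (an either-endpoint variant is available);
* **dominance flag** — fraction of upper-dominant contractions.

Under the default `dominance_weighted` rule, agreeing flags decide jointly;
on disagreement the dominance flag decides, it being a binary judgement and
hence the more reliable one on a short recording — which makes the final label
always equal the dominance verdict. A `strict_both` variant labels prolonged
only when both flags fire. Evaluation reports the confusion matrix with
"prolonged" as the positive class, plus accuracy, sensitivity, and
specificity; degenerate truths (a class absent) yield NaN for the undefined
metric with a warning. The train/test splitter is subject-level (no subject in
both parts) and deterministic for a fixed seed.

The cohort-level Markov annotation assigns each correlation state the modal
dominance label (`U`/`L`) of the contractions occupying it; ties are reported
as `tie` and unvisited states as `unobserved`.

## Synthetic data generator

The generator emulates the statistical structure of the study regime, not the
electrophysiology: 7 channels, 20 Hz (a typical surface-EHG rate; the rate is
configurable and always explicit), 30 minutes, burst rate drawn uniformly from
2–5 per 10 minutes, burst durations uniform 30–90 s, bursts separated by at
least 30 s and 10 s from the record edges, placed uniformly in the remaining
slack. Each burst is band-limited Gaussian noise (0.1–0.8 Hz, a modelling
choice) under a Hanning amplitude envelope, scaled so the burst-interval RMS
is `burst_rms_gain` (default 6) times the baseline noise RMS (default 5 µV;
when the generator is run noise-free the 5 µV reference still anchors the
absolute scale). Baseline is white Gaussian noise plus per-channel slow
sinusoidal wander (3 µV, 0.003–0.02 Hz).

Two knobs map to the analysis targets:

* `consistency_rho` — burst waveform = ρ·shared template + (1−ρ)·fresh noise,
  so ρ controls how strongly later bursts correlate with the first (design
  correlation ρ²/(ρ² + (1−ρ)²));
* `dominance_gamma` — channels E1–E2 carry the burst with gain γ, channels E5
  and E7 with gain 1, so BPU/BPL RMS ≈ γ and γ > 1 makes bursts
  upper-dominant. Each channel also receives an independent burst component
  (mixing weight 0.35); without it the bipolar differences would cancel
  exactly.

Cohorts use profile defaults of ρ = 0.9, γ = 0.5 (normal progress) and
ρ = 0.3, γ = 2.0 (prolonged/arrested progress); per-subject seeds derive from
one master seed, so every record is bit-reproducible.

What the generator does **not** contain — propagation/conduction structure,
maternal/fetal ECG, electrode motion, amplitude nonstationarity within a
burst, inter-subject anatomical variability — bounds what passing tests show:
they validate the algorithmic chain and its sensitivity to the designed
effects, not clinical performance on real recordings.

## Numerical and I/O choices

* Length-preserving transforms throughout (truncated/replicated/reflected
  edges) so interval times align with raw-sample times.
* Similarity is computed with FFT-based sliding sums; variances are clipped at
  zero before the square root and alignments with undefined correlation
  (constant overlap) are excluded. Constant full segments are an error.
* CSV is the canonical record format (header row of channel labels, one
  column per channel, `%.6f`), with the sampling rate in a `.meta.json`
  sidecar or supplied explicitly — a missing rate is an error, never a
  default. EDF support is a minimal in-package 16-bit implementation (single
  data record, fixed header date for byte-reproducibility); round-trip
  resolution is the physical range / 65535.
* Annotations are TSV rows `subject_id, start_s, end_s, label`; inverted or
  negative intervals are rejected on read.
* Results bundles are JSON with sorted keys and no timestamps, so identical
  inputs produce byte-identical files; the schema is versioned.
* Problem sizes in the test suite and acceptance script (30-record detection
  cohorts, 20 + 20 end-to-end cohorts, 50-case oracle sweeps) were chosen to
  make the measured rates stable at a few-percent resolution.

## Known limitations

* The dynamic threshold presumes contraction activity in the analysis window;
  see the detection section for behavior on activity-free signal.
* Min–max normalization makes the consistency states scale-free per subject,
  limiting the consistency criterion's discriminative power on its own; the
  combined rule leans on dominance by construction.
* Dominance requires electrodes 1, 2, 5, 7 to be mapped; records lacking them
  error by electrode name.
* The EDF writer targets interchange of this package's own records (one
  common sampling rate, 16-bit), not the full EDF+ feature set.
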