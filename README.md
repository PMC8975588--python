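# ehgkit

Analysis of intrapartum **electrohysterography (EHG)** — the uterine
electrical activity recorded noninvasively from abdominal surface electrodes —
aimed at flagging the risk of **prolonged/arrested labor** at the start of the
active phase (3–4 cm cervical dilatation). It is written for biomedical-signal
researchers and perinatal-engineering groups who work with multichannel
surface-EHG and need a reproducible, scriptable implementation of an
energy-based contraction detector and of downstream contraction-quality
features.

## What it computes

**Contraction detection.** Each monopolar channel x_t is denoised (running
mean), detrended, and passed through the Teager–Kaiser energy operator

    y_t = x_t² − x_{t−i}·x_{t+i}          (lag i = 1 by default)

then standardized against a quiescent baseline period t_nc,

    z_t = (y_t − μ_{y,t_nc}) / σ_{y,t_nc},

Gaussian-smoothed, and enveloped (analytic-signal modulus). Channel envelopes
are combined into one RMS trace, segmented with a sliding four-minute window
(one-minute slide) and a dynamic threshold

    T = 1.2 · (basal tone + 0.25 · range),   basal tone = mean of the lowest 10%,

keeping runs of supra-threshold samples lasting more than 10 s.

**Contraction consistency.** Every contraction is correlated against the
subject's first contraction (Pearson correlation maximized over alignment
lags). Per-subject coefficients are min–max normalized to [0, 1] and binned
into five equal states (state 1 = [0, 0.2), …, state 5 = [0.8, 1]); pooled
consecutive-pair counts give a 5×5 column-stochastic transition matrix
(columns = source state).

**Fundal dominance.** From the unprocessed signals, bipolar channels
BPU = e1 − e2 (upper uterine segment) and BPL = e5 − e7 (lower segment) are
enveloped by Hilbert transform over each contraction, split into five
equi-temporal regions, and compared by RMS in regions 2–4:
D_k = RMS-u_k − RMS-l_k. Positive D means upper-segment dominance; the
contraction's label is the majority over the three regions.

**Risk rule.** A subject leans prolonged if more than 50% of state transitions
land in state 4 or 5 (consistency criterion) and/or more than 50% of
contractions are upper-dominant (dominance criterion). When the two criteria
disagree, the binary dominance judgement decides.

Since clinical recordings of this kind are not publicly deposited, the package
ships a first-class synthetic-data generator (`ehgkit.synth`) that emulates
the recording regime — 30-minute, 7-channel records with 2–5 contraction
bursts per 10 minutes — with controllable burst consistency (ρ) and
upper/lower amplitude dominance (γ), plus exact ground truth.

## Worked example

```python
from ehgkit import SynthSpec, generate_record, detect_contractions
from ehgkit.pipeline import run_pipeline
from ehgkit.synth import generate_cohort

record, truth = generate_record(SynthSpec(seed=7))
found = detect_contractions(record)
print(f"{record.subject_id}: {len(truth.intervals)} designed bursts, {len(found)} detected")

cohort = generate_cohort(3, 3, seed=1)
truths = {r.subject_id: t.cohort_label for r, t in cohort}
bundle = run_pipeline([r for r, _ in cohort], truth_labels=truths)
for s in bundle["subjects"]:
    print(f"{s['subject_id']}: {s['n_contractions']} contractions, "
          f"upper-dominant {s['fraction_upper_dominant']:.2f} "
          f"-> {s['predicted_label']}")
```

prints

```
synth-7: 13 designed bursts, 13 detected
normal_01: 11 contractions, upper-dominant 0.00 -> normal
normal_02: 11 contractions, upper-dominant 0.00 -> normal
normal_03: 15 contractions, upper-dominant 0.00 -> normal
prolonged_01: 13 contractions, upper-dominant 0.85 -> prolonged
prolonged_02: 12 contractions, upper-dominant 0.92 -> prolonged
prolonged_03: 11 contractions, upper-dominant 1.00 -> prolonged
```

All 13 designed bursts of the first record are recovered, and the six-subject
cohort is labelled perfectly: normal-profile subjects (γ = 0.5) show
lower-segment dominance, prolonged-profile subjects (γ = 2.0) upper-segment
dominance, and the rule follows the dominance criterion.

The same pipeline is available from the shell:

```bash
ehg simulate --profile prolonged --n 3 --seed 1 --out sim/
ehg detect --in sim/prolonged_01.csv --out contractions.tsv
ehg run --records sim/ --out bundle.json
ehg init-config            # dump every tunable default to YAML
```

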