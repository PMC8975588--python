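"""Synthetic multichannel EHG with ground truth.

The generator emulates the statistical structure of an intrapartum surface-EHG
recording at 3–4 cm dilatation: ~30 minutes of 7-channel signal containing
2–5 contraction bursts per 10 minutes, each burst 30–90 s of band-limited
(0.1–0.8 Hz) activity under a Hanning amplitude envelope, riding on Gaussian
sensor noise and slow baseline wander.  Two knobs map to the quantities the
analysis measures:

* ``consistency_rho`` — each burst's waveform is the mixture
  ``rho·shared_template + (1−rho)·fresh noise``, so high rho makes successive
  bursts correlate strongly with the first (consistent contractions);
* ``dominance_gamma`` — channels mapped to electrodes 1–2 carry the burst with
  gain gamma while electrodes 5 and 7 carry gain 1, so the bipolar pair
  BPU = e1−e2 vs BPL = e5−e7 sees an upper/lower RMS ratio of gamma
  (gamma > 1 ⇒ upper-dominant bursts).

Each channel also receives its own independent burst component (mixing weight
``channel_mix``); without it the bipolar differences would cancel exactly.
All randomness flows from a single seed through per-subject and per-burst
substreams, so records are bit-reproducible.  This is a statistical stand-in,
not a biophysical myometrium model: there is no propagation, no maternal ECG
and no motion artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .dominance import LOWER, UPPER
from .io import ContractionInterval, ContractionSet, EHGRecord

__all__ = ["SynthSpec", "GroundTruth", "generate_record", "generate_cohort", "PROFILES"]

# burst amplitude reference when the record is generated noise-free
_REFERENCE_BASELINE_RMS_UV = 5.0


@dataclass(frozen=True)
class SynthSpec:
    """Study-regime parameters of one synthetic recording."""

    n_channels: int = 7
    fs: float = 20.0
    duration_s: float = 1800.0
    contractions_per_10min: tuple[float, float] = (2.0, 5.0)
    burst_duration_s: tuple[float, float] = (30.0, 90.0)
    burst_band_hz: tuple[float, float] = (0.1, 0.8)
    burst_rms_gain: float = 6.0
    consistency_rho: float = 0.9
    dominance_gamma: float = 0.5
    wander_amplitude_uv: float = 3.0
    noise_rms_uv: float = 5.0
    channel_mix: float = 0.35
    min_gap_s: float = 30.0
    edge_margin_s: float = 10.0
    n_bursts: int | None = None  # overrides the rate draw when set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("invalid record geometry")
        if not 0 <= self.consistency_rho <= 1:
            raise ValueError("consistency_rho must lie in [0, 1]")
        if self.dominance_gamma <= 0:
            raise ValueError("dominance_gamma must be positive")
        lo, hi = self.burst_duration_s
        if not 0 < lo <= hi:
            raise ValueError("invalid burst duration range")
        if self.burst_rms_gain <= 0 or self.noise_rms_uv < 0:
            raise ValueError("invalid amplitude parameters")


@dataclass
class GroundTruth:
    """Designed truth of a synthetic record."""

    intervals: ContractionSet
    dominance: list[str]
    cohort_label: str
    template_correlations: list[float]
    spec: SynthSpec


PROFILES: dict[str, dict] = {
    "normal": {"consistency_rho": 0.9, "dominance_gamma": 0.5},
    "prolonged": {"consistency_rho": 0.3, "dominance_gamma": 2.0},
}


def _bandlimited_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-RMS zero-phase band-passed Gaussian noise."""
    lo, hi = band
    nyq = fs / 2
    sos = sps.butter(4, (lo / nyq, hi / nyq), btype="bandpass", output="sos")
    # generate with margin so filtfilt edge transients can be trimmed
    margin = max(int(4 * fs / lo), 64)
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * margin))[margin : margin + n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _place_bursts(
    rng: np.random.Generator, spec: SynthSpec
) -> tuple[list[float], list[float]]:
    """Draw burst count, durations and non-overlapping starts (≥ min_gap apart)."""
    if spec.n_bursts is not None:
        n = spec.n_bursts
    else:
        rate = rng.uniform(*spec.contractions_per_10min)  # contractions / 10 min
        n = int(round(rate * spec.duration_s / 600.0))
    if n < 1:
        raise ValueError("spec yields no bursts; increase duration or rate")
    usable = spec.duration_s - 2 * spec.edge_margin_s
    for _ in range(100):
        durations = rng.uniform(*spec.burst_duration_s, size=n)
        slack = usable - durations.sum() - spec.min_gap_s * (n - 1)
        if slack >= 0:
            break
        if spec.n_bursts is not None:
            raise ValueError(
                f"{n} bursts of {spec.burst_duration_s} s cannot fit in "
                f"{spec.duration_s} s with {spec.min_gap_s} s gaps"
            )
    else:
        raise ValueError("could not place the requested bursts; spec too dense")
    cuts = np.sort(rng.uniform(0, slack, size=n))
    starts = [
        spec.edge_margin_s + cuts[j] + durations[:j].sum() + spec.min_gap_s * j
        for j in range(n)
    ]
    return starts, durations.tolist()


def _electrode_index(spec_labels: tuple[str, ...], k: int) -> int | None:
    label = f"E{k}"
    return spec_labels.index(label) if label in spec_labels else None


def generate_record(spec: SynthSpec) -> tuple[EHGRecord, GroundTruth]:
    """Generate one synthetic recording and its designed ground truth."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n_samples = int(round(spec.duration_s * fs))
    labels = tuple(f"E{k + 1}" for k in range(spec.n_channels))

    baseline_rms = spec.noise_rms_uv if spec.noise_rms_uv > 0 else _REFERENCE_BASELINE_RMS_UV
    burst_rms_uv = spec.burst_rms_gain * baseline_rms

    signals = np.zeros((spec.n_channels, n_samples))
    if spec.noise_rms_uv > 0:
        signals += rng.standard_normal(signals.shape) * spec.noise_rms_uv
    if spec.wander_amplitude_uv > 0:
        t = np.arange(n_samples) / fs
        for c in range(spec.n_channels):
            f0 = rng.uniform(0.003, 0.02)
            phase = rng.uniform(0, 2 * np.pi)
            signals[c] += spec.wander_amplitude_uv * np.sin(2 * np.pi * f0 * t + phase)

    starts, durations = _place_bursts(rng, spec)
    max_len = int(round(max(durations) * fs)) + 1
    template = _bandlimited_noise(rng, max_len, spec.burst_band_hz, fs)

    rho, beta = spec.consistency_rho, spec.channel_mix
    upper_idx = [i for k in (1, 2) if (i := _electrode_index(labels, k)) is not None]
    lower_idx = [i for k in (5, 7) if (i := _electrode_index(labels, k)) is not None]

    intervals: list[ContractionInterval] = []
    dominance: list[str] = []
    design_corr = rho**2 / (rho**2 + (1 - rho) ** 2) if rho < 1 else 1.0
    template_correlations: list[float] = []
    for j, (t0, dur) in enumerate(zip(starts, durations)):
        a = int(round(t0 * fs))
        L = int(round(dur * fs))
        fresh = _bandlimited_noise(rng, L, spec.burst_band_hz, fs)
        core = rho * template[:L] + (1 - rho) * fresh
        core_rms = np.sqrt(np.mean(core**2))
        core = core / core_rms if core_rms > 0 else core
        window = np.hanning(L)
        for c in range(spec.n_channels):
            own = _bandlimited_noise(rng, L, spec.burst_band_hz, fs)
            content = np.sqrt(1 - beta**2) * core + beta * own
            shaped = window * content
            rms = np.sqrt(np.mean(shaped**2))
            shaped = shaped / rms * burst_rms_uv if rms > 0 else shaped
            gain = spec.dominance_gamma if c in upper_idx else 1.0
            signals[c, a : a + L] += gain * shaped
        intervals.append(ContractionInterval(t0, t0 + dur, source="truth"))
        dominance.append(
            UPPER if spec.dominance_gamma > 1 else LOWER if spec.dominance_gamma < 1 else "tie"
        )
        template_correlations.append(1.0 if j == 0 else design_corr)

    record = EHGRecord(
        signals,
        fs=fs,
        channel_labels=labels,
        subject_id=f"synth-{spec.seed}",
        metadata={"synthetic": True, "cohort_label": _label_for_gamma(spec)},
    )
    truth = GroundTruth(
        intervals=ContractionSet(intervals, record_ref=record.subject_id),
        dominance=dominance,
        cohort_label=_label_for_gamma(spec),
        template_correlations=template_correlations,
        spec=spec,
    )
    return record, truth


def _label_for_gamma(spec: SynthSpec) -> str:
    # the generator's own notion of which clinical profile it is emulating
    return "prolonged" if spec.dominance_gamma > 1 else "normal"


def generate_cohort(
    n_normal: int,
    n_prolonged: int,
    seed: int = 0,
    profiles: dict[str, dict] | None = None,
    base_spec: SynthSpec | None = None,
) -> list[tuple[EHGRecord, GroundTruth]]:
    """Generate a labelled cohort; per-subject seeds derive from the master seed."""
    if n_normal + n_prolonged < 1:
        raise ValueError("cohort must contain at least one subject")
    profiles = profiles or PROFILES
    base = base_spec or SynthSpec()
    rng = np.random.default_rng(seed)
    plan = ["normal"] * n_normal + ["prolonged"] * n_prolonged
    child_seeds = rng.integers(0, 2**31 - 1, size=len(plan))
    out = []
    counters = {"normal": 0, "prolonged": 0}
    for profile, child in zip(plan, child_seeds):
        counters[profile] += 1
        spec = replace(base, seed=int(child), **profiles[profile])
        record, truth = generate_record(spec)
        record.subject_id = f"{profile}_{counters[profile]:02d}"
        record.metadata["cohort_label"] = profile
        truth.cohort_label = profile
        truth.intervals.record_ref = record.subject_id
        out.append((record, truth))
    return out
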