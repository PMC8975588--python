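"""Contraction detection from multichannel EHG via the Teager–Kaiser energy operator.

The per-channel chain is: running-mean denoising → linear detrend → TKEO
(``y_t = x_t² − x_{t−i}·x_{t+i}``) → z-scoring against a quiescent-period
baseline → Gaussian smoothing → analytic-signal envelope.  Channel envelopes
are combined into a single root-mean-square trace, which is segmented with a
sliding-window dynamic threshold::

    threshold = 1.2 * (basal tone + 25% of the signal range)

where the basal tone is the mean of the lowest 10% of windowed values, the
window is four minutes long and slides by one minute, and runs of
supra-threshold samples lasting more than 10 s are emitted as contractions.

All transforms are length-preserving (edges replicated or reflected) so that
interval times line up with raw-sample times.  Because the energy trace is
z-scored, detection is invariant to rescaling the raw record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .io import ContractionInterval, ContractionSet, EHGRecord, merge_intervals

logger = logging.getLogger("ehgkit")

__all__ = [
    "DetectionConfig",
    "EnergyTrace",
    "TraceStage",
    "running_mean",
    "detrend_linear",
    "tkeo",
    "estimate_baseline_mask",
    "zscore_energy",
    "gaussian_smooth",
    "envelope",
    "combine_channels",
    "dynamic_threshold",
    "segment_contractions",
    "detect_contractions",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detection chain.

    The threshold constants (multiplier 1.2, 25% range fraction, 10% basal
    quantile, 10 s minimum duration, 4 min window, 1 min slide) define the
    segmentation rule; the filter parameters (running-mean window, Gaussian σ,
    TKEO lag) control pre-conditioning and default to values that preserve
    tens-of-seconds contraction bursts while suppressing sample-scale noise.
    """

    running_mean_window_s: float = 0.5
    tkeo_lag: int = 1
    gaussian_sigma_s: float = 3.0
    window_len_s: float = 240.0
    window_slide_s: float = 60.0
    threshold_multiplier: float = 1.2
    range_fraction: float = 0.25
    basal_quantile: float = 0.10
    min_duration_s: float = 10.0
    # quantile of the smoothed energy trace used as the automatic estimate of
    # the quiescent (non-contraction) baseline period for z-scoring
    baseline_quantile_for_z: float = 0.5
    # optional Hanning taper of window values during threshold estimation
    taper: str = "none"  # "none" | "hann"

    def __post_init__(self) -> None:
        for name in ("running_mean_window_s", "gaussian_sigma_s", "window_len_s",
                     "window_slide_s", "min_duration_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("basal_quantile", "baseline_quantile_for_z"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.tkeo_lag <= 0:
            raise ValueError("tkeo_lag must be a positive sample count")
        if self.threshold_multiplier <= 0 or not 0 <= self.range_fraction <= 1:
            raise ValueError("invalid threshold parameters")
        if self.taper not in ("none", "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")


class TraceStage(str, Enum):
    raw_tkeo = "raw_tkeo"
    zscored = "zscored"
    smoothed = "smoothed"
    envelope = "envelope"


@dataclass
class EnergyTrace:
    """Per-sample energy series at a given stage of the chain."""

    values: np.ndarray
    fs: float
    stage: TraceStage = TraceStage.raw_tkeo
    baseline_mu: float | None = None
    baseline_sigma: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage != TraceStage.raw_tkeo and not (self.baseline_sigma or 0) > 0:
            raise ValueError(f"stage {self.stage} requires a positive baseline_sigma")


# ---------------------------------------------------------------------------
# per-channel transforms


def running_mean(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centered moving average with truncated edge windows (length preserving)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot average an empty signal")
    w = max(1, int(round(window_s * fs)))
    if w == 1:
        return x.copy()
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (baseline wander of order 1)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot detrend an empty signal")
    if x.size < 3:
        return x - x.mean()
    return sps.detrend(x, type="linear")


def tkeo(x: np.ndarray, lag: int = 1) -> np.ndarray:
    """Teager–Kaiser energy ``y_t = x_t² − x_{t−lag}·x_{t+lag}``.

    Interior samples follow the operator exactly; the ``lag`` samples at each
    edge replicate the nearest computed value so the output length equals the
    input length.
    """
    x = np.asarray(x, dtype=float)
    if lag <= 0:
        raise ValueError(f"lag must be positive, got {lag}")
    if x.size <= 2 * lag:
        raise ValueError(f"signal of {x.size} samples too short for lag {lag}")
    y = np.empty_like(x)
    y[lag:-lag] = x[lag:-lag] ** 2 - x[: -2 * lag] * x[2 * lag :]
    y[:lag] = y[lag]
    y[-lag:] = y[-lag - 1]
    return y


def estimate_baseline_mask(
    energy: np.ndarray, quantile: float, fs: float | None = None, smooth_sigma_s: float = 2.0
) -> np.ndarray:
    """Boolean mask of putative quiescent (non-contraction) samples.

    True non-contraction periods are unknown before detection, so the baseline
    is taken as the samples whose smoothed energy lies at or below the given
    quantile.  Callers with a known quiet segment can supply their own mask to
    :func:`zscore_energy` instead.
    """
    energy = np.asarray(energy, dtype=float)
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must lie in (0, 1], got {quantile}")
    smooth = (
        gaussian_filter1d(energy, sigma=smooth_sigma_s * fs, mode="reflect")
        if fs is not None and smooth_sigma_s > 0
        else energy
    )
    return smooth <= np.quantile(smooth, quantile)


def zscore_energy(energy: np.ndarray, baseline_mask: np.ndarray, fs: float) -> EnergyTrace:
    """Standardize energy against the mean/SD of the baseline samples only."""
    energy = np.asarray(energy, dtype=float)
    mask = np.asarray(baseline_mask, dtype=bool)
    if mask.shape != energy.shape:
        raise ValueError("baseline mask must match the energy series shape")
    if mask.sum() < 2:
        raise ValueError("baseline mask must select at least 2 samples")
    mu = float(energy[mask].mean())
    sigma = float(energy[mask].std(ddof=0))
    if sigma == 0:
        raise ValueError(
            "zero variance over the baseline mask; supply a different baseline "
            "estimate (e.g. a wider quantile or a manual quiescent segment)"
        )
    return EnergyTrace((energy - mu) / sigma, fs, TraceStage.zscored, mu, sigma)


def gaussian_smooth(trace: EnergyTrace, sigma_s: float) -> EnergyTrace:
    """Convolve with a unit-area Gaussian of SD ``sigma_s`` seconds (reflected edges)."""
    sigma = sigma_s * trace.fs
    values = gaussian_filter1d(trace.values, sigma=sigma, mode="reflect") if sigma > 0 else trace.values.copy()
    return replace(trace, values=values, stage=TraceStage.smoothed)


def envelope(trace: EnergyTrace) -> EnergyTrace:
    """Magnitude of the analytic signal (Hilbert-transform modulus)."""
    values = np.abs(sps.hilbert(trace.values))
    return replace(trace, values=values, stage=TraceStage.envelope)


def combine_channels(envelopes: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-sample RMS across channel envelopes — the trace segmentation runs on."""
    stack = np.asarray([np.asarray(e, dtype=float) for e in envelopes])
    if stack.ndim != 2 or stack.shape[0] == 0:
        raise ValueError("need at least one channel envelope of equal length")
    return np.sqrt(np.mean(stack**2, axis=0))


# ---------------------------------------------------------------------------
# segmentation


def dynamic_threshold(window_values: np.ndarray, config: DetectionConfig = DetectionConfig()) -> float:
    """Threshold ``m·(basal + f·range)`` for one analysis window.

    Basal tone is the mean of the lowest ``basal_quantile`` fraction of the
    (optionally Hanning-tapered) window values; the range is their max − min.
    An all-equal window degenerates to ``m·basal`` (range 0) without error.
    """
    v = np.asarray(window_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty analysis window")
    if config.taper == "hann" and v.size > 1:
        v = v * np.hanning(v.size)
    k = max(1, int(np.ceil(config.basal_quantile * v.size)))
    basal = float(np.sort(v)[:k].mean())
    vrange = float(v.max() - v.min())
    return config.threshold_multiplier * (basal + config.range_fraction * vrange)


def _supra_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def segment_contractions(
    combined: np.ndarray,
    fs: float,
    config: DetectionConfig = DetectionConfig(),
    record_ref: str = "unknown",
) -> ContractionSet:
    """Sliding-window dynamic-threshold segmentation of the combined RMS trace.

    Each four-minute window (slid by one minute; a shorter record forms a
    single window) gets its own threshold; runs of strictly supra-threshold
    samples lasting strictly more than ``min_duration_s`` become contractions.
    Detections from overlapping windows are merged by interval union, and each
    interval is scored by the peak combined value inside it.
    """
    combined = np.asarray(combined, dtype=float)
    n = combined.size
    wlen = int(round(config.window_len_s * fs))
    slide = max(1, int(round(config.window_slide_s * fs)))
    if n <= wlen:
        starts = [0]
        wlen = n
    else:
        starts = list(range(0, n - wlen + 1, slide))
        if starts[-1] != n - wlen:  # tail coverage
            starts.append(n - wlen)

    min_samples = config.min_duration_s * fs  # strict > comparison below
    raw: list[ContractionInterval] = []
    for s0 in starts:
        window = combined[s0 : s0 + wlen]
        thr = dynamic_threshold(window, config)
        logger.debug("%s: window %.0f-%.0f s threshold %.4g",
                     record_ref, s0 / fs, (s0 + wlen) / fs, thr)
        for a, b in _supra_runs(window > thr):
            if (b - a) > min_samples:
                raw.append(
                    ContractionInterval(
                        (s0 + a) / fs,
                        (s0 + b) / fs,
                        score=float(window[a:b].max()),
                        source="tkeo",
                    )
                )
    return merge_intervals(raw, record_ref=record_ref)


# ---------------------------------------------------------------------------
# end-to-end


def channel_envelope(x: np.ndarray, fs: float, config: DetectionConfig) -> EnergyTrace:
    """Run the full single-channel chain: denoise → detrend → TKEO → z-score → smooth → envelope."""
    x = running_mean(x, config.running_mean_window_s, fs)
    x = detrend_linear(x)
    energy = tkeo(x, config.tkeo_lag)
    mask = estimate_baseline_mask(
        energy, config.baseline_quantile_for_z, fs=fs, smooth_sigma_s=config.gaussian_sigma_s
    )
    trace = zscore_energy(energy, mask, fs)
    trace = gaussian_smooth(trace, config.gaussian_sigma_s)
    return envelope(trace)


def detect_contractions(record: EHGRecord, config: DetectionConfig = DetectionConfig()) -> ContractionSet:
    """Detect contractions on a multichannel record (deterministic for fixed input)."""
    envs = [channel_envelope(ch, record.fs, config).values for ch in record.signals]
    combined = combine_channels(envs)
    return segment_contractions(combined, record.fs, config, record_ref=record.subject_id)
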