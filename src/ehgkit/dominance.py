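"""Upper/lower uterine-segment dominance from bipolar EHG channels.

Activity localized along the vertical (umbilical) axis is obtained in a
differential configuration: the upper bipolar signal BPU is electrode 1 −
electrode 2 and the lower bipolar signal BPL is electrode 5 − electrode 7,
computed on the *unprocessed* monopolar signals.  For each detected
contraction, Hilbert envelopes of BPU and BPL over the contraction are split
into five equi-temporal regions; the low-intensity first and last regions are
discarded and the RMS amplitude of regions 2–4 gives per-region dominance
D_k = RMS-u_k − RMS-l_k.  A positive D means the upper segment dominates that
region; the contraction's overall label is the majority over the three regions.

Exact ties (D == 0) are labelled "tie" and excluded from the majority; an
all-tie contraction defaults to "lower", the modal label of normally
progressing labor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ContractionInterval, EHGRecord

__all__ = [
    "BipolarPair",
    "DominanceResult",
    "bipolar_signals",
    "hilbert_env",
    "equitemporal_regions",
    "region_rms",
    "contraction_dominance",
    "cohort_dominance_fractions",
]

UPPER, LOWER, TIE = "upper", "lower", "tie"
_ANALYZED_REGIONS = (1, 2, 3)  # 0-based indices of regions 2, 3, 4


@dataclass
class BipolarPair:
    """Upper (electrodes 1−2) and lower (electrodes 5−7) difference signals."""

    upper: np.ndarray
    lower: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper and lower bipolar series must have equal length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


@dataclass
class DominanceResult:
    """Per-region RMS amplitudes and dominance for one contraction."""

    rms_upper: tuple[float, float, float]
    rms_lower: tuple[float, float, float]
    D: tuple[float, float, float]
    region_labels: tuple[str, str, str]
    overall: str
    all_tie: bool = False


def bipolar_signals(record: EHGRecord) -> BipolarPair:
    """Build BPU = e1 − e2 and BPL = e5 − e7 from the unprocessed record."""
    upper = record.electrode(1) - record.electrode(2)
    lower = record.electrode(5) - record.electrode(7)
    return BipolarPair(upper, lower, record.fs)


def hilbert_env(x: np.ndarray, pad_fraction: float = 0.05) -> np.ndarray:
    """Analytic-signal modulus with reflected padding against edge artifacts."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short for an envelope")
    pad = int(round(pad_fraction * x.size))
    if pad > 0:
        padded = np.pad(x, pad, mode="reflect")
        return np.abs(sps.hilbert(padded))[pad:-pad]
    return np.abs(sps.hilbert(x))


def equitemporal_regions(n_samples: int, n: int = 5) -> list[slice]:
    """Split ``n_samples`` into ``n`` contiguous near-equal slices.

    Remainder samples are handed out one per region starting from region 1, so
    region lengths differ by at most one sample and the slices exactly
    partition the interval.
    """
    if n_samples < n:
        raise ValueError(f"cannot split {n_samples} samples into {n} regions")
    base, rem = divmod(n_samples, n)
    bounds = [0]
    for k in range(n):
        bounds.append(bounds[-1] + base + (1 if k < rem else 0))
    return [slice(a, b) for a, b in zip(bounds, bounds[1:])]


def region_rms(envelope: np.ndarray, region: slice) -> float:
    seg = np.asarray(envelope, dtype=float)[region]
    if seg.size == 0:
        raise ValueError("empty region")
    return float(np.sqrt(np.mean(seg**2)))


def contraction_dominance(
    pair: BipolarPair,
    interval: ContractionInterval,
    pad_fraction: float = 0.05,
    use_envelope: bool = True,
) -> DominanceResult:
    """Dominance of one contraction from its bipolar envelopes.

    ``use_envelope=False`` computes the region RMS on the raw bipolar signals
    instead of their Hilbert envelopes.
    """
    sl = interval.sample_slice(pair.fs)
    if sl.stop > pair.upper.size:
        raise ValueError(
            f"interval [{interval.start_s},{interval.end_s}) exceeds the record"
        )
    seg_u = pair.upper[sl]
    seg_l = pair.lower[sl]
    if seg_u.size < 10:
        raise ValueError(
            f"contraction of {seg_u.size} samples too short for five regions of ≥ 2 samples"
        )
    env_u = hilbert_env(seg_u, pad_fraction) if use_envelope else np.abs(seg_u)
    env_l = hilbert_env(seg_l, pad_fraction) if use_envelope else np.abs(seg_l)

    regions = equitemporal_regions(seg_u.size, 5)
    rms_u = tuple(region_rms(env_u, regions[k]) for k in _ANALYZED_REGIONS)
    rms_l = tuple(region_rms(env_l, regions[k]) for k in _ANALYZED_REGIONS)
    D = tuple(u - l for u, l in zip(rms_u, rms_l))
    labels = tuple(UPPER if d > 0 else LOWER if d < 0 else TIE for d in D)

    n_up = labels.count(UPPER)
    n_lo = labels.count(LOWER)
    if n_up == n_lo == 0:
        overall, all_tie = LOWER, True  # degenerate: default to the normal-labor mode
    else:
        overall, all_tie = (UPPER if n_up > n_lo else LOWER), False
    return DominanceResult(rms_u, rms_l, D, labels, overall, all_tie)


def cohort_dominance_fractions(results: list[DominanceResult]) -> tuple[float, float]:
    """(fraction upper-dominant, fraction lower-dominant) over contractions."""
    if not results:
        raise ValueError("no dominance results to summarize")
    n_up = sum(r.overall == UPPER for r in results)
    return n_up / len(results), 1 - n_up / len(results)
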