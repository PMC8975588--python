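"""Contraction-consistency analysis via cross-correlation states.

For each subject, the first recorded contraction serves as the reference; every
contraction (the reference included, with self-similarity 1) receives a
similarity coefficient against it.  The similarity is the Pearson correlation
maximized over alignments (the lag whose correlation has the largest magnitude
wins, with overlap required to cover at least half of the shorter segment), so
two identical bursts that merely start at different offsets still score 1.

Per-subject coefficients are min–max normalized to [0, 1] so that subjects with
different absolute similarity levels become comparable, then discretized into
five equal-width states (state 1 = [0, 0.2) … state 5 = [0.8, 1]).  Consecutive
contraction pairs pooled over subjects yield a 5×5 column-stochastic transition
matrix with columns as the source state — the chain's one-step dynamics.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CorrelationSeries",
    "StateSequence",
    "TransitionMatrix",
    "contraction_similarity",
    "normalize_coefficients",
    "assign_state",
    "state_sequence",
    "transition_matrix",
    "correlation_series",
]

N_STATES = 5


def contraction_similarity(
    ref: np.ndarray,
    other: np.ndarray,
    min_overlap_fraction: float = 0.5,
    zero_lag_only: bool = False,
) -> float:
    """Best-alignment Pearson correlation between two contraction segments.

    Scans every relative lag whose overlap spans at least
    ``min_overlap_fraction`` of the shorter segment, computes the Pearson
    correlation of the overlapping parts, and returns the signed coefficient at
    the lag of largest magnitude (ties broken toward zero lag).  With
    ``zero_lag_only`` the segments are compared head-aligned over their common
    prefix, the plain zero-lag Pearson correlation.
    """
    a = np.asarray(ref, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("contraction segments need at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant contraction segment")

    if zero_lag_only:
        n = min(a.size, b.size)
        return _pearson(a[:n], b[:n])

    n, m = a.size, b.size
    min_overlap = max(2, int(np.ceil(min_overlap_fraction * min(n, m))))

    # sliding sums over the overlap at every shift, via correlation with ones
    ones_a, ones_b = np.ones(n), np.ones(m)
    s_ab = sps.correlate(a, b, mode="full", method="auto")
    s_a = sps.correlate(a, ones_b, mode="full", method="auto")
    s_b = sps.correlate(ones_a, b, mode="full", method="auto")
    s_aa = sps.correlate(a**2, ones_b, mode="full", method="auto")
    s_bb = sps.correlate(ones_a, b**2, mode="full", method="auto")
    counts = sps.correlate(ones_a, ones_b, mode="full", method="direct")
    counts = np.rint(counts)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / counts
        var_a = np.clip(s_aa - s_a**2 / counts, 0, None)
        var_b = np.clip(s_bb - s_b**2 / counts, 0, None)
        r = cov / np.sqrt(var_a * var_b)

    # lag of index k is k - (m - 1); restrict to sufficient overlap and defined r
    lags = np.arange(counts.size) - (m - 1)
    valid = (counts >= min_overlap) & np.isfinite(r)
    if not valid.any():
        raise ValueError("no alignment satisfies the minimum-overlap requirement")
    r = np.where(valid, r, 0.0)
    order = np.lexsort((np.abs(lags), -np.abs(r)))  # best |r|, then smallest |lag|
    best = order[0]
    return float(np.clip(r[best], -1.0, 1.0))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for constant overlap")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def normalize_coefficients(raw: list[float] | np.ndarray) -> np.ndarray:
    """Per-subject min–max mapping onto [0, 1]; an all-equal list maps to 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 coefficients to normalize")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


_STATE_EDGES = (0.2, 0.4, 0.6, 0.8)


def assign_state(coef_norm: float) -> int:
    """Equal-width state bins: [0,0.2)→1 … [0.8,1]→5 (top bin closed).

    A coefficient exactly on a bin edge belongs to the higher bin.
    """
    if not 0 <= coef_norm <= 1:
        raise ValueError(f"normalized coefficient {coef_norm} outside [0, 1]")
    return 1 + bisect.bisect_right(_STATE_EDGES, coef_norm)


@dataclass
class CorrelationSeries:
    """Per-subject similarity coefficients; index 0 is the reference itself."""

    subject_id: str
    coefficients_raw: np.ndarray
    coefficients_norm: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.coefficients_raw = np.asarray(self.coefficients_raw, dtype=float)
        if self.coefficients_norm is None:
            self.coefficients_norm = normalize_coefficients(self.coefficients_raw)
        self.coefficients_norm = np.asarray(self.coefficients_norm, dtype=float)
        if np.any((self.coefficients_norm < 0) | (self.coefficients_norm > 1)):
            raise ValueError("normalized coefficients must lie in [0, 1]")


@dataclass
class StateSequence:
    """Ordered correlation states (1..5), one per contraction of a subject."""

    states: list[int]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("empty state sequence")
        if any(not 1 <= s <= N_STATES for s in self.states):
            raise ValueError(f"states must lie in 1..{N_STATES}: {self.states}")

    def __len__(self) -> int:
        return len(self.states)


def state_sequence(series: CorrelationSeries) -> StateSequence:
    return StateSequence(
        [assign_state(c) for c in series.coefficients_norm], subject_id=series.subject_id
    )


def correlation_series(
    subject_id: str,
    segments: list[np.ndarray],
    zero_lag_only: bool = False,
) -> CorrelationSeries:
    """Similarity of every contraction against the subject's first contraction."""
    if len(segments) < 2:
        raise ValueError(f"{subject_id}: need ≥ 2 contractions for a correlation series")
    ref = segments[0]
    raw = [
        contraction_similarity(ref, seg, zero_lag_only=zero_lag_only) for seg in segments
    ]
    return CorrelationSeries(subject_id, np.asarray(raw))


@dataclass
class TransitionMatrix:
    """5×5 state-transition matrix; columns are the source state.

    ``probs[r, c]`` is the probability of moving to state ``r+1`` given the
    current state ``c+1``; every column with at least one observed outgoing
    transition sums to 1, unobserved source columns are zero and listed in
    ``unobserved_sources``.
    """

    counts: np.ndarray
    probs: np.ndarray = field(default=None)  # type: ignore[assignment]
    orientation: str = "columns=source"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_STATES, N_STATES):
            raise ValueError(f"counts must be {N_STATES}x{N_STATES}")
        if self.probs is None:
            totals = self.counts.sum(axis=0, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                self.probs = np.where(totals > 0, self.counts / totals, 0.0)
        self.probs = np.asarray(self.probs, dtype=float)

    @property
    def unobserved_sources(self) -> list[int]:
        return [c + 1 for c in range(N_STATES) if self.counts[:, c].sum() == 0]

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "counts": self.counts.tolist(),
            "probs": [[round(p, 12) for p in row] for row in self.probs.tolist()],
            "unobserved_sources": self.unobserved_sources,
        }


def transition_matrix(sequences: list[StateSequence]) -> TransitionMatrix:
    """Pool consecutive-pair counts over subjects and column-normalize."""
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    for seq in sequences:
        for src, dst in zip(seq.states, seq.states[1:]):
            counts[dst - 1, src - 1] += 1
    if counts.sum() == 0:
        raise ValueError("no transitions observed in any sequence")
    return TransitionMatrix(counts)
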