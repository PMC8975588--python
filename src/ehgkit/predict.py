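"""Threshold rule for prolonged-labor risk and its evaluation.

Two per-subject criteria feed the rule:

* consistency: the fraction of state transitions whose *destination* state is
  4 or 5 — strictly more than 50% leans toward prolonged labor;
* dominance: the fraction of contractions dominant in the upper uterine
  segment — strictly more than 50% leans toward prolonged labor.

Under the default ``dominance_weighted`` rule the two flags decide together
when they agree; on disagreement the dominance flag wins, it being a binary
judgement and therefore the more reliable one on a short recording.  The
``strict_both`` variant labels a subject prolonged only when both flags fire.
Evaluation uses standard confusion-matrix metrics with "prolonged" as the
positive class.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .consistency import N_STATES, StateSequence
from .dominance import LOWER, UPPER

__all__ = [
    "NORMAL",
    "PROLONGED",
    "SubjectFeatures",
    "RiskPrediction",
    "EvaluationReport",
    "consistency_flag",
    "dominance_flag",
    "predict_label",
    "annotate_markov_dominance",
    "evaluate",
    "train_test_split",
]

NORMAL, PROLONGED = "normal", "prolonged"
HIGH_STATES = (4, 5)


@dataclass
class SubjectFeatures:
    """Per-subject inputs to the risk rule."""

    subject_id: str
    state_seq: StateSequence
    dominance_labels: list[str]
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.dominance_labels) != len(self.state_seq):
            raise ValueError(
                f"{self.subject_id}: {len(self.dominance_labels)} dominance labels for "
                f"{len(self.state_seq)} contractions"
            )


@dataclass
class RiskPrediction:
    subject_id: str
    consistency_flag: bool
    dominance_flag: bool
    label: str
    fraction_high_state_transitions: float
    fraction_upper_dominant: float
    rule: str = "dominance_weighted"


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics, "prolonged" positive."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        self.accuracy = (self.tp + self.tn) / total if total else float("nan")
        self.sensitivity = (
            self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")
        )
        self.specificity = (
            self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")
        )

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def consistency_flag(
    seq: StateSequence, endpoint: str = "destination"
) -> tuple[bool, float]:
    """Fraction of transitions landing in state 4 or 5; flag is strictly > 0.5.

    ``endpoint="either"`` counts a transition when either endpoint is a high
    state (an alternative reading of "transitions in state 4 or 5").
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 contractions to count transitions")
    pairs = list(zip(seq.states, seq.states[1:]))
    if endpoint == "destination":
        hits = sum(dst in HIGH_STATES for _, dst in pairs)
    elif endpoint == "either":
        hits = sum(src in HIGH_STATES or dst in HIGH_STATES for src, dst in pairs)
    else:
        raise ValueError(f"unknown endpoint rule {endpoint!r}")
    fraction = hits / len(pairs)
    return fraction > 0.5, fraction


def dominance_flag(labels: list[str]) -> tuple[bool, float]:
    """Fraction of upper-dominant contractions; flag is strictly > 0.5."""
    if not labels:
        raise ValueError("no dominance labels")
    fraction = sum(l == UPPER for l in labels) / len(labels)
    return fraction > 0.5, fraction


def predict_label(
    features: SubjectFeatures,
    rule: str = "dominance_weighted",
    endpoint: str = "destination",
) -> RiskPrediction:
    c_flag, c_frac = consistency_flag(features.state_seq, endpoint=endpoint)
    d_flag, d_frac = dominance_flag(features.dominance_labels)
    if rule == "dominance_weighted":
        # agreeing flags decide jointly; on disagreement the binary dominance
        # judgement outweighs the 5-state consistency one
        label = PROLONGED if d_flag else NORMAL
    elif rule == "strict_both":
        label = PROLONGED if (c_flag and d_flag) else NORMAL
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return RiskPrediction(
        features.subject_id, c_flag, d_flag, label, c_frac, d_frac, rule=rule
    )


def annotate_markov_dominance(cohort: list[SubjectFeatures]) -> dict[int, str]:
    """Modal dominance label per destination correlation state over a cohort.

    Each contraction contributes its dominance label to the state it occupies;
    the modal label ("U"/"L") annotates that state, ties report "tie" and
    states no contraction visits report "unobserved".
    """
    buckets: dict[int, Counter] = {s: Counter() for s in range(1, N_STATES + 1)}
    for feat in cohort:
        for state, dom in zip(feat.state_seq.states, feat.dominance_labels):
            buckets[state][dom] += 1
    out: dict[int, str] = {}
    for state, counter in buckets.items():
        if not counter:
            out[state] = "unobserved"
        elif counter[UPPER] > counter[LOWER]:
            out[state] = "U"
        elif counter[LOWER] > counter[UPPER]:
            out[state] = "L"
        else:
            out[state] = "tie"
    return out


def evaluate(predictions: list[str], truths: list[str]) -> EvaluationReport:
    if len(predictions) != len(truths) or not predictions:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    bad = [l for l in list(predictions) + list(truths) if l not in (NORMAL, PROLONGED)]
    if bad:
        raise ValueError(f"unknown labels {sorted(set(bad))}")
    tp = sum(p == PROLONGED and t == PROLONGED for p, t in zip(predictions, truths))
    fp = sum(p == PROLONGED and t == NORMAL for p, t in zip(predictions, truths))
    tn = sum(p == NORMAL and t == NORMAL for p, t in zip(predictions, truths))
    fn = sum(p == NORMAL and t == PROLONGED for p, t in zip(predictions, truths))
    if tp + fn == 0:
        warnings.warn("no prolonged cases in truth: sensitivity undefined", stacklevel=2)
    if tn + fp == 0:
        warnings.warn("no normal cases in truth: specificity undefined", stacklevel=2)
    return EvaluationReport(tp, fp, tn, fn)


def train_test_split(
    cohort: list[SubjectFeatures], fraction: float = 0.8, seed: int = 0
) -> tuple[list[SubjectFeatures], list[SubjectFeatures]]:
    """Deterministic subject-level split (no subject appears in both parts)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_train = int(round(fraction * len(cohort)))
    if n_train == len(cohort) and fraction < 1:
        n_train -= 1
    train = [cohort[i] for i in sorted(order[:n_train])]
    test = [cohort[i] for i in sorted(order[n_train:])]
    if not test:
        warnings.warn("empty test split", stacklevel=2)
    return train, test
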