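"""End-to-end pipeline: detection → consistency → dominance → risk prediction.

`run_pipeline` is a pure function of (records, config): it detects contractions
on each record, builds the per-subject correlation-state sequence and
dominance labels, applies the risk rule, and pools state transitions into the
cohort transition matrix.  The result is a JSON-serializable bundle with a
versioned schema; serializing the same inputs twice yields identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import consistency as cons
from . import dominance as dom
from . import predict as pred
from .detect import DetectionConfig, detect_contractions
from .io import ContractionSet, EHGRecord

__all__ = ["PipelineConfig", "run_pipeline", "subject_features", "save_bundle"]

logger = logging.getLogger("ehgkit")

BUNDLE_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ConsistencyOptions:
    channel: str = "E3"  # mid-abdomen channel, away from the bipolar electrodes
    zero_lag_only: bool = False
    on_envelope: bool = False


@dataclass(frozen=True)
class DominanceOptions:
    use_envelope: bool = True
    pad_fraction: float = 0.05


@dataclass(frozen=True)
class PredictionOptions:
    rule: str = "dominance_weighted"
    endpoint: str = "destination"


@dataclass(frozen=True)
class PipelineConfig:
    version: str = BUNDLE_SCHEMA_VERSION
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    consistency: ConsistencyOptions = field(default_factory=ConsistencyOptions)
    dominance: DominanceOptions = field(default_factory=DominanceOptions)
    prediction: PredictionOptions = field(default_factory=PredictionOptions)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "detection": DetectionConfig,
            "consistency": ConsistencyOptions,
            "dominance": DominanceOptions,
            "prediction": PredictionOptions,
        }
        kwargs: dict = {}
        for name, klass in sections.items():
            sub = data.pop(name, {})
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
            kwargs[name] = klass(**sub)
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known_top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**data, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def subject_features(
    record: EHGRecord,
    contractions: ContractionSet,
    config: PipelineConfig = PipelineConfig(),
    truth_label: str | None = None,
) -> pred.SubjectFeatures:
    """Correlation states and dominance labels for one subject's contractions."""
    if len(contractions) < 2:
        raise ValueError(
            f"{record.subject_id}: need at least 2 contractions, found {len(contractions)}"
        )
    c_opts = config.consistency
    try:
        channel = record.channel(c_opts.channel)
    except KeyError:
        channel = record.signals[0]
        logger.info(
            "subject %s: channel %s absent, correlating on %s",
            record.subject_id, c_opts.channel, record.channel_labels[0],
        )
    segments = [channel[iv.sample_slice(record.fs)] for iv in contractions]
    if c_opts.on_envelope:
        segments = [dom.hilbert_env(s) for s in segments]
    series = cons.correlation_series(
        record.subject_id, segments, zero_lag_only=c_opts.zero_lag_only
    )
    states = cons.state_sequence(series)

    pair = dom.bipolar_signals(record)
    labels = [
        dom.contraction_dominance(
            pair, iv,
            pad_fraction=config.dominance.pad_fraction,
            use_envelope=config.dominance.use_envelope,
        ).overall
        for iv in contractions
    ]
    return pred.SubjectFeatures(record.subject_id, states, labels, truth_label=truth_label)


def run_pipeline(
    records: list[EHGRecord],
    config: PipelineConfig = PipelineConfig(),
    truth_labels: dict[str, str] | None = None,
) -> dict:
    """Run the full analysis over a cohort and return the results bundle.

    A failure on one subject is recorded (stage and message) without stopping
    the remaining subjects.
    """
    if not records:
        raise ValueError("no records to process")
    truth_labels = truth_labels or {}
    subjects: list[dict] = []
    features: list[pred.SubjectFeatures] = []
    for record in records:
        entry: dict = {"subject_id": record.subject_id}
        try:
            contractions = detect_contractions(record, config.detection)
            entry["n_contractions"] = len(contractions)
            entry["intervals"] = [
                {"start_s": round(iv.start_s, 6), "end_s": round(iv.end_s, 6),
                 "score": round(float(iv.score), 6)}
                for iv in contractions
            ]
            logger.info("subject %s: %d contractions", record.subject_id, len(contractions))
            feats = subject_features(
                record, contractions, config, truth_label=truth_labels.get(record.subject_id)
            )
            prediction = pred.predict_label(
                feats, rule=config.prediction.rule, endpoint=config.prediction.endpoint
            )
        except ValueError as exc:
            entry["error"] = str(exc)
            logger.warning("subject %s failed: %s", record.subject_id, exc)
            subjects.append(entry)
            continue
        features.append(feats)
        entry.update(
            states=feats.state_seq.states,
            dominance_labels=feats.dominance_labels,
            consistency_flag=prediction.consistency_flag,
            dominance_flag=prediction.dominance_flag,
            fraction_high_state_transitions=round(
                prediction.fraction_high_state_transitions, 6
            ),
            fraction_upper_dominant=round(prediction.fraction_upper_dominant, 6),
            predicted_label=prediction.label,
        )
        if record.subject_id in truth_labels:
            entry["truth_label"] = truth_labels[record.subject_id]
        subjects.append(entry)

    bundle: dict = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "config": config.to_dict(),
        "subjects": subjects,
    }
    if features:
        matrix = cons.transition_matrix([f.state_seq for f in features])
        bundle["transition_matrix"] = matrix.to_dict()
        bundle["markov_dominance"] = {
            str(k): v for k, v in pred.annotate_markov_dominance(features).items()
        }
    evaluable = [s for s in subjects if "truth_label" in s and "predicted_label" in s]
    if evaluable:
        report = pred.evaluate(
            [s["predicted_label"] for s in evaluable],
            [s["truth_label"] for s in evaluable],
        )
        bundle["evaluation"] = report.to_dict()
    return bundle


def save_bundle(bundle: dict, path: str | Path) -> None:
    """Serialize a results bundle deterministically (sorted keys, no timestamps)."""
    if bundle.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise ValueError("refusing to write a bundle without a valid schema_version")
    Path(path).write_text(json.dumps(bundle, sort_keys=True, indent=1) + "\n")
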