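"""Data model and I/O for multichannel surface-EHG recordings.

An :class:`EHGRecord` holds the raw monopolar electrode signals (microvolts)
together with the sampling rate and channel labels.  Contraction intervals are
half-open ``[start_s, end_s)`` in seconds; sample index ``i`` covers the time
slice ``[i/fs, (i+1)/fs)``, so interval boundaries never double-count samples.

On-disk formats:

* CSV (canonical): one header row of channel labels, one column per channel.
  The sampling rate travels in a JSON sidecar (``<stem>.meta.json``) or is
  supplied explicitly — it is never silently defaulted.
* EDF: de-facto biosignal interchange format, via :mod:`ehgkit.edf`.
* Annotations: tab-separated ``subject_id  start_s  end_s  label`` rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EHGRecord",
    "ContractionInterval",
    "ContractionSet",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "merge_intervals",
]

DEFAULT_CHANNEL_LABELS = tuple(f"E{k}" for k in range(1, 8))


@dataclass
class EHGRecord:
    """A multichannel EHG recording.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        Unique names, one per channel.  The default monopolar montage is
        ``E1``..``E7``; electrode ``k`` is addressed by label ``Ek`` unless an
        explicit ``electrode_map`` entry in ``metadata`` overrides it.
    """

    signals: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = DEFAULT_CHANNEL_LABELS
    subject_id: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (n_channels, n_samples)")
        if self.signals.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = tuple(self.channel_labels)[: self.signals.shape[0]] or tuple(
            f"E{k + 1}" for k in range(self.signals.shape[0])
        )
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.signals.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError(f"duplicate channel labels: {self.channel_labels}")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r} in {self.channel_labels}") from None
        return self.signals[idx]

    def electrode(self, number: int) -> np.ndarray:
        """Signal of electrode ``number`` via the explicit channel↔electrode map.

        By default label ``Ek`` maps to electrode ``k``; ``metadata["electrode_map"]``
        (``{electrode_number: channel_label}``) overrides this.
        """
        emap: Mapping = self.metadata.get("electrode_map", {})
        label = emap.get(number, emap.get(str(number), f"E{number}"))
        try:
            return self.channel(label)
        except KeyError:
            raise KeyError(
                f"electrode {number} is not mapped: no channel {label!r} "
                f"(labels: {self.channel_labels})"
            ) from None


@dataclass(frozen=True)
class ContractionInterval:
    """Half-open contraction interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    score: float = float("nan")
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(f"invalid interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def sample_slice(self, fs: float) -> slice:
        return slice(int(round(self.start_s * fs)), int(round(self.end_s * fs)))

    def iou(self, other: "ContractionInterval") -> float:
        inter = max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))
        union = self.duration_s + other.duration_s - inter
        return inter / union if union > 0 else 0.0


@dataclass
class ContractionSet:
    """Ordered, non-overlapping contraction intervals for one record."""

    intervals: list[ContractionInterval] = field(default_factory=list)
    record_ref: str = "unknown"

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping intervals [{a.start_s},{a.end_s}) and [{b.start_s},{b.end_s})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]


def merge_intervals(
    intervals: Iterable[ContractionInterval], record_ref: str = "unknown"
) -> ContractionSet:
    """Union of possibly-overlapping intervals; scores combined as the max."""
    ivs = sorted(intervals, key=lambda iv: iv.start_s)
    merged: list[ContractionInterval] = []
    for iv in ivs:
        if merged and iv.start_s <= merged[-1].end_s:
            last = merged[-1]
            merged[-1] = ContractionInterval(
                last.start_s,
                max(last.end_s, iv.end_s),
                score=np.nanmax([last.score, iv.score]),
                source=last.source or iv.source,
            )
        else:
            merged.append(iv)
    return ContractionSet(merged, record_ref=record_ref)


# ---------------------------------------------------------------------------
# record I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "edf"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format='csv' or 'edf'")


def read_record(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
) -> EHGRecord:
    """Read an :class:`EHGRecord` from CSV (+ sidecar) or EDF.

    For CSV the sampling rate must come from the ``.meta.json`` sidecar or the
    ``fs`` argument; a missing rate is an error, never a silent default.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        from . import edf

        signals, rate, labels, meta = edf.read_edf(path)
        return EHGRecord(
            signals,
            fs=rate,
            channel_labels=tuple(labels),
            subject_id=subject_id or meta.get("subject_id", path.stem),
            metadata=meta,
        )
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")

    with open(path) as fh:  # pandas mangles duplicate headers, so check the raw line
        header = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate channel labels in CSV header: {header}")
    frame = pd.read_csv(path)
    labels = tuple(str(c) for c in frame.columns)
    if frame.isna().any().any():
        bad = [c for c in frame.columns if frame[c].isna().any()]
        raise ValueError(f"ragged/missing samples in channel(s) {bad}")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    rate = fs if fs is not None else meta.get("fs")
    if rate is None:
        raise ValueError(
            f"sampling rate for {path.name} not given: supply fs= or a "
            f"{sidecar.name} sidecar with an 'fs' entry"
        )
    return EHGRecord(
        frame.to_numpy(dtype=float).T,
        fs=float(rate),
        channel_labels=labels,
        subject_id=subject_id or meta.get("subject_id", path.stem),
        metadata={k: v for k, v in meta.items() if k not in ("fs", "subject_id")},
    )


def write_record(record: EHGRecord, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        from . import edf

        edf.write_edf(
            path,
            record.signals,
            fs=record.fs,
            labels=record.channel_labels,
            subject_id=record.subject_id,
        )
        return
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    frame = pd.DataFrame(record.signals.T, columns=list(record.channel_labels))
    frame.to_csv(path, index=False, float_format="%.6f")
    sidecar = {"fs": record.fs, "subject_id": record.subject_id}
    sidecar.update({k: v for k, v in record.metadata.items() if _json_safe(v)})
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1) + "\n")


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# annotation I/O

_ANNOT_COLUMNS = ["subject_id", "start_s", "end_s", "label"]


def write_annotations(sets: Mapping[str, ContractionSet], path: str | Path) -> None:
    """Write contraction intervals as TSV rows (subject_id, start_s, end_s, label)."""
    rows = [
        (sid, iv.start_s, iv.end_s, iv.source or "contraction")
        for sid, cset in sets.items()
        for iv in cset
    ]
    frame = pd.DataFrame(rows, columns=_ANNOT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_annotations(path: str | Path) -> dict[str, ContractionSet]:
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _ANNOT_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {missing}")
    out: dict[str, ContractionSet] = {}
    for sid, group in frame.groupby("subject_id", sort=True):
        intervals = []
        for _, row in group.iterrows():
            start, end = float(row["start_s"]), float(row["end_s"])
            if not (0 <= start < end):
                raise ValueError(
                    f"invalid annotation for {sid}: [{start}, {end}) (negative or inverted)"
                )
            intervals.append(
                ContractionInterval(start, end, source=str(row.get("label", "contraction")))
            )
        out[str(sid)] = ContractionSet(intervals, record_ref=str(sid))
    return out
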