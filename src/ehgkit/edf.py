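"""Minimal European Data Format (EDF) reader and writer.

Supports the subset this package needs: continuous recordings with one common
sampling rate, 16-bit samples, written as a single data record spanning the
whole signal.  Amplitudes are linearly quantized between the per-signal
physical min/max, so the round-trip resolution is ``(pmax - pmin) / 65535``.
Header date/time fields are fixed constants so that writing the same record
twice yields byte-identical files.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fit8(value: float) -> str:
    """Render a number into EDF's 8-character ASCII numeric field."""
    for fmt in ("%.8g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        text = fmt % value
        if len(text) <= 8:
            return text
    raise ValueError(f"cannot encode {value!r} in 8 characters")


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    fs: float,
    labels,
    subject_id: str = "unknown",
) -> None:
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] < 1:
        raise ValueError("signals must be a non-empty (n_channels, n_samples) array")
    ns, n_samples = signals.shape
    labels = list(labels)
    if len(labels) != ns:
        raise ValueError(f"{len(labels)} labels for {ns} signals")

    pmins, pmaxs = [], []
    for row in signals:
        lo, hi = float(row.min()), float(row.max())
        if hi <= lo:  # constant channel: open a unit range so the scale is defined
            hi = lo + 1.0
        # widen so the range still contains the data after 8-char ASCII rounding,
        # then quantize against the values as *stored* in the header
        pad = 2e-5 * max(abs(lo), abs(hi), 1.0)
        pmins.append(float(_fit8(lo - pad)))
        pmaxs.append(float(_fit8(hi + pad)))

    header_bytes = 256 + ns * 256
    duration = n_samples / fs
    head = b"".join(
        [
            _pad("0", 8),
            _pad(subject_id, 80),
            _pad("ehgkit recording", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad("1", 8),
            _pad(_fit8(duration), 8),
            _pad(str(ns), 4),
        ]
    )

    def field(values, width):
        return b"".join(_pad(str(v), width) for v in values)

    head += field(labels, 16)
    head += field([""] * ns, 80)  # transducer
    head += field(["uV"] * ns, 8)
    head += field([_fit8(v) for v in pmins], 8)
    head += field([_fit8(v) for v in pmaxs], 8)
    head += field([_DIG_MIN] * ns, 8)
    head += field([_DIG_MAX] * ns, 8)
    head += field([""] * ns, 80)  # prefiltering
    head += field([n_samples] * ns, 8)
    head += field([""] * ns, 32)

    body = bytearray()
    for row, lo, hi in zip(signals, pmins, pmaxs):
        scale = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        digital = np.rint((row - lo) * scale + _DIG_MIN)
        digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
        body += digital.tobytes()
    Path(path).write_bytes(head + bytes(body))


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str], dict]:
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def text(start, width):
        return raw[start : start + width].decode("ascii", errors="replace").strip()

    subject_id = text(8, 80)
    n_records = int(text(236, 8))
    duration = float(text(244, 8))
    ns = int(text(252, 4))
    off = 256

    def signal_field(width, conv=str):
        nonlocal off
        vals = [conv(text(off + i * width, width)) for i in range(ns)]
        off += ns * width
        return vals

    labels = signal_field(16)
    signal_field(80)  # transducer
    signal_field(8)  # physical dimension
    pmins = signal_field(8, float)
    pmaxs = signal_field(8, float)
    dmins = signal_field(8, int)
    dmaxs = signal_field(8, int)
    signal_field(80)  # prefiltering
    nrs = signal_field(8, int)
    signal_field(32)

    if len(set(nrs)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    npr = nrs[0]
    fs = npr / duration

    data = np.frombuffer(raw, dtype="<i2", offset=256 + ns * 256)
    expected = n_records * ns * npr
    if data.size < expected:
        raise ValueError(f"{path}: expected {expected} samples, found {data.size}")
    data = data[:expected].reshape(n_records, ns, npr)
    signals = np.concatenate([data[r] for r in range(n_records)], axis=1).astype(float)
    for k in range(ns):
        scale = (pmaxs[k] - pmins[k]) / (dmaxs[k] - dmins[k])
        signals[k] = (signals[k] - dmins[k]) * scale + pmins[k]
    return signals, fs, labels, {"subject_id": subject_id}
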