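"""Minimal EDF reader/writer for continuous recordings.

Implements the plain EDF profile needed here: one sampling rate for all
channels, int16 samples, 1 s data records.  The true sample count and
montage are stashed in reserved header fields (standard readers ignore
them); shaft assignments ride in the per-signal transducer field.
Written because no EDF library is available in the runtime environment.
"""

from __future__ import annotations

import numpy as np

from .errors import FileFormatError, ValidationError
from .preprocess import ContinuousRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fit8(v: float) -> str:
    """Render a float into <= 8 ASCII chars (EDF numeric header fields)."""
    for fmt in ("%.8g", "%.6g", "%.4g", "%.2g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    return "%8.1e" % v


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str, rec: ContinuousRecording) -> None:
    """Write a recording as EDF (16-bit, shared sampling rate)."""
    fs = rec.sample_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValidationError("EDF writer requires an integer sample rate")
    n_sig = rec.n_channels
    n_samples = rec.n_samples
    n_rec = -(-n_samples // spr)  # ceil

    phys_min, phys_max, scaled = [], [], []
    for ch in range(n_sig):
        x = rec.data[ch]
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        span = hi - lo
        lo, hi = lo - 0.01 * span, hi + 0.01 * span
        # use the values as they will be parsed back, so scaling is exact
        lo, hi = float(_fit8(lo)), float(_fit8(hi))
        if hi <= lo:
            hi = lo + 1.0
        scale = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        dig = np.round((x - lo) / scale).astype(np.int64) + _DIG_MIN
        dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
        pad = n_rec * spr - n_samples
        if pad:
            dig = np.concatenate([dig, np.zeros(pad, dtype="<i2")])
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(dig)

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate X X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad(f"NS={n_samples} MONTAGE={rec.montage}", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_sig), 4))

        shafts = rec.shaft or [""] * n_sig
        for lab in rec.channel_labels:
            f.write(_pad(lab, 16))
        for s in shafts:
            f.write(_pad(f"shaft:{s}" if s else "", 80))
        for _ in range(n_sig):
            f.write(_pad("uV", 8))
        for v in phys_min:
            f.write(_pad(_fit8(v), 8))
        for v in phys_max:
            f.write(_pad(_fit8(v), 8))
        for _ in range(n_sig):
            f.write(_pad(str(_DIG_MIN), 8))
        for _ in range(n_sig):
            f.write(_pad(str(_DIG_MAX), 8))
        for _ in range(n_sig):
            f.write(_pad("", 80))
        for _ in range(n_sig):
            f.write(_pad(str(spr), 8))
        for _ in range(n_sig):
            f.write(_pad("", 32))

        block = np.empty((n_rec, n_sig, spr), dtype="<i2")
        for ch in range(n_sig):
            block[:, ch, :] = scaled[ch].reshape(n_rec, spr)
        f.write(block.tobytes())


def _field(buf: bytes, off: int, n: int, path: str) -> str:
    if off + n > len(buf):
        raise FileFormatError(f"{path}: truncated header at byte offset {off}")
    return buf[off : off + n].decode("ascii", "replace").strip()


def read_edf(path: str, require_channel: str | None = None) -> ContinuousRecording:
    """Read an EDF file into a :class:`ContinuousRecording`.

    Raises :class:`FileFormatError` on truncation (naming the byte
    offset) and on mixed per-channel sampling rates (unsupported).  With
    ``require_channel`` set (e.g. ``"ECG"``), its absence is an error.
    """
    with open(path, "rb") as f:
        raw = f.read()
    if len(raw) < 256:
        raise FileFormatError(f"{path}: truncated header at byte offset {len(raw)}")
    head = raw[:256]
    try:
        n_rec = int(_field(head, 236, 8, path))
        rec_dur = float(_field(head, 244, 8, path))
        n_sig = int(_field(head, 252, 4, path))
    except ValueError as e:
        raise FileFormatError(f"{path}: malformed numeric header field: {e}") from None
    reserved = _field(head, 192, 44, path)

    need = 256 * (1 + n_sig)
    if len(raw) < need:
        raise FileFormatError(f"{path}: truncated header at byte offset {len(raw)}")
    sig = raw[256:need]

    def col(width: int, start: int) -> list[str]:
        return [
            sig[start + i * width : start + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n_sig)
        ]

    off = 0
    labels = col(16, off); off += 16 * n_sig
    transducers = col(80, off); off += 80 * n_sig
    off += 8 * n_sig  # physical dimension
    phys_min = [float(v) for v in col(8, off)]; off += 8 * n_sig
    phys_max = [float(v) for v in col(8, off)]; off += 8 * n_sig
    dig_min = [int(v) for v in col(8, off)]; off += 8 * n_sig
    dig_max = [int(v) for v in col(8, off)]; off += 8 * n_sig
    off += 80 * n_sig  # prefiltering
    spr = [int(v) for v in col(8, off)]; off += 8 * n_sig

    if len(set(spr)) != 1:
        raise FileFormatError(f"{path}: mixed per-channel sample rates are unsupported")
    spr0 = spr[0]
    fs = spr0 / rec_dur

    expect = need + 2 * n_rec * n_sig * spr0
    if len(raw) < expect:
        raise FileFormatError(f"{path}: truncated data at byte offset {len(raw)}")
    dig = np.frombuffer(raw[need:expect], dtype="<i2").reshape(n_rec, n_sig, spr0)

    n_samples = n_rec * spr0
    montage = "referential"
    for tok in reserved.split():
        if tok.startswith("NS="):
            n_samples = min(int(tok[3:]), n_samples)
        elif tok.startswith("MONTAGE="):
            montage = tok[8:]

    data = np.empty((n_sig, n_samples))
    for ch in range(n_sig):
        scale = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
        flat = dig[:, ch, :].reshape(-1)[:n_samples].astype(float)
        data[ch] = (flat - dig_min[ch]) * scale + phys_min[ch]

    shaft = None
    if any(t.startswith("shaft:") for t in transducers):
        shaft = [t[6:] if t.startswith("shaft:") else "" for t in transducers]

    if require_channel is not None and require_channel not in labels:
        raise FileFormatError(
            f"{path}: required channel {require_channel!r} not found "
            f"(channels: {', '.join(labels)})"
        )
    return ContinuousRecording(
        data=data,
        sample_rate=fs,
        channel_labels=labels,
        montage=montage if montage in ("referential", "bipolar") else "referential",
        shaft=shaft,
        provenance=[f"read_edf({path})"],
    )
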