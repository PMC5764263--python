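"""Minimal European Data Format (EDF) writer/reader.

Supports the subset needed here: continuous multichannel recordings with a
single sampling rate, 16-bit samples, physical units of microvolts.  The last
data record is zero-padded when the recording length is not a whole number of
record durations; the true sample count is recovered from the reserved header
field on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise InvalidInputError(f"EDF header field too long: {text!r} ({width})")
    return b.ljust(width)


@dataclass
class EdfData:
    data: np.ndarray  # (n_channels, n_samples), physical units (uV)
    fs: float
    channel_labels: list[str]


def write_edf(path, data: np.ndarray, fs: float, channel_labels) -> None:
    """Write a (n_channels, n_samples) uV array as 16-bit EDF."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise InvalidInputError("data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise InvalidInputError("one label per channel required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise InvalidInputError("EDF writer requires a positive integer sampling rate")
    fs_i = int(round(fs))

    n_records = int(np.ceil(n_samp / fs_i)) if n_samp else 0
    padded = np.zeros((n_ch, n_records * fs_i))
    padded[:, :n_samp] = data

    # symmetric physical range per channel, at least 1 uV to avoid zero span
    phys_max = np.maximum(np.max(np.abs(padded), axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field(f"NSAMP={n_samp}", 44),  # reserved: true sample count
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    header += b"".join(_field(lb, 16) for lb in channel_labels)
    header += b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_field(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_field(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field(str(fs_i), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    # quantize per channel using the header-encoded physical range so the
    # round trip matches what a third-party reader would reconstruct
    enc_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scale = (dig_max - dig_min) / (2 * enc_max)
    digital = np.clip(
        np.rint((padded + enc_max[:, None]) * scale[:, None]) + dig_min,
        dig_min,
        dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * fs_i : (rec + 1) * fs_i]
            fh.write(chunk.tobytes())  # channel-major within a record


def read_edf(path) -> EdfData:
    """Read an EDF file written by :func:`write_edf` (single rate, uV)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    n_records = int(raw[236:244].decode().strip() or 0)
    n_ch = int(raw[252:256].decode().strip())
    reserved = raw[192:236].decode().strip()
    off = 256
    labels = [raw[off + 16 * i : off + 16 * (i + 1)].decode().strip() for i in range(n_ch)]
    off += n_ch * (16 + 80 + 8)
    phys_min = np.array(
        [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)]
    )
    off += 8 * n_ch
    phys_max = np.array(
        [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)]
    )
    off += 8 * n_ch
    dig_min = np.array(
        [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)]
    )
    off += 8 * n_ch
    dig_max = np.array(
        [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)]
    )
    off += 8 * n_ch + 80 * n_ch
    spr = [int(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)]
    if len(set(spr)) > 1:
        raise InvalidInputError("mixed per-signal rates are not supported")
    fs = spr[0] if spr else 0
    off += 8 * n_ch + 32 * n_ch

    body = np.frombuffer(raw[off:], dtype="<i2")
    data = np.zeros((n_ch, n_records * fs))
    per_rec = n_ch * fs
    for rec in range(n_records):
        chunk = body[rec * per_rec : (rec + 1) * per_rec].reshape(n_ch, fs)
        data[:, rec * fs : (rec + 1) * fs] = chunk
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    if reserved.startswith("NSAMP="):
        data = data[:, : int(reserved[6:])]
    return EdfData(data=data, fs=float(fs), channel_labels=labels)
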