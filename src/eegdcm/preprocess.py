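"""Filtering, resampling, epoching and artifact cleaning.

Fixed stage order: band-pass filter -> resample -> epoch -> blink removal ->
block-level amplitude rejection -> bad-channel interpolation.  Epochs are
locked to each block's first dot onset with a half-open sample window
[tmin, tmax); rejection is inclusive at the +-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from . import montage
from .errors import (
    BoundaryError,
    InvalidConfigError,
    UnrecoverableChannelsError,
)
from .synthetic_data import SimulatedRecording, blink_template


@dataclass(frozen=True)
class PreprocConfig:
    band: tuple[float, float] = (0.1, 50.0)
    fs_target: float = 512.0
    epoch_window: tuple[float, float] = (-1.0, 4.0)
    reject_uv: float = 100.0
    blink_removal: str = "template_regression"  # or "none"
    filter_order: int = 4
    flat_ptp_uv: float = 0.2  # flat-channel detector threshold (peak-to-peak)

    def validate(self):
        lo, hi = self.band
        if not 0 < lo < hi:
            raise InvalidConfigError("band must satisfy 0 < low < high")
        if hi >= self.fs_target / 2:
            raise InvalidConfigError("band edge must be below the target Nyquist")
        tmin, tmax = self.epoch_window
        if not tmin < 0 < tmax:
            raise InvalidConfigError("epoch window must straddle the event onset")
        if self.reject_uv <= 0:
            raise InvalidConfigError("reject_uv must be positive")
        if self.blink_removal not in ("template_regression", "none"):
            raise InvalidConfigError("unknown blink_removal mode")


@dataclass
class Epochs:
    data: np.ndarray  # (n_epochs, n_channels, n_samples) uV
    fs: float
    tmin: float
    channel_labels: tuple[str, ...]
    metadata: pd.DataFrame  # block_index, condition, response per epoch
    rejection_log: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs


def bandpass_filter(data: np.ndarray, fs: float, band=(0.1, 50.0), order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    lo, hi = band
    if hi >= fs / 2:
        raise InvalidConfigError("upper band edge must be below Nyquist")
    if lo <= 0 or lo >= hi:
        raise InvalidConfigError("band must satisfy 0 < low < high < Nyquist")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(data, float), axis=-1)


def resample(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased downsampling; output length round(n*fs_out/fs_in)."""
    if fs_out > fs_in:
        raise InvalidConfigError("upsampling is not supported")
    if fs_out == fs_in:
        return np.asarray(data, float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return scipy.signal.resample_poly(np.asarray(data, float), frac.numerator, frac.denominator, axis=-1)


def epoch(
    data: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    window: tuple[float, float],
    channel_labels,
    metadata: pd.DataFrame | None = None,
) -> Epochs:
    """Cut one epoch per onset over the half-open window [tmin, tmax)."""
    tmin, tmax = window
    if not tmin < tmax:
        raise InvalidConfigError("epoch window must have tmin < tmax")
    n_samp = int(round((tmax - tmin) * fs))
    segs = []
    for k, onset in enumerate(np.asarray(onsets_s, float)):
        start = int(round((onset + tmin) * fs))
        if start < 0 or start + n_samp > data.shape[-1]:
            raise BoundaryError(
                f"epoch window for event at {onset:.3f}s exceeds the recording"
            )
        segs.append(data[..., start : start + n_samp])
    arr = np.stack(segs) if segs else np.zeros((0, data.shape[0], n_samp))
    if metadata is None:
        metadata = pd.DataFrame({"block_index": np.arange(len(segs))})
    return Epochs(
        data=arr,
        fs=fs,
        tmin=tmin,
        channel_labels=tuple(channel_labels),
        metadata=metadata.reset_index(drop=True),
    )


def reject_artifacts(epochs: Epochs, reject_uv: float = 100.0) -> Epochs:
    """Drop whole epochs (blocks) whose absolute amplitude exceeds the bound.

    The bound is inclusive: a peak of exactly ``reject_uv`` is retained.
    """
    if reject_uv <= 0:
        raise InvalidConfigError("reject_uv must be positive")
    peaks = np.max(np.abs(epochs.data), axis=(1, 2)) if epochs.n_epochs else np.zeros(0)
    keep = peaks <= reject_uv
    log = list(epochs.rejection_log)
    for i in np.nonzero(~keep)[0]:
        ch = int(np.argmax(np.max(np.abs(epochs.data[i]), axis=1)))
        log.append(
            (
                int(epochs.metadata["block_index"].iloc[i]),
                epochs.channel_labels[ch],
                f"amplitude {peaks[i]:.1f} uV exceeds +-{reject_uv:g} uV",
            )
        )
    return Epochs(
        data=epochs.data[keep],
        fs=epochs.fs,
        tmin=epochs.tmin,
        channel_labels=epochs.channel_labels,
        metadata=epochs.metadata[keep].reset_index(drop=True),
        rejection_log=log,
    )


def _detect_blink_starts(signal: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Matched-filter detection of template occurrences; returns start indices."""
    score = np.abs(np.correlate(signal, template, mode="valid"))
    if score.size == 0 or score.max() <= 0:
        return np.zeros(0, dtype=int)
    floor = 6.0 * np.median(score) + 1e-12
    height = max(0.5 * score.max(), floor)
    peaks, _ = scipy.signal.find_peaks(score, height=height, distance=len(template))
    return peaks


def remove_blinks(
    epochs: Epochs,
    template: np.ndarray | None = None,
    blink_starts: dict | None = None,
) -> Epochs:
    """Least-squares regression of the time-locked blink template, per channel.

    Detection runs on the frontal-channel average unless explicit per-epoch
    start indices are supplied (``blink_starts``: epoch index -> sample list).
    """
    template = template if template is not None else blink_template(epochs.fs)
    if len(template) >= epochs.data.shape[2]:
        raise InvalidConfigError("blink template longer than the epoch")
    frontal = [i for i, lb in enumerate(epochs.channel_labels) if lb.startswith("Fp")]
    if not frontal:
        frontal = list(range(len(epochs.channel_labels)))
    out = epochs.data.copy()
    for e in range(epochs.n_epochs):
        if blink_starts is not None:
            starts = np.asarray(blink_starts.get(e, []), dtype=int)
        else:
            starts = _detect_blink_starts(out[e, frontal].mean(axis=0), template)
        if starts.size == 0:
            continue
        reg = np.zeros(out.shape[2])
        for s in starts:
            seg = template[: out.shape[2] - s]
            reg[s : s + len(seg)] += seg
        denom = reg @ reg
        if denom == 0:
            continue
        beta = out[e] @ reg / denom  # (n_channels,)
        out[e] = out[e] - beta[:, None] * reg[None, :]
    return replace(epochs, data=out)


def detect_flat_channels(epochs: Epochs, ptp_uv: float = 0.2) -> list[str]:
    """Channels whose peak-to-peak stays below ``ptp_uv`` in every epoch."""
    if epochs.n_epochs == 0:
        return []
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (e, c)
    flat = np.all(ptp < ptp_uv, axis=0)
    return [lb for lb, f in zip(epochs.channel_labels, flat) if f]


def interpolate_bad_channels(epochs: Epochs, bad_labels, k: int = 4) -> Epochs:
    """Replace each bad channel by the inverse-distance weighted mean of its
    k nearest good montage neighbours."""
    bad = [lb for lb in bad_labels if lb in epochs.channel_labels]
    if not bad:
        return epochs
    good = [lb for lb in epochs.channel_labels if lb not in bad]
    if not good:
        raise UnrecoverableChannelsError("all channels are bad")
    out = epochs.data.copy()
    idx = {lb: i for i, lb in enumerate(epochs.channel_labels)}
    for lb in bad:
        neigh = montage.nearest_neighbors(lb, good, k=min(k, len(good)))
        w = np.array([1.0 / d for _, d in neigh])
        w /= w.sum()
        rows = [idx[nm] for nm, _ in neigh]
        out[:, idx[lb], :] = np.einsum("j,ejs->es", w, epochs.data[:, rows, :])
    return replace(epochs, data=out)


def save_epochs(path, epochs: Epochs) -> None:
    """Portable array container (NPZ) with JSON-encoded metadata."""
    import json

    np.savez(
        path,
        data=epochs.data,
        fs=epochs.fs,
        tmin=epochs.tmin,
        channel_labels=np.array(epochs.channel_labels),
        metadata=json.dumps(epochs.metadata.to_dict(orient="list")),
        rejection_log=json.dumps(epochs.rejection_log),
    )


def load_epochs(path) -> Epochs:
    import json

    with np.load(path, allow_pickle=False) as z:
        return Epochs(
            data=z["data"],
            fs=float(z["fs"]),
            tmin=float(z["tmin"]),
            channel_labels=tuple(str(s) for s in z["channel_labels"]),
            metadata=pd.DataFrame(json.loads(str(z["metadata"]))),
            rejection_log=[tuple(r) for r in json.loads(str(z["rejection_log"]))],
        )


def run_preprocess(
    recording: SimulatedRecording,
    config: PreprocConfig | None = None,
    metadata: pd.DataFrame | None = None,
) -> Epochs:
    """Full pipeline on a raw recording, epoching on each block's first dot."""
    config = config or PreprocConfig()
    config.validate()
    data = bandpass_filter(recording.data, recording.fs, config.band, config.filter_order)
    data = resample(data, recording.fs, config.fs_target)
    fs = config.fs_target

    dots = recording.events[recording.events["label"] == "dot"]
    first = dots.groupby("block_index")["onset_sample"].min()
    onsets_s = first.to_numpy() / recording.fs
    if metadata is None:
        metadata = pd.DataFrame({"block_index": first.index.to_numpy()})
    ep = epoch(data, fs, onsets_s, config.epoch_window, recording.channel_labels, metadata)
    if config.blink_removal == "template_regression":
        ep = remove_blinks(ep)
    ep = reject_artifacts(ep, config.reject_uv)
    ep = interpolate_bad_channels(ep, detect_flat_channels(ep, config.flat_ptp_uv))
    return ep
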