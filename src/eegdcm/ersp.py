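"""Event-related spectral perturbation (ERSP) and band/window summaries.

Time-frequency power is computed with complex Morlet wavelets (7 cycles,
4-30 Hz by default), averaged over epochs, and normalized by the mean
pre-stimulus baseline power per channel and frequency:
dB = 10 log10(P / mean P_baseline).  Negative values indicate event-related
desynchronization (ERD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .errors import InvalidConfigError, LookupError_
from .preprocess import Epochs

BANDS = {"mu": (8.0, 12.0), "beta": (13.0, 20.0)}
DEFAULT_TRIAL_WINDOWS = ((0.0, 0.8), (1.3, 2.1), (2.6, 3.4))
DEFAULT_FREQS = np.arange(4.0, 31.0, 1.0)


@dataclass
class ERSPMap:
    values: np.ndarray  # (n_channels, n_freqs, n_times) dB
    freqs: np.ndarray
    times: np.ndarray  # s relative to the first dot onset
    channel_labels: tuple[str, ...]
    baseline_window: tuple[float, float]


def _morlet_wavelet(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalised, truncated at 6 sigma."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(6 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_power(
    data: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: float = 7.0
) -> np.ndarray:
    """Wavelet power of (n_epochs, n_channels, n_samples) -> (e, c, f, t).

    Epochs are reflect-padded by the longest wavelet half-width so edge power
    (and hence the pre-stimulus baseline) is not biased by zero-padding.
    """
    data = np.asarray(data, float)
    n = data.shape[-1]
    pad = int(np.ceil(6 * n_cycles / (2 * np.pi * min(freqs)) * fs))
    pad = min(pad, n - 1)
    padded = np.pad(data, [(0, 0), (0, 0), (pad, pad)], mode="reflect")
    out = np.empty(data.shape[:2] + (len(freqs), n))
    for fi, f in enumerate(freqs):
        w = _morlet_wavelet(f, fs, n_cycles)
        conv = scipy.signal.fftconvolve(padded, w[None, None, :], mode="same")
        out[:, :, fi, :] = np.abs(conv[:, :, pad : pad + n]) ** 2
    return out


def compute_ersp(
    epochs: Epochs,
    freqs: np.ndarray | None = None,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    n_cycles: float = 7.0,
) -> ERSPMap:
    """Epoch-averaged wavelet power, dB-normalised to the baseline mean."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    times = epochs.times
    b0, b1 = baseline_window
    if b0 < epochs.tmin - 1e-9 or b1 > 0 + 1e-9 or b0 >= b1:
        raise InvalidConfigError("baseline window must lie within [tmin, 0]")
    power = morlet_power(epochs.data, epochs.fs, freqs, n_cycles).mean(axis=0)
    base_mask = (times >= b0) & (times < b1)
    baseline = power[:, :, base_mask].mean(axis=2, keepdims=True)
    values = 10.0 * np.log10(power / baseline)
    return ERSPMap(
        values=values,
        freqs=freqs,
        times=times,
        channel_labels=epochs.channel_labels,
        baseline_window=baseline_window,
    )


def band_average(
    erspmap: ERSPMap, band: tuple[float, float], window: tuple[float, float]
) -> np.ndarray:
    """Mean dB over the band x window rectangle, one value per channel."""
    f0, f1 = band
    t0, t1 = window
    fm = (erspmap.freqs >= f0) & (erspmap.freqs <= f1)
    tm = (erspmap.times >= t0) & (erspmap.times < t1)
    if not fm.any() or not tm.any():
        raise InvalidConfigError("empty band/window selection")
    return erspmap.values[:, fm][:, :, tm].mean(axis=(1, 2))


def erd_index(
    erspmap: ERSPMap,
    channel: str,
    band: tuple[float, float],
    window: tuple[float, float],
) -> float:
    """Band/window average at a single named channel (negative = ERD)."""
    if channel not in erspmap.channel_labels:
        raise LookupError_(f"channel {channel!r} not in the map")
    i = erspmap.channel_labels.index(channel)
    return float(band_average(erspmap, band, window)[i])


def band_window_table(
    erspmap: ERSPMap,
    bands: dict | None = None,
    windows=DEFAULT_TRIAL_WINDOWS,
) -> pd.DataFrame:
    """Per-channel band/window averages as a long-format table."""
    bands = bands or BANDS
    rows = []
    for bname, band in bands.items():
        for w in windows:
            vals = band_average(erspmap, band, w)
            for ch, v in zip(erspmap.channel_labels, vals):
                rows.append((ch, bname, w[0], w[1], v))
    return pd.DataFrame(
        rows, columns=["channel", "band", "window_start", "window_end", "ersp_db"]
    )
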