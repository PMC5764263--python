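"""Regularized linear inverse and ROI time-series extraction.

A Tikhonov minimum-norm inverse on a known lead field stands in for
anatomical-template source reconstruction; the connectivity analysis only
needs the four ROI time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import montage
from .errors import CoverageError, NumericalRankError, ShapeError

ROI_LABELS = ("PMC", "SMA", "M1", "DLPFC")

# Literature-style left-hemisphere centres (mm; +x right, +y anterior, +z up).
# User-overridable: the source coordinates are a configuration default, not a
# measured quantity.
DEFAULT_ROI_CENTERS = {
    "PMC": (-26.0, -8.0, 54.0),
    "SMA": (-4.0, -6.0, 58.0),
    "M1": (-38.0, -22.0, 52.0),
    "DLPFC": (-40.0, 34.0, 30.0),
}


@dataclass(frozen=True)
class ROISet:
    """Four named spherical ROIs in head coordinates."""

    labels: tuple[str, ...] = ROI_LABELS
    centers: dict = field(default_factory=lambda: dict(DEFAULT_ROI_CENTERS))
    radius: float = 12.0

    def __post_init__(self):
        if len(self.labels) != 4 or len(set(self.labels)) != 4:
            raise ShapeError("ROISet requires 4 unique labels")
        for lb in self.labels:
            c = np.asarray(self.centers[lb])
            if np.linalg.norm(c) >= montage.HEAD_RADIUS_MM:
                raise ShapeError(f"ROI centre {lb} outside the head sphere")

    def center_array(self) -> np.ndarray:
        return np.array([self.centers[lb] for lb in self.labels])


def default_roiset() -> ROISet:
    return ROISet()


@dataclass
class ROITimeSeries:
    data: np.ndarray  # (4, n_samples)
    labels: tuple[str, ...]
    fs: float

    def __post_init__(self):
        if self.data.shape[0] != len(self.labels):
            raise ShapeError("one row per ROI required")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("ROI time series must be finite")


def minimum_norm_inverse(data: np.ndarray, gain: np.ndarray, lam: float) -> np.ndarray:
    """Minimum-norm estimate  s = G' (G G' + lam I)^-1 y  per time sample.

    ``data``: (n_channels, n_samples); ``gain``: (n_channels, n_sources).
    """
    data = np.asarray(data, dtype=float)
    gain = np.asarray(gain, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if data.shape[0] != gain.shape[0]:
        raise ShapeError(
            f"channel mismatch: data has {data.shape[0]}, gain has {gain.shape[0]}"
        )
    gram = gain @ gain.T
    if lam == 0:
        ev = np.linalg.eigvalsh(gram)
        if ev[0] <= ev[-1] * 1e-10:
            raise NumericalRankError("G G' is numerically singular at lam=0")
    K = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), data)
    return gain.T @ K


def choose_lambda_discrepancy(
    data: np.ndarray, gain: np.ndarray, noise_level: float, tol: float = 0.05
) -> float:
    """Pick lam so the residual RMS matches ``noise_level`` (discrepancy principle)."""
    lo, hi = 1e-10, 1e10
    target = noise_level

    def resid(lam):
        s = minimum_norm_inverse(data, gain, lam)
        r = data - gain @ s
        return float(np.sqrt(np.mean(r**2)))

    if resid(lo) >= target:
        return lo
    if resid(hi) <= target:
        return hi
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if resid(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return float(np.sqrt(lo * hi))


def extract_roi_timeseries(
    source_estimates: np.ndarray,
    source_positions: np.ndarray,
    roiset: ROISet,
    fs: float,
) -> ROITimeSeries:
    """First principal component of the sources inside each ROI sphere.

    The component sign is fixed so its inner product with the ROI-mean source
    is positive; amplitude is the singular value scaled by 1/sqrt(k) so a
    single-source ROI returns that source's waveform.
    """
    X = np.asarray(source_estimates, dtype=float)
    pos = np.asarray(source_positions, dtype=float)
    if X.shape[0] != pos.shape[0]:
        raise ShapeError("one position per source row required")
    out = np.zeros((len(roiset.labels), X.shape[1]))
    for i, lb in enumerate(roiset.labels):
        c = np.asarray(roiset.centers[lb])
        inside = np.linalg.norm(pos - c, axis=1) <= roiset.radius
        if not np.any(inside):
            raise CoverageError(f"no sources inside ROI sphere {lb}")
        sub = X[inside]
        if sub.shape[0] == 1:
            out[i] = sub[0]
            continue
        mean_src = sub.mean(axis=0)
        U, S, Vt = np.linalg.svd(sub - 0.0, full_matrices=False)
        comp = S[0] * Vt[0] / np.sqrt(sub.shape[0])
        if comp @ mean_src < 0:
            comp = -comp
        out[i] = comp
    return ROITimeSeries(data=out, labels=roiset.labels, fs=fs)
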