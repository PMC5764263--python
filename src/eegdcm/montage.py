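"""32-channel 10-20 montage geometry on a spherical head model.

Positions are parameterised by (inclination from the vertex, azimuth measured
from the right pre-auricular axis, counter-clockwise toward the nasion) and
projected onto a sphere of ``HEAD_RADIUS_MM``.  Coordinate frame: +x right,
+y anterior, +z superior, origin at the head centre.
"""

from __future__ import annotations

import numpy as np

from .errors import LookupError_

HEAD_RADIUS_MM = 87.5

# label -> (inclination deg, azimuth deg)
_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (90, 108), "Fp2": (90, 72),
    "F7": (90, 144), "F3": (60, 129), "Fz": (45, 90), "F4": (60, 51), "F8": (90, 36),
    "FC5": (70, 160), "FC1": (35, 115), "FC2": (35, 65), "FC6": (70, 20),
    "T7": (90, 180), "C3": (45, 180), "Cz": (0, 0), "C4": (45, 0), "T8": (90, 0),
    "TP9": (100, 198), "CP5": (70, 200), "CP1": (35, 245), "CP2": (35, 295),
    "CP6": (70, 340), "TP10": (100, 342),
    "P7": (90, 216), "P3": (60, 231), "Pz": (45, 270), "P4": (60, 309), "P8": (90, 324),
    "PO9": (100, 234), "O1": (90, 252), "Oz": (90, 270), "O2": (90, 288),
    "PO10": (100, 306),
}

CHANNELS_32: tuple[str, ...] = tuple(_ANGLES)


def channel_position(label: str, radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """3-vector (mm) of one electrode on the spherical scalp."""
    try:
        incl, azim = _ANGLES[label]
    except KeyError:
        raise LookupError_(f"unknown channel label {label!r}") from None
    th, ph = np.deg2rad(incl), np.deg2rad(azim)
    return radius * np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )


def positions(labels=None, radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Stack of electrode positions, shape (n_channels, 3), in mm."""
    labels = CHANNELS_32 if labels is None else labels
    return np.array([channel_position(lb, radius) for lb in labels])


def nearest_neighbors(label: str, labels, k: int = 4) -> list[tuple[str, float]]:
    """The ``k`` montage channels closest to ``label`` (label, distance mm)."""
    ref = channel_position(label)
    dists = []
    for other in labels:
        if other == label:
            continue
        dists.append((other, float(np.linalg.norm(channel_position(other) - ref))))
    dists.sort(key=lambda t: t[1])
    return dists[:k]
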