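"""Idealized 10-10 EEG montage: 62-channel labels, unit-sphere positions, ROIs.

The montage mirrors a 64-channel 10-10 cap with the two mastoids absent
(62 recorded channels). Positions are computed analytically on a unit
sphere from the 10-10 grid geometry: the outer 10% circle sits at 72
degrees of inclination from the vertex, sagittal midline electrodes step
by 18 degrees, and intermediate electrodes are spherically interpolated
along each transverse row arc. These idealized coordinates are adequate
for spherical-spline interpolation weights and the cosmetic scalp falloff
of simulated ERP templates; they are not digitized head positions.
"""

from __future__ import annotations

import numpy as np

# Transverse rows front-to-back: (midline polar angle in degrees, labels
# left-to-right). Odd-length rows are anchored at their midline electrode;
# AFz (the ground electrode, not recorded) anchors the AF arc and is dropped.
_ROWS: list[tuple[float, list[str]]] = [
    (72.0, ["FP1", "FPz", "FP2"]),
    (54.0, ["AF7", "AF3", "AFz", "AF4", "AF8"]),
    (36.0, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    (18.0, ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
    (0.0, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    (-18.0, ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
    (-36.0, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    (-54.0, ["PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8"]),
    (-72.0, ["O1", "Oz", "O2"]),
]

_NOT_RECORDED = {"AFz"}

# A-priori regions of interest over the 62-channel montage.
ROI_CHANNELS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "FP1", "FPz", "FP2", "F7", "F3", "Fz", "F4", "F8",
        "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT7", "FT8",
    ),
    "central": (
        "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
        "CP5", "CP1", "CP2", "CP6", "FC3", "FCz", "FC4",
        "C5", "C1", "C2", "C6", "CP3", "CPz", "CP4", "TP7", "TP8",
    ),
    "parieto-occipital": (
        "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
        "P5", "P1", "P2", "P6", "PO5", "PO3", "PO4", "PO6", "PO7", "PO8",
    ),
}


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between unit vectors a and b."""
    cos_omega = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = np.arccos(cos_omega)
    if omega < 1e-12:
        return a.copy()
    sin_omega = np.sin(omega)
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / sin_omega


def _edge_azimuth(label: str) -> float:
    """Azimuth (deg, x=right ear, y=nasion) of a 10% perimeter electrode."""
    perimeter = {
        "FP1": 108, "FPz": 90, "FP2": 72,
        "AF7": 126, "AF8": 54,
        "F7": 144, "F8": 36,
        "FT7": 162, "FT8": 18,
        "T7": 180, "T8": 0,
        "TP7": 198, "TP8": -18,
        "P7": 216, "P8": -36,
        "PO7": 234, "PO8": -54,
        "O1": 252, "Oz": -90, "O2": -72,
    }
    return float(perimeter[label])


def _perimeter_xyz(label: str) -> np.ndarray:
    incl = np.deg2rad(72.0)
    az = np.deg2rad(_edge_azimuth(label))
    return np.array([np.sin(incl) * np.cos(az), np.sin(incl) * np.sin(az), np.cos(incl)])


def channel_positions() -> dict[str, np.ndarray]:
    """Unit-sphere xyz for every recorded channel (x right, y anterior, z up)."""
    pos: dict[str, np.ndarray] = {}
    for angle, labels in _ROWS:
        mid_idx = len(labels) // 2
        a = np.deg2rad(angle)
        midline = np.array([0.0, np.sin(a), np.cos(a)])
        if angle in (72.0, -72.0):
            for lab in labels:
                pos[lab] = _perimeter_xyz(lab)
            continue
        left_edge = _perimeter_xyz(labels[0])
        right_edge = _perimeter_xyz(labels[-1])
        left = labels[: mid_idx + 1]
        right = labels[mid_idx:]
        for i, lab in enumerate(left):
            pos[lab] = _slerp(left_edge, midline, i / (len(left) - 1))
        for i, lab in enumerate(right):
            pos[lab] = _slerp(midline, right_edge, i / (len(right) - 1))
    for lab in _NOT_RECORDED:
        pos.pop(lab, None)
    return pos


def default_channels() -> list[str]:
    """The 62 recorded channel labels in row-major (front-to-back) order."""
    out = []
    for _, labels in _ROWS:
        out.extend(lab for lab in labels if lab not in _NOT_RECORDED)
    return out


def position_array(channels: list[str] | None = None) -> np.ndarray:
    """Stack channel positions into an (n_channels, 3) array."""
    pos = channel_positions()
    channels = channels if channels is not None else default_channels()
    missing = [c for c in channels if c not in pos]
    if missing:
        raise KeyError(f"channels not in the 10-10 montage: {missing}")
    return np.array([pos[c] for c in channels])


def roi_average(values_by_channel: dict[str, float], roi: str) -> float:
    """Arithmetic mean of a per-channel quantity over one ROI's electrodes.

    Raises KeyError naming any ROI member channel missing from the input.
    """
    if roi not in ROI_CHANNELS:
        raise KeyError(f"unknown ROI {roi!r}; expected one of {sorted(ROI_CHANNELS)}")
    missing = [c for c in ROI_CHANNELS[roi] if c not in values_by_channel]
    if missing:
        raise KeyError(f"ROI {roi!r} channels missing from input: {missing}")
    return float(np.mean([values_by_channel[c] for c in ROI_CHANNELS[roi]]))
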