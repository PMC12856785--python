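"""Fit-quality QC: outlier-channel detection and spherical-spline repair.

Channels whose parameterization R^2 falls more than 1.5 interquartile
ranges below the first quartile (within a participant x load x segment
cell) are flagged and replaced by Perrin-style spherical-spline estimates
from the remaining channels, after which spectra are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

#: Spline order and ridge regularization (Perrin et al. 1989 conventions).
SPLINE_ORDER = 4
SPLINE_LAMBDA = 1e-5
_N_LEGENDRE_TERMS = 50


@dataclass
class QCReport:
    r2_by_channel: dict[str, float]
    q1: float
    q3: float
    iqr: float
    flagged: tuple[str, ...]

    @property
    def threshold(self) -> float:
        return self.q1 - 1.5 * self.iqr


def detect_outlier_channels(r2_by_channel: dict[str, float]) -> QCReport:
    """Flag channels with R^2 strictly below Q1 - 1.5 * IQR.

    Quartiles use linear interpolation of order statistics (numpy's
    default), which is pinned because the flag set can depend on it.
    Requires at least 4 channels for stable quartiles. Deterministic and
    independent of channel ordering.
    """
    if len(r2_by_channel) < 4:
        raise ValueError("need at least 4 channels for quartile-based QC")
    values = np.array(list(r2_by_channel.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    cut = q1 - 1.5 * iqr
    flagged = tuple(sorted(ch for ch, r2 in r2_by_channel.items() if r2 < cut))
    return QCReport(r2_by_channel=dict(r2_by_channel), q1=float(q1), q3=float(q3),
                    iqr=float(iqr), flagged=flagged)


def _g_matrix(cosang: np.ndarray, m: int = SPLINE_ORDER) -> np.ndarray:
    """Perrin g function: sum_n (2n+1) / (n(n+1))^m * P_n(cos) / (4 pi)."""
    n = np.arange(1, _N_LEGENDRE_TERMS + 1, dtype=float)
    coeffs = np.zeros(_N_LEGENDRE_TERMS + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** m
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4.0 * np.pi)


def interpolation_matrix(
    positions: np.ndarray, good_idx: np.ndarray, bad_idx: np.ndarray
) -> np.ndarray:
    """Spherical-spline mapping from good-channel data to bad channels.

    Solves the regularized spline system with a constant term (so a
    constant field is reproduced exactly) and returns the (n_bad, n_good)
    matrix applying it.
    """
    pos = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    g_gg = _g_matrix(pos[good_idx] @ pos[good_idx].T)
    g_bg = _g_matrix(pos[bad_idx] @ pos[good_idx].T)
    n_good = len(good_idx)
    a = np.empty((n_good + 1, n_good + 1))
    a[:n_good, :n_good] = g_gg + SPLINE_LAMBDA * np.eye(n_good)
    a[:n_good, n_good] = 1.0
    a[n_good, :n_good] = 1.0
    a[n_good, n_good] = 0.0
    a_inv = np.linalg.pinv(a)
    lhs = np.concatenate([g_bg, np.ones((len(bad_idx), 1))], axis=1)
    return lhs @ a_inv[:, :n_good]


def interpolate_channels(
    data: np.ndarray,
    channel_labels: list[str],
    flagged: tuple[str, ...] | list[str],
    positions: np.ndarray,
) -> np.ndarray:
    """Replace flagged channels with spherical-spline estimates.

    ``data`` has the channel axis second-to-last ((..., channels, times));
    unflagged channels pass through untouched. Requires at least 4 good
    channels.
    """
    flagged = [ch for ch in flagged]
    unknown = [ch for ch in flagged if ch not in channel_labels]
    if unknown:
        raise KeyError(f"flagged channels not in montage: {unknown}")
    if not flagged:
        return data.copy()
    bad_idx = np.array([channel_labels.index(c) for c in flagged])
    good_idx = np.array([i for i in range(len(channel_labels)) if i not in set(bad_idx)])
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels for spline interpolation")
    mat = interpolation_matrix(np.asarray(positions, dtype=float), good_idx, bad_idx)
    out = np.array(data, copy=True)
    good = np.take(data, good_idx, axis=-2)
    repaired = np.einsum("bg,...gt->...bt", mat, good)
    idx = [slice(None)] * data.ndim
    idx[-2] = bad_idx
    out[tuple(idx)] = repaired
    return out
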