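"""Segmentation into 1-s analysis windows and Hanning-taper power spectra.

Analysis windows relative to probe onset: fixation F = [-6, -5) s (the
last full fixation second inside every epoch) and retention R2 = [-3, -2),
R3 = [-2, -1), R4 = [-1, 0); the first retention second is excluded to
avoid memory-set ERP contamination. Spectra are single Hanning tapers on
single 1-s windows (1-Hz native resolution), optionally zero-padded after
tapering (2-s padding gives 0.5-Hz resolution), with one-sided density
scaling compensated for taper power loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EpochSet


@dataclass(frozen=True)
class SegmentDef:
    label: str
    window: tuple[float, float]  # (start, end) s relative to probe onset, half-open

    def __post_init__(self) -> None:
        start, end = self.window
        if not np.isclose(end - start, 1.0):
            raise ValueError(f"segment {self.label}: window must be exactly 1 s")


DEFAULT_SEGMENTS: tuple[SegmentDef, ...] = (
    SegmentDef("F", (-6.0, -5.0)),
    SegmentDef("R2", (-3.0, -2.0)),
    SegmentDef("R3", (-2.0, -1.0)),
    SegmentDef("R4", (-1.0, 0.0)),
)


@dataclass
class PowerSpectrum:
    """One-sided linear power spectral density on an even frequency grid."""

    freqs: np.ndarray  # Hz, ascending
    power: np.ndarray  # uV^2/Hz; trailing axis = frequency
    df: float  # grid spacing, Hz
    meta: dict | None = None

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        spacing = np.diff(self.freqs)
        if len(spacing) and not np.allclose(spacing, self.df):
            raise ValueError("freqs must be evenly spaced with spacing df")


def segment_epochs(
    epochs: EpochSet, defs: list[SegmentDef] | tuple[SegmentDef, ...] = DEFAULT_SEGMENTS
) -> dict[str, np.ndarray]:
    """Cut each epoch into the requested 1-s windows.

    Sample selection is half-open [start, end): each segment has exactly
    ``fs`` samples and the end-boundary sample is excluded.
    """
    out: dict[str, np.ndarray] = {}
    n_times = epochs.data.shape[2]
    for d in defs:
        start, end = d.window
        i0 = int(round((start - epochs.t0) * epochs.fs))
        i1 = int(round((end - epochs.t0) * epochs.fs))
        if i0 < 0 or i1 > n_times:
            raise ValueError(
                f"segment {d.label!r} window {d.window} falls outside the epoch "
                f"[{epochs.t0}, {epochs.t0 + n_times / epochs.fs})"
            )
        out[d.label] = epochs.data[:, :, i0:i1]
    return out


def compute_psd(
    segment: np.ndarray, fs: float, pad_to: float | None = 2.0
) -> PowerSpectrum:
    """Hanning-taper one-sided PSD of 1-s segments (trailing time axis).

    The taper is applied to the data samples first and zeros are appended
    afterwards, so the taper never touches the padding. Density scaling
    divides by ``fs * sum(w^2)``; the frequency resolution is ``1/pad_to``
    (or ``1/duration`` unpadded).
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    duration = n / fs
    if not np.isclose(duration, 1.0):
        raise ValueError(f"segments must be exactly 1 s long, got {duration:g} s")
    if pad_to is not None and pad_to < duration:
        raise ValueError("pad_to must be >= the segment duration")
    window = np.hanning(n)
    tapered = segment * window
    n_fft = n if pad_to is None else int(round(pad_to * fs))
    spec = np.fft.rfft(tapered, n=n_fft, axis=-1)
    scale = 1.0 / (fs * np.sum(window**2))
    power = (np.abs(spec) ** 2) * scale
    power[..., 1:] *= 2.0
    if n_fft % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=power, df=fs / n_fft)


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Arithmetic mean of linear power across spectra on identical grids."""
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.power.shape != ref.power.shape or not np.allclose(s.freqs, ref.freqs):
            raise ValueError("spectra have mismatched frequency grids")
    stacked = np.stack([s.power for s in spectra])
    return PowerSpectrum(freqs=ref.freqs.copy(), power=stacked.mean(axis=0),
                         df=ref.df, meta=ref.meta)


def average_over_trials(ps: PowerSpectrum) -> PowerSpectrum:
    """Collapse all leading (trial) axes of a multi-trial PSD by averaging."""
    if ps.power.ndim == 1:
        return ps
    power = ps.power.mean(axis=tuple(range(ps.power.ndim - 1)))
    return PowerSpectrum(freqs=ps.freqs.copy(), power=power, df=ps.df, meta=ps.meta)


def spectra_table(
    psd_by_cell: dict[tuple, PowerSpectrum], key_names: tuple[str, ...]
) -> pd.DataFrame:
    """Long-format table (key columns + freq + power) from keyed spectra."""
    frames = []
    for key, ps in psd_by_cell.items():
        df = pd.DataFrame({"freq": ps.freqs, "power": np.asarray(ps.power).ravel()})
        for name, val in zip(key_names, key):
            df[name] = val
        frames.append(df[[*key_names, "freq", "power"]])
    return pd.concat(frames, ignore_index=True)
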