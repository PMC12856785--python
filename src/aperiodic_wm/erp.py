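"""ERP averaging, baseline correction, and P3b peak measurement.

P3b amplitude is the maximum of the trial-averaged, baseline-corrected
waveform at Pz within 300-800 ms after stimulus (memory set or probe)
onset; peak rather than mean amplitude avoids confounding amplitude with
latency differences. Baseline is the -200 to 0 ms pre-stimulus mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EpochSet

P3B_WINDOW = (0.300, 0.800)  # s relative to stimulus onset
BASELINE_WINDOW = (-0.200, 0.0)
P3B_CHANNEL = "Pz"


@dataclass
class ERPWaveform:
    times: np.ndarray  # s relative to stimulus onset
    amplitude: np.ndarray  # uV
    channel: str
    n_trials: int


@dataclass
class P3bMeasure:
    amplitude: float  # uV
    latency: float  # ms post stimulus onset
    phase: str
    load: int


def baseline_correct(erp: ERPWaveform,
                     window: tuple[float, float] = BASELINE_WINDOW) -> ERPWaveform:
    """Subtract the mean over the baseline window from every sample."""
    mask = (erp.times >= window[0]) & (erp.times < window[1])
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    return ERPWaveform(times=erp.times, amplitude=erp.amplitude - erp.amplitude[mask].mean(),
                       channel=erp.channel, n_trials=erp.n_trials)


def average_erp(
    epochs: EpochSet,
    trials: pd.DataFrame,
    phase_onset: float,
    load: int,
    channel: str = P3B_CHANNEL,
    retain: np.ndarray | None = None,
) -> ERPWaveform:
    """Trial-average waveform for one load, time-locked to a phase onset.

    Only correct trials (and, if ``retain`` is given, trials passing the
    RT-outlier filter) enter the average. ``phase_onset`` is in seconds
    relative to probe onset (e.g. -5.0 for encoding, 0.0 for the probe).
    """
    if channel not in epochs.channel_labels:
        raise KeyError(f"channel {channel!r} not in the epoch set")
    # copy: to_numpy can be a zero-copy view of the caller's column
    keep = np.array(trials["correct"].to_numpy(), dtype=bool, copy=True)
    if retain is not None:
        keep &= np.asarray(retain, dtype=bool)
    keep &= trials["load"].to_numpy() == load
    if not keep.any():
        raise ValueError(f"no retained trials at load {load}")
    ci = epochs.channel_labels.index(channel)
    data = epochs.data[keep, ci, :]
    return ERPWaveform(times=epochs.times - phase_onset, amplitude=data.mean(axis=0),
                       channel=channel, n_trials=int(keep.sum()))


def p3b_peak(erp: ERPWaveform, window: tuple[float, float] = P3B_WINDOW,
             phase: str = "encoding", load: int = 0) -> P3bMeasure:
    """Maximum amplitude (and its latency) in the search window.

    Window endpoints are inclusive; a tie resolves to the earliest
    latency (argmax convention on an ascending time grid).
    """
    mask = (erp.times >= window[0]) & (erp.times <= window[1])
    if not mask.any():
        raise ValueError(f"P3b window {window} falls outside the waveform span")
    seg_t = erp.times[mask]
    seg_a = erp.amplitude[mask]
    i = int(np.argmax(seg_a))
    return P3bMeasure(amplitude=float(seg_a[i]), latency=float(seg_t[i] * 1000.0),
                      phase=phase, load=load)
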