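"""Synthetic Sternberg-task EEG and behavior with known ground truth.

Each participant's epoched EEG is built from three additive ingredients:

* **Aperiodic background** — colored noise whose one-sided target spectrum
  is ``10**b / f**chi`` with a phase-specific exponent (fixation chi, plus
  per-retention-segment deltas). Noise is synthesized by inverse Fourier
  transform of the target amplitude spectrum with independent uniform
  random phases per trial/channel/phase, so the single-trial periodogram
  matches the target exactly in expectation (random-phase surrogate).
* **Alpha peak** — the target spectrum is multiplied by a log-Gaussian
  bump ``10**(a * exp(-(f-c)^2 / (2 w^2)))``, i.e. exactly the periodic
  component the spectral parameterization model estimates.
* **ERP templates** — Gaussian bumps peaking 450 ms after memory-set and
  probe onsets, with Pz amplitude ``p3b_base + p3b_load_slope * load`` and
  exponential scalp attenuation with distance from Pz.

Behavior is Bernoulli accuracy per load plus a linear RT-load rule with
additive lognormal jitter. All randomness flows from per-participant
seeds derived from a cohort root seed, so regeneration is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import TaskDesign
from .montage import default_channels, position_array

RETENTION_SEGMENTS = ("R2", "R3", "R4")

#: ERP template shape: peak latency and Gaussian SD, seconds after onset.
ERP_PEAK_LATENCY = 0.45
ERP_PEAK_SD = 0.08
#: Exponential scalp falloff constant (unit-sphere chord distance from Pz).
ERP_SCALP_FALLOFF = 1.0


@dataclass
class ParticipantParams:
    """Ground-truth generative parameters for one synthetic participant."""

    participant: str
    group: str  # "younger" | "older"
    exponent_fixation: float
    segment_deltas: dict[str, float]
    offset: float  # log10(uV^2/Hz) at 1 Hz
    alpha_peak: tuple[float, float, float] | None  # (center Hz, log10 power, width Hz)
    p3b_base: float  # uV at Pz
    p3b_load_slope_encoding: float  # uV per load unit
    p3b_load_slope_probe: float
    rt_intercept: float  # s
    rt_load_slope: float  # s per load unit
    rt_jitter_sd: float  # lognormal sigma of additive jitter
    rt_jitter_scale: float  # median of additive jitter, s
    accuracy: dict[int, float]  # per-load probability correct
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for seg in RETENTION_SEGMENTS:
            if seg not in self.segment_deltas:
                raise ValueError(f"segment_deltas missing {seg}")
            if self.exponent_fixation + self.segment_deltas[seg] <= 0:
                raise ValueError(f"exponent for segment {seg} must stay positive")
        if self.exponent_fixation <= 0:
            raise ValueError("exponent_fixation must be > 0")
        for load, acc in self.accuracy.items():
            if not 0.0 < acc <= 1.0:
                raise ValueError(f"accuracy for load {load} must lie in (0, 1]")
        if self.rt_intercept <= 0 or self.rt_load_slope < 0:
            raise ValueError("RT parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accuracy"] = {str(k): v for k, v in self.accuracy.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantParams":
        d = dict(d)
        d["accuracy"] = {int(k): float(v) for k, v in d["accuracy"].items()}
        if d.get("alpha_peak") is not None:
            d["alpha_peak"] = tuple(d["alpha_peak"])
        return cls(**d)


@dataclass
class EpochSet:
    """Trial x channel x time voltage array with epoch timing metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_times), uV
    fs: float
    t0: float  # epoch start, s relative to probe onset
    channel_labels: list[str]
    trial_index: np.ndarray  # row indices into the trial table

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs


def select_channels(n_channels: int) -> list[str]:
    """A spread subset of the montage, always containing Pz (and Cz if room)."""
    full = default_channels()
    if n_channels >= len(full):
        return full
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    picks = ["Pz"]
    if n_channels >= 2:
        picks.append("Cz")
    remaining = [c for c in full if c not in picks]
    idx = np.linspace(0, len(remaining) - 1, n_channels - len(picks)).round().astype(int)
    picks.extend(remaining[i] for i in sorted(set(idx))[: n_channels - len(picks)])
    return [c for c in full if c in picks]


def _shaped_noise(
    n_samples: int,
    fs: float,
    offset: float,
    exponent: float,
    alpha_peak: tuple[float, float, float] | None,
    rng: np.random.Generator,
    shape: tuple[int, ...],
) -> np.ndarray:
    """Random-phase colored noise matching a 1/f (+ peak) target spectrum."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    log_psd = np.empty_like(freqs)
    log_psd[1:] = offset - exponent * np.log10(freqs[1:])
    if alpha_peak is not None:
        c, a, w = alpha_peak
        log_psd[1:] += a * np.exp(-((freqs[1:] - c) ** 2) / (2.0 * w**2))
    psd = 10.0 ** log_psd
    # One-sided density -> rfft amplitudes: P_k = 2|X_k|^2 / (fs * n) interior bins.
    amp = np.sqrt(psd * fs * n_samples / 2.0)
    amp[0] = 0.0
    if n_samples % 2 == 0:
        amp[-1] = np.sqrt(psd[-1] * fs * n_samples)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape + (len(freqs),))
    spec = amp * np.exp(1j * phases)
    spec[..., 0] = 0.0
    if n_samples % 2 == 0:
        spec[..., -1] = amp[-1] * np.sign(np.cos(phases[..., -1]))
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _erp_template(times: np.ndarray, onset: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(
        -((times - onset - ERP_PEAK_LATENCY) ** 2) / (2.0 * ERP_PEAK_SD**2)
    )


def simulate_epochs(
    params: ParticipantParams,
    design: TaskDesign,
    trials: pd.DataFrame,
    fs: float = 256.0,
    channels: list[str] | int | None = None,
    t0: float = -6.5,
    t_end: float = 1.0,
) -> EpochSet:
    """Simulate one participant's epoched EEG for every trial in the table.

    The epoch is assembled from stationary pieces: the in-epoch part of
    fixation, encoding, four 1-s retention sub-windows (first one carries
    the fixation exponent and is excluded from analysis; R2-R4 carry the
    per-segment deltas), and the probe second. ERP templates are added at
    encoding and probe onsets. Bit-identical under the same seed.
    """
    if isinstance(channels, int):
        channels = select_channels(channels)
    channels = channels if channels is not None else default_channels()
    if "Pz" not in channels:
        raise ValueError("channel set must contain Pz (the P3b electrode)")
    if params.alpha_peak is not None and params.alpha_peak[0] >= fs / 2:
        raise ValueError("alpha center frequency must be below Nyquist")
    ret_start, ret_end = design.phase_times["retention"]
    if not (t0 <= design.phase_times["fixation"][1] and t_end >= ret_end):
        raise ValueError("epoch window inconsistent with task phase times")

    n_trials = len(trials)
    n_chan = len(channels)
    rng = np.random.default_rng([params.seed, 1])

    # Stationary pieces: (start, end, exponent) covering [t0, t_end).
    chi_f = params.exponent_fixation
    pieces: list[tuple[float, float, float]] = [
        (t0, design.phase_times["encoding"][0], chi_f),  # fixation tail
        (*design.phase_times["encoding"], chi_f),
        (ret_start, ret_start + 1.0, chi_f),  # retention R1, excluded downstream
    ]
    for k, seg in enumerate(RETENTION_SEGMENTS, start=1):
        s = ret_start + 1.0 + (k - 1)
        pieces.append((s, s + 1.0, chi_f + params.segment_deltas[seg]))
    pieces.append((ret_end, t_end, chi_f))  # probe

    n_times = int(round((t_end - t0) * fs))
    data = np.zeros((n_trials, n_chan, n_times))
    for start, end, chi in pieces:
        if chi <= 0:
            raise ValueError("piecewise exponent must be > 0")
        i0 = int(round((start - t0) * fs))
        i1 = int(round((end - t0) * fs))
        if i1 <= i0:
            continue
        # Synthesize with a 1-s margin and keep a centered cut so every
        # analysis window is an interior slice of a longer stationary
        # stretch (as in recorded EEG, which has energy below the window's
        # fundamental); windows exactly aligned with circular realizations
        # would otherwise lack sub-window leakage entirely.
        margin = int(fs)
        n_piece = (i1 - i0) + margin
        noise = _shaped_noise(
            n_piece, fs, params.offset, chi, params.alpha_peak, rng,
            shape=(n_trials, n_chan),
        )
        data[:, :, i0:i1] = noise[:, :, margin // 2 : margin // 2 + (i1 - i0)]
    if params.noise_scale != 1.0:
        data *= params.noise_scale

    # ERP templates, scalp-attenuated from Pz.
    times = t0 + np.arange(n_times) / fs
    pos = position_array(channels)
    pz = pos[channels.index("Pz")]
    atten = np.exp(-np.linalg.norm(pos - pz, axis=1) / ERP_SCALP_FALLOFF)
    loads = trials["load"].to_numpy()
    for phase, slope in (
        ("encoding", params.p3b_load_slope_encoding),
        ("probe", params.p3b_load_slope_probe),
    ):
        onset = design.phase_times[phase][0]
        amp = params.p3b_base + slope * loads  # (n_trials,)
        template = _erp_template(times, onset, 1.0)  # (n_times,)
        data += amp[:, None, None] * atten[None, :, None] * template[None, None, :]

    return EpochSet(
        data=data, fs=fs, t0=t0, channel_labels=list(channels),
        trial_index=trials.index.to_numpy(),
    )


def simulate_behavior(
    params: ParticipantParams, trials: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Complete a trial table with responses, correctness, and RT.

    Correctness is Bernoulli(accuracy[load]); the response follows from
    correctness and probe presence. RT is a linear function of load plus
    additive lognormal jitter.
    """
    rng = np.random.default_rng([params.seed if seed is None else seed, 2])
    out = trials.copy()
    loads = out["load"].to_numpy()
    acc = np.array([params.accuracy[int(l)] for l in loads])
    correct = rng.random(len(out)) < acc
    present = out["probe_present"].to_numpy()
    responded_present = np.where(correct, present, ~present)
    jitter = rng.lognormal(np.log(params.rt_jitter_scale), params.rt_jitter_sd, len(out)) \
        if params.rt_jitter_sd > 0 else np.full(len(out), params.rt_jitter_scale)
    out["response"] = np.where(responded_present, "present", "absent")
    out["correct"] = correct
    out["rt"] = params.rt_intercept + params.rt_load_slope * loads + jitter
    return out


@dataclass
class CohortEffects:
    """Population-level generative settings. Defaults encode the effect
    structure typical of aging verbal-WM cohorts: a 0.21 younger-minus-older
    exponent offset, retention flattening of -0.04 (R2) and -0.05 (R3, R4),
    near-ceiling accuracy (~95%) declining with load, and load-dependent
    P3b slopes."""

    young_exponent_mean: float = 1.50
    age_exponent_offset: float = 0.21  # younger minus older
    exponent_sd: float = 0.20
    segment_delta_means: dict[str, float] = field(
        default_factory=lambda: {"R2": -0.04, "R3": -0.05, "R4": -0.05}
    )
    segment_delta_sd: float = 0.01
    offset_mean: float = 1.5
    offset_sd: float = 0.3
    alpha_center_mean: float = 10.0
    alpha_center_sd: float = 0.5
    alpha_power_mean: float = 0.5
    alpha_power_sd: float = 0.1
    alpha_width: float = 1.5
    p3b_base_mean: float = 5.0
    p3b_base_sd: float = 1.0
    p3b_enc_slope_mean: float = 0.25
    p3b_probe_slope_mean: float = -0.34
    p3b_slope_sd: float = 0.25
    rt_intercept_young: float = 0.55
    rt_intercept_old: float = 0.70
    rt_intercept_sd: float = 0.05
    rt_load_slope_mean: float = 0.05
    rt_load_slope_sd: float = 0.015
    rt_jitter_sd: float = 0.4
    rt_jitter_scale: float = 0.10
    accuracy_by_load: dict[int, float] = field(
        default_factory=lambda: {1: 0.960, 3: 0.958, 5: 0.928}
    )
    accuracy_logit_sd: float = 0.3


def _participant_seed(root_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    n_young: int,
    n_old: int,
    effects: CohortEffects | None = None,
    seed: int = 0,
    exact_group_means: bool = False,
) -> list[ParticipantParams]:
    """Draw a cohort of participant parameter sets around the group means.

    Each participant gets a named RNG stream derived from the root seed
    and their cohort index, so partial regeneration is stable.

    With ``exact_group_means`` the drawn fixation exponents are recentered
    so each group's sample mean equals its configured population mean, and
    segment deltas likewise. Between-participant spread is untouched. This
    is the fixed-margins design parameter-recovery studies need: the
    realized (not just the population) group contrast equals the injected
    truth, otherwise a single 24+30 cohort's sampling noise (SE about
    ``exponent_sd * sqrt(1/24 + 1/30)``) swamps the recovery comparison.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("group sizes must be >= 1")
    eff = effects or CohortEffects()
    cohort: list[ParticipantParams] = []
    for i in range(n_young + n_old):
        group = "younger" if i < n_young else "older"
        pseed = _participant_seed(seed, i)
        rng = np.random.default_rng([seed, i, 0])
        mean_chi = eff.young_exponent_mean - (
            0.0 if group == "younger" else eff.age_exponent_offset
        )
        chi = max(0.05, rng.normal(mean_chi, eff.exponent_sd))
        deltas = {
            seg: rng.normal(mu, eff.segment_delta_sd)
            for seg, mu in eff.segment_delta_means.items()
        }
        acc = {}
        for load, a in eff.accuracy_by_load.items():
            logit = np.log(a / (1 - a)) + rng.normal(0.0, eff.accuracy_logit_sd)
            acc[int(load)] = float(1.0 / (1.0 + np.exp(-logit)))
        rt_int = eff.rt_intercept_young if group == "younger" else eff.rt_intercept_old
        cohort.append(
            ParticipantParams(
                participant=f"sub-{i:03d}",
                group=group,
                exponent_fixation=float(chi),
                segment_deltas={k: float(v) for k, v in deltas.items()},
                offset=float(rng.normal(eff.offset_mean, eff.offset_sd)),
                alpha_peak=(
                    float(rng.normal(eff.alpha_center_mean, eff.alpha_center_sd)),
                    float(max(0.05, rng.normal(eff.alpha_power_mean, eff.alpha_power_sd))),
                    float(eff.alpha_width),
                ),
                p3b_base=float(rng.normal(eff.p3b_base_mean, eff.p3b_base_sd)),
                p3b_load_slope_encoding=float(
                    rng.normal(eff.p3b_enc_slope_mean, eff.p3b_slope_sd)
                ),
                p3b_load_slope_probe=float(
                    rng.normal(eff.p3b_probe_slope_mean, eff.p3b_slope_sd)
                ),
                rt_intercept=float(max(0.1, rng.normal(rt_int, eff.rt_intercept_sd))),
                rt_load_slope=float(max(0.0, rng.normal(
                    eff.rt_load_slope_mean, eff.rt_load_slope_sd))),
                rt_jitter_sd=eff.rt_jitter_sd,
                rt_jitter_scale=eff.rt_jitter_scale,
                accuracy=acc,
                seed=pseed,
            )
        )
    if exact_group_means:
        for group, mean_chi in (
            ("younger", eff.young_exponent_mean),
            ("older", eff.young_exponent_mean - eff.age_exponent_offset),
        ):
            members = [p for p in cohort if p.group == group]
            shift = mean_chi - float(np.mean([p.exponent_fixation for p in members]))
            for p in members:
                p.exponent_fixation += shift
        for seg, mu in eff.segment_delta_means.items():
            shift = mu - float(np.mean([p.segment_deltas[seg] for p in cohort]))
            for p in cohort:
                p.segment_deltas[seg] += shift
    return cohort
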