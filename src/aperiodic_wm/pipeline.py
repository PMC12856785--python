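"""End-to-end orchestration: simulate -> spectra -> parameterize -> QC ->
ERP/behavior -> inefficiency -> Bayesian models -> summaries.

Every stage writes a long-format CSV; a JSON manifest records the config
hash, seed, library versions, and all produced files. Identical config
and seed give byte-identical outputs. Epoch arrays are stored as .npy
with a JSON sidecar describing sampling rate, epoch start, and channel
labels; trial tables as CSV with documented, ordered columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bayes import BayesianMixedLM
from .behavior import behavioral_summary, retained_trials
from .design import TaskDesign, make_task_design
from .erp import average_erp, baseline_correct, p3b_peak
from .inefficiency import (delta_exponent, load_slope, median_split,
                           neural_inefficiency)
from .montage import default_channels, position_array
from .qc import detect_outlier_channels, interpolate_channels
from .simulate import (CohortEffects, EpochSet, ParticipantParams, make_cohort,
                       select_channels, simulate_behavior, simulate_epochs)
from .spectra import DEFAULT_SEGMENTS, compute_psd, segment_epochs
from .specfit import SpecParamSettings, fit_model

TRIALS_CSV_COLUMNS = ["block", "trial", "load", "probe_present", "response",
                      "correct", "rt"]
FITS_CSV_COLUMNS = ["participant", "group", "load", "segment", "channel",
                    "offset", "exponent", "n_peaks", "r2", "mae", "flagged"]


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are the full-scale stated world
    (24 + 30 participants, 62 channels, 300 trials)."""

    n_young: int = 24
    n_old: int = 30
    n_blocks: int = 20
    trials_per_block: int = 15
    loads: tuple[int, ...] = (1, 3, 5)
    fs: float = 256.0
    n_channels: int = 62
    pad_to: float | None = 2.0
    fixation_window: tuple[float, float] = (-6.0, -5.0)
    settings: SpecParamSettings = field(default_factory=SpecParamSettings)
    effects: CohortEffects = field(default_factory=CohortEffects)
    apply_qc: bool = True
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"]["segment_delta_means"] = dict(d["effects"]["segment_delta_means"])
        d["effects"]["accuracy_by_load"] = {
            str(k): v for k, v in d["effects"]["accuracy_by_load"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "settings" in d and isinstance(d["settings"], dict):
            s = dict(d["settings"])
            for key in ("freq_range", "peak_width_limits"):
                if key in s:
                    s[key] = tuple(s[key])
            d["settings"] = SpecParamSettings(**s)
        if "effects" in d and isinstance(d["effects"], dict):
            e = dict(d["effects"])
            if "accuracy_by_load" in e:
                e["accuracy_by_load"] = {int(k): float(v)
                                         for k, v in e["accuracy_by_load"].items()}
            d["effects"] = CohortEffects(**e)
        for key in ("loads", "fixation_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _segments(cfg: PipelineConfig):
    from .spectra import SegmentDef
    segs = [SegmentDef("F", cfg.fixation_window)]
    segs.extend(s for s in DEFAULT_SEGMENTS if s.label != "F")
    return tuple(segs)


# ------------------------------------------------------------- participant IO


def save_participant(dir_: Path, params: ParticipantParams,
                     trials: pd.DataFrame, epochs: EpochSet) -> None:
    dir_.mkdir(parents=True, exist_ok=True)
    np.save(dir_ / "epochs.npy", epochs.data)
    (dir_ / "epochs.json").write_text(json.dumps({
        "fs": epochs.fs, "t0": epochs.t0,
        "channel_labels": epochs.channel_labels,
        "shape": list(epochs.data.shape), "dtype": str(epochs.data.dtype),
        "byte_order": "little-endian (numpy .npy)",
    }, indent=1))
    trials[TRIALS_CSV_COLUMNS].to_csv(dir_ / "trials.csv", index=False)
    (dir_ / "params.json").write_text(json.dumps(params.to_dict(), indent=1))


def load_external(epochs_dir: str | Path, trials_csv: str | Path | None = None
                  ) -> tuple[EpochSet, pd.DataFrame]:
    """Ingest externally supplied epochs + trial table in the documented
    layout (epochs.npy + epochs.json sidecar, trials.csv)."""
    epochs_dir = Path(epochs_dir)
    sidecar_path = epochs_dir / "epochs.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("fs", "t0", "channel_labels"):
        if key not in sidecar:
            raise ValueError(f"epochs.json missing required field {key!r}")
    data = np.load(epochs_dir / "epochs.npy")
    if list(data.shape) != sidecar.get("shape", list(data.shape)):
        raise ValueError("epochs.npy shape does not match sidecar")
    if data.shape[1] != len(sidecar["channel_labels"]):
        raise ValueError("channel count does not match channel_labels")
    trials = pd.read_csv(trials_csv or epochs_dir / "trials.csv")
    missing = [c for c in TRIALS_CSV_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials.csv missing columns: {missing}")
    if len(trials) != data.shape[0]:
        raise ValueError("trial count does not match epoch count")
    epochs = EpochSet(data=data, fs=sidecar["fs"], t0=sidecar["t0"],
                      channel_labels=list(sidecar["channel_labels"]),
                      trial_index=trials.index.to_numpy())
    n_expected = int(round(data.shape[2]))
    if abs(data.shape[2] - n_expected) > 0:
        raise ValueError("sample count inconsistent with declared fs")
    return epochs, trials


# ------------------------------------------------------------- spectral stage


def participant_spectral_fits(
    participant: str,
    group: str,
    epochs: EpochSet,
    trials: pd.DataFrame,
    cfg: PipelineConfig,
    retain: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (load, segment, channel) aperiodic/periodic fits with QC.

    Spectra are single-Hanning-taper PSDs of retained (correct,
    non-RT-outlier) trials, averaged within load in linear power. QC
    flags channels whose fit R^2 is an IQR outlier within each load x
    segment cell; flagged channels are spline-interpolated in the time
    domain and their spectra re-estimated and refit.
    """
    segs = segment_epochs(epochs, _segments(cfg))
    retain = retain if retain is not None else retained_trials(trials)
    positions = position_array(epochs.channel_labels)
    rows = []
    for load in cfg.loads:
        mask = retain & (trials["load"].to_numpy() == load)
        if not mask.any():
            raise ValueError(f"{participant}: no retained trials at load {load}")
        for seg_label, arr in segs.items():
            seg_trials = arr[mask]  # (n_trials, n_chan, n_times)
            psd = compute_psd(seg_trials, epochs.fs, pad_to=cfg.pad_to)
            mean_power = psd.power.mean(axis=0)  # (n_chan, n_freq)
            models = {ch: fit_model((psd.freqs, mean_power[ci]), cfg.settings)
                      for ci, ch in enumerate(epochs.channel_labels)}
            flagged: tuple[str, ...] = ()
            if cfg.apply_qc and len(models) >= 4:
                report = detect_outlier_channels(
                    {ch: m.r_squared for ch, m in models.items()})
                flagged = report.flagged
                if flagged:
                    repaired = interpolate_channels(
                        seg_trials, epochs.channel_labels, flagged, positions)
                    psd2 = compute_psd(repaired, epochs.fs, pad_to=cfg.pad_to)
                    mean2 = psd2.power.mean(axis=0)
                    for ch in flagged:
                        ci = epochs.channel_labels.index(ch)
                        models[ch] = fit_model((psd2.freqs, mean2[ci]), cfg.settings)
            for ch, m in models.items():
                rows.append({
                    "participant": participant, "group": group, "load": load,
                    "segment": seg_label, "channel": ch, "offset": m.offset,
                    "exponent": m.exponent, "n_peaks": m.n_peaks,
                    "r2": m.r_squared, "mae": m.mae, "flagged": ch in flagged,
                })
    return pd.DataFrame(rows, columns=FITS_CSV_COLUMNS)


# ----------------------------------------------------------------- ERP stage


def participant_erp_behavior(
    participant: str,
    group: str,
    epochs: EpochSet,
    trials: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """P3b peak (Pz) and signal-detection measures per load and phase."""
    retain = retained_trials(trials)
    behav = behavioral_summary(trials, cfg.loads)
    onsets = {"encoding": -5.0, "probe": 0.0}
    rows = []
    for load in cfg.loads:
        brow = behav[behav["load"] == load].iloc[0]
        for phase, onset in onsets.items():
            erp = average_erp(epochs, trials, onset, load, retain=retain)
            erp = baseline_correct(erp)
            peak = p3b_peak(erp, phase=phase, load=load)
            rows.append({
                "participant": participant, "group": group, "load": load,
                "phase": phase, "p3b_amp": peak.amplitude,
                "p3b_lat": peak.latency, "hit_rate": brow["hit_rate"],
                "fa_rate": brow["fa_rate"], "dl": brow["dl"],
                "dprime": brow["dprime"], "mean_rt": brow["mean_rt"],
                "n_retained": brow["n_retained"],
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------- full run


def simulate_participant(params: ParticipantParams, cfg: PipelineConfig
                         ) -> tuple[pd.DataFrame, EpochSet]:
    design, trials = make_task_design(cfg.n_blocks, cfg.trials_per_block,
                                      cfg.loads, seed=params.seed)
    trials = simulate_behavior(params, trials)
    epochs = simulate_epochs(params, design, trials, fs=cfg.fs,
                             channels=cfg.n_channels)
    return trials, epochs


def _slopes_table(measures: pd.DataFrame, loads: tuple[int, ...]) -> pd.DataFrame:
    """Per-participant OLS load slopes of RT, dL, and P3b (both phases)."""
    rows = []
    for (participant, group), df in measures.groupby(["participant", "group"]):
        by_load = df[df["phase"] == "encoding"].set_index("load").loc[list(loads)]
        rec = {"participant": participant, "group": group,
               "beta_rt": load_slope(by_load["mean_rt"], loads),
               "beta_dl": load_slope(by_load["dl"], loads)}
        for phase in ("encoding", "probe"):
            amp = df[df["phase"] == phase].set_index("load").loc[list(loads), "p3b_amp"]
            rec[f"beta_p3b_{phase}"] = load_slope(amp, loads)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("participant")


def inefficiency_table(measures: pd.DataFrame,
                       loads: tuple[int, ...] = (1, 3, 5)) -> pd.DataFrame:
    """NI per participant for each phase x behavioral-kind combination."""
    slopes = _slopes_table(measures, loads)
    frames = []
    for phase in ("encoding", "probe"):
        for kind, col in (("dL", "beta_dl"), ("RT", "beta_rt")):
            ni = neural_inefficiency(slopes[f"beta_p3b_{phase}"], slopes[col], kind)
            frames.append(pd.DataFrame({
                "participant": ni.index, "group": slopes["group"].to_numpy(),
                "phase": phase, "behav_kind": kind,
                "beta_p3b": slopes[f"beta_p3b_{phase}"].to_numpy(),
                "beta_behav": slopes[col].to_numpy(), "ni": ni.to_numpy(),
            }))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``.

    Returns the manifest dictionary (also written as manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    cfg_hash = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()

    cohort = make_cohort(cfg.n_young, cfg.n_old, cfg.effects, seed=cfg.seed)
    (out / "cohort.json").write_text(json.dumps(
        [p.to_dict() for p in cohort], indent=1))

    fits_frames, measure_frames = [], []
    for params in cohort:
        trials, epochs = simulate_participant(params, cfg)
        pdir = out / "participants" / params.participant
        save_participant(pdir, params, trials, epochs)
        fits_frames.append(participant_spectral_fits(
            params.participant, params.group, epochs, trials, cfg))
        measure_frames.append(participant_erp_behavior(
            params.participant, params.group, epochs, trials, cfg))
    fits = pd.concat(fits_frames, ignore_index=True)
    measures = pd.concat(measure_frames, ignore_index=True)
    fits.to_csv(out / "spectral_fits.csv", index=False)
    measures.to_csv(out / "erp_behavior.csv", index=False)

    # electrode-averaged exponents, deltas, median split
    exp_mean = (fits.groupby(["participant", "group", "load", "segment"],
                             as_index=False)["exponent"].mean())
    deltas = delta_exponent(exp_mean)
    fix_by_participant = (exp_mean[exp_mean["segment"] == "F"]
                          .groupby("participant")["exponent"].mean())
    groups = median_split(fix_by_participant)
    deltas = deltas.merge(groups.rename("fixation_group"), left_on="participant",
                          right_index=True)
    deltas.to_csv(out / "exponent_changes.csv", index=False)

    ni = inefficiency_table(measures, cfg.loads)
    ni.to_csv(out / "inefficiency.csv", index=False)

    # Bayesian models
    model_summaries = run_models(fits, measures, ni, cfg)
    model_summaries.to_csv(out / "model_summaries.csv", index=False)

    produced = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    produced.append("manifest.json")
    manifest = {
        "package_version": _pkg_version,
        "config_sha256": cfg_hash,
        "seed": cfg.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": produced,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def exponent_model(fits: pd.DataFrame, cfg: PipelineConfig) -> BayesianMixedLM:
    """Age x load x segment mixed model on per-channel exponents."""
    data = fits.rename(columns={"channel": "electrode"})
    model = BayesianMixedLM(
        outcome="exponent", fixed=["group", "load", "segment"],
        random=["participant", "electrode"],
        levels={"group": ["younger", "older"], "load": sorted(cfg.loads),
                "segment": ["F", "R2", "R3", "R4"]},
        chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed,
    )
    return model.fit(data)


def run_models(fits: pd.DataFrame, measures: pd.DataFrame, ni: pd.DataFrame,
               cfg: PipelineConfig) -> pd.DataFrame:
    """Fit the standard model set and stack their posterior summaries."""
    summaries = []

    m_exp = exponent_model(fits, cfg)
    s = m_exp.summary()
    s.insert(0, "model", "exponent~group+load+segment")
    summaries.append(s)

    behav = measures[measures["phase"] == "encoding"]
    for outcome in ("dl", "mean_rt"):
        m = BayesianMixedLM(
            outcome=outcome, fixed=["group", "load", "group:load"],
            random=["participant"],
            levels={"group": ["younger", "older"], "load": sorted(cfg.loads)},
            chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed,
        ).fit(behav)
        s = m.summary()
        s.insert(0, "model", f"{outcome}~group*load")
        summaries.append(s)

    for phase in ("encoding", "probe"):
        sub = measures[measures["phase"] == phase]
        m = BayesianMixedLM(
            outcome="p3b_amp", fixed=["group", "load", "group:load"],
            random=["participant"],
            levels={"group": ["younger", "older"], "load": sorted(cfg.loads)},
            chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed,
        ).fit(sub)
        s = m.summary()
        s.insert(0, "model", f"p3b_{phase}~group*load")
        summaries.append(s)

    # NI ~ pre-stimulus exponent x age (GLM, no random effects)
    exp_mean = (fits.groupby(["participant", "group", "load", "segment"],
                             as_index=False)["exponent"].mean())
    pre = {"encoding": "F", "probe": "R4"}
    for phase, seg in pre.items():
        expo = (exp_mean[exp_mean["segment"] == seg]
                .groupby("participant")["exponent"].mean())
        sub = ni[(ni["phase"] == phase) & (ni["behav_kind"] == "dL")].copy()
        sub["exponent"] = expo.loc[sub["participant"]].to_numpy()
        m = BayesianMixedLM(
            outcome="ni", fixed=["exponent", "group", "group:exponent"],
            random=[], levels={"group": ["younger", "older"]},
            chains=cfg.chains, draws=cfg.draws, warmup=cfg.warmup, seed=cfg.seed,
        ).fit(sub)
        s = m.summary()
        s.insert(0, "model", f"ni_{phase}~exponent*group")
        summaries.append(s)

    return pd.concat(summaries, ignore_index=True)
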