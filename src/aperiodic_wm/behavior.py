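"""Behavioral measures: RT outlier filtering and signal detection (dL, d').

Sensitivity dL = ln[H(1-FA) / (FA(1-H))] = logit(H) - logit(FA) is the
logistic-distribution analogue of d' = PhiInv(H) - PhiInv(FA); both
quantify discrimination while accounting for response bias. Boundary
rates (0 or 1) are handled with the Snodgrass-Corwin log-linear
correction (add 0.5 to each count, 1 to each denominator) applied to both
rates whenever either raw rate is at a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class SDTCounts:
    n_signal: int
    n_noise: int
    n_hits: int
    n_fa: int
    hit_rate: float
    fa_rate: float
    dl: float
    d_prime: float
    corrected: bool


def flag_rt_outliers(rts: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean flags for RTs above mean + k * sample SD.

    Computed per participant over correct trials pooled across loads (the
    default granularity). All-identical RTs (SD = 0) flag nothing.
    Order-invariant.
    """
    rts = np.asarray(rts, dtype=float)
    if len(rts) < 2:
        raise ValueError("need at least 2 trials to estimate an RT spread")
    sd = rts.std(ddof=1)
    if sd == 0:
        return np.zeros(len(rts), dtype=bool)
    return rts > rts.mean() + k * sd


def compute_rates(trials: pd.DataFrame, load: int | None = None) -> SDTCounts:
    """Hit and false-alarm rates (and dL, d') from a completed trial table.

    A hit is a "present" response on a probe-present trial; a false alarm
    is a "present" response on a probe-absent trial. The log-linear
    correction is applied to both rates whenever any raw rate is 0 or 1.
    """
    t = trials if load is None else trials[trials["load"] == load]
    present = t["probe_present"].to_numpy(dtype=bool)
    said_present = (t["response"] == "present").to_numpy()
    n_signal = int(present.sum())
    n_noise = int((~present).sum())
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    n_hits = int((said_present & present).sum())
    n_fa = int((said_present & ~present).sum())
    h, fa = n_hits / n_signal, n_fa / n_noise
    corrected = h in (0.0, 1.0) or fa in (0.0, 1.0)
    if corrected:
        h = (n_hits + 0.5) / (n_signal + 1)
        fa = (n_fa + 0.5) / (n_noise + 1)
    return SDTCounts(
        n_signal=n_signal, n_noise=n_noise, n_hits=n_hits, n_fa=n_fa,
        hit_rate=h, fa_rate=fa, dl=compute_dl(h, fa),
        d_prime=compute_dprime(h, fa), corrected=corrected,
    )


def _check_interior(h: float, fa: float) -> None:
    if not (0.0 < h < 1.0 and 0.0 < fa < 1.0):
        raise ValueError(
            "boundary hit/false-alarm rate; use compute_rates, which applies "
            "the log-linear correction"
        )


def compute_dl(h: float, fa: float) -> float:
    """Logistic sensitivity dL = ln[H(1-FA) / (FA(1-H))]."""
    _check_interior(h, fa)
    return float(np.log((h * (1.0 - fa)) / (fa * (1.0 - h))))


def compute_dprime(h: float, fa: float) -> float:
    """Normal-distribution sensitivity d' = PhiInv(H) - PhiInv(FA)."""
    _check_interior(h, fa)
    return float(norm.ppf(h) - norm.ppf(fa))


def behavioral_summary(trials: pd.DataFrame, loads: tuple[int, ...] = (1, 3, 5),
                       rt_outlier_k: float = 3.0) -> pd.DataFrame:
    """Per-load H/FA/dL/d'/mean RT with correct-trial + RT-outlier filtering.

    RT outliers are computed over correct trials pooled across loads; the
    returned ``n_retained`` counts correct, non-outlier trials. Returns
    one row per load plus a ``retain`` column is NOT included here --
    callers needing the trial-level mask should use
    :func:`retained_trials`.
    """
    retain = retained_trials(trials, rt_outlier_k)
    rows = []
    for load in loads:
        counts = compute_rates(trials, load)
        at_load = (trials["load"] == load).to_numpy()
        kept = retain & at_load
        rows.append({
            "load": load, "hit_rate": counts.hit_rate, "fa_rate": counts.fa_rate,
            "dl": counts.dl, "dprime": counts.d_prime,
            "mean_rt": float(trials.loc[kept, "rt"].mean()) if kept.any() else np.nan,
            "n_retained": int(kept.sum()),
        })
    return pd.DataFrame(rows)


def retained_trials(trials: pd.DataFrame, rt_outlier_k: float = 3.0) -> np.ndarray:
    """Mask of correct trials whose RT is not an outlier (pooled across loads)."""
    correct = trials["correct"].to_numpy(dtype=bool)
    retain = correct.copy()
    if correct.sum() >= 2:
        flags = flag_rt_outliers(trials.loc[correct, "rt"].to_numpy(), rt_outlier_k)
        retain[np.flatnonzero(correct)[flags]] = False
    return retain
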