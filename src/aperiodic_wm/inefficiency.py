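"""Load slopes, the neural-inefficiency composite, and exponent covariates.

For each participant, OLS slopes over the three loads {1, 3, 5} summarize
how RT, sensitivity (dL), and P3b peak amplitude scale with memory load.
The neural-inefficiency score standardizes the slopes across the sample
and takes

    NI = z(P3b slope) - z(behavioral slope)

where the behavioral slope is z(dL slope), or -1 * z(RT slope) (inverted
so that higher always means better performance). High NI = more neural
recruitment with load without a matching performance benefit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LOADS = (1, 3, 5)


def load_slope(values, loads=DEFAULT_LOADS) -> float:
    """Closed-form OLS slope of ``values`` against memory load."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(loads, dtype=float)
    if len(y) != len(x):
        raise ValueError("values and loads must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def zscore(values) -> np.ndarray:
    """Sample z-scores: mean 0 and SD 1 (ddof=1) exactly."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 participants to standardize")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; z-scores undefined")
    return (v - v.mean()) / sd


def neural_inefficiency(
    p3b_slopes: pd.Series, behav_slopes: pd.Series, behav_kind: str
) -> pd.Series:
    """NI per participant; both inputs indexed by participant.

    ``behav_kind`` is "dL" (used as-is) or "RT" (sign-inverted before
    standardization enters the difference). Standardization is across the
    full combined sample.
    """
    if behav_kind not in ("dL", "RT"):
        raise ValueError("behav_kind must be 'dL' or 'RT'")
    if set(p3b_slopes.index) != set(behav_slopes.index):
        raise ValueError("participant sets of the two slope vectors differ")
    behav_slopes = behav_slopes.reindex(p3b_slopes.index)
    z_p3b = zscore(p3b_slopes.to_numpy())
    z_behav = zscore(behav_slopes.to_numpy())
    if behav_kind == "RT":
        z_behav = -z_behav
    return pd.Series(z_p3b - z_behav, index=p3b_slopes.index, name="ni")


def delta_exponent(exponents: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, load, segment) exponent change from fixation.

    Input: long table with columns participant, load, segment, exponent,
    where exponents are already averaged across electrodes. Rows for the
    retention segments get ``delta = exponent - fixation exponent`` of the
    matching (participant, load).
    """
    required = {"participant", "load", "segment", "exponent"}
    if not required <= set(exponents.columns):
        raise ValueError(f"missing columns: {required - set(exponents.columns)}")
    fix = exponents[exponents["segment"] == "F"].set_index(["participant", "load"])[
        "exponent"
    ]
    ret = exponents[exponents["segment"] != "F"].copy()
    key = pd.MultiIndex.from_frame(ret[["participant", "load"]])
    if not key.isin(fix.index).all():
        missing = key[~key.isin(fix.index)].unique()
        raise ValueError(f"missing fixation exponent for {list(missing)[:5]}")
    ret["delta_exponent"] = ret["exponent"].to_numpy() - fix.loc[key].to_numpy()
    return ret[["participant", "load", "segment", "delta_exponent"]]


def median_split(fixation_exponents: pd.Series) -> pd.Series:
    """Label participants "steeper" (>= median) or "flatter" (< median).

    The split is taken on fixation exponents averaged across electrodes
    and loads; values tied with the median go to "steeper".
    """
    if len(fixation_exponents) < 2:
        raise ValueError("need at least 2 participants for a median split")
    med = fixation_exponents.median()
    return pd.Series(
        np.where(fixation_exponents >= med, "steeper", "flatter"),
        index=fixation_exponents.index, name="fixation_group",
    )
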