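"""Spectral parameterization: aperiodic 1/f fit plus Gaussian peaks.

The model of the one-sided power spectrum over the fit range is, in log10
power,

    log10 P(f) = b - chi * log10 f + sum_k a_k exp(-(f - c_k)^2 / (2 s_k^2))

with offset ``b``, aperiodic exponent ``chi`` (fixed mode: no knee), and
up to ``max_n_peaks`` Gaussian peaks. The algorithm follows the standard
fit-flatten-extract sequence:

1. robust aperiodic fit (initial log-log line, then refit on points whose
   flattened residual lies below a low percentile, which excludes
   oscillatory peaks from the line fit);
2. flatten the spectrum by subtracting the aperiodic fit;
3. iteratively locate residual maxima, stop when the maximum drops below
   ``peak_threshold`` standard deviations of the current residual, fit a
   bounded Gaussian at each, subtract, then jointly refit all Gaussians;
4. subtract the joint peak model from the original log spectrum and refit
   the aperiodic line on the peak-removed spectrum;
5. compose the full model and score R^2 and mean absolute error in log10
   power.

Peak width is reported as the Gaussian's full bandwidth (2 standard
deviations), the convention in which ``peak_width_limits`` is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectra import PowerSpectrum

try:  # sklearn only supplies the get_params/set_params plumbing
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass


@dataclass(frozen=True)
class SpecParamSettings:
    """Fit settings; defaults are the final-pass analysis settings
    (2-s zero-padded spectra, peak width limits [1, 12] Hz)."""

    freq_range: tuple[float, float] = (2.0, 40.0)
    peak_width_limits: tuple[float, float] = (1.0, 12.0)
    max_n_peaks: int = 6
    peak_threshold: float = 2.0  # SD units of the flattened spectrum
    aperiodic_mode: str = "fixed"
    robust_ap_percentile: float = 2.5  # residual percentile kept in the refit
    min_peak_height: float = 1e-6  # log10 units; numerical floor so that
    # float-precision ripple on an exactly aperiodic spectrum never
    # registers as a peak (the relative SD threshold alone cannot
    # distinguish machine noise from structure)

    def __post_init__(self) -> None:
        lo, hi = self.peak_width_limits
        if not (0 < lo < hi):
            raise ValueError("peak_width_limits must be positive and ordered")
        if self.freq_range[0] >= self.freq_range[1]:
            raise ValueError("freq_range must be (low, high) with low < high")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the fixed (no-knee) aperiodic mode is supported")


@dataclass
class SpectralModel:
    """Fitted decomposition of one power spectrum."""

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (center Hz, log10 power, width Hz)
    r_squared: float
    mae: float
    freqs: np.ndarray
    modeled_spectrum: np.ndarray  # log10 power on the fit grid
    settings: SpecParamSettings = field(default_factory=SpecParamSettings)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _crop(freqs: np.ndarray, power: np.ndarray, freq_range: tuple[float, float]):
    mask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    return freqs[mask], power[..., mask]


def _as_arrays(spectrum, settings: SpecParamSettings):
    if isinstance(spectrum, PowerSpectrum):
        freqs, power = spectrum.freqs, spectrum.power
    else:
        freqs, power = spectrum
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if power.ndim != 1:
        raise ValueError("fit operates on a single 1-D spectrum")
    freqs, power = _crop(freqs, power, settings.freq_range)
    if len(freqs) < 3:
        raise ValueError("fewer than 3 frequency points inside freq_range")
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive over the fit range")
    return freqs, power


def _line(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """Least-squares log-log line; returns (offset, exponent)."""
    slope, intercept = np.polyfit(log_f, log_p, 1)
    return float(intercept), float(-slope)


def fit_aperiodic(spectrum, settings: SpecParamSettings | None = None) -> tuple[float, float]:
    """Two-pass robust aperiodic fit; returns (offset b, exponent chi).

    The refit uses only points whose positive residual from the initial
    line falls at or below ``robust_ap_percentile`` of the clipped
    residual distribution, excluding oscillatory peaks from the line.
    """
    settings = settings or SpecParamSettings()
    freqs, power = _as_arrays(spectrum, settings)
    log_f, log_p = np.log10(freqs), np.log10(power)
    b0, chi0 = _line(log_f, log_p)
    resid = log_p - (b0 - chi0 * log_f)
    resid = np.where(resid < 0, 0.0, resid)
    thresh = np.percentile(resid, settings.robust_ap_percentile)
    mask = resid <= thresh
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable points for the robust aperiodic refit")
    return _line(log_f[mask], log_p[mask])


def flatten_spectrum(spectrum, aperiodic: tuple[float, float],
                     settings: SpecParamSettings | None = None) -> np.ndarray:
    """Log-power residual after removing an aperiodic fit (peak domain)."""
    settings = settings or SpecParamSettings()
    freqs, power = _as_arrays(spectrum, settings)
    b, chi = aperiodic
    return np.log10(power) - (b - chi * np.log10(freqs))


def _gaussian_sum(freqs: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        c, a, s = params[i : i + 3]
        out = out + a * np.exp(-((freqs - c) ** 2) / (2.0 * s**2))
    return out


def _estimate_guess_std(freqs: np.ndarray, flat: np.ndarray, idx: int,
                        settings: SpecParamSettings) -> float:
    """Half-height width estimate for the peak at index ``idx``."""
    half = flat[idx] / 2.0
    li = idx
    while li > 0 and flat[li] > half:
        li -= 1
    ri = idx
    while ri < len(flat) - 1 and flat[ri] > half:
        ri += 1
    fwhm = 2.0 * min(freqs[idx] - freqs[li], freqs[ri] - freqs[idx])
    std = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) if fwhm > 0 else 0.0
    lo, hi = settings.peak_width_limits
    return float(np.clip(std, lo / 2.0, hi / 2.0))


def _refine_guess(freqs: np.ndarray, flat: np.ndarray, center: float,
                  height: float, std: float, settings: SpecParamSettings
                  ) -> tuple[float, float, float]:
    """Local bounded single-Gaussian fit around one candidate peak."""
    std_lo, std_hi = (w / 2.0 for w in settings.peak_width_limits)
    window = (freqs >= center - 3.0 * std_hi / 2) & (freqs <= center + 3.0 * std_hi / 2)
    if window.sum() < 4:
        return center, height, std
    lb = [max(settings.freq_range[0], center - 1.5 * std), 0.0, std_lo]
    ub = [min(settings.freq_range[1], center + 1.5 * std), np.inf, std_hi]
    try:
        popt, _ = curve_fit(
            _gaussian_sum, freqs[window], flat[window],
            p0=np.clip([center, height, std], lb, ub), bounds=(lb, ub), maxfev=2000,
        )
        return float(popt[0]), float(popt[1]), float(popt[2])
    except RuntimeError:  # pragma: no cover - ill-conditioned local fit
        return center, height, std


def _prune_overlapping(guesses: list[tuple[float, float, float]],
                       overlap_thresh: float = 0.75) -> list[tuple[float, float, float]]:
    """Drop the smaller of any two guesses whose +-overlap_thresh*SD
    neighborhoods overlap (prevents one broad peak being fit twice)."""
    keep = sorted(guesses, key=lambda g: g[0])
    changed = True
    while changed:
        changed = False
        for i in range(len(keep) - 1):
            (c1, a1, s1), (c2, a2, s2) = keep[i], keep[i + 1]
            if c1 + overlap_thresh * s1 > c2 - overlap_thresh * s2:
                del keep[i if a1 < a2 else i + 1]
                changed = True
                break
    return keep


def extract_peaks(flattened: np.ndarray, freqs: np.ndarray,
                  settings: SpecParamSettings | None = None
                  ) -> list[tuple[float, float, float]]:
    """Iterative Gaussian peak extraction from a flattened spectrum.

    Stops when the residual maximum drops below ``peak_threshold`` SDs of
    the current residual (SD recomputed each iteration) or at
    ``max_n_peaks``. Candidates whose center sits within one half-width
    (one Gaussian SD) of a fit-range edge are discarded. Ties between
    equal maxima resolve to the lower frequency (argmax convention). All
    surviving Gaussians are jointly refit to the flattened spectrum.
    Returns (center, height, bandwidth = 2 SD) triples sorted by center.
    """
    settings = settings or SpecParamSettings()
    flat = np.asarray(flattened, dtype=float).copy()
    if not np.all(np.isfinite(flat)):
        raise ValueError("flattened spectrum must be finite")
    guesses: list[tuple[float, float, float]] = []
    for _ in range(settings.max_n_peaks):
        sd = float(np.std(flat))
        idx = int(np.argmax(flat))
        height = flat[idx]
        if sd == 0 or height <= max(settings.peak_threshold * sd,
                                    settings.min_peak_height):
            break
        std = _estimate_guess_std(freqs, flat, idx, settings)
        center = float(freqs[idx])
        lo_edge = center - settings.freq_range[0] < std
        hi_edge = settings.freq_range[1] - center < std
        # refine the guess with a local single-Gaussian fit so that the
        # subtraction removes the whole peak (a raw half-height width
        # guess under-covers broad peaks and leaves shoulders that would
        # be picked up as spurious secondary peaks)
        center, height, std = _refine_guess(freqs, flat, center, height, std, settings)
        if not (lo_edge or hi_edge):
            guesses.append((center, float(height), std))
        flat -= height * np.exp(-((freqs - center) ** 2) / (2.0 * std**2))
    guesses = _prune_overlapping(guesses)
    if not guesses:
        return []

    p0, lb, ub = [], [], []
    std_lo, std_hi = (w / 2.0 for w in settings.peak_width_limits)
    for c, a, s in guesses:
        p0.extend([c, a, s])
        # center stays near its guess (as in the standard algorithm), so
        # two refit Gaussians cannot drift onto the same peak
        lb.extend([max(settings.freq_range[0], c - 1.5 * s), 0.0, std_lo])
        ub.extend([min(settings.freq_range[1], c + 1.5 * s), np.inf, std_hi])
    try:
        popt, _ = curve_fit(
            _gaussian_sum, freqs, np.asarray(flattened, dtype=float),
            p0=np.clip(p0, lb, ub), bounds=(lb, ub), maxfev=5000,
        )
    except RuntimeError:
        popt = np.clip(p0, lb, ub)
    peaks = [
        (float(popt[i]), float(popt[i + 1]), float(2.0 * popt[i + 2]))
        for i in range(0, len(popt), 3)
    ]
    return sorted(peaks, key=lambda p: p[0])


def fit_model(spectrum, settings: SpecParamSettings | None = None) -> SpectralModel:
    """Full decomposition: aperiodic + peaks + goodness of fit."""
    settings = settings or SpecParamSettings()
    freqs, power = _as_arrays(spectrum, settings)
    log_p = np.log10(power)

    ap0 = fit_aperiodic((freqs, power), settings)
    flat = flatten_spectrum((freqs, power), ap0, settings)
    peaks = extract_peaks(flat, freqs, settings)

    peak_params = [p for (c, a, w) in peaks for p in (c, a, w / 2.0)]
    peak_model = _gaussian_sum(freqs, *peak_params) if peaks else np.zeros_like(freqs)

    # Final aperiodic refit on the peak-removed spectrum (plain line fit;
    # the peaks have already been taken out, so no robust pass is needed).
    b, chi = _line(np.log10(freqs), log_p - peak_model)
    model = (b - chi * np.log10(freqs)) + peak_model

    ss_res = float(np.sum((log_p - model) ** 2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    mae = float(np.mean(np.abs(log_p - model)))
    return SpectralModel(
        offset=b, exponent=chi, peaks=peaks, r_squared=float(r2), mae=mae,
        freqs=freqs, modeled_spectrum=model, settings=settings,
    )


class SpectralParameterization(BaseEstimator):
    """Estimator wrapper around :func:`fit_model`.

    Parameters mirror :class:`SpecParamSettings`. After ``fit(freqs,
    power)`` the decomposition is exposed as fitted attributes
    (``offset_``, ``exponent_``, ``peaks_``, ``r_squared_``, ``mae_``,
    ``modeled_spectrum_``).
    """

    def __init__(self, freq_range=(2.0, 40.0), peak_width_limits=(1.0, 12.0),
                 max_n_peaks=6, peak_threshold=2.0, aperiodic_mode="fixed",
                 robust_ap_percentile=2.5, min_peak_height=1e-6):
        self.freq_range = freq_range
        self.peak_width_limits = peak_width_limits
        self.max_n_peaks = max_n_peaks
        self.peak_threshold = peak_threshold
        self.aperiodic_mode = aperiodic_mode
        self.robust_ap_percentile = robust_ap_percentile
        self.min_peak_height = min_peak_height

    def _settings(self) -> SpecParamSettings:
        return SpecParamSettings(
            freq_range=tuple(self.freq_range),
            peak_width_limits=tuple(self.peak_width_limits),
            max_n_peaks=self.max_n_peaks,
            peak_threshold=self.peak_threshold,
            aperiodic_mode=self.aperiodic_mode,
            robust_ap_percentile=self.robust_ap_percentile,
            min_peak_height=self.min_peak_height,
        )

    def fit(self, freqs, power=None):
        spectrum = freqs if power is None else (freqs, power)
        m = fit_model(spectrum, self._settings())
        self.model_ = m
        self.offset_ = m.offset
        self.exponent_ = m.exponent
        self.peaks_ = m.peaks
        self.r_squared_ = m.r_squared
        self.mae_ = m.mae
        self.freqs_ = m.freqs
        self.modeled_spectrum_ = m.modeled_spectrum
        return self


def make_synthetic_spectrum(
    offset: float,
    exponent: float,
    peaks: list[tuple[float, float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> PowerSpectrum:
    """Noisy model-class spectrum for validation (peaks as (c, a, bandwidth)).

    Multiplicative log-normal noise: log10 power gets i.i.d. Gaussian
    noise of SD ``noise_sd``.
    """
    if freqs is None:
        freqs = np.arange(0.5, 64.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    log_p = offset - exponent * np.log10(freqs)
    for c, a, w in peaks or []:
        log_p = log_p + a * np.exp(-((freqs - c) ** 2) / (2.0 * (w / 2.0) ** 2))
    if noise_sd > 0:
        log_p = log_p + np.random.default_rng(seed).normal(0.0, noise_sd, len(freqs))
    return PowerSpectrum(freqs=freqs, power=10.0**log_p, df=float(freqs[1] - freqs[0]))
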