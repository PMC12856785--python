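import numpy as np
import pytest
from scipy.stats import theilslopes

from aperiodic_wm.specfit import (SpecParamSettings, SpectralParameterization,
                                  extract_peaks, fit_aperiodic, fit_model,
                                  flatten_spectrum, make_synthetic_spectrum)


def theilsen_exponent(freqs, power, freq_range=(2.0, 40.0)):
    """Independent robust estimator: peak-masked Theil-Sen log-log slope.

    Algorithmically unrelated to the iterative fit-flatten-extract route
    it cross-checks (median-of-pairwise-slopes regression with one
    MAD-based masking pass to down-weight oscillatory peaks).
    """
    m = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    lf, lp = np.log10(freqs[m]), np.log10(power[m])
    slope, intercept, *_ = theilslopes(lp, lf)
    resid = lp - (intercept + slope * lf)
    mad = np.median(np.abs(resid - np.median(resid)))
    keep = resid <= np.median(resid) + 2 * 1.4826 * mad
    return -theilslopes(lp[keep], lf[keep])[0]


# ------------------------------------------------------------ aperiodic fit


def test_noiseless_power_law_exact():
    s = make_synthetic_spectrum(1.0, 1.5)
    b, chi = fit_aperiodic(s)
    assert b == pytest.approx(1.0, abs=1e-9)
    assert chi == pytest.approx(1.5, abs=1e-9)


def test_flat_spectrum_zero_exponent():
    freqs = np.arange(1.0, 50.0)
    _, chi = fit_aperiodic((freqs, np.full_like(freqs, 3.0)))
    assert chi == pytest.approx(0.0, abs=1e-12)


def test_power_law_plus_peak_within_tolerance():
    s = make_synthetic_spectrum(1.2, 1.7, [(10.0, 0.6, 3.0)])
    _, chi = fit_aperiodic(s)
    assert abs(chi - 1.7) < 0.05


def test_non_positive_power_raises():
    freqs = np.arange(1.0, 50.0)
    power = np.ones_like(freqs)
    power[10] = 0.0
    with pytest.raises(ValueError, match="positive"):
        fit_aperiodic((freqs, power))


def test_too_few_points_raises():
    with pytest.raises(ValueError):
        fit_aperiodic((np.array([10.0, 11.0]), np.array([1.0, 1.0])),
                      SpecParamSettings(freq_range=(9.0, 12.0)))


# --------------------------------------------------------------- flattening


def test_flatten_own_fit_is_zero():
    s = make_synthetic_spectrum(1.0, 1.5)
    resid = flatten_spectrum(s, fit_aperiodic(s))
    assert np.allclose(resid, 0.0, atol=1e-9)


def test_flatten_peak_max_at_center():
    s = make_synthetic_spectrum(1.0, 1.5, [(10.0, 0.5, 2.0)])
    settings = SpecParamSettings()
    resid = flatten_spectrum(s, (1.0, 1.5), settings)
    freqs = s.freqs[(s.freqs >= 2) & (s.freqs <= 40)]
    assert freqs[np.argmax(resid)] == pytest.approx(10.0)


def test_flatten_is_invertible():
    s = make_synthetic_spectrum(0.8, 1.2, [(11.0, 0.4, 2.0)], noise_sd=0.02, seed=9)
    settings = SpecParamSettings()
    b, chi = 0.8, 1.2
    resid = flatten_spectrum(s, (b, chi), settings)
    freqs = s.freqs[(s.freqs >= 2) & (s.freqs <= 40)]
    log_p = resid + (b - chi * np.log10(freqs))
    orig = np.log10(s.power[(s.freqs >= 2) & (s.freqs <= 40)])
    assert np.allclose(log_p, orig)


# ------------------------------------------------------------------- peaks


def test_no_excursion_no_peaks():
    rng = np.random.default_rng(0)
    freqs = np.arange(2.0, 40.5, 0.5)
    flat = rng.normal(0, 0.05, len(freqs))
    flat = np.clip(flat, -0.09, 0.09)  # nothing beyond 2 SD
    assert extract_peaks(flat, freqs) == []


def test_single_gaussian_recovered():
    freqs = np.arange(2.0, 40.5, 0.5)
    flat = 0.5 * np.exp(-((freqs - 10.0) ** 2) / (2.0 * 1.0**2))
    flat += np.random.default_rng(1).normal(0, 0.01, len(freqs))
    peaks = extract_peaks(flat, freqs)
    assert len(peaks) >= 1
    c, a, w = max(peaks, key=lambda p: p[1])
    assert abs(c - 10.0) < 0.5
    assert a == pytest.approx(0.5, abs=0.1)


def test_two_gaussians_recovered():
    freqs = np.arange(2.0, 40.5, 0.5)
    flat = (0.5 * np.exp(-((freqs - 10.0) ** 2) / 2.0)
            + 0.4 * np.exp(-((freqs - 20.0) ** 2) / 2.0))
    peaks = extract_peaks(flat, freqs)
    centers = sorted(c for c, _, _ in peaks)
    assert len(peaks) == 2
    assert abs(centers[0] - 10.0) < 0.5 and abs(centers[1] - 20.0) < 0.5


def test_peaks_sorted_and_within_limits():
    s = make_synthetic_spectrum(1.0, 1.5, [(20.0, 0.4, 2.0), (10.0, 0.5, 2.0)])
    m = fit_model(s)
    centers = [c for c, _, _ in m.peaks]
    assert centers == sorted(centers)
    lo, hi = m.settings.peak_width_limits
    for _, _, w in m.peaks:
        assert lo <= w <= hi + 1e-9


# -------------------------------------------------------------- full model


def test_full_model_noiseless_r2_and_zero_peaks():
    m = fit_model(make_synthetic_spectrum(1.0, 1.5))
    assert m.r_squared > 0.999
    assert m.n_peaks == 0
    assert abs(m.offset - 1.0) < 1e-6 and abs(m.exponent - 1.5) < 1e-6


def test_notched_spectrum_has_low_r2():
    s = make_synthetic_spectrum(1.0, 1.5)
    power = s.power.copy()
    power[(s.freqs >= 18) & (s.freqs <= 22)] *= 0.1
    m = fit_model((s.freqs, power))
    assert m.r_squared < 0.9


def test_scale_equivariance():
    s = make_synthetic_spectrum(1.0, 1.6, [(10.0, 0.5, 2.0)], noise_sd=0.01, seed=3)
    m1 = fit_model(s)
    m2 = fit_model((s.freqs, 10.0 * s.power))
    assert m2.offset - m1.offset == pytest.approx(1.0, abs=1e-6)
    assert m2.exponent == pytest.approx(m1.exponent, abs=1e-6)
    for (c1, a1, w1), (c2, a2, w2) in zip(m1.peaks, m2.peaks):
        assert c2 == pytest.approx(c1, abs=1e-4)
        assert a2 == pytest.approx(a1, abs=1e-4)


def test_oracle_equivalence_on_seeded_spectra():
    """50 seeded model-class spectra: exponents match the injected truth
    (median error < 0.02), agree with an independent Theil-Sen estimator,
    and substantial-peak counts match the injected counts >= 90%."""
    rng = np.random.default_rng(2024)
    errs, diffs, agree = [], [], 0
    for _ in range(50):
        chi = rng.uniform(1.0, 2.2)
        b = rng.uniform(0.5, 2.0)
        n_peaks = int(rng.integers(0, 3))
        centers = [10.0, 20.0]
        peaks = [(centers[k] + rng.uniform(-2, 2), rng.uniform(0.3, 0.7),
                  rng.uniform(1.5, 4)) for k in range(n_peaks)]
        s = make_synthetic_spectrum(b, chi, peaks, noise_sd=0.01,
                                    seed=int(rng.integers(2**31)))
        m = fit_model(s)
        errs.append(abs(m.exponent - chi))
        diffs.append(abs(m.exponent - theilsen_exponent(s.freqs, s.power)))
        agree += sum(1 for p in m.peaks if p[1] >= 0.15) == n_peaks
    assert np.median(errs) < 0.02
    assert np.median(diffs) < 0.02
    assert agree >= 45  # >= 90% of 50


def test_estimator_api():
    est = SpectralParameterization(max_n_peaks=3)
    assert est.get_params()["max_n_peaks"] == 3
    est.set_params(peak_threshold=2.5)
    s = make_synthetic_spectrum(1.0, 1.5, [(10.0, 0.5, 2.0)], noise_sd=0.01, seed=4)
    est.fit(s.freqs, s.power)
    assert abs(est.exponent_ - 1.5) < 0.05
    assert est.r_squared_ > 0.95
    assert len(est.peaks_) <= 3


def test_invalid_settings_raise():
    with pytest.raises(ValueError):
        SpecParamSettings(peak_width_limits=(12.0, 1.0))
    with pytest.raises(ValueError):
        SpecParamSettings(aperiodic_mode="knee")
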