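import numpy as np
import pandas as pd
import pytest

from aperiodic_wm.behavior import (compute_dl, compute_dprime, compute_rates,
                                   flag_rt_outliers, retained_trials)
from aperiodic_wm.design import make_task_design
from aperiodic_wm.erp import ERPWaveform, average_erp, baseline_correct, p3b_peak
from aperiodic_wm.simulate import make_cohort, simulate_behavior

from conftest import make_params


def _erp(times, amp):
    return ERPWaveform(times=times, amplitude=amp, channel="Pz", n_trials=1)


# ------------------------------------------------------------------ baseline


def test_baseline_constant_trace_zeroed():
    t = np.linspace(-0.3, 1.0, 300)
    out = baseline_correct(_erp(t, np.full(300, 3.0)))
    assert np.allclose(out.amplitude, 0.0)


def test_baseline_idempotent():
    t = np.linspace(-0.3, 1.0, 300)
    a = np.sin(t * 5) + 2.0
    once = baseline_correct(_erp(t, a))
    twice = baseline_correct(once)
    assert np.allclose(once.amplitude, twice.amplitude)


def test_baseline_translation_invariance():
    t = np.linspace(-0.3, 1.0, 300)
    a = np.sin(t * 5)
    out1 = baseline_correct(_erp(t, a))
    out2 = baseline_correct(_erp(t, a + 11.0))
    assert np.allclose(out1.amplitude, out2.amplitude)


def test_baseline_empty_window_raises():
    t = np.linspace(0.1, 1.0, 100)
    with pytest.raises(ValueError):
        baseline_correct(_erp(t, np.zeros(100)))


# ---------------------------------------------------------------------- P3b


def test_p3b_gaussian_bump():
    t = np.linspace(-0.2, 1.0, 1201)
    amp = 5.0 * np.exp(-((t - 0.45) ** 2) / (2 * 0.05**2))
    peak = p3b_peak(_erp(t, amp))
    assert peak.amplitude == pytest.approx(5.0, abs=1e-6)
    assert peak.latency == pytest.approx(450.0, abs=1.0)


def test_p3b_monotone_decreasing_peaks_at_window_start():
    t = np.linspace(-0.2, 1.0, 1201)
    peak = p3b_peak(_erp(t, -t))
    assert peak.latency == pytest.approx(300.0, abs=1.0)


def test_p3b_tie_breaks_to_earliest():
    t = np.round(np.linspace(0.0, 1.0, 1001), 4)
    amp = np.zeros_like(t)
    amp[t == 0.4] = 2.0
    amp[t == 0.6] = 2.0
    peak = p3b_peak(_erp(t, amp))
    assert peak.latency == pytest.approx(400.0)


def test_p3b_window_outside_span_raises():
    t = np.linspace(-0.2, 0.25, 100)
    with pytest.raises(ValueError):
        p3b_peak(_erp(t, np.zeros(100)))


def test_average_erp_excludes_incorrect(small_epochs):
    epochs, trials = small_epochs
    erp = average_erp(epochs, trials, phase_onset=-5.0, load=1)
    n_correct = int((trials["correct"] & (trials["load"] == 1)).sum())
    assert erp.n_trials == n_correct


def test_average_erp_converges_to_template():
    """Noisy copies of a template average back to it (RMS ~ 1/sqrt(n))."""
    design, trials = make_task_design(10, 15, seed=2)  # 150 trials
    p = make_params(alpha_peak=None, p3b_load_slope_encoding=0.0,
                    p3b_load_slope_probe=0.0, seed=21,
                    accuracy={1: 1.0, 3: 1.0, 5: 1.0})
    from aperiodic_wm.simulate import simulate_behavior, simulate_epochs
    trials = simulate_behavior(p, trials)
    epochs = simulate_epochs(p, design, trials, channels=["Pz"])
    erp = baseline_correct(average_erp(epochs, trials, phase_onset=0.0, load=3))
    peak = p3b_peak(erp, phase="probe", load=3)
    assert peak.amplitude == pytest.approx(5.0, abs=0.8)


def test_average_erp_no_trials_raises(small_epochs):
    epochs, trials = small_epochs
    t = trials.copy()
    t["correct"] = False
    with pytest.raises(ValueError):
        average_erp(epochs, t, phase_onset=0.0, load=1)


# ---------------------------------------------------------------- RT outliers


def test_rt_outlier_flags_extreme_trial():
    rts = np.array([0.5] * 10 + [10.0])
    flags = flag_rt_outliers(rts)
    assert flags.sum() == 1 and flags[-1]


def test_rt_outlier_all_equal_none_flagged():
    assert not flag_rt_outliers(np.full(20, 0.5)).any()


def test_rt_outlier_permutation_invariant():
    rng = np.random.default_rng(3)
    rts = np.concatenate([rng.normal(0.5, 0.05, 30), [5.0]])
    perm = rng.permutation(len(rts))
    assert np.array_equal(flag_rt_outliers(rts)[perm], flag_rt_outliers(rts[perm]))


def test_rt_outlier_needs_two_trials():
    with pytest.raises(ValueError):
        flag_rt_outliers(np.array([0.5]))


# ------------------------------------------------------------ signal detection


def _table(n_hit, n_sig, n_fa, n_noise):
    rows = []
    for i in range(n_sig):
        rows.append({"load": 1, "probe_present": True,
                     "response": "present" if i < n_hit else "absent"})
    for i in range(n_noise):
        rows.append({"load": 1, "probe_present": False,
                     "response": "present" if i < n_fa else "absent"})
    return pd.DataFrame(rows)


def test_rates_simple_counts():
    c = compute_rates(_table(10, 20, 10, 20))
    assert c.hit_rate == pytest.approx(0.5)
    assert c.fa_rate == pytest.approx(0.5)
    assert c.dl == pytest.approx(0.0)
    assert not c.corrected


def test_rates_loglinear_correction_at_boundary():
    c = compute_rates(_table(20, 20, 1, 20))
    assert c.corrected
    assert c.hit_rate == pytest.approx(20.5 / 21)
    assert c.fa_rate == pytest.approx(1.5 / 21)


def test_rates_interior_untouched():
    c = compute_rates(_table(18, 20, 2, 20))
    assert c.hit_rate == pytest.approx(0.9)
    assert c.fa_rate == pytest.approx(0.1)


def test_rates_need_both_trial_types():
    df = _table(5, 10, 0, 0).iloc[:10]
    with pytest.raises(ValueError):
        compute_rates(df)


def test_dl_printed_formula():
    assert compute_dl(0.5, 0.5) == pytest.approx(0.0)
    assert compute_dl(0.95, 0.05) == pytest.approx(np.log(361.0), abs=1e-9)


def test_dl_antisymmetry():
    assert compute_dl(0.9, 0.2) == pytest.approx(-compute_dl(0.2, 0.9))


def test_dprime_values():
    assert compute_dprime(0.6, 0.6) == pytest.approx(0.0)
    assert compute_dprime(0.95, 0.05) == pytest.approx(3.2897, abs=1e-3)


def test_boundary_rates_raise():
    for fn in (compute_dl, compute_dprime):
        with pytest.raises(ValueError):
            fn(1.0, 0.05)


def test_dl_dprime_comonotone_in_hit_rate():
    hs = np.linspace(0.55, 0.99, 20)
    dls = [compute_dl(h, 0.1) for h in hs]
    dps = [compute_dprime(h, 0.1) for h in hs]
    assert all(np.diff(dls) > 0) and all(np.diff(dps) > 0)


def test_dl_dprime_highly_correlated_across_cohort():
    """Near-ceiling simulated cohort: r(dL, d') > 0.99."""
    cohort = make_cohort(15, 15, seed=9)
    dls, dps = [], []
    for p in cohort:
        _, trials = make_task_design(seed=p.seed)
        trials = simulate_behavior(p, trials)
        c = compute_rates(trials)
        dls.append(c.dl)
        dps.append(c.d_prime)
    assert np.corrcoef(dls, dps)[0, 1] > 0.99


def test_measures_invariant_to_block_ordering():
    _, trials = make_task_design(4, 15, seed=6)
    p = make_params(seed=17)
    t = simulate_behavior(p, trials)
    shuffled = t.sample(frac=1.0, random_state=0)
    for load in (1, 3, 5):
        assert compute_rates(t, load).dl == pytest.approx(
            compute_rates(shuffled, load).dl)
    r1 = retained_trials(t)
    r2 = retained_trials(shuffled)
    assert r1.sum() == r2.sum()
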