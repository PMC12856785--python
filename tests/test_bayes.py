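import numpy as np
import pandas as pd
import pytest

import arviz as az

from aperiodic_wm.bayes import (BayesianMixedLM, DesignEncoder, classify_effect,
                                compute_hdi, compute_pd, compute_rhat,
                                rope_percentage)


# -------------------------------------------------------------------- design


def test_encoder_treatment_coding():
    df = pd.DataFrame({"g": ["a", "b", "a", "b"], "x": [1.0, 2.0, 3.0, 4.0]})
    enc = DesignEncoder(df, ["g", "x"], levels={"g": ["a", "b"]})
    x, names = enc.encode(df)
    assert names == ["(Intercept)", "g[b]", "x"]
    assert np.allclose(x[:, 1], [0, 1, 0, 1])


def test_encoder_interaction_and_square():
    df = pd.DataFrame({"g": ["a", "b"], "x": [2.0, 3.0]})
    enc = DesignEncoder(df, ["g", "x", "g:x", "x^2"], levels={"g": ["a", "b"]})
    x, names = enc.encode(df)
    assert "g[b]:x" in names and "x^2" in names
    assert x[1, names.index("g[b]:x")] == pytest.approx(3.0)
    assert x[1, names.index("x^2")] == pytest.approx(9.0)


def test_rank_deficiency_names_aliased_column():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=20)})
    df["x2"] = df["x"]  # perfectly collinear copy
    df["y"] = df["x"] + rng.normal(size=20)
    with pytest.raises(ValueError, match="aliased"):
        BayesianMixedLM(outcome="y", fixed=["x", "x2"], random=[],
                        chains=2, draws=200, warmup=100).fit(df)


# ----------------------------------------------------------------------- HDI


def test_hdi_standard_normal():
    x = np.random.default_rng(0).normal(size=100_000)
    lo, hi = compute_hdi(x)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hdi_exponential_shortest_interval():
    x = np.random.default_rng(1).exponential(1.0, 100_000)
    lo, hi = compute_hdi(x)
    assert lo < 0.01
    assert hi == pytest.approx(-np.log(0.05), abs=0.15)


def test_hdi_point_mass():
    lo, hi = compute_hdi(np.full(200, 3.3))
    assert lo == hi == pytest.approx(3.3)


def test_hdi_not_wider_than_equal_tailed():
    rng = np.random.default_rng(2)
    for x in (rng.normal(size=5000), rng.exponential(size=5000),
              rng.beta(2, 5, 5000)):
        lo, hi = compute_hdi(x)
        q_lo, q_hi = np.quantile(x, [0.025, 0.975])
        assert hi - lo <= (q_hi - q_lo) + 1e-12


def test_hdi_matches_arviz():
    x = np.random.default_rng(3).gamma(2.0, 1.0, 50_000)
    lo, hi = compute_hdi(x)
    ref = az.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(ref[0], abs=0.02)
    assert hi == pytest.approx(ref[1], abs=0.02)


def test_hdi_invalid_prob():
    with pytest.raises(ValueError):
        compute_hdi(np.zeros(200), prob=1.5)


# ------------------------------------------------------------------------ pd


def test_pd_all_positive():
    assert compute_pd(np.abs(np.random.default_rng(0).normal(size=500)) + 0.1) == 100.0


def test_pd_symmetric_about_zero():
    x = np.random.default_rng(1).normal(0, 1, 100_000)
    assert compute_pd(x) == pytest.approx(50.0, abs=0.5)


def test_pd_calibration_97_5():
    """Gaussian with two-sided tail 0.05 beyond zero has pd = 97.5%."""
    x = np.random.default_rng(2).normal(1.959964, 1.0, 100_000)
    assert compute_pd(x) == pytest.approx(97.5, abs=0.2)


def test_pd_permutation_and_negation():
    rng = np.random.default_rng(3)
    x = rng.normal(0.5, 1, 10_000)
    assert compute_pd(x) == compute_pd(rng.permutation(x))
    assert compute_pd(-x) == compute_pd(x)


# ---------------------------------------------------------------------- ROPE


def test_rope_hdi_inside():
    x = np.random.default_rng(0).normal(0.0, 0.01, 10_000)
    assert rope_percentage(x, (-0.1, 0.1)) == 100.0


def test_rope_disjoint():
    x = np.random.default_rng(1).normal(5.0, 0.1, 10_000)
    assert rope_percentage(x, (-0.1, 0.1)) == 0.0


def test_rope_uniform_half_overlap():
    x = np.random.default_rng(2).uniform(0.0, 0.2, 100_000)
    pct = rope_percentage(x, (-0.1, 0.1))
    assert pct == pytest.approx(50.0, abs=3.0)


def test_rope_degenerate_raises():
    with pytest.raises(ValueError):
        rope_percentage(np.zeros(200), (0.1, 0.1))


# ------------------------------------------------------------ classification


@pytest.mark.parametrize("pd_pct,pct_rope,expected", [
    (99.95, 0.0, ("certain", "relevant")),
    (99.5, 2.0, ("probable", "probably relevant")),
    (98.0, 15.0, ("likely", "inconclusive")),
    (60.0, 100.0, ("none", "irrelevant")),
    (97.5, 98.0, ("none", "probably irrelevant")),  # strict boundaries
    (99.0, 99.0, ("likely", "probably irrelevant")),
    (99.9, 1.0, ("probable", "probably relevant")),
])
def test_classification_threshold_table(pd_pct, pct_rope, expected):
    assert classify_effect(pd_pct, pct_rope) == expected


def test_classification_out_of_range():
    with pytest.raises(ValueError):
        classify_effect(40.0, 10.0)
    with pytest.raises(ValueError):
        classify_effect(99.0, 101.0)


# ----------------------------------------------------------------------- rhat


def test_rhat_well_mixed_chains():
    rng = np.random.default_rng(0)
    chains = rng.normal(size=(2, 10_000))
    assert compute_rhat(chains) < 1.01


def test_rhat_separated_chains():
    rng = np.random.default_rng(1)
    chains = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
    assert compute_rhat(chains) > 1.5


def test_rhat_constant_chains_returns_one():
    assert compute_rhat(np.ones((2, 100))) == 1.0


def test_rhat_matches_arviz():
    rng = np.random.default_rng(2)
    for shift in (0.0, 0.3):
        chains = np.stack([rng.normal(0, 1, 4000), rng.normal(shift, 1, 4000)])
        ref = float(az.rhat(az.from_dict({"x": chains}))["x"].values)
        assert compute_rhat(chains) == pytest.approx(ref, abs=0.01)


def test_rhat_single_chain_raises():
    with pytest.raises(ValueError):
        compute_rhat(np.zeros((1, 100)))


# ------------------------------------------------------------------- the LMM


@pytest.fixture(scope="module")
def lmm_data():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(20):
        u = rng.normal(0, 0.3)
        x = rng.normal(size=10)
        y = 1.0 + 0.5 * x + u + rng.normal(0, 0.1, 10)
        rows += [{"participant": f"p{i}", "x": xv, "y": yv}
                 for xv, yv in zip(x, y)]
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def lmm_fit(lmm_data):
    return BayesianMixedLM(outcome="y", fixed=["x"], random=["participant"],
                           chains=2, draws=1000, warmup=500, seed=1).fit(lmm_data)


def test_lmm_recovers_slope(lmm_fit):
    d = lmm_fit.term_draws("x")
    med = float(np.median(d))
    assert 0.4 < med < 0.6
    lo, hi = compute_hdi(d.ravel())
    assert lo < 0.5 < hi


def test_lmm_converges(lmm_fit):
    assert all(r < 1.01 for r in lmm_fit.rhat_.values())


def test_lmm_null_slope_pd_near_half(lmm_data):
    df = lmm_data.copy()
    rng = np.random.default_rng(7)
    df["z"] = rng.normal(size=len(df))  # unrelated predictor
    m = BayesianMixedLM(outcome="y", fixed=["x", "z"], random=["participant"],
                        chains=2, draws=800, warmup=400, seed=2).fit(df)
    assert compute_pd(m.term_draws("z").ravel()) < 80.0


def test_lmm_deterministic(lmm_data):
    kw = dict(outcome="y", fixed=["x"], random=["participant"],
              chains=2, draws=200, warmup=100, seed=5)
    a = BayesianMixedLM(**kw).fit(lmm_data)
    b = BayesianMixedLM(**kw).fit(lmm_data)
    assert np.array_equal(a.coef_draws_, b.coef_draws_)


def test_contrast_self_is_zero(lmm_data):
    df = lmm_data.copy()
    df["g"] = np.where(np.arange(len(df)) % 2 == 0, "a", "b")
    m = BayesianMixedLM(outcome="y", fixed=["g"], random=["participant"],
                        levels={"g": ["a", "b"]},
                        chains=2, draws=300, warmup=200, seed=3).fit(df)
    c = m.contrast([{"g": "a"}, {"g": "a"}], [1.0, -1.0])
    assert np.allclose(c, 0.0)


def test_contrast_equals_dummy_coefficient(lmm_data):
    df = lmm_data.copy()
    df["g"] = np.where(np.arange(len(df)) % 2 == 0, "a", "b")
    m = BayesianMixedLM(outcome="y", fixed=["g", "x"], random=["participant"],
                        levels={"g": ["a", "b"]},
                        chains=2, draws=300, warmup=200, seed=3).fit(df)
    c = m.contrast([{"g": "b", "x": 0.0}, {"g": "a", "x": 0.0}], [1.0, -1.0])
    assert np.allclose(c, m.term_draws("g[b]"))


def test_contrast_antisymmetry(lmm_data):
    df = lmm_data.copy()
    df["g"] = np.where(np.arange(len(df)) % 2 == 0, "a", "b")
    m = BayesianMixedLM(outcome="y", fixed=["g"], random=["participant"],
                        levels={"g": ["a", "b"]},
                        chains=2, draws=300, warmup=200, seed=4).fit(df)
    c1 = m.contrast([{"g": "a"}, {"g": "b"}], [1.0, -1.0])
    c2 = m.contrast([{"g": "a"}, {"g": "b"}], [-1.0, 1.0])
    assert np.allclose(c1, -c2)


def test_summary_table_schema(lmm_fit):
    s = lmm_fit.summary()
    assert set(s.columns) >= {"term", "median", "hdi_lo", "hdi_hi", "pd",
                              "pct_in_rope", "existence", "relevance", "rhat"}
    assert "x" in set(s["term"])
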