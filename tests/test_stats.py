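"""Statistics layer: axial circular statistics, correlation/variance tests,
the two-response linear model with Pillai/approximate-F term tests, and
dual-direction AIC selection — each checked against independent brute-force
oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from ecmlines import stats as st


# ---------------------------------------------------------------------------
# axial circular statistics


def brute_axial(angles_deg):
    """Independent doubling/resultant computation (pure Python)."""
    d = [math.radians(2 * a) for a in angles_deg]
    C = sum(math.cos(x) for x in d) / len(d)
    S = sum(math.sin(x) for x in d) / len(d)
    R = math.hypot(C, S)
    mean = math.degrees(0.5 * math.atan2(S, C))
    if mean <= -90:
        mean += 180
    dev = math.degrees(math.sqrt(2 * (1 - R)) / 2)
    return mean, R, dev


def test_identical_angles_have_zero_deviation():
    s = st.circ_axial_stats([20.0, 20.0, 20.0])
    assert s.mean_deg == pytest.approx(20.0)
    assert s.angular_deviation_deg == pytest.approx(0.0, abs=1e-6)


def test_orthogonal_pair_reaches_axial_maximum():
    s = st.circ_axial_stats([0.0, 90.0])
    assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
    assert s.angular_deviation_deg == pytest.approx(40.5142, abs=1e-3)


def test_axial_stats_match_brute_force_oracle(rng):
    angles = rng.uniform(-90, 90, size=57)
    s = st.circ_axial_stats(angles)
    mean, R, dev = brute_axial(angles)
    assert s.mean_deg == pytest.approx(mean, abs=1e-8)
    assert s.resultant_length == pytest.approx(R, abs=1e-10)
    assert s.angular_deviation_deg == pytest.approx(dev, abs=1e-8)


def test_axial_deviation_matches_wrapped_normal_monte_carlo():
    """n=10⁵ axial wrapped-normal sample (sd 15°): measured deviation agrees
    with a Monte-Carlo oracle within 0.3°."""
    rng = np.random.default_rng(77)
    sd = 15.0
    sample = rng.normal(0.0, sd, size=100_000)
    measured = st.circ_axial_stats(sample).angular_deviation_deg
    # closed-form oracle: E[cos 2Δ] = exp(−2σ²) for wrapped normal
    R = math.exp(-2 * math.radians(sd) ** 2)
    expected = math.degrees(math.sqrt(2 * (1 - R)) / 2)
    assert measured == pytest.approx(expected, abs=0.3)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    hst.lists(hst.floats(-90, 90), min_size=2, max_size=12),
    hst.integers(0, 2**16),
)
def test_axiality_invariance_under_180_shift(angles, pattern):
    """Adding 180° to any subset of angles leaves axial statistics unchanged."""
    shifted = [a + 180.0 * ((pattern >> i) & 1) for i, a in enumerate(angles)]
    a = st.circ_axial_stats(angles)
    b = st.circ_axial_stats(shifted)
    assert a.resultant_length == pytest.approx(b.resultant_length, abs=1e-9)
    assert a.angular_deviation_deg == pytest.approx(b.angular_deviation_deg, abs=1e-7)


def test_empty_angle_sample_rejected():
    with pytest.raises(ValueError):
        st.circ_axial_stats([])


# ---------------------------------------------------------------------------
# Pearson correlation


def test_exact_linear_relation_gives_unit_r():
    x = np.arange(10.0)
    r, r2, p = st.pearson_corr(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_pearson_matches_hand_formula():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 1.0, 4.0])
    r, _, _ = st.pearson_corr(x, y)
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert r == pytest.approx(num / den, abs=1e-12)


def test_pearson_rejects_constant_vectors():
    with pytest.raises(ValueError):
        st.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_type_one_error_rate_calibrated():
    """Independent x, y: rejection rate at α=0.05 lands in [0.04, 0.06]
    over 10⁴ simulations of n=20 (t-distribution calibration)."""
    rng = np.random.default_rng(5)
    n, sims = 20, 10_000
    x = rng.normal(size=(sims, n))
    y = rng.normal(size=(sims, n))
    # vectorized p-values via the same t transform for speed
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy.stats import t as tdist

    pvals = 2 * tdist.sf(np.abs(t), n - 2)
    rate = (pvals < 0.05).mean()
    assert 0.04 <= rate <= 0.06
    # spot-check the vectorized transform against the implementation
    r1, _, p1 = st.pearson_corr(x[0], y[0])
    assert p1 == pytest.approx(pvals[0], rel=1e-9)


# ---------------------------------------------------------------------------
# Levene and ANOVA


def test_levene_identical_groups_zero_W():
    g = [1.0, 2.0, 3.0, 4.0]
    W, p = st.levene_test([g, list(g)])
    assert W == pytest.approx(0.0, abs=1e-12)


def test_levene_matches_hand_formula():
    a = [1.0, 2.0, 6.0]
    b = [3.0, 5.0, 7.0]
    W, _ = st.levene_test([a, b], center="mean")
    # hand computation of W from absolute deviations about group means
    za = [abs(v - np.mean(a)) for v in a]
    zb = [abs(v - np.mean(b)) for v in b]
    zbar = np.mean(za + zb)
    num = (len(a) * (np.mean(za) - zbar) ** 2 + len(b) * (np.mean(zb) - zbar) ** 2) / (2 - 1)
    den = (
        sum((z - np.mean(za)) ** 2 for z in za) + sum((z - np.mean(zb)) ** 2 for z in zb)
    ) / (6 - 2)
    assert W == pytest.approx(num / den, abs=1e-12)


def test_levene_type_one_error_rate_calibrated():
    rng = np.random.default_rng(9)
    hits = 0
    sims = 10_000
    for _ in range(sims):
        g1 = rng.normal(size=15)
        g2 = rng.normal(size=15)
        _, p = st.levene_test([g1, g2])
        hits += p < 0.05
    assert 0.04 <= hits / sims <= 0.06


def test_levene_validates_input():
    with pytest.raises(ValueError):
        st.levene_test([[1.0, 2.0]])
    with pytest.raises(ValueError):
        st.levene_test([[1.0, 2.0], [3.0]])


def test_anova_identical_groups_all_null():
    g = [1.0, 2.0, 3.0, 4.0, 5.0]
    out = st.anova_bonferroni([g, list(g), list(g)])
    assert out["F"] == pytest.approx(0.0, abs=1e-12)
    assert all(v["p_adj"] == 1.0 for v in out["pairwise"].values())


def test_anova_detects_shifted_group():
    rng = np.random.default_rng(3)
    base = [rng.normal(0, 1, 30) for _ in range(2)]
    shifted = rng.normal(3.0, 1, 30)  # Δ = 3σ
    out = st.anova_bonferroni(base + [shifted])
    assert out["pairwise"][(0, 2)]["significant"]
    assert out["pairwise"][(1, 2)]["significant"]
    assert not out["pairwise"][(0, 1)]["significant"]


def test_bonferroni_adjustment_is_capped_product():
    rng = np.random.default_rng(4)
    groups = [rng.normal(size=10) for _ in range(4)]
    out = st.anova_bonferroni(groups)
    m = len(out["pairwise"])
    for v in out["pairwise"].values():
        assert v["p_adj"] == pytest.approx(min(1.0, v["p_raw"] * m))


def test_anova_single_group_rejected():
    with pytest.raises(ValueError):
        st.anova_bonferroni([[1.0, 2.0]])


# ---------------------------------------------------------------------------
# two-response regression


def _toy_data(seed=0, n=20):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {"width": rng.normal(size=n), "alignment": rng.normal(size=n)}
    )
    df["orientation"] = 1 + 2 * df.width - df.alignment + rng.normal(size=n)
    df["aspect_ratio"] = 0.5 - df.width + rng.normal(size=n)
    return df


def test_noiseless_coefficients_recovered_exactly():
    rng = np.random.default_rng(1)
    n = 30
    df = pd.DataFrame({"width": rng.normal(size=n), "alignment": rng.normal(size=n)})
    df["orientation"] = 3.0 + 1.5 * df.width - 0.5 * df.alignment
    df["aspect_ratio"] = -1.0 + 0.25 * df.width
    spec = st.MvRegressionSpec(
        ("orientation", "aspect_ratio"), ("intercept", "width", "alignment"), df
    )
    res = st.mv_regress(spec)
    assert res.coefficients.loc["intercept", "orientation"] == pytest.approx(3.0)
    assert res.coefficients.loc["width", "orientation"] == pytest.approx(1.5)
    assert res.coefficients.loc["alignment", "aspect_ratio"] == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.residual_sscp, 0.0, atol=1e-16)


def test_intercept_only_model_returns_column_means():
    df = _toy_data()
    spec = st.MvRegressionSpec(("orientation", "aspect_ratio"), ("intercept",), df)
    res = st.mv_regress(spec)
    assert res.coefficients.loc["intercept", "orientation"] == pytest.approx(
        df.orientation.mean()
    )
    assert res.coefficients.loc["intercept", "aspect_ratio"] == pytest.approx(
        df.aspect_ratio.mean()
    )


def brute_force_term_test(df, responses, terms, term):
    """SSCP oracle built directly from projection matrices."""
    Y = df[list(responses)].to_numpy()
    n = len(df)

    def X_of(ts):
        cols = []
        for t in ts:
            if t == "intercept":
                cols.append(np.ones(n))
            else:
                v = np.ones(n)
                for c in t.split(":"):
                    v = v * df[c].to_numpy()
                cols.append(v)
        return np.column_stack(cols)

    def P(X):
        return X @ np.linalg.inv(X.T @ X) @ X.T

    Xf = X_of(terms)
    Xr = X_of([t for t in terms if t != term])
    E = Y.T @ (np.eye(n) - P(Xf)) @ Y
    H = Y.T @ (P(Xf) - P(Xr)) @ Y
    V = np.trace(H @ np.linalg.inv(H + E))
    m = len(responses)
    s = min(1, m)
    mm = 0.5 * (abs(1 - m) - 1)
    nn = 0.5 * (n - len(terms) - m - 1)
    df1 = s * (2 * mm + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * (V / (s - V))
    return V, F


def test_term_tests_match_projection_oracle():
    """Per-term Pillai trace and approximate F agree with the brute-force
    SSCP/projection oracle to 10⁻⁸ on a seeded n=20 dataset."""
    df = _toy_data(seed=6, n=20)
    terms = ("intercept", "width", "alignment")
    spec = st.MvRegressionSpec(("orientation", "aspect_ratio"), terms, df)
    res = st.mv_regress(spec)
    for tt in res.term_tests:
        if tt.term == "intercept":
            continue
        V, F = brute_force_term_test(
            df, ("orientation", "aspect_ratio"), terms, tt.term
        )
        assert tt.pillai == pytest.approx(V, abs=1e-8)
        assert tt.approx_F == pytest.approx(F, abs=1e-8)


def test_term_tests_match_statsmodels_manova():
    """Independent library cross-check: Pillai trace and approximate F agree
    with statsmodels MANOVA per term."""
    from statsmodels.multivariate.manova import MANOVA

    df = _toy_data(seed=13, n=40)
    spec = st.MvRegressionSpec(
        ("orientation", "aspect_ratio"), ("intercept", "width", "alignment"), df
    )
    res = st.mv_regress(spec)
    mv = MANOVA.from_formula(
        "orientation + aspect_ratio ~ width + alignment", data=df
    ).mv_test()
    name = {"intercept": "Intercept", "width": "width", "alignment": "alignment"}
    for tt in res.term_tests:
        frame = mv.results[name[tt.term]]["stat"]
        assert tt.pillai == pytest.approx(frame.loc["Pillai's trace", "Value"], abs=1e-10)
        assert tt.approx_F == pytest.approx(
            frame.loc["Pillai's trace", "F Value"], abs=1e-8
        )


def test_single_response_F_equals_univariate_partial_F():
    """With one response the multivariate term F collapses to the classic
    univariate partial (extra-sum-of-squares) F."""
    df = _toy_data(seed=8, n=25)
    spec = st.MvRegressionSpec(("orientation",), ("intercept", "width", "alignment"), df)
    res = st.mv_regress(spec)
    y = df.orientation.to_numpy()
    X_full = np.column_stack([np.ones(25), df.width, df.alignment])
    X_red = np.column_stack([np.ones(25), df.width])
    rss = lambda X: float(
        y @ y - y @ X @ np.linalg.lstsq(X, y, rcond=None)[0]
    )
    partial_F = (rss(X_red) - rss(X_full)) / (rss(X_full) / (25 - 3))
    got = {t.term: t.approx_F for t in res.term_tests}["alignment"]
    assert got == pytest.approx(partial_F, rel=1e-8)


def test_rank_deficiency_is_an_error():
    df = _toy_data()
    df["alignment"] = 2.0 * df["width"]
    spec = st.MvRegressionSpec(
        ("orientation", "aspect_ratio"), ("intercept", "width", "alignment"), df
    )
    with pytest.raises(ValueError, match="rank"):
        st.mv_regress(spec)


def test_hierarchy_enforced_in_spec():
    df = _toy_data()
    with pytest.raises(ValueError, match="hierarchy"):
        st.MvRegressionSpec(
            ("orientation", "aspect_ratio"),
            ("intercept", "width", "width:alignment"),
            df,
        )


# ---------------------------------------------------------------------------
# stepwise selection


def test_intercept_only_start_is_returned_unchanged():
    df = _toy_data()
    spec = st.MvRegressionSpec(("orientation", "aspect_ratio"), ("intercept",), df)
    sel, trace = st.aic_stepwise(spec, direction="backward")
    assert sel.terms == ("intercept",)
    assert len(trace) == 1


def test_trace_is_monotone_nonincreasing_in_aic():
    rng = np.random.default_rng(10)
    n = 300
    df = pd.DataFrame(
        {
            "width": rng.normal(size=n),
            "alignment": rng.normal(size=n),
            "density": rng.normal(size=n),
        }
    )
    df["orientation"] = df.width + rng.normal(size=n)
    df["aspect_ratio"] = df.alignment + rng.normal(size=n)
    spec = st.MvRegressionSpec(
        ("orientation", "aspect_ratio"),
        (
            "intercept",
            "width",
            "alignment",
            "density",
            "width:alignment",
            "alignment:density",
            "width:density",
        ),
        df,
    )
    sel, trace = st.aic_stepwise(spec)
    aics = [t["aic"] for t in trace]
    assert all(a2 <= a1 for a1, a2 in zip(aics, aics[1:]))
    # hierarchy preserved at every step
    for t in trace:
        st.MvRegressionSpec(("orientation", "aspect_ratio"), t["terms"], df)


def test_stepwise_never_drops_strong_main_effects():
    df = _toy_data(seed=11, n=500)
    spec = st.MvRegressionSpec(
        ("orientation", "aspect_ratio"),
        ("intercept", "width", "alignment", "width:alignment"),
        df,
    )
    sel, _ = st.aic_stepwise(spec)
    assert "width" in sel.terms and "alignment" in sel.terms
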