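import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hbref.discrete_centiles import (
    SurveyDesign,
    check_loss,
    check_normality,
    parametric_centile,
    unweighted_sensitivity_centile,
    weighted_qr_centile,
    weighted_quantile,
)
from hbref.reference_filter import InsufficientDataError

Z5 = stats.norm.ppf(0.05)


def brute_force_weighted_quantile(x, w, p):
    """Independent oracle: walk the sorted sample until cumulative weight
    reaches p*W; midpoint when the target lands exactly on a boundary."""
    order = np.argsort(x, kind="stable")
    xs = [x[i] for i in order]
    ws = [w[i] for i in order]
    target = p * sum(ws)
    acc = 0.0
    for i in range(len(xs)):
        acc += ws[i]
        if acc >= target - 1e-9 * sum(ws):
            if i + 1 < len(xs) and abs(acc - target) <= 1e-9 * sum(ws):
                return 0.5 * (xs[i] + xs[i + 1])
            return xs[i]
    return xs[-1]


def make_survey(rng, n, mu=120.0, sigma=10.0, n_strata=2, psus=5,
                weights=None):
    hb = rng.normal(mu, sigma, n)
    stratum = rng.integers(n_strata, size=n)
    psu = rng.integers(psus, size=n)
    if weights is None:
        weights = np.array([50.0, 120.0, 80.0])[stratum % 3] * rng.lognormal(0, 0.3, n)
    return pd.DataFrame({
        "haemoglobin_gL": hb,
        "weight": weights,
        "stratum": [f"s{a}" for a in stratum],
        "psu": [f"s{a}p{b}" for a, b in zip(stratum, psu)],
    })


class TestNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(3).normal(120, 10, 5000)
        rep = check_normality(x)
        assert rep.assessable and rep.passed

    def test_skewed_sample_fails(self):
        x = 100 + np.random.default_rng(3).exponential(10, 5000)
        rep = check_normality(x)
        assert rep.assessable and not rep.passed

    @pytest.mark.parametrize("values", [[120.0] * 20, [1, 2, 3]])
    def test_not_assessable(self, values):
        assert not check_normality(values).assessable


class TestParametricCentile:
    def test_closed_form_estimate_and_se(self):
        rng = np.random.default_rng(8)
        x = rng.normal(130, 10, 500)
        est = parametric_centile(x, 0.05)
        xbar, s, n = np.mean(x), np.std(x, ddof=1), x.size
        assert est.estimate_gL == pytest.approx(xbar + Z5 * s, abs=1e-9)
        assert est.se_gL == pytest.approx(
            s * np.sqrt(1 / n + Z5 ** 2 / (2 * (n - 1))), abs=1e-9)
        zc = stats.norm.ppf(0.95)
        assert est.ci_lo_gL == pytest.approx(est.estimate_gL - zc * est.se_gL)
        assert est.ci_hi_gL == pytest.approx(est.estimate_gL + zc * est.se_gL)

    def test_median_equals_mean(self):
        x = np.random.default_rng(1).normal(120, 10, 100)
        est = parametric_centile(x, 0.5)
        assert est.estimate_gL == pytest.approx(np.mean(x), abs=1e-12)

    def test_degenerate_constant_sample(self):
        est = parametric_centile([120.0] * 50, 0.05)
        assert est.estimate_gL == 120.0
        assert est.se_gL == 0.0
        assert est.ci_lo_gL == est.ci_hi_gL == 120.0

    def test_insufficient_n_raises(self):
        with pytest.raises(InsufficientDataError):
            parametric_centile(np.arange(39.0), 0.05)

    def test_se_formula_matches_monte_carlo(self):
        """sd of xbar + z s over 10^4 Gaussian samples at n=200 within 5%
        of the analytic SE."""
        rng = np.random.default_rng(17)
        n, sigma = 200, 10.0
        draws = rng.normal(120, sigma, (10_000, n))
        ests = draws.mean(axis=1) + Z5 * draws.std(axis=1, ddof=1)
        analytic = sigma * np.sqrt(1 / n + Z5 ** 2 / (2 * (n - 1)))
        assert np.std(ests) == pytest.approx(analytic, rel=0.05)

    def test_ci_width_shrinks_as_root_n(self):
        rng = np.random.default_rng(23)
        widths = {}
        for n in (100, 400):
            w = []
            for _ in range(400):
                est = parametric_centile(rng.normal(120, 10, n), 0.05)
                w.append(est.ci_hi_gL - est.ci_lo_gL)
            widths[n] = np.mean(w)
        assert widths[100] / widths[400] == pytest.approx(2.0, rel=0.10)


class TestWeightedQuantile:
    def test_equal_weights_match_sorted_order_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(5, 200))
            x = rng.normal(120, 10, n)
            w = np.ones(n)
            assert weighted_quantile(x, w, 0.05) == \
                brute_force_weighted_quantile(x, w, 0.05)

    def test_exactness_against_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            n = int(rng.integers(2, 200))
            x = np.round(rng.normal(120, 10, n), 1)   # induce ties
            w = rng.choice([0.5, 1.0, 2.0, 5.0], n)
            p = rng.choice([0.025, 0.05, 0.25, 0.5])
            assert weighted_quantile(x, w, p) == \
                brute_force_weighted_quantile(x, w, p)

    def test_minimises_check_loss(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(2, 100))
            x = rng.normal(0, 1, n)
            w = rng.uniform(0.1, 3.0, n)
            p = float(rng.uniform(0.02, 0.98))
            q = weighted_quantile(x, w, p)
            best = min(check_loss(x, w, p, c) for c in x)
            assert check_loss(x, w, p, q) <= best + 1e-9

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(min_value=50, max_value=200),
                      st.floats(min_value=0.1, max_value=5)),
            min_size=1, max_size=60),
        p=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_bounded_and_loss_optimal_on_arbitrary_samples(self, data, p):
        x = np.array([d[0] for d in data])
        w = np.array([d[1] for d in data])
        q = weighted_quantile(x, w, p)
        assert x.min() <= q <= x.max()
        best = min(check_loss(x, w, p, c) for c in x)
        assert check_loss(x, w, p, q) <= best + 1e-9

    def test_duplication_equals_doubled_weight(self):
        x = np.array([100.0, 110.0, 120.0, 130.0])
        w = np.array([1.0, 1.0, 1.0, 1.0])
        x2 = np.append(x, 110.0)
        w2 = np.ones(5)
        wd = np.array([1.0, 2.0, 1.0, 1.0])
        for p in (0.05, 0.25, 0.5, 0.9):
            assert weighted_quantile(x2, w2, p) == weighted_quantile(x, wd, p)


class TestWeightedQRCentile:
    def test_equal_weights_single_stratum_matches_unweighted_quantile(self):
        rng = np.random.default_rng(9)
        n = 500
        frame = pd.DataFrame({
            "haemoglobin_gL": rng.normal(120, 10, n),
            "weight": 1.0,
            "stratum": "s0",
            "psu": [f"p{i % 10}" for i in range(n)],
        })
        est = weighted_qr_centile(frame, 0.05, SurveyDesign(B=50, seed=0))
        x = frame["haemoglobin_gL"].to_numpy()
        assert est.estimate_gL == brute_force_weighted_quantile(x, np.ones(n), 0.05)

    def test_seeded_determinism(self):
        frame = make_survey(np.random.default_rng(10), 400)
        a = weighted_qr_centile(frame, 0.05, SurveyDesign(B=200, seed=3))
        b = weighted_qr_centile(frame, 0.05, SurveyDesign(B=200, seed=3))
        assert (a.estimate_gL, a.se_gL) == (b.estimate_gL, b.se_gL)
        c = weighted_qr_centile(frame, 0.05, SurveyDesign(B=200, seed=4))
        assert a.se_gL != c.se_gL

    def test_single_psu_stratum_is_an_error(self):
        frame = make_survey(np.random.default_rng(11), 100, psus=1)
        with pytest.raises(ValueError, match="collapse"):
            weighted_qr_centile(frame, 0.05, SurveyDesign(B=20, seed=0))

    def test_weighting_shifts_estimate_towards_upweighted_subpopulation(self):
        # two subpopulations with different haemoglobin levels; the low one
        # carries large weights, so the weighted centile must fall below the
        # unweighted parametric estimate
        rng = np.random.default_rng(12)
        n = 1000
        low = rng.random(n) < 0.3
        hb = np.where(low, rng.normal(105, 8, n), rng.normal(125, 8, n))
        frame = pd.DataFrame({
            "haemoglobin_gL": hb,
            "weight": np.where(low, 10.0, 1.0),
            "stratum": "s0",
            "psu": [f"p{i % 8}" for i in range(n)],
        })
        weighted = weighted_qr_centile(frame, 0.05, SurveyDesign(B=50, seed=1))
        unweighted = unweighted_sensitivity_centile(frame, 0.05)
        oracle_w = brute_force_weighted_quantile(hb, frame["weight"].to_numpy(), 0.05)
        oracle_u = brute_force_weighted_quantile(hb, np.ones(n), 0.05)
        assert weighted.estimate_gL == oracle_w
        assert oracle_w < oracle_u
        assert weighted.estimate_gL < unweighted.estimate_gL

    def test_unweighted_sensitivity_delegates_to_parametric(self):
        frame = make_survey(np.random.default_rng(13), 300)
        a = unweighted_sensitivity_centile(frame, 0.05)
        b = parametric_centile(frame["haemoglobin_gL"].to_numpy(), 0.05)
        assert a.estimate_gL == b.estimate_gL and a.se_gL == b.se_gL
        assert a.method == "unweighted_parametric_sensitivity"
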