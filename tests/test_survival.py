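"""Classification rules, cutoff scaling and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from gsvdcna.survival import (
    classify_by_correlation,
    classify_by_probelet,
    cox_ph,
    dichotomize_age,
    km_estimate,
    logrank_test,
    scale_cutoff,
)

# hand-tabulated log-rank chi-square for (1,2,3) vs (4,5,6), all deaths:
# O-E = 3 - (1/2 + 2/5 + 1/4), Var = 1/4 + 6/25 + 3/16
LOGRANK_SEPARATED = (3 - 1.15) ** 2 / 0.6775


class TestProbeletClassification:
    def test_three_way_rule(self):
        labels = [c.label for c in classify_by_probelet([0.05, 0.001, -0.03], 0.02)]
        assert labels == ["high", "low", "unclassified"]

    def test_all_within_cutoff_low(self):
        labels = [c.label for c in classify_by_probelet([0.01, -0.02, 0.0], 0.02)]
        assert labels == ["low", "low", "low"]

    def test_boundary_is_low(self):
        assert classify_by_probelet([0.02], 0.02)[0].label == "low"
        assert classify_by_probelet([-0.02], 0.02)[0].label == "low"


class TestScaleCutoff:
    def test_norm_ratio(self):
        assert scale_cutoff(0.02, [1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.02)
        assert scale_cutoff(0.02, [2.0, 0.0], [1.0, 0.0]) == pytest.approx(0.01)
        ref = np.array([1.0, 1.0])
        new = 0.85 * ref
        assert scale_cutoff(0.02, ref, new) == pytest.approx(0.017)

    def test_zero_reference_fails(self):
        with pytest.raises(ValueError):
            scale_cutoff(0.02, [0.0, 0.0], [1.0, 1.0])


class TestCorrelationClassification:
    def test_proportional_profile_is_high(self, rng):
        ref = rng.normal(size=200)
        profiles = pd.DataFrame({"P1": 3.0 * ref})
        (cls,) = classify_by_correlation(profiles, ref, cutoff=0.15)
        assert cls.label == "high"
        assert cls.score == pytest.approx(1.0)

    def test_independent_noise_is_low(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=2000)
        low = 0
        for s in range(20):
            prof = pd.DataFrame({"P": np.random.default_rng(100 + s).normal(size=2000)})
            (cls,) = classify_by_correlation(prof, ref, cutoff=0.15)
            low += cls.label == "low"
        assert low >= 19   # |r| ~ 1/sqrt(2000) << 0.15

    def test_insufficient_overlap_rejected(self, rng):
        ref = rng.normal(size=100)
        prof = ref.copy()
        prof[:4] = np.nan   # 96% overlap < 97.5%
        (cls,) = classify_by_correlation(pd.DataFrame({"P": prof}), ref)
        assert cls.label == "rejected"
        assert "overlap" in cls.reason


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1], ["g"] * 3)["g"]
        surv = km["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3, abs=1e-12)
        assert surv.loc[2.0] == pytest.approx(1 / 3, abs=1e-12)
        assert surv.loc[3.0] == pytest.approx(0.0, abs=1e-12)
        assert km["median"] == 2.0

    def test_censoring_adjusts_risk_set(self):
        km = km_estimate([1, 2, 3], [0, 1, 1], ["g"] * 3)["g"]
        assert km["survival"].loc[2.0] == pytest.approx(0.5, abs=1e-12)
        assert km["survival"].loc[3.0] == pytest.approx(0.0, abs=1e-12)
        assert km["median"] == 2.0

    def test_all_censored_median_undefined(self):
        km = km_estimate([1, 2, 3], [0, 0, 0], ["g"] * 3)["g"]
        assert (km["survival"] == 1.0).all()
        assert np.isinf(km["median"])

    def test_no_censoring_matches_empirical(self, rng):
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40, dtype=bool), ["g"] * 40)["g"]
        for time in np.sort(t):
            assert km["survival"].loc[time] == pytest.approx((t > time).mean(), abs=1e-12)

    def test_negative_times_fail(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1], ["g", "g"])


class TestLogrank:
    def test_identical_groups_null(self):
        chi, p = logrank_test([1, 2, 3, 1, 2, 3], [1] * 6, ["a"] * 3 + ["b"] * 3)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_tabulated_value(self):
        chi, _ = logrank_test([1, 2, 3, 4, 5, 6], [1] * 6, ["a"] * 3 + ["b"] * 3)
        assert chi == pytest.approx(LOGRANK_SEPARATED, abs=1e-12)

    def test_label_symmetry(self, rng):
        t = rng.exponential(5, 30)
        e = rng.random(30) < 0.8
        g = np.array(["a"] * 15 + ["b"] * 15)
        chi1, p1 = logrank_test(t, e, g)
        chi2, p2 = logrank_test(t, e, np.where(g == "a", "b", "a"))
        assert chi1 == pytest.approx(chi2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_no_events_fails(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], ["a", "b"])


def efron_partial_loglik(beta, time, event, x):
    """Independent oracle: Efron-tie partial log-likelihood."""
    ll = 0.0
    for ut in np.unique(time[event]):
        d = (time == ut) & event
        risk = time >= ut
        m = int(d.sum())
        xr = np.exp(beta * x[risk]).sum()
        xd = np.exp(beta * x[d]).sum()
        ll += beta * x[d].sum()
        for ell in range(m):
            ll -= np.log(xr - ell / m * xd)
    return ll


class TestCox:
    def make_sample(self, seed=42, n=120, beta=0.7):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(beta * x))
        c = rng.exponential(3.0, n)
        return np.minimum(t, c), t <= c, x

    def test_matches_partial_likelihood_grid_oracle(self):
        time, event, x = self.make_sample()
        res = cox_ph(time, event, pd.DataFrame({"x": x}))
        beta_hat = float(res.loc["x", "coef"])
        opt = minimize_scalar(
            lambda b: -efron_partial_loglik(b, time, event, x),
            bounds=(-3, 3), method="bounded", options={"xatol": 1e-9},
        )
        assert abs(beta_hat - opt.x) < 1e-3

    def test_negated_covariate_reciprocal_hazard(self):
        time, event, x = self.make_sample(7)
        hr = cox_ph(time, event, pd.DataFrame({"x": x})).loc["x", "hazard_ratio"]
        hr_neg = cox_ph(time, event, pd.DataFrame({"x": -x})).loc["x", "hazard_ratio"]
        assert hr * hr_neg == pytest.approx(1.0, rel=1e-8)

    def test_null_covariate_calibration(self):
        """A covariate independent of survival at n=500: log-HR is small."""
        rng = np.random.default_rng(99)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n)
        res = cox_ph(t, np.ones(n, dtype=bool), pd.DataFrame({"x": x}))
        assert abs(res.loc["x", "coef"]) < 0.25
        assert res.loc["x", "p"] > 0.01

    def test_constant_covariate_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            cox_ph([1, 2, 3], [1, 1, 1], pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_no_events_fails(self):
        with pytest.raises(ValueError):
            cox_ph([1, 2], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestAgeDichotomy:
    def test_threshold_and_boundary(self):
        labels = dichotomize_age(pd.Series([45.0, 55.0, 50.0], index=list("abc")))
        assert labels.tolist() == ["younger", "older", "younger"]

    def test_missing_age_excluded(self):
        labels = dichotomize_age(pd.Series([45.0, np.nan, 60.0], index=list("abc")))
        assert list(labels.index) == ["a", "c"]

    def test_single_sided_warns_only(self, caplog):
        labels = dichotomize_age(pd.Series([30.0, 40.0]))
        assert (labels == "younger").all()
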