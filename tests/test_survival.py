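import numpy as np
import pandas as pd
import pytest

from decif import cox_fit, km_estimate, logrank_test, simulate_survival
from decif.survival import CoxResult


def _records(times, events, group=None):
    df = pd.DataFrame({"os_time": times, "os_event": events})
    if group is not None:
        df["group"] = group
    return df


class TestKm:
    def test_no_events_survival_stays_one(self):
        curves, _ = km_estimate(_records([5.0, 8.0, 12.0], [0, 0, 0]))
        assert (curves["all"]["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        curves, _ = km_estimate(_records([1.0, 2.0, 3.0], [1, 1, 1]))
        c = curves["all"].set_index("time")["survival"]
        assert c.loc[1.0] == pytest.approx(2 / 3)
        assert c.loc[2.0] == pytest.approx(1 / 3)
        assert c.loc[3.0] == pytest.approx(0.0)

    def test_all_event_data_equals_empirical_survivor(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=50)
        curves, _ = km_estimate(_records(t, np.ones(50, dtype=int)))
        c = curves["all"]
        emp = [(t > u).mean() for u in c["time"]]
        assert np.allclose(c["survival"], emp)

    def test_censored_at_start_only_shrinks_risk_set(self):
        base, _ = km_estimate(_records([1.0, 2.0], [1, 1]))
        with_c0, _ = km_estimate(_records([0.0, 1.0, 2.0], [0, 1, 1]))
        # the t=0 censored record leaves the estimate at later times unchanged
        a = base["all"].set_index("time")["survival"]
        b = with_c0["all"].set_index("time")["survival"]
        assert a.loc[1.0] == pytest.approx(b.loc[1.0])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(_records([-1.0, 2.0], [1, 1]))

    def test_median_followup_reverse_km(self):
        # reverse KM: censorings at 10 and 20 are the "events"; S drops to
        # 0.5 at t=10, so the median follow-up is 10
        _, med = km_estimate(_records([5.0, 10.0, 20.0], [1, 0, 0]))
        assert med == pytest.approx(10.0)


class TestLogrank:
    def test_identical_groups_near_zero(self):
        t = [1.0, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        rec = _records(t + t, e + e, ["a"] * 5 + ["b"] * 5)
        chi2, p = logrank_test(rec, "group")
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_computed_score_statistic(self):
        # independent oracle: O-E over event times, variance of the
        # hypergeometric at each time (no ties -> exact log-rank)
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 0])
        g = np.array(["a", "b", "a", "b", "a", "b"])
        rec = _records(t, e, g)
        o_minus_e = 0.0
        var = 0.0
        for ti in t[e == 1]:
            at_risk = t >= ti
            n = at_risk.sum()
            n_a = (at_risk & (g == "a")).sum()
            died_a = float(((t == ti) & (e == 1) & (g == "a")).any())
            o_minus_e += died_a - n_a / n
            var += (n_a / n) * (1 - n_a / n)
        chi2_hand = o_minus_e ** 2 / var
        chi2, p = logrank_test(rec, "group")
        assert chi2 == pytest.approx(chi2_hand, rel=1e-6)

    def test_four_group_df_contract(self):
        rng = np.random.default_rng(1)
        lab = pd.Series(rng.choice(list("abcd"), size=80),
                        index=[f"s{i}" for i in range(80)])
        clin = simulate_survival(lab, {k: 1.0 for k in "abcd"}, seed=2)
        chi2, p = logrank_test(clin, "group")
        from scipy.stats import chi2 as chi2_dist
        assert p == pytest.approx(chi2_dist.sf(chi2, 3), rel=1e-6)

    def test_requires_two_groups_and_events(self):
        with pytest.raises(ValueError):
            logrank_test(_records([1.0, 2.0], [1, 1], ["a", "a"]), "group")
        with pytest.raises(ValueError):
            logrank_test(_records([1.0, 2.0], [0, 0], ["a", "b"]), "group")


class TestCox:
    def test_two_group_hr_and_reference_inversion(self):
        rng = np.random.default_rng(3)
        lab = pd.Series(np.where(rng.random(400) < 0.5, "hi", "lo"),
                        index=[f"s{i}" for i in range(400)])
        clin = simulate_survival(lab, {"hi": 2.5, "lo": 1.0}, seed=4)
        fwd = cox_fit(clin, ["group"], {"group": "lo"})[0]
        rev = cox_fit(clin, ["group"], {"group": "hi"})[0]
        assert fwd.hr == pytest.approx(1 / rev.hr, rel=1e-6)
        assert fwd.ci_low == pytest.approx(1 / rev.ci_high, rel=1e-6)
        assert fwd.ci_low <= fwd.hr <= fwd.ci_high

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        lab = pd.Series(np.where(rng.random(200) < 0.5, "hi", "lo"),
                        index=[f"s{i}" for i in range(200)])
        clin = simulate_survival(lab, {"hi": 2.0, "lo": 1.0}, seed=6)
        months = cox_fit(clin, ["group"], {"group": "lo"})[0]
        years = clin.copy()
        years["os_time"] = years["os_time"] / 12.0
        rescaled = cox_fit(years, ["group"], {"group": "lo"})[0]
        assert months.hr == pytest.approx(rescaled.hr, rel=1e-6)

    def test_continuous_covariate_supported(self):
        rng = np.random.default_rng(7)
        n = 300
        age = rng.uniform(40, 70, n)
        lam = 0.004 * np.exp(0.03 * (age - 55))
        t = rng.exponential(1 / lam)
        c = rng.exponential(1 / 0.0027, n)
        rec = pd.DataFrame({"os_time": np.minimum(t, c),
                            "os_event": (t <= c).astype(int), "age": age})
        res = cox_fit(rec, ["age"])[0]
        assert res.ci_low < np.exp(0.03) < res.ci_high

    def test_bivariate_adjustment_reports_both_terms(self):
        rng = np.random.default_rng(8)
        n = 300
        lab = pd.Series(np.where(rng.random(n) < 0.3, "ECM3+/IFN-", "other"),
                        index=[f"s{i}" for i in range(n)])
        clin = simulate_survival(lab, {"ECM3+/IFN-": 3.2, "other": 1.0}, seed=9)
        clin["age"] = rng.uniform(40, 70, n)
        res = cox_fit(clin, ["group", "age"], {"group": "other"})
        terms = {r.term for r in res}
        assert any("group" in t for t in terms) and "age" in terms
        grp = next(r for r in res if "group" in r.term)
        assert grp.adjusted_for == ["age"]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit(_records([1.0, 2.0], [0, 0], ["a", "b"]), ["group"],
                    {"group": "a"})

    def test_logrank_equals_cox_score_relationship(self):
        # untied two-group data: log-rank == Cox score test at beta=0;
        # Wald chi-square agrees to first order on moderate effects
        rng = np.random.default_rng(10)
        lab = pd.Series(np.where(rng.random(300) < 0.5, "a", "b"),
                        index=[f"s{i}" for i in range(300)])
        clin = simulate_survival(lab, {"a": 1.4, "b": 1.0}, seed=11)
        chi2, _ = logrank_test(clin, "group")
        res = cox_fit(clin, ["group"], {"group": "b"})[0]
        wald = (np.log(res.hr) / ((np.log(res.ci_high) - np.log(res.hr)) / 1.959964)) ** 2
        assert chi2 == pytest.approx(wald, rel=0.15)


def test_cox_result_invariants():
    with pytest.raises(ValueError):
        CoxResult("t", hr=-1.0, ci_low=0.5, ci_high=2.0, p_value=0.5,
                  reference_category=None, n=10, adjusted_for=[])
    with pytest.raises(ValueError):
        CoxResult("t", hr=2.0, ci_low=2.5, ci_high=3.0, p_value=0.5,
                  reference_category=None, n=10, adjusted_for=[])
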