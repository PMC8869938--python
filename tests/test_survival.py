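import numpy as np
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

from endorisk.cohort import Cohort
from endorisk.survival import (
    CoxNoFitError,
    concordance,
    cox_fit,
    cox_ordinal_by_group,
    endpoint_arrays,
    goodman_kruskal_gamma,
    km_estimate,
    logrank_test,
    survival_at,
    univariate_screen,
)

from .conftest import harrell_pairs_bruteforce, make_record


# ---------------------------------------------------------------------------
# Kaplan–Meier


def test_km_all_censored_stays_at_one():
    curve = km_estimate(np.arange(1, 11, dtype=float), np.zeros(10, bool))
    assert curve.event_times.size == 0
    assert survival_at(curve, 5.0) == 1.0


def test_km_hand_product_limit():
    curve = km_estimate([10.0, 20.0, 30.0], [True, True, True])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])
    # Greenwood at t=10: S^2 * d/(n(n-d)) = (2/3)^2 * 1/6
    np.testing.assert_allclose(curve.greenwood_var[0], (2 / 3) ** 2 / 6)
    assert survival_at(curve, 25.0) == pytest.approx(1 / 3)
    assert survival_at(curve, 0.0) == 1.0


def test_km_censoring_after_tied_event():
    # a censoring tied with an event stays in the risk set for that event
    curve = km_estimate([10.0, 10.0, 20.0], [True, False, True])
    np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
    assert curve.at_risk[0] == 3


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(42)
    t = rng.exponential(30, size=300)
    curve = km_estimate(t, np.ones_like(t, bool))
    for q in [5.0, 20.0, 50.0]:
        assert survival_at(curve, q) == pytest.approx((t > q).mean())


def test_survival_at_extrapolation_warns():
    curve = km_estimate([10.0, 20.0], [True, False])
    with pytest.warns(UserWarning, match="extrapolation"):
        val = survival_at(curve, 100.0)
    assert val == pytest.approx(0.5)


def test_km_rejects_degenerate_input():
    with pytest.raises(ValueError):
        km_estimate([], [])
    with pytest.raises(ValueError):
        km_estimate([0.0, 0.0], [True, True])
    curve = km_estimate([5.0], [True])
    with pytest.raises(ValueError):
        survival_at(curve, -1.0)


def test_km_ci_brackets_estimate():
    rng = np.random.default_rng(0)
    t = rng.exponential(40, 200)
    e = rng.random(200) < 0.7
    curve = km_estimate(t, e)
    inner = curve.survival > 0
    assert (curve.ci_low[inner] <= curve.survival[inner] + 1e-12).all()
    assert (curve.ci_high[inner] >= curve.survival[inner] - 1e-12).all()


# ---------------------------------------------------------------------------
# Cox fits


def _two_group_sim(rng, n, hr, censor=None):
    x = rng.integers(0, 2, n).astype(float)
    lam = 0.02 * hr**x
    t = rng.exponential(1 / lam)
    if censor is None:
        return t, np.ones(n, bool), x
    c = rng.uniform(0, censor, n)
    return np.minimum(t, c), t <= c, x


def test_cox_null_recovery():
    rng = np.random.default_rng(1)
    t, e, x = _two_group_sim(rng, 2000, hr=1.0)
    fit = cox_fit(t, e, x)
    assert abs(fit.beta) < 3 * fit.se
    assert fit.converged


def test_cox_recovers_true_hazard_ratio():
    rng = np.random.default_rng(2)
    t, e, x = _two_group_sim(rng, 4000, hr=2.0)
    fit = cox_fit(t, e, x)
    assert abs(fit.beta - np.log(2)) < 3 * fit.se
    assert fit.ci95[0] < fit.hr < fit.ci95[1]


def test_cox_matches_lifelines_cross_check():
    import pandas as pd
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(3)
    t, e, x = _two_group_sim(rng, 500, hr=1.8, censor=120)
    fit = cox_fit(t, e, x, ties="efron")
    cph = CoxPHFitter().fit(
        pd.DataFrame({"t": t, "e": e.astype(int), "x": x}),
        duration_col="t",
        event_col="e",
    )
    assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
    assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)


def test_cox_degenerate_covariate_errors():
    with pytest.raises(CoxNoFitError, match="constant"):
        cox_fit([1.0, 2.0, 3.0], [True, True, False], [1.0, 1.0, 1.0])
    with pytest.raises(CoxNoFitError, match="events"):
        cox_fit([1.0, 2.0], [False, False], [0.0, 1.0])


def test_cox_separation_is_flagged_not_silent():
    # perfectly separated groups: monotone partial likelihood
    t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    e = np.ones(6, bool)
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    fit = cox_fit(t, e, x)
    assert not fit.converged


def test_ordinal_sign_and_null():
    rng = np.random.default_rng(4)
    n = 1500
    groups = rng.integers(0, 3, n)
    labels = np.array(["low", "intermediate", "high"])[groups]
    lam = 0.01 * 2.0**groups
    t = rng.exponential(1 / lam)
    fit = cox_ordinal_by_group(labels, t, np.ones(n, bool), ["low", "intermediate", "high"])
    assert fit.beta > 0
    assert "low=1" in fit.covariate_coding and "high=3" in fit.covariate_coding

    lam0 = np.full(n, 0.01)
    t0 = rng.exponential(1 / lam0)
    fit0 = cox_ordinal_by_group(labels, t0, np.ones(n, bool), ["low", "intermediate", "high"])
    assert abs(fit0.beta) < 3 * fit0.se


def test_ordinal_skips_empty_rank():
    rng = np.random.default_rng(5)
    labels = np.array(["low"] * 50 + ["high"] * 50)
    t = rng.exponential(50, 100)
    fit = cox_ordinal_by_group(labels, t, np.ones(100, bool), ["low", "intermediate", "high"])
    assert fit.covariate_coding == "ordinal low=1, high=2"


# ---------------------------------------------------------------------------
# Concordance


def test_concordance_perfect_anti_ordering():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    res = concordance([4.0, 3.0, 2.0, 1.0], t, np.ones(4, bool))
    assert res.c_index == 1.0
    assert res.permissible == 6


def test_concordance_constant_scores_is_half():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    res = concordance([7.0] * 4, t, np.ones(4, bool))
    assert res.c_index == 0.5
    assert res.tied == res.permissible


def test_concordance_worked_example_all_six_pairs():
    """times (2,4,6,8), events (1,1,0,1), scores (4,3,2,1): pairs (1,2),
    (1,3), (1,4), (2,3), (2,4), (4,3 not permissible? censored at 6 precedes 8)
    — enumerated independently by the brute-force oracle."""
    t = [2.0, 4.0, 6.0, 8.0]
    e = [True, True, False, True]
    s = [4.0, 3.0, 2.0, 1.0]
    conc, disc, tied = harrell_pairs_bruteforce(s, t, e)
    res = concordance(s, t, e)
    assert (res.concordant, res.discordant, res.tied) == (conc, disc, tied) == (5, 0, 0)
    assert res.c_index == 1.0


def test_concordance_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(6)
    for _ in range(100):
        n = rng.integers(2, 31)
        t = rng.integers(1, 10, n).astype(float)  # ties likely
        e = rng.random(n) < 0.6
        s = rng.integers(0, 5, n).astype(float)  # score ties likely
        if not e.any():
            continue
        conc, disc, tied = harrell_pairs_bruteforce(s, t, e)
        if conc + disc + tied == 0:
            with pytest.raises(ValueError):
                concordance(s, t, e)
            continue
        res = concordance(s, t, e)
        assert (res.concordant, res.discordant, res.tied) == (conc, disc, tied)


def test_concordance_rank_invariance_and_reversal():
    rng = np.random.default_rng(7)
    n = 200
    t = rng.exponential(50, n)
    e = rng.random(n) < 0.7
    s = rng.normal(size=n)
    base = concordance(s, t, e)
    monotone = concordance(np.exp(2 * s) + 5, t, e)
    assert monotone.c_index == pytest.approx(base.c_index)
    reversed_ = concordance(-s, t, e)
    assert reversed_.c_index == pytest.approx(1 - base.c_index)


def test_concordance_agrees_with_lifelines():
    rng = np.random.default_rng(8)
    n = 300
    t = rng.exponential(50, n)
    e = rng.random(n) < 0.7
    s = rng.normal(size=n)
    res = concordance(s, t, e)
    # lifelines orders by predicted survival time (higher = longer), so pass -s
    assert res.c_index == pytest.approx(lifelines_cindex(t, -s, e))


def test_goodman_kruskal_gamma_from_pair_counts():
    rng = np.random.default_rng(9)
    t = rng.exponential(50, 100)
    e = rng.random(100) < 0.8
    s = rng.integers(0, 3, 100).astype(float)
    res = concordance(s, t, e)
    expected = (res.concordant - res.discordant) / (res.concordant + res.discordant)
    assert goodman_kruskal_gamma(res) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Log-rank


def test_logrank_identical_groups_statistic_zero():
    t = np.array([5.0, 10.0, 15.0, 20.0] * 2)
    e = np.array([1, 1, 0, 1] * 2, bool)
    labels = ["a"] * 4 + ["b"] * 4
    res = logrank_test(labels, t, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.df == 1


def test_logrank_three_groups_df_two():
    rng = np.random.default_rng(10)
    t = rng.exponential(30, 90)
    e = np.ones(90, bool)
    labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
    assert logrank_test(labels, t, e).df == 2


def test_logrank_single_group_errors():
    with pytest.raises(ValueError):
        logrank_test(["a", "a"], [1.0, 2.0], [True, True])


def test_logrank_power_under_strong_effect():
    """Two groups with a three-fold hazard ratio: the test should reject at
    the 5% level in nearly every seeded replicate."""
    rejections = 0
    n_rep = 50
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        lam = np.repeat([0.01, 0.03], 200)
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 150, 400)
        labels = np.repeat(["a", "b"], 200)
        res = logrank_test(labels, np.minimum(t, c), t <= c)
        rejections += res.p_value < 0.05
    assert rejections >= int(0.95 * n_rep)


# ---------------------------------------------------------------------------
# Univariate screen


def _screen_cohort(seed=0, n=600, er_hr=0.4):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        er = "positive" if rng.random() < 0.6 else "negative"
        lam = 0.02 * (er_hr if er == "positive" else 1.0)
        t = float(rng.exponential(1 / lam))
        c = float(rng.uniform(3, 147))
        records.append(
            make_record(
                f"P{i}",
                er=er,
                rfs_time_months=round(min(t, c), 2),
                rfs_event=t <= c,
                os_time_months=round(min(t, c), 2) + 1.0,
                os_event=False,
            )
        )
    return Cohort.from_records(records)


def test_univariate_screen_recovers_protective_er_effect():
    cohort = _screen_cohort(seed=11)
    table = univariate_screen(cohort, ["er"], endpoint="rfs")
    row = table.iloc[0]
    assert row["ci_low"] < 0.4 < row["ci_high"]
    assert row["hr"] < 1.0


def test_univariate_screen_no_fit_for_single_level(record_factory):
    cohort = Cohort.from_records(
        [
            record_factory("P1", pr="positive", rfs_event=True, rfs_time_months=10.0,
                           os_time_months=12.0),
            record_factory("P2", pr="positive"),
            record_factory("P3", pr="NE"),
        ]
    )
    table = univariate_screen(cohort, ["pr"], endpoint="rfs")
    assert table.iloc[0]["note"].startswith("no fit")
    assert np.isnan(table.iloc[0]["hr"])


def test_univariate_screen_excludes_ne_per_covariate(record_factory):
    cohort = Cohort.from_records(
        [record_factory(f"P{i}", er="NE" if i < 3 else "positive") for i in range(6)]
    )
    table = univariate_screen(cohort, ["er"], endpoint="rfs")
    assert table.iloc[0]["n"] == 3


def test_endpoint_arrays_validation(small_cohort):
    t, e = endpoint_arrays(small_cohort, "os")
    assert t.shape == (3,) and e.dtype == bool
    with pytest.raises(ValueError):
        endpoint_arrays(small_cohort, "pfs")
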