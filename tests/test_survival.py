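"""Risk groups, endpoints, Kaplan-Meier, log-rank, Cox."""

import numpy as np
import pandas as pd
import pytest

from methmark import simulate, survival


def _rec(stage, mycn, age_days, outcome, followup, relapse=pd.NA):
    return {
        "sample": "s",
        "stage": stage,
        "mycn": mycn,
        "age_days": age_days,
        "outcome": outcome,
        "followup_days": followup,
        "relapse_days": relapse,
    }


@pytest.mark.parametrize(
    "rec,expected",
    [
        (_rec("4", "single_copy", 500, "dod", 600), "HR-DOD"),
        (_rec("3", "amplified", 800, "dod", 400), "HR-DOD"),
        (_rec("4", "amplified", 200, "dod", 300), "HR-DOD"),
        (_rec("1", "single_copy", 400, "alive", 1200), "LR-SURV"),
        (_rec("3", "single_copy", 200, "alive", 1500), "LR-SURV"),
        (_rec("4", "amplified", 900, "alive", 1500), "HR-SURV"),
        # boundary/negative cases
        (_rec("1", "single_copy", 400, "alive", 900), "unassigned"),
        (_rec("3", "single_copy", 800, "alive", 1500), "unassigned"),
        (_rec("1", "single_copy", 400, "dod", 600), "unassigned"),
        (_rec("4S", "single_copy", 100, "alive", 1500), "unassigned"),
    ],
)
def test_assign_risk_group(rec, expected):
    assert survival.assign_risk_group(rec) == expected


def test_os_efs_definitions():
    clin = pd.DataFrame(
        [
            _rec("4", "amplified", 500, "alive", 1800) | {"sample": "a"},
            _rec("4", "amplified", 500, "dod", 900, relapse=400) | {"sample": "b"},
            _rec("4", "amplified", 500, "dod", 700) | {"sample": "c"},
        ]
    )
    rec = survival.os_efs(clin)
    assert tuple(rec.loc["a", ["os_time", "os_event"]]) == (1800, 0)
    assert tuple(rec.loc["a", ["efs_time", "efs_event"]]) == (1800, 0)
    assert tuple(rec.loc["b", ["efs_time", "efs_event"]]) == (400, 1)
    assert tuple(rec.loc["b", ["os_time", "os_event"]]) == (900, 1)
    assert tuple(rec.loc["c", ["os_time", "os_event"]]) == (700, 1)
    assert tuple(rec.loc["c", ["efs_time", "efs_event"]]) == (700, 1)


def test_relapse_after_followup_rejected():
    clin = pd.DataFrame([_rec("4", "amplified", 500, "dod", 600, relapse=700)])
    with pytest.raises(ValueError, match="relapse"):
        survival.os_efs(clin)


def test_km_no_events_flat():
    km = survival.km_curve([100, 200, 300], [0, 0, 0], censor_at=None)
    assert np.all(km.survival == 1.0)


def test_km_hand_risk_sets():
    km = survival.km_curve([1, 2, 3], [0, 1, 1], censor_at=None)
    s = dict(zip(km.times, km.survival))
    assert s[2.0] == pytest.approx(0.5)
    assert s[3.0] == pytest.approx(0.0)


def test_km_administrative_censoring():
    km = survival.km_curve([2500], [1], censor_at=2000)
    assert km.survival[-1] == 1.0
    assert 2000 in km.censor_times


def test_km_equals_empirical_without_censoring():
    rng = np.random.default_rng(0)
    t = rng.exponential(100, size=50)
    km = survival.km_curve(t, np.ones(50, dtype=int), censor_at=None)
    for time, s in zip(km.times, km.survival):
        assert s == pytest.approx((t > time).mean(), abs=1e-12)


def test_logrank_identical_groups():
    t = [1, 2, 3, 4, 1, 2, 3, 4]
    e = [1, 1, 0, 1] * 2
    g = ["A"] * 4 + ["B"] * 4
    res = survival.logrank(t, e, g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_hand_example():
    res = survival.logrank([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert res.statistic == pytest.approx(2.882, abs=2e-3)
    assert res.p == pytest.approx(0.0896, abs=2e-3)


def test_logrank_single_group_rejected():
    with pytest.raises(ValueError):
        survival.logrank([1, 2], [1, 1], ["A", "A"])


def test_logrank_agrees_with_lifelines():
    from lifelines.statistics import multivariate_logrank_test

    rng = np.random.default_rng(5)
    t = rng.exponential(50, 60)
    e = rng.integers(0, 2, 60)
    g = rng.choice(["A", "B", "C"], 60)
    ours = survival.logrank(t, e, g)
    ref = multivariate_logrank_test(t, g, e)
    assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
    assert ours.p == pytest.approx(ref.p_value, rel=1e-6)


def test_stratified_logrank_ignores_single_group_stratum():
    t = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
    e = np.ones(8, dtype=int)
    g = np.array(["A", "A", "B", "B", "A", "A", "A", "A"])
    strata = np.array([0, 0, 0, 0, 1, 1, 1, 1])  # stratum 1 is all A
    res_strat = survival.logrank(t, e, g, strata=strata)
    res_sub = survival.logrank(t[:4], e[:4], g[:4])
    assert res_strat.statistic == pytest.approx(res_sub.statistic)


def test_logrank_invariant_to_monotone_time_transform():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, 40)
    e = rng.integers(0, 2, 40)
    g = rng.choice(["A", "B"], 40)
    r1 = survival.logrank(t, e, g)
    r2 = survival.logrank(np.log1p(t), e, g)
    assert r1.statistic == pytest.approx(r2.statistic)


def test_cox_constant_covariate_rejected():
    with pytest.raises(ValueError, match="constant"):
        survival.cox_fit([1, 2, 3], [1, 1, 1], [2, 2, 2])


def test_cox_perfect_separation_rejected():
    t = [1, 2, 3, 4, 10, 11, 12, 13]
    e = [1] * 8
    x = [1, 1, 1, 1, 0, 0, 0, 0]  # all early deaths in one group
    with pytest.raises(ValueError, match="non-convergence"):
        survival.cox_fit(t, e, x)


def test_cox_score_statistic_equals_logrank():
    """On tie-free data with a binary covariate, the Cox score test at
    beta = 0 is the log-rank chi-square — even when the MLE diverges,
    as it does here (all early deaths in one group)."""
    t = [1, 2, 3, 4]
    e = [1, 1, 1, 1]
    x = [1, 1, 0, 0]
    score = survival.cox_score_test(t, e, x)
    lr = survival.logrank(t, e, ["A", "A", "B", "B"])
    assert score.statistic == pytest.approx(lr.statistic, rel=1e-9)
    assert score.statistic == pytest.approx(2.882, abs=2e-3)

    # on a fittable fixture the reported score statistic matches too
    rng = np.random.default_rng(1)
    t2 = rng.exponential(1, 30)
    x2 = rng.integers(0, 2, 30).astype(float)
    fit = survival.cox_fit(t2, np.ones(30, dtype=int), x2)
    lr2 = survival.logrank(t2, np.ones(30, dtype=int), x2)
    assert fit.score_statistic == pytest.approx(lr2.statistic, rel=1e-9)


def test_cox_agrees_with_lifelines():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(9)
    n = 80
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / np.exp(0.8 * x))  # continuous: no ties
    e = np.ones(n, dtype=int)
    fit = survival.cox_fit(t, e, x)
    df = pd.DataFrame({"t": t, "e": e, "x": x})
    ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-5)
    assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-5)


def test_cox_recovers_planted_hazard_ratio():
    """Two-arm exponential data with hazard ratio 4 at n = 120."""
    ok = 0
    n_rep = 15
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        x = np.repeat([0.0, 1.0], 60)
        t = rng.exponential(1 / (0.001 * 4.0**x))
        cens = np.full(120, 2500.0)
        e = (t <= cens).astype(int)
        fit = survival.cox_fit(np.minimum(t, cens), e, x)
        if abs(fit.beta - np.log(4)) <= 0.3 * np.log(4):
            ok += 1
    assert ok >= 0.8 * n_rep


def test_dichotomize():
    g = survival.dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]))
    assert list(g) == ["low", "low", "high", "high"]
    g = survival.dichotomize(pd.Series([1.0, 2.0, 3.0]))
    assert list(g) == ["low", "high", "high"]  # median element goes high
    with pytest.raises(ValueError):
        survival.dichotomize(pd.Series([2.0, 2.0]))


def test_cohort_reassignment_roundtrip(bundle):
    groups = survival.assign_risk_groups(bundle.clinical)
    assert (groups.to_numpy() == bundle.clinical["risk_group"].to_numpy()).all()
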