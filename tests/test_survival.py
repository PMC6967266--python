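"""Dichotomization, KM/log-rank, and Cox proportional-hazards fits."""

import numpy as np
import pandas as pd
import pytest

from hccpanel import (
    SurvivalTable,
    cox_multivariate,
    cox_univariate,
    dichotomize_by_mean,
    km_logrank,
)


def cox_score_test_oracle(x, times, events):
    """Score test of a one-covariate Cox model at beta = 0.

    With untied event times this equals the two-group log-rank statistic:
    U = Σ_events (x_i − mean of x over the risk set),
    I = Σ_events var of x over the risk set, statistic U²/I.
    """
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]
    U = I = 0.0
    for j in range(len(times)):
        if events[j] != 1:
            continue
        risk = x[j:]
        m = risk.mean()
        U += x[j] - m
        I += np.mean((risk - m) ** 2)
    return U**2 / I


def _survival_frame(rng, n, hr_group=1.0, censor_scale=None):
    group = rng.integers(0, 2, n)
    hazard = 0.05 * hr_group**group
    t = rng.exponential(1 / hazard)
    if censor_scale:
        c = rng.exponential(censor_scale, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
    else:
        time, event = t, np.ones(n, dtype=int)
    return group, time, event


class TestDichotomize:
    def test_splits_at_strict_mean(self):
        groups = dichotomize_by_mean(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_value_at_mean_goes_low(self):
        groups = dichotomize_by_mean(pd.Series([0.0, 2.0, 4.0]))
        assert list(groups) == ["low", "low", "high"]

    def test_symmetric_values_balanced(self):
        groups = dichotomize_by_mean(pd.Series([-2.0, -1.0, 1.0, 2.0]))
        assert (groups == "high").sum() == 2

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(8, 2, 100))
        groups = dichotomize_by_mean(x)
        expected = np.where(x > x.mean(), "high", "low")
        assert (groups.to_numpy() == expected).all()

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize_by_mean(pd.Series([3.0, 3.0, 3.0]))


class TestKMLogrank:
    def test_km_starts_at_one_and_never_increases(self):
        rng = np.random.default_rng(2)
        group, time, event = _survival_frame(rng, 100, hr_group=2.0)
        _, _, curves = km_logrank(
            np.where(group == 1, "high", "low"), time, event
        )
        for kmf in curves.values():
            sf = kmf.survival_function_.iloc[:, 0].to_numpy()
            assert sf[0] == pytest.approx(1.0)
            assert np.all(np.diff(sf) <= 1e-12)

    def test_duplicated_cohort_halves_give_null_statistic(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(20, 50)
        times = np.concatenate([t, t])
        events = np.ones(100, dtype=int)
        groups = np.array(["a"] * 50 + ["b"] * 50)
        chi2, p, _ = km_logrank(groups, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_cox_score_test(self):
        rng = np.random.default_rng(4)
        group, time, event = _survival_frame(rng, 60, hr_group=2.0)
        chi2, _, _ = km_logrank(np.where(group == 1, "hi", "lo"), time, event)
        oracle = cox_score_test_oracle(group.astype(float), time, event)
        assert chi2 == pytest.approx(oracle, abs=1e-6)

    def test_type_i_error_near_level(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            group, time, event = _survival_frame(rng, 200, hr_group=1.0)
            _, p, _ = km_logrank(group.astype(str), time, event)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_power_against_planted_hr_2(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_sims = 30
        for _ in range(n_sims):
            group, time, event = _survival_frame(
                rng, 500, hr_group=2.0, censor_scale=45.0
            )
            _, p, _ = km_logrank(group.astype(str), time, event)
            rejections += p < 0.05
        assert rejections / n_sims >= 0.9

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(["a", "b", "c"], [1, 2, 3], [1, 1, 1])


class TestCoxUnivariate:
    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        n_sims = 60
        for _ in range(n_sims):
            x = rng.normal(size=300)
            t = rng.exponential(20, 300)
            df = pd.DataFrame({"time": t, "event": 1, "x": x})
            res = cox_univariate("x", SurvivalTable(data=df))
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered / n_sims >= 0.85

    def test_planted_group_hr_recovered(self):
        rng = np.random.default_rng(8)
        group, time, event = _survival_frame(rng, 500, hr_group=2.0, censor_scale=45.0)
        df = pd.DataFrame({"time": time, "event": event, "g": group.astype(float)})
        res = cox_univariate("g", SurvivalTable(data=df))
        assert 1.7 <= res.hr <= 2.3
        assert res.p < 0.05

    def test_high_low_groups_counted(self):
        rng = np.random.default_rng(9)
        x = pd.Series(rng.normal(8, 2, 200))
        groups = dichotomize_by_mean(x)
        df = pd.DataFrame(
            {"time": rng.exponential(20, 200), "event": 1, "grp": groups}
        )
        res = cox_univariate("grp", SurvivalTable(data=df))
        assert res.n_high == (groups == "high").sum()
        assert res.n_low == (groups == "low").sum()

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": 1.0})
        with pytest.raises(ValueError, match="constant"):
            cox_univariate("x", SurvivalTable(data=df))

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfect separation: all events in one group before any in the other
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 50, 60, 70, 80],
                "event": [1, 1, 1, 1, 0, 0, 0, 0],
                "x": [1.0, 1, 1, 1, 0, 0, 0, 0],
            }
        )
        res = cox_univariate("x", SurvivalTable(data=df), min_events=1)
        assert (not res.converged) or res.ci_high > 100


class TestCoxMultivariate:
    def test_single_variable_reduces_to_univariate(self):
        rng = np.random.default_rng(10)
        group, time, event = _survival_frame(rng, 300, hr_group=2.0)
        df = pd.DataFrame({"time": time, "event": event, "g": group.astype(float)})
        table = SurvivalTable(data=df)
        multi = cox_multivariate(["g"], table)[0]
        uni = cox_univariate("g", table)
        assert multi.hr == pytest.approx(uni.hr)
        assert multi.p == pytest.approx(uni.p)

    def test_invariant_to_variable_order(self):
        rng = np.random.default_rng(11)
        n = 300
        df = pd.DataFrame(
            {
                "time": rng.exponential(20, n),
                "event": 1,
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        table = SurvivalTable(data=df)
        fwd = {r.variable: r.hr for r in cox_multivariate(["a", "b", "c"], table)}
        rev = {r.variable: r.hr for r in cox_multivariate(["c", "b", "a"], table)}
        for v in "abc":
            assert fwd[v] == pytest.approx(rev[v])

    def test_stage_only_effect_identified(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_sims = 20
        for _ in range(n_sims):
            n = 400
            stage = rng.choice([1.0, 2, 3, 4], n)
            g1, g2, g3 = (rng.normal(size=n) for _ in range(3))
            hazard = 0.05 * np.exp(0.5 * (stage - stage.mean()))
            t = rng.exponential(1 / hazard)
            df = pd.DataFrame(
                {"time": t, "event": 1, "stage": stage, "g1": g1, "g2": g2, "g3": g3}
            )
            res = cox_multivariate(["stage", "g1", "g2", "g3"], SurvivalTable(data=df))
            by_var = {r.variable: r for r in res}
            stage_sig = not (by_var["stage"].ci_low <= 1.0 <= by_var["stage"].ci_high)
            genes_null = all(
                by_var[g].ci_low <= 1.0 <= by_var[g].ci_high for g in ("g1", "g2", "g3")
            )
            hits += stage_sig and genes_null
        assert hits / n_sims >= 0.8

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=100)
        df = pd.DataFrame(
            {"time": rng.exponential(20, 100), "event": 1, "x1": x, "x2": 2 * x}
        )
        with pytest.raises(ValueError, match="x1.*x2"):
            cox_multivariate(["x1", "x2"], SurvivalTable(data=df))


def test_plot_km_writes_image(tmp_path):
    from hccpanel.survival import plot_km

    rng = np.random.default_rng(14)
    group, time, event = _survival_frame(rng, 80, hr_group=2.0)
    chi2, p, curves = km_logrank(np.where(group == 1, "high", "low"), time, event)
    out = tmp_path / "km.png"
    plot_km(curves, out, title="risk groups", p_value=p)
    assert out.exists() and out.stat().st_size > 0
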