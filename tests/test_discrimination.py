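import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from metaprs.discrimination import (
    _placements,
    auc,
    build_report,
    continuous_nri,
    delong_test,
    nagelkerke_r2,
)
from metaprs.epi import BatteryFit, BatteryResult, ModelSpec
from metaprs.exceptions import FitError, InvalidConfigError

from conftest import mann_whitney_auc


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assert auc(np.array([1, 2, 3, 4, 5, 6.0]), y).auc == 1.0

    def test_all_ties(self):
        y = np.array([0, 1, 0, 1])
        r = auc(np.ones(4), y)
        assert r.auc == 0.5

    def test_four_by_four_brute_force(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.6, 0.6])
        y = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        assert auc(scores, y).auc == pytest.approx(
            mann_whitney_auc(scores, y), abs=1e-12
        )

    def test_matches_trapezoid_and_pair_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 50))
            scores = rng.choice(np.linspace(0, 1, 15), size=n)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            r = auc(scores, y)
            assert r.auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-10)

    def test_single_class_errors(self):
        with pytest.raises(FitError):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_ci_clipped(self):
        y = np.array([0, 0, 1, 1])
        r = auc(np.array([1, 2, 3, 4.0]), y)
        assert r.ci_high <= 1.0 and r.ci_low >= 0.0

    def test_se_shrinks_with_n(self):
        ses = []
        for n in (200, 2000, 20000):
            rng = np.random.default_rng(n)
            s = rng.standard_normal(n)
            y = (rng.random(n) < expit(-1 + s)).astype(int)
            ses.append(auc(s, y).se)
        assert ses[0] > ses[1] > ses[2]


def delong_oracle(a, b, y):
    """Brute-force structural components and their sample covariances."""
    a, b, y = map(np.asarray, (a, b, y))
    cases, controls = np.flatnonzero(y == 1), np.flatnonzero(y == 0)

    def v10(x):
        return np.array([
            np.mean((x[i] > x[controls]) + 0.5 * (x[i] == x[controls]))
            for i in cases
        ])

    def v01(x):
        return np.array([
            np.mean((x[cases] > x[j]) + 0.5 * (x[cases] == x[j]))
            for j in controls
        ])

    va10, vb10 = v10(a), v10(b)
    va01, vb01 = v01(a), v01(b)
    m, n = len(cases), len(controls)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = va10.mean() - vb10.mean()
    return diff, var, (va10, va01, vb10, vb01)


class TestDeLong:
    def test_identical_predictors(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        p = np.array([0.1, 0.8, 0.3, 0.9, 0.4, 0.2])
        d, z, pv = delong_test(p, p, y)
        assert (d, z, pv) == (0.0, 0.0, 1.0)

    def test_antisymmetry(self, rng):
        n = 200
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        y = rng.integers(0, 2, n)
        d1, z1, p1 = delong_test(a, b, y)
        d2, z2, p2 = delong_test(b, a, y)
        assert d1 == -d2 and z1 == -z2 and p1 == pytest.approx(p2, abs=1e-15)

    def test_worked_n12_against_oracle(self):
        rng = np.random.default_rng(99)
        a = rng.standard_normal(12)
        b = 0.5 * a + rng.standard_normal(12)
        y = np.array([1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0])
        diff_o, var_o, (va10, va01, vb10, vb01) = delong_oracle(a, b, y)
        pa10, pa01 = _placements(a, y)
        pb10, pb01 = _placements(b, y)
        np.testing.assert_allclose(pa10, va10, atol=1e-12)
        np.testing.assert_allclose(pa01, va01, atol=1e-12)
        np.testing.assert_allclose(pb10, vb10, atol=1e-12)
        np.testing.assert_allclose(pb01, vb01, atol=1e-12)
        d, z, p = delong_test(a, b, y)
        assert d == pytest.approx(diff_o, abs=1e-12)
        assert z == pytest.approx(diff_o / np.sqrt(var_o), abs=1e-10)

    def test_row_mismatch(self):
        with pytest.raises(InvalidConfigError):
            delong_test(np.zeros(3), np.zeros(4), np.array([0, 1, 0]))


class TestNagelkerke:
    def test_null_model_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_perfect_prediction_one(self):
        assert nagelkerke_r2(-60.0, 0.0, 100) == pytest.approx(1.0)

    def test_likelihood_oracle(self):
        # n = 20, one binary predictor; likelihoods evaluated directly
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 20).astype(float)
        y = (rng.random(20) < np.where(x == 1, 0.8, 0.3)).astype(float)
        X = np.column_stack([np.ones(20), x])
        fit = sm.Logit(y, X).fit(disp=0)
        p_full = 1 / (1 + np.exp(-X @ fit.params))
        l_full = np.sum(np.log(np.where(y == 1, p_full, 1 - p_full)))
        p0 = y.mean()
        l_null = np.sum(np.log(np.where(y == 1, p0, 1 - p0)))
        expected = (1 - np.exp(2 / 20 * (l_null - l_full))) / (
            1 - np.exp(2 / 20 * l_null)
        )
        assert nagelkerke_r2(l_null, l_full, 20) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigError):
            nagelkerke_r2(-10.0, -20.0, 10)
        with pytest.raises(InvalidConfigError):
            nagelkerke_r2(-10.0, -5.0, 0)


class TestNRI:
    def test_no_change_zero(self):
        y = np.array([0, 1, 0, 1])
        r = np.array([0.2, 0.8, 0.3, 0.7])
        res = continuous_nri(r, r, y, n_boot=50, seed=0)
        assert res.nri == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_maximal_improvement(self):
        y = np.array([0, 0, 1, 1])
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.2, 0.1, 0.9, 0.8])
        res = continuous_nri(old, new, y, n_boot=50, seed=0)
        assert res.nri == 2.0

    def test_hand_arithmetic(self):
        y = np.array([1, 1, 0, 0])
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.6, 0.4, 0.4, 0.5])  # event up, event down,
        # nonevent down, nonevent tie
        res = continuous_nri(old, new, y, n_boot=10, seed=0)
        assert res.nri == pytest.approx(0.5)
        assert res.event_component == pytest.approx(0.0)
        assert res.nonevent_component == pytest.approx(0.5)

    def test_components_sum(self, rng):
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        old = rng.random(100)
        new = rng.random(100)
        res = continuous_nri(old, new, y, n_boot=20, seed=1)
        assert res.nri == pytest.approx(
            res.event_component + res.nonevent_component, abs=1e-12
        )
        assert -2.0 <= res.nri <= 2.0

    def test_seeded_bootstrap_deterministic(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        old, new = rng.random(60), rng.random(60)
        r1 = continuous_nri(old, new, y, n_boot=100, seed=9)
        r2 = continuous_nri(old, new, y, n_boot=100, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_bad_inputs(self):
        y = np.array([0, 1])
        with pytest.raises(InvalidConfigError):
            continuous_nri(np.array([0.5, 1.5]), np.array([0.5, 0.5]), y)
        with pytest.raises(FitError):
            continuous_nri(np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                           np.array([1, 1]))


def _fake_battery(rng, n=400):
    """Battery with genuine nesting: model 3 == model 2 (zero score coef)."""
    import statsmodels.api as sm

    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = (rng.random(n) < expit(-1 + x)).astype(int)
    X1 = np.column_stack([np.ones(n), z])
    X2 = np.column_stack([np.ones(n), z, x])
    r1 = sm.Logit(y, X1).fit(disp=0)
    r2 = sm.Logit(y, X2).fit(disp=0)
    llnull = float(sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf)
    fits = {}
    for mid, (X, r) in ((1, (X1, r1)), (2, (X2, r2)), (3, (X2, r2))):
        lp = X @ r.params
        fits[mid] = BatteryFit(
            spec=ModelSpec(mid, ("x",)),
            params=pd.Series(r.params),
            loglik=float(r.llf),
            loglik_null=llnull,
            linear_predictor=lp,
            fitted_prob=expit(lp),
            n=n,
        )
    return BatteryResult(fits=fits, outcome=y, rows=np.arange(n))


class TestBuildReport:
    def test_model3_equals_model2_when_score_inert(self, rng):
        battery = _fake_battery(rng)
        report = build_report(battery, n_boot=50, seed=0)
        t = report.table.set_index("model")
        assert t.loc[3, "auc_pct"] == t.loc[2, "auc_pct"]
        assert t.loc[3, "full_r2_pct"] == t.loc[2, "full_r2_pct"]
        assert t.loc[3, "prs_r2_pct"] == pytest.approx(0.0, abs=1e-10)
        assert t.loc[3, "nri_vs_m2_pct"] == pytest.approx(0.0)
        assert report.delong.loc[2, 3] == 1.0

    def test_report_deterministic(self, rng):
        battery = _fake_battery(rng)
        r1 = build_report(battery, n_boot=50, seed=3)
        r2 = build_report(battery, n_boot=50, seed=3)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_prs_r2_is_increment_over_model2(self, rng):
        battery = _fake_battery(rng)
        report = build_report(battery, n_boot=20, seed=0)
        t = report.table.set_index("model")
        assert t.loc[3, "prs_r2_pct"] == pytest.approx(
            t.loc[3, "full_r2_pct"] - t.loc[2, "full_r2_pct"], abs=1e-10
        )

    def test_tsv_shape(self, rng, tmp_path):
        battery = _fake_battery(rng)
        report = build_report(battery, n_boot=20, seed=0)
        path = tmp_path / "t3.tsv"
        report.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back["model"]) == [1, 2, 3]
        assert "auc_pct" in back.columns and "nri_vs_m2_pct" in back.columns
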