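import numpy as np
import pandas as pd
import pytest

from expolink import cox_fit, cox_score_test, gene_survival_screen, hazard_ratio, \
    km_estimate, logrank_test, stratify_by_alteration
from expolink.survival import ALTERED, NORMAL, MonotoneLikelihoodError, \
    SurvivalCohort, dummy_encode
from expolink.synthetic import CohortSpec, generate_survival_cohort


def breslow_loglik(beta, x, times, events):
    """Independent partial log-likelihood for untied data (direct formula)."""
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestStratify:
    def test_examples(self):
        assert list(stratify_by_alteration([0.0, 0.0], 2.0)) == [NORMAL, NORMAL]
        assert list(stratify_by_alteration([2.5, -2.1, 0.3, 1.9], 2.0)) == \
            [ALTERED, ALTERED, NORMAL, NORMAL]
        assert list(stratify_by_alteration([0.01, -0.02], 1e-9)) == [ALTERED, ALTERED]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            stratify_by_alteration([1.0], 0.0)


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        km = km_estimate([3.0, 5.0, 7.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_hand_example(self):
        km = km_estimate([1, 2, 2, 3], [1, 1, 1, 0])
        assert np.allclose(km.times, [1, 2])
        assert km.survival_at(1) == pytest.approx(3 / 4)
        assert km.survival_at(2) == pytest.approx(1 / 4)
        assert np.allclose(km.at_risk, [4, 3])

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(10, 200)
        km = km_estimate(t, np.ones(200, int))
        for tj in rng.choice(t, 20):
            assert km.survival_at(tj) == pytest.approx((t > tj).mean(), abs=1e-12)

    def test_monotone_nonincreasing(self, rng):
        t = rng.exponential(10, 100)
        e = (rng.random(100) < 0.7).astype(int)
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t, e = [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_oracle_four_event_times(self):
        ta, ea = [1.0, 3.0], [1, 1]
        tb, eb = [2.0, 4.0], [1, 1]
        # hand computation over event times 1,2,3,4 (independent loop)
        t = np.array(ta + tb); e = np.array(ea + eb)
        in_a = np.array([True, True, False, False])
        O = E = V = 0.0
        for tj in [1.0, 2.0, 3.0, 4.0]:
            risk = t >= tj
            n, n1 = risk.sum(), (risk & in_a).sum()
            d = ((t == tj) & (e == 1)).sum()
            d1 = ((t == tj) & (e == 1) & in_a).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx((O - E) ** 2 / V, rel=1e-12)

    def test_group_relabeling_invariance(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(8, 40)
        ea = (rng.random(30) < 0.8).astype(int)
        eb = (rng.random(40) < 0.8).astype(int)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p == pytest.approx(r2.p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])

    def test_equals_cox_score_test_untied(self, rng):
        n = 120
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-0.5 * x) * 20)
        e = (rng.random(n) < 0.8).astype(int)
        lr = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
        stat, p = cox_score_test(x, t, e)
        assert lr.statistic == pytest.approx(stat, rel=1e-10)


class TestCoxFit:
    def _cohort(self, rng, n=200, beta=0.7, censor_scale=40.0):
        x = (rng.random(n) < 0.4).astype(float)
        t = rng.exponential(np.exp(-beta * x) * 20)
        c = rng.exponential(censor_scale, n)
        return x, np.minimum(t, c), (t <= c).astype(int)

    def test_label_shuffled_duplicate_data_gives_null(self):
        t = np.array([1.0, 2.0, 3.0, 5.0, 1.0, 2.0, 3.0, 5.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0.0] * 4 + [1.0] * 4)
        fit = cox_fit(x.reshape(-1, 1), t, e)
        assert abs(fit.beta[0]) < 1e-6
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-6)

    def test_six_patient_grid_search_oracle(self, rng):
        for _ in range(5):
            x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
            t = rng.permutation([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
            e = np.ones(6, int)
            fit = cox_fit(x.reshape(-1, 1), t, e, ties="breslow")
            grid = np.arange(-3.0, 3.0, 2e-4)
            lls = [breslow_loglik(b, x, t, e) for b in grid]
            b_star = grid[int(np.argmax(lls))]
            if abs(b_star) > 2.9:     # near-separable draw; oracle hit the edge
                continue
            assert fit.beta[0] == pytest.approx(b_star, abs=1e-3)

    def test_hr_is_exactly_exp_beta(self, rng):
        x, t, e = self._cohort(rng)
        fit = cox_fit(x.reshape(-1, 1), t, e)
        assert np.array_equal(fit.hr, np.exp(fit.beta))

    def test_breslow_equals_efron_without_ties(self, rng):
        x, t, e = self._cohort(rng)
        f1 = cox_fit(x.reshape(-1, 1), t, e, ties="breslow")
        f2 = cox_fit(x.reshape(-1, 1), t, e, ties="efron")
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-10)
        assert f1.se[0] == pytest.approx(f2.se[0], abs=1e-10)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        x, t, e = self._cohort(rng, n=250)
        z = rng.normal(size=250)
        X = pd.DataFrame({"x": x, "z": z})
        fit = cox_fit(X, t, e, ties="efron")
        df = X.assign(T=t, E=e)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_efron_handles_heavy_ties_against_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 150
        x = (rng.random(n) < 0.5).astype(float)
        t = np.ceil(rng.exponential(np.exp(-0.6 * x) * 5))  # month resolution
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(x.reshape(-1, 1), t, e, ties="efron")
        df = pd.DataFrame({"x": x, "T": t, "E": e})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.beta[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)

    def test_perfect_separation_raises(self):
        t = np.r_[np.arange(1.0, 6.0), np.arange(10.0, 15.0)]
        e = np.r_[np.ones(5, int), np.zeros(5, int)]
        x = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(MonotoneLikelihoodError):
            cox_fit(x.reshape(-1, 1), t, e)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant covariate"):
            cox_fit(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 0, 1])

    def test_unknown_ties_rejected(self, rng):
        x, t, e = self._cohort(rng, n=20)
        with pytest.raises(ValueError, match="ties"):
            cox_fit(x.reshape(-1, 1), t, e, ties="exact")


class TestHazardRatio:
    def test_identity_at_zero(self):
        assert hazard_ratio(0.0) == 1.0

    def test_vectorized(self):
        assert np.allclose(hazard_ratio(np.log([1.0, 2.0, 0.5])), [1.0, 2.0, 0.5])


class TestScreen:
    def test_empty_gene_list_is_empty_report(self):
        cohort = generate_survival_cohort(CohortSpec(50, ("A",), seed=1))
        report = gene_survival_screen(cohort, [])
        assert len(report.table) == 0
        assert report.km_curves == {}

    def test_planted_effect_flagged_in_uni_and_combined(self):
        spec = CohortSpec(500, ("HIT", "NULL1", "NULL2"), beta_true={"HIT": 1.0},
                          censor_rate=0.2, alteration_rate=0.3, seed=5)
        cohort = generate_survival_cohort(spec)
        report = gene_survival_screen(cohort, ["HIT", "NULL1", "NULL2"])
        row = report.table.loc["HIT"]
        assert row["p_uni"] <= 0.05 and row["p_comb"] <= 0.05
        assert row["flagged"] and row["logrank_selected"]
        assert row["beta_uni"] == pytest.approx(1.0, abs=0.45)
        assert "HIT" in report.km_curves
        km_alt = report.km_curves["HIT"][ALTERED]
        km_nrm = report.km_curves["HIT"][NORMAL]
        t_mid = float(np.median(cohort.time))
        assert km_alt.survival_at(t_mid) < km_nrm.survival_at(t_mid)

    def test_null_cohort_rarely_flags(self):
        spec = CohortSpec(300, tuple(f"N{i}" for i in range(10)),
                          censor_rate=0.3, seed=17)
        cohort = generate_survival_cohort(spec)
        report = gene_survival_screen(cohort, list(cohort.genes))
        assert len(report.flagged_genes()) <= 3

    def test_single_level_factor_dropped_with_warning(self):
        cohort = generate_survival_cohort(CohortSpec(80, ("A",), seed=2))
        cohort.clinical["degenerate"] = "only_level"
        with pytest.warns(UserWarning, match="single level"):
            dummy_encode(cohort.clinical)
        report = gene_survival_screen(cohort, ["A"])
        assert any("degenerate" in m for m in report.warnings)

    def test_screen_columns_mirror_three_blocks(self):
        cohort = generate_survival_cohort(
            CohortSpec(150, ("A", "B"), beta_true={"A": 0.5}, seed=9))
        report = gene_survival_screen(cohort, ["A", "B"])
        for block in ("uni", "multi", "comb"):
            for col in (f"beta_{block}", f"hr_{block}", f"p_{block}"):
                assert col in report.table.columns
        finite = report.table.dropna()
        assert np.allclose(finite["hr_uni"], np.exp(finite["beta_uni"]))
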