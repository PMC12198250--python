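"""Survival machinery: oracle identities and hand-computed examples."""

import itertools

import numpy as np
import pandas as pd
import pytest

import egfrsig as es
from egfrsig.errors import FitError, PipelineError
from egfrsig.survival import breslow_loglik, newton_cox


def _surv(times, events, index=None):
    index = index or [f"p{i}" for i in range(len(times))]
    return es.SurvivalData(pd.Series(times, index=index, dtype=float),
                           pd.Series(events, index=index))


def exhaustive_cindex(scores, times, events):
    """Oracle: Harrell's usable-pair enumeration with 0.5 for score ties."""
    num = den = 0.0
    for i, j in itertools.combinations(range(len(times)), 2):
        a, b = (i, j) if times[i] < times[j] else (j, i)
        if times[i] == times[j]:
            continue  # equal times: not usable without an event-tie rule
        if not events[a]:
            continue
        den += 1
        if scores[a] > scores[b]:
            num += 1
        elif scores[a] == scores[b]:
            num += 0.5
    return num / den


class TestKmEstimate:
    def test_all_events_by_hand(self):
        km = es.km_estimate(_surv([1, 2, 3], [1, 1, 1]))
        assert km.survival.tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censored_patient_by_hand(self):
        km = es.km_estimate(_surv([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = es.km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        assert len(km.times) == 0
        assert km.survival_at(99) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(scale=10, size=80).round(1) + 0.1  # ties likely
        surv = _surv(times, [1] * 80)
        km = es.km_estimate(surv)
        for t in km.times:
            assert km.survival_at(t) == pytest.approx((times > t).mean())


class TestLogrank:
    def test_hand_o_minus_e(self):
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        groups = es.RiskGroups(
            labels=pd.Series(["high", "high", "low", "low"], index=surv.patients),
            cutoff=0.0, method="median",
        )
        res = es.logrank_test(groups, surv)
        # O_A=2, E_A=1/2+1/3, V=1/4+2/9 -> (2-5/6)^2 / (17/36)
        assert res.statistic == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36), abs=1e-6)

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(2)
        surv = _surv(rng.exponential(10, 30) + 0.1, rng.integers(0, 2, 30))
        labels = pd.Series(np.where(rng.random(30) < 0.5, "high", "low"),
                           index=surv.patients)
        flipped = labels.map({"high": "low", "low": "high"})
        a = es.logrank_test(es.RiskGroups(labels, 0, "median"), surv)
        b = es.logrank_test(es.RiskGroups(flipped, 0, "median"), surv)
        assert a.statistic == pytest.approx(b.statistic)

    def test_identical_groups_statistic_zero(self):
        surv = _surv([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        labels = pd.Series(["high"] * 3 + ["low"] * 3, index=surv.patients)
        res = es.logrank_test(es.RiskGroups(labels, 0, "median"), surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)


class TestCindex:
    def test_perfect_concordance(self):
        surv = _surv([1, 2, 3], [1, 1, 1])
        assert es.cindex(pd.Series([2.0, 1.0, 0.0], index=surv.patients), surv) == 1.0

    def test_score_tie_half_credit(self):
        surv = _surv([3, 2, 1], [1, 1, 1])
        c = es.cindex(pd.Series([1.0, 2.0, 2.0], index=surv.patients), surv)
        assert c == pytest.approx(2.5 / 3)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        surv = _surv(rng.exponential(10, 40) + 0.1, rng.integers(0, 2, 40))
        s = pd.Series(rng.normal(size=40), index=surv.patients)
        assert es.cindex(s, surv) + es.cindex(-s, surv) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 60
            times = rng.exponential(10, n) + 0.1  # continuous: no time ties
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            scores = rng.integers(0, 5, n).astype(float)
            surv = _surv(times, events)
            got = es.cindex(pd.Series(scores, index=surv.patients), surv)
            assert got == pytest.approx(exhaustive_cindex(scores, times, events))


class TestRiskScore:
    def test_printed_formula(self):
        fit = es.CoxFit(beta=pd.Series({"g1": 0.5, "g2": -0.2}), lambda_=0.0, alpha=1.0)
        expr = pd.DataFrame({"p1": [2.0, 1.0]}, index=["g1", "g2"])
        assert es.risk_score(expr, fit)["p1"] == pytest.approx(0.8)

    def test_zero_beta_zero_scores_and_linearity(self):
        expr = pd.DataFrame({"p1": [2.0, 1.0], "p2": [4.0, 1.0]}, index=["g1", "g2"])
        zero = es.CoxFit(beta=pd.Series({"g1": 0.0, "g2": 0.0}), lambda_=0.0, alpha=1.0)
        assert (es.risk_score(expr, zero) == 0).all()
        fit = es.CoxFit(beta=pd.Series({"g1": 0.5, "g2": -0.2}), lambda_=0.0, alpha=1.0)
        s = es.risk_score(expr, fit)
        assert s["p2"] - s["p1"] == pytest.approx(0.5 * (4.0 - 2.0))

    def test_missing_gene_raises_with_name(self):
        fit = es.CoxFit(beta=pd.Series({"g1": 0.5, "gX": 1.0}), lambda_=0.0, alpha=1.0)
        expr = pd.DataFrame({"p1": [2.0]}, index=["g1"])
        with pytest.raises(FitError, match="gX"):
            es.risk_score(expr, fit)


class TestSplitByCutoff:
    def test_median_split_with_tie_to_low(self):
        surv = _surv([1, 2, 3, 4], [1, 1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=surv.patients)
        groups = es.split_by_cutoff(scores, surv, method="median")
        assert groups.labels.tolist() == ["low", "low", "high", "high"]
        # a score equal to the cutoff goes low
        scores2 = pd.Series([1.0, 2.5, 2.5, 4.0], index=surv.patients)
        groups2 = es.split_by_cutoff(scores2, surv, method="median")
        assert groups2.labels.tolist() == ["low", "low", "low", "high"]

    def test_best_cutoff_recovers_planted_boundary(self):
        rng = np.random.default_rng(5)
        n = 120
        scores = np.sort(rng.normal(size=n))
        fast = rng.exponential(2, n // 2) + 0.1   # high-score half dies fast
        slow = rng.exponential(30, n // 2) + 0.1
        surv = _surv(np.concatenate([slow, fast]), [1] * n)
        groups = es.split_by_cutoff(pd.Series(scores, index=surv.patients),
                                    surv, method="best")
        boundary = (scores[n // 2 - 1] + scores[n // 2]) / 2
        gap = scores[n // 2] - scores[n // 2 - 1]
        assert abs(groups.cutoff - boundary) <= max(gap, 0.2)


class TestCoxFits:
    def test_unpenalized_beta_matches_grid_oracle(self):
        """Newton fit equals a brute-force partial-likelihood maximizer."""
        rng = np.random.default_rng(6)
        n = 60
        x = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(np.exp(-0.8 * x)) + 1e-3
        events = np.ones(n, dtype=int)
        beta_hat, _ = newton_cox(x[:, None], times, events)
        grid = np.linspace(-3, 3, 6001)
        lls = [breslow_loglik(b * x, times, events) for b in grid]
        assert beta_hat[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_coxnet_near_zero_penalty_matches_newton_with_ties(self):
        rng = np.random.default_rng(7)
        n = 80
        x = rng.normal(size=n)
        times = np.ceil(rng.exponential(np.exp(-0.5 * x)) * 5) + 1.0  # tied times
        events = rng.random(n) < 0.8
        surv = _surv(times, events.astype(int))
        expr = pd.DataFrame({p: [v] for p, v in zip(surv.patients, x)}, index=["g"])
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv
        xs = (x - x.mean()) / x.std()
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e-8]).fit(
            xs[:, None], Surv.from_arrays(events, times)
        )
        beta_newton, _ = newton_cox(xs[:, None], times, events.astype(int))
        assert m.coef_[0, 0] == pytest.approx(beta_newton[0], abs=1e-3)

    def test_large_lambda_gives_all_zero(self, ici_cohort):
        fit = es.fit_l1_cox(ici_cohort.expr.iloc[:8], ici_cohort.survival,
                            iterations=2, seed=0)
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv
        X = ici_cohort.expr.iloc[:8].T
        Xs = (X - X.mean()) / X.std(ddof=0)
        big = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e3]).fit(
            Xs.to_numpy(),
            Surv.from_arrays(ici_cohort.survival.event.astype(bool),
                             ici_cohort.survival.time),
        )
        assert (big.coef_ == 0).all()
        assert isinstance(fit.lambda_, float)

    def test_planted_hazard_sign_recovered(self, ici_cohort):
        fit = es.fit_l1_cox(ici_cohort.expr.iloc[:12], ici_cohort.survival,
                            iterations=5, seed=1)
        planted = list(ici_cohort.truth.hazard_genes)
        assert (fit.beta[planted] > 0).all()
        assert fit.selection_frequency[planted].min() > 0.5

    def test_no_events_raises(self):
        surv = _surv([5, 6, 7, 8, 9, 10, 11, 12, 13, 14], [0] * 10)
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 10)),
                            columns=surv.patients)
        with pytest.raises(FitError):
            es.fit_l1_cox(expr, surv, iterations=1)


class TestStepwiseAndGrid:
    def test_stepwise_selects_planted_gene(self):
        rng = np.random.default_rng(8)
        n = 150
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"g{i}" for i in range(5)])
        times = rng.exponential(np.exp(-1.0 * X["g0"])) + 1e-3
        surv = _surv(times, [1] * n, index=list(X.index))
        beta = es.stepwise_cox(X, surv)
        assert beta["g0"] > 0.5
        assert beta.abs().idxmax() == "g0"

    def test_grid_contains_alpha_02_and_ranks_models(self, ici_cohort):
        table = es.benchmark_prognostic_models(
            ici_cohort.expr.iloc[:10], ici_cohort.survival,
            alphas=(0.0, 0.2, 1.0), seed=0, loo_max_n=50,
        )
        assert "enet_a0.2" in table.index
        assert "stepwise_cox" in table.index
        assert table["cindex"].max() > 0.65  # planted hazards are predictive
        assert table.attrs["best_model"] in table.index

    def test_loo_path_runs_on_tiny_cohort(self):
        cfg = es.SimConfig(n_genes=5, n_samples=60, n_planted_genes=2,
                           hazard_effect=1.0, response_effect=1.0, seed=12)
        cohort = es.simulate_ici_cohort(cfg)
        table = es.benchmark_prognostic_models(
            cohort.expr, cohort.survival, alphas=(1.0,), include_stepwise=False,
        )
        assert len(table) == 1 and np.isfinite(table["cindex"]).all()
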