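"""AUC, information criteria, cutoff metrics and LOS stratification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hosprisk.evaluation import (
    evaluate,
    evaluate_by_los,
    information_criteria,
    optimal_cutoff,
    roc_auc,
)
from hosprisk.models import fit_preset, split_by_year

from conftest import exhaustive_cutoff, pairwise_auc


class TestAuc:
    def test_perfect_ordering(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(20_000)
        labels = rng.integers(0, 2, 20_000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_hand_enumerable_ties(self):
        scores = np.array([0.9, 0.8, 0.7, 0.7, 0.5, 0.4])
        labels = np.array([1, 1, 0, 1, 0, 0])
        assert roc_auc(scores, labels).auc == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )

    def test_matches_pairwise_oracle_random_sets(self):
        gen = np.random.default_rng(6)
        for _ in range(25):
            n = int(gen.integers(10, 400))
            scores = np.round(gen.random(n), 2)  # ties likely
            labels = gen.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_ci_contains_estimate_and_is_ordered(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        labels = (rng.random(500) < scores).astype(int)
        r = roc_auc(scores, labels)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(2)
        scores = rng.random(800)
        labels = (rng.random(800) < scores).astype(int)
        d = roc_auc(scores, labels, method="delong")
        b = roc_auc(scores, labels, method="bootstrap", rng=3)
        assert b.se == pytest.approx(d.se, rel=0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_and_monotone_invariance(self, seed):
        gen = np.random.default_rng(seed)
        n = 60
        scores = gen.random(n)
        labels = gen.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels).auc
        assert roc_auc(-scores, labels).auc == pytest.approx(1 - a, abs=1e-12)
        assert roc_auc(np.exp(3 * scores), labels).auc == pytest.approx(a, abs=1e-12)


class TestInformationCriteria:
    def test_closed_form(self):
        aic, bic = information_criteria((-100.0, 2, 50))
        assert aic == 204.0
        assert bic == pytest.approx(2 * math.log(50) + 200)

    def test_aic_bic_crossover_at_n_e_squared(self):
        aic, bic = information_criteria((-100.0, 2, math.e**2))
        assert aic == pytest.approx(bic)

    def test_bic_exceeds_aic_for_realistic_n(self, small_cohort):
        m = fit_preset(small_cohort, "model1")
        aic, bic = information_criteria(m)
        assert bic > aic  # ln(n) > 2

    def test_penalty_increments(self):
        aic1, bic1 = information_criteria((-500.0, 3, 1000))
        aic2, bic2 = information_criteria((-500.0, 4, 1000))
        assert aic2 - aic1 == pytest.approx(2.0)
        assert bic2 - bic1 == pytest.approx(math.log(1000))

    def test_aic_prefers_smaller_model_under_null(self):
        """Adding a pure-noise covariate should usually not pay its AIC
        penalty (simulation under the null)."""
        from hosprisk.models import fit_logistic

        gen = np.random.default_rng(7)
        prefer_small = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 400
            X0 = np.ones((n, 1))
            X1 = np.column_stack([X0, gen.normal(size=n)])
            y = (gen.random(n) < 0.3).astype(float)
            a0, _ = information_criteria(fit_logistic(X0, y))
            a1, _ = information_criteria(fit_logistic(X1, y))
            prefer_small += a0 < a1
        assert prefer_small > n_rep / 2


class TestCutoff:
    def test_perfect_separation_metrics(self):
        m = optimal_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)

    def test_toy_set_matches_exhaustive_search(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        labels = np.array([1, 1, 0, 1, 0])
        m = optimal_cutoff(scores, labels)
        cut, sens, spec = exhaustive_cutoff(scores, labels)
        assert m.cutoff == pytest.approx(cut)
        assert m.sensitivity == pytest.approx(sens)
        assert m.specificity == pytest.approx(spec)

    def test_matches_exhaustive_search_random_sets(self):
        gen = np.random.default_rng(8)
        for _ in range(20):
            n = int(gen.integers(20, 500))
            scores = np.round(gen.random(n), 2)
            labels = gen.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            m = optimal_cutoff(scores, labels)
            cut, sens, spec = exhaustive_cutoff(scores, labels)
            assert m.sensitivity + m.specificity == pytest.approx(sens + spec)
            assert m.cutoff == pytest.approx(cut)

    def test_identical_scores_degenerate_but_defined(self):
        m = optimal_cutoff([0.4] * 10, [0, 1] * 5)
        assert m.sensitivity == 100.0
        assert m.specificity == 0.0
        assert math.isnan(m.npv)
        assert 0 <= m.accuracy <= 100

    def test_cutoff_odds_form(self):
        m = optimal_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.cutoff_odds == pytest.approx(m.cutoff / (1 - m.cutoff))


class TestEvaluate:
    @pytest.fixture(scope="class")
    def fitted(self, small_cohort):
        train, test = split_by_year(small_cohort, 2007)
        return fit_preset(train, "model5c"), train, test

    def test_report_fields_within_ranges(self, fitted):
        model, _, test = fitted
        rep = evaluate(model, test)
        assert 0 <= rep.auc.ci_low <= rep.auc.auc <= rep.auc.ci_high <= 1
        assert rep.bic >= rep.aic
        assert 0 < rep.cutoff.cutoff < 1
        for v in (rep.cutoff.sensitivity, rep.cutoff.specificity, rep.cutoff.accuracy):
            assert 0 <= v <= 100
        assert rep.n_test == len(test)

    def test_true_probability_oracle_within_ci(self, fitted):
        """The generator's own probabilities are the best possible
        scores; the fitted full model must score within their CI."""
        model, _, test = fitted
        rep = evaluate(model, test)
        oracle = roc_auc(test["true_p"].to_numpy(), test["y"].to_numpy())
        assert abs(rep.auc.auc - oracle.auc) < 4 * (oracle.se + rep.auc.se)

    def test_training_auc_optimistic_on_average(self, small_cohort):
        from hosprisk.cohort import CohortConfig, simulate_cohort

        diffs = []
        for rep_i in range(8):
            df = simulate_cohort(CohortConfig(n_admissions=12_000, seed=500 + rep_i))
            train, test = split_by_year(df, 2007)
            m = fit_preset(train, "model5a")
            auc_train = evaluate(m, train).auc.auc
            auc_test = evaluate(m, test).auc.auc
            diffs.append(auc_train - auc_test)
        assert np.mean(diffs) > 0

    def test_by_los_buckets(self, fitted):
        model, _, test = fitted
        table = evaluate_by_los(model, test, max_day=10)
        assert len(table) == 10
        assert table["n"].sum() == len(test)
        assert table.loc[9, "pooled_tail"]
        populated = table.dropna(subset=["auc"])
        assert (populated["auc"] > 0.5).all()

    def test_by_los_single_bucket_when_all_one_day(self, fitted):
        model, _, test = fitted
        short = test.copy()
        short["discharge"] = short["admission"] + np.timedelta64(12, "h")
        short = short.drop(columns=[c for c in short.columns if c.startswith("count_")
                                    or c in ("los_days", "los_weekday", "los_weekend",
                                             "admission_hour")],
                           errors="ignore")
        table = evaluate_by_los(model, short, max_day=5)
        assert table.loc[0, "n"] == len(short)
        assert (table.loc[1:, "n"] == 0).all()

    def test_bucket_without_deaths_reports_nan(self, fitted):
        model, _, test = fitted
        alive = test.copy()
        los = (alive["discharge"] - alive["admission"]).dt.total_seconds() / 86400
        alive["y"] = 0
        alive.loc[alive.index[los <= 1][:30], "y"] = 1  # deaths only on day 1
        table = evaluate_by_los(model, alive, max_day=3)
        assert (table["n"] > 0).all()
        assert not math.isnan(table.loc[0, "auc"])
        assert table["auc"].isna().iloc[1:].all()  # death-free long buckets
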