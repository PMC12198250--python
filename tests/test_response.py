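"""Response harness: AUC identity, CV training, benchmarking, hub votes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import egfrsig as es
from egfrsig.errors import FitError, InputError
from egfrsig.response import (
    CVConfig, IMPORTANCE_METHODS, consensus_hub, rank_feature_importance,
)


def pairwise_auc(scores, labels):
    """Oracle: direct enumeration of positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluateAuc:
    def test_perfect_separation(self):
        res = es.evaluate_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_three_of_four_pairs(self):
        res = es.evaluate_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_negation_symmetry(self):
        scores = [0.2, 0.9, 0.5, 0.7, 0.1]
        labels = [0, 1, 1, 0, 0]
        a = es.evaluate_auc(scores, labels).auc
        b = es.evaluate_auc([-s for s in scores], labels).auc
        assert a + b == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 50))
    def test_matches_pairwise_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
        assert es.evaluate_auc(scores, labels).auc == pytest.approx(
            pairwise_auc(scores, labels)
        )

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        roc = es.evaluate_auc(scores, labels).roc_points
        assert roc[0].tolist() == [0.0, 0.0]
        assert roc[-1].tolist() == [1.0, 1.0]
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(FitError):
            es.evaluate_auc([0.1, 0.2], [1, 1])


class TestTrainResponseClassifier:
    def test_metadata_honors_config(self, ici_cohort):
        cv = CVConfig(folds=5, repeats=2, seeds=(0, 1))
        sig = es.GeneSet("planted", tuple(ici_cohort.truth.response_genes))
        res = es.train_response_classifier(ici_cohort, sig, cv=cv)
        assert res.folds == 5 and res.repeats == 2
        assert len(res.auc_per_repeat) == 2

    def test_planted_effect_beats_null(self, ici_cohort, null_ici_cohort):
        cv = CVConfig(folds=5, repeats=2, seeds=(0, 1))
        sig = es.GeneSet("planted", tuple(ici_cohort.truth.response_genes))
        strong = es.train_response_classifier(ici_cohort, sig, cv=cv)
        null = es.train_response_classifier(null_ici_cohort, sig, cv=cv)
        assert strong.auc > 0.8
        assert 0.35 < null.auc < 0.65

    def test_deterministic_given_seeds(self, ici_cohort):
        cv = CVConfig(folds=5, repeats=2, seeds=(3, 4))
        sig = es.GeneSet("planted", tuple(ici_cohort.truth.response_genes))
        a = es.train_response_classifier(ici_cohort, sig, cv=cv)
        b = es.train_response_classifier(ici_cohort, sig, cv=cv)
        assert a.auc_per_repeat == b.auc_per_repeat

    @pytest.mark.parametrize("algo", ["knn", "naive_bayes", "random_forest"])
    def test_other_algorithms_run(self, ici_cohort, algo):
        cv = CVConfig(folds=3, repeats=1, seeds=(0,))
        sig = es.GeneSet("planted", tuple(ici_cohort.truth.response_genes))
        res = es.train_response_classifier(ici_cohort, sig, algo=algo, cv=cv)
        assert 0.0 <= res.auc <= 1.0

    def test_too_few_genes_raises(self, ici_cohort):
        with pytest.raises(FitError):
            es.train_response_classifier(
                ici_cohort, es.GeneSet("one", (ici_cohort.expr.index[0],)),
                cv=CVConfig(repeats=1, seeds=(0,)),
            )


class TestBenchmarkSignatures:
    def test_duplicated_signature_identical_rows(self, ici_cohort, null_ici_cohort):
        cv = CVConfig(folds=3, repeats=1, seeds=(0,))
        genes = tuple(ici_cohort.truth.response_genes)
        table = es.benchmark_signatures(
            ici_cohort, [null_ici_cohort],
            [es.GeneSet("a", genes), es.GeneSet("b", genes)], cv=cv,
        )
        assert table.loc["a"].tolist() == pytest.approx(table.loc["b"].tolist())

    def test_planted_signature_ranks_first(self, ici_cohort):
        cv = CVConfig(folds=3, repeats=1, seeds=(0,))
        cfg = es.SimConfig(n_genes=40, n_samples=300, n_planted_genes=5,
                           response_effect=0.8, hazard_effect=0.8, seed=777)
        holdout = es.simulate_ici_cohort(cfg, cohort_id="holdout")
        planted = es.GeneSet("planted", tuple(ici_cohort.truth.response_genes))
        random_set = es.GeneSet("random", tuple(ici_cohort.expr.index[-5:]))
        table = es.benchmark_signatures(ici_cohort, [holdout], [planted, random_set], cv=cv)
        assert table.index[0] == "planted"


class TestImportanceAndHub:
    def test_permutation_invariance_univariate(self, ici_cohort):
        cand = es.GeneSet("cand", tuple(ici_cohort.expr.index[:10]))
        base = rank_feature_importance(ici_cohort, cand, "univariate_auc", seed=0)
        perm = ici_cohort.subset(
            ici_cohort.patients[np.random.default_rng(0).permutation(len(ici_cohort.patients))]
        )
        again = rank_feature_importance(perm, cand, "univariate_auc", seed=0)
        assert base["score"].to_numpy() == pytest.approx(again["score"].to_numpy())

    def test_label_like_gene_selected(self, ici_cohort):
        cohort = ici_cohort
        expr = cohort.expr.copy()
        expr.loc["LABELGENE"] = (cohort.response == "R").astype(float).to_numpy()
        spiked = es.ResponseCohort(
            expr=expr, recist=cohort.recist, response=cohort.response,
            cohort_id=cohort.cohort_id, survival=cohort.survival, truth=cohort.truth,
        )
        cand = es.GeneSet("cand", ("LABELGENE",) + tuple(cohort.expr.index[-9:]))
        table = rank_feature_importance(spiked, cand, "univariate_auc", seed=0)
        assert bool(table.loc["LABELGENE", "selected"])

    def test_constant_gene_never_selected(self, ici_cohort):
        expr = ici_cohort.expr.copy()
        expr.loc["FLAT"] = 1.0
        spiked = es.ResponseCohort(
            expr=expr, recist=ici_cohort.recist, response=ici_cohort.response,
            cohort_id=ici_cohort.cohort_id, survival=ici_cohort.survival,
            truth=ici_cohort.truth,
        )
        cand = es.GeneSet("cand", ("FLAT",) + tuple(ici_cohort.expr.index[:9]))
        table = rank_feature_importance(spiked, cand, "nb_loglik", seed=0)
        assert table.loc["FLAT", "score"] == 0.0
        assert not bool(table.loc["FLAT", "selected"])

    def test_consensus_vote_thresholds(self):
        genes = ["g1", "g2", "g3"]
        def table(sel):
            return pd.DataFrame({"score": [1.0] * 3, "selected": sel, "method": "m"},
                                index=genes)
        tables = [
            table([True, True, True]),
            table([True, True, False]),
            table([True, False, False]),
            table([True, False, False]),
            table([True, False, False]),
        ]
        hub = consensus_hub(tables, min_votes=3)
        assert hub.retained == ["g1"]          # 5 and 2 and 1 votes
        assert hub.votes["g1"] == 5
        assert hub.votes["g2"] == 2

    def test_mismatched_tables_raise(self):
        t1 = pd.DataFrame({"score": [1.0], "selected": [True]}, index=["g1"])
        t2 = pd.DataFrame({"score": [1.0], "selected": [True]}, index=["g2"])
        with pytest.raises(InputError):
            consensus_hub([t1, t2, t1], min_votes=3)


class TestCVConfig:
    def test_seed_count_must_match_repeats(self):
        with pytest.raises(InputError):
            CVConfig(repeats=3, seeds=(1, 2))

    def test_default_seeds_derived(self):
        cv = CVConfig(repeats=4)
        assert len(cv.seeds) == 4
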