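import numpy as np
import pandas as pd
import pytest

import treevote as tv
from treevote.containers import DataError
from treevote.ensemble import (
    EnsemblePrediction,
    build_balanced_subsets,
    combine_importance,
    ensemble_predict,
    fit_tree,
    perturbation_importance,
    select_degs,
    tree_weight,
)


class _StubTree:
    def __init__(self, preds):
        self.preds = np.asarray(preds)

    def predict(self, X):
        return self.preds


class TestBalancedSubsets:
    def test_counts_balanced(self, preprocessed_small):
        subsets = build_balanced_subsets(preprocessed_small, n_trees=10, seed=0)
        y = (preprocessed_small.labels == "tumor").astype(int).to_numpy()
        for s in subsets:
            labels = y[s.indices]
            assert (labels == 1).sum() == (labels == 0).sum() == 30

    def test_all_minority_included(self, preprocessed_small):
        subsets = build_balanced_subsets(preprocessed_small, n_trees=5, seed=0)
        y = (preprocessed_small.labels == "tumor").astype(int).to_numpy()
        minority = set(np.where(y == 0)[0])
        for s in subsets:
            assert minority <= set(s.indices.tolist())

    def test_deterministic(self, preprocessed_small):
        a = build_balanced_subsets(preprocessed_small, n_trees=5, seed=9)
        b = build_balanced_subsets(preprocessed_small, n_trees=5, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.indices, sb.indices)

    def test_majority_coverage_over_many_subsets(self, preprocessed_small):
        # with many bootstrap draws every majority sample appears somewhere
        subsets = build_balanced_subsets(preprocessed_small, n_trees=100, seed=1)
        y = (preprocessed_small.labels == "tumor").astype(int).to_numpy()
        majority = set(np.where(y == 1)[0])
        seen = set()
        for s in subsets:
            seen |= set(s.indices.tolist())
        assert majority <= seen

    def test_tiny_minority_rejected(self, labeled_matrix):
        m = labeled_matrix([[1, 2, 3]], tumor_cols={0, 1})
        with pytest.raises(DataError, match="minority"):
            build_balanced_subsets(m, n_trees=2, seed=0)


class TestFitTree:
    def test_separable_gene_perfect_training_accuracy(self, labeled_matrix):
        vals = np.array([[1, 2, 3, 4, 10, 11, 12, 13.0]])
        m = labeled_matrix(vals, tumor_cols={4, 5, 6, 7})
        subsets = build_balanced_subsets(m, n_trees=1, seed=0)
        tree = fit_tree(m, subsets[0], seed=0)
        X = vals.T
        y = (m.labels == "tumor").astype(int).to_numpy()
        assert (tree.predict(X) == y).all()

    def test_same_seed_same_predictions(self, preprocessed_small):
        subsets = build_balanced_subsets(preprocessed_small, n_trees=1, seed=3)
        probe = preprocessed_small.values.to_numpy().T[:20]
        t1 = fit_tree(preprocessed_small, subsets[0], seed=5)
        t2 = fit_tree(preprocessed_small, subsets[0], seed=5)
        assert np.array_equal(t1.predict(probe), t2.predict(probe))


class TestPerturbationImportance:
    def test_unused_gene_scores_zero(self):
        rng = np.random.default_rng(0)
        n = 40
        signal = np.concatenate([rng.normal(0, 0.1, n // 2), rng.normal(5, 0.1, n // 2)])
        constant = np.full(n, 3.14)  # never split on
        X = np.column_stack([signal, constant])
        y = np.repeat([0, 1], n // 2)
        fi, _ = perturbation_importance(X, y, cv=5, seed=0)
        assert fi[1] == 0.0
        assert fi[0] > 0.1

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.random((60, 5))
        y = rng.permutation(np.repeat([0, 1], 30))
        _, baselines = perturbation_importance(X, y, cv=5, seed=1)
        assert abs(np.mean(baselines) - 0.5) < 0.2

    def test_cv_larger_than_class_rejected(self):
        X = np.random.default_rng(0).random((6, 2))
        y = np.repeat([0, 1], 3)
        with pytest.raises(DataError, match="cv"):
            perturbation_importance(X, y, cv=5, seed=0)

    def test_permutation_mode_runs(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 4))
        y = np.repeat([0, 1], 20)
        fi, _ = perturbation_importance(X, y, cv=4, seed=2, perturbation="permute")
        assert fi.shape == (4,)


class TestVotingAndWeights:
    def _prediction(self, votes, truth):
        votes = np.asarray(votes)
        tumor_votes = votes.sum(axis=0)
        ensemble = (2 * tumor_votes >= votes.shape[0]).astype(int)
        acc = float(np.mean(ensemble == np.asarray(truth)))
        return EnsemblePrediction(
            sample_ids=pd.Index([f"s{j}" for j in range(votes.shape[1])]),
            tree_votes=votes,
            ensemble_labels=ensemble,
            acc_ensemble=acc,
        )

    def test_majority_vote_and_tie_toward_tumor(self, labeled_matrix):
        m = labeled_matrix([[1.0, 2.0]], tumor_cols={0})
        trees = [_StubTree([1, 0]), _StubTree([0, 1]), _StubTree([1, 1]), _StubTree([0, 0])]
        pred = ensemble_predict(trees, m)
        # 2/4 votes each -> tie -> tumor for both samples
        assert pred.ensemble_labels.tolist() == [1, 1]

    def test_unanimous_trees_match_any_tree(self, labeled_matrix):
        m = labeled_matrix([[1.0, 2.0, 3.0]], tumor_cols={0, 1})
        trees = [_StubTree([1, 1, 0])] * 3
        pred = ensemble_predict(trees, m)
        assert pred.ensemble_labels.tolist() == [1, 1, 0]
        assert pred.acc_ensemble == pytest.approx(1.0)

    def test_tree_weight_hand_case(self):
        # agreement 90/100 and ensemble accuracy 0.95 -> 0.855
        votes = np.zeros((2, 100), dtype=int)
        votes[0, :90] = 1  # agrees with the ensemble on 90 of 100
        pred = EnsemblePrediction(
            sample_ids=pd.Index([f"s{j}" for j in range(100)]),
            tree_votes=votes,
            ensemble_labels=np.ones(100, dtype=int),
            acc_ensemble=0.95,
        )
        assert tree_weight(pred, 0) == pytest.approx(0.855)
        assert tree_weight(pred, 1) == pytest.approx(0.0)

    def test_weight_bounds(self):
        votes = np.array([[1, 1], [0, 0]])
        pred = self._prediction(votes, [1, 1])
        assert tree_weight(pred, 0) == 1.0
        assert tree_weight(pred, 1) == 0.0


class TestCombineAndSelect:
    def test_hand_combination(self):
        fi = np.array([[0.2], [0.1]])
        assert combine_importance(fi, np.array([0.5, 1.0]))[0] == pytest.approx(0.2)

    def test_single_tree_identity(self):
        fi = np.array([[0.3, 0.1, 0.0]])
        assert np.allclose(combine_importance(fi, np.ones(1)), fi[0])

    def test_dimension_mismatch(self):
        with pytest.raises(DataError, match="mismatch"):
            combine_importance(np.ones((3, 2)), np.ones(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_loop(self, seed):
        rng = np.random.default_rng(seed)
        fi = rng.normal(size=(20, 15))
        w = rng.random(20)
        brute = np.array(
            [sum(fi[i, j] * w[i] for i in range(20)) for j in range(15)]
        )
        assert np.allclose(combine_importance(fi, w), brute, atol=1e-12)

    def test_select_all_zero_empty(self, labeled_matrix):
        m = labeled_matrix([[1, 2, 3, 4]], tumor_cols={0, 1}, gene_ids=["gA"])
        fi = pd.Series([0.0], index=["gA"])
        assert select_degs(fi, m).empty

    def test_select_orders_and_drops_zero(self, labeled_matrix):
        m = labeled_matrix(
            [[5, 5, 1, 1], [1, 1, 1, 1], [1, 1, 5, 5.0]],
            tumor_cols={0, 1},
            gene_ids=["gA", "gB", "gC"],
        )
        fi = pd.Series([0.2, 0.0, 0.01], index=["gA", "gB", "gC"])
        degs = select_degs(fi, m)
        assert degs.index.tolist() == ["gA", "gC"]
        assert degs.loc["gA", "direction"] == "up"
        assert degs.loc["gC", "direction"] == "down"


@pytest.fixture(scope="module")
def fitted(small_dataset, preprocessed_small):
    table = tv.filter_genes(preprocessed_small)
    retained = table.index[table.retained_after_redundancy]
    model = tv.TreeEnsembleSelector(preprocessed_small, genes=retained, n_trees=30, cv=5)
    return small_dataset, model.fit(seed=7)


class TestModelResults:
    def test_weighted_combination_identity(self, fitted):
        _, res = fitted
        brute = res.tree_weights @ res.fi_matrix
        assert np.allclose(res.fi.to_numpy(), brute, atol=1e-12)

    def test_weights_in_unit_interval(self, fitted):
        _, res = fitted
        assert ((res.tree_weights >= 0) & (res.tree_weights <= 1)).all()

    def test_recovers_planted_genes(self, fitted):
        ds, res = fitted
        degs = res.select_degs()
        assert len(degs) > 0
        precision = len(set(degs.index) & ds.truth.planted_gene_ids) / len(degs)
        assert precision >= 0.8

    def test_summary_mentions_key_facts(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "Ensemble accuracy" in text and "Selected DEGs" in text

    def test_refit_same_seed_identical(self, small_dataset, preprocessed_small):
        table = tv.filter_genes(preprocessed_small)
        retained = table.index[table.retained_after_redundancy]
        model = tv.TreeEnsembleSelector(preprocessed_small, genes=retained, n_trees=10)
        r1, r2 = model.fit(seed=4), model.fit(seed=4)
        pd.testing.assert_series_equal(r1.fi, r2.fi)

    def test_hybrid_sampling_mode(self, preprocessed_small):
        table = tv.filter_genes(preprocessed_small)
        retained = table.index[table.retained_after_redundancy]
        model = tv.TreeEnsembleSelector(
            preprocessed_small, genes=retained, n_trees=5, sampling="hybrid"
        )
        res = model.fit(seed=2)
        assert res.fi.shape[0] == len(retained)
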