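import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import treevote as tv
from treevote.containers import DataError, MutationMatrix
from treevote.downstream import (
    SubtypeAssignment,
    cluster_subtypes,
    km_curve,
    logrank_test,
    methylation_correlation,
    mutation_enrichment,
    pca_scores,
    representative_genes,
)


def _assignment(labels_dict, k=None):
    s = pd.Series(labels_dict)
    return SubtypeAssignment(labels=s, k=k or s.nunique(), method="fixed", seed=0)


class TestClusterSubtypes:
    def test_recovers_planted_blobs(self, labeled_matrix):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0, 0], [6, 6, 6], [0, 6, 0]], dtype=float)
        cols, truth = [], []
        for j in range(60):
            k = j % 3
            cols.append(centers[k] + rng.normal(0, 0.4, 3) + 10)
            truth.append(k)
        vals = np.array(cols).T
        m = labeled_matrix(vals, tumor_cols=set(range(60)))
        a = cluster_subtypes(m, k_select=3, seed=0)
        assert adjusted_rand_score(truth, a.labels.to_numpy()) >= 0.9
        assert a.dispersion is not None and 2 in a.dispersion.index

    def test_invalid_k_rejected(self, preprocessed_small):
        with pytest.raises(DataError, match="k_select"):
            cluster_subtypes(preprocessed_small, k_select=1)

    def test_duplicate_samples_cocluster(self, labeled_matrix):
        col = np.array([1.0, 2.0, 3.0])
        vals = np.column_stack([col, col, col + 5, col + 5, col - 0.9, col + 9])
        m = labeled_matrix(vals, tumor_cols=set(range(6)))
        a = cluster_subtypes(m, k_select=3, seed=0)
        assert a.labels.iloc[0] == a.labels.iloc[1]
        assert a.labels.iloc[2] == a.labels.iloc[3]

    def test_labels_renumbered_by_size(self, small_dataset, preprocessed_small):
        panel = sorted(
            g for g in small_dataset.truth.informative_gene_ids
            if g in preprocessed_small.gene_ids
        )
        a = cluster_subtypes(preprocessed_small, panel=panel, k_select=3, seed=0)
        sizes = a.sizes()
        assert sizes.loc[1] >= sizes.loc[2] >= sizes.loc[3]

    def test_pluggable_backend(self, preprocessed_small):
        def fake(X, k, seed):
            return np.arange(len(X)) % k

        a = cluster_subtypes(preprocessed_small, k_select=3, backend=fake, seed=0)
        assert set(a.labels.unique()) == {1, 2, 3}


class TestRepresentativeGenes:
    def test_planted_shift_ranks_top(self, labeled_matrix):
        rng = np.random.default_rng(1)
        vals = rng.random((50, 45)) + 1
        vals[:3, :15] += 2.0  # genes 0-2 shifted in subtype 1
        m = labeled_matrix(vals, tumor_cols=set(range(45)))
        a = _assignment({f"s{j}": 1 if j < 15 else 2 for j in range(45)})
        reps = representative_genes(m, a, top_n=5)
        assert {"g0", "g1", "g2"} <= set(reps[1].index)

    def test_top_n_clips_to_gene_count(self, labeled_matrix):
        vals = np.random.default_rng(2).random((4, 20)) + 1
        m = labeled_matrix(vals, tumor_cols=set(range(20)))
        a = _assignment({f"s{j}": 1 if j < 10 else 2 for j in range(20)})
        reps = representative_genes(m, a, top_n=100)
        assert len(reps[1]) == 4

    def test_degenerate_gene_gets_p_one(self, labeled_matrix, caplog):
        vals = np.vstack([np.full(10, 2.0), np.random.default_rng(3).random(10)])
        m = labeled_matrix(vals, tumor_cols=set(range(10)))
        a = _assignment({f"s{j}": 1 if j < 5 else 2 for j in range(10)})
        with caplog.at_level("WARNING"):
            reps = representative_genes(m, a, top_n=2)
        assert reps[1].loc["g0", "p"] == 1.0


class TestPca:
    def test_one_dimensional_structure(self, labeled_matrix):
        t = np.linspace(0, 1, 30)
        vals = np.vstack([2 * t + 1, 4 * t + 2, -3 * t + 5, 0.01 * np.random.default_rng(0).random(30) + 1])
        m = labeled_matrix(vals, tumor_cols=set(range(30)))
        scores, evr = pca_scores(m)
        assert evr[0] >= 0.9
        assert scores.shape == (30, 2)

    def test_rotation_invariant_spectrum(self, labeled_matrix):
        rng = np.random.default_rng(4)
        X = rng.random((5, 25))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        m1 = labeled_matrix(X + 2, tumor_cols=set(range(25)))
        m2 = labeled_matrix(q @ (X - X.mean(axis=1, keepdims=True)) + 5, tumor_cols=set(range(25)))
        _, evr1 = pca_scores(m1)
        _, evr2 = pca_scores(m2)
        assert np.allclose(evr1, evr2, atol=1e-8)

    def test_duplicate_samples_identical_coordinates(self, labeled_matrix):
        col = np.array([1.0, 4.0, 2.0])
        vals = np.column_stack([col, col, col * 2, col * 3])
        m = labeled_matrix(vals, tumor_cols=set(range(4)))
        scores, _ = pca_scores(m)
        assert np.allclose(scores.iloc[0], scores.iloc[1])


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        surv = pd.DataFrame(
            {"sample_id": list("abc"), "time_days": [5, 10, 15], "event": [0, 0, 0]}
        )
        curve = km_curve(surv)
        assert (curve["survival"] == 1.0).all()

    def test_product_limit_hand_case(self):
        surv = pd.DataFrame(
            {"sample_id": list("abc"), "time_days": [1, 2, 3], "event": [1, 1, 1]}
        )
        curve = km_curve(surv).set_index("time")
        assert curve.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert curve.loc[2.0, "survival"] == pytest.approx(1 / 3)
        assert curve.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_monotone_non_increasing(self, small_dataset):
        curve = km_curve(small_dataset.survival)
        s = curve["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert (s >= 0).all() and (s <= 1).all()

    def test_negative_times_rejected(self):
        surv = pd.DataFrame({"sample_id": ["a"], "time_days": [-1], "event": [1]})
        with pytest.raises(DataError, match="non-negative"):
            km_curve(surv)


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        base = pd.DataFrame(
            {"sample_id": [f"a{i}" for i in range(6)],
             "time_days": [3, 5, 7, 9, 11, 13],
             "event": [1, 0, 1, 1, 0, 1]}
        )
        dup = base.assign(sample_id=[f"b{i}" for i in range(6)])
        surv = pd.concat([base, dup], ignore_index=True)
        labels = {s: 1 for s in base["sample_id"]} | {s: 2 for s in dup["sample_id"]}
        chi2, df, p = logrank_test(surv, _assignment(labels))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_no_events_rejected(self):
        surv = pd.DataFrame(
            {"sample_id": ["a", "b"], "time_days": [1, 2], "event": [0, 0]}
        )
        with pytest.raises(DataError, match="event"):
            logrank_test(surv, _assignment({"a": 1, "b": 2}))

    def test_two_group_hand_case_against_textbook_formula(self):
        rng = np.random.default_rng(5)
        times = rng.integers(1, 15, size=20).astype(float)
        events = rng.integers(0, 2, size=20)
        events[0] = 1
        groups = np.repeat([1, 2], 10)
        surv = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(20)], "time_days": times, "event": events}
        )
        labels = {f"s{i}": int(groups[i]) for i in range(20)}
        chi2, _, _ = logrank_test(surv, _assignment(labels))
        # textbook O-E / hypergeometric variance for two groups
        o_minus_e, var = 0.0, 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (groups == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-10)


class TestMethylationCorrelation:
    def test_monotone_negative_flagged(self, labeled_matrix):
        vals = np.array([np.linspace(1, 10, 20)])
        m = labeled_matrix(vals, tumor_cols=set(range(20)), gene_ids=["gA"])
        meth = pd.DataFrame(
            [1.0 / np.linspace(1, 10, 20)], index=["gA"], columns=m.sample_ids
        )
        res = methylation_correlation(m, meth)
        assert res.loc[0, "rho"] == pytest.approx(-1.0)
        assert bool(res.loc[0, "flagged_negative"])

    def test_absent_gene_omitted(self, labeled_matrix):
        vals = np.random.default_rng(0).random((2, 10))
        m = labeled_matrix(vals, tumor_cols=set(range(10)), gene_ids=["gA", "gB"])
        meth = pd.DataFrame(
            np.random.default_rng(1).random((1, 10)), index=["gA"], columns=m.sample_ids
        )
        res = methylation_correlation(m, meth)
        assert res["gene_id"].tolist() == ["gA"]

    def test_independent_meth_not_flagged(self, labeled_matrix):
        rng = np.random.default_rng(2)
        vals = rng.random((5, 100))
        m = labeled_matrix(vals, tumor_cols=set(range(100)))
        meth = pd.DataFrame(
            rng.random((5, 100)), index=m.gene_ids, columns=m.sample_ids
        )
        res = methylation_correlation(m, meth)
        assert res["flagged_negative"].sum() == 0

    def test_synthetic_methylation_anticorrelates(self, small_dataset):
        res = methylation_correlation(small_dataset.matrix, small_dataset.methylation)
        assert (res["rho"] < 0).mean() >= 0.9


class TestMutationEnrichment:
    def test_fisher_p_matches_hypergeometric_oracle(self):
        # 2x2 table [[10, 5], [2, 40]] checked against tail enumeration
        table = np.array([[10, 5], [2, 40]])
        p_scipy = stats.fisher_exact(table, alternative="two-sided")[1]
        # enumerate the hypergeometric support directly
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        pmf_obs = stats.hypergeom.pmf(table[0, 0], n, r1, c1)
        ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
        pmfs = stats.hypergeom.pmf(ks, n, r1, c1)
        oracle = pmfs[pmfs <= pmf_obs * (1 + 1e-9)].sum()
        assert p_scipy == pytest.approx(oracle, abs=1e-12)

    def test_never_mutated_gene_p_one(self, make_truth):
        ind = pd.DataFrame(
            np.zeros((1, 30), dtype=int),
            index=["gZ"],
            columns=[f"T{i:04d}" for i in range(30)],
        )
        truth = make_truth(30)
        a = _assignment(truth.subtype_of_sample)
        res = mutation_enrichment(MutationMatrix(ind), a)
        assert (res["p"] == 1.0).all()

    def test_planted_enrichment_significant(self, make_truth):
        from treevote.synthetic import SyntheticSpec, generate_mutations

        truth = make_truth(350, seed=5)
        truth.enriched_mutation_genes = {"m001": 3}
        spec = SyntheticSpec(n_major=350, n_minor=50, seed=5)
        mut = generate_mutations(truth, spec)
        a = _assignment(truth.subtype_of_sample)
        res = mutation_enrichment(mut, a)
        row = res[(res.gene_id == "m001") & (res.subtype == 3)]
        assert float(row["q"].iloc[0]) < 0.05

    def test_pairwise_mode_contrasts(self, make_truth):
        truth = make_truth(40, seed=1)
        spec_ind = np.random.default_rng(0).integers(0, 2, size=(3, 40))
        ind = pd.DataFrame(
            spec_ind, index=["gA", "gB", "gC"],
            columns=sorted(truth.subtype_of_sample),
        )
        a = _assignment(truth.subtype_of_sample)
        res = mutation_enrichment(MutationMatrix(ind), a, mode="pairwise")
        assert set(map(tuple, res[["subtype", "versus"]].drop_duplicates().to_numpy())) == {
            (1, 2), (1, 3), (2, 3)
        }
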