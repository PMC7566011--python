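"""Perturbation-importance decision-tree ensemble for imbalanced DEG selection.

This is the package's core estimator.  The class imbalance is neutralised
*before* any tree sees the data: each of ``n_trees`` balanced subsets
takes every minority (normal) sample plus an equal-size bootstrap draw of
the majority (tumor) samples.  On each subset, a per-gene importance is
measured by stratified cross-validation: within fold k the fold-trained
tree's accuracy ACC_ik is compared against the accuracy ACCF_ijk after
gene j in the evaluation part is overwritten with its training-part mean
("mean perturbation"),

    FI_ij = sum_k (ACC_ik - ACCF_ijk) / CV.

Trees are then weighted by how consistent their vote is with the
ensemble's majority vote over all S samples, damped by the ensemble's own
accuracy,

    w_i = [ sum_j 1(Tree_ij = Ensemble_j) / S ] * Acc_Ensemble,

and the final per-gene score is the weight-combined importance

    FI_j = sum_i FI_ij * w_i.

Genes with strictly positive FI_j are the selected differentially
expressed genes (DEGs), annotated up-/down-regulated in tumor by the sign
of the tumor-minus-normal mean difference.

A gene that no fold tree ever splits on cannot change that tree's
predictions when perturbed, so its fold contribution is exactly zero;
only genes appearing in a fitted fold tree are therefore perturbed.

Usage follows the model/results idiom::

    model = TreeEnsembleSelector(matrix, genes=retained, n_trees=500, cv=5)
    res = model.fit(seed=7)
    degs = res.select_degs()
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .containers import ExpressionMatrix, DataError, TUMOR, NORMAL
from ._utils import stage_seed

logger = logging.getLogger(__name__)

__all__ = [
    "BalancedSubset",
    "EnsemblePrediction",
    "build_balanced_subsets",
    "fit_tree",
    "perturbation_importance",
    "ensemble_predict",
    "tree_weight",
    "combine_importance",
    "select_degs",
    "TreeEnsembleSelector",
    "TreeEnsembleResults",
]

_LABEL_CODE = {NORMAL: 0, TUMOR: 1}


@dataclass
class BalancedSubset:
    """A class-balanced training subset for one tree.

    ``indices`` point into the sample axis (bootstrap duplicates allowed);
    alternatively ``X``/``y`` hold materialized vectors when the subset
    was built by hybrid sampling rather than index resampling.
    """

    indices: np.ndarray | None
    seed: int
    X: np.ndarray | None = None
    y: np.ndarray | None = None

    def materialize(self, X_full: np.ndarray, y_full: np.ndarray):
        if self.X is not None:
            return self.X, self.y
        return X_full[self.indices], y_full[self.indices]


@dataclass
class EnsemblePrediction:
    """Per-tree votes, majority-vote labels, and the ensemble accuracy."""

    sample_ids: pd.Index
    tree_votes: np.ndarray       # (n_trees, n_samples) of {0, 1}
    ensemble_labels: np.ndarray  # (n_samples,) of {0, 1}; ties go to tumor
    acc_ensemble: float


def build_balanced_subsets(
    m: ExpressionMatrix, n_trees: int = 500, seed: int = 0
) -> list[BalancedSubset]:
    """All minority samples + an equal-size bootstrap of the majority, per tree."""
    y = m.labels.map(_LABEL_CODE).to_numpy()
    minority_idx = np.where(y == 0)[0]
    majority_idx = np.where(y == 1)[0]
    if len(minority_idx) > len(majority_idx):  # imbalance direction: majority = tumor
        minority_idx, majority_idx = majority_idx, minority_idx
    if len(minority_idx) < 2:
        raise DataError("minority class needs at least 2 samples for balanced subsets")
    subsets = []
    for i in range(n_trees):
        sub_seed = stage_seed(seed, f"subset:{i}")
        rng = np.random.default_rng(sub_seed)
        draw = rng.choice(majority_idx, size=len(minority_idx), replace=True)
        subsets.append(
            BalancedSubset(indices=np.concatenate([minority_idx, draw]), seed=sub_seed)
        )
    return subsets


def _tree(seed: int, **params) -> DecisionTreeClassifier:
    return DecisionTreeClassifier(random_state=seed, **params)


def fit_tree(
    m: ExpressionMatrix, subset: BalancedSubset, seed: int = 0, **tree_params
) -> DecisionTreeClassifier:
    """Train one binary decision tree on a balanced subset."""
    X_full = m.values.to_numpy().T
    y_full = m.labels.map(_LABEL_CODE).to_numpy()
    X, y = subset.materialize(X_full, y_full)
    if len(np.unique(y)) < 2:
        raise DataError("degenerate subset: only one class present")
    return _tree(seed, **tree_params).fit(X, y)


def _used_features(tree: DecisionTreeClassifier) -> np.ndarray:
    f = tree.tree_.feature
    return np.unique(f[f >= 0])


def perturbation_importance(
    X: np.ndarray,
    y: np.ndarray,
    cv: int = 5,
    seed: int = 0,
    perturbation: str = "mean",
    acc_on: str = "validation",
    **tree_params,
) -> tuple[np.ndarray, list]:
    """Cross-validated accuracy-drop importance for every gene on one subset.

    Returns the per-gene FI_i. vector (length = n features; zero for genes
    no fold tree used) and the list of per-fold baseline accuracies.
    """
    if cv < 2:
        raise DataError("perturbation importance needs at least 2 CV folds")
    if perturbation not in ("mean", "permute"):
        raise DataError(f"unknown perturbation mode {perturbation!r}")
    if acc_on not in ("validation", "train"):
        raise DataError(f"unknown accuracy target {acc_on!r}")
    counts = np.bincount(y)
    if counts.min() < cv:
        raise DataError(
            f"cv={cv} exceeds the smallest class count {counts.min()} in the subset"
        )
    n_features = X.shape[1]
    fi = np.zeros(n_features)
    baselines = []
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed % (2**31))
    rng = np.random.default_rng(stage_seed(seed, "perturb"))
    for k, (tr, va) in enumerate(skf.split(X, y)):
        fold_tree = _tree(stage_seed(seed, f"fold:{k}"), **tree_params).fit(X[tr], y[tr])
        Xe, ye = (X[va], y[va]) if acc_on == "validation" else (X[tr], y[tr])
        acc = float(np.mean(fold_tree.predict(Xe) == ye))
        baselines.append(acc)
        for j in _used_features(fold_tree):
            Xp = Xe.copy()
            if perturbation == "mean":
                Xp[:, j] = X[tr, j].mean()
            else:
                Xp[:, j] = rng.permutation(Xe[:, j])
            acc_pert = float(np.mean(fold_tree.predict(Xp) == ye))
            fi[j] += (acc - acc_pert) / cv
    return fi, baselines


def ensemble_predict(trees: list, m: ExpressionMatrix) -> EnsemblePrediction:
    """Majority vote of all trees over all samples; ties go to tumor."""
    if not trees:
        raise DataError("ensemble_predict needs at least one tree")
    X_full = m.values.to_numpy().T
    y_full = m.labels.map(_LABEL_CODE).to_numpy()
    votes = np.vstack([t.predict(X_full) for t in trees])
    tumor_votes = votes.sum(axis=0)
    ensemble = (2 * tumor_votes >= len(trees)).astype(int)
    acc = float(np.mean(ensemble == y_full))
    return EnsemblePrediction(
        sample_ids=m.sample_ids, tree_votes=votes, ensemble_labels=ensemble, acc_ensemble=acc
    )


def tree_weight(pred: EnsemblePrediction, i: int) -> float:
    """Consistency of tree i with the ensemble vote, damped by ensemble accuracy."""
    S = pred.tree_votes.shape[1]
    if S == 0:
        raise DataError("tree weight undefined for an empty sample set")
    agreement = float(np.mean(pred.tree_votes[i] == pred.ensemble_labels))
    return agreement * pred.acc_ensemble


def combine_importance(fi_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted combination FI_j = sum_i FI_ij * w_i."""
    fi_matrix = np.asarray(fi_matrix)
    weights = np.asarray(weights)
    if fi_matrix.shape[0] != weights.shape[0]:
        raise DataError(
            f"dimension mismatch: {fi_matrix.shape[0]} importance rows vs "
            f"{weights.shape[0]} weights"
        )
    return weights @ fi_matrix


def select_degs(
    fi: pd.Series, m: ExpressionMatrix, tol: float = 1e-12
) -> pd.DataFrame:
    """Genes with positive combined importance, ranked, with regulation direction.

    Negative importances (possible when perturbation *helps* a fold) are
    excluded and logged; the empty result is allowed.
    """
    n_negative = int((fi < -tol).sum())
    if n_negative:
        logger.info("select_degs: %d gene(s) with negative importance excluded", n_negative)
    selected = fi[fi > tol].sort_values(ascending=False)
    if selected.empty:
        logger.info("select_degs: no gene has positive importance")
    genes = selected.index
    tumor_mean = m.values.loc[genes, m.tumor_ids].mean(axis=1)
    normal_mean = m.values.loc[genes, m.normal_ids].mean(axis=1)
    return pd.DataFrame(
        {
            "fi": selected.to_numpy(),
            "direction": np.where(tumor_mean >= normal_mean, "up", "down"),
            "rank": np.arange(1, len(genes) + 1),
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TreeEnsembleSelector:
    """Model object for ensemble DEG selection on an imbalanced matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Labeled expression matrix (typically preprocessed and pre-filtered).
    genes : sequence, optional
        Restrict the model to these genes (e.g. the relevance-filtered set).
    n_trees : int
        Number of balanced subsets / trees (500 in the reference setting).
    cv : int
        Stratified folds for the perturbation importance (default 5).
    perturbation : {"mean", "permute"}
        Overwrite the evaluated gene with the training-fold mean, or
        permute it within the evaluation part.
    sampling : {"bootstrap", "hybrid"}
        Balanced subsets by bootstrap under-sampling of the majority
        (default), or by the SMOTE + k-means hybrid sampler.
    acc_on : {"validation", "train"}
        Which fold part the before/after accuracies are measured on.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        genes=None,
        n_trees: int = 500,
        cv: int = 5,
        perturbation: str = "mean",
        sampling: str = "bootstrap",
        acc_on: str = "validation",
        max_depth: int | None = None,
        criterion: str = "gini",
    ):
        self.matrix = matrix.subset_genes(genes) if genes is not None else matrix
        self.matrix._require_labels()
        if sampling not in ("bootstrap", "hybrid"):
            raise DataError(f"unknown sampling mode {sampling!r}")
        self.n_trees = int(n_trees)
        self.cv = int(cv)
        self.perturbation = perturbation
        self.sampling = sampling
        self.acc_on = acc_on
        self.tree_params = {"max_depth": max_depth, "criterion": criterion}

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, labels: pd.Series, **kwargs
    ) -> "TreeEnsembleSelector":
        return cls(ExpressionMatrix(values, labels), **kwargs)

    def _subsets(self, seed: int) -> list[BalancedSubset]:
        if self.sampling == "bootstrap":
            return build_balanced_subsets(self.matrix, self.n_trees, seed)
        from .classify import build_hybrid_datasets  # local import: avoid cycle

        n_minor = min(len(self.matrix.tumor_ids), len(self.matrix.normal_ids))
        datasets = build_hybrid_datasets(
            self.matrix,
            panel=self.matrix.gene_ids,
            n_datasets=self.n_trees,
            size=2 * n_minor,
            seed=seed,
        )
        return [
            BalancedSubset(indices=None, seed=d.seed, X=d.X, y=d.y) for d in datasets
        ]

    def fit(self, seed: int = 0) -> "TreeEnsembleResults":
        m = self.matrix
        X_full = m.values.to_numpy().T
        y_full = m.labels.map(_LABEL_CODE).to_numpy()
        subsets = self._subsets(seed)
        fi_matrix = np.zeros((self.n_trees, m.n_genes))
        baselines = []
        trees = []
        for i, subset in enumerate(subsets):
            X, y = subset.materialize(X_full, y_full)
            tree_seed = stage_seed(seed, f"tree:{i}")
            trees.append(_tree(tree_seed, **self.tree_params).fit(X, y))
            fi_matrix[i], accs = perturbation_importance(
                X,
                y,
                cv=self.cv,
                seed=tree_seed,
                perturbation=self.perturbation,
                acc_on=self.acc_on,
                **self.tree_params,
            )
            baselines.append(accs)
        pred = ensemble_predict(trees, m)
        weights = np.array([tree_weight(pred, i) for i in range(self.n_trees)])
        fi = pd.Series(combine_importance(fi_matrix, weights), index=m.gene_ids, name="fi")
        return TreeEnsembleResults(
            model=self,
            fi_matrix=fi_matrix,
            tree_weights=weights,
            fi=fi,
            prediction=pred,
            baseline_accuracies=np.array(baselines),
            seed=seed,
        )


@dataclass
class TreeEnsembleResults:
    """Fitted ensemble: per-tree importances, weights, combined scores."""

    model: TreeEnsembleSelector
    fi_matrix: np.ndarray          # (n_trees, n_genes)
    tree_weights: np.ndarray       # (n_trees,)
    fi: pd.Series                  # combined FI_j per gene
    prediction: EnsemblePrediction
    baseline_accuracies: np.ndarray  # (n_trees, cv) fold baselines
    seed: int

    @property
    def acc_ensemble(self) -> float:
        return self.prediction.acc_ensemble

    def select_degs(self, tol: float = 1e-12) -> pd.DataFrame:
        return select_degs(self.fi, self.model.matrix, tol=tol)

    def summary(self, top: int = 10) -> str:
        degs = self.select_degs()
        lines = [
            "Decision-tree ensemble DEG selection",
            "=" * 52,
            f"Trees:              {self.model.n_trees}",
            f"CV folds:           {self.model.cv}",
            f"Perturbation:       {self.model.perturbation}",
            f"Sampling:           {self.model.sampling}",
            f"Genes in model:     {self.model.matrix.n_genes}",
            f"Samples:            {self.model.matrix.n_samples} "
            f"({len(self.model.matrix.tumor_ids)} tumor / "
            f"{len(self.model.matrix.normal_ids)} normal)",
            f"Seed:               {self.seed}",
            "-" * 52,
            f"Ensemble accuracy:  {self.acc_ensemble:.4f}",
            f"Tree weights:       min {self.tree_weights.min():.4f}  "
            f"mean {self.tree_weights.mean():.4f}  max {self.tree_weights.max():.4f}",
            f"Selected DEGs:      {len(degs)} (FI_j > 0)",
            "-" * 52,
        ]
        if len(degs):
            lines.append(f"{'rank':>4}  {'gene_id':<14}{'FI_j':>10}  direction")
            for gid, row in degs.head(top).iterrows():
                lines.append(
                    f"{int(row['rank']):>4}  {gid:<14}{row['fi']:>10.5f}  {row['direction']}"
                )
            if len(degs) > top:
                lines.append(f"... and {len(degs) - top} more")
        return "\n".join(lines)

    def to_tsv(self, deg_path, fi_matrix_path=None, weights_path=None) -> None:
        """Write the DEG table and optionally the audit matrices."""
        self.select_degs().to_csv(deg_path, sep="\t")
        m = self.model.matrix
        if fi_matrix_path is not None:
            pd.DataFrame(
                self.fi_matrix,
                index=pd.Index([f"tree_{i}" for i in range(self.model.n_trees)], name="tree"),
                columns=m.gene_ids,
            ).to_csv(fi_matrix_path, sep="\t")
        if weights_path is not None:
            pd.Series(
                self.tree_weights,
                index=pd.Index([f"tree_{i}" for i in range(self.model.n_trees)], name="tree"),
                name="weight",
            ).to_csv(weights_path, sep="\t")
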