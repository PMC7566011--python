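"""Panel validation by hybrid-sampled voting classification with ROC/AUC.

A selected gene panel is judged by how well a simple combined classifier
separates tumor from normal.  The training split is rebalanced by hybrid
sampling: the minority (normal) side is expanded with SMOTE-interpolated
synthetic vectors while the majority (tumor) side is condensed to k-means
cluster representatives (medoids — real samples, so features stay in the
observed value space).  On each balanced dataset a Gaussian naive-Bayes
member and an RBF-kernel SVM member are fitted; a sample's score is the
fraction of all members voting tumor, and the ROC/AUC is computed from
that score with the rank (Mann-Whitney) formulation.

SMOTE is implemented here from its defining rule — each synthetic vector
is x + lambda * (x_nn - x) for a uniform lambda and a random one of the k
nearest minority neighbors of a random minority sample x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split as _sk_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .containers import ExpressionMatrix, DataError, TUMOR, NORMAL
from ._utils import stage_seed

logger = logging.getLogger(__name__)

__all__ = [
    "train_test_split",
    "smote_oversample",
    "kmeans_undersample",
    "HybridDataset",
    "build_hybrid_datasets",
    "HybridVotingClassifier",
    "RocResult",
    "roc_auc",
    "evaluate_panel",
]


def train_test_split(
    m: ExpressionMatrix, train_frac: float = 0.8, seed: int = 0
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Stratified, disjoint, exhaustive split of the samples."""
    labels = m._require_labels()
    counts = labels.value_counts()
    if counts.min() < 2:
        raise DataError("a class is too small to stratify the split")
    train_ids, test_ids = _sk_split(
        m.sample_ids,
        train_size=train_frac,
        stratify=labels.to_numpy(),
        random_state=seed % (2**31),
    )
    return m.subset_samples(train_ids), m.subset_samples(test_ids)


def smote_oversample(
    X: np.ndarray, n_target: int, k_neighbors: int = 5, seed: int = 0
) -> np.ndarray:
    """Generate ``n_target`` synthetic minority vectors by SMOTE interpolation."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 1:
        raise DataError("SMOTE needs at least 2 minority samples")
    k = min(k_neighbors, n - 1)
    if k < k_neighbors:
        logger.warning("SMOTE: k_neighbors clipped from %d to %d", k_neighbors, k)
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, n, size=n_target)
    pick = rng.integers(0, k, size=n_target)
    lam = rng.random(n_target)[:, None]
    anchors = X[base]
    partners = X[neigh[base, pick]]
    return anchors + lam * (partners - anchors)


def kmeans_undersample(
    X: np.ndarray, n_target: int, seed: int = 0
) -> np.ndarray:
    """Indices of ``n_target`` k-means medoid representatives of the majority.

    Runs k-means with k = n_target and returns, per centroid, the nearest
    real sample; a sample already claimed by another centroid is replaced
    by the next-nearest unused one.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_target:
        raise DataError(f"cannot under-sample {n} samples to {n_target}")
    if n == n_target:
        return np.arange(n)
    km = KMeans(n_clusters=n_target, n_init=10, random_state=seed % (2**31)).fit(X)
    chosen: list[int] = []
    used = np.zeros(n, dtype=bool)
    for c in km.cluster_centers_:
        order = np.argsort(((X - c) ** 2).sum(axis=1), kind="stable")
        for idx in order:
            if not used[idx]:
                chosen.append(int(idx))
                used[idx] = True
                break
    return np.array(sorted(chosen))


@dataclass
class HybridDataset:
    """One balanced dataset: SMOTE minority vectors + majority medoids."""

    X: np.ndarray            # (size, n_panel_genes)
    y: np.ndarray            # {0: normal, 1: tumor}
    provenance: np.ndarray   # "synthetic" | "cluster-representative"
    sample_ids: list         # medoid sample IDs; synthetic get "synthetic_<i>"
    seed: int


def build_hybrid_datasets(
    m: ExpressionMatrix,
    panel=None,
    n_datasets: int = 9,
    size: int = 100,
    k_neighbors: int = 5,
    seed: int = 0,
) -> list[HybridDataset]:
    """Build ``n_datasets`` independent balanced datasets of ``size`` samples."""
    if size % 2:
        raise DataError("hybrid dataset size must be even (size/2 per class)")
    sub = m.subset_genes(panel) if panel is not None else m
    half = size // 2
    X_min = sub.values[sub.normal_ids].to_numpy().T
    X_maj = sub.values[sub.tumor_ids].to_numpy().T
    maj_ids = list(sub.tumor_ids)
    datasets = []
    for d in range(n_datasets):
        sub_seed = stage_seed(seed, f"hybrid:{d}")
        synth = smote_oversample(
            X_min, half, k_neighbors=k_neighbors, seed=stage_seed(sub_seed, "smote")
        )
        rep_idx = kmeans_undersample(X_maj, half, seed=stage_seed(sub_seed, "kmeans"))
        X = np.vstack([synth, X_maj[rep_idx]])
        y = np.concatenate([np.zeros(half, dtype=int), np.ones(half, dtype=int)])
        provenance = np.array(["synthetic"] * half + ["cluster-representative"] * half)
        ids = [f"synthetic_{i}" for i in range(half)] + [maj_ids[i] for i in rep_idx]
        datasets.append(HybridDataset(X=X, y=y, provenance=provenance, sample_ids=ids, seed=sub_seed))
    return datasets


class HybridVotingClassifier:
    """NB + SVM members per balanced dataset, combined by flat vote pooling.

    The continuous score of a sample is the fraction of all members voting
    tumor; the hard label is tumor when the score reaches 0.5 (ties go to
    the majority class).
    """

    def __init__(self, svm_kernel: str = "rbf"):
        self.svm_kernel = svm_kernel
        self.members: list[tuple[object, np.ndarray | None]] = []

    @property
    def n_members(self) -> int:
        return len(self.members)

    def fit(self, datasets: list[HybridDataset]) -> "HybridVotingClassifier":
        if not datasets:
            raise DataError("voting classifier needs at least one balanced dataset")
        self.members = []
        for d in datasets:
            constant = d.X.std(axis=0) == 0
            nb_mask = None
            if constant.any():
                logger.warning(
                    "dropping %d constant feature(s) for the NB member", int(constant.sum())
                )
                nb_mask = ~constant
            nb = GaussianNB().fit(d.X if nb_mask is None else d.X[:, nb_mask], d.y)
            svm = SVC(kernel=self.svm_kernel).fit(d.X, d.y)
            self.members.append((nb, nb_mask))
            self.members.append((svm, None))
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (labels, scores); score = tumor-vote fraction across members."""
        if not self.members:
            raise DataError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        votes = np.vstack(
            [clf.predict(X if mask is None else X[:, mask]) for clf, mask in self.members]
        )
        scores = votes.mean(axis=0)
        labels = (scores >= 0.5).astype(int)
        return labels, scores


@dataclass
class RocResult:
    """ROC curve points and the rank-formulation AUC for one split."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    split: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores: np.ndarray, y_true: np.ndarray, split: str = "complete") -> RocResult:
    """ROC curve and tie-corrected Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    ranks = rankdata(scores)  # average ranks: tie correction
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(y_true, scores)
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc), split=split)


def evaluate_panel(
    m: ExpressionMatrix,
    panel,
    train_frac: float = 0.8,
    n_datasets: int = 9,
    size: int = 100,
    k_neighbors: int = 5,
    seed: int = 0,
) -> dict:
    """Full panel evaluation: split, hybrid-sample, fit, score all splits.

    Returns a dict with the fitted classifier, per-split :class:`RocResult`
    under ``roc`` and per-split accuracy under ``accuracy``.
    """
    sub = m.subset_genes(panel)
    train, test = train_test_split(sub, train_frac=train_frac, seed=stage_seed(seed, "split"))
    datasets = build_hybrid_datasets(
        train, n_datasets=n_datasets, size=size, k_neighbors=k_neighbors,
        seed=stage_seed(seed, "hybrid"),
    )
    clf = HybridVotingClassifier().fit(datasets)
    out = {"classifier": clf, "roc": {}, "accuracy": {}, "n_members": clf.n_members}
    for name, part in (("train", train), ("test", test), ("complete", sub)):
        X = part.values.to_numpy().T
        y = (part.labels == TUMOR).astype(int).to_numpy()
        labels, scores = clf.predict(X)
        out["roc"][name] = roc_auc(scores, y, split=name)
        out["accuracy"][name] = float(np.mean(labels == y))
    return out
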