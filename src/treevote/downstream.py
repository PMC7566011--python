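"""Downstream characterisation of the selected panel: tumor subtype
clustering, per-subtype representative genes, PCA, Kaplan-Meier /
log-rank survival comparison, expression-methylation correlation, and
mutation enrichment by Fisher's exact test.

Subtype clustering is a pluggable contract (tumor samples x panel genes
-> k labels); the default backend is deterministic Ward-linkage
agglomerative clustering.  Survival estimation and the k-group log-rank
test go through lifelines; Fisher's exact test through scipy with
Benjamini-Hochberg adjustment from statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MutationMatrix, DataError, validate_survival

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeAssignment",
    "cluster_subtypes",
    "representative_genes",
    "pca_scores",
    "logrank_test",
    "km_curve",
    "methylation_correlation",
    "mutation_enrichment",
]


@dataclass
class SubtypeAssignment:
    """Tumor sample -> subtype label in 1..k (normals are never assigned)."""

    labels: pd.Series
    k: int
    method: str
    seed: int
    dispersion: pd.Series | None = None  # within-cluster SS per candidate k

    def samples_in(self, subtype: int) -> pd.Index:
        return self.labels.index[self.labels == subtype]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_tsv(self, path) -> None:
        self.labels.rename("subtype").rename_axis("sample_id").to_csv(path, sep="\t")


def _ward_backend(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return float(total)


def cluster_subtypes(
    m: ExpressionMatrix,
    panel=None,
    k_select: int = 3,
    k_range: tuple[int, int] = (2, 8),
    backend=None,
    seed: int = 0,
) -> SubtypeAssignment:
    """Cluster tumor samples on panel-gene expression into k subtypes.

    ``backend`` is any callable (X, k, seed) -> integer labels; the default
    is Ward agglomerative clustering.  Cluster labels are renumbered 1..k
    by decreasing size (subtype 1 = largest).  The within-cluster
    dispersion for every k in ``k_range`` is reported alongside, without
    endorsing any particular k.
    """
    lo, hi = k_range
    if not (lo <= k_select <= hi):
        raise DataError(f"k_select={k_select} outside k_range {k_range}")
    sub = m.subset_genes(panel) if panel is not None else m
    tumor_ids = sub.tumor_ids
    if len(tumor_ids) < k_select:
        raise DataError(f"need at least {k_select} tumor samples to form {k_select} subtypes")
    X = sub.values[tumor_ids].to_numpy().T
    fn = backend or _ward_backend
    name = getattr(fn, "__name__", "custom") if backend else "ward"
    dispersion = {}
    labels = None
    for k in range(lo, min(hi, len(tumor_ids)) + 1):
        lab_k = np.asarray(fn(X, k, seed))
        dispersion[k] = _within_dispersion(X, lab_k)
        if k == k_select:
            labels = lab_k
    if labels is None:
        labels = np.asarray(fn(X, k_select, seed))
    # renumber by decreasing cluster size, ties by first appearance
    counts = pd.Series(labels).value_counts()
    order = sorted(counts.index, key=lambda v: (-counts[v], v))
    remap = {old: new + 1 for new, old in enumerate(order)}
    relabeled = pd.Series([remap[v] for v in labels], index=tumor_ids, name="subtype")
    return SubtypeAssignment(
        labels=relabeled,
        k=k_select,
        method=name,
        seed=seed,
        dispersion=pd.Series(dispersion, name="within_cluster_ss"),
    )


def representative_genes(
    m: ExpressionMatrix, assignment: SubtypeAssignment, top_n: int = 100
) -> dict[int, pd.DataFrame]:
    """Per subtype: top genes by one-vs-rest Welch t-test, lowest p first.

    Runs over ALL genes of the matrix (not just the panel), tumor samples
    only.  Genes with zero variance in both groups get p = 1 (logged).
    Overlap between subtype lists is allowed.
    """
    out = {}
    tumor = m.values[assignment.labels.index]
    for subtype in sorted(assignment.labels.unique()):
        in_ids = assignment.samples_in(subtype)
        out_ids = assignment.labels.index.difference(in_ids)
        if len(in_ids) < 2 or len(out_ids) < 2:
            raise DataError(f"subtype {subtype} needs >= 2 samples on each side of the t-test")
        a = tumor[in_ids].to_numpy()
        b = tumor[out_ids].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        bad = ~np.isfinite(p)
        if bad.any():
            logger.warning(
                "representative_genes: %d degenerate gene(s) in subtype %d set to p=1",
                int(bad.sum()), subtype,
            )
            p = np.where(bad, 1.0, p)
            t = np.where(np.isfinite(t), t, 0.0)
        table = (
            pd.DataFrame({"t": t, "p": p}, index=m.gene_ids.rename("gene_id"))
            .sort_values("p", kind="mergesort")
            .head(top_n)
        )
        out[int(subtype)] = table
    return out


def pca_scores(m: ExpressionMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples on the given genes.

    Returns per-sample scores on the leading components (as many as exist,
    up to ``n_components``) and the full explained-variance-ratio spectrum
    for scree inspection.
    """
    if m.n_genes < 2 or m.n_samples < 3:
        raise DataError("PCA needs at least 2 genes and 3 samples")
    X = m.values.to_numpy().T
    max_rank = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_rank, svd_solver="full").fit(X)
    scores = pca.transform(X)[:, : min(n_components, max_rank)]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=m.sample_ids.rename("sample_id"), columns=cols),
        pca.explained_variance_ratio_,
    )


def _merge_survival(surv: pd.DataFrame, assignment: SubtypeAssignment) -> pd.DataFrame:
    surv = validate_survival(surv)
    df = surv.merge(
        assignment.labels.rename("subtype").rename_axis("sample_id").reset_index(),
        on="sample_id",
        how="inner",
    )
    dropped = len(surv) - len(df)
    if dropped:
        logger.info("survival: %d sample(s) without a subtype dropped", dropped)
    return df


def logrank_test(
    surv: pd.DataFrame, assignment: SubtypeAssignment
) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi2 statistic, df = k-1, p)."""
    df = _merge_survival(surv, assignment)
    groups = df["subtype"].unique()
    if len(groups) < 2:
        raise DataError("log-rank test needs at least 2 groups")
    if df["event"].sum() == 0:
        raise DataError("log-rank test needs at least one event")
    res = multivariate_logrank_test(df["time_days"], df["subtype"], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def km_curve(surv: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate: (time, survival) step points."""
    surv = validate_survival(surv)
    if len(surv) == 0:
        raise DataError("empty survival table")
    kmf = KaplanMeierFitter().fit(surv["time_days"], surv["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
    )


def methylation_correlation(
    expr: ExpressionMatrix,
    meth: pd.DataFrame,
    flag_threshold: float = -0.3,
    genes=None,
) -> pd.DataFrame:
    """Spearman correlation between expression and methylation beta per gene.

    Samples are inner-joined on identifier; genes absent from the
    methylation matrix are omitted (join semantics).  A gene is flagged as
    significantly negative when rho < ``flag_threshold``.
    """
    gene_pool = pd.Index(genes) if genes is not None else expr.gene_ids
    common_genes = gene_pool.intersection(meth.index)
    common_samples = expr.sample_ids.intersection(meth.columns)
    rows = []
    for g in common_genes:
        e = expr.values.loc[g, common_samples].to_numpy()
        b = meth.loc[g, common_samples].to_numpy(dtype=float)
        ok = np.isfinite(e) & np.isfinite(b)
        if ok.sum() < 3:
            logger.warning("methylation_correlation: gene %s skipped (<3 matched samples)", g)
            continue
        rho, p = stats.spearmanr(e[ok], b[ok])
        rows.append({"gene_id": g, "rho": float(rho), "p": float(p),
                     "flagged_negative": bool(rho < flag_threshold)})
    return pd.DataFrame(rows, columns=["gene_id", "rho", "p", "flagged_negative"])


def mutation_enrichment(
    mut: MutationMatrix,
    assignment: SubtypeAssignment,
    mode: str = "groupwise",
) -> pd.DataFrame:
    """Per-gene subtype enrichment by two-sided Fisher's exact test.

    groupwise: each subtype vs the rest; pairwise: every subtype pair.
    BH adjustment within the chosen mode; genes never mutated get p = 1
    with no test.  Rows sorted by ascending p.
    """
    if mode not in ("groupwise", "pairwise"):
        raise DataError(f"unknown enrichment mode {mode!r}")
    common = mut.sample_ids.intersection(assignment.labels.index)
    if len(common) == 0:
        raise DataError("no samples shared between mutation matrix and subtypes")
    dropped = len(mut.sample_ids) - len(common)
    if dropped:
        logger.info("mutation_enrichment: %d sample(s) without a subtype dropped", dropped)
    ind = mut.indicators[common]
    labels = assignment.labels.loc[common]
    subtypes = sorted(labels.unique())
    if mode == "groupwise":
        contrasts = [(k, "rest") for k in subtypes]
    else:
        contrasts = [
            (a, b) for i, a in enumerate(subtypes) for b in subtypes[i + 1:]
        ]
    rows = []
    for gene in ind.index:
        mutated = ind.loc[gene].to_numpy().astype(bool)
        never = not mutated.any()
        for grp, other in contrasts:
            in_grp = (labels == grp).to_numpy()
            out_grp = ~in_grp if other == "rest" else (labels == other).to_numpy()
            a = int((mutated & in_grp).sum())      # mutated, in group
            b = int((~mutated & in_grp).sum())     # wild-type, in group
            c = int((mutated & out_grp).sum())     # mutated, comparison
            d = int((~mutated & out_grp).sum())    # wild-type, comparison
            if never:
                p = 1.0
            else:
                p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            rows.append(
                {
                    "gene_id": gene,
                    "subtype": grp,
                    "versus": other,
                    "n_mut_in": a,
                    "n_wt_in": b,
                    "n_mut_out": c,
                    "n_wt_out": d,
                    "p": p,
                }
            )
    result = pd.DataFrame(rows)
    result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    return result.sort_values("p", kind="mergesort").reset_index(drop=True)
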