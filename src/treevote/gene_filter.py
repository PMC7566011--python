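"""Univariate relevance and redundancy filtering.

Relevance is scored by the Fisher ratio

    FR(i) = (mu_i1 - mu_i2)^2 / (s2_i1 + s2_i2),

the squared tumor-vs-normal mean difference over the summed class
variances.  Redundancy between retained genes is measured by Spearman
rank correlation over all samples pooled; within a highly correlated pair
the gene with the lower classified information index (CII)

    d(i) = 1/2 * |mu_i1 - mu_i2| / (s_i1 + s_i2)
         + 1/2 * ln((s2_i1 + s2_i2) / (2 * s_i1 * s_i2))

is deleted.  Unlike the Fisher ratio, the CII's log variance-disparity
term keeps genes whose classes differ in spread even when their means
coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, DataError, TUMOR

logger = logging.getLogger(__name__)

__all__ = [
    "GeneClassStats",
    "class_stats",
    "fisher_ratio",
    "fisher_select",
    "classified_information_index",
    "spearman_matrix",
    "correlated_pairs",
    "redundancy_filter",
    "filter_genes",
]


@dataclass
class GeneClassStats:
    """Per-gene class means/variances; class 1 = tumor, class 2 = normal."""

    gene_ids: pd.Index
    mu1: np.ndarray
    mu2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    n1: int
    n2: int


def class_stats(m: ExpressionMatrix, ddof: int = 1) -> GeneClassStats:
    """Per-gene per-class mean and variance (unbiased, n-1, by default)."""
    tumor = m.values[m.tumor_ids].to_numpy()
    normal = m.values[m.normal_ids].to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise DataError("each class needs at least 2 samples for class statistics")
    return GeneClassStats(
        gene_ids=m.gene_ids,
        mu1=tumor.mean(axis=1),
        mu2=normal.mean(axis=1),
        var1=tumor.var(axis=1, ddof=ddof),
        var2=normal.var(axis=1, ddof=ddof),
        n1=tumor.shape[1],
        n2=normal.shape[1],
    )


def fisher_ratio(s: GeneClassStats) -> pd.Series:
    """Between-class over within-class variance ratio per gene.

    Degenerate genes (both class variances zero) score +inf when the means
    differ — maximal separability — and 0 when they coincide.
    """
    denom = s.var1 + s.var2
    num = (s.mu1 - s.mu2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / denom
    score = np.where(denom == 0, np.where(num > 0, np.inf, 0.0), score)
    return pd.Series(score, index=s.gene_ids, name="fisher_ratio")


def fisher_select(scores: pd.Series, threshold: float = 0.5) -> pd.Index:
    """Genes whose Fisher ratio reaches the threshold.

    Scores strictly below the threshold are deleted; a score exactly at
    the threshold is kept.
    """
    retained = scores.index[scores >= threshold]
    if len(retained) == 0:
        raise DataError(
            f"no gene reaches Fisher-ratio threshold {threshold}; lower the threshold"
        )
    return retained


def classified_information_index(s: GeneClassStats) -> pd.Series:
    """Two-term CII: standardized mean gap plus log variance disparity.

    Zero-variance classes make the log term blow up; such genes are
    maximally distinguishable by spread alone and score +inf (logged).
    """
    sd1 = np.sqrt(s.var1)
    sd2 = np.sqrt(s.var2)
    degenerate = (sd1 == 0) | (sd2 == 0)
    if degenerate.any():
        logger.warning(
            "CII: %d gene(s) with a zero-variance class scored +inf", int(degenerate.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 0.5 * np.abs(s.mu1 - s.mu2) / (sd1 + sd2) + 0.5 * np.log(
            (s.var1 + s.var2) / (2.0 * sd1 * sd2)
        )
    d = np.where(degenerate, np.inf, d)
    return pd.Series(d, index=s.gene_ids, name="cii")


def spearman_matrix(m: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Spearman correlation matrix between genes over all samples pooled.

    Mid-ranks (average ranks on ties) Pearson correlation; a constant gene
    has undefined correlation, treated as 0 with a warning.
    """
    sub = m if genes is None else m.subset_genes(genes)
    if sub.n_samples < 3:
        raise DataError("Spearman correlation needs at least 3 samples")
    ranks = stats.rankdata(sub.values.to_numpy(), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.atleast_2d(np.corrcoef(ranks))
    if np.isnan(rho).any():
        logger.warning("spearman_matrix: constant gene(s); undefined correlations set to 0")
        rho = np.nan_to_num(rho, nan=0.0)
        np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=sub.gene_ids, columns=sub.gene_ids)


def correlated_pairs(corr: pd.DataFrame, rho_threshold: float = 0.7) -> pd.DataFrame:
    """Upper-triangle pairs with |rho| above the threshold, strongest first."""
    genes = corr.index
    iu, ju = np.triu_indices(len(genes), k=1)
    rho = corr.to_numpy()[iu, ju]
    mask = np.abs(rho) > rho_threshold
    pairs = pd.DataFrame(
        {"gene_a": genes[iu[mask]], "gene_b": genes[ju[mask]], "rho": rho[mask]}
    )
    return pairs.sort_values(
        by=["rho", "gene_a", "gene_b"],
        key=lambda c: -c.abs() if c.name == "rho" else c,
        kind="mergesort",
    ).reset_index(drop=True)


def redundancy_filter(
    corr: pd.DataFrame, cii: pd.Series, rho_threshold: float = 0.7
) -> pd.Index:
    """Greedy redundancy removal arbitrated by the CII.

    Pairs are visited in order of decreasing |rho|; whenever both members
    of an above-threshold pair are still retained, the one with the lower
    CII is deleted (CII tie: the lexicographically later gene ID goes).
    Afterwards no retained pair exceeds the threshold.
    """
    pairs = correlated_pairs(corr, rho_threshold)
    retained = set(corr.index)
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        if a in retained and b in retained:
            ca, cb = cii[a], cii[b]
            if ca < cb:
                retained.discard(a)
            elif cb < ca:
                retained.discard(b)
            else:
                retained.discard(max(a, b))
    return pd.Index([g for g in corr.index if g in retained])


def filter_genes(
    m: ExpressionMatrix,
    fisher_threshold: float = 0.5,
    rho_threshold: float = 0.7,
    ddof: int = 1,
) -> pd.DataFrame:
    """Run the full relevance + redundancy filter.

    Returns the per-gene score table (gene_id index) with columns
    ``fisher_ratio``, ``cii``, ``retained_after_fisher`` and
    ``retained_after_redundancy``.
    """
    s = class_stats(m, ddof=ddof)
    fr = fisher_ratio(s)
    cii = classified_information_index(s)
    after_fisher = fisher_select(fr, fisher_threshold)
    corr = spearman_matrix(m, after_fisher)
    after_redundancy = redundancy_filter(corr, cii[after_fisher], rho_threshold)
    table = pd.DataFrame(
        {
            "fisher_ratio": fr,
            "cii": cii,
            "retained_after_fisher": fr.index.isin(after_fisher),
            "retained_after_redundancy": fr.index.isin(after_redundancy),
        }
    )
    logger.info(
        "gene filter funnel: %d genes in -> %d after Fisher ratio -> %d after redundancy",
        len(table), len(after_fisher), len(after_redundancy),
    )
    return table
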