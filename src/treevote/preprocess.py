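"""Expression preprocessing: unexpressed-gene filtering, per-gene min-max
normalization, and randomized zero replacement, applied in that order.

The three rules:

1. drop genes with zero values in strictly more than ``frac_threshold``
   of the samples (default: over 50%);
2. rescale each gene to [0, 1] by its own min and max (constant genes,
   which min-max cannot handle and which carry no class signal, are
   dropped with a warning);
3. replace every remaining zero with an independent uniform draw from the
   open interval (0, min/10), where min is the gene's smallest non-zero
   value in the current (normalized) matrix.

After the full pipeline every value lies in (0, 1] and no gene is
constant.  A ``replace_zeros_first=True`` flag swaps steps 2 and 3 for
users who read the zero-replacement rule as acting on the raw scale; in
that mode the final values are in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, DataError
from ._utils import rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessReport",
    "filter_unexpressed",
    "minmax_normalize",
    "replace_zeros",
    "preprocess",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing run."""

    n_genes_in: int = 0
    n_genes_dropped: int = 0
    n_dropped_unexpressed: int = 0
    n_dropped_constant: int = 0
    n_zeros_replaced: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes_dropped > self.n_genes_in:
            raise DataError("report invariant violated: n_genes_dropped <= n_genes_in")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def filter_unexpressed(
    m: ExpressionMatrix, frac_threshold: float = 0.5
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Drop genes unexpressed (zero) in over ``frac_threshold`` of samples.

    The rule is strict: a gene with zeros in exactly half the samples is
    retained at the default threshold.
    """
    if m.n_genes == 0 or m.n_samples == 0:
        raise DataError("cannot filter an empty expression matrix")
    zero_frac = (m.values.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= frac_threshold
    report = PreprocessReport(
        n_genes_in=m.n_genes,
        n_genes_dropped=int((~keep).sum()),
        n_dropped_unexpressed=int((~keep).sum()),
    )
    if not keep.any():
        raise DataError(
            f"all {m.n_genes} genes unexpressed in over {frac_threshold:.0%} of samples"
        )
    out = ExpressionMatrix(m.values.loc[keep], m.labels)
    logger.info("filter_unexpressed: %d of %d genes dropped", report.n_genes_dropped, m.n_genes)
    return out, report


def minmax_normalize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Per-gene min-max rescaling to [0, 1]; constant genes are dropped."""
    v = m.values.to_numpy()
    gmin = v.min(axis=1, keepdims=True)
    gmax = v.max(axis=1, keepdims=True)
    constant = (gmax == gmin).ravel()
    if constant.any():
        logger.warning(
            "minmax_normalize: dropping %d constant gene(s): %s",
            int(constant.sum()),
            m.gene_ids[constant].tolist()[:5],
        )
    keep = ~constant
    if not keep.any():
        raise DataError("all genes constant; nothing to normalize")
    scaled = (v[keep] - gmin[keep]) / (gmax[keep] - gmin[keep])
    out = ExpressionMatrix(
        pd.DataFrame(scaled, index=m.gene_ids[keep], columns=m.sample_ids), m.labels
    )
    report = PreprocessReport(
        n_genes_in=m.n_genes,
        n_genes_dropped=int(constant.sum()),
        n_dropped_constant=int(constant.sum()),
    )
    return out, report


def replace_zeros(
    m: ExpressionMatrix, seed: int = 0
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Replace each zero with a uniform draw from (0, min/10).

    ``min`` is the gene's smallest non-zero value.  Deterministic given the
    seed.  A gene with no non-zero value has no defined ``min`` and should
    have been removed by :func:`filter_unexpressed`; encountering one is an
    error.
    """
    rng = rng_for(seed, "replace_zeros")
    v = m.values.to_numpy().copy()
    zero_mask = v == 0
    all_zero = zero_mask.all(axis=1)
    if all_zero.any():
        raise DataError(
            f"gene(s) with all-zero expression (min undefined): "
            f"{m.gene_ids[all_zero].tolist()[:5]}; run filter_unexpressed first"
        )
    n_zeros = int(zero_mask.sum())
    if n_zeros:
        with_zero = zero_mask.any(axis=1)
        for i in np.where(with_zero)[0]:
            row = v[i]
            min_nz = row[row > 0].min()
            idx = np.where(zero_mask[i])[0]
            draws = rng.uniform(0.0, min_nz / 10.0, size=len(idx))
            # open interval: redraw the (measure-zero) exact endpoints
            while ((draws == 0.0) | (draws == min_nz / 10.0)).any():
                bad = (draws == 0.0) | (draws == min_nz / 10.0)
                draws[bad] = rng.uniform(0.0, min_nz / 10.0, size=int(bad.sum()))
            row[idx] = draws
    out = ExpressionMatrix(pd.DataFrame(v, index=m.gene_ids, columns=m.sample_ids), m.labels)
    report = PreprocessReport(n_genes_in=m.n_genes, n_zeros_replaced=n_zeros, seed=seed)
    return out, report


def preprocess(
    m: ExpressionMatrix,
    frac_threshold: float = 0.5,
    seed: int = 0,
    replace_zeros_first: bool = False,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Full pipeline: filter -> normalize -> replace zeros (default order)."""
    m1, rep_filter = filter_unexpressed(m, frac_threshold)
    if replace_zeros_first:
        m2, rep_zero = replace_zeros(m1, seed=seed)
        m3, rep_norm = minmax_normalize(m2)
    else:
        m2, rep_norm = minmax_normalize(m1)
        m3, rep_zero = replace_zeros(m2, seed=seed)
    report = PreprocessReport(
        n_genes_in=m.n_genes,
        n_genes_dropped=rep_filter.n_genes_dropped + rep_norm.n_genes_dropped,
        n_dropped_unexpressed=rep_filter.n_dropped_unexpressed,
        n_dropped_constant=rep_norm.n_dropped_constant,
        n_zeros_replaced=rep_zero.n_zeros_replaced,
        seed=seed,
    )
    return m3, report
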