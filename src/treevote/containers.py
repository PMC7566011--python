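"""Core data containers: expression matrices, survival tables, mutation matrices.

The in-memory lingua franca of the package is the pandas DataFrame: an
:class:`ExpressionMatrix` wraps a genes x samples frame of non-negative
values together with an optional per-sample class label series
(``tumor`` / ``normal``).  All stage outputs round-trip through plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"
VALID_LABELS = frozenset({TUMOR, NORMAL})


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene identifiers, columns by unique sample
        identifiers.  Missing entries are coerced to 0 (and counted in the
        log); negative values are rejected.
    labels : pandas.Series, optional
        Per-sample class label, ``"tumor"`` or ``"normal"``, indexed by
        sample identifier.  Optional so unlabeled matrices (e.g. external
        validation sets) can use the same container.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample identifiers: {dup[:5]}")
        n_missing = int(v.isna().to_numpy().sum())
        if n_missing:
            logger.warning("coercing %d missing expression entries to 0", n_missing)
            v = v.fillna(0.0)
        v = v.astype(float)
        if (v.to_numpy() < 0).any():
            raise DataError("expression values must be non-negative")
        self.values = v
        if self.labels is not None:
            lab = pd.Series(self.labels).reindex(v.columns)
            if lab.isna().any():
                missing = lab.index[lab.isna()].tolist()
                raise DataError(f"samples without a class label: {missing[:5]}")
            bad = set(lab.unique()) - VALID_LABELS
            if bad:
                raise DataError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(bad)}")
            self.labels = lab

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def _require_labels(self) -> pd.Series:
        if self.labels is None:
            raise DataError("operation requires per-sample class labels")
        return self.labels

    @property
    def tumor_ids(self) -> pd.Index:
        lab = self._require_labels()
        return lab.index[lab == TUMOR]

    @property
    def normal_ids(self) -> pd.Index:
        lab = self._require_labels()
        return lab.index[lab == NORMAL]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.gene_ids)
        if len(missing):
            raise DataError(f"genes not in matrix: {missing.tolist()[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.labels)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.sample_ids)
        if len(missing):
            raise DataError(f"samples not in matrix: {missing.tolist()[:5]}")
        lab = self.labels.loc[samples] if self.labels is not None else None
        return ExpressionMatrix(self.values[samples], lab)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path, labels_path=None) -> None:
        """Write the matrix (and optionally the labels) in the package TSV dialect.

        Genes as rows; first column ``gene_id``; header row of sample IDs.
        """
        self.values.rename_axis("gene_id").to_csv(path, sep="\t")
        if labels_path is not None and self.labels is not None:
            self.labels.rename("label").rename_axis("sample_id").to_csv(
                labels_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, path, labels_path=None, dialect: str | None = None) -> "ExpressionMatrix":
        return load_expression(path, labels_path=labels_path, dialect=dialect)


def _sep_for(path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise DataError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
        return "\t" if dialect == "tsv" else ","
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_expression(path, labels_path=None, dialect: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix from TSV/CSV (auto-detected by extension).

    Duplicate gene rows, ragged rows and negative values raise
    :class:`DataError` with the offending identifier.
    """
    sep = _sep_for(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataError(f"cannot parse expression file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    labels = None
    if labels_path is not None:
        labels = load_labels(labels_path)
    return ExpressionMatrix(df, labels)


def load_labels(path) -> pd.Series:
    """Read the two-column (sample_id, label) TSV written by the generator."""
    lab = pd.read_csv(path, sep="\t", index_col=0)["label"]
    lab.index = lab.index.astype(str)
    return lab


def load_survival(path) -> pd.DataFrame:
    """Read a clinical survival table: sample_id, time_days, event.

    Times must be >= 0 and the event indicator binary.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event"}
    if not required.issubset(df.columns):
        raise DataError(f"survival table must have columns {sorted(required)}")
    return validate_survival(df)


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    if (df["time_days"] < 0).any():
        raise DataError("survival times must be non-negative")
    if not set(df["event"].unique()).issubset({0, 1}):
        raise DataError("event indicator must be 0 (censored) or 1 (death)")
    return df.reset_index(drop=True)


@dataclass
class MutationMatrix:
    """Binary gene x sample somatic-mutation indicator matrix."""

    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        ind = self.indicators.astype(int)
        vals = set(np.unique(ind.to_numpy())) if ind.size else set()
        if not vals.issubset({0, 1}):
            raise DataError("mutation indicators must be binary")
        self.indicators = ind

    @property
    def gene_ids(self) -> pd.Index:
        return self.indicators.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    @classmethod
    def from_maf(cls, path) -> "MutationMatrix":
        """Collapse a MAF-style table (Hugo_Symbol, Tumor_Sample_Barcode) to binary."""
        maf = pd.read_csv(path, sep="\t", comment="#")
        required = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
        if not required.issubset(maf.columns):
            raise DataError(f"MAF file must contain columns {sorted(required)}")
        ind = (
            maf.assign(_one=1)
            .pivot_table(
                index="Hugo_Symbol",
                columns="Tumor_Sample_Barcode",
                values="_one",
                aggfunc="max",
                fill_value=0,
            )
        )
        ind.index.name = None
        ind.columns.name = None
        return cls(ind)

    def to_tsv(self, path) -> None:
        self.indicators.rename_axis("gene_id").to_csv(path, sep="\t")

    def to_maf(self, path) -> None:
        rows = [
            {"Hugo_Symbol": g, "Tumor_Sample_Barcode": s}
            for g in self.indicators.index
            for s in self.indicators.columns
            if self.indicators.at[g, s]
        ]
        pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)
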