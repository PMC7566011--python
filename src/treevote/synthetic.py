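"""Synthetic unbalanced two-class expression data with known ground truth.

Emulates the data regime the selection pipeline targets: a large majority
tumor class versus a small normal class (371 vs 50 by default), a handful
of planted informative genes with a fixed class-mean shift, noisy
rank-correlated copies of those genes (redundancy), a sea of null noise
genes, latent tumor subtypes with their own expression signatures,
subtype-dependent exponential survival, and subtype-enriched somatic
mutations.  Every generator is a pure function of its spec and seed, so
every downstream stage can be tested against known truth without any
external download.

Expression values are log-normal (exp of Gaussian): non-negative and
right-skewed like RNA-seq-derived abundances.  Effect sizes are expressed
in units of the within-class standard deviation on the log scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ExpressionMatrix, MutationMatrix, DataError, TUMOR, NORMAL
from ._utils import rng_for

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_expression",
    "generate_survival",
    "generate_mutations",
    "generate_methylation",
    "simulate",
]


class SpecError(DataError):
    """A synthetic spec violated one of its invariants."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions end to end: 2000 genes with 20
    informative and 50 redundant, 371 tumor vs 50 normal samples, planted
    effect of 2 within-class SD, three subtypes at proportions
    0.54/0.21/0.25 with relative hazards (1, 1, 3), 30% censoring, and
    mutations at 5% background versus 50% in the enriched subtype.
    """

    n_genes: int = 2000
    n_informative: int = 20
    n_redundant: int = 50
    n_major: int = 371          # tumor (majority) samples
    n_minor: int = 50           # normal (minority) samples
    effect_size: float = 2.0    # class-mean shift, within-class-SD units
    redundancy_rho: float = 0.8  # target pairwise Spearman correlation
    n_subtypes: int = 3
    subtype_props: tuple = (0.54, 0.21, 0.25)
    subtype_shift: float = 1.5  # per-subtype offset, within-class-SD units
    hazard_ratios: tuple = (1.0, 1.0, 3.0)
    baseline_median_days: float = 1825.0
    censoring_rate: float = 0.3
    n_mutation_genes: int = 50
    n_enriched_mutation_genes: int = 5
    mutation_background_rate: float = 0.05
    mutation_enriched_rate: float = 0.5
    mutation_rates: dict | None = None  # optional {gene: {subtype: rate}} override
    dropout_rate: float = 0.05      # zero-inflation, noise genes only
    silent_gene_frac: float = 0.02  # genes unexpressed in most samples
    frac_upregulated: float = 0.8   # share of informative genes up in tumor
    methylation_frac: float = 0.8   # share of informative genes with beta values
    methylation_noise: float = 0.5
    log_sd: float = 0.5             # within-class SD on the log scale
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n_informative + self.n_redundant > self.n_genes:
            raise SpecError("invariant violated: n_informative + n_redundant <= n_genes")
        if self.n_minor < 2:
            raise SpecError("invariant violated: n_minor >= 2")
        if self.n_major < self.n_minor:
            raise SpecError("invariant violated: n_major >= n_minor (majority = tumor)")
        for name in (
            "redundancy_rho", "censoring_rate", "mutation_background_rate",
            "mutation_enriched_rate", "dropout_rate", "silent_gene_frac",
            "frac_upregulated", "methylation_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"invariant violated: {name} in [0,1] (got {v})")
        if self.n_subtypes < 1:
            raise SpecError("invariant violated: n_subtypes >= 1")
        if len(self.hazard_ratios) != self.n_subtypes:
            raise SpecError("invariant violated: one hazard ratio per subtype")
        if len(self.subtype_props) != self.n_subtypes:
            raise SpecError("invariant violated: one proportion per subtype")
        if abs(sum(self.subtype_props) - 1.0) > 1e-8:
            raise SpecError("invariant violated: subtype proportions sum to 1")
        if min(self.hazard_ratios) <= 0:
            raise SpecError("invariant violated: hazard ratios > 0")
        return self


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    informative_gene_ids: set
    redundant_map: dict            # redundant gene -> parent informative gene
    subtype_of_sample: dict        # tumor sample -> subtype label in 1..k
    enriched_mutation_genes: dict  # mutation gene -> target subtype
    direction: dict = field(default_factory=dict)  # informative gene -> +1 (up) / -1 (down)
    mutation_gene_ids: list = field(default_factory=list)

    @property
    def planted_gene_ids(self) -> set:
        """Informative genes plus their redundant proxies."""
        return set(self.informative_gene_ids) | set(self.redundant_map)

    def to_json(self, path) -> None:
        payload = {
            "informative_gene_ids": sorted(self.informative_gene_ids),
            "redundant_map": self.redundant_map,
            "subtype_of_sample": self.subtype_of_sample,
            "enriched_mutation_genes": self.enriched_mutation_genes,
            "direction": self.direction,
            "mutation_gene_ids": list(self.mutation_gene_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            informative_gene_ids=set(d["informative_gene_ids"]),
            redundant_map=d["redundant_map"],
            subtype_of_sample={k: int(v) for k, v in d["subtype_of_sample"].items()},
            enriched_mutation_genes={k: int(v) for k, v in d["enriched_mutation_genes"].items()},
            direction={k: int(v) for k, v in d.get("direction", {}).items()},
            mutation_gene_ids=d.get("mutation_gene_ids", []),
        )


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the unbalanced two-class expression matrix and its answer key.

    Informative genes carry a tumor-vs-normal log-mean shift of exactly
    ``effect_size * log_sd`` (subtype offsets are centred so the planted
    class difference is preserved); redundant genes are noisy copies of a
    parent informative gene calibrated so their expected Spearman
    correlation reaches ``redundancy_rho``; noise genes are class-blind.
    """
    spec.validate()
    rng = rng_for(spec.seed, "expression")
    n_samples = spec.n_major + spec.n_minor
    sigma = spec.log_sd

    width = len(str(spec.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]
    tumor_ids = [f"T{i + 1:04d}" for i in range(spec.n_major)]
    normal_ids = [f"N{i + 1:04d}" for i in range(spec.n_minor)]
    sample_ids = tumor_ids + normal_ids
    labels = pd.Series(
        [TUMOR] * spec.n_major + [NORMAL] * spec.n_minor, index=sample_ids, name="label"
    )
    is_tumor = np.array([True] * spec.n_major + [False] * spec.n_minor)

    # subtype assignment of tumor samples at the spec proportions
    counts = np.floor(np.asarray(spec.subtype_props) * spec.n_major).astype(int)
    counts[0] += spec.n_major - counts.sum()
    subtype_vec = np.repeat(np.arange(1, spec.n_subtypes + 1), counts)
    rng.shuffle(subtype_vec)
    subtype_of_sample = {s: int(k) for s, k in zip(tumor_ids, subtype_vec)}

    mu_g = rng.normal(3.0, 1.0, size=spec.n_genes)
    log_x = mu_g[:, None] + sigma * rng.standard_normal((spec.n_genes, n_samples))

    n_inf, n_red = spec.n_informative, spec.n_redundant
    informative = gene_ids[:n_inf]
    redundant = gene_ids[n_inf:n_inf + n_red]
    noise = gene_ids[n_inf + n_red:]

    # planted class effect (exact mean shift on the log scale)
    signs = np.where(rng.random(n_inf) < spec.frac_upregulated, 1.0, -1.0)
    direction = {g: int(s) for g, s in zip(informative, signs)}
    if spec.effect_size != 0:
        shift = spec.effect_size * sigma * signs
        log_x[:n_inf, :][:, is_tumor] += shift[:, None]

    # subtype signatures over informative genes, centred so the tumor-class
    # mean of every gene is untouched
    if spec.n_subtypes > 1 and spec.subtype_shift != 0:
        pattern = rng.choice([-1.0, 1.0], size=(spec.n_subtypes, n_inf))
        props = counts / counts.sum()
        pattern -= (props[:, None] * pattern).sum(axis=0, keepdims=True)
        offsets = spec.subtype_shift * sigma * pattern  # (k, n_inf)
        tumor_cols = np.where(is_tumor)[0]
        log_x[np.ix_(np.arange(n_inf), tumor_cols)] += offsets[subtype_vec - 1, :].T

    # redundant genes: parent + Gaussian noise scaled so the latent Pearson
    # correlation r maps to a Spearman of redundancy_rho (bivariate-normal
    # identity rho_s = (6/pi) asin(r/2))
    redundant_map = {}
    if n_red:
        rho_s = min(spec.redundancy_rho, 0.999)
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        for j, g in enumerate(redundant):
            parent_idx = j % n_inf if n_inf else 0
            if n_inf == 0:
                raise SpecError("redundant genes require at least one informative parent")
            parent_row = log_x[parent_idx]
            sd_p = parent_row.std()
            tau = sd_p * np.sqrt(1.0 / r**2 - 1.0)
            log_x[n_inf + j] = (
                mu_g[n_inf + j] + (parent_row - parent_row.mean())
                + tau * rng.standard_normal(n_samples)
            )
            redundant_map[g] = informative[parent_idx]

    values = np.exp(log_x)

    # zero inflation confined to noise genes so planted effects stay exact
    n_noise = len(noise)
    if n_noise and spec.dropout_rate > 0:
        drop = rng.random((n_noise, n_samples)) < spec.dropout_rate
        values[n_inf + n_red:][drop] = 0.0
    n_silent = int(round(spec.silent_gene_frac * spec.n_genes))
    n_silent = min(n_silent, n_noise)
    if n_silent:
        silent_rows = n_inf + n_red + np.arange(n_noise - n_silent, n_noise)
        silent_mask = rng.random((n_silent, n_samples)) < 0.7
        values[silent_rows[:, None], np.arange(n_samples)[None, :]] *= ~silent_mask

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), labels)

    # mutation plan: which genes will be enriched, and where
    n_mut = spec.n_mutation_genes
    mutation_gene_ids = [f"m{i + 1:03d}" for i in range(n_mut)]
    n_enr = min(spec.n_enriched_mutation_genes, n_mut)
    enriched = {
        mutation_gene_ids[i]: int(spec.n_subtypes - (i % spec.n_subtypes))
        for i in range(n_enr)
    }

    truth = GroundTruth(
        informative_gene_ids=set(informative),
        redundant_map=redundant_map,
        subtype_of_sample=subtype_of_sample,
        enriched_mutation_genes=enriched,
        direction=direction,
        mutation_gene_ids=mutation_gene_ids,
    )
    return matrix, truth


def _censoring_upper(mean_hazard: float, rate: float) -> float:
    """Upper bound of the uniform censoring window achieving the target rate.

    For T ~ Exp(lam) and C ~ U(0, u) independent,
    P(C < T) = (1 - exp(-lam*u)) / (lam*u); solve for u.
    """
    if rate <= 0:
        return np.inf

    def f(u):
        return (1.0 - np.exp(-mean_hazard * u)) / (mean_hazard * u) - rate

    lo, hi = 1e-9, 1.0 / mean_hazard
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12 / mean_hazard:
            break
    return optimize.brentq(f, lo, hi)


def generate_survival(truth: GroundTruth, spec: SyntheticSpec) -> pd.DataFrame:
    """Exponential survival for tumor samples, hazards scaled per subtype.

    Censoring is independent uniform on (0, u) with u calibrated so the
    expected overall censoring fraction equals ``censoring_rate``.
    Returns a table with columns sample_id, time_days, event.
    """
    spec.validate()
    if not truth.subtype_of_sample:
        raise DataError("survival generation requires subtype assignments")
    rng = rng_for(spec.seed, "survival")
    samples = sorted(truth.subtype_of_sample)
    subtypes = np.array([truth.subtype_of_sample[s] for s in samples])
    if subtypes.min() < 1 or subtypes.max() > spec.n_subtypes:
        raise DataError(f"unknown subtype label in ground truth (expected 1..{spec.n_subtypes})")
    lam0 = np.log(2.0) / spec.baseline_median_days
    hazards = lam0 * np.asarray(spec.hazard_ratios)[subtypes - 1]
    times = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        u = _censoring_upper(hazards.mean(), spec.censoring_rate)
        censor = rng.uniform(0.0, u, size=len(samples))
        event = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
    else:
        event = np.ones(len(samples), dtype=int)
        obs = times
    return pd.DataFrame({"sample_id": samples, "time_days": obs, "event": event})


def generate_mutations(truth: GroundTruth, spec: SyntheticSpec) -> MutationMatrix:
    """Bernoulli mutation indicators for tumor samples.

    Enriched genes mutate at ``mutation_enriched_rate`` in their target
    subtype and at the background rate everywhere else.  An explicit
    ``spec.mutation_rates`` mapping {gene: {subtype: rate}} overrides both.
    """
    spec.validate()
    if not truth.subtype_of_sample:
        raise DataError("mutation generation requires subtype assignments")
    rng = rng_for(spec.seed, "mutations")
    samples = sorted(truth.subtype_of_sample)
    subtypes = np.array([truth.subtype_of_sample[s] for s in samples])
    genes = list(truth.mutation_gene_ids)
    rates = np.full((len(genes), len(samples)), spec.mutation_background_rate)
    for g, target in truth.enriched_mutation_genes.items():
        if g in genes:
            rates[genes.index(g), subtypes == target] = spec.mutation_enriched_rate
    if spec.mutation_rates is not None:
        for g, per_subtype in spec.mutation_rates.items():
            if g not in genes:
                genes.append(g)
                rates = np.vstack([rates, np.full((1, len(samples)), spec.mutation_background_rate)])
            row = genes.index(g)
            for k, rate in per_subtype.items():
                if not (0.0 <= rate <= 1.0):
                    raise SpecError(f"invariant violated: mutation rate in [0,1] (got {rate})")
                rates[row, subtypes == int(k)] = rate
    ind = (rng.random(rates.shape) < rates).astype(int)
    return MutationMatrix(pd.DataFrame(ind, index=genes, columns=samples))


def generate_methylation(
    matrix: ExpressionMatrix, truth: GroundTruth, spec: SyntheticSpec
) -> pd.DataFrame:
    """Per-gene beta values anti-correlated with expression.

    Only a fraction of the informative genes carry methylation data
    (mirroring real panels where some markers lack array probes).  Beta is
    a logistic squash of the negated standardized log-expression plus
    noise, so it lands in (0, 1) and correlates negatively.
    """
    spec.validate()
    rng = rng_for(spec.seed, "methylation")
    informative = sorted(truth.informative_gene_ids)
    n_keep = int(round(spec.methylation_frac * len(informative)))
    genes = informative[:n_keep]
    if not genes:
        return pd.DataFrame(columns=matrix.sample_ids)
    expr = np.log(matrix.values.loc[genes].to_numpy() + 1e-12)
    z = (expr - expr.mean(axis=1, keepdims=True)) / (expr.std(axis=1, keepdims=True) + 1e-12)
    latent = -z + spec.methylation_noise * rng.standard_normal(z.shape)
    beta = 1.0 / (1.0 + np.exp(-latent))
    return pd.DataFrame(beta, index=genes, columns=matrix.sample_ids)


@dataclass
class SyntheticDataset:
    """The full synthetic cohort: every input the pipeline can consume."""

    spec: SyntheticSpec
    matrix: ExpressionMatrix
    truth: GroundTruth
    survival: pd.DataFrame
    mutations: MutationMatrix
    methylation: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Write all tables as plain TSV/JSON; returns {name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "labels": out / "labels.tsv",
            "survival": out / "survival.tsv",
            "mutations": out / "mutations.tsv",
            "maf": out / "mutations.maf.tsv",
            "methylation": out / "methylation.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        self.matrix.to_tsv(paths["expression"], labels_path=paths["labels"])
        self.survival.to_csv(paths["survival"], sep="\t", index=False)
        self.mutations.to_tsv(paths["mutations"])
        self.mutations.to_maf(paths["maf"])
        self.methylation.rename_axis("gene_id").to_csv(paths["methylation"], sep="\t")
        self.truth.to_json(paths["ground_truth"])
        return {k: str(v) for k, v in paths.items()}


def simulate(spec: SyntheticSpec | None = None, **overrides) -> SyntheticDataset:
    """Generate the complete cohort in one call."""
    if spec is None:
        spec = SyntheticSpec(**overrides)
    elif overrides:
        spec = SyntheticSpec(**{**asdict(spec), **overrides})
    matrix, truth = generate_expression(spec)
    survival = generate_survival(truth, spec)
    mutations = generate_mutations(truth, spec)
    methylation = generate_methylation(matrix, truth, spec)
    return SyntheticDataset(spec, matrix, truth, survival, mutations, methylation)
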