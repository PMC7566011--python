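"""End-to-end pipeline orchestration, configuration, and run manifests.

One :class:`RunConfig` carries every tunable (defaults mirror the
reference settings: Fisher threshold 0.5, |rho| threshold 0.7, 500 trees,
5 CV folds, nine balanced datasets of 100, 80/20 split, k = 3 subtypes,
top-100 representative genes) plus a single master seed that every random
stage derives its own seed from by stable hashing, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import classify, downstream, gene_filter, synthetic
from .preprocess import preprocess as _preprocess
from ._utils import stage_seed
from .containers import (
    DataError,
    ExpressionMatrix,
    MutationMatrix,
    load_expression,
    load_survival,
)
from .ensemble import TreeEnsembleSelector

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

ALL_STAGES = ("preprocess", "gene_filter", "ensemble", "classify", "downstream")


@dataclass
class RunConfig:
    """All pipeline tunables with reference defaults, plus file paths."""

    # inputs (expression+labels required unless simulate=True)
    expression_path: str | None = None
    labels_path: str | None = None
    survival_path: str | None = None
    mutation_path: str | None = None
    methylation_path: str | None = None
    out_dir: str = "treevote_out"
    simulate: bool = False
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    # stage tunables
    frac_threshold: float = 0.5
    fisher_threshold: float = 0.5
    rho_threshold: float = 0.7
    n_trees: int = 500
    cv_folds: int = 5
    perturbation: str = "mean"
    sampling: str = "bootstrap"
    n_hybrid_datasets: int = 9
    hybrid_size: int = 100
    train_frac: float = 0.8
    k_subtypes: int = 3
    k_range: tuple = (2, 8)
    top_n_representatives: int = 100
    enrichment_mode: str = "groupwise"
    methylation_flag: float = -0.3
    seed: int = 0
    stages: tuple = ALL_STAGES

    def validate(self) -> "RunConfig":
        for name, lo, hi in (
            ("frac_threshold", 0.0, 1.0),
            ("train_frac", 0.0, 1.0),
            ("rho_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v < hi) and name == "train_frac":
                raise DataError(f"{name} must be in ({lo}, {hi})")
            if not (lo <= v <= hi):
                raise DataError(f"{name} must be in [{lo}, {hi}]")
        if self.fisher_threshold < 0:
            raise DataError("fisher_threshold must be >= 0")
        if self.n_trees < 1 or self.cv_folds < 2:
            raise DataError("need n_trees >= 1 and cv_folds >= 2")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise DataError(f"unknown stage(s): {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["k_range"] = list(self.k_range)
        return d


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, counts, output checksums."""

    config: dict
    stage_seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}
    failed_stage: str | None = None

    def record_output(self, name: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate:
        spec = synthetic.SyntheticSpec(
            **{"seed": stage_seed(config.seed, "simulate"), **config.synthetic}
        )
        ds = synthetic.simulate(spec)
        ds.write(out / "synthetic")
        return ds.matrix, ds.survival, ds.mutations, ds.methylation
    if config.expression_path is None or config.labels_path is None:
        raise DataError("expression_path and labels_path are required unless simulate=True")
    if "downstream" in config.stages and config.survival_path is None:
        raise DataError(
            "downstream (subtype/survival) stage requested but no clinical survival "
            "table was provided (survival_path)"
        )
    matrix = load_expression(config.expression_path, labels_path=config.labels_path)
    survival = load_survival(config.survival_path) if config.survival_path else None
    mutations = (
        MutationMatrix.from_tsv(config.mutation_path) if config.mutation_path else None
    )
    methylation = (
        pd.read_csv(config.methylation_path, sep="\t", index_col=0)
        if config.methylation_path
        else None
    )
    return matrix, survival, mutations, methylation


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages end to end, writing outputs + manifest.

    Stage order: preprocess -> gene_filter -> ensemble -> classify ->
    downstream.  A failed stage aborts with its name and cause; outputs
    produced so far are kept and the manifest carries a FAILED marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    stage = "load"
    try:
        matrix, survival, mutations, methylation = _load_inputs(config, out)
        manifest.counts["genes_in"] = matrix.n_genes
        manifest.counts["samples_in"] = matrix.n_samples

        panel = None
        if "preprocess" in config.stages:
            stage = "preprocess"
            seed = stage_seed(config.seed, stage)
            manifest.stage_seeds[stage] = seed
            matrix, report = _preprocess(
                matrix, frac_threshold=config.frac_threshold, seed=seed
            )
            report.to_json(out / "preprocess_report.json")
            manifest.record_output("preprocess_report", out / "preprocess_report.json")
            manifest.counts["genes_after_preprocess"] = matrix.n_genes

        if "gene_filter" in config.stages:
            stage = "gene_filter"
            scores = gene_filter.filter_genes(
                matrix,
                fisher_threshold=config.fisher_threshold,
                rho_threshold=config.rho_threshold,
            )
            scores.rename_axis("gene_id").to_csv(out / "gene_scores.tsv", sep="\t")
            manifest.record_output("gene_scores", out / "gene_scores.tsv")
            retained = scores.index[scores["retained_after_redundancy"]]
            manifest.counts["genes_after_fisher"] = int(scores["retained_after_fisher"].sum())
            manifest.counts["genes_after_redundancy"] = len(retained)
            matrix_for_trees = matrix.subset_genes(retained)
        else:
            matrix_for_trees = matrix

        if "ensemble" in config.stages:
            stage = "ensemble"
            seed = stage_seed(config.seed, stage)
            manifest.stage_seeds[stage] = seed
            model = TreeEnsembleSelector(
                matrix_for_trees,
                n_trees=config.n_trees,
                cv=config.cv_folds,
                perturbation=config.perturbation,
                sampling=config.sampling,
            )
            res = model.fit(seed=seed)
            res.to_tsv(
                out / "degs.tsv",
                fi_matrix_path=out / "fi_matrix.tsv",
                weights_path=out / "tree_weights.tsv",
            )
            (out / "ensemble_summary.txt").write_text(res.summary())
            for name in ("degs", "fi_matrix", "tree_weights", "ensemble_summary"):
                ext = "txt" if name == "ensemble_summary" else "tsv"
                manifest.record_output(name, out / f"{name}.{ext}")
            degs = res.select_degs()
            panel = degs.index
            manifest.counts["n_degs"] = len(panel)
            if len(panel) == 0:
                logger.warning("ensemble selected no DEGs; downstream stages will be limited")

        if "classify" in config.stages and panel is not None and len(panel) > 0:
            stage = "classify"
            seed = stage_seed(config.seed, stage)
            manifest.stage_seeds[stage] = seed
            ev = classify.evaluate_panel(
                matrix,
                panel,
                train_frac=config.train_frac,
                n_datasets=config.n_hybrid_datasets,
                size=config.hybrid_size,
                seed=seed,
            )
            auc = {split: r.auc for split, r in ev["roc"].items()}
            (out / "auc.json").write_text(
                json.dumps({"auc": auc, "accuracy": ev["accuracy"]}, indent=2, sort_keys=True)
            )
            manifest.record_output("auc", out / "auc.json")
            for split, r in ev["roc"].items():
                r.to_frame().to_csv(out / f"roc_{split}.tsv", sep="\t", index=False)
                manifest.record_output(f"roc_{split}", out / f"roc_{split}.tsv")

        if "downstream" in config.stages and panel is not None and len(panel) > 0:
            stage = "downstream"
            seed = stage_seed(config.seed, stage)
            manifest.stage_seeds[stage] = seed
            assignment = downstream.cluster_subtypes(
                matrix,
                panel=panel,
                k_select=config.k_subtypes,
                k_range=tuple(config.k_range),
                seed=seed,
            )
            assignment.to_tsv(out / "subtypes.tsv")
            manifest.record_output("subtypes", out / "subtypes.tsv")
            manifest.counts["subtype_sizes"] = {
                int(k): int(v) for k, v in assignment.sizes().items()
            }
            reps = downstream.representative_genes(
                matrix, assignment, top_n=config.top_n_representatives
            )
            for k, table in reps.items():
                table.to_csv(out / f"representative_genes_subtype{k}.tsv", sep="\t")
                manifest.record_output(
                    f"representative_genes_subtype{k}",
                    out / f"representative_genes_subtype{k}.tsv",
                )
            if survival is not None:
                chi2, df, p = downstream.logrank_test(survival, assignment)
                curves = []
                for k in sorted(assignment.labels.unique()):
                    ids = assignment.samples_in(k)
                    curve = downstream.km_curve(
                        survival[survival["sample_id"].isin(ids)]
                    ).assign(subtype=k)
                    curves.append(curve)
                pd.concat(curves).to_csv(out / "km_curves.tsv", sep="\t", index=False)
                (out / "logrank.json").write_text(
                    json.dumps({"chi2": chi2, "df": df, "p": p}, indent=2)
                )
                manifest.record_output("km_curves", out / "km_curves.tsv")
                manifest.record_output("logrank", out / "logrank.json")
            if mutations is not None:
                enrich = downstream.mutation_enrichment(
                    mutations, assignment, mode=config.enrichment_mode
                )
                enrich.to_csv(out / "mutation_enrichment.tsv", sep="\t", index=False)
                manifest.record_output("mutation_enrichment", out / "mutation_enrichment.tsv")
            if methylation is not None:
                corr = downstream.methylation_correlation(
                    matrix, methylation, flag_threshold=config.methylation_flag, genes=panel
                )
                corr.to_csv(out / "methylation_correlation.tsv", sep="\t", index=False)
                manifest.record_output(
                    "methylation_correlation", out / "methylation_correlation.tsv"
                )
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.to_json(out / "manifest.FAILED.json")
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.to_json(out / "manifest.json")
    return manifest
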