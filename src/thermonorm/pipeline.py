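"""End-to-end pipeline: filter → TMM → fits → classification → linkage → GO.

A single YAML-serializable :class:`PipelineConfig` carries all paths,
thresholds and seeds. Every stage writes its table under the output
directory and :func:`run_pipeline` returns a :class:`RunReport` (also
written as JSON) with gene counts, the class table and the seeds used.
Reruns with the same config and inputs are bit-identical: the only
stochastic stages (the linkage train/test split and the ranked-enrichment
permutations) are driven by recorded seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import enrichment as _enrichment
from . import linkage as _linkage
from .data import CountMatrix, read_architecture_tsv, read_counts_tsv
from .normalization import filter_expressed, tmm_factors
from .reaction_norm import ReactionNormModel

__all__ = ["PipelineConfig", "RunReport", "ValidationReport", "run_pipeline", "validate_inputs"]

logger = logging.getLogger("thermonorm")


@dataclass
class PipelineConfig:
    counts: str = ""
    samples: str = ""
    architecture: str | None = None
    annotation: str | None = None
    output_dir: str = "thermonorm_out"

    alpha: float = 0.05
    min_fold: float = 1.25
    open_fraction: float = 0.80
    q_go: float = 1e-5
    max_gap: float = 6.0
    train_fraction: float = 0.60
    soc_average: str = "mean"
    trim_M: float = 0.30
    trim_A: float = 0.05
    n_permutations: int = 10_000
    pooled_fdr: bool = False

    split_seed: int = 0
    permutation_seed: int = 0

    run_linkage: bool = True
    run_enrichment: bool = True

    def validate(self) -> None:
        for name, val in (
            ("alpha", self.alpha),
            ("min_fold_minus_1", self.min_fold - 1.0 + 1e-12),
            ("open_fraction", self.open_fraction),
            ("q_go", self.q_go),
            ("train_fraction", self.train_fraction),
        ):
            if not (0.0 < val <= 1.0) and name != "min_fold_minus_1":
                raise ValueError(f"{name} must be in (0, 1]: {val}")
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")
        if self.soc_average not in ("mean", "median"):
            raise ValueError("soc_average must be 'mean' or 'median'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class RunReport:
    config: dict
    stages_run: list[str] = field(default_factory=list)
    stages_failed: dict[str, str] = field(default_factory=dict)
    stages_skipped: list[str] = field(default_factory=list)
    n_genes_input: int = 0
    n_genes_expressed: int = 0
    n_differential: int = 0
    percent_plastic: float = 0.0
    class_counts: dict = field(default_factory=dict)
    linkage_n_complete: int | None = None
    accuracies: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=float) + "\n")


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    n_genes: int = 0
    n_libraries: int = 0
    architecture_complete_cases: int | None = None
    annotation_covered_genes: int | None = None

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Report-only consistency check of all configured inputs."""
    report = ValidationReport()
    counts_path, samples_path = Path(config.counts), Path(config.samples)
    for p in (counts_path, samples_path):
        if not p.exists():
            report.issues.append(f"missing input file: {p}")
    if report.issues:
        return report

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    report.n_genes, report.n_libraries = counts.shape
    if "library_id" not in samples.columns:
        report.issues.append("sample sheet lacks a library_id column")
        return report
    matrix_libs, sheet_libs = set(counts.columns), set(samples["library_id"])
    for lib in sorted(matrix_libs - sheet_libs):
        report.issues.append(f"library {lib} in counts but not in sample sheet")
    for lib in sorted(sheet_libs - matrix_libs):
        report.issues.append(f"library {lib} in sample sheet but not in counts")
    for col in ("temperature", "replicate"):
        if col not in samples.columns:
            report.issues.append(f"sample sheet lacks a {col} column")

    if config.architecture:
        arch_path = Path(config.architecture)
        if not arch_path.exists():
            report.issues.append(f"missing input file: {arch_path}")
        else:
            arch = read_architecture_tsv(arch_path)
            complete = arch.dropna(subset=list(_linkage.ARCHITECTURE_FEATURES))
            report.architecture_complete_cases = int(len(complete))
            n_na = len(arch) - len(complete)
            if n_na:
                report.issues.append(
                    f"architecture table: {n_na} genes with missing covariates "
                    f"(complete cases: {len(complete)})"
                )
    if config.annotation:
        ann_path = Path(config.annotation)
        if not ann_path.exists():
            report.issues.append(f"missing input file: {ann_path}")
        else:
            annotation = _enrichment.read_annotation_tsv(ann_path)
            annotated = set().union(*annotation.values()) if annotation else set()
            report.annotation_covered_genes = int(len(annotated & set(counts.index)))
    return report


def _write_linkage_tables(result: _linkage.LinkageResult, out: Path, q_go: float) -> dict:
    result.soc_model.to_tsv(out / "soc_model.tsv")
    accuracies: dict = {}
    for name, lda, rf in (
        ("direction", result.direction_lda, result.direction_rf),
        ("curvature", result.curvature_lda, result.curvature_rf),
    ):
        if lda is None or rf is None:
            continue
        table = lda.class_means.T
        table["lda_coefficient"] = lda.coefficients
        table["lda_coefficient_standardized"] = lda.coefficients_standardized
        table["rf_importance"] = rf.importances
        table.rename_axis("feature").to_csv(out / f"linkage_{name}.tsv", sep="\t")
        accuracies[name] = {
            "lda": lda.holdout_accuracy,
            "rf": rf.holdout_accuracy,
            "baseline": lda.baseline_accuracy,
        }
    meta = {
        "split_seed": result.split_seed,
        "n_genes": result.soc_model.n_genes,
        "soc_terms": result.soc_model.selected_terms,
        "soc_r2_full": result.soc_model.r2_full,
        "accuracies": accuracies,
    }
    (out / "linkage_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return accuracies


def run_pipeline(
    config: PipelineConfig,
    matrix: CountMatrix | None = None,
    architecture: pd.DataFrame | None = None,
    annotation: dict | None = None,
) -> RunReport:
    """Execute every enabled stage, writing all tables under ``output_dir``.

    Inputs may be passed in memory (``matrix`` etc.) or read from the paths
    in ``config``. Linkage and enrichment failures are recorded in the
    report without discarding earlier stages' outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config=dataclasses.asdict(config),
        seeds={"split_seed": config.split_seed, "permutation_seed": config.permutation_seed},
    )

    def _stage(name: str):
        t0 = time.perf_counter()

        def done():
            report.stages_run.append(name)
            report.timings_s[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s finished in %.2fs", name, report.timings_s[name])

        return done

    done = _stage("load")
    if matrix is None:
        if not Path(config.counts).exists():
            raise FileNotFoundError(f"missing input file: {config.counts}")
        if not Path(config.samples).exists():
            raise FileNotFoundError(f"missing input file: {config.samples}")
        matrix = read_counts_tsv(config.counts, config.samples)
    report.n_genes_input = len(matrix.gene_ids)
    done()

    done = _stage("filter")
    matrix, filter_report = filter_expressed(matrix)
    filter_report.to_json(out / "filter_report.json")
    report.n_genes_expressed = filter_report.n_retained
    done()

    done = _stage("normalize")
    norm = tmm_factors(matrix, trim_M=config.trim_M, trim_A=config.trim_A)
    norm.to_tsv(out / "normalization.tsv")
    done()

    done = _stage("fit")
    model = ReactionNormModel(
        alpha=config.alpha, min_fold=config.min_fold, pooled_fdr=config.pooled_fdr
    ).fit(matrix, norm)
    model.to_tsv(out / "fits.tsv")
    fits = model.results_
    report.n_differential = int(fits["differential"].sum())
    report.percent_plastic = round(100.0 * report.n_differential / len(fits), 2)
    done()

    done = _stage("classify")
    cpm = matrix.counts / norm.effective_library_sizes.to_numpy() * 1e6
    profiles = _classify.build_profiles(
        fits,
        cpm,
        matrix.temperatures,
        open_fraction=config.open_fraction,
        max_gap=config.max_gap,
        average=config.soc_average,
    )
    profiles.rename_axis("gene_id").to_csv(out / "profiles.tsv", sep="\t")
    report.class_counts = _classify.tabulate_classes(profiles)
    (out / "class_counts.json").write_text(json.dumps(report.class_counts, indent=2) + "\n")
    done()

    if config.run_linkage and (architecture is not None or config.architecture):
        done = _stage("link")
        try:
            if architecture is None:
                architecture = read_architecture_tsv(config.architecture)
            linkage_result = _linkage.link_architecture(
                profiles, architecture, config.train_fraction, config.split_seed
            )
            report.accuracies = _write_linkage_tables(linkage_result, out, config.q_go)
            report.linkage_n_complete = linkage_result.soc_model.n_genes
            done()
        except Exception as exc:  # keep earlier outputs, mark failure
            report.stages_failed["link"] = str(exc)
            logger.warning("linkage stage failed: %s", exc)
    else:
        report.stages_skipped.append("link")

    if config.run_enrichment and (annotation is not None or config.annotation):
        done = _stage("enrich")
        try:
            if annotation is None:
                annotation = _enrichment.read_annotation_tsv(config.annotation)
            background = set(profiles.index)
            for label in sorted(profiles["class_label"].unique()):
                target = set(profiles.index[profiles["class_label"] == label])
                res = _enrichment.hypergeom_enrich(target, background, annotation)
                res.to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False)
            for label in ("U", "bell"):
                sub = profiles[profiles["class_label"] == label]
                if len(sub) < 2:
                    continue
                scores = fits.loc[profiles.index, "b2"].where(
                    profiles["class_label"] == label, 0.0
                )
                ranking = _enrichment.rank_genes(scores, absolute=True)
                res = _enrichment.ranked_enrich(
                    ranking,
                    annotation,
                    n_permutations=config.n_permutations,
                    seed=config.permutation_seed,
                )
                res.to_csv(out / f"ranked_enrichment_{label}.tsv", sep="\t", index=False)
            done()
        except Exception as exc:
            report.stages_failed["enrich"] = str(exc)
            logger.warning("enrichment stage failed: %s", exc)
    else:
        report.stages_skipped.append("enrich")

    report.to_json(out / "run_report.json")
    return report
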