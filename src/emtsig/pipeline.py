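"""End-to-end orchestration: discover signature, cluster, label, train the
compound covariate classifier, classify test cohorts, score immunity and
run the survival/association statistics — from a single config, with a
fixed master seed and per-stage derived seeds.

Every threshold the underlying study left implicit (correlation cutoff, FDR
level, clustering distance/linkage, classifier priors, comparison test) is
explicit, versioned configuration here. Stage outputs are written to the
output directory as TSV/JSON/GMT as they are produced, so a failed run
leaves its completed stages on disk next to a FAILED marker naming the
stage that broke.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from .bccp import fit_bccp, loocv_misclassification, predict_bccp
from .immune import compute_immune_panel
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .signature import compute_marker_correlations, select_signature_genes
from .simulate import (
    SyntheticCohortSpec,
    default_cell_sets,
    default_is_genes,
    generate_multi_cohort,
)
from .subgroup import assign_subgroup_labels, hierarchical_cluster_two_way
from .survival import (
    compare_scores_between_groups,
    contingency_association,
    cox_fit,
    enrichment_test,
    km_estimate,
    logrank_test,
)

__all__ = [
    "PipelineConfig",
    "CohortPaths",
    "AnalysisReport",
    "PipelineError",
    "run_pipeline",
    "run_synthetic_demo",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CohortPaths:
    expression: str
    clinical: str
    name: str


@dataclass
class PipelineConfig:
    training: CohortPaths
    test: list[CohortPaths] = field(default_factory=list)
    markers: tuple[str, ...] = ("CDH1", "VIM", "CDH2", "FN1")
    r_min: float = 0.6
    q_max: float = 0.05
    cluster_metric: str = "correlation"
    cluster_method: str = "complete"
    bccp_priors: tuple[float, float] = (0.5, 0.5)
    bccp_standardize: str = "cohort"
    cell_sets_path: str | None = None
    is_genes_path: str | None = None
    annotations_path: str | None = None
    comparison_method: str = "ranksum"
    association_variables: list[str] = field(default_factory=list)
    plots: bool = False
    output_dir: str = "emtsig_out"
    seed: int = 17

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "PipelineConfig":
        if "training" not in cfg or not cfg["training"].get("expression"):
            raise ValueError("config must name a training cohort expression matrix")
        training = CohortPaths(
            expression=cfg["training"]["expression"],
            clinical=cfg["training"]["clinical"],
            name=cfg["training"].get("name", "training"),
        )
        test = [
            CohortPaths(
                expression=t["expression"],
                clinical=t["clinical"],
                name=t.get("name", f"test{i + 1}"),
            )
            for i, t in enumerate(cfg.get("test", []))
        ]
        selection = cfg.get("selection", {})
        clustering = cfg.get("clustering", {})
        bccp = cfg.get("bccp", {})
        gene_sets = cfg.get("gene_sets", {})
        stats_cfg = cfg.get("stats", {})
        return cls(
            training=training,
            test=test,
            markers=tuple(cfg.get("markers", ("CDH1", "VIM", "CDH2", "FN1"))),
            r_min=float(selection.get("r_min", 0.6)),
            q_max=float(selection.get("q_max", 0.05)),
            cluster_metric=clustering.get("metric", "correlation"),
            cluster_method=clustering.get("method", "complete"),
            bccp_priors=tuple(bccp.get("priors", (0.5, 0.5))),
            bccp_standardize=bccp.get("standardize", "cohort"),
            cell_sets_path=gene_sets.get("cell_sets"),
            is_genes_path=gene_sets.get("is_genes"),
            annotations_path=gene_sets.get("annotations"),
            comparison_method=stats_cfg.get("comparison", "ranksum"),
            association_variables=list(stats_cfg.get("association_variables", [])),
            plots=bool(cfg.get("plots", False)),
            output_dir=cfg.get("output_dir", "emtsig_out"),
            seed=int(cfg.get("seed", 17)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["markers"] = list(self.markers)
        d["bccp_priors"] = list(self.bccp_priors)
        return d


@dataclass
class AnalysisReport:
    """Every number the pipeline produced, traceable to its stage."""

    config: dict[str, Any]
    signature: list[dict[str, Any]]
    assignments: dict[str, list[dict[str, Any]]]
    loocv_misclassification: float
    survival: dict[str, Any]
    immune_comparisons: dict[str, Any]
    associations: dict[str, Any]
    enrichment: list[dict[str, Any]] | None
    provenance: dict[str, Any]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _records(frame: pd.DataFrame, index_name: str) -> list[dict[str, Any]]:
    out = frame.reset_index().rename(columns={"index": index_name})
    return json.loads(out.to_json(orient="records"))


def _load_cohort(paths: CohortPaths) -> tuple[ExpressionMatrix, ClinicalTable]:
    expr = cohort_io.read_expression_matrix(paths.expression, name=paths.name)
    clinical = cohort_io.read_clinical_table(paths.clinical)
    return expr, clinical


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis; deterministic given config (incl. seed).

    Stage order: load -> harmonize (signature discovery and clustering use
    the raw training matrix; harmonized matrices feed classification) ->
    marker correlations -> selection -> two-way clustering -> Epi/Mes
    labels -> BCCP fit + LOOCV -> per-test-cohort prediction -> immune
    panels -> KM/log-rank/Cox/score comparisons/associations -> optional
    enrichment -> report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "load_inputs"
    try:
        train_expr, train_clin = _load_cohort(config.training)
        tests = [_load_cohort(t) for t in config.test]
        cell_sets = (
            cohort_io.read_gmt(config.cell_sets_path) if config.cell_sets_path else None
        )
        is_genes = None
        if config.is_genes_path:
            is_genes = [
                line.strip()
                for line in Path(config.is_genes_path).read_text().splitlines()
                if line.strip()
            ]
        annotations = (
            cohort_io.read_gmt(config.annotations_path) if config.annotations_path else None
        )

        stage = "harmonize"
        if tests:
            harmonized = cohort_io.harmonize_cohorts(
                [train_expr] + [expr for expr, _ in tests]
            )
            harmonized_tests = harmonized[1:]
        else:
            harmonized_tests = []

        stage = "marker_correlations"
        correlations = compute_marker_correlations(train_expr, markers=config.markers)

        stage = "select_signature"
        signature = select_signature_genes(correlations, r_min=config.r_min, q_max=config.q_max)
        signature.to_tsv(outdir / "signature.tsv")
        cohort_io.write_gmt(signature.to_gene_sets(), outdir / "signature.gmt")

        stage = "cluster_training"
        clusters = hierarchical_cluster_two_way(
            train_expr,
            signature,
            k=2,
            metric=config.cluster_metric,
            method=config.cluster_method,
        )
        train_assign = assign_subgroup_labels(clusters, train_expr, signature)

        stage = "fit_bccp"
        model = fit_bccp(train_expr, train_assign, signature, priors=config.bccp_priors)
        model.save(outdir / "bccp_model.json")
        loocv = loocv_misclassification(
            train_expr, train_assign, signature, priors=config.bccp_priors
        )

        stage = "predict_test_cohorts"
        assignments = {config.training.name: train_assign}
        clinicals = {config.training.name: train_clin}
        for (expr, clin), hexpr in zip(tests, harmonized_tests):
            assignments[expr.name] = predict_bccp(
                model, hexpr, standardize=config.bccp_standardize
            )
            clinicals[expr.name] = clin
        for name, assign in assignments.items():
            assign.to_frame().to_csv(outdir / f"assignments_{name}.tsv", sep="\t")

        stage = "immune_scores"
        raw_exprs = {config.training.name: train_expr}
        raw_exprs.update({expr.name: expr for expr, _ in tests})
        panels = {
            name: compute_immune_panel(expr, cell_sets=cell_sets, is_genes=is_genes)
            for name, expr in raw_exprs.items()
        }
        for name, panel in panels.items():
            panel.to_frame().to_csv(outdir / f"immune_scores_{name}.tsv", sep="\t")

        stage = "survival_statistics"
        survival_block: dict[str, Any] = {}
        for name, assign in assignments.items():
            clin = clinicals[name]
            curves = km_estimate(clin, assign)
            if config.plots:
                from .survival import plot_km

                plot_km(curves, outdir / f"km_{name}.png", title=name)
            lr = logrank_test(clin, assign)
            cox = cox_fit(clin, ["subgroup"], groups=assign)
            survival_block[name] = {
                "km": {
                    g: {
                        "times": c.times.tolist(),
                        "survival": c.survival.tolist(),
                        "n": c.n,
                    }
                    for g, c in curves.items()
                },
                "logrank": {"statistic": lr.statistic, "p": lr.p},
                "cox_subgroup": _records(cox.table, "covariate"),
                "cox_n": cox.n_used,
            }

        stage = "score_comparisons"
        comparisons: dict[str, Any] = {}
        for name, panel in panels.items():
            table = panel.to_frame()
            if table.shape[1] == 0:
                continue
            cmp = compare_scores_between_groups(
                table, assignments[name], method=config.comparison_method
            )
            comparisons[name] = _records(cmp, "score")

        stage = "associations"
        associations: dict[str, Any] = {}
        for name, assign in assignments.items():
            block = {}
            for var in config.association_variables:
                try:
                    res = contingency_association(clinicals[name], assign, var)
                    block[var] = {"p": res.p, "method": res.method, "odds_ratio": res.odds_ratio}
                except ValueError as exc:
                    block[var] = {"error": str(exc)}
            if block:
                associations[name] = block

        stage = "enrichment"
        enrichment = None
        if annotations is not None:
            enr = enrichment_test(
                signature.genes, annotations, universe=list(train_expr.genes)
            )
            enrichment = _records(enr, "set")

        stage = "report"
        report = AnalysisReport(
            config=config.to_dict(),
            signature=_records(signature.entries.set_index("gene"), "gene"),
            assignments={
                name: _records(assign.to_frame(), "sample")
                for name, assign in assignments.items()
            },
            loocv_misclassification=float(loocv),
            survival=survival_block,
            immune_comparisons=comparisons,
            associations=associations,
            enrichment=enrichment,
            provenance={
                "seed": config.seed,
                "n_signature_genes": len(signature),
                "signature_thresholds": {"r_min": config.r_min, "q_max": config.q_max},
                "bccp_genes": len(model.genes),
                "cohort_sizes": {name: expr.shape[1] for name, expr in raw_exprs.items()},
                "immune_provenance": {name: p.provenance for name, p in panels.items()},
            },
        )
        report.to_json(outdir / "report.json")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc


def run_synthetic_demo(
    output_dir: str | Path = "emtsig_demo",
    seed: int = 17,
    n_test_cohorts: int = 2,
    **spec_overrides: Any,
) -> AnalysisReport:
    """Quickstart: generate a multi-cohort synthetic study and run the pipeline.

    Cohorts are written to disk in the package's own text formats and read
    back, so the demo exercises the full I/O surface. Returns the report;
    all stage outputs land in ``output_dir``.
    """
    outdir = Path(output_dir)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticCohortSpec(seed=seed, **spec_overrides)
    cell_sets = default_cell_sets()
    is_genes = default_is_genes()
    cohorts = generate_multi_cohort(
        spec, n_test_cohorts=n_test_cohorts, cell_sets=cell_sets, extra_immune_genes=is_genes
    )

    cohort_paths = []
    for cohort in cohorts:
        name = cohort.expression.name
        expr_path = datadir / f"{name}_expression.tsv"
        clin_path = datadir / f"{name}_clinical.tsv"
        cohort_io.write_expression_matrix(cohort.expression, expr_path)
        clin = cohort.clinical.data.copy()
        clin.index.name = "id"
        clin.to_csv(clin_path, sep="\t")
        cohort_paths.append(CohortPaths(str(expr_path), str(clin_path), name))
        cohort.true_labels.rename_axis("sample").to_csv(
            datadir / f"{name}_true_labels.tsv", sep="\t"
        )

    cell_sets_path = datadir / "cell_sets.gmt"
    cohort_io.write_gmt(cell_sets, cell_sets_path)
    is_path = datadir / "is_genes.txt"
    is_path.write_text("\n".join(is_genes) + "\n")

    config = PipelineConfig(
        training=cohort_paths[0],
        test=cohort_paths[1:],
        r_min=0.5,
        q_max=0.05,
        cell_sets_path=str(cell_sets_path),
        is_genes_path=str(is_path),
        association_variables=["hpv", "stage"],
        output_dir=str(outdir),
        seed=seed,
    )
    return run_pipeline(config)
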