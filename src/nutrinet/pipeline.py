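"""End-to-end orchestration of the meta-analysis / network pipeline.

Stage order: preprocess → per-study differential expression → cross-study
combination → set overlaps → profile clustering / PCA → co-expression
network → (optional) directed TF network.  Every stage writes its table
under the output directory and contributes gate counts to a JSON run
manifest; any stage failure aborts with the stage name, leaving partial
outputs plus a FAILED marker.

Exit-code convention for the CLI built on top: 0 success, 2 validation
failure, 3 stage failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .cluster import kmeans_profiles, pca_scores
from .coexpr import correlation_edges, hub_nodes
from .diffexpr import DesignInfo, deg_table
from .grn import rf_importance_network, threshold_directed
from .meta import StudyResult, meta_analyze
from .preprocess import collapse_probes, quantile_normalize
from .setstats import mutant_nutrient_intersections, GeneSet

__all__ = ["PipelineConfig", "PipelineError", "ValidationReport", "validate_inputs", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; thresholds default to the
    published analysis settings."""

    sample_sheet: str
    matrix_dir: str
    out_dir: str
    probe_map: str | None = None
    mutant_sets: str | None = None  # GMT of genotype-specific gene sets
    universe: str | None = None  # gene list; default: genes surviving preprocessing
    tf_list: str | None = None
    priors: str | None = None
    grn_expression: str | None = None  # dedicated matrix for the directed stage
    lfc_threshold: float = 1.0
    deg_fdr: float = 0.05
    meta_p: float = 0.05
    min_stress_types: int = 2
    edge_fdr: float = 0.0005
    k: int = 5
    n_trees: int = 1000
    grn_top_n: int = 50
    collapse_rule: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.deg_fdr < 1 and 0 < self.meta_p < 1 and 0 < self.edge_fdr < 1):
            raise ValueError("FDR/p thresholds must lie in (0, 1)")
        if self.lfc_threshold < 0 or self.k < 1 or self.n_trees < 1:
            raise ValueError("invalid threshold configuration")
        if self.min_stress_types < 1:
            raise ValueError("min_stress_types must be >=1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def matrix_path(self, study: str) -> Path:
        return Path(self.matrix_dir) / f"expr_{study}.tsv"


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Consistency checks on the declared inputs; never raises."""
    rep = ValidationReport()
    sheet_path = Path(config.sample_sheet)
    if not sheet_path.exists():
        rep.errors.append(f"sample sheet not found: {sheet_path}")
        return rep
    try:
        sheet = nio.read_sample_sheet(sheet_path)
    except ValueError as exc:
        rep.errors.append(str(exc))
        return rep
    if sheet["sample"].duplicated().any():
        rep.errors.append("duplicate sample IDs in sample sheet")
    for study, sub in sheet.groupby("study"):
        mpath = config.matrix_path(study)
        if not mpath.exists():
            rep.errors.append(f"matrix for study {study} not found: {mpath}")
            continue
        try:
            matrix = nio.read_expression_tsv(mpath)
        except ValueError as exc:
            rep.errors.append(f"study {study}: {exc}")
            continue
        for sample in sub["sample"]:
            if sample not in matrix.columns:
                rep.errors.append(f"sample {sample} (study {study}) missing from {mpath.name}")
        if matrix.index.duplicated().any():
            rep.errors.append(f"study {study}: duplicate gene/probe IDs")
        if matrix.to_numpy().max() > 30:
            rep.warnings.append(
                f"study {study}: max value {matrix.to_numpy().max():.1f} > 30; "
                "matrix appears unlogged"
            )
        conds = set(sub["condition"])
        if not {"control", "stress"} <= conds:
            rep.errors.append(f"study {study}: needs both control and stress samples")
    if config.tf_list and not Path(config.tf_list).exists():
        rep.errors.append(f"TF list not found: {config.tf_list}")
    if config.tf_list and config.grn_expression and Path(config.tf_list).exists():
        if Path(config.grn_expression).exists():
            tfs = set(nio.read_gene_list(config.tf_list))
            grn_genes = set(nio.read_expression_tsv(config.grn_expression).index)
            stray = sorted(tfs - grn_genes)
            if stray:
                rep.errors.append(f"TFs absent from GRN matrix: {stray[:5]}")
        else:
            rep.errors.append(f"GRN matrix not found: {config.grn_expression}")
    for name in ("probe_map", "mutant_sets", "universe", "priors"):
        value = getattr(config, name)
        if value and not Path(value).exists():
            rep.errors.append(f"{name} not found: {value}")
    return rep


def _stage(manifest: dict, name: str):
    """Context manager recording stage success/failure in the manifest."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest["failed_stage"] = name
                manifest["error"] = str(exc)
                out = Path(manifest["out_dir"])
                nio.write_json(manifest, out / "manifest.json")
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage from on-disk inputs; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "out_dir": str(out),
        "thresholds": {
            "lfc_threshold": config.lfc_threshold,
            "deg_fdr": config.deg_fdr,
            "meta_p": config.meta_p,
            "min_stress_types": config.min_stress_types,
            "edge_fdr": config.edge_fdr,
            "k": config.k,
            "n_trees": config.n_trees,
        },
        "stages": {},
    }
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()

    with _stage(manifest, "validate"):
        report = validate_inputs(config)
        if not report.ok:
            raise ValueError("; ".join(report.errors))
        manifest["stages"]["validate"] = {"warnings": report.warnings}

    # ---- preprocess ------------------------------------------------------
    with _stage(manifest, "preprocess"):
        sheet = nio.read_sample_sheet(config.sample_sheet)
        probe_map = nio.read_probe_map(config.probe_map) if config.probe_map else None
        matrices: dict[str, pd.DataFrame] = {}
        designs: dict[str, DesignInfo] = {}
        stress_of: dict[str, str] = {}
        for study, sub in sheet.groupby("study", sort=True):
            matrix = nio.read_expression_tsv(config.matrix_path(study))
            matrix = quantile_normalize(matrix)
            if probe_map is not None:
                matrix = collapse_probes(matrix, probe_map, how=config.collapse_rule)
            matrices[study] = matrix
            groups = {
                row["sample"]: ("treatment" if row["condition"] == "stress" else "control")
                for _, row in sub.iterrows()
            }
            designs[study] = DesignInfo(groups=groups, contrast=("treatment", "control"))
            stress_of[study] = sub["stress"].iloc[0]
            nio.write_expression_tsv(matrix, out / f"normalized_{study}.tsv")
        manifest["stages"]["preprocess"] = {
            "n_studies": len(matrices),
            "genes_per_study": {s: int(m.shape[0]) for s, m in matrices.items()},
        }

    # ---- per-study differential expression -------------------------------
    with _stage(manifest, "diffexpr"):
        deg_counts: dict[str, int] = {}
        study_results: list[StudyResult] = []
        for study, matrix in matrices.items():
            table = deg_table(matrix, designs[study], config.lfc_threshold, config.deg_fdr)
            table.to_csv(out / f"deg_{study}.tsv", sep="\t", index_label="gene")
            deg_counts[study] = int(table["is_deg"].sum())
            study_results.append(
                StudyResult(
                    study=study,
                    stress=stress_of[study],
                    table=pd.DataFrame(
                        {
                            "log2fc": table["log2fc"],
                            "p_value": table["p_value"],
                            "n_samples": table["n_treat"] + table["n_ctrl"],
                            "is_deg": table["is_deg"],
                        }
                    ),
                )
            )
        manifest["stages"]["diffexpr"] = {"degs_per_study": deg_counts}

    # ---- meta combination -------------------------------------------------
    with _stage(manifest, "meta"):
        meta = meta_analyze(
            study_results, p_threshold=config.meta_p, min_stress_types=config.min_stress_types
        )
        for stress, table in meta.per_stress.items():
            table.to_csv(out / f"meta_{stress}.tsv", sep="\t")
        nio.write_gmt({"common_responsive": meta.common_responsive}, out / "common_responsive.gmt")
        nio.write_gene_list(meta.common_responsive, out / "common_responsive.txt")
        manifest["stages"]["meta"] = {
            "n_stress_types": len(meta.per_stress),
            "common_responsive_size": len(meta.common_responsive),
        }
        common = sorted(meta.common_responsive)

    all_genes = sorted(set().union(*(set(m.index) for m in matrices.values())))

    # ---- set overlaps ------------------------------------------------------
    with _stage(manifest, "overlap"):
        overlaps = []
        if config.mutant_sets and common:
            mut = nio.read_gmt(config.mutant_sets)
            universe = (
                set(nio.read_gene_list(config.universe)) if config.universe else set(all_genes)
            )
            universe |= set(common)
            for members in mut.values():
                universe |= members
            sets = [GeneSet.from_iterable(name, members) for name, members in sorted(mut.items())]
            overlaps = mutant_nutrient_intersections(
                GeneSet.from_iterable("common_responsive", common), sets, universe
            )
            pd.DataFrame([o.as_dict() for o in overlaps]).to_csv(
                out / "overlaps.tsv", sep="\t", index=False
            )
        manifest["stages"]["overlap"] = {
            "results": [o.as_dict() for o in overlaps],
        }

    # ---- clustering and PCA -----------------------------------------------
    with _stage(manifest, "cluster"):
        info: dict = {"skipped": True}
        if common:
            # genes x stress-type mean log2FC profile
            profile = {}
            for stress in sorted({sr.stress for sr in study_results}):
                tabs = [sr.table["log2fc"] for sr in study_results if sr.stress == stress]
                profile[stress] = pd.concat(tabs, axis=1).mean(axis=1)
            profiles = pd.DataFrame(profile).reindex(common).dropna()
            k = min(config.k, profiles.shape[0])
            if k >= 1 and profiles.shape[0] >= 1:
                assignment = kmeans_profiles(profiles, k=k, seed=config.seed)
                assignment.labels.to_csv(out / "clusters.tsv", sep="\t", header=["group"])
                assignment.centroids.to_csv(out / "centroids.tsv", sep="\t")
                sizes = assignment.labels.value_counts().to_dict()
                info = {"k": k, "cluster_sizes": {g: int(n) for g, n in sizes.items()}}
            # dataset-similarity PCA: studies x common-gene log2FC
            study_profiles = pd.DataFrame(
                {sr.study: sr.table["log2fc"].reindex(common) for sr in study_results}
            ).T.dropna(axis=1)
            if study_profiles.shape[0] >= 2 and study_profiles.shape[1] >= 2:
                pca = pca_scores(study_profiles)
                pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
                info["pca_variance_explained"] = [float(v) for v in pca.variance_explained[:5]]
        manifest["stages"]["cluster"] = info

    # ---- co-expression network --------------------------------------------
    with _stage(manifest, "coexpr"):
        info = {"skipped": True}
        if common:
            compendium = pd.concat(
                [m.reindex(common) for m in matrices.values()], axis=1
            ).dropna()
            net = correlation_edges(compendium, fdr_threshold=config.edge_fdr)
            nio.write_edge_list(net, out / "coexpr_edges.tsv")
            nio.write_graphml(net, out / "coexpr.graphml")
            nio.write_sif(net, out / "coexpr.sif")
            hubs = hub_nodes(net, top_k=20) if net.number_of_nodes() else []
            info = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "top_hubs": [[g, int(d)] for g, d in hubs[:10]],
            }
        manifest["stages"]["coexpr"] = info

    # ---- directed TF network ----------------------------------------------
    with _stage(manifest, "grn"):
        info = {"skipped": True}
        if config.tf_list:
            tfs = nio.read_gene_list(config.tf_list)
            if config.grn_expression:
                grn_matrix = nio.read_expression_tsv(config.grn_expression)
            else:
                grn_matrix = pd.concat(
                    [m.reindex(common) for m in matrices.values()], axis=1
                ).dropna()
            priors = nio.read_prior_matrix(config.priors) if config.priors else None
            targets = (
                [g for g in grn_matrix.index if g not in set(tfs)]
                if priors is not None
                else None
            )
            scores = rf_importance_network(
                grn_matrix,
                tfs,
                n_trees=config.n_trees,
                priors=priors,
                seed=config.seed,
                targets=targets,
            )
            scores.ranked_edges().to_csv(out / "grn_scores.tsv", sep="\t", index=False)
            net = threshold_directed(scores, top_n=config.grn_top_n)
            nio.write_graphml(net, out / "grn.graphml")
            nio.write_sif(net, out / "grn.sif")
            info = {
                "n_tfs": len(tfs),
                "n_targets": int(scores.scores.shape[1]),
                "n_edges_kept": net.number_of_edges(),
            }
        manifest["stages"]["grn"] = info

    nio.write_json(manifest, out / "manifest.json")
    return manifest
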