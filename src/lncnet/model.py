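"""Model/Results interface orchestrating the full analysis.

:class:`CoexpressionAnalysis` is built from an expression matrix, sample
metadata, gene annotation and (optionally) ASD risk gene lists, with the
stage parameters as keyword arguments whose defaults are the reference
analysis parameters (1 RPKM floor, power 7, biweight network for module
detection, minimum module size 30, merge cut height 0.2, top 5% edges,
FDR 0.05). ``fit(seed=...)`` runs

    curate -> network -> modules -> enrich -> edges -> prioritize

and returns a :class:`CoexpressionResults` carrying every stage output, a
run manifest (counts and elapsed time per stage), and ``summary()`` /
``save()`` helpers. A failing stage raises :class:`PipelineError` naming the
stage; earlier results are preserved on the partially built results object.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import curation as _cur
from . import enrichment as _enr
from . import modules as _mod
from . import network as _net
from . import prioritize as _pri
from . import topology as _top
from .datasets import (
    DataError,
    ExpressionMatrix,
    validate_annotation,
    validate_metadata,
)

__all__ = ["CoexpressionAnalysis", "CoexpressionResults", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineParams:
    """Stage parameters; defaults are the reference analysis values."""

    min_rpkm: float = 1.0
    power: int = 7
    module_corr: str = "bicor"
    network_corr: str = "pearson"
    min_module_size: int = 30
    merge_cut_height: float = 0.2
    edge_fraction: float = 0.05
    fdr_alpha: float = 0.05
    tree_cut_height: float | None = None
    pam_stage: bool = True
    scan_powers: tuple = tuple(range(1, 13))


class CoexpressionAnalysis:
    """Co-expression analysis of lncRNA/ASD structure in a developmental
    expression dataset.

    Parameters
    ----------
    expression : ExpressionMatrix
        RPKM-scale genes x samples matrix.
    metadata : pandas.DataFrame
        One row per sample (sample_id, structure, age, age_unit, period).
    annotation : pandas.DataFrame
        One row per gene (gene_id, biotype, is_lncRNA, is_asd_risk).
    asd_gene_lists : sequence of gene-id collections, optional
        When given, their union replaces the annotation's ASD flags;
        ids absent from the expression matrix are reported, not fatal.
    """

    def __init__(self, expression: ExpressionMatrix, metadata: pd.DataFrame,
                 annotation: pd.DataFrame, asd_gene_lists=None, **params):
        self.params = PipelineParams(**params)
        if expression.scale != "rpkm":
            raise DataError("CoexpressionAnalysis expects RPKM-scale expression")
        self.expression = expression
        self.metadata = validate_metadata(metadata)
        self.annotation = validate_annotation(annotation).copy()

        missing_meta = expression.sample_ids.difference(self.metadata["sample_id"])
        if len(missing_meta):
            raise DataError(f"samples without metadata: {list(missing_meta)[:5]}")
        missing_annot = expression.gene_ids.difference(self.annotation["gene_id"])
        if len(missing_annot):
            raise DataError(f"genes without annotation: {list(missing_annot)[:5]}")

        self.asd_report = None
        if asd_gene_lists is not None:
            union, report = _cur.compile_asd_gene_set(*asd_gene_lists)
            matched = union & set(expression.gene_ids)
            report["n_matched"] = len(matched)
            report["unmatched"] = sorted(union - matched)
            self.asd_report = report
            self.annotation["is_asd_risk"] = self.annotation["gene_id"].isin(matched)

    @classmethod
    def from_files(cls, expression_path, metadata_path, annotation_path,
                   asd_list_paths=(), **params) -> "CoexpressionAnalysis":
        """Build from TSV inputs (ASD lists as one-id-per-line text files)."""
        expr = ExpressionMatrix.from_tsv(expression_path, scale="rpkm")
        meta = pd.read_csv(metadata_path, sep="\t")
        annot = pd.read_csv(annotation_path, sep="\t")
        lists = []
        for path in asd_list_paths:
            with open(path) as fh:
                lists.append([line.strip() for line in fh if line.strip()])
        return cls(expr, meta, annot, asd_gene_lists=lists or None, **params)

    def fit(self, seed: int = 0) -> "CoexpressionResults":
        """Run the full pipeline. Deterministic given (parameters, seed)."""
        res = CoexpressionResults(model=self, seed=seed)
        p = self.params

        def stage(name):
            return _StageTimer(name, res.manifest)

        try:
            with stage("curate"):
                res.curation = _cur.curate(self.expression, min_rpkm=p.min_rpkm,
                                           seed=seed)
                res.manifest["curate"]["n_input"] = res.curation.n_input
                res.manifest["curate"]["n_min_expressed"] = res.curation.n_min_expressed
                res.manifest["curate"]["n_kept"] = res.curation.n_kept
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError("curate", exc) from exc

        logged = res.curation.expression
        try:
            with stage("network"):
                corr = _net.correlation_matrix(logged, kind=p.module_corr)
                res.scale_free_scan = _net.soft_threshold_scan(
                    corr, powers=p.scan_powers
                )
                res.adjacency = _net.soft_threshold_adjacency(
                    corr, power=p.power, corr_kind=p.module_corr
                )
                res.scale_free = _net.scale_free_fit(res.adjacency)
                res.tom = _net.topological_overlap(res.adjacency)
                res.manifest["network"]["scale_free_r2"] = res.scale_free.r_squared
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("network", exc) from exc

        try:
            with stage("modules"):
                linkage = _mod.cluster_dendrogram(res.tom)
                diss = 1.0 - res.tom
                part = _mod.dynamic_tree_cut(
                    linkage, diss, min_size=p.min_module_size,
                    cut_height=p.tree_cut_height, pam_stage=p.pam_stage,
                )
                eig = _mod.module_eigengenes(logged, part)
                res.partition, res.eigengenes = _mod.merge_close_modules(
                    logged, part, eig, cut_height=p.merge_cut_height
                )
                res.gene_dendrogram = linkage
                res.manifest["modules"]["n_modules"] = res.partition.n_modules
                res.manifest["modules"]["n_unassigned"] = int(
                    (res.partition.labels == 0).sum()
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("modules", exc) from exc

        try:
            with stage("enrich"):
                fams = [
                    _enr.module_type_enrichment(
                        res.partition, self.annotation, t, alpha=p.fdr_alpha
                    )
                    for t in ("lncRNA", "asd_risk")
                ]
                res.module_enrichment = pd.concat(fams, ignore_index=True)
                curated = list(logged.gene_ids)
                rpkm = self.expression.subset_genes(curated)
                annot = self.annotation.set_index("gene_id")
                type_sets = {
                    "lncRNA": [g for g in curated if annot.at[g, "is_lncRNA"]],
                    "asd_risk": [g for g in curated if annot.at[g, "is_asd_risk"]],
                }
                res.structure_enrichment = _enr.structure_period_enrichment(
                    rpkm, self.metadata, curated, type_sets,
                    threshold=p.min_rpkm, alpha=p.fdr_alpha,
                )
                res.heatmap = _mod.eigengene_heatmap_table(
                    res.eigengenes, self.metadata,
                    sidebar=_module_sidebar(res.module_enrichment),
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrich", exc) from exc

        try:
            with stage("edges"):
                if p.network_corr == p.module_corr:
                    net_adj = res.adjacency
                else:
                    pcorr = _net.correlation_matrix(logged, kind=p.network_corr)
                    net_adj = _net.soft_threshold_adjacency(
                        pcorr, power=p.power, corr_kind=p.network_corr
                    )
                res.network_adjacency = net_adj
                res.edges = _top.top_fraction_edges(net_adj, fraction=p.edge_fraction)
                counts = {
                    m: _top.classify_and_subset(
                        res.edges, self.annotation, res.partition, m
                    ).class_counts()
                    for m in res.partition.module_ids()
                }
                res.module_edge_classes = pd.DataFrame(counts).T.rename_axis("module")
                res.manifest["edges"]["n_edges"] = len(res.edges)
                res.manifest["edges"]["threshold_weight"] = res.edges.threshold_weight
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("edges", exc) from exc

        try:
            with stage("prioritize"):
                res.priority = _pri.priority_table(
                    res.network_adjacency, self.annotation, res.partition
                )
                res.manifest["prioritize"]["n_lncRNAs"] = len(res.priority)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("prioritize", exc) from exc

        return res


def _module_sidebar(enrichment: pd.DataFrame) -> pd.DataFrame:
    """-log10(FDR) per module for each gene-type family (heatmap sidebar)."""
    wide = enrichment.pivot(index="module", columns="gene_type",
                            values="neg_log10_fdr")
    wide.columns = [f"neg_log10_fdr_{c}" for c in wide.columns]
    return wide


class _StageTimer:
    def __init__(self, name, manifest):
        self.name, self.manifest = name, manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.manifest[self.name] = {}
        return self

    def __exit__(self, *exc):
        self.manifest[self.name]["elapsed_s"] = round(
            time.perf_counter() - self.t0, 4
        )
        return False


@dataclass
class CoexpressionResults:
    """Fitted pipeline outputs; populated stage by stage by ``fit``."""

    model: CoexpressionAnalysis
    seed: int
    manifest: dict = field(default_factory=dict)
    curation: object = None
    adjacency: object = None
    scale_free: object = None
    scale_free_scan: pd.DataFrame | None = None
    tom: pd.DataFrame | None = None
    gene_dendrogram: np.ndarray | None = None
    partition: object = None
    eigengenes: object = None
    module_enrichment: pd.DataFrame | None = None
    structure_enrichment: pd.DataFrame | None = None
    heatmap: object = None
    network_adjacency: object = None
    edges: object = None
    module_edge_classes: pd.DataFrame | None = None
    priority: pd.DataFrame | None = None

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary."""
        p = self.model.params
        lines = [
            "Co-expression lncRNA/ASD analysis",
            "=" * 50,
            f"genes in / curated:     {self.curation.n_input} / {self.curation.n_kept}",
            f"samples:                {self.model.expression.n_samples}",
            f"soft threshold power:   {p.power} ({p.module_corr} network)",
            f"scale-free R^2:         {self.scale_free.r_squared:.3f}",
            f"modules (min size {p.min_module_size}): {self.partition.n_modules}, "
            f"{int((self.partition.labels == 0).sum())} genes unassigned",
        ]
        if self.module_enrichment is not None and len(self.module_enrichment):
            sig = self.module_enrichment[self.module_enrichment["significant"]]
            for t in ("lncRNA", "asd_risk"):
                mods = sorted(sig.loc[sig["gene_type"] == t, "module"])
                lines.append(f"modules enriched for {t}: {mods}")
        if self.edges is not None:
            lines.append(
                f"edges (top {p.edge_fraction:.0%} pairs): {len(self.edges)} "
                f"at weight >= {self.edges.threshold_weight:.3g}"
            )
        if self.priority is not None and len(self.priority):
            lines.append("")
            lines.append(f"top {min(top, len(self.priority))} prioritised lncRNAs:")
            cols = ["rank", "gene_id", "biotype", "norm_asd_connectivity",
                    "module", "norm_intramodular"]
            lines.append(
                self.priority[cols].head(top).to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write all tabular outputs plus the run manifest to a directory."""
        import os

        os.makedirs(out_dir, exist_ok=True)

        def path(name):
            return os.path.join(out_dir, name)

        paths = {}
        self.curation.covariance.to_csv(path("covariance_summary.tsv"), sep="\t",
                                        index_label="gene_id")
        paths["covariance_summary"] = path("covariance_summary.tsv")
        self.curation.expression.to_tsv(path("curated_log2_expression.tsv"))
        paths["curated_log2_expression"] = path("curated_log2_expression.tsv")
        self.scale_free_scan.to_csv(path("scale_free_scan.tsv"), sep="\t", index=False)
        paths["scale_free_scan"] = path("scale_free_scan.tsv")
        self.partition.to_tsv(path("module_partition.tsv"))
        paths["module_partition"] = path("module_partition.tsv")
        self.eigengenes.profiles.to_csv(path("eigengenes.tsv"), sep="\t")
        paths["eigengenes"] = path("eigengenes.tsv")
        self.heatmap.table.to_csv(path("eigengene_heatmap.tsv"), sep="\t")
        paths["eigengene_heatmap"] = path("eigengene_heatmap.tsv")
        self.module_enrichment.to_csv(path("module_enrichment.tsv"), sep="\t",
                                      index=False)
        paths["module_enrichment"] = path("module_enrichment.tsv")
        self.structure_enrichment.to_csv(path("structure_enrichment.tsv"), sep="\t",
                                         index=False)
        paths["structure_enrichment"] = path("structure_enrichment.tsv")
        self.module_edge_classes.to_csv(path("module_edge_classes.tsv"), sep="\t")
        paths["module_edge_classes"] = path("module_edge_classes.tsv")
        self.priority.to_csv(path("priority_table.csv"), index=False)
        paths["priority_table"] = path("priority_table.csv")
        paths.update(
            _top.export_network(self.edges, self.model.annotation, path("network"),
                                part=self.partition)
        )
        manifest = {
            "seed": self.seed,
            "params": asdict(self.model.params),
            "stages": self.manifest,
            "outputs": paths,
        }
        with open(path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        paths["manifest"] = path("manifest.json")
        return paths

    def export_module_network(self, module: int, path_prefix) -> dict:
        """Write one module's classified lncRNA/ASD subnetwork."""
        sub = _top.classify_and_subset(self.edges, self.model.annotation,
                                       self.partition, module)
        return _top.export_network(sub, self.model.annotation, path_prefix,
                                   part=self.partition)
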