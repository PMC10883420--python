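"""End-to-end orchestration: screen -> weight -> test -> cluster -> tree -> enrich."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cluster_reduce import ClusterComponents, GeneClustering, cluster_genes, cluster_pc1
from .data_model import AnalysisConfig, ExpressionTensor, validate_tensor
from .diffexpr import ContrastResult, DegUnion, pairwise_contrasts, pairwise_union
from .enrichment import EnrichmentResult, GeneSetCollection, enrich_clusters
from .errors import ConfigurationError
from .staging_tree import (
    CVReport,
    PairwiseTree,
    StabilityReport,
    TreeModel,
    fit_cart,
    pairwise_trees,
    repeated_cv,
    stability_analysis,
)
from .weighting import (
    WeightedExpression,
    WeightTensor,
    adjust_weights,
    compute_fold_change,
    normalize_regions,
    prescreen_genes,
    region_mean_baseline,
    weight_expression,
)


@dataclass
class PipelineResult:
    config: AnalysisConfig
    prescreened: list[str]
    weights: WeightTensor
    weighted: WeightedExpression
    contrasts: list[ContrastResult]
    degs: DegUnion
    clustering: GeneClustering | None = None
    components: ClusterComponents | None = None
    tree: TreeModel | None = None
    cv: CVReport | None = None
    pairwise: list[PairwiseTree] = field(default_factory=list)
    stability: StabilityReport | None = None
    enrichment: dict[str, EnrichmentResult] | None = None

    def summary(self) -> dict:
        """JSON-serializable digest of the run."""
        out: dict = {
            "n_prescreened": len(self.prescreened),
            "n_degs": len(self.degs),
            "deg_counts_per_contrast": {
                f"{a}~{b}": int((res.direction != "ns").sum())
                for res in self.contrasts
                for a, b in [res.contrast]
            },
            "fallback_count": self.weighted.fallback_count,
            "aggregation_mode": self.weighted.mode,
        }
        if self.clustering is not None:
            out["k"] = self.clustering.k
            out["cluster_sizes"] = {
                str(k): int(v) for k, v in self.clustering.sizes.items()
            }
            out["k_selection"] = {
                str(k): float(v) for k, v in self.clustering.k_selection.items()
            }
        if self.components is not None:
            out["vcr"] = {str(k): float(v) for k, v in self.components.vcr.items()}
            out["low_vcr_classes"] = list(self.components.low_vcr)
        if self.tree is not None:
            out["tree"] = self.tree.to_dict()
        if self.cv is not None:
            out["cv_mean_accuracy"] = self.cv.mean_accuracy
            out["cv_auc"] = self.cv.auc
        if self.pairwise:
            out["pairwise"] = {
                f"{a}~{b}": {
                    "signature": list(pt.model.signature),
                    "cv_mean_accuracy": pt.cv.mean_accuracy if pt.cv else None,
                }
                for pt in self.pairwise
                for a, b in [pt.pair]
            }
        if self.stability is not None:
            out["stability"] = {
                "runs": self.stability.runs,
                "fraction": self.stability.fraction,
                "modal_signature": list(self.stability.modal_signature),
                "modal_count": self.stability.modal_count,
            }
        if self.enrichment is not None:
            out["enrichment_significant"] = {
                label: int((res.table["p_adj"] <= 0.05).sum())
                for label, res in self.enrichment.items()
            }
        return out


def run_pipeline(
    tensor: ExpressionTensor,
    config: AnalysisConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
    aggregation: str = "stw",
) -> PipelineResult:
    """Run the full analysis on a raw tensor.

    ``aggregation`` selects the region-collapsing rule: ``"stw"`` (adjusted
    fold-change weights) or ``"region_mean"`` (the plain-average baseline).
    """
    config = config or AnalysisConfig()
    if tensor.normalized:
        raise ConfigurationError("run_pipeline expects a raw (unnormalized) tensor")
    if config.reference_stage is not None and tensor.stages[0] != config.reference_stage:
        raise ConfigurationError(
            f"tensor reference stage {tensor.stages[0]!r} differs from configured "
            f"{config.reference_stage!r}; reorder at load time"
        )

    if config.min_regions > 1:
        report = validate_tensor(tensor, min_regions=config.min_regions, drop=True)
        tensor = report.tensor if report.tensor is not None else tensor

    prescreened = prescreen_genes(
        tensor,
        config.prescreen_mode,
        alpha=config.prescreen_alpha,
        f=config.prescreen_fc,
        q=config.top_fraction,
        norm_constant=config.norm_constant,
    )
    if not prescreened:
        raise ConfigurationError("prescreen removed every gene; relax its thresholds")

    norm = normalize_regions(tensor, config.norm_constant)
    weights = adjust_weights(compute_fold_change(norm), config.fc_threshold)
    if aggregation == "stw":
        weighted = weight_expression(norm, weights, genes=prescreened)
    elif aggregation == "region_mean":
        weighted = region_mean_baseline(norm, genes=prescreened)
    else:
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")

    contrasts = pairwise_contrasts(weighted, alpha=config.de_alpha, f=config.de_fc)
    degs = pairwise_union(contrasts)

    result = PipelineResult(
        config=config,
        prescreened=prescreened,
        weights=weights,
        weighted=weighted,
        contrasts=contrasts,
        degs=degs,
    )
    needed = (config.k if config.k is not None else config.k_min) + 1
    if len(degs) < max(3, needed):
        return result  # too few DEGs to class; earlier stages still reported

    frame = weighted.to_frame().loc[degs.genes]
    clustering = cluster_genes(
        frame,
        k=config.k,
        k_range=(config.k_min, config.k_max),
        embedding=config.embedding,
        seed=config.seed,
    )
    components = cluster_pc1(frame, clustering)
    result.clustering = clustering
    result.components = components

    X = components.scores
    y = weighted.stage_of_columns()
    result.tree = fit_cart(X, y, config.cp, seed=config.seed)
    counts = pd.Series(y).value_counts()
    if counts.min() >= config.cv_folds:
        result.cv = repeated_cv(
            X,
            y,
            folds=config.cv_folds,
            repeats=config.cv_repeats,
            cp=config.cp,
            seed=config.seed,
        )
        result.pairwise = pairwise_trees(
            X,
            y,
            cp=config.cp,
            seed=config.seed,
            folds=config.cv_folds,
            repeats=config.cv_repeats,
        )
    result.stability = stability_analysis(
        X,
        y,
        runs=config.stability_runs,
        fraction=config.stability_fraction,
        cp=config.cp,
        seed=config.seed,
    )

    if gene_sets is not None and result.clustering is not None:
        members = {
            label: clustering.members(label) for label in clustering.class_labels
        }
        result.enrichment = enrich_clusters(members, gene_sets)
    return result
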