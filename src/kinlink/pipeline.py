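"""End-to-end orchestration of the kinase-inference pipeline.

One comparison flows through: differential calling and regulation
scores -> PSSM scoring and dataset-internal percentiles -> per-site
top-k kinase sets -> directional motif enrichment with BH -> relative
kinase activities -> evidence-augmented interaction scores -> per-site
top filtering -> kinase-substrate, pathway and network aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import differential, enrichment, motifs, netscore, pathways
from .config import RunConfig
from .io import PathwayGeneSet, gene_set_dict
from .motifs import KinaseMotifModel


@dataclass
class InferenceResult:
    """Per-comparison intermediate products of the kinase inference."""

    comparison: str
    calls: pd.DataFrame
    raw_scores: pd.DataFrame
    percentiles: pd.DataFrame
    top_sets: dict
    enrichment: pd.DataFrame
    activities: pd.DataFrame


def run_kinase_inference(
    sites: pd.DataFrame,
    library: list[KinaseMotifModel],
    config: RunConfig,
) -> dict[str, InferenceResult]:
    """Kinase activity inference for every treatment comparison.

    Percentile backgrounds are dataset-internal: each kinase's scores
    against all quantified windows of the comparison.
    """
    scored = differential.regulation_scores(sites, config)
    results: dict[str, InferenceResult] = {}
    for comparison, group in scored.groupby("comparison", sort=True):
        group = group.reset_index(drop=True)
        raw = motifs.score_matrix(list(group["window"]), library)
        percentiles = motifs.percentile_matrix(raw)
        top_sets = motifs.top_kinase_sets(percentiles, raw,
                                          config.top_kinase_percentile_count)
        membership = {
            model.name: {group.at[i, "site"] for i, kinases in top_sets.items()
                         if model.name in kinases}
            for model in library
        }
        enr = enrichment.kinase_enrichment(membership, group, comparison)
        act = enrichment.relative_kinase_activity(enr, config.p_weight_transform)
        # re-key top sets by site id for downstream joins
        results[comparison] = InferenceResult(
            comparison=comparison, calls=group, raw_scores=raw,
            percentiles=percentiles, top_sets=top_sets,
            enrichment=enr, activities=act,
        )
    return results


@dataclass
class NetworkResult:
    """Scored interactions and aggregates for one comparison."""

    comparison: str
    interactions: pd.DataFrame
    retained: pd.DataFrame
    pair_scores: pd.DataFrame
    pathway_scores: pd.DataFrame
    graph: object


def run_network_scoring(
    inference: InferenceResult,
    config: RunConfig,
    evidence: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
    gene_sets: list[PathwayGeneSet] | dict | None = None,
    dependency: pd.DataFrame | None = None,
) -> NetworkResult:
    """Interaction scoring, top-k filtering and aggregation for one comparison."""
    scores = netscore.interaction_scores(
        inference.calls, inference.percentiles, inference.raw_scores,
        inference.top_sets, inference.activities,
        evidence=evidence, interactions=interactions,
    )
    retained = netscore.filter_top_per_site(scores,
                                            config.top_interactions_per_site)
    pairs = netscore.kinase_substrate_scores(retained)
    if gene_sets is None:
        sets_dict: dict = {}
    elif isinstance(gene_sets, dict):
        sets_dict = gene_sets
    else:
        sets_dict = gene_set_dict(gene_sets)
    detected = set(inference.calls["protein"])
    pathway_scores = netscore.pathway_interaction_table(
        sets_dict, retained, detected_proteins=detected,
        as_percent=config.pathway_fraction_percent,
    )
    graph = netscore.build_network(pairs, dependency,
                                   config.chronos_essential_max)
    return NetworkResult(comparison=inference.comparison,
                         interactions=scores, retained=retained,
                         pair_scores=pairs, pathway_scores=pathway_scores,
                         graph=graph)


def run_dependency_ora(
    inference: InferenceResult,
    dependency: pd.DataFrame,
    gene_sets: list[PathwayGeneSet] | dict,
    config: RunConfig,
    protein_class: str = "co-regulated",
) -> dict[str, pd.DataFrame]:
    """Dependency-partitioned ORA of a regulated-protein foreground.

    The foreground is selected by ``protein_class`` from the
    comparison's calls; the background is all detected phosphoproteins.
    """
    sets_dict = gene_sets if isinstance(gene_sets, dict) else gene_set_dict(gene_sets)
    foreground = pathways.select_protein_class(inference.calls, protein_class)
    background = set(inference.calls["protein"])
    return pathways.dependency_partition_ora(
        foreground, dependency, sets_dict, config, background=background)
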