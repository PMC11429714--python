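"""Kinase-substrate interaction scoring and network assembly.

The kinase library score (KLS) for a kinase-phosphosite link is the
product of the kinase-phosphosite percentile (rescaled to 0-1) and the
absolute relative kinase activity.  Curated evidence augments it: 0.5
per PhosphoSitePlus-style evidence level (in vitro, in vivo) and
n/(n+1) for n BioGRID-style interaction references.  The final
interaction score is the augmented KLS times the site's signed
differential-regulation score; each differential site keeps its top
scores, which are then summed per kinase-substrate pair and aggregated
into pathway interaction scores and an exportable bipartite network.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ValidationError

logger = logging.getLogger(__name__)

PSP_EVIDENCE_INCREMENT = 0.5  # per evidence level (in vitro / in vivo)


def base_kls(percentile: float, activity: float) -> float:
    """Percentile (0-1 scale) times |relative kinase activity|."""
    if not 0.0 <= percentile <= 1.0:
        raise ValidationError(
            f"percentile must be rescaled to [0, 1] before the product, got {percentile}"
        )
    return percentile * abs(activity)


def add_psp_evidence(kls: float, in_vitro: bool, in_vivo: bool) -> float:
    """Add 0.5 per curated evidence level; no record leaves the KLS unchanged."""
    return kls + PSP_EVIDENCE_INCREMENT * (bool(in_vitro) + bool(in_vivo))


def add_biogrid(kls: float, n_refs: int) -> float:
    """Add n/(n+1) for n interaction references (0 references add nothing)."""
    if n_refs < 0:
        raise ValidationError(f"reference count must be >= 0, got {n_refs}")
    return kls + n_refs / (n_refs + 1)


def final_interaction_score(augmented_kls: float, regulation_score: float) -> float:
    """Augmented KLS times the signed site regulation score."""
    return augmented_kls * regulation_score


def _psp_lookup(evidence: pd.DataFrame) -> dict:
    """(kinase, protein, position-or-None) -> (in_vitro, in_vivo).

    Site-level rows (with a position) take precedence over protein-level
    rows when both exist for a pair.
    """
    table: dict = {}
    if evidence is None or evidence.empty:
        return table
    for row in evidence.itertuples(index=False):
        position = getattr(row, "position", None)
        if pd.isna(position):
            position = None
        else:
            position = int(position)
        key = (row.kinase, row.protein, position)
        table[key] = (bool(row.in_vitro), bool(row.in_vivo))
    return table


def _biogrid_lookup(interactions: pd.DataFrame) -> dict:
    table: dict = {}
    if interactions is None or interactions.empty:
        return table
    for row in interactions.itertuples(index=False):
        table[(row.kinase, row.protein)] = int(row.n_refs)
    return table


def interaction_scores(
    calls: pd.DataFrame,
    percentiles: pd.DataFrame,
    kls_augment_raw: pd.DataFrame | None,
    top_sets: dict,
    activities: pd.DataFrame,
    evidence: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every (differential site, retained kinase) pair for one comparison.

    Parameters
    ----------
    calls : pandas.DataFrame
        Regulation calls/scores for one comparison (columns ``site``,
        ``protein``, ``position``, ``direction``, ``score``); only sites
        with direction up/down are scored.
    percentiles : pandas.DataFrame
        Sites x kinases percentile matrix (0-100), indexed like ``calls``'
        positional index into the site table.
    kls_augment_raw : pandas.DataFrame or None
        Raw score matrix matching ``percentiles`` (used only to break ties
        downstream); may be None.
    top_sets : dict
        site index -> frozenset of top-k kinase names for that site.
    activities : pandas.DataFrame
        Output of :func:`kinlink.enrichment.relative_kinase_activity`.
    evidence, interactions : pandas.DataFrame, optional
        Curated kinase-substrate evidence and reference-count tables.
    """
    act = dict(zip(activities["kinase"], activities["activity"]))
    psp = _psp_lookup(evidence)
    biogrid = _biogrid_lookup(interactions)
    rows = []
    regulated = calls[calls["direction"].isin(("up", "down"))]
    for idx, row in regulated.iterrows():
        for kinase in sorted(top_sets.get(idx, ())):
            if kinase not in act:
                continue  # untestable kinase: no activity, no link
            percentile = percentiles.at[idx, kinase] / 100.0
            kls = base_kls(percentile, act[kinase])
            ev = psp.get((kinase, row["protein"], int(row["position"])))
            if ev is None:
                ev = psp.get((kinase, row["protein"], None), (False, False))
            psp_inc = PSP_EVIDENCE_INCREMENT * (bool(ev[0]) + bool(ev[1]))
            n_refs = biogrid.get((kinase, row["protein"]), 0)
            biogrid_inc = n_refs / (n_refs + 1)
            augmented = kls + psp_inc + biogrid_inc
            rows.append(dict(
                site=row["site"], protein=row["protein"],
                position=int(row["position"]), comparison=row["comparison"],
                kinase=kinase, direction=row["direction"],
                percentile=percentile, base_kls=kls,
                psp_increment=psp_inc,
                biogrid_increment=biogrid_inc,
                augmented_kls=augmented,
                regulation_score=row["score"],
                final_score=final_interaction_score(augmented, row["score"]),
            ))
    columns = ["site", "protein", "position", "comparison", "kinase",
               "direction", "percentile", "base_kls", "psp_increment",
               "biogrid_increment", "augmented_kls", "regulation_score",
               "final_score"]
    return pd.DataFrame(rows, columns=columns)


def filter_top_per_site(scores: pd.DataFrame, k: int) -> pd.DataFrame:
    """Retain at most k kinases per site, ranked by |final score|.

    Ties are broken by augmented KLS (higher wins), then kinase name.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if scores.empty:
        return scores.copy()
    ordered = scores.assign(
        _rank_abs=-scores["final_score"].abs(),
        _rank_kls=-scores["augmented_kls"],
    ).sort_values(["site", "_rank_abs", "_rank_kls", "kinase"])
    retained = ordered.groupby("site", sort=False).head(k)
    return (retained.drop(columns=["_rank_abs", "_rank_kls"])
            .reset_index(drop=True))


def kinase_substrate_scores(retained: pd.DataFrame) -> pd.DataFrame:
    """Sum retained final scores per (kinase, substrate protein) pair."""
    if retained.empty:
        return pd.DataFrame(columns=["kinase", "protein", "score", "n_sites"])
    agg = (retained.groupby(["kinase", "protein"], as_index=False)
           .agg(score=("final_score", "sum"), n_sites=("site", "nunique")))
    return agg.sort_values(["kinase", "protein"]).reset_index(drop=True)


def protein_score_sums(retained: pd.DataFrame) -> pd.Series:
    """Sum of all retained interaction scores per phosphoprotein."""
    if retained.empty:
        return pd.Series(dtype=float)
    return retained.groupby("protein")["final_score"].sum()


def pathway_interaction_score(
    members,
    protein_sums: pd.Series,
    as_percent: bool = False,
) -> dict | None:
    """Pathway score: (sum of member interaction-score sums) x coverage.

    Coverage is the fraction of member phosphoproteins carrying at least
    one interaction score (0-1 by default; a 0-100 percent scale is a
    pure rescaling offered for presentation).  Pathways with no members
    detected return None and are logged by the caller.
    """
    members = set(members)
    if not members:
        return None
    scored = members & set(protein_sums.index)
    total = float(protein_sums.reindex(sorted(scored)).sum()) if scored else 0.0
    fraction = len(scored) / len(members)
    factor = fraction * 100.0 if as_percent else fraction
    return dict(n_members=len(members), n_scored=len(scored),
                score_sum=total, fraction=fraction,
                pathway_score=total * factor)


def pathway_interaction_table(
    gene_sets: dict,
    retained: pd.DataFrame,
    detected_proteins: set | None = None,
    as_percent: bool = False,
) -> pd.DataFrame:
    """Pathway interaction scores for every gene set.

    ``detected_proteins`` restricts each pathway to its detected
    phosphoproteins before scoring; pathways with zero detected members
    are omitted with a log entry.
    """
    sums = protein_score_sums(retained)
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        if detected_proteins is not None:
            members &= detected_proteins
        result = pathway_interaction_score(members, sums, as_percent=as_percent)
        if result is None:
            logger.info("pathway %s has no detected members; omitted", name)
            continue
        rows.append(dict(pathway=name, **result))
    return pd.DataFrame(rows, columns=["pathway", "n_members", "n_scored",
                                       "score_sum", "fraction", "pathway_score"])


def build_network(
    pair_scores: pd.DataFrame,
    dependency: pd.DataFrame | None = None,
    chronos_essential_max: float = -0.5,
) -> nx.DiGraph:
    """Bipartite kinase -> substrate network with scored edges.

    Edge weight is the kinase-substrate score; the ``direction``
    attribute records its sign.  Substrate nodes carry the Chronos score
    and an essentiality flag when a dependency table is supplied.
    """
    graph = nx.DiGraph()
    chronos = {}
    if dependency is not None and not dependency.empty:
        chronos = dict(zip(dependency["gene"], dependency["chronos"]))
    for row in pair_scores.itertuples(index=False):
        graph.add_node(row.kinase, kind="kinase")
        attrs = {"kind": "substrate"}
        if row.protein in chronos:
            score = float(chronos[row.protein])
            attrs["chronos"] = score
            attrs["essential"] = bool(score <= chronos_essential_max)
        graph.add_node(row.protein, **attrs)
        graph.add_edge(row.kinase, row.protein, weight=float(row.score),
                       direction="up" if row.score >= 0 else "down")
    return graph
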