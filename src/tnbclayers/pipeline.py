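"""End-to-end orchestration: expression -> network -> functional nodes ->
metanodes -> two-layer classification -> centroid transfer -> survival.

The stages are plain functions over the library types; :func:`run_pipeline`
chains them, records a manifest, and returns everything needed by the CLI
and by downstream statistics.  All randomness flows from a single seed
through ``numpy.random.SeedSequence`` spawns, so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify as _classify
from .activity import Metanode, MetanodeClustering, assign_roles, cluster_metanodes, node_activity
from .io import ExpressionMatrix, GeneSetCollection, MarkerConfig
from .network import build_association_graph, max_spanning_forest, mi_threshold_for_r, split_branches
from .nodes import FunctionalNode, label_nodes
from .preprocess import preprocess_pipeline
from .transfer import CentroidSet, assign_cohort, build_centroids

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "run_pipeline",
    "classify_cohort",
    "transfer_to_cohort",
    "spawn_seed",
]


def spawn_seed(seed: int, *path: int) -> int:
    """Derive a child seed (< 2**31) from a root seed and a stage path."""
    ss = np.random.SeedSequence([int(seed), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class PipelineParams:
    top_k: int = 2000
    signed_network: bool = True
    min_edge_r: float = 0.3
    max_branch_size: int = 150
    min_branch_size: int = 10
    enrichment_alpha: float = 0.05
    cut_height: float = 0.7
    sparsity: float | None = None  # None -> permutation gap statistic
    n_restarts: int = 20
    seed: int = 0


@dataclasses.dataclass
class PipelineResult:
    expression: ExpressionMatrix  # preprocessed, centered, collapsed
    branches: list
    functional_nodes: list[FunctionalNode]
    activity: pd.DataFrame
    clustering: MetanodeClustering
    metanodes: list[Metanode]
    claudin_node: FunctionalNode
    calls: pd.DataFrame  # per-sample layer calls + cellular + immune
    layer_results: dict[str, _classify.SparseKMeansResult]
    cellular_centroids: CentroidSet
    immune_centroids: CentroidSet
    manifest: dict


def _layer_activity(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    frame = expr.gene_frame()
    return frame.loc[genes].mean(axis=0)


def classify_cohort(
    expr: ExpressionMatrix,
    metanodes: list[Metanode],
    claudin_node: FunctionalNode,
    params: PipelineParams,
) -> tuple[pd.DataFrame, dict[str, _classify.SparseKMeansResult]]:
    """Sparse k-means high/low calls for the four layers plus the decision
    tree.  Returns (calls table, per-layer sparse k-means results)."""
    by_role = {m.role: m for m in metanodes}
    for role in ("luminal", "basal", "immune"):
        if role not in by_role:
            raise ValueError(f"no metanode carries the {role!r} role")
    layers = {
        "luminal": by_role["luminal"].genes,
        "basal": by_role["basal"].genes,
        "claudin": list(claudin_node.genes),
        "immune": by_role["immune"].genes,
    }
    frame = expr.gene_frame()
    calls: dict[str, pd.Series] = {}
    results: dict[str, _classify.SparseKMeansResult] = {}
    for li, (layer, genes) in enumerate(layers.items()):
        x = frame.loc[genes].to_numpy().T  # samples x genes
        res = _classify.sparse_kmeans(
            x,
            k=2,
            s=params.sparsity,
            n_restarts=params.n_restarts,
            seed=spawn_seed(params.seed, 10, li),
        )
        activity = _layer_activity(expr, genes)
        calls[layer] = _classify.orient_high_low(res, activity)
        results[layer] = res

    cellular = _classify.cellular_workflow(calls["luminal"], calls["basal"], calls["claudin"])
    immune = calls["immune"].map({"high": "IM+", "low": "IM-"})
    table = pd.DataFrame(
        {
            "luminal_call": calls["luminal"],
            "basal_call": calls["basal"],
            "claudin_call": calls["claudin"],
            "cellular": cellular["cellular"],
            "ambiguous": cellular["ambiguous"],
            "immune": immune,
        }
    )
    table.index.name = "sample_id"
    return table, results


def run_pipeline(
    expr: ExpressionMatrix,
    genesets: GeneSetCollection,
    markers: MarkerConfig,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run every stage on one cohort.

    ``expr`` may be raw or log2; preprocessing applies whatever steps the
    declared scale still requires (normalization, log2, batch removal,
    centering, probe collapsing, variance filtering).
    """
    params = params or PipelineParams()
    manifest: dict = {"seed": params.seed, "params": dataclasses.asdict(params)}

    expr = preprocess_pipeline(expr, top_k=params.top_k, manifest=manifest)

    graph = build_association_graph(expr, signed=params.signed_network)
    forest = max_spanning_forest(graph, min_edge_weight=mi_threshold_for_r(params.min_edge_r))
    branches, residue = split_branches(
        forest, max_branch_size=params.max_branch_size, min_branch_size=params.min_branch_size
    )
    manifest["n_branches"] = len(branches)
    manifest["n_residue_components"] = len(residue)

    background = list(expr.gene_ids)
    nodes = label_nodes(branches, genesets, background, alpha=params.enrichment_alpha)
    manifest["n_functional_nodes"] = len(nodes)
    if len(nodes) < 2:
        raise ValueError("fewer than 2 functional nodes; cannot form metanodes")

    act = node_activity(expr, nodes)
    clustering = cluster_metanodes(act, cut_height=params.cut_height)
    metanodes, claudin_node = assign_roles(clustering, nodes, markers, alpha=params.enrichment_alpha)
    manifest["n_metanodes"] = len(metanodes)
    manifest["metanode_roles"] = {m.metanode_id: m.role for m in metanodes}
    manifest["claudin_node"] = claudin_node.node_id

    calls, layer_results = classify_cohort(expr, metanodes, claudin_node, params)
    manifest["cellular_counts"] = calls["cellular"].value_counts().to_dict()
    manifest["immune_counts"] = calls["immune"].value_counts().to_dict()
    manifest["layer_sparsity"] = {k: v.sparsity for k, v in layer_results.items()}

    by_role = {m.role: m for m in metanodes}
    cellular_universe = sorted(
        set(by_role["luminal"].genes) | set(by_role["basal"].genes) | set(claudin_node.genes)
    )
    cellular_centroids = build_centroids(expr, calls["cellular"], cellular_universe)
    immune_centroids = build_centroids(expr, calls["immune"], sorted(by_role["immune"].genes))

    return PipelineResult(
        expression=expr,
        branches=branches,
        functional_nodes=nodes,
        activity=act,
        clustering=clustering,
        metanodes=metanodes,
        claudin_node=claudin_node,
        calls=calls,
        layer_results=layer_results,
        cellular_centroids=cellular_centroids,
        immune_centroids=immune_centroids,
        manifest=manifest,
    )


def transfer_to_cohort(
    result: PipelineResult, new_expr: ExpressionMatrix, top_k: int | None = None
) -> pd.DataFrame:
    """Preprocess a new cohort with the same chain (its own scaling and
    centering) and assign cellular and immune labels by nearest centroid.

    Both layers are assigned by Euclidean distance to the centroids rather
    than correlation: the CLDN-low group is defined by *overall low*
    activity, which correlation discards when it centers the profile, and
    the single-program immune centroids carry no across-gene contrast for a
    correlation to latch onto at all."""
    new_expr = preprocess_pipeline(new_expr, top_k=top_k or new_expr.n_genes)
    cellular = assign_cohort(new_expr, result.cellular_centroids, method="euclidean")
    immune = assign_cohort(new_expr, result.immune_centroids, method="euclidean")
    out = pd.DataFrame(
        {
            "cellular": cellular["label"],
            "immune": immune["label"],
        }
    )
    for label in result.cellular_centroids.labels:
        out[f"r_{label}"] = cellular[label]
    for label in result.immune_centroids.labels:
        out[f"r_{label}"] = immune[label]
    return out
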