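"""Functional-node activity, metanode formation and role assignment.

A node's activity in a sample is the unweighted mean log2 expression of its
member genes.  Nodes are grouped into metanodes by average-linkage
hierarchical clustering of their activity profiles under correlation
distance (1 - Pearson r), and each metanode is tagged with the marker role
(luminal, basal, immune) most enriched in its gene union.  Claudin status
is carried by a single functional node, not a metanode.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

from .io import ExpressionMatrix, MarkerConfig
from .nodes import FunctionalNode, _benjamini_hochberg

__all__ = [
    "node_activity",
    "MetanodeClustering",
    "cluster_metanodes",
    "Metanode",
    "assign_roles",
]


def node_activity(m: ExpressionMatrix, nodes: list[FunctionalNode]) -> pd.DataFrame:
    """Node x sample activity matrix (mean expression of node genes)."""
    frame = m.gene_frame()
    rows = {}
    for node in nodes:
        missing = [g for g in node.genes if g not in frame.index]
        if missing:
            raise ValueError(
                f"node {node.node_id}: gene(s) {missing[:5]} absent from expression matrix"
            )
        rows[node.node_id] = frame.loc[node.genes].mean(axis=0)
    return pd.DataFrame(rows).T.loc[[n.node_id for n in nodes]]


@dataclasses.dataclass
class MetanodeClustering:
    """Average-linkage dendrogram over node-activity profiles plus the flat
    partition obtained by cutting at ``cut_height``."""

    node_ids: list[str]
    linkage_matrix: np.ndarray
    cut_height: float
    partition: dict[str, int]  # node_id -> cluster index (1-based)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for nid in self.node_ids:  # preserve node order within clusters
            out.setdefault(self.partition[nid], []).append(nid)
        return out

    def to_newick(self) -> str:
        """Dendrogram in Newick form, branch lengths from merge heights."""
        n = len(self.node_ids)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.node_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = f"{labels[a]}:{h - heights[a]:.6g}"
            lb = f"{labels[b]}:{h - heights[b]:.6g}"
            labels[n + k] = f"({la},{lb})"
            heights[n + k] = h
        root = n + len(self.linkage_matrix) - 1
        return labels[root] + ";" if n > 1 else f"({labels[0]});"


def cluster_metanodes(activity: pd.DataFrame, cut_height: float = 0.7) -> MetanodeClustering:
    """Group nodes by average-linkage clustering at correlation distance.

    Rows of ``activity`` are nodes.  A constant activity row has no defined
    correlation and is rejected.
    """
    if activity.shape[0] < 2:
        raise ValueError("metanode clustering needs at least 2 nodes")
    values = activity.to_numpy(dtype=float)
    if np.any(values.std(axis=1) == 0):
        bad = activity.index[np.flatnonzero(values.std(axis=1) == 0)].tolist()
        raise ValueError(f"constant activity row(s): {bad}")
    dist = pdist(values, metric="correlation")  # 1 - Pearson r
    z = linkage(dist, method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    node_ids = [str(i) for i in activity.index]
    return MetanodeClustering(
        node_ids=node_ids,
        linkage_matrix=z,
        cut_height=cut_height,
        partition=dict(zip(node_ids, (int(c) for c in flat))),
    )


@dataclasses.dataclass
class Metanode:
    metanode_id: str
    node_ids: list[str]
    role: str  # luminal | basal | immune | other
    genes: list[str]  # union of member node genes

    def __len__(self) -> int:
        return len(self.node_ids)


def assign_roles(
    clustering: MetanodeClustering,
    nodes: list[FunctionalNode],
    markers: MarkerConfig,
    alpha: float = 0.05,
) -> tuple[list[Metanode], FunctionalNode]:
    """Tag metanodes with marker roles and locate the claudin node.

    For each metanode, every non-claudin marker list is tested for
    hypergeometric enrichment in the metanode's gene union against the
    background of all node genes; the best role with BH-adjusted q <= alpha
    wins, otherwise the metanode is 'other'.  Exactly one functional node
    must contain all claudin markers; two metanodes claiming one role is an
    error (refine the markers or the cut height).
    """
    node_by_id = {n.node_id: n for n in nodes}
    background = sorted({g for n in nodes for g in n.genes})
    bg = set(background)
    N = len(bg)

    # claudin: a single functional node carrying all claudin markers
    claudin_markers = set(markers["claudin"]) if "claudin" in markers.markers else set()
    claudin_hits = [
        n for n in nodes if claudin_markers and claudin_markers <= set(n.genes)
    ]
    if len(claudin_hits) != 1:
        raise ValueError(
            f"expected exactly one functional node containing the claudin markers "
            f"{sorted(claudin_markers)}; found {len(claudin_hits)}"
        )
    claudin_node = claudin_hits[0]

    roles_to_test = [r for r in markers.roles() if r != "claudin"]
    metanodes: list[Metanode] = []
    claimed: dict[str, str] = {}
    for idx, (cluster, node_ids) in enumerate(sorted(clustering.clusters().items()), 1):
        members = [node_by_id[nid] for nid in node_ids if nid in node_by_id]
        if not members:
            continue
        union = sorted({g for n in members for g in n.genes})
        union_set = set(union)
        pvals = []
        for role in roles_to_test:
            annotated = set(markers[role]) & bg
            K = len(annotated)
            x = len(annotated & union_set)
            p = float(hypergeom.sf(x - 1, N, K, len(union_set))) if x > 0 else 1.0
            pvals.append(p)
        qvals = _benjamini_hochberg(pvals)
        best = min(zip(qvals, pvals, roles_to_test))
        role = best[2] if best[0] <= alpha else "other"
        mid = f"metanode{idx:02d}"
        if role != "other":
            if role in claimed:
                raise ValueError(
                    f"role {role!r} claimed by both {claimed[role]} and {mid}; "
                    "refine markers or cut height"
                )
            claimed[role] = mid
        metanodes.append(Metanode(mid, list(node_ids), role, union))
    return metanodes, claudin_node
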