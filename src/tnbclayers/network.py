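"""Gene co-expression network inference and branch decomposition.

The association graph weights every gene pair by Gaussian mutual
information, MI = -0.5 * ln(1 - r^2) for Pearson correlation r.  A
Chow-Liu-style maximum-weight spanning forest over these weights gives a
tree-structured dependency skeleton, which is then cut into branches
(candidate functional nodes) by repeatedly removing its weakest edges until
every component is small enough.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "gaussian_mi",
    "mi_threshold_for_r",
    "build_association_graph",
    "max_spanning_forest",
    "split_branches",
    "Branch",
]

_R2_CAP = 1.0 - 1e-12


def gaussian_mi(r):
    """Mutual information (nats) of a bivariate Gaussian with correlation r.

    |r| within 1e-12 of 1 is capped (the MI diverges there) with a warning.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    r2 = r * r
    if np.any(r2 >= _R2_CAP):
        warnings.warn("correlation magnitude ~1; mutual information capped", stacklevel=2)
        r2 = np.minimum(r2, _R2_CAP)
    out = -0.5 * np.log1p(-r2)
    return float(out) if out.ndim == 0 else out


def mi_threshold_for_r(r: float = 0.3) -> float:
    """MI value corresponding to |correlation| = r (default edge cutoff)."""
    return float(gaussian_mi(r))


def build_association_graph(m: ExpressionMatrix, signed: bool = False) -> nx.Graph:
    """Complete graph over genes weighted by pairwise Gaussian MI.

    Requires a centered matrix with >= 3 samples and unique gene ids;
    zero-variance genes make the correlation undefined and are rejected.

    With ``signed=True`` only positively correlated pairs receive an edge
    (signed co-expression convention): anti-correlated gene groups — e.g.
    programs active in mutually exclusive tumor subtypes — then cannot be
    bridged into one branch, since MI itself is blind to the sign of r.
    """
    if m.n_samples < 3:
        raise ValueError("association graph needs at least 3 samples")
    genes = m.gene_ids
    if len(set(genes)) != len(genes):
        raise ValueError("association graph requires collapsed (unique) gene ids")
    sd = m.values.std(axis=1)
    if np.any(sd == 0):
        bad = [genes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # self-correlations on the diagonal
        corr = np.corrcoef(m.values)
    iu, ju = np.triu_indices(len(genes), k=1)
    rs = corr[iu, ju]
    weights = gaussian_mi(rs)
    g = nx.Graph(structure_flag="complete")
    g.add_nodes_from(genes)
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(w))
        for i, j, w, r in zip(iu, ju, weights, rs)
        if not (signed and r <= 0)
    )
    return g


def max_spanning_forest(g: nx.Graph, min_edge_weight: float | None = None) -> nx.Graph:
    """Maximum-weight spanning forest by Kruskal.

    Edges are taken in descending weight, ties broken by the lexicographic
    (min endpoint, max endpoint) pair, so the result is deterministic.
    Edges below ``min_edge_weight`` are discarded (default: MI at |r|=0.3),
    which may leave the forest disconnected.  Every vertex is retained.
    """
    if min_edge_weight is None:
        min_edge_weight = mi_threshold_for_r(0.3)
    forest = nx.Graph(structure_flag="forest")
    forest.add_nodes_from(g.nodes)
    edges = [
        (min(u, v), max(u, v), d["weight"])
        for u, v, d in g.edges(data=True)
        if d["weight"] >= min_edge_weight
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    uf = nx.utils.UnionFind(g.nodes)
    for u, v, w in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            forest.add_edge(u, v, weight=w)
    return forest


@dataclasses.dataclass
class Branch:
    """A connected piece of the forest: a candidate functional node."""

    branch_id: str
    genes: list[str]
    edges: list[tuple[str, str, float]]

    def __len__(self) -> int:
        return len(self.genes)


def split_branches(
    forest: nx.Graph,
    max_branch_size: int = 150,
    min_branch_size: int = 10,
) -> tuple[list[Branch], list[list[str]]]:
    """Cut the forest into branches of bounded size.

    The lightest remaining edge (ties by lexicographic endpoint pair) is
    deleted until every connected component has at most ``max_branch_size``
    vertices.  Components with at least ``min_branch_size`` vertices become
    branches (ordered by size, largest first); the rest are returned as
    residue.  Branch vertex sets partition the forest's vertices between
    branches and residue.
    """
    if max_branch_size < min_branch_size:
        raise ValueError("max_branch_size must be >= min_branch_size")
    work = forest.copy()
    while True:
        oversized = [
            c for c in nx.connected_components(work) if len(c) > max_branch_size
        ]
        if not oversized:
            break
        candidates = []
        for comp in oversized:
            sub = work.subgraph(comp)
            candidates.extend(
                (d["weight"], min(u, v), max(u, v)) for u, v, d in sub.edges(data=True)
            )
        w, u, v = min(candidates)
        work.remove_edge(u, v)

    components = sorted(nx.connected_components(work), key=lambda c: (-len(c), min(c)))
    branches: list[Branch] = []
    residue: list[list[str]] = []
    for comp in components:
        genes = sorted(comp)
        if len(genes) >= min_branch_size:
            sub = work.subgraph(comp)
            branches.append(
                Branch(
                    branch_id=f"branch{len(branches) + 1:02d}",
                    genes=genes,
                    edges=[
                        (min(u, v), max(u, v), d["weight"])
                        for u, v, d in sub.edges(data=True)
                    ],
                )
            )
        else:
            residue.append(genes)
    return branches, residue
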