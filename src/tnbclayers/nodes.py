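"""Functional annotation of network branches by over-representation analysis.

Each branch is tested against every gene set with a one-sided hypergeometric
upper-tail test on a fixed background, Benjamini-Hochberg adjusted within
the branch; branches whose best term passes the threshold become labeled
functional nodes, the rest are logged and dropped from node-level analyses.
"""

from __future__ import annotations

import dataclasses
import logging

from scipy.stats import hypergeom

from .io import GeneSetCollection
from .network import Branch

__all__ = ["FunctionalNode", "enrich_branch", "label_nodes"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FunctionalNode:
    node_id: str
    genes: list[str]
    label_term: str
    label_name: str
    enrichment_p: float
    enrichment_q: float


def enrich_branch(
    branch: Branch | list[str],
    genesets: GeneSetCollection,
    background_genes: list[str],
) -> list[tuple[str, int, float, float]]:
    """Hypergeometric over-representation of each term in one branch.

    With N background genes, K of them annotated to the term and a branch of
    n genes overlapping the term in x, p = P(X >= x), X ~ Hypergeom(N, K, n).
    Returns (term_id, overlap, p, q) sorted by ascending p (ties by term id);
    q is BH-adjusted across the terms tested for this branch.
    """
    genes = branch.genes if isinstance(branch, Branch) else list(branch)
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene list")
    missing = set(genes) - background
    if missing:
        raise ValueError(f"branch genes absent from background: {sorted(missing)[:5]}")
    branch_set = set(genes)
    N, n = len(background), len(branch_set)

    rows = []
    for tid, term_genes in zip(genesets.term_ids, genesets.genes):
        annotated = set(term_genes) & background
        K = len(annotated)
        x = len(annotated & branch_set)
        # upper tail P(X >= x); survival function at x-1
        p = float(hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        rows.append((tid, x, min(p, 1.0)))
    qs = _benjamini_hochberg([p for _, _, p in rows])
    out = [(tid, x, p, q) for (tid, x, p), q in zip(rows, qs)]
    out.sort(key=lambda r: (r[2], r[0]))
    return out


def _benjamini_hochberg(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def label_nodes(
    branches: list[Branch],
    genesets: GeneSetCollection,
    background_genes: list[str],
    alpha: float = 0.05,
) -> list[FunctionalNode]:
    """Turn annotated branches into functional nodes.

    A branch becomes a node labeled by its best term when that term's
    BH-adjusted p is at most ``alpha``; un-annotated branches are logged and
    excluded.  The node keeps the whole branch gene list.
    """
    names = dict(zip(genesets.term_ids, genesets.term_names))
    nodes: list[FunctionalNode] = []
    for branch in branches:
        enriched = enrich_branch(branch, genesets, background_genes)
        tid, overlap, p, q = enriched[0]
        if q <= alpha and overlap > 0:
            nodes.append(
                FunctionalNode(
                    node_id=branch.branch_id,
                    genes=list(branch.genes),
                    label_term=tid,
                    label_name=names.get(tid, tid),
                    enrichment_p=p,
                    enrichment_q=q,
                )
            )
        else:
            logger.info(
                "branch %s (%d genes) has no enriched term (best q=%.3g); dropped",
                branch.branch_id,
                len(branch.genes),
                q,
            )
    return nodes
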