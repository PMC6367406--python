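"""Normalization and gene filtering.

Fixed pipeline order: magnitude normalization -> log2 -> batch-effect
removal -> mean centering -> probe collapsing -> variance filtering.
Each step returns a new :class:`ExpressionMatrix`; nothing mutates in place.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "magnitude_normalize",
    "log2_transform",
    "remove_batch_effect",
    "mean_center",
    "collapse_probes",
    "select_most_variable",
    "preprocess_pipeline",
]


def magnitude_normalize(m: ExpressionMatrix, method: str = "median") -> ExpressionMatrix:
    """Scale each sample by one factor so its median (or mean) equals the
    global median (mean) of per-sample medians (means).

    Requires raw-scale, strictly positive intensities: the log2 step that
    follows would fail otherwise.
    """
    if m.scale_flag != "raw":
        raise ValueError(f"magnitude_normalize expects raw values, got {m.scale_flag}")
    if np.any(m.values <= 0):
        i, j = np.argwhere(m.values <= 0)[0]
        raise ValueError(
            f"non-positive value at probe {m.probe_ids[i]}, sample {m.sample_ids[j]}"
        )
    stat = np.median if method == "median" else np.mean
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    per_sample = stat(m.values, axis=0)
    target = stat(per_sample)
    factors = target / per_sample
    return m.copy_with(values=m.values * factors[None, :])


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    if np.any(m.values <= 0):
        i, j = np.argwhere(m.values <= 0)[0]
        raise ValueError(
            f"log2 of non-positive value at probe {m.probe_ids[i]}, "
            f"sample {m.sample_ids[j]}"
        )
    return m.copy_with(values=np.log2(m.values), scale_flag="log2")


def remove_batch_effect(m: ExpressionMatrix, batch: list[str] | None = None) -> ExpressionMatrix:
    """One-way fixed-effect batch removal.

    For each gene, each batch's mean is subtracted and the gene's grand mean
    added back, so after the call per-gene per-batch means coincide.
    Singleton batches would be zeroed out entirely; they are instead left at
    the grand mean with a warning.
    """
    if m.scale_flag != "log2":
        raise ValueError("remove_batch_effect expects log2 values")
    batch = batch if batch is not None else m.batch
    if batch is None:
        raise ValueError("no batch labels available")
    if len(batch) != m.n_samples:
        raise ValueError("batch length must match sample count")
    levels = sorted(set(batch))
    if len(levels) < 2:
        return m.copy_with()
    b = np.asarray(batch)
    values = m.values.copy()
    grand = values.mean(axis=1, keepdims=True)
    for lev in levels:
        cols = b == lev
        if cols.sum() == 1:
            warnings.warn(
                f"batch {lev!r} has a single sample; adjusted by grand mean only",
                stacklevel=2,
            )
            values[:, cols] = grand
            continue
        values[:, cols] += grand - values[:, cols].mean(axis=1, keepdims=True)
    return m.copy_with(values=values)


def mean_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene at zero mean across samples."""
    return m.copy_with(
        values=m.values - m.values.mean(axis=1, keepdims=True), scale_flag="centered"
    )


def collapse_probes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, for each gene, its highest-variance probe (unbiased variance,
    ties broken toward the lexicographically smallest probe id)."""
    if m.n_samples > 1:
        variances = m.values.var(axis=1, ddof=1)
    else:
        variances = np.zeros(m.n_genes)
    best: dict[str, int] = {}
    for i, gene in enumerate(m.gene_ids):
        j = best.get(gene)
        if j is None:
            best[gene] = i
        elif variances[i] > variances[j] or (
            variances[i] == variances[j] and m.probe_ids[i] < m.probe_ids[j]
        ):
            best[gene] = i
    keep = sorted(best.values())
    return m.copy_with(
        values=m.values[keep],
        probe_ids=[m.probe_ids[i] for i in keep],
        gene_ids=[m.gene_ids[i] for i in keep],
    )


def select_most_variable(m: ExpressionMatrix, k: int = 2000) -> ExpressionMatrix:
    """Keep the k genes of largest variance (ties broken by gene id)."""
    if k >= m.n_genes:
        if k > m.n_genes:
            warnings.warn(
                f"k={k} exceeds gene count {m.n_genes}; keeping all genes", stacklevel=2
            )
        return m.copy_with()
    variances = m.values.var(axis=1, ddof=1)
    order = sorted(range(m.n_genes), key=lambda i: (-variances[i], m.gene_ids[i]))
    keep = sorted(order[:k])
    return m.copy_with(
        values=m.values[keep],
        probe_ids=[m.probe_ids[i] for i in keep],
        gene_ids=[m.gene_ids[i] for i in keep],
    )


def preprocess_pipeline(
    m: ExpressionMatrix,
    top_k: int = 2000,
    normalize_method: str = "median",
    manifest: dict | None = None,
) -> ExpressionMatrix:
    """Run the full chain in its fixed order, recording dimensions.

    Steps are skipped when the input scale already satisfies them (a matrix
    declared log2 skips magnitude normalization and the log2 transform).
    """

    def record(stage: str, mat: ExpressionMatrix) -> None:
        if manifest is not None:
            manifest.setdefault("stages", []).append(
                {"stage": stage, "n_genes": mat.n_genes, "n_samples": mat.n_samples}
            )

    record("input", m)
    if m.scale_flag == "raw":
        m = magnitude_normalize(m, method=normalize_method)
        m = log2_transform(m)
        record("normalized_log2", m)
    if m.batch is not None and len(set(m.batch)) > 1:
        m = remove_batch_effect(m)
        record("batch_removed", m)
    if m.scale_flag != "centered":
        m = mean_center(m)
        record("centered", m)
    m = collapse_probes(m)
    record("collapsed", m)
    m = select_most_variable(m, k=top_k)
    record("variance_filtered", m)
    if manifest is not None:
        manifest["top_k"] = top_k
        manifest["normalize_method"] = normalize_method
    return m
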