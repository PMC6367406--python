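"""Sparse k-means high/low calls per metanode and the cellular decision tree.

Sparse k-means (Witten-Tibshirani) alternates a weighted k-means step with a
closed-form update of nonnegative feature weights under unit L2 and bounded
L1 norms, maximizing the weighted between-cluster sum of squares (BCSS).
With k fixed at 2, each metanode splits the cohort into a high- and a
low-activity group; the cellular workflow then reads the luminal, basal and
claudin calls off in that order (luminal-high -> LAR; basal-high -> basal;
otherwise claudin activity separates CLDN-high from CLDN-low).  The immune
metanode provides an orthogonal IM+/IM- layer.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "SparseKMeansResult",
    "sparse_kmeans",
    "choose_sparsity",
    "orient_high_low",
    "cellular_workflow",
    "immune_call",
    "CELLULAR_LABELS",
]

CELLULAR_LABELS = ("LAR", "basal", "CLDN-low", "CLDN-high")

_NORM_TOL = 1e-8


@dataclasses.dataclass
class SparseKMeansResult:
    labels: np.ndarray  # cluster index per sample (0..k-1)
    weights: np.ndarray  # nonnegative per-feature weights, ||w||_2 = 1
    sparsity: float  # the L1 bound s actually used
    objective: float  # weighted BCSS at the solution
    n_restarts: int
    seed: int
    n_iter: int = 0

    def __post_init__(self) -> None:
        w = self.weights
        assert np.all(w >= -_NORM_TOL)
        assert abs(np.linalg.norm(w) - 1.0) <= _NORM_TOL
        assert np.sum(np.abs(w)) <= self.sparsity + _NORM_TOL


def _bcss_per_feature(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Between-cluster sum of squares for each feature (total SS - within SS)."""
    total = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
    within = np.zeros(x.shape[1])
    for c in np.unique(labels):
        xc = x[labels == c]
        within += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0)
    return np.maximum(total - within, 0.0)


def _soft_threshold_weights(a: np.ndarray, s: float) -> np.ndarray:
    """w = S(a, delta)_+ / ||S(a, delta)_+||_2 with delta chosen so that
    ||w||_1 <= s (delta = 0 when the unthresholded weights already comply)."""

    def weights(delta: float) -> np.ndarray:
        shrunk = np.maximum(a - delta, 0.0)
        norm = np.linalg.norm(shrunk)
        if norm == 0:
            return shrunk
        return shrunk / norm

    w0 = weights(0.0)
    if np.sum(w0) <= s + _NORM_TOL:
        return w0
    lo, hi = 0.0, float(a.max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        l1 = np.sum(weights(mid))
        if l1 > s:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(a.max(), 1.0):
            break
    return weights(hi)


def _kmeans_labels(
    x_scaled: np.ndarray, k: int, rs: int, init: np.ndarray | None = None
) -> np.ndarray:
    if init is not None:
        km = KMeans(n_clusters=k, init=init, n_init=1, random_state=rs)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=rs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return km.fit_predict(x_scaled)


def sparse_kmeans(
    x: np.ndarray,
    k: int = 2,
    s: float | None = None,
    n_restarts: int = 20,
    max_iter: int = 20,
    seed: int = 0,
) -> SparseKMeansResult:
    """Witten-Tibshirani sparse k-means on a samples x features matrix.

    ``s`` is the L1 bound on the weight vector, in (1, sqrt(p)]; when None it
    is chosen by the permutation gap statistic (:func:`choose_sparsity`).
    Each restart alternates (a) k-means on features scaled by sqrt(w) —
    warm-started from the previous partition so the weighted BCSS objective
    is non-decreasing — and (b) the closed-form weight update, until the
    partition stabilizes or ``max_iter``.  The best restart by objective
    wins; everything is deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    total_ss = ((x - x.mean(axis=0)) ** 2).sum()
    if total_ss == 0:
        raise ValueError("all samples identical: no cluster structure to find")
    if s is None:
        s = choose_sparsity(x, k=k, seed=seed)
    if not (1.0 < s <= np.sqrt(p) + _NORM_TOL):
        raise ValueError(f"s must be in (1, sqrt(p)]; got s={s}, p={p}")

    ss = np.random.SeedSequence(seed)
    restart_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_restarts)]

    best: SparseKMeansResult | None = None
    for rs in restart_seeds:
        w = np.full(p, 1.0 / np.sqrt(p))
        labels = _kmeans_labels(x * np.sqrt(w), k, rs)
        # uniform init weights may violate the L1 bound, so the monotone
        # objective sequence starts after the first feasible weight update
        objective = -np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            a = _bcss_per_feature(x, labels)
            w_new = _soft_threshold_weights(a, s)
            if np.linalg.norm(w_new) == 0:
                break
            w = w_new
            x_scaled = x * np.sqrt(w)
            centers = np.vstack(
                [x_scaled[labels == c].mean(axis=0) for c in range(k)]
            )
            new_labels = _kmeans_labels(x_scaled, k, rs, init=centers)
            if len(np.unique(new_labels)) < k:
                new_labels = labels
            new_objective = float(_bcss_per_feature(x, new_labels) @ w)
            cur_objective = float(_bcss_per_feature(x, labels) @ w)
            if new_objective < cur_objective:
                new_labels, new_objective = labels, cur_objective
            # alternating maximization: the objective never decreases
            assert new_objective >= objective - 1e-6 * max(objective, 1.0)
            converged = np.array_equal(new_labels, labels)
            labels, objective = new_labels, new_objective
            if converged:
                break
        result = SparseKMeansResult(
            labels=labels,
            weights=w,
            sparsity=float(s),
            objective=objective,
            n_restarts=n_restarts,
            seed=seed,
            n_iter=n_iter,
        )
        if best is None or result.objective > best.objective:
            best = result
    assert best is not None
    return best


def choose_sparsity(
    x: np.ndarray,
    k: int = 2,
    n_candidates: int = 8,
    n_permutations: int = 25,
    n_restarts: int = 3,
    seed: int = 0,
) -> float:
    """Pick the L1 bound s by the permutation gap statistic.

    For each candidate s, gap(s) = log O(s) - mean_b log O*_b(s), where O is
    the weighted BCSS on the data and O*_b on data with each feature
    permuted independently; the s with the largest gap wins.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if p == 1:
        return 1.0 + _NORM_TOL
    candidates = np.unique(np.geomspace(1.2, np.sqrt(p), n_candidates))
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(n_permutations):
        xp = x.copy()
        for j in range(p):
            rng.shuffle(xp[:, j])
        permuted.append(xp)

    gaps = []
    for s in candidates:
        obj = sparse_kmeans(x, k=k, s=float(s), n_restarts=n_restarts, seed=seed).objective
        perm_obj = [
            sparse_kmeans(xp, k=k, s=float(s), n_restarts=1, seed=seed).objective
            for xp in permuted
        ]
        gaps.append(np.log(max(obj, 1e-300)) - np.mean(np.log(np.maximum(perm_obj, 1e-300))))
    return float(candidates[int(np.argmax(gaps))])


def orient_high_low(
    result: SparseKMeansResult, activity: pd.Series | np.ndarray, sample_ids=None
) -> pd.Series:
    """Name the cluster with the greater mean metanode activity 'high'.

    Equal cluster means are broken toward 'low' (both clusters called low)
    with a warning.  Invariant to swapping the arbitrary cluster indices.
    """
    if isinstance(activity, pd.Series):
        sample_ids = activity.index if sample_ids is None else sample_ids
        act = activity.to_numpy(dtype=float)
    else:
        act = np.asarray(activity, dtype=float)
    labels = result.labels
    means = {c: act[labels == c].mean() for c in np.unique(labels)}
    top = max(means.values())
    high_clusters = [c for c, v in means.items() if v == top]
    if len(high_clusters) > 1:
        # no strictly highest cluster: resolve toward 'low'
        warnings.warn("cluster activity means tie; tied clusters called 'low'", stacklevel=2)
        calls = np.full(len(labels), "low", dtype=object)
    else:
        calls = np.where(labels == high_clusters[0], "high", "low").astype(object)
    index = sample_ids if sample_ids is not None else pd.RangeIndex(len(labels))
    return pd.Series(calls, index=index, name="call")


def cellular_workflow(
    luminal: pd.Series, basal: pd.Series, claudin: pd.Series
) -> pd.DataFrame:
    """Four-way cellular labels from the three high/low layers.

    luminal high -> LAR (flagged ambiguous when basal is also high);
    luminal low, basal high -> basal; both low -> CLDN-high/low by the
    claudin call.  Every sample needs all three calls.
    """
    samples = luminal.index
    for name, series in (("basal", basal), ("claudin", claudin)):
        missing = samples.difference(series.index)
        if len(missing):
            raise ValueError(f"missing {name} call for samples: {list(missing[:5])}")
    labels, ambiguous = [], []
    for sid in samples:
        lum, bas, cldn = luminal[sid], basal[sid], claudin[sid]
        if lum == "high":
            labels.append("LAR")
            ambiguous.append(bas == "high")
        elif bas == "high":
            labels.append("basal")
            ambiguous.append(False)
        elif cldn == "high":
            labels.append("CLDN-high")
            ambiguous.append(False)
        else:
            labels.append("CLDN-low")
            ambiguous.append(False)
    return pd.DataFrame({"cellular": labels, "ambiguous": ambiguous}, index=samples)


def immune_call(
    result: SparseKMeansResult, activity: pd.Series, sample_ids=None
) -> pd.Series:
    """IM+/IM- labels: the higher-activity sparse k-means cluster is IM+."""
    highlow = orient_high_low(result, activity, sample_ids=sample_ids)
    return highlow.map({"high": "IM+", "low": "IM-"}).rename("immune")
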