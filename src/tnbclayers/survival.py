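"""Survival and association statistics for subgroup characterization.

Kaplan-Meier curves and the log-rank test come from lifelines; the
binary-covariate Cox model is a direct Newton-Raphson maximization of the
partial likelihood (Breslow ties by default, Efron by flag) so that the
hazard-ratio contract — Wald 95% CI, explicit non-convergence when a group
has no events — is fully under this package's control.  Rank and
contingency tests wrap scipy; Dunn's post-hoc follows the standard
rank-mean z construction with tie correction.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "km_curve",
    "logrank_test",
    "CoxResult",
    "cox_binary_hr",
    "kruskal_wallis",
    "dunn_posthoc",
    "fisher_2x2",
    "chi2_contingency",
    "percent_report",
    "SurvivalResult",
    "compare_groups",
]


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns time, at_risk,
    events, censored, survival.  Censored-only times reduce the risk set
    without changing the estimate; S(0) = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table.copy()
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def logrank_test(groups: dict | list) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test over two or more groups.

    ``groups`` maps a group label to (times, events) or is a list of such
    pairs.  Returns (chi2, df, p) with df = number of groups - 1.
    """
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = list(enumerate(groups))
    if len(items) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    times, events, labels = [], [], []
    for label, (t, e) in items:
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        times.append(t)
        events.append(e)
        labels.extend([label] * len(t))
    res = multivariate_logrank_test(
        np.concatenate(times), np.array(labels, dtype=object), np.concatenate(events)
    )
    df = len(items) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclasses.dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    converged: bool
    message: str = ""


def cox_binary_hr(times, events, group01, ties: str = "breslow", max_iter: int = 50) -> CoxResult:
    """Cox proportional-hazards fit for a single 0/1 covariate.

    Newton-Raphson on the partial likelihood; Breslow tie handling by
    default, Efron via ``ties='efron'``.  The hazard ratio is exp(beta) for
    group 1 relative to group 0 with Wald 95% CI.  When a group has no
    events the likelihood has no interior maximum; the result is returned
    with ``converged=False`` and an explanatory message rather than a
    spurious estimate.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(group01, dtype=float)
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("group01 must be coded 0/1")
    if len(set(np.unique(x))) < 2:
        raise ValueError("covariate is constant; hazard ratio not identifiable")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    events_in = {g: int(e[x == g].sum()) for g in (0.0, 1.0)}
    if 0 in events_in.values():
        return CoxResult(
            hr=math.nan, ci_low=math.nan, ci_high=math.nan, p=math.nan,
            beta=math.inf if events_in[0.0] == 0 else -math.inf, se=math.inf,
            converged=False,
            message=f"no events in group {[g for g, n in events_in.items() if n == 0]}; "
            "partial likelihood is monotone in beta",
        )

    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])

    def score_info(beta: float) -> tuple[float, float]:
        u, info = 0.0, 0.0
        w = np.exp(beta * x)
        for et in event_times:
            risk = t >= et
            dead = (t == et) & (e == 1)
            d = int(dead.sum())
            s0 = w[risk].sum()
            s1 = (w[risk] * x[risk]).sum()
            sum_x_dead = x[dead].sum()
            if ties == "breslow":
                u += sum_x_dead - d * s1 / s0
                info += d * (s1 / s0 - (s1 / s0) ** 2)
            else:  # efron
                s0d = w[dead].sum()
                s1d = (w[dead] * x[dead]).sum()
                for l in range(d):
                    f = l / d
                    s0l = s0 - f * s0d
                    s1l = s1 - f * s1d
                    u += sum_x_dead / d - s1l / s0l
                    info += s1l / s0l - (s1l / s0l) ** 2
        return u, info

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        u, info = score_info(beta)
        if info <= 0:
            break
        step = u / info
        beta += step
        if abs(step) < 1e-10:
            converged = True
            break
    _, info = score_info(beta)
    se = math.sqrt(1.0 / info) if info > 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        hr=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
        p=float(p),
        beta=beta,
        se=se,
        converged=converged,
        message="" if converged else "Newton-Raphson did not converge",
    )


def kruskal_wallis(samples: list) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; returns (H, p)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    h, p = stats.kruskal(*[np.asarray(s, dtype=float) for s in samples])
    return float(h), float(p)


def dunn_posthoc(
    samples: list, labels: list[str] | None = None, adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test after Kruskal-Wallis.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p,
    adjusted across pairs (Bonferroni by default, 'bh' for
    Benjamini-Hochberg, 'none' to skip).
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        sd = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / sd if sd > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    elif adjust == "bh":
        from .nodes import _benjamini_hochberg

        out["p_adj"] = _benjamini_hochberg(out["p"].tolist())
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError("adjust must be 'bonferroni', 'bh' or 'none'")
    return out


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of tables at most as probable)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("fisher_2x2 expects a 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def chi2_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction; (chi2, df, p)."""
    table = np.asarray(table, dtype=float)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def percent_report(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero (table style)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = 100.0 * numerator / denominator
    return int(math.floor(abs(value) + 0.5) * (1 if value >= 0 else -1))


@dataclasses.dataclass
class SurvivalResult:
    """Bundle for a two-group survival comparison."""

    curves: dict[str, pd.DataFrame]
    n_per_group: dict[str, int]
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult
    reference: str


def compare_groups(
    times, events, labels, reference: str, comparison: str
) -> SurvivalResult:
    """KM curves, log-rank test and hazard ratio for two named groups.

    The hazard ratio is for ``comparison`` relative to ``reference``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels, dtype=object)
    curves, n_per_group = {}, {}
    for g in (reference, comparison):
        mask = labels == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
        curves[g] = km_curve(times[mask], events[mask])
        n_per_group[g] = int(mask.sum())
    keep = np.isin(labels, [reference, comparison])
    chi2, _, p = logrank_test(
        {
            g: (times[keep & (labels == g)], events[keep & (labels == g)])
            for g in (reference, comparison)
        }
    )
    cox = cox_binary_hr(times[keep], events[keep], (labels[keep] == comparison).astype(int))
    return SurvivalResult(curves, n_per_group, chi2, p, cox, reference)
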