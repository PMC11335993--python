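"""Shared rank-statistics core.

One implementation of the Kruskal-Wallis omnibus test with Dunn's post hoc
comparisons, and of Spearman correlation with an exact small-sample
permutation p-value, used by both the disease-sharing and the score/trend
comparison modules so their results are identical on shared inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KruskalDunnResult",
    "kruskal_dunn",
    "dunn_posthoc",
    "spearman",
    "mannwhitney_exact",
]


@dataclass
class KruskalDunnResult:
    H: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p, p_adj
    medians: dict[str, float]
    n: dict[str, int]


def _tie_term(all_values: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups of the pooled sample."""
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], p_adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks for all unordered group pairs.

    Uses the pooled midrank assignment with the standard tie correction of
    the rank variance. ``p_adjust`` is ``bonferroni`` (default) or ``holm``.
    """
    names = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    pooled = np.concatenate([arrays[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        k = len(arrays[g])
        mean_rank[g] = float(np.mean(ranks[start : start + k]))
        start += k
    tie = _tie_term(pooled)
    var_unit = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_unit -= tie / (12.0 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(arrays[a]), len(arrays[b])
        se = np.sqrt(var_unit * (1.0 / na + 1.0 / nb))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    if m == 0:
        out["p_adj"] = []
        return out
    if p_adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    elif p_adjust == "holm":
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_adj"] = adj
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return out


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], p_adjust: str = "bonferroni"
) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis omnibus test plus Dunn's post hoc table.

    A degenerate pooled sample in which every observation is identical gives
    H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*arrays)
    pairwise = dunn_posthoc(groups, p_adjust=p_adjust)
    medians = {g: float(np.median(np.asarray(v, dtype=float))) for g, v in groups.items()}
    sizes = {g: len(v) for g, v in groups.items()}
    return KruskalDunnResult(H=float(H), p=float(p), pairwise=pairwise, medians=medians, n=sizes)


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U (tie-aware, small samples)
# ---------------------------------------------------------------------------

_MW_EXACT_MAX_COMBINATIONS = 200_000


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test, exact for small samples even with ties.

    Enumerates every assignment of the pooled midranks to the two groups and
    reports P(|U - n1 n2 / 2| >= observed). Complete ties therefore give
    p = 1 without special-casing. Beyond ~2e5 label assignments the scipy
    implementation takes over (exact when untied, midrank-normal otherwise).
    Returns (U of the first sample, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    from math import comb

    if comb(n1 + n2, n1) <= _MW_EXACT_MAX_COMBINATIONS:
        centre = n1 * n2 / 2.0
        dev_obs = abs(u_obs - centre)
        hits = total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - centre) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total, "exact"
    has_ties = len(np.unique(pooled)) < n1 + n2
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), f"scipy_{method}"


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n permutation p
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 9  # full permutation enumeration up to this sample size


@lru_cache(maxsize=None)
def _exact_abs_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! rank permutations (no ties)."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    base = np.arange(n, dtype=np.int64)
    s = np.sum((perms - base) ** 2, axis=1)
    rho = 1.0 - 6.0 * s / (n * (n * n - 1.0))
    return np.sort(np.abs(rho))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with midranks and a two-sided p-value.

    For n < 10 with no ties in either variable the p-value is exact (full
    permutation enumeration, cached per n); otherwise the usual
    t-approximation with n - 2 degrees of freedom is used. A constant input
    yields rho = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= _EXACT_N_MAX and no_ties:
        null = _exact_abs_rho_null(n)
        count = len(null) - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return rho, float(count / len(null))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))
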