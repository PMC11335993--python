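"""Biophysical score comparisons and aging expression-trend classification.

Score comparisons contrast the distributions of externally computed
predictors (CamSol intrinsic solubility, Zyggregator aggregation propensity,
catGRANULE LLPS propensity, and the supersaturation score sigma_f) across
protein groups — the core insoluble proteome, the background insoluble
proteome, the whole reference proteome and the disease-amyloid comparators —
using the shared Kruskal-Wallis/Dunn core. The supersaturation summary is
the ratio of arithmetic mean sigma_f between two sets on the linear scale,
with a geometric-mean (log10-scale) variant reported alongside.

The trend analysis classifies each gene's expression change across adult
ages (day 2 to day 10 by default) by Spearman correlation of value against
age, pooling datasets, with BH adjustment across tested genes and classes
up / down / unchanged at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._stats import KruskalDunnResult, kruskal_dunn, spearman
from .enrichment import bh_adjust
from .setops import ProteinSet
from .tables_io import ExpressionSeries, ScoreTable

__all__ = [
    "ScoreComparison",
    "FoldResult",
    "TrendSummary",
    "compare_scores",
    "supersaturation_fold",
    "aging_trend",
]


@dataclass
class ScoreComparison:
    score_name: str
    result: KruskalDunnResult

    @property
    def H(self) -> float:
        return self.result.H

    @property
    def omnibus_p(self) -> float:
        return self.result.p

    @property
    def pairwise(self) -> pd.DataFrame:
        return self.result.pairwise

    @property
    def medians(self) -> dict[str, float]:
        return self.result.medians

    def directions(self, alpha: float = 0.05) -> pd.DataFrame:
        """Significant pairwise rows annotated with the direction of shift.

        ``direction`` is +1 when group_a's median exceeds group_b's.
        """
        sig = self.pairwise[self.pairwise["p_adj"] < alpha].copy()
        sig["direction"] = [
            int(np.sign(self.medians[a] - self.medians[b]))
            for a, b in zip(sig["group_a"], sig["group_b"])
        ]
        return sig


def _group_values(t: ScoreTable, ids: Iterable[str], score_name: str) -> np.ndarray:
    col = t.column(score_name)
    members = ids.members if isinstance(ids, ProteinSet) else frozenset(ids)
    present = col.index.intersection(members)
    return col.loc[present].dropna().to_numpy(dtype=float)


def compare_scores(
    t: ScoreTable,
    sets: Mapping[str, ProteinSet | Iterable[str]],
    score_name: str,
    p_adjust: str = "bonferroni",
) -> ScoreComparison:
    """Compare one score's distribution across named protein groups.

    Missing scores are dropped per group; a group left with fewer than two
    scored proteins is an error. ``score_name`` may be any score column or
    ``sigma_f_log10`` for the display-scale supersaturation values.
    """
    groups: dict[str, np.ndarray] = {}
    for label, ids in sets.items():
        vals = _group_values(t, ids, score_name)
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than two scored proteins")
        groups[label] = vals
    return ScoreComparison(score_name=score_name, result=kruskal_dunn(groups, p_adjust=p_adjust))


@dataclass
class FoldResult:
    fold_linear: float  # ratio of arithmetic means of sigma_f
    fold_geometric: float  # 10 ** (difference of mean log10 sigma_f)
    n_numerator: int
    n_reference: int


def supersaturation_fold(
    t: ScoreTable,
    numerator: ProteinSet | Iterable[str],
    reference: ProteinSet | Iterable[str],
) -> FoldResult:
    """Fold-difference of average supersaturation between two protein sets.

    The primary value is the ratio of linear-scale arithmetic means of
    sigma_f; the geometric-mean variant (ratio of 10^mean-log10) is reported
    alongside since the score is displayed on log10.
    """
    num = _group_values(t, numerator, "sigma_f")
    ref = _group_values(t, reference, "sigma_f")
    if len(num) == 0 or len(ref) == 0:
        raise ValueError("sigma_f must be present for at least one protein per set")
    ref_mean = float(np.mean(ref))
    if ref_mean == 0:
        raise ValueError("reference mean sigma_f is zero")
    linear = float(np.mean(num)) / ref_mean
    geometric = float(10 ** (np.mean(np.log10(num)) - np.mean(np.log10(ref))))
    return FoldResult(
        fold_linear=linear, fold_geometric=geometric, n_numerator=len(num), n_reference=len(ref)
    )


@dataclass
class TrendSummary:
    n_tested: int
    n_up: int
    n_down: int
    n_unchanged: int

    @property
    def frac_up(self) -> float:
        return self.n_up / self.n_tested if self.n_tested else float("nan")

    @property
    def frac_down(self) -> float:
        return self.n_down / self.n_tested if self.n_tested else float("nan")

    @property
    def up_down_ratio(self) -> float:
        return self.n_up / self.n_down if self.n_down else float("nan")


def aging_trend(
    e: ExpressionSeries,
    genes: Iterable[str] | None = None,
    day_window: tuple[int, int] = (2, 10),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, TrendSummary]:
    """Classify per-gene expression trends across adult ages.

    Expression values are windowed to ``day_window`` (inclusive), pooled
    across datasets, and each gene with at least three (age, value) points
    gets a Spearman rho of value against age. P-values are BH-adjusted
    across tested genes; class is ``up``/``down`` by the sign of rho when
    p_adj < alpha, else ``unchanged``. Genes with fewer than three points
    are reported untested (class NaN).
    """
    windowed = e.window(*day_window).values
    if genes is not None:
        wanted = set(genes)
        windowed = windowed[windowed["gene_id"].isin(wanted)]
    rows = []
    for gene, sub in windowed.groupby("gene_id", sort=True):
        ages = sub["age_day"].to_numpy(dtype=float)
        vals = sub["value"].to_numpy(dtype=float)
        if len(sub) < 3:
            rows.append({"gene_id": gene, "rho": np.nan, "p": np.nan, "tested": False})
            continue
        rho, p = spearman(ages, vals)
        rows.append({"gene_id": gene, "rho": rho, "p": p, "tested": True})
    out = pd.DataFrame(rows, columns=["gene_id", "rho", "p", "tested"]).set_index("gene_id")
    tested = out["tested"].to_numpy(dtype=bool)
    p_adj = np.full(len(out), np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(out.loc[tested, "p"])
    out["p_adj"] = p_adj
    cls = np.full(len(out), None, dtype=object)
    sig = tested & (out["p_adj"].to_numpy() < alpha)
    cls[tested] = "unchanged"
    cls[sig & (out["rho"].to_numpy() > 0)] = "up"
    cls[sig & (out["rho"].to_numpy() < 0)] = "down"
    out["class"] = cls
    summary = TrendSummary(
        n_tested=int(tested.sum()),
        n_up=int(np.sum(cls == "up")),
        n_down=int(np.sum(cls == "down")),
        n_unchanged=int(np.sum(cls == "unchanged")),
    )
    return out, summary
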