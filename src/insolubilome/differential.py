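"""Differential insolubility calling from a paired quantification matrix.

Case (amyloid-beta expressing) and control insoluble-fraction intensities
are compared pairwise within biological replicates: per-protein log2
fold-change is the mean over complete pairs of log2(case) - log2(control),
tested with a two-sided paired t-test on those per-pair differences.
Multiple testing is corrected with Storey's q-value method (pi0 estimated by
a cubic smoother over a lambda grid, bootstrap alternative available).
A protein is called significantly increased when it carries at least
``min_peptides`` unique peptides (default 2), q < 0.01 and
log2 fold-change > 0.58 (i.e. > 1.5-fold).

The total-insoluble comparison normalizes each replicate's summed intensity
to the average of that experiment's control totals and tests case vs control
with an exact two-sided Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mannwhitney_exact
from .setops import ProteinSet
from .tables_io import QuantMatrix

__all__ = [
    "QValueModel",
    "SignificanceThresholds",
    "TotalInsolubleResult",
    "DEFAULT_LAMBDA_GRID",
    "ZERO_VARIANCE_P_FLOOR",
    "paired_log_fold_change",
    "storey_pi0",
    "storey_qvalues",
    "add_qvalues",
    "call_significant",
    "total_insoluble_compare",
]

#: Lambda grid for pi0 estimation: 0, 0.05, ..., 0.90.
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.9001, 0.05), 2)

#: p-value assigned when every per-pair difference is identical and nonzero
#: (the t statistic diverges); avoids NaN propagation downstream.
ZERO_VARIANCE_P_FLOOR = 1e-15


@dataclass
class QValueModel:
    """Fitted components of the Storey q-value correction."""

    pi0: float
    lambda_grid: np.ndarray
    pi0_raw: np.ndarray  # pi0 estimate at each lambda before smoothing
    method: str = "smoother"

    def __post_init__(self) -> None:
        if not (0.0 < self.pi0 <= 1.0):
            raise ValueError(f"pi0 must lie in (0, 1], got {self.pi0}")


@dataclass(frozen=True)
class SignificanceThresholds:
    min_peptides: int = 2
    q_max: float = 0.01
    lfc_min: float = 0.58


def paired_log_fold_change(m: QuantMatrix) -> pd.DataFrame:
    """Per-protein paired differential statistics (no multiplicity yet).

    Returns a DataFrame indexed by protein id with columns ``log2fc``,
    ``t_stat``, ``p``, ``n_pairs_used``, ``unique_peptides`` and ``tested``.
    A pair is complete for a protein when both its case and control
    intensities are present and strictly positive (zero cannot be logged and
    is treated as missing). Proteins with fewer than two complete pairs are
    reported untested (NaN statistics).
    """
    case = m.intensities[m.condition_columns("case")].to_numpy(dtype=float)
    ctrl = m.intensities[m.condition_columns("control")].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lc = np.where(case > 0, np.log2(np.where(case > 0, case, 1.0)), np.nan)
        lx = np.where(ctrl > 0, np.log2(np.where(ctrl > 0, ctrl, 1.0)), np.nan)
    d = lc - lx  # per-pair log2 ratios; NaN where the pair is incomplete
    n_used = np.sum(~np.isnan(d), axis=1)
    tested = n_used >= 2

    lfc = np.full(len(d), np.nan)
    t_stat = np.full(len(d), np.nan)
    pvals = np.full(len(d), np.nan)
    mean_d = np.nansum(d, axis=1) / np.maximum(n_used, 1)  # avoids empty-slice noise
    sd_d = np.full(len(d), np.nan)
    for i in np.where(tested)[0]:
        di = d[i][~np.isnan(d[i])]
        sd_d[i] = np.std(di, ddof=1)
    lfc[tested] = mean_d[tested]
    # sd below numerical resolution of the differences counts as zero-variance
    with np.errstate(invalid="ignore"):
        zero_var = tested & (sd_d <= 1e-12 * np.maximum(1.0, np.abs(lfc)))
        regular = tested & ~zero_var
    se = sd_d[regular] / np.sqrt(n_used[regular])
    t_stat[regular] = lfc[regular] / se
    pvals[regular] = 2.0 * stats.t.sf(np.abs(t_stat[regular]), df=n_used[regular] - 1)
    # Degenerate differences: identical-zero -> p = 1; identical-nonzero -> t
    # diverges, floor the p-value instead of propagating NaN.
    with np.errstate(invalid="ignore"):
        exact_null = zero_var & (np.abs(lfc) <= 1e-12)
        exact_shift = zero_var & (np.abs(lfc) > 1e-12)
    t_stat[exact_null] = 0.0
    pvals[exact_null] = 1.0
    t_stat[exact_shift] = np.sign(lfc[exact_shift]) * np.inf
    pvals[exact_shift] = ZERO_VARIANCE_P_FLOOR

    return pd.DataFrame(
        {
            "log2fc": lfc,
            "t_stat": t_stat,
            "p": pvals,
            "n_pairs_used": n_used,
            "unique_peptides": m.unique_peptides.to_numpy(),
            "tested": tested,
        },
        index=m.intensities.index,
    )


def storey_pi0(
    pvals: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    method: str = "smoother",
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Estimate the null proportion pi0 from a p-value vector.

    ``smoother`` (default) fits a cubic polynomial to the raw estimates
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid and
    evaluates it at the largest lambda. ``bootstrap`` picks the lambda whose
    bootstrap mean squared error around the minimum raw estimate is
    smallest. The result is clipped into (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("lambda grid must lie in [0, 1)")
    m = p.size
    raw = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    if method == "smoother":
        if len(lam) >= 4:
            coef = np.polyfit(lam, raw, deg=3)
            pi0 = float(np.polyval(coef, lam.max()))
        else:
            pi0 = float(raw[-1])
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        min_raw = raw.min()
        mse = np.zeros(len(lam))
        for _ in range(n_boot):
            pb = rng.choice(p, size=m, replace=True)
            raw_b = np.array([np.mean(pb > l) / (1.0 - l) for l in lam])
            mse += (raw_b - min_raw) ** 2
        pi0 = float(raw[int(np.argmin(mse))])
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        # Degenerate fit (e.g. very dense signal); fall back to the smallest
        # admissible value so q-values stay defined.
        pi0 = max(raw.min(), 1.0 / m)
        pi0 = min(pi0, 1.0)
    return pi0, raw


def storey_qvalues(
    pvals: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
    pi0_method: str = "smoother",
    seed: int = 0,
) -> tuple[np.ndarray, QValueModel]:
    """Storey q-values for a p-value vector.

    q(i) for the i-th smallest p is min over j >= i of pi0 * m * p(j) / j,
    capped at 1 — i.e. pi0 times the Benjamini-Hochberg step-up quantity, so
    forcing ``pi0=1`` reproduces BH-adjusted p-values exactly. Output order
    matches input order and is monotone non-decreasing in p-rank.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if pi0 is None:
        pi0_hat, raw = storey_pi0(p, lam, method=pi0_method, seed=seed)
    else:
        if not (0.0 < pi0 <= 1.0):
            raise ValueError("pi0 must lie in (0, 1]")
        pi0_hat = float(pi0)
        raw = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0_hat * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    model = QValueModel(pi0=pi0_hat, lambda_grid=lam, pi0_raw=raw, method=pi0_method)
    return q, model


def add_qvalues(
    table: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
    pi0_method: str = "smoother",
) -> tuple[pd.DataFrame, QValueModel]:
    """Attach a ``q`` column to a differential table (tested rows only)."""
    out = table.copy()
    tested = out["tested"].to_numpy(dtype=bool)
    if not tested.any():
        raise ValueError("no tested proteins: cannot estimate q-values")
    q = np.full(len(out), np.nan)
    q[tested], model = storey_qvalues(
        out.loc[tested, "p"].to_numpy(), lambda_grid=lambda_grid, pi0=pi0, pi0_method=pi0_method
    )
    out["q"] = q
    return out, model


def call_significant(
    table: pd.DataFrame,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
    direction: str = "up",
    name: str = "significant",
) -> ProteinSet:
    """Apply the significance filters to a q-annotated differential table.

    ``direction='up'`` (default) returns proteins with log2fc > +lfc_min,
    matching the "robustly increased" reading of the insoluble fraction;
    ``'down'`` the mirrored decrease; ``'both'`` uses |log2fc| > lfc_min.
    """
    if "q" not in table.columns:
        raise ValueError("table has no q column; run add_qvalues first")
    tested = table["tested"].fillna(False).astype(bool)
    base = (
        tested
        & (table["unique_peptides"] >= thresholds.min_peptides)
        & (table["q"] < thresholds.q_max)
    )
    if direction == "up":
        mask = base & (table["log2fc"] > thresholds.lfc_min)
    elif direction == "down":
        mask = base & (table["log2fc"] < -thresholds.lfc_min)
    elif direction == "both":
        mask = base & (table["log2fc"].abs() > thresholds.lfc_min)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ProteinSet(
        name=name,
        members=frozenset(table.index[mask]),
        provenance=(
            f"peptides>={thresholds.min_peptides}, q<{thresholds.q_max}, "
            f"log2fc {direction} {thresholds.lfc_min}"
        ),
    )


@dataclass
class TotalInsolubleResult:
    totals: pd.DataFrame  # columns: pair, condition, total, normalized
    u_stat: float
    p: float
    method: str = field(default="exact")


def total_insoluble_compare(m: QuantMatrix) -> TotalInsolubleResult:
    """Compare total insoluble protein between arms across experiments.

    Each sample's total is the sum of its present intensities; every value
    is normalized to the average of the control totals of its experiment
    (replicate pair). Case vs control normalized totals are compared with a
    two-sided Mann-Whitney U test, exact (full enumeration, tie-aware via
    midranks) at the small sample sizes typical here.
    """
    pairs = m.pair_indices
    if len(pairs) < 2:
        raise ValueError("need at least two experiments per arm")
    rows = []
    for pair in pairs:
        case_total = float(np.nansum(m.intensities[f"case:{pair}"].to_numpy(dtype=float)))
        ctrl_total = float(np.nansum(m.intensities[f"control:{pair}"].to_numpy(dtype=float)))
        if ctrl_total == 0:
            raise ValueError(f"experiment {pair}: control arm has zero total intensity")
        rows.append({"pair": pair, "condition": "case", "total": case_total, "normalized": case_total / ctrl_total})
        rows.append({"pair": pair, "condition": "control", "total": ctrl_total, "normalized": 1.0})
    totals = pd.DataFrame(rows)
    x = totals.loc[totals["condition"] == "case", "normalized"].to_numpy()
    y = totals.loc[totals["condition"] == "control", "normalized"].to_numpy()
    u, p, method = mannwhitney_exact(x, y)
    return TotalInsolubleResult(totals=totals, u_stat=u, p=p, method=method)
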