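"""Gene-set over-representation with BH FDR and the gene-count x FDR score.

One-sided hypergeometric test of a query protein set against each term of a
gene-set collection, restricted to an explicit background universe. FDR is
Benjamini-Hochberg across all tested terms of one namespace (GO-BP is
corrected separately from KEGG, matching per-panel reporting). Results carry
two summary scores: ``score`` = overlap count x FDR-adjusted p (the
product-form presentation) and ``score_neglog`` = count x (-log10 FDR), the
variant in which stronger enrichment gives the larger number (barplot axis).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .setops import ProteinSet
from .tables_io import GeneSetCollection

__all__ = [
    "bh_adjust",
    "enrichment_score",
    "hypergeom_enrich",
    "DEFAULT_MIN_TERM_SIZE",
    "DEFAULT_MAX_TERM_SIZE",
]

DEFAULT_MIN_TERM_SIZE = 3
DEFAULT_MAX_TERM_SIZE = 2000

_NEGLOG_FLOOR = 1e-300  # keeps -log10 finite for underflowed FDRs


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_score(k: int, fdr: float, display: str = "product") -> float:
    """Summary score of one enrichment result.

    ``product`` (default): k x fdr, the literal product of gene count and
    FDR-corrected p-value. ``neglog``: k x (-log10 fdr), which ranks
    stronger enrichment higher.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if not (0.0 <= fdr <= 1.0):
        raise ValueError("fdr must lie in [0, 1]")
    if display == "product":
        return float(k * fdr)
    if display == "neglog":
        return float(k * -np.log10(max(fdr, _NEGLOG_FLOOR)))
    raise ValueError(f"unknown display {display!r}")


def hypergeom_enrich(
    query: ProteinSet | Iterable[str],
    collection: GeneSetCollection,
    background: ProteinSet | Iterable[str],
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    max_term_size: int = DEFAULT_MAX_TERM_SIZE,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each term of ``collection``.

    Term member sets are intersected with ``background`` before testing;
    terms whose intersected size falls outside [min_term_size,
    max_term_size] are skipped. Returns a DataFrame sorted by (fdr, score)
    with columns term_id, term_name, k, K, n, N, p, fdr, score,
    score_neglog. The p-value for a term equals the one-sided Fisher overlap
    p of query vs term members in the same universe.
    """
    q = query.members if isinstance(query, ProteinSet) else frozenset(query)
    bg = background.members if isinstance(background, ProteinSet) else frozenset(background)
    stray = q - bg
    if stray:
        raise ValueError(f"query not contained in background: {sorted(stray)[:10]}")
    N = len(bg)
    n = len(q)
    rows = []
    for gs in collection:
        members = gs.members & bg
        K = len(members)
        if K < min_term_size or K > max_term_size:
            continue
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": gs.term_id, "term_name": gs.name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out["score"] = [enrichment_score(k, f) for k, f in zip(out["k"], out["fdr"])]
        out["score_neglog"] = [
            enrichment_score(k, f, display="neglog") for k, f in zip(out["k"], out["fdr"])
        ]
        out = out.sort_values(["fdr", "score"], kind="mergesort").reset_index(drop=True)
    else:
        for col in ("fdr", "score", "score_neglog"):
            out[col] = []
    return out
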