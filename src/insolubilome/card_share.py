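"""Disease-sharing statistics: GO-BP overlap between proteins and CARDs.

For each protein, its GO biological-process profile is the union of the
term annotations of all its human orthologues. A disease from the
GWAS-derived catalog is "shared" with the protein when at least one GO-BP
term appears in both the disease's risk-term set and the protein's profile.
Per protein this yields: number of shared diseases (split into chronic
age-related diseases, CARDs, and non-age-related diseases) and the number
of the five broad CARD categories hit. Distributions of these counts across
protein sets (CIP, background insoluble, random proteome sample) are
compared with Kruskal-Wallis plus Dunn's post hoc tests, and set-level
disease proportions are normalized by the number of diseases tested per
class.

Term sharing means exact GO term-id equality after orthology mapping; no
ancestor closure is applied unless an ontology parent map is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._stats import KruskalDunnResult, kruskal_dunn
from .setops import ProteinSet
from .tables_io import CARD_CATEGORIES, DiseaseBPCatalog, GeneSetCollection, OrthologyMap

__all__ = [
    "DEFAULT_RANDOM_BACKGROUND_N",
    "DiseaseProportions",
    "protein_bp_profile",
    "share_counts",
    "category_breadth_distribution",
    "set_bp_union",
    "disease_proportion_enrichment",
    "protein_level_disease_proportions",
    "compare_share_distributions",
    "random_background",
]

#: Size of the random reference-proteome sample drawn as the third group.
DEFAULT_RANDOM_BACKGROUND_N = 1600

Annotations = Mapping[str, frozenset[str]]


def _gene_terms(annotations: GeneSetCollection | Annotations) -> Annotations:
    if isinstance(annotations, GeneSetCollection):
        return annotations.gene_to_terms()
    return annotations


def _closure(terms: frozenset[str], parents: Mapping[str, Iterable[str]] | None) -> frozenset[str]:
    if parents is None:
        return terms
    out = set(terms)
    stack = list(terms)
    while stack:
        for parent in parents.get(stack.pop(), ()):  # walk up the ontology
            if parent not in out:
                out.add(parent)
                stack.append(parent)
    return frozenset(out)


def protein_bp_profile(
    protein_id: str,
    orthology: OrthologyMap | None,
    annotations: GeneSetCollection | Annotations,
    ancestor_map: Mapping[str, Iterable[str]] | None = None,
) -> frozenset[str]:
    """GO-BP term profile of one protein: union over its orthologues.

    With ``orthology=None`` the protein id is looked up directly in the
    annotation catalog (already-human identifiers). Unannotated proteins
    yield the empty set.
    """
    gene_terms = _gene_terms(annotations)
    keys = orthology.targets(protein_id) if orthology is not None else frozenset({protein_id})
    terms: set[str] = set()
    for key in keys:
        terms |= gene_terms.get(key, frozenset())
    return _closure(frozenset(terms), ancestor_map)


def share_counts(
    proteins: ProteinSet | Iterable[str],
    catalog: DiseaseBPCatalog,
    annotations: GeneSetCollection | Annotations,
    orthology: OrthologyMap | None = None,
    ancestor_map: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-protein disease-sharing profile.

    Returns a DataFrame indexed by protein id with columns
    ``shared_diseases``, ``shared_ard``, ``shared_nard`` and
    ``categories_hit`` (number of the five broad CARD classes containing at
    least one shared age-related disease).
    """
    if not catalog.diseases:
        raise ValueError("empty disease catalog")
    ids = sorted(proteins.members) if isinstance(proteins, ProteinSet) else list(proteins)
    gene_terms = _gene_terms(annotations)
    records = list(catalog.diseases.values())
    rows = []
    for pid in ids:
        profile = protein_bp_profile(pid, orthology, gene_terms, ancestor_map)
        ard = nard = 0
        cats: set[str] = set()
        if profile:
            for rec in records:
                if rec.terms & profile:
                    if rec.age_related:
                        ard += 1
                        cats.add(rec.category)
                    else:
                        nard += 1
        rows.append(
            {
                "protein_id": pid,
                "shared_diseases": ard + nard,
                "shared_ard": ard,
                "shared_nard": nard,
                "categories_hit": len(cats),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def category_breadth_distribution(profiles: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Fraction of proteins hitting at least c of the 5 broad CARD classes.

    ``profiles`` maps a set label to its share_counts table. Returns one row
    per set with columns ``frac_ge_0`` ... ``frac_ge_5`` (cumulative
    fractions of the categories_hit distribution); ``frac_ge_4`` is the
    "four or more of five broad categories" summary.
    """
    n_cat = len(CARD_CATEGORIES)
    rows = []
    for label, table in profiles.items():
        hits = table["categories_hit"].to_numpy()
        row: dict[str, float | str | int] = {"set": label, "n": len(hits)}
        for c in range(n_cat + 1):
            row[f"frac_ge_{c}"] = float(np.mean(hits >= c)) if len(hits) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")


def set_bp_union(
    proteins: ProteinSet | Iterable[str],
    annotations: GeneSetCollection | Annotations,
    orthology: OrthologyMap | None = None,
    ancestor_map: Mapping[str, Iterable[str]] | None = None,
) -> frozenset[str]:
    """Union of GO-BP profiles over a whole protein set (set-level profile)."""
    ids = proteins.members if isinstance(proteins, ProteinSet) else frozenset(proteins)
    gene_terms = _gene_terms(annotations)
    out: set[str] = set()
    for pid in ids:
        out |= protein_bp_profile(pid, orthology, gene_terms, ancestor_map)
    return frozenset(out)


@dataclass
class DiseaseProportions:
    """Per-class disease-sharing proportions, normalized by class size."""

    ard_shared: int
    ard_tested: int
    nard_shared: int
    nard_tested: int
    ard_proportion: float
    nard_proportion: float
    ratio: float | None  # ARD / non-ARD; None when undefined (0 denominator)


def disease_proportion_enrichment(
    bp_union: frozenset[str] | set[str],
    catalog: DiseaseBPCatalog,
) -> DiseaseProportions:
    """Proportion of diseases per class sharing >=1 BP with a protein set.

    Takes the set-level BP union and reports, separately for age-related and
    non-age-related diseases, (diseases with >=1 shared term) / (diseases
    tested in the class), plus their ratio.
    """
    ard_ids, nard_ids = catalog.ard_ids, catalog.nard_ids
    if not ard_ids or not nard_ids:
        raise ValueError("catalog must contain both age-related and non-age-related diseases")
    bp = frozenset(bp_union)
    ard_shared = sum(1 for d in ard_ids if catalog.diseases[d].terms & bp)
    nard_shared = sum(1 for d in nard_ids if catalog.diseases[d].terms & bp)
    ard_prop = ard_shared / len(ard_ids)
    nard_prop = nard_shared / len(nard_ids)
    ratio = ard_prop / nard_prop if nard_prop > 0 else None
    return DiseaseProportions(
        ard_shared=ard_shared,
        ard_tested=len(ard_ids),
        nard_shared=nard_shared,
        nard_tested=len(nard_ids),
        ard_proportion=ard_prop,
        nard_proportion=nard_prop,
        ratio=ratio,
    )


def protein_level_disease_proportions(
    profile: pd.DataFrame,
    catalog: DiseaseBPCatalog,
) -> DiseaseProportions:
    """Protein-level variant of the normalized disease proportions.

    Instead of the set-level BP union (which saturates for large query
    sets), averages each protein's shared-disease fraction per class:
    mean over proteins of shared_ard / (ARDs tested), likewise for
    non-age-related diseases, and the ratio of those means. The integer
    ``*_shared`` fields carry the rounded mean counts.
    """
    ard_n, nard_n = len(catalog.ard_ids), len(catalog.nard_ids)
    if not ard_n or not nard_n:
        raise ValueError("catalog must contain both age-related and non-age-related diseases")
    mean_ard = float(profile["shared_ard"].mean())
    mean_nard = float(profile["shared_nard"].mean())
    ard_prop = mean_ard / ard_n
    nard_prop = mean_nard / nard_n
    return DiseaseProportions(
        ard_shared=round(mean_ard),
        ard_tested=ard_n,
        nard_shared=round(mean_nard),
        nard_tested=nard_n,
        ard_proportion=ard_prop,
        nard_proportion=nard_prop,
        ratio=ard_prop / nard_prop if nard_prop > 0 else None,
    )


def compare_share_distributions(
    profiles: Mapping[str, pd.DataFrame],
    column: str = "shared_ard",
    p_adjust: str = "bonferroni",
) -> KruskalDunnResult:
    """Kruskal-Wallis + Dunn comparison of per-protein sharing counts.

    ``profiles`` maps set labels (e.g. CIP, background insoluble, random
    proteome) to share_counts tables; ``column`` selects which count to
    compare (default: number of shared CARDs).
    """
    groups = {label: table[column].to_numpy(dtype=float) for label, table in profiles.items()}
    return kruskal_dunn(groups, p_adjust=p_adjust)


def random_background(
    universe_ids: Iterable[str],
    n: int = DEFAULT_RANDOM_BACKGROUND_N,
    seed: int = 0,
    name: str = "random_proteome",
) -> ProteinSet:
    """Seeded random sample of n proteins from the reference proteome."""
    ids = sorted(set(universe_ids))
    if n > len(ids):
        raise ValueError(f"cannot draw {n} proteins from a universe of {len(ids)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return ProteinSet(
        name=name,
        members=frozenset(ids[i] for i in chosen),
        provenance=f"random sample of {n} from {len(ids)} (seed={seed})",
    )
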