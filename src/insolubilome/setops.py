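"""Protein-set algebra, exact overlap testing, and CIP construction.

The core insoluble proteome (CIP) is defined by set algebra: the
intersection of two independently published aging insoluble proteomes gives
a robust "aging core", and its further intersection with the set of proteins
driven insoluble by amyloid-beta gives the CIP. Each overlap is scored with
a one-sided exact hypergeometric (Fisher) test against an explicit universe,
which every result records because the choice of universe changes the
p-value and published reports routinely leave it implicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .tables_io import OrthologyMap

__all__ = [
    "ProteinSet",
    "OverlapTest",
    "CipResult",
    "OrthologProjection",
    "DEFAULT_UNIVERSE_SIZE",
    "fisher_overlap",
    "build_cip",
    "map_orthologs",
]

#: Default Fisher-test universe: approximate C. elegans protein-coding gene
#: count. Always overridable; every OverlapTest records the N actually used.
DEFAULT_UNIVERSE_SIZE = 19_985


@dataclass(frozen=True)
class ProteinSet:
    """A named, provenance-tagged set of protein identifiers."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members

    def intersect(self, other: "ProteinSet", name: str | None = None) -> "ProteinSet":
        return ProteinSet(
            name=name or f"{self.name}&{other.name}",
            members=self.members & other.members,
            provenance=f"intersection of {self.name} and {other.name}",
        )


@dataclass(frozen=True)
class OverlapTest:
    """2x2 overlap of two sets inside a universe of size N.

    ``p_one_sided`` is the exact enrichment tail P(X >= k) of the
    hypergeometric distribution; ``fold_enrichment`` = k*N/(a*b).
    """

    a: int
    b: int
    k: int
    N: int
    p_one_sided: float
    fold_enrichment: float
    p_two_sided: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.a, self.b) and max(self.a, self.b) <= self.N):
            raise ValueError(f"inconsistent 2x2 counts a={self.a} b={self.b} k={self.k} N={self.N}")


def _as_members(s: ProteinSet | Iterable[str]) -> frozenset[str]:
    return s.members if isinstance(s, ProteinSet) else frozenset(s)


def fisher_overlap(
    set_a: ProteinSet | Iterable[str],
    set_b: ProteinSet | Iterable[str],
    universe: int | Iterable[str],
    two_sided: bool = False,
) -> OverlapTest:
    """Exact test of overlap between two protein sets.

    ``universe`` is either an explicit identifier collection (membership of
    both sets is then checked, offenders listed on error) or a bare size N.
    The one-sided enrichment tail P(X >= k) is computed via the log-gamma
    based hypergeometric survival function; a two-sided Fisher p is filled
    in when ``two_sided`` is set.
    """
    A = _as_members(set_a)
    B = _as_members(set_b)
    if isinstance(universe, int):
        N = universe
        if max(len(A), len(B)) > N:
            raise ValueError("set larger than universe size")
    else:
        U = frozenset(universe)
        offenders = sorted((A | B) - U)
        if offenders:
            raise ValueError(f"members outside universe: {offenders[:10]}")
        N = len(U)
    a, b, k = len(A), len(B), len(A & B)
    # P(X >= k), X ~ Hypergeom(N, a, b)
    p_one = float(stats.hypergeom.sf(k - 1, N, a, b))
    p_one = min(max(p_one, 0.0), 1.0)
    fold = float(k * N / (a * b)) if a * b > 0 else float("nan")
    p_two = float("nan")
    if two_sided:
        table = [[k, a - k], [b - k, N - a - b + k]]
        _, p_two = stats.fisher_exact(table, alternative="two-sided")
    return OverlapTest(a=a, b=b, k=k, N=N, p_one_sided=p_one, fold_enrichment=fold, p_two_sided=p_two)


@dataclass
class CipResult:
    aging_core: ProteinSet
    cip: ProteinSet
    test_aging_overlap: OverlapTest
    test_cip_overlap: OverlapTest
    cip_fraction: float  # |cip| / |aging_core|


def build_cip(
    aging_set_1: ProteinSet,
    aging_set_2: ProteinSet,
    abeta_set: ProteinSet,
    universe: int | Iterable[str] = DEFAULT_UNIVERSE_SIZE,
) -> CipResult:
    """Construct the aging core and the core insoluble proteome.

    aging_core = aging_set_1 ∩ aging_set_2 (proteins that reliably become
    insoluble during normal aging in both published datasets); cip =
    aging_core ∩ abeta_set. Both overlaps are tested against ``universe``.
    """
    aging_core = aging_set_1.intersect(aging_set_2, name="aging_core")
    cip = aging_core.intersect(abeta_set, name="cip")
    if not cip.members:
        warnings.warn("CIP intersection is empty", stacklevel=2)
    t_aging = fisher_overlap(aging_set_1, aging_set_2, universe)
    t_cip = fisher_overlap(aging_core, abeta_set, universe)
    fraction = len(cip) / len(aging_core) if len(aging_core) else float("nan")
    return CipResult(
        aging_core=aging_core,
        cip=cip,
        test_aging_overlap=t_aging,
        test_cip_overlap=t_cip,
        cip_fraction=fraction,
    )


@dataclass
class OrthologProjection:
    mapped: ProteinSet
    unmapped: frozenset[str]


def map_orthologs(
    s: ProteinSet,
    m: OrthologyMap,
    policy: str = "expand_all",
) -> OrthologProjection:
    """Project a worm protein set to human identifiers.

    ``expand_all`` (default) maps each source id to all of its targets and
    de-duplicates; ``first_only`` keeps the lexicographically first target.
    Unmapped source ids are reported, never fatal.
    """
    if policy not in ("expand_all", "first_only"):
        raise ValueError(f"unknown policy {policy!r}")
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for src in s.members:
        targets = m.targets(src)
        if not targets:
            unmapped.add(src)
        elif policy == "expand_all":
            mapped |= targets
        else:
            mapped.add(min(targets))
    return OrthologProjection(
        mapped=ProteinSet(
            name=f"{s.name}_human",
            members=frozenset(mapped),
            provenance=f"orthology projection ({policy}) of {s.name}",
        ),
        unmapped=frozenset(unmapped),
    )
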