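"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design end to end without any downloads:

* a paired insoluble-fraction quantification experiment (case = amyloid-beta
  expressing animals, control = background genotype) with four biological
  replicate pairs, a spiked subset of proteins whose case intensities carry
  a known log2 fold-change, completely-at-random missing values and
  per-protein unique-peptide counts;
* a GO-BP annotation world: a worm-to-human orthology map, a human-keyed
  term catalog, and a disease catalog of age-related (default 38, in 5
  broad categories) and non-age-related (default 12) diseases, with a
  planted protein subset whose annotations are biased toward the
  age-related disease term pools by a configurable ``sharing_boost``;
* biophysical score tables with location-shifted distributions per set;
* expression time courses over adult days 2-10 with planted monotone trends.

Every generator is a pure function of its parameters including the seed.
Intensities are generated on the log2 scale and exponentiated (lognormal),
giving strictly positive values with multiplicative noise; missingness is
completely at random (intensity-dependent dropout is deliberately not
modeled); peptide counts are a shifted Poisson (minimum 1) independent of
intensity, since only the >=2-peptide filter consumes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    CARD_CATEGORIES,
    NON_ARD_CATEGORY,
    DiseaseBPCatalog,
    DiseaseRecord,
    ExpressionSeries,
    GeneSet,
    GeneSetCollection,
    OrthologyMap,
    QuantMatrix,
    ScoreTable,
)

__all__ = [
    "QuantSimParams",
    "GroundTruth",
    "gen_quant_experiment",
    "gen_aging_lists",
    "gen_annotation_catalog",
    "gen_score_table",
    "gen_expression_series",
    "DEFAULT_SCORE_DISTRIBUTIONS",
]


@dataclass(frozen=True)
class QuantSimParams:
    """Parameters of the paired quantification simulator.

    Defaults mirror the study design: 1704 quantified proteins across four
    biological replicate pairs with roughly a third of the proteome spiked
    to higher insolubility in the case arm. ``spike_log2fc`` is the mean
    planted effect in log2 units; individual spiked proteins scatter around
    it with spread ``spike_log2fc_sd`` (set to 0 to plant exact effects).
    ``baseline_log_mean``/``baseline_log_sd`` describe log2 peak areas,
    ``noise_sd`` the replicate-level log2 noise.
    """

    n_proteins: int = 1704
    n_pairs: int = 4
    spike_fraction: float = 0.348
    spike_log2fc: float = 2.0
    spike_log2fc_sd: float = 0.25
    baseline_log_mean: float = 20.0
    baseline_log_sd: float = 2.0
    noise_sd: float = 0.2
    missing_rate: float = 0.05
    peptide_count_mean: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spike_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 replicate pairs")
        if self.n_proteins < 1:
            raise ValueError("need at least 1 protein")
        finite = (
            self.spike_log2fc,
            self.spike_log2fc_sd,
            self.baseline_log_mean,
            self.baseline_log_sd,
            self.noise_sd,
            self.peptide_count_mean,
        )
        if not np.all(np.isfinite(finite)):
            raise ValueError("all simulation parameters must be finite")
        if self.noise_sd < 0 or self.spike_log2fc_sd < 0 or self.baseline_log_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        if self.peptide_count_mean < 1:
            raise ValueError("peptide_count_mean must be >= 1")


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    spiked_proteins: frozenset[str] = frozenset()
    true_log2fc: dict[str, float] = field(default_factory=dict)
    planted_shared_proteins: frozenset[str] = frozenset()
    planted_trend_genes: dict[str, int] = field(default_factory=dict)  # gene -> sign

    def to_frame(self) -> pd.DataFrame:
        """Flat sidecar representation (one row per planted fact)."""
        rows = [
            {"kind": "spike", "identifier": p, "value": self.true_log2fc.get(p, np.nan)}
            for p in sorted(self.spiked_proteins)
        ]
        rows += [
            {"kind": "shared", "identifier": p, "value": np.nan}
            for p in sorted(self.planted_shared_proteins)
        ]
        rows += [
            {"kind": "trend", "identifier": g, "value": s}
            for g, s in sorted(self.planted_trend_genes.items())
        ]
        return pd.DataFrame(rows, columns=["kind", "identifier", "value"])


def protein_ids(n: int, prefix: str = "P") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def gen_quant_experiment(params: QuantSimParams) -> tuple[QuantMatrix, GroundTruth]:
    """Simulate one paired case/control insoluble-fraction experiment.

    Per protein i and pair r, log2 intensity is baseline_i + pair-shared
    term + (planted effect for spiked case samples) + independent noise;
    intensities are 2 to that power. Spiked proteins thus have their case
    intensities multiplied by 2^(true log2fc) before noise. Missing values
    are injected completely at random. Identical params give identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    n, R = params.n_proteins, params.n_pairs
    ids = protein_ids(n)
    baseline = rng.normal(params.baseline_log_mean, params.baseline_log_sd, n)

    n_spike = int(round(params.spike_fraction * n))
    if params.spike_fraction > 0 and n_spike < 1:
        warnings.warn("spike_fraction too small for any spike; generating none", stacklevel=2)
    spike_idx = rng.choice(n, size=n_spike, replace=False) if n_spike else np.array([], dtype=int)
    true_lfc = np.zeros(n)
    if n_spike:
        true_lfc[spike_idx] = rng.normal(params.spike_log2fc, params.spike_log2fc_sd, n_spike)

    pair_effect = rng.normal(0.0, params.noise_sd, size=(n, R))
    data: dict[str, np.ndarray] = {}
    for r in range(1, R + 1):
        shared = baseline + pair_effect[:, r - 1]
        case_log = shared + true_lfc + rng.normal(0.0, params.noise_sd, n)
        ctrl_log = shared + rng.normal(0.0, params.noise_sd, n)
        data[f"case:{r}"] = 2.0 ** case_log
        data[f"control:{r}"] = 2.0 ** ctrl_log
    intens = pd.DataFrame(data, index=ids)
    if params.missing_rate > 0:
        mask = rng.random(size=intens.shape) < params.missing_rate
        intens = intens.mask(mask)
    peptides = pd.Series(
        1 + rng.poisson(params.peptide_count_mean - 1.0, n), index=ids, name="unique_peptides"
    )
    truth = GroundTruth(
        spiked_proteins=frozenset(ids[i] for i in spike_idx),
        true_log2fc={ids[i]: float(true_lfc[i]) for i in spike_idx},
    )
    return QuantMatrix(intensities=intens, unique_peptides=peptides), truth


def gen_aging_lists(
    truth: GroundTruth,
    all_ids: Sequence[str],
    core_size: int = 457,
    core_spiked_fraction: float = 0.667,
    extra_per_list: int = 300,
    seed: int = 0,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Simulate two published aging insoluble-proteome lists.

    Both lists contain a common "aging core" of ``core_size`` proteins —
    of which a ``core_spiked_fraction`` are drawn from the spiked
    (case-responsive) proteins, so that roughly two-thirds of the aging
    core also responds in the paired experiment — plus disjoint list-specific
    extras, so list1 ∩ list2 equals the core exactly. Returns
    (list1, list2, core).
    """
    rng = np.random.default_rng(seed)
    spiked = sorted(truth.spiked_proteins)
    others = sorted(set(all_ids) - truth.spiked_proteins)
    n_core_spiked = int(round(core_size * core_spiked_fraction))
    if n_core_spiked > len(spiked) or core_size - n_core_spiked > len(others):
        raise ValueError("core_size incompatible with the available spiked/background proteins")
    core = set(rng.choice(spiked, size=n_core_spiked, replace=False))
    core |= set(rng.choice(others, size=core_size - n_core_spiked, replace=False))
    remaining = sorted(set(all_ids) - core)
    if 2 * extra_per_list > len(remaining):
        raise ValueError("not enough proteins left for disjoint list-specific extras")
    extras = rng.choice(remaining, size=2 * extra_per_list, replace=False)
    list1 = frozenset(core) | set(extras[:extra_per_list])
    list2 = frozenset(core) | set(extras[extra_per_list:])
    return frozenset(list1), frozenset(list2), frozenset(core)


def gen_annotation_catalog(
    n_proteins: int,
    n_terms: int = 300,
    n_diseases_ard: int = 38,
    n_diseases_nard: int = 12,
    n_categories: int = 5,
    planted_set: Iterable[str] = (),
    sharing_boost: float = 1.0,
    seed: int = 0,
    terms_per_disease: int = 8,
    terms_per_protein: int = 12,
) -> tuple[GeneSetCollection, OrthologyMap, DiseaseBPCatalog, GroundTruth]:
    """Simulate the GWAS-analysis inputs with planted disease sharing.

    Builds a worm-to-human orthology (1-to-k, k in {1,2,3}), a GO-BP term
    vocabulary, a disease catalog (age-related diseases cycled over the
    broad categories, plus non-age-related diseases), and per-human-gene
    annotations. Proteins in ``planted_set`` draw their annotation terms
    with probability multiplied by ``sharing_boost`` for terms belonging to
    any age-related disease's pool, so with boost 1 planted and background
    proteins are exchangeable.
    """
    if n_terms < 1:
        raise ValueError("empty term vocabulary")
    if sharing_boost < 1:
        raise ValueError("sharing_boost must be >= 1")
    if not (1 <= n_categories <= len(CARD_CATEGORIES)):
        raise ValueError(f"n_categories must lie in [1, {len(CARD_CATEGORIES)}]")
    ids = protein_ids(n_proteins)
    planted = frozenset(planted_set)
    stray = planted - set(ids)
    if stray:
        raise ValueError(f"planted_set not within generated protein ids: {sorted(stray)[:5]}")

    rng = np.random.default_rng(seed)
    vocab = np.array([f"GO:{i:07d}" for i in range(n_terms)])

    # Orthology: each worm protein maps to 1-3 synthetic human symbols.
    mapping: dict[str, frozenset[str]] = {}
    k_targets = rng.integers(1, 4, size=n_proteins)
    for pid, k in zip(ids, k_targets):
        mapping[pid] = frozenset(f"H{pid}_{j}" for j in range(int(k)))
    orthology = OrthologyMap(mapping)

    # Disease catalog: term pools drawn without replacement per disease.
    diseases: dict[str, DiseaseRecord] = {}
    pool_size = min(terms_per_disease, n_terms)
    for i in range(n_diseases_ard):
        did = f"ARD{i:03d}"
        terms = frozenset(rng.choice(vocab, size=pool_size, replace=False))
        diseases[did] = DiseaseRecord(
            disease_id=did,
            name=f"age-related disease {i}",
            category=CARD_CATEGORIES[i % n_categories],
            age_related=True,
            terms=terms,
        )
    for i in range(n_diseases_nard):
        did = f"NARD{i:03d}"
        terms = frozenset(rng.choice(vocab, size=pool_size, replace=False))
        diseases[did] = DiseaseRecord(
            disease_id=did,
            name=f"non-age-related disease {i}",
            category=NON_ARD_CATEGORY,
            age_related=False,
            terms=terms,
        )
    catalog = DiseaseBPCatalog(diseases)

    # Annotations keyed by human symbol; planted proteins up-weight terms in
    # the union of the age-related disease pools.
    ard_union = set()
    for d in catalog.ard_ids:
        ard_union |= catalog.diseases[d].terms
    in_ard = np.isin(vocab, sorted(ard_union))
    base_w = np.ones(n_terms)
    boost_w = np.where(in_ard, sharing_boost, 1.0)
    term_members: dict[str, set[str]] = {}
    n_draw = min(terms_per_protein, n_terms)
    for pid in ids:
        w = boost_w if pid in planted else base_w
        p = w / w.sum()
        for human in sorted(mapping[pid]):
            terms = rng.choice(vocab, size=n_draw, replace=False, p=p)
            for t in terms:
                term_members.setdefault(str(t), set()).add(human)
    sets = {
        t: GeneSet(term_id=t, name=f"biological process {t[3:]}", members=frozenset(members))
        for t, members in sorted(term_members.items())
    }
    collection = GeneSetCollection(namespace="GO-BP", sets=sets)
    truth = GroundTruth(planted_shared_proteins=planted)
    return collection, orthology, catalog, truth


#: Per-score (location, scale) of the simulated distributions. sigma_f is
#: parameterised on log10 (centre 10^-2, spread one decade), roughly the
#: scale on which supersaturation scores spread over several decades.
DEFAULT_SCORE_DISTRIBUTIONS: Mapping[str, tuple[float, float]] = {
    "camsol": (0.0, 1.0),
    "zyggregator": (0.0, 1.0),
    "catgranule": (0.0, 1.0),
    "sigma_f_log10": (-2.0, 1.0),
}


def gen_score_table(
    sets_with_shifts: Mapping[str, tuple[Sequence[str], float]],
    distribution_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> ScoreTable:
    """Simulate a biophysical score table with set-wise location shifts.

    ``sets_with_shifts`` maps a set label to (protein ids, shift); each
    protein's scores are drawn from the base location family shifted by its
    set's shift — on the natural scale for camsol/zyggregator/catgranule and
    on log10 for sigma_f (a shift of 1 multiplies sigma_f by 10). Proteins
    may appear in only one set.
    """
    dist = dict(DEFAULT_SCORE_DISTRIBUTIONS)
    if distribution_params:
        unknown = set(distribution_params) - set(dist)
        if unknown:
            raise KeyError(f"unknown set identifier(s) in distribution_params: {sorted(unknown)}")
        dist.update(distribution_params)
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows = []
    for label in sets_with_shifts:
        ids, shift = sets_with_shifts[label]
        if not np.isfinite(shift):
            raise ValueError(f"shift for set {label!r} is not finite")
        for pid in ids:
            if pid in seen:
                raise ValueError(f"protein {pid!r} assigned to more than one set")
            seen.add(pid)
            loc_c, sd_c = dist["camsol"]
            loc_z, sd_z = dist["zyggregator"]
            loc_g, sd_g = dist["catgranule"]
            loc_s, sd_s = dist["sigma_f_log10"]
            rows.append(
                {
                    "protein_id": pid,
                    "camsol": rng.normal(loc_c + shift, sd_c),
                    "zyggregator": rng.normal(loc_z + shift, sd_z),
                    "catgranule": rng.normal(loc_g + shift, sd_g),
                    "sigma_f": 10.0 ** rng.normal(loc_s + shift, sd_s),
                }
            )
    return ScoreTable(pd.DataFrame(rows).set_index("protein_id"))


def gen_expression_series(
    n_genes: int,
    timepoints: Sequence[int] = tuple(range(2, 11)),
    trend_fraction: float = 0.1,
    trend_slope: float = 0.5,
    seed: int = 0,
    noise_sd: float = 0.25,
    dataset_id: str = "sim",
) -> tuple[ExpressionSeries, GroundTruth]:
    """Simulate gene expression time courses with planted monotone trends.

    Planted genes (a ``trend_fraction`` of all genes, split equally between
    increasing and decreasing) change linearly by ``trend_slope`` per day of
    adult age plus Gaussian noise; the rest are flat plus noise. Ages
    default to adult days 2 through 10.
    """
    tp = np.asarray(timepoints, dtype=float)
    if len(tp) < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(np.diff(tp) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if not (0.0 <= trend_fraction <= 1.0):
        raise ValueError("trend_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_trend = int(round(trend_fraction * n_genes))
    trend_idx = rng.choice(n_genes, size=n_trend, replace=False) if n_trend else np.array([], dtype=int)
    signs = np.where(np.arange(n_trend) % 2 == 0, 1, -1)
    if n_trend:
        signs = signs[rng.permutation(n_trend)]
    slope = np.zeros(n_genes)
    slope[trend_idx] = signs * trend_slope
    baseline = rng.normal(8.0, 1.0, n_genes)
    rows = []
    for gi, gene in enumerate(genes):
        values = baseline[gi] + slope[gi] * (tp - tp[0]) + rng.normal(0.0, noise_sd, len(tp))
        for day, val in zip(tp, values):
            rows.append(
                {"gene_id": gene, "age_day": int(day), "value": float(val), "dataset_id": dataset_id}
            )
    truth = GroundTruth(
        planted_trend_genes={genes[i]: int(np.sign(slope[i])) for i in trend_idx}
    )
    return ExpressionSeries(pd.DataFrame(rows)), truth
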