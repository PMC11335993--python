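"""Disease-sharing statistic: profiles, counts, breadth, proportions."""

import numpy as np
import pandas as pd
import pytest

from insolubilome.card_share import (
    category_breadth_distribution,
    compare_share_distributions,
    disease_proportion_enrichment,
    protein_bp_profile,
    random_background,
    set_bp_union,
    share_counts,
)
from insolubilome.tables_io import (
    DiseaseBPCatalog,
    DiseaseRecord,
    NON_ARD_CATEGORY,
    OrthologyMap,
)


def make_catalog(ard_terms: list[set[str]], nard_terms: list[set[str]]) -> DiseaseBPCatalog:
    cats = ("neurodegenerative", "metabolic", "cancer", "cardiovascular", "other")
    diseases = {}
    for i, terms in enumerate(ard_terms):
        diseases[f"A{i}"] = DiseaseRecord(f"A{i}", f"ard {i}", cats[i % 5], True, frozenset(terms))
    for i, terms in enumerate(nard_terms):
        diseases[f"N{i}"] = DiseaseRecord(f"N{i}", f"nard {i}", NON_ARD_CATEGORY, False, frozenset(terms))
    return DiseaseBPCatalog(diseases)


class TestProfiles:
    def test_unannotated_protein_has_empty_profile(self):
        assert protein_bp_profile("pX", None, {}) == frozenset()

    def test_profile_is_union_over_orthologues(self):
        orth = OrthologyMap({"w": frozenset({"H1", "H2"})})
        ann = {"H1": frozenset({"T1", "T2"}), "H2": frozenset({"T2", "T3"})}
        assert protein_bp_profile("w", orth, ann) == frozenset({"T1", "T2", "T3"})

    def test_profile_matches_bruteforce_on_random_world(self, annotation_world):
        collection, orthology, _, _ = annotation_world
        gene_terms = collection.gene_to_terms()
        rng = np.random.default_rng(3)
        for pid in rng.choice(sorted(orthology.mapping), 25, replace=False):
            naive = set()
            for h in orthology.mapping[pid]:
                naive |= set(gene_terms.get(h, ()))
            assert protein_bp_profile(pid, orthology, collection) == frozenset(naive)

    def test_ancestor_closure_adds_parents_when_supplied(self):
        ann = {"H": frozenset({"T1"})}
        parents = {"T1": ["T0"], "T0": ["Troot"]}
        prof = protein_bp_profile("H", None, ann, ancestor_map=parents)
        assert prof == frozenset({"T1", "T0", "Troot"})


class TestShareCounts:
    def test_toy_catalog_counts_by_term_intersection(self):
        catalog = make_catalog([{"T1"}, {"T2"}, {"T9"}], [{"T9"}])
        ann = {"p1": frozenset({"T1", "T2"}), "p2": frozenset()}
        prof = share_counts(["p1", "p2"], catalog, ann)
        assert prof.loc["p1", "shared_diseases"] == 2
        assert prof.loc["p1", "shared_ard"] == 2 and prof.loc["p1", "shared_nard"] == 0
        assert prof.loc["p1", "categories_hit"] == 2
        assert prof.loc["p2"].sum() == 0  # empty profile: all counts zero

    def test_counts_match_exhaustive_double_loop(self, annotation_world):
        collection, orthology, catalog, _ = annotation_world
        proteins = sorted(orthology.mapping)[:50]
        prof = share_counts(proteins, catalog, collection, orthology)
        gene_terms = collection.gene_to_terms()
        for pid in proteins:
            profile = set()
            for h in orthology.mapping[pid]:
                profile |= set(gene_terms.get(h, ()))
            ard = sum(
                1
                for d in catalog.diseases.values()
                if d.age_related and set(d.terms) & profile
            )
            nard = sum(
                1
                for d in catalog.diseases.values()
                if not d.age_related and set(d.terms) & profile
            )
            cats = {
                d.category
                for d in catalog.diseases.values()
                if d.age_related and set(d.terms) & profile
            }
            assert prof.loc[pid, "shared_ard"] == ard
            assert prof.loc[pid, "shared_nard"] == nard
            assert prof.loc[pid, "shared_diseases"] == ard + nard
            assert prof.loc[pid, "categories_hit"] == len(cats)

    def test_adding_a_term_never_decreases_counts(self, annotation_world):
        collection, orthology, catalog, _ = annotation_world
        pid = sorted(orthology.mapping)[0]
        gene_terms = dict(collection.gene_to_terms())
        base = share_counts([pid], catalog, gene_terms, orthology).loc[pid]
        human = sorted(orthology.mapping[pid])[0]
        some_disease = next(iter(catalog.diseases.values()))
        extra = next(iter(some_disease.terms))
        gene_terms[human] = gene_terms.get(human, frozenset()) | {extra}
        grown = share_counts([pid], catalog, gene_terms, orthology).loc[pid]
        assert (grown >= base).all()

    def test_removing_a_disease_never_increases_counts(self, annotation_world):
        collection, orthology, catalog, _ = annotation_world
        proteins = sorted(orthology.mapping)[:20]
        full = share_counts(proteins, catalog, collection, orthology)
        smaller = DiseaseBPCatalog(
            {d: r for d, r in list(catalog.diseases.items())[:-5]}
        )
        reduced = share_counts(proteins, smaller, collection, orthology)
        assert (reduced["shared_diseases"] <= full["shared_diseases"]).all()
        assert (reduced["shared_ard"] <= full["shared_ard"]).all()

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            share_counts(["p"], DiseaseBPCatalog({}), {})


class TestBreadthAndProportions:
    def test_all_zero_profiles_all_mass_at_zero(self):
        prof = pd.DataFrame({"categories_hit": [0, 0, 0]}, index=list("abc"))
        dist = category_breadth_distribution({"s": prof})
        assert dist.loc["s", "frac_ge_0"] == 1.0
        assert dist.loc["s", "frac_ge_1"] == 0.0

    def test_mixed_profile_fraction_ge4(self):
        prof = pd.DataFrame({"categories_hit": [5, 4, 3, 0, 0]})
        dist = category_breadth_distribution({"s": prof})
        assert dist.loc["s", "frac_ge_4"] == pytest.approx(0.4)
        assert dist.loc["s", "frac_ge_5"] == pytest.approx(0.2)

    def test_proportions_toy_arithmetic(self):
        # 19 of 38 CARDs and 3 of 12 non-ARDs share -> 0.5 vs 0.25, ratio 2
        ard = [{f"T{i}"} for i in range(38)]
        nard = [{f"U{i}"} for i in range(12)]
        catalog = make_catalog(ard, nard)
        bp = frozenset({f"T{i}" for i in range(19)} | {f"U{i}" for i in range(3)})
        res = disease_proportion_enrichment(bp, catalog)
        assert (res.ard_shared, res.nard_shared) == (19, 3)
        assert res.ard_proportion == pytest.approx(0.5)
        assert res.nard_proportion == pytest.approx(0.25)
        assert res.ratio == pytest.approx(2.0)

    def test_no_sharing_gives_zero_proportions_and_undefined_ratio(self):
        catalog = make_catalog([{"T1"}], [{"T2"}])
        res = disease_proportion_enrichment(frozenset({"ZZ"}), catalog)
        assert res.ard_proportion == 0.0 and res.nard_proportion == 0.0
        assert res.ratio is None

    def test_universal_sharing_gives_unit_ratio(self):
        catalog = make_catalog([{"T"}] * 4, [{"T"}] * 2)
        res = disease_proportion_enrichment(frozenset({"T"}), catalog)
        assert res.ard_proportion == 1.0 and res.ratio == pytest.approx(1.0)

    def test_protein_level_proportions_average_per_protein_fractions(self):
        from insolubilome.card_share import protein_level_disease_proportions

        catalog = make_catalog([{f"T{i}"} for i in range(4)], [{f"U{i}"} for i in range(2)])
        prof = pd.DataFrame(
            {"shared_ard": [2, 4], "shared_nard": [1, 1]}, index=["p1", "p2"]
        )
        res = protein_level_disease_proportions(prof, catalog)
        assert res.ard_proportion == pytest.approx(3 / 4)  # mean 3 of 4 ARDs
        assert res.nard_proportion == pytest.approx(1 / 2)
        assert res.ratio == pytest.approx(1.5)

    def test_set_bp_union_is_union_of_profiles(self):
        ann = {"a": frozenset({"T1"}), "b": frozenset({"T2", "T3"})}
        assert set_bp_union(["a", "b", "c"], ann) == frozenset({"T1", "T2", "T3"})


class TestComparisonsAndBackground:
    def test_identical_groups_give_h_zero(self):
        prof = pd.DataFrame({"shared_ard": [2.0, 2.0, 2.0]})
        res = compare_share_distributions({"a": prof, "b": prof.copy(), "c": prof.copy()})
        assert res.H == 0.0 and res.p == 1.0

    def test_h_matches_direct_rank_formula(self):
        groups = {
            "a": pd.DataFrame({"shared_ard": [1.0, 2.0, 3.0]}),
            "b": pd.DataFrame({"shared_ard": [4.0, 5.0, 6.0]}),
            "c": pd.DataFrame({"shared_ard": [7.0, 8.0, 9.0]}),
        }
        res = compare_share_distributions(groups)
        N = 9
        rank_sums = [6, 15, 24]
        H = 12.0 / (N * (N + 1)) * sum(r * r / 3 for r in rank_sums) - 3 * (N + 1)
        assert res.H == pytest.approx(H, rel=1e-12)
        assert set(res.pairwise["group_a"]) <= set(groups)
        assert len(res.pairwise) == 3  # all unordered pairs

    def test_planted_sharing_separates_from_background(self, annotation_world):
        collection, orthology, catalog, truth = annotation_world
        planted = sorted(truth.planted_shared_proteins)
        background = sorted(set(orthology.mapping) - truth.planted_shared_proteins)[:150]
        profiles = {
            "planted": share_counts(planted, catalog, collection, orthology),
            "background": share_counts(background, catalog, collection, orthology),
        }
        med_p = profiles["planted"]["shared_ard"].median()
        med_b = profiles["background"]["shared_ard"].median()
        assert med_p > med_b
        res = compare_share_distributions(profiles)
        assert res.p < 0.01

    def test_random_background_is_seeded_and_sized(self):
        universe = [f"P{i:05d}" for i in range(500)]
        s1 = random_background(universe, n=100, seed=17)
        s2 = random_background(universe, n=100, seed=17)
        s3 = random_background(universe, n=100, seed=18)
        assert s1.members == s2.members and s1.members != s3.members
        assert len(s1) == 100
        with pytest.raises(ValueError, match="cannot draw"):
            random_background(universe, n=501, seed=0)
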