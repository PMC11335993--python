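"""Generators: determinism, planted-signal recovery, parameter validation."""

import numpy as np
import pandas as pd
import pytest

from insolubilome.differential import paired_log_fold_change
from insolubilome.synthetic_data import (
    DEFAULT_SCORE_DISTRIBUTIONS,
    QuantSimParams,
    gen_aging_lists,
    gen_annotation_catalog,
    gen_expression_series,
    gen_quant_experiment,
    gen_score_table,
)


class TestQuantExperiment:
    def test_no_signal_no_noise_gives_identical_arms(self):
        params = QuantSimParams(
            n_proteins=50, spike_fraction=0.0, noise_sd=0.0, missing_rate=0.0, seed=4
        )
        m, truth = gen_quant_experiment(params)
        assert not truth.spiked_proteins
        for r in range(1, params.n_pairs + 1):
            np.testing.assert_array_equal(
                m.intensities[f"case:{r}"], m.intensities[f"control:{r}"]
            )
        table = paired_log_fold_change(m)
        np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)

    def test_identical_seed_identical_output(self):
        params = QuantSimParams(n_proteins=100, spike_fraction=0.1, spike_log2fc=2, seed=7)
        m1, t1 = gen_quant_experiment(params)
        m2, t2 = gen_quant_experiment(params)
        pd.testing.assert_frame_equal(m1.intensities, m2.intensities)
        pd.testing.assert_series_equal(m1.unique_peptides, m2.unique_peptides)
        assert t1.spiked_proteins == t2.spiked_proteins
        assert t1.true_log2fc == t2.true_log2fc

    def test_spiked_mean_log2fc_recovered(self):
        params = QuantSimParams(
            n_proteins=2000, spike_log2fc=3.0, noise_sd=0.2, missing_rate=0.0, seed=13
        )
        m, truth = gen_quant_experiment(params)
        table = paired_log_fold_change(m)
        observed = table.loc[sorted(truth.spiked_proteins), "log2fc"].mean()
        assert observed == pytest.approx(3.0, abs=0.1)

    def test_missingness_and_peptide_floor(self):
        params = QuantSimParams(n_proteins=3000, missing_rate=0.2, seed=5)
        m, _ = gen_quant_experiment(params)
        frac = float(m.intensities.isna().to_numpy().mean())
        assert frac == pytest.approx(0.2, abs=0.02)
        assert int(m.unique_peptides.min()) >= 1

    def test_zero_spike_fraction_warns_when_rounding_to_none(self):
        with pytest.warns(UserWarning, match="spike_fraction"):
            gen_quant_experiment(
                QuantSimParams(n_proteins=10, spike_fraction=0.01, seed=1)
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spike_fraction": 1.5},
            {"missing_rate": -0.1},
            {"n_pairs": 1},
            {"noise_sd": -1.0},
            {"spike_log2fc": float("inf")},
            {"peptide_count_mean": 0.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            QuantSimParams(n_proteins=10, **kwargs)


class TestAgingLists:
    def test_intersection_is_exactly_the_core(self):
        params = QuantSimParams(n_proteins=1704, seed=3)
        m, truth = gen_quant_experiment(params)
        l1, l2, core = gen_aging_lists(truth, m.protein_ids, seed=9)
        assert l1 & l2 == core
        assert len(core) == 457
        # roughly two-thirds of the core responds in the paired experiment
        assert len(core & truth.spiked_proteins) == round(457 * 0.667)

    def test_incompatible_core_size_rejected(self):
        params = QuantSimParams(n_proteins=100, spike_fraction=0.1, seed=3)
        m, truth = gen_quant_experiment(params)
        with pytest.raises(ValueError, match="core_size"):
            gen_aging_lists(truth, m.protein_ids, core_size=457)


class TestAnnotationCatalog:
    def test_catalog_counts_and_categories(self, annotation_world):
        _, _, catalog, _ = annotation_world
        assert catalog.counts() == (38, 12)
        cats = {catalog.diseases[d].category for d in catalog.ard_ids}
        assert len(cats) == 5

    def test_deterministic_under_seed(self):
        a = gen_annotation_catalog(n_proteins=60, planted_set={"P00001"}, sharing_boost=5, seed=2)
        b = gen_annotation_catalog(n_proteins=60, planted_set={"P00001"}, sharing_boost=5, seed=2)
        assert {t: s.members for t, s in a[0].sets.items()} == {
            t: s.members for t, s in b[0].sets.items()
        }
        assert a[1].mapping == b[1].mapping
        assert {d: r.terms for d, r in a[2].diseases.items()} == {
            d: r.terms for d, r in b[2].diseases.items()
        }

    def test_boost_one_is_exchangeable_with_background(self):
        from insolubilome.card_share import share_counts

        planted = frozenset(f"P{i:05d}" for i in range(60))
        collection, orthology, catalog, _ = gen_annotation_catalog(
            n_proteins=240, planted_set=planted, sharing_boost=1.0, seed=11
        )
        prof = share_counts(sorted(orthology.mapping), catalog, collection, orthology)
        med_p = prof.loc[sorted(planted), "shared_ard"].median()
        background = sorted(set(orthology.mapping) - planted)
        med_b = prof.loc[background, "shared_ard"].median()
        # no planted signal: medians agree within sampling error
        assert abs(med_p - med_b) <= 3

    def test_boost_twenty_raises_planted_median(self, annotation_world):
        from insolubilome.card_share import share_counts

        collection, orthology, catalog, truth = annotation_world
        planted = sorted(truth.planted_shared_proteins)
        background = sorted(set(orthology.mapping) - truth.planted_shared_proteins)[:100]
        prof_p = share_counts(planted, catalog, collection, orthology)
        prof_b = share_counts(background, catalog, collection, orthology)
        assert prof_p["shared_ard"].median() > prof_b["shared_ard"].median()

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            gen_annotation_catalog(n_proteins=10, n_terms=0)

    def test_planted_ids_must_exist(self):
        with pytest.raises(ValueError, match="planted_set"):
            gen_annotation_catalog(n_proteins=10, planted_set={"NOPE"})


class TestScoreTable:
    def test_single_protein_per_set_one_row_each(self):
        t = gen_score_table({"a": (["p1"], 0.0), "b": (["p2"], 1.0)}, seed=0)
        assert len(t.scores) == 2

    def test_deterministic_under_seed(self):
        spec = {"a": (["p1", "p2"], 0.5), "b": (["p3"], 0.0)}
        t1 = gen_score_table(spec, seed=6)
        t2 = gen_score_table(spec, seed=6)
        pd.testing.assert_frame_equal(t1.scores, t2.scores)

    def test_log10_shift_multiplies_sigma_f(self):
        n = 400
        t = gen_score_table(
            {
                "hi": ([f"h{i}" for i in range(n)], 1.97),
                "lo": ([f"l{i}" for i in range(n)], 0.0),
            },
            distribution_params={"sigma_f_log10": (-2.0, 0.01)},
            seed=3,
        )
        hi = t.scores.loc[[f"h{i}" for i in range(n)], "sigma_f"].mean()
        lo = t.scores.loc[[f"l{i}" for i in range(n)], "sigma_f"].mean()
        assert hi / lo == pytest.approx(10**1.97, rel=0.02)

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(ValueError, match="more than one set"):
            gen_score_table({"a": (["p1"], 0.0), "b": (["p1"], 1.0)})

    def test_unknown_distribution_key_rejected(self):
        with pytest.raises(KeyError, match="unknown set identifier"):
            gen_score_table({"a": (["p1"], 0.0)}, distribution_params={"bogus": (0, 1)})


class TestExpressionSeries:
    def test_deterministic_and_day_range(self):
        e1, t1 = gen_expression_series(n_genes=20, seed=8)
        e2, t2 = gen_expression_series(n_genes=20, seed=8)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        assert t1.planted_trend_genes == t2.planted_trend_genes
        assert set(e1.values["age_day"]) == set(range(2, 11))

    def test_equal_up_down_split(self):
        _, truth = gen_expression_series(n_genes=100, trend_fraction=0.4, seed=2)
        signs = list(truth.planted_trend_genes.values())
        assert abs(sum(signs)) <= 1  # near-perfect balance by construction

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"timepoints": (2, 5)}, "3 timepoints"),
            ({"timepoints": (2, 2, 5)}, "strictly increasing"),
            ({"trend_fraction": 1.2}, "trend_fraction"),
        ],
    )
    def test_invalid_series_params_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            gen_expression_series(n_genes=5, **kwargs)
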