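# insolubilome

Analysis pipeline for SDS-insoluble-fraction proteomics of a *C. elegans*
amyloid-beta (Aβ) model, and for asking what the proteins that lose
solubility have to do with aging and chronic age-related disease.

During normal aging, and dramatically faster under Aβ expression, a
sub-proteome of vulnerable proteins leaves the soluble pool and accumulates
in the SDS-insoluble fraction. This package implements the computational
chain from protein-level quantification matrices (the output of DIA/SWATH
extraction) to:

1. **Differential insolubility calls** — per-protein log₂ fold-change of
   case vs control insoluble-fraction intensity across paired biological
   replicates, tested with a paired *t*-test and corrected with Storey
   *q*-values; a protein is called *significantly increased* when it has
   ≥ 2 unique peptides, *q* < 0.01 and log₂FC > 0.58.
2. **The core insoluble proteome (CIP)** — the intersection of two
   published aging insoluble proteomes (the "aging core") further
   intersected with the Aβ-driven insoluble set, with each overlap scored
   by a one-sided exact hypergeometric (Fisher) test
   P(X ≥ k), X ~ Hypergeom(N, |A|, |B|), against an explicit universe.
3. **Gene-set over-representation** — hypergeometric tests against GMT
   collections with Benjamini-Hochberg FDR and the summary score
   *k* × FDR (gene count times adjusted *p*), plus the
   *k* × (−log₁₀ FDR) display variant.
4. **The CARD sharing statistic** — for each protein, the number of chronic
   age-related diseases (CARDs; 38 diseases in 5 broad categories) and
   non-age-related diseases (12) whose GWAS-derived GO biological-process
   term sets intersect the protein's GO-BP profile (union over its human
   orthologues), compared across protein sets by Kruskal-Wallis with
   Dunn's post hoc tests against a seeded 1600-protein random background.
5. **Biophysical score comparisons** — CamSol, Zyggregator, catGRANULE and
   supersaturation (σf) score distributions across protein sets, and the
   ratio of mean σf between sets (linear scale, with a geometric variant).
6. **Aging expression trends** — per-gene Spearman ρ of expression vs adult
   age (days 2–10), BH-adjusted, classified up / down / unchanged at
   p.adj < 0.05.

A synthetic-data module generates every input with known ground truth
(spiked fold-changes, planted disease sharing, shifted score distributions,
planted expression trends), so the whole pipeline is testable end to end
without downloads.

## Worked example

```python
from insolubilome import *

# a paired 4-replicate insoluble-fraction experiment, 1704 proteins
params = QuantSimParams(seed=42)
quant, truth = gen_quant_experiment(params)

table, model = add_qvalues(paired_log_fold_change(quant))
increased = call_significant(table, name="abeta_increased")
print(f"quantified: {int(table['tested'].sum())}  pi0: {model.pi0:.3f}  "
      f"increased: {len(increased)}")

# two synthetic published aging lists intersecting in a 457-protein core
a1, a2, core = gen_aging_lists(truth, quant.protein_ids, seed=43)
res = build_cip(ProteinSet("aging_1", a1), ProteinSet("aging_2", a2),
                increased, universe=19985)
print(f"aging core: {len(res.aging_core)}  CIP: {len(res.cip)} "
      f"({100 * res.cip_fraction:.0f}% of core)  "
      f"overlap p: {res.test_cip_overlap.p_one_sided:.2e}")
```

prints

```
quantified: 1695  pi0: 0.631  increased: 449
aging core: 457  CIP: 235 (51% of core)  overlap p: 1.57e-285
```

1695 of the 1704 simulated proteins have at least two complete
case/control pairs and are testable; the Storey fit estimates that 63% of
tests are null; 449 proteins pass the ≥2-peptide, q<0.01, log₂FC>0.58
filter. The 457-protein aging core intersected with that called set gives a
235-protein CIP whose overlap is astronomically unlikely under independent
draws from a 19,985-protein universe.

## Command line

```sh
insolubilome simulate --out data --n-proteins 1704 --seed 0
insolubilome run --config data/run.toml           # all 7 stages + manifest
insolubilome diff --quant data/quant.tsv --out diff.tsv
insolubilome overlap --a data/aging1.txt --b data/aging2.txt \
    --c diff_called.txt --universe-size 19985
```

Every stage writes plain TSV so it can be inspected or re-run standalone;
`run` writes a JSON manifest with input checksums, the seed and thresholds,
and reruns are byte-identical.

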