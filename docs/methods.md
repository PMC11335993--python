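# Methods

## Differential insolubility

The quantification matrix holds protein-group intensities (peak areas of
extracted ion chromatograms) for paired case (Aβ-expressing) and control
samples, one pair per biological replicate, plus per-protein unique-peptide
counts. Statistics are computed on log₂ intensities; a zero or missing
intensity cannot be logged and makes that pair incomplete for the protein.

For each protein with ≥ 2 complete pairs, the per-pair difference
dᵣ = log₂(caseᵣ) − log₂(controlᵣ) gives the fold-change estimate
log₂FC = mean(d) and the two-sided paired *t* statistic
t = mean(d) / (sd(d)/√n), df = n − 1. Proteins with fewer complete pairs
are reported untested rather than imputed; no normalization is applied
(values are consumed as extracted). Degenerate cases are resolved
deterministically: identically-zero differences give p = 1; identical
nonzero differences make *t* diverge, so p is floored at 10⁻¹⁵ instead of
propagating NaN. "Zero variance" is decided at 10⁻¹² relative resolution of
the differences, since mathematically equal log-ratios of floats can differ
in the last ulp.

Multiplicity is corrected with Storey *q*-values: the null proportion π₀ is
estimated from the raw values π₀(λ) = #{p > λ} / (m(1 − λ)) on the grid
λ = 0, 0.05, …, 0.90, smoothed with a cubic polynomial and evaluated at
λ = 0.90, clipped into (0, 1]; a bootstrap λ-selection (B = 100) is
available behind a flag. q-values are π₀ times the Benjamini-Hochberg
step-up quantity with enforced monotonicity, so forcing π₀ = 1 reproduces
BH exactly — a reduction the tests exploit as an oracle.

Significance filters default to ≥ 2 unique peptides, q < 0.01 and
log₂FC > 0.58 (≈ 1.5-fold), with the increased direction as the primary
call and `down`/`both` available.

The total-insoluble comparison sums each sample's present intensities,
normalizes every value to the average control total of its experiment
(with one control per replicate pair the controls normalize to exactly 1),
and compares arms with a two-sided Mann-Whitney U test computed by full
enumeration of label assignments on midranks — exact even under ties, which
always occur here because of the normalization — up to 2 × 10⁵
combinations, with the scipy implementation beyond that.

## Set algebra and overlap testing

The aging core is the intersection of two published aging insoluble
proteomes; the core insoluble proteome (CIP) is the aging core intersected
with the set of proteins driven insoluble by Aβ. Overlaps are scored with
the one-sided enrichment tail P(X ≥ k) of the hypergeometric distribution
via the log-gamma survival function (≥ 10-digit agreement with exact
integer enumeration across all 2×2 tables with N ≤ 60 is asserted in the
tests). The universe N is never implicit: it defaults to 19,985 (the
approximate *C. elegans* protein-coding gene count), is always
configurable, and is recorded in every result, because the choice of
universe (detected proteins vs whole proteome) changes the p-value and is
a genuinely open reporting decision. Orthology projection maps each worm
identifier to all of its human targets (`expand_all`, the default, used by
all annotation statistics) or to the lexicographically first
(`first_only`); unmapped identifiers are reported, never fatal.

## Over-representation

One-sided hypergeometric tests per term, with term membership intersected
with the explicit background before testing; terms with fewer than 3 or
more than 2000 background members are skipped as degenerate. BH adjustment
runs across all tested terms of one namespace per call (GO-BP separately
from KEGG), matching per-panel reporting. Two summary scores are reported:
the product k × FDR, and k × (−log₁₀ FDR). The product form ranks smaller
values as *weaker* enrichment, which conflicts with barplot intuition; the
neglog variant is therefore computed alongside and neither is asserted to
be "the" display axis.

## CARD sharing statistic

A protein's GO-BP profile is the union of term annotations over all its
human orthologues; sharing with a disease means non-empty intersection of
that profile with the disease's GWAS-derived term set — exact term-id
equality, no ancestor closure (none is described for the source catalog),
though a closure over a user-supplied parent map is available. Per protein
the statistic counts shared diseases split into age-related (CARDs, 38 in
the reference catalog, each carrying one of 5 broad categories:
neurodegenerative, metabolic, cancer, cardiovascular, other) and
non-age-related (12), plus the number of broad categories hit.
Distributions across protein sets are compared with the tie-corrected
Kruskal-Wallis test and Dunn's post hoc z-tests on mean ranks (Bonferroni
correction by default, Holm available); the same single implementation
serves the score comparisons, so results are identical on shared inputs.
The random-proteome background is a seeded sample (default n = 1600) whose
membership is persisted with the run.

Set-level disease proportions (diseases with ≥ 1 shared term over diseases
tested per class, and the ARD/non-ARD ratio) saturate once the query set's
combined BP union covers most disease pools — with several hundred query
proteins both proportions reach 1 and the ratio degenerates to 1. A
protein-level variant (mean per-protein shared fraction per class) is
therefore computed alongside; both are reported and neither is asserted as
the canonical figure definition.

## Scores and trends

Biophysical predictor scores (CamSol solubility, Zyggregator aggregation
propensity, catGRANULE LLPS propensity, supersaturation σf) are consumed
as input tables, never computed from sequence. Distribution comparisons
use the shared Kruskal-Wallis/Dunn core with group medians and the
direction of each significant pairwise shift. The supersaturation summary
is the ratio of arithmetic means of σf on the linear scale — "X-fold
greater average" reads most naturally as a ratio of plain averages — with
the geometric-mean (log₁₀-scale) ratio reported alongside because the
score is displayed on log₁₀ and spreads over decades.

Expression trends pool all datasets' (age, value) points per gene inside
the day 2–10 adult window (values are assumed pre-normalized; no
re-normalization), compute Spearman ρ of value against age with midranks,
and classify at BH-adjusted p < 0.05. For n < 10 points with no ties the
p-value is exact by full permutation enumeration (the null distribution is
cached per n); otherwise the t-approximation with n − 2 df is used.
Constant genes get ρ = 0 and class `unchanged`; genes with < 3 points are
untested. Pooling across datasets (rather than per-dataset correlation
followed by aggregation) is a design choice, not an assertion about the
original analysis.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their parameters including the seed.

**Quantification** (`QuantSimParams`): log₂ intensities are
baseline + pair-shared effect + planted effect (case arm of spiked
proteins) + independent noise, exponentiated — i.e. lognormal peak areas
with multiplicative noise, strictly positive like real MS intensities.
Defaults mirror the study design: 1704 proteins, 4 replicate pairs,
spike fraction 0.348 (so the spiked count matches the scale of the
experimentally increased set), mean planted effect 2 log₂ units with
0.25 between-protein spread, baseline log₂ mean 20 ± 2 (peak areas around
10⁶), replicate noise 0.2 log₂ units, 5% missingness, mean 4 unique
peptides (shifted Poisson, minimum 1, independent of intensity — only the
≥2 filter consumes them). No noise model is published for the source data,
so these are conventions, not estimates. Missingness is completely at
random; real DIA dropout is intensity-dependent, so synthetic power at a
given missing rate is optimistic for low-abundance proteins. Peptide-level
signal, retention time and spectral libraries are not simulated.

**Aging lists**: two lists sharing an exact 457-protein core, two-thirds
of which (305 proteins) is drawn from the spiked set — mirroring the
study-scale relationship between the aging core and the case-responsive
proteome — plus disjoint list-specific extras, so the intersection equals
the core exactly and CIP recovery is limited only by differential-calling
sensitivity.

**Annotation catalog**: a term vocabulary (4000 terms at study scale, of
the order of GO-BP terms carrying GWAS annotations; 300 in fast tests), a
1-to-{1,2,3} worm→human orthology, disease term pools of 8 terms each for
38 ARDs (cycled over the 5 categories) and 12 non-ARDs, and 12 annotation
terms per human gene. Proteins in the planted set draw terms with
probability up-weighted by `sharing_boost` (20 in the standard conditions)
for terms in any ARD pool; boost 1 makes planted and background proteins
exchangeable, which the null-calibration tests verify.

**Scores**: location-family draws per set — normal on the natural scale
for CamSol/Zyggregator/catGRANULE, normal on log₁₀ for σf (centre 10⁻²,
spread one decade), so a set shift of s multiplies σf by 10ˢ. The
supersaturation benchmark plants a log₁₀(94) shift with 0.05 decade spread
and recovers the ratio as the noise vanishes; with realistic decade-wide
spread the linear-mean ratio is heavy-tailed and seed-noisy, which is a
property of the statistic, not the implementation.

**Expression**: linear trends of ±0.5 per adult day (balanced up/down)
plus Gaussian noise on days 2–10, flat otherwise.

Passing tests on these generators demonstrates correctness of the
statistical machinery and recoverability of planted signal under the
stated conditions; they do not validate biological conclusions about real
insoluble proteomes, and database-dependent tallies (median diseases
shared, enrichment-term counts, proportion ratios) depend on the catalog's
density parameters.

## Problem sizes and calibration conditions in the test suite

The suite and the acceptance script run at the study's natural sizes where
cheap (1704 proteins × 8 samples; 457/305 core construction; 38 + 12
disease catalog) and scale down elsewhere as the package's own choice:
null calibrations use 50–100 seeds at 300 proteins / 60 genes / 3×60
observations; exhaustive oracles cover all 2×2 tables with N ≤ 60, all
Mann-Whitney layouts with ≤ 6 per arm, and 10⁴ random p-vectors for the
Storey-to-BH reduction. Recovery benchmarks (planted log₂FC = 3, noise
0.2) run on complete data: with only four replicate pairs, random dropout
reduces the paired *t* to 1–2 degrees of freedom for affected proteins,
which collapses power — a property of the experimental design that the
calibration deliberately isolates from implementation correctness.

## Known limitations

- No peptide-to-protein roll-up, protein inference or batch correction;
  the pipeline starts at the protein quant matrix.
- No GO graph propagation by default and no fuzzy identifier matching;
  the orthology and annotation join keys must already agree.
- The Storey smoother can be unstable for very small test families
  (m < ~50); the bootstrap alternative or a fixed π₀ = 1 (pure BH) are the
  safe fallbacks there.
- Exact Spearman p-values are only available for ≤ 9 untied points; tied
  small samples fall back to the t-approximation.
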