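# Methods

This note records the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic-data generators
do and do not emulate.

## Screen counts and QC

Spacer counting is exact-match: a read contributes to a guide only when
the 20 bases following the first occurrence of the anchor (the
invariant vector sequence 5′ of the spacer) equal a library spacer
exactly. Searching for the anchor at any offset accommodates the
staggered forward primers used to diversify sequencing. For
perfect-match counting this is equivalent to no-mismatch alignment of
the spacer region, while being simpler and dependency-free; reads with
any mismatch, or without the anchor, are tallied as unmapped, so
mapped + unmapped always equals the read count.

Normalization is median-of-ratios: a sample's size factor is the median
over guides (with nonzero geometric mean across samples) of
count / geometric mean. When fewer than 100 guides qualify the code
falls back to total-count scaling; normalization is a positive
per-sample rescaling and therefore preserves within-sample guide ranks.

Library representation QC reports the percent of guides detected and
the ratio of the quantiles bracketing the central 80% of detected
counts (90th/10th percentile by default). The central mass is a
parameter because "representation of 80% of guides" admits more than
one reading; the quantile-ratio reading is used throughout.

Coverage arithmetic assumes 7.5 pg of genomic DNA per (diploid human)
cell, a conventional figure that makes 10 µg over 2930 guides ≈ 455×;
the value is a parameter. Viral titer is the standard survival-fraction
formula: survival × cells per well × 1000 / virus volume (µL).

## α-RRA gene scoring

Per-guide testing compares the treatment-arm mean of normalized counts
against a negative-binomial null parametrized by the control-arm mean
and a variance from a mean–variance trend (log variance regressed
linearly on log mean over control replicates, floored at the Poisson
variance; with fewer than two control replicates the Poisson floor is
used outright). Two-sided p-values double the smaller tail; the
depletion ranking uses the lower-tail probability, with ties broken by
sgRNA id for determinism. Guide percentiles are rank/(n+1) over the
whole library.

The gene score is alpha-truncated robust rank aggregation: with a
gene's sorted guide percentiles p₍₁₎ ≤ … ≤ p₍ₖ₎,

  ρ = min over {i : p₍ᵢ₎ < α} of BetaCDF(p₍ᵢ₎; i, k − i + 1),

and ρ = 1 when no percentile falls below α. Under the null the p₍ᵢ₎
are uniform order statistics, whose marginal laws are Beta(i, k−i+1);
ρ is by construction invariant to percentiles at or above α. The
default α = 0.05 on the percentile scale is a convention (exposed as a
parameter). Gene p-values come from redrawing k uniform percentiles
n_perm times (default 10,000) and applying the add-one rule
p = (1 + #{ρ* ≤ ρ}) / (n_perm + 1), which bounds p below by
1/(n_perm+1); null draws are shared across genes with equal guide
counts. Non-targeting guides are grouped into pseudo-genes of the modal
real-gene guide count and scored identically, giving an internal
calibration set.

A consequence of truncation worth stating: under the null a gene has
probability (1−α)^k of having no qualifying guide, hence ρ = 1 and
p ≈ 1. Truncated gene p-values are therefore conservative (sub-uniform)
rather than uniform; exact null uniformity holds for the untruncated
statistic (α = 1), and that is the setting in which the package's
uniformity calibration is run. Only depletion (negative selection) is
scored; enrichment analysis would rank by the upper tail instead.

## Hit consolidation

Hits per condition are genes with p strictly below the cut (default
0.045). Consolidation is the plain union; counter-screen exclusion
removes any gene also hit in the counter condition; intersection sets
use UpSet semantics (each gene belongs to exactly one signature — the
full set of conditions containing it — so the sets partition the
union). Gene symbols are uppercased and trimmed; no alias resolution is
attempted. The packaged per-condition top-depleted gene lists reproduce
the published consolidation arithmetic: 81 genes in the five-condition
union, 58 after removing BMH-21 overlap, and the common-to-all-G4
intersection contains RAD54L, H2AFX, POLQ, ATM, LIG4 and RNF168 (that
intersection also holds RAD51 and RAD9A, which the counter-screen
removes from the final list).

## Blocked bootstrap for competitive growth assays

An experiment is N_a assays × N_r replicates × conditions of DRX2+
proportions. Each bootstrap replicate draws N_a assay indices with
replacement, then N_r replicate indices with replacement within each
drawn assay; each arm's proportions are averaged on the logit scale,
back-transformed, and differenced (drug − vehicle). Percentile CIs at
95/99/99.9/99.99% are read from the B differences (default
B = 400,000; the calibration suites run at B = 10,000). By default the
same resampled indices are applied to both arms (paired resampling),
reflecting that an assay contains both conditions, so shared
assay-level effects cancel in the difference; independent-arm
resampling is available as a flag. Proportions of exactly 0 or 1 are
rejected; the clamping preprocessor applies (x+0.5)/(n+1) when raw cell
counts are available, else clips to [1e−4, 1−1e−4]. Family-wise calls
are Bonferroni: significance at family α requires the CI at level
1 − α/n_comparisons to exclude zero (α 0.05 over 50 comparisons →
0.001; 0.01 → 0.0002); a warning fires when B × adjusted α < 20, since
the extreme percentile is then poorly resolved.

Known limitation: with very few outer blocks the percentile bootstrap
is anticonservative. Resampling N_a-of-N_a with replacement
underestimates the between-assay variance component by the factor
(N_a−1)/N_a, so at N_a = 3 a nominal 95% interval behaves like a
z-interval at ≈1.96·√(2/3) ≈ 1.60σ when assay variance dominates
(≈89% coverage) and ≈1.96·√(8/9) ≈ 1.85σ when replicate noise
dominates (≈93.5%). The package's calibration suite measures ≈92%
(null, where paired resampling cancels assay effects) and ≈90%
(planted effect) at N_a = N_r = 3 — a property of the procedure itself,
shared by any B. Users with few assays should read the intervals as
approximate.

## Dose-response and synergy

The 4PL ("variable slope") model y = bottom + (top−bottom)/(1+(d/IC50)^h)
is fitted by least squares on the log10-dose axis with multi-start
initialization (hill ∈ {0.5, 1, 1.5, 3} × IC50 at dose quantiles) and
bottom constrained non-negative (responses are viability fractions).
Flat responses raise a non-identifiability error rather than returning
an arbitrary IC50. The IC50 CI is profile likelihood: the profile RSS
is bisected against the F-ratio threshold RSS·(1 + F(1, n−4)/(n−4)).

IC50 comparison is one-way ANOVA with pooled variance followed by
Dunnett's many-to-one test; the multivariate-t tail is evaluated by
scipy's randomized quasi-Monte-Carlo integration with a fixed seed, so
adjusted p-values are deterministic to integration accuracy (relative
error of a few percent in deep tails).

Checkerboards express each well as fractional inhibition
1 − response/untreated mean (in %). The Bliss-expected combination
inhibition is fx + fy − fx·fy from the monotherapy means. Per-cell
deviations (observed − expected) get two-sided t-intervals whose
standard error propagates, by the delta method, both the combination
replicate variance and the variance of the expected surface through
the monotherapy means — coefficients (1−fy)² and (1−fx)² — with
Welch–Satterthwaite degrees of freedom; omitting the monotherapy
component inflates the family-wise false-flag rate well above nominal.
The per-cell level is Bonferroni-adjusted, 1 − (1−confidence)/n_combos
by default. Volumes accumulate significant deviations weighted by each
cell's dose-interval area (trapezoid split: half-intervals at the grid
edges): synergy = Σ max(0, CI lower)·w, antagonism = Σ min(0, CI
upper)·w, so antagonism ≤ 0 ≤ synergy always. Linear-dose weights are
the default (matching volumes printed in dose²·% units); log10-dose
weights give the log-volume variant, and unit weights are available for
grid-count bookkeeping. Unthresholded ("raw") volumes are reported
alongside for reference. The 5 × 9 equipotency design helper scales two
IC50s by fold-factor ladders (0.25–4× and 0.03125–8×), yielding the
45-combination grid.

## Validation-assay statistics

Densitometry ANCOVA fits log2(signal) ~ log2(loading) + genotype ×
treatment by least squares under the equal-slopes assumption. The ANOVA
table is sequential (Type I) in the fixed order covariate → genotype →
treatment → interaction — built from nested fits, since that order is
part of the table's meaning — with F against the full-model residual
mean square. Treatment-coded contrasts against the reference cell
(wild-type vehicle when such labels exist) exponentiate to fold-changes
with monotone-transformed CIs. Zero or negative densities are rejected
rather than offset, because the log2 transform is the analysis scale.
Mixed-effects modelling is out of scope (the design sizes this targets
cannot support it).

Foci positivity uses per-marker minimum counts (γ-H2AX ≥ 5, 53BP1 ≥ 3,
RNF168 ≥ 3, FK2 ≥ 10 by default) and reports percent positive per
condition; co-localization reports, per direction, the per-cell percent
of one marker's foci overlapping the other, averaged within condition
(the two directions are not symmetric). t-tests are two-tailed unpaired
Student or Welch (Welch–Satterthwaite df); two constant equal samples
give p = 1 by convention. Tukey HSD uses the studentized range with
pooled variance.

## Synthetic data: what it emulates, and what it does not

The screen generator draws guide abundances from a log-normal plasmid
representation (σ = 0.4 by default, consistent with a sub-eightfold
90th/10th spread), evolves them multiplicatively — essential genes
decay by a chosen log2 fold-change per passage everywhere,
drug-interacting genes additionally in the matching arm only —
renormalizes per sample (sequencing measures relative composition at
fixed depth) and draws negative-binomial counts with a gene-independent
size parameter (default 20; larger is closer to Poisson). Defaults
mirror the study design: 480 genes × 6 guides + 50 non-targeting,
passages on days 4/7/10/13/16, harvests on days 1 and 19, triplicates.
Dropout kinetics per passage are a modelling convention, not a measured
quantity. Not emulated: sequencing error, PCR jackpotting, guide
efficacy heterogeneity within genes, or cell-cycle dynamics — so
passing tests demonstrate the statistics recover planted effects under
the stated noise model, not robustness to those artifacts.

The growth-assay generator is logit-normal: logit(p) = baseline +
assay effect + condition shift + replicate noise, with assay effects
(SD 0.3) shared across conditions within an assay — the pairing the
blocked bootstrap exploits — and replicate noise SD 0.15, chosen as
typical scales for flow-cytometry assay repeats versus technical
wells. Checkerboards are generated exactly Bliss-consistent from two
4PL monotherapies (surviving-fraction scale) with optional planted
deviation bumps and additive Gaussian noise. Dose-response tables use
multiplicative log-normal noise of a given CV. Densitometry follows
the ANCOVA generative model exactly; foci counts are a two-component
Poisson mixture with a binomial overlap thinning. Everything is
deterministic given its seed.

## Problem sizes in the calibration suites

The shipped calibration runs use 500 simulated growth-assay
experiments at B = 10,000 (CI coverage), 50 seeded screens for
planted-gene ranking plus one 480-gene null screen for uniformity
(n_perm = 5000), 200 noisy dose-response fits, and 500 noisy null
checkerboards — sizes chosen to keep Monte-Carlo error a small
fraction of the tolerance each check asserts while the full suite
runs in about a minute.
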