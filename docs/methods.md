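# Methods

This note records the models, numerical choices, and limitations behind
cmmosaic, at the level of detail a maintainer or reviewer needs to audit a
result.

## Burden estimation

A single amplified cell does not expose its whole genome to calling:
detection sensitivity varies with depth, and some territory has no reads at
all.  The estimator measures sensitivity as the fraction of known germline
heterozygous sites recovered in the cell, stratified by bin depth, and
restricted to a trimmed central depth region (default the 25th–75th
percentile of the bin-depth distribution, 4 equal-count depth strata;
both configurable).  Genome-wide burden per GB is then

    burden/GB = calls in trimmed strata / Σ_s sensitivity_s · length_s (GB).

Two variants differ only in the depth distribution used for trimming:
`standard` uses all bins, so a large zero-depth block can drag both
quantile bounds to zero and leave the trimmed strata uncallable (the
estimate is then undefined and an explicit error is raised);
`zero-depth-refined` removes zero-depth bins before trimming, which
rescues such cells and is identical to `standard` whenever no zero-depth
bins exist (tested invariant).

Per-cell burden multiplies the per-GB rate by a diploid genome constant of
**5.845 GB**.  This value is chosen so the per-GB and per-cell scales are
mutually consistent (686/GB ↔ ~4,010/cell; 7.90/GB/yr ↔ ~46/cell/yr); it is
a documented constant, configurable per call.

## Mixed-effects burden models

Models 1–3 (README) are fitted by maximum likelihood with the donor random
intercept profiled analytically: for fixed variance components
θ = (σ_u², σ²) the fixed effects are the GLS solution, V⁻¹ applied
blockwise by the Woodbury identity, and θ is optimized by L-BFGS-B from
three starting points with σ_u² bounded at 0.  Fixed-effect t-tests use
Satterthwaite degrees of freedom: df_j = 2·f_j²/(g_jᵀ A g_j), with f_j the
coefficient's GLS variance, g_j its finite-difference gradient in θ, and A
the inverse observed information of the profiled likelihood (finite-
difference Hessian).  When that Hessian is not positive definite (boundary
fits), the residual degrees of freedom are used and flagged.  The
implementation was cross-checked against an independent mixed-model
implementation (statsmodels MixedLM with ML) in the test suite;
coefficients, σ² and Satterthwaite df/P also agree with the reference R
implementation (lme4 + lmerTest, ML) to four digits on shared data.

Degenerate and boundary cases, all flagged in the returned fit:

- interpolating (noiseless) data: the fixed effects are returned exactly
  via the ordinary least-squares path;
- σ_u² estimated below 1e-8·σ²: the fit is singular and falls back to the
  fixed-effects-only linear model (model 3).  The fallback drops **only**
  the random term; the fixed-effect structure (including the condition
  indicator) is preserved, which is what makes disease effects estimable
  for signatures with near-zero control burden;
- signature-specific series: a signature whose control-group mean burden is
  below 6 sSNVs/GB is sent directly to the linear model, since a donor
  intercept is not identifiable from an essentially empty control arm.

Known limitation: ML variance components are biased low when donors are
few.  With 10 donors × 5 cells the nominal 95% Satterthwaite intervals
cover at ≈0.89 — for this implementation and for lme4/lmerTest alike — and
reach the nominal band (≈0.94) at 20 donors.  The parameter estimates
themselves are unbiased at both sizes (tested over 200 simulated cohorts).
Covariate adjustment (depth, coverage, MAPD, CoV, sex) adds fixed effects;
a covariate exactly collinear with the condition indicator is rejected.

## Signature analysis

Spectra use the 96 pyrimidine-standardized trinucleotide channels in COSMIC
order; contexts are always read from the reference sequence, never trusted
from a VCF, and a REF mismatch is an error.  Catalog attribution solves a
non-negative least-squares problem and rescales the solution to the
spectrum total; both the rescaled exposures and the raw LS solution are
returned, and the reconstruction-error optimality of the raw solution over
a 0.01-step mixture grid is a tested invariant.  Duplicate catalog columns
make the problem ill-posed; they are detected, warned about, and resolved
deterministically.

De novo extraction runs multiplicative-update NMF (Frobenius loss) with
random restarts (default 50) per candidate rank on the 96×cells matrix.
Per rank we record (i) the best-restart residual sum of squares and (ii)
the cophenetic correlation of the consensus matrix built from
dominant-signature cell assignments across restarts.  The chosen rank is
the largest whose incremental fit still at least halves the RSS — the
operational reading of the "RSS inflection", since factors beyond the true
rank only soak noise and the curve flattens — stepped down if its
cophenetic coefficient has collapsed below 0.8.  A cophenetic-decrease rule
alone is not operational: the coefficient is trivially 1 at rank 1 and
fluctuates above the true rank even when the RSS elbow is unambiguous
(observed on synthetic rank-4 data).  Both curves are emitted so the choice
is auditable.  With a fixed seed the extraction is reproducible; permuting
cell order changes only the random pairing of initializations with cells,
and recovered signatures match to cosine ≥ 0.95.

Strand bias uses the convention that a pyrimidine-standardized substitution
on the same strand as the gene annotation is "untranscribed" and on the
opposite strand "transcribed"; calls inside antisense-overlapping genes get
conflicting labels and are excluded (tallied).  Per substitution class the
per-cell transcribed and untranscribed counts are compared with a two-sided
Wilcoxon rank-sum test; an all-zero class reports P = 1 with a degenerate
flag.

## Permutation enrichment

Units (genes, or fixed-width bins for accessibility; default 10 kb) are
ranked and split into eight equal-count groups.  Equal-count grouping —
rather than equal genomic span — is deliberate: footprint-size differences
between groups are exactly what the permutation null corrects for.  Each
permutation reassigns every call to a uniformly drawn position with the
same standardized trinucleotide context inside phaseable intervals,
sampling without replacement within a permutation (somatic calls are unique
sites), so the context histogram is conserved exactly (tested).  Expected
group density is the permutation mean; the ratio SD is reported via the
delta method (ratio · SD(perm)/mean(perm)); the across-group trend is the
Pearson R and P of a least-squares fit of ratio on group index.  Groups
with zero expected density are excluded with a warning.  Default 1,000
permutations; a seed is mandatory in the CLI.

## Annotation and selection

Region categories use 1 kb upstream/downstream windows and a 2 bp splice
window (the first/last two intronic bases of each intron).  Precedence when
categories collide: splicing > exonic > UTR5/UTR3 > intronic >
upstream/downstream > intergenic; multi-transcript hits resolve to the most
severe category.  Functional classes translate the affected codon under the
standard genetic code, reverse-complementing for minus-strand genes; an
in-frame internal stop in the reference produces a warning.  Selection
statistics form 2×2 tables (somatic vs germline × category A vs B); the
normalized ratio is (somA/somB)/(germA/germB) and the P value is a
two-sided Fisher exact test, which matches full hypergeometric enumeration
(tested for tables with totals ≤ 200).

## LOO consensus differential expression

Counts are library-size normalized to 10,000 and log1p-transformed; the
log-fold change is ln(mean_A+1) − ln(mean_B+1) on normalized (pre-log)
counts — the ecosystem convention the 0.30/0.25 thresholds were tuned
against.  Genes pass to a two-sided Wilcoxon rank-sum test only if
expressed in ≥ min.pct (default 0.1) of either group and |lfc| clears the
direction-specific threshold.  The consensus enumerates every (control,
diseased) donor pair, refits with both excluded, and intersects the up- and
down-calls across all iterations; with 3+3 donors that is 9 iterations.
The donor-level cell-type proportion test uses an exact rank-sum null
(complete enumeration of assignments, midranks for ties) because donor
counts are tiny; larger samples fall back to the normal approximation.

## Synthetic cohort generator

The generator is the analysis run forward.  Per-cell burden follows the
mixed-effects generative model; by default it is truncated at zero
(realized burdens are counts), but parameter-recovery experiments use
`truncate=False` because their estimand is the linear coefficient and
truncation would bias it — most visibly for near-zero-baseline signature
burdens.  Realized mutation counts are Poisson with mean burden ×
callable GB × detection sensitivity (default 0.9); channels are multinomial
draws from the condition's signature mixture; positions are drawn uniformly
from a precomputed context→position index restricted to phaseable
intervals, without replacement within a cell and independently across
cells.  Donor ages default to an even spread over 0.5–82 years; sex is
generated but carries no effect by default.  Depth profiles are
gamma-distributed per bin with a contiguous zero-depth block (default 5% of
bins) to exercise the refined burden path; germline recovery follows the
saturating dropout curve 1 − 2^(−depth/5).

What the generator does not emulate — and hence what passing tests do not
establish about real data: read-level artifacts (chimeras, allelic
imbalance of amplification), genuine mutation clustering (kataegis),
regional covariates such as replication timing, indels and structural
variants, and real gene-length/GC biases in expression.  Tests on this
generator validate the estimators under their assumed models, not the
upstream calling.

## Problem sizes and determinism

Defaults in the test suite and acceptance script are scaled for a single
CPU: toy genomes of 0.1–0.4 Mb, cohorts of 10–15 donors × 2–5 cells,
100–1,000 permutations, 5–10 NMF restarts in tests (50 in production
defaults), and 20–80 replicate cohorts for recovery experiments.  All
randomness flows from explicit seeds; the pipeline derives per-stage seeds
from the master seed by stable hashing, and a rerun with the same config
reproduces output checksums exactly.
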