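# Methods

## The causal model

Two-sample Mendelian randomization treats genetic variants as instrumental
variables for a modifiable exposure. For instrument j, let γⱼ be its true
effect on exposure liability (log-odds scale) and Γⱼ its true effect on the
outcome. Under the three IV assumptions — relevance (γⱼ ≠ 0), independence
from confounders, and exclusion restriction (no pathway to the outcome
except through the exposure) — the model is

    Γⱼ = β·γⱼ + αⱼ ,

where β is the causal log-OR of the outcome per 1-log-unit increase in
exposure liability and αⱼ is the horizontal-pleiotropy effect, zero when
the exclusion restriction holds. The two samples (exposure GWAS, outcome
GWAS) are assumed non-overlapping, so the estimation errors of β̂_Xⱼ and
β̂_Yⱼ are independent.

## Estimators

**Wald ratio.** θ̂ⱼ = β̂_Yⱼ/β̂_Xⱼ with first-order se(θ̂ⱼ) = se_Yⱼ/|β̂_Xⱼ|.
Exposure-side uncertainty is ignored; for the instrument strengths this
package targets (F ≥ 30, typically ≫ 100) the second-order correction is
below 5 % of the se (verified against Monte-Carlo sampling of the ratio in
the test suite).

**IVW, multiplicative random effects.** Weighted regression of β̂_Y on β̂_X
through the origin with weights wⱼ = 1/se_Yⱼ². The fixed-effect se is
inflated by φ = max(1, √(Q/(J−1))) where Q is Cochran's statistic; the
floor at 1 means under-dispersion is never credited, so IVW is mildly
conservative when instruments are homogeneous (measured type-I error
≈ 0.039 at J = 9 over 10,000 null replicates). I² = max(0, (Q−df)/Q)·100
is reported with the conventional >25/>50/>75 low/moderate/high reading.
P-values use the standard normal; CIs are β̂ ± 1.96·se on the log-OR scale.

**Weighted median.** Wald ratios are sorted and weighted by
(β̂_Xⱼ/se_Yⱼ)² (the inverse first-order ratio variance); the estimate
interpolates the 50 % point of the cumulative weight distribution. It is
consistent whenever more than half of the total weight comes from valid
instruments. The se is a parametric bootstrap: β̂_X and β̂_Y are resampled
from normals centred at their observed values with their reported ses and
the median recomputed; the se is the sd over replicates. The seed is a
required argument — there is no silent default — and identical seeds give
bit-identical ses. Default 1,000 replicates standalone; the scenario grid
uses 200 per fit, at which the se of a 9-SNP median is stable to well
under the band widths being tested. Known limitation: the bootstrap
propagates only the reported sampling noise, not between-SNP pleiotropy
dispersion, so under balanced pleiotropy the weighted median (unlike IVW,
whose φ absorbs over-dispersion) is anti-conservative.

**MR-Egger.** After orienting every instrument so β̂_Xⱼ ≥ 0 (negating both
betas together, which makes the fit invariant to per-SNP sign
conventions), a weighted regression of β̂_Y on β̂_X with a free intercept
and weights 1/se_Y². The intercept estimates the average directional
pleiotropy; under the InSIDE assumption the slope is a pleiotropy-adjusted
causal estimate. Inference uses the estimated residual scale and a t
reference with J−2 df — the exact WLS t-test, which keeps the intercept's
size at its nominal level (measured 0.04–0.05 under zero pleiotropy). We
deliberately do not floor the Egger residual scale at 1: flooring (as some
toolchains do) drives the intercept test's size down to ≈ 0.01 at J = 9,
crippling the diagnostic the test exists to provide. IVW keeps its floor;
the asymmetry is intentional and this paragraph is its record.

**Meta-analysis.** Per-outcome estimates from independent sources are
pooled with fixed-effect weights 1/se². Bonferroni classification uses the
exact quotient α/k (0.05/8 = 0.00625), never its rounded presentation;
p-values in [α/k, α) are labelled suggestive.

## Instrument validation

Selection is an ordered, fully ledgered cascade: (1) keep p < 5×10⁻⁸
(strict); (2) greedy LD pruning — candidates in ascending p-value order
(ties: chromosome, position, id), accept iff r² < 0.001 with every
accepted SNP, using an externally supplied r² matrix (computing LD from a
reference panel is out of scope); (3) curated exclusions for confounder-
or outcome-associated SNPs, supplied as a frozen JSON-lines file rather
than live database queries so results do not drift with catalogue
versions. Every removal is one reason-coded ledger entry, and
|input| = |kept| + |removals| always holds.

Per-SNP variance explained uses the standardized-effect approximation
R² = 2β²q(1−q) / (2β²q(1−q) + 2Nq(1−q)·se²), algebraically
β²/(β² + N·se²); F = R²(N−2)/(1−R²). The formula is a documented choice —
callers with trait-scale betas from other pipelines can substitute their
own R² and feed `f_statistic` directly.

## Harmonization

The outcome record is rewritten onto the exposure's effect allele:
identical alleles pass through; swapped alleles negate β_Y and reflect the
frequency; strand complements are relabelled first. Palindromic SNPs (A/T,
C/G) cannot be strand-resolved from alleles, so orientation falls to
allele-frequency concordance, and the SNP is dropped when either study's
frequency lies within 0.08 of 0.5 (configurable) or is missing. Standard
errors are never modified. Harmonizing an already-harmonized pair is the
identity, and the β_X·β_Y product is invariant to how the outcome study
chose to report its alleles — both properties are tested.

## Synthetic data generator

The generator emulates the paired summary-statistics layout of a
two-sample MR study. Defaults are the conditions of the asthma →
cardiovascular application: J = 9 independent instruments, exposure GWAS
n = 127,669, outcome GWAS n = 500,000, MAF ~ Uniform(0.10, 0.40).
Instrument effects are half-normal, γⱼ = |N(0, 0.125)| — effect alleles
oriented to the exposure-increasing allele, the convention under which
"directional" pleiotropy is well-defined (with symmetric γ the Egger
orientation step would scramble pleiotropy signs and no mean pleiotropy
could survive orientation). The scale 0.125 makes E[γ²]·2q(1−q) ≈ 0.58 %
per SNP, i.e. nine instruments explain ≈ 5 % of exposure variance with
F-statistics in the tens-to-hundreds — the strength regime of a validated
genome-wide-significant instrument set; draws are rejected until the
analytic F exceeds 30. Pleiotropy is αⱼ ~ N(mean, sd): (0, 0) encodes all
IV assumptions, (0, s) balanced pleiotropy satisfying InSIDE, (m > 0, s)
directional pleiotropy. Standard errors use the standardized-trait
approximation se = 1/√(2n·q(1−q)) on the liability/log-odds scale —
case-control ascertainment is deliberately not modelled, since the
estimators consume betas and ses agnostically. Observed effects are
normal around the truths; p-values are two-sided normal.

What the generator does **not** emulate: LD between instruments (they are
independent by construction, as after pruning at r² < 0.001), winner's
curse from in-sample instrument discovery, sample overlap between the two
GWAS, allele-coding errors (those are exercised separately by the
harmonization tests), and binary-trait effect attenuation. Passing
simulation tests therefore demonstrates estimator correctness under the
stated model, not robustness to those real-data pathologies.

Per-replicate seeds derive from `SeedSequence([config_seed, replicate])`
reduced mod 2³¹ — stable across platforms, documented, and collision-free
in practice. Identical seeds give bitwise-identical tables end to end.

## Numerical choices and degenerate inputs

- Exactly proportional data (β_Y = c·β_X): all three estimators return c,
  Q = 0, I² = 0, Egger intercept = 0; the Egger residual scale is then 0
  and a zero coefficient is reported with p = 1, a non-zero one with
  p → 0.
- β_X = 0 for a Wald ratio, J < 2 (IVW), J < 3 (median, Egger), zero
  exposure-effect variance (Egger), and empty instrument sets all raise
  typed errors rather than returning NaNs.
- Tables round-trip bitwise: floats serialize via `repr` (17 significant
  digits); missing eaf is the literal `NA`.
- P-values are floored at the smallest positive double rather than
  reported as 0.
- Display rounding (2 dp for OR/CI, 3 significant figures for p) happens
  only in the forest table; `results.tsv` keeps full precision.

## Problem sizes

The verification suite uses 1,000 replicates for each operating-
characteristic estimate (binomial se ≈ 0.007 at a rate of 0.05), 100
random instrument sets for oracle equivalence, 200-replicate bootstraps
inside simulation grids and 1,000 standalone, and 2,000 draws for
dispersion checks — sizes at which every Monte-Carlo band tested is wide
relative to its standard error.
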