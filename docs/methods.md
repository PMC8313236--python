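# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Effect sizes

The unit of analysis is one effect size describing how within-group
relatedness relates to mortality or pathogen abundance across the
groups of one study.

**Zr.** Reported statistics are converted to a Pearson correlation `r`
using the canonical meta-analytic conversions (`t → sqrt(t²/(t²+df))`;
F with one numerator df treated as `t² = F`; `χ²(1) → sqrt(χ²/N)`), or
computed from high/low-relatedness arm summaries via the standardised
mean difference `d` with pooled SD and the unequal-n conversion
`r = d / sqrt(d² + (n_L+n_H)²/(n_L n_H))`, which reduces to
`d/sqrt(d²+4)` at equal arm sizes. `r` is Fisher-transformed,
`Zr = atanh(r)`, with sampling variance `1/(n−3)` where `n` is the
number of *groups*. Values reported on a survival scale are
sign-flipped once onto the mortality scale, tracked by a provenance
column so the flip can never be applied twice.

When only per-group descriptive statistics are available, `r` is
estimated by Monte Carlo: each of (by default) 1000 replicate datasets
draws one value per group for relatedness and outcome independently
from normal distributions with the reported means and SDs, computes
the Pearson correlation across groups, and the replicate average is
used. Draws are untruncated by default (clipping to a natural range is
available behind a flag): the Pearson correlation is shift/scale
equivariant, so truncation mainly matters for strongly bounded
outcomes, and leaving it off keeps the estimator's behaviour
transparent. The normal family is an assumption; nothing in the
reported summaries identifies the true within-group distribution.

**LnCVR.** Differences in *across-group variability* are measured by
the log coefficient-of-variation ratio
`ln(CV_high) − ln(CV_low) + 1/(2(n_H−1)) − 1/(2(n_L−1))`
(small-sample corrections cancel at equal arm sizes). Its sampling
variance sums, over both arms,
`s²/(n x̄²) + 1/(2(n−1)) − 2ρ sqrt(s²/(n x̄²) · 1/(2(n−1)))`,
where ρ is the correlation between log mean and log SD. ρ defaults to
0; `log_mean_sd_correlation` estimates it empirically across all arms
of a dataset (falling back to 0 below four usable arms), and callers
can override it per arm. Whether ρ should be estimated globally or
per study is not determined by the data themselves; the global
empirical estimate is the package's default because individual studies
rarely contain enough arms to estimate it stably.

Dispersions reported as SE or 95% CI half-widths are converted to SD
(`se·sqrt(n)`; CI half-width divided by 1.96 first).

## Phylogeny

Without a dated molecular phylogeny, a topology is derived from ranked
taxonomic lineages: species sharing a longer lineage prefix nest more
deeply; ranks constant across the whole dataset and unary chains are
collapsed; polytomies are kept as-is (taxonomy cannot resolve them and
the correlation matrix handles them natively — no random resolution).
Grafen heights are then assigned: a node with `k` descendant tips gets
height `((k−1)/(S−1))^power` (power 1 by default, exposed as an
option), tips sit at height 0, and branch lengths are parent−child
height differences. The result is ultrametric with depth 1, so the
species correlation is directly the shared fraction of the
root-to-tip path: `corr(i,j) = depth(MRCA(i,j))`. Scaling to depth 1
loses nothing — the meta-regression multiplies the matrix by a free
phylogenetic variance component.

## The meta-regression (BPMM)

Effect sizes are modelled as

    y_i = x_i'β + u_study(i) + u_species(i) + u_phylo(i) + m_i + e_i

with `u_study ~ N(0, σ²_study I)`, `u_species ~ N(0, σ²_species I)`,
`u_phylo ~ N(0, σ²_phylo A)` for the species correlation matrix `A`,
residual `e_i ~ N(0, σ²_e)`, and the measurement term
`m_i ~ N(0, v_i)` whose variance is the effect size's known sampling
variance. `m_i` is sampled in the Gibbs sweep but its variance is
never updated; this is how inverse-variance weighting enters the
model, and it is deliberately excluded from heterogeneity summaries.

Priors: each fixed effect `N(0, 10^10)`; each free variance component
inverse-gamma with `V = 1, nu = 0.002`, parameterised as
shape `= nu/2 = 0.001` and rate `= V·nu/2 = 0.001` (stated explicitly
because inverse-gamma parameterisations differ across texts).

Sampling is conjugate Gibbs in a fixed order — β (one blocked
multivariate-normal draw, which cuts autocorrelation relative to
scalar updates) → study → species → phylo → measurement deviates →
variances. The phylogenetic block is a joint S-dimensional draw using
the precomputed `A⁻¹`. Two numerically identical engines exist: a
numpy reference implementation and a numba-compiled sweep (the
default); they draw from the same RNG stream in the same order and a
test asserts their draws agree.

Observations are canonically sorted inside `fit`, so posterior draws
depend only on the data multiset, not on input row order.
`fix_residual_variance` and `fix_variance_components` hold variance
components constant; these are testing hooks that enable exact
closed-form cross-checks (precision-weighted normal posterior with no
random effects; dense multivariate-normal marginal with all components
fixed).

**Chain schedules.** `paper`: 1.1M iterations, 100k burn-in, thinning
1000, 3 chains (1000 retained draws per chain). `desk`: 110k/10k/100,
3 chains — the same estimand and retained-draw count at a tenth the
cost; the package's working default. `smoke`: 11k/1k/10, 2 chains, for
pipeline checks only. Replicate batteries (parameter recovery, Egger
calibration) use single-chain variants since convergence diagnostics
are not the quantity under study there; the Egger battery uses a
33k/3k/30 single chain, which retains the standard 1000 draws.

**Summaries.** Point estimates are posterior modes from a Gaussian KDE
(Silverman bandwidth, 512-point grid over the draw range); intervals
are 95% highest-posterior-density (shortest) intervals; significance
is `pMCMC = 2·max(1/N, min(frac above 0, frac below 0))`, capped at 1,
with the `2/N` floor acknowledging the finite posterior sample. A
contrast of a level with itself yields `pMCMC = 1` by convention.
Convergence is monitored by the Gelman–Rubin PSRF
`sqrt(((n−1)/n·W + B/n)/W)` floored at 1 (values below 1 are
finite-sample artifacts; identical chains report exactly 1.0).

The *phylogenetic variance fraction* (and its analogues) is, per draw,
`100·σ²_c / (σ²_study + σ²_species + σ²_phylo + σ²_e)`. The fixed
measurement variances are excluded from the denominator, following the
conventional phylogenetic-heritability definition; including the mean
`v_i` would make the fraction depend on study sizes rather than
biology.

With `A = I` the species and phylogenetic terms are exchangeable and
only their sum is identified; tests therefore assert recovery of the
sum, never the split.

## The analysis battery

All models are fitted without a global intercept — one coefficient per
factor level — so level posteriors and pairwise contrasts are direct
linear combinations of β, computed per draw. The battery: (1)
intercept only; (2) three-level fitness measure (mortality with
pathogens present / mortality with pathogens absent / pathogen
abundance); (3) pathogen presence × pathogen manipulation (4 levels);
(4) pathogen presence × relatedness manipulation (4 levels, the "full
model"); (5) kin structure × pathogen presence × pathogen manipulation
(8 levels); (6) the LnCVR refits of structures 1–4 (variance data are
too sparse across non-kin species for the eight-level model). Empty
factor cells are reported as *unavailable* — never silently dropped —
and every expected level pair appears in the contrast table.

**Verification refits** of the full model: (a) excluding records where
inbreeding could have contaminated relatedness estimates; (b)
restricting to observational-pathogen records and crossing pathogen
presence with the lab/field setting (experimental studies are all
laboratory studies, so the lab/field question is only identified in
the observational subset); (c) adding the reported analysis technique
as an extra iid random term.

**Publication bias.** Egger's test refits the full model with the
mean-centred inverse sampling variance `1/v_i` as a continuous
covariate; centring shifts the level coefficients but not the slope.
A slope CI excluding zero indicates funnel asymmetry. `funnel_data`
exports per-record meta-analytic residuals (observed minus
fixed-effect prediction at the posterior mean) against precision
`1/sqrt(v_i)`; rendering is out of scope.

**Relevance scoring.** The literature screening helper scores an
abstract by summed weighted counts of positive minus negative
keywords, lowercase word matching, default weight 1. The priority
*ordering* of the positive list is ignored — it existed to sort
manual screening queues and has no defined numerical semantics.

## Synthetic data

The generator emulates the structure of the real evidence base: 56
species on a taxonomy-derived tree, 75 studies (every species gets at
least one), 210 Zr effect sizes (1–6 per study), 106 of them with
LnCVR companions, per-effect sampling variances `1/(n_groups−3)` with
group counts drawn from a shifted negative binomial (minimum 4, mode
~10 — echoing that the underlying studies overwhelmingly used five or
more individuals per group and giving a realistic spread for funnel
diagnostics). Moderators are assigned balanced by default; a
`kin_imbalance` option reproduces the observed 41 kin / 15 non-kin
species split. Default truth: experimental absent-vs-present contrast
−0.4 (±0.2 level means), observational levels at 0.05, all four
variance components 0.05. LnCVR companions carry their own
random-effect draws (a variance response is a different quantity) with
zero true contrasts by default and plug-in sampling variances at a
CV of 0.3.

Raw-study simulation produces group-level tables (binomial mortality
or negative-binomial pathogen counts) with a latent generating
correlation, for end-to-end tests of the effect-size converters. The
selection-bias operator drops qualifying records (negative value with
above-median sampling variance, the classic censoring) with a set
probability and/or inflates them, recording what it did so tests can
condition on the induced censoring.

What the generator does *not* emulate: non-Gaussian effect-size
distributions, correlated moderators (confounding), unbalanced or
missing-not-at-random moderator cells beyond what censoring induces,
within-study correlation of effect sizes beyond the shared study
intercept, and real phylogenetic signal strength. Passing recovery
tests therefore demonstrates correctness of the machinery under the
model's own assumptions, not robustness to their violation on real
data.

## Problem sizes and tolerances

The recovery battery uses 20 replicates of 200 effects across 50
species with the `desk` schedule (single chain): large enough that
the 95% HPD should cover a −0.4 contrast in at least 18 of 20
replicates with posterior-mode bias under 0.1. The Egger battery uses
400 effects across 120 studies: a pilot power analysis showed the
slope of the induced censoring signal at 200 effects is comparable to
its posterior spread, so the battery size was set where the induced
asymmetry is reliably detectable while unbiased data still cover zero.
Monte-Carlo cross-checks (LnCVR variance formula) use 10,000
replicates and a 15% tolerance, consistent with the delta-method
character of the formula. Numerical tolerances: ultrametricity 1e−9,
PSD eigenvalue floor −1e−10, Newick round-trip 1e−12.

## Known limitations

* The Gibbs sampler is Gaussian-response only; no parameter expansion
  or slice sampling, so extremely small variance components mix slowly
  (mitigated by thinning).
* KDE posterior modes wobble on the bandwidth scale; for strongly
  skewed posteriors the mode can sit outside narrow HPD intervals'
  midpoints — both are reported so neither is silently preferred.
* Taxonomy-derived trees place all structure at rank boundaries;
  Grafen heights are a topology transform, not divergence times.
* The relevance scorer is a bag-of-words helper for sorting abstracts,
  not a screening classifier.
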