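# Methods

`scdpaf` implements the population-attributable-fraction (PAF) analysis
used in the dementia-prevention literature — and in the 2015–2018 BRFSS
analysis of subjective cognitive decline (SCD) whose published panels
this package replays — as a tested, reusable pipeline over
complex-survey microdata.  This note records the models, the default
parameters and why, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The outcome and the nine factors

SCD is the self-reported experience of worsening or more frequent
confusion or memory loss over the past 12 months, captured by a single
yes/no survey item; "Don't know" and "Refused" responses are excluded
from the analytic set, as are respondents under 45.  The nine modifiable
risk factors (limited education, deafness, social isolation, depression,
current smoking, physical inactivity, obesity, hypertension, diabetes)
are tri-state recodes of standard BRFSS items.  The recode rules follow
the published coding exactly; two deserve note:

* *Social isolation* is yes when needed social/emotional support is
  never or rarely received **or** arthritis limits social activities "a
  lot"; no when support is always/usually/sometimes received; missing
  when the support item is unanswered and the arthritis item gives no
  positive signal.  The arthritis item alone can therefore assert yes
  but never no — the literal reading of the published rule.
* *Hypertension* and *diabetes* count pregnancy-only and
  borderline/pre-conditions as **no**.

Unknown response codes raise a coding error rather than becoming
missing, so instrument drift is surfaced, and factor-level missingness
is carried through: every estimator is complete-case *per factor*,
because each factor is observed on a different subsample (year
availability and state module election).

## Design-based estimation

All survey estimates are Horvitz–Thompson ratio estimators over the
stratum/PSU/weight triplet, with stratified between-PSU Taylor
linearization for variances — the estimator SAS's SURVEY procedures and
R's `survey` package use.  Domain estimates keep the full design and
zero out-of-domain scores.  Single-PSU strata are handled by the
"adjust" policy (center the stratum at the grand mean of PSU totals),
switchable to "fail"; synthetic designs can produce singleton PSUs, so a
silent default mattered.  The demographic association test is the
second-order (Satterthwaite) Rao–Scott-corrected Pearson chi-square
referred to F with the design degrees of freedom.  Its null calibration
is checked by simulation against a cluster-correlated true null in which
both table margins vary independently at PSU level — independence holds
exactly while the design effect exceeds one.

## Relative risks

The default risk model is modified Poisson regression: a log-link
working-Poisson model of the binary outcome with survey weights, whose
exponentiated coefficients are relative risks; variances come from a
sandwich whose meat is the stratified between-PSU covariance of the
weighted score.  Log-binomial is available behind `family="binomial"`
but fails to converge far more often with ~50%-prevalent exposures,
which is why it is not the default.  Categorical covariates are
reference-coded at their most frequent level (stable at any sample
size).  95% CIs are Wald on the log scale, matching the symmetric-in-log
intervals of the published tables.  A crosstab route (`unadjusted_rr`
on weighted 2×2 masses with a linearized log-RR CI) is provided because
the published unadjusted estimates may come from either route; the PAF
layer accepts both.

## Communality

The factors' shared variance is estimated from the *weighted* (no
strata, no clusters — deliberately, matching the published analysis)
tetrachoric correlation matrix.  Each pairwise tetrachoric is the
maximum-likelihood latent correlation: thresholds are inverse-normal of
the weighted margins and rho solves "bivariate-normal upper-orthant mass
= weighted joint proportion" by monotone Brent root-finding, clipped to
±(1−10⁻⁶).  A table with one empty cell gets the standard continuity
correction (0.5 × mean weight added to every cell); a table with *both*
cells of a diagonal empty is perfect concordance/discordance and attains
the clipped boundary directly (a continuity correction there would
manufacture an interior estimate for a boundary ML solution).  Pairs are
estimated on pairwise-complete cases with per-pair n recorded; the
matrix is repaired to the nearest unit-diagonal PSD matrix (eigenvalue
clipping) when needed, and the repair is flagged.

Communality is then PCA on that matrix: components retained by the
Kaiser rule (eigenvalue > 1; the convention of the attributable-fraction
literature this follows), configurable to a fixed count; the communality
of factor *i* is its sum of squared retained loadings
(eigenvector element × √eigenvalue).  Under Kaiser, a matrix of mutually
independent factors retains nothing and raises a degenerate-case error
rather than returning zeros.

## The PAF calculus

Per factor, Levin's formula `PAF = p(RR−1)/(1+p(RR−1))`; negative PAFs
(RR < 1) propagate untruncated.  The overall PAF combines
multiplicatively, `1 − Π(1−PAF_i)`; the communality-weighted overall
discounts each factor by its unique-variance share,
`1 − Π(1−(1−c_i)·PAF_i)`; and per-factor weighted PAFs apportion that
overall by unweighted-PAF share, `wPAF_i = PAF_i/ΣPAF_j · wPAF`, summing
to the overall exactly.  The apportionment-by-PAF-share form was
validated cell-by-cell against all six published panels before the build
(maximum discrepancy 0.033 percentage points); the plausible alternative
— apportioning by (1−c_i)-discounted share — misses the published cells
by 3–8 points and is therefore not what the published tables used.

All arithmetic is on fractions; percentages appear only at the reporting
boundary, rounded half-even to two decimals.

One reproducibility limit is inherent: the published per-factor inputs
are printed to two decimals.  Because ∂PAF/∂RR ≈ p/(1+p(RR−1))² reaches
~0.3 at p≈0.5, the half-ulp RR rounding (±0.005) alone permits ±0.15pp
of slack in a recomputed PAF cell, and about a quarter of the published
PAF cells recompute 0.05–0.11pp away from print.  The weighted-PAF and
overall cells are insensitive to this and reproduce to ≤0.05pp on the
reporting scale.  The test suite asserts both the strict sweep and the
rigorous version (printed cell inside the Levin image of the input
rounding intervals); the strict PAF-column sweep fails only where input
rounding makes it unattainable.

## The synthetic generator

The generator emulates the structure the estimators assume, with every
parameter a recoverable truth:

* **Factors** — thresholded latent multivariate normal (Gaussian
  copula), so configured latent correlations *are* tetrachoric truths.
  The default correlation matrix has a single common factor with
  loadings √(published all-adults communality), making the implied PCA
  communalities land near the published ones.
* **Age confounding** — a per-factor latent mean shift per standardized
  age score (positive for hypertension, diabetes, deafness, inactivity;
  negative for smoking, depression), with thresholds re-solved over the
  discrete age mixture so superpopulation marginals stay at their
  targets (published all-adults prevalences, 4.78–52.38%).  The implied
  marginal latent correlation gains a rank-one term from the shared age
  score; the truth record reports this adjusted matrix in closed form.
* **Outcome** — Bernoulli with log-link risk: baseline × Π RR_f^{x_f} ×
  age multiplier, the published adjusted RRs as conditional truths.  A
  log link (not logistic) makes the configured RRs exactly the modified
  Poisson estimand — no noncollapsibility slack in recovery tests.
  Configs are rejected at load if the maximal lattice risk (all
  harmful factors on, most at-risk age) exceeds 1.  With the nine
  published RRs multiplying to ~51, that cap binds the baseline at
  ≈0.019; the default (0.0185, age multipliers ≤ 1 anchored at the
  oldest group) yields an implied SCD marginal of ≈5.9%, below the
  survey's observed 10.9%.  That trade-off is deliberate: exact
  conditional RR truths were prioritized over matching the observed
  outcome prevalence, which a log-link model with these joint RRs
  cannot reach without invalid risks.
* **Design** — 48 strata × 6 PSUs, respondents sampled with an
  age-increasing inclusion probability (0.60→1.00) and weight =
  inverse inclusion × lognormal noise (σ = 0.3, residual within-cell
  variation), so weighting demonstrably matters: unweighted prevalences
  of age-linked factors are visibly biased, weighted ones are not.
* **Missingness** — year availability (deafness 2016–18, social
  isolation 2015–17), state-coverage fractions calibrated to the
  published per-factor analytic sample shares (social isolation ~13% of
  respondents, hypertension ~61%, deafness ~47%), and per-item
  Don't-know/Refused rates (outcome: 0.7%/0.2%).  The generator's audit
  counts are asserted to match the recode module's output exactly.

What it does **not** emulate: CDC raking and the real BRFSS weight
distribution, state geography, real demographic–factor associations
(demographics other than age are drawn independently), and the observed
SCD prevalence (see the baseline cap above).  Passing recovery tests
therefore show estimator correctness under the assumed structure, not
robustness to real-data model violations.

## Problem sizes and replications

Unit tests use 4,000–100,000 synthetic respondents per scenario.  The
headline recovery study runs 20 replicates of n = 50,000 (fixed seeds)
with one joint modified-Poisson fit per replicate — all nine factors
plus age dummies, the correct conditional estimand under the correlated
default config; CI coverage is pooled over the 180 resulting intervals
because per-factor coverage at 20 replicates moves in 5-point steps.
Rao–Scott calibration uses 500 null tables of n = 20,000.  The full
suite runs in about a minute on one CPU; `scripts/acceptance.py`
(published-panel replay, a 100,000-respondent synthetic round trip, a
25-table oracle comparison and a 250-table calibration) in under ten
seconds.

## Known limitations

* PAF confidence intervals are out of scope (the published tables print
  none), as are case-control PAF variants, replicate-weight variances,
  and polychoric (>2-level) correlations.
* The tetrachoric model assumes an underlying bivariate normal; with
  age-shifted latents the marginal latent distribution is a normal
  mixture, so the closed-form "true" matrix is itself a (very good,
  |shift| ≤ 0.35) approximation.
* The Rao–Scott F reference is mildly conservative at small design
  degrees of freedom.
* Raw-data interchange is CSV; SAS transport files are not read
  directly.
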