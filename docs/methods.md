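# Methods

`caretraj` implements a person-centered analysis of children's mental-health
service utilization: from raw visit records to latent service-use patterns
and their prediction from intake characteristics. This note documents the
models, the synthetic-data generator that stands in for restricted registry
data, the numerical choices, and the limitations of each.

## Cohort construction

A child's **index visit** is the earliest face-to-face visit inside the
intake window (default 2004-01-01 to 2006-12-31) preceded by at least 18
months (548 days = round(365.25 × 1.5)) with no face-to-face contact.
Children are then excluded, in order, if younger than 5 or older than 13 at
the index visit (age as completed years from exact dates; eligibility is
5 ≤ age < 14), if flagged for a pervasive-developmental-disorder /
developmental-disability program, or if a complete prior episode of care
ended within 548 days before the intake window opened. The last rule is
anchored at the window start deliberately: the index rule already
guarantees a visit-free 548-day span before the index, so "a prior episode
ending within 548 days of the index" is unsatisfiable; anchoring at the
window start is the only reading under which the rule can remove anyone.
Attrition is logged per rule in application order, so counts are
order-dependent but exactly reproducible.

## Months and episodes

Month *m* after the index covers day offsets
[round((m−1)·365.25/12), round(m·365.25/12)) — fixed-width ~30.44-day bins,
deterministic and timezone-free, rather than calendar months. The
**trajectory matrix** holds one 0/1 indicator per child-month over 48
months; column 1 is all ones by construction.

An **episode of care (EoC)** is a chronological cluster of ≥ 3 visits;
clusters split wherever the gap since the previous visit is ≥ 180 days
(six months taken as the conventional 180 days; the gap is measured from
the last visit of one cluster to the first of the next, with a split at
exactly 180). Sub-threshold clusters are retained as non-episode contacts
so scattered pre- and post-episode visits remain reportable. Greedy
splitting at every ≥ 180-day gap yields the unique partition consistent
with the rule; the test suite checks it against an exhaustive partition
enumerator on small instances. Duration of involvement is
(last − first visit)/365.25 years; "long involvement" is strictly more
than 2 years (a duration of exactly 2.0 does not count).

## Latent class analysis

Visit indicators are modelled as a finite mixture of independent Bernoulli
profiles: with class weights π_k and conditional visit probabilities θ_kj,

  P(x_i) = Σ_k π_k Π_j θ_kj^{x_ij} (1−θ_kj)^{1−x_ij}.

Estimation is EM from 10 random starts (θ initialized uniform on
[0.25, 0.75], weights uniform), E-step in log space, up to 250 iterations
at relative log-likelihood tolerance 1e-7 followed by a polish phase of up
to 50 further EM iterations at 1e-8. The polish phase replaces the
Newton-Raphson finisher of commercial LCA software: the maximizer, not the
algorithm, defines the estimate, and continued EM reaches the same
stationary point. θ is floored at ε = 1e-6 to keep log-likelihoods finite.
Classes are reported in canonical order of descending π (label switching),
and substantive pattern names are assigned afterwards from descriptives,
never from class index.

Model selection scans K = 2..10 (2..7 in the packaged runs) and keeps
growing while the mean relative improvement of AIC (−2ℓ+2p),
BIC (−2ℓ+p ln n) and CAIC (−2ℓ+p(ln n+1)) over the previous K is at least
2% — an a-priori rule, not a significance test. Improvement denominators
use the raw (positive) index values; a guard raises if an index is ≤ 0.
Relative entropy 1 − Σ_i Σ_k(−p_ik ln p_ik)/(n ln K) summarizes
classification certainty. A parametric bootstrap of the goodness-of-fit
statistic G² = 2(ℓ_saturated − ℓ_model) is available (500 replications by
default; the packaged pipeline leaves it off for speed). A grouped-weights
variant (π varying by cohort year or agency, θ shared, (G−1)(K−1) extra
parameters) stands in for multilevel LCA: comparing its BIC with the plain
fit checks whether group structure adds anything. The exact multilevel
parameterization of commercial software (random vs fixed group effects) is
not reproduced.

## Missing data

The four intake scales are handled under a multivariate-normal working
model. One EM engine estimates (μ, Σ) from incomplete data by iterating
conditional expectations over the distinct missingness patterns (a ridge
of 1e-8·I stabilizes pattern-covariance inversions). **Little's MCAR
test** sums n_j (ȳ_j − μ̂_j)ᵀ Σ̂_j⁻¹ (ȳ_j − μ̂_j) over patterns j restricted
to their observed variables, with df = Σ_j p_j − p; a single missingness
pattern is signaled as undefined rather than silently passed.
**EM imputation** replaces each missing cell by its conditional mean given
the row's observed variables at the final (μ̂, Σ̂); observed cells are never
altered. Only the four scale scores enter (age and sex are complete by
construction). Single imputation is intentional; multiple imputation is
out of scope.

## Discriminant function analysis

Canonical linear discriminant analysis predicts pattern membership from
six predictors (sex coded M=1, age at index, four scales). Functions are
eigenvectors of W⁻¹B (within/between SSCP), scaled to unit pooled
within-group variance (pooled covariance divisor n − g); standardized
coefficients multiply by pooled within-group SDs, structure coefficients
are pooled within-group predictor-score correlations. Sequential tests use
Bartlett's approximation: Λ_m = Π_{i>m} 1/(1+λ_i),
χ² = −(n−1−(p+g)/2) ln Λ_m, df = (p−m)(g−1−m). Classification maximizes
the equal-covariance Gaussian posterior with priors (proportional to group
size by default), using all s = min(p, g−1) functions; cross-validation is
a jackknife that refits without each case in turn. Eigenvector signs are
fixed so each function's largest-magnitude standardized loading is
positive. A singular within-groups matrix (collinear predictors) raises
rather than silently regularizing.

## Descriptive layer

Pattern summaries mirror a registry "Table 1": per-pattern n, %, % male,
age, episode-category distribution (0/1/2+), duration, % beyond 2 years,
visits and volume share, plus a prevalence-weighted total row (identical
to pooled child-level values — an exact identity the tests assert).
Chi-square tests report adjusted standardized residuals
(O−E)/√(E(1−row/n)(1−col/n)), whose square is a 1-df cell chi-square.
One-way ANOVA uses Bonferroni-adjusted pairwise t tests on the pooled MSE,
rendered as a compact letter display (groups sharing a letter not
significantly different). Clinical flags use T ≥ 65 (93rd percentile);
comorbidity is three-level: both Externalizing and Internalizing ≥ 65,
exactly one, or neither. Pattern naming from descriptives: highest mean
visits → Ongoing/Intensive-Episodic; lowest → Minimal; of the rest, modal
episode category "2+" → Brief Episodic; the higher-visit remainder →
Intensive, the other → Acute. The episode-category test uses the 3-level
(0/1/2+) categorization throughout.

## Synthetic cohort generator

Real registry data of this kind are restricted, so the generator is the
package's test bed. Per child it draws: a class from the prevalence vector
(53.2, 20.1, 7.9, 13.0, 5.8 %); an index date uniform in the intake
window; a monthly "active" indicator from the class's 48-month probability
profile (month 1 always active — the index visit); 1 + Poisson(rate)
visits per active month, capped at 20, on uniform days within the month
bin; sex (class-specific male probabilities near 62%); an integer age-year
from the marginal distribution 8/10/9/11/12/12/12/13/14 % over ages 5–13
plus a uniform within-year fraction (reconciling the integer-age histogram
with a mean near 9.9); and four T-scores from the class-conditional normal
with exchangeable correlation 0.4 (no published inter-scale correlations
exist; 0.4 is a typical value for related behavioural scales).

The profiles are explicit piecewise-constant 48-vectors — transparent to
calibrate and audit — satisfying three published anchors (Ongoing month 11
= 0.63; Intensive month 21 = 0.22; Brief Episodic month 21 = 0.08), with
the Brief Episodic class showing two activity bumps separated by a
14-month near-zero span and the Ongoing class sustaining 0.63 for 24
months. Per-class visit rates come from the closed form
rate = target_visits / Σ_m profile_m − 1, matching published mean 4-year
visit counts (3.1, 15.6, 28.6, 32.6, 86.7); late-tail monthly rates solve
1 − (1−q)^24 = published share still in contact beyond 2 years.

Missingness defaults to per-scale rates (0.003, 0.03, 0.08, 0.124) for
Externalizing, Internalizing, Impairment and Family Burden — only the two
extreme rates are published; the interior two are placeholders — under a
not-random mechanism: the three non-Externalizing
scales' missingness probabilities follow a logistic curve in the child's
standardized Externalizing score (slope 1.0), rescaled to preserve the
marginal rates. An MCAR mode exists for calibration studies. Demographics
are never masked.

What the generator does **not** emulate: overdispersed per-child visit
counts (real children share therapists and schedules; the conditional
independence of months given class is the LCA's own assumption, so
generated data are "well-specified" for the model in a way real data are
not — parameter-recovery results are upper bounds on real-data fidelity);
agency- or cohort-year heterogeneity (the grouped-weights check is
exercised on separately constructed data); phone/indirect contacts beyond
a constant tag; and within-class skew of visit intensity, which compresses
the episode-category spread of the low-intensity classes relative to
published tables.

## Problem sizes in the packaged runs

The test suite and the acceptance script use n = 3000 children for class-
number selection and weight recovery (the five-class structure is decided
well before this size), n = 5000 for generator-calibration checks, 500
replications at n = 2000 for the MCAR type-I-error study, and n ≈ 1500
for discriminant-analysis examples. These sizes are the package's own
defaults for fast, reproducible verification; the pipeline accepts
arbitrary n.

## Known limitations

- Episode segmentation assumes visit dates are exact days; ties on one day
  count as multiple visits.
- The EM for LCA can in principle stop at a local maximum; 10 starts make
  this unlikely at the packaged sizes but do not exclude it.
- Little's test relies on multivariate normality of the scales; heavy
  tails inflate its rejection rate.
- The jackknife refits the discriminant model n times (O(n · p³));
  adequate up to tens of thousands of cases, not millions.
- Headline real-data quantities (e.g. a ~51% cross-validated
  classification accuracy) depend on the restricted registry and are
  bracketed by property tests on synthetic data, not reproduced exactly.
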