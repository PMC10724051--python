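# Methods

## The model

`cogtraj` analyses longitudinal cognitive composite scores (a Z-scaled
preclinical Alzheimer's cognitive composite, PACC-style) with a hierarchical
Bayesian bent-line regression: each participant's expected score is a
continuous piecewise-linear function of age with a person-specific change
point (CP),

    y_ij ~ Normal( f(a_ij; theta_i), sigma )
    f(a; theta) = alpha1 + alpha2 * min(a - tau, 0) + alpha3 * max(a - tau, 0)

with person-level parameters theta_i = (alpha1 = score at the CP [Z],
alpha2 = pre-CP slope [Z/year], alpha3 = post-CP slope [Z/year],
tau = CP age [years]).  Each parameter is exchangeable across participants
with a normal population law, `theta_k,i ~ Normal(mu_k, sd_k)`.  The CP is
*not* restricted to a participant's observation window: trajectories whose
bend lies before the first or after the last visit are admissible, and their
CPs are informed mainly by the hierarchical prior.  That choice is essential
for preclinical cohorts, where the large majority of change points have not
yet been observed.

Hyperpriors are weakly informative: `mu_alpha* ~ Normal(0, 5)`,
`mu_tau ~ Normal(mean visit age, 15 y)`, half-normal(2.5) on the
between-person SDs (half-normal(10 y) for `sd_tau`) and half-normal(2) on
the residual SD.  All are configurable through `PriorConfig`.  The bend is
exact (max/min algebra); an optional smooth-transition width exists for
sensitivity analyses and defaults to 0.

## Posterior computation

Sampling is Metropolis-within-Gibbs, designed around the model's conjugate
structure:

* the three linear person parameters have Gaussian full conditionals and
  are drawn in closed form (batched 3x3 Cholesky solves across
  participants);
* the population means of the linear block are drawn from their *collapsed*
  Gaussian conditional with the person-level parameters integrated out
  (Woodbury identity), which removes the mean/random-effect ridge;
* each CP is updated by a collapsed Metropolis step against the marginal
  likelihood (linear block integrated out).  Proposals mix a per-person
  adaptive random walk with independence draws from the hierarchical prior
  (and a widened version of it), so weakly identified CPs can jump between
  the before-window / in-window / after-window modes;
* between-person SDs and the residual SD use adaptive random-walk
  Metropolis on the log scale;
* two families of joint moves improve mixing along the remaining slow
  directions: *translation* moves shift one whole hierarchy and its
  population mean together, and *non-centered scale* moves rescale a
  hierarchy about its mean while proposing its SD (a plain MH step in the
  standardized parameterization), which removes the funnel that pins a
  hierarchy when its SD approaches zero.

All adaptation runs during warmup only; retained draws come from a fixed
kernel.  Chain starts are over-dispersed around per-person straight-line
fits so split-R-hat can detect unexplored mass.  Convergence is summarized
with arviz (split-R-hat and bulk ESS per parameter, plus the maximum R-hat
over all person-level parameters); a fit whose maximum R-hat exceeds the
threshold (default 1.05) is flagged, never silently accepted.

Defaults are 4 chains x 5000 iterations with the first half discarded;
desk-scale work (tests, validation studies) uses 2 chains x 1500-2500,
which the mixing improvements above were designed to make adequate.  One
integer seed deterministically derives per-chain seeds.

## Trajectory clustering

The clustering features are the four posterior-median person-level
parameters, standardized to sample Z-scores (mean 0, SD 1, denominator
n-1) so the CP's year units do not dominate Euclidean distance.  K-means is
Lloyd's algorithm with k-means++ initialization, 25 restarts per k and an
assertion that the objective never increases within a run.  The cluster
count is chosen by the Calinski-Harabasz index over k = 2..10; an
all-singleton degenerate solution maps to a +infinity sentinel.  Clusters
are labelled by severity using the mean unstandardized post-CP slope (most
negative = "steep", then "intermediate", then "minimal" for k = 3; ordinal
labels otherwise), with ties broken by the lower mean score-at-CP.  The
severity ordering is a labelling convention only; it never influences the
fit.  A principal-component projection of the standardized features (with a
deterministic sign convention: each component's largest-magnitude loading
is positive) is computed for visual inspection.

## Biomarker harmonization

Non-amyloid biomarkers are Z-scored against a reference subset of
cognitively unimpaired, amyloid-PET-negative participants (global PiB DVR
<= 1.16, last available measure per participant, ties broken by record
order).  Tau PET composites and plasma pTau217 use the simple
(value - mean)/SD transform; the MRI measures (hippocampal volume, global
brain atrophy = CSF/(GM+WM), WMH volume) are first regressed on total
intracranial volume (TICV = GM+WM+CSF) within the reference, and the
Z-score is (observed - predicted)/RMSE with RMSE on n-2 degrees of
freedom.  Primary positivity is a strict fixed threshold (Z > 1.5 where
higher is abnormal; Z < -1.5 for hippocampal volume, where lower is
abnormal); amyloid positivity is DVR > 1.16, strict.  Secondary positivity
fits a two-component unequal-variance Gaussian mixture per modality
(EM via scikit-learn with random restarts, a k-means start and a
tail-quantile start, keeping the highest-likelihood converged fit — a
single initialization can settle in a poor local optimum when the
components are strongly unbalanced).  The abnormal component is the one
whose mean lies further in the pathological direction; the cut-point is the
Z where its posterior membership crosses 0.5 (nearest crossing to the
component-mean midpoint), and flags are posterior >= 0.5.  Fits whose
components fail Ashman's bimodality check (D < 2) carry a low-separation
warning.

## Group comparisons

Health covariates are recoded to standard categories (BMI bands with
half-open bins; sex-specific waist-to-hip-ratio bands, with the overlap at
1.0 for men resolved in favour of "high"; 0-4/5-9/10+ polypharmacy; 3-level
self-rated health and self-rated memory; depression = self-report or, when
absent, CES-D >= 16; sample tertiles of the lifestyle risk score with
type-7 quantile cuts).  Omnibus tests are chi-square (uncorrected) for
categorical variables, switching to Fisher's exact when any expected cell
is below 5 (for tables larger than 2x2, a seeded Monte-Carlo conditional
chi-square permutation test stands in for the exact computation and is
flagged in the output); continuous variables use Kruskal-Wallis by default
or Welch's heteroscedastic ANOVA (statsmodels) by per-variable policy.
Significant omnibus tests (p < 0.05) are followed by all-pairs post-hocs of
the same family; Benjamini-Hochberg correction is applied across all
post-hoc pairs of one reporting table (the family definition is a
configuration choice recorded in the output).  Effect sizes are Cramer's V
(categorical; zero-margin rows/columns dropped with a warning) and Cliff's
delta (continuous).  Sensitivity analyses compute age/sex-adjusted
least-squares group means from a linear model `outcome ~ group + age + sex`
evaluated at the sample-mean age and sex mix, with BH-corrected pairwise
contrasts.  Missing values are excluded pairwise per variable.

## Synthetic cohorts

The generator emulates a late-midlife longitudinal cohort: baseline age
truncated-normal N(58.4, 6.4) on [40, 74], visits at positive
truncated-normal ~2-year intervals, a three-class mixture of bent-line
trajectories with weights (0.072, 0.418, 0.510), and class-correlated
biomarkers and covariates (worse amyloid/tau/neurodegeneration/vascular
values and risk-factor profiles in steeper classes; the female and APOE e4
class prevalences reproduce marginals of 69.1% and 38.1%).  Tissue volumes
satisfy TICV = GM + WM + CSF by construction and hippocampal volume is
generated with positive dependence on TICV, so the head-size adjustment has
real signal to remove.  One seed per cohort is split deterministically per
participant, so growing the cohort never reshuffles earlier participants.
Biomarker missingness is independent Bernoulli per modality (configurable;
no informative-missingness mechanism).

By default the generator emulates the unimpaired-at-entry selection effect
of such cohorts: participants enroll before their change point, so each
person's CP law is truncated below at their first visit age + 0.5 years
(`enroll_before_cp=True`).  Cohorts of initially unimpaired adults report
change points before the first observation only in a percent or so of
participants; unconditional CP draws would instead produce a sizeable
before-window subgroup whose score-at-CP estimates are back-extrapolations
along the post-CP slope — a feature-space artifact real cohorts do not
show.  The flag can be disabled (the parameter-recovery preset does so, so
that recovery cohorts contain CPs on both sides of the observation
window).

Class-conditional trajectory distributions are synthetic conventions, not
estimates: they are chosen once so that the three classes are clearly
separated and recoverable by the full pipeline, and they echo the
qualitative cluster portraits (steep: average level at the CP, earlier CP,
much faster post-CP decline; intermediate: low-average level; minimal: high
level, mild decline).  Three presets exist:

* `GeneratorConfig.default()` — the well-separated three-class validation
  cohort used by the end-to-end cluster-recovery checks;
* `GeneratorConfig.parameter_recovery()` — a single-class design with a
  clearly identifiable bend (pre-CP slope ~0, post-CP slope -0.2 Z/y,
  residual SD 0.3, 6 visits) whose CP law N(63, 4) straddles the
  observation windows, for population-parameter recovery studies;
* `GeneratorConfig.mostly_unobserved_cp()` — late, dispersed CPs
  (N(75, 7)) so that >= 70% of true CPs fall outside observation windows,
  mirroring cohorts in which most change points have not yet occurred.

What passing tests on these cohorts do *not* show: the generator has no
practice effects, attrition-by-decline, test-version changes or item-level
structure, and person-level parameters are independent by default (an
optional correlation matrix exists).  Real cohort data are messier in all
of these respects, and per-person identifiability of the bend is far weaker
in real composites; results on synthetic cohorts validate the machinery,
not the substantive conclusions one would draw from a real cohort.

## Numerical choices and degenerate inputs

* Strict inequalities at every positivity boundary (DVR 1.16, Z +/-1.5).
* Feature standardization refuses zero-variance columns by name.
* The CH index raises for k outside 2..n and returns +infinity when the
  within-cluster sum of squares is exactly zero.
* Empty k-means clusters are re-seeded at the farthest point.
* Tertile cuts use numpy's default (type-7) quantiles; an all-equal score
  vector yields a degenerate single group with a warning.
* A participant with fewer than three visits, non-increasing ages or
  non-finite scores is rejected at construction.
* R-hat with a single chain is reported as not assessable, never silently
  passed.

## Known limitations

* The sampler is single-machine and sequential over chains; very large
  cohorts (tens of thousands) would need a compiled backend.
* Population-mean credible intervals are mildly overconfident for the CP
  age at desk-scale chain lengths when many CPs are unobserved; the
  validation battery tracks interval coverage explicitly rather than
  assuming nominal calibration.
* The Monte-Carlo conditional test for sparse r x c tables is a permutation
  approximation to Fisher's exact test, not the exact network algorithm.
* GMM positivity assumes exactly two components; multi-modal biomarker
  distributions are out of scope.
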