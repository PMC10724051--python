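# cogtraj

Preclinical cognitive decline rarely announces itself: years before a
diagnosis of mild cognitive impairment, a person's cognitive composite
trajectory can quietly bend from stable performance into accelerating
decline.  `cogtraj` is a Python toolkit for characterizing that bend and
what travels with it.  It is written for biostatisticians and cognitive-aging
researchers working with longitudinal cohort data (repeated cognitive
composites, PET/MRI/plasma biomarkers, health covariates).

The pipeline has four stages, each usable on its own:

1. **Bent-line mixed model** (`BentLineModel`) — a hierarchical Bayesian
   random change-point regression.  For participant *i* at age *a*:

       y ~ Normal( α₁ᵢ + α₂ᵢ·min(a − τᵢ, 0) + α₃ᵢ·max(a − τᵢ, 0), σ )
       (α₁ᵢ, α₂ᵢ, α₃ᵢ, τᵢ) ~ Normal(μ, diag(sd²))

   α₁ is the composite score at the change point, α₂/α₃ the slopes before
   and after it, τ the change-point age.  Change points may fall outside a
   participant's observation window.  Posterior sampling is a collapsed
   Metropolis-within-Gibbs scheme written in numpy (see `docs/methods.md`).
2. **Trajectory clustering** (`TrajectoryClusterer`) — K-means on the
   standardized posterior-median person parameters, with the cluster count
   chosen by the Caliński–Harabasz criterion (k ≤ 10) and clusters labelled
   steep / intermediate / minimal decline by mean post-CP slope.
3. **Biomarker harmonization** (`ReferenceZScorer`) — Z-scores anchored to
   a cognitively-unimpaired, amyloid-negative reference subset (simple
   Z for tau PET and plasma pTau217; TICV-regression-adjusted Z for MRI
   volumes), with strict-threshold (±1.5 Z, DVR > 1.16) and
   Gaussian-mixture positivity calls.
4. **Group comparisons** (`compare_groups`) — covariate recoding, omnibus
   tests (χ²/Fisher, Kruskal–Wallis/Welch ANOVA), BH-corrected pairwise
   post-hocs, Cramér's V / Cliff's delta effect sizes, and age/sex-adjusted
   least-squares means.

A synthetic-cohort generator (`GeneratorConfig`, `generate_cohort`) with
known ground truth makes every stage testable end to end; real cohort data
drop in through the same CSV interfaces.

## Worked example

```python
from cogtraj import (BentLineModel, GeneratorConfig, TrajectoryClusterer,
                     generate_cohort)

cohort = generate_cohort(GeneratorConfig.default(n_participants=300, seed=7))
fit = BentLineModel(chains=2, iterations=2500, seed=8).fit(cohort.long)
print(fit.fixed_effects_.loc[["mu_alpha3", "mu_tau"], ["median", "q5", "q95"]])

clusters = TrajectoryClusterer(kmax=10, random_state=9).fit(fit.person_params_)
print("selected k:", clusters.best_k_)
print(clusters.results_frame()["severity_label"].value_counts())
```

prints (numbers from this exact invocation):

```
            median       q5      q95
mu_alpha3  -0.1427  -0.1633  -0.1228
mu_tau     64.4918  63.9206  65.0236
selected k: 3
severity_label
minimal         157
intermediate    124
steep            19
```

The population post-CP slope and change-point age are recovered near the
generator's mixture-averaged truth, the Caliński–Harabasz criterion selects
three trajectory groups, and the severity labels split the cohort into a
small steep-decline group and two larger groups — the qualitative structure
such cohorts show.

The same pipeline runs from the shell:

```bash
cogtraj run-all --seed 7 --n 300 --out results/demo
cogtraj simulate --seed 1 --n 500 --out results/sim   # single stages
cogtraj fit --input results/sim/cohort_long.csv --chains 2 --iter 1500 \
    --seed 2 --out results/fit
```

Every run writes CSV/JSON artifacts plus a `manifest.json` with checksums,
stage timings and convergence summaries.

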