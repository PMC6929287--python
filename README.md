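# caretraj

Person-centered analysis of longitudinal service-use trajectories in
children's mental-health care.

Administrative registries record when a child visits a community
mental-health agency, but "average number of visits" hides the structure
that matters for planning: some children come a handful of times and leave,
others return in discrete episodes years apart, a small group stays in
near-continuous care and absorbs a third of all delivered visits.
`caretraj` is a library for finding and characterizing those patterns. It
is aimed at health-services researchers and biostatisticians working with
visit-level administrative data (or, as here, with a calibrated synthetic
stand-in, since real registries of this kind are access-restricted).

## What it does

- **Cohort construction** — index-visit identification (first face-to-face
  visit with an 18-month clean lookback), age/diagnosis/prior-episode
  exclusions, ordered attrition logging.
- **Episode-of-care segmentation** — clusters of ≥ 3 visits separated by
  ≥ 6 months without contact, plus per-child utilization descriptives
  (visits, duration, episode counts, volume shares).
- **Latent class analysis** — binary-indicator mixture model
  P(x_i) = Σ_k π_k Π_j θ_kj^{x_ij}(1−θ_kj)^{1−x_ij} over 48 monthly visit
  indicators, fit by multi-start EM; the number of classes K is chosen by
  an a-priori rule: keep adding classes while AIC, BIC and CAIC improve by
  ≥ 2% on average. Entropy, modal assignment, parametric-bootstrap
  goodness of fit, and a grouped-weights variant for agency/cohort checks.
- **Missing data** — Little's MCAR test and multivariate-normal EM
  imputation for the four intake T-score scales.
- **Discriminant prediction** — canonical discriminant function analysis
  (eigenvectors of W⁻¹B) of pattern membership from sex, age and the four
  scales: Wilks' Λ sequential χ² tests, standardized and structure
  coefficients, centroids, prior-weighted classification, jackknife
  cross-validation.
- **Synthetic cohorts** — a seeded generator calibrated to published
  registry descriptives (five classes with prevalences 53.2/20.1/7.9/13.0/
  5.8%, per-class monthly visit-probability profiles, visit volumes,
  class-conditional T-scores, non-random missingness), so the whole
  pipeline is testable without any data access.

## Worked example

```python
import pandas as pd
from caretraj import simulate, trajectories, lca, groupstats

cfg = simulate.default_config(n_children=1500, seed=5)
sim = simulate.sample_cohort(cfg)
idx = pd.Series(sim.visits.groupby("child_id")["visit_date"].min())
X = trajectories.trajectory_matrix(sim.visits, idx)

trace = lca.select_num_classes(X.to_numpy(), range(2, 8), seed=5)
fit = trace.fits[trace.chosen_k]
print(trace.chosen_k, round(fit.entropy, 3))

assign = pd.Series(lca.modal_assignment(fit.posteriors), index=X.index)
summaries = trajectories.summarize_cohort(sim.visits, idx)
names = groupstats.assign_pattern_names(summaries, assign)
for k, w in enumerate(fit.model.pi):
    print(f"{names[k]:<28s} {w * 100:5.1f}%")
```

prints

```
5 0.953
Minimal                       55.1%
Acute                         18.2%
Intensive                     12.4%
Brief Episodic                 8.3%
Ongoing/Intensive-Episodic     6.0%
```

The selection rule lands on five classes; the estimated weights recover
the generating prevalences within sampling error, and entropy near 1
indicates sharply separated posteriors. Each script in `examples/`
demonstrates one capability the same way (simulation, filtering, episode
segmentation, class discovery, missing data, discriminant prediction,
full pipeline). A thin CLI wraps the stages:
`caretraj all --n 3000 --seed 1 --outdir run/`.

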