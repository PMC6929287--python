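"""Predict service-use pattern from intake characteristics with canonical
discriminant function analysis.

Six predictors (sex, age, four T-scored scales) discriminate the five
patterns; Bartlett's chi-square tests the canonical functions sequentially,
and classification uses prior-weighted Gaussian discriminant scores with
jackknife cross-validation.
"""

import numpy as np

from caretraj import dfa, simulate

cfg = simulate.default_config(n_children=1200, seed=4)
sim = simulate.sample_cohort(cfg)
cov = sim.covariates
X = np.column_stack([
    (cov["sex"] == "M").astype(float),
    cov["age_at_index"].to_numpy(float),
    cov[list(simulate.SCALES)].to_numpy(float)])
labels = np.array([simulate.CLASS_NAMES[k] for k in sim.true_labels])

model = dfa.fit(X, labels)
print("eigenvalues:", model.eigenvalues.round(4),
      "| % variance:", model.percent_variance().round(1))
for row in dfa.wilks_sequence(model):
    print(f"  after removing {row['functions_removed']} function(s): "
          f"Wilks lambda = {row['wilks_lambda']:.3f}, "
          f"chi2({row['df']}) = {row['chi2']:.1f}, p = {row['p']:.3g}")

rep = dfa.report(X, labels)
print(f"resubstitution accuracy {rep.resubstitution_accuracy:.1f}%, "
      f"leave-one-out {rep.loo_accuracy:.1f}%")
# Accuracy sits well above the largest-class share only when the intake
# scales genuinely separate the patterns; overlapping T-score
# distributions keep it modest, as in real registries.
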