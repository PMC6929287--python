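"""Discover service-use patterns with binary latent class analysis.

Monthly 0/1 visit indicators are modelled as a mixture of independent
Bernoulli profiles. The number of classes grows while AIC, BIC and CAIC
improve by at least 2% on average; classes are then named from their
descriptives.
"""

import pandas as pd

from caretraj import groupstats, lca, simulate, trajectories

cfg = simulate.default_config(n_children=1500, seed=5)
sim = simulate.sample_cohort(cfg)
idx = pd.Series(sim.visits.groupby("child_id")["visit_date"].min())
X = trajectories.trajectory_matrix(sim.visits, idx)

trace = lca.select_num_classes(X.to_numpy(), range(2, 8), seed=5)
print("K  BIC        avg improvement")
for row in trace.table:
    imp = ("" if row["avg_improvement"] is None
           else f"{row['avg_improvement'] * 100:5.2f}%")
    mark = "  <- chosen" if row["chosen"] else ""
    print(f"{row['K']}  {row['bic']:10.1f} {imp}{mark}")

fit = trace.fits[trace.chosen_k]
print(f"\nentropy {fit.entropy:.3f} (1 = perfectly separated classes)")
assign = pd.Series(lca.modal_assignment(fit.posteriors), index=X.index)
summaries = trajectories.summarize_cohort(sim.visits, idx)
names = groupstats.assign_pattern_names(summaries, assign)
print("estimated class weights:")
for k, w in enumerate(fit.model.pi):
    print(f"  {names[k]:<28s} {w * 100:5.1f}%")
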