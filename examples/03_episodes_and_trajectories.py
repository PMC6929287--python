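"""Segment a visit stream into episodes of care and code monthly indicators.

An episode of care is a cluster of at least three visits separated from
other clusters by at least six months (180 days) without contact. Smaller
clusters are kept as non-episode contacts.
"""

import numpy as np

from caretraj.trajectories import (month_indicators, segment_episodes,
                                   summarize_service_use)

# two scattered early visits, a 13-visit episode ~2 years in, a long gap,
# then an 18-visit episode over 7 months, all inside the 48-month window
days = [0, 60] + list(range(730, 912, 14)) + list(range(1240, 1444, 12))
part = segment_episodes(days)
summary = summarize_service_use(part, days)

print(f"{len(part.clusters)} clusters, {part.n_episodes} episodes of care")
for c in part.clusters:
    kind = "episode" if c.is_episode else "contact"
    print(f"  days {c.first:5.0f}-{c.last:5.0f}: {c.n_visits:2d} visits "
          f"({kind})")
print(f"total visits {summary.total_visits}, duration "
      f"{summary.duration_years:.2f} years, category "
      f"{summary.episode_category!r}, gap between episodes "
      f"{summary.inter_episode_gap_months:.1f} months")

v = month_indicators(np.array(days))
print("months with >=1 visit:", [int(m) for m in np.nonzero(v)[0] + 1])
# The binary 48-vector above is one row of the matrix the latent class
# analysis consumes.
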