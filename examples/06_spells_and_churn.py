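"""Longitudinal checks: spells, durations, churn, trajectory screens.

The worked micro-example: a unit observed in periods {1,2,3,6,7} has two
spells separated by a 2-period gap — churn under a 4-month window, not
under a 1-month window.  Then the same machinery runs on a synthetic
panel with planted trajectory defects.
"""

import pandas as pd

from adminqc import PanelDataset, churn_events, extract_spells, spell_statistics, trajectory_checks
from adminqc.synthetic import SyntheticConfig, simulate_panel

rows = [("A", f"2011-{m:02d}") for m in (2, 3, 4, 7, 8)]  # periods 1,2,3,6,7
rows += [("B", "2011-01"), ("B", "2011-10")]  # fixes the 10-period window
panel = PanelDataset.from_frame(pd.DataFrame(rows, columns=["id", "month"]), "id", "month")
st = extract_spells(panel)
print(st.spells.to_string(index=False))
for g in (4, 1):
    print(f"churn events with window G={g}: {churn_events(st, window=g).n_events} (unit A's gap is 2 periods)")

cfg = SyntheticConfig(n_units=2000, seed=5, stable_flip_rate=0.01, monotone_violation_rate=0.01)
big, truth = simulate_panel(cfg)
spells = extract_spells(big)
stats = spell_statistics(spells)
churn = churn_events(spells, window=4)
print()
print(stats.durations.to_string(index=False))
print(f"churn rate per completed spell: {churn.rate_per_completed_spell:.3f} "
      f"(re-entry within {churn.window} months after an exit)")

traj = trajectory_checks(big)
print(
    f"trajectory screens: {traj.stable['sex']['count']} sex flips, "
    f"{traj.monotone['months_on_benefits']['count']} benefit-counter decreases "
    f"(injected: {truth.count('stable_flip')} and {truth.count('monotone')})"
)
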