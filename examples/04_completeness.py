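"""Completeness: coverage by county, duplicates, item nonresponse.

Generates a small synthetic panel with injected duplicates and
domain-dependent income missingness, then shows each completeness check
recovering what was planted.
"""

from adminqc import detect_duplicates, coverage_by_area, missingness_by_domain, missingness_by_variable
from adminqc.synthetic import SyntheticConfig, simulate_panel

cfg = SyntheticConfig(
    n_units=2000,
    seed=42,
    duplicate_rate=0.005,
    missing_rates={"single_parent": 0.15, "two_parent": 0.05},
)
panel, truth = simulate_panel(cfg)

dup = detect_duplicates(panel)
print(f"duplicates: {dup.excess_records} excess records detected "
      f"(ledger says {truth.count('duplicate')} were injected)")

miss = missingness_by_variable(panel, key_vars=["income", "benefit"])
print(f"units with any missing key variable: {miss.unit_any_missing_count} "
      f"({miss.unit_any_missing_proportion:.1%})")

dom = missingness_by_domain(panel, "income", "case_type")
print()
print(dom.to_string(index=False))
print("Income nonresponse differs by case type exactly as injected "
      "(0.15 / 0.05 / 0) — complete-case subgroup comparisons would be biased.")

cov = coverage_by_area(panel, "county")
print()
print(f"coverage screen: {cov.n_findings} flagged county-month cells "
      f"(zero or < {cov.low_fraction:.0%} of the county's own median count)")
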