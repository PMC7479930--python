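# adminqc

Data-quality assessment for state and local administrative panel data.

Agencies that administer assistance programs (SNAP, TANF, Medicaid,
unemployment insurance, child-care subsidies) hold monthly caseload files
that are valuable for policy research but were never designed as
statistical datasets: metadata are thin, entry errors and duplicates are
common, and eligibility rules change over time. `adminqc` packages the
standard quality checks an analyst should run on such a file **before**
using it for research, organized by the quality dimensions that matter
most for a standalone administrative source:

- **Accuracy** — identification-key syntax (e.g. SSN structure), a
  declarative edit-rule engine (validity rules from the codebook plus
  *dubious*-value plausibility screens), and outlier analysis via Tukey
  fences and letter-value (boxen) summaries;
- **Completeness** — record counts by geographic area with an
  undercoverage screen, exact-duplicate detection over the id/time key or
  any analysis-variable tuple, and item-nonresponse analysis overall, by
  unit, and by analyst-defined domain;
- **Comparability** — quantile tables and histograms, *tableplots*
  (equal-size percentile-bin summaries of many variables against one sort
  variable, including time), per-period subgroup statistics with a robust
  anomaly screen, and longitudinal checks: receipt **spells**, durations,
  **churn** (exit followed by quick re-entry), and within-unit screens for
  variables that should be stable or monotone.

The expected input is one rectangular **long-format** flat file: one row
per unit per time period, with an identification variable and a time
variable. Duplicated (id, time) rows are loaded, not rejected — they are
themselves a finding.

A seeded **synthetic benefits panel** (100,000 units observed monthly
2011–2015, ≈1.5 million unit-month rows, with recipients, benefit amount,
funding source, other-benefit receipt, case type, county, income and
demographics) plus a labeled **defect injector** (bad keys, duplicate
rows, domain-dependent missingness, outliers, stable-variable flips,
monotone-counter decreases) make the whole pipeline testable with no
access to confidential data: every injected defect is written to a
ground-truth ledger that the checks are tested against.

## Core conventions

All outlier machinery shares the letter-value depth recursion

```
d_1 = (1 + n) / 2,      d_{i+1} = (1 + ⌊d_i⌋) / 2
```

with midpoint interpolation at half-integer depths. Depth 2 gives the
fourths F_L, F_U; Tukey fences are `F_L − k·(F_U − F_L)` and
`F_U + k·(F_U − F_L)` with multiplier `k = 1.5` (3.0 for "far out");
deeper levels give the eighths, sixteenths, … of letter-value displays,
with the number of levels set by the trustworthy rule
`k = max(2, ⌊log₂ n⌋ − 3)`. Tableplots cut the records, stably sorted by
the chosen variable (ties broken by id then period), into `n_bins = 100`
equal-size bins — percentiles of the sort variable — and summarize each
bin per column: mean ± SD for numerics, level frequencies for
categoricals.

## Worked example

```python
from adminqc import tukey_fences, tableplot_over_time
from adminqc.synthetic import SyntheticConfig, simulate_panel

for vals in [range(1, 9), list(range(1, 9)) + [100]]:
    fr = tukey_fences(vals)
    print(fr.lower_fourth, fr.upper_fourth, fr.lower_fence, fr.upper_fence,
          fr.outlier_values.tolist())

panel, _ = simulate_panel(SyntheticConfig(n_units=3000, seed=7))
tpt = tableplot_over_time(panel, ["benefit"], n_bins=10)
print(tpt.numeric["benefit"]["mean"].round(1).tail(5).to_string())
```

prints

```
2.5 6.5 -3.5 12.5 []
3.0 7.0 -3.0 13.0 [100.0]
5    707.0
6    695.4
7    701.0
8    732.8
9    752.5
```

For 1..8 the fourths are 2.5 and 6.5, the fences (−3.5, 12.5) and nothing
is flagged; adding one value of 100 moves the fourths to (3, 7), the
fences to (−3, 13), and 100 is the sole outlier. In the time-sorted
tableplot each bin is a 6-month slice of the synthetic panel: the last
two bins (calendar 2015) sit roughly 50 above the earlier level — the
generator's planted comparability break, exactly what the display exists
to reveal.

The scripts in `examples/` walk one capability each (loading and
structure, outliers, edit rules, completeness, tableplots, spells and
churn, the full rendered report); each prints its numbers with a line on
what they mean.

## Command line

```sh
adminqc simulate --out sim/ --n-units 10000 --seed 7 --duplicate-rate 0.01
adminqc rules check config.yaml
adminqc run --input sim/panel.csv --config config.yaml --out report/ --format html
```

`run` executes any subset of checks (`--checks
accuracy,completeness,duplicates,...`) and writes a self-contained HTML or
Markdown report with per-check CSV tables, figures, guidance text and a
machine-readable `summary.json`. Quality findings never change the exit
status; `--fail-on-findings` opts in for CI.

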