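# Methods

This note records the statistical conventions, generator design and
numerical choices behind `adminqc`, and what the test suite does and does
not demonstrate.

## Data model

A panel is one rectangular long-format table: one row per unit per
period, a declared identification variable and time variable, and
per-variable metadata (role, allowed range/levels, missing codes, and an
expected within-unit trajectory class). Time is modeled as **discrete
consecutive periods**; monthly `YYYY-MM` (or `YYYY-MM-DD`) is the default
granularity, with quarterly, yearly and plain-integer axes available in
config. Every calendar period between the earliest and latest observed
period receives an index even if no record falls in it, so within-unit
gaps are well defined. All declared missing codes are replaced at load by
a single internal missing marker (NaN): every downstream check shares one
definition of missingness. Duplicate (id, time) rows are preserved at
load — duplicate detection is itself a check, and silently dropping rows
would hide the defect being screened for.

Unparseable cells in numeric-role columns become missing with a logged
warning rather than an error; the rule engine and nonresponse checks then
surface them. Ragged rows and unparseable time values do abort the load,
with offending line numbers / raw values in the message, because they
mean the file does not satisfy the rectangular contract at all.

## Quantile conventions

Two conventions coexist deliberately:

* **Outlier machinery** (boxplot fourths, Tukey fences, letter values)
  uses the letter-value depth recursion `d₁ = (1+n)/2`,
  `d_{i+1} = (1+⌊d_i⌋)/2`, taking order statistics at integer depths and
  midpoints at half-integer depths. Depth 2 yields the fourths, so fences
  and letter-value boxes are mutually consistent by construction — the
  fourths a fence uses are exactly the second letter-value level.
* **Descriptive quantile tables** use linear interpolation of order
  statistics (the numpy default), the convention analysts expect in a
  summary table.

Letter-value displays stop, by default, at `k = max(2, ⌊log₂ n⌋ − 3)`
levels (the "trustworthy" rule from the letter-value-plot literature;
`fixed-k` is available in config). Points strictly beyond the outermost
letter values are listed as outliers. Note that for very small n the
outermost level sits inside the extremes, so minima/maxima can be listed;
letter values are a large-file tool and the toolkit's displays are
intended for n in the thousands and up. The Tukey fence multiplier
defaults to the conventional 1.5, with 3.0 ("far out") exposed.

A property worth recording: Tukey fences are *not* monotone under data
growth — appending a far-out point widens the fourth-spread, so a
marginal outlier of the original batch can fall inside the new fences.
The suite therefore tests the properties that do hold (outliers are
exactly the points beyond the fences; raising the multiplier from 1.5 to
3.0 only removes outliers) rather than cross-batch monotonicity.

## Edit rules

Rules are declarative data (`{var, op, value}` conditions combined with
`all`/`any`/`not`, an optional `when` guard, and a severity of `invalid`
or `dubious`), not arbitrary code: rule files stay auditable, diffable
and testable. Every record evaluates to exactly one of pass / fail /
not-applicable per rule; conservation (pass + fail + NA = records, per
rule and per group/interval cell) is asserted in tests. A record with a
missing value in **any** referenced variable is not-applicable, never a
failure — missingness is the completeness dimension's subject and
double-counting it as a rule failure would conflate dimensions. Dubious
flags are tallied like failures but reported separately; they are
advisory.

Key-syntax validation classifies **distinct units** (matching the
per-unit proportions the reports present); a per-record variant exists
for files where the key field varies over time. The built-in `ssn9`
pattern implements the published structural rule: nine digits, optional
3-2-4 hyphenation, area ∉ {000, 666, 900–999}, group ≠ 00,
serial ≠ 0000.

## Completeness screens

Undercoverage is screened **without an external benchmark** (the toolkit
analyzes a dataset on its own): each area×period record count is
compared with that area's own median over time, flagging zero cells
always and cells below `low_fraction` (default 0.5) of the median. This
is a triage heuristic and is labeled as such in output; it cannot detect
an area that is uniformly undercovered in every period.

Duplicate detection is exact-match over the key tuple, defaulting to
(id, time) and accepting any analysis-variable set. Missing key values
compare equal by default (clerical double entry typically copies
blanks); `missing_match: never` excludes rows with missing keys.

Item nonresponse is reported per variable, as the share of units with at
least one missing value in any key variable (the complete-case loss a
listwise deletion would incur), as a missingness-pattern table over the
key variables, and per domain level for bias screening. Imputation is
deliberately out of scope; the report text points the analyst to it.

## Tableplots and time patterns

A tableplot stably sorts all records by the chosen variable (descending
by default for analysis variables, ascending for time) with ties broken
by (unit id, period), then cuts them into `n_bins` equal-size bins —
sizes ⌊n/k⌋ or ⌈n/k⌉ with the larger bins first — so each bin is a
percentile slice of the sort variable. Equal sort values may straddle a
bin boundary; the deterministic tie-break makes the output invariant to
input row order, which the suite asserts by permutation. Numeric columns
report per-bin mean, SD (n−1 denominator, missing when a bin has fewer
than two observed values) and missing fraction — missing values are
omitted from moments, never imputed as zero, and the missing fraction is
carried so the figure legend can show it. Categorical columns report
per-bin level frequencies including an explicit missing level. Records
with a missing sort value sort last, deterministically, so bin counts
still sum to n.

Histograms use Freedman–Diaconis bin widths, falling back to Sturges
when the IQR is zero or n < 4, and a single degenerate bin for constant
variables.

The per-period summary attaches a robust anomaly score to each period's
mean: |mean − median of period means| / (1.4826 × MAD), flagged above
3.5. This is a documented triage heuristic, not a changepoint test; on
stationary noise the suite checks the flag rate stays below 5% (it is
far lower in practice), and a zero MAD with any deviation yields an
infinite score by convention.

## Spells, churn, trajectories

A spell is a maximal run of consecutive receipt periods; receipt
defaults to row presence (a row exists iff benefits were paid that
month), with an indicator-variable mode for files that carry
non-recipient rows (missing indicator values are treated as non-receipt,
with a warning — conservative splitting surfaces problems rather than
hiding them). Spells touching the panel edges are censoring-flagged and
included in the headline duration summary, with a censored-excluded
variant alongside, since no censoring treatment is universally right for
a descriptive screen.

A churn event is a gap of at most `window` periods (default 4 months,
prominently configurable — "soon resumes" has no single convention)
between two spells of the same unit. Because the normalization also
varies across studies, three rates are emitted — per completed
(non-right-censored) spell (headline), per unit, and per spell.

Trajectory screens: a declared-stable variable violates when a unit has
more than one distinct non-missing value; a declared-monotone variable
violates on any strictly decreasing consecutive non-missing pair in
period order (equal values are fine; within-unit comparison skips
missing entries).

## The synthetic benefits panel

The generator emulates a hypothetical monthly cash-benefits program
observed January 2011 – December 2015 (60 periods). Its defaults are the
package's study conditions:

* **Spell process** — 35% of units are in the caseload at the window
  start; the rest enter at a uniformly random month. Spell lengths are
  geometric with mean 12 months; after an uncensored exit a unit
  re-enters with probability 0.40 after a geometric gap of mean 4
  months. These four numbers were calibrated once so that the default
  100,000 units produce ≈15 observed months per unit, i.e. on the order
  of 1.5 million rows over the window; the process itself (uniform entry
  + geometric spells/gaps) is the simplest memoryless story consistent
  with visible churn.
* **Variables** — recipients per case drawn from a declining
  distribution on 1..8; benefit = 300 + 150·recipients + Gaussian noise
  (SD 40), clipped at zero; noise SD ×2.5 when recipients = 1 (a planted
  multivariate irregularity the tableplot should reveal); household
  income a 45% point mass at zero with a lognormal(7, 0.6) positive
  part; categorical funding source, other-benefit receipt and case type
  with documented default probabilities; 12 counties with 1/√rank size
  weights; stable demographics (sex, birth year); and a cumulative
  months-on-benefits counter, strictly increasing within unit by
  construction. Unit keys are sequential structurally valid SSN-style
  strings.
* **Comparability break** — from January 2015 the benefit mean shifts by
  +50 and the noise SD is multiplied by 1.6, the scenario the
  time-sorted tableplot and the per-period summary are tested against.
* **Defect injection**, applied in a fixed order with every action
  ledgered: whole-unit key corruption (uniqueness-preserving malformed
  variants, so corrupted units never merge and the distinct-unit
  denominator stays exact); exact row duplication; per-domain blanking
  of income; benefit outlier substitution (×50); one stable-variable
  flip per chosen unit; one monotone-counter decrease per chosen unit.
  Trajectory-defect targets are restricted to units with ≥2 rows and no
  duplicated rows — a single-row flip is undetectable by a within-unit
  screen, and duplicated same-period rows would make within-unit
  ordering ambiguous — which is what makes ledger recovery exact rather
  than approximate.

Identical seed + config give identical output (a single `numpy`
Generator drives everything).

**What the generator does not emulate:** real entry-error processes
(typos correlated with office or period), eligibility-rule changes that
alter the caseload composition, seasonal patterns, correlated
missingness mechanisms beyond the domain-dependent rates, or any actual
program's parameter values. Passing recovery tests shows the checks
detect the defect classes they target at the injected rates in clean
surroundings; it does not show they would catch every real-world
manifestation of those defects.

## Tolerances and problem sizes

* Exact assertions: ledger recovery of duplicates, stable flips and
  monotone violations; all oracle-equivalence and conservation checks;
  hand-computed micro-examples.
* Binomially injected rates (invalid keys, domain missingness) are
  asserted within 3 binomial standard errors at ≥5,000 records per cell.
* The 2015 level-shift estimate (difference of period-mean averages,
  2015 vs 2011–14) carries unit-composition noise — which units are
  active in 2015 is random, and benefit depends on the unit-level
  recipients draw at 150 per recipient — so its sampling SD is ≈5 at
  10,000 units and ≈8 at 2,000 (measured across seeds). Tests assert
  recovery within ≈3× that SD (±15 and ±25 respectively).
* Suite problem sizes: oracle equivalence up to n = 10⁵ (quantiles) and
  n = 10⁴ (letter values, histograms); pairwise duplicate oracle at
  n = 2,000; spell oracle at 500 units × 24 periods; defect recovery at
  10,000 units; the percentile-bin identity on an exactly
  1,500,000-record panel. The clean-data identity — zero findings of
  every defect class when all rates are zero — is asserted for the
  defect-detecting checks (key syntax, rules, duplicates, missingness,
  trajectories, structure); heuristic screens (coverage low-cell flags,
  fence outliers, anomaly flags) intentionally respond to distributional
  features that clean data, and the deliberately planted 2015 break,
  legitimately have.

## Reporting

Checks are independent: running any subset yields results identical to
running all and discarding the rest (asserted in tests). The rendered
report (Markdown or HTML, hand-written emitters, no template engine) is
self-contained: metadata with a config hash, the relevance checklist
(qualitative questions on units, population, variables, timing and
domains that no computation can answer — answers come from the config),
one section per executed check with tables, figures and interpretation
guidance, per-check CSVs, and a `summary.json` whose structure is
enforced by `validate_summary` and which is byte-stable across runs on
identical input/config/seed. Quality findings never affect the process
exit code — the toolkit informs judgment rather than gating pipelines —
with an explicit `--fail-on-findings` opt-in for CI.

## Known limitations

No record linkage or second-source validation (standalone-file design);
no imputation; no probabilistic/fuzzy duplicate matching; no formal
changepoint tests or survival modeling of spell durations; coverage
screening cannot see uniform undercoverage; quality measures are
indirect — a value passing every screen is not thereby correct.
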