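"""Accuracy dimension: key syntax, edit rules, distributions and outliers.

Outlier screening deliberately offers several complementary views — no
single method settles whether an extreme value is an error — built on one
shared quantile convention, the *letter-value depth recursion*:

    d_1 = (1 + n) / 2,     d_{i+1} = (1 + floor(d_i)) / 2

The value at an integer depth d is the d-th order statistic from either
end; a half-integer depth takes the midpoint of the two neighbouring order
statistics.  Depth 2 of this recursion yields the *fourths* used for Tukey
fences, and continuing the recursion yields the eighths, sixteenths, ... of
letter-value (boxen) displays, so boxplot, fences and letter values are
mutually consistent by construction.  Letter-value displays suit large
administrative files: they show the tails in more detail than a boxplot and
flag far fewer routine points as outliers.

General-purpose quantile tables (``numeric_profile``) use the conventional
linear interpolation of order statistics instead.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, SchemaError
from .panel import PanelDataset

# re-exported so the accuracy dimension exposes its full surface in one place
from .rules import EditRule, RuleResult, evaluate_rules, parse_rule  # noqa: F401

PROFILE_QUANTILES = (0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99)


# ---------------------------------------------------------------------------
# Letter values and fences


def _value_at_depth(sorted_vals: np.ndarray, depth: float, upper: bool) -> float:
    n = len(sorted_vals)
    if depth == int(depth):
        i = int(depth)
        return float(sorted_vals[n - i] if upper else sorted_vals[i - 1])
    i = int(math.floor(depth))
    if upper:
        return float((sorted_vals[n - i] + sorted_vals[n - i - 1]) / 2.0)
    return float((sorted_vals[i - 1] + sorted_vals[i]) / 2.0)


def letter_depths(n: int, k: int) -> list[float]:
    """First ``k`` depths of the recursion (truncated when depth hits 1)."""
    depths = [(1 + n) / 2.0]
    while len(depths) < k and depths[-1] > 1:
        depths.append((1 + math.floor(depths[-1])) / 2.0)
    return depths


def trustworthy_k(n: int) -> int:
    """Default number of letter-value levels: max(2, floor(log2 n) - 3)."""
    return max(2, int(math.floor(math.log2(n))) - 3)


@dataclass
class LetterValueSummary:
    """Letter values of one numeric batch, median outward.

    ``levels[i] = (depth, lower, upper)``; level 0 is the median (lower ==
    upper), level 1 the fourths, level 2 the eighths, and so on.  Outliers
    are the data points strictly beyond the outermost letter values.
    """

    n: int
    k: int
    levels: list[tuple[float, float, float]]
    outliers: np.ndarray
    stopping_rule: str

    @property
    def median(self) -> float:
        return self.levels[0][1]

    @property
    def fourths(self) -> tuple[float, float]:
        d, lo, hi = self.levels[1]
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        names = _level_names(len(self.levels))
        return pd.DataFrame(
            [(names[i], d, lo, hi) for i, (d, lo, hi) in enumerate(self.levels)],
            columns=["letter", "depth", "lower", "upper"],
        )


def _level_names(k: int) -> list[str]:
    base = ["M", "F", "E", "D", "C", "B", "A", "Z", "Y", "X", "W", "V", "U", "T", "S", "R"]
    if k <= len(base):
        return base[:k]
    return base + [f"L{i}" for i in range(len(base), k)]


def letter_values(
    values, rule: str = "trustworthy", k: int | None = None
) -> LetterValueSummary:
    """Compute letter values with the chosen stopping rule.

    ``rule="trustworthy"`` shows ``max(2, floor(log2 n) - 3)`` levels;
    ``rule="fixed-k"`` shows exactly ``k`` levels (both truncate when the
    depth recursion reaches 1, i.e. the extremes).
    """
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    arr = arr[~np.isnan(arr)]
    n = len(arr)
    if n < 2:
        raise InsufficientDataError(
            f"letter values need at least 2 non-missing values, got {n}"
        )
    if rule == "trustworthy":
        k_eff = trustworthy_k(n)
    elif rule == "fixed-k":
        if k is None or k < 2:
            raise ConfigurationError("rule 'fixed-k' requires k >= 2")
        k_eff = k
    else:
        raise ConfigurationError(f"unknown letter-value stopping rule {rule!r}")
    srt = np.sort(arr)
    depths = letter_depths(n, k_eff)
    levels = [
        (d, _value_at_depth(srt, d, upper=False), _value_at_depth(srt, d, upper=True))
        for d in depths
    ]
    lo_k, hi_k = levels[-1][1], levels[-1][2]
    outliers = srt[(srt < lo_k) | (srt > hi_k)]
    return LetterValueSummary(
        n=n, k=len(levels), levels=levels, outliers=outliers, stopping_rule=rule
    )


@dataclass
class FenceReport:
    """Tukey fences at fourths +/- multiplier x fourth-spread."""

    n: int
    lower_fourth: float
    upper_fourth: float
    multiplier: float
    lower_fence: float
    upper_fence: float
    outlier_indices: np.ndarray
    outlier_values: np.ndarray

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measure": [
                    "n",
                    "lower fourth",
                    "upper fourth",
                    "multiplier",
                    "lower fence",
                    "upper fence",
                    "outliers",
                ],
                "value": [
                    self.n,
                    self.lower_fourth,
                    self.upper_fourth,
                    self.multiplier,
                    self.lower_fence,
                    self.upper_fence,
                    self.n_outliers,
                ],
            }
        )


def tukey_fences(values, multiplier: float = 1.5) -> FenceReport:
    """Fences from the depth-recursion fourths; outliers fall outside them.

    The conventional multiplier is 1.5; 3.0 screens only "far out" points.
    """
    ser = pd.to_numeric(pd.Series(values), errors="coerce")
    arr = ser.to_numpy(dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 4:
        raise InsufficientDataError(
            f"Tukey fences need at least 4 non-missing values, got {n}"
        )
    srt = np.sort(arr[mask])
    d1, d2 = letter_depths(n, 2)
    lf = _value_at_depth(srt, d2, upper=False)
    uf = _value_at_depth(srt, d2, upper=True)
    spread = uf - lf
    lower = lf - multiplier * spread
    upper = uf + multiplier * spread
    out_mask = mask & ((arr < lower) | (arr > upper))
    idx = np.flatnonzero(out_mask)
    return FenceReport(
        n=n,
        lower_fourth=lf,
        upper_fourth=uf,
        multiplier=multiplier,
        lower_fence=lower,
        upper_fence=upper,
        outlier_indices=idx,
        outlier_values=arr[idx],
    )


# ---------------------------------------------------------------------------
# Identification-key syntax


_SSN_CLEAN = re.compile(r"^(\d{3})-?(\d{2})-?(\d{4})$")


def _ssn9_ok(key: str) -> bool:
    m = _SSN_CLEAN.match(key)
    if not m:
        return False
    area, group, serial = m.groups()
    if area == "000" or area == "666" or "900" <= area <= "999":
        return False
    return group != "00" and serial != "0000"


BUILTIN_PATTERNS = {"ssn9": _ssn9_ok}


@dataclass
class IDSyntaxReport:
    """Classification of identification keys as missing/correct/incorrect."""

    pattern_name: str
    n_keys: int
    counts: dict
    proportions: dict
    offending_sample: list = field(default_factory=list)
    per_record: bool = False

    @property
    def n_findings(self) -> int:
        return self.counts["incorrect"] + self.counts["missing"]

    def to_frame(self) -> pd.DataFrame:
        order = ["missing", "correct", "incorrect"]
        return pd.DataFrame(
            {
                "syntax": order,
                "count": [self.counts[c] for c in order],
                "proportion": [self.proportions[c] for c in order],
            }
        )


def validate_id_syntax(
    panel: PanelDataset,
    pattern: str = "ssn9",
    per_record: bool = False,
    sample_cap: int = 20,
) -> IDSyntaxReport:
    """Classify identification keys as missing, correct, or incorrect.

    ``pattern`` is a built-in name (``"ssn9"``: nine digits with optional
    hyphens in 3-2-4 grouping; area not 000/666/900-999; group not 00;
    serial not 0000) or a user regular expression that a correct key must
    fully match.  Classification is per distinct unit key by default, with a
    per-record variant for datasets where the key field varies over time.
    """
    if pattern in BUILTIN_PATTERNS:
        checker = BUILTIN_PATTERNS[pattern]
        name = pattern
    else:
        try:
            rex = re.compile(pattern)
        except re.error as exc:
            raise ConfigurationError(f"invalid key-syntax regular expression: {exc}") from exc
        checker = lambda key: rex.fullmatch(key) is not None  # noqa: E731
        name = f"regex:{pattern}"
    keys = panel.records[panel.id_var]
    if not per_record:
        keys = pd.Series(keys.unique())
    missing_mask = keys.isna() | (keys.astype(str).str.strip() == "")
    n_missing = int(missing_mask.sum())
    present = keys[~missing_mask].astype(str)
    ok_mask = present.map(checker)
    n_correct = int(ok_mask.sum())
    bad = present[~ok_mask]
    n = len(keys)
    counts = {"missing": n_missing, "correct": n_correct, "incorrect": len(bad)}
    props = {c: (v / n if n else 0.0) for c, v in counts.items()}
    return IDSyntaxReport(
        pattern_name=name,
        n_keys=n,
        counts=counts,
        proportions=props,
        offending_sample=bad.head(sample_cap).tolist(),
        per_record=per_record,
    )


# ---------------------------------------------------------------------------
# Descriptive profiles


def _restrict_periods(panel: PanelDataset, period_range) -> pd.DataFrame:
    if period_range is None:
        return panel.records
    start, end = period_range
    lo = start if isinstance(start, (int, np.integer)) else panel.period_of(start)
    hi = end if isinstance(end, (int, np.integer)) else panel.period_of(end)
    mask = (panel.periods >= lo) & (panel.periods <= hi)
    return panel.records[mask.fillna(False).to_numpy(dtype=bool)]


def numeric_profile(
    panel: PanelDataset,
    variables: Sequence[str] | None = None,
    period_range: tuple | None = None,
) -> pd.DataFrame:
    """Per-variable distribution table: n, missing, mean, SD, extrema and
    quantiles at 1/5/10/25/50/75/90/95/99% (linear interpolation)."""
    if variables is None:
        variables = panel.variables("numeric")
    df = _restrict_periods(panel, period_range)
    rows = []
    for var in variables:
        panel.require_column(var)
        s = panel.schema_for(var)
        if s is not None and s.role != "numeric":
            raise ConfigurationError(
                f"numeric_profile: variable {var!r} has role {s.role!r}, not numeric"
            )
        vals = pd.to_numeric(df[var], errors="coerce").to_numpy(dtype=float)
        good = vals[~np.isnan(vals)]
        row: dict = {"variable": var, "n": len(good), "missing": int(np.isnan(vals).sum())}
        if len(good):
            qs = np.quantile(good, PROFILE_QUANTILES)
            row.update(
                mean=float(good.mean()),
                sd=float(good.std(ddof=1)) if len(good) > 1 else np.nan,
                min=float(good.min()),
                **{f"q{int(q * 100):02d}": float(v) for q, v in zip(PROFILE_QUANTILES, qs)},
                max=float(good.max()),
            )
        rows.append(row)
    cols = ["variable", "n", "missing", "mean", "sd", "min"] + [
        f"q{int(q * 100):02d}" for q in PROFILE_QUANTILES
    ] + ["max"]
    return pd.DataFrame(rows, columns=cols)


def categorical_profile(
    panel: PanelDataset,
    variables: Sequence[str] | None = None,
    period_range: tuple | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-variable level frequencies (including a missing row and declared
    but unobserved levels at zero); proportions sum to 1 per variable."""
    if variables is None:
        variables = [
            s.name for s in panel.schema if s.role in ("categorical", "domain", "geography")
        ]
    df = _restrict_periods(panel, period_range)
    out: dict[str, pd.DataFrame] = {}
    for var in variables:
        panel.require_column(var)
        col = df[var]
        n = len(col)
        counts = col.value_counts(dropna=True)
        s = panel.schema_for(var)
        if s is not None and s.levels is not None:
            counts = counts.reindex(list(s.levels), fill_value=0).add(
                counts[~counts.index.isin(list(s.levels))], fill_value=0
            )
            counts = counts.astype(int)
        table = counts.rename_axis("level").reset_index(name="count")
        missing_row = pd.DataFrame(
            [{"level": "(missing)", "count": int(col.isna().sum())}]
        )
        table = pd.concat([table, missing_row], ignore_index=True)
        table["proportion"] = table["count"] / n if n else 0.0
        out[var] = table
    return out
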