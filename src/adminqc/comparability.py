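"""Comparability dimension: distributions, tableplots, time patterns.

The workhorse here is the *tableplot*, a binned multivariate display for
large files: all records are sorted by one variable, split into equal-size
percentile bins (100 by default, so each bin is one percentile of the sort
variable), and each bin is summarized per column — mean and SD band for
numeric columns, stacked level frequencies for categorical ones.  A million
rows reduce to a hundred summary rows in which jumps, kinks and mix shifts
across the sort variable stand out.  Sorting by time instead of an analysis
variable turns the same display into a comparability-over-time screen.

Ties in the sort variable are broken by (unit id, period) under a stable
sort, so the output is invariant to input row order; equal values may
straddle a bin boundary, deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .panel import PanelDataset
from .accuracy import numeric_profile

ROBUST_Z_SCALE = 1.4826  # MAD -> SD under normality


# ---------------------------------------------------------------------------
# Histograms and distribution summaries


@dataclass
class HistogramSpec:
    """Bin edges + counts for one numeric variable."""

    variable: str
    edges: np.ndarray
    counts: np.ndarray
    rule: str
    n_missing: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "count": self.counts,
            }
        )


def _histogram(values: np.ndarray, variable: str, max_bins: int = 1000) -> HistogramSpec:
    """Freedman-Diaconis bin width, falling back to Sturges when the IQR is
    zero or the sample is tiny; a constant variable gets one degenerate bin."""
    n = len(values)
    n_missing = int(np.isnan(values).sum())
    x = values[~np.isnan(values)]
    n = len(x)
    if n == 0:
        return HistogramSpec(variable, np.array([0.0, 1.0]), np.array([0]), "empty", n_missing)
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
        return HistogramSpec(variable, edges, np.array([n]), "degenerate", n_missing)
    q25, q75 = np.quantile(x, [0.25, 0.75])
    iqr = q75 - q25
    if iqr > 0 and n >= 4:
        width = 2.0 * iqr / n ** (1.0 / 3.0)
        n_bins = min(max_bins, max(1, math.ceil((hi - lo) / width)))
        rule = "freedman-diaconis"
    else:
        n_bins = max(1, math.ceil(math.log2(n)) + 1)
        rule = "sturges"
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return HistogramSpec(variable, edges, counts, rule, n_missing)


def distribution_summary(
    panel: PanelDataset, var: str, by: str | None = None
):
    """Quantile table + histogram for one numeric variable, optionally per
    group.  Returns ``(quantile_table, HistogramSpec)`` or, with ``by``, a
    dict mapping group level to such a pair."""
    panel.require_column(var)
    s = panel.schema_for(var)
    if s is not None and s.role != "numeric":
        raise ConfigurationError(
            f"distribution_summary: {var!r} has role {s.role!r}; "
            "use categorical_profile for categorical variables"
        )
    if by is None:
        table = numeric_profile(panel, [var])
        vals = pd.to_numeric(panel.records[var], errors="coerce").to_numpy(dtype=float)
        return table, _histogram(vals, var)
    panel.require_column(by, "by")
    out = {}
    df = panel.records
    gvals = df[by].astype("object").where(df[by].notna(), "(missing)")
    for level, idx in gvals.groupby(gvals, sort=True).groups.items():
        sub = df.loc[idx, var]
        vals = pd.to_numeric(sub, errors="coerce").to_numpy(dtype=float)
        good = vals[~np.isnan(vals)]
        qs = (
            np.quantile(good, (0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99))
            if len(good)
            else [np.nan] * 9
        )
        table = pd.DataFrame(
            [
                {
                    "variable": var,
                    "group": level,
                    "n": len(good),
                    "missing": int(np.isnan(vals).sum()),
                    "mean": float(good.mean()) if len(good) else np.nan,
                    **{
                        f"q{int(q * 100):02d}": float(v)
                        for q, v in zip((0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99), qs)
                    },
                }
            ]
        )
        out[level] = (table, _histogram(vals, var))
    return out


# ---------------------------------------------------------------------------
# Tableplots


@dataclass
class TableplotSummary:
    """Equal-size percentile-bin summary of many columns at once.

    ``bins`` has one row per bin: record count and the sort-variable range
    covered.  ``numeric[col]`` holds per-bin mean / sd / missing fraction;
    ``categorical[col]`` holds per-bin level counts (including a
    ``"(missing)"`` level), each row summing to the bin size.
    """

    sort_var: str
    n: int
    n_bins: int
    descending: bool
    bins: pd.DataFrame
    numeric: dict[str, pd.DataFrame] = field(default_factory=dict)
    categorical: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        for col, stats in self.numeric.items():
            out[f"{col}_mean"] = stats["mean"].to_numpy()
            out[f"{col}_sd"] = stats["sd"].to_numpy()
            out[f"{col}_missing_frac"] = stats["missing_frac"].to_numpy()
        for col, freq in self.categorical.items():
            for level in freq.columns:
                out[f"{col}={level}"] = freq[level].to_numpy()
        return out

    def to_dict(self) -> dict:
        return {
            "sort_var": self.sort_var,
            "n": self.n,
            "n_bins": self.n_bins,
            "descending": self.descending,
            "bin_sizes": self.bins["count"].tolist(),
        }


def _bin_ids(n: int, n_bins: int) -> np.ndarray:
    """Consecutive bin labels with sizes floor(n/k) or ceil(n/k), larger first."""
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    return np.repeat(np.arange(n_bins), sizes)


def tableplot(
    panel: PanelDataset,
    sort_var: str,
    columns: Sequence[str],
    n_bins: int = 100,
    descending: bool = True,
) -> TableplotSummary:
    """Sort records by ``sort_var``, cut into ``n_bins`` equal-size bins,
    summarize every requested column per bin."""
    panel.require_column(sort_var)
    sort_vals = pd.to_numeric(panel.records[sort_var], errors="coerce")
    return _tableplot_core(panel, sort_var, sort_vals, columns, n_bins, descending)


def tableplot_over_time(
    panel: PanelDataset,
    columns: Sequence[str],
    n_bins: int | None = None,
) -> TableplotSummary:
    """Tableplot with the time axis as sort variable (ascending), so bins
    are consecutive time slices and the display screens comparability over
    time."""
    sort_vals = pd.Series(
        panel.periods.to_numpy(dtype="float64", na_value=np.nan),
        index=panel.records.index,
    )
    if n_bins is None:
        n_bins = max(2, min(100, panel.n_periods))
    summary = _tableplot_core(
        panel, panel.time_var, sort_vals, columns, n_bins, descending=False
    )
    return summary


def _tableplot_core(
    panel: PanelDataset,
    sort_name: str,
    sort_vals: pd.Series,
    columns: Sequence[str],
    n_bins: int,
    descending: bool,
) -> TableplotSummary:
    df = panel.records
    n = len(df)
    if n_bins < 2:
        raise ConfigurationError("tableplot: n_bins must be >= 2")
    if n < n_bins:
        raise DataError(
            f"tableplot: {n} records is fewer than n_bins={n_bins}; "
            f"choose n_bins <= {n}"
        )
    for col in columns:
        panel.require_column(col, "tableplot columns")
    order_frame = pd.DataFrame(
        {
            "sort": sort_vals.to_numpy(dtype=float),
            "id": df[panel.id_var].to_numpy(),
            "period": panel.periods.to_numpy(dtype="float64", na_value=np.inf),
        }
    )
    order = order_frame.sort_values(
        ["sort", "id", "period"],
        ascending=[not descending, True, True],
        kind="stable",
        na_position="last",
    ).index.to_numpy()
    bins = _bin_ids(n, n_bins)
    sorted_vals = order_frame["sort"].to_numpy()[order]
    bin_tbl = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "count": np.bincount(bins, minlength=n_bins),
        }
    )
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    ser = pd.Series(sorted_vals).groupby(bins)
    lo_vals = ser.min()
    hi_vals = ser.max()
    lo[lo_vals.index.to_numpy()] = lo_vals.to_numpy()
    hi[hi_vals.index.to_numpy()] = hi_vals.to_numpy()
    bin_tbl["sort_min"] = lo
    bin_tbl["sort_max"] = hi

    numeric: dict[str, pd.DataFrame] = {}
    categorical: dict[str, pd.DataFrame] = {}
    for col in columns:
        s = panel.schema_for(col)
        is_numeric = (s is not None and s.role == "numeric") or (
            s is None and pd.api.types.is_numeric_dtype(df[col])
        )
        reordered = df[col].to_numpy()[order]
        if is_numeric:
            vals = pd.to_numeric(pd.Series(reordered), errors="coerce")
            grp = vals.groupby(bins)
            mean = grp.mean()
            counts = grp.count()
            sd = grp.std(ddof=1).where(counts >= 2)
            missing_frac = 1.0 - counts / bin_tbl["count"].to_numpy()
            numeric[col] = pd.DataFrame(
                {
                    "mean": mean.to_numpy(),
                    "sd": sd.to_numpy(),
                    "missing_frac": missing_frac.to_numpy(),
                },
                index=pd.RangeIndex(n_bins, name="bin"),
            )
        else:
            ser_col = pd.Series(reordered, dtype="object")
            ser_col = ser_col.where(ser_col.notna(), "(missing)")
            freq = (
                pd.crosstab(bins, ser_col)
                .reindex(range(n_bins), fill_value=0)
            )
            freq.index.name = "bin"
            categorical[col] = freq
    return TableplotSummary(
        sort_var=sort_name,
        n=n,
        n_bins=n_bins,
        descending=descending,
        bins=bin_tbl,
        numeric=numeric,
        categorical=categorical,
    )


# ---------------------------------------------------------------------------
# Time-series summaries


@dataclass
class PeriodSummary:
    """Per-period (x group) statistics with a robust anomaly screen.

    The anomaly score for a period is ``|mean_p - median(means)| /
    (1.4826 * MAD(means))``, a robust z-score of the period mean within its
    group's series; scores above ``threshold`` flag the period for manual
    investigation.  This is a triage heuristic, not a changepoint test.
    """

    var: str
    group_var: str | None
    threshold: float
    table: pd.DataFrame
    flagged: pd.DataFrame

    @property
    def n_findings(self) -> int:
        return len(self.flagged)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _robust_scores(means: np.ndarray) -> np.ndarray:
    med = np.nanmedian(means)
    dev = np.abs(means - med)
    mad = np.nanmedian(dev)
    if mad == 0 or np.isnan(mad):
        return np.where(dev > 0, np.inf, 0.0)
    return dev / (ROBUST_Z_SCALE * mad)


def timeseries_summary(
    panel: PanelDataset,
    var: str,
    group_var: str | None = None,
    threshold: float = 3.5,
) -> PeriodSummary:
    """Per-period count/mean/SD/quartiles of ``var`` (optionally per group)
    plus robust anomaly scores over the period means."""
    panel.require_column(var)
    if group_var is not None:
        panel.require_column(group_var, "group_var")
    df = panel.records
    work = pd.DataFrame(
        {
            "period": panel.periods.to_numpy(dtype="float64", na_value=np.nan),
            "value": pd.to_numeric(df[var], errors="coerce").to_numpy(dtype=float),
        }
    )
    keys = ["period"]
    if group_var is not None:
        work["group"] = (
            df[group_var].astype("object").where(df[group_var].notna(), "(missing)").to_numpy()
        )
        keys = ["group", "period"]
    work = work.dropna(subset=["period"])
    grp = work.groupby(keys, sort=True)["value"]
    table = grp.agg(
        count="count",
        mean="mean",
        sd=lambda s: s.std(ddof=1),
        q25=lambda s: s.quantile(0.25),
        median="median",
        q75=lambda s: s.quantile(0.75),
    ).reset_index()
    table["period_label"] = table["period"].map(
        lambda p: panel.period_labels[int(p)] if panel.period_labels else int(p)
    )
    if group_var is None:
        table["anomaly_score"] = _robust_scores(table["mean"].to_numpy())
    else:
        table["anomaly_score"] = np.nan
        for _, idx in table.groupby("group").groups.items():
            sub = table.loc[idx, "mean"].to_numpy()
            table.loc[idx, "anomaly_score"] = _robust_scores(sub)
    table["flagged"] = table["anomaly_score"] > threshold
    flagged = table[table["flagged"]].copy()
    return PeriodSummary(
        var=var,
        group_var=group_var,
        threshold=threshold,
        table=table,
        flagged=flagged,
    )
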