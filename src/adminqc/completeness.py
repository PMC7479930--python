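"""Completeness dimension: coverage, duplicates, item nonresponse.

Coverage screening works on the dataset alone (no external population
benchmark is assumed): each geographic area's record count per period is
compared with that area's own median over the panel, so sudden drops and
absent periods surface even without knowing the true population.  The
resulting flags are a heuristic triage aid, not a coverage estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .panel import PanelDataset


# ---------------------------------------------------------------------------
# Geographic coverage


@dataclass
class CoverageReport:
    """Record counts by area x period with undercoverage screen flags.

    ``counts`` is areas x period labels; ``zero_flags`` marks empty cells
    (always suspicious) and ``low_flags`` marks cells whose count falls
    below ``low_fraction`` times the area's own median count (heuristic —
    no external benchmark is used).
    """

    geo_var: str
    low_fraction: float
    counts: pd.DataFrame
    zero_flags: pd.DataFrame
    low_flags: pd.DataFrame

    @property
    def n_findings(self) -> int:
        return int(self.zero_flags.values.sum() + self.low_flags.values.sum())

    def flagged_cells(self) -> pd.DataFrame:
        rows = []
        for area in self.counts.index:
            for period in self.counts.columns:
                z = bool(self.zero_flags.loc[area, period])
                lo = bool(self.low_flags.loc[area, period])
                if z or lo:
                    rows.append(
                        {
                            "area": area,
                            "period": period,
                            "count": int(self.counts.loc[area, period]),
                            "flag": "zero_count" if z else "low",
                        }
                    )
        return pd.DataFrame(rows, columns=["area", "period", "count", "flag"])

    def to_frame(self) -> pd.DataFrame:
        return self.counts


def coverage_by_area(
    panel: PanelDataset, geo_var: str, low_fraction: float = 0.5
) -> CoverageReport:
    """Tabulate records per geographic area per period and screen for
    undercoverage (zero or suspiciously low cells)."""
    if geo_var not in panel.records.columns:
        raise ConfigurationError(f"coverage_by_area: geo_var {geo_var!r} not in panel")
    if not 0 < low_fraction <= 1:
        raise ConfigurationError("low_fraction must be in (0, 1]")
    df = pd.DataFrame(
        {"area": panel.records[geo_var], "period": panel.periods}
    ).dropna()
    labels = panel.period_labels
    counts = (
        df.groupby(["area", "period"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(len(labels)), fill_value=0)
    )
    counts.columns = labels
    zero = counts == 0
    if counts.shape[1] > 1:
        med = counts.median(axis=1)
        low = counts.lt(low_fraction * med, axis=0) & ~zero
    else:
        low = pd.DataFrame(False, index=counts.index, columns=counts.columns)
    return CoverageReport(
        geo_var=geo_var,
        low_fraction=low_fraction,
        counts=counts,
        zero_flags=zero,
        low_flags=low,
    )


# ---------------------------------------------------------------------------
# Duplicates


@dataclass
class DuplicateReport:
    """Exact-match duplicate groups over a key tuple.

    ``excess_records = records_involved - duplicated_keys`` is the number of
    rows that would vanish if each duplicated group kept a single row.
    """

    keys: list[str]
    n_duplicated_keys: int
    records_involved: int
    excess_records: int
    sample_groups: pd.DataFrame = field(repr=False)
    per_period: pd.DataFrame | None = None
    missing_match: str = "match"

    @property
    def n_findings(self) -> int:
        return self.excess_records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measure": ["duplicated keys", "records involved", "excess records"],
                "value": [self.n_duplicated_keys, self.records_involved, self.excess_records],
            }
        )


def detect_duplicates(
    panel: PanelDataset,
    keys: Sequence[str] | None = None,
    per_period: bool = False,
    missing_match: str = "match",
    sample_cap: int = 20,
) -> DuplicateReport:
    """Find rows sharing an identical key tuple.

    ``keys`` defaults to ``[id_var, time_var]`` (the same unit registered
    twice in a period); passing a set of analysis variables instead screens
    for clerical double entry under different identifiers.  Missing key
    values match each other by default (``missing_match="match"``); with
    ``"never"`` rows with any missing key are excluded from matching.
    """
    if keys is not None and len(keys) == 0:
        raise ConfigurationError("detect_duplicates: key list must not be empty")
    if keys is None:
        keys = [panel.id_var, panel.time_var]
    keys = list(keys)
    for k in keys:
        if k not in panel.records.columns:
            raise ConfigurationError(f"detect_duplicates: key variable {k!r} not in panel")
    if missing_match not in ("match", "never"):
        raise ConfigurationError("missing_match must be 'match' or 'never'")
    df = panel.records[keys]
    if missing_match == "never":
        df = df.dropna(subset=keys)
    sizes = df.groupby(keys, dropna=False, sort=False).size()
    dup = sizes[sizes > 1]
    n_keys = int(len(dup))
    involved = int(dup.sum())
    excess = involved - n_keys
    sample = (
        dup.sort_values(ascending=False)
        .head(sample_cap)
        .rename("multiplicity")
        .reset_index()
    )
    per_period_tbl = None
    if per_period:
        dfp = df.copy()
        dfp["_period"] = panel.periods.loc[df.index]
        rows = []
        for period, sub in dfp.groupby("_period", dropna=True, sort=True):
            s = sub.groupby(keys, dropna=False, sort=False).size()
            d = s[s > 1]
            rows.append(
                {
                    "period": panel.period_labels[int(period)],
                    "duplicated_keys": int(len(d)),
                    "excess_records": int((d - 1).sum()),
                }
            )
        per_period_tbl = pd.DataFrame(rows, columns=["period", "duplicated_keys", "excess_records"])
    return DuplicateReport(
        keys=keys,
        n_duplicated_keys=n_keys,
        records_involved=involved,
        excess_records=excess,
        sample_groups=sample,
        per_period=per_period_tbl,
        missing_match=missing_match,
    )


# ---------------------------------------------------------------------------
# Item nonresponse


@dataclass
class MissingnessReport:
    """Item-nonresponse summary.

    ``per_variable``: missing count/proportion per variable over records.
    ``unit_any_missing``: units with >= 1 missing value in any key variable.
    ``pattern_table``: distinct observed/missing combinations over the key
    variables with frequencies (frequencies sum to the record count).
    """

    key_vars: list[str]
    n_records: int
    n_units: int
    per_variable: pd.DataFrame
    unit_any_missing_count: int
    unit_any_missing_proportion: float
    pattern_table: pd.DataFrame

    @property
    def n_findings(self) -> int:
        return int(self.per_variable["missing"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.per_variable


def missingness_by_variable(
    panel: PanelDataset, key_vars: Sequence[str] | None = None
) -> MissingnessReport:
    """Per-variable missingness plus the unit-level any-missing share.

    ``key_vars`` (default: every non-identifier, non-time variable) defines
    both the unit-level screen and the missingness-pattern table.
    """
    if key_vars is None:
        key_vars = [
            s.name for s in panel.schema if s.role not in ("identifier", "time")
        ]
    key_vars = list(key_vars)
    for var in key_vars:
        panel.require_column(var, "key_vars")
    df = panel.records
    all_vars = [s.name for s in panel.schema if s.role not in ("identifier", "time")]
    n = len(df)
    per_var = pd.DataFrame(
        {
            "variable": all_vars,
            "missing": [int(df[v].isna().sum()) for v in all_vars],
        }
    )
    per_var["proportion"] = per_var["missing"] / n if n else 0.0
    if key_vars:
        any_missing = df[key_vars].isna().any(axis=1)
        ids = df[panel.id_var]
        units_missing = ids[any_missing & ids.notna()].nunique()
    else:
        units_missing = 0
    n_units = panel.n_units
    if key_vars and n:
        labels = df[key_vars].isna().apply(
            lambda c: c.map({True: "missing", False: "observed"})
        )
        pattern = (
            labels.groupby(key_vars, sort=True)
            .size()
            .rename("frequency")
            .reset_index()
        )
    else:
        pattern = pd.DataFrame(columns=[*key_vars, "frequency"])
    return MissingnessReport(
        key_vars=key_vars,
        n_records=n,
        n_units=n_units,
        per_variable=per_var,
        unit_any_missing_count=int(units_missing),
        unit_any_missing_proportion=(units_missing / n_units) if n_units else 0.0,
        pattern_table=pattern,
    )


def missingness_by_domain(
    panel: PanelDataset, var: str, domain_var: str
) -> pd.DataFrame:
    """Missing proportion of ``var`` within each level of ``domain_var``.

    Differential nonresponse across analyst-defined domains is a bias risk
    for subgroup comparisons; the returned table is the data behind the
    per-domain nonresponse bar plot.
    """
    if domain_var not in panel.records.columns:
        raise ConfigurationError(f"missingness_by_domain: domain_var {domain_var!r} not in panel")
    panel.require_column(var)
    df = panel.records
    dom = df[domain_var].astype("object").where(df[domain_var].notna(), "(missing)")
    grp = df[var].isna().groupby(dom, sort=True)
    out = grp.agg(n="size", missing="sum").reset_index().rename(columns={domain_var: "domain"})
    out.columns = ["domain", "n", "missing"]
    out["missing"] = out["missing"].astype(int)
    out["proportion"] = out["missing"] / out["n"]
    return out
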