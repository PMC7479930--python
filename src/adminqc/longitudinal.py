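"""Longitudinal checks: spells, durations, churn, within-unit stability.

A *spell* is a maximal run of consecutive periods in which a unit receives
benefits (by default: has a row in the data, matching programs where a
record exists exactly when benefits are paid).  Spell counts, durations and
*churn* — an exit followed by re-entry within a short window — are central
descriptives for benefits-program panels, and abrupt changes in them often
signal processing artifacts rather than real dynamics.

Within-unit screens cover variables that should never change (declared
``trajectory="stable"``, e.g. demographics) and cumulative counters that
must never decrease (``trajectory="monotone_nondecreasing"``, e.g. months
of benefit receipt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .panel import PanelDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spell extraction


@dataclass
class SpellTable:
    """Receipt episodes per unit plus the gaps separating them.

    ``spells`` columns: unit, spell (0-based index within unit), start, end
    (period indices, inclusive), duration (= end - start + 1), plus
    left/right censoring flags at the panel edges.  ``gaps`` columns: unit,
    gap_start, length — one row per gap between consecutive spells.
    """

    spells: pd.DataFrame
    gaps: pd.DataFrame
    first_period: int
    last_period: int
    receipt: str = "presence"

    @property
    def n_spells(self) -> int:
        return len(self.spells)

    @property
    def n_units(self) -> int:
        return int(self.spells["unit"].nunique()) if len(self.spells) else 0

    def to_frame(self) -> pd.DataFrame:
        return self.spells


def extract_spells(panel: PanelDataset, receipt: str = "presence") -> SpellTable:
    """Find maximal runs of consecutive receipt periods per unit.

    ``receipt="presence"`` treats the existence of a row as receipt that
    period; any other value names a binary indicator variable (1/0, with
    missing treated as non-receipt, logged).  Duplicate (id, time) rows
    count once.
    """
    df = pd.DataFrame(
        {"unit": panel.records[panel.id_var], "period": panel.periods}
    ).dropna(subset=["unit", "period"])
    if receipt != "presence":
        panel.require_column(receipt, "receipt indicator")
        ind = panel.records[receipt]
        vals = pd.to_numeric(ind, errors="coerce")
        nonmiss = ind.notna()
        bad = sorted(set(ind[nonmiss & ~vals.isin([0, 1])].unique()))
        if bad:
            raise DataError(
                f"receipt indicator {receipt!r} has non-binary values: {bad[:10]}"
            )
        n_miss = int((~nonmiss).sum())
        if n_miss:
            logger.warning(
                "receipt indicator %r: %d missing value(s) treated as non-receipt",
                receipt,
                n_miss,
            )
        df = df[vals.reindex(df.index).fillna(0).to_numpy(dtype=float) == 1]
    if df.empty:
        empty_spells = pd.DataFrame(
            columns=["unit", "spell", "start", "end", "duration", "left_censored", "right_censored"]
        )
        empty_gaps = pd.DataFrame(columns=["unit", "gap_start", "length"])
        return SpellTable(empty_spells, empty_gaps, 0, max(panel.n_periods - 1, 0), receipt)
    obs = (
        df.drop_duplicates()
        .astype({"period": "int64"})
        .sort_values(["unit", "period"], kind="stable")
        .reset_index(drop=True)
    )
    unit = obs["unit"].to_numpy()
    period = obs["period"].to_numpy()
    new_unit = np.ones(len(obs), dtype=bool)
    new_unit[1:] = unit[1:] != unit[:-1]
    breaks = new_unit.copy()
    breaks[1:] |= period[1:] != period[:-1] + 1
    spell_id = np.cumsum(breaks) - 1
    grp = pd.DataFrame({"unit": unit, "period": period, "spell_id": spell_id}).groupby(
        "spell_id", sort=True
    )
    spells = grp.agg(
        unit=("unit", "first"), start=("period", "min"), end=("period", "max")
    ).reset_index(drop=True)
    spells["duration"] = spells["end"] - spells["start"] + 1
    spells["spell"] = spells.groupby("unit", sort=False).cumcount()
    first_p, last_p = 0, max(panel.n_periods - 1, 0)
    spells["left_censored"] = spells["start"] == first_p
    spells["right_censored"] = spells["end"] == last_p
    spells = spells[
        ["unit", "spell", "start", "end", "duration", "left_censored", "right_censored"]
    ]
    prev_end = spells["end"].shift(1)
    same_unit = spells["unit"] == spells["unit"].shift(1)
    gap_len = (spells["start"] - prev_end - 1).where(same_unit)
    gaps = pd.DataFrame(
        {
            "unit": spells["unit"],
            "gap_start": (prev_end + 1),
            "length": gap_len,
        }
    ).dropna(subset=["length"])
    gaps = gaps.astype({"gap_start": "int64", "length": "int64"}).reset_index(drop=True)
    return SpellTable(spells.reset_index(drop=True), gaps, first_p, last_p, receipt)


# ---------------------------------------------------------------------------
# Spell statistics


@dataclass
class SpellStatistics:
    """Distributional summaries of spells per unit and spell durations."""

    n_units: int
    n_spells: int
    spells_per_unit: pd.DataFrame
    durations: pd.DataFrame
    n_left_censored: int
    n_right_censored: int
    by_group: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.durations


def _describe(vals: np.ndarray, label: str) -> pd.DataFrame:
    if len(vals) == 0:
        return pd.DataFrame([{"series": label, "n": 0}])
    qs = np.quantile(vals, [0.25, 0.50, 0.75])
    return pd.DataFrame(
        [
            {
                "series": label,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "q25": float(qs[0]),
                "median": float(qs[1]),
                "q75": float(qs[2]),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
        ]
    )


def spell_statistics(
    spells: SpellTable,
    panel: PanelDataset | None = None,
    by: str | None = None,
) -> SpellStatistics:
    """Summaries of spells per unit and durations.

    Edge spells are censoring-flagged and *included* in the headline
    duration summary; a censored-excluded variant is reported alongside.
    With ``panel`` and ``by``, per-subgroup duration summaries are added
    (each unit's group is its first non-missing value of ``by``).
    """
    tbl = spells.spells
    per_unit = tbl.groupby("unit", sort=False).size() if len(tbl) else pd.Series(dtype=int)
    spu = _describe(per_unit.to_numpy(dtype=float), "spells_per_unit")
    dur_all = _describe(tbl["duration"].to_numpy(dtype=float), "durations_all")
    completed = tbl[~(tbl["left_censored"] | tbl["right_censored"])]
    dur_completed = _describe(
        completed["duration"].to_numpy(dtype=float), "durations_uncensored"
    )
    durations = pd.concat([dur_all, dur_completed], ignore_index=True)
    by_group = None
    if by is not None:
        if panel is None:
            raise ConfigurationError("spell_statistics: 'by' requires the panel")
        panel.require_column(by, "by")
        unit_group = (
            panel.records[[panel.id_var, by]]
            .dropna()
            .drop_duplicates(panel.id_var)
            .set_index(panel.id_var)[by]
        )
        tmp = tbl.copy()
        tmp["group"] = tmp["unit"].map(unit_group).fillna("(missing)")
        rows = []
        for level, sub in tmp.groupby("group", sort=True):
            d = _describe(sub["duration"].to_numpy(dtype=float), "durations")
            d.insert(0, "group", level)
            rows.append(d)
        by_group = pd.concat(rows, ignore_index=True) if rows else None
    return SpellStatistics(
        n_units=spells.n_units,
        n_spells=spells.n_spells,
        spells_per_unit=spu,
        durations=durations,
        n_left_censored=int(tbl["left_censored"].sum()) if len(tbl) else 0,
        n_right_censored=int(tbl["right_censored"].sum()) if len(tbl) else 0,
        by_group=by_group,
    )


# ---------------------------------------------------------------------------
# Churn


@dataclass
class ChurnSummary:
    """Churn: exits followed by re-entry within ``window`` periods.

    A churn event is a gap of length <= window between two spells of the
    same unit.  The headline rate divides events by completed
    (non-right-censored) spells; per-unit and per-spell rates are reported
    alongside because the normalization convention varies across studies.
    """

    window: int
    n_events: int
    n_completed_spells: int
    n_spells: int
    n_units: int
    rate_per_completed_spell: float
    rate_per_unit: float
    rate_per_spell: float
    reentries_by_period: pd.Series = field(repr=False, default=None)

    @property
    def n_findings(self) -> int:
        return self.n_events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measure": [
                    "window",
                    "churn events",
                    "completed spells",
                    "rate per completed spell",
                    "rate per unit",
                    "rate per spell",
                ],
                "value": [
                    self.window,
                    self.n_events,
                    self.n_completed_spells,
                    self.rate_per_completed_spell,
                    self.rate_per_unit,
                    self.rate_per_spell,
                ],
            }
        )


def churn_events(spells: SpellTable, window: int = 4) -> ChurnSummary:
    """Count churn events (gap <= window) and normalize them three ways."""
    if window < 1:
        raise ConfigurationError("churn window must be >= 1 period")
    gaps = spells.gaps
    events = int((gaps["length"] <= window).sum()) if len(gaps) else 0
    tbl = spells.spells
    completed = int((~tbl["right_censored"]).sum()) if len(tbl) else 0
    n_spells = spells.n_spells
    n_units = spells.n_units
    reentry_starts = tbl.loc[tbl["spell"] > 0, "start"] if len(tbl) else pd.Series(dtype=int)
    reentries = reentry_starts.value_counts().sort_index()
    return ChurnSummary(
        window=window,
        n_events=events,
        n_completed_spells=completed,
        n_spells=n_spells,
        n_units=n_units,
        rate_per_completed_spell=(events / completed) if completed else 0.0,
        rate_per_unit=(events / n_units) if n_units else 0.0,
        rate_per_spell=(events / n_spells) if n_spells else 0.0,
        reentries_by_period=reentries,
    )


# ---------------------------------------------------------------------------
# Trajectory screens


@dataclass
class TrajectoryViolations:
    """Units whose declared-stable variables change or declared-monotone
    variables decrease."""

    stable: dict[str, dict]
    monotone: dict[str, dict]

    @property
    def n_findings(self) -> int:
        return sum(v["count"] for v in self.stable.values()) + sum(
            v["count"] for v in self.monotone.values()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": var, "check": "stable", "violating_units": info["count"]}
            for var, info in self.stable.items()
        ] + [
            {"variable": var, "check": "monotone_nondecreasing", "violating_units": info["count"]}
            for var, info in self.monotone.items()
        ]
        return pd.DataFrame(rows, columns=["variable", "check", "violating_units"])


def trajectory_checks(panel: PanelDataset, sample_cap: int = 20) -> TrajectoryViolations:
    """Screen every declared stable/monotone variable for within-unit
    violations.

    A stable violation is more than one distinct non-missing value within a
    unit; a monotone violation is any strictly decreasing consecutive
    non-missing pair (ordered by period).
    """
    stable_vars = [s.name for s in panel.schema if s.trajectory == "stable"]
    monotone_vars = [
        s.name for s in panel.schema if s.trajectory == "monotone_nondecreasing"
    ]
    df = panel.records
    ids = df[panel.id_var]
    stable: dict[str, dict] = {}
    for var in stable_vars:
        sub = pd.DataFrame({"unit": ids, "value": df[var]}).dropna()
        nuniq = sub.groupby("unit", sort=False)["value"].nunique()
        bad = nuniq[nuniq > 1]
        stable[var] = {
            "count": int(len(bad)),
            "sample_units": bad.index[:sample_cap].tolist(),
        }
    monotone: dict[str, dict] = {}
    for var in monotone_vars:
        sub = pd.DataFrame(
            {
                "unit": ids,
                "period": panel.periods,
                "value": pd.to_numeric(df[var], errors="coerce"),
            }
        ).dropna()
        sub = sub.sort_values(["unit", "period"], kind="stable")
        u = sub["unit"].to_numpy()
        v = sub["value"].to_numpy()
        p = sub["period"].to_numpy()
        same = np.zeros(len(sub), dtype=bool)
        same[1:] = u[1:] == u[:-1]
        dec = same.copy()
        dec[1:] &= v[1:] < v[:-1]
        offenders = pd.DataFrame({"unit": u[dec], "period": p[dec]})
        first = (
            offenders.groupby("unit", sort=False)["period"].min()
            if len(offenders)
            else pd.Series(dtype=float)
        )
        monotone[var] = {
            "count": int(first.shape[0]),
            "sample_units": first.index[:sample_cap].tolist(),
            "first_offense": first.head(sample_cap).to_dict(),
        }
    return TrajectoryViolations(stable=stable, monotone=monotone)
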