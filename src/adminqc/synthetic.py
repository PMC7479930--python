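"""Seeded synthetic benefits panel with labeled defect injection.

The generator emulates a hypothetical monthly benefits program observed
2011-2015: units enter the caseload, receive benefits for geometric-length
spells, may exit and later re-enter, and each unit-month row carries the
program variables (number of recipients, benefit amount, funding source,
receipt of other benefits, case type) plus geography, income and
demographics.  The default configuration is calibrated so 100,000 units
produce on the order of 1.5 million unit-month rows over the 60-month
window.

Benefit amount is proportional to the number of recipients plus noise,
with two planted comparability features mirroring patterns a data user
should be able to find: extra variability when the number of recipients is
1, and a level shift with inflated variance from a configurable start
period (2015-01 by default).

``inject_defects`` then plants the defect classes the check suite targets
— ID-syntax corruption, row duplication, domain-dependent item
missingness, outlier substitution, stable-variable flips, and
monotone-counter decreases — and records every action in a
:class:`DefectTruth` ledger, the ground truth for recovery tests.
Identical seed + config give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .panel import PanelDataset, VariableSchema
from .rules import EditRule, parse_rule

_DEFECT_CLASSES = (
    "invalid_id",
    "duplicate",
    "missing",
    "outlier",
    "stable_flip",
    "monotone",
)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults give the full-scale study panel."""

    # scale and window
    n_units: int = 100_000
    start: str = "2011-01"
    n_periods: int = 60
    seed: int = 12345
    # spell process
    initial_stock_frac: float = 0.35
    spell_mean: float = 12.0
    reentry_prob: float = 0.40
    gap_mean: float = 4.0
    # variable models
    recipients_probs: tuple = (0.30, 0.27, 0.18, 0.11, 0.07, 0.04, 0.02, 0.01)
    benefit_base: float = 300.0
    benefit_per_recipient: float = 150.0
    benefit_noise_sd: float = 40.0
    single_recipient_noise_mult: float = 2.5
    income_zero_prob: float = 0.45
    income_log_mean: float = 7.0
    income_log_sd: float = 0.6
    funding_levels: tuple = ("federal", "state", "mixed")
    funding_probs: tuple = (0.50, 0.35, 0.15)
    other_benefit_prob: float = 0.30
    case_types: tuple = ("single_parent", "two_parent", "child_only")
    case_type_probs: tuple = (0.50, 0.30, 0.20)
    n_counties: int = 12
    county_weights: tuple | None = None
    # comparability shift (2015 scenario)
    shift_start: str = "2015-01"
    shift_delta: float = 50.0
    shift_variance_mult: float = 1.6
    # defect rates (all zero = clean panel)
    invalid_id_rate: float = 0.0
    duplicate_rate: float = 0.0
    missing_rates: dict = field(default_factory=dict)  # domain level -> rate
    missing_var: str = "income"
    domain_var: str = "case_type"
    outlier_rate: float = 0.0
    outlier_mult: float = 50.0
    stable_flip_rate: float = 0.0
    stable_var: str = "sex"
    monotone_violation_rate: float = 0.0
    monotone_var: str = "months_on_benefits"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if self.n_periods < 1:
            raise ConfigurationError("n_periods must be >= 1")
        if self.spell_mean < 1 or self.gap_mean < 1:
            raise ConfigurationError("spell_mean and gap_mean must be >= 1 period")
        if self.shift_variance_mult < 1:
            raise ConfigurationError("shift_variance_mult must be >= 1")
        rates = {
            "initial_stock_frac": self.initial_stock_frac,
            "reentry_prob": self.reentry_prob,
            "income_zero_prob": self.income_zero_prob,
            "other_benefit_prob": self.other_benefit_prob,
            "invalid_id_rate": self.invalid_id_rate,
            "duplicate_rate": self.duplicate_rate,
            "outlier_rate": self.outlier_rate,
            "stable_flip_rate": self.stable_flip_rate,
            "monotone_violation_rate": self.monotone_violation_rate,
            **{f"missing_rates[{k}]": v for k, v in self.missing_rates.items()},
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name, probs in (
            ("recipients_probs", self.recipients_probs),
            ("funding_probs", self.funding_probs),
            ("case_type_probs", self.case_type_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def shift_period(self) -> int:
        """Period index (months since start) at which the shift begins."""
        sy, sm = (int(x) for x in self.start.split("-"))
        ty, tm = (int(x) for x in self.shift_start.split("-"))
        return (ty * 12 + tm) - (sy * 12 + sm)


@dataclass
class DefectTruth:
    """Ground-truth ledger of injected defects, one frame per class.

    Frames share the columns (unit, period, variable, detail); ``period``
    is the period index or ``<NA>`` for unit-level defects such as ID
    corruption.
    """

    frames: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in _DEFECT_CLASSES:
            self.frames.setdefault(
                cls, pd.DataFrame(columns=["unit", "period", "variable", "detail"])
            )

    def count(self, cls: str) -> int:
        return len(self.frames[cls])

    @property
    def total(self) -> int:
        return sum(len(f) for f in self.frames.values())

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for cls, frame in self.frames.items():
            if len(frame):
                f = frame.copy()
                f.insert(0, "defect_class", cls)
                parts.append(f)
        if not parts:
            return pd.DataFrame(columns=["defect_class", "unit", "period", "variable", "detail"])
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Clean generation


def _make_unit_ids(n: int) -> np.ndarray:
    """Sequential syntactically valid SSN-style keys (area 100+, 3-2-4)."""
    idx = np.arange(n)
    serial = idx % 9999 + 1
    group = (idx // 9999) % 99 + 1
    area = idx // (9999 * 99) + 100
    if area.max() > 665:
        raise ConfigurationError("n_units exceeds the valid key space of the generator")
    return np.array(
        [f"{a:03d}-{g:02d}-{s:04d}" for a, g, s in zip(area, group, serial)],
        dtype=object,
    )


def _month_labels(start: str, n_periods: int) -> list[str]:
    sy, sm = (int(x) for x in start.split("-"))
    base = sy * 12 + (sm - 1)
    return [f"{(base + i) // 12:04d}-{(base + i) % 12 + 1:02d}" for i in range(n_periods)]


def _simulate_spell_rows(cfg: SyntheticConfig, rng: np.random.Generator):
    """Row-level (unit index, period index) arrays from the spell process."""
    n, T = cfg.n_units, cfg.n_periods
    stock = rng.random(n) < cfg.initial_stock_frac
    start = np.where(stock, 0, rng.integers(0, T, n))
    active = np.arange(n)
    cur = start
    seg_units, seg_starts, seg_ends = [], [], []
    while len(active):
        length = rng.geometric(1.0 / cfg.spell_mean, size=len(active))
        raw_end = cur + length - 1
        end = np.minimum(raw_end, T - 1)
        seg_units.append(active)
        seg_starts.append(cur)
        seg_ends.append(end)
        truncated = raw_end > T - 1
        reenter = (rng.random(len(active)) < cfg.reentry_prob) & ~truncated
        gap = rng.geometric(1.0 / cfg.gap_mean, size=len(active))
        nxt = end + 1 + gap
        keep = reenter & (nxt <= T - 1)
        active = active[keep]
        cur = nxt[keep]
    u = np.concatenate(seg_units)
    s = np.concatenate(seg_starts)
    e = np.concatenate(seg_ends)
    lens = e - s + 1
    total = int(lens.sum())
    row_unit = np.repeat(u, lens)
    offsets = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    row_period = np.repeat(s, lens) + offsets
    order = np.lexsort((row_period, row_unit))
    return row_unit[order], row_period[order]


def default_schema(cfg: SyntheticConfig) -> list[VariableSchema]:
    return [
        VariableSchema("id", role="identifier"),
        VariableSchema("month", role="time"),
        VariableSchema("recipients", role="numeric", vmin=1, vmax=8),
        VariableSchema("benefit", role="numeric", vmin=0),
        VariableSchema("income", role="numeric", vmin=0),
        VariableSchema(
            "months_on_benefits",
            role="numeric",
            vmin=1,
            trajectory="monotone_nondecreasing",
        ),
        VariableSchema("funding_source", role="categorical", levels=list(cfg.funding_levels)),
        VariableSchema("other_benefits", role="categorical", levels=["yes", "no"]),
        VariableSchema("case_type", role="domain", levels=list(cfg.case_types)),
        VariableSchema(
            "county",
            role="geography",
            levels=[f"county_{i + 1:02d}" for i in range(cfg.n_counties)],
        ),
        VariableSchema("sex", role="categorical", levels=["F", "M"], trajectory="stable"),
        VariableSchema("birth_year", role="numeric", trajectory="stable"),
    ]


def default_rules(cfg: SyntheticConfig | None = None) -> list[EditRule]:
    """Edit rules matching the synthetic codebook (all hold on clean data)."""
    cfg = cfg or SyntheticConfig(n_units=1)
    specs = [
        {
            "id": "recipients_range",
            "severity": "invalid",
            "description": "number of recipients must be between 1 and 8",
            "assert": {"var": "recipients", "op": "between", "value": [1, 8]},
        },
        {
            "id": "benefit_nonnegative",
            "severity": "invalid",
            "description": "benefit amount cannot be negative",
            "assert": {"var": "benefit", "op": "ge", "value": 0},
        },
        {
            "id": "income_nonnegative",
            "severity": "invalid",
            "description": "household income cannot be negative",
            "assert": {"var": "income", "op": "ge", "value": 0},
        },
        {
            "id": "funding_known",
            "severity": "invalid",
            "description": "funding source must be a documented level",
            "assert": {"var": "funding_source", "op": "in", "value": list(cfg.funding_levels)},
        },
        {
            "id": "months_positive",
            "severity": "invalid",
            "description": "months of benefit receipt starts at 1",
            "assert": {"var": "months_on_benefits", "op": "ge", "value": 1},
        },
        {
            "id": "benefit_implausibly_high",
            "severity": "dubious",
            "description": "benefit amount above 10,000 is implausible for this program",
            "flag_when": {"var": "benefit", "op": "gt", "value": 10_000},
        },
        {
            "id": "benefit_with_high_income",
            "severity": "dubious",
            "description": "means-tested receipt alongside very high household income",
            "flag_when": {
                "all": [
                    {"var": "other_benefits", "op": "eq", "value": "yes"},
                    {"var": "income", "op": "gt", "value": 50_000},
                ]
            },
        },
    ]
    return [parse_rule(s, i) for i, s in enumerate(specs)]


def _generate_clean(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    row_unit, row_period = _simulate_spell_rows(cfg, rng)
    total = len(row_unit)
    n = cfg.n_units
    ids = _make_unit_ids(n)
    recipients = rng.choice(
        np.arange(1, len(cfg.recipients_probs) + 1), size=n, p=cfg.recipients_probs
    )
    county_names = [f"county_{i + 1:02d}" for i in range(cfg.n_counties)]
    if cfg.county_weights is None:
        w = 1.0 / np.sqrt(np.arange(1, cfg.n_counties + 1))
    else:
        w = np.asarray(cfg.county_weights, dtype=float)
        if len(w) != cfg.n_counties:
            raise ConfigurationError("county_weights length must equal n_counties")
    w = w / w.sum()
    county = rng.choice(np.array(county_names, dtype=object), size=n, p=w)
    case_type = rng.choice(np.array(cfg.case_types, dtype=object), size=n, p=cfg.case_type_probs)
    funding = rng.choice(np.array(cfg.funding_levels, dtype=object), size=n, p=cfg.funding_probs)
    sex = rng.choice(np.array(["F", "M"], dtype=object), size=n)
    birth_year = rng.integers(1950, 2001, size=n)

    rec_row = recipients[row_unit]
    shift_p = cfg.shift_period
    in_shift = row_period >= shift_p
    sd = np.full(total, cfg.benefit_noise_sd)
    sd[rec_row == 1] *= cfg.single_recipient_noise_mult
    sd[in_shift] *= cfg.shift_variance_mult
    noise = rng.standard_normal(total)
    benefit = (
        cfg.benefit_base
        + cfg.benefit_per_recipient * rec_row
        + cfg.shift_delta * in_shift
        + noise * sd
    )
    np.clip(benefit, 0.0, None, out=benefit)

    zero_income = rng.random(total) < cfg.income_zero_prob
    income = rng.lognormal(cfg.income_log_mean, cfg.income_log_sd, size=total)
    income[zero_income] = 0.0
    other = np.where(
        rng.random(total) < cfg.other_benefit_prob,
        np.array("yes", dtype=object),
        np.array("no", dtype=object),
    )

    # cumulative months of receipt: rows are sorted by (unit, period)
    new_unit = np.ones(total, dtype=bool)
    new_unit[1:] = row_unit[1:] != row_unit[:-1]
    unit_first = np.flatnonzero(new_unit)
    counts = np.diff(np.append(unit_first, total))
    months = np.arange(total) - np.repeat(unit_first, counts) + 1

    labels = _month_labels(cfg.start, cfg.n_periods)
    month_arr = np.array(labels, dtype=object)[row_period]
    return pd.DataFrame(
        {
            "id": ids[row_unit],
            "month": month_arr,
            "recipients": rec_row.astype(float),
            "benefit": np.round(benefit, 2),
            "income": np.round(income, 2),
            "months_on_benefits": months.astype(float),
            "funding_source": funding[row_unit],
            "other_benefits": other,
            "case_type": case_type[row_unit],
            "county": county[row_unit],
            "sex": sex[row_unit],
            "birth_year": birth_year[row_unit].astype(float),
        }
    )


# ---------------------------------------------------------------------------
# Defect injection


def _ledger(unit, period, variable, detail) -> pd.DataFrame:
    return pd.DataFrame(
        {"unit": unit, "period": period, "variable": variable, "detail": detail}
    )


def _inject(df: pd.DataFrame, cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, DefectTruth]:
    truth = DefectTruth()
    labels = _month_labels(cfg.start, cfg.n_periods)
    label_to_idx = {lab: i for i, lab in enumerate(labels)}

    # 1. ID-syntax corruption: whole units get a malformed key.  Both
    # variants preserve uniqueness so corrupted units never merge.
    n_bad = int(round(cfg.invalid_id_rate * df["id"].nunique()))
    if n_bad:
        units = rng.choice(df["id"].unique(), size=n_bad, replace=False)
        variant = rng.integers(0, 2, size=n_bad)
        mapping = {
            u: ("9" + u[1:]) if v == 0 else (u + "X")
            for u, v in zip(units, variant)
        }
        mask = df["id"].isin(mapping)
        df.loc[mask, "id"] = df.loc[mask, "id"].map(mapping)
        truth.frames["invalid_id"] = _ledger(
            list(mapping.values()), pd.NA, "id", [f"was {u}" for u in mapping]
        )

    # 2. Row duplication: exact copies of sampled rows appended.
    n_dup = int(round(cfg.duplicate_rate * len(df)))
    dup_units: set = set()
    if n_dup:
        pos = rng.choice(len(df), size=n_dup, replace=False)
        dups = df.iloc[pos]
        dup_units = set(dups["id"])
        truth.frames["duplicate"] = _ledger(
            dups["id"].to_numpy(),
            dups["month"].map(label_to_idx).to_numpy(),
            "(row)",
            "duplicated",
        )
        df = pd.concat([df, dups], ignore_index=True)

    # 3. Domain-dependent item missingness on the target variable.
    miss_parts = []
    for level, rate in cfg.missing_rates.items():
        level_pos = np.flatnonzero((df[cfg.domain_var] == level).to_numpy())
        n_miss = int(round(rate * len(level_pos)))
        if not n_miss:
            continue
        chosen = rng.choice(level_pos, size=n_miss, replace=False)
        df.iloc[chosen, df.columns.get_loc(cfg.missing_var)] = np.nan
        miss_parts.append(
            _ledger(
                df["id"].iloc[chosen].to_numpy(),
                df["month"].iloc[chosen].map(label_to_idx).to_numpy(),
                cfg.missing_var,
                f"blanked (domain {level})",
            )
        )
    if miss_parts:
        truth.frames["missing"] = pd.concat(miss_parts, ignore_index=True)

    # 4. Outlier substitution on benefit amount.
    n_out = int(round(cfg.outlier_rate * len(df)))
    if n_out:
        bcol = df.columns.get_loc("benefit")
        candidates = np.flatnonzero(df["benefit"].notna().to_numpy())
        chosen = rng.choice(candidates, size=min(n_out, len(candidates)), replace=False)
        old = df.iloc[chosen, bcol].to_numpy(dtype=float)
        df.iloc[chosen, bcol] = np.round(old * cfg.outlier_mult, 2)
        truth.frames["outlier"] = _ledger(
            df["id"].iloc[chosen].to_numpy(),
            df["month"].iloc[chosen].map(label_to_idx).to_numpy(),
            "benefit",
            [f"{o} -> {o * cfg.outlier_mult}" for o in old],
        )

    # Units with >= 2 rows and no duplicated rows are eligible for the
    # within-unit trajectory defects: a single-row unit's flip is
    # undetectable, and duplicated same-period rows would make the
    # within-unit ordering ambiguous.
    sizes = df["id"].value_counts()
    eligible = sizes[(sizes >= 2) & ~sizes.index.isin(dup_units)].index.to_numpy()
    rng.shuffle(eligible)
    row_pos_by_unit = None

    def _positions(unit):
        nonlocal row_pos_by_unit
        if row_pos_by_unit is None:
            row_pos_by_unit = (
                pd.Series(np.arange(len(df)), index=df["id"]).groupby(level=0).apply(list)
            )
        return row_pos_by_unit[unit]

    # 5. Stable-variable flips (one row per chosen unit).
    n_flip = int(round(cfg.stable_flip_rate * df["id"].nunique()))
    n_flip = min(n_flip, len(eligible))
    flip_units = eligible[:n_flip]
    if n_flip:
        scol = df.columns.get_loc(cfg.stable_var)
        rows, olds, news, pers = [], [], [], []
        for unit in flip_units:
            pos = _positions(unit)
            j = pos[rng.integers(0, len(pos))]
            old = df.iat[j, scol]
            new = "M" if old == "F" else "F"
            df.iat[j, scol] = new
            rows.append(unit)
            olds.append(old)
            news.append(new)
            pers.append(label_to_idx[df.iat[j, df.columns.get_loc("month")]])
        truth.frames["stable_flip"] = _ledger(
            rows, pers, cfg.stable_var, [f"{o} -> {n2}" for o, n2 in zip(olds, news)]
        )

    # 6. Monotone-counter decreases (one row, never the unit's first).
    n_mono = int(round(cfg.monotone_violation_rate * df["id"].nunique()))
    rest = eligible[n_flip:]
    n_mono = min(n_mono, len(rest))
    mono_units = rest[:n_mono]
    if n_mono:
        mcol = df.columns.get_loc(cfg.monotone_var)
        tcol = df.columns.get_loc("month")
        rows, pers, details = [], [], []
        for unit in mono_units:
            pos = sorted(_positions(unit), key=lambda j: label_to_idx[df.iat[j, tcol]])
            k = int(rng.integers(1, len(pos)))
            j = pos[k]
            prev = float(df.iat[pos[k - 1], mcol])
            old = float(df.iat[j, mcol])
            new = prev - 1.0
            df.iat[j, mcol] = new
            rows.append(unit)
            pers.append(label_to_idx[df.iat[j, tcol]])
            details.append(f"{old} -> {new}")
        truth.frames["monotone"] = _ledger(rows, pers, cfg.monotone_var, details)

    return df, truth


# ---------------------------------------------------------------------------
# Public API


def simulate_panel(config: SyntheticConfig | None = None) -> tuple[PanelDataset, DefectTruth]:
    """Generate the benefits panel and apply configured defect injection.

    Returns the (possibly defective) panel and the ground-truth ledger;
    with all defect rates zero the ledger is empty and the panel passes
    every check with zero findings.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    df = _generate_clean(cfg, rng)
    df, truth = _inject(df, cfg, rng)
    panel = PanelDataset.from_frame(
        df, id_var="id", time_var="month", schema=default_schema(cfg), granularity="month"
    )
    return panel, truth


def inject_defects(
    panel: PanelDataset, config: SyntheticConfig, seed: int | None = None
) -> tuple[PanelDataset, DefectTruth]:
    """Apply the configured defect classes to an existing panel.

    Actions are applied in a fixed order (ID corruption, duplication,
    missingness, outliers, stable flips, monotone decreases) and every one
    is appended to the returned :class:`DefectTruth`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    df, truth = _inject(panel.records.copy(), config, rng)
    out = PanelDataset.from_frame(
        df,
        id_var=panel.id_var,
        time_var=panel.time_var,
        schema=panel.schema,
        granularity=panel.granularity,
    )
    return out, truth


def write_synthetic(
    panel: PanelDataset, truth: DefectTruth, config: SyntheticConfig, outdir
) -> dict:
    """Write panel CSV, truth ledger CSV and the resolved config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel_path = outdir / "panel.csv"
    truth_path = outdir / "defect_truth.csv"
    config_path = outdir / "config.yaml"
    panel.records.to_csv(panel_path, index=False)
    truth.to_frame().to_csv(truth_path, index=False)
    config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return {"panel": panel_path, "truth": truth_path, "config": config_path}
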