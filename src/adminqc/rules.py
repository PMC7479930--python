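"""Declarative edit-rule engine for validity and plausibility checks.

Administrative records are screened against user-declared rules: range and
set-membership constraints from the codebook, and logical relations among
variables from program knowledge (for example, persons under age sixteen
must be recorded as out of the labour force).  Rules carry a severity:

* ``invalid`` — the record violates the codebook or a hard logical relation;
* ``dubious`` — the value is formally valid but implausible by judgment
  (a household of sixteen members; a means-tested benefit alongside high
  household income).  Dubious findings are advisory and tallied separately.

Every record evaluates to exactly one of pass / fail / not-applicable per
rule.  A record with a missing value in any variable the rule references is
*not applicable* — missingness belongs to the completeness dimension and is
never double-counted as a rule failure.  Records where the optional ``when``
guard is false are also not applicable.

Predicates are data, not code: a condition is ``{var, op, value}`` with ops
``eq ne lt le gt ge in not_in between matches``, and conditions combine with
``all`` / ``any`` / ``not``.  This keeps rule files auditable and portable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

_OPS = {"eq", "ne", "lt", "le", "gt", "ge", "in", "not_in", "between", "matches"}


@dataclass(frozen=True)
class Condition:
    var: str
    op: str
    value: object

    def variables(self) -> set[str]:
        return {self.var}


@dataclass(frozen=True)
class Combinator:
    kind: str  # "all" | "any" | "not"
    parts: tuple

    def variables(self) -> set[str]:
        out: set[str] = set()
        for p in self.parts:
            out |= p.variables()
        return out


Predicate = Condition | Combinator


def parse_predicate(obj, where: str = "predicate") -> Predicate:
    if not isinstance(obj, dict):
        raise ConfigurationError(f"{where}: expected a mapping, got {type(obj).__name__}")
    keys = set(obj)
    if keys & {"all", "any", "not"}:
        if len(keys) != 1:
            raise ConfigurationError(f"{where}: combinator mapping must have exactly one key")
        kind = next(iter(keys))
        val = obj[kind]
        if kind == "not":
            return Combinator("not", (parse_predicate(val, f"{where}.not"),))
        if not isinstance(val, list) or not val:
            raise ConfigurationError(f"{where}.{kind}: expected a non-empty list")
        return Combinator(kind, tuple(parse_predicate(v, f"{where}.{kind}[{i}]") for i, v in enumerate(val)))
    if keys != {"var", "op", "value"}:
        raise ConfigurationError(
            f"{where}: condition must have exactly the keys var/op/value, got {sorted(keys)}"
        )
    op = obj["op"]
    if op not in _OPS:
        raise ConfigurationError(f"{where}: unknown op {op!r}; expected one of {sorted(_OPS)}")
    if op == "between":
        v = obj["value"]
        if not isinstance(v, (list, tuple)) or len(v) != 2:
            raise ConfigurationError(f"{where}: 'between' value must be a 2-element list")
    if op == "matches":
        try:
            re.compile(str(obj["value"]))
        except re.error as exc:
            raise ConfigurationError(f"{where}: invalid regular expression: {exc}") from exc
    return Condition(str(obj["var"]), op, obj["value"])


def _predicate_to_dict(p: Predicate) -> dict:
    if isinstance(p, Condition):
        return {"var": p.var, "op": p.op, "value": p.value}
    if p.kind == "not":
        return {"not": _predicate_to_dict(p.parts[0])}
    return {p.kind: [_predicate_to_dict(q) for q in p.parts]}


def _eval_predicate(p: Predicate, df: pd.DataFrame) -> np.ndarray:
    """Boolean truth array; missing inputs yield False (masked to NA later)."""
    if isinstance(p, Combinator):
        sub = [_eval_predicate(q, df) for q in p.parts]
        if p.kind == "not":
            return ~sub[0]
        stacked = np.vstack(sub)
        return stacked.all(axis=0) if p.kind == "all" else stacked.any(axis=0)
    col = df[p.var]
    if p.op in ("lt", "le", "gt", "ge", "between"):
        vals = pd.to_numeric(col, errors="coerce")
        if p.op == "lt":
            out = vals < p.value
        elif p.op == "le":
            out = vals <= p.value
        elif p.op == "gt":
            out = vals > p.value
        elif p.op == "ge":
            out = vals >= p.value
        else:
            lo, hi = p.value
            out = pd.Series(True, index=col.index)
            if lo is not None:
                out &= vals >= lo
            if hi is not None:
                out &= vals <= hi
        return out.fillna(False).to_numpy(dtype=bool)
    if p.op in ("eq", "ne"):
        if isinstance(p.value, (int, float)) and not isinstance(p.value, bool):
            vals = pd.to_numeric(col, errors="coerce")
            out = vals == p.value
        else:
            out = col.astype("object") == p.value
        out = pd.Series(out).fillna(False)
        arr = out.to_numpy(dtype=bool)
        return ~arr if p.op == "ne" else arr
    if p.op in ("in", "not_in"):
        values = list(p.value) if isinstance(p.value, (list, tuple, set)) else [p.value]
        arr = col.isin(values).to_numpy(dtype=bool)
        return ~arr if p.op == "not_in" else arr
    if p.op == "matches":
        pat = re.compile(str(p.value))
        arr = col.astype("string").str.match(pat).fillna(False).to_numpy(dtype=bool)
        return arr
    raise ConfigurationError(f"unknown op {p.op!r}")  # pragma: no cover


@dataclass
class EditRule:
    """One declarative validity (``invalid``) or plausibility (``dubious``) rule."""

    rule_id: str
    severity: str
    check: Predicate
    when: Predicate | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.severity not in ("invalid", "dubious"):
            raise ConfigurationError(
                f"rule {self.rule_id!r}: severity must be 'invalid' or 'dubious'"
            )

    def variables(self) -> set[str]:
        out = self.check.variables()
        if self.when is not None:
            out |= self.when.variables()
        return out

    def to_dict(self) -> dict:
        d: dict = {
            "id": self.rule_id,
            "severity": self.severity,
            "assert": _predicate_to_dict(self.check),
        }
        if self.when is not None:
            d["when"] = _predicate_to_dict(self.when)
        if self.description:
            d["description"] = self.description
        return d


def parse_rule(obj, i: int = 0) -> EditRule:
    """Parse one rule mapping.

    Exactly one of ``assert`` (condition that must hold) or ``flag_when``
    (condition that, when true, flags the record) is required; ``flag_when``
    is sugar for ``assert: {not: ...}``.
    """
    if not isinstance(obj, dict):
        raise ConfigurationError(f"rules[{i}] must be a mapping")
    rid = str(obj.get("id", f"rule_{i}"))
    known = {"id", "severity", "description", "when", "assert", "flag_when"}
    extra = set(obj) - known
    if extra:
        raise ConfigurationError(f"rule {rid!r}: unknown key(s) {sorted(extra)}")
    has_assert = "assert" in obj
    has_flag = "flag_when" in obj
    if has_assert == has_flag:
        raise ConfigurationError(
            f"rule {rid!r}: exactly one of 'assert' or 'flag_when' is required"
        )
    if has_assert:
        check = parse_predicate(obj["assert"], f"rule {rid!r} assert")
    else:
        check = Combinator("not", (parse_predicate(obj["flag_when"], f"rule {rid!r} flag_when"),))
    when = None
    if obj.get("when") is not None:
        when = parse_predicate(obj["when"], f"rule {rid!r} when")
    return EditRule(
        rule_id=rid,
        severity=obj.get("severity", "invalid"),
        check=check,
        when=when,
        description=str(obj.get("description", "")),
    )


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class RuleResult:
    """Tallies for a rule evaluation run.

    ``per_rule`` has one row per rule with pass/fail/not_applicable counts
    (summing to the number of records for every rule) and the failure
    proportion among applicable records.  ``unit_any_failure`` counts units
    with at least one failing record, per severity.  Optional ``by_group``
    and ``by_interval`` frames repeat the tallies per group level / time
    interval.
    """

    n_records: int
    n_units: int
    per_rule: pd.DataFrame
    unit_any_failure: dict
    by_group: pd.DataFrame | None = None
    by_interval: pd.DataFrame | None = None

    @property
    def n_findings(self) -> int:
        return int(self.per_rule["fail"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.per_rule


def _tally(status: np.ndarray) -> tuple[int, int, int]:
    # status codes: 1 pass, 0 fail, -1 not applicable
    return int((status == 1).sum()), int((status == 0).sum()), int((status == -1).sum())


def evaluate_rules(
    panel,
    rules: Sequence[EditRule],
    group_var: str | None = None,
    intervals: Sequence[tuple] | None = None,
) -> RuleResult:
    """Evaluate every rule over every record of the panel.

    Parameters
    ----------
    panel : PanelDataset
    rules : sequence of EditRule
    group_var : str, optional
        Categorical variable for per-group breakdowns; missing group values
        form a ``"(missing)"`` level so group tallies conserve record counts.
    intervals : sequence of (start, end), optional
        Inclusive period ranges, given either as raw time values (e.g.
        ``("2011-01", "2011-12")``) or period indices, for per-interval
        breakdowns.
    """
    df = panel.records
    for rule in rules:
        for var in sorted(rule.variables()):
            if var not in df.columns:
                raise ConfigurationError(
                    f"rule {rule.rule_id!r} references unknown variable {var!r}"
                )
    if group_var is not None:
        panel.require_column(group_var, "group_var")

    statuses: dict[str, np.ndarray] = {}
    for rule in rules:
        refd = sorted(rule.variables())
        any_missing = np.zeros(len(df), dtype=bool)
        for var in refd:
            any_missing |= df[var].isna().to_numpy()
        ok = _eval_predicate(rule.check, df)
        status = np.where(ok, 1, 0)
        if rule.when is not None:
            applicable = _eval_predicate(rule.when, df)
            status = np.where(applicable, status, -1)
        status = np.where(any_missing, -1, status)
        statuses[rule.rule_id] = status

    rows = []
    for rule in rules:
        p, f, na = _tally(statuses[rule.rule_id])
        applicable = p + f
        rows.append(
            {
                "rule_id": rule.rule_id,
                "severity": rule.severity,
                "description": rule.description,
                "pass": p,
                "fail": f,
                "not_applicable": na,
                "fail_prop_applicable": (f / applicable) if applicable else np.nan,
            }
        )
    per_rule = pd.DataFrame(
        rows,
        columns=[
            "rule_id",
            "severity",
            "description",
            "pass",
            "fail",
            "not_applicable",
            "fail_prop_applicable",
        ],
    )

    ids = df[panel.id_var]
    n_units = panel.n_units
    unit_any: dict[str, dict] = {}
    for severity in ("invalid", "dubious"):
        fail_any = np.zeros(len(df), dtype=bool)
        for rule in rules:
            if rule.severity == severity:
                fail_any |= statuses[rule.rule_id] == 0
        failed_units = ids[fail_any & ids.notna()].nunique()
        unit_any[severity] = {
            "units_with_failure": int(failed_units),
            "proportion": (failed_units / n_units) if n_units else 0.0,
        }

    by_group = None
    if group_var is not None and rules:
        gvals = df[group_var].astype("object").where(df[group_var].notna(), "(missing)")
        grows = []
        for level, idx in gvals.groupby(gvals, sort=True).groups.items():
            pos = df.index.get_indexer(idx)
            for rule in rules:
                p, f, na = _tally(statuses[rule.rule_id][pos])
                grows.append(
                    {"group": level, "rule_id": rule.rule_id, "pass": p, "fail": f, "not_applicable": na}
                )
        by_group = pd.DataFrame(grows)

    by_interval = None
    if intervals and rules:
        periods = panel.periods.to_numpy(dtype="float64", na_value=np.nan)
        irows = []
        for start, end in intervals:
            lo = start if isinstance(start, (int, np.integer)) else panel.period_of(start)
            hi = end if isinstance(end, (int, np.integer)) else panel.period_of(end)
            mask = (periods >= lo) & (periods <= hi)
            label = f"{start}..{end}"
            for rule in rules:
                p, f, na = _tally(statuses[rule.rule_id][mask])
                irows.append(
                    {"interval": label, "rule_id": rule.rule_id, "pass": p, "fail": f, "not_applicable": na}
                )
        by_interval = pd.DataFrame(irows)

    return RuleResult(
        n_records=len(df),
        n_units=n_units,
        per_rule=per_rule,
        unit_any_failure=unit_any,
        by_group=by_group,
        by_interval=by_interval,
    )
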