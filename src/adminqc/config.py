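"""Assessment configuration: variable roles, rules, check parameters.

The published config format is a YAML or JSON mapping with keys::

    id_var: caseid            # required
    time_var: month           # required
    delimiter: ","            # optional, default ","
    granularity: month        # month | quarter | year | integer
    variables:                # optional per-variable declarations
      - name: benefit
        role: numeric         # identifier|time|numeric|categorical|geography|domain
        range: [0, null]      # allowed numeric range (either end null = open)
        levels: [a, b]        # allowed categories
        missing_codes: [-9]
        trajectory: free      # free | stable | monotone_nondecreasing
    rules:                    # optional edit rules (see adminqc.rules)
      - id: r1
        severity: invalid     # invalid | dubious
        description: ...
        when: {var: age, op: lt, value: 16}        # optional applicability
        assert: {var: employment, op: eq, value: out of labour force}
    checks:                   # optional per-check parameter overrides
      duplicates: {keys: null, per_period: false}
      coverage: {geo_var: county, low_fraction: 0.5}
      ...
    relevance:                # optional free-text relevance checklist answers
      units: "households receiving benefits"

Unknown top-level keys raise a configuration error so typos surface early.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .panel import GRANULARITIES, VariableSchema
from .rules import EditRule, parse_rule

_TOP_KEYS = {
    "id_var",
    "time_var",
    "delimiter",
    "granularity",
    "variables",
    "rules",
    "checks",
    "relevance",
}


@dataclass
class AssessmentConfig:
    id_var: str
    time_var: str
    delimiter: str = ","
    granularity: str = "month"
    variables: list[VariableSchema] = field(default_factory=list)
    rules: list[EditRule] = field(default_factory=list)
    checks: dict = field(default_factory=dict)
    relevance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id_var or not self.time_var:
            raise ConfigurationError("config must name both id_var and time_var")
        if self.granularity not in GRANULARITIES:
            raise ConfigurationError(
                f"granularity {self.granularity!r} not one of {sorted(GRANULARITIES)}"
            )

    def to_dict(self) -> dict:
        """Plain-dict form (round-trips through load_config)."""
        out: dict = {
            "id_var": self.id_var,
            "time_var": self.time_var,
            "delimiter": self.delimiter,
            "granularity": self.granularity,
        }
        if self.variables:
            out["variables"] = [_schema_to_dict(s) for s in self.variables]
        if self.rules:
            out["rules"] = [r.to_dict() for r in self.rules]
        if self.checks:
            out["checks"] = self.checks
        if self.relevance:
            out["relevance"] = self.relevance
        return out


def _schema_to_dict(s: VariableSchema) -> dict:
    d: dict = {"name": s.name, "role": s.role}
    if s.levels is not None:
        d["levels"] = list(s.levels)
    if s.vmin is not None or s.vmax is not None:
        d["range"] = [s.vmin, s.vmax]
    if s.missing_codes:
        d["missing_codes"] = list(s.missing_codes)
    if s.trajectory != "free":
        d["trajectory"] = s.trajectory
    return d


def _parse_variable(entry, i: int) -> VariableSchema:
    if not isinstance(entry, dict) or "name" not in entry:
        raise ConfigurationError(f"variables[{i}] must be a mapping with a 'name' key")
    known = {"name", "role", "levels", "range", "missing_codes", "trajectory"}
    extra = set(entry) - known
    if extra:
        raise ConfigurationError(
            f"variables[{i}] ({entry['name']}): unknown key(s) {sorted(extra)}"
        )
    vmin = vmax = None
    rng = entry.get("range")
    if rng is not None:
        if not isinstance(rng, (list, tuple)) or len(rng) != 2:
            raise ConfigurationError(
                f"variables[{i}] ({entry['name']}): 'range' must be a 2-element list"
            )
        vmin, vmax = rng
    return VariableSchema(
        name=str(entry["name"]),
        role=entry.get("role", "categorical"),
        levels=entry.get("levels"),
        vmin=vmin,
        vmax=vmax,
        missing_codes=entry.get("missing_codes", ()),
        trajectory=entry.get("trajectory", "free"),
    )


def load_config(source) -> AssessmentConfig:
    """Build an :class:`AssessmentConfig` from a dict or a YAML/JSON path."""
    if isinstance(source, AssessmentConfig):
        return source
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    elif isinstance(source, dict):
        raw = source
    else:
        raise ConfigurationError(
            f"config must be a mapping or a path, got {type(source).__name__}"
        )
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping at top level")
    extra = set(raw) - _TOP_KEYS
    if extra:
        raise ConfigurationError(f"unknown config key(s): {sorted(extra)}")
    for key in ("id_var", "time_var"):
        if key not in raw:
            raise ConfigurationError(f"config is missing required key {key!r}")
    variables = [_parse_variable(v, i) for i, v in enumerate(raw.get("variables") or [])]
    rules = [parse_rule(r, i) for i, r in enumerate(raw.get("rules") or [])]
    checks = raw.get("checks") or {}
    if not isinstance(checks, dict):
        raise ConfigurationError("'checks' must be a mapping of check name -> parameters")
    return AssessmentConfig(
        id_var=str(raw["id_var"]),
        time_var=str(raw["time_var"]),
        delimiter=str(raw.get("delimiter", ",")),
        granularity=str(raw.get("granularity", "month")),
        variables=variables,
        rules=rules,
        checks=checks,
        relevance=raw.get("relevance") or {},
    )
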