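"""Long-format panel data model.

Administrative extracts analyzed by this toolkit are rectangular flat files
where every row describes one unit (household, family, individual, case) at
one time period.  :class:`PanelDataset` wraps such a table together with the
declared identification variable, time variable and per-variable metadata,
and maps raw time values onto consecutive integer period indices so that all
longitudinal checks share a single ordered, discrete time axis.

Duplicate (id, time) rows are deliberately *permitted* at load time: the
toolkit treats them as a quality defect to detect, never a reason to reject
the file.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, SchemaError

logger = logging.getLogger(__name__)

ROLES = frozenset(
    {"identifier", "time", "numeric", "categorical", "geography", "domain"}
)
TRAJECTORY_CLASSES = frozenset({"free", "stable", "monotone_nondecreasing"})
GRANULARITIES = frozenset({"month", "quarter", "year", "integer"})

#: Internal missing marker.  All declared missing codes are replaced by NaN
#: at load so every downstream check shares one missingness definition.
MISSING = np.nan


@dataclass
class VariableSchema:
    """Declared metadata for one column of the panel.

    Parameters
    ----------
    name : str
        Column name in the flat file.
    role : str
        One of ``identifier``, ``time``, ``numeric``, ``categorical``,
        ``geography``, ``domain``.
    levels : sequence, optional
        Allowed category list for categorical/domain/geography variables.
    vmin, vmax : float, optional
        Allowed numeric range endpoints (inclusive); ``None`` = unbounded.
    missing_codes : sequence
        Raw values (compared as strings on load) to convert to the internal
        missing marker.
    trajectory : str
        Expected within-unit trajectory: ``free`` (default), ``stable``
        (demographics that should never change), or
        ``monotone_nondecreasing`` (cumulative counters such as months of
        benefit receipt).
    """

    name: str
    role: str = "categorical"
    levels: Sequence | None = None
    vmin: float | None = None
    vmax: float | None = None
    missing_codes: Sequence = ()
    trajectory: str = "free"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(
                f"variable {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {sorted(ROLES)}"
            )
        if self.trajectory not in TRAJECTORY_CLASSES:
            raise SchemaError(
                f"variable {self.name!r}: unknown trajectory class "
                f"{self.trajectory!r}; expected one of {sorted(TRAJECTORY_CLASSES)}"
            )
        if self.trajectory != "free" and self.role in ("identifier", "time"):
            raise SchemaError(
                f"variable {self.name!r}: trajectory class {self.trajectory!r} "
                "cannot be declared on identifier/time variables"
            )


# ---------------------------------------------------------------------------
# Time parsing


_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})(?:-(\d{2}))?$")
_QUARTER_RE = re.compile(r"^(\d{4})-?Q([1-4])$", re.IGNORECASE)
_YEAR_RE = re.compile(r"^(\d{4})$")
_INT_RE = re.compile(r"^-?\d+$")


def _time_code(raw: str, granularity: str) -> int | None:
    """Absolute integer code for one raw time value, or None if unparseable."""
    s = str(raw).strip()
    if granularity == "month":
        m = _MONTH_RE.match(s)
        if not m:
            return None
        year, month = int(m.group(1)), int(m.group(2))
        if not 1 <= month <= 12:
            return None
        return year * 12 + (month - 1)
    if granularity == "quarter":
        m = _QUARTER_RE.match(s)
        if not m:
            return None
        return int(m.group(1)) * 4 + (int(m.group(2)) - 1)
    if granularity == "year":
        m = _YEAR_RE.match(s)
        return int(m.group(1)) if m else None
    if granularity == "integer":
        return int(s) if _INT_RE.match(s) else None
    raise SchemaError(f"unknown time granularity {granularity!r}")


def _time_label(code: int, granularity: str) -> str:
    if granularity == "month":
        return f"{code // 12:04d}-{code % 12 + 1:02d}"
    if granularity == "quarter":
        return f"{code // 4:04d}-Q{code % 4 + 1}"
    return str(code)


def parse_time_values(
    values: Iterable, granularity: str = "month"
) -> tuple[pd.Series, dict, list]:
    """Map raw time values to consecutive period indices.

    Returns ``(periods, period_index, period_labels)`` where *periods* is an
    integer Series (``<NA>`` where the raw value is missing), *period_index*
    maps each observed raw value to its index, and *period_labels* gives one
    canonical label per index over the full consecutive range from the
    earliest to the latest observed period (calendar periods with no records
    still get an index, so gaps are visible).
    """
    ser = pd.Series(list(values), dtype="object")
    missing = ser.isna() | (ser.astype(str).str.strip() == "")
    codes = pd.array([None] * len(ser), dtype="Int64")
    bad: list = []
    cache: dict = {}
    raw_to_code: dict = {}
    for raw in ser[~missing].unique():
        code = cache.get(raw)
        if code is None and raw not in cache:
            code = _time_code(raw, granularity)
            cache[raw] = code
        if code is None:
            bad.append(raw)
        else:
            raw_to_code[raw] = code
    if bad:
        shown = ", ".join(repr(v) for v in bad[:10])
        more = "" if len(bad) <= 10 else f" (and {len(bad) - 10} more)"
        raise DataFormatError(
            f"unparseable time values for granularity {granularity!r}: {shown}{more}"
        )
    if raw_to_code:
        lo = min(raw_to_code.values())
        hi = max(raw_to_code.values())
        period_labels = [_time_label(c, granularity) for c in range(lo, hi + 1)]
        period_index = {raw: code - lo for raw, code in raw_to_code.items()}
        mapped = ser.map(period_index)
        codes = pd.array(mapped, dtype="Int64")
    else:
        period_labels, period_index = [], {}
    return pd.Series(codes, index=ser.index, name="period"), period_index, period_labels


# ---------------------------------------------------------------------------
# The dataset


@dataclass
class PanelDataset:
    """A long-format unit x period table with declared roles.

    ``records`` keeps the original column order; ``periods`` is an aligned
    integer Series giving each row's period index (consecutive integers over
    the observed calendar range).
    """

    records: pd.DataFrame
    id_var: str
    time_var: str
    schema: list[VariableSchema]
    period_index: dict
    period_labels: list
    periods: pd.Series
    granularity: str = "month"

    def __post_init__(self) -> None:
        for col in (self.id_var, self.time_var):
            if col not in self.records.columns:
                raise SchemaError(f"declared variable {col!r} not found in data columns")
        by_name = {s.name for s in self.schema}
        n_id = sum(1 for s in self.schema if s.role == "identifier")
        n_time = sum(1 for s in self.schema if s.role == "time")
        if n_id != 1 or n_time != 1:
            raise SchemaError(
                f"schema must declare exactly one identifier and one time variable "
                f"(got {n_id} identifier, {n_time} time)"
            )
        missing_cols = by_name - set(self.records.columns)
        if missing_cols:
            raise SchemaError(f"schema declares unknown columns: {sorted(missing_cols)}")

    # -- convenience -------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_periods(self) -> int:
        return len(self.period_labels)

    def unit_ids(self) -> pd.Series:
        return self.records[self.id_var]

    @property
    def n_units(self) -> int:
        return int(self.records[self.id_var].nunique(dropna=True))

    def schema_for(self, name: str) -> VariableSchema | None:
        for s in self.schema:
            if s.name == name:
                return s
        return None

    def variables(self, role: str | None = None) -> list[str]:
        if role is None:
            return [s.name for s in self.schema]
        return [s.name for s in self.schema if s.role == role]

    def require_column(self, name: str, context: str = "") -> None:
        if name not in self.records.columns:
            where = f" ({context})" if context else ""
            raise SchemaError(f"variable {name!r} not found in panel{where}")

    def period_of(self, raw) -> int:
        """Period index for one raw time value (must be observed)."""
        if raw in self.period_index:
            return self.period_index[raw]
        code = _time_code(str(raw), self.granularity)
        if code is None:
            raise DataFormatError(f"unparseable time value {raw!r}")
        lo = min(self.period_index.values()) if self.period_index else 0
        # reconstruct offset from any known mapping
        if self.period_index:
            any_raw, any_idx = next(iter(self.period_index.items()))
            base = _time_code(str(any_raw), self.granularity) - any_idx
            return code - base
        return code - lo

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        id_var: str,
        time_var: str,
        schema: Sequence[VariableSchema] | None = None,
        granularity: str = "month",
    ) -> "PanelDataset":
        """Wrap an in-memory DataFrame (already typed) as a panel."""
        for col in (id_var, time_var):
            if col not in df.columns:
                raise SchemaError(f"declared variable {col!r} not found in data columns")
        schema = _complete_schema(df, id_var, time_var, schema)
        df = df.copy()
        _apply_missing_codes(df, schema, raw_strings=False)
        periods, pindex, plabels = parse_time_values(df[time_var], granularity)
        return cls(
            records=df,
            id_var=id_var,
            time_var=time_var,
            schema=list(schema),
            period_index=pindex,
            period_labels=plabels,
            periods=periods,
            granularity=granularity,
        )


def _complete_schema(
    df: pd.DataFrame,
    id_var: str,
    time_var: str,
    schema: Sequence[VariableSchema] | None,
) -> list[VariableSchema]:
    declared = {s.name: s for s in (schema or [])}
    out: list[VariableSchema] = []
    for col in df.columns:
        if col in declared:
            out.append(declared[col])
        elif col == id_var:
            out.append(VariableSchema(col, role="identifier"))
        elif col == time_var:
            out.append(VariableSchema(col, role="time"))
        elif pd.api.types.is_numeric_dtype(df[col]):
            out.append(VariableSchema(col, role="numeric"))
        else:
            out.append(VariableSchema(col, role="categorical"))
    id_schema = next((s for s in out if s.name == id_var), None)
    time_schema = next((s for s in out if s.name == time_var), None)
    if id_schema is not None and id_schema.role != "identifier":
        raise SchemaError(f"id_var {id_var!r} must have role 'identifier', got {id_schema.role!r}")
    if time_schema is not None and time_schema.role != "time":
        raise SchemaError(f"time_var {time_var!r} must have role 'time', got {time_schema.role!r}")
    return out


def _apply_missing_codes(
    df: pd.DataFrame, schema: Sequence[VariableSchema], raw_strings: bool
) -> None:
    """Replace declared missing codes with the internal marker, in place."""
    for s in schema:
        if not s.missing_codes or s.name not in df.columns:
            continue
        col = df[s.name]
        if raw_strings:
            codes = {str(c) for c in s.missing_codes}
            mask = col.astype(str).isin(codes)
        else:
            mask = col.isin(list(s.missing_codes))
            str_codes = {str(c) for c in s.missing_codes}
            mask = mask | col.astype(str).isin(str_codes)
        if mask.any():
            df[s.name] = col.mask(mask, MISSING)


def _scan_ragged_rows(text: io.TextIOBase, delimiter: str) -> list[int]:
    """Return 1-based line numbers whose field count differs from the header."""
    reader = csv.reader(text, delimiter=delimiter)
    bad: list[int] = []
    try:
        header = next(reader)
    except StopIteration:
        return bad
    width = len(header)
    for lineno, row in enumerate(reader, start=2):
        if row and len(row) != width:
            bad.append(lineno)
            if len(bad) >= 20:
                break
    return bad


def load_panel(source, config) -> PanelDataset:
    """Read a delimited flat file into a :class:`PanelDataset`.

    ``config`` is an :class:`~adminqc.config.AssessmentConfig`, a mapping with
    the same keys, or a path to a YAML/JSON config file.  Declared missing
    codes are replaced by the internal missing marker; numeric-role columns
    are coerced to floats (unparseable cells become missing, with a logged
    warning); time values are parsed to consecutive period indices.
    """
    from .config import AssessmentConfig, load_config

    if not isinstance(config, AssessmentConfig):
        config = load_config(config)
    path = Path(source)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        bad_rows = _scan_ragged_rows(fh, config.delimiter)
    if bad_rows:
        raise DataFormatError(
            f"{path.name}: ragged rows (field count differs from header) at "
            f"line(s) {bad_rows}"
        )
    df = pd.read_csv(
        path,
        sep=config.delimiter,
        dtype=str,
        keep_default_na=False,
        na_values=[""],
    )
    for col in (config.id_var, config.time_var):
        if col not in df.columns:
            raise SchemaError(
                f"declared variable {col!r} not found in data columns "
                f"{list(df.columns)}"
            )
    schema = _complete_schema(df, config.id_var, config.time_var, config.variables)
    _apply_missing_codes(df, schema, raw_strings=True)
    for s in schema:
        if s.role == "numeric":
            coerced = pd.to_numeric(df[s.name], errors="coerce")
            n_new = int((coerced.isna() & df[s.name].notna()).sum())
            if n_new:
                logger.warning(
                    "variable %r: %d non-numeric value(s) treated as missing",
                    s.name,
                    n_new,
                )
            df[s.name] = coerced
    periods, pindex, plabels = parse_time_values(df[config.time_var], config.granularity)
    return PanelDataset(
        records=df,
        id_var=config.id_var,
        time_var=config.time_var,
        schema=schema,
        period_index=pindex,
        period_labels=plabels,
        periods=periods,
        granularity=config.granularity,
    )


def write_panel(panel: PanelDataset, path, delimiter: str = ",") -> None:
    """Write the panel back to a flat file (missing cells as empty fields).

    ``load_panel`` on the written file reproduces records, missing markers
    and period indices (floats are written in shortest-round-trip form).
    """
    panel.records.to_csv(path, sep=delimiter, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Structure report


@dataclass
class StructureReport:
    """Conformance summary for the long-format contract."""

    n_records: int
    n_units: int
    period_range: tuple | None
    per_unit_periods: pd.Series = field(repr=False)
    n_duplicate_pairs: int = 0
    n_excess_duplicate_rows: int = 0
    n_gap_periods: int = 0
    n_units_with_gaps: int = 0

    def to_frame(self) -> pd.DataFrame:
        rng = "-" if self.period_range is None else f"{self.period_range[0]}..{self.period_range[1]}"
        rows = [
            ("records", self.n_records),
            ("units", self.n_units),
            ("period range", rng),
            ("duplicate (id,time) pairs", self.n_duplicate_pairs),
            ("excess duplicate rows", self.n_excess_duplicate_rows),
            ("within-unit gap periods", self.n_gap_periods),
            ("units with gaps", self.n_units_with_gaps),
        ]
        return pd.DataFrame(rows, columns=["measure", "value"])


def check_panel_structure(panel: PanelDataset) -> StructureReport:
    """Summarize conformance: per-unit coverage, duplicates, period gaps.

    A *gap* is a period strictly between a unit's first and last observed
    period for which the unit has no row.  Duplicate (id, time) pairs are
    counted, never removed.
    """
    df = pd.DataFrame({"id": panel.records[panel.id_var], "period": panel.periods})
    obs = df.dropna(subset=["id", "period"])
    if obs.empty:
        return StructureReport(
            n_records=panel.n_records,
            n_units=panel.n_units,
            period_range=None,
            per_unit_periods=pd.Series(dtype="int64"),
        )
    grp = obs.groupby("id", sort=False)["period"]
    nuniq = grp.nunique()
    span = grp.max() - grp.min() + 1
    gaps = (span - nuniq).astype("int64")
    pair_sizes = obs.groupby(["id", "period"], sort=False).size()
    dup_pairs = int((pair_sizes > 1).sum())
    excess = int((pair_sizes - 1).clip(lower=0).sum())
    lo = int(obs["period"].min())
    hi = int(obs["period"].max())
    labels = panel.period_labels
    rng = (labels[lo], labels[hi]) if labels else (lo, hi)
    return StructureReport(
        n_records=panel.n_records,
        n_units=panel.n_units,
        period_range=rng,
        per_unit_periods=nuniq.astype("int64"),
        n_duplicate_pairs=dup_pairs,
        n_excess_duplicate_rows=excess,
        n_gap_periods=int(gaps.sum()),
        n_units_with_gaps=int((gaps > 0).sum()),
    )
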