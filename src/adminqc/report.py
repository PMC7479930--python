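"""Assessment orchestration and report rendering.

``run_pipeline`` executes any subset of the configured checks over one
panel — checks are independent, so running a subset gives results identical
to running everything and discarding the rest — and collects them into a
:class:`QualityReport`.  ``render_report`` writes a self-contained
Markdown or HTML document plus per-check CSV tables, figures and a stable
machine-readable ``summary.json``.

Quality findings are informational: they flag records and variables for
the analyst's judgment and never make the run fail.  Each rendered section
carries guidance text on how to read its output, and the report opens with
the relevance checklist — the qualitative questions (units, population,
variables, timing, domains) an analyst should answer from metadata and
program history before trusting any quantitative check.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy, completeness, comparability, longitudinal
from .config import AssessmentConfig, load_config
from .errors import AdminQCError, ConfigurationError
from .panel import PanelDataset, check_panel_structure, load_panel

logger = logging.getLogger(__name__)

TOOLKIT_VERSION = "0.1.0"

DIMENSIONS = {
    "structure": "accuracy",
    "id_syntax": "accuracy",
    "rules": "accuracy",
    "numeric_profile": "accuracy",
    "categorical_profile": "accuracy",
    "outliers": "accuracy",
    "coverage": "completeness",
    "duplicates": "completeness",
    "missingness": "completeness",
    "missingness_by_domain": "completeness",
    "distributions": "comparability",
    "tableplot": "comparability",
    "tableplot_time": "comparability",
    "timeseries": "comparability",
    "spells": "longitudinal",
    "trajectory": "longitudinal",
}

GUIDANCE = {
    "structure": (
        "Confirm the file matches the expected long format: one row per unit "
        "per period. Duplicate (id, time) pairs and within-unit gaps are not "
        "errors by themselves, but both feed later checks and can distort "
        "longitudinal statistics."
    ),
    "id_syntax": (
        "Keys with missing or malformed syntax cannot be trusted to identify "
        "units over time. Investigate whether incorrect keys cluster in "
        "particular periods or offices, which suggests an entry-system change."
    ),
    "rules": (
        "Failed invalid-severity rules contradict the codebook or hard logic "
        "and usually indicate entry or processing errors. Dubious-severity "
        "flags are values that are possible but implausible; review them "
        "before deciding whether a sensitivity analysis is needed."
    ),
    "numeric_profile": (
        "Compare the quantiles and extremes against the codebook ranges and "
        "program rules. Watch the missing counts: variables unimportant to "
        "program administration are often poorly filled."
    ),
    "categorical_profile": (
        "Check that observed levels match documentation and that no level "
        "unexpectedly dominates or disappears. Declared levels with zero "
        "frequency may indicate retired codes or an extraction filter."
    ),
    "outliers": (
        "Fences and letter values offer two severities of outlier screening. "
        "Points beyond the outermost letter values of a large file deserve "
        "individual review; whether to exclude them is an analytic judgment, "
        "not a mechanical rule."
    ),
    "coverage": (
        "Areas with zero or unusually low record counts in some periods "
        "suggest undercoverage or missing extracts. The low-count screen "
        "compares each area only with its own history (heuristic; no "
        "external population benchmark is used)."
    ),
    "duplicates": (
        "Duplicate keys threaten overcoverage and double-counting. Repeats "
        "of a full analysis-variable tuple under different ids can reveal "
        "clerical double entry."
    ),
    "missingness": (
        "Item nonresponse limits complete-case analysis: the unit-level "
        "any-missing share approximates the records a listwise deletion "
        "would discard. Consider imputation if key variables are affected."
    ),
    "missingness_by_domain": (
        "If nonresponse differs across domains, complete-case estimates of "
        "domain comparisons are biased. Large differences warrant imputation "
        "or weighting before subgroup analysis."
    ),
    "distributions": (
        "Judge each distribution against program expectations, e.g. recipient "
        "income concentrated at zero. Isolated spikes, gaps just above zero, "
        "or impossible masses usually reflect coding conventions or errors."
    ),
    "tableplot": (
        "Read each column against the sort variable: the black line is the "
        "bin mean, the band one standard deviation, colours are category "
        "shares. Sharp jumps or kinks in a relationship that theory says is "
        "smooth (e.g. benefit proportional to recipients) flag comparability "
        "risks."
    ),
    "tableplot_time": (
        "With time as the sort variable each bin is a time slice; level "
        "shifts, variance changes or category-mix changes across bins point "
        "to collection or policy changes. Consult program history before "
        "interpreting them as real."
    ),
    "timeseries": (
        "Flagged periods have means far from the series' typical level "
        "(robust z-score above the threshold). Seasonality, eligibility "
        "changes and processing backlogs are common explanations."
    ),
    "spells": (
        "Spell counts, durations and churn summarize program dynamics. "
        "Implausibly many one-period spells or abrupt churn changes often "
        "reflect reporting gaps rather than true exits and re-entries."
    ),
    "trajectory": (
        "Units whose stable characteristics change, or whose cumulative "
        "counters decrease, indicate key breaks or entry errors; both "
        "undermine longitudinal analysis of those units."
    ),
}


@dataclass
class CheckSection:
    name: str
    dimension: str
    findings: int
    summary: dict
    tables: dict = field(default_factory=dict)
    result: dict = field(default_factory=dict)
    guidance: str = ""


@dataclass
class QualityReport:
    metadata: dict
    sections: list[CheckSection]
    relevance: dict = field(default_factory=dict)

    def section(self, name: str) -> CheckSection:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def total_findings(self) -> int:
        return sum(s.findings for s in self.sections)

    def summary_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "total_findings": int(self.total_findings),
            "sections": {
                s.name: {
                    "dimension": s.dimension,
                    "findings": int(s.findings),
                    "summary": s.summary,
                }
                for s in self.sections
            },
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# Check runners


def _first_var(panel: PanelDataset, role: str) -> str | None:
    names = panel.variables(role)
    return names[0] if names else None


def _run_structure(panel, config, params):
    rep = check_panel_structure(panel)
    # gaps are normal program dynamics (exits/re-entries); only duplicate
    # (id, time) pairs count as findings here
    findings = rep.n_duplicate_pairs
    return CheckSection(
        name="structure",
        dimension="accuracy",
        findings=findings,
        summary=_jsonable(
            {
                "n_records": rep.n_records,
                "n_units": rep.n_units,
                "duplicate_pairs": rep.n_duplicate_pairs,
                "gap_periods": rep.n_gap_periods,
            }
        ),
        tables={"structure": rep.to_frame()},
        result={"structure": rep},
    )


def _run_id_syntax(panel, config, params):
    rep = accuracy.validate_id_syntax(
        panel,
        pattern=params.get("pattern", "ssn9"),
        per_record=bool(params.get("per_record", False)),
    )
    return CheckSection(
        name="id_syntax",
        dimension="accuracy",
        findings=rep.n_findings,
        summary=_jsonable({"counts": rep.counts, "proportions": rep.proportions}),
        tables={"id_syntax": rep.to_frame()},
        result={"id_syntax": rep},
    )


def _run_rules(panel, config, params):
    rules = config.rules
    if not rules:
        raise ConfigurationError("rules check selected but config declares no rules")
    res = accuracy.evaluate_rules(
        panel,
        rules,
        group_var=params.get("group_var"),
        intervals=params.get("intervals"),
    )
    tables = {"per_rule": res.per_rule}
    if res.by_group is not None:
        tables["by_group"] = res.by_group
    if res.by_interval is not None:
        tables["by_interval"] = res.by_interval
    return CheckSection(
        name="rules",
        dimension="accuracy",
        findings=res.n_findings,
        summary=_jsonable(
            {
                "n_rules": len(rules),
                "total_failures": res.n_findings,
                "unit_any_failure": res.unit_any_failure,
            }
        ),
        tables=tables,
        result={"rules": res},
    )


def _run_numeric_profile(panel, config, params):
    table = accuracy.numeric_profile(panel, params.get("variables"))
    return CheckSection(
        name="numeric_profile",
        dimension="accuracy",
        findings=0,
        summary=_jsonable({"variables": table["variable"].tolist()}),
        tables={"numeric_profile": table},
        result={"profile": table},
    )


def _run_categorical_profile(panel, config, params):
    tables = accuracy.categorical_profile(panel, params.get("variables"))
    return CheckSection(
        name="categorical_profile",
        dimension="accuracy",
        findings=0,
        summary=_jsonable({"variables": list(tables)}),
        tables={f"freq_{var}": tbl for var, tbl in tables.items()},
        result={"profiles": tables},
    )


def _run_outliers(panel, config, params):
    variables = params.get("variables") or panel.variables("numeric")
    multiplier = float(params.get("multiplier", 1.5))
    fences, letters, rows = {}, {}, []
    for var in variables:
        vals = panel.records[var]
        try:
            fr = accuracy.tukey_fences(vals, multiplier=multiplier)
            lv = accuracy.letter_values(vals)
        except AdminQCError as exc:
            logger.warning("outliers: skipping %r (%s)", var, exc)
            continue
        fences[var], letters[var] = fr, lv
        rows.append(
            {
                "variable": var,
                "lower_fence": fr.lower_fence,
                "upper_fence": fr.upper_fence,
                "fence_outliers": fr.n_outliers,
                "letter_value_levels": lv.k,
                "letter_value_outliers": len(lv.outliers),
            }
        )
    table = pd.DataFrame(rows)
    findings = int(table["fence_outliers"].sum()) if len(table) else 0
    return CheckSection(
        name="outliers",
        dimension="accuracy",
        findings=findings,
        summary=_jsonable(
            {r["variable"]: {"fence_outliers": r["fence_outliers"]} for r in rows}
        ),
        tables={"outliers": table},
        result={"fences": fences, "letters": letters},
    )


def _run_coverage(panel, config, params):
    geo_var = params.get("geo_var") or _first_var(panel, "geography")
    if geo_var is None:
        raise ConfigurationError("coverage check needs a geography-role variable")
    rep = completeness.coverage_by_area(
        panel, geo_var, low_fraction=float(params.get("low_fraction", 0.5))
    )
    return CheckSection(
        name="coverage",
        dimension="completeness",
        findings=rep.n_findings,
        summary=_jsonable(
            {
                "geo_var": geo_var,
                "areas": int(rep.counts.shape[0]),
                "flagged_cells": rep.n_findings,
            }
        ),
        tables={"coverage_counts": rep.counts.reset_index(), "flagged": rep.flagged_cells()},
        result={"coverage": rep},
    )


def _run_duplicates(panel, config, params):
    rep = completeness.detect_duplicates(
        panel,
        keys=params.get("keys"),
        per_period=bool(params.get("per_period", False)),
        missing_match=params.get("missing_match", "match"),
    )
    tables = {"duplicates": rep.to_frame(), "sample_groups": rep.sample_groups}
    if rep.per_period is not None:
        tables["per_period"] = rep.per_period
    return CheckSection(
        name="duplicates",
        dimension="completeness",
        findings=rep.n_findings,
        summary=_jsonable(
            {
                "keys": rep.keys,
                "duplicated_keys": rep.n_duplicated_keys,
                "excess_records": rep.excess_records,
            }
        ),
        tables=tables,
        result={"duplicates": rep},
    )


def _run_missingness(panel, config, params):
    rep = completeness.missingness_by_variable(panel, params.get("key_vars"))
    return CheckSection(
        name="missingness",
        dimension="completeness",
        findings=rep.n_findings,
        summary=_jsonable(
            {
                "unit_any_missing": rep.unit_any_missing_count,
                "unit_any_missing_proportion": rep.unit_any_missing_proportion,
            }
        ),
        tables={"per_variable": rep.per_variable, "patterns": rep.pattern_table},
        result={"missingness": rep},
    )


def _run_missingness_by_domain(panel, config, params):
    domain_var = params.get("domain_var") or _first_var(panel, "domain")
    if domain_var is None:
        raise ConfigurationError("missingness_by_domain needs a domain-role variable")
    var = params.get("var")
    if var is None:
        numerics = panel.variables("numeric")
        if not numerics:
            raise ConfigurationError("missingness_by_domain needs a target variable")
        counts = {v: int(panel.records[v].isna().sum()) for v in numerics}
        var = max(counts, key=counts.get)
    tbl = completeness.missingness_by_domain(panel, var, domain_var)
    spread = float(tbl["proportion"].max() - tbl["proportion"].min()) if len(tbl) else 0.0
    return CheckSection(
        name="missingness_by_domain",
        dimension="completeness",
        findings=int(tbl["missing"].sum()) if len(tbl) else 0,
        summary=_jsonable({"var": var, "domain_var": domain_var, "spread": spread}),
        tables={"by_domain": tbl},
        result={"by_domain": tbl, "var": var},
    )


def _run_distributions(panel, config, params):
    variables = params.get("variables") or panel.variables("numeric")
    tables, hists = {}, {}
    for var in variables:
        qt, hist = comparability.distribution_summary(panel, var)
        tables[f"quantiles_{var}"] = qt
        tables[f"hist_{var}"] = hist.to_frame()
        hists[var] = hist
    return CheckSection(
        name="distributions",
        dimension="comparability",
        findings=0,
        summary=_jsonable({"variables": list(hists)}),
        tables=tables,
        result={"histograms": hists},
    )


def _tableplot_columns(panel, params):
    cols = params.get("columns")
    if cols:
        return list(cols)
    return [
        s.name
        for s in panel.schema
        if s.role in ("numeric", "categorical", "domain")
    ][:6]


def _run_tableplot(panel, config, params):
    sort_var = params.get("sort_var") or _first_var(panel, "numeric")
    if sort_var is None:
        raise ConfigurationError("tableplot needs a numeric sort variable")
    summary = comparability.tableplot(
        panel,
        sort_var,
        _tableplot_columns(panel, params),
        n_bins=int(params.get("n_bins", 100)),
        descending=bool(params.get("descending", True)),
    )
    return CheckSection(
        name="tableplot",
        dimension="comparability",
        findings=0,
        summary=_jsonable(summary.to_dict()),
        tables={"tableplot": summary.to_frame()},
        result={"tableplot": summary},
    )


def _run_tableplot_time(panel, config, params):
    summary = comparability.tableplot_over_time(
        panel,
        _tableplot_columns(panel, params),
        n_bins=params.get("n_bins"),
    )
    return CheckSection(
        name="tableplot_time",
        dimension="comparability",
        findings=0,
        summary=_jsonable(summary.to_dict()),
        tables={"tableplot_time": summary.to_frame()},
        result={"tableplot": summary},
    )


def _run_timeseries(panel, config, params):
    var = params.get("var") or _first_var(panel, "numeric")
    if var is None:
        raise ConfigurationError("timeseries check needs a numeric variable")
    rep = comparability.timeseries_summary(
        panel,
        var,
        group_var=params.get("group_var"),
        threshold=float(params.get("threshold", 3.5)),
    )
    return CheckSection(
        name="timeseries",
        dimension="comparability",
        findings=rep.n_findings,
        summary=_jsonable(
            {
                "var": var,
                "flagged_periods": rep.flagged["period_label"].tolist(),
            }
        ),
        tables={"by_period": rep.table},
        result={"timeseries": rep},
    )


def _run_spells(panel, config, params):
    spells = longitudinal.extract_spells(panel, receipt=params.get("receipt", "presence"))
    stats = longitudinal.spell_statistics(spells, panel=panel, by=params.get("by"))
    churn = longitudinal.churn_events(spells, window=int(params.get("window", 4)))
    tables = {
        "spells_per_unit": stats.spells_per_unit,
        "durations": stats.durations,
        "churn": churn.to_frame(),
    }
    if stats.by_group is not None:
        tables["durations_by_group"] = stats.by_group
    return CheckSection(
        name="spells",
        dimension="longitudinal",
        findings=0,
        summary=_jsonable(
            {
                "n_spells": spells.n_spells,
                "churn_events": churn.n_events,
                "churn_rate_per_completed_spell": churn.rate_per_completed_spell,
            }
        ),
        tables=tables,
        result={"spells": spells, "stats": stats, "churn": churn},
    )


def _run_trajectory(panel, config, params):
    rep = longitudinal.trajectory_checks(panel)
    return CheckSection(
        name="trajectory",
        dimension="longitudinal",
        findings=rep.n_findings,
        summary=_jsonable(
            {
                "stable": {v: info["count"] for v, info in rep.stable.items()},
                "monotone": {v: info["count"] for v, info in rep.monotone.items()},
            }
        ),
        tables={"trajectory": rep.to_frame()},
        result={"trajectory": rep},
    )


_RUNNERS = {
    "structure": _run_structure,
    "id_syntax": _run_id_syntax,
    "rules": _run_rules,
    "numeric_profile": _run_numeric_profile,
    "categorical_profile": _run_categorical_profile,
    "outliers": _run_outliers,
    "coverage": _run_coverage,
    "duplicates": _run_duplicates,
    "missingness": _run_missingness,
    "missingness_by_domain": _run_missingness_by_domain,
    "distributions": _run_distributions,
    "tableplot": _run_tableplot,
    "tableplot_time": _run_tableplot_time,
    "timeseries": _run_timeseries,
    "spells": _run_spells,
    "trajectory": _run_trajectory,
}


def available_checks() -> list[str]:
    return list(_RUNNERS)


def _resolve_checks(config: AssessmentConfig, checks) -> list[str]:
    if checks:
        resolved: list[str] = []
        for item in checks:
            if item in _RUNNERS:
                resolved.append(item)
            elif item in ("accuracy", "completeness", "comparability", "longitudinal"):
                resolved.extend(
                    name for name, dim in DIMENSIONS.items() if dim == item
                )
            else:
                raise ConfigurationError(
                    f"unknown check or dimension {item!r}; "
                    f"available: {sorted(_RUNNERS)}"
                )
        seen, out = set(), []
        for name in resolved:
            if name not in seen:
                seen.add(name)
                out.append(name)
        return out
    if config.checks:
        return _resolve_checks(config, list(config.checks))
    return list(_RUNNERS)


def run_pipeline(
    source,
    config,
    checks=None,
    seed: int | None = None,
) -> QualityReport:
    """Run the selected checks over one flat file or panel.

    ``checks`` may list check names and/or dimension names
    (``accuracy``, ``completeness``, ``comparability``, ``longitudinal``);
    by default the checks named in the config (or all feasible checks) run.
    Checks whose preconditions the schema cannot satisfy (e.g. coverage
    without a geography variable) are skipped with a warning unless they
    were requested explicitly.
    """
    if not isinstance(config, AssessmentConfig):
        config = load_config(config)
    explicit = checks is not None or bool(config.checks)
    names = _resolve_checks(config, checks)
    if isinstance(source, PanelDataset):
        panel = source
        input_path = "(in-memory panel)"
    else:
        panel = load_panel(source, config)
        input_path = str(source)
    sections: list[CheckSection] = []
    for name in names:
        params = dict(config.checks.get(name) or {})
        try:
            section = _RUNNERS[name](panel, config, params)
        except ConfigurationError:
            if explicit and checks and name in checks:
                raise
            logger.warning("skipping check %r: preconditions not met", name)
            continue
        section.guidance = GUIDANCE.get(name, "")
        sections.append(section)
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    metadata = {
        "input": input_path,
        "config_hash": cfg_hash,
        "seed": seed,
        "toolkit_version": TOOLKIT_VERSION,
        "n_records": int(panel.n_records),
        "n_units": int(panel.n_units),
        "checks": [s.name for s in sections],
    }
    return QualityReport(metadata=metadata, sections=sections, relevance=dict(config.relevance))


# ---------------------------------------------------------------------------
# Rendering


RELEVANCE_QUESTIONS = [
    ("units", "Do the units of analysis match the research question?"),
    ("population", "Does the reference population match the target population?"),
    ("variables", "Are the variables needed for the analysis present and documented?"),
    ("timing", "Do the time coverage and periodicity support the analysis?"),
    ("domains", "Are the subgroups (domains) of interest identifiable?"),
    ("program_history", "Have program history and policy changes been reviewed?"),
]


def _pipe_table(df: pd.DataFrame, max_rows: int = 30) -> str:
    df = df.head(max_rows)
    def fmt(v):
        if isinstance(v, float):
            if np.isnan(v):
                return ""
            return f"{v:.4g}"
        return str(v)
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def _render_figures(report: QualityReport, figdir: Path) -> dict[str, list[str]]:
    """Create per-section figures; returns section -> list of relative paths."""
    import matplotlib.pyplot as plt

    from . import plots

    figdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, list[str]] = {}

    def save(section: str, stem: str, fig) -> None:
        path = figdir / f"{section}_{stem}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        out.setdefault(section, []).append(f"figures/{path.name}")

    for section in report.sections:
        try:
            if section.name == "outliers":
                letters = section.result.get("letters", {})
                for var, lv in list(letters.items())[:3]:
                    ax = plots.letter_value_plot(lv, label=var)
                    save(section.name, f"letters_{var}", ax.figure)
            elif section.name == "missingness_by_domain":
                tbl = section.result["by_domain"]
                ax = plots.missingness_bar_plot(tbl, section.result["var"])
                save(section.name, "by_domain", ax.figure)
            elif section.name == "distributions":
                for var, hist in list(section.result["histograms"].items())[:3]:
                    ax = plots.histogram_plot(hist)
                    save(section.name, f"hist_{var}", ax.figure)
            elif section.name in ("tableplot", "tableplot_time"):
                fig = plots.tableplot_figure(section.result["tableplot"])
                save(section.name, "tableplot", fig)
            elif section.name == "timeseries":
                ax = plots.timeseries_plot(section.result["timeseries"])
                save(section.name, "means", ax.figure)
            elif section.name == "spells":
                durations = section.result["spells"].spells["duration"]
                if len(durations):
                    ax = plots.duration_histogram(durations)
                    save(section.name, "durations", ax.figure)
        except Exception:  # a failed figure never voids the report
            logger.exception("figure rendering failed for section %r", section.name)
    return out


def render_report(
    report: QualityReport,
    out_dir,
    format: str = "markdown",
    figures: bool = True,
) -> dict:
    """Write the report document, per-check CSVs, figures and summary.json."""
    if format not in ("markdown", "html"):
        raise ConfigurationError("format must be 'markdown' or 'html'")
    out = Path(out_dir)
    tables_dir = out / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    fig_paths = _render_figures(report, out / "figures") if figures else {}

    for section in report.sections:
        for tname, tbl in section.tables.items():
            tbl.to_csv(tables_dir / f"{section.name}_{tname}.csv", index=False)

    summary = report.summary_dict()
    summary["metadata"] = dict(summary["metadata"])
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))

    meta = dict(report.metadata)
    meta["generated_at"] = datetime.now(timezone.utc).isoformat(timespec="seconds")

    if format == "markdown":
        doc = _markdown_doc(report, meta, fig_paths)
        doc_path = out / "report.md"
    else:
        doc = _html_doc(report, meta, fig_paths)
        doc_path = out / "report.html"
    doc_path.write_text(doc)
    return {"report": doc_path, "summary": summary_path, "tables": tables_dir}


def _relevance_block(report: QualityReport) -> list[tuple[str, str, str]]:
    return [
        (key, question, str(report.relevance.get(key, "(not answered)")))
        for key, question in RELEVANCE_QUESTIONS
    ]


def _markdown_doc(report, meta, fig_paths) -> str:
    lines = ["# Data quality assessment", ""]
    for k, v in meta.items():
        lines.append(f"- **{k}**: {v}")
    lines += ["", "## Relevance checklist", ""]
    lines.append(
        "Quantitative checks cannot establish that a dataset fits a research "
        "question; review these against the metadata and program history:"
    )
    lines.append("")
    for key, question, answer in _relevance_block(report):
        lines.append(f"- **{question}** {answer}")
    for section in report.sections:
        lines += ["", f"## {section.name} ({section.dimension})", ""]
        lines.append(f"Findings: **{section.findings}**")
        if section.guidance:
            lines += ["", f"> {section.guidance}"]
        for tname, tbl in section.tables.items():
            if not len(tbl):
                continue
            lines += ["", f"### {tname}", "", _pipe_table(tbl)]
            if len(tbl) > 30:
                lines.append(f"\n*(first 30 of {len(tbl)} rows; full table in tables/)*")
        for rel in fig_paths.get(section.name, []):
            lines += ["", f"![{section.name}]({rel})"]
    lines.append("")
    return "\n".join(lines)


def _html_doc(report, meta, fig_paths) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Data quality assessment</title>",
        "<style>body{font-family:sans-serif;margin:2em;max-width:70em}"
        "table{border-collapse:collapse}td,th{border:1px solid #bbb;"
        "padding:2px 8px;font-size:90%}blockquote{color:#444;"
        "border-left:3px solid #999;padding-left:1em}</style></head><body>",
        "<h1>Data quality assessment</h1><ul>",
    ]
    for k, v in meta.items():
        parts.append(f"<li><b>{k}</b>: {v}</li>")
    parts.append("</ul><h2>Relevance checklist</h2><ul>")
    for key, question, answer in _relevance_block(report):
        parts.append(f"<li><b>{question}</b> {answer}</li>")
    parts.append("</ul>")
    for section in report.sections:
        parts.append(f"<h2>{section.name} ({section.dimension})</h2>")
        parts.append(f"<p>Findings: <b>{section.findings}</b></p>")
        if section.guidance:
            parts.append(f"<blockquote>{section.guidance}</blockquote>")
        for tname, tbl in section.tables.items():
            if not len(tbl):
                continue
            parts.append(f"<h3>{tname}</h3>")
            parts.append(tbl.head(30).to_html(index=False, na_rep=""))
        for rel in fig_paths.get(section.name, []):
            parts.append(f"<p><img src='{rel}' style='max-width:100%'></p>")
    parts.append("</body></html>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# summary.json structural contract


def validate_summary(summary: dict) -> None:
    """Check a summary.json payload against the published structure.

    Raises :class:`ConfigurationError` on the first violation.
    """
    if not isinstance(summary, dict):
        raise ConfigurationError("summary must be a JSON object")
    for key in ("metadata", "total_findings", "sections"):
        if key not in summary:
            raise ConfigurationError(f"summary missing required key {key!r}")
    meta = summary["metadata"]
    if not isinstance(meta, dict):
        raise ConfigurationError("summary.metadata must be an object")
    for key in ("input", "config_hash", "toolkit_version", "checks"):
        if key not in meta:
            raise ConfigurationError(f"summary.metadata missing key {key!r}")
    if not isinstance(summary["total_findings"], int):
        raise ConfigurationError("summary.total_findings must be an integer")
    sections = summary["sections"]
    if not isinstance(sections, dict):
        raise ConfigurationError("summary.sections must be an object")
    for name, sec in sections.items():
        for key in ("dimension", "findings", "summary"):
            if key not in sec:
                raise ConfigurationError(f"summary.sections[{name!r}] missing key {key!r}")
        if not isinstance(sec["findings"], int):
            raise ConfigurationError(f"summary.sections[{name!r}].findings must be an integer")
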