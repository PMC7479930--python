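"""Matplotlib renderings of the check summaries.

Every function takes a computed summary object (never raw data) and an
optional Axes, so figures are reproducible from the exported tables alone.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering; reports never need a display

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .accuracy import FenceReport, LetterValueSummary
from .comparability import HistogramSpec, PeriodSummary, TableplotSummary


def letter_value_plot(summary: LetterValueSummary, ax=None, label: str = ""):
    """Horizontal letter-value (boxen) display: nested boxes from the
    median outward, outliers as points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    k = len(summary.levels)
    for i, (depth, lo, hi) in enumerate(summary.levels):
        if i == 0:
            ax.axvline(lo, color="black", lw=2, zorder=5)
            continue
        h = 0.9 * (1 - i / (k + 1))
        ax.add_patch(
            plt.Rectangle(
                (lo, -h / 2), hi - lo, h,
                facecolor=plt.cm.Blues(0.9 - 0.7 * i / k),
                edgecolor="white", lw=0.5, zorder=k - i,
            )
        )
    if len(summary.outliers):
        ax.plot(summary.outliers, np.zeros(len(summary.outliers)), "k.", ms=4, zorder=6)
    ax.set_ylim(-0.6, 0.6)
    ax.set_yticks([])
    vals = [v for _, lo, hi in summary.levels for v in (lo, hi)] + list(summary.outliers)
    pad = 0.05 * (max(vals) - min(vals) or 1.0)
    ax.set_xlim(min(vals) - pad, max(vals) + pad)
    ax.set_title(label or f"letter values (n={summary.n}, k={summary.k})", fontsize=10)
    return ax


def fence_plot(report: FenceReport, values, ax=None, label: str = ""):
    """Boxplot with Tukey fences marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    vals = pd.to_numeric(pd.Series(values), errors="coerce").dropna()
    ax.boxplot(vals, vert=False, whis=report.multiplier, widths=0.5)
    for fence in (report.lower_fence, report.upper_fence):
        ax.axvline(fence, color="firebrick", ls="--", lw=1)
    ax.set_yticks([])
    ax.set_title(label or f"Tukey fences ({report.n_outliers} outliers)", fontsize=10)
    return ax


def histogram_plot(spec: HistogramSpec, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    widths = np.diff(spec.edges)
    ax.bar(spec.edges[:-1], spec.counts, width=widths, align="edge",
           color="#4878a8", edgecolor="white", lw=0.3)
    ax.set_xlabel(spec.variable)
    ax.set_ylabel("records")
    ax.set_title(f"{spec.variable} ({spec.rule} bins)", fontsize=10)
    return ax


def missingness_bar_plot(table: pd.DataFrame, var: str, ax=None):
    """Per-domain item-nonresponse bars (output of missingness_by_domain)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.bar(table["domain"].astype(str), table["proportion"], color="#b06060")
    ax.set_ylabel(f"missing proportion of {var}")
    ax.set_ylim(0, max(0.05, table["proportion"].max() * 1.2))
    ax.tick_params(axis="x", rotation=30)
    return ax


def timeseries_plot(summary: PeriodSummary, ax=None):
    """Period means with +/- 1 SD band; flagged periods marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    tbl = summary.table
    if summary.group_var is None:
        ax.plot(tbl["period"], tbl["mean"], color="black", lw=1.2)
        ax.fill_between(
            tbl["period"], tbl["mean"] - tbl["sd"], tbl["mean"] + tbl["sd"],
            color="#4878a8", alpha=0.4, lw=0,
        )
        bad = tbl[tbl["flagged"]]
        if len(bad):
            ax.plot(bad["period"], bad["mean"], "rv", ms=6)
    else:
        for level, sub in tbl.groupby("group"):
            ax.plot(sub["period"], sub["mean"], lw=1.0, label=str(level))
        ax.legend(fontsize=7)
    ax.set_xlabel("period")
    ax.set_ylabel(f"mean {summary.var}")
    return ax


def tableplot_figure(summary: TableplotSummary, figsize=None):
    """Multi-panel tableplot: one column per variable, y = bin rank
    (percentiles of the sort variable), numeric columns as mean with a
    +/- 1 SD band, categorical columns as stacked level frequencies."""
    cols = list(summary.numeric) + list(summary.categorical)
    n_panels = len(cols)
    fig, axes = plt.subplots(
        1, n_panels, figsize=figsize or (2.2 * n_panels + 1, 6), sharey=True
    )
    if n_panels == 1:
        axes = [axes]
    y = np.arange(summary.n_bins)
    for ax, col in zip(axes, cols):
        if col in summary.numeric:
            stats = summary.numeric[col]
            m = stats["mean"].to_numpy()
            s = np.nan_to_num(stats["sd"].to_numpy())
            ax.fill_betweenx(y, m - s, m + s, color="#4878a8", alpha=0.5, lw=0)
            ax.plot(m, y, color="black", lw=1.0)
        else:
            freq = summary.categorical[col]
            shares = freq.div(freq.sum(axis=1), axis=0)
            left = np.zeros(summary.n_bins)
            cmap = plt.cm.tab10
            for i, level in enumerate(shares.columns):
                w = shares[level].to_numpy()
                ax.barh(y, w, left=left, height=1.0,
                        color=cmap(i % 10), label=str(level))
                left += w
            ax.legend(fontsize=6, loc="lower right")
        ax.set_title(col, fontsize=9)
    axes[0].set_ylabel(
        f"{summary.sort_var} percentile bins "
        f"({'descending' if summary.descending else 'ascending'})"
    )
    axes[0].invert_yaxis()
    fig.tight_layout()
    return fig


def duration_histogram(durations: pd.Series, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    d = pd.to_numeric(pd.Series(durations), errors="coerce").dropna()
    if len(d):
        ax.hist(d, bins=np.arange(0.5, d.max() + 1.5), color="#4878a8",
                edgecolor="white", lw=0.3)
    ax.set_xlabel("spell duration (periods)")
    ax.set_ylabel("spells")
    return ax
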