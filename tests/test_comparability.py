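"""Distribution summaries, tableplots, and time-pattern screens."""

import numpy as np
import pandas as pd
import pytest

from adminqc import (
    ConfigurationError,
    DataError,
    PanelDataset,
    distribution_summary,
    tableplot,
    tableplot_over_time,
    timeseries_summary,
)
from adminqc.comparability import _bin_ids
from adminqc.synthetic import SyntheticConfig, simulate_panel

from conftest import make_panel, month


def numeric_panel(values, extra=None):
    df = pd.DataFrame(
        {
            "id": [f"u{i}" for i in range(len(values))],
            "month": [month(0)] * len(values),
            "x": values,
        }
    )
    if extra is not None:
        df["g"] = extra
    return PanelDataset.from_frame(df, "id", "month")


class TestDistributionSummary:
    def test_zero_mass_visible_in_first_bin(self, rng):
        vals = np.where(rng.random(1000) < 0.4, 0.0, rng.lognormal(6, 0.5, 1000))
        panel = numeric_panel(vals)
        table, hist = distribution_summary(panel, "x")
        assert hist.counts[0] >= (vals == 0).sum()
        assert hist.counts.sum() == 1000

    def test_uniform_conservation(self, rng):
        vals = rng.integers(1, 11, 500).astype(float)
        _, hist = distribution_summary(numeric_panel(vals), "x")
        assert hist.counts.sum() == 500
        assert np.all(np.diff(hist.edges) > 0)

    def test_constant_variable_degenerate_bin(self):
        _, hist = distribution_summary(numeric_panel([3.0] * 20), "x")
        assert len(hist.counts) == 1 and hist.counts[0] == 20

    def test_histogram_counts_match_oracle(self, rng):
        vals = rng.normal(size=2000)
        _, hist = distribution_summary(numeric_panel(vals), "x")
        expected = [
            ((vals >= lo) & (vals < hi)).sum()
            for lo, hi in zip(hist.edges[:-2], hist.edges[1:-1])
        ]
        expected.append(((vals >= hist.edges[-2]) & (vals <= hist.edges[-1])).sum())
        assert hist.counts.tolist() == expected

    def test_categorical_variable_rejected(self, clean_panel):
        with pytest.raises(ConfigurationError, match="categorical_profile"):
            distribution_summary(clean_panel, "funding_source")

    def test_per_group_output(self, rng):
        vals = rng.normal(size=100)
        groups = np.where(np.arange(100) < 60, "a", "b")
        out = distribution_summary(numeric_panel(vals, extra=groups), "x", by="g")
        assert set(out) == {"a", "b"}
        assert out["a"][0]["n"].iloc[0] == 60


class TestTableplot:
    def test_two_bin_means(self):
        rows = [(f"u{i}", month(0), float(10 - i), float(10 - i)) for i in range(10)]
        panel = make_panel(rows, columns=("id", "month", "s", "v"))
        tp = tableplot(panel, "s", ["v"], n_bins=2)
        assert tp.bins["count"].tolist() == [5, 5]
        assert tp.numeric["v"]["mean"].tolist() == [8.0, 3.0]

    def test_bin_sizes_larger_first(self):
        assert np.bincount(_bin_ids(10, 3)).tolist() == [4, 3, 3]
        assert np.bincount(_bin_ids(100, 100)).tolist() == [1] * 100

    def test_categorical_frequencies_conserve_bin_size(self):
        rows = [(f"u{i}", month(0), float(i), ["a", "a", "a", "b", "b"][i]) for i in range(5)]
        panel = make_panel(rows, columns=("id", "month", "s", "c"))
        tp = tableplot(panel, "s", ["c"], n_bins=2, descending=False)
        freq = tp.categorical["c"]
        assert freq.sum(axis=1).tolist() == tp.bins["count"].tolist()
        assert freq.to_numpy().sum() == 5

    def test_permutation_invariance(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "id": [f"u{i % 40}" for i in range(n)],
                "month": [month(i % 5) for i in range(n)],
                "s": rng.integers(0, 20, n).astype(float),  # many ties
                "v": rng.normal(size=n),
                "c": rng.choice(["a", "b"], n),
            }
        )
        p1 = PanelDataset.from_frame(df, "id", "month")
        p2 = PanelDataset.from_frame(
            df.sample(frac=1, random_state=7).reset_index(drop=True), "id", "month"
        )
        t1 = tableplot(p1, "s", ["v", "c"], n_bins=8)
        t2 = tableplot(p2, "s", ["v", "c"], n_bins=8)
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())

    def test_weighted_bin_means_reproduce_overall_mean(self, rng):
        vals = rng.lognormal(size=997)
        panel = numeric_panel(vals)
        tp = tableplot(panel, "x", ["x"], n_bins=10)
        weighted = (tp.numeric["x"]["mean"] * tp.bins["count"]).sum() / 997
        assert weighted == pytest.approx(vals.mean())

    def test_too_few_records_suggests_smaller_n_bins(self):
        panel = numeric_panel([1.0, 2.0, 3.0])
        with pytest.raises(DataError, match="n_bins"):
            tableplot(panel, "x", ["x"], n_bins=10)

    def test_sort_ranges_ordered_descending(self, rng):
        panel = numeric_panel(rng.normal(size=300))
        tp = tableplot(panel, "x", ["x"], n_bins=10)
        assert (tp.bins["sort_min"].diff().dropna() <= 1e-12).all()


class TestTableplotOverTime:
    def test_bins_align_with_months(self):
        rows = [(f"u{i}", month(t), float(t)) for t in range(60) for i in range(3)]
        panel = make_panel(rows, columns=("id", "month", "v"))
        tp = tableplot_over_time(panel, ["v"], n_bins=60)
        assert tp.bins["count"].tolist() == [3] * 60
        assert tp.numeric["v"]["mean"].tolist() == [float(t) for t in range(60)]

    def test_coarser_bins_span_equal_months(self):
        rows = [(f"u{i}", month(t), 1.0) for t in range(60) for i in range(2)]
        panel = make_panel(rows, columns=("id", "month", "v"))
        tp = tableplot_over_time(panel, ["v"], n_bins=10)
        assert tp.bins["count"].tolist() == [12] * 10
        spans = tp.bins["sort_max"] - tp.bins["sort_min"]
        assert spans.tolist() == [5.0] * 10

    def test_shift_elevates_late_bins(self):
        panel, _ = simulate_panel(SyntheticConfig(n_units=800, seed=31))
        tp = tableplot_over_time(panel, ["benefit"], n_bins=20)
        means = tp.numeric["benefit"]["mean"]
        shift_frac = 12 / 60  # 2015 is the last fifth of the window
        late = means.iloc[-3:].mean()  # bins fully inside 2015
        early = means.iloc[:16].mean()
        assert late - early > 25  # at least half the injected +50 shift


class TestTimeseriesSummary:
    def test_level_shift_recovered(self):
        cfg = SyntheticConfig(n_units=2000, seed=13)
        panel, _ = simulate_panel(cfg)
        rep = timeseries_summary(panel, "benefit")
        tbl = rep.table
        shift_idx = cfg.shift_period
        est = (
            tbl[tbl["period"] >= shift_idx]["mean"].mean()
            - tbl[tbl["period"] < shift_idx]["mean"].mean()
        )
        # tolerance ~3x the estimator's sampling SD at this scale (the
        # period means carry unit-composition noise via the recipients mix)
        assert est == pytest.approx(cfg.shift_delta, abs=25)

    def test_variance_inflation_visible(self):
        cfg = SyntheticConfig(n_units=2000, seed=13)
        panel, _ = simulate_panel(cfg)
        tbl = timeseries_summary(panel, "benefit").table
        shift_idx = cfg.shift_period
        late_sd = tbl[tbl["period"] >= shift_idx]["sd"].median()
        early_sd = tbl[tbl["period"] < shift_idx]["sd"].median()
        assert late_sd > early_sd

    def test_constant_series_no_flags(self):
        rows = [(f"u{i}", month(t), 5.0) for t in range(12) for i in range(4)]
        panel = make_panel(rows, columns=("id", "month", "v"))
        rep = timeseries_summary(panel, "v")
        assert (rep.table["anomaly_score"] == 0).all()
        assert rep.n_findings == 0

    def test_stationary_false_flag_rate_below_5pct(self, rng):
        """Robust screen at the default threshold rarely flags stationary
        noise (200 replicate series)."""
        flags = total = 0
        for _ in range(200):
            n_per = 30
            vals = rng.normal(100, 10, size=24 * n_per)
            df = pd.DataFrame(
                {
                    "id": [f"u{i % n_per}" for i in range(len(vals))],
                    "month": [month(i // n_per) for i in range(len(vals))],
                    "v": vals,
                }
            )
            panel = PanelDataset.from_frame(df, "id", "month")
            rep = timeseries_summary(panel, "v")
            flags += int(rep.table["flagged"].sum())
            total += len(rep.table)
        assert flags / total < 0.05

    def test_grouped_summary_conserves_counts(self, clean_panel):
        rep = timeseries_summary(clean_panel, "benefit", group_var="case_type")
        total = rep.table["count"].sum()
        assert total == clean_panel.records["benefit"].notna().sum()
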