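"""Spell extraction, durations, churn, and trajectory screens."""

import numpy as np
import pandas as pd
import pytest

from adminqc import (
    ConfigurationError,
    DataError,
    PanelDataset,
    VariableSchema,
    churn_events,
    extract_spells,
    spell_statistics,
    trajectory_checks,
)

from conftest import make_panel, month


def presence_panel(observed, n_periods=8):
    """Panel where unit 'A' is observed at the given period indices."""
    rows = [("A", month(t)) for t in observed]
    rows.append(("pad", month(0)))
    rows.append(("pad", month(n_periods - 1)))  # fixes the panel window
    return make_panel(rows)


def rle_oracle(periods):
    """Run-length encoding of a sorted period set: list of (start, end)."""
    runs, start = [], None
    prev = None
    for p in sorted(set(periods)):
        if start is None:
            start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            runs.append((start, prev))
            start = prev = p
    if start is not None:
        runs.append((start, prev))
    return runs


class TestExtractSpells:
    def test_two_spells_with_gap(self):
        st = extract_spells(presence_panel([1, 2, 3, 6, 7]))
        a = st.spells[st.spells["unit"] == "A"]
        assert list(zip(a["start"], a["end"], a["duration"])) == [(1, 3, 3), (6, 7, 2)]
        gaps = st.gaps[st.gaps["unit"] == "A"]
        assert gaps["length"].tolist() == [2]

    def test_fully_observed_unit_single_censored_spell(self):
        rows = [("A", month(t)) for t in range(60)]
        st = extract_spells(make_panel(rows))
        assert st.n_spells == 1
        row = st.spells.iloc[0]
        assert row["duration"] == 60
        assert row["left_censored"] and row["right_censored"]
        assert len(st.gaps) == 0

    def test_duplicate_rows_count_once(self):
        st = extract_spells(presence_panel([1, 1, 2]))
        a = st.spells[st.spells["unit"] == "A"]
        assert a["duration"].tolist() == [2]

    def test_matches_rle_oracle_on_random_panels(self, rng):
        rows = []
        truth = {}
        for i in range(500):
            mask = rng.random(24) < 0.4
            periods = np.flatnonzero(mask)
            if len(periods) == 0:
                continue
            truth[f"u{i}"] = rle_oracle(periods.tolist())
            rows += [(f"u{i}", month(int(t))) for t in periods]
        rows += [("pad0", month(0)), ("pad1", month(23))]
        st = extract_spells(make_panel(rows))
        for unit, runs in truth.items():
            sub = st.spells[st.spells["unit"] == unit]
            assert list(zip(sub["start"], sub["end"])) == runs
        # idempotence of the definition: durations sum to observed periods
        df = pd.DataFrame(rows, columns=["id", "m"])
        per_unit = df.groupby("id")["m"].nunique()
        sums = st.spells.groupby("unit")["duration"].sum()
        pd.testing.assert_series_equal(
            sums.sort_index(), per_unit.sort_index(), check_names=False
        )

    def test_indicator_mode(self):
        rows = [("A", month(t), float(v)) for t, v in enumerate([1, 1, 0, 1])]
        panel = make_panel(rows, columns=("id", "month", "recv"))
        st = extract_spells(panel, receipt="recv")
        a = st.spells[st.spells["unit"] == "A"]
        assert list(zip(a["start"], a["end"])) == [(0, 1), (3, 3)]

    def test_non_binary_indicator_rejected(self):
        rows = [("A", month(0), 2.0)]
        panel = make_panel(rows, columns=("id", "month", "recv"))
        with pytest.raises(DataError, match="non-binary"):
            extract_spells(panel, receipt="recv")

    def test_removing_middle_row_splits_spell(self):
        whole = extract_spells(presence_panel([2, 3, 4, 5]))
        broken = extract_spells(presence_panel([2, 3, 5]))
        n_a = lambda st: len(st.spells[st.spells["unit"] == "A"])
        assert n_a(broken) == n_a(whole) + 1


class TestSpellStatistics:
    def test_mean_spells_per_unit(self):
        rows = [("A", month(1)), ("B", month(1)), ("B", month(3))]
        rows += [("pad", month(0)), ("pad", month(5))]
        stats = spell_statistics(extract_spells(make_panel(rows)))
        spu = stats.spells_per_unit.iloc[0]
        assert spu["mean"] == pytest.approx((1 + 2 + 2) / 3)  # pad has 2 spells too

    def test_duration_summary(self):
        st = extract_spells(presence_panel([1, 2, 3, 6, 7]))
        stats = spell_statistics(st)
        row = stats.durations.set_index("series").loc["durations_all"]
        # spells: A (3, 2) and the two pad singletons
        assert row["n"] == 4

    def test_right_censoring_flag(self):
        rows = [("A", month(t)) for t in (5, 6, 7)] + [("pad", month(0))]
        st = extract_spells(make_panel(rows))
        a = st.spells[st.spells["unit"] == "A"].iloc[0]
        assert a["right_censored"] and not a["left_censored"]
        stats = spell_statistics(st)
        assert stats.n_right_censored == 1

    def test_by_group_durations(self):
        rows = [
            ("A", month(1), "g1"),
            ("A", month(2), "g1"),
            ("B", month(1), "g2"),
            ("pad", month(0), "g2"),
            ("pad", month(4), "g2"),
        ]
        panel = make_panel(rows, columns=("id", "month", "dom"))
        stats = spell_statistics(extract_spells(panel), panel=panel, by="dom")
        grp = stats.by_group.set_index("group")
        assert grp.loc["g1", "mean"] == 2.0


class TestChurn:
    def test_gap_within_window_is_churn(self):
        st = extract_spells(presence_panel([1, 2, 3, 6, 7]))
        assert churn_events(st, window=4).n_events == 1

    def test_short_window_excludes_long_gap(self):
        st = extract_spells(presence_panel([1, 2, 3, 6, 7]))
        assert churn_events(st, window=1).n_events == 0

    def test_single_spell_units_never_churn(self):
        rows = [(f"u{i}", month(t)) for i in range(5) for t in range(3)]
        st = extract_spells(make_panel(rows))
        for g in (1, 4, 50):
            assert churn_events(st, window=g).n_events == 0

    def test_monotone_in_window_and_saturates(self, rng):
        rows = []
        for i in range(100):
            periods = np.flatnonzero(rng.random(20) < 0.5)
            rows += [(f"u{i}", month(int(t))) for t in periods]
        rows += [("pad0", month(0)), ("pad1", month(19))]
        st = extract_spells(make_panel(rows))
        counts = [churn_events(st, window=g).n_events for g in range(1, 21)]
        assert counts == sorted(counts)
        total_transitions = int((st.spells.groupby("unit").size() - 1).sum())
        assert counts[-1] == total_transitions

    def test_invalid_window(self):
        st = extract_spells(presence_panel([1]))
        with pytest.raises(ConfigurationError):
            churn_events(st, window=0)

    def test_rate_denominator_excludes_right_censored(self):
        st = extract_spells(presence_panel([1, 2, 5, 7], n_periods=8))
        ch = churn_events(st, window=4)
        # A: spells (1-2),(5-5),(7-7 right-censored); pads censored singletons
        assert ch.n_events == 2
        assert ch.n_completed_spells == 3
        assert ch.rate_per_completed_spell == pytest.approx(2 / 3)


class TestTrajectoryChecks:
    def _panel(self, rows, columns, schema):
        df = pd.DataFrame(rows, columns=columns)
        return PanelDataset.from_frame(df, "id", "month", schema=schema)

    def test_stable_variable_flip_detected(self):
        panel = self._panel(
            [("A", month(0), "F"), ("A", month(1), "F"), ("A", month(2), "M")],
            ("id", "month", "sex"),
            [VariableSchema("sex", role="categorical", trajectory="stable")],
        )
        rep = trajectory_checks(panel)
        assert rep.stable["sex"]["count"] == 1
        assert rep.stable["sex"]["sample_units"] == ["A"]

    def test_monotone_decrease_detected_with_first_offense(self):
        panel = self._panel(
            [("A", month(t), float(v)) for t, v in enumerate([3, 4, 4, 2])],
            ("id", "month", "mob"),
            [VariableSchema("mob", role="numeric", trajectory="monotone_nondecreasing")],
        )
        rep = trajectory_checks(panel)
        assert rep.monotone["mob"]["count"] == 1
        assert rep.monotone["mob"]["first_offense"]["A"] == 3

    def test_equal_consecutive_values_are_not_violations(self):
        panel = self._panel(
            [("A", month(t), 4.0) for t in range(3)],
            ("id", "month", "mob"),
            [VariableSchema("mob", role="numeric", trajectory="monotone_nondecreasing")],
        )
        assert trajectory_checks(panel).monotone["mob"]["count"] == 0

    def test_injected_flips_recovered_exactly(self, defect_panel_with_truth):
        (panel, truth), cfg = defect_panel_with_truth
        rep = trajectory_checks(panel)
        injected_stable = set(truth.frames["stable_flip"]["unit"])
        injected_monotone = set(truth.frames["monotone"]["unit"])
        assert rep.stable["sex"]["count"] == len(injected_stable)
        assert rep.monotone["months_on_benefits"]["count"] == len(injected_monotone)
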