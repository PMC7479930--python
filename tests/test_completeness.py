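"""Coverage screening, duplicate detection, item nonresponse."""

import itertools

import numpy as np
import pandas as pd
import pytest

from adminqc import (
    ConfigurationError,
    coverage_by_area,
    detect_duplicates,
    missingness_by_domain,
    missingness_by_variable,
)
from adminqc.panel import PanelDataset, VariableSchema

from conftest import make_panel, month


def geo_panel(rows):
    return make_panel(rows, columns=("id", "month", "county"))


class TestCoverage:
    def test_zero_count_cell_flagged(self):
        rows = []
        for t, (x, y) in enumerate([(100, 50), (102, 0), (98, 49)]):
            rows += [(f"x{i}_{t}", month(t), "X") for i in range(x)]
            rows += [(f"y{i}_{t}", month(t), "Y") for i in range(y)]
        rep = coverage_by_area(geo_panel(rows), "county")
        assert bool(rep.zero_flags.loc["Y", month(1)])
        assert not rep.zero_flags.loc["X"].any()

    def test_low_cell_vs_own_median(self):
        rows = []
        for t, z in enumerate([100, 100, 40]):
            rows += [(f"z{i}_{t}", month(t), "Z") for i in range(z)]
        rep = coverage_by_area(geo_panel(rows), "county", low_fraction=0.5)
        assert bool(rep.low_flags.loc["Z", month(2)])  # 40 < 0.5 * 100
        assert rep.low_flags.loc["Z"].sum() == 1

    def test_single_period_no_low_flags(self):
        rows = [(f"u{i}", month(0), "A") for i in range(10)]
        rep = coverage_by_area(geo_panel(rows), "county")
        assert rep.low_flags.values.sum() == 0 and rep.zero_flags.values.sum() == 0

    def test_counts_conserve_nonmissing_geography(self, rng):
        rows = [
            (f"u{i}", month(int(rng.integers(0, 6))), rng.choice(["A", "B", None]))
            for i in range(300)
        ]
        panel = geo_panel(rows)
        rep = coverage_by_area(panel, "county")
        assert rep.counts.values.sum() == panel.records["county"].notna().sum()

    def test_unknown_geo_var(self, clean_panel):
        with pytest.raises(ConfigurationError):
            coverage_by_area(clean_panel, "nowhere")


class TestDuplicates:
    def test_id_time_duplicates(self):
        panel = make_panel([("A", month(1)), ("A", month(1)), ("B", month(1))])
        rep = detect_duplicates(panel)
        assert rep.n_duplicated_keys == 1
        assert rep.records_involved == 2
        assert rep.excess_records == 1

    def test_no_duplicates_identity(self):
        panel = make_panel([("A", month(1)), ("B", month(1))])
        rep = detect_duplicates(panel)
        assert rep.n_duplicated_keys == rep.records_involved == rep.excess_records == 0

    def test_analysis_variable_keys(self):
        rows = [
            ("A", month(0), 30.0, "X", 100.0),
            ("B", month(0), 30.0, "X", 100.0),
            ("C", month(0), 31.0, "X", 100.0),
        ]
        panel = make_panel(rows, columns=("id", "month", "age", "county", "benefit"))
        by_vars = detect_duplicates(panel, keys=["age", "county", "benefit"])
        by_id = detect_duplicates(panel)
        assert by_vars.n_duplicated_keys == 1
        assert by_id.n_duplicated_keys == 0

    def test_empty_key_list_rejected(self, clean_panel):
        with pytest.raises(ConfigurationError):
            detect_duplicates(clean_panel, keys=[])

    def test_missing_matches_missing_by_default_but_not_with_never(self):
        rows = [("A", month(0), None), ("B", month(0), None), ("C", month(0), "v")]
        panel = make_panel(rows, columns=("id", "month", "k"))
        assert detect_duplicates(panel, keys=["month", "k"]).n_duplicated_keys == 1
        assert (
            detect_duplicates(panel, keys=["month", "k"], missing_match="never").n_duplicated_keys
            == 0
        )

    def test_matches_pairwise_oracle(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "id": [f"u{i}" for i in range(n)],
                "month": [month(int(rng.integers(0, 3))) for _ in range(n)],
                "a": rng.integers(0, 6, n).astype(float),
                "b": rng.choice(["p", "q", None], n),
            }
        )
        panel = PanelDataset.from_frame(df, "id", "month")
        rep = detect_duplicates(panel, keys=["a", "b"])
        # O(n^2) oracle counting pairs that agree on the full key tuple
        keys = list(zip(df["a"], df["b"].where(df["b"].notna(), "\0NA")))
        in_dup_group = set()
        for i, j in itertools.combinations(range(n), 2):
            if keys[i] == keys[j]:
                in_dup_group |= {i, j}
        groups = {}
        for i in in_dup_group:
            groups.setdefault(keys[i], []).append(i)
        assert rep.n_duplicated_keys == len(groups)
        assert rep.records_involved == len(in_dup_group)
        assert rep.excess_records == len(in_dup_group) - len(groups)

    def test_per_period_breakdown(self):
        rows = [("A", month(0)), ("A", month(0)), ("A", month(1))]
        rep = detect_duplicates(make_panel(rows), per_period=True)
        tbl = rep.per_period.set_index("period")
        assert tbl.loc[month(0), "excess_records"] == 1
        assert tbl.loc[month(1), "excess_records"] == 0


class TestMissingness:
    def test_unit_level_any_missing(self):
        rows = [
            ("u1", month(0), None),
            ("u1", month(1), 5.0),
            ("u2", month(0), 4.0),
            ("u3", month(0), 3.0),
        ]
        panel = make_panel(rows, columns=("id", "month", "income"))
        rep = missingness_by_variable(panel, ["income"])
        assert rep.unit_any_missing_proportion == pytest.approx(1 / 3)

    def test_fully_observed_variable(self):
        rows = [("u", month(t), 1.0) for t in range(4)]
        panel = make_panel(rows, columns=("id", "month", "x"))
        rep = missingness_by_variable(panel)
        assert rep.per_variable.set_index("variable").loc["x", "proportion"] == 0.0

    def test_pattern_table_enumeration(self):
        rows = [
            ("a", month(0), 1.0, 1.0),
            ("b", month(0), 1.0, None),
            ("c", month(0), 1.0, None),
            ("d", month(0), None, None),
        ]
        panel = make_panel(rows, columns=("id", "month", "x", "y"))
        rep = missingness_by_variable(panel, ["x", "y"])
        tbl = rep.pattern_table
        assert len(tbl) == 3
        assert sorted(tbl["frequency"]) == [1, 1, 2]
        assert tbl["frequency"].sum() == panel.n_records

    def test_any_missing_dominates_per_variable_unit_share(self, defect_panel_with_truth):
        (panel, truth), cfg = defect_panel_with_truth
        key_vars = ["income", "benefit", "recipients"]
        rep = missingness_by_variable(panel, key_vars)
        ids = panel.records[panel.id_var]
        for var in key_vars:
            per_var_units = ids[panel.records[var].isna()].nunique() / panel.n_units
            assert rep.unit_any_missing_proportion >= per_var_units

    def test_domain_proportions(self):
        rows = [("u%d" % i, month(0), None if i < 2 else 1.0, "g1") for i in range(10)]
        rows += [("v%d" % i, month(0), 1.0, "g2") for i in range(10)]
        panel = make_panel(rows, columns=("id", "month", "x", "dom"))
        tbl = missingness_by_domain(panel, "x", "dom").set_index("domain")
        assert tbl.loc["g1", "proportion"] == 0.2
        assert tbl.loc["g2", "proportion"] == 0.0

    def test_flat_profile_when_missingness_equal(self):
        rows = [("u%d" % i, month(0), None if i % 5 == 0 else 1.0, "g%d" % (i % 2)) for i in range(20)]
        panel = make_panel(rows, columns=("id", "month", "x", "dom"))
        tbl = missingness_by_domain(panel, "x", "dom")
        assert tbl["proportion"].nunique() == 1

    def test_injected_domain_rates_recovered(self):
        from adminqc.synthetic import SyntheticConfig, simulate_panel

        cfg = SyntheticConfig(
            n_units=1500,
            seed=77,
            missing_rates={"single_parent": 0.15, "two_parent": 0.05},
        )
        panel, truth = simulate_panel(cfg)
        tbl = missingness_by_domain(panel, "income", "case_type").set_index("domain")
        for level, rate in cfg.missing_rates.items():
            n = tbl.loc[level, "n"]
            assert n >= 5000
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(tbl.loc[level, "proportion"] - rate) <= 3 * se
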