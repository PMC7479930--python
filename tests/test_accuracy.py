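"""Letter values, Tukey fences, ID syntax, descriptive profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adminqc import (
    ConfigurationError,
    InsufficientDataError,
    categorical_profile,
    letter_values,
    numeric_profile,
    tukey_fences,
    validate_id_syntax,
)
from adminqc.accuracy import letter_depths, trustworthy_k

from conftest import make_panel, month


def oracle_letter_values(values, k):
    """Independent oracle: order statistics at hand-iterated depths."""
    x = sorted(values)
    n = len(x)
    depths, d = [], (1 + n) / 2
    while len(depths) < k and (not depths or depths[-1] > 1):
        depths.append(d)
        d = (1 + int(d)) / 2
    out = []
    for d in depths:
        if d == int(d):
            lo, hi = x[int(d) - 1], x[n - int(d)]
        else:
            i = int(d)
            lo = (x[i - 1] + x[i]) / 2
            hi = (x[n - i] + x[n - i - 1]) / 2
        out.append((d, lo, hi))
    return out


class TestLetterValues:
    def test_one_to_eight_by_hand(self):
        lv = letter_values(range(1, 9), rule="fixed-k", k=3)
        assert lv.levels == [(4.5, 4.5, 4.5), (2.5, 2.5, 6.5), (1.5, 1.5, 7.5)]

    def test_trustworthy_rule_level_count(self):
        assert trustworthy_k(10_000) == 10
        lv = letter_values(np.arange(10_000), rule="trustworthy")
        assert lv.k == 10

    def test_constant_data_no_outliers(self):
        lv = letter_values([0.0] * 32)
        assert all(lo == 0 and hi == 0 for _, lo, hi in lv.levels)
        assert len(lv.outliers) == 0

    def test_matches_depth_oracle_on_random_data(self, rng):
        for n in (5, 17, 256, 10_001):
            vals = rng.normal(size=n)
            k = trustworthy_k(n)
            lv = letter_values(vals)
            assert lv.levels == pytest.approx(oracle_letter_values(vals, k))

    def test_nesting_invariant(self, rng):
        vals = rng.exponential(size=501)
        lv = letter_values(vals)
        lowers = [lo for _, lo, _ in lv.levels]
        uppers = [hi for _, _, hi in lv.levels]
        assert lowers == sorted(lowers, reverse=True)
        assert uppers == sorted(uppers)
        lo_k, hi_k = lowers[-1], uppers[-1]
        assert all(v < lo_k or v > hi_k for v in lv.outliers)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            letter_values([np.nan, 1.0])


class TestTukeyFences:
    def test_one_to_eight(self):
        fr = tukey_fences(range(1, 9))
        assert (fr.lower_fourth, fr.upper_fourth) == (2.5, 6.5)
        assert (fr.lower_fence, fr.upper_fence) == (-3.5, 12.5)
        assert fr.n_outliers == 0

    def test_with_extreme_point(self):
        fr = tukey_fences(list(range(1, 9)) + [100])
        assert (fr.lower_fourth, fr.upper_fourth) == (3.0, 7.0)
        assert (fr.lower_fence, fr.upper_fence) == (-3.0, 13.0)
        assert fr.outlier_values.tolist() == [100.0]

    def test_zero_spread(self):
        fr = tukey_fences([5, 5, 5, 5])
        assert (fr.lower_fence, fr.upper_fence) == (5.0, 5.0)
        assert fr.n_outliers == 0

    def test_fourths_shared_with_letter_values(self, rng):
        for n in (4, 9, 100, 1234):
            vals = rng.normal(size=n)
            fr = tukey_fences(vals)
            lv = letter_values(vals, rule="fixed-k", k=2)
            assert (fr.lower_fourth, fr.upper_fourth) == lv.fourths

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    def test_outlier_set_shrinks_with_wider_multiplier(self, values):
        """Raising the fence multiplier (1.5 -> 3, 'far out') can only
        remove outliers, and outliers are exactly the points beyond the
        fences."""
        inner = tukey_fences(values, multiplier=1.5)
        outer = tukey_fences(values, multiplier=3.0)
        assert set(outer.outlier_indices.tolist()) <= set(inner.outlier_indices.tolist())
        arr = np.asarray(values, dtype=float)
        expected = np.flatnonzero((arr < inner.lower_fence) | (arr > inner.upper_fence))
        assert inner.outlier_indices.tolist() == expected.tolist()


class TestIDSyntax:
    def test_valid_ssn(self):
        panel = make_panel([("123-45-6789", month(0))])
        rep = validate_id_syntax(panel, "ssn9")
        assert rep.counts == {"missing": 0, "correct": 1, "incorrect": 0}

    def test_structurally_invalid_ssns(self):
        panel = make_panel([("000-12-3456", month(0)), ("12345678", month(0))])
        rep = validate_id_syntax(panel, "ssn9")
        assert rep.counts["incorrect"] == 2

    @pytest.mark.parametrize(
        "key,ok",
        [
            ("123456789", True),
            ("666-12-3456", False),
            ("900-12-3456", False),
            ("123-00-4567", False),
            ("123-45-0000", False),
        ],
    )
    def test_ssn_structural_rules(self, key, ok):
        panel = make_panel([(key, month(0))])
        rep = validate_id_syntax(panel, "ssn9")
        assert (rep.counts["correct"] == 1) is ok

    def test_missing_keys_counted_once_per_unit(self):
        panel = make_panel([(None, month(0)), ("123-45-6789", month(0)), ("123-45-6789", month(1))])
        rep = validate_id_syntax(panel, "ssn9")
        assert rep.counts == {"missing": 1, "correct": 1, "incorrect": 0}
        assert rep.proportions == {"missing": 0.5, "correct": 0.5, "incorrect": 0.0}

    def test_user_regex_and_invalid_regex(self):
        panel = make_panel([("AB12", month(0)), ("zz", month(0))])
        rep = validate_id_syntax(panel, r"[A-Z]{2}\d{2}")
        assert rep.counts["correct"] == 1 and rep.counts["incorrect"] == 1
        with pytest.raises(ConfigurationError):
            validate_id_syntax(panel, "([")


class TestProfiles:
    def test_numeric_profile_median_and_extrema(self):
        rows = [("u", month(0), float(v)) for v in range(1, 101)]
        panel = make_panel(rows, columns=("id", "month", "x"))
        prof = numeric_profile(panel, ["x"]).iloc[0]
        assert prof["q50"] == 50.5 and prof["min"] == 1 and prof["max"] == 100

    def test_missing_counted(self):
        vals = [1.0, 2, 3, 4, 5, 6, 7] + [np.nan] * 3
        rows = [("u", month(i), v) for i, v in enumerate(vals)]
        panel = make_panel(rows, columns=("id", "month", "x"))
        prof = numeric_profile(panel, ["x"]).iloc[0]
        assert prof["n"] == 7 and prof["missing"] == 3

    def test_degenerate_single_value(self):
        panel = make_panel([("u", month(0), 7.0)], columns=("id", "month", "x"))
        prof = numeric_profile(panel, ["x"]).iloc[0]
        assert all(prof[f"q{q:02d}"] == 7.0 for q in (1, 25, 50, 75, 99))

    def test_quantiles_match_sort_oracle(self, rng):
        vals = rng.lognormal(size=5000)
        rows = pd.DataFrame(
            {"id": "u", "month": month(0), "x": vals}
        )
        from adminqc import PanelDataset

        panel = PanelDataset.from_frame(rows, "id", "month")
        prof = numeric_profile(panel, ["x"]).iloc[0]
        x = np.sort(vals)
        n = len(x)
        for q in (0.01, 0.25, 0.50, 0.90, 0.99):
            h = (n - 1) * q
            lo = int(np.floor(h))
            expected = x[lo] + (h - lo) * (x[min(lo + 1, n - 1)] - x[lo])
            assert prof[f"q{int(q*100):02d}"] == pytest.approx(expected)

    def test_rejects_non_numeric_role(self, clean_panel):
        with pytest.raises(ConfigurationError):
            numeric_profile(clean_panel, ["funding_source"])

    def test_categorical_frequencies(self):
        rows = [("u", month(i), v) for i, v in enumerate(["a", "a", "b", None])]
        panel = make_panel(rows, columns=("id", "month", "g"))
        tbl = categorical_profile(panel, ["g"])["g"].set_index("level")
        assert tbl.loc["a", "proportion"] == 0.5
        assert tbl.loc["b", "proportion"] == 0.25
        assert tbl.loc["(missing)", "proportion"] == 0.25
        assert tbl["proportion"].sum() == 1.0

    def test_all_missing(self):
        rows = [("u", month(0), None), ("u", month(1), None)]
        panel = make_panel(rows, columns=("id", "month", "g"))
        tbl = categorical_profile(panel, ["g"])["g"].set_index("level")
        assert tbl.loc["(missing)", "proportion"] == 1.0

    def test_declared_unobserved_level_reported_zero(self):
        from adminqc import VariableSchema

        rows = pd.DataFrame({"id": ["u", "u"], "month": [month(0), month(1)], "g": ["a", "b"]})
        from adminqc import PanelDataset

        panel = PanelDataset.from_frame(
            rows,
            "id",
            "month",
            schema=[VariableSchema("g", role="categorical", levels=["a", "b", "c"])],
        )
        tbl = categorical_profile(panel, ["g"])["g"].set_index("level")
        assert tbl.loc["c", "count"] == 0
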