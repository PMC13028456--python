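"""Patient-category binning, anchor truncation, and table extrapolation."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from marie.tables import (AnchorRow, CATEGORIES, DomainError, POINTS_RANGE,
                          assign_patient_category, build_table,
                          lookup_base_price, truncate_anchor, verify_table)


class TestAssignPatientCategory:
    @pytest.mark.parametrize("n,label", [
        (1, "1 to 10"),
        (2_500_000, "More than 2,000,000"),
        (10_000, "10,000 to 30,000"),       # boundary goes to the upper bin
        (9_999, "5000 to 10,000"),
        (2_000_000, "More than 2,000,000"),
        (999, "500 to 1000"),
    ])
    def test_examples(self, n, label):
        assert assign_patient_category(n).label == label

    @pytest.mark.parametrize("bad", [0, -5])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(DomainError):
            assign_patient_category(bad)

    @given(st.integers(min_value=1, max_value=5_000_000))
    def test_agrees_with_brute_force_interval_scan(self, n):
        cat = assign_patient_category(n)
        hits = [c for c in CATEGORIES
                if c.lower <= n and (c.upper is None or n < c.upper)]
        assert hits == [cat]

    def test_categories_are_contiguous_and_cover_from_one(self):
        assert CATEGORIES[0].lower == 1
        assert CATEGORIES[-1].upper is None
        for a, b in zip(CATEGORIES, CATEGORIES[1:]):
            assert a.upper == b.lower


class TestTruncateAnchor:
    @pytest.mark.parametrize("raw,expected", [
        (455, 450),          # 3 digits: drop last digit
        (141_187, 141_100),  # >=4 digits: drop last two
        (84, 84),            # <=2 digits: unchanged
        (99.9, 99),          # fractional medians floored first
        (1000, 1000),
        (999, 990),
    ])
    def test_examples(self, raw, expected):
        assert truncate_anchor(raw) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(DomainError):
            truncate_anchor(0)

    @given(st.floats(min_value=0.5, max_value=1e7,
                     allow_nan=False, allow_infinity=False))
    def test_idempotent_and_never_increasing(self, x):
        t = truncate_anchor(x)
        assert t <= x
        assert truncate_anchor(max(t, 1)) == max(t, 1) or t == 0
        if t >= 1:
            assert truncate_anchor(t) == t


def _random_anchor_prices(draw_ints):
    # valid anchors: positive and already truncated
    return tuple(truncate_anchor(v) for v in draw_ints)


anchor_strategy = st.builds(
    lambda vals: AnchorRow(tuple(max(truncate_anchor(v), 1) for v in vals)),
    st.lists(st.integers(min_value=10, max_value=500_000),
             min_size=len(CATEGORIES), max_size=len(CATEGORIES)),
)


class TestBuildTable:
    def test_published_rows_from_anchor(self, table_2015_2024, table_2012_2021):
        t = build_table(table_2015_2024.anchor)
        assert t.cell(50, "More than 2,000,000") == 104
        assert t.cell(5, "1 to 10") == 56_440
        t_old = build_table(table_2012_2021.anchor)
        assert t_old.cell(50, "1 to 10") == 120_250

    @pytest.mark.parametrize("window", ["FY2012-FY2021", "FY2015-FY2024"])
    def test_full_grid_regenerated_from_anchor(self, window, request):
        """Every cell of both published grids equals its anchor
        extrapolation."""
        fixture = {"FY2012-FY2021": "table_2012_2021",
                   "FY2015-FY2024": "table_2015_2024"}[window]
        printed = request.getfixturevalue(fixture)
        rebuilt = build_table(printed.anchor, printed.provenance)
        for p in POINTS_RANGE:
            assert rebuilt.rows[p] == printed.rows[p]

    @given(anchor_strategy)
    def test_monotone_in_points_and_linear(self, anchor):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-div-10 anchors warn
            t = build_table(anchor)
        for idx, cat in enumerate(CATEGORIES):
            col = [t.cell(p, cat) for p in POINTS_RANGE]
            assert all(a < b for a, b in zip(col, col[1:]))
            if anchor.prices[idx] % 10 == 0:
                steps = {b - a for a, b in zip(col, col[1:])}
                assert steps == {anchor.prices[idx] // 10}

    def test_non_divisible_anchor_rounds_half_up_with_warning(self):
        prices = list(load_anchor_ones())
        with pytest.warns(UserWarning, match="not divisible by 10"):
            t = build_table(AnchorRow(tuple(prices)))
        # 35 -> 5 points multiplies by 0.4: 45*0.4 = 18 exactly; 35->40 is
        # 45*1.1 = 49.5, rounded half-up to 50
        assert t.cell(40, CATEGORIES[0]) == 50

    def test_rejects_invalid_anchor(self):
        with pytest.raises(DomainError):
            AnchorRow(tuple([0] * len(CATEGORIES)))
        with pytest.raises(DomainError):
            AnchorRow(tuple([123] * len(CATEGORIES)))  # not truncated


def load_anchor_ones():
    # a legal (truncated) anchor not divisible by 10: two-digit value 45
    return [45] * len(CATEGORIES)


class TestLookup:
    def test_reads_cells_exactly(self, table_2015_2024):
        assert lookup_base_price(table_2015_2024, 50, "More than 2,000,000") == 104
        assert lookup_base_price(table_2015_2024, 35, "1 to 10") == 141_100

    @pytest.mark.parametrize("points", [37, 0, 55, -5])
    def test_no_interpolation(self, table_2015_2024, points):
        with pytest.raises(DomainError):
            lookup_base_price(table_2015_2024, points, "1 to 10")


class TestVerifyTable:
    def test_published_grids_are_consistent(self, table_2015_2024,
                                            table_2012_2021):
        assert verify_table(table_2015_2024) == []
        assert verify_table(table_2012_2021) == []

    def test_single_perturbed_cell_reported(self, table_2015_2024):
        rows = {p: list(r) for p, r in table_2015_2024.rows.items()}
        rows[20][3] += 1
        perturbed = type(table_2015_2024)(
            anchor=table_2015_2024.anchor,
            provenance=table_2015_2024.provenance,
            rows={p: tuple(r) for p, r in rows.items()})
        report = verify_table(perturbed)
        assert len(report) == 1
        m = report[0]
        assert m.points == 20 and m.category == CATEGORIES[3].label
        assert m.actual == m.expected + 1
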