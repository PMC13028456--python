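"""Listing filters, per-category medians, table rebuild and comparison."""

import datetime

import pytest
from hypothesis import given, strategies as st

from marie.simulate import generate_listings, invert_anchor_targets
from marie.tables import CATEGORIES, DomainError
from marie.update import (FiscalWindow, ListingRecord, compare_tables,
                          compute_category_medians, filter_listings,
                          fiscal_year_of, update_table)

WINDOW = FiscalWindow(2015, 2024)


def rec(drug_id="D", fy=2020, price=1000.0, patients=100, basis="per_day",
        derivable=True):
    return ListingRecord(drug_id, fy, price, patients, basis, derivable)


class TestFiscalYear:
    @pytest.mark.parametrize("date,fy", [
        (datetime.date(2025, 2, 1), 2024),   # Jan-Mar belong to prior FY
        (datetime.date(2025, 4, 1), 2025),
        (datetime.date(2024, 12, 31), 2024),
    ])
    def test_april_start_convention(self, date, fy):
        assert fiscal_year_of(date) == fy

    def test_window_parse(self):
        assert FiscalWindow.parse("FY2015:FY2024") == WINDOW
        assert FiscalWindow.parse("2015-2024") == WINDOW
        with pytest.raises(DomainError):
            FiscalWindow.parse("sometime")


class TestFilterListings:
    @pytest.mark.parametrize("record,reason", [
        (rec(basis="per_treatment"), "per_treatment_basis"),
        (rec(basis="per_season"), "per_season_basis"),
        (rec(derivable=False, price=None), "price_not_stated_or_derivable"),
        (rec(price=None), "price_not_stated_or_derivable"),
        (rec(fy=2012), "outside_window"),
    ])
    def test_exclusion_reasons(self, record, reason):
        included, log = filter_listings([record], WINDOW)
        assert included == []
        assert [e.reason for e in log.exclusions] == [reason]

    def test_all_valid_batch_passes(self):
        batch = [rec(drug_id=f"D{i}") for i in range(20)]
        included, log = filter_listings(batch, WINDOW)
        assert included == batch and len(log) == 0

    @given(st.lists(st.tuples(
        st.integers(min_value=2010, max_value=2027),
        st.sampled_from(["per_day", "per_treatment", "per_season"]),
        st.booleans(), st.booleans())))
    def test_partition_invariant(self, specs):
        records = [rec(drug_id=f"D{i}", fy=fy, basis=basis,
                       derivable=deriv, price=(1000.0 if has_price else None))
                   for i, (fy, basis, deriv, has_price) in enumerate(specs)]
        included, log = filter_listings(records, WINDOW)
        assert len(included) + len(log) == len(records)
        kept_ids = {r.drug_id for r in included}
        excl_ids = {e.drug_id for e in log.exclusions}
        assert kept_ids | excl_ids == {r.drug_id for r in records}
        assert kept_ids & excl_ids == set()


class TestCategoryMedians:
    def test_odd_even_and_singleton(self):
        records = (
            [rec(drug_id=f"A{i}", patients=5, price=p)
             for i, p in enumerate([100, 200, 300])] +
            [rec(drug_id=f"B{i}", patients=50, price=p)
             for i, p in enumerate([100, 201])] +
            [rec(drug_id="C0", patients=200, price=92_513)]
        )
        summaries = {s.category: s for s in compute_category_medians(records)}
        assert summaries["1 to 10"].median == 200          # odd count
        assert summaries["10 to 100"].median == 150        # floored midpoint
        assert summaries["100 to 500"].median == 92_513    # singleton
        assert summaries["500 to 1000"].count == 0
        assert summaries["500 to 1000"].median is None

    def test_empty_categories_flagged_not_filled(self):
        summaries = compute_category_medians([])
        assert all(s.count == 0 and s.median is None for s in summaries)
        assert len(summaries) == len(CATEGORIES)


class TestUpdateTable:
    def _full_records(self, table):
        cfg = invert_anchor_targets(table.anchor, seed=7, n_drugs=3000)
        return generate_listings(cfg)

    def test_reproduces_published_table(self, table_2015_2024):
        records = self._full_records(table_2015_2024)
        table, log, report = update_table(records, WINDOW)
        assert table.anchor == table_2015_2024.anchor
        assert table.rows == dict(table_2015_2024.rows)
        assert report.n_included + report.n_excluded == report.n_input

    def test_filtered_record_does_not_change_result(self, table_2015_2024):
        records = self._full_records(table_2015_2024)
        noisy = records + [rec(drug_id="PERTREAT", basis="per_treatment",
                               price=1e6, patients=3)]
        t_clean, _, _ = update_table(records, WINDOW)
        t_noisy, log, _ = update_table(noisy, WINDOW)
        assert t_noisy.rows == t_clean.rows
        assert log.reasons() == {"per_treatment_basis": 1}

    def test_order_invariance(self, table_2015_2024):
        records = self._full_records(table_2015_2024)
        t_fwd, _, _ = update_table(records, WINDOW)
        t_rev, _, _ = update_table(list(reversed(records)), WINDOW)
        assert t_fwd.rows == t_rev.rows

    def test_empty_category_refused_by_name(self, table_2015_2024):
        records = [r for r in self._full_records(table_2015_2024)
                   if r.max_patients >= 10]  # empty the smallest bin
        with pytest.raises(DomainError, match="1 to 10"):
            update_table(records, WINDOW)


class TestCompareTables:
    def test_published_window_to_window_trends(self, table_2012_2021,
                                               table_2015_2024):
        cmp = compare_tables(table_2012_2021, table_2015_2024)
        ultra = cmp.change("1 to 10")
        assert ultra.old_anchor == 92_500 and ultra.new_anchor == 141_100
        assert ultra.percent_change == pytest.approx(52.5405405)
        assert ultra.percent_change_rounded == 50
        mid = cmp.change("3000 to 5000")
        assert mid.percent_change == pytest.approx(-21.2962963)
        assert mid.percent_change_rounded == -20

    def test_self_comparison_is_zero(self, table_2015_2024):
        cmp = compare_tables(table_2015_2024, table_2015_2024)
        assert all(c.percent_change == 0 and c.percent_change_rounded == 0
                   for c in cmp.changes)

    def test_rebuilt_table_comparison_is_zero(self, table_2015_2024):
        from marie.tables import build_table
        rebuilt = build_table(table_2015_2024.anchor)
        cmp = compare_tables(table_2015_2024, rebuilt)
        assert all(c.percent_change == 0 for c in cmp.changes)
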