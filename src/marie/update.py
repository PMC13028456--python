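"""Rebuilding a conversion table from drug-listing data, and comparing
table versions.

The update pipeline mirrors how the published anchor rows were produced:
keep newly listed drugs inside a 10-year fiscal window whose daily price is
stated (or derivable from dosage and administration) on a per-day basis,
take the median daily price per maximum-patient category, truncate each
median by the fraction-adjustment rule, and extrapolate the full grid from
the resulting anchor row.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .tables import (AnchorRow, CATEGORIES, ConversionTable, DomainError,
                     assign_patient_category, build_table, truncate_anchor)

__all__ = [
    "PriceBasis",
    "ListingRecord",
    "FiscalWindow",
    "fiscal_year_of",
    "ExclusionLog",
    "Exclusion",
    "CategorySummary",
    "UpdateReport",
    "TableComparison",
    "filter_listings",
    "compute_category_medians",
    "update_table",
    "compare_tables",
]

PRICE_BASES = ("per_day", "per_treatment", "per_season")


@dataclass(frozen=True)
class ListingRecord:
    """One drug newly added to the reimbursement price list."""

    drug_id: str
    fiscal_year: int
    daily_price: float | int | None  # JPY/day; None when not stated
    max_patients: int
    price_basis: str  # per_day | per_treatment | per_season
    price_derivable: bool

    def __post_init__(self) -> None:
        if self.price_basis not in PRICE_BASES:
            raise DomainError(
                f"{self.drug_id}: price_basis must be one of {PRICE_BASES}, "
                f"got {self.price_basis!r}")
        if self.daily_price is not None and self.daily_price <= 0:
            raise DomainError(f"{self.drug_id}: daily_price must be positive "
                              f"when present, got {self.daily_price}")
        if self.max_patients < 1:
            raise DomainError(f"{self.drug_id}: max_patients must be >= 1")


@dataclass(frozen=True)
class FiscalWindow:
    """Inclusive range of Japanese fiscal years (each running April–March)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DomainError(f"fiscal window start {self.start} after end {self.end}")

    def __contains__(self, fiscal_year: int) -> bool:
        return self.start <= fiscal_year <= self.end

    def __str__(self) -> str:
        return f"FY{self.start}-FY{self.end}"

    @classmethod
    def parse(cls, text: str) -> "FiscalWindow":
        """Parse "FY2015:FY2024", "FY2015-FY2024" or "2015:2024"."""
        m = re.fullmatch(r"(?:FY)?(\d{4})\s*[:\-]\s*(?:FY)?(\d{4})", text.strip())
        if not m:
            raise DomainError(f"cannot parse fiscal window: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


def fiscal_year_of(date: _dt.date) -> int:
    """Japanese fiscal year of a calendar date (April starts the year:
    2025-02-01 belongs to FY2024)."""
    return date.year if date.month >= 4 else date.year - 1


@dataclass(frozen=True)
class Exclusion:
    drug_id: str
    reason: str  # price_not_stated_or_derivable | per_treatment_basis |
    #              per_season_basis | outside_window


@dataclass(frozen=True)
class ExclusionLog:
    exclusions: tuple[Exclusion, ...]

    def __len__(self) -> int:
        return len(self.exclusions)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.exclusions:
            out[e.reason] = out.get(e.reason, 0) + 1
        return out


def _exclusion_reason(rec: ListingRecord, window: FiscalWindow) -> str | None:
    if rec.fiscal_year not in window:
        return "outside_window"
    if rec.price_basis == "per_treatment":
        return "per_treatment_basis"
    if rec.price_basis == "per_season":
        return "per_season_basis"
    if not rec.price_derivable or rec.daily_price is None:
        return "price_not_stated_or_derivable"
    return None


def filter_listings(records: Iterable[ListingRecord],
                    window: FiscalWindow) -> tuple[list[ListingRecord], ExclusionLog]:
    """Apply the inclusion criteria.

    Kept: listings inside the fiscal window, priced per day, with a stated or
    derivable daily price.  Everything else is logged with a reason, so the
    kept and excluded sets always partition the input.
    """
    included: list[ListingRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        reason = _exclusion_reason(rec, window)
        if reason is None:
            included.append(rec)
        else:
            excluded.append(Exclusion(rec.drug_id, reason))
    return included, ExclusionLog(tuple(excluded))


def _median(values: Sequence[float | int]) -> float | int:
    """Median with the even-count convention used throughout: the mean of the
    two central values floored to an integer (keeps downstream arithmetic
    integral when inputs are integral)."""
    s = sorted(values)
    n = len(s)
    if n == 0:
        raise DomainError("median of empty sample")
    if n % 2 == 1:
        return s[n // 2]
    return math.floor((s[n // 2 - 1] + s[n // 2]) / 2)


@dataclass(frozen=True)
class CategorySummary:
    category: str
    count: int
    median: float | int | None  # None when the category is empty
    anchor: int | None  # truncated median


def compute_category_medians(included: Iterable[ListingRecord]) -> list[CategorySummary]:
    """Median daily price per patient category.

    Empty categories are reported explicitly (median None), never silently
    filled.
    """
    by_cat: dict[str, list[float | int]] = {c.label: [] for c in CATEGORIES}
    for rec in included:
        cat = assign_patient_category(rec.max_patients)
        if rec.daily_price is None:
            raise DomainError(f"{rec.drug_id}: cannot take median of a record "
                              "with no daily price (filter first)")
        by_cat[cat.label].append(rec.daily_price)
    out = []
    for c in CATEGORIES:
        prices = by_cat[c.label]
        if prices:
            med = _median(prices)
            out.append(CategorySummary(c.label, len(prices), med, truncate_anchor(med)))
        else:
            out.append(CategorySummary(c.label, 0, None, None))
    return out


@dataclass(frozen=True)
class UpdateReport:
    window: FiscalWindow
    n_input: int
    n_included: int
    n_excluded: int
    summaries: tuple[CategorySummary, ...]

    def to_dict(self) -> dict:
        return {
            "window": str(self.window),
            "n_input": self.n_input,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "categories": [
                {"category": s.category, "count": s.count,
                 "median": s.median, "anchor": s.anchor}
                for s in self.summaries
            ],
        }


def update_table(records: Iterable[ListingRecord], window: FiscalWindow,
                 provenance: str | None = None,
                 ) -> tuple[ConversionTable, ExclusionLog, UpdateReport]:
    """Full rebuild: filter → per-category medians → truncation → extrapolated
    table.

    Refuses to emit a table when any category has no included listing: a
    partial anchor row is not meaningful.
    """
    records = list(records)
    included, log = filter_listings(records, window)
    summaries = compute_category_medians(included)
    empty = [s.category for s in summaries if s.count == 0]
    if empty:
        raise DomainError(
            "cannot build a conversion table: no included listings in "
            f"categories {empty}")
    anchor = AnchorRow(tuple(s.anchor for s in summaries))  # type: ignore[arg-type]
    table = build_table(anchor, provenance or str(window))
    report = UpdateReport(window=window, n_input=len(records),
                          n_included=len(included), n_excluded=len(log),
                          summaries=tuple(summaries))
    return table, log, report


@dataclass(frozen=True)
class CategoryChange:
    category: str
    old_anchor: int
    new_anchor: int
    percent_change: float
    percent_change_rounded: int  # nearest multiple of 10


@dataclass(frozen=True)
class TableComparison:
    changes: tuple[CategoryChange, ...]

    def change(self, category_label: str) -> CategoryChange:
        for c in self.changes:
            if c.category == category_label:
                return c
        raise DomainError(f"no such category in comparison: {category_label!r}")

    def to_dict(self) -> dict:
        return {
            c.category: {
                "old_anchor": c.old_anchor, "new_anchor": c.new_anchor,
                "percent_change": c.percent_change,
                "percent_change_rounded": c.percent_change_rounded,
            }
            for c in self.changes
        }


def _round_to_nearest_10(x: Fraction) -> int:
    # half away from zero, exact arithmetic
    sign = -1 if x < 0 else 1
    return sign * 10 * math.floor(abs(x) / 10 + Fraction(1, 2))


def compare_tables(old: ConversionTable, new: ConversionTable) -> TableComparison:
    """Per-category percent change of the anchor row between two table
    versions, with a nearest-10% rounding that matches how one-significant-
    figure trends are usually quoted."""
    if old.anchor_points != new.anchor_points:
        raise DomainError("tables use different anchor rows; not comparable")
    changes = []
    for cat, old_a, new_a in zip(CATEGORIES, old.anchor.prices, new.anchor.prices):
        pct = Fraction(100) * Fraction(new_a - old_a, old_a)
        changes.append(CategoryChange(
            category=cat.label, old_anchor=old_a, new_anchor=new_a,
            percent_change=float(pct),
            percent_change_rounded=_round_to_nearest_10(pct)))
    return TableComparison(tuple(changes))
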