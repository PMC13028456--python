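"""Conversion tables mapping (base points, patient category) to a base daily price.

A conversion table is fully determined by its *anchor row*: the truncated
median daily listing price per maximum-patient category, conventionally
placed at 35 base points.  Every other row is an extrapolation — the price
moves by 10% of the anchor for every 5-point step away from the anchor row.
All arithmetic is exact (integers and :class:`fractions.Fraction`) so that
published grids reproduce bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = [
    "PatientCategory",
    "CATEGORIES",
    "AnchorRow",
    "ConversionTable",
    "Mismatch",
    "POINTS_RANGE",
    "ANCHOR_POINTS",
    "STEP_RATE",
    "assign_patient_category",
    "truncate_anchor",
    "build_table",
    "lookup_base_price",
    "verify_table",
]

#: Valid base-point rows of a conversion table.
POINTS_RANGE: tuple[int, ...] = tuple(range(5, 55, 5))

#: Row that holds the data-derived (truncated median) prices.
ANCHOR_POINTS: int = 35

#: Fractional price change per 5-point step away from the anchor row.
STEP_RATE: Fraction = Fraction(1, 10)


class DomainError(ValueError):
    """An input falls outside the framework's defined domain."""


@dataclass(frozen=True, order=False)
class PatientCategory:
    """One maximum-patient bin, a half-open interval [lower, upper).

    ``upper is None`` marks the unbounded top bin.  The half-open convention
    makes the leading number of each printed label inclusive: exactly 10,000
    projected patients falls in "10,000 to 30,000", exactly 2,000,000 in
    "More than 2,000,000".
    """

    label: str
    lower: int
    upper: int | None  # exclusive; None = unbounded

    def __contains__(self, max_patients: int) -> bool:
        if self.upper is None:
            return max_patients >= self.lower
        return self.lower <= max_patients < self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _make_categories() -> tuple[PatientCategory, ...]:
    bounds = [1, 10, 100, 500, 1000, 3000, 5000, 10_000, 30_000, 50_000,
              100_000, 300_000, 500_000, 1_000_000, 2_000_000]

    def fmt(n: int) -> str:
        return f"{n:,}" if n >= 10_000 else str(n)

    cats = []
    for lo, hi in zip(bounds, bounds[1:]):
        cats.append(PatientCategory(f"{fmt(lo)} to {fmt(hi)}", lo, hi))
    cats.append(PatientCategory("More than 2,000,000", 2_000_000, None))
    return tuple(cats)


#: The 15 maximum-patient categories, ordered by increasing patient count.
CATEGORIES: tuple[PatientCategory, ...] = _make_categories()

_BY_LABEL: dict[str, PatientCategory] = {c.label: c for c in CATEGORIES}


def category_by_label(label: str) -> PatientCategory:
    """Return the canonical category carrying *label* (exact match)."""
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise DomainError(f"unknown patient category label: {label!r}") from None


def assign_patient_category(max_patients: int) -> PatientCategory:
    """Bin a maximum-patient count into its category.

    Categories are half-open from below, so a count equal to a printed
    boundary falls in the higher bin.
    """
    if not isinstance(max_patients, int) or isinstance(max_patients, bool):
        raise DomainError(f"max_patients must be an integer, got {max_patients!r}")
    if max_patients < 1:
        raise DomainError(f"max_patients must be >= 1, got {max_patients}")
    for cat in CATEGORIES:
        if max_patients in cat:
            return cat
    raise AssertionError("categories do not cover [1, inf)")  # unreachable


def truncate_anchor(median_price: float | int | Fraction) -> int:
    """Truncate a median daily price for use as an anchor value.

    The fraction-adjustment rule: floor to an integer, then drop the last
    digit of a 3-digit value and the last two digits of a value with 4 or
    more digits.  Values of at most 2 digits pass through unchanged.
    """
    if median_price <= 0:
        raise DomainError(f"median price must be positive, got {median_price}")
    m = math.floor(median_price)
    if m >= 1000:
        return m - m % 100
    if m >= 100:
        return m - m % 10
    return m


@dataclass(frozen=True)
class AnchorRow:
    """Truncated median base daily price (JPY) per category, at the anchor row.

    ``prices`` aligns with :data:`CATEGORIES` (increasing patient count).
    """

    prices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.prices) != len(CATEGORIES):
            raise DomainError(
                f"anchor row needs {len(CATEGORIES)} prices, got {len(self.prices)}"
            )
        for cat, p in zip(CATEGORIES, self.prices):
            if not isinstance(p, int) or isinstance(p, bool) or p <= 0:
                raise DomainError(
                    f"anchor price for {cat.label!r} must be a positive integer, got {p!r}"
                )
            if truncate_anchor(p) != p:
                raise DomainError(
                    f"anchor price {p} for {cat.label!r} violates the truncation rule"
                )

    @classmethod
    def from_mapping(cls, prices: Mapping[str, int]) -> "AnchorRow":
        missing = [c.label for c in CATEGORIES if c.label not in prices]
        if missing:
            raise DomainError(f"anchor mapping missing categories: {missing}")
        extra = set(prices) - set(_BY_LABEL)
        if extra:
            raise DomainError(f"anchor mapping has unknown categories: {sorted(extra)}")
        return cls(tuple(int(prices[c.label]) for c in CATEGORIES))

    def price(self, category: PatientCategory | str) -> int:
        label = category if isinstance(category, str) else category.label
        return self.prices[CATEGORIES.index(category_by_label(label))]

    def as_mapping(self) -> dict[str, int]:
        return {c.label: p for c, p in zip(CATEGORIES, self.prices)}


def _extrapolate(anchor_price: int, points: int,
                 anchor_points: int = ANCHOR_POINTS,
                 step_rate: Fraction = STEP_RATE) -> int | Fraction:
    steps = Fraction(points - anchor_points, 5)
    value = anchor_price * (1 + step_rate * steps)
    if value.denominator == 1:
        return int(value)
    return value


def _round_half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


@dataclass(frozen=True)
class ConversionTable:
    """Grid of base daily prices: one row per base-points value, one column
    per patient category.

    The grid carries no information beyond its anchor row — every cell of a
    consistent table equals ``anchor × (1 + step_rate × (points − anchor_points)/5)``.
    Tables read from files keep the cells as printed so they can be audited
    with :func:`verify_table`.
    """

    anchor: AnchorRow
    provenance: str = ""
    anchor_points: int = ANCHOR_POINTS
    step_rate: Fraction = STEP_RATE
    rows: Mapping[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor_points not in POINTS_RANGE:
            raise DomainError(f"anchor_points must be one of {POINTS_RANGE}")
        if self.step_rate <= 0:
            raise DomainError("step_rate must be positive")

    def expected_cell(self, points: int, category: PatientCategory | str) -> int | Fraction:
        """Anchor-extrapolated value for a cell (exact arithmetic)."""
        a = self.anchor.price(category)
        return _extrapolate(a, points, self.anchor_points, self.step_rate)

    def cell(self, points: int, category: PatientCategory | str) -> int:
        label = category if isinstance(category, str) else category.label
        idx = CATEGORIES.index(category_by_label(label))
        return self.rows[points][idx]


def build_table(anchor: AnchorRow, provenance: str = "",
                anchor_points: int = ANCHOR_POINTS,
                step_rate: Fraction = STEP_RATE) -> ConversionTable:
    """Extrapolate a full conversion table from its anchor row.

    Anchors divisible by 10 give exact integer cells throughout.  A
    user-supplied anchor not divisible by 10 produces fractional cells; those
    are rounded half-up to whole JPY with a warning.
    """
    rows: dict[int, tuple[int, ...]] = {}
    warned = False
    for p in POINTS_RANGE:
        row = []
        for a in anchor.prices:
            v = _extrapolate(a, p, anchor_points, step_rate)
            if isinstance(v, Fraction):
                if not warned:
                    warnings.warn(
                        "anchor not divisible by 10: extrapolated cells rounded "
                        "half-up to integer JPY", stacklevel=2)
                    warned = True
                v = _round_half_up(v)
            if v <= 0:
                raise DomainError(
                    f"extrapolation produced non-positive price at {p} points; "
                    "step_rate/points range inconsistent with anchor_points")
            row.append(v)
        rows[p] = tuple(row)
    return ConversionTable(anchor=anchor, provenance=provenance,
                           anchor_points=anchor_points, step_rate=step_rate,
                           rows=rows)


def lookup_base_price(table: ConversionTable, base_points: int,
                      category: PatientCategory | str) -> int:
    """Read one cell of the table.  No interpolation: *base_points* must be a
    multiple of 5 in [5, 50]."""
    if base_points not in POINTS_RANGE:
        raise DomainError(
            f"base points must be a multiple of 5 in "
            f"[{POINTS_RANGE[0]}, {POINTS_RANGE[-1]}], got {base_points}")
    return table.cell(base_points, category)


@dataclass(frozen=True)
class Mismatch:
    points: int
    category: str
    expected: int | Fraction
    actual: int


def verify_table(table: ConversionTable) -> list[Mismatch]:
    """Audit a table's cells against its anchor row.

    Returns one :class:`Mismatch` per cell that differs from the
    anchor-extrapolated value; an empty list means the grid is internally
    consistent.
    """
    out: list[Mismatch] = []
    for p in POINTS_RANGE:
        if p not in table.rows:
            raise DomainError(f"table has no row for {p} points")
        for cat, actual in zip(CATEGORIES, table.rows[p]):
            expected = table.expected_cell(p, cat)
            if actual != expected:
                out.append(Mismatch(p, cat.label, expected, actual))
    return out
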