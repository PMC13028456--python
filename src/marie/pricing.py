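"""Final daily-price computation: base price from the conversion table, then
a linear premium of 2% of the base price per additional point.

The premium is linear, not compounding: 5 additional points give exactly a
10% uplift, and the 50-point maximum doubles the base price.  Quotes carry
the exact (unrounded) final price; a display value rounded half-up to 0.01
JPY is provided alongside, since reimbursement list prices may carry
fractions of a yen.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Any

from .scoring import ValueAssessment, score_additional, score_base
from .tables import (ConversionTable, DomainError, PatientCategory,
                     assign_patient_category, lookup_base_price)

__all__ = ["PriceQuote", "DEFAULT_PREMIUM_RATE", "apply_premium", "price_drug"]

#: Premium fraction per additional point.
DEFAULT_PREMIUM_RATE: Fraction = Fraction(2, 100)

MAX_ADDITIONAL_POINTS = 50


def _as_fraction(x: float | int | str | Fraction) -> Fraction:
    # route floats through str so 0.02 means the decimal 0.02, not its
    # binary approximation
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


def apply_premium(base_price: int | Fraction,
                  additional_points: int,
                  premium_rate: float | Fraction = DEFAULT_PREMIUM_RATE) -> Fraction:
    """Apply the additional-point premium to a base daily price.

    Returns ``base_price × (1 + premium_rate × additional_points)`` exactly.
    """
    if base_price <= 0:
        raise DomainError(f"base price must be positive, got {base_price}")
    if not isinstance(additional_points, int) or isinstance(additional_points, bool):
        raise DomainError(f"additional points must be an integer, got {additional_points!r}")
    if not 0 <= additional_points <= MAX_ADDITIONAL_POINTS:
        raise DomainError(
            f"additional points must be in [0, {MAX_ADDITIONAL_POINTS}], "
            f"got {additional_points}")
    rate = _as_fraction(premium_rate)
    if rate < 0:
        raise DomainError(f"premium rate must be non-negative, got {premium_rate}")
    return Fraction(base_price) * (1 + rate * additional_points)


@dataclass(frozen=True)
class PriceQuote:
    """Complete pricing result for one drug."""

    drug_id: str
    base_points: int
    additional_points: int
    category: PatientCategory
    base_price: int
    premium_rate: Fraction
    premium_factor: Fraction
    final_price: Fraction  # exact, unrounded

    @property
    def final_price_rounded(self) -> Decimal:
        """Final price rounded half-up to 0.01 JPY, for display."""
        num = Decimal(self.final_price.numerator)
        den = Decimal(self.final_price.denominator)
        return (num / den).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)

    def to_dict(self) -> dict[str, Any]:
        return {
            "drug_id": self.drug_id,
            "base_points": self.base_points,
            "additional_points": self.additional_points,
            "category": self.category.label,
            "base_price": self.base_price,
            "premium_rate": float(self.premium_rate),
            "premium_factor": float(self.premium_factor),
            "final_price": float(self.final_price),
            "final_price_rounded": str(self.final_price_rounded),
        }


def price_drug(assessment: ValueAssessment, max_patients: int,
               table: ConversionTable,
               premium_rate: float | Fraction = DEFAULT_PREMIUM_RATE) -> PriceQuote:
    """Score an assessment and convert it to a final daily price.

    Composes base scoring -> conversion-table lookup -> additional scoring
    -> premium.
    """
    base_points = score_base(assessment)
    additional_points = score_additional(assessment)
    category = assign_patient_category(max_patients)
    base_price = lookup_base_price(table, base_points, category)
    rate = _as_fraction(premium_rate)
    final = apply_premium(base_price, additional_points, rate)
    return PriceQuote(
        drug_id=assessment.drug_id,
        base_points=base_points,
        additional_points=additional_points,
        category=category,
        base_price=base_price,
        premium_rate=rate,
        premium_factor=1 + rate * additional_points,
        final_price=final,
    )
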