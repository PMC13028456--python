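"""Framework constants gathered in one place.

The framework fixes a 2%-per-point premium, a 35-point anchor row, and a
10%-per-5-points extrapolation step, but it is meant to be adapted to other
pricing environments, so all three are carried as configuration rather than
hard-coded logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .tables import ANCHOR_POINTS, DomainError, POINTS_RANGE, STEP_RATE


@dataclass(frozen=True)
class RunConfig:
    """Constants in effect for one run of the framework."""

    premium_rate: Fraction = Fraction(2, 100)  # per additional point
    anchor_points: int = ANCHOR_POINTS
    step_rate: Fraction = STEP_RATE  # per 5 base points
    points_range: tuple[int, ...] = POINTS_RANGE
    display_rounding: str = "0.01-half-up"

    def __post_init__(self) -> None:
        if self.premium_rate <= 0 or self.step_rate <= 0:
            raise DomainError("rates must be positive")
        if self.anchor_points not in self.points_range:
            raise DomainError("anchor_points must lie in points_range")


DEFAULT_CONFIG = RunConfig()
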