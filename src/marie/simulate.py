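"""Synthetic drug-listing datasets with the statistical structure the
table-update procedure expects.

The real source material (council listing documents) is not machine
readable, so the update pipeline is exercised on generated data: each
synthetic drug draws a patient category, a maximum-patient count uniform
within that category's bounds, and a daily price from a log-normal
distribution whose median equals the category's target.  Log-normal noise is
the natural choice for prices spanning tens to hundreds of thousands of
JPY/day; the per-category target medians default to the published
FY2015–FY2024 anchor structure, in which the median daily price rises as the
maximum number of patients falls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tables import AnchorRow, CATEGORIES, DomainError, truncate_anchor
from .update import FiscalWindow, ListingRecord

__all__ = ["SimulationConfig", "config_from_mapping",
           "default_simulation_config", "generate_listings",
           "invert_anchor_targets"]

#: Sampling ceiling for the unbounded top patient category.
DEFAULT_TOP_CATEGORY_CAP = 10_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic listing dataset.

    ``target_medians`` and ``weights`` align with the canonical category
    order (increasing patient count).  ``dispersion`` is the log-scale
    standard deviation of the price noise; ``exclusion_fractions`` give the
    probabilities that a drug is flagged per-treatment, per-season, or
    non-derivable (mutually exclusive, checked in that order).
    """

    seed: int
    n_drugs: int = 372
    window: FiscalWindow = field(default_factory=lambda: FiscalWindow(2015, 2024))
    target_medians: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    dispersion: float = 0.6
    exclusion_fractions: tuple[float, float, float] = (0.005, 0.0025, 0.10)
    top_category_cap: int = DEFAULT_TOP_CATEGORY_CAP

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise DomainError("n_drugs must be >= 1")
        if self.dispersion <= 0:
            raise DomainError("dispersion must be > 0")
        if len(self.target_medians) != len(CATEGORIES):
            raise DomainError(
                f"target_medians must have {len(CATEGORIES)} entries")
        if any(t <= 0 for t in self.target_medians):
            raise DomainError("target medians must be positive")
        if len(self.weights) != len(CATEGORIES):
            raise DomainError(f"weights must have {len(CATEGORIES)} entries")
        if any(w < 0 for w in self.weights) or not math.isclose(
                sum(self.weights), 1.0, rel_tol=1e-9):
            raise DomainError("weights must be non-negative and sum to 1")
        if any(f < 0 for f in self.exclusion_fractions) or \
                sum(self.exclusion_fractions) > 1:
            raise DomainError("exclusion fractions must be non-negative with sum <= 1")
        if self.top_category_cap <= CATEGORIES[-1].lower:
            raise DomainError("top_category_cap must exceed the top bin's lower bound")
        # the empirical trend: price medians fall as patient counts grow.
        # Published anchor rows contain ties and one local inversion, so the
        # check is advisory and only on the extremes: the rarest-disease
        # category should carry the highest target, the largest-population
        # category the lowest.
        if (self.target_medians[0] != max(self.target_medians)
                or self.target_medians[-1] != min(self.target_medians)):
            warnings.warn("target medians do not place the highest price in "
                          "the smallest patient category; the generated data "
                          "will not show the usual price-vs-population trend",
                          stacklevel=2)


def default_simulation_config(seed: int) -> SimulationConfig:
    """The generator's reference conditions: 372 drugs over FY2015–FY2024,
    uniform category weights, log-sd 0.6 price noise around per-category
    targets matching the published FY2015–FY2024 anchor structure, and small
    exclusion fractions (≈0.5% per-treatment, ≈0.25% per-season, ≈10%
    price-not-derivable, the rough shares seen in real listing rounds)."""
    from .io import load_reference_table  # local import: io is a consumer too
    anchor = load_reference_table("FY2015-FY2024").anchor
    k = len(CATEGORIES)
    return SimulationConfig(
        seed=seed,
        target_medians=tuple(_preimage_midpoint(a) for a in anchor.prices),
        weights=tuple([1.0 / k] * k),
    )


def config_from_mapping(doc: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/JSON document.

    ``target_medians`` and ``weights`` may be lists in canonical category
    order (increasing patient count) or mappings keyed by category label;
    ``window`` is a string like "FY2015:FY2024".  ``seed`` is mandatory.
    """
    if "seed" not in doc:
        raise DomainError("simulation config must set a seed")

    def per_category(value, name):
        if isinstance(value, dict):
            missing = [c.label for c in CATEGORIES if c.label not in value]
            if missing:
                raise DomainError(f"{name} missing categories: {missing}")
            return tuple(float(value[c.label]) for c in CATEGORIES)
        return tuple(float(v) for v in value)

    kwargs: dict = {"seed": int(doc["seed"])}
    if "n_drugs" in doc:
        kwargs["n_drugs"] = int(doc["n_drugs"])
    if "window" in doc:
        w = doc["window"]
        kwargs["window"] = (FiscalWindow.parse(w) if isinstance(w, str)
                            else FiscalWindow(int(w[0]), int(w[1])))
    if "target_medians" in doc:
        kwargs["target_medians"] = per_category(doc["target_medians"],
                                                "target_medians")
    if "weights" in doc:
        kwargs["weights"] = per_category(doc["weights"], "weights")
    if "dispersion" in doc:
        kwargs["dispersion"] = float(doc["dispersion"])
    if "exclusion_fractions" in doc:
        f = doc["exclusion_fractions"]
        if isinstance(f, dict):
            kwargs["exclusion_fractions"] = (
                float(f.get("per_treatment", 0.0)),
                float(f.get("per_season", 0.0)),
                float(f.get("not_derivable", 0.0)))
        else:
            kwargs["exclusion_fractions"] = tuple(float(v) for v in f)
    if "top_category_cap" in doc:
        kwargs["top_category_cap"] = int(doc["top_category_cap"])
    unknown = set(doc) - {"seed", "n_drugs", "window", "target_medians",
                          "weights", "dispersion", "exclusion_fractions",
                          "top_category_cap"}
    if unknown:
        raise DomainError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)


def generate_listings(config: SimulationConfig) -> list[ListingRecord]:
    """Draw a reproducible synthetic listing dataset.

    For a fixed config (seed included) the output is identical call to call.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_drugs
    cat_idx = rng.choice(len(CATEGORIES), size=n, p=np.asarray(config.weights))
    z = rng.standard_normal(n)
    u_flags = rng.random(n)
    years = rng.integers(config.window.start, config.window.end + 1, size=n)

    f_treat, f_season, f_nonderiv = config.exclusion_fractions
    records: list[ListingRecord] = []
    for i in range(n):
        cat = CATEGORIES[int(cat_idx[i])]
        hi = cat.upper if cat.upper is not None else config.top_category_cap + 1
        max_patients = int(rng.integers(cat.lower, hi))
        price = float(config.target_medians[int(cat_idx[i])] *
                      math.exp(config.dispersion * float(z[i])))
        basis = "per_day"
        derivable = True
        daily_price: float | None = price
        u = float(u_flags[i])
        if u < f_treat:
            basis = "per_treatment"
        elif u < f_treat + f_season:
            basis = "per_season"
        elif u < f_treat + f_season + f_nonderiv:
            derivable = False
            daily_price = None
        records.append(ListingRecord(
            drug_id=f"SYN-{i:05d}", fiscal_year=int(years[i]),
            daily_price=daily_price, max_patients=max_patients,
            price_basis=basis, price_derivable=derivable))
    return records


def _preimage_midpoint(anchor_value: int) -> float:
    """Centre of the interval of medians that truncate to *anchor_value*.

    Truncation floors 3-digit values to a multiple of 10 and >=4-digit values
    to a multiple of 100; a target at the centre of the preimage keeps the
    empirical median safely inside it under small sampling noise.
    """
    if anchor_value >= 1000:
        return anchor_value + 50.0
    if anchor_value >= 100:
        return anchor_value + 5.0
    return anchor_value + 0.5


def invert_anchor_targets(anchor: AnchorRow, seed: int = 0,
                          n_drugs: int = 10_000,
                          dispersion: float = 1e-9,
                          window: FiscalWindow | None = None) -> SimulationConfig:
    """Build a config whose generated data reconstructs *anchor* exactly.

    Target medians are placed at the midpoint of each anchor value's
    truncation preimage, category weights are uniform, exclusion fractions
    zero, and the dispersion near-degenerate, so the per-category sample
    medians truncate back to the anchor for any seed once every category is
    populated.
    """
    targets = tuple(_preimage_midpoint(a) for a in anchor.prices)
    for t, a in zip(targets, anchor.prices):
        assert truncate_anchor(t) == a
    k = len(CATEGORIES)
    return SimulationConfig(
        seed=seed, n_drugs=n_drugs,
        window=window or FiscalWindow(2015, 2024),
        target_medians=targets,
        weights=tuple([1.0 / k] * k),
        dispersion=dispersion,
        exclusion_fractions=(0.0, 0.0, 0.0),
    )
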