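"""Ecosystem-service metrics: monthly PM absorption and Shannon diversity.

Monthly particulate-matter absorption (MPA) of a site is the sum over
species of tree count times per-tree monthly absorption. In *flat* mode
the per-tree monthly absorption is simply the annual rate divided by 12;
in *seasonal* mode it is the annual rate times the species' weight for
the current calendar month, so deciduous species absorb little or nothing
in their leaf-off winter months while evergreens keep absorbing. The
twelve weights of every species sum to 1, so flat and seasonal modes
agree on any whole-year total.

Seasonal weights are parameterized shapes derived from leaf-phenology
patterns (leaf-area-index seasonality): a leaf-on window with optional
ramp months for deciduous species, and a year-round plateau with a damped
winter level for evergreens.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .params import SiteComposition, SpeciesParams, ValidationError, species_index, validate_composition

__all__ = [
    "SeasonalProfileParams",
    "MetricsRecord",
    "WINTER_MONTHS",
    "monthly_pm_absorption",
    "seasonal_weights",
    "apply_seasonal_profile",
    "shannon_index",
    "winter_mean_absorption",
]

#: Northern-hemisphere meteorological winter (December, January, February).
WINTER_MONTHS: frozenset[int] = frozenset({12, 1, 2})

MODES = ("flat", "seasonal")


@dataclass(frozen=True)
class SeasonalProfileParams:
    """Shape parameters for phenology-driven monthly absorption weights.

    Defaults: deciduous leaf-on April–November with one transition month
    at each end; evergreen winter absorption at 60% of the summer level.
    """

    leaf_on_start_month: int = 4
    leaf_on_end_month: int = 11
    ramp_months: int = 1
    evergreen_winter_fraction: float = 0.6

    def __post_init__(self) -> None:
        for m in (self.leaf_on_start_month, self.leaf_on_end_month):
            if not (1 <= m <= 12):
                raise ValidationError(f"calendar months must be in 1..12, got {m}")
        if self.leaf_on_start_month > self.leaf_on_end_month:
            raise ValidationError(
                "leaf-on window must not wrap the year "
                f"(start {self.leaf_on_start_month} > end {self.leaf_on_end_month})"
            )
        if self.ramp_months < 0:
            raise ValidationError("ramp_months must be >= 0")
        if not (0 < self.evergreen_winter_fraction <= 1):
            raise ValidationError("evergreen_winter_fraction must be in (0, 1]")


@dataclass(frozen=True)
class MetricsRecord:
    """One month of simulated metrics."""

    month_index: int
    calendar_month: int
    mpa_g: float
    shannon: float

    def __post_init__(self) -> None:
        if not (1 <= self.calendar_month <= 12):
            raise ValidationError("calendar_month must be in 1..12")
        if self.mpa_g < 0:
            raise ValidationError("mpa_g must be >= 0")
        if self.shannon < 0:
            raise ValidationError("shannon must be >= 0")


def monthly_pm_absorption(
    composition: SiteComposition | Mapping[str, float],
    species: Mapping[str, SpeciesParams] | Sequence[SpeciesParams],
    calendar_month: int | None = None,
    mode: str = "flat",
) -> float:
    """Total PM absorbed by the site in one month, in grams.

    ``flat`` mode: sum of count * annual_rate / 12. ``seasonal`` mode:
    sum of count * annual_rate * monthly_weight[calendar_month], which
    requires ``calendar_month``. Every species in the composition must
    have parameters.
    """
    composition = validate_composition(composition)
    index = species_index(species)
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "seasonal":
        if calendar_month is None:
            raise ValidationError("seasonal mode requires calendar_month")
        if not (1 <= calendar_month <= 12):
            raise ValidationError("calendar_month must be in 1..12")
    total = 0.0
    for sp, count in composition.items():
        if sp not in index:
            raise ValidationError(f"no parameters for species {sp!r}")
        p = index[sp]
        if mode == "flat":
            total += count * p.annual_pm_g / 12.0
        else:
            total += count * p.annual_pm_g * p.monthly_weights[calendar_month - 1]
    return total


def seasonal_weights(
    phenology: str, profile: SeasonalProfileParams | None = None
) -> tuple[float, ...]:
    """Twelve monthly absorption weights for a phenology class.

    Deciduous: zero weight outside the leaf-on window; inside the window
    a plateau at full level, with the first and last ``ramp_months``
    months linearly ramped (a 1-month ramp puts the edge months at half
    level). Evergreen: full level outside winter, damped to
    ``evergreen_winter_fraction`` in December–February. Both shapes are
    normalized to sum to 1.
    """
    profile = profile or SeasonalProfileParams()
    if phenology == "deciduous":
        start, end = profile.leaf_on_start_month, profile.leaf_on_end_month
        window = list(range(start, end + 1))
        ramp = profile.ramp_months
        if 2 * ramp >= len(window):
            raise ValidationError(
                f"ramp_months={ramp} leaves no plateau in a "
                f"{len(window)}-month leaf-on window"
            )
        levels = np.zeros(12)
        for j, m in enumerate(window):
            up = (j + 1) / (ramp + 1)
            down = (len(window) - j) / (ramp + 1)
            levels[m - 1] = min(1.0, up, down)
    elif phenology == "evergreen":
        levels = np.ones(12)
        for m in WINTER_MONTHS:
            levels[m - 1] = profile.evergreen_winter_fraction
    else:
        raise ValidationError(f"unknown phenology {phenology!r}")
    total = levels.sum()
    if total <= 0:
        raise ValidationError("seasonal profile has zero total weight")
    return tuple(float(w) for w in levels / total)


def apply_seasonal_profile(
    species: Sequence[SpeciesParams] | Mapping[str, SpeciesParams],
    profile: SeasonalProfileParams | None = None,
) -> tuple[SpeciesParams, ...]:
    """Return a species table whose weights follow the seasonal profile."""
    index = species_index(species)
    profile = profile or SeasonalProfileParams()
    return tuple(
        SpeciesParams(
            species_id=p.species_id,
            annual_pm_g=p.annual_pm_g,
            phenology=p.phenology,
            monthly_weights=seasonal_weights(p.phenology, profile),
        )
        for p in index.values()
    )


def shannon_index(
    composition: SiteComposition | Mapping[str, float], base: float = math.e
) -> float:
    """Shannon diversity index H = -sum p_i log(p_i) of the composition.

    Natural logarithm by default (``base`` is configurable for
    sensitivity runs); species with zero count contribute nothing
    (0 log 0 := 0). Requires at least one tree. Bounded by log(k) for k
    positive-count species and invariant to rescaling all counts.
    """
    composition = validate_composition(composition)
    total = composition.total()
    if total <= 0:
        raise ValidationError("Shannon index undefined for a site with 0 trees")
    h = 0.0
    for count in composition.values():
        if count > 0:
            p = count / total
            h -= p * math.log(p)
    if base != math.e:
        h /= math.log(base)
    # guard against -0.0 from a single-species site
    return abs(h) if h == 0 else h


def winter_mean_absorption(records: Iterable[MetricsRecord]) -> float:
    """Mean monthly PM absorption over winter months (Dec, Jan, Feb)."""
    values = [r.mpa_g for r in records if r.calendar_month in WINTER_MONTHS]
    if not values:
        raise ValidationError("trajectory contains no winter months")
    return float(np.mean(values))
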