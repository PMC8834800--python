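"""Species parameters and site composition types.

The simulation tracks a street-tree site as continuous per-species tree
counts (the stocks of the stock-flow model). Each species carries an annual
per-tree particulate-matter (PM) absorption rate, a phenology class
(deciduous or evergreen), and a 12-entry vector of monthly absorption
weights that distributes the annual total over the calendar year.

The bundled default parameter table holds the per-species annual PM
absorption rates measured for common Korean urban street trees
(leaf-sampling estimates), plus a pooled "other species" category
at the national per-tree average of 35.7 g/year.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "ValidationError",
    "SpeciesParams",
    "SiteComposition",
    "FLAT_WEIGHTS",
    "default_species_table",
    "species_index",
    "validate_composition",
]

#: Uniform monthly weights: the annual rate is spread evenly over 12 months.
FLAT_WEIGHTS: tuple[float, ...] = tuple([1.0 / 12.0] * 12)

PHENOLOGIES = ("deciduous", "evergreen")

_WEIGHT_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species parameters of the absorption model.

    Parameters
    ----------
    species_id
        Short label used as the key everywhere (compositions, policies,
        output columns).
    annual_pm_g
        PM absorbed by one tree of this species per year, in grams.
    phenology
        ``"deciduous"`` or ``"evergreen"``; drives the seasonal profile.
    monthly_weights
        Twelve non-negative fractions, one per calendar month (January
        first), summing to 1 so that the monthly absorptions over a full
        year recover the annual total exactly.
    """

    species_id: str
    annual_pm_g: float
    phenology: str = "deciduous"
    monthly_weights: tuple[float, ...] = FLAT_WEIGHTS

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be a non-empty string")
        if not math.isfinite(self.annual_pm_g) or self.annual_pm_g < 0:
            raise ValidationError(
                f"annual_pm_g for {self.species_id!r} must be finite and >= 0, "
                f"got {self.annual_pm_g!r}"
            )
        if self.phenology not in PHENOLOGIES:
            raise ValidationError(
                f"phenology for {self.species_id!r} must be one of {PHENOLOGIES}, "
                f"got {self.phenology!r}"
            )
        weights = tuple(float(w) for w in self.monthly_weights)
        object.__setattr__(self, "monthly_weights", weights)
        if len(weights) != 12:
            raise ValidationError(
                f"monthly_weights for {self.species_id!r} must have 12 entries"
            )
        if any(w < 0 or not math.isfinite(w) for w in weights):
            raise ValidationError(
                f"monthly_weights for {self.species_id!r} must be non-negative"
            )
        if abs(sum(weights) - 1.0) > _WEIGHT_SUM_TOL:
            raise ValidationError(
                f"monthly_weights for {self.species_id!r} must sum to 1 "
                f"(got {sum(weights)!r})"
            )


@dataclass(frozen=True)
class SiteComposition(Mapping):
    """Continuous per-species tree counts at a site.

    Counts are real numbers, not integers: the replacement flow (total
    divided by the replacement period, e.g. 208/240 trees per month) is
    fractional, and the stocks accumulate it. Rounding to whole trees
    happens only in reports.

    Behaves as a read-only mapping ``species_id -> count``; iteration
    preserves insertion order.
    """

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for sp, n in self.counts.items():
            try:
                val = float(n)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"count for species {sp!r} is not numeric: {n!r}"
                ) from None
            if not math.isfinite(val) or val < 0:
                raise ValidationError(
                    f"count for species {sp!r} must be finite and >= 0, got {n!r}"
                )
            clean[str(sp)] = val
        object.__setattr__(self, "counts", clean)

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, species: str) -> float:
        return self.counts[species]

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    # Domain helpers ---------------------------------------------------
    def total(self) -> float:
        """Total number of trees at the site."""
        return sum(self.counts.values())

    def species(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def proportions(self) -> dict[str, float]:
        """Species shares p_i = count_i / total; requires a non-empty site."""
        tot = self.total()
        if tot <= 0:
            raise ValidationError("proportions undefined for a site with 0 trees")
        return {sp: n / tot for sp, n in self.counts.items()}


def validate_composition(counts: Mapping[str, float] | SiteComposition) -> SiteComposition:
    """Validate a species->count mapping and return a :class:`SiteComposition`.

    Idempotent: validating an already-validated composition returns an
    equal composition and preserves totals exactly.
    """
    if isinstance(counts, SiteComposition):
        return SiteComposition(counts.counts)
    return SiteComposition(counts)


# Species identifiers of the bundled default table.
ZELKOVA = "zelkova_serrata"
PRUNUS = "prunus_yedoensis"
PINUS = "pinus_densiflora"
OTHER = "other"


def default_species_table() -> tuple[SpeciesParams, ...]:
    """The bundled street-tree parameter set.

    Annual per-tree PM absorption (g/tree/year): Zelkova serrata 66.6,
    Prunus yedoensis 45.3, Pinus densiflora 24.2, and a pooled "other
    species" category at the Korean national per-tree estimate of 35.7.
    Pinus densiflora is evergreen; the rest (including the pooled
    category) are treated as deciduous. Monthly weights default to the
    flat 1/12 profile; seasonal profiles are applied separately (see
    :mod:`arborsim.metrics`).
    """
    return (
        SpeciesParams(ZELKOVA, 66.6, "deciduous"),
        SpeciesParams(PRUNUS, 45.3, "deciduous"),
        SpeciesParams(PINUS, 24.2, "evergreen"),
        SpeciesParams(OTHER, 35.7, "deciduous"),
    )


def species_index(
    species: Mapping[str, SpeciesParams] | tuple[SpeciesParams, ...] | list[SpeciesParams],
) -> dict[str, SpeciesParams]:
    """Index a species collection by ``species_id``."""
    if isinstance(species, Mapping):
        return dict(species)
    out: dict[str, SpeciesParams] = {}
    for sp in species:
        if sp.species_id in out:
            raise ValidationError(f"duplicate species_id {sp.species_id!r}")
        out[sp.species_id] = sp
    return out
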