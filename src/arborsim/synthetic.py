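"""Seeded generators for synthetic sites, species tables and policies.

These exist so every pipeline stage can be property-tested without any
external data: random species parameter sets (log-normal annual
absorption centered on the 35.7 g/tree/year national per-tree estimate),
random site compositions (Dirichlet split of a fixed total), and random
planting policies. Each operation takes an explicit seed; there is no
global RNG state. The distributional families are declared test
conventions, not scientific claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import POLICY_MODES, PlantingPolicy
from .params import SiteComposition, SpeciesParams, ValidationError

__all__ = ["SyntheticSpec", "generate_species", "generate_site", "generate_policy"]

#: National per-tree annual PM absorption estimate, g/tree/year.
DEFAULT_ANNUAL_PM_MEDIAN = 35.7


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic site/species bundle."""

    seed: int
    n_species: int = 4
    total_trees: float = 208.0
    composition_concentration: float = 1.0
    absorption_log_mean: float = math.log(DEFAULT_ANNUAL_PM_MEDIAN)
    absorption_log_sd: float = 0.5
    evergreen_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if not (self.total_trees > 0):
            raise ValidationError("total_trees must be > 0")
        if not (self.composition_concentration > 0):
            raise ValidationError("composition_concentration must be > 0")
        if self.absorption_log_sd < 0:
            raise ValidationError("absorption_log_sd must be >= 0")
        if not (0.0 <= self.evergreen_prob <= 1.0):
            raise ValidationError("evergreen_prob must be in [0, 1]")


def _species_ids(n: int) -> list[str]:
    return [f"sp{i:02d}" for i in range(1, n + 1)]


def generate_species(spec: SyntheticSpec) -> tuple[SpeciesParams, ...]:
    """Draw a reproducible species parameter table.

    Annual absorption is log-normal (median ``exp(absorption_log_mean)``,
    defaulting to 35.7 g/tree/year); each species is evergreen with
    probability ``evergreen_prob``; weights start flat.
    """
    rng = np.random.default_rng(spec.seed)
    rates = np.exp(rng.normal(spec.absorption_log_mean, spec.absorption_log_sd, spec.n_species))
    evergreen = rng.random(spec.n_species) < spec.evergreen_prob
    return tuple(
        SpeciesParams(sid, float(rate), "evergreen" if ever else "deciduous")
        for sid, rate, ever in zip(_species_ids(spec.n_species), rates, evergreen)
    )


def generate_site(
    spec: SyntheticSpec, species: tuple[SpeciesParams, ...]
) -> SiteComposition:
    """Split ``total_trees`` across the species by a Dirichlet draw.

    The symmetric concentration parameter controls evenness: large values
    approach an equal split, values below 1 favor skewed sites.
    """
    rng = np.random.default_rng(spec.seed + 1)
    shares = rng.dirichlet([spec.composition_concentration] * len(species))
    return SiteComposition(
        {p.species_id: float(spec.total_trees * s) for p, s in zip(species, shares)}
    )


def generate_policy(seed: int, species: tuple[SpeciesParams, ...]) -> PlantingPolicy:
    """Draw a random valid planting policy over the given species."""
    if not species:
        raise ValidationError("need at least one species")
    rng = np.random.default_rng(seed)
    mode = POLICY_MODES[rng.integers(len(POLICY_MODES))]
    if mode == "status_quo":
        return PlantingPolicy("status_quo")
    if mode == "single_priority":
        target = species[rng.integers(len(species))].species_id
        return PlantingPolicy(
            "single_priority", priority_species=target, target_ratio=float(rng.random())
        )
    shares = rng.dirichlet([1.0] * len(species))
    shares = shares / shares.sum()
    return PlantingPolicy(
        "fixed_mix", mix={p.species_id: float(s) for p, s in zip(species, shares)}
    )
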