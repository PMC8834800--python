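"""Stock-flow turnover dynamics of a street-tree population.

The model is the standard system-dynamics formulation of a replaced
population: each species' tree count is a stock, trees retire at the end
of a replacement cycle, and every retired tree is immediately replaced by
a newly planted one, so the site total is conserved. What changes over
time is *which* species the replacements are, governed by a planting
policy:

``status_quo``
    Each retired tree is replaced by the same species, i.e. plantings are
    split across species in proportion to the current composition. The
    composition is a fixed point of this policy.

``single_priority``
    A designated priority species receives a fixed target fraction ``r``
    of all plantings; the remaining ``1 - r`` is split over the other
    species in proportion to their current counts (excluding the priority
    species). The priority species' stock relaxes exponentially toward
    ``r`` times the site total.

``fixed_mix``
    Plantings follow a fixed species distribution (e.g. 30/30/30/10),
    pulling the composition toward that mix.

Turnover scheduling: the default (and recommended) mode is first-order
turnover — the retirement outflow of each species is its stock divided by
the replacement period, the standard stock-flow convention when no age
census exists. An optional ``cohort`` mode retires the *initial* stock at
a constant rate over exactly one replacement period (uniform age spread)
for sensitivity analysis; trees planted during the run are not retired
again within the horizon in that mode.

Integration is explicit Euler with a 1-month step by default; the whole
module is deterministic (no random numbers anywhere).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .params import SiteComposition, ValidationError, validate_composition

__all__ = [
    "PlantingPolicy",
    "TurnoverSettings",
    "retirement_flow",
    "allocate_plantings",
    "step",
    "closed_form_priority_share",
    "run_dynamics",
]

logger = logging.getLogger(__name__)

POLICY_MODES = ("status_quo", "single_priority", "fixed_mix")
TURNOVER_MODES = ("first_order", "cohort")

_MIX_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PlantingPolicy:
    """Rule that allocates replacement plantings across species.

    Parameters
    ----------
    mode
        One of ``status_quo``, ``single_priority``, ``fixed_mix``.
    priority_species
        Required for ``single_priority``: the species receiving the
        target fraction of plantings.
    target_ratio
        Fraction of plantings reserved for the priority species, in
        [0, 1]. Default 0.7.
    mix
        Required for ``fixed_mix``: mapping species -> planting fraction,
        non-negative and summing to 1.
    """

    mode: str
    priority_species: str | None = None
    target_ratio: float = 0.7
    mix: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in POLICY_MODES:
            raise ValidationError(
                f"policy mode must be one of {POLICY_MODES}, got {self.mode!r}"
            )
        if self.mode == "single_priority":
            if not self.priority_species:
                raise ValidationError("single_priority policy needs priority_species")
            if not (0.0 <= self.target_ratio <= 1.0):
                raise ValidationError(
                    f"target_ratio must lie in [0, 1], got {self.target_ratio!r}"
                )
        if self.mode == "fixed_mix":
            if not self.mix:
                raise ValidationError("fixed_mix policy needs a mix mapping")
            mix = {str(k): float(v) for k, v in self.mix.items()}
            if any(v < 0 or not math.isfinite(v) for v in mix.values()):
                raise ValidationError("mix fractions must be non-negative and finite")
            if abs(sum(mix.values()) - 1.0) > _MIX_SUM_TOL:
                raise ValidationError(
                    f"mix fractions must sum to 1, got {sum(mix.values())!r}"
                )
            object.__setattr__(self, "mix", mix)


@dataclass(frozen=True)
class TurnoverSettings:
    """Replacement-cycle settings.

    ``replacement_period_months`` defaults to 240 (a 20-year cycle);
    ``dt_months`` is the Euler step, default 1 month. ``turnover`` selects
    the scheduling mode (``first_order`` default, ``cohort`` optional).
    """

    replacement_period_months: float = 240.0
    dt_months: float = 1.0
    turnover: str = "first_order"

    def __post_init__(self) -> None:
        if not (self.replacement_period_months > 0):
            raise ValidationError("replacement_period_months must be > 0")
        if not (0 < self.dt_months <= self.replacement_period_months):
            raise ValidationError(
                "dt_months must satisfy 0 < dt <= replacement_period_months"
            )
        if self.turnover not in TURNOVER_MODES:
            raise ValidationError(
                f"turnover must be one of {TURNOVER_MODES}, got {self.turnover!r}"
            )


def retirement_flow(
    composition: SiteComposition, settings: TurnoverSettings
) -> dict[str, float]:
    """First-order retirement outflow, in trees per month per species.

    Each species loses ``count / replacement_period`` trees per month, so
    the total outflow is ``total / period`` (e.g. 208/240 ≈ 0.867 trees
    per month for a 208-tree site on a 20-year cycle).
    """
    composition = validate_composition(composition)
    T = settings.replacement_period_months
    return {sp: n / T for sp, n in composition.items()}


def allocate_plantings(
    total_replacements: float,
    composition: SiteComposition,
    policy: PlantingPolicy,
) -> dict[str, float]:
    """Split a planting flow across species according to the policy.

    Returns trees per month per species; the allocations always sum to
    ``total_replacements`` (to within floating-point round-off). Species
    that can receive plantings but are currently absent must appear in the
    composition with a zero count (scenario builders do this for you).
    """
    composition = validate_composition(composition)
    if total_replacements < 0:
        raise ValidationError("total_replacements must be >= 0")
    species = composition.species()
    if policy.mode == "fixed_mix":
        # mix may introduce species not yet present at the site
        out = {sp: 0.0 for sp in species}
        for sp, frac in policy.mix.items():  # type: ignore[union-attr]
            out[sp] = total_replacements * frac
        return out
    if total_replacements == 0:
        return {sp: 0.0 for sp in species}

    total = composition.total()
    if policy.mode == "status_quo":
        if total <= 0:
            raise ValidationError(
                "status_quo allocation undefined for an empty site"
            )
        return {sp: total_replacements * n / total for sp, n in composition.items()}

    # single_priority
    b = policy.priority_species
    if b not in composition:
        raise ValidationError(
            f"priority species {b!r} not among site species {list(species)}"
        )
    if total <= 0:
        raise ValidationError(
            "single_priority allocation undefined for an empty site"
        )
    r = policy.target_ratio
    out = {sp: 0.0 for sp in species}
    out[b] = r * total_replacements
    remainder = (1.0 - r) * total_replacements
    rest_total = sum(n for sp, n in composition.items() if sp != b)
    if remainder > 0:
        if rest_total > 0:
            for sp, n in composition.items():
                if sp != b:
                    out[sp] = remainder * n / rest_total
        else:
            # degenerate single-species site: nothing to split the
            # remainder over, so it goes to the priority species too
            logger.debug(
                "no non-priority trees present; remainder %.6g assigned to %r",
                remainder,
                b,
            )
            out[b] += remainder
    return out


def step(
    composition: SiteComposition,
    policy: PlantingPolicy,
    settings: TurnoverSettings,
) -> SiteComposition:
    """One explicit-Euler step of first-order turnover under a policy.

    ``count_i' = count_i + (planting_i - retirement_i) * dt``. The total
    is conserved because plantings exactly balance retirements; any
    negative count produced by floating-point round-off is clipped to 0
    with a warning.
    """
    composition = validate_composition(composition)
    retire = retirement_flow(composition, settings)
    total_rep = sum(retire.values())
    plant = allocate_plantings(total_rep, composition, policy)
    dt = settings.dt_months
    new: dict[str, float] = {}
    for sp in composition:
        val = composition[sp] + (plant.get(sp, 0.0) - retire[sp]) * dt
        if val < 0:
            logger.warning(
                "count for %r dipped below zero (%.3e); clipping to 0", sp, val
            )
            val = 0.0
        new[sp] = val
    return SiteComposition(new)


def closed_form_priority_share(
    t_months: float, b0: float, r: float, n_total: float, period_months: float
) -> float:
    """Exact continuous-time stock of the priority species.

    Under single-priority replacement with continuous first-order
    turnover, the priority species' stock obeys a linear ODE whose
    solution is

        B(t) = r N + (B0 - r N) exp(-t / T)

    i.e. exponential relaxation from the initial stock toward the target
    share ``r`` of the site total. Used as an independent verification
    oracle for the Euler integrator.
    """
    if not (period_months > 0):
        raise ValidationError("period_months must be > 0")
    equilibrium = r * n_total
    return equilibrium + (b0 - equilibrium) * math.exp(-t_months / period_months)


def run_dynamics(
    initial: SiteComposition,
    policy: PlantingPolicy,
    settings: TurnoverSettings,
    horizon_months: int,
) -> list[SiteComposition]:
    """Simulate the composition forward and return all snapshots.

    Returns ``horizon_months + 1`` compositions, the initial state first.
    Deterministic; total tree count is conserved at every step.

    In ``cohort`` turnover mode the initial stock retires linearly over
    one replacement period (uniform age spread); replacements planted
    during the run are assumed not to retire again within the horizon.
    """
    initial = validate_composition(initial)
    if horizon_months < 1:
        raise ValidationError("horizon_months must be >= 1")
    if settings.turnover == "first_order":
        out = [initial]
        current = initial
        for _ in range(horizon_months):
            current = step(current, policy, settings)
            out.append(current)
        return out
    return _run_cohort(initial, policy, settings, horizon_months)


def _run_cohort(
    initial: SiteComposition,
    policy: PlantingPolicy,
    settings: TurnoverSettings,
    horizon_months: int,
) -> list[SiteComposition]:
    T = settings.replacement_period_months
    dt = settings.dt_months
    out = [initial]
    current = dict(initial.counts)
    # remaining trees of the original (pre-simulation) cohort per species
    remaining = dict(initial.counts)
    for _ in range(horizon_months):
        retire = {
            sp: min(remaining[sp], initial[sp] * dt / T) for sp in remaining
        }
        total_rep = sum(retire.values())
        plant = allocate_plantings(
            total_rep / dt if dt else 0.0, SiteComposition(current), policy
        )
        for sp in current:
            val = current[sp] + plant.get(sp, 0.0) * dt - retire[sp]
            current[sp] = max(val, 0.0)
            remaining[sp] -= retire[sp]
        out.append(SiteComposition(current))
    return out
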