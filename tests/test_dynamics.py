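import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from arborsim.dynamics import (
    PlantingPolicy,
    TurnoverSettings,
    allocate_plantings,
    closed_form_priority_share,
    retirement_flow,
    run_dynamics,
    step,
)
from arborsim.params import ValidationError, validate_composition

SETTINGS = TurnoverSettings()  # 240-month cycle, 1-month Euler step

Z, P, PI, O = "zelkova_serrata", "prunus_yedoensis", "pinus_densiflora", "other"


def priority(sp, r=0.7):
    return PlantingPolicy("single_priority", priority_species=sp, target_ratio=r)


compositions = st.dictionaries(
    st.sampled_from(["a", "b", "c", "d", "e"]),
    st.floats(0, 1e4, allow_nan=False),
    min_size=1,
    max_size=5,
)


# --- retirement -----------------------------------------------------------


def test_retirement_total_is_stock_over_period(base_composition):
    flow = retirement_flow(base_composition, SETTINGS)
    assert math.isclose(sum(flow.values()), 208 / 240)


def test_retirement_unit_ratio():
    flow = retirement_flow(validate_composition({Z: 240}), SETTINGS)
    assert flow == {Z: 1.0}


def test_retirement_empty_site_is_zero():
    assert retirement_flow(validate_composition({}), SETTINGS) == {}


# --- allocation -----------------------------------------------------------


def test_status_quo_reproduces_composition_shape():
    comp = validate_composition({Z: 6, P: 3, O: 3})
    alloc = allocate_plantings(12, comp, PlantingPolicy("status_quo"))
    assert alloc == {Z: 6, P: 3, O: 3}


def test_single_priority_hand_worked_allocation(base_composition):
    """Priority species gets r*total; the remainder is split over the
    other species in proportion to their counts (hand-derived values)."""
    alloc = allocate_plantings(10, base_composition, priority(PI, 0.7))
    assert math.isclose(alloc[PI], 7.0)
    assert math.isclose(alloc[Z], 3.0 * 112 / 208)  # 1.61538...
    assert math.isclose(alloc[P], 3.0 * 70 / 208)  # 1.00961...
    assert math.isclose(alloc[O], 3.0 * 26 / 208)  # 0.375
    assert math.isclose(sum(alloc.values()), 10.0, abs_tol=1e-9)


def test_degenerate_ratio_sends_everything_to_priority(base_composition):
    alloc = allocate_plantings(10, base_composition, priority(P, 1.0))
    assert alloc[P] == 10.0
    assert sum(v for k, v in alloc.items() if k != P) == 0.0


def test_zero_replacements_allocate_nothing(base_composition):
    for policy in [
        PlantingPolicy("status_quo"),
        priority(Z),
        PlantingPolicy("fixed_mix", mix={Z: 0.5, P: 0.5}),
    ]:
        assert set(allocate_plantings(0, base_composition, policy).values()) == {0.0}


def test_fixed_mix_follows_mix_fractions(base_composition):
    mix = {Z: 0.3, P: 0.3, PI: 0.3, O: 0.1}
    alloc = allocate_plantings(10, base_composition, PlantingPolicy("fixed_mix", mix=mix))
    assert alloc == {Z: 3.0, P: 3.0, PI: 3.0, O: 1.0}


def test_empty_site_proportional_allocation_is_an_error():
    empty = validate_composition({Z: 0})
    with pytest.raises(ValidationError):
        allocate_plantings(1, empty, PlantingPolicy("status_quo"))
    with pytest.raises(ValidationError):
        allocate_plantings(1, empty, priority(Z))


def test_unknown_priority_species_rejected(base_composition):
    with pytest.raises(ValidationError, match="ginkgo"):
        allocate_plantings(1, base_composition, priority("ginkgo"))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(mode="single_priority"),  # missing priority species
        dict(mode="single_priority", priority_species="a", target_ratio=1.3),
        dict(mode="fixed_mix"),  # missing mix
        dict(mode="fixed_mix", mix={"a": 0.5, "b": 0.6}),
        dict(mode="fixed_mix", mix={"a": 1.5, "b": -0.5}),
        dict(mode="cull"),
    ],
)
def test_policy_invariants_enforced(kwargs):
    with pytest.raises(ValidationError):
        PlantingPolicy(**kwargs)


# --- stepping -------------------------------------------------------------


def test_status_quo_is_a_fixed_point(base_composition):
    after = step(base_composition, PlantingPolicy("status_quo"), SETTINGS)
    for sp in base_composition:
        assert math.isclose(after[sp], base_composition[sp], abs_tol=1e-12)


def test_priority_step_gains_hand_checked_amount(base_composition):
    """One month of Pinus-priority replacement plants 0.7*(208/240) pines."""
    after = step(base_composition, priority(PI, 0.7), SETTINGS)
    assert math.isclose(after[PI], 0.7 * 208 / 240)


@given(counts=compositions, mode_seed=st.integers(0, 2), ratio=st.floats(0, 1))
def test_total_is_conserved_under_every_policy(counts, mode_seed, ratio):
    comp = validate_composition(counts)
    if comp.total() <= 0:
        return
    species = comp.species()
    policy = [
        PlantingPolicy("status_quo"),
        PlantingPolicy("single_priority", priority_species=species[0], target_ratio=ratio),
        PlantingPolicy("fixed_mix", mix={species[0]: 1.0}),
    ][mode_seed]
    after = step(comp, policy, SETTINGS)
    assert abs(after.total() - comp.total()) <= 1e-9 * max(comp.total(), 1.0)


@given(counts=compositions, ratio=st.floats(0, 1))
def test_allocations_sum_to_total_replacements(counts, ratio):
    comp = validate_composition(counts)
    if comp.total() <= 0:
        return
    species = comp.species()
    for policy in [
        PlantingPolicy("status_quo"),
        PlantingPolicy("single_priority", priority_species=species[-1], target_ratio=ratio),
        PlantingPolicy("fixed_mix", mix={sp: 1.0 / len(species) for sp in species}),
    ]:
        alloc = allocate_plantings(5.0, comp, policy)
        assert abs(sum(alloc.values()) - 5.0) <= 1e-9


# --- closed-form oracle ---------------------------------------------------


def test_closed_form_initial_condition():
    assert closed_form_priority_share(0, 42.0, 0.7, 208, 240) == 42.0


def test_closed_form_equilibrium():
    assert math.isclose(
        closed_form_priority_share(1e9, 0.0, 0.7, 208, 240), 145.6, abs_tol=1e-6
    )


def test_closed_form_one_period_value():
    """After one full period: rN (1 - e^-1) = 92.0368 trees from zero."""
    val = closed_form_priority_share(240, 0.0, 0.7, 208, 240)
    assert math.isclose(val, 145.6 * (1 - math.exp(-1)))
    assert round(val, 2) == 92.04


def test_euler_matches_closed_form_within_one_percent(base_composition):
    traj = run_dynamics(base_composition, priority(PI, 0.7), SETTINGS, 360)
    n = base_composition.total()
    for t, comp in enumerate(traj):
        exact = closed_form_priority_share(t, 0.0, 0.7, n, 240)
        assert abs(comp[PI] - exact) <= 0.01 * n


def test_non_priority_ratios_preserved(base_composition):
    traj = run_dynamics(base_composition, priority(PI, 0.7), SETTINGS, 360)
    ref = base_composition[Z] / base_composition[O]
    for comp in traj:
        assert abs(comp[Z] / comp[O] - ref) <= 1e-6 * ref


def test_priority_share_converges_monotonically(base_composition):
    traj = run_dynamics(base_composition, priority(PI, 0.7), SETTINGS, 360)
    shares = [c[PI] / c.total() for c in traj]
    assert all(b >= a for a, b in zip(shares, shares[1:]))
    assert shares[-1] <= 0.7


def test_fixed_mix_deviation_shrinks_monotonically(base_composition):
    mix = {Z: 0.3, P: 0.3, PI: 0.3, O: 0.1}
    traj = run_dynamics(
        base_composition, PlantingPolicy("fixed_mix", mix=mix), SETTINGS, 360
    )
    n = base_composition.total()
    devs = [max(abs(c[sp] - mix[sp] * n) for sp in c) for c in traj]
    assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))


# --- run_dynamics ---------------------------------------------------------


def test_run_returns_initial_plus_horizon_snapshots(base_composition):
    traj = run_dynamics(base_composition, PlantingPolicy("status_quo"), SETTINGS, 12)
    assert len(traj) == 13
    assert traj[0] == base_composition


def test_run_rejects_zero_horizon(base_composition):
    with pytest.raises(ValidationError):
        run_dynamics(base_composition, PlantingPolicy("status_quo"), SETTINGS, 0)


def test_settings_invariants():
    with pytest.raises(ValidationError):
        TurnoverSettings(replacement_period_months=0)
    with pytest.raises(ValidationError):
        TurnoverSettings(dt_months=0)
    with pytest.raises(ValidationError):
        TurnoverSettings(dt_months=300, replacement_period_months=240)
    with pytest.raises(ValidationError):
        TurnoverSettings(turnover="random")


def test_cohort_mode_conserves_total_and_converges(base_composition):
    """Under uniform-age cohort turnover the original stock is fully
    converted after exactly one replacement period."""
    settings = TurnoverSettings(turnover="cohort")
    traj = run_dynamics(base_composition, priority(PI, 0.7), settings, 360)
    for comp in traj:
        assert abs(comp.total() - 208) <= 1e-7
    # converged by month 240 and static afterwards
    assert math.isclose(traj[240][PI], traj[360][PI], abs_tol=1e-9)
    assert traj[240][PI] == pytest.approx(0.7 * 208, rel=1e-6)
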