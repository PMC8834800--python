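# Methods

## Model

`arborsim` models a street-tree site as a system-dynamics stock-flow system.
Each species' tree count is a continuous stock $N_i(t)$; counts are real
numbers because the replacement flow (site total divided by the replacement
period, e.g. $208/240 \approx 0.87$ trees/month) is fractional and accumulates.
Rounding to whole trees happens only in reports.

**Turnover.** Trees retire after a replacement cycle of $T$ months (default
240, a 20-year cycle) and are immediately replaced, so the site total is an
invariant of the dynamics. Because no age census of the initial stock is
available, the default scheduling is *first-order* turnover — outflow
$N_i/T$ per month, the standard stock-flow convention, equivalent to assuming
exponentially distributed remaining lifetimes. An optional *cohort* mode
(uniform age spread: the initial stock converts linearly over exactly one
period; replacements are not re-retired within the horizon) is provided for
sensitivity analysis of how results depend on this assumption.

**Planting policies.** The replacement flow $R = N/T$ is allocated by one of
three rules: proportionally to the current composition (`status_quo`, whose
fixed point is the initial composition); a fixed target ratio $r$ to one
priority species with the remainder split over the other species in
proportion to their current counts (`single_priority`); or a fixed
distribution (`fixed_mix`). The "proportion without the priority species" is
recomputed every step from the current composition; a consequence is that the
pairwise ratios of non-priority species are exactly preserved. Under
`single_priority` the priority stock obeys a linear ODE with closed form
$B(t) = rN + (B_0 - rN)e^{-t/T}$, implemented separately
(`closed_form_priority_share`) and used purely as a verification oracle for
the integrator — the simulation itself never calls it.

**Integration.** Explicit Euler, $\Delta t = 1$ month. At $\Delta t / T =
1/240$ the first-order Euler error against the closed form stays well below
1% of the site total over a 360-month horizon (asserted in the test suite
over 100 random configurations). There is no randomness anywhere in the
dynamics; two runs of the same scenario are bit-identical. Counts that dip
below zero through floating-point round-off are clipped to zero with a logged
warning; this cannot occur in first-order mode with $\Delta t \le T$.

## Metrics

**Monthly PM absorption.** $\mathrm{MPA}(t) = \sum_i N_i(t)\, a_i\, w_i(m_t)$
with $a_i$ the annual per-tree absorption (g/tree/year) and $w_i(m)$ the
species' calendar-month weight. Flat mode uses $w = 1/12$ for every month;
seasonal mode uses phenology-derived profiles. Weights always sum to 1, so
flat and seasonal agree on any whole-year total (asserted to $10^{-9}$).

**Seasonal profiles.** Published leaf-area-index seasonality motivates the
shapes but no monthly values are published, so profiles are parameterized:

| parameter | default | meaning |
|---|---|---|
| `leaf_on_start_month` / `leaf_on_end_month` | 4 / 11 | deciduous leaf-on window (April–November, temperate East Asia) |
| `ramp_months` | 1 | linear leaf-out/leaf-fall transition months at each window edge (a 1-month ramp puts edge months at half level) |
| `evergreen_winter_fraction` | 0.6 | evergreen winter absorption relative to its summer plateau |

Deciduous weight is exactly zero outside the window — in particular in
December–February — while evergreens retain 60% of their plateau, which is
what makes the winter criterion favor pines. All profile parameters are
config-overridable; the package's conclusions about winter rely only on the
qualitative property that evergreen winter mass exceeds deciduous winter
mass, not on the default numbers.

**Diversity.** Shannon index $H = -\sum_i p_i \ln p_i$ over the species
shares, natural log by default (configurable base), $0 \ln 0 := 0$, the
pooled "other species" counted as one category. With the bundled 112/70/26
composition $H = 0.9598$.

**Winter.** December, January, February (Northern-hemisphere meteorological
winter, the conventional reading for Korea); the winter mean is the
arithmetic mean of MPA over those calendar months of the simulated horizon.

## Bundled scenarios and parameters

The bundled species table: *Zelkova serrata* 66.6, *Prunus yedoensis* 45.3,
*Pinus densiflora* 24.2 g/tree/year (leaf-sampling estimates for Korean
street trees), pooled "other" at the national per-tree estimate of
35.7 g/tree/year. Only the pine is evergreen; the pooled category's phenology
is not documented anywhere, so it is treated as deciduous (configurable).

Nine scenarios share $T = 240$ months and a 360-month horizon starting
January 2021. Replace-only scenarios keep 208 trees and change only the
replacement rule (priority Zelkova / Prunus / Pinus at target ratio $r$, or a
30/30/30/10 fixed mix); Additional Tree Planting scenarios start with 180
extra trees already in place (total 388) — the densification is instantaneous
at simulation start, since the published initial compositions already include
the added trees — and use the corresponding replacement rule. The target
ratio is a scalar scenario parameter, default 0.7; the 0.9 variant used for
ratio-intensity sensitivity is obtained by rebuilding the scenarios with
`target_ratio=0.9` rather than by any mid-run schedule, because no schedule
for moving between the two is documented.

## Summaries and ranking

Trajectory means are arithmetic means over simulated months 1..360; the
month-0 snapshot contributes only the initial value. Scenario comparison uses
four criteria: mean MPA (descending), **final-month** Shannon index
(descending; the long-term diversity outcome is the object of interest, and
the mean is also reported), the subset improving both mean MPA and final
Shannon over baseline, and winter-mean MPA (descending, from seasonal-mode
runs). Ties are broken lexicographically by scenario name and logged.

## Synthetic data

The generators exist to property-test every stage without external data.
They emulate the statistical shape of the study inputs: per-species annual
absorption log-normal with median 35.7 g/tree/year (strictly positive,
right-skewed; spread 0.5 log units), a Dirichlet split of a fixed site total
(concentration 1 — a uniform simplex draw spanning balanced and skewed
sites), an evergreen probability of 0.25 (one species in four, matching the
bundled table), and uniformly drawn policies. Each operation takes an
explicit seed; there is no global RNG state. These distributional families
are declared test conventions, not scientific claims; the generators do not
emulate spatial structure, measurement error in absorption rates, tree
mortality, or correlations between abundance and absorption, so passing
property tests demonstrates internal consistency of the pipeline, not
real-world predictive skill.

## Numerical choices

- Validation tolerances: monthly weights and mix fractions must sum to 1
  within $10^{-9}$; conservation is asserted to a relative $10^{-9}$.
- Euler-vs-closed-form acceptance: 1% of site total, the first-order error
  bound at $\Delta t / T = 1/240$; the synthetic sweep keeps $T \ge 24$
  months, below which a monthly Euler step visibly distorts the exponential.
- Degenerate inputs: proportional allocation on an empty site is an error
  (undefined proportions); a single-species site under `single_priority`
  routes the remainder to the priority species with a debug log.
- CSV output prints floats at 6 significant digits; configs round-trip
  bit-identically through YAML.

## Known limitations

- First-order turnover spreads replacement over an exponential tail, so
  compositions converge more slowly than under an age-structured scheduler:
  at month 360 only $1 - e^{-1.5} \approx 78\%$ of the gap to the policy
  equilibrium has closed. Long-run orderings that depend on full convergence
  are therefore sensitive to the turnover mode: under first-order turnover
  the "improves both" set at month 360 is {Plant_more_Mix, Plant_more_Pinus}
  (the pine scenario's diversity is still transiting above baseline on its
  way down toward its equilibrium value 0.90, crossing baseline only around
  month 455), whereas cohort turnover — fully converged by month 240 — leaves
  Plant_more_Mix as the unique member. The test suite pins the first-order
  behavior.
- No tree mortality, growth, pest/disease dynamics, climate feedbacks, costs,
  or spatial arrangement; PM absorption is a per-tree rate times stock, with
  no deposition physics, concentration fields or health dose-response.
- Absolute long-run MPA and Shannon levels inherit the turnover-scheduling
  assumption and the parameterized seasonal shapes; the robust outputs are
  the conserved quantities, the exactly derivable initial values, and the
  qualitative orderings asserted in the test suite.
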