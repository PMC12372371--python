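# Methods

## The model

`nursecast` is a discrete-time (annual step) stock-and-flow projection of
a national nursing and midwifery workforce, measured throughout in
whole-time equivalents (WTE) of professionally active staff. The
default parameterisation describes Ireland from a 2021 base year over a
30-year horizon.

**Supply.** The workforce is held in four stocks — {female, male} ×
{domestically educated, foreign educated} — each disaggregated by single
year of age (default span 20–70). Three outflows drain the stocks as
annual fractions of the start-of-year cells: retirement, emigration, and
net attrition (register exits net of re-entries; may be negative per
cell, though default schedules keep it non-negative). Competing risks
are additive rates, validated to sum to at most 1 per cell and never
silently clipped. Survivors age one year; the oldest cohort retires in
full (rate forced to 1), which prevents immortal cohorts. WTE is
conserved exactly at every step:
`stock(t) = survivors + retirement + emigration + attrition`.

**Demand.** Demand is aggregate, not age-structured:
`D_t = D_0 (1+g)^(t-2021)` with `D_0 = 64,383` WTE and `g = 1.4 %` per
year. Demand is structurally independent of every supply parameter; the
sensitivity analysis relies on this.

**Recruitment requirement.** For the year starting at `t`,

```
expansion_t   = D_{t+1} − D_t
replacement_t = total outflow from the start-of-year stock
requirement_t = expansion_t + replacement_t
```

A ledger row is labelled by its start year: the 2021 row shows the 2021
stocks, the outflows during 2021, and the requirement toward 2022
demand (901 + 2,118 = 3,019 under the defaults). This backward-looking
attribution is the only convention under which the base-year
decomposition, the 1,550 foreign recruits (3,019 − 1,469 domestic
inflow), and end-of-year stock = next-year demand are simultaneously
consistent. Demand is projected one year past the horizon so the final
row's expansion is defined.

**Gap rule.** Foreign recruitment fills whatever the domestic pipeline
leaves: `foreign_t = max(0, requirement_t − domestic_inflow_t)`.
Requirements are computed on start-of-year stocks, so the year's
recruits are exactly the gap closers and, whenever foreign recruitment
is positive, end-of-year supply equals demand to machine precision.
When domestic inflow exceeds the requirement the surplus is retained
(no forced exits) and logged as `surplus_wte`.

**Education pipeline.** Student places convert to WTE inflow through a
fixed two-factor chain with a 4-year lag: completion 3,495/3,965 ≈
0.8815 and graduate→WTE conversion 3,019/3,495 ≈ 0.8638, calibrated to
the anchored chain 3,019 WTE ⇐ 3,495 graduates ⇐ 3,965 places. The
chain is exactly invertible (`required_places`). The baseline historical
intake is seeded so baseline inflow equals the published constant of
1,469 WTE/yr (≈ 1,929 places/yr at these factors). Note the published
2021 figure of 2,032 actual places implies a lower overall conversion
(≈ 0.723) than the 3,965→3,019 chain (≈ 0.761); the source does not
reconcile the two, and this package keeps the chain factors as defaults
(both are config-overridable) because the 1,469 inflow is the constant
the projection actually uses.

## Scenarios

* **A (baseline):** intake constant; demand growth met by foreign
  recruitment.
* **B (rapid reform):** intake ramps linearly from 2024, reaching the
  self-sufficiency level at the 2030 intake year.
* **C (slow reform):** as B with target 2040.

Two published statements — intake parity "by 2030/2040" and inflow
parity "by 2034/2044" — are reconciled through the 4-year course lag:
intake reaches the self-sufficiency level at the target year, and
graduate inflow equals the recruitment requirement four years later.

The ramp is anchored one year before its start, so places already rise
in 2024 and the first ramp-affected inflow year is 2028; scenario
ledgers are identical to baseline before then. Interior ramp years
interpolate toward a provisional self-sufficiency level taken from a
constant-intake reference run. From the target year on, each intake
year's places are set by a 4-year-ahead forecast of the requirement,
obtained by simulating forward from the current state with
already-planned inflows and the gap rule. Since every inflow inside the
forecast window is already fixed by earlier intake decisions, the
forecast coincides with the realised run, inflow equals the requirement
exactly from `target + 4` on, and foreign recruitment is exactly zero
thereafter — a deterministic single forward pass, no fixed-point
iteration. Whether a planner would set intake with this much foresight
or track the requirement contemporaneously is unknowable from the
published description; the forecast convention is the one that delivers
the published parity years exactly. Intake years too late to affect the
horizon hold the last decided level.

`self_sufficiency_year` returns the first year with (numerically) zero
foreign recruitment and inflow ≥ requirement, with a 1e-6 WTE absolute
tolerance for float round-trip noise.

## Sensitivity analysis

One-at-a-time ±15 % on exactly two parameters: the demand growth rate
(0.014 → 0.0161 / 0.0119) and the net-attrition schedule (every cell
scaled; the forced-retirement row carries no attrition). Percent
changes are computed against the unperturbed baseline run and rounded
to printed precision only in the rendered table; the CSV keeps raw
values. On the default fixture the rendered table prints: growth +15 %
→ demand 103,960 (+6.4 %), requirement +10 %; growth −15 % → 91,812
(−6 %), requirement −9 %; attrition ±15 % → demand unchanged (0 %),
requirement +3/−3 % (raw +3.4/−3.3 %). Demand invariance under
attrition is structural and asserted elementwise, not approximately.

## The synthetic register

The register underlying the original parameterisation is not public, so
`synthetic_data` generates stand-ins calibrated to the published 2021
aggregates: total 64,383 WTE; foreign 29,285; domestic inflow 1,469/yr;
recruitment requirement 3,019 decomposing into ≈ 901 expansion and
≈ 2,118 replacement.

**Age structure.** The anchor set is exactly the flow balance of a
stable population growing at the demand rate (total inflow 3,019 =
outflow 2,118 + growth 0.014 × 64,383). The generator therefore builds
each origin × gender population as the stable-growth age structure
implied by its entrant age distribution and the exit schedules
(renewal recursion `n(a+1) = n(a)·s(a)/(1+g) + entry(a+1)`), jittered
multiplicatively by the seed and scaled to the anchor totals. Schedules
and structure are solved jointly by fixed-point iteration (schedules
calibrated on the structure; structure rebuilt as the stable population
of the schedules), converging to ~1e-10 in a few hundred cheap sweeps.
This choice is load-bearing: it keeps aggregate exit percentages close
to their base-year values across the horizon — the behaviour the
published trajectories exhibit (replacement ≈ 70 % of the requirement
throughout) — whereas an arbitrary unimodal age bulge drifts through
the rate schedules and pushes the 2051 requirement and foreign share
far off the published values.

**Rate shapes.** Retirement ramps linearly from an onset age (default
52) to the top age; emigration decays exponentially with age (default
0.08/yr of age); net attrition is flat with an early-career bump
(default +80 % around age 27, s.d. 6). Calibration applies one
multiplicative factor per component so 2021 component outflows equal a
configurable split of replacement demand — default attrition 41 % :
emigration 21 % : retirement 38 %, a working assumption chosen for
consistency with the published sensitivity responses, not a published
fact. Forced top-age exits count against the retirement target before
its factor is solved; anchors that would need per-cell rates above 1,
or a retirement target below the structural forced exits, are rejected
with the binding constraint named.

**Entrants.** Domestic graduates enter at ages 21–30, foreign recruits
at 23–40, both with linearly declining weight over the span and a 90 %
female share — plausibility defaults, config-overridable, never
asserted as facts about the real register.

**Determinism.** All randomness lives in this module and flows from a
single integer seed through one PCG64 generator; downstream modules are
fully deterministic given the generated parameters.

## What the fixture does and does not show

Passing tests on these fixtures demonstrate that the *model mechanics*
reproduce the published aggregate trajectories when the base-year
aggregates and flow balance are matched. They do not validate the true
age profiles: the real register's attrition/emigration/retirement split
and age structure are unpublished, and any schedule set consistent with
the same aggregates would pass. Specific known artificialities: the
calibrated retirement schedule is mild below the top age (much of
retirement arrives as the forced exit at 70), late-career retirement
concentration is understated, and nurse/midwife and regional
distinctions are absent, as in the source model. Supply-side dynamic
quantities (2051 requirement, 2051 foreign share, convergence levels)
are therefore checked at scaled tolerances (±3 %, ±1 percentage point,
±6 % respectively), while demand-side and chain quantities, which do
not depend on the register, are checked tightly (±2–10 WTE, exact
rounding).

## Numerical choices

* Annual discrete steps; all published outputs are annual and the
  original continuous-time integration is not reproducible without the
  unpublished parameter tables.
* Within-year order: outflows on the start-of-year stock → ageing →
  entrants. Entrants face exit risk from their first full year.
* Everything is real-valued internally; integers appear only in
  reporting, rounded half away from zero at the final step
  (`round_half_up`), matching printed integer WTEs.
* 64,383 × 1.014³⁰ = 97,703.4, versus a printed 97,704; the ≤1-WTE gap
  (rounded published inputs or the original solver's integration step)
  is noted, not resolved. Tolerances on demand-side checks are ±2 WTE
  for this reason.
* Ledger CSVs use pandas' shortest-round-trip float formatting, so
  re-running an identical configuration reproduces byte-identical
  files and reloading reproduces the in-memory series exactly.

## Problem sizes

Default runs are small by construction: 51 ages × 2 genders × 2 origins
= 204 cells, 31 simulated years, and scenario schedule-building adds at
most ~20 four-year forecast sub-simulations. A full scenario suite plus
sensitivity table completes in well under a second, and the whole test
suite in a few seconds.
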