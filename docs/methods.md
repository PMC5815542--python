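# Methods

## Decision problem

Two strategies for bladder emptying after spinal cord injury (SCI) with
detrusor sphincter dyssynergia are compared over a lifetime horizon:
intermittent catheterization with uncoated PVC catheters plus lubricant, or
with hydrophilic-coated catheters. The payer is the Brazilian public system;
all costs are BRL. The cohort enters at age 36, 80% male, with no renal
impairment and no UTI.

## Evidence synthesis

Four randomized/prospective trials provide per-arm UTI data. For each arm
the monthly rate is `incidence / follow-up months` when incidence is
reported, otherwise the directly reported UTIs per month. The per-study
relative risk (RR) is the ratio of unrounded monthly rates, hydrophilic over
PVC. Pooling is the sample-size-weighted mean: per-study RRs (at 2-decimal
display precision, the published convention; full-precision pooling is
available via `rounded_rr=False` and rounds to the same 0.84) weighted by
hydrophilic-arm N, and PVC monthly rates weighted by PVC-arm N. This yields
RR = 0.84 and a pooled PVC monthly rate of 0.6248.

Data note: one trial's printed per-month rates (0.48/0.48) are inconsistent
at full precision with its printed patient-weighted products; the packaged
table stores the full-precision rates recovered from the weighted products
(54.49/114 = 0.47798, 50.30/105 = 0.47905), whose 2-decimal display is 0.48.
Only with these does the pooled PVC rate reproduce 0.6248. Another trial
reports follow-up as a 3–6-month range; the midpoint 4.5 is stored but never
used, since its rates are reported directly.

## State space and cycle structure

Alive states are the product of three renal stages (no impairment →
significant impairment → renal failure; progression only, never regression)
and four UTI levels (no UTI; UTI on first-line antibiotics; resistant to
first line; resistant to second line). Death is absorbing; 13 states total.
Cycles are monthly.

A UTI episode lasts exactly one cycle: each cycle, survivors are
independently redrawn across the four UTI levels with probabilities
(1−p, p(1−r₁), p·r₁(1−r₂), p·r₁·r₂), where p is the arm's monthly UTI
probability, r₁ = 0.34 the first-line (ciprofloxacin) resistance and
r₂ = 0.034 the second-line (cefuroxime) resistance. The UTI risk is the same
at every renal stage. This memoryless one-cycle episode is the simplest
structure consistent with a constant per-cycle UTI risk; episode duration is
not otherwise identifiable from the inputs.

The pooled monthly value 0.6248 is used directly as a monthly probability,
mirroring its published label as a monthly adverse-event rate, even though
it was derived as an event rate (one trial's arm exceeds 1 event/month).
Setting `flags.rate_to_prob: true` applies 1 − exp(−rate) instead; the
default is the faithful direct-probability reading.

Stones (bladder 0.0012/mo, kidney 0.0012/mo), urethral injury (0.0019/mo)
and urosepsis (0.0032/mo) are **overlay events**: expected counts
proportional to alive occupancy, not Markov states. They carry costs and
utility decrements; urosepsis additionally contributes mortality (below).
The hydrophilic arm multiplies the UTI probability by RR 0.84 and every
overlay probability by 0.90.

## Mortality

Background mortality comes from a sex-specific annual life table, converted
to monthly probabilities by p = 1 − (1−q)^(1/12) at the cohort's current
integer age. Excess mortality is applied on the hazard scale:
q′ = 1 − exp(−h(1+m)) with h = −ln(1−q), so m = 0 reproduces background
mortality exactly. Multipliers add across sources:
m = m_renal + m_UTI + p_sepsis·m_sepsis, where

- m_renal: 18 (significant impairment), 54 (renal failure);
- m_UTI, default **weighted mode**: the fixed input 49.3918 (= 145.27 × 0.34)
  on all three active-UTI states; `state_specific` mode instead applies 0 to
  first-line UTI and 145.27 to the two resistant states;
- urosepsis (797.6) enters as an excess hazard weighted by its per-cycle
  event probability, since it is an overlay, not a state. Whether the
  original model applied it per event or per state is unstated; this
  per-event expected-hazard overlay is our documented choice.

Additive excess hazards (rather than multiplicative stacking) avoid
explosive compounding when a state qualifies for several multipliers; this
is an interpretation, flagged as such.

**The weighted UTI multiplier is a model input, not a derived quantity.**
It equals first-line resistance × resistant-UTI multiplier at the base case,
but it is deliberately *not* recomputed when the resistance rate is varied
in one-way sensitivity analysis: the published sensitivity pattern (ICER
moving by <0.3% across resistance 16.5–45%) is only consistent with the
mortality input being held fixed while the resistance rate shifts the
treatment-cascade mix. With dynamic recomputation the resistance scenario
moved the ICER by ~23%, contradicting that pattern. Users who want the
derived value can recompute it with `weighted_uti_multiplier()` and override
`mortality_multipliers.uti_weighted`.

Renal progression probabilities are **not published**: the defaults
(0.0004/mo no→significant, 0.0029/mo significant→failure) are
order-of-magnitude placeholder assumptions, exposed in configuration and
marked as such. The headline evidence outputs and all directional/invariant
checks are independent of them.

## Synthetic life tables

The official 2014 Brazilian table is not redistributable here, so the
package generates Gompertz–Makeham tables: annual hazard a + b·cˣ, q_x = 1 −
exp(−(a + b·cˣ)), terminal age 110 with q = 1. Frozen defaults — male
a = 1.3e−3, b = 7e−5, c = 1.092 (e₀ ≈ 71.4 y); female a = 6e−4, b = 3.8e−5,
c = 1.094 (e₀ ≈ 78.6 y) — were chosen once to match 2014 Brazilian life
expectancy at birth by sex and never adjusted afterwards. They reproduce the
*level* of mortality, not its age shape (no infant-mortality hump, no
young-adult excess), so absolute model outputs differ from what the official
table would give; orderings, ratios and invariants do not depend on this.
Users can supply real tables as CSV (`life_table.kind: file`).

Male and female cohorts are simulated separately against their own tables
and combined 0.80/0.20 at the outcome level; q-values are never blended.

## Economics

Monthly consumables: PVC 74.27 + lubricant 132.75 (at 2 tubes/day — half a
tube per catheterization, 4/day; scales linearly in `tubes_per_day`);
hydrophilic 608.27. Per event: UTI 554.16 + antibiotics 60.50 (one pooled
antibiotics price regardless of line; third-line parenteral excess is
assumed inside the event cost), urosepsis 708.36, urethral injury 605.33,
kidney stones 524.30, bladder stones 721.95. Per month of state:
significant impairment 82.60, renal failure 2,589.02. A narrative figure of
≈525.60 BRL per UTI hospitalization circulates alongside the declared input
554.16; the declared input table wins.

Utility: baseline u₀ minus decrements — UTI 0.060, resistant UTI 0.104,
stones 0.050, urethral injury 0.104, urosepsis 0.160, significant impairment
0.155, renal failure 0.250 — floored at 0, × 1/12 per cycle. State
decrements (renal, current UTI level) apply via occupancy; overlay-event
decrements per expected event for one cycle. **u₀ = 0.50 is an assumption**:
no baseline utility for this cohort is published. It scales QALYs nearly
linearly, so the ICER per QALY moves with it; the ICER per LYG and all UTI
outcomes do not depend on it.

Costs, QALYs and LYG are discounted at 5%/yr as (1.05)^(−t/12) per cycle t;
UTI counts are undiscounted. Default person-time accounting is
start-of-cycle (spreadsheet-style); `flags.half_cycle: true` applies the
trapezoid (mid-period) correction, under which the zero-disease model's LYG
equals the life table's mid-period remaining expectation to ~1e−14. The two
conventions differ by 1/24 year by construction.

Incremental results use full-precision deltas; reports round costs to whole
BRL and effects to 3 decimals. A strategy is dominant if no costlier and no
less effective (and not identical), dominated in reverse; ICERs are reported
for interior comparisons and compared with the 147,000 BRL/QALY threshold.
The secondary (UTI-only) analysis zeroes the stone/injury/urosepsis
probabilities and reports cost per UTI avoided.

## Validation

- **Microsimulation oracle**: an independent per-patient sampler applies the
  same per-state monthly transition probabilities and accumulations; cohort
  outcomes agree within Monte-Carlo error (checked at 20,000 patients,
  3 standard errors, both arms).
- **Life-table limit**: with all disease parameters zeroed, undiscounted
  LYG equals the life-table expectation (mid-period convention, half-cycle
  accounting) to ~1e−14; discounted LYG matches an independent discounted
  survival-product oracle.
- **Structural invariants**: occupancy sums to 1 every cycle; the dead
  fraction and the cumulative impaired+dead mass are nondecreasing; pooling
  is a convex combination; 12 monthly probabilities compose back to the
  annual q to 1e−12; outcomes are nonincreasing in the discount rate; UTI
  counts are discount-invariant.

Problem sizes used in the shipped checks — 20,000-patient microsimulation,
110-year tables, ~900-cycle traces — keep the full suite under a few
seconds while leaving Monte-Carlo error far below the effect sizes tested.

## Known limitations

- Synthetic life tables reproduce mortality level, not age shape.
- Renal progression rates and baseline utility are assumptions (above);
  absolute costs/QALYs/LYG should not be quoted without sensitivity to them.
- One-cycle UTI episodes; no persistent urethral stricture state; indwelling
  catheters and urostomies are out of scope (different risk profiles).
- No probabilistic sensitivity analysis or budget-impact analysis; the
  sensitivity module is deterministic one-way only.
- Hospital-acquired resistance dynamics, hematuria, phthalate exposure and
  patient preference are not modelled.
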