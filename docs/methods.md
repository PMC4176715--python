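# Methods

## Model structure and conventions

Both stage models are discrete-time Markov cohort models over five states
(remission on intervention; one-cycle non-fatal-AE tunnel; remission after
unplanned discontinuation; recurrence; death) with 1-year cycles, a
20-year horizon, entry at age 65 in remission, and a closed cohort of
10,000 whose size is purely a scale factor (occupancy is continuous
expected counts; all results are per person).

**Accrual and discounting.** All costs and outcomes accrue at the end of
the year: the occupancy at the end of cycle *t* earns cycle *t*'s state
rewards discounted by (1+r)^−t, with r = 5 %/year for costs and 3 %/year
for health outcomes.  There is deliberately *no* half-cycle correction,
and a death within a cycle earns nothing for that cycle — an approximation
that slightly understates both costs and QALYs symmetrically across arms.
Cycle *t* spans ages 65+t−1 to 65+t; age-indexed inputs use the age at the
start of the cycle.  One-time event costs (fatal-AE episodes) are attached
to the state occupied at the start of the cycle as an expected cost per
occupant.

**Within-cycle event ordering.** Published cohort models rarely state how
competing events inside one cycle are ordered; some ordering is required
for the rows to be exactly stochastic.  We resolve each alive state's row
as an event tree with conditional probabilities — fatal AE first, then
other-cause death, then non-fatal AE, then recurrence — so for the
on-treatment remission state

```
P(death)      = p_f + (1−p_f)·p_do
P(AE tunnel)  = (1−p_f)(1−p_do)·p_nf
P(recurrence) = (1−p_f)(1−p_do)(1−p_nf)·min(rr·p_rec, 1)
P(stay)       = the residual
```

Putting fatal events first is the conservative choice for an intervention
that carries iatrogenic mortality.  Because the annual probabilities are
generated from continuous hazards as 1−exp(−ΔH), the product form of
P(stay) is *exact* for the survival margin; only the split among exits
carries discretization error.  Tunnel occupants are alive and face
unmodified natural history during their tunnel year (treatment has
stopped: no AE risk, no benefit), then land in discontinued remission.
Discontinued patients revert to RR 1 — no residual benefit is retained, a
deliberate reading of "benefit while on treatment".  Recurrence is
incurable (no transition back to remission).

## Treatment arms

| input | aspirin | capecitabine | no treatment |
|---|---|---|---|
| RR of progression (95 % CI) | 0.53 (0.33–0.86) | 0.78 (0.67–0.91) | 1 |
| benefit window | cycles 1–5 | cycles 1–5 | — |
| treatment window (drug cost, AE risk) | cycles 1–5 | cycle 1 | — |
| fatal AE /year | 0.0008→0.0030 by age | 0.003 | 0 |
| non-fatal AE /year | 0.0036→0.0111 by age | 0.0291 | 0 |
| drug cost | USD 30/year | USD 55,569 once | 0 |
| pill disutility | utility ×0.999 while treated | — | — |

The six-month capecitabine regimen is collapsed into cycle 1 of the
annual model (drug cost, AE risk and discontinuation all first-cycle),
while its progression benefit runs five years like aspirin's.

**Age profiles.** The aspirin bleeding inputs are published as ranges over
the cohort's age span; we interpolate linearly between the age-65 and
age-85 endpoints over the full 20-year grid and then apply only the first
five years' values (the treatment window).  Compressing the whole range
into the five treatment ages would imply a four-fold rise in bleeding risk
between 65 and 69, which the underlying cardiovascular safety literature
(spanning decades of age) does not support.  Explicit per-age values can
be supplied through the configuration document to override this.

**Utilities.** Stage-specific remission utility (0.84 Stage I, 0.86
Stage II) applies to both remission states; recurrence uses the
metastatic-disease utility 0.84; death is 0.  The tunnel state's utility
is not published anywhere; it is set to the discontinued-remission
utility (occupants have stopped treatment).  Life years weight every alive
state — including the tunnel — at 1.  The base case is reported with and
without the ×0.999 pill-taking disutility.

## Costs

All amounts are November-2013 US dollars; earlier source years convert via
the medical-care CPI factors 1.64 (2000), 1.33 (2005), 1.28 (2006), 1.22
(2007), 1.07 (2011).  Surveillance (physician visits quarterly years 1–2
then annual; blood + CEA tests quarterly year 1 then annual; annual CT)
attaches to every alive state; colonoscopy (years 1, 4, then 5-yearly) and
metastatic care (USD 138,453/year) and terminal-phase patient time
(USD 10,437/year) attach to recurrence; remission-phase patient time
(USD 255/year) to the non-recurrence alive states.  Patient-time costs
apply only in cycles 1–3 (full retirement age 67 from a 65-year-old
cohort, following the source's stated three-year rule).  Capecitabine's
chemotherapy phase adds six extra physician visits in cycle 1.

The aspirin AE episode costs are probability-weighted means of
gastrointestinal (USD 21,700, 2005) and intracranial (USD 32,400, 2005)
bleeding charges, weighted by the per-event age profiles and re-derived
per age — so the cost fixture stays consistent with its stated derivation
rather than hard-coding a printed range.

Every cost item is stored with its raw amount, source year and published
2013 value; `economics.check_cost_derivations` regenerates each from
raw × CPI and flags the items whose published figure drifts from its own
derivation by more than a dollar (colonoscopy, the capecitabine monthly
price and its AE costs, and metastatic care, whose source-year CPI factor
is not published).  For these the published value is authoritative.

## Synthetic natural history

Registry-derived transition tables for the untreated disease are not
redistributable, so the default natural history is generated from
continuous hazards and converted to annual probabilities via
1−exp(−ΔH):

- **Recurrence**: Weibull with shape 0.75 (front-loaded hazard — most
  relapses occur early after resection) and scale 204 years (Stage I,
  ≈ 6 % cumulative recurrence by year 5) or 37 years (Stage II, ≈ 20 %).
- **Other-cause death**: Gompertz a = 5·10⁻⁵, b = 0.088/year — hazard
  ≈ 1.5 %/year at 65 doubling every ≈ 8 years, matching US 65+ life-table
  behaviour.
- **Post-recurrence death**: constant hazard ln2/2.0 (median survival
  2 years, metastatic colorectal cancer of the era); its age-dependence is
  unknown and therefore not modelled, but the table is overridable.

These defaults were fixed from the epidemiology before any
cost-effectiveness output was inspected and are exposed in
`NaturalHistoryParams`, not hard-coded.  `closed_form_survival` integrates
the equivalent continuous three-compartment system (SciPy `solve_ivp`,
rtol 1e-9) and replaces an external-registry check: the annual-cycle
cohort tracks it within 1 % absolute alive-fraction for Stage I and 2 %
for Stage II (the discretization gap grows with the recurrence hazard,
mainly because recurrence-year entrants cannot die of recurrence until the
next cycle).

What the generator does *not* emulate: calendar-period effects, site
(colon vs rectum) differences, cure fractions, surgically salvageable
recurrence, or correlation between recurrence and background mortality.
Passing tests therefore demonstrate internal consistency of the method on
a realistic disease shape, not agreement with any registry's point
estimates; real tables can be dropped in as a CSV (`age, p_rec,
p_death_other, p_death_rec`).

## Sensitivity analyses

**One-way / tornado.** Each parameter moves to its range ends with the
rest at base; the outcome is the incremental net monetary benefit of
aspirin versus the best comparator at λ = 100,000 USD/QALY (well-defined
under dominance, unlike the ICER).  Time-varying inputs are scaled as a
whole profile, with the range convention anchored to the largest base
value.  Entries sort by descending spread; spread > 50,000 flags the
parameter as highly uncertain.

**Threshold scans** bracket every classification change on a ≥ 100-point
grid and bisect to 1e-4 (probabilities, utilities, relative risks) or
1 USD (costs); multiple crossings are all returned and indicate a
non-monotone response.

**PSA.** 10,000 iterations by default (2,000 in the packaged acceptance
run; fractions then carry Monte-Carlo error ≈ 1 %).  Draws are jointly
independent — no correlation structure is published.  Distributions:
lognormal for relative risks (μ = ln RR, σ = (ln hi − ln lo)/3.92), beta
by moment-matching for utilities, gamma by moment-matching for costs, a
fixed Beta(3, 990) for capecitabine's fatal-AE probability.  The
metastatic-care gamma prior (mean 138,453, SD 630,923 ⇒ shape ≈ 0.048) is
extremely heavy-tailed — most draws fall far below the mean — but is used
as published.  The age-dependent aspirin AE schedules are drawn with one
uniform scalar per schedule that rescales the whole profile (shape
preserved) so its mean annual probability spans the published age band
(fatal 0.0008–0.0030, non-fatal 0.0036–0.0111), centred on the base
profile; drawing each age independently would produce implausible
sawtooth risk profiles, and drawing over the extensive-analysis scan
ranges would put 5–12× the base fatal risk at the prior mean.  Iteration
*i* uses `default_rng([seed, i])`, so results are independent of batching.
Out-of-domain draws (a rescaled probability above 1) are clamped and
counted.

**CEAC.** At each willingness-to-pay value the winning strategy of an
iteration maximizes net monetary benefit; exact ties break to the
lexicographically first name, so fractions are deterministic and sum
to 1.

## Numerical choices

Row-stochasticity tolerance 1e-12; cohort conservation 1e-9 relative;
matrix validation happens at construction, so an invalid row can never
propagate.  ICER is reported as NaN when Δeffect = 0; a strategy is
*dominated* only under strict inequality on both axes (equal-effect,
higher-cost comparators are labelled `icer_undefined` rather than
dominated).  Extended dominance (increasing-ICER frontier pruning) is
implemented for user-supplied strategy sets of three or more but never
triggers with the shipped arms, where strict dominance suffices.
`apply_relative_risk` clamps rr·p at 1 with a warning.

## Problem sizes used in the shipped checks

Cohort runs use the full 10,000 × 20-cycle specification.  The
microsimulation cross-check samples 50,000 individual trajectories
(agreement within 3 binomial standard errors per cycle); the acceptance
PSA uses 2,000 iterations per stage; threshold scans use a 101-point
pre-scan.  These sizes keep the whole verification suite in the
tens-of-seconds range on one CPU while leaving Monte-Carlo error well
below the effects being checked.

## Known limitations

End-of-year accrual without half-cycle correction biases absolute totals
slightly low; comparisons between arms are much less affected.  The
competing-event ordering is a modelling convention — alternatives
(e.g. recurrence before death) would shift third-decimal probabilities.
Aspirin's cardiovascular and chemoprevention side benefits and
biomarker-stratified effects (PIK3CA, COX-2) are out of scope, as are
value-of-information analyses and correlated PSA draws.  Base-case totals
depend on the natural-history table in use; with the synthetic default the
*qualitative* structure (aspirin dominant in both stages, dominance
reversal only as RR approaches 1) is the reproducible claim, not any
specific dollar figure.
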