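# crcea — cost-effectiveness of adjuvant aspirin in early-stage colorectal cancer

`crcea` implements, as a tested and configuration-driven Python pipeline, a
pair of discrete-time Markov cohort models asking whether daily low-cost
aspirin, given for five years after curative resection of Stage I or
Stage II colorectal cancer, is cost-effective for patients aged 65+ from
the US societal perspective.  Aspirin is compared with no adjuvant
treatment (both stages) and with six months of capecitabine chemotherapy
(Stage II).  It is aimed at health-economics and biostatistics users who
want a transparent, scriptable alternative to GUI decision-tree software
for this class of model.

## The model

Five mutually exclusive health states: *remission on the assigned
intervention*, a one-cycle tunnel state for *treatment of a non-fatal
grade 3/4 adverse event* (AE), *remission after unplanned treatment
discontinuation*, incurable *recurrence*, and *death*.  A closed cohort of
10,000 patients enters remission at age 65 and is followed in annual
cycles for 20 years.  Per cycle and strategy, a row-stochastic transition
matrix is assembled from an event tree (fatal AE, then other-cause death,
then non-fatal AE, then recurrence), with:

- a relative risk of disease progression applied to the recurrence
  transition during the first five years (aspirin RR 0.53, capecitabine
  RR 0.78),
- age-dependent AE probabilities during treatment only (aspirin years
  1–5; capecitabine's six-month regimen collapsed into cycle 1), with
  Grade 3/4 AEs forcing discontinuation,
- no transition from recurrence back to remission.

Costs (November-2013 USD, medical-care CPI) cover drugs, surveillance,
metastatic care (USD 138,453/year), AE episodes and patient time; costs
discount at 5 %/year and health outcomes at 3 %/year, all accrued at the
end of each year.  Outcomes are discounted QALYs and life years; strategies
are compared by incremental cost-effectiveness ratios (ICER = ΔC/ΔE) and
dominance against aspirin, and by net monetary benefit
NMB = λ·QALY − cost at a willingness-to-pay λ = USD 100,000/QALY.

Registry-derived age-indexed natural-history tables are not
redistributable, so the package ships a synthetic generator (Weibull
time-to-recurrence with decreasing hazard, Gompertz background mortality,
exponential post-recurrence survival) whose annual probabilities drop into
the same loader that accepts a real `age, p_rec, p_death_other,
p_death_rec` CSV.  See `docs/methods.md` for every modelling choice.

## Worked example

```bash
crcea base-case --stage I --out out/
```

prints (costs in 2013 USD, outcomes per person, discounted):

```
strategy             aspirin  no_treatment
total_cost      36357.026296  45308.783106
delta_cost               NaN    8951.75681
total_qaly          9.266511       9.14484
delta_qaly               NaN     -0.121671
icer_qaly                NaN -73573.629918
total_ly           11.035753     10.886714
delta_ly                 NaN     -0.149039
icer_ly                  NaN -60063.155495
classification     reference     dominated
```

Read: under the packaged synthetic natural history, a Stage I patient on
the no-treatment strategy costs USD 8,952 *more* and gains 0.12 *fewer*
QALYs than one on aspirin — no treatment is dominated, and the negative
ratio (−73,574/QALY) is only reported parenthetically, as is conventional.
The same command with `--stage II` adds capecitabine, which is also
dominated (far more costly and less effective than aspirin).

Other entry points: `crcea tornado` (one-way sensitivity, NMB spread per
parameter), `crcea threshold --param rr_aspirin` (break-even scan; with
the packaged inputs no treatment starts to dominate aspirin once its RR
exceeds ≈ 0.97), `crcea psa` (Monte-Carlo probabilistic sensitivity
analysis + cost-effectiveness acceptability curves), `crcea generate-nh`
and `crcea validate`.  Every command writes CSV/JSON plus a
`manifest.json`; identical inputs and `--seed` reproduce identical
outputs.

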