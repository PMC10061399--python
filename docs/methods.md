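# Methods

## Model structure and assumptions

The simulator is a discrete individual (patient-level) model with annual
cycles over a configurable horizon (default 40 years). The modelled
population is community-dwelling adults aged 60+ in one local health
economy; because commissioners oversee a jurisdiction rather than a closed
cohort, cohorts of 60-year-olds enter every cycle. Socioeconomic status
(SES quartile) is static from entry. States are community-dwelling (the only
state simulated longitudinally), long-term care (LTC) and dead; LTC and
death are absorbing exits. LTC residents are not simulated further: on
admission they receive the admission cost (split between public and
self-funded shares by SES quartile) and a fixed mean remaining QALY, both
discounted at the admission cycle.

Within-cycle event order is fixed: pathway assignment → mortality → falls
cascade → acute consequences → outcome accrual → frailty progression → LTC
admission → covariate update. Consequences of the order:

* intervention costs accrue at assignment, even for people who die later in
  the same cycle;
* someone admitted to LTC at the end of a cycle still accrues that cycle's
  utility and costs, then the LTC terminals;
* deaths forfeit the rest of the cycle's accruals except the cost of dying.

No half-cycle correction is applied; discounting is end-of-cycle,
`(1 + r)^-t` with `t` the cycle index (cycle 1 → t = 1), applied identically
to costs and health outcomes (default r = 3.5 %/yr each, settable to 0 % or
6 % as plain configuration).

**Reactive pathway timing.** The reactive intervention is triggered by a
medical-attention (MA) fall in the *previous* cycle, is delivered and costed
at the start of the current cycle, and its efficacy applies to the current
cycle's falls risk. The alternative (same-cycle treatment of the triggering
fall) would make the intervention act on an event that has already been
realised; the chosen convention keeps the cascade strictly sequential.

**Fatal falls.** Fatal-fall risk is a separate hazard (by age band and
frailty category) applied as an independent competing Bernoulli alongside
other-cause mortality, not conditioned on the realised faller type. This
keeps mortality draws independent of the cascade, which is what makes paired
runs comparable; the fatal-fall hazard is small enough that the distinction
is immaterial at the population level.

**Frailty index.** Deficit accumulation over 52 items: score = 100 × (mean
deficit), range 0–100. Categories use the literature cut-offs with upper
bounds inclusive: fit [0, 10], mild (10, 23], moderate (23, 37], severe
> 37. Baseline scores are log-normal with median 10 and σ ≈ 0.804, chosen so
the category shares approximate the defining centiles (≈ 50/35/12/3 %).

**Falls–frailty feedback.** Annual frailty progression is a linear model
containing categorical falls-incidence terms (single non-MA, single MA,
recurrent non-MA, recurrent with MA). Comorbidity care costs, EQ-5D, falls
risk, LTC admission and mortality all worsen with frailty, so a prevented
fall pays both acutely and through the forestalled progression. The
`remove_falls_frailty_feedback` toggle zeroes the falls terms (the
coefficients, not the realised falls), exactly as the corresponding scenario
analysis demands; frailty trajectories then become invariant to fall
realisations (verified by a paired test).

**Mortality-gradient scenario.** `frailty_hr_gap_multiplier` g maps each
hazard ratio HR → 1 + g·(HR − 1) and renormalises the base risk against the
supplied population so the population-average risk is unchanged (the
gradient changes, the mean does not; preserved within 0.5 % at n = 10⁵ in
the tests).

## Pathways and strategies

| Pathway | Usual care (UC) | Recommended care (RC) |
|---|---|---|
| Reactive | HAM, hospitalised MA fallers only | multifactorial, all MA fallers |
| Proactive | screen 31 % at GP contact, uptake 34 %, cognitively intact, first receipt only | screen 100 % at GP contact, uptake 60 %, any cognitive status, ≤ 3 re-receipts |
| Self-referred | 0.1 % of quartile 1, self-financed | publicly funded, demand model with exercise-history feedback |

GP contact is 81 %/yr in both strategies. High falls risk (the proactive
screening criterion) is recurrent falls in the past year and/or abnormal
gait/balance. A person receives at most one pathway per cycle, with
reactive > proactive > self-referred precedence. Self-referred uptake sets an
exercise-history flag that raises next-cycle demand (a behavioural feedback
loop, RC only — under UC demand is a flat rate).

**Co-payments.** The headline published comparison shows substantial RC
co-payments despite "publicly funded" self-referral, so which component
carries them is a configuration choice: by default RC applies a co-payment
share (15 %) of the intervention base cost across all pathways, with the
public sector paying the remainder; UC self-referred exercise is fully
self-financed (public cost 0, co-payment = full cost). Caregiver
time-opportunity cost accrues only when the participant is cognitively
impaired (a caregiver accompanies them).

## Synthetic default parameters

The original parameterisation rests on survey regressions and trial evidence
that are not shipped here. `default_synthetic_parameters(seed)` generates a
complete stand-in with the same schema. Design rules:

* **Published structural constants are kept exactly**: access rates
  0.81/0.31/0.34, RC screening 1.0, UC self-referral 0.001,
  hospitalised-MA share 0.28, the frailty cut-offs, thresholds
  λ = £30,000/£60,000, the £85,025 caregiver-burden and 40 %-of-capacity
  expenditure thresholds, 3.5 % discounting. These are never jittered.
* **Unknown coefficients get practitioner-plausible magnitudes**, jittered a
  few percent by seed so nothing downstream can depend on one magic vector:
  annual any-fall probability ≈ 0.25–0.45, rising with age, frailty, falls
  history, fear of falling and gait impairment and falling with high
  physical activity; recurrent-given-any ≈ 0.4; MA-given-single ≈ 0.25,
  MA-given-recurrent ≈ 0.37; efficacy risk ratios HAM 0.88, multifactorial
  0.73, exercise 0.77 (typical trial-synthesis values); acute QALY losses
  0.002–0.06 per fall by severity; fall costs £60 (non-MA) to £7,500
  (hospitalised MA), additive over the up-to-two MA falls of type v;
  comorbidity care cost rising ≈ £35 per frailty point (the channel that
  makes feedback removal matter); productivity declining to zero around the
  late 70s (the zero boundary doubles as the any-work flag); informal-care
  cost rising steeply with frailty and cognitive impairment; LTC admission
  ≈ £60,000 with public share 35→90 % from quartile 1 to 4 (privileged
  quartiles self-fund more); capacity to pay £130k/£85k/£55k/£32k by
  quartile; other-cause mortality from a Gompertz-like age-band table with
  frailty hazard ratios 1/1.4/2/3.
* **Baseline population**: entry ages follow a geometric-decay pyramid
  (ratio 0.93/yr, 60–99), 55 % female, equal SES quartiles, falls history
  72/18/10 % none/single/recurrent, covariate flags sampled from their
  logistic models in a fixed documented order (activity → cognition → fear →
  gait), each conditional on demographics, frailty and earlier flags.

**What the generator emulates and what it does not.** It reproduces the
*structure* of the evaluated system — the cascade, the feedback loop, the
three pathways, the cost architecture and their directional couplings — and
is calibrated only to the frailty category shares. It does not reproduce the
original effect sizes, baseline risks or cost levels, so simulation outputs
match the published evaluation in *direction* (positive QALY gain, expanded
use of every pathway, fewer person-years of any fall, and a QALY gain that
collapses when the feedback is removed) but not in magnitude: under these
defaults recommended care is *not* cost-effective at £30,000/QALY, whereas
the published full-scale evaluation found that it was. Passing tests
therefore certify the engine and its invariants, not the real-world
cost-effectiveness of the strategy.

## Randomness and paired comparisons

Every stochastic event draws from its own Philox stream keyed by
(base seed, event code, cycle), with draws row-aligned to individuals.
Because populations and entry cohorts are synthesized from the same seed in
both strategies, row orderings coincide and the two runs consume identical
randomness — common random numbers by construction. With all efficacy
multipliers at 1 the strategies' health trajectories are bitwise identical
(the null-equivalence test), and a strategy compared with itself yields
exactly zero incrementals in every stream. Draws are made for every row
(including the dead) so that alignment never drifts.

PSA holds one simulation seed fixed across replicates and redraws parameters
per replicate — Beta for probabilities, Gamma for costs (parameterised by
shape and mean), Normal for regression coefficients — so run-to-run spread
isolates parameter (second-order) uncertainty; degenerate distributions give
bitwise-identical replicates. First-order uncertainty is handled separately
by multi-seed deterministic averaging (field-wise means of the paired
summaries; 20 seeds by default). The jack-knife mean ICER over PSA pairs is
n·θ̂ − (n−1)·mean of leave-one-out pooled ratios, with a 95 % interval from
the normal approximation on the pseudo-values (the interval method is a
package choice); it is verified against a brute-force leave-one-out oracle.

## Equity analytics

Per-quartile per-capita societal net health benefit:
`NHB_q = (QALY_q + societal_net_q/λ_societal − public_cost_q/λ_public) / n_q`,
with societal net = productivity − participant TOC − OOP − co-payments −
informal care − caregiver TOC, and public cost including intervention costs.
The DCEA collapses the four quartile values through Atkinson
(ε ∈ {0, 3, 5, 11, 15, 20, 25, 30}; ε = 1 handled as the geometric-mean
limit; requires positive values) and Kolm (α ∈ {0.025–0.5}; evaluated via
log-sum-exp) EDE functions, and compares the incremental EDE NHB with the
no-aversion INAB. The quartile means are unweighted (subgroups treated as
equal-sized). DCEA runs on deterministic outputs only; a probabilistic DCEA
is out of scope. NHBs are not covariate-adjusted before the DCEA.

Lifetime outcomes are counted on the initial cohort entering at age 65:
fair health- and wellbeing-innings thresholds are 60 % of that cohort's
usual-care *median* discounted lifetime QALY and wellbeing-years
(undiscounted variants available via a flag; the LTC-assigned mean remaining
QALY counts toward the lifetime total); productive ageing is ≥ 10 years with
positive work value from age 65; catastrophic private expenditure applies to
quartiles 3–4 only and uses a strict inequality against 40 % of capacity to
pay, computed with and without co-payments (undiscounted cumulative spend,
including self-funded LTC); excessive caregiver burden is a strict
inequality against £85,025, with and without caregiver time-opportunity
costs. Ties at a threshold therefore do *not* count as exceeding it, while
fair-innings comparisons are ≥ (reaching the innings counts).

CASP-19 wellbeing-years are discounted identically to QALYs, and the acute
fall QALY decrement is applied to the wellbeing accrual as well, keeping the
two fair-innings metrics structurally parallel.

## Problem sizes and numerical choices

Default desk-scale runs use 20,000 baseline individuals plus 250 entrants
per cycle over 40 cycles (≈ 30,000 individuals in total) — large enough for
stable directional contrasts at seconds-per-run cost; the engine is fully
vectorised over the population. Test-suite property checks use 10⁵–10⁶
draws for Monte-Carlo probabilities (tolerance 2 %), 0.5 % relative
tolerance for the mortality renormalisation, and exact (bitwise) assertions
for determinism, partition and null-equivalence properties. Frailty scores
are clamped to [0, 100] after progression; linear outcome models declare
clamping ranges (e.g. EQ-5D in [−0.2, 1], costs ≥ 0); probabilities after
efficacy scaling are clamped to [0, 1].

## Known limitations

* The synthetic coefficients are plausible but uncalibrated to any dataset;
  absolute ICERs, cost levels and equity gradients from the defaults are
  illustrative only (see above).
* No supply-side capacity constraints: the only flow cap is the RC proactive
  re-receipt exclusion.
* LTC is a terminal lump (cost + mean remaining QALY); no within-LTC
  longitudinal simulation, no multiple care levels.
* No within-year timing of falls; the five faller types summarise the year.
* Covariate flags other than falls history, exercise history and frailty are
  fixed at entry; fear of falling and gait impairment do not progress.
* SES is static; there is no geographic dimension.
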