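# fallsim

Discrete individual simulation of **community-based falls prevention** for
adults aged 60+, built for health-economic analysis at the level of a local
commissioning jurisdiction. It compares **usual care (UC)** — reactive home
assessment for hospitalised fallers, limited opportunistic screening, a sliver
of self-financed exercise — against **recommended care (RC)** — guideline-style
multifactorial intervention for all medical-attention (MA) fallers, universal
screening at GP contact, and publicly funded self-referred exercise — from a
**societal perspective**: QALYs, public-sector costs, productivity (paid and
unpaid work), out-of-pocket expenditure and co-payments, and informal-care
costs, plus distributional (equity) analysis over socioeconomic quartiles.

It is written for health economists and modellers who want a transparent,
testable engine for falls-prevention strategy questions: what the
falls–frailty feedback contributes, how co-payments shift private burden, and
whether a strategy is equitable as well as efficient.

## Model

Individuals carry age, sex, SES quartile (1 = most privileged), falls history,
a 0–100 deficit-accumulation **frailty index** (52 items; categories
fit ≤ 10 < mild ≤ 23 < moderate ≤ 37 < severe), and risk covariates sampled
from logistic models (high physical activity, cognitive impairment, fear of
falling, abnormal gait/balance). Each annual cycle runs, in order:

1. **pathway assignment** — reactive (previous cycle's MA fall), proactive
   (GP contact × screening × high falls risk × uptake), or self-referred
   exercise; at most one pathway per person-year; interventions carry public
   costs, co-payments, participant and caregiver time-opportunity costs, and a
   falls-risk multiplier `m ≤ 1`;
2. **mortality** — competing Bernoulli risks: other-cause (age-band × sex base
   risk × frailty-category hazard ratio) and fatal fall;
3. **falls cascade** — sequential logistic risks
   P(any fall)·m → P(recurrent | any) → P(MA | single or recurrent), producing
   five faller types (no fall; single non-MA; single MA; recurrent non-MA;
   recurrent with 1–2 MA falls), each MA fall hospitalised w.p. ≈ 0.28;
4. **acute consequences** — fall healthcare cost and acute QALY loss by type;
5. **accrual** — EQ-5D utility and CASP-19 wellbeing, comorbidity/community/
   social-care costs, productivity value, OOP spend, informal-care cost; all
   discounted at (1+r)^−t, r = 3.5 %/yr by default;
6. **frailty progression** — linear model whose categorical falls-incidence
   terms are the **falls→frailty feedback loop** (falls accelerate frailty,
   which raises future falls risk, care costs and mortality);
7. **long-term-care admission** — logistic in the frailty delta and
   covariates; an absorbing exit with a public/self-funded cost split by SES
   quartile and an assigned mean remaining QALY.

Analytics: incremental cost-utility in the societal-table shape
(ICER = ΔC_public/ΔQ_societal with societal costs converted at
λ_societal = £60,000/QALY; INMB = λ·ΔQ − ΔC at λ_public = £30,000/QALY),
jack-knife mean ICER over PSA replicates, CEAC, 20-seed deterministic
averaging, Atkinson/Kolm equally-distributed-equivalent net health benefits
by SES quartile (DCEA), and individual-level lifetime equity outcomes (fair
innings, productive ageing, catastrophic private expenditure, excessive
caregiver burden).

The regression coefficients of the original survey-based parameterisation are
not publicly available, so the package ships a **documented synthetic default
parameter set** (`default_synthetic_parameters`) with practitioner-plausible
magnitudes; see `docs/methods.md` for the data dictionary and what that does
and does not allow you to conclude.

## Worked example

```python
import fallsim as fs

params = fs.default_synthetic_parameters(seed=1)
scenario = fs.ScenarioConfig(horizon_years=40, population_size=20_000,
                             entry_cohort_size_per_cycle=250)
uc = fs.run_strategy(params, scenario, seed=1)
rc = fs.run_strategy(params, scenario.replace(strategy="RC"), seed=1)
print(fs.compare(uc, rc))
```

Running `python examples/01_compare_strategies.py` (which does the above)
prints:

```
individuals simulated:        29,750
QALY gain (RC - UC):          805.9
all-cause public cost delta:  £-15,292,256
intervention cost delta:      £49,277,221
net productivity gain:        £-9,293,460
net personal finance cost:    £9,303,138
net informal care cost:       £-105,371
societal gain, QALY equiv:    -308.2
ICER (all-cause):             £68,279 per societal QALY
person-years of any fall:     187,476 (UC) -> 172,118 (RC)
```

Reading: under the synthetic defaults, recommended care prevents falls
(−8.2 % person-years of any fall) and gains QALYs, it saves all-cause public
costs, but the intervention outlay and time-opportunity costs dominate the
societal side, so the strategy is not cost-effective at £30,000/QALY *with
these stand-in parameters*. The structural signatures are the point: rerun
`examples/05_scenarios.py` and the QALY gain collapses from 806 to 295 when
the falls–frailty feedback is switched off — most of the benefit of
preventing a fall is the frailty progression it forestalls.

Other examples: `02_psa_ceac.py` (PSA, CEAC, jack-knife ICER),
`03_dcea_equity.py` (quartile NHBs and EDE curves), `04_lifetime_outcomes.py`
(fair innings, productive ageing, catastrophic expenditure). A thin CLI
mirrors them: `fallsim compare`, `fallsim psa`, `fallsim dcea`,
`fallsim report --table T2`, `fallsim params out.yaml`.

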