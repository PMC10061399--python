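"""Paired strategy comparison: usual care (UC) vs recommended care (RC).

Runs both strategies on common random numbers at desk scale and prints the
incremental cost-utility summary.  Positive delta-QALY with incremental
intervention cost gives the cost per societal QALY gained (ICER); an ICER
below the public threshold of £30,000/QALY reads as cost-effective.
"""

import fallsim as fs

params = fs.default_synthetic_parameters(seed=1)
scenario = fs.ScenarioConfig(horizon_years=40, population_size=20_000,
                             entry_cohort_size_per_cycle=250)

uc = fs.run_strategy(params, scenario, seed=1)
rc = fs.run_strategy(params, scenario.replace(strategy="RC"), seed=1)
s = fs.compare(uc, rc)

print(f"individuals simulated:        {uc.n_individuals:,}")
print(f"QALY gain (RC - UC):          {s.delta_qaly:,.1f}")
print(f"all-cause public cost delta:  £{s.delta_allcause_cost:,.0f}")
print(f"intervention cost delta:      £{s.delta_intervention_cost:,.0f}")
print(f"net productivity gain:        £{s.net_productivity_gain:,.0f}")
print(f"net personal finance cost:    £{s.net_personal_finance_cost:,.0f}")
print(f"net informal care cost:       £{s.net_informal_care_cost:,.0f}")
print(f"societal gain, QALY equiv:    {s.societal_gain_qaly_equivalent:,.1f}")
print(f"ICER (all-cause):             £{s.icer_allcause:,.0f} per societal QALY")
print(f"person-years of any fall:     {uc.person_years_any_fall:,} (UC) -> "
      f"{rc.person_years_any_fall:,} (RC)")
print()
print("A negative fall person-year delta shows prevention working; whether the")
print("QALY and societal gains justify the intervention spend is what the ICER")
print("and net-benefit lines summarise.")
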