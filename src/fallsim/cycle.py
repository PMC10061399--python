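"""One simulation year: mortality, the falls cascade, acute consequences,
frailty progression with the falls-frailty feedback, and long-term-care
admission.

Within-cycle event order (fixed):

1. pathway assignment (reactive eligibility from the previous cycle's MA
   fall; intervention costs accrue at assignment)
2. mortality (fatal fall and other-cause, independent competing Bernoullis)
3. falls cascade producing the five faller types
4. acute consequences (fall healthcare cost, acute QALY loss)
5. outcome accrual (utility, wellbeing, cost and value streams)
6. frailty progression (linear model with categorical falls-incidence terms
   — the falls->frailty feedback loop)
7. LTC admission (logistic on the frailty delta and covariates)
8. covariate update (age +1, falls-history refresh, fall memory for next
   cycle's reactive pathway)

Deaths and LTC exits forfeit the remainder of the cycle's accruals except
the cost of dying / the LTC admission cost and assigned remaining QALYs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accounting import EXIT_DEATH, EXIT_LTC, OutcomeLedger, discount_factor
from .params import ParameterSet, ScenarioConfig, evaluate_model
from .pathways import assign_pathways_vectorised
from .population import (
    FALLS_NONE,
    FALLS_RECURRENT,
    FALLS_SINGLE,
    STATUS_COMMUNITY,
    STATUS_DEAD,
    STATUS_LTC,
    Population,
    covariate_dict,
    frailty_category_codes,
)
from .rng import EventRng

__all__ = [
    "FT_NO_FALL", "FT_SINGLE_NONMA", "FT_SINGLE_MA",
    "FT_RECURRENT_NONMA", "FT_RECURRENT_MA",
    "FallerType", "frailty_hr_with_gap", "other_cause_risk",
    "sample_faller_type_vectorised", "acute_consequences_vectorised",
    "progress_frailty_vectorised", "step_cycle",
]

# five faller types
FT_NO_FALL, FT_SINGLE_NONMA, FT_SINGLE_MA, FT_RECURRENT_NONMA, FT_RECURRENT_MA = range(5)
FALLER_TYPE_NAMES = (
    "no_fall", "single_nonMA", "single_MA", "recurrent_nonMA", "recurrent_with_MA",
)

_HR_KEYS = ("fit", "mild", "moderate", "severe")


@dataclass
class FallerType:
    """Scalar faller-type record (category, MA-fall count, hospitalisations)."""

    category: int = FT_NO_FALL
    n_ma_falls: int = 0
    hospitalised: tuple = ()

    @property
    def any_hospitalised(self) -> bool:
        return any(self.hospitalised)


def frailty_hr_with_gap(hr: float, gap_multiplier: float) -> float:
    """Shrink the mortality hazard-ratio gap to the fit category:
    HR' = 1 + gap_multiplier x (HR - 1)."""
    return 1.0 + gap_multiplier * (hr - 1.0)


def _age_band_index(params: ParameterSet, age) -> np.ndarray:
    bands = np.asarray(params.mortality_age_bands, dtype=float)
    idx = np.searchsorted(bands, np.asarray(age, dtype=float), side="right") - 1
    return np.clip(idx, 0, len(bands) - 1)


def other_cause_risk(
    params: ParameterSet,
    age,
    sex_female,
    frailty_score,
    *,
    mortality_multiplier: float = 1.0,
    hr_gap_multiplier: float = 1.0,
    renormalise: bool = True,
):
    """Annual other-cause mortality risk: base(age band, sex) x frailty HR.

    The scenario that shrinks the HR gradient renormalises the base risk so
    the *population-average* risk over the supplied individuals is unchanged
    (the gradient changes, the mean does not).
    """
    idx = _age_band_index(params, age)
    base_m = np.asarray(params.mortality_base_male)[idx]
    base_f = np.asarray(params.mortality_base_female)[idx]
    base = np.where(np.asarray(sex_female) == 1, base_f, base_m)
    hr_table = np.array([params.mortality_frailty_hr[k] for k in _HR_KEYS])
    cat = frailty_category_codes(frailty_score)
    hr = hr_table[cat]
    hr_adj = frailty_hr_with_gap(hr, hr_gap_multiplier)
    risk = base * hr_adj
    if renormalise and hr_gap_multiplier != 1.0:
        target = float(np.sum(base * hr))
        actual = float(np.sum(risk))
        if actual > 0:
            risk = risk * (target / actual)
    return np.clip(risk * mortality_multiplier, 0.0, 1.0)


def fatal_fall_risk(params: ParameterSet, age, frailty_score) -> np.ndarray:
    idx = _age_band_index(params, age)
    base = np.asarray(params.fatal_fall_base)[idx]
    factor_table = np.array([params.fatal_fall_frailty_factor[k] for k in _HR_KEYS])
    factor = factor_table[frailty_category_codes(frailty_score)]
    return np.clip(base * factor, 0.0, 1.0)


def sample_faller_type_vectorised(pop, efficacy_multiplier, params, ern: EventRng, cycle: int):
    """Sequential Bernoulli cascade over the whole population.

    Returns (faller_type, n_ma_falls, hosp1, hosp2) row-aligned arrays.  The
    efficacy multiplier scales the any-fall probability (clamped to [0, 1]).
    All uniform streams are drawn for every row so that paired strategies
    consume identical randomness.
    """
    mult = np.asarray(efficacy_multiplier, dtype=float)
    if np.any(mult <= 0):
        raise ValueError("efficacy multiplier must be positive")
    n = len(pop)
    cov = covariate_dict(pop)

    def _p(name):  # broadcast covariate-free blocks to full length
        return np.broadcast_to(
            np.asarray(evaluate_model(params.cascade_models[name], cov), dtype=float), (n,)
        )

    p_any = np.clip(_p("any_fall") * mult, 0.0, 1.0)
    p_rec = _p("recurrent_given_any")
    p_ma_s = _p("ma_given_single")
    p_ma_r = _p("ma_given_recurrent")
    p_2ma = _p("second_ma_given_recurrent_ma")
    p_hosp = params.access["hospitalised_ma_share"]

    u_any = ern.uniforms("fall_any", cycle, n)
    u_rec = ern.uniforms("fall_recurrent", cycle, n)
    u_ma = ern.uniforms("fall_ma", cycle, n)
    u_2ma = ern.uniforms("fall_second_ma", cycle, n)
    u_h1 = ern.uniforms("fall_hosp_1", cycle, n)
    u_h2 = ern.uniforms("fall_hosp_2", cycle, n)

    any_fall = u_any < p_any
    recurrent = any_fall & (u_rec < p_rec)
    single = any_fall & ~recurrent
    ma = np.where(single, u_ma < p_ma_s, u_ma < p_ma_r) & any_fall

    ftype = np.zeros(n, dtype=np.int64)
    ftype[single & ~ma] = FT_SINGLE_NONMA
    ftype[single & ma] = FT_SINGLE_MA
    ftype[recurrent & ~ma] = FT_RECURRENT_NONMA
    ftype[recurrent & ma] = FT_RECURRENT_MA

    n_ma = np.zeros(n, dtype=np.int64)
    n_ma[ftype == FT_SINGLE_MA] = 1
    rec_ma = ftype == FT_RECURRENT_MA
    n_ma[rec_ma] = 1 + (u_2ma[rec_ma] < p_2ma[rec_ma]).astype(np.int64)

    hosp1 = (n_ma >= 1) & (u_h1 < p_hosp)
    hosp2 = (n_ma >= 2) & (u_h2 < p_hosp)
    return ftype, n_ma, hosp1, hosp2


def acute_consequences_vectorised(ftype, n_ma, hosp1, hosp2, params):
    """Acute QALY loss and fall-related healthcare cost by faller type.

    Non-MA falls take the flat per-type amounts; each MA fall adds the
    hospitalised or non-hospitalised per-event amount (additive for the two
    MA falls of the recurrent-with-MA type)."""
    uc, ql = params.unit_costs, params.acute_qaly_loss
    cost = np.zeros(len(ftype))
    loss = np.zeros(len(ftype))
    cost[ftype == FT_SINGLE_NONMA] = uc["fall_nonma_single"]
    loss[ftype == FT_SINGLE_NONMA] = ql["fall_nonma_single"]
    cost[ftype == FT_RECURRENT_NONMA] = uc["fall_nonma_recurrent"]
    loss[ftype == FT_RECURRENT_NONMA] = ql["fall_nonma_recurrent"]
    first = n_ma >= 1
    cost[first] += np.where(hosp1[first], uc["fall_ma_hosp"], uc["fall_ma_nonhosp"])
    loss[first] += np.where(hosp1[first], ql["fall_ma_hosp"], ql["fall_ma_nonhosp"])
    second = n_ma >= 2
    cost[second] += np.where(hosp2[second], uc["fall_ma_hosp"], uc["fall_ma_nonhosp"])
    loss[second] += np.where(hosp2[second], ql["fall_ma_hosp"], ql["fall_ma_nonhosp"])
    return loss, cost


_FALL_DUMMIES = {
    FT_SINGLE_NONMA: "fall_single_nonma",
    FT_SINGLE_MA: "fall_single_ma",
    FT_RECURRENT_NONMA: "fall_recurrent_nonma",
    FT_RECURRENT_MA: "fall_recurrent_ma",
}


def progress_frailty_vectorised(pop, ftype, scenario: ScenarioConfig, params):
    """Annual frailty-score delta from the linear progression model.

    With the feedback removed the categorical falls-incidence coefficients
    are treated as zero, making the delta invariant to fall realisations."""
    extra = {}
    for code, name in _FALL_DUMMIES.items():
        if scenario.toggles.remove_falls_frailty_feedback:
            extra[name] = np.zeros(len(pop))
        else:
            extra[name] = (np.asarray(ftype) == code).astype(float)
    delta = np.asarray(
        evaluate_model(params.frailty_progression_model, covariate_dict(pop, extra))
    )
    return delta * scenario.toggles.progression_rate_multiplier


def step_cycle(
    pop: Population,
    ledger: OutcomeLedger,
    params: ParameterSet,
    scenario: ScenarioConfig,
    strategy: str,
    cycle: int,
    ern: EventRng,
) -> dict:
    """Advance the population by one year; returns cycle-level counters."""
    n = len(pop)
    df_c = discount_factor(scenario.discount_rate_cost, cycle)
    df_h = discount_factor(scenario.discount_rate_health, cycle)
    tg = scenario.toggles

    # 1. pathway assignment -------------------------------------------------
    assignment = assign_pathways_vectorised(pop, strategy, params, ern, cycle)
    pathway = assignment["pathway"]
    ledger.arrays["intervention_public_cost"] += df_c * assignment["public_cost"]
    ledger.arrays["co_payment"] += df_c * assignment["co_payment"]
    ledger.arrays["participant_toc"] += df_c * assignment["participant_toc"]
    ledger.arrays["caregiver_toc"] += df_c * assignment["caregiver_toc"]
    ledger.arrays["private_expenditure_cum"] += assignment["co_payment"]
    ledger.arrays["caregiver_toc_cum"] += assignment["caregiver_toc"]

    alive = pop.status == STATUS_COMMUNITY

    # 2. mortality ----------------------------------------------------------
    p_other = np.zeros(n)
    if np.any(alive):
        p_other[alive] = other_cause_risk(
            params, pop.age[alive], pop.sex_female[alive], pop.frailty_score[alive],
            mortality_multiplier=tg.other_cause_mortality_multiplier,
            hr_gap_multiplier=tg.frailty_hr_gap_multiplier,
        )
    p_fatal = fatal_fall_risk(params, pop.age, pop.frailty_score)
    u_other = ern.uniforms("mortality_other", cycle, n)
    u_fatal = ern.uniforms("mortality_fatal_fall", cycle, n)
    died = alive & ((u_other < p_other) | (u_fatal < p_fatal))
    if np.any(died):
        ledger.arrays["cost_of_dying"][died] += df_c * params.unit_costs["cost_of_dying"]
        ledger.mark_exit(died, EXIT_DEATH, cycle)
        status = pop.status.copy()
        status[died] = STATUS_DEAD
        pop.set("status", status)
    surv = alive & ~died

    # 3-4. falls cascade and acute consequences -----------------------------
    ftype, n_ma, hosp1, hosp2 = sample_faller_type_vectorised(
        pop, assignment["efficacy_multiplier"], params, ern, cycle
    )
    ftype[~surv] = FT_NO_FALL
    n_ma[~surv] = 0
    hosp1 &= surv
    hosp2 &= surv
    acute_loss, fall_cost = acute_consequences_vectorised(ftype, n_ma, hosp1, hosp2, params)

    # 5. outcome accrual ----------------------------------------------------
    cov = covariate_dict(pop)
    om = params.baseline_outcome_models
    utility = np.asarray(evaluate_model(om["eq5d"], cov)) - acute_loss
    wellbeing = np.asarray(evaluate_model(om["casp19"], cov)) - acute_loss
    comorb = np.asarray(evaluate_model(om["healthcare_cost"], cov))
    community = np.asarray(evaluate_model(om["community_care_cost"], cov))
    social = np.asarray(evaluate_model(om["social_care_cost"], cov))
    productivity = np.asarray(evaluate_model(om["productivity_value"], cov))
    oop = np.asarray(evaluate_model(om["oop_expenditure"], cov))
    informal = np.asarray(evaluate_model(om["informal_care_cost"], cov))

    ledger.arrays["qaly"][surv] += df_h * utility[surv]
    ledger.arrays["wellbeing"][surv] += df_h * wellbeing[surv]
    ledger.arrays["fall_healthcare"][surv] += df_c * fall_cost[surv]
    ledger.arrays["comorbidity_care"][surv] += df_c * comorb[surv]
    ledger.arrays["community_care"][surv] += df_c * community[surv]
    ledger.arrays["social_care"][surv] += df_c * social[surv]
    ledger.arrays["productivity_value"][surv] += df_c * productivity[surv]
    ledger.arrays["oop_expenditure"][surv] += df_c * oop[surv]
    ledger.arrays["informal_care_cost"][surv] += df_c * informal[surv]

    ledger.arrays["lifetime_qaly"][surv] += utility[surv]
    ledger.arrays["lifetime_wellbeing"][surv] += wellbeing[surv]
    working = surv & (productivity > 0) & (pop.age >= 65)
    ledger.arrays["work_years_since_65"][working] += 1.0
    ledger.arrays["private_expenditure_cum"][surv] += oop[surv]
    ledger.arrays["private_expenditure_excl_copay_cum"][surv] += oop[surv]
    ledger.arrays["informal_care_value_cum"][surv] += informal[surv]

    # 6. frailty progression ------------------------------------------------
    delta = progress_frailty_vectorised(pop, ftype, scenario, params)
    new_score = np.clip(pop.frailty_score + np.where(surv, delta, 0.0), 0.0, 100.0)

    # 7. LTC admission ------------------------------------------------------
    p_ltc = np.asarray(
        evaluate_model(params.ltc_admission_model, covariate_dict(pop, {"frailty_delta": delta}))
    )
    u_ltc = ern.uniforms("ltc_admission", cycle, n)
    admitted = surv & (u_ltc < p_ltc)
    if np.any(admitted):
        share = np.asarray(params.ltc_public_share)[pop.ses_quartile[admitted] - 1]
        total = params.unit_costs["ltc_admission"]
        ledger.arrays["public_ltc"][admitted] += df_c * total * share
        ledger.arrays["oop_expenditure"][admitted] += df_c * total * (1.0 - share)
        ledger.arrays["private_expenditure_cum"][admitted] += total * (1.0 - share)
        ledger.arrays["private_expenditure_excl_copay_cum"][admitted] += total * (1.0 - share)
        ledger.arrays["qaly"][admitted] += df_h * params.ltc_mean_remaining_qaly
        ledger.arrays["lifetime_qaly"][admitted] += params.ltc_mean_remaining_qaly
        ledger.mark_exit(admitted, EXIT_LTC, cycle)
        status = pop.status.copy()
        status[admitted] = STATUS_LTC
        pop.set("status", status)

    # 8. covariate update ---------------------------------------------------
    remaining = surv & ~admitted
    age = pop.age.copy()
    age[remaining] += 1.0
    pop.set("age", age)
    pop.set("frailty_score", np.where(remaining, new_score, pop.frailty_score))

    falls_history = pop.falls_history.copy()
    falls_history[remaining & (ftype == FT_NO_FALL)] = FALLS_NONE
    falls_history[remaining & np.isin(ftype, (FT_SINGLE_NONMA, FT_SINGLE_MA))] = FALLS_SINGLE
    falls_history[
        remaining & np.isin(ftype, (FT_RECURRENT_NONMA, FT_RECURRENT_MA))
    ] = FALLS_RECURRENT
    pop.set("falls_history", falls_history)
    pop.set("prev_ma_fall", np.where(remaining, (n_ma > 0).astype(np.int64), 0))
    pop.set(
        "prev_hospitalised_ma",
        np.where(remaining, (hosp1 | hosp2).astype(np.int64), 0),
    )

    return {
        "cycle": cycle,
        "n_alive_start": int(alive.sum()),
        "deaths": int(died.sum()),
        "ltc_admissions": int(admitted.sum()),
        "person_years_any_fall": int((surv & (ftype != FT_NO_FALL)).sum()),
        "faller_type_counts": np.bincount(ftype[surv], minlength=5).tolist(),
        "usage_reactive": int((pathway == 1).sum()),
        "usage_proactive": int((pathway == 2).sum()),
        "usage_self_referred": int((pathway == 3).sum()),
    }
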