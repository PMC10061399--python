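"""Documented synthetic default parameter set.

The original model was parameterised from longitudinal survey regressions and
UK trial evidence that are not shipped here.  This module generates a
*synthetic* stand-in parameter set with the same schema and with magnitudes a
falls-epidemiology practitioner would call plausible (annual any-fall risk
rising with age, frailty and falls history; comorbidity care costs rising with
frailty; intervention risk ratios below one; right-skewed positive costs).
The published access probabilities and structural constants (81% GP contact,
31%/34% usual-care screening/uptake, 28% hospitalised share of
medical-attention falls, 0.1% usual-care self-referral, frailty cut-offs) are
kept at their stated values and are not jittered.

``default_synthetic_parameters(seed)`` is deterministic for a seed; different
seeds jitter the regression coefficients and unit costs by a few percent so
that downstream code cannot silently depend on one magic coefficient set.

The baseline frailty-score distribution is log-normal with median 10 and
sigma chosen so the category shares under the 10/23/37 cut-offs approximate
the defining centiles (~50/35/12/3%).
"""

from __future__ import annotations

import math

import numpy as np

from .params import ParameterSet, RegressionSpec

__all__ = ["default_synthetic_parameters", "FRAILTY_LOGNORM_MU", "FRAILTY_LOGNORM_SIGMA"]

# median 10 -> mu = ln 10; 85th centile at 23 -> sigma = (ln 23 - ln 10) / z_0.85
FRAILTY_LOGNORM_MU = math.log(10.0)
FRAILTY_LOGNORM_SIGMA = (math.log(23.0) - math.log(10.0)) / 1.0364333894937898


def _jitter(rng: np.random.Generator, scale: float = 0.03):
    """Multiplicative jitter factor ~ U(1-scale, 1+scale)."""
    return float(rng.uniform(1.0 - scale, 1.0 + scale))


def default_synthetic_parameters(seed: int = 1) -> ParameterSet:
    """Build the documented synthetic default :class:`ParameterSet`.

    Deterministic for ``seed``; see ``docs/methods.md`` for the data
    dictionary justifying each magnitude.
    """
    rng = np.random.default_rng(seed)
    j = lambda s=0.03: _jitter(rng, s)  # noqa: E731 - local shorthand

    covariate_models = {
        "high_physical_activity": RegressionSpec(
            "high_physical_activity", "logistic", -0.5 * j(),
            {"age_minus_60": -0.04 * j(), "frailty_score": -0.03 * j()},
        ),
        "cognitive_impairment": RegressionSpec(
            "cognitive_impairment", "logistic", -3.2 * j(),
            {"age_minus_60": 0.05 * j(), "frailty_score": 0.02 * j()},
        ),
        "fear_of_falling": RegressionSpec(
            "fear_of_falling", "logistic", -1.6 * j(),
            {"frailty_score": 0.03 * j(), "falls_single": 0.5 * j(),
             "falls_recurrent": 1.0 * j()},
        ),
        "abnormal_gait_balance": RegressionSpec(
            "abnormal_gait_balance", "logistic", -2.0 * j(),
            {"frailty_score": 0.035 * j(), "age_minus_60": 0.02 * j()},
        ),
    }

    outcome_models = {
        # health utility (EQ-5D-3L scale): declines with age and frailty
        "eq5d": RegressionSpec(
            "eq5d", "linear", 0.92,
            {"frailty_score": -0.0045 * j(), "age_minus_60": -0.003 * j(),
             "fear_of_falling": -0.04 * j(), "falls_recurrent": -0.03 * j(),
             "high_physical_activity": 0.03 * j()},
            value_range=[-0.2, 1.0],
        ),
        # social wellbeing (CASP-19 rescaled 0-1)
        "casp19": RegressionSpec(
            "casp19", "linear", 0.80,
            {"frailty_score": -0.003 * j(), "age_minus_60": -0.0015 * j(),
             "cognitive_impairment": -0.03 * j(),
             "high_physical_activity": 0.02 * j()},
            value_range=[0.0, 1.0],
        ),
        # comorbidity primary/secondary healthcare cost, £/yr; rises with
        # frailty — this is the channel that makes feedback removal matter
        "healthcare_cost": RegressionSpec(
            "healthcare_cost", "linear", 700.0 * j(),
            {"frailty_score": 35.0 * j(), "age_minus_60": 30.0 * j()},
            value_range=[0.0, 1e9],
        ),
        "community_care_cost": RegressionSpec(
            "community_care_cost", "linear", 120.0 * j(),
            {"frailty_score": 14.0 * j()}, value_range=[0.0, 1e9],
        ),
        "social_care_cost": RegressionSpec(
            "social_care_cost", "linear", 80.0 * j(),
            {"frailty_score": 10.0 * j()}, value_range=[0.0, 1e9],
        ),
        # paid + unpaid work value, £/yr; clamped at zero — the zero boundary
        # doubles as the any-work flag for the productive-ageing metric
        "productivity_value": RegressionSpec(
            "productivity_value", "linear", 4000.0 * j(),
            {"age_minus_60": -270.0 * j(), "frailty_score": -45.0 * j(),
             "high_physical_activity": 900.0 * j(), "sex_female": 150.0 * j()},
            value_range=[0.0, 1e9],
        ),
        # out-of-pocket care expenditure, £/yr; privileged quartiles spend more
        "oop_expenditure": RegressionSpec(
            "oop_expenditure", "linear", 250.0 * j(),
            {"frailty_score": 18.0 * j(), "ses_q2": -80.0 * j(),
             "ses_q3": -150.0 * j(), "ses_q4": -220.0 * j()},
            value_range=[0.0, 1e9],
        ),
        "informal_care_cost": RegressionSpec(
            "informal_care_cost", "linear", 400.0 * j(),
            {"frailty_score": 80.0 * j(), "age_minus_60": 15.0 * j(),
             "cognitive_impairment": 2500.0 * j()},
            value_range=[0.0, 1e9],
        ),
    }

    cascade_models = {
        "any_fall": RegressionSpec(
            "any_fall", "logistic", -1.1 * j(),
            {"frailty_score": 0.025 * j(), "age_minus_60": 0.015 * j(),
             "falls_single": 0.35 * j(), "falls_recurrent": 0.7 * j(),
             "fear_of_falling": 0.3 * j(), "abnormal_gait_balance": 0.4 * j(),
             "high_physical_activity": -0.2 * j()},
        ),
        "recurrent_given_any": RegressionSpec(
            "recurrent_given_any", "logistic", -0.4 * j(),
            {"frailty_score": 0.015 * j(), "falls_recurrent": 0.3 * j()},
        ),
        "ma_given_single": RegressionSpec(
            "ma_given_single", "logistic", -1.2 * j(), {"frailty_score": 0.01 * j()},
        ),
        "ma_given_recurrent": RegressionSpec(
            "ma_given_recurrent", "logistic", -0.6 * j(), {"frailty_score": 0.01 * j()},
        ),
        "second_ma_given_recurrent_ma": RegressionSpec(
            "second_ma_given_recurrent_ma", "logistic", -0.85 * j(), {},
        ),
    }

    frailty_progression = RegressionSpec(
        "frailty_progression", "linear", 0.35 * j(),
        {"age_minus_60": 0.015 * j(), "high_physical_activity": -0.25 * j(),
         # categorical falls-incidence terms — the falls->frailty feedback
         "fall_single_nonma": 0.25 * j(), "fall_single_ma": 0.7 * j(),
         "fall_recurrent_nonma": 0.5 * j(), "fall_recurrent_ma": 1.1 * j()},
    )

    ltc_admission = RegressionSpec(
        "ltc_admission", "logistic", -7.5 * j(0.02),
        {"frailty_score": 0.05 * j(), "age_minus_60": 0.07 * j(),
         "frailty_delta": 0.35 * j(), "falls_recurrent": 0.3 * j()},
    )

    self_referral_demand_rc = RegressionSpec(
        "self_referral_demand_rc", "logistic", -3.4 * j(0.02),
        {"exercise_history": 1.5 * j()},
    )

    params = ParameterSet(
        baseline_covariate_models=covariate_models,
        baseline_outcome_models=outcome_models,
        cascade_models=cascade_models,
        frailty_progression_model=frailty_progression,
        ltc_admission_model=ltc_admission,
        self_referral_demand_rc=self_referral_demand_rc,
        # 5-year bands: 60-64, 65-69, ..., 90-94, 95+
        mortality_age_bands=[60, 65, 70, 75, 80, 85, 90, 95],
        mortality_base_male=[0.008, 0.012, 0.019, 0.031, 0.053, 0.092, 0.16, 0.27],
        mortality_base_female=[0.005, 0.008, 0.013, 0.022, 0.039, 0.071, 0.13, 0.24],
        mortality_frailty_hr={"fit": 1.0, "mild": 1.4, "moderate": 2.0, "severe": 3.0},
        fatal_fall_base=[1e-4, 1.5e-4, 2e-4, 3e-4, 5e-4, 8e-4, 1.3e-3, 2e-3],
        fatal_fall_frailty_factor={"fit": 1.0, "mild": 1.5, "moderate": 2.5, "severe": 4.0},
        unit_costs={
            "fall_nonma_single": 60.0 * j(),
            "fall_nonma_recurrent": 120.0 * j(),
            "fall_ma_nonhosp": 1400.0 * j(),
            "fall_ma_hosp": 7500.0 * j(),
            "cost_of_dying": 5500.0 * j(),
            "ltc_admission": 60000.0 * j(),
            "copay_share_rc": 0.15,
            "participant_toc": 180.0 * j(),
            "caregiver_toc": 200.0 * j(),
        },
        intervention_public_cost={
            "HAM": 550.0 * j(), "multifactorial": 1150.0 * j(), "exercise": 250.0 * j(),
        },
        acute_qaly_loss={
            "fall_nonma_single": 0.002, "fall_nonma_recurrent": 0.004,
            "fall_ma_nonhosp": 0.015, "fall_ma_hosp": 0.06,
        },
        efficacy={
            "HAM": min(1.0, 0.88 * j(0.02)),
            "multifactorial": min(1.0, 0.73 * j(0.02)),
            "exercise": min(1.0, 0.77 * j(0.02)),
        },
        access={
            "gp_contact": 0.81,
            "screening_uc": 0.31,
            "screening_rc": 1.0,
            "uptake_uc": 0.34,
            "uptake_rc": 0.6,
            "self_referral_uc": 0.001,
            "hospitalised_ma_share": 0.28,
        },
        ltc_public_share=[0.35, 0.55, 0.75, 0.90],
        capacity_to_pay=[130000.0, 85000.0, 55000.0, 32000.0],
        ltc_mean_remaining_qaly=1.3,
        baseline_population={
            "age_decay": 0.93,          # P(entry age a) ∝ age_decay^(a-60)
            "max_age": 99,
            "female_share": 0.55,
            "falls_history_probs": [0.72, 0.18, 0.10],  # none / single / recurrent
            "frailty_lognorm_mu": FRAILTY_LOGNORM_MU,
            "frailty_lognorm_sigma": FRAILTY_LOGNORM_SIGMA,
            "ses_probs": [0.25, 0.25, 0.25, 0.25],
        },
        psa_distributions={
            # probabilities ~ Beta, costs ~ Gamma, coefficients ~ Normal
            "efficacy_multifactorial": {
                "path": "efficacy.multifactorial", "family": "beta", "a": 73.0, "b": 27.0,
            },
            "efficacy_exercise": {
                "path": "efficacy.exercise", "family": "beta", "a": 77.0, "b": 23.0,
            },
            "efficacy_ham": {
                "path": "efficacy.HAM", "family": "beta", "a": 88.0, "b": 12.0,
            },
            "uptake_rc": {
                "path": "access.uptake_rc", "family": "beta", "a": 60.0, "b": 40.0,
            },
            "cost_ma_hosp": {
                "path": "unit_costs.fall_ma_hosp", "family": "gamma",
                "shape": 100.0, "mean": 7500.0,
            },
            "cost_multifactorial": {
                "path": "intervention_public_cost.multifactorial", "family": "gamma",
                "shape": 100.0, "mean": 1150.0,
            },
            "any_fall_intercept": {
                "path": "cascade_models.any_fall.intercept", "family": "normal",
                "mu": -1.1, "sd": 0.05,
            },
            "frailty_fall_recurrent_ma": {
                "path": "frailty_progression_model.coefficients.fall_recurrent_ma",
                "family": "normal", "mu": 1.1, "sd": 0.1,
            },
        },
    )
    params.validate()
    return params
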