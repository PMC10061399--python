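"""Scenario transformations, subgroup reporting and usage reporting.

Scenario toggles (horizon, discount rates, feedback removal, the 20%
frailty/mortality multipliers) are plain configuration values interpreted by
the engine at run time; ``apply_scenario`` never mutates its input.  Subgroup
reports slice the paired per-individual frames on entry characteristics and
conserve population totals exactly (partition property).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .economics import (
    LAMBDA_PUBLIC,
    LAMBDA_SOCIETAL,
    StrategyResult,
    icer,
    net_components,
)
from .params import ParameterSet, ScenarioConfig
from .population import frailty_category_codes

__all__ = [
    "apply_scenario", "scale_initial_frailty", "SUBGROUP_DIMENSIONS",
    "subgroup_report", "usage_report", "annual_average", "fold_change",
]


def scale_initial_frailty(score, multiplier: float):
    """Entry-frailty scenario: multiply baseline scores, clamped to [0, 100]."""
    return np.clip(np.asarray(score, dtype=float) * multiplier, 0.0, 100.0)


def apply_scenario(params: ParameterSet, scenario: ScenarioConfig):
    """Validate and bind a (parameters, scenario) pair for execution.

    Returns a deep copy of ``params`` together with the validated scenario;
    the multiplicative toggles are interpreted by the engine per cycle (the
    mortality-gradient scenario in particular needs the live population to
    renormalise against), so the source parameter set is never mutated.
    """
    scenario.validate()
    out = params.copy()
    out.validate()
    return out, scenario


# ---------------------------------------------------------------------------
# subgroup reporting
# ---------------------------------------------------------------------------

_CATEGORY_NAMES = np.array(["fit", "mild", "moderate", "severe"])


def _age_band(age: pd.Series) -> pd.Series:
    lo = (np.minimum(age, 90) // 5 * 5).astype(int)
    return lo.astype(str) + "-" + (lo + 4).astype(str)


SUBGROUP_DIMENSIONS = {
    "entry_cohort": lambda df: np.where(df["entry_cycle"] == 1, "initial", "new"),
    "age_band_at_entry": lambda df: _age_band(df["age_at_entry"]),
    "sex": lambda df: np.where(df["sex_female"] == 1, "female", "male"),
    "initial_frailty_category": lambda df: _CATEGORY_NAMES[
        frailty_category_codes(df["frailty_at_entry"])
    ],
    "initial_physical_activity": lambda df: np.where(
        df["high_physical_activity"] == 1, "high", "not_high"
    ),
    "initial_cognitive_status": lambda df: np.where(
        df["cognitive_impairment"] == 1, "impaired", "intact"
    ),
    "initial_fear_of_falling": lambda df: np.where(
        df["fear_of_falling"] == 1, "fearful", "not_fearful"
    ),
    "initial_gait_balance": lambda df: np.where(
        df["abnormal_gait_balance"] == 1, "abnormal", "normal"
    ),
    "initial_falls_history": lambda df: np.array(["none", "single", "recurrent"])[
        df["falls_history_at_entry"]
    ],
    "ses_quartile": lambda df: "Q" + df["ses_quartile"].astype(str),
}

_REPORT_STREAMS = (
    "qaly", "allcause_public_cost", "fall_healthcare", "intervention_public_cost",
    "productivity_value", "participant_toc", "oop_expenditure", "co_payment",
    "informal_care_cost", "caregiver_toc",
)


def subgroup_report(
    uc: StrategyResult, rc: StrategyResult, dimension: str,
    lambda_public: float = LAMBDA_PUBLIC, lambda_societal: float = LAMBDA_SOCIETAL,
) -> pd.DataFrame:
    """Per-level incremental summaries on common random numbers.

    Row sums over levels conserve the population-level deltas exactly.
    """
    if dimension not in SUBGROUP_DIMENSIONS:
        raise KeyError(f"unknown subgroup dimension {dimension!r}")
    if len(uc.individuals) != len(rc.individuals):
        raise ValueError("paired results must hold identical populations")
    key = SUBGROUP_DIMENSIONS[dimension]
    du, dr = uc.individuals, rc.individuals
    labels = pd.Series(key(du), name="level")
    sums_uc = du[list(_REPORT_STREAMS)].groupby(labels).sum()
    sums_rc = dr[list(_REPORT_STREAMS)].groupby(pd.Series(key(dr), name="level")).sum()
    delta = (sums_rc - sums_uc).add_prefix("delta_")
    delta["n"] = labels.value_counts()

    net_prod, net_fin, net_inf, soc_equiv = net_components(
        delta["delta_productivity_value"], delta["delta_participant_toc"],
        delta["delta_oop_expenditure"], delta["delta_co_payment"],
        delta["delta_informal_care_cost"], delta["delta_caregiver_toc"],
        lambda_societal,
    )
    delta["net_productivity_gain"] = net_prod
    delta["net_personal_finance_cost"] = net_fin
    delta["net_informal_care_cost"] = net_inf
    delta["societal_gain_qaly_equivalent"] = soc_equiv
    delta["delta_societal_qaly"] = delta["delta_qaly"] + soc_equiv
    d_cost = delta["delta_allcause_public_cost"] + delta["delta_intervention_public_cost"]
    delta["icer_allcause"] = [
        icer(c, q) if q != 0 else np.nan
        for c, q in zip(d_cost, delta["delta_societal_qaly"])
    ]
    return delta


# ---------------------------------------------------------------------------
# usage reporting
# ---------------------------------------------------------------------------

def annual_average(total_person_years: float, horizon_years: int) -> float:
    """Annual average intervention use from total person-years."""
    if horizon_years < 1:
        raise ValueError("horizon must be >= 1")
    return total_person_years / horizon_years


def fold_change(uc_value: float, rc_value: float) -> float:
    """RC/UC fold change; NaN marks an undefined ratio (zero UC use)."""
    if uc_value == 0:
        return float("nan")
    return rc_value / uc_value


def usage_report(uc: StrategyResult, rc: StrategyResult) -> pd.DataFrame:
    """Per-pathway person-years of use, annual averages and fold changes."""
    rows = []
    pathways = list(uc.usage) + ["total"]
    totals_uc = {**uc.usage, "total": sum(uc.usage.values())}
    totals_rc = {**rc.usage, "total": sum(rc.usage.values())}
    for p in pathways:
        rows.append({
            "pathway": p,
            "person_years_uc": totals_uc[p],
            "person_years_rc": totals_rc[p],
            "annual_average_uc": annual_average(totals_uc[p], uc.horizon),
            "annual_average_rc": annual_average(totals_rc[p], rc.horizon),
            "fold_change": fold_change(totals_uc[p], totals_rc[p]),
        })
    return pd.DataFrame(rows).set_index("pathway")
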