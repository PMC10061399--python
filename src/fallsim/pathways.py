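"""Intervention pathways: eligibility, access and costing.

Three parallel pathways feed falls-prevention interventions:

* **reactive** — triggered by a medical-attention (MA) fall in the previous
  cycle.  Usual care (UC) refers only hospitalised MA fallers to home
  assessment and modification (HAM); recommended care (RC) refers every MA
  faller to the multifactorial intervention.
* **proactive** — screening at routine GP contact.  The chain is
  GP contact x screened x high falls risk x uptake; UC additionally requires
  the person to be cognitively intact and never previously served, RC screens
  everyone at contact regardless of cognitive status but caps re-receipt
  (three previous re-receipts exclude the fourth).
* **self-referred** — exercise.  Under UC a 0.1% demand confined to the most
  privileged SES quartile, fully self-financed; under RC publicly funded with
  demand rising once someone has an exercise history.

A person receives at most one pathway per cycle (reactive > proactive >
self-referred precedence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, evaluate_model
from .population import FALLS_RECURRENT, STATUS_COMMUNITY, covariate_dict

__all__ = [
    "PATHWAY_NONE", "PATHWAY_REACTIVE", "PATHWAY_PROACTIVE", "PATHWAY_SELF",
    "PathwayAssignment", "assess_high_falls_risk", "eligible_reactive",
    "proactive_access_probability", "sample_proactive_access",
    "sample_self_referred", "assign_intervention", "assign_pathways_vectorised",
]

PATHWAY_NONE, PATHWAY_REACTIVE, PATHWAY_PROACTIVE, PATHWAY_SELF = 0, 1, 2, 3
_PATHWAY_NAMES = ("none", "reactive", "proactive", "self_referred")

#: RC re-receipt cap: three previous re-receipts (four receipts) exclude further ones
MAX_PROACTIVE_RECEIPTS_RC = 4


@dataclass
class PathwayAssignment:
    """Outcome of pathway assignment for one person-cycle."""

    pathway: str = "none"
    intervention: str | None = None
    public_cost: float = 0.0
    co_payment: float = 0.0
    participant_toc: float = 0.0
    caregiver_toc: float = 0.0
    efficacy_multiplier: float = 1.0


def assess_high_falls_risk(x):
    """High falls risk: recurrent falls in the past year and/or abnormal
    gait/balance (guideline screening criterion)."""
    falls = np.asarray(x.falls_history)
    gait = np.asarray(x.abnormal_gait_balance)
    out = (falls == FALLS_RECURRENT) | (gait == 1)
    if out.ndim == 0:
        return bool(out)
    return out


def eligible_reactive(x, last_cycle_fall, strategy: str) -> bool:
    """Reactive eligibility from the previous cycle's fall record.

    ``last_cycle_fall`` is any object exposing ``n_ma_falls`` and
    ``any_hospitalised`` (see :class:`fallsim.cycle.FallerType`), or None.
    """
    if last_cycle_fall is None or last_cycle_fall.n_ma_falls == 0:
        return False
    if strategy == "UC":
        return bool(last_cycle_fall.any_hospitalised)
    return True


def proactive_access_probability(x, strategy: str, params: ParameterSet) -> float:
    """Joint probability of proactive access for a person this cycle."""
    access = params.access
    if not assess_high_falls_risk(x):
        return 0.0
    if strategy == "UC":
        if x.cognitive_impairment or x.proactive_receipts > 0:
            return 0.0
        return access["gp_contact"] * access["screening_uc"] * access["uptake_uc"]
    if x.proactive_receipts >= MAX_PROACTIVE_RECEIPTS_RC:
        return 0.0
    return access["gp_contact"] * access["screening_rc"] * access["uptake_rc"]


def sample_proactive_access(x, strategy, params, rng, size: int | None = None):
    """Bernoulli draw(s) of proactive access (GP contact x screening x risk
    x uptake chain).  ``size`` draws the same person repeatedly."""
    p = proactive_access_probability(x, strategy, params)
    if size is None:
        return bool(rng.random() < p)
    return rng.random(size) < p


def self_referral_probability(x, strategy: str, params: ParameterSet) -> float:
    if strategy == "UC":
        if x.ses_quartile != 1:
            return 0.0
        return params.access["self_referral_uc"]
    return float(evaluate_model(params.self_referral_demand_rc, covariate_dict(x)))


def sample_self_referred(x, strategy, params, rng, size: int | None = None):
    """Bernoulli draw(s) of self-referred exercise uptake."""
    p = self_referral_probability(x, strategy, params)
    if size is None:
        return bool(rng.random() < p)
    return rng.random(size) < p


def _intervention_for(pathway: int, strategy: str) -> str | None:
    if pathway == PATHWAY_REACTIVE:
        return "HAM" if strategy == "UC" else "multifactorial"
    if pathway == PATHWAY_PROACTIVE:
        return "multifactorial"
    if pathway == PATHWAY_SELF:
        return "exercise"
    return None


def assign_intervention(x, pathway: str, strategy: str, params: ParameterSet) -> PathwayAssignment:
    """Cost and efficacy assignment for a granted pathway (scalar form)."""
    code = _PATHWAY_NAMES.index(pathway)
    if code == PATHWAY_NONE:
        return PathwayAssignment()
    intervention = _intervention_for(code, strategy)
    base = params.intervention_public_cost[intervention]
    if strategy == "UC":
        if code == PATHWAY_SELF:
            public, copay = 0.0, base            # self-financed
        else:
            public, copay = base, 0.0
    else:
        share = params.unit_costs["copay_share_rc"]
        public, copay = base * (1.0 - share), base * share
    return PathwayAssignment(
        pathway=pathway,
        intervention=intervention,
        public_cost=public,
        co_payment=copay,
        participant_toc=params.unit_costs["participant_toc"],
        caregiver_toc=params.unit_costs["caregiver_toc"] if x.cognitive_impairment else 0.0,
        efficacy_multiplier=params.efficacy[intervention],
    )


def assign_pathways_vectorised(pop, strategy: str, params: ParameterSet, ern, cycle: int):
    """One cycle of pathway assignment over a Population.

    Returns a dict of row-aligned arrays: pathway codes, per-stream costs and
    the efficacy multiplier feeding the falls cascade.  Mutates the
    population's ``gp_contact_this_cycle``, ``proactive_receipts`` and
    ``exercise_history`` fields.
    """
    n = len(pop)
    alive = pop.status == STATUS_COMMUNITY
    access = params.access

    u_gp = ern.uniforms("gp_contact", cycle, n)
    gp_contact = alive & (u_gp < access["gp_contact"])
    pop.set("gp_contact_this_cycle", gp_contact.astype(np.int64))

    # reactive: previous cycle's MA fall
    if strategy == "UC":
        reactive = alive & (pop.prev_hospitalised_ma == 1)
    else:
        reactive = alive & (pop.prev_ma_fall == 1)

    # proactive
    high_risk = assess_high_falls_risk(pop)
    u_screen = ern.uniforms("screening", cycle, n)
    u_uptake = ern.uniforms("uptake", cycle, n)
    screening_rate = access["screening_uc"] if strategy == "UC" else access["screening_rc"]
    uptake_rate = access["uptake_uc"] if strategy == "UC" else access["uptake_rc"]
    proactive = (
        alive & ~reactive & gp_contact & high_risk
        & (u_screen < screening_rate) & (u_uptake < uptake_rate)
    )
    if strategy == "UC":
        proactive &= (pop.cognitive_impairment == 0) & (pop.proactive_receipts == 0)
    else:
        proactive &= pop.proactive_receipts < MAX_PROACTIVE_RECEIPTS_RC

    # self-referred
    u_self = ern.uniforms("self_referral", cycle, n)
    if strategy == "UC":
        p_self = np.where(pop.ses_quartile == 1, access["self_referral_uc"], 0.0)
    else:
        p_self = np.asarray(
            evaluate_model(params.self_referral_demand_rc, covariate_dict(pop))
        )
    self_ref = alive & ~reactive & ~proactive & (u_self < p_self)

    pathway = np.zeros(n, dtype=np.int64)
    pathway[reactive] = PATHWAY_REACTIVE
    pathway[proactive] = PATHWAY_PROACTIVE
    pathway[self_ref] = PATHWAY_SELF

    pop.set("proactive_receipts", pop.proactive_receipts + proactive.astype(np.int64))
    pop.set("exercise_history", np.maximum(pop.exercise_history, self_ref.astype(np.int64)))

    base = np.zeros(n)
    efficacy = np.ones(n)
    reactive_iv = "HAM" if strategy == "UC" else "multifactorial"
    base[reactive] = params.intervention_public_cost[reactive_iv]
    efficacy[reactive] = params.efficacy[reactive_iv]
    base[proactive] = params.intervention_public_cost["multifactorial"]
    efficacy[proactive] = params.efficacy["multifactorial"]
    base[self_ref] = params.intervention_public_cost["exercise"]
    efficacy[self_ref] = params.efficacy["exercise"]

    any_pathway = pathway > 0
    if strategy == "UC":
        public_cost = np.where(self_ref, 0.0, base)
        co_payment = np.where(self_ref, base, 0.0)
    else:
        share = params.unit_costs["copay_share_rc"]
        public_cost = base * (1.0 - share)
        co_payment = base * share

    participant_toc = np.where(any_pathway, params.unit_costs["participant_toc"], 0.0)
    caregiver_toc = np.where(
        any_pathway & (pop.cognitive_impairment == 1),
        params.unit_costs["caregiver_toc"], 0.0,
    )

    return {
        "pathway": pathway,
        "public_cost": public_cost,
        "co_payment": co_payment,
        "participant_toc": participant_toc,
        "caregiver_toc": caregiver_toc,
        "efficacy_multiplier": efficacy,
    }
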