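"""Distributional cost-effectiveness analysis and lifetime equity metrics.

Equity is assessed over socioeconomic-status (SES) quartiles.  Each
strategy's per-capita societal net health benefit (NHB) per quartile is
collapsed into an equally distributed equivalent (EDE) under relative
(Atkinson, aversion ε) or absolute (Kolm, aversion α) inequality aversion:

    EDE_Atkinson = [ (1/n) Σ v_i^(1-ε) ]^(1/(1-ε))        (ε = 1: geometric mean)
    EDE_Kolm     = -(1/α) log( (1/n) Σ exp(-α v_i) )

The incremental EDE NHB of recommended vs usual care is compared with the
incremental no-aversion benefit (INAB, the plain mean difference): both
positive with EDE INHB > INAB means the strategy improves efficiency *and*
equity; EDE INHB < INAB signals an equity-efficiency trade-off.

Individual-level lifetime outcomes count persons reaching normative
thresholds: fair health/wellbeing innings (60% of the usual-care median
lifetime QALY / wellbeing-year total), productive ageing (>= 10 work years
from age 65), catastrophic private expenditure (deprived quartiles spending
more than 40% of capacity to pay) and excessive informal caregiver burden
(accumulated caregiving value above five years' national-living-wage income).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .economics import LAMBDA_PUBLIC, LAMBDA_SOCIETAL, StrategyResult

__all__ = [
    "ATKINSON_GRID", "KOLM_GRID", "EXCESSIVE_BURDEN_THRESHOLD",
    "atkinson_ede", "kolm_ede", "QuartileNhb", "per_quartile_nhb",
    "EdeCurve", "dcea", "LifetimeOutcomeCounts", "lifetime_outcomes",
    "baseline_cohort_aged",
]

ATKINSON_GRID = (0.0, 3.0, 5.0, 11.0, 15.0, 20.0, 25.0, 30.0)
KOLM_GRID = (0.025, 0.05, 0.15, 0.25, 0.4, 0.5)

#: five times annual national-living-wage income, £
EXCESSIVE_BURDEN_THRESHOLD = 85_025.0

#: catastrophic expenditure: spend exceeding this share of capacity to pay
CPE_CAPACITY_SHARE = 0.4


def atkinson_ede(values, epsilon: float) -> float:
    """Atkinson (relative-aversion) equally distributed equivalent."""
    v = np.asarray(values, dtype=float)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return float(v.mean())
    if np.any(v <= 0):
        raise ValueError("Atkinson EDE requires strictly positive values for epsilon > 0")
    if epsilon == 1.0:
        return float(np.exp(np.mean(np.log(v))))  # continuity limit
    return float(np.mean(v ** (1.0 - epsilon)) ** (1.0 / (1.0 - epsilon)))


def kolm_ede(values, alpha: float) -> float:
    """Kolm (absolute-aversion) EDE, evaluated via log-sum-exp for stability."""
    v = np.asarray(values, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(-(logsumexp(-alpha * v) - np.log(v.size)) / alpha)


@dataclass
class QuartileNhb:
    """Per-capita societal NHB by SES quartile (1 most privileged .. 4)."""

    strategy: str
    values: np.ndarray                 # shape (4,)
    n_per_quartile: np.ndarray

    @property
    def mean(self) -> float:
        """Unweighted mean over quartiles (subgroups treated as equal size)."""
        return float(np.mean(self.values))


_SOCIETAL_GAIN_STREAMS = (
    ("productivity_value", +1),
    ("participant_toc", -1),
    ("oop_expenditure", -1),
    ("co_payment", -1),
    ("informal_care_cost", -1),
    ("caregiver_toc", -1),
)


def per_quartile_nhb(
    result: StrategyResult,
    lambda_public: float = LAMBDA_PUBLIC,
    lambda_societal: float = LAMBDA_SOCIETAL,
) -> QuartileNhb:
    """Per-capita societal NHB per quartile:
    (QALY + societal net gain/λ_soc − public cost/λ_pub) / n."""
    df = result.individuals
    values = np.empty(4)
    counts = np.empty(4, dtype=np.int64)
    for q in range(1, 5):
        sub = df[df["ses_quartile"] == q]
        if len(sub) == 0:
            raise ValueError(f"SES quartile {q} is empty")
        societal = sum(sign * sub[name].sum() for name, sign in _SOCIETAL_GAIN_STREAMS)
        public = sub["allcause_public_cost"].sum() + sub["intervention_public_cost"].sum()
        nhb = sub["qaly"].sum() + societal / lambda_societal - public / lambda_public
        values[q - 1] = nhb / len(sub)
        counts[q - 1] = len(sub)
    return QuartileNhb(strategy=result.strategy, values=values, n_per_quartile=counts)


@dataclass
class EdeCurve:
    """DCEA output: EDE levels and incremental EDE NHBs over aversion grids."""

    inab: float
    table: pd.DataFrame                # aversion_type, aversion, ede_uc, ede_rc, ede_inhb
    classification: str

    def row(self, aversion_type: str, aversion: float) -> pd.Series:
        t = self.table
        match = t[(t["aversion_type"] == aversion_type) & (t["aversion"] == aversion)]
        if match.empty:
            raise KeyError((aversion_type, aversion))
        return match.iloc[0]


def _classify(inab: float, ede_inhbs: np.ndarray) -> str:
    if inab > 0 and np.all(ede_inhbs > 0):
        if np.all(ede_inhbs[1:] >= inab):
            return "joint efficiency and equity improvement"
        return "efficient with equity-efficiency trade-off"
    if inab <= 0 and np.all(ede_inhbs <= 0):
        return "not preferred on efficiency or equity"
    return "mixed"


def dcea(
    uc: QuartileNhb, rc: QuartileNhb,
    atkinson_grid=ATKINSON_GRID, kolm_grid=KOLM_GRID,
) -> EdeCurve:
    """Incremental DCEA of RC versus UC over the aversion grids."""
    inab = rc.mean - uc.mean
    rows = []
    for eps in atkinson_grid:
        ede_uc = atkinson_ede(uc.values, eps)
        ede_rc = atkinson_ede(rc.values, eps)
        rows.append({
            "aversion_type": "atkinson", "aversion": float(eps),
            "ede_uc": ede_uc, "ede_rc": ede_rc, "ede_inhb": ede_rc - ede_uc,
        })
    for alpha in kolm_grid:
        ede_uc = kolm_ede(uc.values, alpha)
        ede_rc = kolm_ede(rc.values, alpha)
        rows.append({
            "aversion_type": "kolm", "aversion": float(alpha),
            "ede_uc": ede_uc, "ede_rc": ede_rc, "ede_inhb": ede_rc - ede_uc,
        })
    table = pd.DataFrame(rows)
    table["ratio_to_inab"] = table["ede_inhb"] / inab if inab != 0 else np.nan
    return EdeCurve(
        inab=inab, table=table,
        classification=_classify(inab, table["ede_inhb"].to_numpy()),
    )


@dataclass
class LifetimeOutcomeCounts:
    """Counts of cohort members reaching each lifetime equity threshold."""

    n_cohort: int
    fair_health_innings: int
    fair_wellbeing_innings: int
    productive_ageing: int
    catastrophic_private_expenditure: int
    cpe_excluding_copayments: int
    excessive_informal_burden: int
    burden_excluding_toc: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def baseline_cohort_aged(result: StrategyResult, age: float = 65.0) -> pd.DataFrame:
    """Members of the initial cohort who entered at the given age."""
    df = result.individuals
    return df[(df["entry_cycle"] == 1) & (df["age_at_entry"] == age)]


def lifetime_outcomes(
    cohort: pd.DataFrame,
    uc_reference: pd.DataFrame,
    capacity_to_pay,
    *,
    discounted: bool = True,
) -> LifetimeOutcomeCounts:
    """Individual-level lifetime outcome counts for one strategy's cohort.

    Fair-innings thresholds are 60% of the usual-care median lifetime QALY
    (and wellbeing-year) total for the same cohort; by default the discounted
    lifetime totals are used (set ``discounted=False`` for the undiscounted
    counters).  Catastrophic private expenditure applies only to SES
    quartiles 3-4 and uses a strict inequality, as does the caregiver-burden
    threshold.
    """
    if len(cohort) == 0 or len(uc_reference) == 0:
        raise ValueError("cohort and UC reference must be non-empty")
    qaly_col = "qaly" if discounted else "lifetime_qaly"
    well_col = "wellbeing" if discounted else "lifetime_wellbeing"
    fair_q = 0.6 * float(uc_reference[qaly_col].median())
    fair_w = 0.6 * float(uc_reference[well_col].median())

    capacity = np.asarray(capacity_to_pay, dtype=float)
    ses = cohort["ses_quartile"].to_numpy()
    deprived = ses >= 3
    cpe_limit = CPE_CAPACITY_SHARE * capacity[ses - 1]

    burden_with_toc = (
        cohort["informal_care_value_cum"].to_numpy()
        + cohort["caregiver_toc_cum"].to_numpy()
    )
    return LifetimeOutcomeCounts(
        n_cohort=len(cohort),
        fair_health_innings=int((cohort[qaly_col] >= fair_q).sum()),
        fair_wellbeing_innings=int((cohort[well_col] >= fair_w).sum()),
        productive_ageing=int((cohort["work_years_since_65"] >= 10).sum()),
        catastrophic_private_expenditure=int(
            (deprived & (cohort["private_expenditure_cum"].to_numpy() > cpe_limit)).sum()
        ),
        cpe_excluding_copayments=int(
            (deprived
             & (cohort["private_expenditure_excl_copay_cum"].to_numpy() > cpe_limit)).sum()
        ),
        excessive_informal_burden=int((burden_with_toc > EXCESSIVE_BURDEN_THRESHOLD).sum()),
        burden_excluding_toc=int(
            (cohort["informal_care_value_cum"].to_numpy() > EXCESSIVE_BURDEN_THRESHOLD).sum()
        ),
    )
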