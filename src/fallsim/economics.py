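"""Strategy execution and societal cost-utility analytics.

``run_strategy`` simulates one strategy end-to-end (baseline population plus
annual entry cohorts of 60-year-olds) and returns population aggregates plus
a per-individual outcome frame.  ``compare`` forms the incremental summary of
recommended care (RC) against usual care (UC) on common random numbers:
public-sector cost deltas, QALY gain, the three net societal components and
their QALY equivalent at the societal threshold, ICERs and net benefits.

Uncertainty handling follows standard health-economics practice: parameter
(second-order) uncertainty via probabilistic sensitivity analysis with a
cost-effectiveness acceptability curve, and first-order uncertainty via
multi-seed deterministic averaging.  Averaging ratios across runs is biased,
so the pooled ICER is reported with its jack-knife (leave-one-out) mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .accounting import EXIT_NONE, EXIT_HORIZON, OutcomeLedger
from .cycle import step_cycle
from .params import ParameterSet, ScenarioConfig
from .population import Population, spawn_entry_cohort, synthesize_population
from .rng import EventRng

__all__ = [
    "StrategyResult", "CuaSummary", "run_strategy", "compare", "net_components",
    "icer", "inmb", "inhb", "jackknife_mean_icer", "run_psa", "ceac",
    "run_deterministic", "LAMBDA_PUBLIC", "LAMBDA_SOCIETAL",
]

#: cost-effectiveness thresholds, £ per QALY gained
LAMBDA_PUBLIC = 30_000.0
LAMBDA_SOCIETAL = 60_000.0

_ENTRY_COLUMNS = (
    "id", "age", "sex_female", "ses_quartile", "falls_history", "frailty_score",
    "high_physical_activity", "cognitive_impairment", "fear_of_falling",
    "abnormal_gait_balance", "entry_cycle",
)


@dataclass
class StrategyResult:
    """Population aggregates for one simulated strategy."""

    strategy: str
    seed: int
    horizon: int
    n_individuals: int
    totals: dict
    person_years_any_fall: int
    usage: dict                       # pathway -> person-years of use
    individuals: pd.DataFrame         # entry covariates + lifetime ledger
    cycle_stats: list = field(default_factory=list)


def _entry_snapshot(pop: Population) -> pd.DataFrame:
    df = pd.DataFrame({col: pop.arrays[col] for col in _ENTRY_COLUMNS})
    return df.rename(columns={"age": "age_at_entry", "frailty_score": "frailty_at_entry",
                              "falls_history": "falls_history_at_entry"})


def run_strategy(params: ParameterSet, scenario: ScenarioConfig, seed: int) -> StrategyResult:
    """Simulate the full horizon for ``scenario.strategy``; deterministic per seed."""
    scenario.validate()
    strategy = scenario.strategy
    ern = EventRng(seed)
    mult = scenario.toggles.initial_frailty_multiplier

    pop = synthesize_population(
        params, scenario.population_size, seed, initial_frailty_multiplier=mult
    )
    entries = [_entry_snapshot(pop)]
    ledger = OutcomeLedger.empty(len(pop))

    cycle_stats = []
    for cycle in range(1, scenario.horizon_years + 1):
        if cycle > 1 and scenario.entry_cohort_size_per_cycle > 0:
            cohort = spawn_entry_cohort(
                params, cycle, scenario.entry_cohort_size_per_cycle, seed,
                id_offset=len(pop), initial_frailty_multiplier=mult,
            )
            entries.append(_entry_snapshot(cohort))
            pop.append(cohort)
            ledger.extend(len(cohort))
        cycle_stats.append(
            step_cycle(pop, ledger, params, scenario, strategy, cycle, ern)
        )

    # horizon exit: no terminal additions
    open_rows = ledger.arrays["exit_kind"] == EXIT_NONE
    ledger.mark_exit(open_rows, EXIT_HORIZON, scenario.horizon_years)

    individuals = pd.concat(entries, ignore_index=True)
    individuals = pd.concat([individuals, ledger.to_frame()], axis=1)
    individuals["status"] = pop.status

    usage = {
        "reactive": sum(s["usage_reactive"] for s in cycle_stats),
        "proactive": sum(s["usage_proactive"] for s in cycle_stats),
        "self_referred": sum(s["usage_self_referred"] for s in cycle_stats),
    }
    totals = ledger.totals()
    totals["public_cost_with_intervention"] = (
        totals["allcause_public_cost"] + totals["intervention_public_cost"]
    )
    return StrategyResult(
        strategy=strategy, seed=seed, horizon=scenario.horizon_years,
        n_individuals=len(pop), totals=totals,
        person_years_any_fall=sum(s["person_years_any_fall"] for s in cycle_stats),
        usage=usage, individuals=individuals, cycle_stats=cycle_stats,
    )


# ---------------------------------------------------------------------------
# incremental analytics
# ---------------------------------------------------------------------------

def net_components(
    delta_productivity: float, delta_participant_toc: float,
    delta_oop: float, delta_co_payment: float,
    delta_informal_care: float, delta_caregiver_toc: float,
    lambda_societal: float = LAMBDA_SOCIETAL,
) -> tuple[float, float, float, float]:
    """Net societal components and their QALY equivalent.

    Sign convention: savings are negative deltas, costs positive.  Returns
    (net productivity gain, net personal finance cost, net informal caregiver
    cost, societal gain in QALY equivalents at ``lambda_societal``).
    """
    net_productivity = delta_productivity - delta_participant_toc
    net_personal_finance = delta_oop + delta_co_payment
    net_informal = delta_informal_care + delta_caregiver_toc
    societal_qaly_equivalent = (
        net_productivity - net_personal_finance - net_informal
    ) / lambda_societal
    return net_productivity, net_personal_finance, net_informal, societal_qaly_equivalent


def icer(delta_cost: float, delta_societal_qaly: float) -> float:
    """Incremental public-sector cost per societal QALY gained."""
    if delta_societal_qaly == 0:
        raise ZeroDivisionError("ICER undefined for zero QALY delta")
    return delta_cost / delta_societal_qaly


def inmb(delta_societal_qaly: float, delta_public_cost: float, lam: float) -> float:
    """Incremental net monetary benefit: λ·ΔQ_soc − ΔC_pub."""
    if lam <= 0:
        raise ValueError("threshold must be positive")
    return lam * delta_societal_qaly - delta_public_cost


def inhb(delta_societal_qaly: float, delta_public_cost: float, lam: float) -> float:
    """Incremental net health benefit: ΔQ_soc − ΔC_pub/λ (= INMB/λ)."""
    if lam <= 0:
        raise ValueError("threshold must be positive")
    return delta_societal_qaly - delta_public_cost / lam


@dataclass
class CuaSummary:
    """Incremental cost-utility summary of RC versus UC (Table-2 shape)."""

    delta_allcause_cost: float
    delta_fallrelated_cost: float
    delta_intervention_cost: float
    delta_qaly: float
    delta_productivity_value: float
    delta_participant_toc: float
    delta_oop: float
    delta_co_payment: float
    delta_informal_care: float
    delta_caregiver_toc: float
    net_productivity_gain: float
    net_personal_finance_cost: float
    net_informal_care_cost: float
    societal_gain_qaly_equivalent: float
    delta_societal_qaly: float
    icer_allcause: float
    icer_fallrelated: float
    inmb_allcause: float
    inmb_fallrelated: float
    inhb_allcause: float
    delta_person_years_any_fall: float
    lambda_public: float = LAMBDA_PUBLIC
    lambda_societal: float = LAMBDA_SOCIETAL

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compare(
    uc: StrategyResult, rc: StrategyResult,
    lambda_public: float = LAMBDA_PUBLIC, lambda_societal: float = LAMBDA_SOCIETAL,
) -> CuaSummary:
    """Pairwise incremental summary (RC − UC) on common random numbers."""
    tu, tr = uc.totals, rc.totals
    d = {k: tr[k] - tu[k] for k in tu}
    net_prod, net_fin, net_inf, soc_equiv = net_components(
        d["productivity_value"], d["participant_toc"], d["oop_expenditure"],
        d["co_payment"], d["informal_care_cost"], d["caregiver_toc"],
        lambda_societal,
    )
    d_allcause = d["allcause_public_cost"] + d["intervention_public_cost"]
    d_fallrel = d["fall_healthcare"] + d["intervention_public_cost"]
    dq_soc = d["qaly"] + soc_equiv
    return CuaSummary(
        delta_allcause_cost=d["allcause_public_cost"],
        delta_fallrelated_cost=d["fall_healthcare"],
        delta_intervention_cost=d["intervention_public_cost"],
        delta_qaly=d["qaly"],
        delta_productivity_value=d["productivity_value"],
        delta_participant_toc=d["participant_toc"],
        delta_oop=d["oop_expenditure"],
        delta_co_payment=d["co_payment"],
        delta_informal_care=d["informal_care_cost"],
        delta_caregiver_toc=d["caregiver_toc"],
        net_productivity_gain=net_prod,
        net_personal_finance_cost=net_fin,
        net_informal_care_cost=net_inf,
        societal_gain_qaly_equivalent=soc_equiv,
        delta_societal_qaly=dq_soc,
        icer_allcause=icer(d_allcause, dq_soc) if dq_soc else float("nan"),
        icer_fallrelated=icer(d_fallrel, dq_soc) if dq_soc else float("nan"),
        inmb_allcause=inmb(dq_soc, d_allcause, lambda_public),
        inmb_fallrelated=inmb(dq_soc, d_fallrel, lambda_public),
        inhb_allcause=inhb(dq_soc, d_allcause, lambda_public),
        delta_person_years_any_fall=rc.person_years_any_fall - uc.person_years_any_fall,
        lambda_public=lambda_public, lambda_societal=lambda_societal,
    )


def jackknife_mean_icer(psa_pairs) -> tuple[float, tuple[float, float]]:
    """Jack-knife mean ICER over PSA replicates of (ΔC, ΔQ).

    The pooled estimate is the ratio of means; the jack-knife mean is
    n·θ̂ − (n−1)·mean of leave-one-out ratios, with a normal-approximation
    95% interval from the pseudo-values.
    """
    pairs = np.asarray(psa_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least two (delta_cost, delta_qaly) pairs")
    n = pairs.shape[0]
    sc, sq = pairs.sum(axis=0)
    if sq == 0:
        raise ZeroDivisionError("pooled QALY delta is zero")
    theta = sc / sq
    loo_q = sq - pairs[:, 1]
    if np.any(loo_q == 0):
        raise ZeroDivisionError("a leave-one-out QALY delta sums to zero")
    loo = (sc - pairs[:, 0]) / loo_q
    pseudo = n * theta - (n - 1) * loo
    mean = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / np.sqrt(n))
    return mean, (mean - 1.96 * se, mean + 1.96 * se)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def sample_psa_parameters(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Draw one PSA parameter set: Beta for probabilities, Gamma for costs,
    Normal for regression coefficients."""
    sampled = params.copy()
    for name, desc in params.psa_distributions.items():
        family = desc["family"]
        if family == "beta":
            value = float(rng.beta(desc["a"], desc["b"]))
        elif family == "gamma":
            shape = desc["shape"]
            value = float(rng.gamma(shape, desc["mean"] / shape))
        elif family == "normal":
            value = float(rng.normal(desc["mu"], desc["sd"]))
        else:
            raise ValueError(f"psa distribution {name!r}: unknown family {family!r}")
        sampled.set_path(desc["path"], value)
    sampled.validate()
    return sampled


@dataclass
class PsaResult:
    pairs_allcause: np.ndarray        # (n_runs, 2): ΔC_pub all-cause, ΔQ_societal
    summaries: list

    def ceac(self, lambdas) -> pd.DataFrame:
        return ceac(self.pairs_allcause, lambdas)


def ceac(pairs, lambdas) -> pd.DataFrame:
    """Probability RC is cost-effective: fraction of runs with INMB > 0."""
    pairs = np.asarray(pairs, dtype=float)
    rows = []
    for lam in lambdas:
        nb = lam * pairs[:, 1] - pairs[:, 0]
        rows.append({"lambda": lam, "probability_cost_effective": float((nb > 0).mean())})
    return pd.DataFrame(rows)


def run_psa(
    params: ParameterSet, scenario: ScenarioConfig, n_runs: int, seed: int,
) -> PsaResult:
    """PSA: per run, sample parameters, run paired UC/RC on common random
    numbers, record the incremental cost and societal QALY pair.

    One simulation seed (derived from ``seed``) is shared by every run so
    that run-to-run variation isolates parameter (second-order) uncertainty.
    """
    pairs = np.empty((n_runs, 2))
    summaries = []
    sim_seed = int(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(8,)).generate_state(1)[0]
        % (2**31)
    )
    for r in range(n_runs):
        prng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(7, r))
        )
        run_params = sample_psa_parameters(params, prng)
        uc = run_strategy(run_params, scenario.replace(strategy="UC"), sim_seed)
        rc = run_strategy(run_params, scenario.replace(strategy="RC"), sim_seed)
        summary = compare(uc, rc)
        pairs[r] = (
            summary.delta_allcause_cost + summary.delta_intervention_cost,
            summary.delta_societal_qaly,
        )
        summaries.append(summary)
    return PsaResult(pairs_allcause=pairs, summaries=summaries)


# ---------------------------------------------------------------------------
# deterministic multi-seed averaging
# ---------------------------------------------------------------------------

@dataclass
class DeterministicResult:
    mean_summary: CuaSummary
    per_seed_summaries: list
    pair_metrics: list                # per-seed extras from the callback


def run_deterministic(
    params: ParameterSet, scenario: ScenarioConfig, seeds, pair_metrics=None,
) -> DeterministicResult:
    """Average paired UC/RC summaries over random-number seeds.

    ``pair_metrics(uc_result, rc_result) -> dict`` optionally extracts extra
    per-seed quantities (e.g. per-quartile aggregates) before the heavy
    per-individual frames are dropped.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    summaries, extras = [], []
    for seed in seeds:
        uc = run_strategy(params, scenario.replace(strategy="UC"), seed)
        rc = run_strategy(params, scenario.replace(strategy="RC"), seed)
        summaries.append(compare(uc, rc))
        if pair_metrics is not None:
            extras.append(pair_metrics(uc, rc))
    mean_kwargs = {
        f.name: float(np.mean([getattr(s, f.name) for s in summaries]))
        for f in fields(CuaSummary)
    }
    return DeterministicResult(
        mean_summary=CuaSummary(**mean_kwargs),
        per_seed_summaries=summaries,
        pair_metrics=extras,
    )
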