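"""Individuals, frailty index and population synthesis.

State lives in two equivalent forms: a scalar :class:`IndividualState`
(convenient for unit-level reasoning and the spec-level operations) and a
vectorised :class:`Population` of numpy arrays sharing the same attribute
names, which is what the annual-cycle engine operates on.  Functions written
against the attribute names (e.g. ``assess_high_falls_risk``) work on both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .params import ParameterSet, RegressionSpec, evaluate_model

__all__ = [
    "FALLS_NONE", "FALLS_SINGLE", "FALLS_RECURRENT",
    "STATUS_COMMUNITY", "STATUS_LTC", "STATUS_DEAD",
    "N_DEFICITS",
    "IndividualState", "Population",
    "frailty_score_from_deficits", "classify_frailty", "frailty_category_codes",
    "covariate_dict", "synthesize_population", "spawn_entry_cohort",
]

# falls history in the past year
FALLS_NONE, FALLS_SINGLE, FALLS_RECURRENT = 0, 1, 2
# status
STATUS_COMMUNITY, STATUS_LTC, STATUS_DEAD = 0, 1, 2

#: items in the deficit-accumulation frailty index
N_DEFICITS = 52

FRAILTY_CUTOFFS = (10.0, 23.0, 37.0)  # fit <= 10 < mild <= 23 < moderate <= 37 < severe
_CATEGORY_NAMES = ("fit", "mild", "moderate", "severe")


def frailty_score_from_deficits(deficits) -> float:
    """Deficit-accumulation frailty score: 100 x mean of the 52 items."""
    d = np.asarray(deficits, dtype=float)
    if d.shape != (N_DEFICITS,):
        raise ValueError(f"deficit vector must have length {N_DEFICITS}, got {d.shape}")
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("deficit items must lie in [0, 1]")
    return float(100.0 * d.sum() / N_DEFICITS)


def frailty_category_codes(scores) -> np.ndarray:
    """Vectorised category codes 0=fit, 1=mild, 2=moderate, 3=severe."""
    s = np.asarray(scores, dtype=float)
    if np.any(s < 0) or np.any(s > 100):
        raise ValueError("frailty score outside [0, 100]")
    # upper bounds inclusive: fit [0,10], mild (10,23], moderate (23,37], severe >37
    return np.digitize(s, FRAILTY_CUTOFFS, right=True).astype(np.int64)


def classify_frailty(score: float) -> str:
    """Category of a frailty score under the 10/23/37 cut-offs (upper bounds
    inclusive: fit is [0, 10], mild (10, 23], moderate (23, 37], severe > 37)."""
    return _CATEGORY_NAMES[int(frailty_category_codes(score))]


@dataclass
class IndividualState:
    """One simulated person (scalar view of the state vector)."""

    id: int
    age: float
    sex_female: int                 # 0 male, 1 female
    ses_quartile: int               # 1 most privileged .. 4 most deprived
    falls_history: int = FALLS_NONE
    frailty_score: float = 5.0
    high_physical_activity: int = 0
    cognitive_impairment: int = 0
    fear_of_falling: int = 0
    abnormal_gait_balance: int = 0
    gp_contact_this_cycle: int = 0
    exercise_history: int = 0
    proactive_receipts: int = 0
    status: int = STATUS_COMMUNITY
    entry_cycle: int = 1

    @property
    def frailty_category(self) -> str:
        return classify_frailty(self.frailty_score)


_ARRAY_FIELDS = [
    ("id", np.int64), ("age", np.float64), ("sex_female", np.int64),
    ("ses_quartile", np.int64), ("falls_history", np.int64),
    ("frailty_score", np.float64), ("high_physical_activity", np.int64),
    ("cognitive_impairment", np.int64), ("fear_of_falling", np.int64),
    ("abnormal_gait_balance", np.int64), ("gp_contact_this_cycle", np.int64),
    ("exercise_history", np.int64), ("proactive_receipts", np.int64),
    ("status", np.int64), ("entry_cycle", np.int64),
    # previous-cycle fall information driving reactive eligibility
    ("prev_ma_fall", np.int64), ("prev_hospitalised_ma", np.int64),
]


@dataclass
class Population:
    """Struct-of-arrays population state (one entry per individual ever)."""

    arrays: dict = field(default_factory=dict)

    def __getattr__(self, name):
        arrays = object.__getattribute__(self, "arrays")
        if name in arrays:
            return arrays[name]
        raise AttributeError(name)

    def __len__(self) -> int:
        return len(self.arrays["id"])

    @classmethod
    def empty(cls) -> "Population":
        return cls({name: np.empty(0, dtype=dt) for name, dt in _ARRAY_FIELDS})

    def append(self, other: "Population") -> None:
        for name, _ in _ARRAY_FIELDS:
            self.arrays[name] = np.concatenate([self.arrays[name], other.arrays[name]])

    def set(self, name: str, values: np.ndarray) -> None:
        self.arrays[name] = values

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({name: self.arrays[name] for name, _ in _ARRAY_FIELDS})
        df["frailty_category"] = np.asarray(_CATEGORY_NAMES)[
            frailty_category_codes(self.arrays["frailty_score"])
        ]
        return df

    def individual(self, i: int) -> IndividualState:
        a = self.arrays
        return IndividualState(
            id=int(a["id"][i]), age=float(a["age"][i]),
            sex_female=int(a["sex_female"][i]), ses_quartile=int(a["ses_quartile"][i]),
            falls_history=int(a["falls_history"][i]),
            frailty_score=float(a["frailty_score"][i]),
            high_physical_activity=int(a["high_physical_activity"][i]),
            cognitive_impairment=int(a["cognitive_impairment"][i]),
            fear_of_falling=int(a["fear_of_falling"][i]),
            abnormal_gait_balance=int(a["abnormal_gait_balance"][i]),
            gp_contact_this_cycle=int(a["gp_contact_this_cycle"][i]),
            exercise_history=int(a["exercise_history"][i]),
            proactive_receipts=int(a["proactive_receipts"][i]),
            status=int(a["status"][i]), entry_cycle=int(a["entry_cycle"][i]),
        )


def covariate_dict(x, extra: dict | None = None) -> dict:
    """Covariate vocabulary from an IndividualState or Population.

    ``extra`` supplies contextual covariates (e.g. faller-type dummies or the
    cycle's frailty delta) that are not part of the persistent state.
    """
    age = np.asarray(x.age, dtype=float)
    falls = np.asarray(x.falls_history)
    ses = np.asarray(x.ses_quartile)
    cov = {
        "age": age,
        "age_minus_60": age - 60.0,
        "sex_female": np.asarray(x.sex_female, dtype=float),
        "frailty_score": np.asarray(x.frailty_score, dtype=float),
        "falls_single": (falls == FALLS_SINGLE).astype(float),
        "falls_recurrent": (falls == FALLS_RECURRENT).astype(float),
        "high_physical_activity": np.asarray(x.high_physical_activity, dtype=float),
        "cognitive_impairment": np.asarray(x.cognitive_impairment, dtype=float),
        "fear_of_falling": np.asarray(x.fear_of_falling, dtype=float),
        "abnormal_gait_balance": np.asarray(x.abnormal_gait_balance, dtype=float),
        "exercise_history": np.asarray(x.exercise_history, dtype=float),
        "ses_q2": (ses == 2).astype(float),
        "ses_q3": (ses == 3).astype(float),
        "ses_q4": (ses == 4).astype(float),
    }
    if extra:
        cov.update(extra)
    return cov


def _sample_individuals(
    params: ParameterSet,
    n: int,
    rng: np.random.Generator,
    *,
    entry_cycle: int,
    id_offset: int,
    fixed_age: float | None = None,
    initial_frailty_multiplier: float = 1.0,
) -> Population:
    bp = params.baseline_population
    pop = Population.empty()

    if fixed_age is None:
        ages_grid = np.arange(60, int(bp["max_age"]) + 1)
        w = np.asarray(bp["age_decay"], dtype=float) ** (ages_grid - 60)
        age = rng.choice(ages_grid, size=n, p=w / w.sum()).astype(float)
    else:
        age = np.full(n, float(fixed_age))

    sex_female = (rng.random(n) < bp["female_share"]).astype(np.int64)
    ses = rng.choice(np.arange(1, 5), size=n, p=np.asarray(bp["ses_probs"])).astype(np.int64)
    falls = rng.choice(
        np.array([FALLS_NONE, FALLS_SINGLE, FALLS_RECURRENT]),
        size=n, p=np.asarray(bp["falls_history_probs"]),
    ).astype(np.int64)
    frailty = np.clip(
        rng.lognormal(bp["frailty_lognorm_mu"], bp["frailty_lognorm_sigma"], size=n),
        0.0, 100.0,
    )
    # entry-frailty scenario scales the (already bounded) score itself
    frailty = np.clip(frailty * initial_frailty_multiplier, 0.0, 100.0)

    pop.set("id", id_offset + np.arange(n, dtype=np.int64))
    pop.set("age", age)
    pop.set("sex_female", sex_female)
    pop.set("ses_quartile", ses)
    pop.set("falls_history", falls)
    pop.set("frailty_score", frailty)
    for name in (
        "high_physical_activity", "cognitive_impairment", "fear_of_falling",
        "abnormal_gait_balance", "gp_contact_this_cycle", "exercise_history",
        "proactive_receipts", "prev_ma_fall", "prev_hospitalised_ma",
    ):
        pop.set(name, np.zeros(n, dtype=np.int64))
    pop.set("status", np.full(n, STATUS_COMMUNITY, dtype=np.int64))
    pop.set("entry_cycle", np.full(n, entry_cycle, dtype=np.int64))

    # covariate flags sampled in a fixed documented order, each conditional on
    # demographics, frailty, falls history and previously sampled flags
    for flag in (
        "high_physical_activity", "cognitive_impairment",
        "fear_of_falling", "abnormal_gait_balance",
    ):
        spec = params.baseline_covariate_models[flag]
        p = evaluate_model(spec, covariate_dict(pop))
        pop.set(flag, (rng.random(n) < p).astype(np.int64))

    return pop


def synthesize_population(
    params: ParameterSet,
    n: int,
    seed: int,
    *,
    entry_cycle: int = 1,
    id_offset: int = 0,
    initial_frailty_multiplier: float = 1.0,
) -> Population:
    """Sample a community-dwelling baseline population aged 60+."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    return _sample_individuals(
        params, n, rng, entry_cycle=entry_cycle, id_offset=id_offset,
        initial_frailty_multiplier=initial_frailty_multiplier,
    )


def spawn_entry_cohort(
    params: ParameterSet,
    cycle: int,
    size: int,
    seed: int,
    *,
    id_offset: int = 0,
    initial_frailty_multiplier: float = 1.0,
) -> Population:
    """Entry cohort of individuals aged exactly 60 joining at ``cycle``."""
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    if size == 0:
        return Population.empty()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(1, int(cycle)))
    )
    return _sample_individuals(
        params, size, rng, entry_cycle=cycle, id_offset=id_offset,
        fixed_age=60.0, initial_frailty_multiplier=initial_frailty_multiplier,
    )
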