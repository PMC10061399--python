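"""Parameter schema: regression blocks, unit costs, access rates, scenarios.

The simulator is driven entirely by a :class:`ParameterSet` — a collection of
small generalized-linear-model blocks (:class:`RegressionSpec`), probability
tables, and unit costs — plus a :class:`ScenarioConfig` that fixes strategy,
horizon, discounting and the scenario toggles.  Parameter files are plain YAML
with one block per model component; ``save_parameters``/``load_parameters``
round-trip bit-exactly.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml
from scipy.special import expit

__all__ = [
    "COVARIATE_VOCABULARY",
    "RegressionSpec",
    "ParameterSet",
    "ScenarioToggles",
    "ScenarioConfig",
    "ParameterValidationError",
    "load_parameters",
    "save_parameters",
    "evaluate_model",
]

#: Individual-level covariates a regression block may reference.
COVARIATE_VOCABULARY = frozenset(
    {
        "age",
        "age_minus_60",
        "sex_female",
        "frailty_score",
        "frailty_delta",
        "falls_single",
        "falls_recurrent",
        "high_physical_activity",
        "cognitive_impairment",
        "fear_of_falling",
        "abnormal_gait_balance",
        "exercise_history",
        "ses_q2",
        "ses_q3",
        "ses_q4",
        # categorical falls-incidence terms used by the frailty-progression block
        "fall_single_nonma",
        "fall_single_ma",
        "fall_recurrent_nonma",
        "fall_recurrent_ma",
    }
)

FRAILTY_CATEGORIES = ("fit", "mild", "moderate", "severe")
PATHWAYS = ("reactive", "proactive", "self_referred")
INTERVENTIONS = ("HAM", "multifactorial", "exercise")


class ParameterValidationError(ValueError):
    """A parameter file or in-memory parameter set violates the schema."""


@dataclass
class RegressionSpec:
    """One regression block: ``link(intercept + Σ coef·covariate)``.

    ``link`` is ``"logistic"`` (output in (0,1)) or ``"linear"`` (output on the
    real line, optionally clamped to ``value_range``).
    """

    outcome_name: str
    link: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    value_range: list[float] | None = None

    def validate(self) -> None:
        if self.link not in ("logistic", "linear"):
            raise ParameterValidationError(
                f"{self.outcome_name}: unknown link {self.link!r}"
            )
        for cov in self.coefficients:
            if cov not in COVARIATE_VOCABULARY:
                raise ParameterValidationError(
                    f"{self.outcome_name}: unknown covariate {cov!r}"
                )
        if self.value_range is not None and len(self.value_range) != 2:
            raise ParameterValidationError(
                f"{self.outcome_name}: value_range must be [lo, hi]"
            )


def evaluate_model(spec: RegressionSpec, covariates: Mapping[str, Any]):
    """Evaluate a regression block on scalar or array covariates.

    Every covariate named by ``spec`` must be resolvable from ``covariates``
    (a mapping or an object exposing the names as attributes).  Returns a
    float (scalar inputs) or an ndarray (vector inputs).
    """
    eta = np.asarray(spec.intercept, dtype=float)
    for name, coef in spec.coefficients.items():
        if isinstance(covariates, Mapping):
            if name not in covariates:
                raise KeyError(f"covariate {name!r} not supplied for {spec.outcome_name}")
            value = covariates[name]
        else:
            try:
                value = getattr(covariates, name)
            except AttributeError as exc:
                raise KeyError(
                    f"covariate {name!r} not supplied for {spec.outcome_name}"
                ) from exc
        eta = eta + coef * np.asarray(value, dtype=float)
    if spec.link == "logistic":
        out = expit(eta)
    else:
        out = eta
        if spec.value_range is not None:
            out = np.clip(out, spec.value_range[0], spec.value_range[1])
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class ParameterSet:
    """All model inputs.  See ``docs/methods.md`` for the data dictionary."""

    # -- regression blocks -------------------------------------------------
    baseline_covariate_models: dict[str, RegressionSpec]
    baseline_outcome_models: dict[str, RegressionSpec]
    cascade_models: dict[str, RegressionSpec]
    frailty_progression_model: RegressionSpec
    ltc_admission_model: RegressionSpec
    self_referral_demand_rc: RegressionSpec

    # -- mortality ---------------------------------------------------------
    # annual other-cause risk by 5-year age band (60-64 ... 95+) and sex,
    # multiplied by a hazard ratio per frailty category (fit = 1.0)
    mortality_age_bands: list[float]
    mortality_base_male: list[float]
    mortality_base_female: list[float]
    mortality_frailty_hr: dict[str, float]
    fatal_fall_base: list[float]
    fatal_fall_frailty_factor: dict[str, float]

    # -- unit costs and acute consequences ---------------------------------
    unit_costs: dict[str, float]
    intervention_public_cost: dict[str, float]
    acute_qaly_loss: dict[str, float]
    efficacy: dict[str, float]

    # -- access / implementation -------------------------------------------
    access: dict[str, float]

    # -- LTC and equity inputs ---------------------------------------------
    ltc_public_share: list[float]       # by SES quartile 1..4
    capacity_to_pay: list[float]        # by SES quartile 1..4, £
    ltc_mean_remaining_qaly: float

    # -- baseline population -----------------------------------------------
    baseline_population: dict[str, Any]

    # -- PSA distribution descriptors --------------------------------------
    psa_distributions: dict[str, dict[str, Any]] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for block in (
            *self.baseline_covariate_models.values(),
            *self.baseline_outcome_models.values(),
            *self.cascade_models.values(),
            self.frailty_progression_model,
            self.ltc_admission_model,
            self.self_referral_demand_rc,
        ):
            block.validate()
        if self.frailty_progression_model.link != "linear":
            raise ParameterValidationError("frailty_progression_model must be linear")

        hr = self.mortality_frailty_hr
        if set(hr) != set(FRAILTY_CATEGORIES):
            raise ParameterValidationError("mortality_frailty_hr must cover all categories")
        if hr["fit"] != 1.0:
            raise ParameterValidationError(
                f"mortality_frailty_hr['fit'] must equal 1.0, got {hr['fit']}"
            )
        n_bands = len(self.mortality_age_bands)
        for name, risks in (
            ("mortality_base_male", self.mortality_base_male),
            ("mortality_base_female", self.mortality_base_female),
            ("fatal_fall_base", self.fatal_fall_base),
        ):
            if len(risks) != n_bands:
                raise ParameterValidationError(f"{name}: expected {n_bands} age bands")
            for r in risks:
                if not 0.0 <= r <= 1.0:
                    raise ParameterValidationError(f"{name}: risk {r} outside [0, 1]")

        for name, cost in {**self.unit_costs, **self.intervention_public_cost}.items():
            if cost < 0:
                raise ParameterValidationError(f"unit cost {name!r} is negative: {cost}")
        for name, loss in self.acute_qaly_loss.items():
            if loss < 0:
                raise ParameterValidationError(f"acute_qaly_loss {name!r} is negative")
        for name, mult in self.efficacy.items():
            if not 0.0 < mult <= 1.0:
                raise ParameterValidationError(
                    f"efficacy {name!r} must be in (0, 1], got {mult}"
                )
        for name, p in self.access.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterValidationError(
                    f"access rate {name!r} outside [0, 1]: {p}"
                )
        for name, shares in (
            ("ltc_public_share", self.ltc_public_share),
            ("capacity_to_pay", self.capacity_to_pay),
        ):
            if len(shares) != 4:
                raise ParameterValidationError(f"{name} needs 4 quartile entries")
        for s in self.ltc_public_share:
            if not 0.0 <= s <= 1.0:
                raise ParameterValidationError("ltc_public_share outside [0, 1]")
        for c in self.capacity_to_pay:
            if c <= 0:
                raise ParameterValidationError("capacity_to_pay must be positive")
        if self.ltc_mean_remaining_qaly < 0:
            raise ParameterValidationError("ltc_mean_remaining_qaly must be >= 0")
        probs = self.baseline_population.get("falls_history_probs")
        if probs is None or len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9:
            raise ParameterValidationError(
                "baseline_population.falls_history_probs must be 3 values summing to 1"
            )

    # -- dotted-path access (used by scenario transforms and PSA) ----------
    def get_path(self, path: str):
        obj: Any = self
        for part in path.split("."):
            if isinstance(obj, Mapping):
                obj = obj[part]
            elif isinstance(obj, list):
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        return obj

    def set_path(self, path: str, value) -> None:
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            if isinstance(obj, Mapping):
                obj = obj[part]
            elif isinstance(obj, list):
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        last = parts[-1]
        if isinstance(obj, Mapping):
            obj[last] = value
        elif isinstance(obj, list):
            obj[int(last)] = value
        else:
            setattr(obj, last, value)


@dataclass
class ScenarioToggles:
    """Structural scenario switches (defaults reproduce the base case)."""

    remove_falls_frailty_feedback: bool = False
    initial_frailty_multiplier: float = 1.0
    progression_rate_multiplier: float = 1.0
    other_cause_mortality_multiplier: float = 1.0
    frailty_hr_gap_multiplier: float = 1.0

    def validate(self) -> None:
        for name in (
            "initial_frailty_multiplier",
            "progression_rate_multiplier",
            "other_cause_mortality_multiplier",
            "frailty_hr_gap_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ParameterValidationError(f"{name} must be > 0")


@dataclass
class ScenarioConfig:
    """What to run: strategy, horizon, discounting, population, seeds."""

    strategy: str = "UC"
    horizon_years: int = 40
    discount_rate_cost: float = 0.035
    discount_rate_health: float = 0.035
    population_size: int = 20_000
    entry_cohort_size_per_cycle: int = 250
    seeds: list[int] = field(default_factory=lambda: list(range(1, 21)))
    toggles: ScenarioToggles = field(default_factory=ScenarioToggles)

    def validate(self) -> None:
        if self.strategy not in ("UC", "RC"):
            raise ParameterValidationError(f"strategy must be UC or RC, got {self.strategy!r}")
        if self.horizon_years < 1:
            raise ParameterValidationError("horizon_years must be >= 1")
        if self.population_size < 1:
            raise ParameterValidationError("population_size must be >= 1")
        if self.entry_cohort_size_per_cycle < 0:
            raise ParameterValidationError("entry_cohort_size_per_cycle must be >= 0")
        if self.discount_rate_cost < 0 or self.discount_rate_health < 0:
            raise ParameterValidationError("discount rates must be >= 0")
        if not self.seeds:
            raise ParameterValidationError("seeds must be non-empty")
        self.toggles.validate()

    def replace(self, **kwargs) -> "ScenarioConfig":
        new = copy.deepcopy(self)
        for key, value in kwargs.items():
            if not hasattr(new, key):
                raise AttributeError(key)
            setattr(new, key, value)
        return new


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _spec_from_plain(d: Mapping) -> RegressionSpec:
    return RegressionSpec(
        outcome_name=d["outcome_name"],
        link=d["link"],
        intercept=float(d["intercept"]),
        coefficients=dict(d.get("coefficients") or {}),
        value_range=list(d["value_range"]) if d.get("value_range") else None,
    )


def parameters_to_dict(params: ParameterSet) -> dict:
    return _to_plain(params)


def parameters_from_dict(data: Mapping) -> ParameterSet:
    try:
        params = ParameterSet(
            baseline_covariate_models={
                k: _spec_from_plain(v) for k, v in data["baseline_covariate_models"].items()
            },
            baseline_outcome_models={
                k: _spec_from_plain(v) for k, v in data["baseline_outcome_models"].items()
            },
            cascade_models={k: _spec_from_plain(v) for k, v in data["cascade_models"].items()},
            frailty_progression_model=_spec_from_plain(data["frailty_progression_model"]),
            ltc_admission_model=_spec_from_plain(data["ltc_admission_model"]),
            self_referral_demand_rc=_spec_from_plain(data["self_referral_demand_rc"]),
            mortality_age_bands=list(data["mortality_age_bands"]),
            mortality_base_male=list(data["mortality_base_male"]),
            mortality_base_female=list(data["mortality_base_female"]),
            mortality_frailty_hr=dict(data["mortality_frailty_hr"]),
            fatal_fall_base=list(data["fatal_fall_base"]),
            fatal_fall_frailty_factor=dict(data["fatal_fall_frailty_factor"]),
            unit_costs=dict(data["unit_costs"]),
            intervention_public_cost=dict(data["intervention_public_cost"]),
            acute_qaly_loss=dict(data["acute_qaly_loss"]),
            efficacy=dict(data["efficacy"]),
            access=dict(data["access"]),
            ltc_public_share=list(data["ltc_public_share"]),
            capacity_to_pay=list(data["capacity_to_pay"]),
            ltc_mean_remaining_qaly=float(data["ltc_mean_remaining_qaly"]),
            baseline_population=dict(data["baseline_population"]),
            psa_distributions=dict(data.get("psa_distributions") or {}),
        )
    except KeyError as exc:
        raise ParameterValidationError(f"missing parameter block: {exc}") from exc
    params.validate()
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to YAML (one block per model component)."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=False)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML parameter file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParameterValidationError(f"{path}: not a mapping")
    return parameters_from_dict(data)


def scenario_to_dict(config: ScenarioConfig) -> dict:
    return _to_plain(config)


def scenario_from_dict(data: Mapping) -> ScenarioConfig:
    toggles = ScenarioToggles(**(data.get("toggles") or {}))
    kwargs = {k: v for k, v in data.items() if k != "toggles"}
    config = ScenarioConfig(toggles=toggles, **kwargs)
    config.validate()
    return config


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(config), fh, sort_keys=False)
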