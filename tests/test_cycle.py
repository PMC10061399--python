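"""Annual cycle: mortality, falls cascade, frailty progression, LTC."""

import numpy as np
import pytest

import fallsim as fs
from fallsim.accounting import OutcomeLedger
from fallsim.cycle import (
    FT_NO_FALL,
    FT_RECURRENT_MA,
    FT_SINGLE_MA,
    acute_consequences_vectorised,
    fatal_fall_risk,
    progress_frailty_vectorised,
    sample_faller_type_vectorised,
    step_cycle,
)
from fallsim.population import STATUS_COMMUNITY, STATUS_DEAD, STATUS_LTC
from fallsim.rng import EventRng


def enumerate_faller_type_probabilities(p_any, p_rec, p_ma_s, p_ma_r):
    """Independent oracle: exhaustive branch-tree enumeration."""
    return {
        0: 1 - p_any,
        1: p_any * (1 - p_rec) * (1 - p_ma_s),
        2: p_any * (1 - p_rec) * p_ma_s,
        3: p_any * p_rec * (1 - p_ma_r),
        4: p_any * p_rec * p_ma_r,
    }


def _force_cascade(params, p_any, p_rec, p_ma):
    p = params.copy()
    big = 50.0
    for name, prob in (("any_fall", p_any), ("recurrent_given_any", p_rec),
                       ("ma_given_single", p_ma), ("ma_given_recurrent", p_ma)):
        spec = p.cascade_models[name]
        spec.coefficients = {}
        spec.intercept = big if prob == 1.0 else (-big if prob == 0.0 else np.log(prob / (1 - prob)))
    return p


class TestMortality:
    def test_hazard_ratio_gap_shrinkage(self):
        assert fs.frailty_hr_with_gap(2.0, 0.8) == pytest.approx(1.8)
        assert fs.frailty_hr_with_gap(1.0, 0.8) == 1.0  # fit reference unchanged

    def test_mortality_multiplier_scales_base_risk(self, params):
        base = fs.other_cause_risk(params, [70.0], [0], [5.0])
        scaled = fs.other_cause_risk(params, [70.0], [0], [5.0], mortality_multiplier=0.8)
        assert scaled[0] == pytest.approx(0.8 * base[0])

    def test_gap_renormalisation_preserves_mean_risk(self, params):
        """Shrinking the frailty gradient must not change average mortality."""
        pop = fs.synthesize_population(params, 100_000, 2)
        base = fs.other_cause_risk(params, pop.age, pop.sex_female, pop.frailty_score)
        shrunk = fs.other_cause_risk(
            params, pop.age, pop.sex_female, pop.frailty_score, hr_gap_multiplier=0.8
        )
        assert shrunk.mean() == pytest.approx(base.mean(), rel=0.005)
        # but the gradient across frailty categories is compressed
        from fallsim.population import frailty_category_codes

        codes = frailty_category_codes(pop.frailty_score)
        gap_base = base[codes == 3].mean() - base[codes == 0].mean()
        gap_shrunk = shrunk[codes == 3].mean() - shrunk[codes == 0].mean()
        assert gap_shrunk < gap_base

    def test_fatal_fall_risk_rises_with_age_and_frailty(self, params):
        low = fatal_fall_risk(params, [62.0], [5.0])[0]
        old = fatal_fall_risk(params, [92.0], [5.0])[0]
        frail = fatal_fall_risk(params, [62.0], [60.0])[0]
        assert old > low and frail > low


class TestFallsCascade:
    def test_forced_branches(self, params):
        pop = fs.synthesize_population(params, 500, 1)
        forced = _force_cascade(params, 1.0, 0.0, 1.0)
        ftype, n_ma, h1, h2 = sample_faller_type_vectorised(
            pop, np.ones(len(pop)), forced, EventRng(1), 1
        )
        assert np.all(ftype == FT_SINGLE_MA)
        assert np.all(n_ma == 1)
        none = _force_cascade(params, 0.0, 0.0, 0.0)
        ftype, n_ma, h1, h2 = sample_faller_type_vectorised(
            pop, np.ones(len(pop)), none, EventRng(1), 1
        )
        assert np.all(ftype == FT_NO_FALL) and np.all(n_ma == 0)

    def test_enumeration_oracle_matches_sampler(self, params, rng):
        """Branch-tree probabilities sum to one and match sampled shares."""
        for trial in range(3):
            probs = rng.uniform(0.05, 0.95, size=4)
            oracle = enumerate_faller_type_probabilities(*probs)
            assert sum(oracle.values()) == pytest.approx(1.0, abs=1e-12)
            forced = params.copy()
            for name, p in zip(
                ("any_fall", "recurrent_given_any", "ma_given_single", "ma_given_recurrent"),
                probs,
            ):
                spec = forced.cascade_models[name]
                spec.coefficients = {}
                spec.intercept = float(np.log(p / (1 - p)))
            pop = fs.synthesize_population(params, 200_000, 4)
            ftype, *_ = sample_faller_type_vectorised(
                pop, np.ones(len(pop)), forced, EventRng(trial), 1
            )
            shares = np.bincount(ftype, minlength=5) / len(pop)
            for code, expected in oracle.items():
                assert shares[code] == pytest.approx(expected, abs=0.006)

    def test_efficacy_scales_any_fall_probability(self, params):
        pop = fs.synthesize_population(params, 200_000, 5)
        full, *_ = sample_faller_type_vectorised(pop, np.ones(len(pop)), params, EventRng(2), 1)
        halved, *_ = sample_faller_type_vectorised(
            pop, np.full(len(pop), 0.5), params, EventRng(2), 1
        )
        p_full = (full != FT_NO_FALL).mean()
        p_half = (halved != FT_NO_FALL).mean()
        assert p_half == pytest.approx(0.5 * p_full, rel=0.02)

    def test_nonpositive_multiplier_rejected(self, params):
        pop = fs.synthesize_population(params, 10, 1)
        with pytest.raises(ValueError):
            sample_faller_type_vectorised(pop, np.zeros(10), params, EventRng(1), 1)


class TestAcuteConsequences:
    def test_no_fall_costs_nothing(self, params):
        loss, cost = acute_consequences_vectorised(
            np.array([FT_NO_FALL]), np.array([0]), np.array([False]), np.array([False]),
            params,
        )
        assert loss[0] == 0.0 and cost[0] == 0.0

    def test_hospitalised_dominates_and_two_ma_falls_additive(self, params):
        ft = np.array([FT_SINGLE_MA, FT_SINGLE_MA, FT_RECURRENT_MA])
        n_ma = np.array([1, 1, 2])
        h1 = np.array([True, False, False])
        h2 = np.array([False, False, False])
        loss, cost = acute_consequences_vectorised(ft, n_ma, h1, h2, params)
        assert cost[0] > cost[1]  # hospitalised MA fall costs more
        assert cost[2] == pytest.approx(2 * params.unit_costs["fall_ma_nonhosp"])
        assert loss[2] == pytest.approx(2 * params.acute_qaly_loss["fall_ma_nonhosp"])


class TestFrailtyProgression:
    def test_feedback_removal_ignores_faller_type(self, params):
        pop = fs.synthesize_population(params, 1_000, 6)
        sc = fs.ScenarioConfig(toggles=fs.ScenarioToggles(remove_falls_frailty_feedback=True))
        d_no = progress_frailty_vectorised(pop, np.zeros(len(pop), dtype=int), sc, params)
        d_ma = progress_frailty_vectorised(
            pop, np.full(len(pop), FT_RECURRENT_MA), sc, params
        )
        np.testing.assert_allclose(d_no, d_ma)
        sc_on = fs.ScenarioConfig()
        d_on_ma = progress_frailty_vectorised(
            pop, np.full(len(pop), FT_RECURRENT_MA), sc_on, params
        )
        assert np.all(d_on_ma > d_no)

    def test_progression_multiplier_scales_delta(self, params):
        pop = fs.synthesize_population(params, 100, 6)
        ftype = np.zeros(len(pop), dtype=int)
        base = progress_frailty_vectorised(pop, ftype, fs.ScenarioConfig(), params)
        sc = fs.ScenarioConfig(toggles=fs.ScenarioToggles(progression_rate_multiplier=0.8))
        scaled = progress_frailty_vectorised(pop, ftype, sc, params)
        np.testing.assert_allclose(scaled, 0.8 * base)

    def test_score_clamped_to_range(self, params, small_scenario):
        """No trajectory leaves [0, 100] even under extreme progression."""
        extreme = params.copy()
        extreme.frailty_progression_model.intercept = 30.0
        pop = fs.synthesize_population(extreme, 500, 1)
        ledger = OutcomeLedger.empty(len(pop))
        for cycle in range(1, 6):
            step_cycle(pop, ledger, extreme, small_scenario, "UC", cycle, EventRng(1))
            assert np.all((pop.frailty_score >= 0) & (pop.frailty_score <= 100))


class TestStepCycle:
    def test_absorbing_states(self, params, small_scenario):
        pop = fs.synthesize_population(params, 2_000, 8)
        ledger = OutcomeLedger.empty(len(pop))
        seen_dead = np.zeros(len(pop), dtype=bool)
        seen_ltc = np.zeros(len(pop), dtype=bool)
        for cycle in range(1, 11):
            step_cycle(pop, ledger, params, small_scenario, "UC", cycle, EventRng(3))
            assert np.all(pop.status[seen_dead] == STATUS_DEAD)
            assert np.all(pop.status[seen_ltc] == STATUS_LTC)
            seen_dead |= pop.status == STATUS_DEAD
            seen_ltc |= pop.status == STATUS_LTC
        assert seen_dead.any() and (pop.status == STATUS_COMMUNITY).any()

    def test_dead_individuals_untouched(self, params, small_scenario):
        pop = fs.synthesize_population(params, 500, 9)
        status = pop.status.copy()
        status[:100] = STATUS_DEAD
        pop.set("status", status)
        ledger = OutcomeLedger.empty(len(pop))
        ledger.arrays["exit_kind"][:100] = 1
        frailty_before = pop.frailty_score[:100].copy()
        age_before = pop.age[:100].copy()
        step_cycle(pop, ledger, params, small_scenario, "UC", 1, EventRng(4))
        np.testing.assert_array_equal(pop.frailty_score[:100], frailty_before)
        np.testing.assert_array_equal(pop.age[:100], age_before)
        assert ledger.arrays["qaly"][:100].sum() == 0.0

    def test_cycle_deterministic_for_seed(self, params, small_scenario):
        outs = []
        for _ in range(2):
            pop = fs.synthesize_population(params, 1_000, 10)
            ledger = OutcomeLedger.empty(len(pop))
            stats = step_cycle(pop, ledger, params, small_scenario, "RC", 1, EventRng(10))
            outs.append((stats, ledger.arrays["qaly"].copy()))
        assert outs[0][0] == outs[1][0]
        np.testing.assert_array_equal(outs[0][1], outs[1][1])

    def test_feedback_removal_makes_frailty_invariant_to_falls(self, params):
        """Paired runs differing only in fall realisations (efficacy halved)
        leave frailty trajectories identical when the feedback is removed."""
        sc = fs.ScenarioConfig(
            horizon_years=6, population_size=3_000, entry_cohort_size_per_cycle=0,
            toggles=fs.ScenarioToggles(remove_falls_frailty_feedback=True),
        )
        base = params.copy()
        # silence the LTC exit so the only difference between the two runs is
        # the fall realisations themselves (LTC admission responds to falls
        # history, which would freeze frailty at different admission times)
        base.ltc_admission_model.intercept = -50.0
        p_eff = base.copy()
        for k in p_eff.efficacy:
            p_eff.efficacy[k] = 0.5
        frailty = {}
        for label, p in (("base", base), ("efficacious", p_eff)):
            pop = fs.synthesize_population(p, sc.population_size, 21)
            ledger = OutcomeLedger.empty(len(pop))
            for cycle in range(1, sc.horizon_years + 1):
                step_cycle(pop, ledger, p, sc, "RC", cycle, EventRng(21))
            frailty[label] = pop.frailty_score.copy()
        # mortality/LTC exits can differ; compare those in community throughout
        np.testing.assert_allclose(frailty["base"], frailty["efficacious"])
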