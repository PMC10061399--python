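"""EDE social-welfare measures, DCEA and lifetime equity metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fallsim as fs
from fallsim.equity import EXCESSIVE_BURDEN_THRESHOLD, QuartileNhb, lifetime_outcomes

positive_quartets = st.lists(
    st.floats(min_value=0.1, max_value=50.0), min_size=4, max_size=4
)


def longdouble_atkinson(values, eps):
    v = np.asarray(values, dtype=np.longdouble)
    if eps == 0:
        return float(v.mean())
    if eps == 1:
        return float(np.exp(np.mean(np.log(v))))
    return float(np.mean(v ** (1 - np.longdouble(eps))) ** (1 / (1 - np.longdouble(eps))))


def longdouble_kolm(values, alpha):
    v = np.asarray(values, dtype=np.longdouble)
    a = np.longdouble(alpha)
    return float(-np.log(np.mean(np.exp(-a * v))) / a)


class TestAtkinson:
    def test_equal_distribution_identity(self):
        for eps in fs.ATKINSON_GRID:
            assert fs.atkinson_ede([5, 5, 5, 5], eps) == pytest.approx(5.0)

    def test_hand_worked_example(self):
        assert fs.atkinson_ede([2, 4], 2.0) == pytest.approx(2.6667, abs=1e-4)

    def test_zero_aversion_is_mean_and_one_is_geometric(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert fs.atkinson_ede(v, 0.0) == pytest.approx(2.5)
        assert fs.atkinson_ede(v, 1.0) == pytest.approx(float(np.prod(v)) ** 0.25)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fs.atkinson_ede([1.0, -2.0], 3.0)
        with pytest.raises(ValueError):
            fs.atkinson_ede([1.0, 2.0], -0.5)

    @given(positive_quartets, st.floats(min_value=0, max_value=30))
    @settings(max_examples=150, deadline=None)
    def test_jensen_bound_and_oracle(self, values, eps):
        ede = fs.atkinson_ede(values, eps)
        assert ede <= np.mean(values) + 1e-9
        assert ede == pytest.approx(longdouble_atkinson(values, eps), rel=1e-6)

    @given(positive_quartets, st.floats(min_value=0.1, max_value=20),
           st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=150, deadline=None)
    def test_scale_invariance(self, values, eps, k):
        scaled = fs.atkinson_ede([k * v for v in values], eps)
        assert scaled == pytest.approx(k * fs.atkinson_ede(values, eps), rel=1e-7)

    def test_monotone_nonincreasing_in_aversion(self):
        v = [1.0, 2.0, 5.0, 9.0]
        edes = [fs.atkinson_ede(v, eps) for eps in fs.ATKINSON_GRID]
        assert all(a >= b - 1e-12 for a, b in zip(edes, edes[1:]))


class TestKolm:
    def test_equal_distribution_identity(self):
        for alpha in fs.KOLM_GRID:
            assert fs.kolm_ede([3.3, 3.3, 3.3, 3.3], alpha) == pytest.approx(3.3)

    def test_hand_worked_example(self):
        # -(1/0.5) ln( (e^-1 + e^-2)/2 ) evaluated directly
        assert fs.kolm_ede([2, 4], 0.5) == pytest.approx(2.759771, abs=1e-5)

    def test_small_aversion_limit_is_mean(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert fs.kolm_ede(v, 1e-8) == pytest.approx(np.mean(v), abs=1e-4)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            fs.kolm_ede([1.0, 2.0], 0.0)

    def test_large_values_no_overflow(self):
        # log-sum-exp keeps huge negative NHBs finite
        assert np.isfinite(fs.kolm_ede([-2000.0, 1000.0], 0.5))

    @given(positive_quartets, st.floats(min_value=0.01, max_value=2.0))
    @settings(max_examples=150, deadline=None)
    def test_jensen_bound_and_oracle(self, values, alpha):
        ede = fs.kolm_ede(values, alpha)
        assert ede <= np.mean(values) + 1e-9
        assert ede == pytest.approx(longdouble_kolm(values, alpha), rel=1e-6, abs=1e-9)

    @given(positive_quartets, st.floats(min_value=0.01, max_value=2.0),
           st.floats(min_value=-5, max_value=5))
    @settings(max_examples=150, deadline=None)
    def test_translation_invariance(self, values, alpha, c):
        shifted = fs.kolm_ede([v + c for v in values], alpha)
        assert shifted == pytest.approx(fs.kolm_ede(values, alpha) + c, abs=1e-7)

    def test_monotone_nonincreasing_in_aversion(self):
        v = [1.0, 2.0, 5.0, 9.0]
        edes = [fs.kolm_ede(v, a) for a in fs.KOLM_GRID]
        assert all(a >= b - 1e-12 for a, b in zip(edes, edes[1:]))


class TestPerQuartileNhb:
    def _toy_result(self, frame):
        from fallsim.economics import StrategyResult

        return StrategyResult(
            strategy="UC", seed=0, horizon=1, n_individuals=len(frame),
            totals={}, person_years_any_fall=0, usage={}, individuals=frame,
        )

    def _frame(self, n_per_q=2, qaly=1.0, public=0.0, productivity=0.0):
        rows = []
        for q in range(1, 5):
            for _ in range(n_per_q):
                rows.append({
                    "ses_quartile": q, "qaly": qaly, "allcause_public_cost": public,
                    "intervention_public_cost": 0.0, "productivity_value": productivity,
                    "participant_toc": 0.0, "oop_expenditure": 0.0, "co_payment": 0.0,
                    "informal_care_cost": 0.0, "caregiver_toc": 0.0,
                })
        return pd.DataFrame(rows)

    def test_zero_streams_give_zero(self):
        out = fs.per_quartile_nhb(self._toy_result(self._frame(qaly=0.0)))
        np.testing.assert_allclose(out.values, 0.0)

    def test_scale_invariance_per_capita(self):
        small = fs.per_quartile_nhb(self._toy_result(self._frame(n_per_q=2)))
        large = fs.per_quartile_nhb(self._toy_result(self._frame(n_per_q=4)))
        np.testing.assert_allclose(small.values, large.values)

    def test_hand_arithmetic(self):
        frame = self._frame(n_per_q=1, qaly=2.0, public=60_000.0, productivity=120_000.0)
        out = fs.per_quartile_nhb(self._toy_result(frame))
        # per person: 2 + 120000/60000 - 60000/30000 = 2 + 2 - 2 = 2
        np.testing.assert_allclose(out.values, 2.0)

    def test_empty_quartile_rejected(self):
        frame = self._frame()
        frame = frame[frame["ses_quartile"] != 3]
        with pytest.raises(ValueError):
            fs.per_quartile_nhb(self._toy_result(frame))


class TestDcea:
    def test_published_inab(self):
        uc = QuartileNhb("UC", np.full(4, 4.1774), np.full(4, 1))
        rc = QuartileNhb("RC", np.full(4, 4.2081), np.full(4, 1))
        curve = fs.dcea(uc, rc)
        assert curve.inab == pytest.approx(0.0307, abs=1e-9)
        # equal distributions: every EDE INHB equals the INAB
        np.testing.assert_allclose(curve.table["ede_inhb"], curve.inab)

    def test_identical_distributions_give_zero(self):
        v = np.array([4.0, 4.2, 4.4, 4.6])
        same = QuartileNhb("UC", v, np.full(4, 1))
        curve = fs.dcea(same, QuartileNhb("RC", v.copy(), np.full(4, 1)))
        assert curve.inab == 0.0
        np.testing.assert_allclose(curve.table["ede_inhb"], 0.0, atol=1e-12)

    def test_lifting_worst_off_beats_inab(self):
        uc = QuartileNhb("UC", np.array([5.0, 4.0, 3.0, 2.0]), np.full(4, 1))
        rc = QuartileNhb("RC", np.array([5.0, 4.0, 3.0, 2.4]), np.full(4, 1))
        curve = fs.dcea(uc, rc)
        atk = curve.table[curve.table["aversion_type"] == "atkinson"]
        assert np.all(atk[atk["aversion"] > 0]["ede_inhb"] > curve.inab)
        assert curve.classification == "joint efficiency and equity improvement"

    def test_zero_aversion_rows_equal_mean_difference(self):
        uc = QuartileNhb("UC", np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 1))
        rc = QuartileNhb("RC", np.array([1.5, 2.0, 3.0, 4.0]), np.full(4, 1))
        curve = fs.dcea(uc, rc)
        assert curve.row("atkinson", 0.0)["ede_inhb"] == pytest.approx(curve.inab)


class TestLifetimeOutcomes:
    def _cohort(self, rows):
        defaults = {
            "ses_quartile": 3, "qaly": 5.0, "wellbeing": 5.0,
            "lifetime_qaly": 6.0, "lifetime_wellbeing": 6.0,
            "work_years_since_65": 0.0, "private_expenditure_cum": 0.0,
            "private_expenditure_excl_copay_cum": 0.0,
            "informal_care_value_cum": 0.0, "caregiver_toc_cum": 0.0,
        }
        return pd.DataFrame([{**defaults, **r} for r in rows])

    def test_fair_innings_threshold_is_60pct_of_uc_median(self):
        uc = self._cohort([{"qaly": 7.0}, {"qaly": 7.0}, {"qaly": 7.0}])
        cohort = self._cohort([{"qaly": 4.3}, {"qaly": 4.1}, {"qaly": 4.2}])
        counts = lifetime_outcomes(cohort, uc, [1e5] * 4)
        # threshold 0.6 x 7 = 4.2; 4.2 and 4.3 reach it, 4.1 does not
        assert counts.fair_health_innings == 2

    def test_productive_ageing_requires_ten_work_years(self):
        cohort = self._cohort([
            {"work_years_since_65": 9.0}, {"work_years_since_65": 10.0},
            {"work_years_since_65": 25.0},
        ])
        counts = lifetime_outcomes(cohort, cohort, [1e5] * 4)
        assert counts.productive_ageing == 2

    def test_cpe_strict_boundary_and_quartile_restriction(self):
        capacity = [10_000.0] * 4
        cohort = self._cohort([
            {"ses_quartile": 3, "private_expenditure_cum": 4_000.0},
            {"ses_quartile": 3, "private_expenditure_cum": 4_000.01},
            {"ses_quartile": 1, "private_expenditure_cum": 9_999.0},
        ])
        counts = lifetime_outcomes(cohort, cohort, capacity)
        assert counts.catastrophic_private_expenditure == 1  # strict >40%; Q1 exempt

    def test_caregiver_burden_with_and_without_toc(self):
        cohort = self._cohort([
            {"informal_care_value_cum": EXCESSIVE_BURDEN_THRESHOLD - 1.0,
             "caregiver_toc_cum": 2.0},
            {"informal_care_value_cum": EXCESSIVE_BURDEN_THRESHOLD + 1.0},
            {"informal_care_value_cum": EXCESSIVE_BURDEN_THRESHOLD},  # strict
        ])
        counts = lifetime_outcomes(cohort, cohort, [1e5] * 4)
        assert counts.excessive_informal_burden == 2
        assert counts.burden_excluding_toc == 1

    def test_empty_cohort_rejected(self):
        cohort = self._cohort([{}])
        with pytest.raises(ValueError):
            lifetime_outcomes(cohort.iloc[:0], cohort, [1e5] * 4)
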