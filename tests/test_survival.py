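import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tmescope as tm
from tmescope.errors import ValidationError


def _cohort(expr_dict, times=None, events=None):
    expr = pd.DataFrame(expr_dict)
    expr.index = pd.Index([f"p{i}" for i in range(len(expr))], name="patient_id")
    n = len(expr)
    clinical = pd.DataFrame(
        {
            "os_time": times if times is not None else np.arange(1.0, n + 1),
            "os_event": events if events is not None else [1] * n,
        },
        index=expr.index,
    )
    return tm.BulkCohort(expr, clinical)


class TestBinarize:
    def test_even_cohort_midpoint_median(self):
        cohort = _cohort({"g": [1.0, 2.0, 3.0, 4.0]})
        b = tm.binarize_vs_median(cohort, tm.GeneSet("s", ["g"]))
        assert list(b["g"]) == [0, 0, 1, 1]  # median 2.5

    def test_at_median_is_one_odd_cohort(self):
        cohort = _cohort({"g": [1.0, 2.0, 3.0]})
        b = tm.binarize_vs_median(cohort, tm.GeneSet("s", ["g"]))
        assert list(b["g"]) == [0, 1, 1]  # the patient AT the median scores 1

    def test_constant_gene_all_ones(self):
        cohort = _cohort({"g": [5.0] * 4})
        b = tm.binarize_vs_median(cohort, tm.GeneSet("s", ["g"]))
        assert (b["g"] == 1).all()

    def test_missing_genes_shrink_k_with_warning(self, caplog):
        cohort = _cohort({"g1": [1.0, 2.0], "g2": [3.0, 4.0]})
        with caplog.at_level("WARNING"):
            b = tm.binarize_vs_median(cohort, tm.GeneSet("s", ["g1", "gone"]))
        assert list(b.columns) == ["g1"]
        assert "absent" in caplog.text

    def test_fully_absent_signature_rejected(self):
        cohort = _cohort({"g": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            tm.binarize_vs_median(cohort, tm.GeneSet("s", ["x", "y"]))


class TestScorePatients:
    def test_hand_built_matrix(self):
        b = pd.DataFrame(
            [[1, 0, 1], [0, 0, 0], [1, 1, 1], [0, 1, 0]],
            index=list("abcd"), columns=["g1", "g2", "g3"],
        )
        s = tm.score_patients(b)
        assert s.to_dict() == {"a": 2, "b": 0, "c": 3, "d": 1}

    def test_score_conservation(self, bulk_sim):
        _, cohort, _ = bulk_sim
        b = tm.binarize_vs_median(cohort, tm.GeneSet("s", list(cohort.expr.columns[:20])))
        assert tm.score_patients(b).sum() == b.to_numpy().sum()


class TestStratify:
    def test_distinct_scores_definition(self):
        s = pd.Series(np.arange(1, 9), index=[f"p{i}" for i in range(8)])
        g = tm.stratify_quartiles(s)
        assert set(s[g == "low"]) == {1, 2}
        assert set(s[g == "high"]) == {7, 8}
        assert (g == "excluded").sum() == 4

    def test_boundary_ties_all_included(self):
        s = pd.Series([1, 1, 1, 2, 3, 4, 5, 5], index=[f"p{i}" for i in range(8)])
        g = tm.stratify_quartiles(s)
        assert (g == "low").sum() == 3  # every score-1 patient
        assert (g == "high").sum() == 2

    def test_hundred_distinct_scores(self):
        s = pd.Series(np.arange(100), index=[f"p{i}" for i in range(100)])
        g = tm.stratify_quartiles(s)
        assert (g == "high").sum() == 25 and (g == "low").sum() == 25

    def test_identical_scores_rejected(self):
        s = pd.Series([3] * 10, index=[f"p{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            tm.stratify_quartiles(s)

    @given(st.permutations(list(range(12))))
    def test_monotone_transform_invariance(self, values):
        s = pd.Series(values, index=[f"p{i}" for i in range(12)])
        a = tm.stratify_quartiles(s)
        b = tm.stratify_quartiles(s * 7 + 2)
        c = tm.stratify_quartiles(np.exp(s / 3.0))
        assert a.equals(b) and a.equals(c)


class TestKaplanMeier:
    def test_all_censored_survival_one(self):
        km = tm.kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_all_events_product_limit(self):
        km = tm.kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(km["survival"], [1.0, 2 / 3, 1 / 3, 0.0])

    def test_hand_computed_mixed_table(self):
        # 6 subjects: events at 1, 2, 4, 6; censored at 3 and 5
        km = tm.kaplan_meier([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        surv = km.set_index("time")["survival"]
        assert surv[1.0] == pytest.approx(5 / 6)
        assert surv[2.0] == pytest.approx(5 / 6 * 4 / 5)
        assert surv[4.0] == pytest.approx(2 / 3 * 2 / 3)
        assert surv[6.0] == pytest.approx(0.0)

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, 200)
        km = tm.kaplan_meier(t, np.ones(200, dtype=int))
        for _, row in km.iloc[1:].iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_monotone_from_one(self, bulk_sim):
        _, cohort, _ = bulk_sim
        km = tm.kaplan_meier(
            cohort.clinical["os_time"].to_numpy(),
            cohort.clinical["os_event"].to_numpy(),
        )
        assert km["survival"].iloc[0] == 1.0
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tm.kaplan_meier([], [])


class TestLogrankHr:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        res = tm.logrank_hr((t, e), (t, e))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0)

    def test_label_swap_inverts_hr(self, bulk_sim):
        _, cohort, truth = bulk_sim
        hi = truth.latent > 0.5
        lo = truth.latent < -0.5
        clin = cohort.clinical
        a = (clin.loc[hi, "os_time"].to_numpy(), clin.loc[hi, "os_event"].to_numpy())
        b = (clin.loc[lo, "os_time"].to_numpy(), clin.loc[lo, "os_event"].to_numpy())
        fwd, rev = tm.logrank_hr(a, b), tm.logrank_hr(b, a)
        assert rev.hr == pytest.approx(1.0 / fwd.hr)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_hand_computed_six_subject_fixture(self):
        """O, E, V, chi2, HR hand-derived from the 2x2 tables at each
        event time of: high (1+,3+,5c), low (2+,4+,6+)."""
        res = tm.logrank_hr(
            (np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])),
            (np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1])),
        )
        e1 = 0.5 + 2 / 5 + 0.5 + 1 / 3
        var = 0.25 + 6 / 25 + 0.25 + 2 / 9
        assert res.o1 == 2 and res.o2 == 3
        assert res.e1 == pytest.approx(e1)
        assert res.chi_square == pytest.approx((2 - e1) ** 2 / var)
        assert res.hr == pytest.approx((2 / e1) / (3 / (5 - e1)))

    def test_matches_lifelines_on_random_fixtures(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(5, 40, 2)
            t1, t2 = rng.exponential(1.0, n1), rng.exponential(1.6, n2)
            e1 = rng.integers(0, 2, n1)
            e2 = rng.integers(0, 2, n2)
            if e1.sum() + e2.sum() == 0:
                e1[0] = 1
            mine = tm.logrank_hr((t1, e1), (t2, e2))
            ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-6)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            tm.logrank_hr(
                (np.array([1.0]), np.array([0])), (np.array([2.0]), np.array([0]))
            )


class TestSignatureSurvival:
    def test_planted_effect_detected(self, bulk_sim):
        _, cohort, _ = bulk_sim
        sig = tm.GeneSet("s", list(cohort.expr.columns[:20]))
        res = tm.signature_survival(cohort, sig)
        assert res.hr > 1.0
        assert res.p_value < 0.05
        assert res.scores is not None and res.groups is not None

    def test_cox_cross_check_close_to_mh(self, bulk_sim):
        _, cohort, _ = bulk_sim
        sig = tm.GeneSet("s", list(cohort.expr.columns[:20]))
        res = tm.signature_survival(cohort, sig, hr_method="cox")
        assert res.cox_hr is not None
        assert np.log(res.cox_hr) == pytest.approx(np.log(res.hr), abs=0.35)

    def test_hr_monotone_in_beta(self):
        medians = []
        for beta in (0.0, 0.5, 1.0):
            hrs = []
            for rep in range(25):
                cohort, _ = tm.simulate_bulk(
                    tm.BulkSimConfig(n_patients=160, n_genes=30, beta=beta, seed=1000 + rep)
                )
                sig = tm.GeneSet("s", list(cohort.expr.columns[:20]))
                hrs.append(tm.signature_survival(cohort, sig).hr)
            medians.append(np.median(hrs))
        assert medians[0] < medians[1] < medians[2]

    def test_power_grows_with_n_and_beta(self):
        def power(n, beta, reps=20):
            hits = 0
            for rep in range(reps):
                cohort, _ = tm.simulate_bulk(
                    tm.BulkSimConfig(n_patients=n, n_genes=30, beta=beta, seed=5000 + rep)
                )
                sig = tm.GeneSet("s", list(cohort.expr.columns[:20]))
                hits += tm.signature_survival(cohort, sig).p_value < 0.05
            return hits / reps

        assert power(240, 1.2) >= power(80, 0.4)
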