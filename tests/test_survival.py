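"""Survival and mutation statistics: hand oracles, lifelines cross-checks,
calibration against the generator's truth."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from memtarget import (
    ClinicalTable,
    SimulationConfig,
    cox_score_test,
    cox_univariate,
    km_estimate,
    logrank_test,
    median_split,
    mutation_association,
    risk_ordered_view,
    simulate_cohort,
)
from memtarget.survival import feature_survival_split


class TestKaplanMeier:
    def test_all_events_hand_oracle(self):
        (curve,) = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        (curve,) = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_tied_events_hand_oracle(self):
        """Times (2,2,3,5), events (1,1,1,0): S = 1/2 after t=2, 1/4 after t=3."""
        (curve,) = km_estimate([2, 2, 3, 5], [1, 1, 1, 0])
        np.testing.assert_allclose(curve.times, [2, 3])
        np.testing.assert_allclose(curve.n_risk, [4, 2])
        np.testing.assert_allclose(curve.survival, [0.5, 0.25])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40)
        (curve,) = km_estimate(t, np.ones(40, int))
        for et, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > et).mean(), abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 60).round(1)  # rounding forces ties
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        (curve,) = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(et).iloc[0]), abs=1e-10
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        """Step-by-step O-E/V tabulation for two groups of three subjects.

        Times/events: A = (1,1), (3,1), (5,0); B = (2,1), (4,1), (6,1).
        Hand tabulation over the event times 1, 2, 3, 4, 6:

        ====  ===  ====  ====  =====  =======
        time    n   n_A   O_A    E_A      Var
        ====  ===  ====  ====  =====  =======
           1    6     3     1    1/2      1/4
           2    5     2     0    2/5     6/25
           3    4     2     1    1/2      1/4
           4    3     1     0    1/3      2/9
           6    1     0     0      0        0
        ====  ===  ====  ====  =====  =======

        U = 2 - 26/15 = 4/15, V = 433/450, chi-square = U^2/V = 32/433.
        """
        t = np.array([1, 3, 5, 2, 4, 6], float)
        e = np.array([1, 1, 0, 1, 1, 1])
        g = np.array(["A", "A", "A", "B", "B", "B"])
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(32 / 433, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_matches_lifelines_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(8, 20))
            t = rng.exponential(10, n)
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            res = logrank_test(t, e, g)
            ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.p_value, abs=1e-10)

    def test_two_group_chi_square_is_squared_standardized_sum(self):
        """df-1 identity: chi-square equals (O-E)^2 / V for two groups."""
        rng = np.random.default_rng(7)
        t = rng.exponential(8, 30)
        e = rng.integers(0, 2, 30)
        e[:3] = 1
        g = rng.integers(0, 2, 30)
        res = logrank_test(t, e, g)
        # recompute U and V directly
        labels = [0, 1]
        u = v = 0.0
        for et in np.unique(t[e == 1]):
            at_risk = t >= et
            n = at_risk.sum()
            d = ((t == et) & (e == 1)).sum()
            n0 = (at_risk & (g == labels[0])).sum()
            d0 = ((t == et) & (e == 1) & (g == labels[0])).sum()
            u += d0 - d * n0 / n
            if n > 1:
                v += d * (n - d) / (n - 1) * (n0 / n) * (1 - n0 / n)
        assert res.chi_square == pytest.approx(u * u / v, abs=1e-10)

    def test_power_against_generator_truth(self):
        """log HR ln 2 at n=200: rejection rate at alpha 0.05 above 0.8."""
        rejections = 0
        reps = 60
        for rep in range(reps):
            cohort = simulate_cohort(
                SimulationConfig(
                    seed=2000 + rep,
                    n_ln_pos=100,
                    n_ln_neg=100,
                    n_features=4,
                    n_planted_membrane=1,
                    n_decoy_membrane=1,
                )
            )
            tumor = cohort.clinical.data[cohort.clinical.data.tissue == "tumor"]
            res = logrank_test(
                tumor["pfs_time"], tumor["pfs_event"], tumor["ln_status"]
            )
            rejections += res.p_value < 0.05
        assert rejections / reps > 0.8


class TestCox:
    def test_null_covariate_beta_near_zero(self):
        """Independent covariate: |beta| < 3 SE in the vast majority of reps."""
        rng = np.random.default_rng(11)
        ok = 0
        reps = 100
        for _ in range(reps):
            n = 60
            t = rng.exponential(10, n)
            e = np.ones(n, int)
            x = rng.normal(size=n)
            fit = cox_univariate(t, e, x)
            ok += abs(fit.beta) < 3 * fit.se
        assert ok / reps >= 0.95

    def test_recovers_generator_log_hazard_ratio(self):
        """Mean beta over 100 reps at n=500 within 0.15 of ln 2."""
        betas = []
        for rep in range(100):
            cohort = simulate_cohort(
                SimulationConfig(
                    seed=3000 + rep,
                    n_ln_pos=250,
                    n_ln_neg=250,
                    n_features=4,
                    n_planted_membrane=1,
                    n_decoy_membrane=1,
                )
            )
            tumor = cohort.clinical.data[cohort.clinical.data.tissue == "tumor"]
            fit = cox_univariate(
                tumor["pfs_time"],
                tumor["pfs_event"],
                (tumor["ln_status"] == "metastatic").astype(float),
            )
            assert fit.converged
            betas.append(fit.beta)
        assert abs(np.mean(betas) - math.log(2)) < 0.15

    def test_matches_lifelines_breslow(self):
        rng = np.random.default_rng(13)
        n = 50
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        x = rng.normal(size=n)
        fit = cox_univariate(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")  # untied times: Efron == Breslow
        assert fit.beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-4)
        assert fit.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-4)

    def test_score_test_equals_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(10, 30)  # continuous, no ties
        e = rng.integers(0, 2, 30)
        e[:3] = 1
        g = rng.integers(0, 2, 30)
        ref = logrank_test(t, e, g)
        score = cox_score_test(t, e, g.astype(float))
        assert score.chi_square == pytest.approx(ref.chi_square, abs=1e-10)

    def test_perfect_separation_flags_non_convergence(self):
        """Covariate perfectly ordering events drives beta off to infinity."""
        t = np.arange(1.0, 11.0)
        e = np.ones(10, int)
        x = np.arange(10.0)  # later death <=> larger x: monotone likelihood
        fit = cox_univariate(t, e, x)
        assert not fit.converged

    def test_partial_likelihood_ascends(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        e[:4] = 1
        x = rng.normal(size=40)
        from memtarget.survival import _breslow_loglik

        fit = cox_univariate(t, e, x)
        assert fit.log_likelihood >= _breslow_loglik(0.0, t, e, x) - 1e-12


class TestMutationAssociation:
    @staticmethod
    def _cohort_tables(counts):
        """Build MutationTable + ClinicalTable realizing given 2x2 counts."""
        from memtarget import MutationTable

        mut_met, mut_non, wt_met, wt_non = counts
        samples, tissues, statuses = [], [], []
        rows = []
        i = 0
        for group, status, mutated in (
            (mut_met, "metastatic", True),
            (wt_met, "metastatic", False),
            (mut_non, "non_metastatic", True),
            (wt_non, "non_metastatic", False),
        ):
            for _ in range(group):
                sid = f"S{i:03d}"
                i += 1
                samples.append(sid)
                tissues.append("tumor")
                statuses.append(status)
                if mutated:
                    rows.append(("G1", sid, "missense"))
        clinical = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "tissue": tissues,
                    "ln_status": statuses,
                    "os_time": 1.0,
                    "os_event": 0,
                    "pfs_time": 1.0,
                    "pfs_event": 0,
                }
            )
        )
        mut = MutationTable(
            pd.DataFrame(rows, columns=["gene", "sample_id", "variant_class"]),
            sample_ids=samples,
        )
        return mut, clinical

    def test_balanced_table_chi_zero(self):
        mut, clinical = self._cohort_tables((10, 10, 10, 10))
        res = mutation_association(mut, clinical, top_n=5)
        assert res.loc[0, "chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_hand_formula_on_skewed_table(self):
        """[[20,5],[5,20]]: chi-square = n(ad-bc)^2/(r1 r2 c1 c2) = 18."""
        mut, clinical = self._cohort_tables((20, 5, 5, 20))
        res = mutation_association(mut, clinical, top_n=5)
        assert res.loc[0, "chi_square"] == pytest.approx(18.0, abs=1e-10)

    def test_chi_square_matches_hand_formula_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            counts = tuple(int(c) for c in rng.integers(1, 15, 4))
            mut, clinical = self._cohort_tables(counts)
            res = mutation_association(mut, clinical, top_n=3)
            a, b, c, d = counts  # mut_met, mut_non, wt_met, wt_non
            n = a + b + c + d
            hand = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert res.loc[0, "chi_square"] == pytest.approx(hand, abs=1e-10)

    def test_zero_margin_flagged_degenerate(self):
        mut, clinical = self._cohort_tables((0, 0, 10, 10))
        res = mutation_association(mut, clinical, top_n=5)
        # G1 never mutated -> it is absent from rows entirely; nothing to rank
        assert res.empty or bool(res.loc[0, "degenerate"])

    def test_fisher_available(self):
        mut, clinical = self._cohort_tables((20, 5, 5, 20))
        res = mutation_association(mut, clinical, top_n=5, method="fisher")
        assert 0 <= res.loc[0, "p_value"] < 0.001

    def test_enriched_genes_rank_more_significant_than_background(self, default_cohort):
        res = mutation_association(
            default_cohort.mutations, default_cohort.clinical, top_n=50
        )
        truth = default_cohort.truth
        enriched = set(truth.loc[truth["mutation_enriched"].astype(bool), "id"])
        res_valid = res.dropna(subset=["p_value"])
        p_enriched = res_valid.loc[res_valid["gene"].isin(enriched), "p_value"]
        p_background = res_valid.loc[~res_valid["gene"].isin(enriched), "p_value"]
        assert p_enriched.median() < p_background.median()

    def test_top_n_ranked_by_frequency(self, default_cohort):
        res = mutation_association(
            default_cohort.mutations, default_cohort.clinical, top_n=10
        )
        assert len(res) == 10
        assert list(res["frequency"]) == sorted(res["frequency"], reverse=True)


class TestRiskViewAndSplits:
    def test_descending_order_with_id_tiebreak(self, tiny_clinical):
        expr = pd.Series(
            {"S1": 3.0, "S2": 5.0, "S3": 3.0, "S4": 1.0, "S5": 2.0, "S6": 4.0}
        )
        view = risk_ordered_view(expr, tiny_clinical)
        assert list(view["sample_id"]) == ["S2", "S6", "S1", "S3", "S5", "S4"]
        assert len(view) == 6  # tumor samples only

    def test_missing_tumor_expression_rejected(self, tiny_clinical):
        expr = pd.Series({"S1": 1.0})
        with pytest.raises(KeyError):
            risk_ordered_view(expr, tiny_clinical)

    def test_median_split_ties_go_low(self):
        values = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        labels = median_split(values)
        assert list(labels) == ["low", "low", "low", "high"]

    def test_feature_survival_split_runs_on_cohort(self, default_cohort):
        fid = default_cohort.planted_ids[0]
        result, curves = feature_survival_split(
            default_cohort.proteome, default_cohort.clinical, fid, endpoint="pfs"
        )
        assert 0 <= result.p_value <= 1
        assert {c.label for c in curves} == {"high", "low"}
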