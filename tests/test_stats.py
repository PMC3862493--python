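"""Permutation tests, FDR, and partial correlation."""

import numpy as np
import pytest
from scipy import stats as sps

import strokenet as sn

import oracles


class TestPermutationTest:
    def test_all_equal_values_give_p_one(self):
        res = sn.permutation_test([1, 1], [1, 1], n_perm=50, seed=0)
        assert res.observed_diff == 0.0
        assert np.all(res.null_diffs == 0)
        assert res.p_one_tailed == 1.0  # ties count as exceedances

    def test_exact_enumeration_matches_oracle(self):
        a, b = [10.0, 11.0], [0.0, 1.0]
        res = sn.permutation_test(a, b, side="greater", exact=True)
        assert res.p_one_tailed == pytest.approx(1 / 6)
        assert res.n_perm == 6
        assert res.p_one_tailed == oracles.exact_permutation_p(a, b, "greater")

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("side", ["greater", "less"])
    def test_exact_matches_oracle_random_small_samples(self, seed, side):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 5))
        n_b = int(rng.integers(2, 9 - n_a))
        a, b = rng.normal(size=n_a), rng.normal(size=n_b)
        res = sn.permutation_test(a, b, side=side, exact=True)
        assert res.p_one_tailed == pytest.approx(
            oracles.exact_permutation_p(list(a), list(b), side), abs=1e-12
        )

    def test_sampled_p_converges_to_exact(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1.0, 1, 4), rng.normal(0.0, 1, 4)
        exact = sn.permutation_test(a, b, exact=True).p_one_tailed
        sampled = sn.permutation_test(a, b, n_perm=20000, seed=2).p_one_tailed
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_minimum_p_is_one_over_n_perm_or_zero(self):
        # observed diff recurs in the identity permutation -> p >= 1/n_perm
        res = sn.permutation_test([100.0, 101.0], [0.0, 1.0], n_perm=100, seed=0)
        assert res.p_one_tailed >= 1 / res.n_perm

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            sn.permutation_test([], [1.0], n_perm=10)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=12)
        r1 = sn.permutation_test(a, b, n_perm=500, seed=9)
        r2 = sn.permutation_test(a, b, n_perm=500, seed=9)
        assert r1.p_one_tailed == r2.p_one_tailed
        assert np.array_equal(r1.null_diffs, r2.null_diffs)


class TestFdrBH:
    def test_hand_executed_stepup(self):
        rejected, critical = sn.fdr_bh([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert list(rejected) == [True, True, True, False]
        assert critical == 0.03

    def test_all_ones_nothing_rejected_critical_zero(self):
        rejected, critical = sn.fdr_bh([1.0, 1.0, 1.0])
        assert not rejected.any()
        assert critical == 0.0

    def test_single_small_p_rejected(self):
        rejected, critical = sn.fdr_bh([0.04], q=0.05)
        assert rejected.all() and critical == 0.04

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_stepup_oracle_and_contains_bonferroni(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.random(25) ** 2, 4)
        rejected, critical = sn.fdr_bh(p, q=0.05)
        oracle_rej, oracle_crit = oracles.bh_stepup(list(p), 0.05)
        assert list(rejected) == oracle_rej
        assert critical == pytest.approx(oracle_crit)
        bonferroni = p <= 0.05 / len(p)
        assert np.all(rejected[bonferroni])  # BH rejects a superset

    def test_q_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="q"):
            sn.fdr_bh([0.5], q=1.5)


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = sn.partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_matches_pingouin_with_covariates(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(1)
        n = 50
        age = rng.normal(70, 8, n)
        x = 0.3 * age + rng.normal(size=n)
        y = 0.6 * x + 0.2 * age + rng.normal(size=n)
        res = sn.partial_correlation(x, y, age)
        df = pd.DataFrame({"x": x, "y": y, "age": age})
        ref = pg.partial_corr(df, x="x", y="y", covar="age")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_exact_linear_function_of_covariates_rejected(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(20, 2))
        x = rng.normal(size=20)
        y = 2.0 + z @ np.array([1.5, -0.7])
        with pytest.raises(ValueError, match="zero residual variance"):
            sn.partial_correlation(x, y, z)

    def test_planted_partial_correlation_recovered(self):
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            age = rng.normal(70, 8, n)
            x = rng.normal(size=n)
            y = 0.6 * x + 0.5 * (age - 70) / 8 + np.sqrt(1 - 0.36) * rng.normal(size=n)
            res = sn.partial_correlation(x, y, age)
            hits.append(abs(res.r - 0.6 / np.sqrt(0.36 + (1 - 0.36))) < 0.1)
        assert np.mean(hits) >= 0.8

    def test_gender_coding_invariance(self):
        rng = np.random.default_rng(3)
        n = 40
        g = (rng.random(n) < 0.5).astype(float)
        x = rng.normal(size=n) + g
        y = 0.5 * x + rng.normal(size=n)
        r1 = sn.partial_correlation(x, y, g).r
        r2 = sn.partial_correlation(x, y, 1.0 - g).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(20, 1))
        with pytest.raises(ValueError, match="rank-deficient"):
            sn.partial_correlation(
                rng.normal(size=20), rng.normal(size=20), np.hstack([z, z])
            )

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            sn.partial_correlation([1.0, 2.0], [2.0, 1.0], np.ones((2, 1)))


def _null_cohort(seed, n_per_group=6, n_nodes=20):
    spec = sn.SyntheticCohortSpec(
        n_nc=n_per_group,
        n_patient=n_per_group,
        n_nodes=n_nodes,
        ring_neighbors=4,
        lesion_attenuation=1.0,
        lesion_nodes=(),
        master_seed=seed,
        nihss_link=sn.NihssLink(target_node=0),
    )
    return sn.generate_cohort(spec)[0]


class TestCompareGroups:
    def test_nodal_comparison_deterministic(self):
        cohort = _null_cohort(0)
        per_subject = sn.stats.cohort_nodal_metrics(cohort)
        r1 = sn.compare_groups_nodal(cohort, per_subject, n_perm=10, seed=4)
        r2 = sn.compare_groups_nodal(cohort, per_subject, n_perm=10, seed=4)
        for metric in r1:
            assert r1[metric].table.equals(r2[metric].table)
            assert r1[metric].fdr_critical_p == r2[metric].fdr_critical_p

    def test_identical_groups_rarely_significant(self):
        # null cohorts: expected FDR-significant node count ~ 0
        counts = []
        for seed in range(5):
            cohort = _null_cohort(seed)
            res = sn.compare_groups_nodal(cohort, n_perm=100, seed=seed, q=0.05)
            counts.append(
                sum(r.table["fdr_significant"].sum() for r in res.values())
            )
        assert np.mean(counts) <= 1.0

    def test_lesioned_nodes_detected_as_decreased_strength(self):
        spec = sn.SyntheticCohortSpec(
            n_nc=15, n_patient=15, n_nodes=30, ring_neighbors=4,
            lesion_nodes=(3, 9, 15), lesion_attenuation=0.6,
            master_seed=1, nihss_link=sn.NihssLink(target_node=0),
        )
        cohort, truth = sn.generate_cohort(spec)
        res = sn.compare_groups_nodal(
            cohort, metric_names=["strength"], n_perm=500, seed=0, q=0.05
        )["strength"]
        flagged = res.table.loc[list(truth.lesion_nodes)]
        assert flagged["fdr_significant"].all()
        assert (flagged["observed_diff"] < 0).all()  # patient minus NC
        assert (flagged["side"] == "less").all()

    def test_global_comparison_columns_and_side_rule(self):
        cohort = _null_cohort(2)
        table = sn.global_metric_table(cohort)
        res = sn.compare_groups_global(table, n_perm=50, seed=0)
        assert set(res["metric"]) == set(sn.GlobalMetrics.METRIC_NAMES)
        # side always follows the observed difference by default
        follows = (res["observed_diff"] >= 0) == (res["side"] == "greater")
        assert follows.all()


class TestCorrelateClinical:
    def test_planted_nihss_link_found(self):
        spec = sn.SyntheticCohortSpec(
            n_nc=2, n_patient=40, n_nodes=30, ring_neighbors=4,
            lesion_attenuation=1.0, lesion_nodes=(), master_seed=3,
            nihss_link=sn.NihssLink(target_node=12, coefficient=0.9, noise_sd=0.3),
        )
        cohort, truth = sn.generate_cohort(spec)
        table = sn.correlate_clinical(cohort, "nihss", level="nodal", alpha=0.001)
        hit = table[
            (table["metric"] == "betweenness")
            & (table["region"] == cohort.atlas.abbreviations[12])
        ]
        assert bool(hit["significant"].iloc[0])
        assert hit["r"].iloc[0] > 0.5

    def test_constant_score_rejected(self):
        cohort = _null_cohort(4, n_per_group=8)
        for s in cohort.group("patient"):
            s.nihss = 3
        with pytest.raises(ValueError, match="zero residual variance"):
            sn.correlate_clinical(cohort, "nihss", level="nodal")

    def test_subjects_missing_score_dropped(self):
        cohort = _null_cohort(5, n_per_group=8)
        patients = cohort.group("patient")
        patients[0].nihss = None
        table = sn.correlate_clinical(cohort, "nihss", level="nodal", alpha=0.05)
        assert (table["n"] == len(patients) - 1).all()
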