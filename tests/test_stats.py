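import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bgosc.stats import (
    aggregate_hemispheres,
    cluster_permutation,
    correlate_with_severity,
    fdr_correct,
    permutation_test,
)


class TestPermutationTest:
    def test_identical_paired_samples_give_p_one(self):
        a = np.arange(10.0)
        with pytest.warns(UserWarning):
            res = permutation_test(a, a, paired=True, n_perm=200, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_strong_separation_hits_the_floor(self, rng):
        a = rng.normal(0, 1, 19)
        b = rng.normal(3, 1, 19)
        res = permutation_test(b, a, paired=True, n_perm=500, seed=0)
        assert res.p_value == pytest.approx(1 / 501)

    def test_p_never_zero(self, rng):
        res = permutation_test(rng.normal(5, 0.1, 10), rng.normal(0, 0.1, 10),
                               paired=False, n_perm=200, seed=0)
        assert res.p_value >= 1 / 201

    def test_same_seed_reproduces(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        r1 = permutation_test(a, b, paired=True, n_perm=300, seed=9)
        r2 = permutation_test(a, b, paired=True, n_perm=300, seed=9)
        assert r1.p_value == r2.p_value

    def test_unpaired_label_exchange(self, rng):
        a = rng.normal(2.0, 1.0, 15)
        b = rng.normal(0.0, 1.0, 12)
        res = permutation_test(a, b, paired=False, n_perm=500, seed=1)
        assert res.p_value < 0.01


class TestFdr:
    def test_stepup_keeps_all_when_all_below_thresholds(self):
        mask, adj = fdr_correct(np.array([0.01, 0.02, 0.03]), alpha=0.05)
        assert mask.all()
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_single_large_p_not_rejected(self):
        mask, adj = fdr_correct(np.array([0.5]), alpha=0.05)
        assert not mask.any() and adj[0] == 0.5

    def test_empty_input_gives_empty_output(self):
        mask, adj = fdr_correct(np.array([]))
        assert mask.size == 0 and adj.size == 0

    def test_matches_reference_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            mask, adj = fdr_correct(p, alpha=0.05)
            ref_mask, ref_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
            np.testing.assert_array_equal(mask, ref_mask)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_monotone_in_raw_p(self, ps):
        p = np.array(ps)
        _, adj = fdr_correct(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all((adj >= p - 1e-12) & (adj <= 1.0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_invariant_to_input_order(self, ps, rnd):
        p = np.array(ps)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        mask1, adj1 = fdr_correct(p)
        mask2, adj2 = fdr_correct(p[perm])
        np.testing.assert_allclose(adj1[perm], adj2, atol=1e-12)
        assert mask1[perm].sum() == mask2.sum()


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self, rng):
        A = rng.standard_normal((8, 40))
        assert cluster_permutation(A, A.copy(), n_perm=100, seed=0) == []

    def test_band_limited_offset_detected(self, rng):
        freqs = np.arange(1, 41)
        A = rng.standard_normal((12, 40))
        B = A + 0.1 * rng.standard_normal((12, 40))
        B[:, (freqs >= 3) & (freqs <= 12)] += 2.0
        clusters = cluster_permutation(B, A, n_perm=500, seed=0)
        sig = [c for c in clusters if c.p_value <= 0.05]
        assert len(sig) == 1
        assert freqs[sig[0].start] >= 3 and freqs[sig[0].stop - 1] <= 12

    def test_single_noisy_bin_rarely_clusters(self, rng):
        A = rng.standard_normal((8, 40))
        B = A + rng.standard_normal((8, 40)) * 2.0
        B[:, 20] += 1.0
        clusters = cluster_permutation(B, A, n_perm=300, seed=0)
        assert all(c.p_value > 0.05 for c in clusters)

    def test_fewer_than_two_units_is_an_error(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((1, 10)), np.zeros((1, 10)))


class TestSeverityCorrelation:
    def test_exact_affine_relation_gives_r_one(self):
        table = pd.DataFrame({"est": np.arange(10.0), "severity": 3.0 + 2.0 * np.arange(10.0)})
        res = correlate_with_severity(table, "est")
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_zero_variance_is_an_error(self):
        table = pd.DataFrame({"est": np.ones(5), "severity": np.arange(5.0)})
        with pytest.raises(ValueError, match="variance"):
            correlate_with_severity(table, "est")

    def test_affine_rescaling_preserves_r(self, rng):
        x = rng.standard_normal(12)
        y = x + 0.3 * rng.standard_normal(12)
        t1 = pd.DataFrame({"est": x, "severity": y})
        t2 = pd.DataFrame({"est": 100.0 * x + 5.0, "severity": y})
        assert correlate_with_severity(t1, "est").r == pytest.approx(
            correlate_with_severity(t2, "est").r
        )

    def test_too_few_subjects_is_an_error(self):
        table = pd.DataFrame({"est": [1.0, 2.0], "severity": [1.0, 2.0]})
        with pytest.raises(ValueError, match="three"):
            correlate_with_severity(table, "est")


class TestAggregateHemispheres:
    def test_two_hemispheres_average(self):
        df = pd.DataFrame({"subject_id": ["s1", "s1"], "est": [0.2, 0.4]})
        out = aggregate_hemispheres(df)
        assert out.loc[0, "est"] == pytest.approx(0.3)

    def test_unilateral_subject_passes_through(self):
        df = pd.DataFrame({"subject_id": ["s1", "s2", "s2"], "est": [0.7, 0.1, 0.3]})
        out = aggregate_hemispheres(df).set_index("subject_id")
        assert out.loc["s1", "est"] == pytest.approx(0.7)

    def test_19_hemispheres_become_10_rows(self):
        subjects = [f"s{i}" for i in range(10) for _ in range(2)][:-1]
        df = pd.DataFrame({"subject_id": subjects, "est": np.arange(19.0)})
        assert aggregate_hemispheres(df).shape[0] == 10

    def test_severity_join(self):
        df = pd.DataFrame({"subject_id": ["s1", "s1"], "est": [1.0, 3.0]})
        sev = pd.DataFrame({"subject_id": ["s1"], "severity": [7.0]})
        out = aggregate_hemispheres(df, severity=sev)
        assert out.loc[0, "severity"] == 7.0
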