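import numpy as np
import pytest
from scipy import stats

from devgeo.cohort import GroundTruthMixture, simulate_patterns
from devgeo.rsm import (
    RSM,
    cohort_group_rsm,
    enumerate_pairs,
    group_rsm,
    pair_rsm,
    spearman_brown,
    split_half_noise_ceiling,
    zscore_rsm,
)


def brute_pair_rsm(a, b):
    """Symmetrized cross-measurement Pearson matrix, entry by entry."""
    n = a.shape[0]
    out = np.zeros((n, n))
    for p in range(n):
        for q in range(n):
            r1 = np.corrcoef(a[p], b[q])[0, 1]
            r2 = np.corrcoef(a[q], b[p])[0, 1]
            out[p, q] = (r1 + r2) / 2
    return out


class TestEnumeratePairs:
    def test_17_subjects_subject_level_gives_136(self):
        units = [(f"s{i}", -1) for i in range(17)]
        assert len(enumerate_pairs(units, "subject")) == 136

    def test_two_subjects_one_run_each(self):
        units = [("a", 0), ("b", 0)]
        assert len(enumerate_pairs(units)) == 1

    def test_run_level_excludes_within_subject(self):
        units = [("a", 0), ("a", 1), ("b", 0), ("c", 0)]
        # exhaustive: 2*1 + 2*1 + 1*1 = 5 cross-subject pairs
        assert len(enumerate_pairs(units)) == 5

    def test_pair_count_identity_on_random_cohorts(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            run_counts = rng.integers(1, 4, size=rng.integers(2, 8))
            units = [
                (f"s{i}", r) for i, k in enumerate(run_counts) for r in range(k)
            ]
            total = sum(run_counts)
            expected = total * (total - 1) // 2 - sum(
                k * (k - 1) // 2 for k in run_counts
            )
            assert len(enumerate_pairs(units)) == expected

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs([("a", 0), ("a", 1)])


class TestPairRSM:
    def test_identical_patterns_have_unit_diagonal(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 40))
        r = pair_rsm(a, a)
        np.testing.assert_allclose(np.diag(r.values), 1.0, atol=1e-12)

    def test_independent_noise_entries_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [
            pair_rsm(
                rng.standard_normal((4, 200)), rng.standard_normal((4, 200))
            ).values.mean()
            for _ in range(20)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((3, 4))
        np.testing.assert_allclose(pair_rsm(a, b).values, brute_pair_rsm(a, b), atol=1e-8)

    def test_symmetrization_swap_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((6, 30))
        b = rng.standard_normal((6, 30))
        np.testing.assert_allclose(
            pair_rsm(a, b).values, pair_rsm(b, a).values, atol=1e-12
        )

    def test_too_few_shared_voxels_rejected(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((3, 10))
        mask = np.zeros(10, bool)
        mask[0] = True
        with pytest.raises(ValueError):
            pair_rsm(a, a, voxel_mask=mask)


class TestGroupRSM:
    def test_single_rsm_is_identity_operation(self):
        m = RSM(np.eye(3))
        np.testing.assert_array_equal(group_rsm([m]).values, m.values)

    def test_opposite_rsms_cancel(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((4, 4))
        v = (v + v.T) / 2
        out = group_rsm([RSM(v), RSM(-v)])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_weighted_mean_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        mats = [rng.standard_normal((3, 3)) for _ in range(5)]
        mats = [(m + m.T) / 2 for m in mats]
        w = rng.uniform(0.1, 2.0, 5)
        out = group_rsm([RSM(m) for m in mats], weights=w)
        oracle = sum(wi * m for wi, m in zip(w / w.sum(), mats))
        np.testing.assert_allclose(out.values, oracle, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_rsm([])

    def test_blocked_cohort_computation_matches_pairwise_loop(self, category_cohort):
        g, prs = cohort_group_rsm(category_cohort)
        units = dict(category_cohort.units("run"))
        oracle = np.mean(
            [
                brute_pair_rsm(units[a], units[b])
                for a, b in enumerate_pairs(list(units))
            ],
            axis=0,
        )
        np.testing.assert_allclose(g.values, oracle, atol=1e-8)


class TestZScore:
    def test_idempotent_on_standardized_matrix(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((5, 5))
        v = (v + v.T) / 2
        z1 = zscore_rsm(RSM(v))
        z2 = zscore_rsm(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((4, 4))
        v = (v + v.T) / 2
        a = zscore_rsm(RSM(v)).values
        b = zscore_rsm(RSM(3.0 * v + 7.0)).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_hand_computed_fixture(self):
        v = np.array([[1.0, 2.0, 3.0], [2.0, 5.0, 4.0], [3.0, 4.0, 9.0]])
        sel = np.triu_indices(3, 0)
        vals = v[sel]
        oracle = (v - vals.mean()) / vals.std()
        np.testing.assert_allclose(zscore_rsm(RSM(v)).values, oracle, atol=1e-12)

    def test_constant_rsm_rejected(self):
        with pytest.raises(ValueError):
            zscore_rsm(RSM(np.ones((3, 3))))


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.0, 0.0), (0.5, 2 / 3)])
    def test_prophecy_formula(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            spearman_brown(-1.0)


class TestNoiseCeiling:
    def test_noiseless_structured_cohort_reaches_ceiling(self, sset, cat_models):
        mix = GroundTruthMixture(
            weights={"category": (1.0, cat_models["category"].values)},
            sigma_noise=0.0,
        )
        cohort = simulate_patterns(sset, mix, 6, 1, 300, seed=0)
        nc = split_half_noise_ceiling(cohort, n_splits=10, seed=0)
        assert nc.corrected > 0.99 and nc.valid

    def test_monotone_in_snr(self, sset, cat_models):
        ceilings = []
        for sigma in (4.0, 1.5, 0.5):
            mix = GroundTruthMixture(
                weights={"category": (1.0, cat_models["category"].values)},
                sigma_noise=sigma,
            )
            cohort = simulate_patterns(sset, mix, 8, 1, 120, seed=1)
            nc = split_half_noise_ceiling(cohort, n_splits=20, seed=2)
            ceilings.append(nc.corrected)
        assert ceilings == sorted(ceilings)

    def test_too_few_subjects_rejected(self, sset):
        mix = GroundTruthMixture(weights={}, sigma_noise=1.0)
        cohort = simulate_patterns(sset, mix, 3, 1, 50, seed=0)
        with pytest.raises(ValueError):
            split_half_noise_ceiling(cohort)

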