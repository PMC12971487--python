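import numpy as np
import pytest
from scipy import stats

from devgeo.cohort import GroundTruthMixture, simulate_patterns
from devgeo.inference import (
    bootstrap_statistic,
    bootstrap_statistic_subjects,
    group_difference,
    importance_weights,
    longitudinal_permutation_test,
    maturity_correlation,
    normalize_by_ceiling,
    partial_rsa,
    recover_mixture_weights,
    rsa_correlation,
)
from devgeo.rsm import NoiseCeiling, cohort_group_rsm


def sym(rng, n):
    v = rng.standard_normal((n, n))
    return (v + v.T) / 2


class TestRSACorrelation:
    def test_model_with_itself_is_one(self, cat_models):
        m = cat_models["category"].values
        assert rsa_correlation(m, m) == pytest.approx(1.0)

    def test_model_with_negation_is_minus_one(self, cat_models):
        m = cat_models["animacy_tripartite"].values
        assert rsa_correlation(m, -m) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        a, b = sym(rng, 4), sym(rng, 4)
        iu = np.triu_indices(4, 0)
        oracle = np.corrcoef(stats.rankdata(a[iu]), stats.rankdata(b[iu]))[0, 1]
        assert rsa_correlation(a, b, include_diagonal=True) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rsa_correlation(np.ones((3, 3)), np.eye(3))


class TestPartialRSA:
    def test_empty_covariates_equals_plain(self):
        rng = np.random.default_rng(1)
        a, b = sym(rng, 6), sym(rng, 6)
        assert partial_rsa(a, b, []) == pytest.approx(rsa_correlation(a, b), abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(2)
        a, b = sym(rng, 5), sym(rng, 5)
        covs = [sym(rng, 5), sym(rng, 5)]
        iu = np.triu_indices(5, 0)
        ra = stats.rankdata(a[iu])
        rb = stats.rankdata(b[iu])
        z = np.column_stack(
            [np.ones(ra.size)] + [stats.rankdata(c[iu]) for c in covs]
        )
        res_a = ra - z @ np.linalg.lstsq(z, ra, rcond=None)[0]
        res_b = rb - z @ np.linalg.lstsq(z, rb, rcond=None)[0]
        oracle = np.corrcoef(res_a, res_b)[0, 1]
        assert partial_rsa(a, b, covs) == pytest.approx(oracle, abs=1e-12)

    def test_null_semantic_weight_gives_near_zero_partial(self, sset, cat_models):
        # generator carries only perceptual structure, built from feature
        # values with no systematic alignment to animacy class; the
        # semantic partial controlling that model should vanish
        from devgeo.models import feature_rsm

        rng = np.random.default_rng(0)
        size_model = feature_rsm(rng.permutation(np.linspace(0, 1, 36)), name="size")
        mix = GroundTruthMixture(
            weights={"size": (1.0, size_model.values)}, sigma_noise=1.0
        )
        cohort = simulate_patterns(sset, mix, 40, 1, 300, seed=5)
        g, _ = cohort_group_rsm(cohort, level="subject")
        rho = partial_rsa(g, cat_models["animacy_tripartite"].values, [size_model.values])
        assert abs(rho) < 0.05

    def test_collinear_model_rejected(self):
        rng = np.random.default_rng(3)
        a, b = sym(rng, 5), sym(rng, 5)
        with pytest.raises(ValueError):
            partial_rsa(a, b, [b])

    def test_degenerate_covariate_dropped(self):
        rng = np.random.default_rng(4)
        a, b = sym(rng, 5), sym(rng, 5)
        assert partial_rsa(a, b, [np.ones((5, 5))]) == pytest.approx(
            rsa_correlation(a, b), abs=1e-12
        )


class TestMixtureWeights:
    def test_noiseless_recovery_exact(self, cat_models):
        c = cat_models["category"].values + 0.5 * cat_models["animacy_tripartite"].values
        w = recover_mixture_weights(
            c,
            {
                "category": cat_models["category"].values,
                "animacy": cat_models["animacy_tripartite"].values,
            },
        )
        assert w["category"] == pytest.approx(1.0, abs=1e-10)
        assert w["animacy"] == pytest.approx(0.5, abs=1e-10)


class TestImportanceWeights:
    def test_matched_distributions_give_uniform_weights(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 0.5, 2000)
        w = importance_weights(x, x.copy())
        assert np.ptp(w.weights) < 1e-12

    def test_density_ratio_arithmetic(self):
        # source has twice the density of the target in the low bin, so
        # low-bin units get half the weight of high-bin units
        source = np.array([0.1] * 40 + [1.0] * 20)
        target = np.array([0.1] * 20 + [1.0] * 20)
        w = importance_weights(source, target, n_bins=2)
        lo = w.weights[0]
        hi = w.weights[-1]
        assert hi / lo == pytest.approx(2.0, rel=1e-6)

    def test_source_bin_absent_from_target_gets_zero(self):
        source = np.array([0.1] * 30 + [0.3] * 20 + [10.0] * 10)
        target = np.array([0.1] * 20 + [0.3] * 20)
        w = importance_weights(source, target, n_bins=3)
        assert (w.weights[-10:] == 0).all()
        assert w.weights[:50].min() > 0

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ValueError):
            importance_weights(np.full(20, 10.0), np.full(20, 0.1), n_bins=2)


class TestBootstrap:
    def test_identical_units_give_zero_width_ci(self):
        unit = np.eye(4)
        res = bootstrap_statistic(
            [unit] * 5, lambda m: float(m.sum()), n_boot=50, seed=0
        )
        assert res.ci[0] == res.ci[1] == res.point

    def test_distribution_length_is_n_boot(self):
        rng = np.random.default_rng(0)
        units = [sym(rng, 3) for _ in range(4)]
        res = bootstrap_statistic(units, lambda m: float(m.mean()), n_boot=1000, seed=1)
        assert res.distribution.size == 1000

    def test_uniform_weights_reproduce_unweighted_draws(self):
        rng = np.random.default_rng(0)
        units = [sym(rng, 3) for _ in range(6)]
        stat = lambda m: float(m.mean())
        a = bootstrap_statistic(units, stat, n_boot=200, seed=3)
        b = bootstrap_statistic(units, stat, n_boot=200, seed=3, weights=np.ones(6))
        np.testing.assert_array_equal(a.distribution, b.distribution)

    def test_exclusion_removes_units(self):
        units = [np.full((2, 2), v) for v in (0.0, 0.0, 100.0)]
        res = bootstrap_statistic(
            units,
            lambda m: float(m.mean()),
            n_boot=50,
            seed=0,
            exclude=np.array([False, False, True]),
        )
        assert res.point == 0.0 and res.distribution.max() == 0.0

    def test_subject_resampling_widens_ci_over_pair_resampling(
        self, sset, cat_models
    ):
        # pairs share subjects; treating them as iid units understates
        # the sampling variance of the pair average
        mix = GroundTruthMixture(
            weights={"category": (1.0, cat_models["category"].values)},
            sigma_noise=2.0,
        )
        cohort = simulate_patterns(sset, mix, 10, 1, 120, seed=11)
        _, prs = cohort_group_rsm(cohort, level="subject")
        m = cat_models["category"].values
        stat = lambda r: recover_mixture_weights(r, {"m": m})["m"]
        pair_res = bootstrap_statistic(prs, stat, n_boot=300, seed=0)
        subj_res = bootstrap_statistic_subjects(prs, stat, n_boot=300, seed=0)
        assert (subj_res.ci[1] - subj_res.ci[0]) > (pair_res.ci[1] - pair_res.ci[0])


class TestGroupDifference:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(500)
        a = _result(d)
        b = _result(d.copy())
        ci, sig, _ = group_difference(a, b)
        assert not sig and ci[0] <= 0 <= ci[1]

    def test_disjoint_distributions_significant(self):
        a = _result(np.linspace(10, 11, 300))
        b = _result(np.linspace(0, 1, 300))
        _, sig, diff = group_difference(a, b)
        assert sig and diff.min() > 0

    def test_age_graded_animacy_contrast_detected(self, sset, cat_models):
        # two cohorts whose animacy weight differs (0.2 vs 0.55)
        m = cat_models["animacy_tripartite"].values
        results = []
        for w, seed in ((0.2, 0), (0.55, 1)):
            mix = GroundTruthMixture(weights={"anim": (w, m)}, sigma_noise=1.0)
            cohort = simulate_patterns(sset, mix, 40, 1, 300, seed=seed)
            _, prs = cohort_group_rsm(cohort, level="subject")
            stat = lambda r: recover_mixture_weights(r, {"anim": m})["anim"]
            results.append(bootstrap_statistic_subjects(prs, stat, n_boot=300, seed=seed))
        _, sig, diff = group_difference(results[1], results[0])
        assert sig and np.median(diff) > 0


def _result(dist):
    from devgeo.inference import BootstrapResult

    return BootstrapResult(
        point=float(np.mean(dist)),
        distribution=np.asarray(dist, float),
        ci=(float(np.percentile(dist, 2.5)), float(np.percentile(dist, 97.5))),
        n_boot=len(dist),
        seed=None,
    )


class TestCeilingNormalization:
    def test_direct_division(self):
        nc = NoiseCeiling(corrected=0.6, raw=0.43, n_splits=10, valid=True)
        val, ok = normalize_by_ceiling(0.3, nc)
        assert val == pytest.approx(0.5) and ok

    def test_unit_ceiling_is_identity(self):
        nc = NoiseCeiling(corrected=1.0, raw=1.0, n_splits=10, valid=True)
        assert normalize_by_ceiling(0.42, nc)[0] == pytest.approx(0.42)

    def test_low_ceiling_reports_raw_flagged(self):
        nc = NoiseCeiling(corrected=0.03, raw=0.015, n_splits=10, valid=False)
        val, ok = normalize_by_ceiling(0.2, nc)
        assert val == 0.2 and not ok


class TestMaturity:
    def test_cloned_structure_approaches_one(self, sset, cat_models):
        # infants generated on the same structured basis as adults:
        # identical representational geometry, so maturity approaches 1
        mix = GroundTruthMixture(
            weights={"category": (1.0, cat_models["category"].values)},
            sigma_noise=0.1,
        )
        basis = np.random.default_rng(99).standard_normal((36, 300))
        adult = simulate_patterns(sset, mix, 6, 1, 300, seed=0, structured_basis=basis)
        infant = simulate_patterns(sset, mix, 6, 1, 300, seed=1, structured_basis=basis)
        g_adult, _ = cohort_group_rsm(adult, level="subject")
        _, infant_prs = cohort_group_rsm(infant, level="subject")
        res = maturity_correlation(infant_prs, g_adult, n_boot=100, seed=0)
        assert res.point > 0.9

    def test_unrelated_structure_near_zero(self, sset, noise_cohort, cat_models):
        g_adult, _ = cohort_group_rsm(noise_cohort, level="subject")
        mix = GroundTruthMixture(
            weights={"category": (1.0, cat_models["category"].values)},
            sigma_noise=0.5,
        )
        infant = simulate_patterns(sset, mix, 6, 1, 150, seed=2)
        _, prs = cohort_group_rsm(infant, level="subject")
        res = maturity_correlation(prs, g_adult, n_boot=100, seed=0)
        assert abs(res.point) < 0.15


class TestLongitudinalPermutation:
    def _rsms(self, rng, n_sub, n=8):
        return {f"s{i}": sym(rng, n) for i in range(n_sub)}

    def test_exact_copies_give_small_p(self):
        rng = np.random.default_rng(0)
        t1 = self._rsms(rng, 10)
        t2 = {k: v.copy() for k, v in t1.items()}
        links = {k: k for k in t1}
        p, obs, _ = longitudinal_permutation_test(t1, t2, links, n_perm=1000, seed=0)
        assert p <= 0.01 and obs == pytest.approx(1.0)

    def test_add_one_rule_lower_bound(self):
        rng = np.random.default_rng(1)
        t1 = self._rsms(rng, 6)
        t2 = {k: v.copy() for k, v in t1.items()}
        links = {k: k for k in t1}
        p, _, _ = longitudinal_permutation_test(t1, t2, links, n_perm=200, seed=0)
        assert p >= 1.0 / 201.0

    def test_duplicate_links_rejected(self):
        rng = np.random.default_rng(2)
        t1 = self._rsms(rng, 5)
        links = {f"s{i}": "s0" for i in range(5)}
        with pytest.raises(ValueError):
            longitudinal_permutation_test(t1, t1, links)
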