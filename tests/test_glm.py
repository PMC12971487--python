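import numpy as np
import pytest

from devgeo.cohort import MotionTrace
from devgeo.glm import (
    build_design_matrix,
    censor_and_qc,
    compute_tsnr,
    filter_voxels_by_dispersion,
    fit_glm,
    mean_center_runs,
)
from devgeo.stimuli import make_events, make_stimulus_set


def tiny_run(n_cond=4, n_frames=60, tr=1.0, seed=0, noise=0.5, n_vox=7):
    """Small forward-modeled run for oracle comparisons."""
    rng = np.random.default_rng(seed)
    s = make_stimulus_set(1, n_cond, 1)
    ev = make_events(
        s, n_repetitions_per_run=2, soa_range=(5.0, 6.0), seed=seed, tr=tr,
        n_frames=n_frames, start_offset=1.0,
    )
    design = build_design_matrix(ev)
    pats = rng.standard_normal((n_cond, n_vox))
    cond_cols = design.matrix[:, design.condition_columns]
    ts = cond_cols @ pats + noise * rng.standard_normal((n_frames, n_vox))
    return ev, design, ts, pats


class TestCensorQC:
    def test_single_frame_above_threshold_censored(self):
        report, mask = censor_and_qc(MotionTrace(np.array([0.1, 2.0, 0.3])), 1.5, 0.5)
        assert report.n_censored == 1 and report.accepted
        np.testing.assert_array_equal(mask, [False, True, False])

    def test_all_high_motion_rejected(self):
        report, _ = censor_and_qc(MotionTrace(np.full(50, 2.0)))
        assert not report.accepted and report.censored_fraction == 1.0

    def test_still_run_fully_accepted(self):
        report, mask = censor_and_qc(MotionTrace(np.zeros(50)))
        assert report.accepted and report.n_censored == 0 and not mask.any()


class TestDesignMatrix:
    def test_full_design_has_36_condition_columns(self, sset):
        ev = make_events(sset, seed=0)
        d = build_design_matrix(ev)
        assert d.condition_columns.size == 36

    def test_no_censoring_means_no_spike_columns(self, sset):
        ev = make_events(sset, seed=0)
        d = build_design_matrix(ev, censor_mask=np.zeros(ev.n_frames, bool))
        assert d.n_spikes == 0

    def test_one_spike_column_per_censored_frame(self, sset):
        ev = make_events(sset, seed=0)
        mask = np.zeros(ev.n_frames, bool)
        mask[[5, 17, 300]] = True
        d = build_design_matrix(ev, censor_mask=mask)
        assert d.n_spikes == 3
        spikes = d.matrix[:, [i for i, r in enumerate(d.roles) if r == "spike"]]
        assert (spikes.sum(axis=0) == 1).all()

    def test_hrf_peaks_near_six_seconds(self):
        # single event at t=0, TR 0.61 s: response peaks around frame 10
        s = make_stimulus_set(1, 1, 1)
        import pandas as pd

        events = pd.DataFrame(
            {"onset": [0.0], "duration": [3.0], "condition": [0], "run": [0]}
        )
        d = build_design_matrix(events, tr=0.61, n_frames=60)
        peak_frame = int(np.argmax(d.matrix[:, 0]))
        assert 8 <= peak_frame <= 13

    def test_nuisance_columns_present(self, sset):
        ev = make_events(sset, seed=0)
        d = build_design_matrix(ev, motion_params=np.random.default_rng(0).standard_normal((ev.n_frames, 6)))
        roles = set(d.roles)
        assert {"motion", "trend", "cosine", "intercept"} <= roles
        assert d.roles.count("motion") == 6

    def test_frame_mismatch_rejected(self, sset):
        ev = make_events(sset, seed=0)
        with pytest.raises(ValueError):
            build_design_matrix(ev, censor_mask=np.zeros(10, bool))


class TestFitGLM:
    def test_matches_normal_equations_oracle(self):
        # brute-force (X'X)^-1 X'y on a small run, 1e-8 agreement
        _, design, ts, _ = tiny_run()
        betas = fit_glm(ts, design)
        x = design.matrix
        oracle = np.linalg.solve(x.T @ x, x.T @ ts)
        np.testing.assert_allclose(
            betas.betas, oracle[design.condition_columns], atol=1e-8
        )

    def test_dispersion_matches_oracle(self):
        _, design, ts, _ = tiny_run()
        betas = fit_glm(ts, design)
        x = design.matrix
        beta_full = np.linalg.solve(x.T @ x, x.T @ ts)
        resid = ts - x @ beta_full
        rms = (resid**2).sum(0) / (x.shape[0] - x.shape[1])
        var_diag = np.diag(np.linalg.inv(x.T @ x))[design.condition_columns]
        oracle = (var_diag[:, None] * rms[None, :]).max(0)
        np.testing.assert_allclose(betas.dispersion, oracle, atol=1e-10)

    def test_spike_column_equivalent_to_row_deletion(self):
        # censoring one frame via a spike regressor equals deleting the row
        ev, design, ts, _ = tiny_run()
        f = 7
        mask = np.zeros(ts.shape[0], bool)
        mask[f] = True
        d_spike = build_design_matrix(ev, censor_mask=mask)
        b_spike = fit_glm(ts, d_spike)
        keep = ~mask
        x_del = design.matrix[keep]
        oracle = np.linalg.lstsq(x_del, ts[keep], rcond=None)[0]
        np.testing.assert_allclose(
            b_spike.betas, oracle[design.condition_columns], atol=1e-8
        )

    def test_pure_noise_betas_center_on_zero(self):
        _, design, _, _ = tiny_run()
        rng = np.random.default_rng(1)
        betas = np.concatenate(
            [
                fit_glm(rng.standard_normal((design.matrix.shape[0], 50)), design).betas
                for _ in range(20)
            ]
        )
        assert abs(betas.mean()) < 0.05

    def test_censoring_inflates_dispersion(self):
        ev, design, ts, _ = tiny_run(n_frames=120)
        mask = np.zeros(ts.shape[0], bool)
        mask[: int(0.49 * ts.shape[0])] = True
        d_cens = build_design_matrix(ev, censor_mask=mask)
        plain = fit_glm(ts, design)
        cens = fit_glm(ts, d_cens)
        assert cens.dispersion.mean() > plain.dispersion.mean()

    def test_rank_deficient_design_names_columns(self, sset):
        ev = make_events(sset, seed=0)
        d = build_design_matrix(ev)
        d.matrix[:, 1] = d.matrix[:, 0]  # duplicate a condition column
        with pytest.raises(np.linalg.LinAlgError, match="cond_0"):
            fit_glm(np.zeros((d.matrix.shape[0], 3)), d)


class TestVoxelFilter:
    def test_threshold_excludes_expected_voxel(self):
        from devgeo.glm import BetaPatterns

        b = BetaPatterns(
            "s", 0, np.zeros((2, 3)), np.array([1.0, 11.0, 5.0]), np.ones(3, bool)
        )
        out, prop = filter_voxels_by_dispersion(b, 10.0)
        np.testing.assert_array_equal(out.valid, [True, False, True])
        assert prop == pytest.approx(1 / 3)

    def test_zero_dispersion_and_infinite_threshold_are_identity(self):
        from devgeo.glm import BetaPatterns

        b = BetaPatterns(
            "s", 0, np.zeros((2, 3)), np.zeros(3), np.ones(3, bool)
        )
        assert filter_voxels_by_dispersion(b, 10.0)[1] == 0.0
        assert filter_voxels_by_dispersion(b, np.inf)[1] == 0.0

    def test_exclusion_monotone_in_threshold(self):
        from devgeo.glm import BetaPatterns

        disp = np.random.default_rng(0).uniform(0, 20, 100)
        b = BetaPatterns("s", 0, np.zeros((2, 100)), disp, np.ones(100, bool))
        props = [filter_voxels_by_dispersion(b, t)[1] for t in (15, 10, 5, 1)]
        assert props == sorted(props)


class TestMeanCenter:
    def test_constant_voxel_becomes_zero(self):
        from devgeo.glm import BetaPatterns

        b = BetaPatterns("s", 0, np.full((36, 2), 3.14), np.zeros(2), np.ones(2, bool))
        out = mean_center_runs(b)
        assert np.abs(out.betas).max() < 1e-10

    def test_three_condition_example(self):
        from devgeo.glm import BetaPatterns

        b = BetaPatterns(
            "s", 0, np.array([[1.0], [2.0], [3.0]]), np.zeros(1), np.ones(1, bool)
        )
        np.testing.assert_allclose(
            mean_center_runs(b).betas.ravel(), [-1.0, 0.0, 1.0]
        )

    def test_idempotent(self):
        from devgeo.glm import BetaPatterns

        rng = np.random.default_rng(0)
        b = BetaPatterns("s", 0, rng.standard_normal((5, 4)), np.zeros(4), np.ones(4, bool))
        once = mean_center_runs(b)
        twice = mean_center_runs(once)
        np.testing.assert_allclose(once.betas, twice.betas, atol=1e-12)


class TestTSNR:
    def test_known_mean_over_sd(self):
        rng = np.random.default_rng(0)
        ts = 100.0 + 10.0 * rng.standard_normal((5000, 20))
        val, n_bad = compute_tsnr(ts, detrend=False)
        assert val == pytest.approx(10.0, rel=0.05)
        assert n_bad == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        ts = 50.0 + 5.0 * rng.standard_normal((200, 10))
        a, _ = compute_tsnr(ts)
        b, _ = compute_tsnr(2.0 * ts)
        assert a == pytest.approx(b, rel=1e-10)

    def test_zero_mean_noise_gives_near_zero(self):
        rng = np.random.default_rng(2)
        vals = [compute_tsnr(rng.standard_normal((500, 30)))[0] for _ in range(10)]
        assert abs(np.mean(vals)) < 0.05

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_tsnr(np.ones((10, 3)))
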