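"""Joint solver components: CG, LM, multiresolution, subdivision."""

import numpy as np
import pytest

from disorder import motion as mo
from disorder import operators as op
from disorder import orders as od
from disorder import recon
from disorder import synth


class TestLevelsAndMask:
    def test_pyramid_depth_formula(self):
        assert recon.n_levels(1.0) == 3
        assert recon.n_levels(2.0) == 2
        assert recon.n_levels(4.0) == 1
        assert recon.n_levels(5.0) == 1

    def test_soft_mask_profile(self):
        m = recon.soft_mask((64, 64), 0.8, 1.0)
        assert m[32, 32] == 1.0
        assert m[32, 60] < 1.0
        assert m[0, 0] == 0.0
        assert np.all((m >= 0) & (m <= 1))


class TestCG:
    def test_full_sampling_identity_in_two_iterations(self, rng):
        g = od.PEGrid(16, 16)
        vo = od.make_view_order(g, traversal="sequential", n_segments=1)
        model = op.EncodingModel.from_order(
            op.CoilMaps(np.ones((1, 16, 16), complex)), vo)
        x = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        y = model.encode(x)
        xh, losses, _ = recon.cg_reconstruct(model, y, n_iter=2)
        assert np.abs(xh - x).max() < 1e-10

    def test_matches_dense_least_squares(self, rng):
        """CG solution equals the dense normal-equation solution on an
        8x8 grid with R = 2 and 4 coils."""
        maps = synth.make_coilmaps(8, 4)
        g = od.PEGrid(8, 8, 2, 1)
        vo = od.make_view_order(g, od.build_tiling(g, 2, 2),
                                "random_checkered", seed=2)
        model = op.EncodingModel.from_order(maps, vo)
        e = np.zeros((model.n_rows * 4, 64), complex)
        for j in range(64):
            u = np.zeros(64)
            u[j] = 1.0
            e[:, j] = model.encode(u.reshape(8, 8)).ravel()
        x_true = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        y = model.encode(x_true)
        dense = np.linalg.lstsq(e, y.ravel(), rcond=None)[0].reshape(8, 8)
        xh, _, _ = recon.cg_reconstruct(model, y, n_iter=200,
                                        mask=np.ones((8, 8)))
        assert np.abs(xh - dense).max() < 1e-8

    def test_zero_weight_segment_does_not_affect_solution(self, ds_motion,
                                                          rng):
        model = ds_motion.model(trace=ds_motion.trace_true)
        model.weights = np.ones(8)
        model.weights[5] = 0.0
        y = ds_motion.bundle.y.copy()
        xa, _, _ = recon.cg_reconstruct(model, y, n_iter=8)
        y[model.seg_rows(5)] += rng.normal(size=y[model.seg_rows(5)].shape)
        model2 = ds_motion.model(trace=ds_motion.trace_true)
        model2.weights = model.weights
        xb, _, _ = recon.cg_reconstruct(model2, y, n_iter=8)
        assert np.abs(xa - xb).max() < 1e-10

    def test_loss_non_increasing(self, ds_motion):
        model = ds_motion.model(trace=ds_motion.trace_true)
        _, losses, _ = recon.cg_reconstruct(model, ds_motion.bundle.y,
                                            n_iter=15)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(losses, losses[1:]))


class TestLM:
    def test_stationary_at_truth_on_exact_data(self, ds_clean):
        """At theta = theta* with exact data the LM update vanishes."""
        cfg = synth.SimulationConfig(n=64, n_coils=8, n_segments=8,
                                     theta_deg=6.0, snr_db=np.inf, seed=8)
        ds = synth.simulate(cfg)
        model = ds.model(trace=ds.trace_true.copy())
        lm = recon.LMState.for_states(8)
        applied = recon.lm_update_motion(model, ds.bundle.y, ds.x_true, lm,
                                         tau=np.array([0.05, 0.05, 0.02]))
        assert np.abs(applied).max() < 1e-6

    def test_single_shift_matches_exhaustive_scan(self):
        """One translated state, noiseless: LM lands on the 1D loss
        minimizer found by brute-force scanning."""
        cfg = synth.SimulationConfig(n=64, n_coils=8, n_segments=1,
                                     traversal="sequential", theta_deg=0.0,
                                     snr_db=np.inf, seed=10)
        ds = synth.simulate(cfg)
        true_shift = 0.6
        trace = mo.MotionTrace(np.array([[true_shift, 0.0, 0.0]]))
        y = ds.model(trace=trace).encode(ds.x_true)

        shifts = np.linspace(0.55, 0.65, 201)
        losses = [ds.model(trace=mo.MotionTrace(
            np.array([[s, 0.0, 0.0]]))).loss(ds.x_true, y)[0]
            for s in shifts]
        scan_min = shifts[int(np.argmin(losses))]

        model = ds.model(trace=mo.MotionTrace(np.array([[0.3, 0.0, 0.0]])))
        lm = recon.LMState.for_states(1)
        for _ in range(10):
            recon.lm_update_motion(model, y, ds.x_true, lm,
                                   tau=np.array([1e-5, 1e-5, 1e-5]))
        assert abs(model.trace.params[0, 0] - scan_min) < 1e-3

    def test_accepted_steps_never_increase_segment_loss(self, ds_motion):
        model = ds_motion.model()  # start from zero motion
        y = ds_motion.bundle.y
        x0 = model.decode(y) / ds_motion.maps.rss() ** 2
        lm = recon.LMState.for_states(8)
        before = np.array([
            (np.abs(model.encode(x0) - y)[model.seg_rows(m)] ** 2).sum()
            for m in range(8)])
        recon.lm_update_motion(model, y, x0, lm,
                               tau=np.array([0.05, 0.05, 0.02]))
        after = np.array([
            (np.abs(model.encode(x0) - y)[model.seg_rows(m)] ** 2).sum()
            for m in range(8)])
        assert np.all(after <= before * (1 + 1e-7))


class TestMultiresolution:
    def test_finest_level_is_identity(self, ds_motion):
        y_l, model_l, present = recon.restrict_level(
            ds_motion.bundle, ds_motion.maps, ds_motion.trace_true, 2, 2)
        assert np.array_equal(y_l, ds_motion.bundle.y)
        assert model_l.shape == (64, 64)
        assert len(present) == 8
        assert np.abs(model_l.maps.maps - ds_motion.maps.maps).max() < 1e-12

    def test_coarse_level_consistency(self, ds_clean):
        """Restricted model reproduces the retained samples of noiseless
        zero-motion data from the Fourier-cropped image."""
        y_l, model_l, _ = recon.restrict_level(
            ds_clean.bundle, ds_clean.maps, ds_clean.trace_true, 1, 2)
        k = op.cfft2(ds_clean.x_true)[16:48, 16:48]
        x_c = op.cifft2(k)
        y_hat = model_l.encode(x_c)
        rel = np.abs(y_hat - y_l).max() / np.abs(y_l).max()
        assert rel < 0.05  # smooth-map commutation approximation

    def test_every_segment_present_in_half_window(self):
        cfg = synth.SimulationConfig(n=32, n_coils=2, n_segments=16,
                                     traversal="checkered", theta_deg=0,
                                     seed=1)
        ds = synth.simulate(cfg)
        _, model_l, present = recon.restrict_level(
            ds.bundle, ds.maps, ds.trace_true, 1, 2)
        assert len(present) == 16
        assert min(len(f) for f in model_l.seg_flat) >= 1

    def test_promote_restrict_spectrum_roundtrip(self, rng):
        x = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        up = recon.promote_image(x, (64, 64))
        k = op.cfft2(up)
        assert np.abs(op.cifft2(k[16:48, 16:48]) - x).max() < 1e-10


class TestIntraShotSubdivision:
    def test_depth_zero_identity(self, ds_motion):
        order2, trace2 = recon.intra_shot_subdivide(
            ds_motion.bundle.order, ds_motion.trace_true, 0)
        assert order2 is ds_motion.bundle.order
        assert np.array_equal(trace2.params, ds_motion.trace_true.params)

    def test_depth_four_gives_sixteen_states_per_shot(self, ds_motion):
        order2, trace2 = recon.intra_shot_subdivide(
            ds_motion.bundle.order, ds_motion.trace_true, 4)
        assert trace2.n_states == 8 * 16
        assert order2.n_segments == 8 * 16

    def test_child_masks_partition_parent(self, ds_motion):
        order = ds_motion.bundle.order
        order2, _ = recon.intra_shot_subdivide(order, ds_motion.trace_true, 2)
        parent = od.segment_masks(order)
        child = od.segment_masks(order2)
        for m in range(order.n_segments):
            union = child[4 * m:4 * (m + 1)].sum(axis=0)
            assert np.array_equal(union, parent[m].astype(int))


class TestJointSolve:
    def test_zero_motion_fixed_point(self, ds_clean):
        rc = recon.ReconConfig(levels=1, max_joint_iters=5, mode="flags")
        res = recon.joint_solve(ds_clean.bundle, ds_clean.maps, rc)
        tau_rot = rc.tau_rotation * ds_clean.config.spacing
        assert np.abs(res.trace.params[:, 2]).max() < tau_rot
        assert np.abs(res.trace.params[:, :2]).max() < \
            rc.tau_translation * ds_clean.config.spacing
        rel = np.linalg.norm(res.x - ds_clean.x_true) \
            / np.linalg.norm(ds_clean.x_true)
        assert rel < 1e-3  # soft mask + CG tolerance on noiseless data

    def test_outer_loss_monotone_within_level(self):
        cfg = synth.SimulationConfig(n=64, n_coils=8, n_segments=8,
                                     theta_deg=6.0, snr_db=30.0, seed=12)
        ds = synth.simulate(cfg)
        rc = recon.ReconConfig(levels=1, max_joint_iters=10, mode="flags",
                               dtype=np.complex64)
        res = recon.joint_solve(ds.bundle, ds.maps, rc)
        losses = res.log.loss
        assert all(b <= a * (1 + 1e-3) for a, b in zip(losses, losses[1:]))

    def test_reset_points(self):
        pts = recon._reset_points(40)
        assert pts == {1, 2, 4, 7, 11, 16, 22, 29, 37}

    def test_convergence_log_validation(self):
        log = recon.ConvergenceLog()
        log.append(1, 10.0, 5.0, 1, 0, 0.0)
        with pytest.raises(ValueError):
            log.append(1, 20.0, 4.0, 1, 0, 0.0)  # non-increasing iteration
        with pytest.raises(ValueError):
            log.append(2, 20.0, np.nan, 1, 0, 0.0)


def test_recenter_trace_keeps_model_equivalent(ds_motion):
    """Removing the common rigid mode and compounding it into the image
    leaves the predicted data unchanged (to composition accuracy)."""
    trace = ds_motion.trace_true.copy()
    model = ds_motion.model(trace=trace.copy())
    y0 = model.encode(ds_motion.x_true)
    mu = recon.recenter_trace(trace)
    assert np.abs(trace.params.mean(axis=0)[2]) < 1e-10
    x2 = mo.apply_rigid2d(ds_motion.x_true, mu)
    y1 = ds_motion.model(trace=trace).encode(x2)
    # agreement is limited by the shear rotations' composition accuracy
    assert np.abs(y1 - y0).max() / np.abs(y0).max() < 0.01
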