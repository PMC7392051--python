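"""Measurement operator: adjointness, reductions, loss, noise calibration."""

import numpy as np
import pytest
from scipy import stats

from disorder import motion as mo
from disorder import operators as op
from disorder import orders as od
from disorder import synth


def dense_encoding_matrix(maps, order, params=None):
    """Independent dense construction of A F S T (explicit centered DFT)."""
    n2, n3 = maps.shape
    c2, c3 = n2 // 2, n3 // 2

    def dft(n, c):
        k, u = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        return np.exp(-2j * np.pi * k * u / n) / np.sqrt(n)

    f2d = np.kron(dft(n2, c2), dft(n3, c3))          # (N, N) on vec(x)
    flat = order.flat_indices()
    rows = []
    for m, ridx in enumerate(order.segment_rows()):
        for c in range(maps.n_coils):
            block = f2d * maps.maps[c].ravel()[None, :]
            rows.append((m, c, block[flat[ridx]]))
    return rows  # list of (segment, coil, submatrix)


class TestEncodeDecode:
    def test_single_coil_full_sampling_is_dft(self, rng):
        g = od.PEGrid(16, 16)
        vo = od.make_view_order(g, traversal="sequential", n_segments=1)
        model = op.EncodingModel.from_order(
            op.CoilMaps(np.ones((1, 16, 16), complex)), vo)
        x = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        y = model.encode(x)
        k = np.zeros(256, complex)
        k[vo.flat_indices()] = y[:, 0]
        assert np.abs(k.reshape(16, 16) - op.cfft2(x)).max() < 1e-12
        assert np.abs(model.decode(y) - x).max() < 1e-12

    def test_adjoint_identity_with_motion_and_weights(self, ds_motion, rng):
        model = ds_motion.model(trace=ds_motion.trace_true)
        model.weights = rng.uniform(0.0, 1.0, model.n_segments)
        x = rng.normal(size=model.shape) + 1j * rng.normal(size=model.shape)
        y = rng.normal(size=(model.n_rows, 8)) \
            + 1j * rng.normal(size=(model.n_rows, 8))
        w_rows = model.row_weights()
        lhs = np.vdot(y, w_rows[:, None] * model.encode(x))
        rhs = np.vdot(model.decode(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10
        assert np.abs(model.normal(x)
                      - model.decode(model.encode(x))).max() == 0.0

    def test_zero_weight_segment_is_ignored(self, ds_motion, rng):
        model = ds_motion.model(trace=ds_motion.trace_true)
        model.weights = np.ones(model.n_segments)
        model.weights[3] = 0.0
        y = ds_motion.bundle.y.copy()
        a = model.decode(y)
        y[model.seg_rows(3)] = rng.normal(size=y[model.seg_rows(3)].shape)
        b = model.decode(y)
        assert np.abs(a - b).max() < 1e-12

    def test_energy_partition_zero_motion(self, ds_clean):
        """With theta = 0 and disjoint full-cover masks, the sampled energy
        equals the full spectral energy of S x."""
        model = ds_clean.model()
        y = model.encode(ds_clean.x_true)
        full = op.cfft2(ds_clean.x_true[None] * ds_clean.maps.maps)
        assert (np.abs(y) ** 2).sum() == pytest.approx(
            float((np.abs(full) ** 2).sum()), rel=1e-12)

    def test_dense_sense_equivalence_8x8(self, rng):
        """Zero-motion pipeline matches an explicit dense matrix to 1e-12."""
        maps = synth.make_coilmaps(8, 4)
        g = od.PEGrid(8, 8, 2, 1)
        vo = od.make_view_order(g, od.build_tiling(g, 2, 2),
                                "random_checkered", seed=1)
        model = op.EncodingModel.from_order(maps, vo)
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        y = model.encode(x)
        for m, c, block in dense_encoding_matrix(maps, vo):
            got = y[model.seg_rows(m), c]
            want = block @ x.ravel()
            assert np.abs(got - want).max() < 1e-12

    def test_effective_state_binning_matches_expansion(self, ds_motion):
        tr = ds_motion.trace_true.copy()
        tr.effective_map = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        binned = ds_motion.model(trace=tr)
        expanded = ds_motion.model(trace=mo.MotionTrace(
            tr.effective_params()[tr.effective_map]))
        assert np.abs(binned.encode(ds_motion.x_true)
                      - expanded.encode(ds_motion.x_true)).max() < 1e-12


class TestLoss:
    def test_exact_data_zero_loss(self, ds_clean):
        model = ds_clean.model()
        y = model.encode(ds_clean.x_true)
        r, per = model.loss(ds_clean.x_true, y)
        assert r < 1e-18 and per.max() < 1e-20

    def test_homogeneity(self, ds_motion):
        model = ds_motion.model(trace=ds_motion.trace_true)
        y = ds_motion.bundle.y
        r1, _ = model.loss(ds_motion.x_true, y)
        y2 = model.encode(ds_motion.x_true)
        r2, _ = model.loss(ds_motion.x_true, 2 * y - y2)
        assert r2 == pytest.approx(4 * r1, rel=1e-9)

    def test_per_profile_losses_chi_squared(self):
        """Whitened-noise per-profile losses follow a scaled chi2(2C) law."""
        cfg = synth.SimulationConfig(n=128, n_coils=4, n_segments=16,
                                     theta_deg=0.0, snr_db=30.0, seed=9)
        ds = synth.simulate(cfg)
        model = ds.model()
        _, per = model.loss(ds.x_true, ds.bundle.y)
        assert per.size >= 10_000
        sigma2 = ds.bundle.noise_std ** 2
        ks = stats.kstest(per, stats.chi2(df=2 * 4, scale=sigma2 / 2).cdf)
        assert ks.pvalue > 0.01


class TestNoise:
    def test_infinite_snr_is_identity(self, ds_clean):
        out = op.add_noise(ds_clean.bundle, np.inf, 0, ds_clean.x_true,
                           ds_clean.maps)
        assert out is ds_clean.bundle

    def test_image_domain_noise_std_calibrated(self):
        """Measured reconstruction-domain noise std matches the 30 dB
        prescription within 5% on a 256-squared grid."""
        n, c_coils = 256, 8
        x = synth.make_phantom(n)
        maps = synth.make_coilmaps(n, c_coils)
        g = od.PEGrid(n, n)
        vo = od.make_view_order(g, traversal="sequential", n_segments=1)
        model = op.EncodingModel.from_order(maps, vo)
        y0 = model.encode(x)
        bundle = op.KSpaceBundle(y0, vo)
        noisy = op.add_noise(bundle, 30.0, 11, x, maps)
        # full sampling, zero motion: closed-form SENSE combination
        noise = noisy.y - y0
        kimg = np.zeros((c_coils, n * n), complex)
        kimg[:, vo.flat_indices()] = noise.T
        imgs = op.cifft2(kimg.reshape(c_coils, n, n))
        rec = (np.conj(maps.maps) * imgs).sum(axis=0) / maps.rss() ** 2
        support = op.object_support(x)
        measured = np.sqrt(np.mean(np.abs(rec[support]) ** 2))
        sig = np.abs(x)[support].mean()
        target = sig / 10 ** (30.0 / 20.0)
        assert measured == pytest.approx(target, rel=0.05)

    def test_seeds_differ_but_moments_agree(self, ds_clean):
        a = op.add_noise(ds_clean.bundle, 30.0, 1, ds_clean.x_true,
                         ds_clean.maps)
        b = op.add_noise(ds_clean.bundle, 30.0, 2, ds_clean.x_true,
                         ds_clean.maps)
        na = a.y - ds_clean.bundle.y
        nb = b.y - ds_clean.bundle.y
        assert np.abs(na - nb).max() > 0
        assert np.mean(np.abs(na) ** 2) == pytest.approx(
            np.mean(np.abs(nb) ** 2), rel=0.02)

    def test_empty_support_rejected(self, ds_clean):
        with pytest.raises(ValueError):
            op.object_support(np.zeros((8, 8)))
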