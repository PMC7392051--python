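"""View-order construction: tilings, repulsion, traversals, masks."""

import itertools

import numpy as np
import pytest

from disorder import orders as od


def toroidal_dist(a, b, u2, u3):
    d2 = min(abs(a[0] - b[0]), u2 - abs(a[0] - b[0]))
    d3 = min(abs(a[1] - b[1]), u3 - abs(a[1] - b[1]))
    return np.hypot(d2, d3)


class TestTiling:
    def test_single_tile_lexicographic_cells(self):
        g = od.PEGrid(4, 4)
        t = od.build_tiling(g, 4, 4)
        assert t.n_tiles == 1 and t.m == 16
        i2, i3 = np.meshgrid(range(4), range(4), indexing="ij")
        cells = t.cell_of(i2, i3)
        assert np.array_equal(cells.ravel(), np.arange(16))

    def test_translation_invariance_of_cells(self):
        g = od.PEGrid(4, 4)
        t = od.build_tiling(g, 2, 2)
        assert t.n_tiles == 4
        base = np.array([[t.cell_of(a, b) for b in range(2)] for a in range(2)])
        for o2, o3 in ((0, 2), (2, 0), (2, 2)):
            shifted = np.array([[t.cell_of(a + o2, b + o3) for b in range(2)]
                                for a in range(2)])
            assert np.array_equal(base, shifted)

    def test_figure_configuration_tile_count(self):
        # 32x32 with 4x4 tiles: 64 tiles of 16 cells each (M = 16)
        t = od.build_tiling(od.PEGrid(32, 32), 4, 4)
        assert t.n_tiles == 64 and t.m == 16

    def test_invalid_tiling_rejected(self):
        with pytest.raises(ValueError):
            od.Tiling(0, 4, 8, 8)
        with pytest.raises(ValueError):
            od.build_tiling(od.PEGrid(4, 4), 8, 1)


class TestRepulsion:
    def test_singleton(self):
        t = od.build_tiling(od.PEGrid(4, 4), 1, 1)
        assert np.array_equal(od.repulsion_cell_order(t), [0])

    def test_2x2_matches_exhaustive_maxmin(self):
        """Greedy pick attains the exhaustive max-min neighbor distance."""
        t = od.build_tiling(od.PEGrid(4, 4), 2, 2)
        order = od.repulsion_cell_order(t, horizon=1)
        cells = [(c // 2, c % 2) for c in range(4)]

        def min_neighbor_dist(perm):
            return min(toroidal_dist(cells[a], cells[b], 2, 2)
                       for a, b in zip(perm, perm[1:]))

        best = max(min_neighbor_dist(p)
                   for p in itertools.permutations(range(4)))
        assert min_neighbor_dist(list(order)) == pytest.approx(best)
        # second cell is the toroidally farthest from the origin cell
        d = [toroidal_dist(cells[0], cells[c], 2, 2) for c in range(4)]
        assert d[order[1]] == max(d)

    def test_6x5_beats_lexicographic_neighbor_distance(self):
        t = od.build_tiling(od.PEGrid(66, 55), 6, 5)
        order = od.repulsion_cell_order(t)
        assert sorted(order) == list(range(30))
        cells = [(c // 5, c % 5) for c in range(30)]

        def mean_neighbor(perm):
            return np.mean([toroidal_dist(cells[a], cells[b], 6, 5)
                            for a, b in zip(perm, perm[1:])])

        assert mean_neighbor(order) > mean_neighbor(range(30))


class TestViewOrders:
    def test_checkered_figure_configuration(self):
        # 32x32, M = 16: each segment has P/M = 64 profiles, one per tile
        g = od.PEGrid(32, 32)
        t = od.build_tiling(g, 4, 4)
        vo = od.make_view_order(g, t, "checkered")
        assert vo.n_segments == 16
        assert np.all(vo.segment_sizes == 64)
        tiles = vo.tile_ids()
        for m in range(16):
            seg_tiles = tiles[vo.segment_of == m]
            assert len(np.unique(seg_tiles)) == 64

    def test_sequential_limit(self):
        vo = od.make_view_order(od.PEGrid(4, 4), traversal="sequential",
                                n_segments=2)
        seg1 = vo.profiles[vo.segment_of == 0]
        assert np.array_equal(seg1[:, 1], [0, 0, 0, 0, 1, 1, 1, 1])
        assert np.array_equal(seg1[:, 0], [0, 1, 2, 3, 0, 1, 2, 3])

    def test_random_checkered_deterministic_per_seed(self):
        g = od.PEGrid(32, 32)
        t = od.build_tiling(g, 4, 4)
        a = od.make_view_order(g, t, "random_checkered", seed=7)
        b = od.make_view_order(g, t, "random_checkered", seed=7)
        c = od.make_view_order(g, t, "random_checkered", seed=8)
        assert np.array_equal(a.profiles, b.profiles)
        assert not np.array_equal(a.profiles, c.profiles)

    def test_configuration_errors(self):
        g = od.PEGrid(8, 8)
        with pytest.raises(ValueError):
            od.make_view_order(g, od.build_tiling(g, 1, 1), "checkered")
        with pytest.raises(ValueError):
            od.make_view_order(g, traversal="sequential")  # needs n_segments
        with pytest.raises(ValueError):
            od.make_view_order(g, traversal="spiral")

    @pytest.mark.parametrize("traversal,tile_order,r,elliptical", [
        ("sequential", "zigzag", 1, False),
        ("random", "zigzag", 1, False),
        ("checkered", "zigzag", 1, False),
        ("checkered", "alternating_zigzag", 1, True),
        ("random_checkered", "zigzag", 2, False),
        ("random_checkered", "alternating_zigzag", 2, True),
    ])
    def test_masks_partition_retained_set(self, traversal, tile_order, r,
                                          elliptical):
        """Concatenated segment masks equal the retained-profile indicator."""
        g = od.PEGrid(24, 24, r, r, elliptical)
        t = od.build_tiling(g, 3, 4)
        kw = dict(n_segments=12) if traversal in ("sequential", "random") \
            else {}
        vo = od.make_view_order(g, t, traversal, tile_order, seed=5, **kw)
        masks = od.segment_masks(vo)
        assert np.array_equal(masks.sum(axis=0), g.retained_mask().astype(int))
        assert vo.n_profiles == g.n_retained

    def test_acceleration_counts(self):
        g = od.PEGrid(32, 32, 2, 2)
        assert g.n_retained == 256
        t = od.build_tiling(g, 4, 4)
        vo = od.make_view_order(g, t, "random_checkered")
        assert od.segment_masks(vo).sum() == 256


class TestTrajectories:
    def test_sequential_unit_steps(self):
        vo = od.make_view_order(od.PEGrid(16, 16), traversal="sequential",
                                n_segments=4)
        d = od.trajectory_derivatives(vo)
        interior = d[d[:, 1] == 0]  # within a k3 column
        assert np.all(np.abs(interior[:, 0]) <= 1)

    def test_alternating_zigzag_suppresses_spikes(self):
        """Alternating sweep polarity removes the large dk3 jumps at
        sweep boundaries (P = 3630, M = 30, 6x5 tiling)."""
        g = od.PEGrid(66, 55)
        t = od.build_tiling(g, 6, 5)
        zz = od.make_view_order(g, t, "checkered", "zigzag")
        az = od.make_view_order(g, t, "checkered", "alternating_zigzag")
        m_zz = np.abs(od.trajectory_derivatives(zz)[:, 1]).max()
        m_az = np.abs(od.trajectory_derivatives(az)[:, 1]).max()
        assert m_az < m_zz

    def test_random_checkered_steps_below_random(self):
        """Random-checkered trajectory steps stay well below the fully
        random order's (Monte Carlo over seeds)."""
        g = od.PEGrid(32, 32)
        t = od.build_tiling(g, 4, 4)
        rc, rd = [], []
        for seed in range(5):
            vo_rc = od.make_view_order(g, t, "random_checkered", seed=seed)
            vo_rd = od.make_view_order(g, traversal="random", seed=seed,
                                       n_segments=16)
            rc.append(np.abs(od.trajectory_derivatives(vo_rc)[:, 0]).mean())
            rd.append(np.abs(od.trajectory_derivatives(vo_rd)[:, 0]).mean())
        assert np.mean(rd) > np.mean(rc)

    def test_summary_statistics(self):
        vo = od.make_view_order(od.PEGrid(16, 16), traversal="sequential",
                                n_segments=2)
        s = od.trajectory_summary(vo)
        assert set(s) == {"max_dk2", "max_dk3", "mean_dk2", "mean_dk3"}


def test_coarse_window_covers_all_segments():
    """Half-resolution window profiles are spread across all segments for
    checkered orders (the central window holds >= M tiles)."""
    g = od.PEGrid(32, 32)
    t = od.build_tiling(g, 4, 4)
    for traversal in ("checkered", "random_checkered"):
        vo = od.make_view_order(g, t, traversal, seed=3)
        lo, hi = 16 - 8, 16 + 8
        p = vo.profiles
        inside = ((p[:, 0] >= lo) & (p[:, 0] < hi)
                  & (p[:, 1] >= lo) & (p[:, 1] < hi))
        segs = np.unique(vo.segment_of[inside])
        assert len(segs) == vo.n_segments


def test_limit_equivalences():
    """Random-checkered with full-grid tiles equals a uniform permutation
    chunking; sequential is its 1x1-tile limit in distribution."""
    g = od.PEGrid(8, 8)
    vo = od.make_view_order(g, od.build_tiling(g, 8, 8), "random_checkered",
                            seed=3)
    # one tile of 64 cells: a single random permutation of all profiles
    assert vo.n_segments == 64
    assert np.all(vo.segment_sizes == 1)
    flat = vo.flat_indices()
    assert len(np.unique(flat)) == 64
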