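"""Cartesian phase-encode (PE) view orders.

A 3D Cartesian scan covers a K2 x K3 grid of phase-encode *profiles* (one
readout per profile).  The temporal order in which profiles are visited is
free, and it determines how well per-segment rigid motion can be resolved
retrospectively: orders that distribute every segment's profiles across the
whole spectrum (checkered / random-checkered) make each segment "see" the
full object at all scales, whereas a sequential order confines a segment to
a thin spectral slab.

This module builds the order family:

* ``sequential``        -- lexicographic profiles split into contiguous chunks;
* ``checkered``         -- a U2 x U3 tiling with one cell per segment per tile,
                           cells assigned by an electrostatic-repulsion rule;
* ``random_checkered``  -- per-tile independent random cell permutations;
* ``random``            -- a uniform random permutation of all profiles.

Tiles are visited in a zig-zag (boustrophedon) sequence so that central
k-space is acquired mid-segment, or in an alternating zig-zag whose polarity
reverses between consecutive sweeps to suppress large trajectory jumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TRAVERSALS = ("sequential", "checkered", "random_checkered", "random")
TILE_ORDERS = ("zigzag", "alternating_zigzag")


@dataclass(frozen=True)
class PEGrid:
    """Phase-encode grid with optional elliptical support and acceleration.

    Coordinates are integer grid indices with the DC profile at
    ``(k2 // 2, k3 // 2)`` (even-length FFT convention).  Uniform acceleration
    ``(r2, r3)`` decimates the grid to every r-th row/column, aligned so the
    DC profile is retained.
    """

    k2: int
    k3: int
    r2: int = 1
    r3: int = 1
    elliptical: bool = False

    def __post_init__(self) -> None:
        if self.k2 < 1 or self.k3 < 1:
            raise ValueError("grid extents must be positive")
        if self.r2 < 1 or self.r3 < 1:
            raise ValueError("acceleration factors must be >= 1")
        if not self.retained_mask().any():
            raise ValueError("retained profile set is empty")

    @property
    def center(self) -> tuple[int, int]:
        return self.k2 // 2, self.k3 // 2

    def sub_rows(self) -> np.ndarray:
        """Retained k2 indices after decimation (DC row included)."""
        return np.arange(self.center[0] % self.r2, self.k2, self.r2)

    def sub_cols(self) -> np.ndarray:
        return np.arange(self.center[1] % self.r3, self.k3, self.r3)

    def elliptical_mask(self) -> np.ndarray:
        c2, c3 = self.center
        i2 = np.arange(self.k2)[:, None]
        i3 = np.arange(self.k3)[None, :]
        ell = ((i2 - c2) / (self.k2 / 2)) ** 2 + ((i3 - c3) / (self.k3 / 2)) ** 2
        return ell <= 1.0

    def retained_mask(self) -> np.ndarray:
        """Boolean (K2, K3) mask of retained profiles."""
        m = np.zeros((self.k2, self.k3), dtype=bool)
        m[np.ix_(self.sub_rows(), self.sub_cols())] = True
        if self.elliptical:
            m &= self.elliptical_mask()
        return m

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask().sum())


@dataclass(frozen=True)
class Tiling:
    """Rectangular tiling of the (decimated) PE grid into U2 x U3 tiles.

    Each tile holds ``m = u2 * u3`` cells, one per segment; cells are indexed
    in spectral lexicographic order within a tile, identically for all tiles
    (extension by translation).  Boundary tiles may be partial when the tile
    size does not divide the grid extent.
    """

    u2: int
    u3: int
    k2s: int  # decimated-grid extents the tiling partitions
    k3s: int

    def __post_init__(self) -> None:
        if self.u2 < 1 or self.u3 < 1:
            raise ValueError("invalid tiling: tile extents must be positive")
        if self.u2 > self.k2s or self.u3 > self.k3s:
            raise ValueError("tile larger than (decimated) grid")

    @property
    def m(self) -> int:
        """Number of segments (= cells per tile)."""
        return self.u2 * self.u3

    @property
    def t2(self) -> int:
        return -(-self.k2s // self.u2)

    @property
    def t3(self) -> int:
        return -(-self.k3s // self.u3)

    @property
    def n_tiles(self) -> int:
        return self.t2 * self.t3

    def tile_of(self, i2, i3):
        """Tile id of decimated-grid coordinates, row-major over tiles."""
        return (np.asarray(i2) // self.u2) * self.t3 + np.asarray(i3) // self.u3

    def cell_of(self, i2, i3):
        """Lexicographic cell id within the tile (translation invariant)."""
        return (np.asarray(i2) % self.u2) * self.u3 + np.asarray(i3) % self.u3


def build_tiling(grid: PEGrid, u2: int, u3: int) -> Tiling:
    """Tile the decimated PE grid of ``grid`` with U2 x U3 tiles."""
    return Tiling(u2, u3, len(grid.sub_rows()), len(grid.sub_cols()))


def _toroidal_dist2(a2, a3, b2, b3, u2, u3):
    d2 = np.minimum(np.abs(a2 - b2), u2 - np.abs(a2 - b2))
    d3 = np.minimum(np.abs(a3 - b3), u3 - np.abs(a3 - b3))
    return d2 * d2 + d3 * d3


def repulsion_cell_order(tiling: Tiling, horizon: int | None = None) -> np.ndarray:
    """Temporal order of tile cells by greedy electrostatic repulsion.

    Returns ``order`` with ``order[s]`` the cell id visited by segment ``s``.
    Starting from the tile origin, each next segment's cell maximizes the
    minimum toroidal Euclidean distance to the most recently placed cells
    (``horizon`` of them, default ``ceil(M / 4)``); ties are broken by the
    smallest lexicographic cell id.  Deterministic for a fixed tiling.
    """
    m, u2, u3 = tiling.m, tiling.u2, tiling.u3
    if horizon is None:
        horizon = max(1, math.ceil(m / 4))
    c2 = np.arange(m) // u3
    c3 = np.arange(m) % u3
    order = [0]
    remaining = np.ones(m, dtype=bool)
    remaining[0] = False
    for _ in range(m - 1):
        recent = order[-horizon:]
        cand = np.flatnonzero(remaining)
        d = np.full(cand.shape, np.inf)
        for r in recent:
            d = np.minimum(
                d, _toroidal_dist2(c2[cand], c3[cand], c2[r], c3[r], u2, u3)
            )
        best = cand[int(np.argmax(d))]  # argmax keeps first (smallest id) on ties
        order.append(int(best))
        remaining[best] = False
    return np.asarray(order, dtype=np.int64)


def zigzag_tile_sequence(tiling: Tiling) -> np.ndarray:
    """Boustrophedon tile sequence, sweeping k3 tile bands edge to edge.

    Within each k3 band the k2 tile rows alternate direction, so the
    trajectory remains smooth; central bands are visited mid-sequence, which
    places the spectrum center in the middle of each shot.
    """
    seq = []
    for t3 in range(tiling.t3):
        rows = range(tiling.t2) if t3 % 2 == 0 else range(tiling.t2 - 1, -1, -1)
        seq.extend(t2 * tiling.t3 + t3 for t2 in rows)
    return np.asarray(seq, dtype=np.int64)


@dataclass(frozen=True)
class ViewOrder:
    """Temporally ordered profile sequence with segment labels.

    ``profiles`` is a (P, 2) array of full-grid ``(k2, k3)`` coordinates, a
    permutation of the retained profile set; ``segment_of`` gives the segment
    id of each temporal position and is non-decreasing (segments are
    contiguous in time, one per shot/sweep).
    """

    grid: PEGrid
    profiles: np.ndarray
    segment_of: np.ndarray
    traversal: str
    tile_order: str = "zigzag"
    seed: int = 0
    tiling: Tiling | None = None

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_segments(self) -> int:
        return int(self.segment_of.max()) + 1

    @property
    def segment_sizes(self) -> np.ndarray:
        return np.bincount(self.segment_of, minlength=self.n_segments)

    def segment_rows(self) -> list[np.ndarray]:
        """Temporal row indices of each segment (contiguous)."""
        return [np.flatnonzero(self.segment_of == m) for m in range(self.n_segments)]

    def flat_indices(self) -> np.ndarray:
        """Row-major flat k-space index of each profile."""
        return self.profiles[:, 0] * self.grid.k3 + self.profiles[:, 1]

    def tile_ids(self) -> np.ndarray:
        """Tile id per profile (-1 when the order has no tiling)."""
        if self.tiling is None:
            return np.full(self.n_profiles, -1, dtype=np.int64)
        rows, cols = self.grid.sub_rows(), self.grid.sub_cols()
        i2 = np.searchsorted(rows, self.profiles[:, 0])
        i3 = np.searchsorted(cols, self.profiles[:, 1])
        return np.asarray(self.tiling.tile_of(i2, i3))


def _chunked_order(grid: PEGrid, coords: np.ndarray, n_segments: int,
                   traversal: str, tile_order: str, seed: int) -> ViewOrder:
    if n_segments < 1 or n_segments > coords.shape[0]:
        raise ValueError("invalid number of segments")
    seg = np.concatenate(
        [np.full(len(c), i) for i, c in enumerate(np.array_split(np.arange(coords.shape[0]), n_segments))]
    )
    return ViewOrder(grid, coords, seg, traversal, tile_order, seed)


def make_view_order(grid: PEGrid, tiling: Tiling | None = None,
                    traversal: str = "random_checkered",
                    tile_order: str = "zigzag", seed: int = 0,
                    n_segments: int | None = None) -> ViewOrder:
    """Construct a view order of the requested traversal family.

    ``tiling`` is required for checkered traversals and must have more than
    one cell; ``n_segments`` is required for the sequential and random limits
    (which correspond to 1 x 1 and K2 x K3 tilings with free segment
    definition).  Random draws are keyed by ``seed`` and are independent per
    tile for the random-checkered traversal.
    """
    if traversal not in TRAVERSALS:
        raise ValueError(f"unknown traversal {traversal!r}")
    if tile_order not in TILE_ORDERS:
        raise ValueError(f"unknown tile order {tile_order!r}")

    rows, cols = grid.sub_rows(), grid.sub_cols()
    retained_sub = grid.retained_mask()[np.ix_(rows, cols)]

    if traversal in ("sequential", "random"):
        if n_segments is None:
            raise ValueError(f"{traversal} traversal needs n_segments")
        i2, i3 = np.nonzero(retained_sub)
        coords = np.stack([rows[i2], cols[i3]], axis=1)
        # lexicographic with k3 major: consecutive profiles step through k2
        lex = np.lexsort((coords[:, 0], coords[:, 1]))
        coords = coords[lex]
        if traversal == "random":
            rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xD15])
            coords = coords[rng.permutation(coords.shape[0])]
        return _chunked_order(grid, coords, n_segments, traversal, tile_order, seed)

    if tiling is None:
        raise ValueError("checkered traversals need a tiling")
    if tiling.m < 2:
        raise ValueError("checkered traversal with a 1x1 tiling: use sequential")
    if n_segments is not None and n_segments != tiling.m:
        raise ValueError("n_segments must equal the tile cell count U2*U3")
    m = tiling.m
    tiles = zigzag_tile_sequence(tiling)
    # per-tile map cell -> segment
    if traversal == "checkered":
        rep = repulsion_cell_order(tiling)  # segment s -> cell rep[s]
        seg_to_cell = {t: rep for t in range(tiling.n_tiles)}
    else:
        seg_to_cell = {}
        for t in range(tiling.n_tiles):
            rng = np.random.default_rng([seed & 0x7FFFFFFF, int(t)])
            seg_to_cell[t] = rng.permutation(m)

    prof_list: list[tuple[int, int]] = []
    seg_list: list[int] = []
    for s in range(m):
        seq = tiles
        if tile_order == "alternating_zigzag" and s % 2 == 1:
            seq = tiles[::-1]
        for t in seq:
            cell = seg_to_cell[int(t)][s]
            i2 = (int(t) // tiling.t3) * tiling.u2 + cell // tiling.u3
            i3 = (int(t) % tiling.t3) * tiling.u3 + cell % tiling.u3
            if i2 < tiling.k2s and i3 < tiling.k3s and retained_sub[i2, i3]:
                prof_list.append((int(rows[i2]), int(cols[i3])))
                seg_list.append(s)
    profiles = np.asarray(prof_list, dtype=np.int64)
    segment_of = np.asarray(seg_list, dtype=np.int64)
    return ViewOrder(grid, profiles, segment_of, traversal, tile_order, seed, tiling)


def trajectory_derivatives(order: ViewOrder) -> np.ndarray:
    """First differences (dk2, dk3) of consecutive profile coordinates."""
    if order.n_profiles < 2:
        raise ValueError("need at least two profiles")
    return np.diff(order.profiles, axis=0)


def trajectory_summary(order: ViewOrder) -> dict:
    """Max and mean absolute trajectory steps, for eddy-current assessment."""
    d = trajectory_derivatives(order)
    a = np.abs(d)
    return {
        "max_dk2": int(a[:, 0].max()),
        "max_dk3": int(a[:, 1].max()),
        "mean_dk2": float(a[:, 0].mean()),
        "mean_dk3": float(a[:, 1].mean()),
    }


def segment_masks(order: ViewOrder) -> np.ndarray:
    """Per-segment binary sampling masks, shape (M, K2, K3).

    Masks are disjoint and sum to the indicator of the retained profile set.
    """
    grid = order.grid
    masks = np.zeros((order.n_segments, grid.k2, grid.k3), dtype=bool)
    masks[order.segment_of, order.profiles[:, 0], order.profiles[:, 1]] = True
    return masks
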