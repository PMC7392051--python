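"""Synthetic phantom, coil maps, motion traces and corrupted k-space.

The generators emulate the statistical structure of a 2D motion-corruption
study on an axial brain slice: a piecewise-smooth complex anatomical phantom
(nested ellipses with a cortical ribbon and mild texture), smooth complex
coil sensitivities from an encircling array, per-segment rigid states drawn
uniformly at random on ``[-theta/2, theta/2]`` (rotations about the FOV
center) and ``[-trans/2, trans/2]`` (translations), and circularly symmetric
complex Gaussian noise calibrated to a mean image-domain SNR in dB for the
motion-free, unaccelerated reconstruction.

All generators are pure functions of (configuration, seed).  The phantom is
zero outside a margin of at least 25% of the FOV so that the periodic
FFT-shear transforms introduce no wrap-around of object signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from . import motion as mo
from . import operators as op
from .orders import PEGrid, build_tiling, make_view_order


def _ellipse(n: int, c2: float, c3: float, a2: float, a3: float,
             angle_deg: float = 0.0) -> np.ndarray:
    """Boolean ellipse mask; center/axes in units of the grid size n."""
    i2, i3 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    u2 = (i2 - c2 * n) / n
    u3 = (i3 - c3 * n) / n
    t = np.deg2rad(angle_deg)
    v2 = np.cos(t) * u2 + np.sin(t) * u3
    v3 = -np.sin(t) * u2 + np.cos(t) * u3
    return (v2 / a2) ** 2 + (v3 / a3) ** 2 <= 1.0


def make_phantom(n: int) -> np.ndarray:
    """Deterministic brain-like complex phantom of size (n, n).

    Nested ellipses (scalp, skull, brain parenchyma, ventricles) plus a
    bright cortical ribbon and smooth random texture; a low-order smooth
    phase emulates receive/field phase.  Support stays inside half the FOV
    (margin >= 25% per side).
    """
    if n < 32:
        raise ValueError("phantom size must be at least 32 per axis")
    img = np.zeros((n, n))
    scalp = _ellipse(n, 0.5, 0.5, 0.36, 0.30)
    skull = _ellipse(n, 0.5, 0.5, 0.34, 0.28)
    brain = _ellipse(n, 0.5, 0.5, 0.31, 0.25)
    inner = _ellipse(n, 0.5, 0.5, 0.27, 0.21)
    img[scalp] = 0.9
    img[skull] = 0.25
    img[brain] = 1.0   # cortical ribbon (brain minus inner overwritten below)
    img[inner] = 0.65
    for c3, s in ((0.44, 1.0), (0.56, -1.0)):
        img[_ellipse(n, 0.47, c3, 0.10, 0.035, s * 20.0)] = 0.15  # ventricles
    img[_ellipse(n, 0.62, 0.5, 0.05, 0.09)] = 0.8  # deep grey nucleus

    rng = np.random.default_rng(20240117)
    tex = ndimage.gaussian_filter(rng.normal(size=(n, n)), 0.03 * n)
    tex /= max(np.abs(tex).max(), 1e-12)
    img = img * (1.0 + 0.18 * tex)
    img = ndimage.gaussian_filter(img, 0.8)  # mildly band-limit the edges
    img[~scalp] = 0.0

    i2, i3 = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n),
                         indexing="ij")
    phase = 0.6 * i2 + 0.3 * i3 - 0.8 * i2 * i3 + 0.4 * (i2 ** 2 - i3 ** 2)
    return img * np.exp(1j * phase)


def make_coilmaps(n: int, n_coils: int) -> op.CoilMaps:
    """Smooth complex sensitivities of an encircling receive array.

    Each coil is a Gaussian magnitude lobe centered on the FOV perimeter
    with a low-order polynomial phase; the root-sum-of-squares is normalized
    to ~1 over the central FOV.  ``n_coils = 1`` yields a uniform map.
    """
    if n_coils == 1:
        return op.CoilMaps(np.ones((1, n, n), dtype=complex))
    rng = np.random.default_rng(777)
    i2, i3 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    u2 = (i2 - n / 2) / n
    u3 = (i3 - n / 2) / n
    maps = np.empty((n_coils, n, n), dtype=complex)
    r0, width = 0.52, 0.35
    for c in range(n_coils):
        phi = 2 * np.pi * c / n_coils
        d2 = u2 - r0 * np.cos(phi)
        d3 = u3 - r0 * np.sin(phi)
        mag = np.exp(-(d2 ** 2 + d3 ** 2) / (2 * width ** 2))
        a, b, g = rng.uniform(-1.2, 1.2, size=3)
        phase = phi + a * u2 + b * u3 + 0.5 * g * u2 * u3
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    disk = (u2 ** 2 + u3 ** 2) <= 0.4 ** 2
    maps /= rss[disk].mean()
    return op.CoilMaps(maps)


def make_motion_trace(m: int, theta_deg: float, trans_mm: float = 0.0,
                      seed: int = 0) -> mo.MotionTrace:
    """Per-segment i.i.d. uniform rigid states.

    Rotations are uniform on ``[-theta/2, theta/2]`` (degrees, about the FOV
    center) and translations uniform on ``[-trans/2, trans/2]`` (mm, both
    in-plane axes); deterministic per seed.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x0E])
    params = np.zeros((m, 3))
    params[:, :2] = rng.uniform(-trans_mm / 2, trans_mm / 2, size=(m, 2)) \
        if trans_mm > 0 else 0.0
    params[:, 2] = rng.uniform(-theta_deg / 2, theta_deg / 2, size=m) \
        if theta_deg > 0 else 0.0
    return mo.MotionTrace(params)


def _near_square_factors(m: int) -> tuple[int, int]:
    u2 = int(math.isqrt(m))
    while m % u2:
        u2 -= 1
    return u2, m // u2


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic acquisition."""

    n: int = 256                 # grid size (square)
    n_coils: int = 8
    n_segments: int = 16
    traversal: str = "random_checkered"
    tile_order: str = "zigzag"
    u2: int | None = None        # tile extents; near-square factors of M if None
    u3: int | None = None
    theta_deg: float = 0.0       # full width of the rotation interval
    trans_mm: float = 0.0
    snr_db: float = 30.0
    r2: int = 1
    r3: int = 1
    elliptical: bool = False
    spacing: float = 1.0         # voxel size in mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 32 or self.n_coils < 1 or self.n_segments < 1:
            raise ValueError("invalid simulation configuration")
        if self.theta_deg < 0 or self.trans_mm < 0:
            raise ValueError("motion levels must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls(**json.loads(s))


@dataclass
class SimulatedDataset:
    bundle: op.KSpaceBundle
    x_true: np.ndarray
    trace_true: mo.MotionTrace
    maps: op.CoilMaps
    config: SimulationConfig

    def model(self, trace: mo.MotionTrace | None = None,
              **kw) -> op.EncodingModel:
        """Encoding model on the full grid (zero motion by default)."""
        return op.EncodingModel.from_order(
            self.maps, self.bundle.order, trace=trace,
            spacing=self.config.spacing, **kw)


def make_order(config: SimulationConfig):
    grid = PEGrid(config.n, config.n, config.r2, config.r3, config.elliptical)
    if config.traversal in ("sequential", "random"):
        return make_view_order(grid, traversal=config.traversal,
                               tile_order=config.tile_order, seed=config.seed,
                               n_segments=config.n_segments)
    u2, u3 = config.u2, config.u3
    if u2 is None or u3 is None:
        u2, u3 = _near_square_factors(config.n_segments)
    if u2 * u3 == 1:  # single segment: checkered degenerates to sequential
        return make_view_order(grid, traversal="sequential",
                               tile_order=config.tile_order, seed=config.seed,
                               n_segments=1)
    tiling = build_tiling(grid, u2, u3)
    return make_view_order(grid, tiling, config.traversal, config.tile_order,
                           config.seed)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a motion- and noise-corrupted acquisition.

    Applies the forward model with the drawn per-segment rigid states to the
    phantom and adds noise at the configured SNR.
    """
    x = make_phantom(config.n)
    maps = make_coilmaps(config.n, config.n_coils)
    order = make_order(config)
    trace = make_motion_trace(config.n_segments, config.theta_deg,
                              config.trans_mm, config.seed)
    model = op.EncodingModel.from_order(maps, order, trace=trace,
                                        spacing=config.spacing)
    y = model.encode(x)
    bundle = op.KSpaceBundle(y, order, config.spacing,
                             attrs={"config": config.to_json()})
    bundle = op.add_noise(bundle, config.snr_db, config.seed, x, maps)
    return SimulatedDataset(bundle, x, trace, maps, config)
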