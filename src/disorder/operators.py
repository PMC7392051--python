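"""SENSE measurement operator with per-segment rigid motion.

The forward model is ``y = A F S T(theta) x``: each temporal segment m has
its own rigid state theta_m; the image is transformed by T(theta_m),
multiplied by the coil sensitivities S, Fourier transformed (centered,
orthonormal DFT, DC at ``n // 2``) and sampled on the segment's phase-encode
mask A_m.  Measurement noise is assumed whitened (identity covariance), so
the data-consistency loss is a plain (optionally segment-weighted) sum of
squared residual magnitudes.

The readout dimension is fully sampled and motion-free within a profile, so
the 2D simulation works directly in the k2-k3 phase-encode plane: one
complex sample per profile and coil.

``EncodingModel.encode``/``decode`` are exact adjoints of one another
(including segment weights) and process motion states in chunks, batching
the FFTs over states and coils.  Each encode or decode application adds
``n_states * n_coils * level_cost`` to the model's effective-iteration
counter, the cost unit being one operator application for one state and one
coil at full resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from . import motion as mo
from .motion import _as_complex
from .orders import ViewOrder


def _checker(n2: int, n3: int):
    """(-1)^(i2 + i3) checkerboard and the global sign making, for even
    extents, ``sign * chk * fft2(chk * x) == fftshift(fft2(ifftshift(x)))``."""
    s2 = 1 - 2 * (np.arange(n2) % 2)
    s3 = 1 - 2 * (np.arange(n3) % 2)
    chk = np.outer(s2, s3).astype(np.int8)
    sign = 1 if ((n2 // 2) + (n3 // 2)) % 2 == 0 else -1
    return chk, sign


def cfft2(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D DFT over the trailing axes (DC at n//2)."""
    x = _as_complex(np.asarray(x))
    n2, n3 = x.shape[-2:]
    if n2 % 2 == 0 and n3 % 2 == 0:
        chk, sign = _checker(n2, n3)
        y = sfft.fft2(x * chk, axes=(-2, -1), norm="ortho", overwrite_x=True)
        y *= sign * chk
        return y
    y = np.fft.ifftshift(x, axes=(-2, -1))
    y = sfft.fft2(y, axes=(-2, -1), norm="ortho")
    return np.fft.fftshift(y, axes=(-2, -1))


def cifft2(x: np.ndarray) -> np.ndarray:
    x = _as_complex(np.asarray(x))
    n2, n3 = x.shape[-2:]
    if n2 % 2 == 0 and n3 % 2 == 0:
        chk, sign = _checker(n2, n3)
        y = sfft.ifft2(x * chk, axes=(-2, -1), norm="ortho", overwrite_x=True)
        y *= sign * chk
        return y
    y = np.fft.ifftshift(x, axes=(-2, -1))
    y = sfft.ifft2(y, axes=(-2, -1), norm="ortho")
    return np.fft.fftshift(y, axes=(-2, -1))


@dataclass
class CoilMaps:
    """Complex coil sensitivity maps on the reconstruction grid, (C, N2, N3).

    Noise covariance is assumed whitened to identity; the root-sum-of-squares
    must be bounded away from zero over the object support.
    """

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.atleast_3d(np.asarray(self.maps, dtype=complex))
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("maps must be (C, N2, N3) with C >= 1")
        if not np.isfinite(self.maps).all():
            raise ValueError("maps must be finite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


@dataclass
class KSpaceBundle:
    """Measured k-space samples in temporal order.

    ``y`` is (P, C): one row per profile (temporal order of the view order),
    one column per coil.  ``noise_std`` is the per-sample complex standard
    deviation of the whitened noise (0 when noiseless).
    """

    y: np.ndarray
    order: ViewOrder
    spacing: float = 1.0
    noise_std: float = 0.0
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=complex)
        if self.y.shape[0] != self.order.n_profiles:
            raise ValueError("sample rows must match the view order length")

    @property
    def n_coils(self) -> int:
        return self.y.shape[1]


class EncodingModel:
    """Bundled measurement operator A F S T(theta) with loss bookkeeping.

    Parameters
    ----------
    maps : CoilMaps
    seg_flat : list of int arrays
        Flat (row-major) k-space index of each segment's profiles, on the
        model grid.  Segment rows of the data vector are contiguous and in
        this same order.
    trace : MotionTrace
        Per-segment rigid parameters; the effective map groups segments that
        share one (binned) motion state.
    weights : (M,) array or None
        Per-segment robustness weights W (1 = fully trusted).
    """

    def __init__(self, maps: CoilMaps, seg_flat: list[np.ndarray],
                 trace: mo.MotionTrace | None = None,
                 weights: np.ndarray | None = None, spacing: float = 1.0,
                 level_cost: float = 1.0, state_chunk: int = 64,
                 dtype=np.complex128):
        self.maps = maps
        self.dtype = np.dtype(dtype)
        self._maps = maps.maps.astype(dtype, copy=False)
        self._cmaps = np.conj(self._maps)
        n2, n3 = maps.shape
        # even grids: work in unshifted FFT layout with the centering
        # checkerboard folded into the maps and a per-sample sign correction,
        # avoiding four full-array shift/modulation passes per application
        self._fast = (n2 % 2 == 0) and (n3 % 2 == 0)
        if self._fast:
            chk, sign = _checker(n2, n3)
            fdt = np.float32 if self.dtype == np.complex64 else np.float64
            self._chk = chk.astype(fdt)
            self._chk_sign = sign
            self._maps_chk = self._maps * self._chk
            self._cmaps_chk = np.conj(self._maps_chk)
            self._ortho = 1.0 / np.sqrt(n2 * n3)
        self.seg_flat = [np.asarray(f, dtype=np.int64) for f in seg_flat]
        m = len(self.seg_flat)
        if trace is None:
            trace = mo.MotionTrace(np.zeros((m, 3)))
        if trace.n_states != m:
            raise ValueError("trace length must match the segment count")
        self.trace = trace
        self.weights = None if weights is None else np.asarray(weights, float)
        self.spacing = float(spacing)
        self.level_cost = float(level_cost)
        self.state_chunk = int(state_chunk)
        self.cost = 0.0  # effective-iteration counter j
        sizes = [len(f) for f in self.seg_flat]
        self.row_start = np.concatenate([[0], np.cumsum(sizes)])

    # -- structural helpers -------------------------------------------------

    @classmethod
    def from_order(cls, maps: CoilMaps, order: ViewOrder, **kw) -> "EncodingModel":
        if maps.shape != (order.grid.k2, order.grid.k3):
            raise ValueError(
                f"coil maps {maps.shape} do not match the PE grid "
                f"({order.grid.k2}, {order.grid.k3})")
        flat = order.flat_indices()
        seg_flat = [flat[r] for r in order.segment_rows()]
        return cls(maps, seg_flat, **kw)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape

    @property
    def n_segments(self) -> int:
        return len(self.seg_flat)

    @property
    def n_rows(self) -> int:
        return int(self.row_start[-1])

    def seg_rows(self, m: int) -> slice:
        return slice(int(self.row_start[m]), int(self.row_start[m + 1]))

    def _effective_groups(self):
        """Effective parameters plus concatenated row/flat indices per
        effective state (cached on the effective map)."""
        eff = self.trace.effective_map
        params = self.trace.effective_params()
        key = eff.tobytes()
        cached = getattr(self, "_idx_cache", None)
        if cached is None or cached[0] != key:
            n_eff = int(eff.max()) + 1
            rows = [[] for _ in range(n_eff)]
            flats = [[] for _ in range(n_eff)]
            for m, e in enumerate(eff):
                rows[int(e)].append(np.arange(self.row_start[m], self.row_start[m + 1]))
                flats[int(e)].append(self.seg_flat[m])
            eff_rows = [np.concatenate(r) for r in rows]
            eff_flat = [np.concatenate(f) for f in flats]
            if self._fast:
                n2, n3 = self.shape
                # chk * fft2(chk * x) * sign recenters in place: same flat
                # indices, only a per-sample sign correction
                eff_sign = [(self._chk_sign * self._chk[f // n3, f % n3]
                             ).astype(self._chk.dtype) for f in eff_flat]
            else:
                eff_sign = None
            self._idx_cache = (key, eff_rows, eff_flat, eff_sign)
        return (params,) + self._idx_cache[1:]

    def row_weights(self) -> np.ndarray | None:
        if self.weights is None:
            return None
        return np.repeat(self.weights, np.diff(self.row_start))

    # -- operator -----------------------------------------------------------

    def _active(self, states):
        if states is None:
            return list(range(self.trace.n_effective))
        return sorted({int(self.trace.effective_map[m])
                       for m in np.atleast_1d(states)})

    @staticmethod
    def _chunk_index(eff_rows, eff_flat, chunk):
        sizes = [len(eff_rows[e]) for e in chunk]
        g = np.repeat(np.arange(len(chunk)), sizes)
        rows = np.concatenate([eff_rows[e] for e in chunk])
        flat = np.concatenate([eff_flat[e] for e in chunk])
        return g, rows, flat

    def _fwd_k(self, xb: np.ndarray) -> np.ndarray:
        """Per-coil k-space of a transformed image stack, (G, C, N2*N3).

        Fast path: unshifted layout with the checkerboard folded into the
        maps (sample gathers use translated indices and sign corrections).
        """
        g, n2, n3 = xb.shape
        if self._fast:
            kb = sfft.fft2(xb[:, None, :, :] * self._maps_chk[None],
                           axes=(-2, -1), norm="ortho", overwrite_x=True)
        else:
            kb = cfft2(xb[:, None, :, :] * self._maps[None])
        return kb.reshape(g, self.maps.n_coils, n2 * n3)

    def _adj_img(self, kb: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`_fwd_k`: coil-combined image stack (G, N2, N3)."""
        g = kb.shape[0]
        c = self.maps.n_coils
        n2, n3 = self.shape
        kb = kb.reshape(g, c, n2, n3)
        if self._fast:
            ib = sfft.ifft2(kb, axes=(-2, -1), norm="ortho", overwrite_x=True)
            return np.einsum("gcij,cij->gij", ib, self._cmaps_chk)
        return (self._cmaps[None] * cifft2(kb)).sum(axis=1)

    def encode(self, x: np.ndarray, states: np.ndarray | None = None) -> np.ndarray:
        """Forward model; returns (P, C) samples (rows of ``states``' segments
        only when a state subset is given, other rows zero)."""
        params, eff_rows, eff_flat, eff_sign = self._effective_groups()
        act = self._active(states)
        c = self.maps.n_coils
        n2, n3 = self.shape
        x = np.asarray(x).astype(self.dtype, copy=False)
        y = np.zeros((self.n_rows, c), dtype=self.dtype)
        for lo in range(0, len(act), self.state_chunk):
            chunk = act[lo:lo + self.state_chunk]
            xb = mo.apply_rigid2d(np.broadcast_to(x, (len(chunk), n2, n3)),
                                  params[chunk], self.spacing)
            kb = self._fwd_k(xb)
            g, rows, flat = self._chunk_index(eff_rows, eff_flat, chunk)
            vals = kb[g, :, flat]
            if self._fast:
                sign = np.concatenate([eff_sign[e] for e in chunk])
                vals = vals * sign[:, None]
            y[rows] = vals
            self.cost += len(chunk) * c * self.level_cost
        return y

    def decode(self, y: np.ndarray, states: np.ndarray | None = None,
               weighted: bool = True) -> np.ndarray:
        """Exact adjoint of ``encode`` (with W applied when present)."""
        params, eff_rows, eff_flat, eff_sign = self._effective_groups()
        act = self._active(states)
        c = self.maps.n_coils
        n2, n3 = self.shape
        y = np.asarray(y).astype(self.dtype, copy=False)
        rw = self.row_weights() if weighted else None
        x = np.zeros((n2, n3), dtype=self.dtype)
        for lo in range(0, len(act), self.state_chunk):
            chunk = act[lo:lo + self.state_chunk]
            kb = np.zeros((len(chunk), c, n2 * n3), dtype=self.dtype)
            g, rows, flat = self._chunk_index(eff_rows, eff_flat, chunk)
            vals = y[rows]
            if self._fast:
                sign = np.concatenate([eff_sign[e] for e in chunk])
                vals = vals * sign[:, None]
            if rw is not None:
                vals = vals * rw[rows, None]
            kb[g, :, flat] = vals
            xb = self._adj_img(kb)
            x += mo.apply_rigid2d_adjoint(xb, params[chunk], self.spacing).sum(axis=0)
            self.cost += len(chunk) * c * self.level_cost
        return x

    def normal(self, x: np.ndarray) -> np.ndarray:
        """E^H W E x, fused (no sample gather/scatter; the sign corrections
        of the unshifted layout cancel)."""
        params, eff_rows, eff_flat, eff_sign = self._effective_groups()
        act = self._active(None)
        c = self.maps.n_coils
        n2, n3 = self.shape
        x = np.asarray(x).astype(self.dtype, copy=False)
        out = np.zeros((n2, n3), dtype=self.dtype)
        wkey = (self.trace.effective_map.tobytes(),
                None if self.weights is None else self.weights.tobytes())
        wcache = getattr(self, "_wmask_cache", None)
        if wcache is None or wcache[0] != wkey:
            rw = self.row_weights()
            wmask_all = np.zeros((len(act), n2 * n3),
                                 dtype=np.float32 if self.dtype == np.complex64
                                 else np.float64)
            for g, e in enumerate(act):
                wmask_all[g, eff_flat[e]] = 1.0 if rw is None else rw[eff_rows[e]]
            self._wmask_cache = (wkey, wmask_all)
        wmask_all = self._wmask_cache[1]
        for lo in range(0, len(act), self.state_chunk):
            chunk = act[lo:lo + self.state_chunk]
            xb = mo.apply_rigid2d(np.broadcast_to(x, (len(chunk), n2, n3)),
                                  params[chunk], self.spacing)
            kb = self._fwd_k(xb)
            kb *= wmask_all[lo:lo + self.state_chunk, None, :]
            xb = self._adj_img(kb)
            out += mo.apply_rigid2d_adjoint(xb, params[chunk], self.spacing).sum(axis=0)
            self.cost += 2 * len(chunk) * c * self.level_cost
        return out

    # -- loss ---------------------------------------------------------------

    def loss(self, x: np.ndarray, y: np.ndarray, weighted: bool = False):
        """Total loss r and per-profile losses r[m, e] (as a flat (P,) array
        in temporal order; sum over coils of squared residual magnitudes)."""
        res = self.encode(x) - y
        per_profile = (np.abs(res) ** 2).sum(axis=1)
        if weighted and self.weights is not None:
            w = np.repeat(self.weights, np.diff(self.row_start))
            return float((w * per_profile).sum()), per_profile
        return float(per_profile.sum()), per_profile

    def loss_table(self, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        """Per-segment arrays of per-profile losses."""
        _, pp = self.loss(x, y)
        return [pp[self.seg_rows(m)] for m in range(self.n_segments)]

    def residual_table(self, res_per_profile: np.ndarray) -> list[np.ndarray]:
        return [res_per_profile[self.seg_rows(m)] for m in range(self.n_segments)]

    def with_trace(self, trace: mo.MotionTrace) -> "EncodingModel":
        out = EncodingModel(self.maps, self.seg_flat, trace, self.weights,
                            self.spacing, self.level_cost, self.state_chunk,
                            self.dtype)
        out.cost = self.cost
        return out


def object_support(x: np.ndarray, rel: float = 0.05) -> np.ndarray:
    """Support mask: voxels above ``rel`` times the maximum magnitude."""
    a = np.abs(x)
    m = a > rel * a.max()
    if not m.any():
        raise ValueError("empty object support")
    return m


def noise_std_for_snr(x: np.ndarray, maps: CoilMaps, snr_db: float,
                      support: np.ndarray | None = None) -> float:
    """Per-sample k-space noise std realizing a mean image-domain SNR.

    SNR is defined as ``20 log10(mean |x| over the object support / mean
    image-domain noise std over the support)`` for the motion-free,
    unaccelerated SENSE reconstruction, whose per-voxel complex noise std is
    ``sigma_k / rss(v)``.
    """
    if support is None:
        support = object_support(x)
    sig = np.abs(x)[support].mean()
    target_img_std = sig / 10.0 ** (snr_db / 20.0)
    inv_rss = (1.0 / maps.rss()[support]).mean()
    return float(target_img_std / inv_rss)


def add_noise(bundle: KSpaceBundle, snr_db: float, seed: int,
              reference_image: np.ndarray, maps: CoilMaps,
              support: np.ndarray | None = None) -> KSpaceBundle:
    """Add i.i.d. circularly symmetric complex Gaussian noise at a mean SNR.

    ``snr_db = inf`` returns the bundle unchanged.  Deterministic per seed.
    """
    if not np.isfinite(snr_db):
        return bundle
    sigma = noise_std_for_snr(reference_image, maps, snr_db, support)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xA0])
    n = rng.normal(size=bundle.y.shape) + 1j * rng.normal(size=bundle.y.shape)
    return replace(bundle, y=bundle.y + (sigma / np.sqrt(2.0)) * n,
                   noise_std=sigma)
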