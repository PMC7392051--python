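"""Rigid-body motion states and unitary image-domain transforms.

Rigid transforms are applied on the periodic FFT grid: translations as
k-space linear phases and rotations via a three-shear factorization, each
shear being a pure phase multiplication in a mixed (frequency x space)
domain.  Every factor is therefore exactly unitary, and the inverse
transform (reversed shears with negated parameters) composes with the
forward one to the identity to machine precision.

Angles are stored in degrees, translations in mm; the rotation center is the
FOV center, i.e. voxel index ``n // 2`` along each axis.

Batched variants operate on stacks ``(B, N2, N3)`` with per-item parameter
vectors -- this is what the encoding operator uses, one item per motion
state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
import scipy.fft as sfft

from . import _kernels

_TWO_PI = 2.0 * np.pi


def _as_complex(x: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(x):
        return x
    return x.astype(np.complex128 if x.dtype != np.float32 else np.complex64)


def _wrap_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


@dataclass
class RigidParams:
    """One rigid motion state: translations (mm) and Euler angles (degrees).

    2D states carry 2 translations + 1 angle; 3D states 3 translations +
    3 intrinsic Z-Y-X Euler angles.
    """

    translation: np.ndarray
    rotation: np.ndarray
    center: np.ndarray | None = None  # rotation center in mm; FOV center if None

    def __post_init__(self) -> None:
        self.translation = np.atleast_1d(np.asarray(self.translation, dtype=float))
        self.rotation = _wrap_angle(np.atleast_1d(self.rotation))
        if not (np.isfinite(self.translation).all() and np.isfinite(self.rotation).all()):
            raise ValueError("rigid parameters must be finite")
        d = self.translation.size
        if (d, self.rotation.size) not in ((2, 1), (3, 3)):
            raise ValueError("expected 2 translations + 1 angle or 3 + 3")

    @property
    def ndim(self) -> int:
        return self.translation.size

    def vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation])


@dataclass
class MotionTrace:
    """Per-segment rigid parameters as an (M, P) array.

    For 2D, columns are ``(t2, t3, angle)`` with translations in mm and the
    angle in degrees; for 3D, ``(t1, t2, t3, rz, ry, rx)``.  ``effective_map``
    maps each original state to its effective (binned) state id and is
    monotone non-decreasing over time.
    """

    params: np.ndarray
    ndim: int = 2
    converged: np.ndarray | None = None
    effective_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.converged is None:
            self.converged = np.zeros(self.n_states, dtype=bool)
        if self.effective_map is None:
            self.effective_map = np.arange(self.n_states)
        self.effective_map = np.asarray(self.effective_map)
        if np.any(np.diff(self.effective_map) < 0):
            raise ValueError("effective_map must be non-decreasing")

    @property
    def n_states(self) -> int:
        return self.params.shape[0]

    @property
    def n_effective(self) -> int:
        return int(self.effective_map.max()) + 1

    def effective_params(self) -> np.ndarray:
        """Mean original parameters within each effective group."""
        out = np.zeros((self.n_effective, self.params.shape[1]))
        counts = np.bincount(self.effective_map)
        np.add.at(out, self.effective_map, self.params)
        return out / counts[:, None]

    def state(self, m: int) -> RigidParams:
        d = self.ndim
        return RigidParams(self.params[m, :d], self.params[m, d:])

    def copy(self) -> "MotionTrace":
        return MotionTrace(self.params.copy(), self.ndim,
                           self.converged.copy(), self.effective_map.copy())


# ---------------------------------------------------------------------------
# FFT shear primitives


def _fft_ints(n: int) -> np.ndarray:
    """Integer FFT frequencies in unshifted layout."""
    return np.fft.fftfreq(n) * n


_RAMP_CACHE: dict = {}


def _shear_ramp(x_shape, shear_axis: int, coord_axis: int, dtype=np.float64):
    """Mixed-domain ramp k * u / n for a shear, broadcast to the image shape."""
    nd = len(x_shape)
    shear_axis %= nd
    coord_axis %= nd
    n = x_shape[shear_axis]
    nc = x_shape[coord_axis]
    key = (n, nc, shear_axis - nd, coord_axis - nd, np.dtype(dtype).str)
    hit = _RAMP_CACHE.get(key)
    if hit is not None:
        return hit.reshape([x_shape[i] if i in (shear_axis, coord_axis) else 1
                            for i in range(nd)])
    k = _fft_ints(n)
    u = np.arange(nc) - nc // 2
    if shear_axis < coord_axis:
        ramp = (np.outer(k, u) / n).astype(dtype)
    else:
        ramp = (np.outer(u, k) / n).astype(dtype)
    if len(_RAMP_CACHE) > 64:
        _RAMP_CACHE.clear()
    _RAMP_CACHE[key] = ramp
    return ramp.reshape([x_shape[i] if i in (shear_axis, coord_axis) else 1
                         for i in range(nd)])


def _trailing_ramp(x_shape, shear_axis: int, coord_axis: int, dtype):
    """Contiguous 2D ramp over the two trailing axes, or None if the shear
    does not act on them (then the broadcasting fallback is used)."""
    nd = len(x_shape)
    sa, ca = shear_axis % nd, coord_axis % nd
    if nd not in (2, 3) or {sa, ca} != {nd - 2, nd - 1}:
        return None
    ramp = _shear_ramp(x_shape, shear_axis, coord_axis, dtype)
    return np.ascontiguousarray(ramp.reshape(x_shape[-2:]))


def _bshape(s, x_ndim: int) -> np.ndarray:
    """Reshape a batch of scalars to broadcast against trailing image axes."""
    s = np.asarray(s, dtype=float)
    return s.reshape(s.shape + (1,) * (x_ndim - s.ndim))


def shear(x: np.ndarray, s, shear_axis: int, coord_axis: int) -> np.ndarray:
    """Apply the unitary shear ``u_a <- u_a + s * u_c`` (periodic grid).

    ``s`` may be a scalar or a batch matching the leading axes of ``x``.
    Single-precision input stays single precision.
    """
    x = _as_complex(np.asarray(x))
    rdt = x.real.dtype
    X = sfft.fft(x, axis=shear_axis)
    r2d = _trailing_ramp(x.shape, shear_axis, coord_axis, rdt)
    if r2d is not None:
        Xv = X if X.ndim == 3 else X[None]
        sb = np.broadcast_to(np.atleast_1d(np.asarray(s, float)) * -_TWO_PI,
                             (Xv.shape[0],))
        if _kernels.ramp_mult(Xv, sb, r2d):
            return sfft.ifft(X, axis=shear_axis, overwrite_x=True)
    ramp = _shear_ramp(x.shape, shear_axis, coord_axis, rdt)
    arg = (_bshape(s, x.ndim) * (-_TWO_PI)).astype(rdt) * ramp
    X *= np.exp(1j * arg)
    return sfft.ifft(X, axis=shear_axis, overwrite_x=True)


def shear_deriv(x: np.ndarray, s, shear_axis: int, coord_axis: int) -> np.ndarray:
    """Derivative of ``shear(x, s, ...)`` with respect to ``s`` (analytic)."""
    x = _as_complex(np.asarray(x))
    rdt = x.real.dtype
    X = sfft.fft(x, axis=shear_axis)
    r2d = _trailing_ramp(x.shape, shear_axis, coord_axis, rdt)
    if r2d is not None:
        Xv = X if X.ndim == 3 else X[None]
        sb = np.broadcast_to(np.atleast_1d(np.asarray(s, float)) * -_TWO_PI,
                             (Xv.shape[0],))
        if _kernels.ramp_mult_deriv(Xv, sb, r2d, -_TWO_PI):
            return sfft.ifft(X, axis=shear_axis, overwrite_x=True)
    ramp = _shear_ramp(x.shape, shear_axis, coord_axis, rdt)
    arg = (_bshape(s, x.ndim) * (-_TWO_PI)).astype(rdt) * ramp
    X *= np.exp(1j * arg) * ((-1j * _TWO_PI) * ramp).astype(
        np.result_type(1j, rdt))
    return sfft.ifft(X, axis=shear_axis, overwrite_x=True)


def _rot90_center(x: np.ndarray, q: int, axes=(-2, -1)) -> np.ndarray:
    """Exact rotation by q quarter turns about voxel ``n // 2`` with wrap."""
    q = int(q) % 4
    a2, a3 = axes
    for _ in range(q):
        n2, n3 = x.shape[a2], x.shape[a3]
        c2, c3 = n2 // 2, n3 // 2
        # y[i2, i3] = x[c2 + (i3 - c3), c3 - (i2 - c2)]  (CCW quarter turn)
        i2 = np.arange(n2)
        i3 = np.arange(n3)
        j2 = (c2 + (i3 - c3)) % n2  # length n3, indexes axis a2 of x
        j3 = (c3 - (i2 - c2)) % n3  # length n2, indexes axis a3 of x
        xt = np.moveaxis(x, (a2, a3), (-2, -1))
        yt = xt[..., j2[None, :], j3[:, None]]
        x = np.moveaxis(yt, (-2, -1), (a2, a3))
    return x


def rotate(x: np.ndarray, angle_rad, axes=(-2, -1)) -> np.ndarray:
    """Unitary rotation about the FOV center in the plane ``axes``.

    Angles of magnitude above 45 degrees are decomposed into exact quarter
    turns (index permutations) plus a residual three-shear rotation, so any
    angle is admissible.
    """
    ang = np.atleast_1d(np.asarray(angle_rad, dtype=float))
    scalar_batch = np.asarray(angle_rad).ndim == 0
    q = np.round(ang / (np.pi / 2)).astype(int)
    res = ang - q * (np.pi / 2)
    if scalar_batch:
        y = _as_complex(np.asarray(x))
        if q[0] % 4:
            y = _rot90_center(y, int(q[0]), axes)
        return _shear_rotate(y, float(res[0]), axes)
    if not np.any(q % 4):
        return _shear_rotate(_as_complex(np.asarray(x)), res, axes)
    out = np.array(_as_complex(np.asarray(x)), copy=True)
    for qv in np.unique(q % 4):
        sel = (q % 4) == qv
        y = out[sel]
        if qv:
            y = _rot90_center(y, int(qv), axes)
        out[sel] = _shear_rotate(y, res[sel], axes)
    return out


def rotate_adjoint(x: np.ndarray, angle_rad, axes=(-2, -1)) -> np.ndarray:
    """Exact adjoint (= inverse) of :func:`rotate` for the same angle.

    The forward operator is ``Shear(res) o Rot90(q)``; quarter turns and
    shear rotations do not commute as discrete operators, so the inverse
    applies ``Shear(-res)`` first and then ``Rot90(-q)``.
    """
    ang = np.atleast_1d(np.asarray(angle_rad, dtype=float))
    scalar_batch = np.asarray(angle_rad).ndim == 0
    q = np.round(ang / (np.pi / 2)).astype(int)
    res = ang - q * (np.pi / 2)
    if scalar_batch:
        y = _shear_rotate(_as_complex(np.asarray(x)), -float(res[0]), axes)
        if q[0] % 4:
            y = _rot90_center(y, -int(q[0]), axes)
        return y
    if not np.any(q % 4):
        return _shear_rotate(_as_complex(np.asarray(x)), -res, axes)
    out = np.empty_like(_as_complex(np.asarray(x)))
    xs = _as_complex(np.asarray(x))
    for qv in np.unique(q):
        sel = q == qv
        y = _shear_rotate(xs[sel], -res[sel], axes)
        if qv % 4:
            y = _rot90_center(y, -int(qv), axes)
        out[sel] = y
    return out


def _shear_rotate(x: np.ndarray, ang, axes=(-2, -1)) -> np.ndarray:
    """Three-shear rotation for |angle| <= 45 degrees (+ slack)."""
    a2, a3 = axes
    ang = np.asarray(ang, dtype=float)
    a = -np.tan(ang / 2)
    b = np.sin(ang)
    y = shear(x, a, a2, a3)
    y = shear(y, b, a3, a2)
    return shear(y, a, a2, a3)


def _shear_rotate_deriv(x: np.ndarray, ang, axes=(-2, -1)):
    """Return (R(ang) x, d/dang R(ang) x) for |angle| <= 45 degrees."""
    a2, a3 = axes
    ang = np.asarray(ang, dtype=float)
    a = -np.tan(ang / 2)
    b = np.sin(ang)
    da = -0.5 / np.cos(ang / 2) ** 2
    db = np.cos(ang)
    z1 = shear(x, a, a2, a3)
    z2 = shear(z1, b, a3, a2)
    y = shear(z2, a, a2, a3)
    t_outer = shear_deriv(z2, a, a2, a3) * _bshape(da, x.ndim)
    t_mid = shear(shear_deriv(z1, b, a3, a2), a, a2, a3) * _bshape(db, x.ndim)
    t_inner = shear(shear(shear_deriv(x, a, a2, a3), b, a3, a2), a, a2, a3) \
        * _bshape(da, x.ndim)
    return y, t_outer + t_mid + t_inner


def translate(x: np.ndarray, shifts, axes=None) -> np.ndarray:
    """Periodic sub-voxel translation via k-space linear phases.

    ``shifts`` has one voxel-unit entry per translated axis (trailing axes by
    default); a leading batch dimension is allowed.
    """
    x = _as_complex(np.asarray(x))
    rdt = x.real.dtype
    shifts = np.asarray(shifts, dtype=float)
    d = shifts.shape[-1]
    if axes is None:
        axes = tuple(range(-d, 0))
    X = sfft.fftn(x, axes=axes)
    nd = x.ndim
    if (d == 2 and nd in (2, 3)
            and tuple(a % nd for a in axes) == (nd - 2, nd - 1)
            and X.flags.c_contiguous):
        Xv = X if nd == 3 else X[None]
        b = Xv.shape[0]
        sh = np.broadcast_to(shifts.reshape(-1, 2) * -_TWO_PI, (b, 2))
        k1 = _fft_ints(x.shape[-2]) / x.shape[-2]
        k2 = _fft_ints(x.shape[-1]) / x.shape[-1]
        if _kernels.sep_mult(Xv, sh[:, 0], sh[:, 1], k1, k2):
            return sfft.ifftn(X, axes=axes, overwrite_x=True)
    arg = np.zeros((1,) * x.ndim, dtype=rdt)
    for j, ax in enumerate(axes):
        k = (_fft_ints(x.shape[ax]) / x.shape[ax]).astype(rdt)
        ks = k.reshape([x.shape[ax] if i % x.ndim == ax % x.ndim else 1
                        for i in range(x.ndim)])
        arg = arg + ((-_TWO_PI) * _bshape(shifts[..., j], x.ndim)).astype(rdt) * ks
    X *= np.exp(1j * arg)
    return sfft.ifftn(X, axes=axes, overwrite_x=True)


# ---------------------------------------------------------------------------
# 2D rigid transform and Jacobian (batched)


def apply_rigid2d(x: np.ndarray, params: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Apply T(theta): rotation about the FOV center, then translation.

    ``x`` is ``(..., N2, N3)``; ``params`` is ``(..., 3)`` = (t2 mm, t3 mm,
    angle deg) with leading axes broadcasting against the batch axes of
    ``x``.  The operator is unitary on the periodic grid.
    """
    params = np.asarray(params, dtype=float)
    ang = np.deg2rad(params[..., 2])
    y = rotate(x, ang)
    return translate(y, params[..., :2] / spacing)


def apply_rigid2d_adjoint(x: np.ndarray, params: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Adjoint (= inverse) transform: translate back, then rotate back."""
    params = np.asarray(params, dtype=float)
    y = translate(x, -params[..., :2] / spacing)
    return rotate_adjoint(y, np.deg2rad(params[..., 2]))


def rigid_jacobian2d(x: np.ndarray, params: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Per-parameter derivatives of ``apply_rigid2d``.

    Returns an array with a parameter axis inserted before the image axes:
    for ``x`` of shape (B, N2, N3) and params (B, 3) the result is
    (B, 3, N2, N3), ordered (d/dt2, d/dt3, d/dangle).  Translation
    derivatives are analytic phase ramps; the rotation derivative is obtained
    by differentiating the three shear phases (parameters are differentiated
    independently, holding the others fixed).
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    x = _as_complex(np.asarray(x))
    if x.ndim == 2:
        x = np.broadcast_to(x, params.shape[:-1] + x.shape)
    ang = np.deg2rad(params[..., 2])
    q = np.round(ang / (np.pi / 2)).astype(int)
    res = ang - q * (np.pi / 2)
    rot = np.empty_like(x)
    drot = np.empty_like(x)
    for qv in np.unique(q % 4):
        sel = (q % 4) == qv
        y = x[sel]
        if qv:
            y = _rot90_center(y, int(qv))
        rot[sel], drot[sel] = _shear_rotate_deriv(y, res[sel])
    shifts = params[..., :2] / spacing
    t_rot = translate(rot, shifts)
    t_drot = translate(drot, shifts)

    # translation derivatives: multiply the 2D spectrum of T x by -2 pi i k / (n * spacing)
    cdt = t_rot.dtype
    X = sfft.fftn(t_rot, axes=(-2, -1))
    n2, n3 = x.shape[-2:]
    k2 = (_fft_ints(n2) / n2)[:, None]
    k3 = (_fft_ints(n3) / n3)[None, :]
    d_t2 = sfft.ifftn(X * ((-1j * _TWO_PI / spacing) * k2).astype(cdt), axes=(-2, -1))
    d_t3 = sfft.ifftn(X * ((-1j * _TWO_PI / spacing) * k3).astype(cdt), axes=(-2, -1))
    d_ang = t_drot * (np.pi / 180.0)
    return np.stack([d_t2, d_t3, d_ang], axis=-3)


def compose_rigid2d(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Parameters of ``T(outer) o T(inner)`` about the shared center.

    With ``T(p) = Translate(t) Rotate(phi)``, the composition has
    ``phi = phi_o + phi_i`` and ``t = t_o + R(phi_o) t_i``.
    """
    outer = np.asarray(outer, float)
    inner = np.asarray(inner, float)
    phi_o = np.deg2rad(outer[..., 2])
    c, s = np.cos(phi_o), np.sin(phi_o)
    t2 = outer[..., 0] + c * inner[..., 0] - s * inner[..., 1]
    t3 = outer[..., 1] + s * inner[..., 0] + c * inner[..., 1]
    ang = _wrap_angle(outer[..., 2] + inner[..., 2])
    return np.stack([t2, t3, ang], axis=-1)


def invert_rigid2d(p: np.ndarray) -> np.ndarray:
    """Parameters of ``T(p)^-1``: negate the angle, counter-rotate t."""
    p = np.asarray(p, float)
    phi = np.deg2rad(p[..., 2])
    c, s = np.cos(phi), np.sin(phi)
    t2 = -(c * p[..., 0] + s * p[..., 1])
    t3 = -(-s * p[..., 0] + c * p[..., 1])
    return np.stack([t2, t3, _wrap_angle(-p[..., 2])], axis=-1)


# ---------------------------------------------------------------------------
# 3D rigid transform (intrinsic Z-Y-X Euler convention)

_EULER_PLANES = ((-3, -2), (-3, -1), (-2, -1))  # rz (axis1-axis2), ry, rx planes


def apply_rigid3d(x: np.ndarray, params: np.ndarray, spacing: float = 1.0,
                  adjoint: bool = False) -> np.ndarray:
    """Apply (or invert) a 3D rigid transform to a single volume.

    ``params`` = (t1, t2, t3 mm, rz, ry, rx deg); rotations are applied as
    successive in-plane shear rotations about the FOV center in the order
    rz, ry, rx (intrinsic Z-Y-X), followed by the translation.
    """
    params = np.asarray(params, dtype=float)
    angs = np.deg2rad(params[3:])
    if adjoint:
        y = translate(x, -params[:3] / spacing)
        for ang, plane in zip(angs[::-1], _EULER_PLANES[::-1]):
            y = rotate_adjoint(y, ang, axes=plane)
        return y
    y = _as_complex(np.asarray(x))
    for ang, plane in zip(angs, _EULER_PLANES):
        y = rotate(y, ang, axes=plane)
    return translate(y, params[:3] / spacing)


def rigid_jacobian3d(x: np.ndarray, params: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Per-parameter derivatives of ``apply_rigid3d`` (simplified: each
    parameter differentiated holding the others at their current value)."""
    params = np.asarray(params, dtype=float)
    angs = np.deg2rad(params[3:])
    stages = [_as_complex(np.asarray(x))]
    dstages = []
    for ang, plane in zip(angs, _EULER_PLANES):
        y, dy = _shear_rotate_deriv_any(stages[-1], ang, plane)
        stages.append(y)
        dstages.append(dy)
    rot = stages[-1]
    shifts = params[:3] / spacing
    t_rot = translate(rot, shifts)
    out = []
    X = sfft.fftn(t_rot, axes=(-3, -2, -1))
    for j, ax in enumerate((-3, -2, -1)):
        n = x.shape[ax]
        k = _fft_ints(n) / n
        ks = k.reshape([n if i - x.ndim == ax else 1 for i in range(x.ndim)])
        out.append(sfft.ifftn(X * ((-1j * _TWO_PI / spacing) * ks).astype(X.dtype),
                              axes=(-3, -2, -1)))
    for j, plane in enumerate(_EULER_PLANES):
        d = dstages[j]
        for ang, pl in zip(angs[j + 1:], _EULER_PLANES[j + 1:]):
            d = rotate(d, ang, axes=pl)
        out.append(translate(d, shifts) * (np.pi / 180.0))
    return np.stack(out, axis=0)


def _shear_rotate_deriv_any(x, ang, plane):
    q = int(np.round(ang / (np.pi / 2)))
    res = ang - q * (np.pi / 2)
    y = _rot90_center(x, q, plane) if q % 4 else x
    return _shear_rotate_deriv(y, res, plane)


# ---------------------------------------------------------------------------
# Motion compression (binning) by Haar truncation


def _haar_denoise(v: np.ndarray, tau: float) -> np.ndarray:
    """Hard-threshold the Haar detail coefficients of a 1D trace."""
    n = v.size
    if n < 2 or tau <= 0:
        return v.copy()
    p = 1 << (n - 1).bit_length()  # next power of two
    vp = np.pad(v, (0, p - n), mode="edge")
    coeffs = pywt.wavedec(vp, "haar", level=int(np.log2(p)))
    out = [coeffs[0]]
    for c in coeffs[1:]:
        out.append(np.where(np.abs(c) < tau, 0.0, c))
    return pywt.waverec(out, "haar")[:n]


def haar_compress_trace(trace: MotionTrace, tau_translation: float,
                        tau_rotation: float) -> MotionTrace:
    """Bin contiguous similar motion states via Haar truncation.

    Each parameter trace over time is Haar-transformed, detail coefficients
    with magnitude below the per-parameter-type threshold are zeroed, and
    contiguous states whose reconstructed parameters coincide are grouped
    into one effective state whose parameters are the mean of the originals.
    ``tau = 0`` leaves the trace unbinned.
    """
    if tau_translation < 0 or tau_rotation < 0:
        raise ValueError("thresholds must be non-negative")
    if tau_translation == 0 and tau_rotation == 0:
        out = trace.copy()
        out.effective_map = np.arange(trace.n_states)
        return out
    m, p = trace.params.shape
    d = trace.ndim
    taus = np.array([tau_translation] * d + [tau_rotation] * (p - d))
    rec = np.stack([_haar_denoise(trace.params[:, j], taus[j]) for j in range(p)], axis=1)
    # group contiguous identical reconstructed rows
    if m == 1:
        changes = np.zeros(0, dtype=bool)
    else:
        changes = ~np.all(np.isclose(rec[1:], rec[:-1], rtol=1e-9, atol=1e-12), axis=1)
    eff_map = np.concatenate([[0], np.cumsum(changes)])
    out = trace.copy()
    out.effective_map = eff_map
    return out
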