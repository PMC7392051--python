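"""Fused phase-multiply kernels for the FFT-shear transforms.

The shear and translation operators multiply large mixed-domain arrays by
unit-modulus phase factors; evaluating ``exp`` through numpy allocates
several temporaries of the full array size.  These numba kernels fuse the
argument computation, the complex exponential and the in-place multiply.
numpy fallbacks keep the package functional if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _ramp_mult(X, s, ramp):
        """X[b, i, j] *= exp(1j * s[b] * ramp[i, j]) in place."""
        b_n, n1, n2 = X.shape
        for b in range(b_n):
            sb = s[b]
            for i in range(n1):
                for j in range(n2):
                    a = sb * ramp[i, j]
                    X[b, i, j] = X[b, i, j] * complex(np.cos(a), np.sin(a))

    @numba.njit(cache=True, fastmath=True)
    def _ramp_mult_deriv(X, s, ramp, q):
        """X[b,i,j] *= exp(1j*s[b]*ramp[i,j]) * (1j * q * ramp[i, j])."""
        b_n, n1, n2 = X.shape
        for b in range(b_n):
            sb = s[b]
            for i in range(n1):
                for j in range(n2):
                    a = sb * ramp[i, j]
                    ph = complex(np.cos(a), np.sin(a)) * complex(0.0, q * ramp[i, j])
                    X[b, i, j] = X[b, i, j] * ph

    @numba.njit(cache=True, fastmath=True)
    def _sep_mult(X, p, q, k1, k2):
        """X[b, i, j] *= exp(1j * (p[b] * k1[i] + q[b] * k2[j]))."""
        b_n, n1, n2 = X.shape
        for b in range(b_n):
            pb, qb = p[b], q[b]
            for i in range(n1):
                ai = pb * k1[i]
                for j in range(n2):
                    a = ai + qb * k2[j]
                    X[b, i, j] = X[b, i, j] * complex(np.cos(a), np.sin(a))


def ramp_mult(X: np.ndarray, s: np.ndarray, ramp: np.ndarray) -> bool:
    """In-place ``X[b] *= exp(1j s[b] ramp)``; returns False on fallback."""
    if not (_HAVE_NUMBA and X.ndim == 3 and X.flags.c_contiguous):
        return False
    _ramp_mult(X, np.ascontiguousarray(s, dtype=X.real.dtype.type),
               np.ascontiguousarray(ramp, dtype=X.real.dtype.type))
    return True


def ramp_mult_deriv(X: np.ndarray, s: np.ndarray, ramp: np.ndarray,
                    q: float) -> bool:
    if not (_HAVE_NUMBA and X.ndim == 3 and X.flags.c_contiguous):
        return False
    _ramp_mult_deriv(X, np.ascontiguousarray(s, dtype=X.real.dtype.type),
                     np.ascontiguousarray(ramp, dtype=X.real.dtype.type),
                     X.real.dtype.type(q))
    return True


def sep_mult(X: np.ndarray, p: np.ndarray, q: np.ndarray,
             k1: np.ndarray, k2: np.ndarray) -> bool:
    if not (_HAVE_NUMBA and X.ndim == 3 and X.flags.c_contiguous):
        return False
    rdt = X.real.dtype.type
    _sep_mult(X, np.ascontiguousarray(p, dtype=rdt),
              np.ascontiguousarray(q, dtype=rdt),
              np.ascontiguousarray(k1, dtype=rdt),
              np.ascontiguousarray(k2, dtype=rdt))
    return True
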