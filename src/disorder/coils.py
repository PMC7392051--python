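"""Coil compression to virtual channels.

An SVD of the coil sensitivity matrix over the object support yields
virtual channels ordered by sensitivity energy; retaining the leading C'
channels trades a small predicted SNR loss for proportional savings in every
encode/decode application.  The compression matrix has orthonormal columns,
so whitened noise stays white.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .operators import CoilMaps, KSpaceBundle


@dataclass
class CompressionReport:
    n_retained: int
    singular_values: np.ndarray       # non-increasing
    snr_loss: float                   # predicted mean relative SNR loss
    matrix: np.ndarray                # (C, C') orthonormal columns


def compress_coils(maps: CoilMaps, y: KSpaceBundle | np.ndarray | None = None,
                   snr_loss_budget: float = 0.1,
                   support: np.ndarray | None = None):
    """Compress coils to the fewest virtual channels within an SNR budget.

    The predicted SNR loss of retaining C' channels is
    ``1 - mean(rss_projected / rss)`` over the object support (sensitivity
    energy retention).  Returns ``(maps', y', report)``; ``y'`` is None when
    no data are supplied.
    """
    if not 0 < snr_loss_budget < 1:
        raise ValueError("snr_loss_budget must lie in (0, 1)")
    c = maps.n_coils
    rss = maps.rss()
    if support is None:
        support = rss > 0.05 * rss.max()
    smat = maps.maps.reshape(c, -1)[:, support.ravel()].T   # (Nsup, C)
    _, svals, vh = np.linalg.svd(smat, full_matrices=False)
    v = vh.conj().T                                          # (C, C)

    rss_sup = rss[support]
    proj = smat @ np.conj(v)          # virtual-channel coefficients, support
    energy = np.abs(proj) ** 2
    cum = np.cumsum(energy, axis=1)
    n_retained = c
    loss = 0.0
    for cp in range(1, c + 1):
        lp = float(1.0 - (np.sqrt(cum[:, cp - 1]) / rss_sup).mean())
        if lp <= snr_loss_budget:
            n_retained, loss = cp, lp
            break
    if n_retained == c:
        loss = 0.0
        warnings.warn("SNR budget admits no compression; returning all "
                      "channels")
    mat = v[:, :n_retained]
    vmaps = np.tensordot(mat.conj().T, maps.maps, axes=(1, 0))
    maps_c = CoilMaps(vmaps)
    report = CompressionReport(n_retained, svals, loss, mat)
    if y is None:
        return maps_c, None, report
    if isinstance(y, KSpaceBundle):
        y_c = replace(y, y=y.y @ np.conj(mat))
    else:
        y_c = np.asarray(y) @ np.conj(mat)
    return maps_c, y_c, report
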