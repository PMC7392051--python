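"""Robust per-segment outlier statistics and rejection weights.

Under the true model with whitened noise, per-profile losses (summed squared
residual magnitudes over coils) follow a chi-squared law, so segments whose
residuals are anomalously high can be detected and down-weighted.  To be
insensitive to the underlying signal, trimmed statistics are computed on a
logarithmic scale: for each segment m and centile c(b), ``r_b[m]`` is the
100 c(b)% centile of ``log r[m, e]`` over the segment's profiles.  Across
segments, a robust scale and mean are derived by matching lower-tail
Gaussian quantiles,

    sigma_b = (P_cU - P_cL) / (sqrt(2) (erfcinv(2 cL) - erfcinv(2 cU)))
    mu_b    = P_(cU+cL)/2 + sqrt(2) sigma_b erfcinv(cU + cL)

with cU = 0.25, cL = 0.125 (both below the median, so high outliers do not
contaminate the estimates; the constants are fixed by requiring exact
consistency on Gaussian samples, q_p = mu - sqrt(2) sigma erfcinv(2p)).
The normalized average ``rbar[m] = mean_b (r_b[m] - mu_b) / sigma_b`` is
converted to a Bonferroni-corrected one-sided Gaussian tail weight

    w[m] = min(M erfc(rbar[m] / sqrt(2)) / (2 tau_w), 1)

so that, under the null, about a fraction tau_w of experiments reject any
segment at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, erfcinv

DEFAULT_C_UPPER = 0.25
DEFAULT_C_LOWER = 0.125
DEFAULT_TAU_W = 0.05
DEFAULT_N_CENTILES = 21


@dataclass
class SegmentWeights:
    """Per-segment robustness weights and the statistics behind them."""

    w: np.ndarray                 # (M,) in [0, 1]
    rbar: np.ndarray              # (M,) normalized averaged statistic
    rb: np.ndarray                # (M, B) log-loss centiles
    centiles: np.ndarray          # (B,) strictly increasing in (0, 1)
    sigma: np.ndarray             # (B,)
    mu: np.ndarray                # (B,)
    tau_w: float

    def __post_init__(self) -> None:
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("weights must lie in [0, 1]")
        if self.centiles.size < 1 or np.any(np.diff(self.centiles) <= 0) \
                or np.any((self.centiles <= 0) | (self.centiles >= 1)):
            raise ValueError("centiles must be strictly increasing in (0, 1)")


def centile_statistics(loss_table: list[np.ndarray],
                       centiles: np.ndarray) -> np.ndarray:
    """Per-segment centiles of the log per-profile losses, (M, B).

    Linear interpolation between order statistics; zero losses are clamped
    at machine epsilon before the log (with a warning).
    """
    centiles = np.asarray(centiles, dtype=float)
    out = np.empty((len(loss_table), centiles.size))
    tiny = np.finfo(float).tiny
    for m, losses in enumerate(loss_table):
        losses = np.asarray(losses, dtype=float)
        if losses.size < 2:
            raise ValueError(f"segment {m} has fewer than 2 profiles")
        if np.any(losses <= 0):
            warnings.warn("non-positive per-profile loss clamped before log")
            losses = np.maximum(losses, tiny)
        out[m] = np.quantile(np.log(losses), centiles)
    return out


def robust_scale_mean(rb: np.ndarray, c_upper: float = DEFAULT_C_UPPER,
                      c_lower: float = DEFAULT_C_LOWER):
    """Gaussian-quantile-matched scale and mean across segments, per centile.

    Returns ``(sigma, mu)`` of shape (B,); exact on Gaussian samples in the
    large-M limit.  Requires M >= 4.
    """
    rb = np.atleast_2d(rb)
    if rb.shape[0] < 4:
        raise ValueError("need at least 4 segments for robust statistics")
    if not 0 < c_lower < c_upper < 0.5:
        raise ValueError("centile levels must satisfy 0 < cL < cU < 0.5")
    q_u = np.quantile(rb, c_upper, axis=0)
    q_l = np.quantile(rb, c_lower, axis=0)
    denom = np.sqrt(2.0) * (erfcinv(2 * c_lower) - erfcinv(2 * c_upper))
    sigma = (q_u - q_l) / denom
    mid = np.quantile(rb, 0.5 * (c_upper + c_lower), axis=0)
    mu = mid + np.sqrt(2.0) * sigma * erfcinv(c_upper + c_lower)
    return sigma, mu


def segment_weights(rb: np.ndarray, sigma: np.ndarray, mu: np.ndarray,
                    tau_w: float = DEFAULT_TAU_W,
                    centiles: np.ndarray | None = None) -> SegmentWeights:
    """Bonferroni-corrected one-sided tail weights from the centile table."""
    if not 0 < tau_w < 1:
        raise ValueError("tau_w must lie in (0, 1)")
    rb = np.atleast_2d(rb)
    m = rb.shape[0]
    if centiles is None:
        centiles = np.linspace(0.25, 0.75, rb.shape[1])
    if np.any(sigma <= 0):
        # degenerate spread: accept everything
        w = np.ones(m)
        rbar = np.zeros(m)
    else:
        rbar = ((rb - mu) / sigma).mean(axis=1)
        w = np.minimum(m * erfc(rbar / np.sqrt(2.0)) / (2.0 * tau_w), 1.0)
    return SegmentWeights(w, rbar, rb, np.asarray(centiles, float),
                          np.atleast_1d(sigma), np.atleast_1d(mu), tau_w)


def centile_grid(voxel_mm: float, n_centiles: int = DEFAULT_N_CENTILES) -> np.ndarray:
    """Centile interval 0.5 + (0.35 / max(voxel, 1)) [-1, 1], densely sampled."""
    half = 0.35 / max(voxel_mm, 1.0)
    return 0.5 + np.linspace(-half, half, n_centiles)


def reject_and_weight(model, x: np.ndarray, y: np.ndarray,
                      voxel_mm: float | None = None,
                      tau_w: float = DEFAULT_TAU_W,
                      n_centiles: int = DEFAULT_N_CENTILES,
                      max_voxel_mm: float = 2.0) -> SegmentWeights:
    """Compute segment weights from current residuals and attach them.

    Rejection runs only at resolutions of ``max_voxel_mm`` (2 mm) or finer;
    at coarser levels all weights are 1 (no-op).  The centile grid is
    resolution dependent per :func:`centile_grid`.
    """
    m = model.n_segments
    if voxel_mm is None:
        voxel_mm = model.spacing
    if voxel_mm > max_voxel_mm:
        sw = SegmentWeights(np.ones(m), np.zeros(m),
                            np.zeros((m, n_centiles)),
                            centile_grid(voxel_mm, n_centiles),
                            np.ones(n_centiles), np.zeros(n_centiles), tau_w)
        model.weights = sw.w
        return sw
    centiles = centile_grid(voxel_mm, n_centiles)
    rb = centile_statistics(model.loss_table(x, y), centiles)
    sigma, mu = robust_scale_mean(rb)
    sw = segment_weights(rb, sigma, mu, tau_w, centiles)
    model.weights = sw.w
    model._wmask_cache = None  # weights changed; invalidate the normal cache
    return sw
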