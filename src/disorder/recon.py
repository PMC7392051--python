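"""Joint rigid-motion estimation and image reconstruction.

The joint problem ``min_{x, theta} || A F S T(theta) x - y ||^2`` is a
separable nonlinear least squares problem.  It is addressed by alternating:

* a conjugate-gradient (CG) update of the image on the normal equations of
  the (weighted) linear subproblem at fixed motion, and
* a Levenberg-Marquardt (LM) update of each motion state at fixed image,
  using analytic per-parameter Jacobians, per-state damping heuristics and a
  backtracking line search (states decouple given the image).

Initialization is the zero-motion condition, so the first step is a standard
SENSE reconstruction.  A spatial multiresolution pyramid (2x subsampling)
solves coarse levels first and promotes image and motion estimates; per-state
provisional-convergence flags (update below tau) save motion work and are
reset at iterations ``i = n(n-1)/2 + 1`` to account for the impact of the
refreshed reconstruction.  Progress is logged in effective iterations ``j``:
one application of the encoding or decoding operator for one motion state
and one coil at full resolution costs 1 (coarse levels cost 4^-(L-l) in 2D).

On synthetic data where the true motion ``theta*`` is known, convergence to
the global basin is certified by the criterion ``r(x, theta) <= r(x_ref,
theta*)`` with the reference loss computed from a motion-aware
reconstruction at the true parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import motion as mo
from . import operators as op


class ReconDivergence(RuntimeError):
    """CG loss increased beyond tolerance (inconsistent model or data)."""


@dataclass
class ReconConfig:
    """Solver settings for the aligned reconstruction."""

    levels: int = 1                  # multiresolution levels L (1 = single scale)
    cg_iters_joint: int = 1          # CG iterations per joint iteration
    lm_iters_joint: int = 1          # LM iterations per joint iteration
    max_joint_iters: int = 60        # outer iterations across all levels
    j_max: float = np.inf            # effective-iteration budget
    tau_translation: float = 0.05    # mm per mm of voxel size (x voxel_l)
    tau_rotation: float = 0.02       # deg per mm of voxel size (x voxel_l)
    cg_sat_rtol: float = 1e-3        # saturation: rel. loss drop over window
    cg_sat_window: int = 3
    cg_max_iters: int = 30
    cg_final_rtol: float = 2e-4      # tighter saturation for reference and
    cg_final_window: int = 4         # consolidation reconstructions
    cg_final_iters: int = 60
    lm_damping_init: float = 1e-2    # x trace(J^H J)/dof
    lm_damping_up: float = 10.0
    lm_damping_down: float = 2.0
    lm_max_backtracks: int = 5
    soft_mask_start: float = 0.8     # raised cosine: 1 inside, 0 at `stop`
    soft_mask_stop: float = 1.0      # (fractions of the FOV radius)
    mode: str = "criterion"          # or "flags": stop on converged flags only
    subdivide_depth: int = 0         # intra-shot binary subdivision depth
    dtype: type = np.complex128
    state_chunk: int = 64

    def __post_init__(self) -> None:
        if self.levels < 1 or self.max_joint_iters < 1:
            raise ValueError("invalid reconstruction configuration")


def n_levels(voxel_mm: float, coarsest_mm: float = 4.0) -> int:
    """Pyramid depth: floor(log2(coarsest / voxel)) + 1 (2x subsampling,
    operating at a minimum resolution of ``coarsest_mm``)."""
    if voxel_mm > coarsest_mm:
        return 1
    return int(np.floor(np.log2(coarsest_mm / voxel_mm))) + 1


def soft_mask(shape: tuple[int, int], start: float = 0.8,
              stop: float = 1.0) -> np.ndarray:
    """Raised-cosine spatial apodization confining the solution support.

    1 inside ``start`` x FOV radius, 0 outside ``stop`` x FOV radius.
    """
    n2, n3 = shape
    u2 = (np.arange(n2) - n2 // 2) / (n2 / 2)
    u3 = (np.arange(n3) - n3 // 2) / (n3 / 2)
    r = np.sqrt(u2[:, None] ** 2 + u3[None, :] ** 2)
    t = np.clip((r - start) / max(stop - start, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


@dataclass
class ConvergenceLog:
    """Per-joint-iteration solver diagnostics."""

    iteration: list[int] = field(default_factory=list)
    effective: list[float] = field(default_factory=list)   # j
    loss: list[float] = field(default_factory=list)        # r(x, theta)
    level: list[int] = field(default_factory=list)
    n_converged: list[int] = field(default_factory=list)
    damping: list[float] = field(default_factory=list)     # median LM damping

    def append(self, i: int, j: float, r: float, level: int,
               n_conv: int, damping: float) -> None:
        if not np.isfinite(r):
            raise ValueError("non-finite loss")
        if self.iteration and i <= self.iteration[-1]:
            raise ValueError("iteration counter must increase")
        self.iteration.append(int(i))
        self.effective.append(float(j))
        self.loss.append(float(r))
        self.level.append(int(level))
        self.n_converged.append(int(n_conv))
        self.damping.append(float(damping))

    def to_dict(self) -> dict:
        return {k: list(getattr(self, k)) for k in
                ("iteration", "effective", "loss", "level", "n_converged",
                 "damping")}


# ---------------------------------------------------------------------------
# CG image update


def cg_reconstruct(model: op.EncodingModel, y: np.ndarray,
                   x0: np.ndarray | None = None, n_iter: int | None = None,
                   saturate: bool = False, mask: np.ndarray | None = None,
                   sat_rtol: float = 1e-3, sat_window: int = 3,
                   max_iters: int = 30, divergence_tol: float = 0.1):
    """CG on the normal equations of the weighted linear subproblem.

    Solves ``min_z || W^(1/2) (E (mask * z) - y) ||`` and returns
    ``(mask * z, losses, z)``; warm starts must pass the *unmasked* variable
    ``z`` as ``x0`` so the apodization is not applied twice.  The
    data-consistency loss is tracked without extra operator applications and
    is non-increasing across iterations (a > 10% increase raises
    :class:`ReconDivergence`).  With ``saturate`` the loop stops when the
    relative loss decrease over ``sat_window`` iterations falls below
    ``sat_rtol``.
    """
    n2, n3 = model.shape
    if mask is None:
        mask = np.ones((n2, n3))
    mask = np.asarray(mask, dtype=float)
    rw = model.row_weights()
    y = np.asarray(y)
    ynorm2 = float((np.abs(y) ** 2).sum()) if rw is None else \
        float((rw[:, None] * np.abs(y) ** 2).sum())

    def A(v):
        return mask * model.normal(mask * v)

    # Jacobi preconditioner: for full sampling and zero motion the normal
    # operator is exactly diag(rss^2); with motion/undersampling it stays
    # diagonally dominated by the (density-scaled) coil energy.
    rss2 = model.maps.rss() ** 2
    density = model.n_rows / (n2 * n3)
    diag = mask ** 2 * rss2 * density
    precond = 1.0 / (diag + 0.05 * diag.mean() + 1e-30)

    b = mask * model.decode(y)
    z = np.zeros_like(b) if x0 is None else np.asarray(x0).astype(model.dtype)
    r = b - (A(z) if x0 is not None else 0.0)
    s = precond * r
    p = s.copy()
    rs = float(np.vdot(r, s).real)
    if n_iter is None:
        n_iter = max_iters
    losses = []
    best = z
    for it in range(n_iter):
        q = A(p)
        pq = float(np.vdot(p, q).real)
        if pq <= 0:
            break
        alpha = rs / pq
        z = z + alpha * p
        r = r - alpha * q
        s = precond * r
        rs_new = float(np.vdot(r, s).real)
        # data loss without extra applications:
        # r(x) = ||y||_W^2 - Re<z, b> - Re<z, r_cg>
        loss = ynorm2 - float(np.vdot(z, b).real) - float(np.vdot(z, r).real)
        if losses and loss > losses[-1] * (1.0 + divergence_tol) \
                and loss > ynorm2 * 1e-9:
            raise ReconDivergence(
                f"CG loss increased from {losses[-1]:.4g} to {loss:.4g} "
                f"at iteration {it}")
        losses.append(loss)
        best = z
        if saturate and len(losses) > sat_window:
            prev = losses[-1 - sat_window]
            if prev - losses[-1] < sat_rtol * max(prev, 1e-30):
                break
        if rs_new < 1e-28 * max(ynorm2, 1e-30):
            break
        p = s + (rs_new / rs) * p
        rs = rs_new
    return mask * best, losses, best


# ---------------------------------------------------------------------------
# LM motion update


@dataclass
class LMState:
    """Per-state damping and provisional-convergence flags."""

    damping: np.ndarray
    converged: np.ndarray

    @classmethod
    def for_states(cls, m: int) -> "LMState":
        return cls(np.full(m, np.nan), np.zeros(m, dtype=bool))


def _per_segment_loss(model: op.EncodingModel, x, y, states):
    yh = model.encode(x, states=states)
    pp = (np.abs(yh - y) ** 2).sum(axis=1)
    return np.array([pp[model.seg_rows(m)].sum() for m in states])


def lm_update_motion(model: op.EncodingModel, y: np.ndarray, x: np.ndarray,
                     lm: LMState, tau: np.ndarray,
                     damping_init: float = 1e-2, damping_up: float = 10.0,
                     damping_down: float = 2.0, max_backtracks: int = 5,
                     jac_chunk: int = 32) -> np.ndarray:
    """One LM pass over all non-converged motion states (image fixed).

    Builds the per-state Gauss-Newton system from the analytic transform
    Jacobian projected through coils, DFT and sampling mask, damps it with a
    per-state Levenberg factor, and accepts steps by a halving line search on
    the per-segment loss (never increasing it).  Accepted updates whose
    magnitude falls below ``tau`` (per parameter) set the state's provisional
    convergence flag; rejected passes increase damping.

    Returns the per-state applied update (zeros for skipped states); the
    model trace is updated in place.
    """
    m_states = model.n_segments
    if model.trace.n_effective != m_states:
        raise ValueError("motion update requires unbinned states")
    active = np.flatnonzero(~lm.converged)
    applied = np.zeros((m_states, model.trace.params.shape[1]))
    if active.size == 0:
        return applied
    params = model.trace.params
    n2, n3 = model.shape
    npar = params.shape[1]
    c = model.maps.n_coils

    yh = model.encode(x, states=active)
    pp = (np.abs(yh - y) ** 2).sum(axis=1)
    cur_loss = np.array([pp[model.seg_rows(m)].sum() for m in active])
    delta = np.zeros((active.size, npar))
    xc = np.asarray(x).astype(model.dtype, copy=False)
    for lo in range(0, active.size, jac_chunk):
        sel = active[lo:lo + jac_chunk]
        jimg = mo.rigid_jacobian2d(xc, params[sel], model.spacing)  # (G,3,n2,n3)
        jk = op.cfft2(jimg[:, :, None, :, :] * model._maps[None, None])
        jk = jk.reshape(len(sel), npar, c, n2 * n3)
        model.cost += len(sel) * npar * c * model.level_cost
        for g, mseg in enumerate(sel):
            flat = model.seg_flat[mseg]
            rows = model.seg_rows(mseg)
            J = np.transpose(jk[g][:, :, flat], (0, 2, 1)).reshape(npar, -1)
            res = (yh[rows] - y[rows]).reshape(-1)  # (Em*C,), matching J
            jhj = (np.conj(J) @ J.T).real
            jhr = (np.conj(J) @ res).real
            if np.isnan(lm.damping[mseg]):
                lm.damping[mseg] = damping_init
            lam = lm.damping[mseg]
            diag = np.maximum(np.diag(jhj), 1e-12 * max(np.trace(jhj), 1e-30))
            try:
                delta[lo + g] = np.linalg.solve(jhj + lam * np.diag(diag), -jhr)
            except np.linalg.LinAlgError:
                lm.damping[mseg] *= damping_up
                delta[lo + g] = 0.0

    # backtracking line search, batched over still-unaccepted states
    step = np.ones(active.size)
    accepted = np.zeros(active.size, dtype=bool)
    stuck = np.all(delta == 0, axis=1)
    for _ in range(max_backtracks + 1):
        trial = np.flatnonzero(~accepted & ~stuck)
        if trial.size == 0:
            break
        cand = params.copy()
        cand[active[trial]] += step[trial, None] * delta[trial]
        trial_model = model.with_trace(mo.MotionTrace(cand, model.trace.ndim))
        new_loss = _per_segment_loss(trial_model, x, y, active[trial])
        model.cost = trial_model.cost
        ok = new_loss < cur_loss[trial]
        for t, good in zip(trial, ok):
            if good:
                mseg = active[t]
                upd = step[t] * delta[t]
                params[mseg] += upd
                applied[mseg] = upd
                accepted[t] = True
                lm.damping[mseg] = max(lm.damping[mseg] / damping_down, 1e-30)
                if np.all(np.abs(upd) < tau):
                    lm.converged[mseg] = True
            else:
                step[t] *= 0.5
    for t in np.flatnonzero(~accepted):
        lm.damping[active[t]] *= damping_up
    model.trace.params = params
    return applied


# ---------------------------------------------------------------------------
# Multiresolution restriction


def restrict_level(bundle: op.KSpaceBundle, maps: op.CoilMaps,
                   trace: mo.MotionTrace, level: int, n_levels: int,
                   weights: np.ndarray | None = None,
                   dtype=np.complex128, state_chunk: int = 64):
    """Build the restricted (y, model) pair for pyramid level ``level``.

    Level ``n_levels`` is the identity restriction; level l keeps the
    centered spectral window at 2^(L-l)-fold reduced extent.  Coil maps are
    Fourier-cropped (value-preserving); segments whose profiles all fall
    outside the window are excluded at this level (their states carry over
    untouched).  Returns ``(y_l, model_l, seg_present)``.
    """
    order = bundle.order
    n2, n3 = order.grid.k2, order.grid.k3
    f = 2 ** (n_levels - level)
    m2, m3 = n2 // f, n3 // f
    lo2 = n2 // 2 - m2 // 2
    lo3 = n3 // 2 - m3 // 2
    spacing_l = bundle.spacing * f

    if f == 1:
        maps_l = maps
    else:
        km = op.cfft2(maps.maps)
        km = km[:, lo2:lo2 + m2, lo3:lo3 + m3]
        maps_l = op.CoilMaps(op.cifft2(km) * (m2 * m3) ** 0.5 / (n2 * n3) ** 0.5)

    rows_all = []
    seg_flat = []
    seg_present = []
    for m, rows in enumerate(order.segment_rows()):
        p = order.profiles[rows]
        keep = ((p[:, 0] >= lo2) & (p[:, 0] < lo2 + m2)
                & (p[:, 1] >= lo3) & (p[:, 1] < lo3 + m3))
        if not keep.any():
            continue
        seg_present.append(m)
        rows_all.append(rows[keep])
        pk = p[keep]
        seg_flat.append((pk[:, 0] - lo2) * m3 + (pk[:, 1] - lo3))
    y_l = bundle.y[np.concatenate(rows_all)]
    trace_l = mo.MotionTrace(trace.params[seg_present], trace.ndim)
    w_l = None if weights is None else weights[seg_present]
    model_l = op.EncodingModel(maps_l, seg_flat, trace_l, w_l, spacing_l,
                               level_cost=1.0 / f ** 2, dtype=dtype,
                               state_chunk=state_chunk)
    return y_l, model_l, np.asarray(seg_present)


# operation-style alias
multiresolution_restrict = restrict_level


def promote_image(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad the spectrum of a coarse image onto a finer grid."""
    n2, n3 = x.shape
    m2, m3 = shape
    k = op.cfft2(x)
    out = np.zeros(shape, dtype=k.dtype)
    lo2, lo3 = m2 // 2 - n2 // 2, m3 // 2 - n3 // 2
    out[lo2:lo2 + n2, lo3:lo3 + n3] = k
    return op.cifft2(out)


def intra_shot_subdivide(order, trace: mo.MotionTrace, depth: int):
    """Split each segment into 2^depth contiguous temporal sub-segments.

    Each sub-segment becomes a motion state initialized from its parent;
    returns ``(new_order, new_trace)`` with rebuilt segment labels.  The
    union of the child masks equals the parent mask.
    """
    from .orders import ViewOrder
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth == 0:
        return order, trace.copy()
    k = 2 ** depth
    new_seg = np.empty(order.n_profiles, dtype=np.int64)
    new_params = []
    nxt = 0
    min_rows = order.grid.k2  # heuristic floor for determinedness warning
    for m, rows in enumerate(order.segment_rows()):
        for part in np.array_split(rows, k):
            if part.size == 0:
                continue
            new_seg[part] = nxt
            new_params.append(trace.params[m])
            nxt += 1
            min_rows = min(min_rows, part.size)
    if min_rows < 3:
        warnings.warn("sub-segments with very few profiles: motion states "
                      "may be under-determined")
    new_order = ViewOrder(order.grid, order.profiles, new_seg,
                          order.traversal, order.tile_order, order.seed,
                          order.tiling)
    return new_order, mo.MotionTrace(np.asarray(new_params), trace.ndim)


# ---------------------------------------------------------------------------
# Joint solver


def _reset_points(max_iter: int) -> set[int]:
    """Iterations i = n(n-1)/2 + 1 at which convergence flags are reset."""
    pts, n = set(), 1
    while True:
        i = n * (n - 1) // 2 + 1
        if i > max_iter:
            return pts
        pts.add(i)
        n += 1


@dataclass
class JointResult:
    x: np.ndarray
    trace: mo.MotionTrace
    log: ConvergenceLog
    converged: bool
    success_iteration: int | None     # first i with r <= reference loss (finest level)
    effective_iterations: float
    reference_loss: dict | None


def recenter_trace(trace: mo.MotionTrace) -> np.ndarray:
    """Fix the gauge: remove the common rigid mode so the trace has zero
    mean, returning the removed mean ``mu`` (compose ``T(mu)`` into the
    image to keep the model equivalent).

    The joint problem only determines motion up to a common rigid transform
    shared between the image and all states; the solver's convention is a
    zero-mean trace.
    """
    mu = trace.params.mean(axis=0)
    inv = mo.invert_rigid2d(mu)
    trace.params = mo.compose_rigid2d(trace.params, inv[None, :])
    return mu


def reference_losses(bundle: op.KSpaceBundle, maps: op.CoilMaps,
                     trace_true: mo.MotionTrace, config: ReconConfig,
                     center: bool = True) -> dict:
    """Reference loss r(x_ref, theta*) per pyramid level (CG to saturation
    at the true motion parameters).

    With ``center`` (default) the true trace is first expressed in the
    solver's gauge convention (zero-mean common rigid mode), so the
    reference is comparable with zero-initialized joint estimates.
    """
    trace_true = trace_true.copy()
    if center:
        recenter_trace(trace_true)
    out = {}
    for level in range(1, config.levels + 1):
        y_l, model_l, _ = restrict_level(bundle, maps, trace_true, level,
                                         config.levels, dtype=config.dtype,
                                         state_chunk=config.state_chunk)
        msk = soft_mask(model_l.shape, config.soft_mask_start,
                        config.soft_mask_stop)
        _, losses, _ = cg_reconstruct(
            model_l, y_l, saturate=True, mask=msk,
            sat_rtol=config.cg_final_rtol, sat_window=config.cg_final_window,
            max_iters=config.cg_final_iters)
        out[level] = losses[-1]
    return out


def joint_solve(bundle: op.KSpaceBundle, maps: op.CoilMaps,
                config: ReconConfig,
                reference_loss: dict | None = None,
                weights: np.ndarray | None = None) -> JointResult:
    """Alternating CG/LM solution of the joint problem with multiresolution.

    ``reference_loss`` (per level, from :func:`reference_losses`) enables the
    global-convergence criterion; without it the solver runs until all
    motion states' provisional-convergence flags are set (or budgets are
    exhausted).
    """
    order = bundle.order
    trace = mo.MotionTrace(np.zeros((order.n_segments, 3)))
    if config.subdivide_depth:
        order, trace = intra_shot_subdivide(order, trace,
                                            config.subdivide_depth)
        bundle = op.KSpaceBundle(bundle.y, order, bundle.spacing,
                                 bundle.noise_std, bundle.attrs)
    log = ConvergenceLog()
    resets = _reset_points(config.max_joint_iters)
    i = 0
    x = None
    z = None  # unmasked CG variable, carried across warm starts
    success_iter = None
    converged = False
    cost_total = 0.0

    for level in range(1, config.levels + 1):
        y_l, model_l, present = restrict_level(
            bundle, maps, trace, level, config.levels,
            weights=weights, dtype=config.dtype,
            state_chunk=config.state_chunk)
        model_l.cost = cost_total
        msk = soft_mask(model_l.shape, config.soft_mask_start,
                        config.soft_mask_stop)
        voxel_l = model_l.spacing
        tau = np.array([config.tau_translation * voxel_l,
                        config.tau_translation * voxel_l,
                        config.tau_rotation * voxel_l])
        r_ref = None if reference_loss is None else reference_loss.get(level)
        lm = LMState.for_states(model_l.n_segments)

        z0 = None if z is None else promote_image(z, model_l.shape)
        x, _, z = cg_reconstruct(model_l, y_l, x0=z0, saturate=True, mask=msk,
                                 sat_rtol=config.cg_sat_rtol,
                                 sat_window=config.cg_sat_window,
                                 max_iters=config.cg_max_iters)
        level_done = False
        while not level_done:
            if i >= config.max_joint_iters or model_l.cost > config.j_max:
                break
            i += 1
            if i in resets:
                lm.converged[:] = False
            for _ in range(config.lm_iters_joint):
                lm_update_motion(model_l, y_l, x, lm, tau,
                                 damping_init=config.lm_damping_init,
                                 damping_up=config.lm_damping_up,
                                 damping_down=config.lm_damping_down,
                                 max_backtracks=config.lm_max_backtracks)
            x, cg_losses, z = cg_reconstruct(model_l, y_l, x0=z,
                                             n_iter=config.cg_iters_joint,
                                             mask=msk)
            r = cg_losses[-1] if cg_losses else \
                model_l.loss(x, y_l, weighted=weights is not None)[0]
            med_damp = float(np.nanmedian(lm.damping)) if np.any(
                np.isfinite(lm.damping)) else 0.0
            log.append(i, model_l.cost, r, level, int(lm.converged.sum()),
                       med_damp)
            crit_ok = r_ref is not None and r <= r_ref
            if crit_ok and level == config.levels and success_iter is None:
                success_iter = i
            if config.mode == "criterion" and crit_ok:
                level_done = True
                converged = level == config.levels
            elif lm.converged.all():
                # provisional convergence of all states: consolidate with a
                # full CG, recheck, and (in criterion mode) resume if unmet
                if level == config.levels:
                    mu = recenter_trace(model_l.trace)
                    if np.any(mu != 0):
                        z = mo.apply_rigid2d(z, mu, model_l.spacing)
                x, cg_losses, z = cg_reconstruct(
                    model_l, y_l, x0=z, saturate=True, mask=msk,
                    sat_rtol=config.cg_final_rtol,
                    sat_window=config.cg_final_window,
                    max_iters=config.cg_final_iters)
                r = cg_losses[-1] if cg_losses else r
                crit_ok = r_ref is not None and r <= r_ref
                if crit_ok and level == config.levels and success_iter is None:
                    success_iter = i
                if config.mode != "criterion" or r_ref is None or crit_ok:
                    level_done = True
                    converged = level == config.levels and (
                        r_ref is None or crit_ok)
                else:
                    lm.converged[:] = False
        # carry the level's motion estimates back to the full state list
        trace.params[present] = model_l.trace.params
        cost_total = model_l.cost

    # consolidation: full CG with the final (gauge-centered) parameters
    mu = recenter_trace(trace)
    if z is not None and np.any(mu != 0):
        z = mo.apply_rigid2d(z, mu, bundle.spacing)
    y_f, model_f, _ = restrict_level(bundle, maps, trace, config.levels,
                                     config.levels, weights=weights,
                                     dtype=config.dtype,
                                     state_chunk=config.state_chunk)
    model_f.cost = cost_total
    msk = soft_mask(model_f.shape, config.soft_mask_start,
                    config.soft_mask_stop)
    x, losses, z = cg_reconstruct(model_f, y_f, x0=z, saturate=True, mask=msk,
                                  sat_rtol=config.cg_final_rtol,
                                  sat_window=config.cg_final_window,
                                  max_iters=config.cg_final_iters)
    r_final = losses[-1] if losses else model_f.loss(x, y_f)[0]
    ref_f = None if reference_loss is None else reference_loss.get(config.levels)
    if ref_f is not None and r_final <= ref_f:
        if success_iter is None:
            success_iter = i
        converged = True
    return JointResult(x, trace, log, converged, success_iter,
                       model_f.cost, reference_loss)
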