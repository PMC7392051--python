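# Methods

## Problem and model

Volumetric Cartesian brain MRI acquires one readout line ("profile") of
k-space per repetition, traversing a K2 × K3 grid of phase-encode (PE)
coordinates over minutes. Head motion during the scan assigns different
rigid poses to different temporal *segments* (shots or sweeps) of the
acquisition. With coil sensitivities S, centered orthonormal DFT F,
per-segment sampling masks A_m and per-segment rigid transforms T(θ_m), the
measured multi-coil data follow

    y = A F S T(θ) x + n,          n ~ CN(0, σ² I)  (whitened),

and the aligned reconstruction is the separable nonlinear least squares
problem

    (x̂, θ̂) = argmin_{x, θ} r(x, θ) = argmin ‖A F S T(θ) x − y‖²₂ .

Whether this joint problem is solvable from the data alone depends on the
*view order*: if every segment samples the whole spectrum (distributed
coverage) with some incoherence between segments, the coil array's encoding
redundancy makes the per-segment poses identifiable; a sequential order
confines each segment to a spectral slab and the alternating solver stalls
in local optima. The package constructs the order family (sequential,
checkered, random-checkered, random; zig-zag and alternating zig-zag tile
orders), the measurement operator, and the solver, and validates the whole
pipeline on 2D synthetic data (the simulated plane plays the role of the
k2–k3 PE plane of a 3D scan; motion is assumed negligible within a single
readout).

## View orders

The PE grid (optionally restricted to the inscribed ellipse and decimated
by uniform acceleration factors R2 × R3, DC profile retained) is tiled by
U2 × U3 rectangles with U2·U3 = M cells. Cell indices are spectral
lexicographic within a tile and extend to all tiles by translation.

* **Checkered** — segment m takes, from every tile, the single cell that an
  electrostatic-repulsion rule maps to m, so each segment covers the whole
  plane with exactly one profile per tile. The repulsion rule is a
  deterministic greedy max–min: starting from the tile origin, each next
  segment's cell maximizes the minimum toroidal Euclidean distance to the
  ⌈M/4⌉ most recently placed cells, ties broken by smallest cell id.
* **Random-checkered** — the cell-to-segment map is an independent uniform
  permutation per tile, keyed by a counter-based RNG on (seed, tile id), so
  coverage is distributed in probability and incoherent across tiles.
* **Sequential / random** — the two limits: contiguous chunks of the
  lexicographic order, and contiguous chunks of a uniform permutation.

Within a segment, tiles are visited in a boustrophedon ("zig-zag") sweep
over k3 tile bands; central bands are reached mid-segment, which places the
contrast-defining center of k-space in the middle of each shot. The
alternating zig-zag reverses the sweep polarity on consecutive
segments/sweeps, which removes the large trajectory jumps (|dk3| spikes) at
sweep boundaries that would otherwise stress eddy-current behaviour in
steady-state sequences. (The tile sequence runs edge-to-edge, not
center-out: a center-out sequence would put central k-space at the
*beginning* of each shot rather than mid-shot.)

Boundary tiles that fall partly outside the grid simply lose the missing
cells (those segments are shorter); with elliptical sampling or
acceleration the same rule applies on the decimated grid.

## Rigid transforms

T(θ) applies the rotation about the FOV center (voxel index n//2 per axis)
followed by the translation. Translations are k-space linear phases;
rotations use the three-shear factorization
R(φ) = Shear₂(−tan φ/2) · Shear₃(sin φ) · Shear₂(−tan φ/2), each shear a
pure phase in a mixed (frequency × space) domain. Every factor is exactly
unitary on the periodic grid, the adjoint is the exact inverse, and shears
along one axis compose additively, so the rotate-then-unrotate round trip
is exact to machine precision. Angles above 45° are reduced by exact
quarter-turn index permutations about the same center. 3D volumes use
intrinsic Z–Y–X Euler angles, each rotation applied in its coordinate
plane by the same factorization.

Parameter derivatives are analytic: translation derivatives are −2πi k/n
phase ramps, rotation derivatives differentiate the three shear phases by
the chain rule. Each parameter is differentiated with the others held at
their current value (no second-order coupling), which is the "simplified
Jacobian" the motion update needs; agreement with central finite
differences is at the 1e−9 relative level on smooth images.

Two numerical caveats matter and are tested rather than assumed:

* The shear factorization is unitary but only *approximately* a group:
  composing two rotations differs from the single composed rotation at the
  ~1e−6 level on band-limited content and ~1e−3 on noise-bandwidth content
  (spectral shearing aliases near Nyquist). See "gauge convention" below.
* Object support must keep a margin from the FOV boundary (the synthetic
  phantom stays within 75% of the FOV radius) so the periodic wrap of the
  shears never touches object signal.

## Measurement operator

`EncodingModel` bundles maps, per-segment sample indices, the motion trace
(optionally binned into effective states) and per-segment robustness
weights. Encode transforms the image once per (effective) motion state,
multiplies by each coil map, applies the centered orthonormal 2D DFT and
gathers the segment's samples; decode is the exact adjoint (weighted when
W is present), and the fused normal operator E^H W E skips the
gather/scatter round trip. States are processed in chunks with all FFTs
batched over states and coils; on even grids the centered DFT is computed
in unshifted layout with the centering checkerboard folded into the maps
and a cached per-sample sign correction. Every encode/decode application
adds (states × coils × 4^{−(L−l)}) to the model's cost counter — the
effective-iteration unit j: one operator application for one motion state
and one coil at full resolution.

Per-profile losses r[m,e] = Σ_c |residual|² are kept alongside the total;
under the true model they follow a σ²/2 · χ²(2C) law, which the suite
verifies by a Kolmogorov–Smirnov test and the outlier module exploits.

**Noise calibration.** "Mean SNR of s dB" is concretized as: the per-sample
k-space noise std σ is chosen so that the mean over the object support of
the per-voxel complex noise std of the motion-free, unaccelerated SENSE
reconstruction (= σ/rss(v)) equals mean(|x|)/10^{s/20}. The definition is
recorded in the bundle configuration so experiments are self-describing.

## Synthetic data

`make_phantom` builds a deterministic brain-like complex phantom (scalp,
skull, parenchyma, ventricles, a deep nucleus, a bright cortical ribbon,
mild Gaussian-filtered texture, smooth polynomial phase), support within
75% of the FOV radius. `make_coilmaps` places C Gaussian magnitude lobes
on the FOV perimeter with low-order polynomial phases, rss-normalized to
~1 over the central FOV; C = 1 degenerates to a uniform map (plain
Fourier). `make_motion_trace` draws per-segment i.i.d. rotations uniform
on [−θ/2, θ/2] (about the FOV center) and translations uniform on
[−trans/2, trans/2]; the study default trans = 0 uses rotations only.
`simulate` composes generator → encode → noise; everything is a pure
function of (config, seed).

What the generator does *not* emulate: sequence contrast evolution across
a shot (MP-RAGE/FSE signal models), off-resonance/eddy-current/spin-history
confounders, inaccurate coil maps, non-rigid motion. Passing tests
therefore demonstrate the encoding-order and solver behaviour under the
stated statistical model, not robustness to those physical confounders.

## Joint solver

Initialization is the zero-motion condition, so the first image is a
standard SENSE reconstruction. Each pyramid level (2× spectral windowing
per level, coarsest at four times the voxel size; L =
⌊log2(4mm/Δy_min)⌋ + 1 when auto) starts with a soft-masked CG
reconstruction run to loss-reduction saturation, then alternates one LM
motion pass and one CG image iteration per joint iteration i:

* **CG** runs on the normal equations of the weighted linear subproblem
  with a raised-cosine spatial apodization (pass band to 80% of the FOV
  radius, zero from 100%) and a Jacobi preconditioner diag(mask²·rss²·
  sampling density) — exact for full sampling at zero motion. The data
  loss is tracked from CG inner products at no extra operator cost and is
  non-increasing; warm starts carry the unmasked CG variable so the
  apodization is never applied twice.
* **LM** updates each non-converged state independently (states decouple
  given x): Gauss–Newton system from the analytic Jacobian projected
  through coils/DFT/mask, Marquardt damping λ·diag(J^H J) with λ init
  1e−2, ×10 on rejection, ÷2 on acceptance, and a batched backtracking
  line search (≤ 5 halvings) that only ever accepts per-segment loss
  decreases. An accepted update below τ_Δθ = {0.05 mm, 0.02°} × Δy_l sets
  the state's provisional-convergence flag; flags are reset whenever
  i = n(n−1)/2 + 1 to account for the refreshed reconstruction.

When all flags are set the level consolidates with a full CG; in
criterion mode (synthetic studies) the solver then rechecks the
global-convergence criterion and, if unmet, resets the flags and resumes.
Motion estimated at a coarse level initializes the next level; segments
whose profiles all fall outside a coarse window are excluded there and
rejoin later. Intra-shot (temporal) subdivision splits each segment into
2^depth contiguous sub-segments, each a motion state initialized from its
parent.

**Global-convergence criterion.** On synthetic data, success is declared
when r(x̂, θ̂) ≤ r(x̂_ref, θ*), the reference loss being a CG-to-saturation
reconstruction at the true parameters (per level). Reference and
consolidation CGs use the same, tighter saturation rule (relative drop
< 2e−4 over 4 iterations by default) so the comparison is symmetric.

**Gauge convention.** The joint problem determines (x, θ) only up to a
common rigid transform shared between the image and all states. Because
the zero-initialized solver anchors its estimates near a zero-mean trace
while the drawn θ* has a nonzero sample mean, and because the shear
transforms are not an exact group on noise-bandwidth content, evaluating
the reference at the raw θ* would penalize the estimator's gauge by more
than the criterion's margin. Both sides therefore use the same convention:
the solver re-centers its trace to zero mean at consolidations (composing
the removed mean into the image), and `reference_losses` centers θ* the
same way before computing the reference. This is a coordinate convention,
not a tolerance.

**Study sizes.** The simulation studies run at 128² with 8 synthetic
coils in single precision, the solver capped at 30 joint iterations
(18–25 for the single-level and sequential arms, whose censored values
enter comparisons as lower bounds, which can only make those comparisons
harder to pass). These are the package's desk-scale study conditions;
effective iterations j normalize operator cost so budgets remain
comparable across levels and state counts.

## Robust outlier weighting

Per-segment trimmed statistics on the log per-profile losses
(resolution-dependent centile grid 0.5 ± 0.35/max(Δy,1), 21 points,
active only at Δy ≤ 2 mm), across-segment scale/mean by lower-tail
Gaussian quantile matching (c_U = 0.25, c_L = 0.125; constants fixed by
exact Gaussian consistency of q_p = μ − √2 σ erfc⁻¹(2p), which the suite
verifies by Monte Carlo), normalized average r̄[m], and Bonferroni-
corrected one-sided tail weights w[m] = min(M·erfc(r̄/√2)/(2τ_w), 1) with
τ_w = 0.05. Weights enter the reconstruction as per-sample multipliers
constant within a segment. Degenerate spread (σ_b = 0) falls back to all
weights 1.

## Coil and motion compression

Coil compression takes the SVD of the sensitivity matrix over the object
support and retains the fewest virtual channels whose sensitivity-energy
retention keeps the predicted mean SNR loss within budget (default 10%);
the projection is orthonormal, so whitening is preserved. Motion
compression Haar-transforms each parameter trace over time (edge-padded to
a power of two), zeroes detail coefficients below the per-parameter-type
threshold (the τ_Δθ values), reconstructs, and groups contiguous states
with identical reconstructed values into effective states whose parameters
are the mean of the originals; τ = 0 is the identity and the effective
count is non-increasing in τ.

## Regularized reconstruction

The final reconstruction option solves
‖W^{1/2}(E x − y)‖² + 2λ‖Ψx‖₁ by IRWLS: 2 outer reweightings (majorizing
|u| with the ε-smoothed quadratic, ε = 1e−3 × median |Ψx₀| fixed at entry)
of 3 preconditioned CG iterations each. Ψ defaults to a translation-
invariant (stationary) wavelet tight frame (db2, 2 levels; adjoint =
inverse); directional systems such as shearlets can be plugged in through
the same interface. λ = 0 reduces bit-compatibly to the plain CG
reconstruction. The adaptive λ rule is λ = t̂ · σ̂_res with t̂ a
normalized Rayleigh-quotient (stochastic) trace of the masked normal
operator (8 complex Rademacher probes, seeded) and σ̂_res a median-based
residual scale; it doubles with the noise std and vanishes on exact data,
and the values used are recorded in the solver info. The rule is this
package's own concretization of an adaptive-λ interface and is labelled as
such in logs.

## Known limitations

* 2D validation plane only for the full pipeline; 3D rigid transforms and
  Jacobians are implemented and tested at the operator level.
* The FFT-shear group error bounds how precisely large common-mode poses
  can be compared across gauges (~1e−3 relative on noisy content).
* The LM basin for a single segment shrinks with motion amplitude; the
  multiresolution pyramid mitigates but does not eliminate this (the
  sequential order's failures are the expected, physical behaviour).
* Uniform Cartesian sampling only; no variable density, no CAIPI shifts,
  no non-Cartesian trajectories; no modeling of off-resonance, eddy
  currents, spin history or fat–water effects.
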