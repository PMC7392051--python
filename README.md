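# disorder-mri

Rigid-motion-tolerant parallel MRI by **D**istributed and **I**ncoherent
**S**ample **O**rders for **R**econstruction **D**eblurring using
**E**ncoding **R**edundancy: Cartesian phase-encode view orders that spread
every temporal segment across the whole spectrum, plus a joint
retrospective motion-estimation / image-reconstruction solver that
exploits the coil array's redundancy — no navigators, sensors or training
data.

## Who this is for

MRI reconstruction researchers and sequence developers who want to (a)
generate and analyze checkered / random-checkered view orders for 3D
Cartesian scans, and (b) study or apply retrospective inter- and
intra-shot rigid motion correction on simulated or stored k-space data.

## Model

With coil sensitivities **S**, centered orthonormal DFT **F**, per-segment
sampling masks **A** and per-segment rigid transforms **T**(θ_m)
(translations as k-space phases, rotations as unitary FFT shears), the
data model is `y = A F S T(θ) x + n` and the aligned reconstruction is the
separable nonlinear least squares problem

```
(x̂, θ̂) = argmin_{x,θ} ‖ A F S T(θ) x − y ‖²₂
```

solved by alternating conjugate-gradient image updates and per-segment
Levenberg–Marquardt motion updates (analytic Jacobians), with spatial
multiresolution, provisional-convergence flags, optional robust outlier
segment weighting `w[m] = min(M·erfc(r̄[m]/√2)/(2τ_w), 1)`, coil and
motion (Haar-binning) compression, and an optional ℓ1-regularized IRWLS
final reconstruction. On synthetic data, global convergence is certified
by `r(x̂, θ̂) ≤ r(x̂_ref, θ*)` against a reconstruction at the true motion.

## Worked example

Simulate a 128² brain-like phantom acquired with a random-checkered order
in M = 64 segments, each with its own random rotation drawn from ±5°, at
30 dB SNR — then jointly estimate the motion and the image:

```python
import numpy as np
from disorder import synth, recon

cfg = synth.SimulationConfig(n=128, n_coils=8, n_segments=64,
                             traversal="random_checkered",
                             theta_deg=10.0, snr_db=30.0, seed=1)
ds = synth.simulate(cfg)

rc = recon.ReconConfig(levels=2, dtype=np.complex64)
refs = recon.reference_losses(ds.bundle, ds.maps, ds.trace_true, rc)
res = recon.joint_solve(ds.bundle, ds.maps, rc, reference_loss=refs)

rot_err = res.trace.params[:, 2] - (ds.trace_true.params[:, 2]
                                    - ds.trace_true.params[:, 2].mean())
print(f"converged: {res.converged} at joint iteration {res.success_iteration}")
print(f"max |rotation error|: {np.abs(rot_err).max():.3f} deg")
print(f"final loss / reference: {res.log.loss[-1] / refs[rc.levels]:.4f}")
```

prints

```
converged: True at joint iteration 12
max |rotation error|: 0.114 deg
final loss / reference: 1.0011
```

i.e. the solver recovers all 64 rotations (drawn from a 10°-wide interval)
to better than a tenth of a degree and reaches the loss level of a
reconstruction given the true motion (the logged trajectory is the loss
after the single CG iteration of each joint step; the consolidating CG at
termination takes it to or below the reference, which is what `converged`
reports). Motion errors are reported in the solver's gauge: the estimated
trace is zero-mean, so the true rotations are compared after removing
their sample mean — the common pose is shared between the image and the
trace and is not observable.

The same pipeline is scriptable from the shell:

```
disorder order --k2 32 --k3 32 --traversal random_checkered \
         --u2 4 --u3 4 --out order.csv --plot segments.png
disorder simulate --config sim.json --out bundle.h5 --gt gt.nii.gz
disorder reconstruct --bundle bundle.h5 --levels 2 --out recon.nii.gz \
         --trace trace.csv --log log.json
disorder benchmark --traversals random_checkered,sequential \
         --segments 16 --thetas 5 --seeds 0,1,2 --out results.csv
```

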