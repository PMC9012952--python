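# slctkd

Constrained Tucker-2 decomposition of multi-subject fMRI data, with
core-tensor feature extraction and subject clustering.

## The problem

Group fMRI studies produce a voxels × time × subjects tensor
X ∈ ℝ^{V×T×K}.  Blind source separation of such data must recover spatial
maps (SMs) and time courses (TCs) shared across subjects while preserving
how strongly — and in what spatial/temporal pattern — each subject
expresses them.  A CP decomposition forces a diagonal core and discards
that per-subject structure; an unconstrained Tucker-2 model keeps it but is
rotation-ambiguous and noise-sensitive.

`slctkd` fits the sparsity- and low-rank-constrained Tucker-2 model

    min ‖X − G ×₁ S ×₂ B − E‖²_F + μ_S‖S‖²_F + μ_B‖B‖²_F
        + δ‖S‖_p + λ‖G‖₁ + γ‖E‖₁ ,     0 < p ≤ 1,

where S (V×N) and B (T×N) are shared SMs/TCs, G (N×N×K) is the core tensor
and E a sparse residual.  The ℓp term encodes the spatial sparsity of real
activations; the ℓ1 terms keep core and residual sparse; the Frobenius
terms act as a low-rank pull.  Optimisation is ADMM with a split core
variable (solved per subject as a discrete-time Sylvester equation) and
half-quadratic splitting with Newton steps for the ℓp term; penalties grow
geometrically (η) per iteration.  See `docs/methods.md` for the full
update scheme, parameter table and design rationale.

From the fitted core the package extracts subject-specific intensities
(mode-3 fibres of G), spatial and temporal feature matrices (mode-1/mode-2
fibres), and clusters subjects on those features with k-means — separating
subgroups whose activation patterns differ even when every subject
expresses the same components.

A synthetic benchmark generator (`slctkd.simulate`) reproduces the
standard simulation protocol for this task: 8 sparse fMRI-like sources on
a 60×60 grid (task-related, transiently task-related, artifact-like),
100-point TCs, 10 subjects with up to 10% random per-subject deactivation
of active voxels, and Gaussian noise at a prescribed SNR
(20·log₁₀(σ_s/σ_n)).

## Worked example

```python
import numpy as np
from slctkd import (SimulationSpec, generate_dataset, fit_slctkd, HyperParams,
                    match_components, core_from_data, subject_intensities)

spec = SimulationSpec(seed=1, snr_db=5.0)        # 3600 voxels x 100 TRs x 10 subjects
X, truth = generate_dataset(spec)

fit = fit_slctkd(X, HyperParams(n_components=8))
print(f"stopped after {fit.n_iterations} iterations ({fit.converged_reason}), "
      f"final relative residual eps = {fit.eps_trace[-1]:.2e}")

refs = [0, 1, 5]                                  # task + two transient sources
m = match_components(fit.S, fit.B, truth.S_true[:, refs], truth.B_true[:, refs])
for r, name in enumerate(["task", "transient-1", "transient-2"]):
    print(f"{name:12s} -> component {m.permutation[r]:2d}   "
          f"|rho| SM = {m.rho_sm[r]:.3f}   |rho| TC = {m.rho_tc[r]:.3f}")

G = core_from_data(X.values, fit.E, fit.S, fit.B)
task = int(m.permutation[0])
c = subject_intensities(G, task, task, normalize=True)
rho = abs(np.corrcoef(c, truth.subject_scales[:, 0])[0, 1])
print(f"subject intensities (task component): {np.round(c, 2)}")
print(f"correlation with planted subject scales: {rho:.3f}")
```

Output:

```
stopped after 56 iterations (eps_min), final relative residual eps = 8.33e-08
task         -> component  0   |rho| SM = 0.978   |rho| TC = 0.991
transient-1  -> component  2   |rho| SM = 0.987   |rho| TC = 0.972
transient-2  -> component  1   |rho| SM = 0.983   |rho| TC = 0.978
subject intensities (task component): [0.91 0.91 0.93 1.   0.78 0.91 0.95 0.94 0.83 0.88]
correlation with planted subject scales: 0.997
```

The relative residual ε = ‖X − G ×₁ S ×₂ B − E‖_F/‖X‖_F drops below the
10⁻⁷ stopping tolerance in 56 iterations.  Each planted source of interest
is matched to an estimated component with absolute Pearson correlation
|ρ| ≈ 0.97–0.99 for both its map and its time course, and the task-column
intensities read out of the core track the planted per-subject amplitudes
at |ρ| = 0.997.

## Command line

The same pipeline is exposed as a CLI:

```sh
slctkd simulate --snr 10 --seed 1 --out sim.npz
slctkd fit --input sim.npz --order 20 --out results.h5 --trace trace.csv
slctkd evaluate --est results.h5 --truth sim.npz --out metrics.tsv
slctkd features --est results.h5 --input sim.npz --component-i 0 \
    --clusters 2 --out-prefix feat
```

`fit` accepts a JSON/YAML config mirroring `HyperParams`, logs
(iter, ε, Δε, α, β) per iteration, and stores a provenance record (config,
seed, library versions) in the output HDF5.  Real data enters either as a
packed NPZ/HDF5 tensor or as per-subject 4-D NIfTI volumes plus a binary
brain mask via `slctkd.io.load_fmri_tensor`, which flattens masked voxels
in a documented column-major scan order and can write component maps back
to volume space.

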