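# equitomo

Self-supervised denoising and missing-wedge correction for cryo-electron
tomograms.

## The problem

A cryo-ET tilt series covers a limited angular range (typically ±60°), so
filtered backprojection (FBP) leaves a double wedge of 3D Fourier space
empty — the *missing wedge* — producing anisotropic streaking, on top of
severe noise from low-dose imaging. `equitomo` trains a 3D restoration
network **without any clean reference data**, using only two independently
noisy reconstructions of the same field of view (obtained by splitting
detector frames or tilt angles), and corrects both defects at once.

## The method

Let `A = F⁺F` be the orthogonal projector that zeroes Fourier components
inside the missing wedge, and let `y₀, y₁ = Nᵢ(A(x))` be two independent
noisy observations of a subtomogram `x`. A network `f_ϕ` is trained with
two complementary self-supervision signals:

* **Noise2Noise data fidelity** — one observation predicts the other:
  `L_N2N = ‖f_ϕ(y₀) − y₁‖²` (symmetrized over the swap `y₀ ↔ y₁`).
  Because the noise realizations are independent, this equals the
  supervised objective plus a constant, but it only constrains the
  *observed* region of Fourier space.
* **Rotation equivariance** — subtomogram statistics are invariant under
  rotations while the wedge is not. With `G` the 40 interpolation-free
  cube rotations/flips (24 proper rotations minus identity and the three
  axis-aligned 180° rotations, each also composed with a mirror), `R_g`
  the action on volumes and `A_g = R_g A R_g⁻¹`, the current outputs
  `x̂ᵢ = f_ϕ(yᵢ)` serve as plug-in estimates of `x` and

  `L_EQ = ‖A_g[ f_ϕ(A(R_g x̂₀)) − R_g x̂₁ ]‖²` (swap-symmetrized),

  i.e. the network must restore a rotated, re-corrupted version of its own
  output. Gradients flow through **both** applications of `f_ϕ`.

The total objective is `L_N2N + λ·L_EQ` with `λ = 2`, minimized with Adam
(default protocol: 72³ patches, batch 8, 50 000 iterations; fine-tuning
from a pretrained network needs only 5000). Inference applies the trained
network **twice** — denoise each observation, average, then refine the
wedge fill — tiling large volumes into overlapping patches blended with a
partition-of-unity window.

Consistency between two independently processed half-reconstructions is
quantified by the Fourier shell correlation (FSC).

## Worked example

```python
import numpy as np
from equitomo import (EquivariantDenoiser, NoiseModel, PhantomSpec,
                      TiltScheme, generate_paired_dataset)

# two independently noisy ±60° FBP observations of a synthetic 48³ phantom
data = generate_paired_dataset(
    PhantomSpec(shape=(48, 48, 48), seed=0),
    TiltScheme(-60, 60, 3),
    NoiseModel("gaussian", sigma=2.0, seed=100),
)

est = EquivariantDenoiser(patch_size=24, batch_size=2, max_iterations=150,
                          base_channels=8, seed=0)
est.fit(data)
restored = est.transform(data[0])

from equitomo import make_wedge_mask
from equitomo.inference import evaluate_synthetic
m = make_wedge_mask((48, 48, 48), TiltScheme(-60, 60, 3))
print({k: round(v, 3) for k, v in
       evaluate_synthetic(est.network_, data[0], m, patch=24).items()})
```

At this smoke scale (a few minutes on one CPU core) the run prints

```
{'psnr_input': 17.161, 'psnr_recon': 19.12, 'wedge_energy_input': 0.0,
 'wedge_energy_recon': 0.006, 'wedge_energy_clean': 0.028,
 'wedge_corr_input': 0.0, 'wedge_corr_recon': 0.04}
```

— PSNR against the known clean phantom rises by ~2 dB, and the missing
wedge, exactly empty in the FBP input (`wedge_corr_input = 0`), acquires
spectral content positively correlated with the ground truth.

The same pipeline is available from the shell:

```bash
equitomo simulate --out run/ --size 48 --seed 1
equitomo train --y0 run/y0.mrc --y1 run/y1.mrc --out run/net.npz \
               --patch-size 24 --batch-size 2 --max-iterations 150 --seed 1
equitomo predict --checkpoint run/net.npz --y0 run/y0.mrc --y1 run/y1.mrc \
                 --out run/restored.mrc --patch-size 24
equitomo fsc --a run/restored.mrc --b run/x.mrc --out run/fsc.tsv
```

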