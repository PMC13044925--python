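# Methods

This note records the models, conventions, and numerical choices behind
`equitomo`, and what the synthetic experiments do and do not demonstrate.

## Acquisition model and conventions

Volumes are `(z, y, x)` ndarrays; the tilt axis is `y` and the beam at
zero tilt runs along `z`. The projection at tilt θ is the line integral
along the beam; `project` evaluates it through the Fourier slice theorem:
the centered 3D FFT is sampled on the plane `(u·sinθ, k_y, u·cosθ)` with
trilinear interpolation, after zero-padding the z/x axes by an
oversampling factor (default 2) to keep interpolation error small. `fbp`
is the adjoint-style inverse: each projection's 2D FFT is spread onto its
plane with bilinear weights, accumulated values are divided by
accumulated weights, and untouched frequencies stay zero. On a smooth
compact 32³ phantom, dense ±90°/1° sampling reconstructs with ≈3% NRMSE;
a ±60° scheme leaves ≤10⁻³ relative energy in the wedge interior
(excluding a 2-voxel boundary shell over which the bilinear gridding
spreads slice energy).

The corruption operator `A` is a hard binary mask in Fourier space: a
frequency `(k_x, k_z)` is observed iff its angle from the `k_x` axis lies
in `[θ_min, θ_max]` after Hermitian symmetrization; the mask is
independent of `k_y` and the origin is always observed. Between-tilt gaps
are treated as observed (the wedge is defined by the covered interval,
not the discrete tilt list); a cosine soft edge is available
(`soft_edge_deg`) but off by default, keeping `A` an exact orthogonal
projector. On even-sized grids the Nyquist planes are symmetrized
explicitly so `mask(k) = mask(−k)` holds in wrap-around index arithmetic.

## The rotation/flip sampling set

The equivariance loss draws from the 40 signed-permutation volume
transforms: the 24 proper cube rotations minus the identity and the three
axis-aligned 180° rotations (20 elements, det +1), each also composed
with a fixed mirror (x-axis reversal; 20 elements, det −1). Excluding
only the *axis-aligned* 180° rotations is the unique reading consistent
with a 20-element proper part; edge-axis 180° rotations are retained.
Transforms act about the patch center `(N−1)/2`, which for signed
permutations reduces to an axis transpose plus axis reversals — exact for
any patch size, no interpolation. Element order is frozen
(lexicographic over the rotation part, proper then mirrored), so seeded
sampling is reproducible. `A_g = R_g A R_g⁻¹` is applied by index-
remapping the mask (`m_g[k] = m[Mᵀk mod N]`); the phase factors from the
half-integer center cancel under conjugation, and the identity is tested
exhaustively over all 40 elements.

## Losses

* Data fidelity: `½(‖f(y₀) − y₁‖² + ‖f(y₁) − y₀‖²)` (mean squared error,
  swap-symmetrized). With independent zero-mean noise this equals the
  supervised loss plus the noise variance — verified by Monte Carlo in
  the tests at 10⁵ samples, 2%.
* Equivariance: with plug-ins `x̂ᵢ = f(yᵢ)`, the residual
  `f(A(R_g x̂₀)) − R_g x̂₁`, masked by `A_g` before the squared norm, and
  symmetrized over the swap. Masking with `A_g` restricts the comparison
  to frequencies where the rotated target is data-grounded (its own
  original wedge, now at orientation g, is excluded); setting
  `mask_original_wedge=False` recovers the plain equivariant-imaging
  residual, which a unit test confirms against a direct computation.
  Gradients are **not** detached anywhere — the double application of the
  network is differentiated end to end (`detach_plugin=True` exists for
  ablation only).
* Total: `L_N2N + λ·L_EQ`, λ = 2 by default.

One group element is drawn uniformly per example per iteration; an
additional random swap (p = ½) is applied per example (a no-op for the
symmetrized losses, retained for the non-symmetrized configuration).

## Network and optimization

The restorer is a pluggable shape-preserving component; the default is a
small residual 3D U-Net (3×3×3 convs, leaky ReLU 0.1, 2× average-pool
down / nearest-neighbour up with additive skips, global residual path),
sized by `depth` and `base_channels`, He-initialized from a seed. The
network and all loss terms run on a built-in numpy reverse-mode autodiff
engine: convolutions are evaluated as 27 shifted 1×1 channel-mixing
matmuls (BLAS), and the two linear volume operators have closed-form
adjoints (`A` is self-adjoint; the adjoint of `R_g` is `R_{g⁻¹}`).
Backprop is validated by directional-derivative checks.

Optimization is Adam, learning rate 4·10⁻⁴ (a common setting for 3D
U-Nets at this batch size; the rate is not otherwise prescribed),
no schedule. Training stops at a fixed iteration budget (default 50 000;
fine-tuning 5000). The `mixed_precision` flag rounds activations to
float16 between layers (storage precision), while all FFT-based
operators always run in single precision or better. Training is
deterministic given the seed; a non-finite loss aborts with a
diagnostic.

## Subtomograms, tiling, inference

Patches are cubic, 0-based, half-open crops at identical positions in
both half-tomograms, sampled uniformly over an interest mask. The
built-in mask is a lightweight heuristic — a central z-slab intersected
with a local-standard-deviation quantile — intended as a stand-in for
dedicated lamella-masking tools; user-supplied mask volumes bypass it.
Because `A` is nonlocal, it does not commute with cropping (`AC ≠ CA`);
the per-patch application of `A` is the standard approximation, and a
test quantifies the commutator energy on a 64³ volume.

Inference tiles the volume with overlap `patch/4` (default), blends with
a strictly positive separable raised-cosine window renormalized to sum
to one (partition of unity: an identity network reproduces the input to
float32 precision), and applies the network in two full tile-blend
passes: denoise each observation, average, then restore the wedge. The
two-pass variant is the default because the second pass sees blended
context rather than patch seams; averaging between passes feeds the
highest-SNR volume into the wedge-refinement pass.

## Synthetic data

`generate_phantom` emulates the visual vocabulary of cellular tomograms —
spherical shells (membranes), finite rods (filaments), gaussian blobs
(particles) — at random poses with seeded determinism, deliberately
mixing rotationally symmetric and asymmetric content so the equivariance
loss is exercised nontrivially. Observations are
`y_i = A(fbp(add_noise(project(x))))` with independent noise seeds; the
final `A` removes residual gridding leakage so each observation satisfies
the corruption model exactly. Defaults: 48³ phantoms, ±60°/3° scheme,
gaussian noise σ = 2 on projections (observation SNR ≈ 1).

What this does **not** model: CTF, dose-dependent damage, detector MTF,
alignment errors, the spatial statistics of real cellular crowding, and
non-gaussian detector noise (a poisson-gaussian option exists). Passing
tests therefore demonstrate the correctness of the operators and the
training mechanics, and that the method denoises and fills the wedge on
model-consistent data — not field performance on real tomograms.

## Smoke-scale protocols

The full-scale defaults (72³ patches, batch 8, 50 000 iterations) are
impractical for a CPU test suite, so the experiments in the tests and in
`scripts/acceptance.py` use fixed smoke-scale protocols, chosen once:

* **Training efficacy**: one 48³ phantom pair, 24³ patches, batch 2,
  150 iterations, 3 seeds. Expectations: ≥50% reduction of the running
  total loss relative to the first iterations, and (majority of seeds)
  higher PSNR and higher wedge spectral correlation with the clean
  phantom for the double-applied reconstruction than for the FBP input.
* **Warm start**: pretrain 200 iterations on two phantoms (16³ patches),
  then on held-out phantoms compare 100 fine-tune iterations against 100
  from random init, same seeds; the fine-tuned run must reach a lower
  final loss in a majority of 3 seeds.

At this scale the wedge-correlation gain is small (≈0.03–0.07) — wedge
inpainting is the hardest part of the task and benefits most from the
full-scale budget — but it is consistently positive while the FBP input
is exactly zero by construction.

## Numerical choices and degenerate inputs

Projector identities are asserted at relative 10⁻⁵ in single precision.
FSC uses integer-radius shells (width 1 frequency voxel) up to the
inscribed Nyquist sphere, no taper or soft mask (the evaluation protocol
crops instead); `resolution_at_threshold` interpolates linearly and
returns Nyquist if the curve never crosses. Normalization rejects
zero-variance volumes; empty interest masks raise with advice to supply
a manual mask; patch sizes must divide by `2^(depth−1)`; non-cubic
patches are rejected by the group action and equivariance loss. PSNR of
identical volumes is reported as a capped sentinel (100 dB).

## Known limitations

The CPU engine makes full-scale training (50 000 iterations at 72³)
far slower than a GPU implementation — the package is faithful in
mechanism, not in throughput. The interest-mask heuristic is not a
substitute for dedicated masking tools on real lamellae. FSC between two
half-reconstructions measures consistency/stability, not resolution, and
aggressive denoising can inflate it; synthetic evaluations here always
report PSNR and wedge metrics against the known clean volume alongside.
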