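"""Training objective: Noise2Noise data fidelity plus masked equivariance.

Two self-supervision signals constrain the network ``f``:

* **Data fidelity (Noise2Noise).**  ``f`` applied to one noisy observation
  must predict the other: ``E ||f(y0) - y1||^2``.  Since both observations
  share the signal and have independent zero-mean noise, the minimizer
  matches the supervised regression target up to an additive constant
  (the noise variance) — no clean data needed.  The loss constrains only
  the measured (wedge-observed) content.

* **Equivariance.**  The distribution of subtomograms is (approximately)
  invariant under the finite rotation/flip set ``G``, while the wedge
  corruption ``A`` is not.  Using the current outputs ``x̂_i = f(y_i)`` as
  plug-in estimates of the clean patch, the network must restore a
  rotated, re-corrupted version of its own output:
  ``|| A_g [ f(A(R_g x̂_0)) - R_g x̂_1 ] ||^2`` (swap-symmetrized), where
  ``A_g = R_g A R_g^{-1}`` masks the original wedge in the rotated frame
  so the target is compared only where it is data-grounded (this masking
  is optional; disabling it yields the plain equivariant-imaging loss).
  Gradients flow through both applications of ``f``.

The total objective is ``n2n + λ · equivariance`` with ``λ = 2`` by
default, minimized with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .geometry import build_group
from .model import Network, NetworkSpec, build_network
from .phantoms import PairedObservation
from .subtomo import InterestMask, extract_pair, sample_patch_centers
from .wedge import WedgeMask, make_wedge_mask, rotate_mask

#: conventional warm-start budget: a tenth of a from-scratch run
FINETUNE_ITERATIONS = 5000

__all__ = [
    "LossConfig",
    "TrainConfig",
    "FINETUNE_ITERATIONS",
    "n2n_loss",
    "equivariance_loss",
    "total_loss",
    "train",
    "finetune",
]


@dataclass(frozen=True)
class LossConfig:
    """Weights and options of the training objective."""

    lambda_equiv: float = 2.0
    mask_original_wedge: bool = True
    swap_augment: bool = True
    detach_plugin: bool = False

    def __post_init__(self) -> None:
        if self.lambda_equiv < 0:
            raise ValueError("lambda_equiv must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    Defaults follow the full-scale protocol (patch 72, batch 8, 50 000
    iterations, Adam); smoke-scale runs override them.
    """

    patch_size: int = 72
    batch_size: int = 8
    max_iterations: int = 50_000
    learning_rate: float = 4e-4
    mixed_precision: bool = False
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    network: NetworkSpec = field(default_factory=NetworkSpec)

    def __post_init__(self) -> None:
        if self.patch_size < 4 or self.batch_size < 1 or self.max_iterations < 0:
            raise ValueError("patch_size/batch_size/max_iterations out of range")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def _as_batch(p: np.ndarray) -> Tensor:
    return Tensor(p[None, None])


def _maybe_detach(t: Tensor, detach: bool) -> Tensor:
    return Tensor(t.data.copy()) if detach else t


def n2n_loss(f: Network, y0: np.ndarray, y1: np.ndarray,
             symmetrize: bool = True) -> Tensor:
    """Noise2Noise data-fidelity term on one subtomogram pair."""
    if y0.shape != y1.shape:
        raise ValueError(f"pair shapes differ: {y0.shape} vs {y1.shape}")
    t0, t1 = _as_batch(y0), _as_batch(y1)
    l01 = ad.mse(f(t0), t1)
    if not symmetrize:
        return l01
    l10 = ad.mse(f(t1), t0)
    return ad.scale(ad.add(l01, l10), 0.5)


def _equi_direction(f: Network, xh_in: Tensor, xh_tgt: Tensor,
                    mask: np.ndarray, mask_g: np.ndarray | None,
                    g) -> Tensor:
    """One swap direction of the equivariance residual."""
    rot_in = ad.rotate(xh_in, g)
    recor = ad.wedge_project(rot_in, mask)  # A(R_g x̂_in)
    pred = f(recor)
    target = ad.rotate(xh_tgt, g)
    resid = ad.sub(pred, target)
    if mask_g is not None:
        resid = ad.wedge_project(resid, mask_g)  # restrict to data-grounded freqs
    return ad.mse(resid, Tensor(np.zeros_like(resid.data)))


def equivariance_loss(
    f: Network,
    y0: np.ndarray,
    y1: np.ndarray,
    g,
    m: WedgeMask,
    cfg: LossConfig = LossConfig(),
    plug_in: tuple[Tensor, Tensor] | None = None,
) -> Tensor:
    """Masked rotation-equivariance term on one subtomogram pair.

    ``plug_in`` may carry precomputed ``(f(y0), f(y1))`` graph nodes so the
    first network application is shared with the data-fidelity term.
    """
    if y0.ndim != 3 or len(set(y0.shape)) != 1:
        raise ValueError(f"equivariance loss needs cubic patches, got {y0.shape}")
    if plug_in is None:
        xh0, xh1 = f(_as_batch(y0)), f(_as_batch(y1))
    else:
        xh0, xh1 = plug_in
    xh0 = _maybe_detach(xh0, cfg.detach_plugin)
    xh1 = _maybe_detach(xh1, cfg.detach_plugin)
    mg = rotate_mask(g, m) if cfg.mask_original_wedge else None
    d0 = _equi_direction(f, xh0, xh1, m.mask, mg, g)
    if not cfg.swap_augment:
        return d0
    d1 = _equi_direction(f, xh1, xh0, m.mask, mg, g)
    return ad.scale(ad.add(d0, d1), 0.5)


def total_loss(
    f: Network,
    y0: np.ndarray,
    y1: np.ndarray,
    g,
    m: WedgeMask,
    cfg: LossConfig = LossConfig(),
) -> tuple[Tensor, float, float]:
    """Combined objective; returns (loss node, n2n value, equivariance value).

    The first application of ``f`` to each observation is shared between
    the two terms.
    """
    t0, t1 = _as_batch(y0), _as_batch(y1)
    xh0, xh1 = f(t0), f(t1)
    l01 = ad.mse(xh0, t1)
    l10 = ad.mse(xh1, t0)
    n2n = ad.scale(ad.add(l01, l10), 0.5)
    equi = equivariance_loss(f, y0, y1, g, m, cfg, plug_in=(xh0, xh1))
    tot = ad.add(n2n, ad.scale(equi, cfg.lambda_equiv))
    return tot, n2n.item(), equi.item()


def _normalize_pair(obs: PairedObservation) -> PairedObservation:
    """Joint zero-mean/unit-std normalization of a half-tomogram pair."""
    both = np.stack([obs.y0, obs.y1])
    mu, sd = float(both.mean()), float(both.std())
    if sd == 0:
        raise ValueError("observation pair has zero variance")
    return PairedObservation(
        (obs.y0 - mu) / sd, (obs.y1 - mu) / sd, obs.x,
        {**obs.provenance, "norm_stats": (mu, sd)},
    )


def train(
    dataset: list[PairedObservation],
    tcfg: TrainConfig,
    lcfg: LossConfig = LossConfig(),
    scheme=None,
    masks: list[InterestMask] | None = None,
    network: Network | None = None,
    progress: bool = False,
) -> tuple[Network, list[dict]]:
    """Minimize the combined objective over subtomograms of the dataset.

    Per iteration: pick a tomogram pair, sample ``batch_size`` patch
    centers (uniform over the interest mask), draw one group element per
    example, evaluate the total loss and take one Adam step.  Fully
    deterministic given ``tcfg.seed``.

    ``scheme`` is the tilt scheme whose wedge defines the corruption
    operator; if omitted it is taken from the first observation's
    provenance.  Returns the trained network and the per-iteration loss
    history.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if scheme is None:
        scheme = dataset[0].provenance.get("scheme")
        if scheme is None:
            raise ValueError("no tilt scheme given and none in provenance")
    rng = np.random.default_rng(tcfg.seed)
    group = build_group()
    m = make_wedge_mask((tcfg.patch_size,) * 3, scheme)
    data = [_normalize_pair(o) for o in dataset]
    if masks is None:
        masks = [InterestMask(np.ones(o.y0.shape, dtype=bool)) for o in data]
    f = network if network is not None else build_network(tcfg.network)
    if tcfg.mixed_precision:
        _enable_half_storage(f)
    opt = Adam(f.params, lr=tcfg.learning_rate)
    history: list[dict] = []
    iterator = range(1, tcfg.max_iterations + 1)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="train")
    for it in iterator:
        vi = int(rng.integers(len(data)))
        obs, mask = data[vi], masks[vi]
        centers = sample_patch_centers(
            mask, tcfg.batch_size, tcfg.patch_size,
            seed=int(rng.integers(2**31 - 1)),
        )
        opt.zero_grad()
        losses, n2ns, equis = [], [], []
        for c in centers:
            pair = extract_pair(obs.y0, obs.y1, c, tcfg.patch_size)
            y0, y1 = pair.y0, pair.y1
            if lcfg.swap_augment and rng.random() < 0.5:
                y0, y1 = y1, y0
            g = group.sample(rng)
            tot, v_n2n, v_equi = total_loss(f, y0, y1, g, m, lcfg)
            losses.append(tot)
            n2ns.append(v_n2n)
            equis.append(v_equi)
        batch_loss = ad.mean_of(losses)
        val = batch_loss.item()
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite loss at iteration {it} "
                f"(n2n={np.mean(n2ns)}, equi={np.mean(equis)}); "
                "reduce the learning rate or check input normalization"
            )
        batch_loss.backward()
        opt.step()
        history.append({
            "iteration": it,
            "n2n": float(np.mean(n2ns)),
            "equivariance": float(np.mean(equis)),
            "total": val,
            "lr": tcfg.learning_rate,
        })
        if tcfg.checkpoint_every and tcfg.checkpoint_dir and \
                it % tcfg.checkpoint_every == 0:
            from .model import save_checkpoint

            save_checkpoint(
                f"{tcfg.checkpoint_dir}/ckpt_{it:07d}.npz", f, iteration=it
            )
    return f, history


def finetune(
    pretrained: Network,
    dataset: list[PairedObservation],
    tcfg: TrainConfig,
    lcfg: LossConfig = LossConfig(),
    scheme=None,
    masks: list[InterestMask] | None = None,
) -> tuple[Network, list[dict]]:
    """Warm-start training from a pretrained network.

    Identical loop to :func:`train` but initialized from the given
    parameters; the conventional budget is 5000 iterations (a tenth of a
    from-scratch run).  The pretrained spec must match ``tcfg.network``.
    """
    if pretrained.spec != tcfg.network:
        raise ValueError(
            f"checkpoint spec {pretrained.spec} incompatible with "
            f"config network {tcfg.network}"
        )
    f = build_network(pretrained.spec)
    f.load_state_dict(pretrained.state_dict())
    if tcfg.max_iterations == 0:
        return f, []
    return train(dataset, tcfg, lcfg, scheme=scheme, masks=masks, network=f)


def _enable_half_storage(f: Network) -> None:
    """Store activations in float16 between layers (compute stays float32).

    Emulates mixed-precision training's storage precision on the CPU
    backend; wedge projections and rotations always run in full precision.
    """
    orig_act = f._act

    def act(t):
        out = orig_act(t)
        out.data = out.data.astype(np.float16).astype(np.float32)
        return out

    f._act = act
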