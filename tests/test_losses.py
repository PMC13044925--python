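"""Data-fidelity and equivariance losses, and the training loop."""

import numpy as np
import pytest

from equitomo import autodiff as ad
from equitomo.autodiff import Tensor
from equitomo.losses import (
    LossConfig,
    TrainConfig,
    equivariance_loss,
    finetune,
    n2n_loss,
    total_loss,
    train,
)
from equitomo.model import NetworkSpec, build_network
from equitomo.phantoms import PairedObservation, PhantomSpec, generate_phantom
from equitomo.wedge import TiltScheme, apply_wedge, make_wedge_mask


class _IdentityNet:
    """Minimal stand-in network: f(y) = y, differentiable."""

    spec = None

    def __call__(self, t: Tensor) -> Tensor:
        return ad.scale(t, 1.0)


@pytest.fixture(scope="module")
def mask16():
    return make_wedge_mask((16, 16, 16), TiltScheme(-60, 60, 3))


@pytest.fixture(scope="module")
def mask_full16():
    return make_wedge_mask((16, 16, 16), TiltScheme(-90, 90, 1))


class TestN2NLoss:
    def test_identity_on_equal_pair_is_zero(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((16, 16, 16)).astype(np.float32)
        assert n2n_loss(_IdentityNet(), y, y.copy()).item() == 0.0

    def test_swap_symmetry_exact(self):
        rng = np.random.default_rng(1)
        f = build_network(NetworkSpec(depth=1, base_channels=4, seed=0))
        y0 = rng.standard_normal((8, 8, 8)).astype(np.float32)
        y1 = rng.standard_normal((8, 8, 8)).astype(np.float32)
        assert n2n_loss(f, y0, y1).item() == n2n_loss(f, y1, y0).item()

    def test_noise2noise_equals_supervised_plus_variance(self):
        """Monte-Carlo check of the bias-variance decomposition:
        E||c - y1||^2 = E||c - x||^2 + sigma^2 for any predictor c
        independent of y1 (here a constant), at 1e5 gaussian samples."""
        rng = np.random.default_rng(2)
        n = 100_000
        x = 0.7
        sigma = 1.3
        y1 = x + sigma * rng.standard_normal(n)
        c = 0.2  # arbitrary fixed prediction
        lhs = np.mean((c - y1) ** 2)
        rhs = (c - x) ** 2 + sigma**2
        assert lhs == pytest.approx(rhs, rel=0.02)
        # and the minimizing constant is the mean of y1 (= x)
        grid = np.linspace(-1, 2, 61)
        losses = [(g - y1) ** 2 for g in grid]
        best = grid[int(np.argmin([l.mean() for l in losses]))]
        assert best == pytest.approx(np.mean(y1), abs=0.05)


class TestEquivarianceLoss:
    def test_zero_for_identity_on_invariant_patch_full_coverage(
        self, group, mask_full16
    ):
        """Spherically symmetric patch, no corruption, f = id -> loss 0."""
        n = 16
        z, y, x = np.indices((n, n, n)) - (n - 1) / 2
        sphere = np.exp(-(z**2 + y**2 + x**2) / 18.0).astype(np.float32)
        loss = equivariance_loss(
            _IdentityNet(), sphere, sphere.copy(), group[3], mask_full16,
            LossConfig(mask_original_wedge=False),
        )
        assert loss.item() <= 1e-5

    def test_positive_for_wedge_corrupted_asymmetric_patch(self, group, mask16):
        phantom = generate_phantom(
            PhantomSpec(shape=(16, 16, 16), seed=4)
        ).astype(np.float32)
        yw = apply_wedge(phantom, mask16).astype(np.float32)
        loss = equivariance_loss(_IdentityNet(), yw, yw.copy(), group[5], mask16)
        assert loss.item() > 1e-4

    def test_swap_symmetrized_invariant_exact(self, group, mask16):
        rng = np.random.default_rng(5)
        f = build_network(NetworkSpec(depth=1, base_channels=4, seed=1))
        y0 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        y1 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        a = equivariance_loss(f, y0, y1, group[9], mask16).item()
        b = equivariance_loss(f, y1, y0, group[9], mask16).item()
        assert a == b

    def test_unmasked_variant_is_plain_equivariant_imaging(self, group, mask16):
        """mask_original_wedge=False must drop the A_g factor: computed
        residual equals || f(A R_g f(y0)) - R_g f(y1) ||^2 directly."""
        from equitomo.geometry import apply_transform
        rng = np.random.default_rng(6)
        y0 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        y1 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        g = group[21]
        f = _IdentityNet()
        loss = equivariance_loss(
            f, y0, y1, g, mask16,
            LossConfig(mask_original_wedge=False, swap_augment=False),
        ).item()
        pred = apply_wedge(apply_transform(g, y0.astype(np.float64)), mask16)
        tgt = apply_transform(g, y1.astype(np.float64))
        oracle = np.mean((pred - tgt) ** 2)
        assert loss == pytest.approx(oracle, rel=1e-4)

    def test_non_cubic_rejected(self, group, mask16):
        with pytest.raises(ValueError, match="cubic"):
            equivariance_loss(
                _IdentityNet(), np.zeros((8, 8, 4), np.float32),
                np.zeros((8, 8, 4), np.float32), group[0], mask16,
            )

    def test_gradient_flows_through_both_applications(self, group, mask16):
        """The equivariance term alone must reach every parameter."""
        rng = np.random.default_rng(7)
        f = build_network(NetworkSpec(depth=1, base_channels=4, seed=2))
        y0 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        y1 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        loss = equivariance_loss(f, y0, y1, group[11], mask16)
        for p in f.params.values():
            p.grad = None
        loss.backward()
        grads = [np.abs(p.grad).max() for p in f.params.values()]
        assert all(g > 0 for g in grads)
        # detached plug-in still leaves a path through the second application
        loss_d = equivariance_loss(
            f, y0, y1, group[11], mask16, LossConfig(detach_plugin=True)
        )
        for p in f.params.values():
            p.grad = None
        loss_d.backward()
        assert all(p.grad is not None for p in f.params.values())


class TestTotalLoss:
    def test_lambda_zero_reduces_to_n2n(self, group, mask16):
        rng = np.random.default_rng(8)
        f = build_network(NetworkSpec(depth=1, base_channels=4, seed=3))
        y0 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        y1 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        tot, v_n2n, _ = total_loss(
            f, y0, y1, group[2], mask16, LossConfig(lambda_equiv=1e-12)
        )
        assert tot.item() == pytest.approx(v_n2n, rel=1e-5)
        assert n2n_loss(f, y0, y1).item() == pytest.approx(v_n2n, rel=1e-6)

    def test_total_at_least_n2n_and_default_lambda(self, group, mask16):
        rng = np.random.default_rng(9)
        f = build_network(NetworkSpec(depth=1, base_channels=4, seed=4))
        y0 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        y1 = rng.standard_normal((16, 16, 16)).astype(np.float32)
        cfg = LossConfig()
        assert cfg.lambda_equiv == 2.0
        tot, v_n2n, v_eq = total_loss(f, y0, y1, group[2], mask16, cfg)
        assert tot.item() >= v_n2n
        assert tot.item() == pytest.approx(v_n2n + 2.0 * v_eq, rel=1e-5)

    def test_wedge_only_perturbation_leaves_n2n_unchanged(self, mask16):
        """Content strictly inside the missing wedge is invisible to the
        data-fidelity term once inputs are wedge-filtered."""
        rng = np.random.default_rng(10)
        f = build_network(NetworkSpec(depth=1, base_channels=4, seed=5))
        base = rng.standard_normal((16, 16, 16))
        pert = rng.standard_normal((16, 16, 16))
        wedge_only = pert - apply_wedge(pert, mask16)  # lives in the wedge
        y0 = apply_wedge(base, mask16).astype(np.float32)
        y1a = apply_wedge(base + 0.5 * np.roll(base, 1, 0), mask16)
        y1b = apply_wedge(base + 0.5 * np.roll(base, 1, 0) + wedge_only, mask16)
        la = n2n_loss(f, y0, y1a.astype(np.float32)).item()
        lb = n2n_loss(f, y0, y1b.astype(np.float32)).item()
        assert lb == pytest.approx(la, rel=1e-4)


def _quick_dataset(shape=(32, 32, 32), seed=0, sigma=1.0):
    scheme = TiltScheme(-60, 60, 6)
    from equitomo.phantoms import generate_paired_dataset
    from equitomo.simulate import NoiseModel

    spec = PhantomSpec(shape=shape, seed=seed)
    return (
        generate_paired_dataset(spec, scheme, NoiseModel("gaussian", sigma, seed=seed + 50), 1),
        scheme,
    )


class TestTrainingLoop:
    def test_loss_decreases_and_history_complete(self):
        data, scheme = _quick_dataset()
        tcfg = TrainConfig(
            patch_size=16, batch_size=1, max_iterations=30,
            learning_rate=1e-3, seed=0,
            network=NetworkSpec(depth=2, base_channels=4, seed=0),
        )
        net, hist = train(data, tcfg, scheme=scheme)
        assert len(hist) == 30
        assert {"iteration", "n2n", "equivariance", "total", "lr"} <= set(hist[0])
        head = np.mean([h["total"] for h in hist[:5]])
        tail = np.mean([h["total"] for h in hist[-5:]])
        assert tail < head

    def test_training_reproducible_given_seed(self):
        data, scheme = _quick_dataset(seed=1)
        tcfg = TrainConfig(
            patch_size=16, batch_size=1, max_iterations=8,
            learning_rate=1e-3, seed=3,
            network=NetworkSpec(depth=2, base_channels=4, seed=3),
        )
        _, h1 = train(data, tcfg, scheme=scheme)
        _, h2 = train(data, tcfg, scheme=scheme)
        t1 = np.array([h["total"] for h in h1])
        t2 = np.array([h["total"] for h in h2])
        assert np.allclose(t1, t2, rtol=1e-4)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TrainConfig(patch_size=16, max_iterations=1))

    def test_checkpoint_resume_bit_compatible(self, tmp_path):
        from equitomo.model import load_checkpoint, save_checkpoint

        data, scheme = _quick_dataset(seed=2)
        tcfg = TrainConfig(
            patch_size=16, batch_size=1, max_iterations=5,
            learning_rate=1e-3, seed=4,
            network=NetworkSpec(depth=2, base_channels=4, seed=4),
        )
        net, _ = train(data, tcfg, scheme=scheme)
        save_checkpoint(tmp_path / "c.npz", net, 5)
        loaded, _ = load_checkpoint(tmp_path / "c.npz")
        y = np.random.default_rng(0).standard_normal((16,) * 3).astype(np.float32)
        from equitomo.model import apply_network

        assert np.array_equal(apply_network(net, y), apply_network(loaded, y))


class TestFinetune:
    def test_zero_iterations_returns_pretrained_unchanged(self):
        data, scheme = _quick_dataset(seed=3)
        pre = build_network(NetworkSpec(depth=2, base_channels=4, seed=5))
        tcfg = TrainConfig(
            patch_size=16, batch_size=1, max_iterations=0,
            seed=5, network=NetworkSpec(depth=2, base_channels=4, seed=5),
        )
        net, hist = finetune(pre, data, tcfg, scheme=scheme)
        assert hist == []
        for k in pre.params:
            assert np.array_equal(net.params[k].data, pre.params[k].data)
        assert net is not pre  # a copy, not the same object

    def test_incompatible_spec_rejected(self):
        data, scheme = _quick_dataset(seed=4)
        pre = build_network(NetworkSpec(depth=1, base_channels=4, seed=6))
        tcfg = TrainConfig(
            patch_size=16, max_iterations=1,
            network=NetworkSpec(depth=2, base_channels=4, seed=6),
        )
        with pytest.raises(ValueError, match="incompatible"):
            finetune(pre, data, tcfg, scheme=scheme)

    def test_default_budget_constant(self):
        from equitomo.losses import FINETUNE_ITERATIONS

        assert FINETUNE_ITERATIONS == 5000
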