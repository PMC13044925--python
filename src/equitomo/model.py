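"""Shape-preserving 3D restoration network.

The method treats the denoiser as a pluggable component: any deterministic
shape-preserving volume-to-volume network works.  The default here is a
small residual 3D U-Net — per-level double 3x3x3 convolutions with leaky
ReLU, 2x average-pool downsampling, nearest-neighbour upsampling with
additive skip connections, and a global residual path so the network
learns a correction to its input.

Parameters are initialized deterministically from ``NetworkSpec.seed``
(He-normal fan-in scaling).  Checkpoints are ``.npz`` containers holding
the spec, the seed and every parameter array.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["NetworkSpec", "Network", "build_network", "apply_network",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``depth`` is the number of resolution levels (1 = no down/upsampling);
    patch sizes must be divisible by ``2**(depth-1)``.
    """

    depth: int = 2
    base_channels: int = 8
    activation: str = "leaky_relu"
    normalization: str = "none"
    residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.activation not in ("leaky_relu", "relu"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.normalization != "none":
            raise ValueError(
                f"unsupported normalization {self.normalization!r} (use 'none')"
            )


class Network:
    """Residual 3D U-Net over the autodiff engine."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(spec.seed)
        C = spec.base_channels
        chans = [C * 2**l for l in range(spec.depth)]
        self._chans = chans
        self._add_conv(rng, "in", 1, chans[0])
        for l in range(spec.depth):
            self._add_conv(rng, f"enc{l}a", chans[l], chans[l])
            self._add_conv(rng, f"enc{l}b", chans[l], chans[l])
            if l + 1 < spec.depth:
                self._add_conv(rng, f"down{l}", chans[l], chans[l + 1])
        for l in range(spec.depth - 2, -1, -1):
            self._add_conv(rng, f"up{l}", chans[l + 1], chans[l])
            self._add_conv(rng, f"dec{l}", chans[l], chans[l])
        self._add_conv(rng, "out", chans[0], 1)
        self.n_parameters = sum(p.data.size for p in self.params.values())

    def _add_conv(self, rng, name: str, cin: int, cout: int) -> None:
        std = float(np.sqrt(2.0 / (cin * 27)))
        w = rng.standard_normal((cout, cin, 3, 3, 3)).astype(np.float32) * std
        b = np.zeros(cout, dtype=np.float32)
        self.params[f"{name}.w"] = Tensor(w, requires_grad=True)
        self.params[f"{name}.b"] = Tensor(b, requires_grad=True)

    def _act(self, t: Tensor) -> Tensor:
        alpha = 0.1 if self.spec.activation == "leaky_relu" else 0.0
        return ad.leaky_relu(t, alpha)

    def _conv(self, name: str, t: Tensor) -> Tensor:
        return ad.conv3d(t, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def forward(self, x: Tensor) -> Tensor:
        """Map (B, 1, N, N, N) to (B, 1, N, N, N)."""
        d = self.spec.depth
        size = x.data.shape[-1]
        if size % 2 ** (d - 1) != 0:
            raise ValueError(
                f"patch size {size} not divisible by 2**(depth-1) = {2**(d-1)}"
            )
        h = self._act(self._conv("in", x))
        skips = []
        for l in range(d):
            h = self._act(self._conv(f"enc{l}a", h))
            h = self._act(self._conv(f"enc{l}b", h))
            if l + 1 < d:
                skips.append(h)
                h = self._act(self._conv(f"down{l}", ad.avg_pool(h)))
        for l in range(d - 2, -1, -1):
            h = self._act(self._conv(f"up{l}", ad.upsample(h)))
            h = ad.add(h, skips.pop())
            h = self._act(self._conv(f"dec{l}", h))
        out = self._conv("out", h)
        if self.spec.residual:
            out = ad.add(out, x)
        return out

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def apply_volume(self, v: np.ndarray) -> np.ndarray:
        """Evaluate on a single bare (N, N, N) volume, no gradient tape."""
        t = Tensor(v[None, None])
        return self.forward(t).data[0, 0]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            if k not in state:
                raise ValueError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != p.data.shape:
                raise ValueError(
                    f"parameter {k!r}: checkpoint shape {state[k].shape} "
                    f"!= model shape {p.data.shape}"
                )
            p.data = state[k].astype(np.float32).copy()


def build_network(spec: NetworkSpec) -> Network:
    """Deterministically initialize a network from its spec."""
    return Network(spec)


def apply_network(f: Network, y: np.ndarray) -> np.ndarray:
    """Evaluate the network on one cubic patch (plain ndarray in/out)."""
    y = np.asarray(y)
    if y.ndim != 3:
        raise ValueError(f"expected a 3D patch, got shape {y.shape}")
    return f.apply_volume(y)


def save_checkpoint(path, f: Network, iteration: int = 0,
                    extra: dict | None = None) -> None:
    meta = {"spec": asdict(f.spec), "iteration": iteration, **(extra or {})}
    np.savez(path, __meta__=json.dumps(meta), **f.state_dict())


def load_checkpoint(path) -> tuple[Network, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        spec = NetworkSpec(**meta["spec"])
        f = build_network(spec)
        f.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return f, meta
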