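"""Scikit-learn style front end for the whole pipeline.

``EquivariantDenoiser`` wraps training and double-application inference
behind the familiar ``fit`` / ``transform`` interface so the restorer
composes with sklearn tooling (``get_params``/``set_params``, cloning,
grid search over ``lambda_equiv`` etc.).  ``fit`` consumes a list of
:class:`~equitomo.phantoms.PairedObservation` (two independently noisy
half-tomograms each); ``transform`` restores a volume, or a pair, with
the trained network.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .losses import LossConfig, TrainConfig, finetune, train
from .model import Network, NetworkSpec
from .phantoms import PairedObservation
from .inference import reconstruct
from .wedge import TiltScheme

__all__ = ["EquivariantDenoiser"]


class EquivariantDenoiser(TransformerMixin, BaseEstimator):
    """Self-supervised tomogram restorer (denoising + wedge correction).

    Parameters mirror the training protocol: ``lambda_equiv`` balances the
    equivariance term against Noise2Noise data fidelity; ``patch_size``,
    ``batch_size`` and ``max_iterations`` set the optimization budget;
    ``depth``/``base_channels`` size the residual U-Net.

    Fitted attributes (trailing underscore): ``network_``, ``history_``,
    ``n_iterations_``.
    """

    def __init__(
        self,
        *,
        patch_size: int = 72,
        batch_size: int = 8,
        max_iterations: int = 50_000,
        learning_rate: float = 4e-4,
        lambda_equiv: float = 2.0,
        mask_original_wedge: bool = True,
        swap_augment: bool = True,
        depth: int = 2,
        base_channels: int = 8,
        theta_min: float = -60.0,
        theta_max: float = 60.0,
        increment: float = 3.0,
        passes: int = 2,
        overlap: int | None = None,
        seed: int = 0,
        warm_start_network: Network | None = None,
    ):
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.max_iterations = max_iterations
        self.learning_rate = learning_rate
        self.lambda_equiv = lambda_equiv
        self.mask_original_wedge = mask_original_wedge
        self.swap_augment = swap_augment
        self.depth = depth
        self.base_channels = base_channels
        self.theta_min = theta_min
        self.theta_max = theta_max
        self.increment = increment
        self.passes = passes
        self.overlap = overlap
        self.seed = seed
        self.warm_start_network = warm_start_network

    # -- sklearn plumbing ---------------------------------------------------
    def _configs(self) -> tuple[TrainConfig, LossConfig, TiltScheme]:
        tcfg = TrainConfig(
            patch_size=self.patch_size,
            batch_size=self.batch_size,
            max_iterations=self.max_iterations,
            learning_rate=self.learning_rate,
            seed=self.seed,
            network=NetworkSpec(
                depth=self.depth, base_channels=self.base_channels, seed=self.seed
            ),
        )
        lcfg = LossConfig(
            lambda_equiv=self.lambda_equiv,
            mask_original_wedge=self.mask_original_wedge,
            swap_augment=self.swap_augment,
        )
        scheme = TiltScheme(self.theta_min, self.theta_max, self.increment)
        return tcfg, lcfg, scheme

    def fit(self, X: list[PairedObservation], y=None) -> "EquivariantDenoiser":
        """Train the restorer on paired noisy observations.

        ``X`` is a list of :class:`PairedObservation`; ``y`` is ignored
        (self-supervised).
        """
        if not isinstance(X, (list, tuple)) or not X:
            raise ValueError("X must be a non-empty list of PairedObservation")
        tcfg, lcfg, scheme = self._configs()
        if self.warm_start_network is not None:
            net, hist = finetune(
                self.warm_start_network, list(X), tcfg, lcfg, scheme=scheme
            )
        else:
            net, hist = train(list(X), tcfg, lcfg, scheme=scheme)
        self.network_ = net
        self.history_ = hist
        self.n_iterations_ = len(hist)
        return self

    def transform(self, X):
        """Restore volumes with the trained network (double application).

        ``X`` may be one ndarray volume, a ``(y0, y1)`` tuple, a
        :class:`PairedObservation`, or a list of any of these; returns the
        restored volume(s) accordingly.
        """
        if not hasattr(self, "network_"):
            raise ValueError("EquivariantDenoiser is not fitted yet; call fit first")
        if isinstance(X, list):
            return [self.transform(x) for x in X]
        if isinstance(X, PairedObservation):
            y0, y1 = X.y0, X.y1
        elif isinstance(X, tuple):
            y0, y1 = X
        else:
            y0, y1 = np.asarray(X), None
        both = y0 if y1 is None else np.stack([y0, y1])
        mu, sd = float(both.mean()), float(both.std())
        sd = sd or 1.0
        y0n = (y0 - mu) / sd
        y1n = None if y1 is None else (y1 - mu) / sd
        return reconstruct(
            self.network_, y0n, y1n,
            patch=self.patch_size, overlap=self.overlap,
            passes=self.passes, norm_stats=(mu, sd),
        )

    def score(self, X, y=None) -> float:
        """Negative final training loss (higher is better)."""
        if not hasattr(self, "history_") or not self.history_:
            raise ValueError("not fitted")
        tail = self.history_[-10:]
        return -float(np.mean([h["total"] for h in tail]))
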