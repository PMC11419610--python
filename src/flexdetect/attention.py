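"""SimAM: parameter-free 3-D attention from a per-element energy function.

Each element t of a channel is scored by how much it stands out from the
other elements of that channel.  With channel mean mu and biased variance
sigma^2 computed over all M = H*W elements, the energy is

    E(t) = 4 * (sigma^2 + lambda)^2 / ((t - mu)^2 + 2*sigma^2 + 2*lambda)

which is maximal at t = mu and decreases with |t - mu|; distinctive elements
therefore have *low* energy.  The attention weight is sigmoid(1/E), applied
elementwise: ``X_hat = sigmoid(1/E) * X``.  The module has exactly zero
learnable parameters.

The mean/variance include the target element itself; ``exclude_self=True``
switches to the leave-one-out statistics used by some formulations.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import Module

__all__ = ["simam_energy", "simam", "SimAM"]

DEFAULT_LAMBDA = 1e-4


def _channel_stats(x: np.ndarray, exclude_self: bool):
    """Per-channel mean/variance over spatial positions, axes (-2, -1)."""
    m = x.shape[-1] * x.shape[-2]
    mu = x.mean(axis=(-2, -1), keepdims=True)
    var = x.var(axis=(-2, -1), keepdims=True)  # biased, 1/M
    if not exclude_self:
        return mu, var
    if m < 2:
        raise ValueError("exclude_self requires at least 2 elements per channel")
    # leave-one-out mean/variance for each element
    mu_loo = (m * mu - x) / (m - 1)
    # sum of squared deviations about mu_loo, excluding x itself
    ss = m * var + m * mu ** 2 - x ** 2 - (m - 1) * mu_loo ** 2
    return mu_loo, np.maximum(ss, 0.0) / (m - 1)


def simam_energy(x: np.ndarray, lam: float = DEFAULT_LAMBDA,
                 exclude_self: bool = False) -> np.ndarray:
    """Per-element SimAM energy map, same shape as ``x`` (C x H x W or N x C x H x W).

    Always strictly positive; a constant channel gives E = 2*lambda everywhere.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    x = np.asarray(x, dtype=float)
    mu, var = _channel_stats(x, exclude_self)
    return 4.0 * (var + lam) ** 2 / ((x - mu) ** 2 + 2.0 * var + 2.0 * lam)


def simam(x: np.ndarray, lam: float = DEFAULT_LAMBDA,
          exclude_self: bool = False) -> np.ndarray:
    """Apply SimAM attention: ``sigmoid(1/E) * x`` elementwise."""
    e = simam_energy(x, lam, exclude_self)
    with np.errstate(over="ignore"):
        weights = 1.0 / (1.0 + np.exp(-1.0 / e))
    return weights * np.asarray(x, dtype=float)


class SimAM(Module):
    """Differentiable SimAM layer for N x C x H x W Tensors (0 parameters)."""

    def __init__(self, lam: float = DEFAULT_LAMBDA):
        super().__init__()
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        self.lam = lam

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        energy = (4.0 * (var + self.lam) ** 2
                  / ((x - mu) ** 2 + 2.0 * var + 2.0 * self.lam))
        return (1.0 / energy).sigmoid() * x
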