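"""Coloured (red) environmental noise.

Temporally autocorrelated forcing is generated as a stationary AR(1) process

    xi(T+1) = k * xi(T) + sigma * sqrt(1 - k^2) * phi(T) + beta * w(T) * sqrt(1 - beta^2)

with ``phi`` and ``w`` i.i.d. standard normal.  ``k`` is the autocorrelation
coefficient, ``sigma`` the noise intensity and ``rho`` the species response
correlation with ``beta = (1 - |rho|) / |rho|``.  For a single species
(``rho = 1``) the ``beta`` term vanishes and the stationary distribution is
N(0, sigma^2) with lag-1 autocorrelation ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseConfig", "generate_coloured_noise"]

#: training regime bound on |k|
K_MAX = 0.8


@dataclass(frozen=True)
class NoiseConfig:
    """Parameters of the AR(1) environmental-noise process.

    Parameters
    ----------
    k : float
        Autocorrelation coefficient, dimensionless, |k| <= 0.8 (the training
        regime; red noise for k > 0).
    sigma : float
        Noise intensity in state units (stationary standard deviation when
        rho = 1).
    rho : float
        Species response correlation in (0, 1].  rho = 1 (the default) makes
        the inter-species term vanish.
    """

    k: float = 0.0
    sigma: float = 1.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.k, self.sigma, self.rho]).all():
            raise ValueError("noise parameters must be finite")
        if abs(self.k) > K_MAX:
            raise ValueError(f"|k| must be <= {K_MAX}, got {self.k}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")

    @property
    def beta(self) -> float:
        """Derived inter-species weight, (1 - |rho|)/|rho|; 0 iff rho = 1."""
        return (1.0 - abs(self.rho)) / abs(self.rho)


def _stationary_std(noise: NoiseConfig) -> float:
    # Var = k^2 Var + sigma^2 (1-k^2) + beta^2 (1-beta^2)
    b = noise.beta
    extra = b * b * max(0.0, 1.0 - b * b)
    return float(np.sqrt(noise.sigma**2 + extra / (1.0 - noise.k**2)))


def generate_coloured_noise(
    n_steps: int,
    noise: NoiseConfig,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_steps`` values of the stationary AR(1) noise process.

    The first value is drawn from the stationary distribution, so the whole
    sequence is stationary.  Identical seeds give identical sequences.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    b = noise.beta
    if b > 1.0:
        raise ValueError(
            "beta = (1-|rho|)/|rho| exceeds 1 (rho < 0.5); the inter-species "
            "term sqrt(1-beta^2) is undefined"
        )
    return _ar1_sequence(n_steps, noise.k, noise.sigma, b, rng)


def _ar1_sequence(
    n_steps: int, k: float, sigma: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) recursion without parameter-range validation.

    The public entry point validates against the training regime; the SDE
    integrator calls this directly with its substep-rescaled coefficient.
    """
    extra = beta * beta * max(0.0, 1.0 - beta * beta)
    std0 = float(np.sqrt(sigma**2 + extra / (1.0 - k**2)))
    xi = np.empty(n_steps)
    xi[0] = rng.normal(0.0, std0)
    if n_steps == 1:
        return xi
    innov = sigma * np.sqrt(1.0 - k**2) * rng.standard_normal(n_steps - 1)
    if beta > 0.0:
        innov = innov + beta * np.sqrt(1.0 - beta * beta) * rng.standard_normal(n_steps - 1)
    if k == 0.0:
        xi[1:] = innov
    else:
        for t in range(1, n_steps):
            xi[t] = k * xi[t - 1] + innov[t - 1]
    return xi


def generate_coloured_noise_batch(
    n_series: int,
    n_steps: int,
    k: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised stationary AR(1) noise for many series at once (rho = 1).

    ``k`` and ``sigma`` broadcast to ``(n_series,)``; returns shape
    ``(n_series, n_steps)``.  Used by the batched SDE integrator.
    """
    k = np.broadcast_to(np.asarray(k, dtype=float), (n_series,))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n_series,))
    xi = np.empty((n_series, n_steps))
    xi[:, 0] = rng.standard_normal(n_series) * sigma
    scale = sigma * np.sqrt(1.0 - k**2)
    innov = rng.standard_normal((n_series, n_steps - 1)) * scale[:, None]
    if np.any(k != 0.0):
        for t in range(1, n_steps):
            xi[:, t] = k * xi[:, t - 1] + innov[:, t - 1]
    else:
        xi[:, 1:] = innov
    return xi
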