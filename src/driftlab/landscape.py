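"""Two-dimensional toy landscape L(x, y) = (xy)².

The loss is exactly zero on both axes, but the curvature across the
x-axis manifold grows with x²: near (x₀, 0) the Hessian is
[[2y², 4xy], [4xy, 2x²]] with eigenvalues {0, 2x₀²} on the manifold.
Noisy gradient descent therefore drifts along the manifold toward the
flat region near the origin — the minimal demonstration of implicit
regularization by noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = ["ToyTrajectory", "run_toy", "toy_grad", "toy_hessian", "toy_hessian_eigs", "toy_loss"]


def toy_loss(x: float, y: float) -> float:
    return float((x * y) ** 2)


def toy_grad(x: float, y: float) -> NDArray[np.float64]:
    """∇L = (2xy², 2x²y); identically zero on both axes."""
    return np.array([2.0 * x * y**2, 2.0 * x**2 * y])


def toy_hessian(x: float, y: float) -> NDArray[np.float64]:
    """Exact Hessian of (xy)²."""
    return np.array([[2.0 * y**2, 4.0 * x * y], [4.0 * x * y, 2.0 * x**2]])


def toy_hessian_eigs(x: float, y: float) -> NDArray[np.float64]:
    """Eigenvalues of the exact Hessian, ascending.

    On the manifold (x₀, 0) these are {0, 2x₀²}, with the non-flat
    eigenvector along the y axis.
    """
    return np.linalg.eigvalsh(toy_hessian(x, y))


@dataclass
class ToyTrajectory:
    """Path of noisy gradient descent on the toy loss."""

    points: NDArray[np.float64]  # (steps + 1, 2)
    lr: float
    noise_variance: float
    seed: int

    @property
    def x(self) -> NDArray[np.float64]:
        return self.points[:, 0]

    @property
    def y(self) -> NDArray[np.float64]:
        return self.points[:, 1]


def run_toy(
    start: tuple[float, float],
    lr: float,
    noise_variance: float,
    steps: int,
    seed: int,
) -> ToyTrajectory:
    """Noisy GD on (xy)²: p' = p − η∇L(p) + ξ, ξ ~ N(0, var·I).

    Raises on divergence (|p| > 10⁶); for stability keep
    η · 2·max(x², y²) < 1 at the start.
    """
    rng = np.random.default_rng(seed)
    p = np.array(start, dtype=float)
    pts = np.empty((steps + 1, 2))
    pts[0] = p
    sigma = float(np.sqrt(noise_variance))
    noise = rng.normal(0.0, sigma, size=(steps, 2)) if sigma > 0 else np.zeros((steps, 2))
    for t in range(steps):
        x, y = p
        p = p - lr * np.array([2.0 * x * y * y, 2.0 * x * x * y]) + noise[t]
        if not np.all(np.isfinite(p)) or np.any(np.abs(p) > 1e6):
            raise RuntimeError(
                f"toy dynamics diverged at step {t} (|p|={np.abs(p).max():.3g}); "
                "reduce the learning rate"
            )
        pts[t + 1] = p
    return ToyTrajectory(points=pts, lr=lr, noise_variance=noise_variance, seed=seed)
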