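"""Flatness of the loss landscape along training.

Near a zero-residual point the loss Hessian equals the Gauss–Newton
matrix, a sum of outer products of model-output gradients — symmetric and
positive semi-definite.  Its spectrum carries the sparsity structure of
the network: every hidden unit that is inactive on all inputs contributes
its parameter rows/columns as exact zeros, hence at least d+1+k zero
eigenvalues (input dim d, output dim k).

Two regularizer functionals are tracked across checkpoints: the number of
(non-)zero eigenvalues together with the sum of logs of the non-zero ones
(the quantity update noise implicitly minimizes), and the plain eigenvalue
sum (the quantity label noise implicitly minimizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .metrics import sparsity_metrics
from .model import NetworkParams, forward, gauss_newton_hessian, gauss_newton_trace

__all__ = ["HessianSpectrum", "regularizer_tracks", "spectrum_at", "trace_track"]

#: Eigenvalues below this fraction of the largest count as zero.
DEFAULT_ZERO_TOL = 1e-8


@dataclass
class HessianSpectrum:
    """Eigenvalues of the Gauss–Newton Hessian at one checkpoint."""

    eigenvalues: NDArray[np.float64]  # ascending
    zero_tol: float                   # absolute threshold actually applied
    step: int | None = None

    @property
    def zero_count(self) -> int:
        return int(np.sum(self.eigenvalues < self.zero_tol))

    @property
    def nonzero_count(self) -> int:
        return self.eigenvalues.size - self.zero_count

    @property
    def total(self) -> float:
        """Sum of eigenvalues (= trace of the Gauss–Newton matrix)."""
        return float(self.eigenvalues.sum())

    @property
    def sum_log_nonzero(self) -> float:
        nz = self.eigenvalues[self.eigenvalues >= self.zero_tol]
        return float(np.sum(np.log(nz))) if nz.size else float("-inf")


def spectrum_at(
    params: NetworkParams,
    X: NDArray,
    zero_tol: float = DEFAULT_ZERO_TOL,
    step: int | None = None,
) -> HessianSpectrum:
    """Full symmetric eigendecomposition of the Gauss–Newton Hessian.

    ``zero_tol`` is relative to the largest eigenvalue; eigenvalues below
    ``zero_tol · λ_max`` are counted as zero.
    """
    H = gauss_newton_hessian(params, X)
    w = np.linalg.eigvalsh(H)
    lam_max = float(w[-1]) if w.size else 0.0
    abs_tol = zero_tol * max(lam_max, np.finfo(float).tiny)
    return HessianSpectrum(eigenvalues=w, zero_tol=abs_tol, step=step)


def regularizer_tracks(
    checkpoints: list[NetworkParams],
    X: NDArray,
    steps: list[int] | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> pd.DataFrame:
    """Spectrum summaries aligned with sparsity metrics per checkpoint.

    Returns one row per checkpoint with columns ``step``, ``zero_count``,
    ``nonzero_count``, ``eig_sum``, ``sum_log_nonzero``,
    ``active_fraction`` and ``fraction_active_units``.
    """
    if len(checkpoints) < 2:
        raise ValueError("need at least 2 checkpoints to form a track")
    shape0 = (checkpoints[0].n_input, checkpoints[0].n_output, checkpoints[0].n_hidden)
    rows = []
    steps = steps if steps is not None else list(range(len(checkpoints)))
    for step, params in zip(steps, checkpoints):
        if (params.n_input, params.n_output, params.n_hidden) != shape0:
            raise ValueError("checkpoints have inconsistent network shapes")
        spec = spectrum_at(params, X, zero_tol=zero_tol, step=step)
        acts, _ = forward(params, X)
        af, fu = sparsity_metrics(acts)
        rows.append(
            {
                "step": step,
                "zero_count": spec.zero_count,
                "nonzero_count": spec.nonzero_count,
                "eig_sum": spec.total,
                "sum_log_nonzero": spec.sum_log_nonzero,
                "active_fraction": af,
                "fraction_active_units": fu,
            }
        )
    return pd.DataFrame(rows)


def trace_track(
    checkpoints: list[NetworkParams], X: NDArray, steps: list[int] | None = None
) -> pd.DataFrame:
    """Eigenvalue sums only (exact, via the closed-form trace) — cheap
    alternative to :func:`regularizer_tracks` when no eigendecomposition
    is needed (label-noise analyses)."""
    steps = steps if steps is not None else list(range(len(checkpoints)))
    return pd.DataFrame(
        {
            "step": steps,
            "eig_sum": [gauss_newton_trace(p, X) for p in checkpoints],
        }
    )
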