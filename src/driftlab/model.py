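"""Single-hidden-layer ReLU predictive network.

The network maps an input vector x to an output ŷ = σ(x mᵀ + b) nᵀ with
σ(x) = max(0, x).  Hidden units of such networks, trained on a predictive
task driven by a latent position, develop spatial tuning; the package
tracks how that tuning and the network's sparseness evolve under noisy
continual training.

Parameter flattening order (used for gradients and Hessians) is fixed:
``m`` row-major, then ``b``, then ``n`` row-major.  Rows/columns of the
Gauss–Newton Hessian therefore map directly onto units: unit ``h`` owns
``m[h, :]``, ``b[h]`` and ``n[:, h]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "ACTIVE_TOL",
    "ActivationMatrix",
    "Dataset",
    "NetworkParams",
    "ResourceLimitError",
    "forward",
    "loss",
    "gradient",
    "gauss_newton_hessian",
    "gauss_newton_trace",
    "save_checkpoint",
    "load_checkpoint",
]

#: A hidden unit counts as active on an input when its activation exceeds
#: this tolerance ("non-zero activation for at least one input", made
#: robust to floating point).
ACTIVE_TOL = 1e-12

#: Dense Hessians are P×P; refuse to build them past this parameter count.
MAX_DENSE_PARAMS = 6000


class ResourceLimitError(RuntimeError):
    """Raised when a dense computation would exceed the configured cap."""


@dataclass
class NetworkParams:
    """Parameters θ = (m, b, n) of the one-hidden-layer network."""

    m: NDArray[np.float64]  # (hidden, input)
    b: NDArray[np.float64]  # (hidden,)
    n: NDArray[np.float64]  # (output, hidden)

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.m.ndim != 2 or self.n.ndim != 2 or self.b.ndim != 1:
            raise ValueError("m and n must be matrices, b a vector")
        if self.b.shape[0] != self.m.shape[0] or self.n.shape[1] != self.m.shape[0]:
            raise ValueError(
                f"inconsistent shapes: m {self.m.shape}, b {self.b.shape}, n {self.n.shape}"
            )

    @property
    def n_hidden(self) -> int:
        return self.m.shape[0]

    @property
    def n_input(self) -> int:
        return self.m.shape[1]

    @property
    def n_output(self) -> int:
        return self.n.shape[0]

    @property
    def n_params(self) -> int:
        return self.m.size + self.b.size + self.n.size

    def flatten(self) -> NDArray[np.float64]:
        """Flattened θ in the documented order (m row-major, b, n row-major)."""
        return np.concatenate([self.m.ravel(), self.b, self.n.ravel()])

    @classmethod
    def unflatten(
        cls, theta: NDArray[np.float64], n_input: int, n_output: int, n_hidden: int
    ) -> "NetworkParams":
        theta = np.asarray(theta, dtype=float)
        sm, sb = n_hidden * n_input, n_hidden
        if theta.size != sm + sb + n_output * n_hidden:
            raise ValueError("theta length does not match the given dimensions")
        return cls(
            m=theta[:sm].reshape(n_hidden, n_input).copy(),
            b=theta[sm : sm + sb].copy(),
            n=theta[sm + sb :].reshape(n_output, n_hidden).copy(),
        )

    @classmethod
    def init(
        cls,
        n_input: int,
        n_output: int,
        n_hidden: int,
        seed: int | np.random.Generator = 0,
        scale: float = 1.0,
    ) -> "NetworkParams":
        """Random initialization: N(0, 1/fan_in) weights, zero bias.

        ``scale`` multiplies the weight standard deviations; the trainer
        uses it to switch between lazy (1.0) and rich (0.1) regimes.
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        m = rng.normal(0.0, scale / np.sqrt(n_input), size=(n_hidden, n_input))
        n = rng.normal(0.0, scale / np.sqrt(n_hidden), size=(n_output, n_hidden))
        return cls(m=m, b=np.zeros(n_hidden), n=n)

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.m.copy(), self.b.copy(), self.n.copy())


@dataclass
class ActivationMatrix:
    """Hidden activations, one row per unit, one column per input."""

    values: NDArray[np.float64]  # (units, inputs), post-ReLU
    tol: float = ACTIVE_TOL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation matrix must be 2-D (units x inputs)")
        if np.any(self.values < 0):
            raise ValueError("post-ReLU activations cannot be negative")

    @property
    def mask(self) -> NDArray[np.bool_]:
        return self.values > self.tol

    @property
    def active_units(self) -> NDArray[np.bool_]:
        """Units with non-zero activation for at least one input."""
        return self.mask.any(axis=1)


@dataclass
class Dataset:
    """Supervised samples; for predictive tasks Y is X's signal one step ahead.

    ``positions``/``directions`` carry the latent location of each sample
    when the task has one (corridor or ring tasks), enabling tuning-curve
    analyses of the hidden layer.
    """

    X: NDArray[np.float64]
    Y: NDArray[np.float64]
    positions: NDArray[np.float64] | None = None
    directions: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.X.shape[0] == 0:
            raise ValueError("empty dataset")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def _forward_parts(
    m: NDArray, b: NDArray, n: NDArray, X: NDArray
) -> tuple[NDArray, NDArray, NDArray]:
    """Pre-activations, hidden activations and outputs (internal fast path)."""
    pre = X @ m.T + b
    hidden = np.maximum(pre, 0.0)
    return pre, hidden, hidden @ n.T


def forward(params: NetworkParams, X: NDArray) -> tuple[ActivationMatrix, NDArray]:
    """Evaluate the network on a batch of inputs.

    Returns the hidden-layer activation matrix (units x inputs, i.e.
    transposed relative to the batch layout) and the output batch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_input:
        raise ValueError(f"input dim {X.shape[1]} != network input dim {params.n_input}")
    _, hidden, out = _forward_parts(params.m, params.b, params.n, X)
    return ActivationMatrix(hidden.T), out


def loss(params: NetworkParams, data: Dataset, baseline: bool = False) -> float:
    """Mean squared prediction error f(m, n, b) = E_t (ŷ_t − y_t)².

    With ``baseline=True`` the MSE of the constant column-mean predictor is
    subtracted, so a network no better than predicting the mean target maps
    to zero (the convention used when plotting loss curves).
    """
    _, _, out = _forward_parts(params.m, params.b, params.n, data.X)
    mse = float(np.mean((out - data.Y) ** 2))
    if baseline:
        mse -= float(np.mean((data.Y - data.Y.mean(axis=0)) ** 2))
    return mse


def _grads(
    m: NDArray, b: NDArray, n: NDArray, X: NDArray, Y: NDArray,
    resid_noise: NDArray | None = None,
) -> tuple[float, NDArray, NDArray, NDArray]:
    """Loss and exact gradients w.r.t. (m, b, n); optional residual noise."""
    pre, hidden, out = _forward_parts(m, b, n, X)
    resid = out - Y
    if resid_noise is not None:
        resid = resid + resid_noise
    nk = resid.size
    value = float(np.sum(resid**2)) / nk
    dout = (2.0 / nk) * resid                        # (N, K)
    gn = dout.T @ hidden                             # (K, H)
    ghid = (dout @ n) * (pre > 0)                    # (N, H)
    gm = ghid.T @ X                                  # (H, D)
    gb = ghid.sum(axis=0)                            # (H,)
    return value, gm, gb, gn


def gradient(params: NetworkParams, data: Dataset) -> NDArray[np.float64]:
    """Exact gradient of the MSE loss, flattened in the documented order.

    All entries belonging to a unit that is inactive on every sample are
    zero (the ReLU gate kills its input, bias and output partials).
    """
    _, gm, gb, gn = _grads(params.m, params.b, params.n, data.X, data.Y)
    return np.concatenate([gm.ravel(), gb, gn.ravel()])


def _output_jacobian(params: NetworkParams, X: NDArray) -> NDArray[np.float64]:
    """Per-(sample, output-coordinate) model gradients, stacked (N·K, P)."""
    N, D = X.shape
    H, K = params.n_hidden, params.n_output
    pre = X @ params.m.T + params.b
    hidden = np.maximum(pre, 0.0)
    # the same activity tolerance as the sparsity metrics, so dead units
    # correspond exactly to zero rows/columns of the Hessian
    A = (hidden > ACTIVE_TOL).astype(float)          # (N, H)
    # d f_k(x_i) / dm[h, d] = n[k, h] * 1(pre>0)[i, h] * x[i, d]
    Jm = np.einsum("kh,ih,id->ikhd", params.n, A, X).reshape(N, K, H * D)
    Jb = np.einsum("kh,ih->ikh", params.n, A)
    Jn = np.zeros((N, K, K, H))
    for k in range(K):
        Jn[:, k, k, :] = hidden
    return np.concatenate([Jm, Jb, Jn.reshape(N, K, K * H)], axis=2).reshape(N * K, -1)


def gauss_newton_hessian(
    params: NetworkParams, X: NDArray, max_params: int = MAX_DENSE_PARAMS
) -> NDArray[np.float64]:
    """Gauss–Newton Hessian of the MSE loss: scaled sum over samples and
    output coordinates of outer products of model-output gradients.

    At any zero-residual point this equals the exact Hessian of the loss.
    The 2/(N·K) factor from the squared-error mean is included; it rescales
    all eigenvalues uniformly.  Symmetric and positive semi-definite; the
    rows and columns of every unit inactive on all inputs are identically
    zero, so each dead unit contributes at least d+1+k zero eigenvalues.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if params.n_params > max_params:
        raise ResourceLimitError(
            f"dense Hessian would be {params.n_params}x{params.n_params}; "
            f"cap is {max_params} parameters — use a smaller network"
        )
    J = _output_jacobian(params, X)
    scale = 2.0 / J.shape[0]
    return scale * (J.T @ J)


def gauss_newton_trace(params: NetworkParams, X: NDArray) -> float:
    """Trace of :func:`gauss_newton_hessian` (= sum of its eigenvalues),
    computed in closed form without building the dense matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pre = X @ params.m.T + params.b
    hidden = np.maximum(pre, 0.0)
    A = (hidden > ACTIVE_TOL).astype(float)
    n_sq = np.sum(params.n**2, axis=0)               # (H,)
    x_sq = np.sum(X**2, axis=1)                      # (N,)
    per_unit = A.T @ (x_sq + 1.0)                    # Σ_i 1_ih (|x_i|² + 1)
    K = params.n_output
    total = float(n_sq @ per_unit) + K * float(np.sum(hidden**2))
    return 2.0 / (X.shape[0] * K) * total


def save_checkpoint(path, params: NetworkParams, **metadata) -> None:
    """Store parameters (and optional scalar metadata) as an .npz archive."""
    np.savez(path, m=params.m, b=params.b, n=params.n, **metadata)


def load_checkpoint(path) -> tuple[NetworkParams, dict]:
    with np.load(path) as f:
        params = NetworkParams(f["m"], f["b"], f["n"])
        meta = {k: f[k][()] for k in f.files if k not in ("m", "b", "n")}
    return params, meta
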