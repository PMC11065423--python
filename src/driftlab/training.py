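"""Training rules, task family, and the noisy continual trainer.

The central object of study is gradient descent continued long past
convergence with some source of stochasticity:

- update noise:  θ' = θ − η ∇f(θ) + ξ            (ξ Gaussian)
- label noise:   f(θ) = E_t (ŷ_t − y_t + ξ_t)²    (fresh ξ each step)
- SED:           θ' = θ − η (f(θ+ξ) − f(θ)) ξ     (gradient-free)
- Adam / RMSprop: standard formulations, no added noise (their second
  moment itself acts as a noise source near the solution manifold).

``train`` runs a configured rule on one of four tasks, logging loss,
sparsity and mean spatial information on a geometric schedule, and storing
parameter checkpoints for Hessian analysis.

A note on the update-noise amplitude: the trainer treats the configured
``noise_variance`` as the variance of a noisy-gradient term, i.e. the step
is θ' = θ − η(∇f + ζ) with ζ ~ N(0, σ²I), so the noise injected into the
parameters has variance η²σ².  This keeps the stationary excess loss
proportional to η·σ² and lets the network sit on its loss plateau while
drifting — the regime the package exists to study.  The ``gd_update``
primitive itself takes the parameter-noise variance directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import yaml
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter1d

from .environment import CorridorConfig, generate_wall_texture, render_visual_input, simulate_trajectory
from .metrics import compute_rate_maps, mean_spatial_information, sparsity_metrics
from .model import Dataset, NetworkParams, _grads

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "dataset_for",
    "gd_update",
    "label_noise_loss",
    "make_task",
    "sed_update",
    "train",
    "train_ensemble",
    "load_training_config",
]

ALGORITHMS = ("gd", "adam", "rmsprop", "sed")
NOISE_TYPES = ("update", "label", "none")
TASKS = ("corridor", "abstract-predictive", "random", "random-smoothed")


@dataclass(frozen=True)
class TrainingConfig:
    """Everything needed to reproduce one training run from its seed."""

    algorithm: str = "gd"
    noise_type: str = "update"
    noise_variance: float = 0.05
    learning_rate: float = 0.05
    steps: int = 200_000
    task: str = "corridor"
    input_dim: int = 16
    output_dim: int = 15
    hidden: int = 100
    n_samples: int = 64
    init_regime: str = "lazy"   # lazy = standard 1/sqrt(fan-in); rich = 0.1x
    seed: int = 0
    batch: int | None = None    # None = full batch (plain GD); else SGD minibatch
    log_base: float = 1.2       # geometric logging schedule
    si_bins: int = 20           # spatial bins per direction for logged mean SI

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; one of {ALGORITHMS}")
        if self.noise_type not in NOISE_TYPES:
            raise ValueError(f"unknown noise type {self.noise_type!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; one of {TASKS}")
        if self.noise_variance < 0 or self.learning_rate < 0:
            raise ValueError("noise_variance and learning_rate must be >= 0")
        if self.algorithm in ("adam", "rmsprop") and self.noise_type != "none":
            raise ValueError(f"{self.algorithm} runs without added noise; set noise_type='none'")
        if self.algorithm == "sed" and self.noise_type != "none":
            raise ValueError("SED's perturbation is its own noise; set noise_type='none'")
        if self.init_regime not in ("lazy", "rich"):
            raise ValueError("init_regime must be 'lazy' or 'rich'")
        if self.log_base <= 1.0:
            raise ValueError("log_base must exceed 1")


@dataclass
class TrainingTrace:
    """Logged curves and parameter checkpoints of one training run."""

    steps: NDArray[np.int64]
    raw_loss: NDArray[np.float64]
    loss: NDArray[np.float64]              # baseline-adjusted (mean estimator = 0)
    active_fraction: NDArray[np.float64]
    fraction_active_units: NDArray[np.float64]
    mean_si: NDArray[np.float64]           # NaN when the task has no latent position
    checkpoints: list[NetworkParams]
    config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.steps) <= 0):
            raise ValueError("log steps must be strictly increasing")

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "step": self.steps,
                "raw_loss": self.raw_loss,
                "loss": self.loss,
                "active_fraction": self.active_fraction,
                "fraction_active_units": self.fraction_active_units,
                "mean_si": self.mean_si,
            }
        )


# ---------------------------------------------------------------- tasks


def _abstract_predictive(input_dim, output_dim, n_samples, rng) -> Dataset:
    """Latent random walk on a ring observed through a fixed smooth map."""
    n_harmonics = 3
    dim = max(input_dim, output_dim)
    a = rng.normal(0, 1 / np.sqrt(n_harmonics), size=(dim, n_harmonics))
    b = rng.normal(0, 1 / np.sqrt(n_harmonics), size=(dim, n_harmonics))
    h = np.arange(1, n_harmonics + 1)

    def observe(z):
        return a @ np.cos(np.outer(h, z)) + b @ np.sin(np.outer(h, z))  # (dim, T)

    z = np.cumsum(0.15 + rng.normal(0, 0.05, size=n_samples + 1)) % (2 * np.pi)
    obs = observe(z).T
    return Dataset(
        X=obs[:-1, :input_dim],
        Y=obs[1:, :output_dim],
        positions=z[:-1],
        directions=None,
    )


def make_task(
    kind: str,
    input_dim: int,
    output_dim: int,
    n_samples: int,
    seed: int,
    corridor: CorridorConfig | None = None,
) -> Dataset:
    """Build one of the four task datasets, deterministic given the seed.

    - ``random``: i.i.d. Gaussian inputs and independent Gaussian targets.
    - ``random-smoothed``: as random, targets smoothed along the sample
      ordering (Gaussian kernel, σ = 2 samples, circular).
    - ``abstract-predictive``: 1-D latent walk on a ring, fixed random
      smooth observation map, target = next-step observation.
    - ``corridor``: the visual corridor task; the input is the current
      frame plus the normalized forward velocity (input_dim = L_vis + 1),
      the target the next frame (output_dim = L_vis).
    """
    if min(input_dim, output_dim, n_samples) < 1:
        raise ValueError("dims and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "random" or kind == "random-smoothed":
        X = rng.standard_normal((n_samples, input_dim))
        Y = rng.standard_normal((n_samples, output_dim))
        if kind == "random-smoothed":
            Y = gaussian_filter1d(Y, sigma=2.0, axis=0, mode="wrap")
        return Dataset(X=X, Y=Y)
    if kind == "abstract-predictive":
        return _abstract_predictive(input_dim, output_dim, n_samples, rng)
    if kind == "corridor":
        if output_dim != input_dim - 1:
            raise ValueError(
                "corridor task: input is frame + velocity, so output_dim must be input_dim - 1"
            )
        cfg = corridor if corridor is not None else CorridorConfig(L_vis=input_dim - 1)
        if cfg.L_vis != input_dim - 1:
            raise ValueError("corridor config L_vis must equal input_dim - 1")
        texture = generate_wall_texture(cfg, seed=seed, normalize=True)
        traj = simulate_trajectory(cfg, T=n_samples + 1, seed=seed + 1)
        frames = render_visual_input(traj, texture, cfg).frames
        vy = traj.velocities[:, 1] / cfg.V0
        return Dataset(
            X=np.column_stack([frames[:-1], vy[:-1]]),
            Y=frames[1:],
            positions=traj.positions[:-1, 1],
            directions=np.sign(vy[:-1]),
        )
    raise ValueError(f"unknown task kind {kind!r}")


# ------------------------------------------------------------- updates


def gd_update(
    theta: NDArray,
    grad: NDArray,
    lr: float,
    noise_variance: float,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    """One noisy gradient-descent step: θ − η·grad + ξ, ξ ~ N(0, var·I)."""
    theta = np.asarray(theta, dtype=float)
    new = theta - lr * np.asarray(grad, dtype=float)
    if noise_variance > 0:
        new = new + rng.normal(0.0, np.sqrt(noise_variance), size=theta.shape)
    return new


def sed_update(
    theta: NDArray,
    loss_fn: Callable[[NDArray], float],
    lr: float,
    perturb_variance: float,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    """Stochastic error descent: θ − η·(f(θ+ξ) − f(θ))·ξ.

    To first order the expected update is −η·σ²·∇f, i.e. SED performs
    gradient descent on average with intrinsic exploration noise.
    """
    theta = np.asarray(theta, dtype=float)
    xi = rng.normal(0.0, np.sqrt(perturb_variance), size=theta.shape)
    delta = loss_fn(theta + xi) - loss_fn(theta)
    return theta - lr * delta * xi


def label_noise_loss(
    params: NetworkParams,
    data: Dataset,
    noise_variance: float,
    rng: np.random.Generator,
) -> tuple[float, NDArray[np.float64]]:
    """Loss and gradient with fresh Gaussian noise added to the residual.

    The noisy gradient is unbiased for the plain gradient; at zero
    residual the noisy loss averages to the noise variance.
    """
    noise = (
        rng.normal(0.0, np.sqrt(noise_variance), size=data.Y.shape)
        if noise_variance > 0
        else None
    )
    value, gm, gb, gn = _grads(params.m, params.b, params.n, data.X, data.Y, resid_noise=noise)
    return value, np.concatenate([gm.ravel(), gb, gn.ravel()])


# ------------------------------------------------------------- trainer


def _log_steps(total: int, base: float) -> NDArray[np.int64]:
    pts = {0, total}
    v = 1.0
    while v < total:
        pts.add(int(v))
        v *= base
    return np.array(sorted(pts), dtype=np.int64)


def dataset_for(config: TrainingConfig) -> Dataset:
    """The exact dataset a :func:`train` run of this config trains on
    (the task seed is derived from ``config.seed`` the same way)."""
    ss = np.random.SeedSequence(config.seed)
    task_seed = int(ss.generate_state(3)[0] >> 1)
    return make_task(
        config.task, config.input_dim, config.output_dim, config.n_samples, seed=task_seed
    )


def train(config: TrainingConfig) -> TrainingTrace:
    """Run the configured rule for ``steps`` updates and log the trace.

    Fully reproducible from ``config.seed``: the task, the initialization
    and the noise stream each get an independent child seed.  Aborts with
    a diagnostic if the loss exceeds 10⁶ × its initial value.
    """
    ss = np.random.SeedSequence(config.seed)
    task_seed, init_seed, noise_seed = [int(s) for s in ss.generate_state(3) >> 1]
    data = make_task(
        config.task, config.input_dim, config.output_dim, config.n_samples, seed=task_seed
    )
    scale = 1.0 if config.init_regime == "lazy" else 0.1
    params = NetworkParams.init(
        data.X.shape[1], data.Y.shape[1], config.hidden, seed=init_seed, scale=scale
    )
    rng = np.random.default_rng(noise_seed)

    m, b, n = params.m, params.b, params.n
    X, Y = data.X, data.Y
    baseline_mse = float(np.mean((Y - Y.mean(axis=0)) ** 2))
    eta = config.learning_rate
    sigma_update = eta * np.sqrt(config.noise_variance)  # noisy-gradient convention

    # Adam / RMSprop state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mom = [np.zeros_like(m), np.zeros_like(b), np.zeros_like(n)]
    sec = [np.zeros_like(m), np.zeros_like(b), np.zeros_like(n)]

    def full_loss_flat(theta: NDArray) -> float:
        p = NetworkParams.unflatten(theta, m.shape[1], n.shape[0], m.shape[0])
        pre = X @ p.m.T + p.b
        out = np.maximum(pre, 0.0) @ p.n.T
        return float(np.mean((out - Y) ** 2))

    fast_ok = config.algorithm == "gd" and config.batch is None
    if fast_ok:
        return _train_gd_fast(config, data, params, noise_seed, baseline_mse)

    log_at = set(int(s) for s in _log_steps(config.steps, config.log_base))
    rec: dict[str, list] = {k: [] for k in
                            ("steps", "raw", "active_frac", "frac_units", "si")}
    checkpoints: list[NetworkParams] = []

    def record(step: int) -> None:
        pre = X @ m.T + b
        hidden = np.maximum(pre, 0.0)
        out = hidden @ n.T
        raw = float(np.mean((out - Y) ** 2))
        af, fu = sparsity_metrics(hidden.T)
        si = np.nan
        if data.positions is not None:
            maps = compute_rate_maps(
                hidden, data.positions, n_bins=config.si_bins, directions=data.directions
            )
            si = mean_spatial_information(maps)
        rec["steps"].append(step)
        rec["raw"].append(raw)
        rec["active_frac"].append(af)
        rec["frac_units"].append(fu)
        rec["si"].append(si)
        checkpoints.append(NetworkParams(m.copy(), b.copy(), n.copy()))

    initial_raw = None
    batch_rng = np.random.default_rng(noise_seed + 1)
    for step in range(config.steps):
        if step in log_at:
            record(step)
        if config.batch is not None and config.algorithm == "gd":
            sel = batch_rng.integers(0, X.shape[0], size=config.batch)
            Xs, Ys = X[sel], Y[sel]
        else:
            Xs, Ys = X, Y

        if config.algorithm == "sed":
            theta = np.concatenate([m.ravel(), b, n.ravel()])
            theta = sed_update(theta, full_loss_flat, eta, config.noise_variance, rng)
            p = NetworkParams.unflatten(theta, m.shape[1], n.shape[0], m.shape[0])
            m[...], b[...], n[...] = p.m, p.b, p.n
            raw = full_loss_flat(theta)
        else:
            resid_noise = None
            if config.noise_type == "label" and config.noise_variance > 0:
                resid_noise = rng.normal(
                    0.0, np.sqrt(config.noise_variance), size=Ys.shape
                )
            raw, gm, gb, gn = _grads(m, b, n, Xs, Ys, resid_noise=resid_noise)
            if config.algorithm == "gd":
                m -= eta * gm
                b -= eta * gb
                n -= eta * gn
                if config.noise_type == "update" and config.noise_variance > 0:
                    m += rng.normal(0.0, sigma_update, size=m.shape)
                    b += rng.normal(0.0, sigma_update, size=b.shape)
                    n += rng.normal(0.0, sigma_update, size=n.shape)
            else:  # adam / rmsprop
                for i, (arr, g) in enumerate(((m, gm), (b, gb), (n, gn))):
                    sec[i] = beta2 * sec[i] + (1 - beta2) * g**2
                    if config.algorithm == "adam":
                        mom[i] = beta1 * mom[i] + (1 - beta1) * g
                        mhat = mom[i] / (1 - beta1 ** (step + 1))
                        vhat = sec[i] / (1 - beta2 ** (step + 1))
                        arr -= eta * mhat / (np.sqrt(vhat) + eps)
                    else:
                        arr -= eta * g / (np.sqrt(sec[i]) + eps)

        if initial_raw is None:
            initial_raw = max(raw, 1e-30)
        if not np.isfinite(raw) or raw > 1e6 * initial_raw:
            raise RuntimeError(
                f"training diverged at step {step}: loss {raw:.3g} "
                f"(initial {initial_raw:.3g}); reduce the learning rate or noise"
            )
    record(config.steps)

    return TrainingTrace(
        steps=np.array(rec["steps"], dtype=np.int64),
        raw_loss=np.array(rec["raw"]),
        loss=np.array(rec["raw"]) - baseline_mse,
        active_fraction=np.array(rec["active_frac"]),
        fraction_active_units=np.array(rec["frac_units"]),
        mean_si=np.array(rec["si"]),
        checkpoints=checkpoints,
        config=config,
    )


def _train_gd_fast(
    config: TrainingConfig,
    data: Dataset,
    params: NetworkParams,
    noise_seed: int,
    baseline_mse: float,
) -> TrainingTrace:
    """Full-batch GD via the compiled loop (same logging semantics)."""
    from ._fast import run_gd_loop

    eta = config.learning_rate
    sig_upd = sig_lab = 0.0
    if config.noise_type == "update" and config.noise_variance > 0:
        sig_upd = eta * np.sqrt(config.noise_variance)  # noisy-gradient convention
    elif config.noise_type == "label" and config.noise_variance > 0:
        sig_lab = np.sqrt(config.noise_variance)

    log_steps = _log_steps(config.steps, config.log_base)
    D, K, H = data.X.shape[1], data.Y.shape[1], config.hidden
    raw, af, fu, ckpts, diverged_at = run_gd_loop(
        np.ascontiguousarray(data.X),
        np.ascontiguousarray(data.Y),
        params.m,
        params.b,
        params.n,
        float(eta),
        float(sig_upd),
        float(sig_lab),
        int(config.steps),
        log_steps,
        int(noise_seed & 0x7FFFFFFF),
    )
    if diverged_at >= 0:
        raise RuntimeError(
            f"training diverged at step {diverged_at}; "
            "reduce the learning rate or noise"
        )
    checkpoints = []
    si = np.full(log_steps.size, np.nan)
    for i in range(log_steps.size):
        theta = ckpts[i]
        mT = theta[: D * H].reshape(D, H)
        b = theta[D * H : D * H + H]
        nT = theta[D * H + H :].reshape(H, K)
        p = NetworkParams(np.ascontiguousarray(mT.T), b.copy(), np.ascontiguousarray(nT.T))
        checkpoints.append(p)
        if data.positions is not None:
            hidden = np.maximum(data.X @ p.m.T + p.b, 0.0)
            maps = compute_rate_maps(
                hidden, data.positions, n_bins=config.si_bins, directions=data.directions
            )
            si[i] = mean_spatial_information(maps)
    return TrainingTrace(
        steps=log_steps,
        raw_loss=raw,
        loss=raw - baseline_mse,
        active_fraction=af,
        fraction_active_units=fu,
        mean_si=si,
        checkpoints=checkpoints,
        config=config,
    )


def train_ensemble(
    configs: list[TrainingConfig], log_si: bool = False
) -> list[TrainingTrace]:
    """Run many GD configurations in lockstep with batched linear algebra.

    The scaled sweep runner: all members must share task kind, dimensions,
    sample count, step count, logging schedule and noise type, but may
    differ in seed, noise variance and learning rate.  Each member's data
    and initialization derive from its own seed exactly as in
    :func:`train`; the noise streams are drawn from a single ensemble
    generator, so a member's trace is statistically — not bitwise —
    equivalent to a serial :func:`train` run of its config.

    Mean SI logging is off by default (it is the one per-member
    sequential cost); enable ``log_si`` when the tuning curves matter.
    """
    if not configs:
        raise ValueError("empty ensemble")
    base = configs[0]
    for c in configs:
        if c.algorithm != "gd" or c.batch is not None:
            raise ValueError("train_ensemble supports full-batch GD members only")
        shared = ("task", "input_dim", "output_dim", "hidden", "n_samples",
                  "steps", "log_base", "noise_type", "init_regime", "si_bins")
        if any(getattr(c, k) != getattr(base, k) for k in shared):
            raise ValueError("ensemble members must share task, shape and schedule fields")
    R = len(configs)
    data, inits = [], []
    for c in configs:
        ss = np.random.SeedSequence(c.seed)
        task_seed, init_seed, _ = [int(s) for s in ss.generate_state(3) >> 1]
        d = make_task(c.task, c.input_dim, c.output_dim, c.n_samples, seed=task_seed)
        scale = 1.0 if c.init_regime == "lazy" else 0.1
        inits.append(
            NetworkParams.init(d.X.shape[1], d.Y.shape[1], c.hidden, seed=init_seed, scale=scale)
        )
        data.append(d)
    X = np.stack([d.X for d in data])                 # (R, N, D)
    Y = np.stack([d.Y for d in data])                 # (R, N, K)
    m = np.stack([p.m for p in inits])                # (R, H, D)
    b = np.stack([p.b for p in inits])                # (R, H)
    n = np.stack([p.n for p in inits])                # (R, K, H)
    baseline = np.mean((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=(1, 2))

    eta = np.array([c.learning_rate for c in configs])
    var = np.array([c.noise_variance for c in configs])
    sig_upd = (eta * np.sqrt(var))[:, None, None]     # noisy-gradient convention
    sig_lab = np.sqrt(var)[:, None, None]
    eta3 = eta[:, None, None]
    rng = np.random.default_rng(
        np.random.SeedSequence([c.seed & 0x7FFFFFFF for c in configs])
    )

    log_at = set(int(s) for s in _log_steps(base.steps, base.log_base))
    rec: dict[str, list] = {k: [] for k in ("steps", "raw", "af", "fu", "si")}
    checkpoints: list[list[NetworkParams]] = [[] for _ in range(R)]

    def record(step: int) -> None:
        pre = X @ m.transpose(0, 2, 1) + b[:, None, :]
        hidden = np.maximum(pre, 0.0)
        out = hidden @ n.transpose(0, 2, 1)
        rec["steps"].append(step)
        rec["raw"].append(np.mean((out - Y) ** 2, axis=(1, 2)))
        active = hidden > 1e-12
        rec["af"].append(active.mean(axis=(1, 2)))
        rec["fu"].append(active.any(axis=1).mean(axis=1))
        si = np.full(R, np.nan)
        if log_si:
            for r in range(R):
                if data[r].positions is not None:
                    maps = compute_rate_maps(
                        hidden[r], data[r].positions, n_bins=base.si_bins,
                        directions=data[r].directions,
                    )
                    si[r] = mean_spatial_information(maps)
        rec["si"].append(si)
        for r in range(R):
            checkpoints[r].append(NetworkParams(m[r].copy(), b[r].copy(), n[r].copy()))

    initial_raw = None
    nk = X.shape[1] * Y.shape[2]
    for step in range(base.steps):
        if step in log_at:
            record(step)
        pre = X @ m.transpose(0, 2, 1) + b[:, None, :]
        hidden = np.maximum(pre, 0.0)
        out = hidden @ n.transpose(0, 2, 1)
        resid = out - Y
        if base.noise_type == "label":
            resid = resid + rng.standard_normal(resid.shape) * sig_lab
        dout = (2.0 / nk) * resid
        gn = dout.transpose(0, 2, 1) @ hidden
        ghid = (dout @ n) * (pre > 0)
        gm = ghid.transpose(0, 2, 1) @ X
        gb = ghid.sum(axis=1)
        m -= eta3 * gm
        b -= eta[:, None] * gb
        n -= eta3 * gn
        if base.noise_type == "update":
            m += rng.standard_normal(m.shape) * sig_upd
            b += rng.standard_normal(b.shape) * sig_upd[:, :, 0]
            n += rng.standard_normal(n.shape) * sig_upd
        raw = float(np.max(np.mean(resid**2, axis=(1, 2))))
        if initial_raw is None:
            initial_raw = max(raw, 1e-30)
        if not np.isfinite(raw) or raw > 1e6 * initial_raw:
            raise RuntimeError(f"an ensemble member diverged at step {step} (loss {raw:.3g})")
    record(base.steps)

    steps_arr = np.array(rec["steps"], dtype=np.int64)
    traces = []
    for r in range(R):
        raw = np.array([v[r] for v in rec["raw"]])
        traces.append(
            TrainingTrace(
                steps=steps_arr.copy(),
                raw_loss=raw,
                loss=raw - baseline[r],
                active_fraction=np.array([v[r] for v in rec["af"]]),
                fraction_active_units=np.array([v[r] for v in rec["fu"]]),
                mean_si=np.array([v[r] for v in rec["si"]]),
                checkpoints=checkpoints[r],
                config=configs[r],
            )
        )
    return traces


def load_training_config(path) -> TrainingConfig:
    """Read a TrainingConfig from a YAML mapping of field names."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return TrainingConfig(**raw)
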