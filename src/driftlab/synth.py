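"""Synthetic multi-session recordings with controlled drift statistics.

The generator emulates the structure of chronic CA1 recordings on a
linear track: per animal and day, a back-and-forth trajectory with a
configurable speed distribution, Gaussian place fields whose widths
shrink and centres drift across days, a per-day Bernoulli silencing that
implements the declining active-cell count, and Poisson event counts.
Every generator knob (decline rate, shrink rate, drift rate) is chosen to
be recoverable by the corresponding pipeline statistic, which is what the
tests exercise.

On day d (0-based):

- a cell is active with probability 1 − decline_rate·d, so the expected
  normalized active-cell count is exactly 1 − decline_rate·d (slope
  −decline_rate per day);
- field width is width₀·(1 − shrink_rate)^d, so mean SI rises with d;
- field centres random-walk with std drift_cm_per_day per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from numpy.typing import NDArray

from .session import SessionRecording
from .training import TrainingTrace

__all__ = ["SynthCohortConfig", "generate_cohort", "generate_session", "generate_trace_fixture"]


@dataclass(frozen=True)
class SynthCohortConfig:
    """Study conditions for a synthetic cohort (a typical 10-day chronic
    linear-track experiment with ~100 imaged cells per animal)."""

    n_animals: int = 8
    n_days: int = 10
    n_cells: int = 100
    track_length: float = 100.0     # cm
    duration: int = 2000            # timesteps per session
    dt: float = 0.1                 # s per timestep (10 Hz frames)
    speed_mean: float = 12.0        # cm/s
    speed_std: float = 4.0
    pause_prob: float = 0.05        # fraction of frames at near-zero speed
    decline_rate: float = 0.03      # active-cell probability lost per day
    shrink_rate: float = 0.02       # fractional tuning-width loss per day
    drift_cm_per_day: float = 2.0   # std of the field-centre random walk
    tuning_width: float = 8.0       # cm, day-0 field width
    peak_rate_range: tuple[float, float] = (2.0, 8.0)  # Hz at field centre
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animals, self.n_days, self.n_cells, self.duration) < 1:
            raise ValueError("counts must be positive")
        if self.decline_rate * (self.n_days - 1) >= 1.0:
            raise ValueError("decline_rate drives the active fraction below zero within n_days")
        if not 0.0 <= self.shrink_rate < 1.0:
            raise ValueError("shrink_rate must lie in [0, 1)")
        if self.track_length <= 0 or self.dt <= 0 or self.tuning_width <= 0:
            raise ValueError("track_length, dt and tuning_width must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SynthCohortConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "peak_rate_range" in raw:
            raw["peak_rate_range"] = tuple(raw["peak_rate_range"])
        return cls(**raw)


def _trajectory(config: SynthCohortConfig, rng: np.random.Generator):
    """Back-and-forth run along the track with occasional pauses."""
    T = config.duration
    speed = np.abs(rng.normal(config.speed_mean, config.speed_std, size=T))
    paused = rng.random(T) < config.pause_prob
    speed[paused] = rng.uniform(0.0, 0.8, size=int(paused.sum()))
    pos = np.empty(T)
    x, d = config.track_length * rng.random(), 1.0
    for t in range(T):
        pos[t] = x
        x += d * speed[t] * config.dt
        if x >= config.track_length:
            x, d = 2 * config.track_length - x, -1.0
        elif x <= 0.0:
            x, d = -x, 1.0
    return pos, speed


def generate_session(
    config: SynthCohortConfig,
    animal: str,
    day: int,
    centers: NDArray,
    amps: NDArray,
    active: NDArray,
    rng: np.random.Generator,
) -> SessionRecording:
    """One session given the day's per-cell field parameters."""
    pos, speed = _trajectory(config, rng)
    width = config.tuning_width * (1.0 - config.shrink_rate) ** day
    rate = amps[None, :] * np.exp(-((pos[:, None] - centers[None, :]) ** 2) / (2 * width**2))
    rate = rate * active[None, :]
    counts = rng.poisson(rate * config.dt).astype(float)
    return SessionRecording(
        animal=animal,
        day=day,
        time=np.arange(config.duration) * config.dt,
        position=pos,
        speed=speed,
        activity=counts,
        track_length=config.track_length,
    )


def generate_cohort(config: SynthCohortConfig) -> dict[str, list[SessionRecording]]:
    """Full cohort: ``n_animals`` animals × ``n_days`` daily sessions.

    Deterministic given ``config.seed``.  On day 0 every cell is active,
    so the per-animal normalization of the active-cell count is exact.
    """
    rng = np.random.default_rng(config.seed)
    cohort: dict[str, list[SessionRecording]] = {}
    for a in range(config.n_animals):
        animal = f"animal_{a:02d}"
        centers = config.track_length * rng.random(config.n_cells)
        amps = rng.uniform(*config.peak_rate_range, size=config.n_cells)
        sessions = []
        for day in range(config.n_days):
            p_active = 1.0 - config.decline_rate * day
            active = rng.random(config.n_cells) < p_active
            sessions.append(
                generate_session(config, animal, day, centers, amps, active, rng)
            )
            centers = np.clip(
                centers + rng.normal(0.0, config.drift_cm_per_day, size=config.n_cells),
                0.0,
                config.track_length,
            )
        cohort[animal] = sessions
    return cohort


def generate_trace_fixture(kind: str, seed: int = 0) -> TrainingTrace:
    """Analytic training traces with known structure, for testing the
    phase segmentation and timescale fitting.

    - ``three-phase``: loss step at t=100, sparsity step at t=10⁴.
    - ``flat``: all curves constant.
    - ``noisy-exponential``: fraction-active curve a·exp(−t/500)+c with
      5% amplitude Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    if kind == "three-phase":
        steps = np.unique(np.geomspace(1, 1e5, 120).astype(int))
        steps = np.concatenate([[0], steps])
        loss = np.where(steps < 100, 1.0, 0.0)
        frac = np.where(steps < 10_000, 1.0, 0.5)
        si = np.where(steps < 10_000, 1.0, 2.0)
    elif kind == "flat":
        steps = np.arange(0, 1000, 10)
        loss = np.full(steps.size, 0.3)
        frac = np.full(steps.size, 0.8)
        si = np.ones(steps.size)
    elif kind == "noisy-exponential":
        steps = np.arange(0, 5001, 25)
        frac = 0.4 * np.exp(-steps / 500.0) + 0.5
        frac = frac + rng.normal(0.0, 0.05 * 0.4, size=steps.size)
        loss = np.full(steps.size, 0.01)
        si = np.ones(steps.size)
    else:
        raise ValueError(f"unknown trace fixture kind {kind!r}")
    return TrainingTrace(
        steps=steps.astype(np.int64),
        raw_loss=loss + 1.0,
        loss=loss,
        active_fraction=frac * 0.6,
        fraction_active_units=frac,
        mean_si=si,
        checkpoints=[],
        config=None,
    )
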