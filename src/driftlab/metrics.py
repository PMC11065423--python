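"""Tuning curves, spatial information, sparsity, drift correlation,
sparsification-timescale fitting, and phase segmentation.

Spatial information follows the classic occupancy-weighted form

    SI = Σ_i p_i (r_i / r̄) log2(r_i / r̄),

with p_i the probability of visiting bin i, r_i the occupancy-normalized
mean activity in bin i, and r̄ = Σ_i p_i r_i the overall mean rate.  Bins
with zero occupancy are excluded; zero-rate bins contribute 0; units with
r̄ = 0 have SI defined as 0.  Units are measured separately per running
direction ("each direction is a separate location").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import optimize

from .model import ACTIVE_TOL, ActivationMatrix

__all__ = [
    "PhaseLabels",
    "RateMaps",
    "TimescaleFit",
    "compute_rate_maps",
    "fit_sparsification_timescale",
    "mean_spatial_information",
    "ratemap_correlation",
    "segment_phases",
    "segment_trace",
    "spatial_information",
    "sparsity_metrics",
    "time_to_plateau",
]


@dataclass
class RateMaps:
    """Occupancy-normalized tuning curves for a population of units.

    ``rates[u, i]`` is the mean activity of unit u in location bin i and is
    NaN where the bin was never visited; ``occupancy`` sums to 1 over the
    visited bins.  When directions are split, the two direction maps are
    concatenated along the bin axis and ``direction_labels`` records which
    direction each bin belongs to.
    """

    rates: NDArray[np.float64]       # (units, total_bins), NaN = unvisited
    occupancy: NDArray[np.float64]   # (total_bins,)
    n_bins: int                      # spatial bins per direction
    direction_labels: NDArray[np.float64]  # (total_bins,)

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def visited(self) -> NDArray[np.bool_]:
        return self.occupancy > 0

    def to_frame(self) -> pd.DataFrame:
        units, bins = np.meshgrid(
            np.arange(self.n_units), np.arange(self.rates.shape[1]), indexing="ij"
        )
        return pd.DataFrame(
            {
                "unit": units.ravel(),
                "direction": np.broadcast_to(self.direction_labels, self.rates.shape).ravel(),
                "bin": bins.ravel() % self.n_bins,
                "rate": self.rates.ravel(),
            }
        )


def compute_rate_maps(
    activations: NDArray,
    positions: NDArray,
    n_bins: int = 100,
    directions: NDArray | None = None,
    split_directions: bool = True,
    pos_range: tuple[float, float] | None = None,
) -> RateMaps:
    """Bin a 1-D position signal and average unit activity per bin.

    ``activations`` is (T, units) time-major (an ``ActivationMatrix`` is
    accepted and transposed); each running direction is treated as a
    separate set of locations when ``split_directions`` is on.
    """
    if isinstance(activations, ActivationMatrix):
        acts = activations.values.T
    else:
        acts = np.atleast_2d(np.asarray(activations, dtype=float))
    positions = np.asarray(positions, dtype=float)
    if acts.shape[0] != positions.shape[0]:
        raise ValueError("activations and positions must share the time axis")
    lo, hi = pos_range if pos_range is not None else (positions.min(), positions.max())
    span = hi - lo if hi > lo else 1.0
    idx = np.clip(((positions - lo) / span * n_bins).astype(int), 0, n_bins - 1)

    if split_directions and directions is not None:
        dirs = np.sign(np.asarray(directions, dtype=float))
        if dirs.shape[0] != positions.shape[0]:
            raise ValueError("directions must share the time axis")
        idx = idx + np.where(dirs > 0, 0, n_bins)  # direction < 0 → second block
        total_bins = 2 * n_bins
        direction_labels = np.concatenate([np.full(n_bins, 1.0), np.full(n_bins, -1.0)])
    else:
        total_bins = n_bins
        direction_labels = np.zeros(n_bins)

    counts = np.bincount(idx, minlength=total_bins).astype(float)
    sums = np.zeros((total_bins, acts.shape[1]))
    np.add.at(sums, idx, acts)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = (sums / counts[:, None]).T
    rates[:, counts == 0] = np.nan
    return RateMaps(
        rates=rates,
        occupancy=counts / counts.sum(),
        n_bins=n_bins,
        direction_labels=direction_labels,
    )


def spatial_information(occupancy: NDArray, rates: NDArray) -> float:
    """SI of one tuning curve, in bits per unit activity (log base 2)."""
    p = np.asarray(occupancy, dtype=float)
    r = np.asarray(rates, dtype=float)
    ok = (p > 0) & np.isfinite(r)
    p, r = p[ok], r[ok]
    if r.size == 0:
        return 0.0
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    p = p / p.sum()
    rbar = float(p @ r)
    if rbar <= 0:
        return 0.0
    pos = r > 0
    ratio = r[pos] / rbar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def mean_spatial_information(
    maps: RateMaps, active_only: bool = True, tol: float = ACTIVE_TOL
) -> float:
    """Mean SI over units; dead units (never above tol) are excluded by
    default since their tuning is undefined."""
    si = np.array([spatial_information(maps.occupancy, maps.rates[u]) for u in range(maps.n_units)])
    if active_only:
        with np.errstate(invalid="ignore"):
            active = np.nansum(np.where(np.isfinite(maps.rates), maps.rates, 0.0), axis=1) > tol
        if not active.any():
            return float("nan")
        si = si[active]
    return float(si.mean())


def sparsity_metrics(acts, tol: float = ACTIVE_TOL) -> tuple[float, float]:
    """(active_fraction, fraction_of_active_units) of a unit×input matrix.

    The matrix is binarized at ``tol``; active_fraction is the mean of the
    binary matrix, and the second value is the fraction of rows (units)
    with at least one active entry.
    """
    values = acts.values if isinstance(acts, ActivationMatrix) else np.asarray(acts, dtype=float)
    if values.size == 0:
        raise ValueError("empty activation matrix")
    binary = values > tol
    return float(binary.mean()), float(binary.any(axis=1).mean())


def ratemap_correlation(
    maps_t1: RateMaps, maps_t2: RateMaps, active_only: bool = True, tol: float = ACTIVE_TOL
) -> tuple[NDArray[np.float64], float]:
    """Per-unit Pearson correlation between two sets of rate maps.

    Bins are pooled over directions.  Units must match; by default only
    units active at both times enter the mean.  Units whose map has zero
    variance get NaN and are excluded from the mean (their count is the
    number of NaNs in the returned vector).
    """
    if maps_t1.rates.shape != maps_t2.rates.shape:
        raise ValueError("rate-map sets must have matching shapes")
    r1, r2 = maps_t1.rates, maps_t2.rates
    corrs = np.full(maps_t1.n_units, np.nan)
    for u in range(maps_t1.n_units):
        a, b = r1[u], r2[u]
        ok = np.isfinite(a) & np.isfinite(b)
        if active_only and not (np.any(a[ok] > tol) and np.any(b[ok] > tol)):
            continue
        if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
            continue
        corrs[u] = np.corrcoef(a[ok], b[ok])[0, 1]
    mean = float(np.nanmean(corrs)) if np.any(np.isfinite(corrs)) else float("nan")
    return corrs, mean


@dataclass
class TimescaleFit:
    """Result of the exponential fit to a declining fraction-active curve."""

    tau: float
    amplitude: float
    plateau: float
    converged: bool  # False = curve had no declining segment to fit

    def __bool__(self) -> bool:
        return self.converged


def fit_sparsification_timescale(
    steps: NDArray, values: NDArray, clip_fraction: float = 0.9
) -> TimescaleFit:
    """Exponential time constant of a declining curve (e.g. fraction of
    active units over training).

    The curve is shifted so its plateau (final value) is zero, clipped at
    the first point where it has completed ``clip_fraction`` of its total
    change (to avoid fitting noise in the plateau), and fit with
    a·exp(−t/τ) by least squares, initialized from a log-linear fit.
    A non-decreasing curve yields ``converged=False`` rather than an error.
    """
    t = np.asarray(steps, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.size < 4:
        raise ValueError("need matching step/value arrays with >= 4 points")
    plateau = y[-1]
    shifted = y - plateau
    a0 = shifted[0]
    if a0 <= 0 or not np.any(shifted[1:] < a0):
        return TimescaleFit(tau=np.nan, amplitude=np.nan, plateau=plateau, converged=False)

    # clip where the curve first completes clip_fraction of its change
    done = shifted <= (1.0 - clip_fraction) * a0
    end = int(np.argmax(done)) + 1 if done.any() else t.size
    end = max(end, 4)
    tc, yc = t[:end], shifted[:end]

    pos = yc > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(tc[pos], np.log(yc[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else (tc[-1] - tc[0])
    else:
        tau0 = tc[-1] - tc[0]
    tau0 = float(np.clip(tau0, 1e-9, 1e12))
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            tc,
            yc,
            p0=(a0, tau0),
            maxfev=10000,
        )
    except RuntimeError:
        return TimescaleFit(tau=np.nan, amplitude=np.nan, plateau=plateau, converged=False)
    a, tau = popt
    if tau <= 0:
        return TimescaleFit(tau=np.nan, amplitude=a, plateau=plateau, converged=False)
    return TimescaleFit(tau=float(tau), amplitude=float(a), plateau=float(plateau), converged=True)


@dataclass
class PhaseLabels:
    """Index boundaries of the three phases of noisy learning.

    Phase 1 (task learning) runs up to the loss plateau; phase 2 (directed
    drift) up to the sparsity plateau; phase 3 (null drift) is the rest.
    Boundaries are indices into the logged trace, with
    ``0 <= end_learning <= end_directed <= n``.
    """

    end_learning: int
    end_directed: int
    n: int

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(0, self.end_learning),
            slice(self.end_learning, self.end_directed),
            slice(self.end_directed, self.n),
        )


def segment_trace(trace, loss_frac: float = 0.25, sparsity_tol: float = 0.05) -> "PhaseLabels":
    """Segment a training trace with tolerances tied to its own scales.

    The loss tolerance is ``loss_frac`` of the total (baseline-adjusted)
    loss drop — the plateau begins once the loss has durably completed
    that fraction of its approach to the final value.  The sparsity
    tolerance is an absolute band on the fraction of active units.
    """
    drop = abs(float(trace.loss[0]) - float(trace.loss[-1]))
    return segment_phases(
        trace.steps,
        trace.loss,
        trace.fraction_active_units,
        loss_tol=loss_frac * drop if drop > 0 else 1e-12,
        sparsity_tol=sparsity_tol,
    )


def time_to_plateau(steps: NDArray, loss: NDArray, frac: float = 0.25) -> int:
    """Time-to-criterion measure of initial convergence: the first logged
    step at which the loss has completed ``1 − frac`` of its total drop
    (entered the ±frac·drop band around its final value).

    Unlike the settling times used for phase segmentation, a first
    crossing is robust to the slow second-order loss improvement during
    the directed-drift phase (sparsification reduces the noise-induced
    excess loss, so a noisy run's loss keeps creeping down long after the
    fast learning phase is over).
    """
    loss = np.asarray(loss, dtype=float)
    drop = loss[0] - loss[-1]
    if drop <= 0:
        return int(np.asarray(steps)[0])
    inside = np.abs(loss - loss[-1]) <= frac * drop
    return int(np.asarray(steps)[int(np.argmax(inside))])


def _first_settled(values: NDArray, tol: float) -> int:
    """First index from which the series stays within tol of its final value."""
    final = values[-1]
    inside = np.abs(values - final) <= tol
    # last index that is outside, +1
    outside = np.nonzero(~inside)[0]
    return int(outside[-1] + 1) if outside.size else 0


def segment_phases(
    steps: NDArray,
    loss: NDArray,
    fraction_active_units: NDArray,
    loss_tol: float,
    sparsity_tol: float,
) -> PhaseLabels:
    """Split a training trace into learning / directed drift / null drift.

    Phase 1 ends when the (baseline-adjusted) loss first stays within
    ``loss_tol`` of its final plateau; phase 2 ends when the fraction of
    active units first stays within ``sparsity_tol`` of its final value.
    A never-settling loss makes phase 1 cover the whole trace.
    """
    loss = np.asarray(loss, dtype=float)
    frac = np.asarray(fraction_active_units, dtype=float)
    n = loss.size
    if frac.size != n or np.asarray(steps).size != n:
        raise ValueError("trace arrays must share length")
    end_learning = _first_settled(loss, loss_tol)
    end_directed = max(_first_settled(frac, sparsity_tol), end_learning)
    return PhaseLabels(end_learning=end_learning, end_directed=end_directed, n=n)
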