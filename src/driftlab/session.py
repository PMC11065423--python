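"""Multi-session place-cell statistics and cross-day trends.

The pipeline mirrors standard chronic-recording analyses of hippocampal
CA1: per session, timesteps are speed-filtered, occupancy-normalized rate
maps are built per cell and running direction, place cells are classified
by a circular-shift shuffle test on spatial information, and per-session
summary statistics (fraction of place cells or number of active cells,
mean SI) are normalized to each animal's first session.  Trends across
days are then assessed by ordinary least squares with an intercept and a
two-sided t-test on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.typing import NDArray

from .metrics import RateMaps, compute_rate_maps, spatial_information

__all__ = [
    "SessionRecording",
    "SessionStats",
    "TrendResult",
    "classify_place_cells",
    "cohort_statistics",
    "preprocess",
    "session_rate_maps",
    "session_statistics",
    "trend_regression",
]


@dataclass
class SessionRecording:
    """One recording session on a 1-D track.

    ``activity`` holds per-timestep event counts or rates, one column per
    cell.  ``day`` is the experience-day index (sessions from interleaved
    environments that share an experience day carry the same index and are
    pooled by :func:`session_statistics`).
    """

    animal: str
    day: int
    time: NDArray[np.float64]       # seconds
    position: NDArray[np.float64]   # cm along the track
    speed: NDArray[np.float64]      # cm/s
    activity: NDArray[np.float64]   # (T, n_cells)
    track_length: float
    cell_ids: NDArray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.activity = np.atleast_2d(np.asarray(self.activity, dtype=float))
        T = self.time.shape[0]
        if self.position.shape[0] != T or self.speed.shape[0] != T or self.activity.shape[0] != T:
            raise ValueError("time, position, speed and activity must share the time axis")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.activity.shape[1])

    @property
    def n_cells(self) -> int:
        return self.activity.shape[1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size > 1 else 0.0

    @property
    def directions(self) -> NDArray[np.float64]:
        """Running direction inferred from the position signal."""
        d = np.sign(np.gradient(self.position))
        d[d == 0] = 1.0
        return d

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "position": self.position, "speed": self.speed})
        for j, cid in enumerate(self.cell_ids):
            df[f"cell_{cid}"] = self.activity[:, j]
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, animal: str, day: int, track_length: float
    ) -> "SessionRecording":
        cells = [c for c in df.columns if c.startswith("cell_")]
        return cls(
            animal=animal,
            day=day,
            time=df["time"].to_numpy(),
            position=df["position"].to_numpy(),
            speed=df["speed"].to_numpy(),
            activity=df[cells].to_numpy(),
            track_length=track_length,
            cell_ids=np.array([c.removeprefix("cell_") for c in cells]),
        )


def preprocess(
    session: SessionRecording,
    speed_threshold: float = 1.0,
    min_rate: float | None = None,
) -> SessionRecording:
    """Movement filter and optional low-rate cell exclusion.

    Only timesteps where the animal moved faster than ``speed_threshold``
    (cm/s, strictly) are kept.  ``min_rate`` (Hz) excludes cells whose
    average event rate falls at or below it — used for dataset styles
    where place-cell classification is impossible and "active cells" is
    the statistic instead.
    """
    keep = session.speed > speed_threshold
    if not keep.any():
        raise ValueError("speed filter removed every timestep (empty session)")
    out = replace(
        session,
        time=session.time[keep],
        position=session.position[keep],
        speed=session.speed[keep],
        activity=session.activity[keep],
    )
    if min_rate is not None:
        dt = np.median(np.diff(session.time)) if session.time.size > 1 else 1.0
        duration = out.activity.shape[0] * dt
        rates = out.activity.sum(axis=0) / max(duration, 1e-12)
        cells = rates > min_rate
        out = replace(out, activity=out.activity[:, cells], cell_ids=out.cell_ids[cells])
    return out


def session_rate_maps(
    session: SessionRecording, bin_cm: float = 4.0, split_directions: bool = True
) -> RateMaps:
    """Occupancy-normalized maps per cell and running direction, with
    spatial bins of ``bin_cm`` centimetres."""
    n_bins = max(int(np.ceil(session.track_length / bin_cm)), 1)
    return compute_rate_maps(
        session.activity,
        session.position,
        n_bins=n_bins,
        directions=session.directions if split_directions else None,
        split_directions=split_directions,
        pos_range=(0.0, session.track_length),
    )


def _si_per_cell(session: SessionRecording, bin_cm: float, activity: NDArray | None = None) -> NDArray:
    acts = session.activity if activity is None else activity
    n_bins = max(int(np.ceil(session.track_length / bin_cm)), 1)
    maps = compute_rate_maps(
        acts, session.position, n_bins=n_bins, directions=session.directions,
        pos_range=(0.0, session.track_length),
    )
    return np.array(
        [spatial_information(maps.occupancy, maps.rates[u]) for u in range(maps.n_units)]
    )


def classify_place_cells(
    session: SessionRecording,
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
    bin_cm: float = 4.0,
    min_shift_s: float = 10.0,
) -> NDArray[np.bool_]:
    """Shuffle test for place cells.

    Each cell's observed SI is compared against a null distribution built
    by circularly shifting its activity against position by uniform random
    offsets of at least ``min_shift_s`` seconds (from either end).  A cell
    is a place cell iff its SI exceeds the given percentile of its null.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    T = session.activity.shape[0]
    dt = np.median(np.diff(session.time)) if T > 1 else 1.0
    min_shift = int(np.ceil(min_shift_s / dt))
    if T <= 2 * min_shift:
        raise ValueError(
            f"session too short for circular shifts of >= {min_shift_s} s "
            f"({T} steps, minimum shift {min_shift})"
        )
    rng = np.random.default_rng(seed)
    observed = _si_per_cell(session, bin_cm)
    null = np.empty((n_shuffles, session.n_cells))
    offsets = rng.integers(min_shift, T - min_shift, size=n_shuffles)
    for s, off in enumerate(offsets):
        shifted = np.roll(session.activity, int(off), axis=0)
        null[s] = _si_per_cell(session, bin_cm, activity=shifted)
    threshold = np.percentile(null, percentile, axis=0)
    return observed > threshold


@dataclass
class SessionStats:
    """Per-(animal, day) summary statistics, normalized to day one."""

    table: pd.DataFrame  # columns: animal, day, n_active, stat, mean_si, stat_norm, si_norm

    def __post_init__(self) -> None:
        first = self.table.sort_values("day").groupby("animal").first()
        if not np.allclose(first["stat_norm"], 1.0) or not np.allclose(first["si_norm"], 1.0):
            raise ValueError("first-session normalized values must equal 1")


def session_statistics(
    sessions: list[SessionRecording],
    mode: str = "place_fraction",
    speed_threshold: float = 1.0,
    min_rate: float | None = 0.1,
    bin_cm: float = 4.0,
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day statistics for one animal's sessions.

    ``mode='place_fraction'`` classifies place cells per session and
    reports their fraction; ``mode='active_count'`` skips classification
    and reports the number of cells passing the ``min_rate`` filter (for
    data where spikes are unavailable).  Mean SI is taken over the
    included cells.  Sessions sharing an experience day are pooled.
    Values are normalized to the animal's first session.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if mode not in ("place_fraction", "active_count"):
        raise ValueError("mode must be 'place_fraction' or 'active_count'")
    animal = sessions[0].animal
    per_day: dict[int, dict[str, list]] = {}
    for sess in sorted(sessions, key=lambda s: s.day):
        pre = preprocess(
            sess,
            speed_threshold=speed_threshold,
            min_rate=min_rate if mode == "active_count" else None,
        )
        si = _si_per_cell(pre, bin_cm)
        if mode == "place_fraction":
            is_pc = classify_place_cells(
                pre, n_shuffles=n_shuffles, percentile=percentile, seed=seed + sess.day,
                bin_cm=bin_cm,
            )
            stat_num, stat_den = float(is_pc.sum()), float(pre.n_cells)
            si_cells = si[is_pc] if is_pc.any() else si
        else:
            stat_num, stat_den = float(pre.n_cells), 1.0
            si_cells = si
        d = per_day.setdefault(sess.day, {"num": [], "den": [], "si": []})
        d["num"].append(stat_num)
        d["den"].append(stat_den)
        d["si"].append(si_cells)

    rows = []
    for day in sorted(per_day):
        d = per_day[day]
        pooled_si = np.concatenate(d["si"]) if d["si"] else np.array([np.nan])
        stat = sum(d["num"]) / sum(d["den"])
        rows.append(
            {
                "animal": animal,
                "day": day,
                "n_active": sum(d["num"]) if mode == "active_count" else np.nan,
                "stat": stat,
                "mean_si": float(np.mean(pooled_si)) if pooled_si.size else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    first = df.iloc[0]
    if first["stat"] == 0 or not np.isfinite(first["mean_si"]) or first["mean_si"] == 0:
        raise ValueError("first-session statistic is zero; cannot normalize")
    df["stat_norm"] = df["stat"] / first["stat"]
    df["si_norm"] = df["mean_si"] / first["mean_si"]
    return df


def cohort_statistics(
    cohort: dict[str, list[SessionRecording]], mode: str = "place_fraction", **kwargs
) -> pd.DataFrame:
    """Concatenated per-animal statistics for a whole cohort."""
    return pd.concat(
        [session_statistics(sessions, mode=mode, **kwargs) for sessions in cohort.values()],
        ignore_index=True,
    )


@dataclass
class TrendResult:
    """OLS slope of a normalized statistic against time."""

    slope: float
    intercept: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def trend_regression(values: NDArray, times: NDArray) -> TrendResult:
    """OLS of the statistic on time with an intercept; two-sided t-test
    on the slope against zero."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if y.size < 3:
        raise ValueError("need at least 3 finite points for a trend")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis (no spread)")
    if np.allclose(y, y[0], rtol=0.0, atol=1e-12 * max(1.0, abs(float(y[0])))):
        return TrendResult(slope=0.0, intercept=float(y[0]), p_value=1.0, n=int(y.size))
    res = sm.OLS(y, sm.add_constant(t)).fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    p = float(res.pvalues[1])
    if not np.isfinite(p):  # exact fit: zero residual variance degenerates the t-test
        p = 0.0 if abs(slope) > 0 else 1.0
    return TrendResult(
        slope=slope,
        intercept=intercept,
        p_value=float(min(max(p, 0.0), 1.0)),
        n=int(y.size),
    )
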