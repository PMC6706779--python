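"""Fitness bookkeeping for serial-transfer evolution experiments.

A lineage is propagated by repeated dilution into fresh medium.  Each passage
contributes ``log2(OD_f / OD_i)`` generations of binary fission, the running
sum of those contributions is the accumulated-generation clock, and the
doubling time of a passage is its wall-clock duration divided by the
generations it contributed.  Doubling time plotted against accumulated
generations is the standard fitness trajectory of such experiments.

The module also estimates specific growth rates (per hour) from microplate
OD600 kinetics with a sliding log-linear window, the usual replacement for a
plate-reader vendor's black-box estimator: blank-subtract, log-transform,
fit every window of consecutive points, and keep the steepest slope among
windows whose fit is good enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError, UndefinedDoublingTimeError

__all__ = [
    "PassageRecord",
    "TrajectoryPoint",
    "FitnessTrajectory",
    "GrowthCurve",
    "GrowthRateFit",
    "generations_per_passage",
    "accumulated_generations",
    "doubling_time_per_passage",
    "fitness_trajectory",
    "estimate_growth_rate",
]


@dataclass(frozen=True)
class PassageRecord:
    """One serial-transfer passage of one lineage."""

    lineage_id: str
    passage_index: int  # 1-based, contiguous per lineage
    od_initial: float
    od_final: float
    elapsed_hours: float

    def __post_init__(self):
        if self.od_initial <= 0 or self.od_final <= 0:
            raise DomainError("optical densities must be positive")
        if self.elapsed_hours <= 0:
            raise DomainError("elapsed_hours must be positive")
        if self.passage_index < 1:
            raise DomainError("passage_index is 1-based")


@dataclass(frozen=True)
class TrajectoryPoint:
    passage_index: int
    accumulated_generations: float
    doubling_time_hours: float


@dataclass(frozen=True)
class FitnessTrajectory:
    """Doubling time as a function of accumulated generations.

    ``flagged_passages`` lists passages (beyond the first) that showed zero or
    negative net growth and were therefore omitted from ``points``.
    """

    lineage_id: str
    points: tuple[TrajectoryPoint, ...]
    flagged_passages: tuple[int, ...] = ()


@dataclass(frozen=True)
class GrowthCurve:
    """Time-stamped OD600 series for one well."""

    well_id: str
    substrate: str
    times_hours: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times_hours, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.size != y.size:
            raise DomainError("times and OD values must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.times_hours, dtype=float),
            np.asarray(self.od, dtype=float),
        )


@dataclass(frozen=True)
class GrowthRateFit:
    """Result of the sliding-window growth-rate estimate.

    ``rate`` is 0.0 when no window passed the R-squared gate; ``flag`` then
    explains why ("no_growth" or "low_signal").
    """

    rate: float
    r_squared: float = float("nan")
    window_start_hours: float = float("nan")
    window_end_hours: float = float("nan")
    flag: str = ""

    @property
    def doubling_time_hours(self) -> float:
        if self.rate <= 0:
            return float("inf")
        return float(np.log(2.0) / self.rate)


def generations_per_passage(od_initial: float, od_final: float) -> float:
    """Generations of growth in one passage: log2 of the OD fold-expansion.

    Negative when the culture shrank.
    """
    if od_initial <= 0 or od_final <= 0:
        raise DomainError("optical densities must be positive")
    return float(np.log2(od_final / od_initial))


def accumulated_generations(log: Iterable[PassageRecord]) -> float:
    """Sum of per-passage generations over the whole log (empty log -> 0)."""
    return float(
        sum(generations_per_passage(r.od_initial, r.od_final) for r in log)
    )


def doubling_time_per_passage(record: PassageRecord) -> float:
    """Wall-clock hours per generation within one passage."""
    g = generations_per_passage(record.od_initial, record.od_final)
    if g <= 0:
        raise UndefinedDoublingTimeError(
            f"passage {record.passage_index} of {record.lineage_id} did not grow"
        )
    return record.elapsed_hours / g


def fitness_trajectory(log: Sequence[PassageRecord]) -> FitnessTrajectory:
    """Build the doubling-time-vs-generation trajectory for one lineage.

    The first passage is excluded from the reported points because cultures
    coming out of stationary-phase stocks carry physiological history that
    distorts its doubling time; it still advances the generation clock.
    Later passages without net growth are omitted and flagged rather than
    failing the whole lineage.
    """
    records = sorted(log, key=lambda r: r.passage_index)
    if len(records) < 2:
        raise InsufficientDataError("a trajectory needs at least two passages")
    lineage_ids = {r.lineage_id for r in records}
    if len(lineage_ids) != 1:
        raise DomainError(f"records from multiple lineages: {sorted(lineage_ids)}")
    indices = [r.passage_index for r in records]
    if indices != list(range(indices[0], indices[0] + len(records))):
        raise DomainError("passage indices must be contiguous")

    points: list[TrajectoryPoint] = []
    flagged: list[int] = []
    acc = 0.0
    for i, rec in enumerate(records):
        acc += generations_per_passage(rec.od_initial, rec.od_final)
        if i == 0:
            continue
        try:
            td = doubling_time_per_passage(rec)
        except UndefinedDoublingTimeError:
            flagged.append(rec.passage_index)
            continue
        points.append(TrajectoryPoint(rec.passage_index, acc, td))
    return FitnessTrajectory(
        lineage_id=records[0].lineage_id,
        points=tuple(points),
        flagged_passages=tuple(flagged),
    )


def _window_fits(t: np.ndarray, y: np.ndarray, w: int):
    """Least-squares slope and R^2 of every window of ``w`` consecutive points.

    Vectorised via windowed sums; returns (slopes, r2) arrays of length
    ``len(t) - w + 1``.
    """
    n = t.size
    k = n - w + 1

    def winsum(x):
        c = np.concatenate(([0.0], np.cumsum(x)))
        return c[w:] - c[:-w]

    st, sy = winsum(t), winsum(y)
    stt, syy, sty = winsum(t * t), winsum(y * y), winsum(t * y)
    var_t = stt - st * st / w
    var_y = syy - sy * sy / w
    cov = sty - st * sy / w
    slopes = np.divide(cov, var_t, out=np.zeros(k), where=var_t > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var_y > 0, cov * cov / (var_t * var_y), 1.0)
    return slopes, r2


def estimate_growth_rate(
    curve: GrowthCurve,
    blank: float = 0.0,
    window_points: int = 8,
    min_r2: float = 0.98,
    signal_floor: float = 0.005,
) -> GrowthRateFit:
    """Maximum log-linear slope of the blank-subtracted curve.

    Parameters
    ----------
    curve:
        OD600 kinetic series.
    blank:
        Background OD to subtract (e.g. the medium blank level).
    window_points:
        Number of consecutive points per regression window (>= 4).  Wider
        windows trade time resolution for noise suppression.
    min_r2:
        Windows with a coefficient of determination below this are rejected.
    signal_floor:
        Points with ``OD - blank`` below this are discarded before the log
        transform; 0.005 OD is around the resolution of a plate reader.

    Returns
    -------
    GrowthRateFit
        ``rate`` is the steepest qualifying slope in 1/h; 0.0 with a flag when
        nothing qualifies.  Doubling time follows as ``ln 2 / rate``.
    """
    if window_points < 4:
        raise DomainError("window_points must be >= 4")
    t, y = curve.arrays()
    signal = y - blank
    usable = signal >= signal_floor
    if usable.sum() < window_points:
        return GrowthRateFit(0.0, flag="low_signal")
    # windows must be consecutive *usable* samples: scan each contiguous run
    best = None
    idx = np.flatnonzero(usable)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    for run in runs:
        if run.size < window_points:
            continue
        tt = t[run]
        yy = np.log(signal[run])
        slopes, r2 = _window_fits(tt, yy, window_points)
        ok = r2 >= min_r2
        if not np.any(ok):
            continue
        j = int(np.flatnonzero(ok)[np.argmax(slopes[ok])])
        cand = (float(slopes[j]), float(r2[j]), float(tt[j]), float(tt[j + window_points - 1]))
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None or best[0] <= 1e-10:  # numerically flat
        return GrowthRateFit(0.0, flag="no_growth")
    return GrowthRateFit(best[0], best[1], best[2], best[3])
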