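"""Strain-ratio quantification for paired-competition experiments.

Two strains sharing a culture are distinguished by strain-specific qPCR
primer sets: set A amplifies only the wild-type marker locus, set B only the
deletion-scar of the mutator.  Because genomic DNA quantity tracks cell
density and one qPCR cycle corresponds to one template doubling (at perfect
efficiency), the mutator:wild-type abundance ratio follows directly from the
difference of quantification cycles:

    ratio = 1 / 2**(Cq_B - Cq_A) = 2**(Cq_A - Cq_B)

A mixing series of known compositions regressed against their measured
ratios validates the readout; on competition time courses, the generation at
which the losing strain drops below a displacement threshold (0.1% by
convention) summarises the outcome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import (
    CalibrationError,
    DomainError,
    InsufficientDataError,
    OneSidedDetectionError,
)
from .synth_data import QpcrSample

__all__ = [
    "CalibrationResult",
    "CompetitionTrace",
    "Displacement",
    "ratio_from_cq",
    "fraction_from_ratio",
    "ratio_to_fraction_trace",
    "calibrate",
    "displacement_generation",
]


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class CompetitionTrace:
    """Mutator fraction over the generation clock of a competition culture."""

    generations: tuple[float, ...]
    fraction_mutator: tuple[float, ...]

    def __post_init__(self):
        g = np.asarray(self.generations)
        f = np.asarray(self.fraction_mutator)
        if g.size != f.size:
            raise DomainError("generations and fractions must align")
        if g.size and np.any(np.diff(g) <= 0):
            raise DomainError("generations must be strictly increasing")
        if f.size and (np.min(f) < 0 or np.max(f) > 1):
            raise DomainError("fractions must lie in [0, 1]")


class Displacement(NamedTuple):
    generation: float
    displaced: str  # "wildtype" or "mutator"


def ratio_from_cq(cq_a: float | None, cq_b: float | None, efficiency: float = 1.0) -> float:
    """Mutator:wild-type ratio from a pair of quantification cycles.

    With the fixed primer convention (A = wild-type-specific, B =
    mutator-specific) and per-cycle gain ``efficiency`` this is
    ``(1 + efficiency)**(cq_a - cq_b)``, i.e. ``1 / 2**(cq_b - cq_a)`` at
    perfect doubling.  Values above 1 mean mutator excess.

    A ``None`` on either side (no amplification) raises
    :class:`OneSidedDetectionError` — the true ratio is then zero or
    infinite, which callers must handle as an outcome, not a number.
    """
    if cq_a is None and cq_b is None:
        raise DomainError("neither target amplified")
    if cq_a is None:
        raise OneSidedDetectionError("B")
    if cq_b is None:
        raise OneSidedDetectionError("A")
    if not 0 < efficiency <= 1:
        raise DomainError("efficiency must lie in (0, 1]")
    return float((1.0 + efficiency) ** (cq_a - cq_b))


def fraction_from_ratio(ratio: float) -> float:
    """Convert a mutator:wild-type ratio r to the mutator fraction r/(1+r)."""
    if ratio < 0:
        raise DomainError("ratio must be non-negative")
    if math.isinf(ratio):
        return 1.0
    return ratio / (1.0 + ratio)


def _mean_cq(values: Sequence[float | None]) -> float | None:
    """Average duplicate Cq measurements on the cycle scale; None if any failed."""
    if any(v is None for v in values) or not values:
        return None
    return float(np.mean([float(v) for v in values]))


def ratio_to_fraction_trace(samples: Sequence[QpcrSample]) -> CompetitionTrace:
    """Collapse replicate Cq pairs per generation into a mutator-fraction trace.

    Duplicates are averaged on the Cq scale before the ratio is formed.
    One-sided detections map to fraction 0 or 1 (complete displacement).
    """
    by_gen: dict[float, list[QpcrSample]] = {}
    for s in samples:
        by_gen.setdefault(s.generation, []).append(s)
    gens, fracs = [], []
    for gen in sorted(by_gen):
        group = by_gen[gen]
        cq_a = _mean_cq([s.cq_a for s in group])
        cq_b = _mean_cq([s.cq_b for s in group])
        try:
            frac = fraction_from_ratio(ratio_from_cq(cq_a, cq_b))
        except OneSidedDetectionError as exc:
            frac = 1.0 if exc.detected == "B" else 0.0
        gens.append(gen)
        fracs.append(frac)
    return CompetitionTrace(tuple(gens), tuple(fracs))


def calibrate(
    theoretical_fractions: Sequence[float],
    samples: Sequence[QpcrSample],
    efficiency: float = 1.0,
) -> CalibrationResult:
    """Mixing-series calibration: regress empirical on theoretical ratio.

    ``samples`` must carry one distinct ``sample_id`` per mixing point, in
    the same order as ``theoretical_fractions`` (first appearance order);
    replicate ratios within a point are averaged after the delta-Cq
    transform.  Ordinary least squares of empirical on theoretical ratio;
    note R-squared of a simple linear regression is direction-invariant, so
    the reported fit quality does not depend on that orientation choice.

    One-sided detections are excluded with a warning; fewer than two
    surviving points (or fewer than two distinct theoretical ratios) is a
    :class:`CalibrationError`.
    """
    order: list[str] = []
    groups: dict[str, list[QpcrSample]] = {}
    for s in samples:
        if s.sample_id not in groups:
            order.append(s.sample_id)
            groups[s.sample_id] = []
        groups[s.sample_id].append(s)
    if len(order) != len(theoretical_fractions):
        raise CalibrationError(
            f"{len(order)} mixing points in samples vs "
            f"{len(theoretical_fractions)} theoretical fractions"
        )
    xs, ys = [], []
    for frac, sid in zip(theoretical_fractions, order):
        if not 0 < frac < 1:
            raise DomainError("theoretical fractions must lie strictly in (0, 1)")
        ratios = []
        for s in groups[sid]:
            try:
                ratios.append(ratio_from_cq(s.cq_a, s.cq_b, efficiency))
            except OneSidedDetectionError:
                warnings.warn(
                    f"one-sided detection in mixing point {sid!r} excluded",
                    stacklevel=2,
                )
        if not ratios:
            continue
        xs.append(frac / (1.0 - frac))
        ys.append(float(np.mean(ratios)))
    if len(xs) < 2 or len(set(xs)) < 2:
        raise CalibrationError("need at least two distinct mixing points")
    fit = stats.linregress(xs, ys)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(xs),
    )


def displacement_generation(
    trace: CompetitionTrace, threshold: float = 0.001
) -> Displacement | None:
    """First generation at which either strain falls below ``threshold``.

    Returns the crossing generation and which strain was displaced, or
    ``None`` if neither strain ever drops that low.
    """
    if not 0 < threshold < 0.5:
        raise DomainError("threshold must lie in (0, 0.5)")
    if not trace.generations:
        raise InsufficientDataError("empty competition trace")
    for gen, f in zip(trace.generations, trace.fraction_mutator):
        if f < threshold:
            return Displacement(gen, "mutator")
        if 1.0 - f < threshold:
            return Displacement(gen, "wildtype")
    return None
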