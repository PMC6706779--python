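"""Phenotype-microarray (96-well carbon panel) fitness-landscape analysis.

Each plate carries 95 single-carbon substrates plus a nutrient-free negative
control in well A01.  The specific growth rate estimated from the control
well sets the growth threshold: a substrate supports growth only if its rate
strictly exceeds the control's apparent rate.  Evolved-vs-ancestor
comparisons on each substrate follow a fixed decision order:

1. neither grows                      -> no_growth
2. only the evolved strain grows      -> gain_of_function
3. only the ancestor grows            -> loss_of_function
4. two-sample equal-variance t-test on technical-replicate rates,
   p > 0.05                           -> non_significant
5. otherwise log2 fold-change of mean rates; positive changes fall into
   half-open magnitude tiers low [0, 0.5), mid [0.5, 1.0), high [1.0, inf),
   negative ones into fitness_loss

Tier boundaries are half-open by design so that every fold-change maps to
exactly one tier.  Strain contrasts on category counts use Pearson's
chi-squared on 2x2 tables (substrates in/out of the category per strain),
either per carbon condition (denominator 95) or pooled across carbons
(denominator 190); no continuity correction unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTableError,
    DomainError,
    InsufficientDataError,
    TabulationError,
)
from .fitness_kinetics import GrowthCurve, estimate_growth_rate

__all__ = [
    "PM_CATEGORIES",
    "CONTRASTS",
    "SubstrateOutcome",
    "PmTabulation",
    "ContingencyTable2x2",
    "growth_threshold",
    "call_growth",
    "substrate_outcome",
    "analyze_plates",
    "tabulate",
    "pearson_chi2",
    "strain_contrasts",
]

PM_CATEGORIES = (
    "gain_of_function",
    "loss_of_function",
    "no_growth",
    "non_significant",
    "fitness_gain_low",
    "fitness_gain_mid",
    "fitness_gain_high",
    "fitness_loss",
)

#: contrasts reported by strain_contrasts: name -> categories counted as "in"
CONTRASTS: dict[str, tuple[str, ...]] = {
    "gain_of_function": ("gain_of_function",),
    "loss_of_function": ("loss_of_function",),
    "fitness_gain_total": ("fitness_gain_low", "fitness_gain_mid", "fitness_gain_high"),
    "fitness_gain_mid": ("fitness_gain_mid",),
    "fitness_gain_high": ("fitness_gain_high",),
}

PLATE_SIZE = 95  # substrate wells per plate (A01 is the control)


@dataclass(frozen=True)
class SubstrateOutcome:
    substrate: str
    rate_ancestor: float
    rate_evolved: float
    log2fc: float  # NaN unless both strains grow
    p_value: float  # NaN when the t-test was not reached
    category: str


@dataclass(frozen=True)
class PmTabulation:
    """Category counts for one strain x carbon condition (sums to 95)."""

    counts: Mapping[str, int]

    def __post_init__(self):
        unknown = set(self.counts) - set(PM_CATEGORIES)
        if unknown:
            raise TabulationError(f"unknown categories: {unknown}")
        if sum(self.counts.values()) != PLATE_SIZE:
            raise TabulationError(
                f"categories must partition the {PLATE_SIZE} substrates "
                f"(got {sum(self.counts.values())})"
            )

    def __getitem__(self, category: str) -> int:
        return int(self.counts.get(category, 0))

    @property
    def fitness_gain_total(self) -> int:
        return sum(self[c] for c in CONTRASTS["fitness_gain_total"])

    def in_contrast(self, name: str) -> int:
        if name == "fitness_gain_total":
            return self.fitness_gain_total
        return sum(self[c] for c in CONTRASTS[name])


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DegenerateTableError("empty table")


def growth_threshold(plate: Sequence[GrowthCurve], blank: float = 0.0, **rate_kwargs) -> float:
    """Apparent specific growth rate of the negative-control well A01.

    Any drift the nutrient-free control shows is instrument/evaporation
    artefact; substrate wells must beat it to count as growing.
    """
    controls = [c for c in plate if c.well_id == "A01"]
    if not controls:
        raise InsufficientDataError("plate has no A01 negative-control well")
    return estimate_growth_rate(controls[0], blank=blank, **rate_kwargs).rate


def call_growth(rate: float, threshold: float) -> bool:
    """Growth iff the rate strictly exceeds the control threshold."""
    return rate > threshold


def substrate_outcome(
    substrate: str,
    ancestor_rates: Sequence[float],
    evolved_rates: Sequence[float],
    threshold: float,
    alpha: float = 0.05,
) -> SubstrateOutcome:
    """Categorise one substrate from replicate growth rates of both strains.

    Requires at least two technical replicates per strain (the t-test is run
    exactly as fragile as a two-vs-two design makes it: equal-variance,
    two-sided).
    """
    anc = np.asarray(ancestor_rates, dtype=float)
    evo = np.asarray(evolved_rates, dtype=float)
    if anc.size < 2 or evo.size < 2:
        raise InsufficientDataError("need >= 2 replicate rates per strain")
    rate_a, rate_e = float(anc.mean()), float(evo.mean())
    grows_a = call_growth(rate_a, threshold)
    grows_e = call_growth(rate_e, threshold)
    nan = float("nan")
    if not grows_a and not grows_e:
        return SubstrateOutcome(substrate, rate_a, rate_e, nan, nan, "no_growth")
    if not grows_a:
        return SubstrateOutcome(substrate, rate_a, rate_e, nan, nan, "gain_of_function")
    if not grows_e:
        return SubstrateOutcome(substrate, rate_a, rate_e, nan, nan, "loss_of_function")
    t, p = stats.ttest_ind(evo, anc, equal_var=True)
    p = float(p)
    if rate_a <= 0:
        raise DomainError(f"{substrate}: growth call with non-positive ancestor mean")
    log2fc = float(np.log2(rate_e / rate_a))
    if p > alpha:
        return SubstrateOutcome(substrate, rate_a, rate_e, log2fc, p, "non_significant")
    if log2fc < 0:
        category = "fitness_loss"
    elif log2fc >= 1.0:
        category = "fitness_gain_high"
    elif log2fc >= 0.5:
        category = "fitness_gain_mid"
    else:
        category = "fitness_gain_low"
    return SubstrateOutcome(substrate, rate_a, rate_e, log2fc, p, category)


def analyze_plates(
    ancestor_plates: Sequence[Sequence[GrowthCurve]],
    evolved_plates: Sequence[Sequence[GrowthCurve]],
    blank: float = 0.0,
    alpha: float = 0.05,
    **rate_kwargs,
) -> list[SubstrateOutcome]:
    """Full-plate comparison from replicate kinetic reads.

    Each element of ``*_plates`` is one technical-replicate plate (a list of
    96 curves).  Thresholds are estimated per plate from each A01 and
    averaged within strain; per-substrate replicate rates feed
    :func:`substrate_outcome`.  The comparison threshold is the mean of the
    two strains' thresholds.
    """
    def plate_rates(plates):
        thresholds = [growth_threshold(p, blank=blank, **rate_kwargs) for p in plates]
        rates: dict[str, list[float]] = {}
        for plate in plates:
            for curve in plate:
                if curve.well_id == "A01":
                    continue
                rates.setdefault(curve.substrate, []).append(
                    estimate_growth_rate(curve, blank=blank, **rate_kwargs).rate
                )
        return float(np.mean(thresholds)), rates

    thr_a, rates_a = plate_rates(ancestor_plates)
    thr_e, rates_e = plate_rates(evolved_plates)
    if set(rates_a) != set(rates_e):
        raise TabulationError("ancestor and evolved plates disagree on substrates")
    threshold = 0.5 * (thr_a + thr_e)
    return [
        substrate_outcome(s, rates_a[s], rates_e[s], threshold, alpha=alpha)
        for s in sorted(rates_a)
    ]


def tabulate(outcomes: Sequence[SubstrateOutcome]) -> PmTabulation:
    """Count categories over a complete plate of 95 substrate outcomes."""
    substrates = [o.substrate for o in outcomes]
    if len(substrates) != PLATE_SIZE or len(set(substrates)) != PLATE_SIZE:
        raise TabulationError(
            f"expected {PLATE_SIZE} distinct substrates, got {len(substrates)} "
            f"({len(set(substrates))} distinct)"
        )
    counts = {c: 0 for c in PM_CATEGORIES}
    for o in outcomes:
        counts[o.category] += 1
    return PmTabulation(counts)


def pearson_chi2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson's chi-squared test for a 2x2 table (1 degree of freedom).

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, with the optional
    Yates continuity correction subtracting N/2 from ``|ad - bc|``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise DegenerateTableError(f"zero margin in table {[a, b, c, d]}")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / float(np.prod(margins, dtype=float))
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def strain_contrasts(
    tab_wt: Mapping[str, PmTabulation],
    tab_mut: Mapping[str, PmTabulation],
    pooling: str = "pooled",
    yates: bool = False,
) -> pd.DataFrame:
    """Chi-squared contrasts of category counts between the two strains.

    ``tab_wt`` / ``tab_mut`` map carbon condition to the strain's
    tabulation.  ``pooling="pooled"`` stacks carbons (each strain then
    contributes 95 x number-of-carbons substrates); ``"per_carbon"`` tests
    each condition separately.  Rows report the 2x2 table cells
    (mutator-in, mutator-out, wildtype-in, wildtype-out), the statistic and
    p-value, and the construction used.
    """
    if pooling not in ("pooled", "per_carbon"):
        raise DomainError(f"unknown pooling mode {pooling!r}")
    if set(tab_wt) != set(tab_mut):
        raise TabulationError("strains were tabulated on different conditions")
    carbons = sorted(tab_wt)
    rows = []

    def one(contrast, carbon_set, label):
        n_per = PLATE_SIZE * len(carbon_set)
        k_mut = sum(tab_mut[c].in_contrast(contrast) for c in carbon_set)
        k_wt = sum(tab_wt[c].in_contrast(contrast) for c in carbon_set)
        table = ContingencyTable2x2(k_mut, n_per - k_mut, k_wt, n_per - k_wt)
        try:
            chi2, p = pearson_chi2(table, yates=yates)
        except DegenerateTableError:
            chi2, p = float("nan"), float("nan")
        rows.append(
            {
                "contrast": contrast,
                "condition": label,
                "mutator_in": table.a,
                "mutator_out": table.b,
                "wildtype_in": table.c,
                "wildtype_out": table.d,
                "chi2": chi2,
                "p_value": p,
                "pooling": pooling,
                "yates": yates,
            }
        )

    for contrast in CONTRASTS:
        if pooling == "pooled":
            one(contrast, carbons, "+".join(carbons))
        else:
            for c in carbons:
                one(contrast, [c], c)
    return pd.DataFrame(rows)
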