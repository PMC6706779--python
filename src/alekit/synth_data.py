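"""Synthetic serial-transfer evolution data with known ground truth.

This module generates every input the analysis stages consume: passage logs,
checkpointed mutation tables, paired-competition traces with qPCR readouts,
and phenotype-microarray plate kinetics.  The evolutionary model is a
serial-transfer Wright-Fisher approximation:

* Within a passage, genotypes grow deterministically in proportion to
  ``w ** g`` where ``w = 1 + sum(selection coefficients active under the
  current carbon)`` and ``g = log2(fold expansion)`` is the number of
  generations the passage contributes.
* Mutation arrivals are Poisson with mean ``mu_eff * N * g`` per passage
  (``mu_eff = mu_basal * mutator_multiplier``); each arrival hits one cell
  and one gene unit drawn uniformly from the catalog.  Genotypes are sets of
  mutated units (infinite alleles at unit granularity — a repeat hit on an
  already-mutated unit changes nothing).
* At transfer, exactly ``bottleneck_size`` cells are drawn multinomially
  from the grown population, so the post-transfer census is conserved.

Stochasticity therefore enters only through mutation supply and the
bottleneck; this is the standard fast approximation for serial-dilution
experiments and keeps the neutral dynamics an exact martingale, which the
test suite exploits.

Variant readout emulates population sequencing: at every checkpoint
generation, units whose population frequency reaches the detection floor
(default 10%, the conventional minimum variant frequency of short-read
population calling) are emitted as mutation records.  The planted class of
every unit is retained so classification can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .fitness_kinetics import GrowthCurve, PassageRecord

__all__ = [
    "UnitClass",
    "GeneUnit",
    "SimConfig",
    "CompetitionConfig",
    "QpcrModel",
    "QpcrSample",
    "MutationRecord",
    "LineageResult",
    "CompetitionResult",
    "default_unit_catalog",
    "catalog_annotation",
    "simulate_ale_lineage",
    "simulate_competition",
    "simulate_qpcr",
    "simulate_pm_plate",
    "default_rate_map",
    "pm_plate_wells",
    "draw_snv",
]

UnitClass = Literal["generalist", "lactate_specialist", "glycerol_specialist", "neutral"]

_PURINES = {"A", "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}


@dataclass(frozen=True)
class GeneUnit:
    """One mutable gene (or intergenic) unit of the synthetic genome."""

    unit_id: str
    unit_class: UnitClass
    s_lactate: float = 0.0
    s_glycerol: float = 0.0
    start: int = 0  # 1-based inclusive genomic interval, for position assignment
    end: int = 0
    unit_type: str = "gene"

    def selection(self, carbon: str) -> float:
        return self.s_lactate if carbon == "lactate" else self.s_glycerol


def default_unit_catalog(
    n_neutral: int = 200,
    s_generalist: float = 0.08,
    s_specialist: float = 0.06,
    unit_length: int = 900,
    spacing: int = 1000,
) -> tuple[GeneUnit, ...]:
    """A catalog shaped like a minimal-medium carbon-adaptation experiment.

    Six generalist units beneficial under both carbons, three lactate
    specialists, two glycerol specialists (counts mirror the loci repeatedly
    reported in carbon-limited E. coli evolution: rpoB/hfq/rph/ptsP/crp and
    the pyrE-rph intergenic region; ppsA/cyaA/ydcI; glpK/rpoC), plus a pool
    of selectively neutral units that can only drift to detectability.
    Each unit occupies a disjoint interval so positions can be assigned and
    re-collapsed by the annotation machinery.
    """
    names_general = ["rpoB", "hfq", "rph", "ptsP", "crp", "pyrE/rph"]
    names_lac = ["ppsA", "cyaA", "ydcI"]
    names_gly = ["glpK", "rpoC"]
    units: list[GeneUnit] = []

    def add(name: str, cls: UnitClass, s_lac: float, s_gly: float):
        i = len(units)
        start = i * spacing + 1
        units.append(
            GeneUnit(
                unit_id=name,
                unit_class=cls,
                s_lactate=s_lac,
                s_glycerol=s_gly,
                start=start,
                end=start + unit_length - 1,
                unit_type="intergenic" if "/" in name else "gene",
            )
        )

    for n in names_general:
        add(n, "generalist", s_generalist, s_generalist)
    for n in names_lac:
        add(n, "lactate_specialist", s_specialist, 0.0)
    for n in names_gly:
        add(n, "glycerol_specialist", 0.0, s_specialist)
    for k in range(n_neutral):
        add(f"yneu{k:04d}", "neutral", 0.0, 0.0)
    return tuple(units)


def catalog_annotation(catalog: Sequence[GeneUnit]):
    """Annotation rows (unit_id, unit_type, start, end) for a catalog."""
    return [(u.unit_id, u.unit_type, u.start, u.end) for u in catalog]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated lineage.

    Defaults follow the serial-transfer design being emulated: growth from
    OD600 ~0.03 to mid-exponential ~0.48 per passage (16-fold, i.e. 4
    generations), 800 total generations sampled at 100-generation
    checkpoints, and a 10% variant detection floor.  ``bottleneck_size``
    defaults to 1e4, a computationally tractable stand-in for the ~1e7-1e8
    cells of a real transfer; the analysis properties checked downstream
    (martingale neutrality, supply linearity) are scale-free.
    """

    bottleneck_size: int = 10_000
    target_fold_expansion: float = 16.0
    total_generations: float = 800.0
    checkpoint_interval: float = 100.0
    mu_basal: float = 1e-3  # mutations per genome per generation
    mutator_multiplier: float = 1.0
    unit_catalog: tuple[GeneUnit, ...] = field(default_factory=default_unit_catalog)
    carbon: str = "lactate"
    detection_floor: float = 0.10
    seed: int = 0
    strain: str = "WT"
    replicate: int = 1
    # fraction of initial cells carrying a given unit (for marked founders)
    founders: Mapping[str, float] | None = None
    od_initial: float = 0.03
    base_doubling_hours: float = 2.5
    ts_tv_ratio: float = 3.0  # transition:transversion odds of emitted SNVs
    indel_fraction: float = 0.1

    def __post_init__(self):
        if self.bottleneck_size < 10:
            raise ConfigurationError("bottleneck_size must be >= 10")
        if self.target_fold_expansion <= 1:
            raise ConfigurationError("target_fold_expansion must exceed 1")
        if self.mu_basal < 0:
            raise ConfigurationError("mu_basal must be >= 0")
        if self.mutator_multiplier < 1:
            raise ConfigurationError("mutator_multiplier must be >= 1")
        if not 0 <= self.detection_floor <= 1:
            raise ConfigurationError("detection_floor must lie in [0, 1]")
        if self.carbon not in ("lactate", "glycerol"):
            raise ConfigurationError(f"unknown carbon {self.carbon!r}")
        if self.total_generations <= 0 or self.checkpoint_interval <= 0:
            raise ConfigurationError("generation counts must be positive")
        n_checkpoints = self.total_generations / self.checkpoint_interval
        if abs(n_checkpoints - round(n_checkpoints)) > 1e-9:
            raise ConfigurationError(
                "checkpoint_interval must divide total_generations"
            )
        if self.founders:
            tot = sum(self.founders.values())
            if not 0 <= tot <= 1:
                raise ConfigurationError("founder fractions must sum to <= 1")
            ids = {u.unit_id for u in self.unit_catalog}
            missing = set(self.founders) - ids
            if missing:
                raise ConfigurationError(f"founder units not in catalog: {missing}")

    @property
    def generations_per_passage(self) -> float:
        return math.log2(self.target_fold_expansion)

    @property
    def lineage_id(self) -> str:
        return f"{self.strain}_{self.carbon}_{self.replicate}"

    @property
    def mu_eff(self) -> float:
        return self.mu_basal * self.mutator_multiplier


@dataclass(frozen=True)
class QpcrModel:
    """Idealised qPCR signal: Cq falls one cycle per doubling of template.

    ``Cq = intercept_c0 - log_{1+efficiency}(template quantity) + noise``.
    ``efficiency`` is the per-cycle amplification gain (1 = perfect
    doubling); ``noise_sd`` is Gaussian cycle noise, 0 for a deterministic
    instrument.
    """

    intercept_c0: float = 30.0
    efficiency: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not 0 < self.efficiency <= 1:
            raise ConfigurationError("efficiency must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def cq(self, quantity: float) -> float:
        if quantity <= 0:
            raise DomainError("template quantity must be positive")
        return self.intercept_c0 - math.log(quantity, 1.0 + self.efficiency)


@dataclass(frozen=True)
class QpcrSample:
    """Paired quantification cycles for one mixed-culture sample.

    Primer set A amplifies the wild-type-specific target (mutS-internal),
    primer set B the mutator-specific target (deletion-scar-flanking).
    ``None`` encodes no amplification.
    """

    sample_id: str
    generation: float
    cq_a: float | None
    cq_b: float | None
    replicate: int = 1


@dataclass(frozen=True)
class MutationRecord:
    """One detected variant at one checkpoint of one lineage."""

    lineage_id: str
    strain: str
    carbon: str
    replicate: int
    generation: float
    unit_id: str
    unit_type: str
    position: int
    ref: str
    alt: str
    variant_class: str  # SNV / insertion / deletion
    frequency: float


@dataclass(frozen=True)
class CompetitionConfig:
    """Paired wild-type-vs-mutator competition under shared conditions.

    The two per-strain configs must agree on everything except mutation
    supply (and strain labels); the shared culture parameters are taken from
    ``wildtype``.
    """

    wildtype: SimConfig
    mutator: SimConfig
    initial_fraction_mutator: float = 0.5
    displacement_threshold: float = 0.001

    def __post_init__(self):
        if not 0 <= self.initial_fraction_mutator <= 1:
            raise ConfigurationError("initial_fraction_mutator must lie in [0, 1]")
        if not 0 < self.displacement_threshold < 0.5:
            raise ConfigurationError("displacement_threshold must lie in (0, 0.5)")
        for attr in (
            "bottleneck_size",
            "target_fold_expansion",
            "total_generations",
            "carbon",
            "unit_catalog",
        ):
            if getattr(self.wildtype, attr) != getattr(self.mutator, attr):
                raise ConfigurationError(f"strains disagree on shared parameter {attr!r}")


@dataclass
class LineageResult:
    passage_log: list[PassageRecord]
    mutation_timeline: list[MutationRecord]
    truth: dict[str, UnitClass]  # planted class of every emitted unit
    checkpoint_frequencies: dict[float, dict[str, float]]  # unfiltered truth


@dataclass
class CompetitionResult:
    generations: list[float]
    fraction_mutator: list[float]


def draw_snv(rng: np.random.Generator, ts_tv_ratio: float) -> tuple[str, str]:
    """Draw a (ref, alt) substitution with the given transition:transversion odds."""
    ref = "ACGT"[rng.integers(4)]
    p_ts = ts_tv_ratio / (1.0 + ts_tv_ratio)
    if rng.random() < p_ts:
        return ref, _TRANSITION[ref]
    return ref, _TRANSVERSIONS[ref][rng.integers(2)]


class _Population:
    """Genotype book-keeping shared by the lineage and competition simulators.

    Genotypes form a forest: each is its parent plus one extra mutated unit,
    so the unit set of a genotype is recovered lazily (and memoised) from the
    parent chain.  Counts are kept only for currently active genotypes.
    """

    def __init__(self, catalog: Sequence[GeneUnit], carbon: str):
        self.catalog = list(catalog)
        self.s = np.array([u.selection(carbon) for u in catalog])
        self.parent: list[int] = []
        self.unit: list[int] = []  # -1 for founders
        self.w: list[float] = []
        self.strain_of: list[int] = []  # index into strain labels
        self._unit_sets: dict[int, frozenset[int]] = {}

    def add_genotype(self, parent: int, unit: int, strain: int) -> int:
        gid = len(self.parent)
        self.parent.append(parent)
        self.unit.append(unit)
        if parent < 0:
            w = 1.0 + (self.s[unit] if unit >= 0 else 0.0)
        else:
            w = self.w[parent] + (self.s[unit] if unit >= 0 else 0.0)
        self.w.append(w)
        self.strain_of.append(strain)
        return gid

    def unit_set(self, gid: int) -> frozenset[int]:
        chain = []
        g = gid
        while g >= 0 and g not in self._unit_sets:
            chain.append(g)
            g = self.parent[g]
        acc = self._unit_sets.get(g, frozenset()) if g >= 0 else frozenset()
        for g in reversed(chain):
            u = self.unit[g]
            acc = acc | {u} if u >= 0 else acc
            self._unit_sets[g] = acc
        return self._unit_sets.get(gid, frozenset())

    def unit_frequencies(self, gids: np.ndarray, counts: np.ndarray, census: float):
        freq: dict[int, float] = {}
        for gid, c in zip(gids.tolist(), counts.tolist()):
            if c == 0:
                continue
            for u in self.unit_set(gid):
                freq[u] = freq.get(u, 0.0) + c
        return {u: c / census for u, c in freq.items()}


def _evolve(
    configs: Sequence[SimConfig],
    initial_counts: Sequence[int],
    rng: np.random.Generator,
):
    """Run the joint serial-transfer dynamics for one or two strains.

    Yields ``(passage_number, accumulated_generations, gids, counts,
    mean_fitness, strain_counts)`` after every transfer.
    """
    base = configs[0]
    n = base.bottleneck_size
    g = base.generations_per_passage
    fold = base.target_fold_expansion
    pop = _Population(base.unit_catalog, base.carbon)
    unit_index = {u.unit_id: i for i, u in enumerate(base.unit_catalog)}

    gids_list: list[int] = []
    counts_list: list[int] = []
    for strain_i, (cfg, count) in enumerate(zip(configs, initial_counts)):
        if count == 0:
            continue
        remaining = count
        if cfg.founders:
            for unit_id, frac in cfg.founders.items():
                k = int(round(frac * count))
                if k == 0:
                    continue
                gid = pop.add_genotype(-1, unit_index[unit_id], strain_i)
                gids_list.append(gid)
                counts_list.append(k)
                remaining -= k
        gid = pop.add_genotype(-1, -1, strain_i)
        gids_list.append(gid)
        counts_list.append(remaining)
    gids = np.array(gids_list, dtype=np.int64)
    counts = np.array(counts_list, dtype=np.int64)

    n_passages = int(round(base.total_generations / g))
    if abs(n_passages * g - base.total_generations) > 1e-6:
        n_passages = math.ceil(base.total_generations / g - 1e-9)

    mu_eff = np.array([c.mu_eff for c in configs])
    w_arr = np.array(pop.w)
    acc = 0.0
    for passage in range(1, n_passages + 1):
        if len(w_arr) < len(pop.w):
            w_arr = np.array(pop.w)
        grown = counts * w_arr[gids] ** g
        strain_arr = np.array([pop.strain_of[i] for i in gids.tolist()])
        # mutation supply per strain: Poisson(mu_eff * N_strain * g)
        new_gids: list[int] = []
        for strain_i in range(len(configs)):
            mask = strain_arr == strain_i
            n_strain = counts[mask].sum()
            if n_strain == 0 or mu_eff[strain_i] == 0:
                continue
            m = rng.poisson(mu_eff[strain_i] * n_strain * g)
            if m == 0:
                continue
            p = grown[mask] / grown[mask].sum()
            rows = rng.choice(np.flatnonzero(mask), size=m, p=p)
            units = rng.integers(0, len(pop.catalog), size=m)
            accepted_rows = []
            for row, pi, u in zip(rows.tolist(), gids[rows].tolist(), units.tolist()):
                if u in pop.unit_set(pi):  # repeat hit on an occupied unit
                    continue
                new_gids.append(pop.add_genotype(pi, int(u), pop.strain_of[pi]))
                accepted_rows.append(row)
            # each mutant converts one cell of its parent genotype
            if accepted_rows:
                np.subtract.at(grown, np.array(accepted_rows), 1.0)
        if new_gids:
            np.clip(grown, 0.0, None, out=grown)
            grown = np.concatenate([grown, np.ones(len(new_gids))])
            gids = np.concatenate([gids, np.array(new_gids, dtype=np.int64)])
            w_arr = np.array(pop.w)
        probs = grown / grown.sum()
        counts = rng.multinomial(n, probs)
        keep = counts > 0
        gids, counts = gids[keep], counts[keep].astype(np.int64)
        acc += g
        w_mean = float(
            (counts * np.array([pop.w[i] for i in gids.tolist()])).sum() / n
        )
        strain_counts = np.zeros(len(configs), dtype=np.int64)
        for gid, c in zip(gids.tolist(), counts.tolist()):
            strain_counts[pop.strain_of[gid]] += c
        yield passage, acc, pop, gids, counts, w_mean, strain_counts


def simulate_ale_lineage(config: SimConfig) -> LineageResult:
    """Simulate one lineage and read it out like the real experiment.

    Returns the per-passage OD log, the checkpointed mutation table (only
    units at or above the detection floor), the planted class of every unit
    ever emitted, and the floor-free frequency truth at each checkpoint.
    """
    rng = np.random.default_rng(config.seed)
    g = config.generations_per_passage
    fold = config.target_fold_expansion
    catalog = config.unit_catalog

    checkpoints = [
        config.checkpoint_interval * (k + 1)
        for k in range(int(round(config.total_generations / config.checkpoint_interval)))
    ]
    next_cp = 0
    passage_log: list[PassageRecord] = []
    timeline: list[MutationRecord] = []
    truth: dict[str, UnitClass] = {}
    cp_freqs: dict[float, dict[str, float]] = {}
    alleles: dict[int, tuple[int, str, str, str]] = {}  # unit -> (pos, ref, alt, class)

    for passage, acc, pop, gids, counts, w_mean, _ in _evolve(
        [config], [config.bottleneck_size], rng
    ):
        elapsed = g * config.base_doubling_hours / w_mean
        passage_log.append(
            PassageRecord(
                lineage_id=config.lineage_id,
                passage_index=passage,
                od_initial=config.od_initial,
                od_final=config.od_initial * fold,
                elapsed_hours=elapsed,
            )
        )
        while next_cp < len(checkpoints) and acc >= checkpoints[next_cp] - 1e-9:
            gen = checkpoints[next_cp]
            freqs = pop.unit_frequencies(gids, counts, config.bottleneck_size)
            cp_freqs[gen] = {catalog[u].unit_id: f for u, f in freqs.items()}
            for u, f in sorted(freqs.items()):
                if f < config.detection_floor:
                    continue
                unit = catalog[u]
                if u not in alleles:
                    pos = int(rng.integers(unit.start, unit.end + 1)) if unit.end else 0
                    if rng.random() < config.indel_fraction:
                        base = "ACGT"[rng.integers(4)]
                        ins = "ACGT"[rng.integers(4)]
                        if rng.random() < 0.5:
                            alleles[u] = (pos, base, base + ins, "insertion")
                        else:
                            alleles[u] = (pos, base + ins, base, "deletion")
                    else:
                        ref, alt = draw_snv(rng, config.ts_tv_ratio)
                        alleles[u] = (pos, ref, alt, "SNV")
                pos, ref, alt, vclass = alleles[u]
                truth[unit.unit_id] = unit.unit_class
                timeline.append(
                    MutationRecord(
                        lineage_id=config.lineage_id,
                        strain=config.strain,
                        carbon=config.carbon,
                        replicate=config.replicate,
                        generation=gen,
                        unit_id=unit.unit_id,
                        unit_type=unit.unit_type,
                        position=pos,
                        ref=ref,
                        alt=alt,
                        variant_class=vclass,
                        frequency=float(f),
                    )
                )
            next_cp += 1
    return LineageResult(passage_log, timeline, truth, cp_freqs)


def simulate_competition(config: CompetitionConfig) -> CompetitionResult:
    """Joint wild-type/mutator serial transfer; records the mutator fraction.

    The trace starts at the (exact) initial inoculation fraction and appends
    one point per transfer.
    """
    base = config.wildtype
    rng = np.random.default_rng(base.seed)
    n = base.bottleneck_size
    n_mut = int(round(config.initial_fraction_mutator * n))
    generations = [0.0]
    fractions = [config.initial_fraction_mutator]
    for _, acc, _, _, _, _, strain_counts in _evolve(
        [base, config.mutator], [n - n_mut, n_mut], rng
    ):
        generations.append(acc)
        fractions.append(float(strain_counts[1]) / n)
    return CompetitionResult(generations, fractions)


def simulate_qpcr(
    fraction_mutator: float,
    total_quantity: float,
    model: QpcrModel,
    replicates: int = 2,
    rng: np.random.Generator | None = None,
    sample_id: str = "mix",
    generation: float = 0.0,
) -> list[QpcrSample]:
    """Paired Cq readouts for a mixed sample.

    Primer A sees the wild-type share ``(1 - fraction) * quantity``, primer B
    the mutator share.  A fraction of exactly 0 or 1 yields a no-amplification
    sentinel (``None``) for the absent target rather than a Cq number.
    """
    if not 0 <= fraction_mutator <= 1:
        raise DomainError("fraction_mutator must lie in [0, 1]")
    if total_quantity <= 0:
        raise DomainError("total_quantity must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for rep in range(1, replicates + 1):
        cq_a = cq_b = None
        if fraction_mutator < 1:
            cq_a = model.cq(total_quantity * (1.0 - fraction_mutator))
        if fraction_mutator > 0:
            cq_b = model.cq(total_quantity * fraction_mutator)
        if model.noise_sd > 0:
            if cq_a is not None:
                cq_a += rng.normal(0.0, model.noise_sd)
            if cq_b is not None:
                cq_b += rng.normal(0.0, model.noise_sd)
        out.append(QpcrSample(sample_id, generation, cq_a, cq_b, rep))
    return out


def pm_plate_wells() -> list[str]:
    """Well ids A01..H12 in row-major plate order."""
    return [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]


def default_rate_map(
    base_rate: float = 0.25,
    rng: np.random.Generator | None = None,
    spread: float = 0.3,
) -> dict[str, float]:
    """Synthetic substrate-to-growth-rate map for the 95 non-control wells.

    Substrates are labelled by well position ("substrate_A02" ...); the real
    plate's proprietary substrate layout is deliberately not reproduced.
    Rates are lognormal around ``base_rate`` per hour.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rates = {}
    for well in pm_plate_wells()[1:]:
        rates[f"substrate_{well}"] = float(
            base_rate * math.exp(rng.normal(0.0, spread))
        )
    return rates


def simulate_pm_plate(
    rate_map: Mapping[str, float],
    duration_hours: float = 24.0,
    interval_minutes: float = 10.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    od_inoculum: float = 0.01,
    carrying_capacity: float = 1.0,
    blank_od: float = 0.05,
) -> list[GrowthCurve]:
    """Simulate a 96-well kinetic read of a phenotype microarray plate.

    Each substrate well follows a logistic curve
    ``OD(t) = K * OD0 * e^{rt} / (K + OD0 * (e^{rt} - 1))`` on top of the
    blank medium turbidity, sampled every ``interval_minutes`` (the default
    10 min over 24 h gives 145 points).  Multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` applies to every reading.  Well A01
    is the nutrient-free negative control: blank-level OD, rate 0, same
    noise.
    """
    if interval_minutes <= 0:
        raise ConfigurationError("interval_minutes must be positive")
    if duration_hours < interval_minutes / 60.0:
        raise ConfigurationError("duration must cover at least one interval")
    for s, r in rate_map.items():
        if r < 0:
            raise ConfigurationError(f"negative growth rate for {s!r}")
    rng = np.random.default_rng(seed)
    n_points = int(round(duration_hours * 60.0 / interval_minutes)) + 1
    t = np.arange(n_points) * interval_minutes / 60.0
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    else:
        sigma = 0.0

    wells = pm_plate_wells()
    substrates = ["negative_control"] + sorted(rate_map)
    if len(substrates) > len(wells):
        raise ConfigurationError("rate_map has more than 95 substrates")
    curves = []
    for well, substrate in zip(wells, substrates):
        if substrate == "negative_control":
            od = np.full(n_points, blank_od)
        else:
            r = rate_map[substrate]
            growth = np.exp(r * t)
            od = blank_od + carrying_capacity * od_inoculum * growth / (
                carrying_capacity + od_inoculum * (growth - 1.0)
            )
        if sigma > 0:
            od = od * rng.lognormal(-0.5 * sigma**2, sigma, size=n_points)
        curves.append(
            GrowthCurve(
                well_id=well,
                substrate=substrate,
                times_hours=tuple(t.tolist()),
                od=tuple(od.tolist()),
            )
        )
    return curves
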