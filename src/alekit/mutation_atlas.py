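"""Recurrence-based classification of mutations across evolved lineages.

The experimental design is 8 lineages: {wild-type, mutator} x {lactate,
glycerol} x 2 biological replicates, sequenced as populations at regular
generation checkpoints.  Analysis works at gene-unit granularity — a gene
(or intergenic region) counts as mutated regardless of which position within
it was hit.  Replicate lineages of one strain x carbon group are merged
(union of units, higher frequency wins on overlap), and each unit is
categorised by where it recurs:

* present in only one of the 8 lineages            -> random
* groups span both carbons and both strains        -> generalist
* both strains, one carbon                         -> lactate/glycerol-specific
* one strain, both carbons                         -> mutator/wildtype-specific
* one strain and one carbon, both replicates       -> carbon-specific of its
  carbon, flagged ``single_strain_recurrence`` (the recurrence still implies
  carbon-dependent selection, but the strain breadth is unresolved)

Recurrence between replicate-merged groups drives the specific/generalist
split, while the random category is decided on raw lineage uniqueness; this
reconciles merged reporting with uniqueness over the eight lineages.

The module also provides the unit x checkpoint frequency matrix (heat-map
style trajectory export), the transition/transversion spectrum, and COG
functional-category over-representation by one-sided hypergeometric test
with Benjamini-Hochberg correction across categories.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, GridError, GroupingError, UnassignedUnitError
from .synth_data import MutationRecord

__all__ = [
    "CATEGORIES",
    "UnitPresence",
    "CogEnrichment",
    "Annotation",
    "collapse_to_units",
    "merge_replicates",
    "build_presence",
    "classify_units",
    "count_by_category",
    "snv_type",
    "trajectory_matrix",
    "cog_enrichment",
]

CATEGORIES = (
    "generalist",
    "lactate_specific",
    "glycerol_specific",
    "mutator_specific",
    "wildtype_specific",
    "random",
)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class UnitPresence:
    """Where one gene unit was observed across the lineage panel."""

    unit_id: str
    unit_type: str
    lineages_present: frozenset[str]
    groups_present: frozenset[tuple[str, str]]  # (strain, carbon)
    max_frequency: float = float("nan")
    category: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CogEnrichment:
    category_code: str
    mutated_count: int
    background_count: int
    genome_size: int
    mutated_total: int
    fold_enrichment: float
    p_value: float
    q_value: float = float("nan")


class Annotation:
    """Interval map from genomic position to gene unit.

    Built from 1-based inclusive gene intervals (non-overlapping).  Positions
    between genes map to the flanking intergenic unit, named
    ``"upstreamGene/downstreamGene"``; beyond the first/last gene the missing
    flank is ``"-"``.
    """

    def __init__(self, rows: Iterable[tuple[str, str, int, int]]):
        genes = sorted(
            (start, end, unit_id)
            for unit_id, unit_type, start, end in rows
            if unit_type == "gene"
        )
        self._explicit_intergenic = sorted(
            (start, end, unit_id)
            for unit_id, unit_type, start, end in rows
            if unit_type == "intergenic"
        )
        for (s1, e1, u1), (s2, e2, u2) in zip(genes, genes[1:]):
            if s2 <= e1:
                raise DomainError(f"gene intervals overlap: {u1} and {u2}")
        self._starts = [g[0] for g in genes]
        self._genes = genes

    def lookup(self, position: int) -> tuple[str, str]:
        """Return (unit_id, unit_type) for a 1-based position."""
        if position < 1:
            raise DomainError("positions are 1-based")
        for start, end, unit_id in self._explicit_intergenic:
            if start <= position <= end:
                return unit_id, "intergenic"
        i = bisect_right(self._starts, position) - 1
        if i >= 0:
            start, end, unit_id = self._genes[i]
            if position <= end:
                return unit_id, "gene"
        left = self._genes[i][2] if i >= 0 else "-"
        right = self._genes[i + 1][2] if i + 1 < len(self._genes) else "-"
        if left == "-" and right == "-":
            raise DomainError("annotation contains no genes")
        return f"{left}/{right}", "intergenic"


def collapse_to_units(
    records: Sequence[MutationRecord], annotation: Annotation
) -> list[MutationRecord]:
    """Resolve every record's genomic position to its gene unit.

    Distinct positions within one unit stay separate records but share the
    unit id; positions that cannot be mapped raise
    :class:`UnassignedUnitError` listing the offenders.
    """
    out, bad = [], []
    for rec in records:
        try:
            unit_id, unit_type = annotation.lookup(rec.position)
        except DomainError:
            bad.append(rec)
            continue
        out.append(replace(rec, unit_id=unit_id, unit_type=unit_type))
    if bad:
        raise UnassignedUnitError(bad)
    return out


def merge_replicates(
    rep1: Sequence[MutationRecord], rep2: Sequence[MutationRecord]
) -> list[MutationRecord]:
    """Merge the two biological replicates of one strain x carbon group.

    Works at unit level per checkpoint: the merged set is the union of
    mutated units; where a unit appears in both replicates the
    higher-frequency observation is the representative.  Idempotent and
    commutative at unit level.  Lineage provenance stays in the records'
    ``lineage_id``, so downstream uniqueness tests still see raw lineages.
    """
    groups = {(r.strain, r.carbon) for r in list(rep1) + list(rep2)}
    if len(groups) > 1:
        raise GroupingError(f"records from multiple strain x carbon groups: {groups}")
    best: dict[tuple[float, str], MutationRecord] = {}
    for rec in list(rep1) + list(rep2):
        key = (rec.generation, rec.unit_id)
        cur = best.get(key)
        if cur is None or rec.frequency > cur.frequency:
            best[key] = rec
    return [best[k] for k in sorted(best)]


def build_presence(
    records: Sequence[MutationRecord], checkpoint: float | None = None
) -> list[UnitPresence]:
    """Presence pattern of every unit at one checkpoint (default: end point).

    ``records`` must carry raw (unmerged) lineage ids — presence and the
    random category are evaluated per lineage, groups per strain x carbon.
    """
    if not records:
        return []
    if checkpoint is None:
        checkpoint = max(r.generation for r in records)
    at_cp = [r for r in records if r.generation == checkpoint]
    by_unit: dict[str, list[MutationRecord]] = {}
    for rec in at_cp:
        by_unit.setdefault(rec.unit_id, []).append(rec)
    out = []
    for unit_id in sorted(by_unit):
        recs = by_unit[unit_id]
        out.append(
            UnitPresence(
                unit_id=unit_id,
                unit_type=recs[0].unit_type,
                lineages_present=frozenset(r.lineage_id for r in recs),
                groups_present=frozenset((r.strain, r.carbon) for r in recs),
                max_frequency=max(r.frequency for r in recs),
            )
        )
    return out


def classify_units(
    presences: Sequence[UnitPresence], wildtype_label: str = "WT"
) -> list[UnitPresence]:
    """Assign each unit exactly one recurrence category.

    The decision table is evaluated in order (uniqueness first), is total
    over all non-empty presence patterns, and follows the presence pattern
    alone — a unit's literature reputation never overrides where it was
    actually seen.
    """
    out = []
    for p in presences:
        if not p.lineages_present:
            raise DomainError(f"unit {p.unit_id!r} has empty lineage presence")
        strains = {s for s, _ in p.groups_present}
        carbons = {c for _, c in p.groups_present}
        flags: tuple[str, ...] = ()
        if len(p.lineages_present) == 1:
            category = "random"
        elif len(strains) == 2 and len(carbons) == 2:
            category = "generalist"
        elif len(strains) == 2:
            category = f"{next(iter(carbons))}_specific"
        elif len(carbons) == 2:
            strain = next(iter(strains))
            category = "wildtype_specific" if strain == wildtype_label else "mutator_specific"
        else:
            # recurrent in both replicates of a single strain x carbon group:
            # carbon-dependent selection is evidenced, strain breadth is not
            category = f"{next(iter(carbons))}_specific"
            flags = ("single_strain_recurrence",)
        out.append(replace(p, category=category, flags=flags))
    return out


def count_by_category(
    classified: Sequence[UnitPresence], records: Sequence[MutationRecord]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mutation counts per category x strain x carbon, plus global tallies.

    Counts *mutation observations* (records), not units; a generalist unit
    seen in all eight lineages contributes eight.  The summary dict reports
    the three defensible definitions of "number of mutations": distinct
    genomic positions, distinct unit-level events (unit x lineage), and raw
    checkpoint observations, along with gene/intergenic unit splits.
    """
    category_of = {p.unit_id: p.category for p in classified}
    rows = []
    for rec in records:
        cat = category_of.get(rec.unit_id)
        if cat is None:
            continue
        rows.append((cat, rec.strain, rec.carbon, rec.unit_id, rec.position, rec.lineage_id))
    df = pd.DataFrame(
        rows, columns=["category", "strain", "carbon", "unit_id", "position", "lineage_id"]
    )
    if df.empty:
        table = pd.DataFrame(
            0,
            index=pd.Index(CATEGORIES, name="category"),
            columns=pd.MultiIndex.from_tuples([], names=["strain", "carbon"]),
        )
    else:
        table = (
            df.groupby(["category", "strain", "carbon"])
            .size()
            .unstack(["strain", "carbon"], fill_value=0)
            .reindex(CATEGORIES, fill_value=0)
        )
    totals = {
        "observations": len(df),
        "distinct_positions": int(df["position"].nunique()) if not df.empty else 0,
        "unit_events": int(df.drop_duplicates(["unit_id", "lineage_id"]).shape[0])
        if not df.empty
        else 0,
        "units": len({p.unit_id for p in classified}),
        "gene_units": sum(1 for p in classified if p.unit_type == "gene"),
        "intergenic_units": sum(1 for p in classified if p.unit_type == "intergenic"),
    }
    return table, totals


def snv_type(ref: str, alt: str) -> str:
    """Classify a substitution as transition or transversion.

    Purine<->purine and pyrimidine<->pyrimidine swaps are transitions;
    cross-class swaps are transversions.  Indels and multi-base alleles are
    ``not_applicable``.
    """
    if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
        return "not_applicable"
    ref, alt = ref.upper(), alt.upper()
    bases = _PURINES | _PYRIMIDINES
    if ref not in bases or alt not in bases:
        raise DomainError(f"non-ACGT alleles: {ref!r} -> {alt!r}")
    if ref == alt:
        raise DomainError("ref and alt are identical")
    if (ref in _PURINES) == (alt in _PURINES):
        return "transition"
    return "transversion"


def trajectory_matrix(
    records: Sequence[MutationRecord],
    classified: Sequence[UnitPresence],
    checkpoints: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Unit x checkpoint frequency matrix, ordered by category block.

    Rows are grouped generalist, lactate-specific, glycerol-specific,
    mutator-specific, wildtype-specific, random (then unit id); a unit's
    value at a checkpoint is its maximum frequency across lineages, 0 where
    undetected.  All record generations must lie on the checkpoint grid.
    """
    if checkpoints is None:
        checkpoints = sorted({r.generation for r in records})
    grid = set(checkpoints)
    off = {r.generation for r in records} - grid
    if off:
        raise GridError(f"record generations off the checkpoint grid: {sorted(off)}")
    order = {c: i for i, c in enumerate(CATEGORIES)}
    units = sorted(
        (p for p in classified),
        key=lambda p: (order.get(p.category, len(order)), p.unit_id),
    )
    mat = pd.DataFrame(
        0.0, index=[p.unit_id for p in units], columns=list(checkpoints)
    )
    mat.index.name = "unit_id"
    unit_set = set(mat.index)
    for rec in records:
        if rec.unit_id not in unit_set:
            continue
        cur = mat.at[rec.unit_id, rec.generation]
        if rec.frequency > cur:
            mat.at[rec.unit_id, rec.generation] = rec.frequency
    return mat


def cog_enrichment(
    mutated_genes: Iterable[str],
    cog_map: Mapping[str, str],
    genome_genes: Iterable[str],
) -> list[CogEnrichment]:
    """COG-category over-representation of mutated genes.

    For each single-letter category: ``fold = (k / n_mut) / (K / N)`` and a
    one-sided hypergeometric tail ``P(X >= k)`` drawing ``n_mut`` genes from
    a genome of ``N`` with ``K`` category members.  Genes may carry several
    category letters and then count in each.  Intergenic units must be
    excluded by the caller (they have no COG assignment).  Benjamini-
    Hochberg q-values are reported across categories alongside raw p.
    """
    genome = set(genome_genes)
    mutated = set(mutated_genes) & genome
    if not set(mutated_genes):
        warnings.warn("empty mutated gene set", stacklevel=2)
        return []
    n_genome = len(genome)
    n_mut = len(mutated)
    letters = sorted({l for g in genome for l in cog_map.get(g, "")})
    results = []
    for letter in letters:
        members = {g for g in genome if letter in cog_map.get(g, "")}
        k = len(mutated & members)
        big_k = len(members)
        expected = big_k / n_genome
        fold = (k / n_mut) / expected if n_mut and expected else 0.0
        p = float(stats.hypergeom.sf(k - 1, n_genome, big_k, n_mut))
        results.append(
            CogEnrichment(letter, k, big_k, n_genome, n_mut, fold, p)
        )
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [replace(r, q_value=float(qv)) for r, qv in zip(results, q)]
    return results
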