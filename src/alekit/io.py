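"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: CSV/TSV with fixed column orders, "NA" for missing values
(including qPCR no-amplification), genomic coordinates 1-based inclusive
internally (VCF convention); BED exclusion intervals are converted from
0-based half-open on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .competition_quant import CalibrationResult, CompetitionTrace
from .errors import AleError
from .fitness_kinetics import FitnessTrajectory, GrowthCurve, PassageRecord
from .mutation_atlas import Annotation, UnitPresence
from .phenome_pm import PmTabulation, SubstrateOutcome
from .synth_data import MutationRecord, QpcrSample

__all__ = [
    "read_passage_log_csv",
    "write_passage_log_csv",
    "read_plate_csv",
    "write_plate_csv",
    "read_cq_csv",
    "write_cq_csv",
    "read_mutation_table",
    "write_mutation_tsv",
    "read_annotation_tsv",
    "read_exclusion_bed",
    "apply_exclusions",
    "read_cog_map_tsv",
    "write_trajectory_tsv",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_calibration_json",
    "write_classified_tsv",
    "write_outcomes_tsv",
    "write_tabulation_tsv",
    "file_digest",
    "RunManifest",
]

_NA = "NA"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise AleError(f"{path}: missing required columns {missing}")


# -- passage logs -----------------------------------------------------------

PASSAGE_COLUMNS = ["lineage_id", "passage_index", "od_initial", "od_final", "elapsed_hours"]


def write_passage_log_csv(records: Iterable[PassageRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records])
    df = df.reindex(columns=PASSAGE_COLUMNS)
    df.to_csv(path, index=False)


def read_passage_log_csv(path) -> list[PassageRecord]:
    df = pd.read_csv(path)
    _require_columns(df, PASSAGE_COLUMNS, path)
    return [
        PassageRecord(
            lineage_id=str(r.lineage_id),
            passage_index=int(r.passage_index),
            od_initial=float(r.od_initial),
            od_final=float(r.od_final),
            elapsed_hours=float(r.elapsed_hours),
        )
        for r in df.itertuples()
    ]


# -- plate kinetics (long format) -------------------------------------------

PLATE_COLUMNS = ["well", "substrate", "time_min", "od"]


def write_plate_csv(curves: Iterable[GrowthCurve], path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times_hours, c.od):
            rows.append((c.well_id, c.substrate, t * 60.0, od))
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_csv(path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    curves = []
    for (well, substrate), grp in df.groupby(["well", "substrate"], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(
                well_id=str(well),
                substrate=str(substrate),
                times_hours=tuple((grp["time_min"] / 60.0).tolist()),
                od=tuple(grp["od"].tolist()),
            )
        )
    return curves


# -- qPCR Cq tables ----------------------------------------------------------

CQ_COLUMNS = ["sample_id", "generation", "primer_set", "replicate", "cq"]


def write_cq_csv(samples: Iterable[QpcrSample], path) -> None:
    rows = []
    for s in samples:
        for primer, cq in (("A", s.cq_a), ("B", s.cq_b)):
            rows.append(
                (s.sample_id, s.generation, primer, s.replicate, _NA if cq is None else cq)
            )
    pd.DataFrame(rows, columns=CQ_COLUMNS).to_csv(path, index=False)


def read_cq_csv(path) -> list[QpcrSample]:
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=True)
    _require_columns(df, CQ_COLUMNS, path)
    samples = []
    for (sid, gen, rep), grp in df.groupby(
        ["sample_id", "generation", "replicate"], sort=True
    ):
        cq = {"A": None, "B": None}
        for r in grp.itertuples():
            cq[str(r.primer_set)] = None if pd.isna(r.cq) else float(r.cq)
        samples.append(
            QpcrSample(
                sample_id=str(sid),
                generation=float(gen),
                cq_a=cq["A"],
                cq_b=cq["B"],
                replicate=int(rep),
            )
        )
    return samples


# -- mutation tables ---------------------------------------------------------

MUTATION_COLUMNS = [
    "lineage_id",
    "strain",
    "carbon",
    "replicate",
    "generation",
    "unit_id",
    "unit_type",
    "position",
    "ref",
    "alt",
    "variant_class",
    "frequency",
]


def write_mutation_tsv(records: Iterable[MutationRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records])
    df = df.reindex(columns=MUTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def _filter_floor(records: list[MutationRecord], floor: float):
    kept = [r for r in records if r.frequency >= floor]
    return kept, len(records) - len(kept)


def read_mutation_table(
    path,
    fmt: str = "tsv",
    annotation: Annotation | None = None,
    floor: float = 0.10,
    lineage_id: str = "",
    strain: str = "",
    carbon: str = "",
    replicate: int = 1,
    generation: float = 0.0,
) -> tuple[list[MutationRecord], int]:
    """Read a mutation table; returns (records, n_dropped_below_floor).

    ``fmt="tsv"`` expects the full column set; ``fmt="vcf"`` reads a minimal
    VCF (CHROM/POS/REF/ALT with INFO AF) and needs the lineage metadata and
    an annotation to resolve units.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, MUTATION_COLUMNS, path)
        records = []
        for i, r in enumerate(df.itertuples(), start=2):
            try:
                freq = float(r.frequency)
            except (TypeError, ValueError):
                raise AleError(f"{path}:{i}: unparseable frequency {r.frequency!r}")
            if not 0 <= freq <= 1:
                raise AleError(f"{path}:{i}: frequency {freq} outside [0, 1]")
            records.append(
                MutationRecord(
                    lineage_id=str(r.lineage_id),
                    strain=str(r.strain),
                    carbon=str(r.carbon),
                    replicate=int(r.replicate),
                    generation=float(r.generation),
                    unit_id=str(r.unit_id),
                    unit_type=str(r.unit_type),
                    position=int(r.position),
                    ref=str(r.ref),
                    alt=str(r.alt),
                    variant_class=str(r.variant_class),
                    frequency=freq,
                )
            )
        return _filter_floor(records, floor)
    if fmt == "vcf":
        if annotation is None:
            raise AleError("VCF ingestion requires an annotation to resolve units")
        from cyvcf2 import VCF  # deferred: only needed on this path

        records = []
        for variant in VCF(str(path)):
            af = variant.INFO.get("AF")
            if af is None:
                raise AleError(f"{path}: record at POS {variant.POS} lacks INFO/AF")
            ref, alt = variant.REF, variant.ALT[0]
            if len(ref) == 1 and len(alt) == 1:
                vclass = "SNV"
            elif len(alt) > len(ref):
                vclass = "insertion"
            else:
                vclass = "deletion"
            unit_id, unit_type = annotation.lookup(int(variant.POS))
            records.append(
                MutationRecord(
                    lineage_id=lineage_id,
                    strain=strain,
                    carbon=carbon,
                    replicate=replicate,
                    generation=generation,
                    unit_id=unit_id,
                    unit_type=unit_type,
                    position=int(variant.POS),
                    ref=ref,
                    alt=alt,
                    variant_class=vclass,
                    frequency=float(af),
                )
            )
        return _filter_floor(records, floor)
    raise AleError(f"unknown mutation table format {fmt!r}")


# -- annotation / exclusions / COG ------------------------------------------


def read_annotation_tsv(path) -> Annotation:
    """Annotation TSV: unit_id, unit_type, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["unit_id", "unit_type", "start", "end"], path)
    return Annotation(
        (str(r.unit_id), str(r.unit_type), int(r.start), int(r.end))
        for r in df.itertuples()
    )


def write_annotation_tsv(rows: Iterable[tuple[str, str, int, int]], path) -> None:
    pd.DataFrame(rows, columns=["unit_id", "unit_type", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_exclusion_bed(path) -> list[tuple[int, int]]:
    """BED intervals (0-based half-open) as 1-based inclusive tuples."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise AleError(f"{path}: malformed BED line {line!r}")
        start, end = int(fields[1]), int(fields[2])
        intervals.append((start + 1, end))
    return intervals


def apply_exclusions(
    records: Sequence[MutationRecord], intervals: Sequence[tuple[int, int]]
) -> tuple[list[MutationRecord], int]:
    """Drop records falling in excluded (repeat/rRNA/transposase) intervals."""
    kept = [
        r
        for r in records
        if not any(s <= r.position <= e for s, e in intervals)
    ]
    return kept, len(records) - len(kept)


def read_cog_map_tsv(path) -> dict[str, str]:
    """Gene -> COG category letters (a gene may carry several letters)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "letters"], path)
    return {str(r.gene): str(r.letters) for r in df.itertuples()}


def write_cog_map_tsv(cog_map: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(cog_map.items()), columns=["gene", "letters"]
    ).to_csv(path, sep="\t", index=False)


# -- analysis outputs --------------------------------------------------------


def write_trajectory_tsv(trajectories: Iterable[FitnessTrajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for p in tr.points:
            rows.append(
                (tr.lineage_id, p.passage_index, p.accumulated_generations, p.doubling_time_hours)
            )
    pd.DataFrame(
        rows,
        columns=["lineage_id", "passage_index", "accumulated_generations", "doubling_time_h"],
    ).to_csv(path, sep="\t", index=False)


def write_trace_tsv(trace: CompetitionTrace, path) -> None:
    frac = np.asarray(trace.fraction_mutator)
    with np.errstate(divide="ignore"):
        ratio = np.where(frac < 1.0, frac / (1.0 - frac), np.inf)
    pd.DataFrame(
        {
            "generation": trace.generations,
            "ratio": ratio,
            "fraction_mutator": frac,
        }
    ).to_csv(path, sep="\t", index=False)


def read_trace_tsv(path) -> CompetitionTrace:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["generation", "fraction_mutator"], path)
    df = df.sort_values("generation")
    return CompetitionTrace(
        tuple(float(g) for g in df["generation"]),
        tuple(float(f) for f in df["fraction_mutator"]),
    )


def write_calibration_json(result: CalibrationResult, path) -> None:
    Path(path).write_text(json.dumps(asdict(result), indent=2) + "\n")


def write_classified_tsv(classified: Iterable[UnitPresence], path) -> None:
    rows = [
        {
            "unit_id": p.unit_id,
            "unit_type": p.unit_type,
            "category": p.category,
            "n_lineages": len(p.lineages_present),
            "lineages": ";".join(sorted(p.lineages_present)),
            "groups": ";".join(f"{s}:{c}" for s, c in sorted(p.groups_present)),
            "max_frequency": p.max_frequency,
            "flags": ";".join(p.flags),
        }
        for p in classified
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_outcomes_tsv(outcomes: Iterable[SubstrateOutcome], path) -> None:
    pd.DataFrame([asdict(o) for o in outcomes]).to_csv(
        path, sep="\t", index=False, na_rep=_NA
    )


def write_tabulation_tsv(tabs: Mapping[str, Mapping[str, PmTabulation]], path) -> None:
    """Table-1-style layout: rows categories (+ total), columns condition/strain."""
    from .phenome_pm import PM_CATEGORIES

    cols = {}
    for carbon, by_strain in sorted(tabs.items()):
        for strain, tab in sorted(by_strain.items()):
            col = {cat: tab[cat] for cat in PM_CATEGORIES}
            col["fitness_gain_total"] = tab.fitness_gain_total
            cols[f"{carbon}:{strain}"] = col
    pd.DataFrame(cols).to_csv(path, sep="\t")


# -- manifests ---------------------------------------------------------------


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, config, seed, outputs."""

    seed: int
    config: dict
    outputs: dict[str, str]  # relative path -> sha256
    counts: dict[str, int]
    complete: bool = True
    version: str = "0.1.0"

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
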