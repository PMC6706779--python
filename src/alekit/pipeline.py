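"""End-to-end orchestration: simulate a study, run every analysis stage.

``run_pipeline`` wires the stages together the way the underlying experiment
is analysed: simulate (or load) the eight-lineage serial-transfer design,
derive fitness trajectories from the passage logs, quantify a wild-type vs
mutator competition through the qPCR chain, classify mutations by recurrence,
and categorise phenotype-microarray outcomes.  Every output is a plain-text
table plus a JSON manifest with content digests, so a rerun with the same
config and seed reproduces the deterministic artefacts bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .competition_quant import (
    calibrate,
    displacement_generation,
    ratio_to_fraction_trace,
)
from .errors import ConfigurationError
from .fitness_kinetics import fitness_trajectory
from .mutation_atlas import (
    build_presence,
    classify_units,
    cog_enrichment,
    count_by_category,
    trajectory_matrix,
)
from .phenome_pm import analyze_plates, strain_contrasts, tabulate
from .synth_data import (
    CompetitionConfig,
    QpcrModel,
    SimConfig,
    default_rate_map,
    default_unit_catalog,
    simulate_ale_lineage,
    simulate_competition,
    simulate_pm_plate,
    simulate_qpcr,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "dump_config"]

_COG_LETTERS = "EQKJGPT"  # synthetic round-robin assignment for simulated genomes


@dataclass
class RunConfig:
    """Parameters of a full simulated-study run.

    Defaults are the documented design decisions of each stage; everything a
    stage exposes as tunable appears here so the YAML config is the single
    source of truth.
    """

    seed: int = 0
    out_dir: str = "ale_run"
    # simulator scale
    bottleneck_size: int = 10_000
    target_fold_expansion: float = 16.0
    total_generations: float = 800.0
    checkpoint_interval: float = 100.0
    mu_basal: float = 1e-3
    mutator_multiplier: float = 50.0
    detection_floor: float = 0.10
    n_neutral_units: int = 200
    # qPCR
    qpcr_noise_sd: float = 0.0
    qpcr_intercept: float = 30.0
    qpcr_efficiency: float = 1.0
    mixing_fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    displacement_threshold: float = 0.001
    # phenotype microarray
    pm_noise_cv: float = 0.02
    pm_gain_high_folds: tuple[float, ...] = ()
    pm_window_points: int = 24
    pm_min_r2: float = 0.98
    pm_alpha: float = 0.05
    pm_blank_od: float = 0.05
    contrast_pooling: str = "pooled"
    yates: bool = False
    log_level: str = "INFO"

    def sim_config(self, strain: str, carbon: str, replicate: int, seed: int) -> SimConfig:
        multiplier = self.mutator_multiplier if strain == "mutS" else 1.0
        return SimConfig(
            bottleneck_size=self.bottleneck_size,
            target_fold_expansion=self.target_fold_expansion,
            total_generations=self.total_generations,
            checkpoint_interval=self.checkpoint_interval,
            mu_basal=self.mu_basal,
            mutator_multiplier=multiplier,
            unit_catalog=default_unit_catalog(n_neutral=self.n_neutral_units),
            carbon=carbon,
            detection_floor=self.detection_floor,
            seed=seed,
            strain=strain,
            replicate=replicate,
        )


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("mixing_fractions", "pm_gain_high_folds"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def dump_config(config: RunConfig) -> str:
    data = dataclasses.asdict(config)
    for key in ("mixing_fractions", "pm_gain_high_folds"):
        data[key] = list(data[key])
    return yaml.safe_dump(data, sort_keys=True)


def run_pipeline(config: RunConfig) -> io.RunManifest:
    """Simulate the eight-lineage study and run all analysis stages.

    Writes every stage output under ``config.out_dir`` and returns the
    manifest.  Seeds for each stage are drawn deterministically from
    ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=64)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    def register(name: str):
        outputs[name] = io.file_digest(out / name)

    # -- stage 1: simulate the 8 lineages -----------------------------------
    lineages = []
    si = 0
    for strain in ("WT", "mutS"):
        for carbon in ("lactate", "glycerol"):
            for rep in (1, 2):
                cfg = config.sim_config(strain, carbon, rep, int(seeds[si]))
                si += 1
                lineages.append((cfg, simulate_ale_lineage(cfg)))
    all_passages = [p for _, res in lineages for p in res.passage_log]
    all_records = [m for _, res in lineages for m in res.mutation_timeline]
    io.write_passage_log_csv(all_passages, out / "passages.csv")
    register("passages.csv")
    io.write_mutation_tsv(all_records, out / "mutations.tsv")
    register("mutations.tsv")
    counts["mutation_records"] = len(all_records)
    truth = {}
    for _, res in lineages:
        truth.update(res.truth)
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    register("ground_truth.json")

    # -- stage 2: fitness trajectories ---------------------------------------
    trajectories = []
    for cfg, res in lineages:
        trajectories.append(fitness_trajectory(res.passage_log))
    io.write_trajectory_tsv(trajectories, out / "fitness_trajectories.tsv")
    register("fitness_trajectories.tsv")

    # -- stage 3: competition + qPCR chain -----------------------------------
    wt = config.sim_config("WT", "lactate", 1, int(seeds[si]))
    mut = config.sim_config("mutS", "lactate", 1, int(seeds[si]))
    si += 1
    comp = simulate_competition(
        CompetitionConfig(wildtype=wt, mutator=mut,
                          displacement_threshold=config.displacement_threshold)
    )
    model = QpcrModel(
        intercept_c0=config.qpcr_intercept,
        efficiency=config.qpcr_efficiency,
        noise_sd=config.qpcr_noise_sd,
    )
    qpcr_rng = np.random.default_rng(int(seeds[si])); si += 1
    cq_samples = []
    for gen, frac in zip(comp.generations, comp.fraction_mutator):
        cq_samples.extend(
            simulate_qpcr(
                min(max(frac, 0.0), 1.0), 100.0, model, replicates=2,
                rng=qpcr_rng, sample_id=f"g{gen:g}", generation=gen,
            )
        )
    io.write_cq_csv(cq_samples, out / "competition_cq.csv")
    register("competition_cq.csv")
    trace = ratio_to_fraction_trace(cq_samples)
    io.write_trace_tsv(trace, out / "competition_trace.tsv")
    register("competition_trace.tsv")
    disp = displacement_generation(trace, config.displacement_threshold)
    mix_samples = []
    for i, frac in enumerate(config.mixing_fractions):
        mix_samples.extend(
            simulate_qpcr(frac, 100.0, model, replicates=2, rng=qpcr_rng,
                          sample_id=f"mix{i}")
        )
    calib = calibrate(config.mixing_fractions, mix_samples)
    io.write_calibration_json(calib, out / "calibration.json")
    register("calibration.json")

    # -- stage 4: mutation atlas ---------------------------------------------
    presences = build_presence(all_records)
    classified = classify_units(presences)
    io.write_classified_tsv(classified, out / "classified_units.tsv")
    register("classified_units.tsv")
    table, totals = count_by_category(classified, all_records)
    table.to_csv(out / "category_counts.tsv", sep="\t")
    register("category_counts.tsv")
    counts.update({f"mutations_{k}": v for k, v in totals.items()})
    matrix = trajectory_matrix(all_records, classified)
    matrix.to_csv(out / "trajectory_matrix.tsv", sep="\t")
    register("trajectory_matrix.tsv")
    catalog = default_unit_catalog(n_neutral=config.n_neutral_units)
    genes = [u.unit_id for u in catalog if u.unit_type == "gene"]
    cog_map = {g: _COG_LETTERS[i % len(_COG_LETTERS)] for i, g in enumerate(genes)}
    mutated_genes = {
        p.unit_id for p in classified if p.unit_type == "gene"
    }
    enrich = cog_enrichment(mutated_genes, cog_map, genes) if mutated_genes else []
    pd.DataFrame([dataclasses.asdict(e) for e in enrich]).to_csv(
        out / "cog_enrichment.tsv", sep="\t", index=False
    )
    register("cog_enrichment.tsv")

    # -- stage 5: phenotype microarray ---------------------------------------
    rate_rng = np.random.default_rng(int(seeds[si])); si += 1
    base_rates = default_rate_map(rng=rate_rng)
    substrates = sorted(base_rates)
    gain_high = {
        s: f for s, f in zip(substrates, config.pm_gain_high_folds)
    }
    evolved_rates = {
        s: r * gain_high.get(s, 1.0) for s, r in base_rates.items()
    }
    tabs_wt, tabs_mut = {}, {}
    outcome_frames = {}
    for carbon in ("lactate", "glycerol"):
        for strain, tabs in (("WT", tabs_wt), ("mutS", tabs_mut)):
            anc = [
                simulate_pm_plate(base_rates, noise_cv=config.pm_noise_cv,
                                  seed=int(seeds[si]) + k, blank_od=config.pm_blank_od)
                for k in range(2)
            ]
            si += 1
            evo = [
                simulate_pm_plate(evolved_rates, noise_cv=config.pm_noise_cv,
                                  seed=int(seeds[si]) + k, blank_od=config.pm_blank_od)
                for k in range(2)
            ]
            si += 1
            outcomes = analyze_plates(
                anc, evo, blank=config.pm_blank_od, alpha=config.pm_alpha,
                window_points=config.pm_window_points, min_r2=config.pm_min_r2,
            )
            outcome_frames[f"{carbon}:{strain}"] = outcomes
            tabs[carbon] = tabulate(outcomes)
    for key, outcomes in outcome_frames.items():
        name = f"pm_outcomes_{key.replace(':', '_')}.tsv"
        io.write_outcomes_tsv(outcomes, out / name)
        register(name)
    io.write_tabulation_tsv(
        {"lactate": {"WT": tabs_wt["lactate"], "mutS": tabs_mut["lactate"]},
         "glycerol": {"WT": tabs_wt["glycerol"], "mutS": tabs_mut["glycerol"]}},
        out / "pm_tabulation.tsv",
    )
    register("pm_tabulation.tsv")
    contrasts = strain_contrasts(
        tabs_wt, tabs_mut, pooling=config.contrast_pooling, yates=config.yates
    )
    contrasts.to_csv(out / "pm_contrasts.tsv", sep="\t", index=False)
    register("pm_contrasts.tsv")

    report = {
        "displacement_generation": None if disp is None else disp.generation,
        "displaced_strain": None if disp is None else disp.displaced,
        "calibration_r_squared": calib.r_squared,
        "category_units": {
            c: int(sum(1 for p in classified if p.category == c))
            for c in sorted({p.category for p in classified})
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    register("report.json")

    manifest = io.RunManifest(
        seed=config.seed,
        config=dataclasses.asdict(config),
        outputs=outputs,
        counts=counts,
    )
    # tuples are not JSON-stable; normalise the config snapshot
    for key in ("mixing_fractions", "pm_gain_high_folds"):
        manifest.config[key] = list(manifest.config[key])
    manifest.write(out / "manifest.json")
    return manifest
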