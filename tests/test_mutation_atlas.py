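"""Unit collapsing, replicate merging, recurrence classification, spectra."""

import itertools
import math

import numpy as np
import pytest

from alekit.errors import DomainError, GridError, GroupingError, UnassignedUnitError
from alekit.mutation_atlas import (
    Annotation,
    UnitPresence,
    build_presence,
    classify_units,
    cog_enrichment,
    collapse_to_units,
    count_by_category,
    merge_replicates,
    snv_type,
    trajectory_matrix,
)
from alekit.synth_data import (
    MutationRecord,
    SimConfig,
    default_unit_catalog,
    simulate_ale_lineage,
)

LINEAGES = [
    (f"{strain}_{carbon}_{rep}", strain, carbon, rep)
    for strain in ("WT", "mutS")
    for carbon in ("lactate", "glycerol")
    for rep in (1, 2)
]


def rec(lineage, unit="u1", gen=800.0, freq=0.5, pos=150, unit_type="gene",
        ref="A", alt="G", vclass="SNV"):
    lid, strain, carbon, rep = lineage
    return MutationRecord(
        lineage_id=lid, strain=strain, carbon=carbon, replicate=rep,
        generation=gen, unit_id=unit, unit_type=unit_type, position=pos,
        ref=ref, alt=alt, variant_class=vclass, frequency=freq,
    )


class TestCollapse:
    def annotation(self):
        return Annotation(
            [("geneA", "gene", 101, 200), ("geneB", "gene", 301, 400)]
        )

    def test_positions_in_one_gene_share_unit(self):
        records = [
            rec(LINEAGES[0], pos=110),
            rec(LINEAGES[0], pos=190, alt="T"),
        ]
        out = collapse_to_units(records, self.annotation())
        assert len(out) == 2
        assert {r.unit_id for r in out} == {"geneA"}

    def test_intergenic_named_by_flanks(self):
        out = collapse_to_units([rec(LINEAGES[0], pos=250)], self.annotation())
        assert out[0].unit_id == "geneA/geneB"
        assert out[0].unit_type == "intergenic"

    def test_beyond_last_gene(self):
        out = collapse_to_units([rec(LINEAGES[0], pos=999)], self.annotation())
        assert out[0].unit_id == "geneB/-"

    def test_empty_input(self):
        assert collapse_to_units([], self.annotation()) == []

    def test_unmappable_position_raises(self):
        with pytest.raises(UnassignedUnitError):
            collapse_to_units([rec(LINEAGES[0], pos=0)], self.annotation())

    def test_overlapping_genes_rejected(self):
        with pytest.raises(DomainError):
            Annotation([("a", "gene", 1, 100), ("b", "gene", 50, 150)])


class TestMerge:
    def test_union_of_disjoint_sets(self):
        r1 = [rec(LINEAGES[0], unit="a"), rec(LINEAGES[0], unit="b")]
        r2 = [rec(LINEAGES[1], unit="c")]
        merged = merge_replicates(r1, r2)
        assert {m.unit_id for m in merged} == {"a", "b", "c"}

    def test_higher_frequency_wins(self):
        r1 = [rec(LINEAGES[0], unit="x", freq=0.40)]
        r2 = [rec(LINEAGES[1], unit="x", freq=0.25)]
        merged = merge_replicates(r1, r2)
        assert len(merged) == 1
        assert merged[0].frequency == 0.40
        assert merged[0].lineage_id == LINEAGES[0][0]  # provenance retained

    def test_idempotent_and_commutative(self):
        r1 = [rec(LINEAGES[0], unit="x", freq=0.4), rec(LINEAGES[0], unit="y", freq=0.2)]
        r2 = [rec(LINEAGES[1], unit="x", freq=0.3)]
        assert merge_replicates(r1, r1) == sorted(
            r1, key=lambda r: (r.generation, r.unit_id)
        )
        assert merge_replicates(r1, r2) == merge_replicates(r2, r1)

    def test_mixed_groups_rejected(self):
        r1 = [rec(LINEAGES[0])]
        r2 = [rec(LINEAGES[2])]  # different carbon
        with pytest.raises(GroupingError):
            merge_replicates(r1, r2)


def oracle_category(lineage_ids: frozenset, wildtype="WT") -> str:
    """Straight-line re-statement of the recurrence rules, kept independent
    of the implementation: uniqueness, then strain/carbon breadth."""
    if len(lineage_ids) == 1:
        return "random"
    strains = set()
    carbons = set()
    for lid in lineage_ids:
        s, c, _ = lid.split("_")
        strains.add(s)
        carbons.add(c)
    both_strains = len(strains) == 2
    both_carbons = len(carbons) == 2
    if both_strains and both_carbons:
        return "generalist"
    if both_strains:
        return "lactate_specific" if "lactate" in carbons else "glycerol_specific"
    if both_carbons:
        return "wildtype_specific" if strains == {wildtype} else "mutator_specific"
    # two replicate lineages of a single strain x carbon group
    return "lactate_specific" if "lactate" in carbons else "glycerol_specific"


def presence_for(lineage_subset):
    lookup = {l[0]: l for l in LINEAGES}
    groups = frozenset(
        (lookup[lid][1], lookup[lid][2]) for lid in lineage_subset
    )
    return UnitPresence(
        unit_id="u", unit_type="gene",
        lineages_present=frozenset(lineage_subset), groups_present=groups,
    )


class TestClassification:
    def test_exhaustive_oracle_agreement(self):
        """All 255 non-empty subsets of the 8 lineages match the oracle."""
        all_ids = [l[0] for l in LINEAGES]
        subsets = [
            frozenset(combo)
            for k in range(1, 9)
            for combo in itertools.combinations(all_ids, k)
        ]
        assert len(subsets) == 255
        classified = classify_units([presence_for(s) for s in subsets])
        for subset, result in zip(subsets, classified):
            assert result.category == oracle_category(subset), subset

    @pytest.mark.parametrize(
        "lineage_idx, expected",
        [
            ((0, 4), "lactate_specific"),  # WT-lac + mutS-lac
            ((4, 6), "mutator_specific"),  # mutS-lac + mutS-gly
            ((3,), "random"),
            ((0, 2, 4, 6), "generalist"),
        ],
    )
    def test_named_patterns(self, lineage_idx, expected):
        subset = frozenset(LINEAGES[i][0] for i in lineage_idx)
        [result] = classify_units([presence_for(subset)])
        assert result.category == expected

    def test_single_group_recurrence_flagged(self):
        subset = frozenset([LINEAGES[4][0], LINEAGES[5][0]])  # both mutS-lac reps
        [result] = classify_units([presence_for(subset)])
        assert result.category == "lactate_specific"
        assert "single_strain_recurrence" in result.flags

    def test_empty_presence_rejected(self):
        bad = UnitPresence("u", "gene", frozenset(), frozenset())
        with pytest.raises(DomainError):
            classify_units([bad])

    def test_category_conservation(self):
        """Unit counts per category sum to the number of distinct units."""
        rng = np.random.default_rng(0)
        all_ids = [l[0] for l in LINEAGES]
        presences = []
        for i in range(50):
            k = int(rng.integers(1, 9))
            subset = frozenset(rng.choice(all_ids, size=k, replace=False).tolist())
            p = presence_for(subset)
            presences.append(
                UnitPresence(f"u{i}", "gene", p.lineages_present, p.groups_present)
            )
        classified = classify_units(presences)
        by_cat = {}
        for p in classified:
            by_cat[p.category] = by_cat.get(p.category, 0) + 1
        assert sum(by_cat.values()) == 50


class TestCounting:
    def test_planted_random_mutations_counted_per_strain(self):
        records = []
        for lineage in LINEAGES[4:]:  # the four mutator lineages
            for k in range(10):
                records.append(rec(lineage, unit=f"r_{lineage[0]}_{k}", freq=0.2))
        classified = classify_units(build_presence(records))
        table, totals = count_by_category(classified, records)
        assert int(table.loc["random", "mutS"].sum()) == 40
        assert totals["observations"] == 40

    def test_empty_inputs(self):
        table, totals = count_by_category([], [])
        assert totals["observations"] == 0
        assert int(table.to_numpy().sum()) == 0

    def test_generalist_counting_convention(self):
        records = [rec(lineage, unit="gnrl") for lineage in LINEAGES]
        classified = classify_units(build_presence(records))
        table, totals = count_by_category(classified, records)
        assert int(table.loc["generalist"].sum()) == 8  # mutation observations
        assert totals["units"] == 1


class TestSnvType:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "G", "transition"),
            ("G", "A", "transition"),
            ("C", "T", "transition"),
            ("A", "T", "transversion"),
            ("G", "C", "transversion"),
            ("-", "G", "not_applicable"),
            ("A", "AG", "not_applicable"),
        ],
    )
    def test_classification(self, ref, alt, expected):
        assert snv_type(ref, alt) == expected

    def test_non_acgt_rejected(self):
        with pytest.raises(DomainError):
            snv_type("N", "A")


class TestTrajectoryMatrix:
    def test_late_detection_row(self):
        records = [rec(LINEAGES[0], unit="u1", gen=800.0, freq=0.6)]
        classified = classify_units(build_presence(records))
        mat = trajectory_matrix(records, classified, checkpoints=[100.0 * k for k in range(1, 9)])
        row = mat.loc["u1"]
        assert row[800.0] == 0.6
        assert (row[[100.0 * k for k in range(1, 8)]] == 0).all()

    def test_constant_floor_row(self):
        cps = [100.0 * k for k in range(1, 9)]
        records = [rec(LINEAGES[0], unit="u1", gen=g, freq=0.10) for g in cps]
        classified = classify_units(build_presence(records))
        mat = trajectory_matrix(records, classified, checkpoints=cps)
        assert (mat.loc["u1"] == 0.10).all()

    def test_off_grid_rejected(self):
        records = [rec(LINEAGES[0], gen=137.0)]
        classified = classify_units(build_presence(records))
        with pytest.raises(GridError):
            trajectory_matrix(records, classified, checkpoints=[100.0, 200.0])

    def test_category_block_ordering(self):
        records = (
            [rec(l, unit="zgen") for l in LINEAGES]
            + [rec(LINEAGES[0], unit="arand")]
        )
        classified = classify_units(build_presence(records))
        mat = trajectory_matrix(records, classified, checkpoints=[800.0])
        assert list(mat.index) == ["zgen", "arand"]  # generalist block first

    def test_selective_sweep_rises_monotonically(self):
        """Mean frequency of a beneficial founder never drops between
        checkpoints (within sampling noise) on the way to fixation."""
        cat = default_unit_catalog(n_neutral=3, s_generalist=0.1, s_specialist=0.0)
        trajs = []
        for seed in range(20):
            cfg = SimConfig(
                bottleneck_size=2000, total_generations=100, checkpoint_interval=25,
                mu_basal=0.0, unit_catalog=cat, founders={"rpoB": 0.15}, seed=seed,
            )
            res = simulate_ale_lineage(cfg)
            trajs.append(
                [res.checkpoint_frequencies[g].get("rpoB", 0.0)
                 for g in (25.0, 50.0, 75.0, 100.0)]
            )
        mean = np.mean(trajs, axis=0)
        assert all(b >= a - 0.05 for a, b in zip(mean, mean[1:]))


def hypergeom_tail_oracle(k, big_n, big_k, n):
    """P(X >= k) by direct combinatorial summation."""
    total = 0.0
    for i in range(k, min(big_k, n) + 1):
        total += (
            math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
        ) / math.comb(big_n, n)
    return total


class TestCogEnrichment:
    def test_pure_category_fold(self):
        genome = [f"g{i}" for i in range(100)]
        cog = {g: ("E" if i < 10 else "K") for i, g in enumerate(genome)}
        mutated = [f"g{i}" for i in range(10)]  # all category E
        res = {r.category_code: r for r in cog_enrichment(mutated, cog, genome)}
        assert res["E"].fold_enrichment == pytest.approx(10.0)

    def test_hypergeometric_oracle(self):
        genome = [f"g{i}" for i in range(100)]
        cog = {g: ("E" if i < 20 else "K") for i, g in enumerate(genome)}
        mutated = [f"g{i}" for i in [0, 1, 2, 3, 4, 50, 51, 52, 53, 54]]  # 5 of 10 in E
        res = {r.category_code: r for r in cog_enrichment(mutated, cog, genome)}
        assert res["E"].p_value == pytest.approx(
            hypergeom_tail_oracle(5, 100, 20, 10), rel=1e-10
        )

    def test_background_proportion_gives_unit_fold(self):
        genome = [f"g{i}" for i in range(100)]
        cog = {g: ("E" if i % 10 == 0 else "K") for i, g in enumerate(genome)}
        mutated = ["g0", "g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8", "g9"]
        res = {r.category_code: r for r in cog_enrichment(mutated, cog, genome)}
        assert res["E"].fold_enrichment == pytest.approx(1.0)

    def test_empty_mutated_warns(self):
        with pytest.warns(UserWarning):
            assert cog_enrichment([], {"g": "E"}, ["g"]) == []


def test_ground_truth_category_recovery():
    """Planted selected units are recovered at >= 90% when detected in two
    or more lineages; planted-neutral singletons are always random."""
    cat = default_unit_catalog(n_neutral=200, s_generalist=0.1, s_specialist=0.08)
    expected = {
        "generalist": "generalist",
        "lactate_specialist": "lactate_specific",
        "glycerol_specialist": "glycerol_specific",
    }
    total = correct = 0
    neutral_singletons = neutral_random = 0
    for seed_block in range(20):
        records, truth = [], {}
        s = 1000 + 100 * seed_block
        for strain in ("WT", "mutS"):
            for carbon in ("lactate", "glycerol"):
                for rep in (1, 2):
                    cfg = SimConfig(
                        bottleneck_size=10_000, total_generations=400,
                        checkpoint_interval=400, mu_basal=1e-3,
                        mutator_multiplier=50.0 if strain == "mutS" else 1.0,
                        unit_catalog=cat, carbon=carbon, seed=s,
                        strain=strain, replicate=rep,
                    )
                    s += 1
                    res = simulate_ale_lineage(cfg)
                    records += res.mutation_timeline
                    truth.update(res.truth)
        classified = classify_units(build_presence(records))
        for p in classified:
            planted = truth.get(p.unit_id)
            if planted in expected and len(p.lineages_present) >= 2:
                total += 1
                correct += p.category == expected[planted]
            if planted == "neutral" and len(p.lineages_present) == 1:
                neutral_singletons += 1
                neutral_random += p.category == "random"
    assert total > 0
    assert correct / total >= 0.90
    assert neutral_random == neutral_singletons
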