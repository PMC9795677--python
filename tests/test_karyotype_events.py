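import numpy as np
import pytest

from conftest import anchors_from_cells, make_table
from oracles import brute_force_matching

from synkaryo.collinearity import BlockAnchor, SyntenyBlock
from synkaryo.errors import ValidationError
from synkaryo.genome_io import filter_top_hits
from synkaryo.karyotype_events import (
    GainRecord,
    build_chromosome_map,
    classify_gains,
    infer_events,
    infer_karyotype_events,
    match_descendant_chromosomes,
)
from synkaryo.synthetic_data import EventPlan, SimConfig, simulate_three_genomes


def block(chrom_a, chrom_b, n=5, direction=1):
    anchors = tuple(BlockAnchor(f"{chrom_a}.g{i}", f"{chrom_b}.g{i}", i, i)
                    for i in range(n))
    return SyntenyBlock(chrom_a, chrom_b, anchors, direction, (0, n * 100), (0, n * 100))


def run_sim_pipeline(config, min_blocks=1, min_anchors=4):
    b = simulate_three_genomes(config)
    result = infer_karyotype_events(
        b.outgroup, b.d1, b.d2,
        filter_top_hits(b.anchors("og_d1")),
        filter_top_hits(b.anchors("og_d2")),
        filter_top_hits(b.anchors("d1_d2")),
        self_anchors_d1=filter_top_hits(b.anchors("self_d1")),
        self_anchors_d2=filter_top_hits(b.anchors("self_d2")),
        min_blocks=min_blocks, min_anchors=min_anchors,
    )
    return b, result


class TestMatching:
    def test_identity_genomes_pair_everything(self):
        blocks = [block(f"A{i:02d}", f"B{i:02d}") for i in range(30)]
        protos = match_descendant_chromosomes(blocks)
        assert len(protos) == 30
        assert all(p.paired for p in protos)
        assert all(p.member_d1[1:] == p.member_d2[1:] for p in protos)

    def test_weighted_case_matches_brute_force(self):
        weights = {("a1", "b1"): 100, ("a1", "b2"): 10, ("a2", "b2"): 90}
        blocks = [block(c1, c2, n=w) for (c1, c2), w in weights.items()]
        protos = match_descendant_chromosomes(blocks)
        got = {(p.member_d1, p.member_d2) for p in protos if p.paired}
        assert got == brute_force_matching(weights)
        assert got == {("a1", "b1"), ("a2", "b2")}

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(25):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            weights = {}
            for i in range(n1):
                for j in range(n2):
                    if rng.random() < 0.5:
                        # distinct weights keep the optimum unique
                        weights[(f"a{i}", f"b{j}")] = int(rng.integers(1, 10_000))
            if not weights:
                continue
            blocks = [block(c1, c2, n=w) for (c1, c2), w in weights.items()]
            protos = match_descendant_chromosomes(blocks)
            got = {(p.member_d1, p.member_d2) for p in protos if p.paired}
            assert got == brute_force_matching(weights)

    def test_no_blocks_means_no_pairs(self):
        with pytest.warns(UserWarning, match="unpaired"):
            protos = match_descendant_chromosomes([], ["a1", "a2"], ["b1"])
        assert all(not p.paired for p in protos)
        assert len(protos) == 3


class TestChromosomeMap:
    def test_retention_requires_both_descendants(self):
        protos = match_descendant_chromosomes([block("a1", "b1", 10)])
        cmap = build_chromosome_map(
            [block("N1", "a1", 6)],   # outgroup linked to d1 only
            [],
            protos, outgroup_chromosomes=["N1"],
        )
        assert cmap.edges == []
        assert cmap.orphan_outgroup == ["N1"]

    def test_identity_three_genome_map(self):
        protos = match_descendant_chromosomes(
            [block(f"a{i}", f"b{i}", 10) for i in range(5)]
        )
        cmap = build_chromosome_map(
            [block(f"N{i}", f"a{i}", 6) for i in range(5)],
            [block(f"N{i}", f"b{i}", 6) for i in range(5)],
            protos, outgroup_chromosomes=[f"N{i}" for i in range(5)],
        )
        assert len(cmap.edges) == 5
        assert cmap.orphan_outgroup == []
        assert cmap.orphan_proto == []
        events = infer_events(cmap)
        assert events.totals() == {"fissions": 0, "fusions": 0, "losses": 0, "gains": 0}

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            build_chromosome_map([], [], [], min_blocks=0)

    def test_threshold_monotonicity(self, rng):
        # raising min_blocks can only orphan more outgroup chromosomes
        protos = match_descendant_chromosomes(
            [block(f"a{i}", f"b{i}", 10) for i in range(6)]
        )
        blocks1, blocks2 = [], []
        for i in range(6):
            for _ in range(int(rng.integers(1, 4))):
                blocks1.append(block(f"N{i}", f"a{i}", 5))
            for _ in range(int(rng.integers(1, 4))):
                blocks2.append(block(f"N{i}", f"b{i}", 5))
        og = [f"N{i}" for i in range(6)]
        prev_losses, prev_edges = -1, None
        for mb in (1, 2, 3, 4):
            cmap = build_chromosome_map(blocks1, blocks2, protos,
                                        outgroup_chromosomes=og, min_blocks=mb)
            losses = len(cmap.orphan_outgroup)
            assert losses >= prev_losses
            if prev_edges is not None:
                assert len(cmap.edges) <= prev_edges
            prev_losses, prev_edges = losses, len(cmap.edges)


class TestInferEvents:
    def make_map(self, edge_list, og, protos_pairs):
        protos = match_descendant_chromosomes(
            [block(d1, d2, 10) for d1, d2 in protos_pairs]
        )
        by_member = {p.member_d1: p.id for p in protos}
        blocks1 = [block(ogc, d1, 6) for ogc, (d1, d2) in edge_list]
        blocks2 = [block(ogc, d2, 6) for ogc, (d1, d2) in edge_list]
        return build_chromosome_map(blocks1, blocks2, protos,
                                    outgroup_chromosomes=og)

    def test_fission_counts_n_minus_1(self):
        cmap = self.make_map(
            [("N1", ("a1", "b1")), ("N1", ("a2", "b2")), ("N1", ("a3", "b3"))],
            ["N1"], [("a1", "b1"), ("a2", "b2"), ("a3", "b3")],
        )
        events = infer_events(cmap)
        assert events.total_fissions == 2
        assert events.fissions[0].n_protos == 3

    def test_fusion_counts_m_minus_1(self):
        cmap = self.make_map(
            [("N1", ("a1", "b1")), ("N2", ("a1", "b1")), ("N3", ("a1", "b1"))],
            ["N1", "N2", "N3"], [("a1", "b1")],
        )
        events = infer_events(cmap)
        assert events.total_fusions == 2

    def test_event_rule_identities_on_random_maps(self, rng):
        # fission/fusion totals must equal the sum rules recomputed directly
        for _ in range(200):
            n_og, n_proto = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            pairs = [(f"a{j}", f"b{j}") for j in range(n_proto)]
            edges = []
            for i in range(n_og):
                for j in range(n_proto):
                    if rng.random() < 0.3:
                        edges.append((f"N{i}", pairs[j]))
            cmap = self.make_map(edges, [f"N{i}" for i in range(n_og)], pairs)
            events = infer_events(cmap)
            deg_og = {}
            deg_proto = {}
            for e in cmap.edges:
                deg_og[e.outgroup_chrom] = deg_og.get(e.outgroup_chrom, 0) + 1
                deg_proto[e.proto_id] = deg_proto.get(e.proto_id, 0) + 1
            assert events.total_fissions == sum(max(0, n - 1) for n in deg_og.values())
            assert events.total_fusions == sum(max(0, m - 1) for m in deg_proto.values())
            assert set(events.losses) == {f"N{i}" for i in range(n_og)} - set(deg_og)


class TestClassifyGains:
    def test_no_self_blocks_means_not_duplicative(self):
        gains = [GainRecord("P01", "a9", "b9")]
        out = classify_gains(gains, [], [])
        assert out[0].duplicative_origin is False

    def test_self_block_to_other_chromosome_flags(self):
        gains = [GainRecord("P01", "a9", "b9")]
        out = classify_gains(gains, [block("a9", "a3", 6)], [])
        assert out[0].duplicative_origin is True

    def test_same_chromosome_self_blocks_ignored(self):
        gains = [GainRecord("P01", "a9", "b9")]
        out = classify_gains(gains, [block("a9", "a9", 6)], [])
        assert out[0].duplicative_origin is False


class TestSimulatedScenarios:
    CFG = dict(n_chromosomes=12, genes_per_chromosome=60, with_sequences=False)

    def test_planted_fission_appears_in_map(self):
        config = SimConfig(seed=11, event_plan=EventPlan(fissions=1), **self.CFG)
        bundle, result = run_sim_pipeline(config)
        events = result["events"]
        assert events.totals() == {"fissions": 1, "fusions": 0, "losses": 0, "gains": 0}
        fission_chroms = [f.outgroup_chrom for f in events.fissions]
        planted = [e["source"] for e in bundle.truth.events if e["type"] == "fission"]
        assert fission_chroms == planted
        assert events.fissions[0].n_protos == 2

    def test_planted_mixed_plan_recovered(self):
        config = SimConfig(
            seed=5,
            event_plan=EventPlan(fissions=5, fusions=3, losses=1, gains=2),
            **self.CFG,
        )
        bundle, result = run_sim_pipeline(config)
        assert result["events"].totals() == {"fissions": 5, "fusions": 3,
                                             "losses": 1, "gains": 2}

    def test_duplicative_gain_flagged_and_novel_not(self):
        config = SimConfig(
            seed=8, event_plan=EventPlan(gains=1, duplicative_gains=1), **self.CFG
        )
        bundle, result = run_sim_pipeline(config)
        flags = sorted(g.duplicative_origin for g in result["events"].gains)
        assert flags == [False, True]

    def test_descendant_symmetry(self):
        config = SimConfig(
            seed=13, event_plan=EventPlan(fissions=2, fusions=2, losses=1, gains=1),
            **self.CFG,
        )
        b = simulate_three_genomes(config)
        swap = lambda anchors: [
            type(a)(a.subject_gene, a.query_gene, a.evalue, a.bitscore)
            for a in anchors
        ]
        fwd = infer_karyotype_events(
            b.outgroup, b.d1, b.d2,
            filter_top_hits(b.anchors("og_d1")), filter_top_hits(b.anchors("og_d2")),
            filter_top_hits(b.anchors("d1_d2")),
        )["events"]
        rev = infer_karyotype_events(
            b.outgroup, b.d2, b.d1,
            filter_top_hits(b.anchors("og_d2")), filter_top_hits(b.anchors("og_d1")),
            filter_top_hits(swap(b.anchors("d1_d2"))),
        )["events"]
        assert fwd.totals() == rev.totals()
        assert fwd.losses == rev.losses
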