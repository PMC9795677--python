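import hashlib
import json

import numpy as np
import pytest

from synkaryo.collinearity import BlockParams, find_collinear_blocks
from synkaryo.errors import ValidationError
from synkaryo.genome_io import filter_top_hits, read_anchor_table, read_gff3
from synkaryo.synthetic_data import (
    Burst,
    EventPlan,
    SimConfig,
    apply_karyotype_events,
    evaluate_recovery,
    expected_p,
    load_truth,
    simulate_ancestor,
    simulate_three_genomes,
    write_bundle,
)

SMALL = dict(n_chromosomes=6, genes_per_chromosome=30, with_sequences=False)


def dir_digest(path):
    h = hashlib.sha256()
    for f in sorted(path.iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestAncestor:
    def test_shape_and_uniqueness(self, rng):
        config = SimConfig(n_chromosomes=5, genes_per_chromosome=10)
        anc = simulate_ancestor(config, rng)
        assert len(anc.chrom_genes) == 5
        ids = anc.gene_ids
        assert len(ids) == 50 == len(set(ids))
        assert all(len(anc.sequences[g]) == config.seq_length for g in ids)

    def test_invalid_chromosome_count(self):
        with pytest.raises(ValidationError):
            SimConfig(n_chromosomes=0)


class TestKaryotypeEventApplication:
    def test_fission_conserves_genes(self, rng):
        config = SimConfig(event_plan=EventPlan(fissions=1), **SMALL)
        anc = simulate_ancestor(config, rng)
        from synkaryo.synthetic_data import SimTruth
        proto, _ = apply_karyotype_events(anc, config.event_plan, rng, config,
                                          SimTruth("t"))
        assert len(proto.chrom_genes) == 7
        assert sorted(proto.gene_ids) == sorted(anc.gene_ids)

    def test_loss_removes_exactly_one_chromosome(self, rng):
        config = SimConfig(event_plan=EventPlan(losses=1), **SMALL)
        anc = simulate_ancestor(config, rng)
        from synkaryo.synthetic_data import SimTruth
        truth = SimTruth("t")
        proto, _ = apply_karyotype_events(anc, config.event_plan, rng, config, truth)
        lost = next(e["chromosome"] for e in truth.events if e["type"] == "loss")
        lost_genes = dict(anc.chrom_genes)[lost]
        assert sorted(proto.gene_ids) == sorted(set(anc.gene_ids) - set(lost_genes))

    def test_infeasible_plan_rejected_before_mutation(self, rng):
        config = SimConfig(event_plan=EventPlan(losses=5, fusions=2), **SMALL)
        anc = simulate_ancestor(config, rng)
        from synkaryo.synthetic_data import SimTruth
        with pytest.raises(ValidationError, match="infeasible"):
            apply_karyotype_events(anc, EventPlan(losses=5, fusions=5), rng,
                                   config, SimTruth("t"))

    def test_truth_log_counts_match_plan(self, rng):
        for seed in range(30):
            plan = EventPlan(
                fissions=int(rng.integers(0, 4)), fusions=int(rng.integers(0, 3)),
                losses=int(rng.integers(0, 2)), gains=int(rng.integers(0, 2)),
            )
            config = SimConfig(seed=seed, event_plan=plan, n_chromosomes=8,
                               genes_per_chromosome=100, with_sequences=False)
            bundle = simulate_three_genomes(config)
            counts = {"fission": 0, "fusion": 0, "loss": 0, "gain": 0}
            for e in bundle.truth.events:
                if e["type"] == "fusion":
                    counts["fusion"] += e["n_events"]
                else:
                    counts[e["type"]] += 1
            assert counts == {"fission": plan.fissions, "fusion": plan.fusions,
                              "loss": plan.losses, "gain": plan.total_gains}


class TestDescendants:
    def test_zero_noise_anchors_reproduce_ortholog_map(self):
        config = SimConfig(seed=4, n_inversions=0, **SMALL)
        b = simulate_three_genomes(config)
        anchors = b.anchors("d1_d2")
        got = {(a.query_gene, a.subject_gene) for a in anchors}
        maps = b.truth.ortholog_maps
        expected = {(maps["d1"][g], maps["d2"][g]) for g in maps["d1"]}
        assert got == expected

    def test_planted_inversion_yields_descending_block(self):
        config = SimConfig(seed=4, n_inversions=1, n_chromosomes=2,
                           genes_per_chromosome=40, inversion_size=(6, 6),
                           with_sequences=False)
        b = simulate_three_genomes(config)
        blocks = find_collinear_blocks(
            b.d1, b.d2, filter_top_hits(b.anchors("d1_d2")), BlockParams()
        )
        descending = [bl for bl in blocks if bl.direction == -1]
        # two independent descendants, one inversion each; the flanking
        # ascending chain may absorb one edge anchor of an inverted run
        assert len(descending) == 2
        assert all(5 <= bl.n_anchors <= 6 for bl in descending)

    def test_dropout_binomial_expectation(self):
        kept = []
        for seed in range(50):
            config = SimConfig(seed=seed, anchor_dropout=0.1, n_chromosomes=4,
                               genes_per_chromosome=50, with_sequences=False)
            b = simulate_three_genomes(config)
            kept.append(len(b.anchor_frames["d1_d2"]))
        mean = np.mean(kept)
        # 200 anchors, p_keep=0.9 -> mean 180, SE ~ 4.2/sqrt(50)
        assert mean == pytest.approx(180, abs=3)

    def test_label_integrity(self):
        config = SimConfig(seed=9,
                           event_plan=EventPlan(fissions=2, gains=1,
                                                duplicative_gains=1),
                           burst_plan=(Burst(20.0, 10, "alpha"),), **SMALL)
        b = simulate_three_genomes(config)
        maps = b.truth.ortholog_maps
        for species, table in (("d1", b.d1), ("d2", b.d2)):
            from_proto = set(maps[species].values())
            from_bursts = set(b.truth.subfamilies[species])
            all_genes = set(table.df["gene_id"])
            assert all_genes == from_proto | from_bursts
            assert not from_proto & from_bursts


class TestSequencesAndBursts:
    def test_burst_age_zero_pairs_identical(self):
        config = SimConfig(seed=2, n_chromosomes=2, genes_per_chromosome=20,
                           burst_plan=(Burst(0.0, 5, "a"),), with_sequences=False)
        b = simulate_three_genomes(config)
        assert all(ap.seq1 == ap.seq2 for ap in b.aligned_pairs["d1"])

    def test_burst_divergence_matches_jc_expectation(self):
        config = SimConfig(seed=3, n_chromosomes=2, genes_per_chromosome=20,
                           burst_plan=(Burst(65.0, 200, "a"),), r=1e-3,
                           seq_length=10_000, with_sequences=False)
        b = simulate_three_genomes(config)
        from synkaryo.family_dating import AlignedPair, p_distance
        ps = [p_distance(ap) for ap in b.aligned_pairs["d1"]]
        assert np.mean(ps) == pytest.approx(expected_p(2 * 1e-3 * 65.0), rel=0.02)


class TestDeterminismAndFiles:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        config = SimConfig(seed=77, event_plan=EventPlan(fissions=1, losses=1),
                           burst_plan=(Burst(30.0, 5, "a"),),
                           n_chromosomes=4, genes_per_chromosome=20,
                           seq_length=100, anchor_dropout=0.05,
                           spurious_anchor_rate=0.05)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_bundle(simulate_three_genomes(config), d1)
        write_bundle(simulate_three_genomes(config), d2)
        assert dir_digest(d1) == dir_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        base = dict(n_chromosomes=4, genes_per_chromosome=20, seq_length=100)
        d1, d2 = tmp_path / "s1", tmp_path / "s2"
        write_bundle(simulate_three_genomes(SimConfig(seed=1, **base)), d1)
        write_bundle(simulate_three_genomes(SimConfig(seed=2, **base)), d2)
        assert dir_digest(d1) != dir_digest(d2)

    def test_emitted_files_parse_and_agree_with_memory(self, tmp_path):
        config = SimConfig(seed=6, event_plan=EventPlan(fissions=1), **SMALL)
        b = simulate_three_genomes(config)
        write_bundle(b, tmp_path)
        og = read_gff3(tmp_path / "outgroup.gff3", species="outgroup")
        assert og.df.equals(b.outgroup.df)
        anchors = read_anchor_table(tmp_path / "d1_d2.tsv")
        assert len(anchors) == len(b.anchors("d1_d2"))
        truth = load_truth(tmp_path / "truth.json")
        assert truth.planted_totals == b.truth.planted_totals


class TestRecoveryReport:
    def test_perfect_run_passes(self):
        from synkaryo.genome_io import filter_top_hits
        from synkaryo.karyotype_events import infer_karyotype_events

        config = SimConfig(seed=21, event_plan=EventPlan(fissions=2, losses=1),
                           n_chromosomes=10, genes_per_chromosome=50,
                           with_sequences=False)
        b = simulate_three_genomes(config)
        result = infer_karyotype_events(
            b.outgroup, b.d1, b.d2,
            filter_top_hits(b.anchors("og_d1")), filter_top_hits(b.anchors("og_d2")),
            filter_top_hits(b.anchors("d1_d2")),
        )
        report = evaluate_recovery(b.truth, result["events"])
        assert report["passed"]
        assert all(v["match"] for v in report["per_type"].values())

    def test_sim_id_mismatch_rejected(self):
        config = SimConfig(seed=21, **SMALL)
        b = simulate_three_genomes(config)
        from synkaryo.karyotype_events import EventSet
        with pytest.raises(ValidationError, match="mismatch"):
            evaluate_recovery(b.truth, EventSet([], [], [], []), sim_id="other")

    def test_stress_report_well_formed_under_heavy_dropout(self):
        from synkaryo.genome_io import filter_top_hits
        from synkaryo.karyotype_events import infer_karyotype_events

        config = SimConfig(seed=30, event_plan=EventPlan(fissions=1),
                           anchor_dropout=0.5, **SMALL)
        b = simulate_three_genomes(config)
        result = infer_karyotype_events(
            b.outgroup, b.d1, b.d2,
            filter_top_hits(b.anchors("og_d1")), filter_top_hits(b.anchors("og_d2")),
            filter_top_hits(b.anchors("d1_d2")),
        )
        report = evaluate_recovery(b.truth, result["events"])
        assert set(report["per_type"]) == {"fissions", "fusions", "losses", "gains"}
        json.dumps(report)   # serialisable
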