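"""Forward simulation of a three-genome system with planted rearrangements.

The generator produces one outgroup genome (a stand-in for the ancestral
karyotype), applies a planted event plan (fissions, fusions, losses, gains)
to form the ingroup proto-ancestor, and derives two descendant genomes with
independent inversions and sequence divergence under a Jukes-Cantor clock.
It emits exactly the file formats the analysis pipeline consumes — GFF3,
12-column tabular anchors, aligned FASTA — plus a machine-readable truth log,
so every inference stage can be scored against known ground truth.

Tandem-duplication bursts plant gene-family expansions of known age on a
single chromosome, mirroring the cluster-on-one-chromosome organisation of
expanded neural gene families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .family_dating import AlignedPair
from .genome_io import (
    ANCHOR_COLUMNS,
    AnchorPair,
    GenomeTable,
    write_anchor_table,
    write_gff3,
)

__all__ = [
    "EventPlan",
    "Burst",
    "SimConfig",
    "SimTruth",
    "SimGenome",
    "SimBundle",
    "simulate_ancestor",
    "apply_karyotype_events",
    "derive_descendants",
    "simulate_tandem_bursts",
    "simulate_three_genomes",
    "write_bundle",
    "load_truth",
    "anchors_from_frame",
    "evaluate_recovery",
    "evaluate_event_recovery",
    "evaluate_peak_recovery",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EventPlan:
    """Counts of karyotype events to plant (non-overlapping chromosomes)."""

    fissions: int = 0
    fusions: int = 0
    losses: int = 0
    gains: int = 0
    duplicative_gains: int = 0

    def __post_init__(self) -> None:
        if min(self.fissions, self.fusions, self.losses, self.gains,
               self.duplicative_gains) < 0:
            raise ValidationError("event counts must be >= 0")

    @property
    def total_gains(self) -> int:
        return self.gains + self.duplicative_gains


@dataclass(frozen=True)
class Burst:
    """One tandem-duplication burst: n duplications at a fixed age (Ma)."""

    age: float
    n: int
    subfamily: str
    chromosome: str | None = None


@dataclass
class SimConfig:
    """Study conditions for one simulation run.

    Defaults emulate a nautilus-like outgroup karyotype (26 chromosomes), a
    44 Ma descendant divergence, and a two-burst protocadherin-like family
    expansion (65 Ma and 11 Ma).  ``r`` is the clock used both to evolve
    sequences and, downstream, to date them.
    """

    seed: int = 0
    n_chromosomes: int = 26
    genes_per_chromosome: int | tuple[int, int] = 100
    event_plan: EventPlan = field(default_factory=EventPlan)
    n_inversions: int = 5
    inversion_size: tuple[int, int] = (4, 12)
    anchor_dropout: float = 0.0
    spurious_anchor_rate: float = 0.0
    burst_plan: tuple[Burst, ...] = ()
    r: float = 1e-3
    divergence_age: float = 44.0
    outgroup_divergence_age: float = 250.0
    seq_length: int = 1500
    with_sequences: bool = True
    evalue_cutoff: float = 1e-5
    min_segment_genes: int = 8

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValidationError("n_chromosomes must be >= 1")
        if not (0 <= self.anchor_dropout < 1):
            raise ValidationError("anchor_dropout must be in [0, 1)")
        if not (0 <= self.spurious_anchor_rate < 1):
            raise ValidationError("spurious_anchor_rate must be in [0, 1)")
        if self.r <= 0:
            raise ValidationError("r must be > 0")


@dataclass
class SimTruth:
    """Ground truth for one simulation."""

    sim_id: str
    events: list[dict] = field(default_factory=list)
    planted_totals: dict[str, int] = field(default_factory=dict)
    proto_composition: dict[str, list[str]] = field(default_factory=dict)
    ortholog_maps: dict[str, dict[str, str]] = field(default_factory=dict)
    duplications: dict[str, list[dict]] = field(default_factory=dict)
    subfamilies: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimGenome:
    """Working representation of one genome during simulation."""

    species: str
    chrom_genes: list[tuple[str, list[str]]]
    strands: dict[str, str]
    sequences: dict[str, np.ndarray] | None = None

    @property
    def gene_ids(self) -> list[str]:
        return [g for _, genes in self.chrom_genes for g in genes]

    def to_table(self, rng: np.random.Generator, gene_span: int = 1500,
                 gap_range: tuple[int, int] = (200, 5000)) -> GenomeTable:
        """Lay genes out with random intergenic spacing and build a table."""
        records = []
        lengths = {}
        order = []
        for chrom, genes in self.chrom_genes:
            order.append(chrom)
            pos = 0
            for g in genes:
                pos += int(rng.integers(gap_range[0], gap_range[1] + 1))
                start = pos + 1
                end = pos + gene_span
                records.append((g, chrom, start, end, self.strands[g]))
                pos = end
            lengths[chrom] = pos + int(rng.integers(gap_range[0], gap_range[1] + 1))
        return GenomeTable.from_coords(self.species, records,
                                       chrom_lengths=lengths, chrom_order=order)


@dataclass
class SimBundle:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    truth: SimTruth
    outgroup: GenomeTable
    d1: GenomeTable
    d2: GenomeTable
    anchor_frames: dict[str, pd.DataFrame]
    aligned_pairs: dict[str, list[AlignedPair]]
    sequences: dict[str, dict[str, str]]

    def anchors(self, key: str) -> list[AnchorPair]:
        return anchors_from_frame(self.anchor_frames[key], self.config.evalue_cutoff)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor draw after expected ``d`` substitutions/site."""
    if d <= 0:
        return seq.copy()
    p_same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
    change = rng.random(seq.size) >= p_same
    out = seq.copy()
    out[change] = (seq[change] + rng.integers(1, 4, size=int(change.sum()),
                                              dtype=np.uint8)) % 4
    return out


def _seq_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def expected_p(d: float) -> float:
    """Expected p-distance after ``d`` substitutions/site under Jukes-Cantor."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


# ---------------------------------------------------------------------------
# ancestor and karyotype events
# ---------------------------------------------------------------------------

def _genes_per_chrom(config: SimConfig, rng: np.random.Generator) -> int:
    gpc = config.genes_per_chromosome
    if isinstance(gpc, tuple):
        return int(rng.integers(gpc[0], gpc[1] + 1))
    return int(gpc)


def simulate_ancestor(config: SimConfig, rng: np.random.Generator) -> SimGenome:
    """Random outgroup-like ancestor: unique gene ids, random strands."""
    chrom_genes: list[tuple[str, list[str]]] = []
    strands: dict[str, str] = {}
    sequences: dict[str, np.ndarray] | None = {} if config.with_sequences else None
    serial = 0
    for i in range(config.n_chromosomes):
        chrom = f"N{i + 1:02d}"
        n = _genes_per_chrom(config, rng)
        genes = []
        for _ in range(n):
            gid = f"anc{serial:05d}"
            serial += 1
            genes.append(gid)
            strands[gid] = "+" if rng.random() < 0.5 else "-"
            if sequences is not None:
                sequences[gid] = _random_seq(rng, config.seq_length)
        chrom_genes.append((chrom, genes))
    return SimGenome("outgroup", chrom_genes, strands, sequences)


def apply_karyotype_events(
    ancestor: SimGenome,
    plan: EventPlan,
    rng: np.random.Generator,
    config: SimConfig,
    truth: SimTruth,
) -> tuple[SimGenome, list[tuple[str, str]]]:
    """Apply the planted plan to the ancestor, producing the ingroup
    proto-ancestor.

    Event chromosomes are disjoint across event types (a fission chromosome
    is never also fused or lost), so planted totals are exactly recoverable.
    Returns the proto genome and the (copy, original) paralog gene pairs
    created by duplicative gains.  Raises before any mutation if the plan is
    infeasible.
    """
    names = [c for c, _ in ancestor.chrom_genes]
    genes_by_chrom = {c: list(g) for c, g in ancestor.chrom_genes}
    K = len(names)
    min_seg = config.min_segment_genes

    fission_reserve = 1 if plan.fissions else 0
    fusion_min_sources = plan.fusions + 1 if plan.fusions else 0
    if plan.losses + fusion_min_sources + fission_reserve > K:
        raise ValidationError(
            f"infeasible plan: {plan} needs more chromosomes than {K}"
        )

    loss_chroms = sorted(rng.choice(names, size=plan.losses, replace=False).tolist()) \
        if plan.losses else []
    remaining = [c for c in names if c not in loss_chroms]

    fusion_groups: list[list[str]] = []
    fusion_sources: set[str] = set()
    if plan.fusions:
        max_sources = len(remaining) - fission_reserve
        g_max = min(plan.fusions, max_sources - plan.fusions)
        if g_max < 1:
            raise ValidationError(f"infeasible plan: not enough chromosomes to fuse")
        g = int(rng.integers(1, g_max + 1))
        n_sources = plan.fusions + g
        chosen = rng.choice(remaining, size=n_sources, replace=False).tolist()
        sizes = [2] * g
        for _ in range(n_sources - 2 * g):
            sizes[int(rng.integers(0, g))] += 1
        idx = 0
        for s in sizes:
            fusion_groups.append(chosen[idx:idx + s])
            idx += s
        fusion_sources = set(chosen)

    fission_pool = [c for c in remaining if c not in fusion_sources]
    # simulate fissions on working copies first to validate feasibility
    pieces: dict[str, list[list[str]]] = {}   # ancestor chrom -> ordered gene runs
    fission_events: list[dict] = []
    for _ in range(plan.fissions):
        candidates = []
        for c in fission_pool:
            runs = pieces.get(c, [genes_by_chrom[c]])
            if any(len(run) >= 2 * min_seg for run in runs):
                candidates.append(c)
        if not candidates:
            raise ValidationError("infeasible plan: no chromosome left to split")
        c = str(rng.choice(candidates))
        runs = pieces.get(c, [genes_by_chrom[c]])
        big = [i for i, run in enumerate(runs) if len(run) >= 2 * min_seg]
        i = int(rng.choice(big))
        run = runs[i]
        cut = int(rng.integers(min_seg, len(run) - min_seg + 1))
        pieces[c] = runs[:i] + [run[:cut], run[cut:]] + runs[i + 1:]
        fission_events.append({"type": "fission", "source": c, "breakpoint_rank": cut})

    # assemble proto chromosome list (temporary identities)
    proto_units: list[tuple[list[str], list[str]]] = []  # (source chroms, genes)
    fused_done: set[str] = set()
    for c in names:
        if c in loss_chroms:
            continue
        if c in fusion_sources:
            group = next(gr for gr in fusion_groups if c in gr)
            if group[0] != c or c in fused_done:
                continue
            order = list(rng.permutation(group))
            merged: list[str] = []
            for src in order:
                merged.extend(genes_by_chrom[src])
            proto_units.append((order, merged))
            fused_done.update(group)
            continue
        if c in pieces:
            for run in pieces[c]:
                proto_units.append(([c], run))
        else:
            proto_units.append(([c], genes_by_chrom[c]))

    strands = dict(ancestor.strands)
    sequences = dict(ancestor.sequences) if ancestor.sequences is not None else None
    paralog_pairs: list[tuple[str, str]] = []
    gain_units: list[tuple[str, list[str]]] = []   # (mode, genes)
    serial = 0
    for _ in range(plan.gains):
        n = _genes_per_chrom(config, rng)
        genes = []
        for _ in range(n):
            gid = f"gain{serial:05d}"
            serial += 1
            genes.append(gid)
            strands[gid] = "+" if rng.random() < 0.5 else "-"
            if sequences is not None:
                sequences[gid] = _random_seq(rng, config.seq_length)
        gain_units.append(("novel", genes))
    dup_serial = 0
    for _ in range(plan.duplicative_gains):
        template_idx = int(rng.integers(0, len(proto_units)))
        template_genes = proto_units[template_idx][1]
        genes = []
        for orig in template_genes:
            gid = f"dup{dup_serial:05d}"
            dup_serial += 1
            genes.append(gid)
            strands[gid] = strands[orig]
            if sequences is not None:
                sequences[gid] = sequences[orig].copy()
            paralog_pairs.append((gid, orig))
        gain_units.append(("duplicative", genes))

    # final naming and truth records
    chrom_genes: list[tuple[str, list[str]]] = []
    for i, (sources, genes) in enumerate(proto_units):
        name = f"P{i + 1:02d}"
        chrom_genes.append((name, genes))
        truth.proto_composition[name] = sources
        if len(sources) > 1:
            truth.events.append(
                {"type": "fusion", "sources": sources, "product": name,
                 "n_events": len(sources) - 1}
            )
    for j, (mode, genes) in enumerate(gain_units):
        name = f"P{len(proto_units) + j + 1:02d}"
        chrom_genes.append((name, genes))
        truth.proto_composition[name] = []
        truth.events.append({"type": "gain", "mode": mode, "chromosome": name})
    truth.events.extend(fission_events)
    for c in loss_chroms:
        truth.events.append({"type": "loss", "chromosome": c})
    truth.planted_totals = {
        "fissions": plan.fissions,
        "fusions": plan.fusions,
        "losses": plan.losses,
        "gains": plan.total_gains,
        "duplicative_gains": plan.duplicative_gains,
    }
    return SimGenome("proto", chrom_genes, strands, sequences), paralog_pairs


def derive_descendants(
    proto: SimGenome,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[SimGenome, SimGenome, dict[str, dict[str, str]]]:
    """Two descendants of the proto-ancestor with independent inversions and
    Jukes-Cantor sequence divergence.  Returns (d1, d2, ortholog maps keyed
    by species, proto gene -> descendant gene)."""
    maps: dict[str, dict[str, str]] = {}
    out: list[SimGenome] = []
    for species, prefix in (("d1", "A"), ("d2", "B")):
        mapping: dict[str, str] = {}
        chrom_genes: list[tuple[str, list[str]]] = []
        strands: dict[str, str] = {}
        sequences: dict[str, np.ndarray] | None = (
            {} if proto.sequences is not None else None
        )
        d = config.r * config.divergence_age
        for i, (chrom, genes) in enumerate(proto.chrom_genes):
            new_chrom = f"{prefix}{i + 1:02d}"
            new_genes = []
            for g in genes:
                ng = f"{species}.{g}"
                mapping[g] = ng
                new_genes.append(ng)
                strands[ng] = proto.strands[g]
                if sequences is not None:
                    sequences[ng] = _evolve(proto.sequences[g], d, rng)
            chrom_genes.append((new_chrom, new_genes))
        genome = SimGenome(species, chrom_genes, strands, sequences)
        lo, hi = config.inversion_size
        for _ in range(config.n_inversions):
            eligible = [k for k, (_, genes) in enumerate(genome.chrom_genes)
                        if len(genes) >= lo]
            if not eligible:
                break
            k = int(rng.choice(eligible))
            chrom, genes = genome.chrom_genes[k]
            size = int(rng.integers(lo, min(hi, len(genes)) + 1))
            start = int(rng.integers(0, len(genes) - size + 1))
            segment = genes[start:start + size][::-1]
            genes[start:start + size] = segment
            for g in segment:
                genome.strands[g] = "-" if genome.strands[g] == "+" else "+"
        maps[species] = mapping
        out.append(genome)
    return out[0], out[1], maps


# ---------------------------------------------------------------------------
# tandem bursts
# ---------------------------------------------------------------------------

def simulate_tandem_bursts(
    genome: SimGenome,
    burst_plan: Sequence[Burst],
    r: float,
    seq_length: int,
    rng: np.random.Generator,
) -> tuple[list[AlignedPair], list[dict], dict[str, str]]:
    """Plant tandem-duplication bursts on one chromosome of ``genome``
    (modified in place).

    Each subfamily gets a founder gene placed on the target chromosome
    (subfamilies spread apart so their arrays form distinct clusters); each
    duplication copies a random current member, inserts the copy adjacent to
    its parent, and diverges the pair by a Jukes-Cantor draw of expected
    2 r age substitutions/site.  Returns (aligned pairs, duplication log,
    subfamily labels).
    """
    if not burst_plan:
        return [], [], {}
    chrom_names = [c for c, _ in genome.chrom_genes]
    labels = list(dict.fromkeys(b.subfamily for b in burst_plan))
    members: dict[str, list[str]] = {lab: [] for lab in labels}
    founder_seqs: dict[str, np.ndarray] = {}
    aligned: list[AlignedPair] = []
    dup_log: list[dict] = []
    subfam: dict[str, str] = {}
    serial = {lab: 0 for lab in labels}

    def chrom_index(name: str) -> int:
        try:
            return chrom_names.index(name)
        except ValueError:
            raise ValidationError(f"burst chromosome {name!r} not in genome") from None

    # default target: the gene-richest chromosome, so founders can be spread
    # far enough apart to form distinct clusters
    default_chrom = max(genome.chrom_genes, key=lambda cg: (len(cg[1]), cg[0]))[0]
    seqs: dict[str, np.ndarray] = {}
    # place every subfamily founder first, spread along its target chromosome,
    # so the arrays grown around them stay separate clusters
    founder_chrom = {b.subfamily: (b.chromosome or default_chrom) for b in burst_plan}
    for lab in reversed(labels):
        k = chrom_index(founder_chrom[lab])
        _, genes = genome.chrom_genes[k]
        fid = f"{genome.species}.{lab}F"
        pos = (labels.index(lab) + 1) * len(genes) // (len(labels) + 1)
        genes.insert(pos, fid)
        genome.strands[fid] = "+"
        seqs[fid] = _random_seq(rng, seq_length)
        if genome.sequences is not None:
            genome.sequences[fid] = seqs[fid]
        members[lab].append(fid)
        subfam[fid] = lab
    for burst in burst_plan:
        target = burst.chromosome or default_chrom
        k = chrom_index(target)
        _, genes = genome.chrom_genes[k]
        lab = burst.subfamily
        for _ in range(burst.n):
            parent = str(rng.choice(members[lab]))
            child = f"{genome.species}.{lab}{serial[lab]:04d}"
            serial[lab] += 1
            child_seq = _evolve(seqs[parent], 2.0 * r * burst.age, rng)
            seqs[child] = child_seq
            pos = genes.index(parent) + 1
            genes.insert(pos, child)
            genome.strands[child] = genome.strands[parent]
            if genome.sequences is not None:
                genome.sequences[child] = child_seq
            members[lab].append(child)
            subfam[child] = lab
            aligned.append(
                AlignedPair(parent, child, _seq_str(seqs[parent]), _seq_str(child_seq))
            )
            dup_log.append({"parent": parent, "child": child,
                            "age": burst.age, "subfamily": lab})
    return aligned, dup_log, subfam


# ---------------------------------------------------------------------------
# anchor emission
# ---------------------------------------------------------------------------

def _anchor_frame(
    true_pairs: list[tuple[str, str, float]],
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    seq_length: int,
    dropout: float,
    spurious_rate: float,
    evalue_cutoff: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build a 12-column hit table from (query, subject, expected p) pairs,
    applying dropout and injecting spurious near-cutoff pairs."""
    rows = []
    for q, s, p in true_pairs:
        if dropout and rng.random() < dropout:
            continue
        mism = int(round(p * seq_length))
        bits = max(60.0, round(2.0 * seq_length * (1.0 - p), 1))
        rows.append((q, s, round(100.0 * (1.0 - p), 2), seq_length, mism, 0,
                     1, seq_length, 1, seq_length, 1e-180, bits))
    n_spurious = int(round(spurious_rate * len(true_pairs)))
    true_set = {(q, s) for q, s, _ in true_pairs}
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    for _ in range(n_spurious):
        for _attempt in range(20):
            q = str(rng.choice(genes_a))
            s = str(rng.choice(genes_b))
            if q != s and (q, s) not in true_set:
                break
        else:
            continue
        evalue = float(evalue_cutoff * 10 ** (-rng.random()))   # just under cutoff
        rows.append((q, s, 31.5, 120, 80, 3, 1, 120, 1, 120, evalue, 52.0))
    return pd.DataFrame(rows, columns=list(ANCHOR_COLUMNS))


def anchors_from_frame(df: pd.DataFrame, evalue_cutoff: float = 1e-5) -> list[AnchorPair]:
    """Same filtering semantics as read_anchor_table, on an in-memory frame."""
    if df.empty:
        return []
    keep = (df["evalue"].astype(float) <= evalue_cutoff) & (df["query"] != df["subject"])
    return [
        AnchorPair(str(q), str(s), float(e), float(b))
        for q, s, e, b in zip(df["query"][keep], df["subject"][keep],
                              df["evalue"][keep], df["bitscore"][keep])
    ]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_three_genomes(config: SimConfig) -> SimBundle:
    """Run a full simulation: ancestor -> planted events -> two descendants
    (+ optional tandem bursts), with anchor tables and truth log."""
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(sim_id=f"sim-{config.seed}")
    ancestor = simulate_ancestor(config, rng)
    proto, paralog_pairs = apply_karyotype_events(
        ancestor, config.event_plan, rng, config, truth
    )
    d1, d2, maps = derive_descendants(proto, config, rng)

    aligned_pairs: dict[str, list[AlignedPair]] = {}
    for genome in (d1, d2):
        aligned, dup_log, subfam = simulate_tandem_bursts(
            genome, config.burst_plan, config.r, config.seq_length, rng
        )
        aligned_pairs[genome.species] = aligned
        truth.duplications[genome.species] = dup_log
        truth.subfamilies[genome.species] = subfam

    truth.ortholog_maps = maps
    proto_genes = proto.gene_ids
    anc_genes = set(ancestor.gene_ids)

    d_og = config.r * config.outgroup_divergence_age * 2
    d_dd = config.r * config.divergence_age * 2
    p_og = float(expected_p(d_og))
    p_dd = float(expected_p(d_dd))

    frames: dict[str, pd.DataFrame] = {}
    for species, genome in (("d1", d1), ("d2", d2)):
        pairs = [(g, maps[species][g], p_og) for g in proto_genes if g in anc_genes]
        frames[f"og_{species}"] = _anchor_frame(
            pairs, ancestor.gene_ids, genome.gene_ids, config.seq_length,
            config.anchor_dropout, config.spurious_anchor_rate,
            config.evalue_cutoff, rng,
        )
    dd_pairs = [(maps["d1"][g], maps["d2"][g], p_dd) for g in proto_genes]
    frames["d1_d2"] = _anchor_frame(
        dd_pairs, d1.gene_ids, d2.gene_ids, config.seq_length,
        config.anchor_dropout, config.spurious_anchor_rate,
        config.evalue_cutoff, rng,
    )
    for species, genome in (("d1", d1), ("d2", d2)):
        self_pairs: list[tuple[str, str, float]] = []
        for copy, orig in paralog_pairs:
            self_pairs.append((maps[species][copy], maps[species][orig], 0.02))
            self_pairs.append((maps[species][orig], maps[species][copy], 0.02))
        for rec in truth.duplications[species]:
            p = float(expected_p(2.0 * config.r * rec["age"]))
            self_pairs.append((rec["parent"], rec["child"], p))
            self_pairs.append((rec["child"], rec["parent"], p))
        frames[f"self_{species}"] = _anchor_frame(
            self_pairs, genome.gene_ids, genome.gene_ids, config.seq_length,
            0.0, 0.0, config.evalue_cutoff, rng,
        )

    sequences: dict[str, dict[str, str]] = {}
    for genome in (ancestor, d1, d2):
        if genome.sequences is not None:
            sequences[genome.species] = {
                g: _seq_str(genome.sequences[g]) for g in genome.gene_ids
            }

    return SimBundle(
        config=config,
        truth=truth,
        outgroup=ancestor.to_table(rng, gene_span=config.seq_length),
        d1=d1.to_table(rng, gene_span=config.seq_length),
        d2=d2.to_table(rng, gene_span=config.seq_length),
        anchor_frames=frames,
        aligned_pairs=aligned_pairs,
        sequences=sequences,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Emit every simulated artefact as text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in (("outgroup", bundle.outgroup), ("d1", bundle.d1),
                        ("d2", bundle.d2)):
        write_gff3(table, outdir / f"{name}.gff3")
    for key, df in sorted(bundle.anchor_frames.items()):
        df.to_csv(outdir / f"{key}.tsv", sep="\t", header=False, index=False)
    for species, pairs in sorted(bundle.aligned_pairs.items()):
        with open(outdir / f"{species}.pairs.fasta", "w") as fh:
            for i, ap in enumerate(pairs):
                pid = f"pair{i:05d}"
                fh.write(f">{ap.gene1} pair={pid}\n{ap.seq1}\n")
                fh.write(f">{ap.gene2} pair={pid}\n{ap.seq2}\n")
    for species, subfam in sorted(bundle.truth.subfamilies.items()):
        with open(outdir / f"{species}.family.txt", "w") as fh:
            for gene in sorted(subfam):
                fh.write(f"{gene}\t{subfam[gene]}\n")
    for species, seqs in sorted(bundle.sequences.items()):
        with open(outdir / f"{species}.fasta", "w") as fh:
            for gene, seq in seqs.items():
                fh.write(f">{gene}\n{seq}\n")
    (outdir / "truth.json").write_text(bundle.truth.to_json())


def load_truth(path: str | Path) -> SimTruth:
    data = json.loads(Path(path).read_text())
    return SimTruth(**data)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def evaluate_event_recovery(truth: SimTruth, events) -> dict:
    """Confusion of planted vs inferred karyotype event totals."""
    inferred = events.totals()
    planted = {k: truth.planted_totals.get(k, 0)
               for k in ("fissions", "fusions", "losses", "gains")}
    per_type = {
        k: {"planted": planted[k], "inferred": inferred[k],
            "match": planted[k] == inferred[k]}
        for k in planted
    }
    dup_expected = truth.planted_totals.get("duplicative_gains", 0)
    dup_flagged = sum(1 for g in events.gains if g.duplicative_origin)
    report = {
        "sim_id": truth.sim_id,
        "per_type": per_type,
        "duplicative_gains": {"planted": dup_expected, "flagged": dup_flagged,
                              "match": dup_expected == dup_flagged},
        "passed": all(v["match"] for v in per_type.values())
        and dup_expected == dup_flagged,
    }
    return report


def evaluate_peak_recovery(
    truth: SimTruth, peaks, species: str = "d1", rel_tol: float = 0.15
) -> dict:
    """Match planted burst ages to inferred density peaks."""
    dup_log = truth.duplications.get(species, [])
    planted: dict[str, float] = {}
    for rec in dup_log:
        planted[rec["subfamily"]] = rec["age"]
    matches = {}
    ok = True
    for lab, age in sorted(planted.items()):
        best = min(peaks, key=lambda p: abs(p.mode - age))
        rel_err = abs(best.mode - age) / age if age else abs(best.mode)
        frac = best.subfamily_fractions.get(lab, 0.0) if best.subfamily_fractions else None
        matches[lab] = {"planted_age": age, "peak_mode": best.mode,
                        "rel_error": rel_err, "subfamily_fraction": frac}
        if rel_err > rel_tol:
            ok = False
        if frac is not None and frac <= 0.5:
            ok = False
    return {"sim_id": truth.sim_id, "n_peaks": len(peaks),
            "matches": matches, "passed": ok and len(peaks) >= len(planted)}


def evaluate_recovery(truth: SimTruth, inferred, sim_id: str | None = None, **kw) -> dict:
    """Score an inference result against the truth it was simulated from."""
    if sim_id is not None and sim_id != truth.sim_id:
        raise ValidationError(
            f"simulation id mismatch: truth is {truth.sim_id!r}, result is {sim_id!r}"
        )
    if hasattr(inferred, "totals"):
        return evaluate_event_recovery(truth, inferred, **kw)
    return evaluate_peak_recovery(truth, inferred, **kw)
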