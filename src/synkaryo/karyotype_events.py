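"""Karyotype event calculus.

Given synteny blocks among one outgroup genome and two ingroup descendants,
reconstruct the proto-chromosomes of the ingroup ancestor (maximum-weight
matching of descendant chromosomes on shared anchors) and count chromosome
rearrangement events against the outgroup:

* an outgroup chromosome mapping to n >= 2 proto-chromosomes records n-1
  fissions;
* m >= 2 outgroup chromosomes mapping to one proto-chromosome record m-1
  fusions;
* an outgroup chromosome with no mapped proto-chromosome is a loss;
* a proto-chromosome (present and paired in both descendants) with no
  outgroup support is a gain.

An outgroup-proto edge exists only when blocks link the outgroup chromosome
to BOTH descendant members of the proto-chromosome (the retention condition).
Many-to-many maps are decomposed edge-wise, so one chromosome may contribute
to both the fission and the fusion tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .collinearity import BlockParams, SyntenyBlock, find_collinear_blocks
from .errors import ValidationError
from .genome_io import AnchorPair, GenomeTable

__all__ = [
    "ProtoChromosome",
    "MapEdge",
    "ChromosomeMap",
    "FissionRecord",
    "FusionRecord",
    "GainRecord",
    "EventSet",
    "match_descendant_chromosomes",
    "build_chromosome_map",
    "infer_events",
    "classify_gains",
    "infer_karyotype_events",
]


@dataclass(frozen=True)
class ProtoChromosome:
    """A reconstructed chromosome of the two descendants' last common ancestor."""

    id: str
    member_d1: str | None
    member_d2: str | None
    support: int
    paired: bool


@dataclass(frozen=True)
class MapEdge:
    """Support linking one outgroup chromosome to one proto-chromosome."""

    outgroup_chrom: str
    proto_id: str
    blocks_d1: int
    anchors_d1: int
    blocks_d2: int
    anchors_d2: int


@dataclass
class ChromosomeMap:
    """Bipartite outgroup-chromosome / proto-chromosome support map."""

    edges: list[MapEdge]
    protos: dict[str, ProtoChromosome]
    outgroup_chromosomes: list[str]

    def protos_for(self, outgroup_chrom: str) -> list[str]:
        return sorted(e.proto_id for e in self.edges if e.outgroup_chrom == outgroup_chrom)

    def outgroups_for(self, proto_id: str) -> list[str]:
        return sorted(e.outgroup_chrom for e in self.edges if e.proto_id == proto_id)

    @property
    def orphan_outgroup(self) -> list[str]:
        linked = {e.outgroup_chrom for e in self.edges}
        return sorted(c for c in self.outgroup_chromosomes if c not in linked)

    @property
    def orphan_proto(self) -> list[str]:
        linked = {e.proto_id for e in self.edges}
        return sorted(p for p, proto in self.protos.items()
                      if proto.paired and p not in linked)


@dataclass(frozen=True)
class FissionRecord:
    outgroup_chrom: str
    n_protos: int

    @property
    def events(self) -> int:
        return max(0, self.n_protos - 1)


@dataclass(frozen=True)
class FusionRecord:
    proto_id: str
    n_outgroup: int

    @property
    def events(self) -> int:
        return max(0, self.n_outgroup - 1)


@dataclass(frozen=True)
class GainRecord:
    proto_id: str
    member_d1: str | None
    member_d2: str | None
    duplicative_origin: bool | None = None


@dataclass
class EventSet:
    fissions: list[FissionRecord]
    fusions: list[FusionRecord]
    losses: list[str]
    gains: list[GainRecord]

    @property
    def total_fissions(self) -> int:
        return sum(f.events for f in self.fissions)

    @property
    def total_fusions(self) -> int:
        return sum(f.events for f in self.fusions)

    @property
    def total_losses(self) -> int:
        return len(self.losses)

    @property
    def total_gains(self) -> int:
        return len(self.gains)

    def totals(self) -> dict[str, int]:
        return {
            "fissions": self.total_fissions,
            "fusions": self.total_fusions,
            "losses": self.total_losses,
            "gains": self.total_gains,
        }


# ---------------------------------------------------------------------------

def match_descendant_chromosomes(
    blocks_d1d2: Iterable[SyntenyBlock],
    d1_chromosomes: Sequence[str] | None = None,
    d2_chromosomes: Sequence[str] | None = None,
) -> list[ProtoChromosome]:
    """Pair descendant chromosomes into proto-chromosomes.

    Maximum-weight one-to-one matching where the weight of a (d1, d2)
    chromosome pair is the total anchor count of the blocks linking them.
    Chromosomes left without a positive-weight partner become singleton
    protos flagged unpaired.  Ties between equal-weight matchings are broken
    toward lexicographically earlier chromosome pairs.
    """
    blocks = list(blocks_d1d2)
    weights: dict[tuple[str, str], int] = {}
    for b in blocks:
        key = (b.chrom_a, b.chrom_b)
        weights[key] = weights.get(key, 0) + b.n_anchors
    rows = sorted(set(d1_chromosomes or []) | {c1 for c1, _ in weights})
    cols = sorted(set(d2_chromosomes or []) | {c2 for _, c2 in weights})
    if not weights:
        warnings.warn("no blocks between descendants: every chromosome is unpaired")
    pairs: list[tuple[str, str, int]] = []
    if weights and rows and cols:
        nr, nc = len(rows), len(cols)
        w = np.zeros((nr, nc), dtype=np.int64)
        for (c1, c2), anchors in weights.items():
            w[rows.index(c1), cols.index(c2)] = anchors
        # integer tie-break: prefer lexicographically earlier (row, col) pairs
        scale = nr * nc * min(nr, nc) + 1
        penalty = np.arange(nr)[:, None] * nc + np.arange(nc)[None, :]
        ri, ci = linear_sum_assignment(w * scale - penalty, maximize=True)
        for i, j in zip(ri, ci):
            if w[i, j] > 0:
                pairs.append((rows[i], cols[j], int(w[i, j])))
    pairs.sort()
    protos: list[ProtoChromosome] = []
    used_d1 = {p[0] for p in pairs}
    used_d2 = {p[1] for p in pairs}
    counter = 1
    for c1, c2, support in pairs:
        protos.append(ProtoChromosome(f"P{counter:02d}", c1, c2, support, True))
        counter += 1
    for c1 in rows:
        if c1 not in used_d1:
            protos.append(ProtoChromosome(f"P{counter:02d}", c1, None, 0, False))
            counter += 1
    for c2 in cols:
        if c2 not in used_d2:
            protos.append(ProtoChromosome(f"P{counter:02d}", None, c2, 0, False))
            counter += 1
    return protos


def _side_support(
    blocks: Iterable[SyntenyBlock], min_anchors: int
) -> dict[tuple[str, str], tuple[int, int]]:
    """(outgroup chrom, descendant chrom) -> (n qualifying blocks, n anchors)."""
    support: dict[tuple[str, str], tuple[int, int]] = {}
    for b in blocks:
        if b.n_anchors < min_anchors:
            continue
        key = (b.chrom_a, b.chrom_b)
        nb, na = support.get(key, (0, 0))
        support[key] = (nb + 1, na + b.n_anchors)
    return support


def build_chromosome_map(
    blocks_og_d1: Iterable[SyntenyBlock],
    blocks_og_d2: Iterable[SyntenyBlock],
    protos: Sequence[ProtoChromosome],
    outgroup_chromosomes: Sequence[str] | None = None,
    min_blocks: int = 1,
    min_anchors: int = 4,
) -> ChromosomeMap:
    """Build the outgroup/proto support map under the retention condition.

    Blocks must be oriented outgroup-side first (chrom_a = outgroup).  An
    edge (outgroup chr, proto) exists iff at least ``min_blocks`` blocks of
    >= ``min_anchors`` anchors link the outgroup chromosome to member_d1 AND
    (independently) to member_d2.  The outgroup chromosome list is needed to
    report fully unlinked (candidate-loss) chromosomes.
    """
    if min_blocks < 1 or min_anchors < 1:
        raise ValidationError("support thresholds must be >= 1")
    blocks_og_d1 = list(blocks_og_d1)
    blocks_og_d2 = list(blocks_og_d2)
    sup1 = _side_support(blocks_og_d1, min_anchors)
    sup2 = _side_support(blocks_og_d2, min_anchors)
    og_chroms = set(outgroup_chromosomes or [])
    og_chroms.update(c for c, _ in sup1)
    og_chroms.update(c for c, _ in sup2)
    edges: list[MapEdge] = []
    for proto in protos:
        if not proto.paired:
            continue
        for og in sorted(og_chroms):
            nb1, na1 = sup1.get((og, proto.member_d1), (0, 0))
            nb2, na2 = sup2.get((og, proto.member_d2), (0, 0))
            if nb1 >= min_blocks and nb2 >= min_blocks:
                edges.append(MapEdge(og, proto.id, nb1, na1, nb2, na2))
    edges.sort(key=lambda e: (e.outgroup_chrom, e.proto_id))
    return ChromosomeMap(
        edges=edges,
        protos={p.id: p for p in protos},
        outgroup_chromosomes=sorted(og_chroms),
    )


def infer_events(cmap: ChromosomeMap) -> EventSet:
    """Count fission/fusion/loss/gain events from a chromosome map."""
    fissions = []
    for og in cmap.outgroup_chromosomes:
        n = len(cmap.protos_for(og))
        if n >= 2:
            fissions.append(FissionRecord(og, n))
    fusions = []
    for pid in sorted(cmap.protos):
        m = len(cmap.outgroups_for(pid))
        if m >= 2:
            fusions.append(FusionRecord(pid, m))
    gains = []
    for pid in cmap.orphan_proto:
        proto = cmap.protos[pid]
        gains.append(GainRecord(pid, proto.member_d1, proto.member_d2))
    return EventSet(
        fissions=fissions,
        fusions=fusions,
        losses=cmap.orphan_outgroup,
        gains=gains,
    )


def classify_gains(
    gains: Sequence[GainRecord],
    self_blocks_d1: Iterable[SyntenyBlock],
    self_blocks_d2: Iterable[SyntenyBlock],
) -> list[GainRecord]:
    """Flag gained proto-chromosomes of duplicative origin.

    A gain is duplicative iff either member chromosome shares a within-genome
    synteny block with a *different* chromosome of the same genome; gains
    whose members have no such block cannot stem from genome duplication.
    """
    def linked(blocks: Iterable[SyntenyBlock]) -> set[str]:
        out: set[str] = set()
        for b in blocks:
            if b.chrom_a != b.chrom_b:
                out.add(b.chrom_a)
                out.add(b.chrom_b)
        return out

    linked_d1 = linked(self_blocks_d1)
    linked_d2 = linked(self_blocks_d2)
    return [
        replace(
            g,
            duplicative_origin=(g.member_d1 in linked_d1) or (g.member_d2 in linked_d2),
        )
        for g in gains
    ]


# ---------------------------------------------------------------------------

def infer_karyotype_events(
    outgroup: GenomeTable,
    d1: GenomeTable,
    d2: GenomeTable,
    anchors_og_d1: Iterable[AnchorPair],
    anchors_og_d2: Iterable[AnchorPair],
    anchors_d1_d2: Iterable[AnchorPair],
    self_anchors_d1: Iterable[AnchorPair] = (),
    self_anchors_d2: Iterable[AnchorPair] = (),
    params: BlockParams = BlockParams(),
    min_blocks: int = 1,
    min_anchors: int = 4,
) -> dict:
    """End-to-end event inference from genome tables and anchor sets.

    Returns a dict with the intermediate block sets, proto-chromosomes, the
    chromosome map, and the final EventSet (gains classified when self-genome
    anchors are provided).
    """
    blocks_og_d1 = find_collinear_blocks(outgroup, d1, anchors_og_d1, params)
    blocks_og_d2 = find_collinear_blocks(outgroup, d2, anchors_og_d2, params)
    blocks_d1_d2 = find_collinear_blocks(d1, d2, anchors_d1_d2, params)
    protos = match_descendant_chromosomes(
        blocks_d1_d2, d1.chromosomes, d2.chromosomes
    )
    cmap = build_chromosome_map(
        blocks_og_d1, blocks_og_d2, protos,
        outgroup_chromosomes=outgroup.chromosomes,
        min_blocks=min_blocks, min_anchors=min_anchors,
    )
    events = infer_events(cmap)
    self_blocks_d1 = find_collinear_blocks(d1, d1, self_anchors_d1, params)
    self_blocks_d2 = find_collinear_blocks(d2, d2, self_anchors_d2, params)
    events.gains = classify_gains(events.gains, self_blocks_d1, self_blocks_d2)
    return {
        "blocks_og_d1": blocks_og_d1,
        "blocks_og_d2": blocks_og_d2,
        "blocks_d1_d2": blocks_d1_d2,
        "self_blocks_d1": self_blocks_d1,
        "self_blocks_d2": self_blocks_d2,
        "protos": protos,
        "map": cmap,
        "events": events,
    }
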