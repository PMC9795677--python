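"""Micro-synteny block detection.

A synteny block is a maximal monotone chain of anchor pairs in rank space:
gene order is conserved (ascending chains) or conserved-but-inverted
(descending chains) between a pair of chromosomes, with bounded rank gaps.
Gene strand is ignored throughout.  Chains are found by longest-chain dynamic
programming and extracted greedily by anchor count, so each anchor belongs to
at most one reported block.

To make results independent of which genome is passed first, every chromosome
pair is canonicalised to a fixed orientation (lexicographic on
(species, chromosome)) before chaining and the resulting blocks are swapped
back into the caller's orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .genome_io import AnchorPair, GenomeTable

__all__ = [
    "BlockParams",
    "SyntenyBlock",
    "find_collinear_blocks",
    "block_coverage",
    "write_blocks",
    "read_blocks",
]


@dataclass(frozen=True)
class BlockParams:
    """Chaining parameters.

    min_anchors: minimum chain length for a reported block (default 4,
        i.e. more than 3 consecutive homologous genes).
    max_rank_gap: largest allowed rank step between consecutive anchors on
        either chromosome (1 = strict adjacency).
    allow_descending: also chain inverted (descending) runs.
    """

    min_anchors: int = 4
    max_rank_gap: int = 25
    allow_descending: bool = True

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValidationError("min_anchors must be >= 2")
        if self.max_rank_gap < 1:
            raise ValidationError("max_rank_gap must be >= 1")


@dataclass(frozen=True)
class BlockAnchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal monotone chain of anchors between two chromosomes.

    ``span_a``/``span_b`` are half-open bp intervals [start, end) covering the
    anchor genes on each side.
    """

    chrom_a: str
    chrom_b: str
    anchors: tuple[BlockAnchor, ...]
    direction: int
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def swapped(self) -> "SyntenyBlock":
        """The same block seen from the other genome's side."""
        anchors = tuple(
            sorted(
                (BlockAnchor(a.gene_b, a.gene_a, a.rank_b, a.rank_a) for a in self.anchors),
                key=lambda a: a.rank_a,
            )
        )
        return SyntenyBlock(self.chrom_b, self.chrom_a, anchors, self.direction,
                            self.span_b, self.span_a)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _collapse_tandem(cells: list[tuple[int, int, str, str]]) -> list[tuple[int, int, str, str]]:
    """Collapse tandem-duplicate anchors: where one gene on either side hits a
    run of rank-consecutive genes on the other, keep only the lowest-rank hit.
    Applied left side then right side, in canonical orientation."""
    for side in (0, 1):
        by_gene: dict[str, list[tuple[int, int, str, str]]] = {}
        for c in cells:
            by_gene.setdefault(c[2 + side], []).append(c)
        kept: list[tuple[int, int, str, str]] = []
        other = 1 - side
        for gene in by_gene:
            hits = sorted(by_gene[gene], key=lambda c: c[other])
            kept.append(hits[0])
            for prev, cur in zip(hits, hits[1:]):
                if cur[other] - prev[other] > 1:
                    kept.append(cur)
        cells = sorted(set(kept))
    return cells


def _best_chain(
    ra: np.ndarray, rb: np.ndarray, params: BlockParams
) -> tuple[tuple, list[int]] | None:
    """Best chain among the given cells (sorted by (ra, rb)).

    Returns (comparison key, indices).  Key orders by longer chain first, then
    ascending before descending, then lexicographically smallest (ra, rb)
    sequence; smaller key wins.
    """
    n = len(ra)
    gap = params.max_rank_gap
    best: tuple[tuple, list[int]] | None = None
    directions = (1, -1) if params.allow_descending else (1,)
    for direction in directions:
        f = np.ones(n, dtype=np.int64)
        for i in range(n - 2, -1, -1):
            da = ra[i + 1:] - ra[i]
            db = (rb[i + 1:] - rb[i]) * direction
            ok = (da >= 1) & (da <= gap) & (db >= 1) & (db <= gap)
            if ok.any():
                f[i] = 1 + f[i + 1:][ok].max()
        length = int(f.max())
        # reconstruct the lexicographically smallest chain of maximal length
        i = int(np.argmax(f == length))
        chain = [i]
        rem = length - 1
        while rem:
            da = ra - ra[chain[-1]]
            db = (rb - rb[chain[-1]]) * direction
            ok = (da >= 1) & (da <= gap) & (db >= 1) & (db <= gap) & (f == rem)
            j = int(np.argmax(ok))
            chain.append(j)
            rem -= 1
        key = (
            -length,
            0 if direction == 1 else 1,
            tuple((int(ra[k]), int(rb[k])) for k in chain),
        )
        if best is None or key < best[0]:
            best = (key, chain)
    return best


def _extract_chains(
    cells: list[tuple[int, int, str, str]], params: BlockParams
) -> list[tuple[int, list[tuple[int, int, str, str]]]]:
    """Greedy extraction of maximal chains: repeatedly take the best remaining
    chain until none reaches min_anchors.  Returns (direction, cells) per
    block, in extraction order."""
    remaining = sorted(cells)
    out: list[tuple[int, list[tuple[int, int, str, str]]]] = []
    while len(remaining) >= params.min_anchors:
        ra = np.fromiter((c[0] for c in remaining), dtype=np.int64, count=len(remaining))
        rb = np.fromiter((c[1] for c in remaining), dtype=np.int64, count=len(remaining))
        best = _best_chain(ra, rb, params)
        if best is None or -best[0][0] < params.min_anchors:
            break
        key, idx = best
        direction = 1 if key[1] == 0 else -1
        chain_cells = [remaining[k] for k in idx]
        out.append((direction, chain_cells))
        drop = set(idx)
        remaining = [c for k, c in enumerate(remaining) if k not in drop]
    return out


def find_collinear_blocks(
    table_a: GenomeTable,
    table_b: GenomeTable,
    anchors: Iterable[AnchorPair],
    params: BlockParams = BlockParams(),
) -> list[SyntenyBlock]:
    """Detect synteny blocks between two genomes from an anchor set.

    Every anchor gene must resolve to a rank in its table; unknown ids raise a
    ValidationError listing them.  Anchors inside tandem arrays are collapsed
    before chaining, and each anchor ends up in at most one reported block.
    """
    anchors = list(anchors)
    unknown = sorted(
        {a.query_gene for a in anchors if a.query_gene not in table_a}
        | {a.subject_gene for a in anchors if a.subject_gene not in table_b}
    )
    if unknown:
        raise ValidationError(f"anchor genes absent from genome tables: {unknown[:20]}")

    key_a = table_a.species
    key_b = table_b.species
    groups: dict[tuple[tuple[str, str], tuple[str, str], bool], set] = {}
    for a in anchors:
        ga = table_a.gene(a.query_gene)
        gb = table_b.gene(a.subject_gene)
        left = (key_a, ga.chromosome)
        right = (key_b, gb.chromosome)
        if left <= right:
            cell = (ga.rank, gb.rank, ga.gene_id, gb.gene_id)
            groups.setdefault((left, right, False), set()).add(cell)
        else:
            cell = (gb.rank, ga.rank, gb.gene_id, ga.gene_id)
            groups.setdefault((right, left, True), set()).add(cell)

    blocks: list[SyntenyBlock] = []
    for (left, right, flipped) in sorted(groups, key=lambda k: (k[0], k[1])):
        cells = _collapse_tandem(sorted(groups[(left, right, flipped)]))
        for direction, chain in _extract_chains(cells, params):
            if flipped:
                chrom_a, chrom_b = right[1], left[1]
                pairs = sorted(
                    ((c[3], c[2], c[1], c[0]) for c in chain), key=lambda p: p[2]
                )
            else:
                chrom_a, chrom_b = left[1], right[1]
                pairs = [(c[2], c[3], c[0], c[1]) for c in chain]
            banchors = tuple(BlockAnchor(*p) for p in pairs)
            genes_a = [table_a.gene(p.gene_a) for p in banchors]
            genes_b = [table_b.gene(p.gene_b) for p in banchors]
            span_a = (min(g.start for g in genes_a) - 1, max(g.end for g in genes_a))
            span_b = (min(g.start for g in genes_b) - 1, max(g.end for g in genes_b))
            blocks.append(
                SyntenyBlock(chrom_a, chrom_b, banchors, direction, span_a, span_b)
            )
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, -b.n_anchors,
                               b.anchors[0].rank_a))
    return blocks


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def block_coverage(
    blocks: Iterable[SyntenyBlock], table: GenomeTable, side: str = "a"
) -> float:
    """Fraction of the assembly covered by the union of block spans on one side.

    Overlapping spans are merged before summing, so shared bp are counted once.
    """
    if side not in ("a", "b"):
        raise ValidationError("side must be 'a' or 'b'")
    if table.assembly_length == 0:
        raise ValidationError("coverage undefined on an empty genome table")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        chrom = b.chrom_a if side == "a" else b.chrom_b
        span = b.span_a if side == "a" else b.span_b
        by_chrom.setdefault(chrom, []).append(span)
    covered = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = start, end
        covered += cur_end - cur_start
    return covered / table.assembly_length


# ---------------------------------------------------------------------------
# block file I/O (MCScanX-collinearity-like text)
# ---------------------------------------------------------------------------

def write_blocks(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# synkaryo collinearity\n")
        for i, b in enumerate(blocks):
            sign = "plus" if b.direction == 1 else "minus"
            fh.write(
                f"## Alignment {i}: {b.chrom_a}&{b.chrom_b} {sign} "
                f"n={b.n_anchors} span_a={b.span_a[0]}-{b.span_a[1]} "
                f"span_b={b.span_b[0]}-{b.span_b[1]}\n"
            )
            for a in b.anchors:
                fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.rank_a}\t{a.rank_b}\n")


def read_blocks(path: str | Path) -> list[SyntenyBlock]:
    blocks: list[SyntenyBlock] = []
    header: dict | None = None
    anchors: list[BlockAnchor] = []

    def flush() -> None:
        if header is not None:
            blocks.append(
                SyntenyBlock(header["chrom_a"], header["chrom_b"], tuple(anchors),
                             header["direction"], header["span_a"], header["span_b"])
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line == "# synkaryo collinearity":
                continue
            if line.startswith("## Alignment"):
                flush()
                try:
                    _, rest = line.split(":", 1)
                    fields = rest.split()
                    chrom_a, chrom_b = fields[0].split("&")
                    direction = 1 if fields[1] == "plus" else -1
                    spans = {}
                    for tok in fields[3:]:
                        name, rng = tok.split("=")
                        lo, hi = rng.rsplit("-", 1)
                        spans[name] = (int(lo), int(hi))
                    header = {"chrom_a": chrom_a, "chrom_b": chrom_b,
                              "direction": direction,
                              "span_a": spans["span_a"], "span_b": spans["span_b"]}
                    anchors = []
                except (ValueError, KeyError) as exc:
                    raise ParseError(f"{path}: line {lineno}: bad block header "
                                     f"({exc})") from None
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 anchor columns")
            anchors.append(BlockAnchor(cols[0], cols[1], int(cols[2]), int(cols[3])))
    flush()
    return blocks
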