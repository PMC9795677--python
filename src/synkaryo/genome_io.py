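"""Genome and homology-table input.

Parses GFF3 gene coordinates into rank-indexed genome tables and BLAST/DIAMOND
tabular hit files (12-column ``-outfmt 6``) into filtered anchor sets.  Gene
*rank* — the 0-based order index of a gene along its chromosome — is the
coordinate system every downstream collinearity computation runs in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GeneModel",
    "GenomeTable",
    "AnchorPair",
    "read_gff3",
    "write_gff3",
    "read_anchor_table",
    "write_anchor_table",
    "filter_top_hits",
]

ANCHOR_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class GeneModel:
    """One gene: chromosome, 1-based inclusive coordinates, strand, and rank.

    ``rank`` is the 0-based order index among genes on the same chromosome,
    sorted by ascending start (ties: ascending end, then gene_id).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenomeTable:
    """Ordered gene complement of one assembly.

    Thin wrapper around a pandas DataFrame (columns ``gene_id, chromosome,
    start, end, strand, rank``) plus per-chromosome assembly lengths in bp.
    Chromosome order is the order of first appearance in the input.
    """

    def __init__(
        self,
        species: str,
        genes: Iterable[GeneModel],
        chrom_lengths: Mapping[str, int] | None = None,
        chrom_order: Sequence[str] | None = None,
    ) -> None:
        self.species = species
        genes = list(genes)
        self.df = pd.DataFrame(
            [(g.gene_id, g.chromosome, g.start, g.end, g.strand, g.rank) for g in genes],
            columns=["gene_id", "chromosome", "start", "end", "strand", "rank"],
        )
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(g.chromosome for g in genes))
        self.chromosomes: list[str] = list(chrom_order)
        lengths = dict(chrom_lengths or {})
        for chrom in self.chromosomes:
            if chrom not in lengths:
                sub = self.df[self.df["chromosome"] == chrom]
                lengths[chrom] = int(sub["end"].max()) if len(sub) else 0
        self.chrom_lengths: dict[str, int] = lengths
        self._validate()
        self._by_id = {
            row.gene_id: GeneModel(row.gene_id, row.chromosome, row.start,
                                   row.end, row.strand, row.rank)
            for row in self.df.itertuples(index=False)
        }

    # -- construction -----------------------------------------------------

    @classmethod
    def from_coords(
        cls,
        species: str,
        records: Iterable[tuple[str, str, int, int, str]],
        chrom_lengths: Mapping[str, int] | None = None,
        chrom_order: Sequence[str] | None = None,
    ) -> "GenomeTable":
        """Build a table from (gene_id, chromosome, start, end, strand) rows,
        assigning ranks per chromosome by (start, end, gene_id)."""
        by_chrom: dict[str, list[tuple[str, str, int, int, str]]] = {}
        for rec in records:
            by_chrom.setdefault(rec[1], []).append(rec)
        genes: list[GeneModel] = []
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r[2], r[3], r[0]))
            for rank, (gid, _, start, end, strand) in enumerate(recs):
                genes.append(GeneModel(gid, chrom, int(start), int(end), strand, rank))
        return cls(species, genes, chrom_lengths=chrom_lengths, chrom_order=chrom_order)

    def _validate(self) -> None:
        if self.df.empty:
            return
        dup = self.df[self.df.duplicated("gene_id", keep=False)]
        if len(dup):
            ids = sorted(dup["gene_id"].unique())
            raise ValidationError(f"duplicate gene ids: {ids[:10]}")
        for chrom, sub in self.df.groupby("chromosome", sort=False):
            ranks = sorted(sub["rank"])
            if ranks != list(range(len(sub))):
                raise ValidationError(
                    f"chromosome {chrom}: ranks are not a gapless 0..n-1 sequence"
                )
            if chrom not in self.chromosomes:
                raise ValidationError(f"chromosome {chrom} missing from chromosome list")

    # -- queries ----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.df)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise ValidationError(f"unknown gene id {gene_id!r} in {self.species}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, chrom: str) -> list[GeneModel]:
        sub = self.df[self.df["chromosome"] == chrom].sort_values("rank")
        return [GeneModel(*row) for row in sub.itertuples(index=False)]

    def gene_counts(self) -> dict[str, int]:
        counts = self.df["chromosome"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in self.chromosomes}

    @property
    def assembly_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GenomeTable({self.species!r}, {self.n_genes} genes, "
                f"{len(self.chromosomes)} chromosomes)")


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair from a similarity search (one tabular hit row)."""

    query_gene: str
    subject_gene: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative evalue for {self.query_gene}")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _prescan_gff3(path: str | Path, feature_types: set[str]) -> tuple[dict[str, int], int]:
    """Validate column counts line by line and collect ##sequence-region lengths.

    Returns (chrom_lengths, n_feature_lines).  Raises ParseError naming the
    offending line number on a malformed feature line.
    """
    lengths: dict[str, int] = {}
    n_features = 0
    in_fasta = False
    seen: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if in_fasta or line.startswith(">"):
                in_fasta = True
                continue
            if not line.strip():
                continue
            if line.startswith("##FASTA"):
                in_fasta = True
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated GFF3 "
                    f"columns, found {len(cols)}"
                )
            n_features += 1
            ftype = cols[2]
            if ftype in feature_types:
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                fid = attrs.get("ID")
                if fid is not None:
                    key = (cols[0], fid)
                    if key in seen:
                        raise ValidationError(
                            f"{path}: line {lineno}: duplicate {ftype} id {fid!r} "
                            f"on {cols[0]} (first seen line {seen[key]})"
                        )
                    seen[key] = lineno
    return lengths, n_features


def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    longest_isoform: bool = False,
    species: str | None = None,
) -> GenomeTable:
    """Read gene coordinates from a GFF3 file into a rank-indexed GenomeTable.

    Ranks are assigned per chromosome by ascending start (ties: ascending end,
    then gene_id).  If no features of ``feature_type`` exist, falls back to
    "mRNA" records collapsed onto their parent gene.  With ``longest_isoform``,
    each gene is represented by its longest transcript: summed CDS length when
    CDS children exist, otherwise mRNA span; genes without mRNA children keep
    their own coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if species is None:
        species = path.stem
    lengths, n_features = _prescan_gff3(path, {feature_type})
    if n_features == 0:
        return GenomeTable(species, [], chrom_lengths=lengths,
                           chrom_order=list(lengths))
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=False,
    )
    feats = list(db.features_of_type(feature_type, order_by=("seqid", "start")))
    collapsed_from_mrna = False
    if not feats and feature_type == "gene":
        feats = list(db.features_of_type("mRNA", order_by=("seqid", "start")))
        collapsed_from_mrna = True

    records: list[tuple[str, str, int, int, str]] = []
    if collapsed_from_mrna:
        by_parent: dict[str, list] = {}
        for f in feats:
            parent = f.attributes.get("Parent", [f.id])[0]
            by_parent.setdefault(parent, []).append(f)
        for parent, group in by_parent.items():
            start = min(f.start for f in group)
            end = max(f.end for f in group)
            records.append((parent, group[0].seqid, start, end, group[0].strand or "."))
    else:
        for f in feats:
            start, end = f.start, f.end
            if longest_isoform:
                mrnas = list(db.children(f, featuretype="mRNA"))
                best_len, best_span = -1, None
                for m in mrnas:
                    cds = list(db.children(m, featuretype="CDS"))
                    if cds:
                        tlen = sum(c.end - c.start + 1 for c in cds)
                    else:
                        tlen = m.end - m.start + 1
                    if tlen > best_len:
                        best_len = tlen
                        best_span = (m.start, m.end)
                if best_span is not None:
                    start, end = best_span
            records.append((f.id, f.seqid, start, end, f.strand or "."))

    chrom_order = list(lengths) if lengths else None
    if chrom_order is not None:
        # keep chromosomes that carry genes but lack a sequence-region pragma
        extra = [c for c in dict.fromkeys(r[1] for r in records) if c not in lengths]
        chrom_order = chrom_order + extra
    return GenomeTable.from_coords(species, records, chrom_lengths=lengths,
                                   chrom_order=chrom_order)


def write_gff3(table: GenomeTable, path: str | Path) -> None:
    """Serialise a GenomeTable as GFF3 gene features (round-trips read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in table.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {table.chrom_lengths[chrom]}\n")
        for chrom in table.chromosomes:
            for g in table.genes_on(chrom):
                fh.write(
                    f"{chrom}\tsynkaryo\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Tabular anchors
# ---------------------------------------------------------------------------

def read_anchor_table(
    path: str | Path,
    evalue_cutoff: float = 1e-5,
) -> list[AnchorPair]:
    """Read a 12-column tabular hit file, dropping rows above the E-value
    cutoff and self-hits (query == subject)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(
            f"{path}: expected 12 tab-separated columns (outfmt 6), "
            f"found {df.shape[1]}"
        )
    df.columns = list(ANCHOR_COLUMNS)
    try:
        evalue = df["evalue"].astype(float)
        bitscore = df["bitscore"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric evalue/bitscore column: {exc}") from None
    keep = (evalue <= evalue_cutoff) & (df["query"] != df["subject"])
    return [
        AnchorPair(q, s, float(e), float(b))
        for q, s, e, b in zip(df["query"][keep], df["subject"][keep],
                              evalue[keep], bitscore[keep])
    ]


def write_anchor_table(anchors: Iterable[AnchorPair], path: str | Path) -> None:
    """Write anchors back out as minimal 12-column rows (identity placeholders
    for the alignment statistics the pairs no longer carry)."""
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(
                f"{a.query_gene}\t{a.subject_gene}\t100.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{a.evalue:g}\t{a.bitscore:g}\n"
            )


def filter_top_hits(anchors: Iterable[AnchorPair]) -> list[AnchorPair]:
    """Keep one hit per query: highest bitscore, then lowest evalue, then
    lexicographically smallest subject id."""
    best: dict[str, AnchorPair] = {}
    for a in anchors:
        cur = best.get(a.query_gene)
        if cur is None or (
            (-a.bitscore, a.evalue, a.subject_gene)
            < (-cur.bitscore, cur.evalue, cur.subject_gene)
        ):
            best[a.query_gene] = a
    return [best[q] for q in sorted(best)]
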