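import numpy as np
import pytest

from synkaryo.genome_io import AnchorPair, GenomeTable


def make_table(species: str, chrom_sizes: dict[str, int], gene_span: int = 500,
               spacing: int = 1000, prefix: str | None = None) -> GenomeTable:
    """Deterministic genome table: genes laid out every ``spacing`` bp."""
    prefix = prefix if prefix is not None else species
    records = []
    lengths = {}
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            start = i * spacing + 1
            records.append((f"{prefix}.{chrom}.g{i:03d}", chrom, start,
                            start + gene_span - 1, "+"))
        lengths[chrom] = n * spacing
    return GenomeTable.from_coords(species, records, chrom_lengths=lengths,
                                   chrom_order=list(chrom_sizes))


def anchors_from_cells(table_a: GenomeTable, table_b: GenomeTable,
                       chrom_a: str, chrom_b: str,
                       cells: list[tuple[int, int]]) -> list[AnchorPair]:
    """Turn (rank_a, rank_b) cells into AnchorPair objects for one
    chromosome pair."""
    genes_a = table_a.genes_on(chrom_a)
    genes_b = table_b.genes_on(chrom_b)
    return [
        AnchorPair(genes_a[ra].gene_id, genes_b[rb].gene_id, 1e-50, 200.0)
        for ra, rb in cells
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
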