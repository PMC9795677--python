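"""Gene-family expansion dating and tandem-cluster detection.

Paralog divergence is measured as a p-distance on aligned sequence pairs
(gap/ambiguity columns excluded pairwise), corrected with the Jukes-Cantor
formula jc = -(3/4) ln(1 - 4p/3), and converted to an age with

    age = jc / (2 r)

where r is the substitution rate per site per million years (supplied by the
user; it is never assumed).  The age distribution of a family is decomposed
into expansion peaks by Gaussian kernel density estimation: each local
maximum above a height threshold is a peak, and every pair is assigned to the
basin (watershed at the density minima) it falls into.  Tandem clusters are
runs of family genes along a chromosome within rank- and bp-gap thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from scipy.stats import gaussian_kde

from .errors import ParseError, SaturationError, ValidationError
from .genome_io import AnchorPair, GeneModel, GenomeTable

__all__ = [
    "AlignedPair",
    "ParalogPair",
    "DatingConfig",
    "ExpansionPeak",
    "TandemCluster",
    "read_aligned_pairs",
    "identify_paralog_pairs",
    "p_distance",
    "jc_distance",
    "date_from_jc",
    "date_pairs",
    "density_peaks",
    "peak_subfamily_fractions",
    "detect_tandem_clusters",
]

@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped nucleotide sequences for one gene pair."""

    gene1: str
    gene2: str
    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2) or not self.seq1:
            raise ValidationError(
                f"pair ({self.gene1}, {self.gene2}): aligned lengths differ or are zero"
            )

    @property
    def pair_id(self) -> str:
        return f"{self.gene1}--{self.gene2}"


@dataclass
class ParalogPair:
    """A dated within-genome gene pair."""

    gene1: str
    gene2: str
    p: float
    jc: float
    age: float
    subfamily: str = "unlabeled"

    @property
    def pair_id(self) -> str:
        return f"{self.gene1}--{self.gene2}"


@dataclass(frozen=True)
class DatingConfig:
    """Dating and peak-decomposition settings.

    r: substitution rate in substitutions/site/Ma (no default: the clock is
        the user's responsibility).
    bandwidth: KDE bandwidth in age units (Ma), or "silverman" for
        Silverman's rule of thumb.
    min_peak_fraction: minimum density height of a reported peak, relative
        to the global density maximum.
    """

    r: float
    bandwidth: float | str = "silverman"
    min_peak_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValidationError("substitution rate r must be > 0")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ValidationError("numeric bandwidth must be > 0")


@dataclass
class ExpansionPeak:
    """One mode of the paralog-age density with its assigned pairs."""

    mode: float
    members: list[str]
    basin: tuple[float, float]
    height: float
    subfamily_fractions: dict[str, float] = field(default_factory=dict)
    subfamily_gene_fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class TandemCluster:
    """A run of family genes along one chromosome."""

    chromosome: str
    genes: list[GeneModel]
    span_bp: int
    max_gap_genes: int
    max_gap_bp: int

    @property
    def size(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# alignment input
# ---------------------------------------------------------------------------

def read_aligned_pairs(path: str | Path) -> list[AlignedPair]:
    """Read pairwise alignments from FASTA.

    Records carrying a ``pair=<id>`` token in their description are grouped
    by that id (two records per id); otherwise consecutive records are paired
    in file order.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        return []
    tokens = []
    for rec in records:
        token = None
        for word in rec.description.split():
            if word.startswith("pair="):
                token = word[5:]
        tokens.append(token)
    pairs: list[AlignedPair] = []
    if all(t is not None for t in tokens):
        groups: dict[str, list] = {}
        for rec, t in zip(records, tokens):
            groups.setdefault(t, []).append(rec)
        for t in sorted(groups):
            group = groups[t]
            if len(group) != 2:
                raise ParseError(f"{path}: pair {t!r} has {len(group)} records, expected 2")
            a, b = group
            pairs.append(AlignedPair(a.id, b.id, str(a.seq).upper(), str(b.seq).upper()))
    else:
        if len(records) % 2:
            raise ParseError(f"{path}: odd number of records without pair= tokens")
        for a, b in zip(records[::2], records[1::2]):
            pairs.append(AlignedPair(a.id, b.id, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def identify_paralog_pairs(
    self_anchors: Iterable[AnchorPair],
    family: Iterable[str],
) -> list[tuple[str, str]]:
    """Paralog pairs within a gene family from a self-genome hit table.

    Each family gene contributes its top within-family non-self hit (highest
    bitscore, then lowest evalue, then smallest subject id); unordered pairs
    are deduplicated.  Returns sorted (gene1, gene2) tuples with gene1 < gene2.
    """
    family = set(family)
    if not family:
        warnings.warn("empty gene family: no paralog pairs")
        return []
    best: dict[str, AnchorPair] = {}
    for a in self_anchors:
        if a.query_gene not in family or a.subject_gene not in family:
            continue
        if a.query_gene == a.subject_gene:
            continue
        cur = best.get(a.query_gene)
        if cur is None or (
            (-a.bitscore, a.evalue, a.subject_gene)
            < (-cur.bitscore, cur.evalue, cur.subject_gene)
        ):
            best[a.query_gene] = a
    pairs = {tuple(sorted((a.query_gene, a.subject_gene))) for a in best.values()}
    return sorted(pairs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# distances and dates
# ---------------------------------------------------------------------------

def p_distance(pair: AlignedPair) -> float:
    """Proportion of differing sites, excluding columns with a gap or N in
    either sequence."""
    s1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8)
    s2 = np.frombuffer(pair.seq2.encode(), dtype=np.uint8)
    valid_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    ok = np.isin(s1, valid_codes) & np.isin(s2, valid_codes)
    n = int(ok.sum())
    if n == 0:
        raise ValidationError(
            f"pair ({pair.gene1}, {pair.gene2}): no comparable (ungapped) sites"
        )
    return float((s1[ok] != s2[ok]).sum()) / n


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction of a p-distance: -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValidationError(f"p-distance must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(
            f"p-distance {p} >= 0.75: Jukes-Cantor distance undefined (saturation)"
        )
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def date_from_jc(jc: float, r: float) -> float:
    """Age in Ma of a divergence at Jukes-Cantor distance ``jc`` under
    substitution rate ``r`` (substitutions/site/Ma): age = jc / (2 r)."""
    if r <= 0:
        raise ValidationError(f"substitution rate r must be > 0, got {r}")
    if jc < 0:
        raise ValidationError(f"jc distance must be >= 0, got {jc}")
    return jc / (2.0 * r)


def date_pairs(
    aligned: Iterable[AlignedPair],
    config: DatingConfig,
    subfamilies: Mapping[str, str] | None = None,
) -> list[ParalogPair]:
    """Compute p, jc, and age for each aligned pair.

    A pair's subfamily is looked up by gene id (either gene; gene1 wins on
    conflict); unknown genes get "unlabeled".
    """
    subfamilies = subfamilies or {}
    out: list[ParalogPair] = []
    for ap in aligned:
        p = p_distance(ap)
        jc = jc_distance(p)
        age = date_from_jc(jc, config.r)
        sub = subfamilies.get(ap.gene1) or subfamilies.get(ap.gene2) or "unlabeled"
        out.append(ParalogPair(ap.gene1, ap.gene2, p, jc, age, sub))
    return out


# ---------------------------------------------------------------------------
# peak decomposition
# ---------------------------------------------------------------------------

def density_peaks(
    ages: Sequence[float],
    config: DatingConfig,
    ids: Sequence[str] | None = None,
    grid_size: int = 1024,
) -> list[ExpansionPeak]:
    """Decompose an age distribution into density peaks.

    Gaussian KDE on the ages; peaks are local maxima whose height reaches
    ``min_peak_fraction`` of the global maximum; every age is assigned to the
    basin delimited by the density minima between retained peaks (boundary
    ties go to the lower-age peak).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValidationError("need at least 2 ages for a density decomposition")
    if ids is None:
        ids = [str(i) for i in range(ages.size)]
    ids = list(ids)
    if len(ids) != ages.size:
        raise ValidationError("ids and ages differ in length")

    if np.ptp(ages) == 0:
        return [ExpansionPeak(mode=float(ages[0]), members=ids,
                              basin=(float(ages[0]), float(ages[0])), height=math.inf)]

    if isinstance(config.bandwidth, str):
        kde = gaussian_kde(ages, bw_method=config.bandwidth)
    else:
        # scipy's scalar bw_method is a factor on the sample SD; convert an
        # absolute bandwidth in Ma to that factor
        kde = gaussian_kde(ages, bw_method=config.bandwidth / float(np.std(ages, ddof=1)))
    bw = float(np.sqrt(kde.covariance[0, 0]))
    lo = float(ages.min()) - 3 * bw
    hi = float(ages.max()) + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)

    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    ) + 1
    height_cut = config.min_peak_fraction * dens.max()
    peak_idx = [i for i in interior if dens[i] >= height_cut]
    if not peak_idx:
        peak_idx = [int(np.argmax(dens))]

    # basin boundaries at the minimum density between adjacent peaks
    bounds = [lo]
    for left, right in zip(peak_idx, peak_idx[1:]):
        k = left + int(np.argmin(dens[left:right + 1]))
        bounds.append(float(grid[k]))
    bounds.append(hi)

    peaks: list[ExpansionPeak] = []
    for k, i in enumerate(peak_idx):
        basin = (bounds[k], bounds[k + 1])
        members = [
            pid for pid, age in zip(ids, ages)
            if (basin[0] <= age <= basin[1]) and not (k > 0 and age <= basin[0])
        ]
        peaks.append(ExpansionPeak(mode=float(grid[i]), members=members,
                                   basin=basin, height=float(dens[i])))
    return peaks


def peak_subfamily_fractions(
    peaks: Sequence[ExpansionPeak],
    pairs: Sequence[ParalogPair],
) -> list[ExpansionPeak]:
    """Fill per-peak subfamily fractions.

    ``subfamily_fractions`` counts pairs: for each subfamily, the fraction of
    its pairs assigned to the peak (fractions sum to 1 per subfamily across
    peaks).  ``subfamily_gene_fractions`` counts genes, each gene attributed
    to the peak of its youngest pair.
    """
    by_id = {p.pair_id: p for p in pairs}
    totals: dict[str, int] = {}
    for p in pairs:
        totals[p.subfamily] = totals.get(p.subfamily, 0) + 1

    gene_age: dict[str, float] = {}
    gene_sub: dict[str, str] = {}
    for p in pairs:
        for g in (p.gene1, p.gene2):
            if g not in gene_age or p.age < gene_age[g]:
                gene_age[g] = p.age
            gene_sub[g] = p.subfamily
    gene_peak: dict[str, int] = {}
    for k, peak in enumerate(peaks):
        for pid in peak.members:
            pair = by_id.get(pid)
            if pair is None:
                continue
            for g in (pair.gene1, pair.gene2):
                if gene_age[g] == pair.age and g not in gene_peak:
                    gene_peak[g] = k
    gene_totals: dict[str, int] = {}
    for g, sub in gene_sub.items():
        if g in gene_peak:
            gene_totals[sub] = gene_totals.get(sub, 0) + 1

    for k, peak in enumerate(peaks):
        counts: dict[str, int] = {}
        for pid in peak.members:
            pair = by_id.get(pid)
            if pair is None:
                continue
            counts[pair.subfamily] = counts.get(pair.subfamily, 0) + 1
        peak.subfamily_fractions = {
            sub: counts.get(sub, 0) / totals[sub] for sub in totals
        }
        gcounts: dict[str, int] = {}
        for g, kk in gene_peak.items():
            if kk == k:
                gcounts[gene_sub[g]] = gcounts.get(gene_sub[g], 0) + 1
        peak.subfamily_gene_fractions = {
            sub: gcounts.get(sub, 0) / gene_totals[sub]
            for sub in gene_totals
        }
    return list(peaks)


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

def detect_tandem_clusters(
    table: GenomeTable,
    family: Iterable[str],
    max_gap_genes: int = 10,
    max_gap_bp: int = 1_000_000,
) -> list[TandemCluster]:
    """Single-linkage clustering of family genes along each chromosome.

    Consecutive family genes join a cluster when their rank gap is at most
    ``max_gap_genes`` AND their bp gap (next start minus previous end) is at
    most ``max_gap_bp``.  Singletons are reported as size-1 clusters.
    Output is sorted by (chromosome, first gene start) and is independent of
    the input order of ``family``.
    """
    family = set(family)
    missing = sorted(g for g in family if g not in table)
    if missing:
        raise ValidationError(f"family genes absent from genome table: {missing[:20]}")
    clusters: list[TandemCluster] = []
    for chrom in table.chromosomes:
        genes = [g for g in table.genes_on(chrom) if g.gene_id in family]
        if not genes:
            continue
        current = [genes[0]]
        runs: list[list[GeneModel]] = []
        for prev, cur in zip(genes, genes[1:]):
            rank_gap = cur.rank - prev.rank
            bp_gap = max(0, cur.start - prev.end)
            if rank_gap <= max_gap_genes and bp_gap <= max_gap_bp:
                current.append(cur)
            else:
                runs.append(current)
                current = [cur]
        runs.append(current)
        for run in runs:
            span = run[-1].end - run[0].start + 1
            gaps_g = [b.rank - a.rank for a, b in zip(run, run[1:])]
            gaps_bp = [max(0, b.start - a.end) for a, b in zip(run, run[1:])]
            clusters.append(
                TandemCluster(
                    chromosome=chrom,
                    genes=run,
                    span_bp=span,
                    max_gap_genes=max(gaps_g) if gaps_g else 0,
                    max_gap_bp=max(gaps_bp) if gaps_bp else 0,
                )
            )
    return clusters
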