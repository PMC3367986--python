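"""SNP and structural-variant overlap with gene models and promoters.

Wild-relative resequencing yields SNPs and large structural variants
(deletions, insertions, inversions) relative to the target genome.
Each SNP is categorised per gene as CDS, genic non-coding (gene body
outside every CDS; UTRs and introns are not distinguished), promoter
(1 kb strand-aware upstream by default) or outside.  The census of
genes whose SNPs all avoid CDS — candidates for regulatory rather than
protein change — and a Fisher exact enrichment test over a gene subset
complete the module.  Coordinates are 1-based inclusive throughout
(GFF3 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import scipy.stats

PROMOTER_LENGTH = 1000


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """A gene body with merged CDS intervals and a derived promoter."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list[tuple[int, int]] = field(default_factory=list)
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"{self.gene_id}: bad gene interval")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for s, e in self.cds:
            if s > e or s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: CDS ({s},{e}) outside gene bounds"
                )
        self.cds = _merge_intervals(self.cds)

    @property
    def promoter(self) -> tuple[int, int] | None:
        return build_promoter(self)


@dataclass(frozen=True)
class VariantRecord:
    """A SNP position or SV interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    type: str  # SNP | deletion | insertion | inversion
    id: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"variant {self.id}: bad interval")
        if self.type not in ("SNP", "deletion", "insertion", "inversion"):
            raise ValueError(f"variant {self.id}: unknown type {self.type!r}")

    @property
    def position(self) -> int:
        return self.start


@dataclass
class GeneVariantReport:
    """Per-gene SNP category counts and SV overlap flags."""

    gene_id: str
    n_snps_cds: int = 0
    n_snps_genic_noncoding: int = 0
    n_snps_promoter: int = 0
    sv_overlap_types: set[str] = field(default_factory=set)

    @property
    def n_snps(self) -> int:
        return self.n_snps_cds + self.n_snps_genic_noncoding + self.n_snps_promoter

    @property
    def noncoding_only(self) -> bool:
        return self.n_snps_cds == 0 and (
            self.n_snps_genic_noncoding + self.n_snps_promoter > 0
        )


def build_promoter(
    model: GeneModel, length: int = PROMOTER_LENGTH
) -> tuple[int, int] | None:
    """Strand-aware upstream promoter interval, clamped to the chromosome.

    Plus strand: ``[gene_start − length, gene_start − 1]``; minus strand:
    ``[gene_end + 1, gene_end + length]``.  Returns ``None`` when the
    gene abuts the chromosome boundary and no upstream base exists.
    """
    if model.strand == "+":
        start, end = model.start - length, model.start - 1
        start = max(start, 1)
    else:
        start, end = model.end + 1, model.end + length
        if model.chrom_length is not None:
            end = min(end, model.chrom_length)
    if end < start:
        return None
    return (start, end)


def categorize_snp(
    snp: VariantRecord,
    model: GeneModel,
    promoter_length: int = PROMOTER_LENGTH,
) -> str:
    """Category of a SNP with respect to one gene model.

    ``CDS`` > ``genic_noncoding`` > ``promoter`` > ``outside``; the
    categories partition the chromosome for a given gene because the
    promoter never overlaps the gene body.
    """
    if snp.chrom != model.chrom:
        warnings.warn(
            f"SNP {snp.id} on {snp.chrom} vs gene {model.gene_id} on "
            f"{model.chrom}: treating as outside",
            stacklevel=2,
        )
        return "outside"
    pos = snp.position
    if model.start <= pos <= model.end:
        for s, e in model.cds:
            if s <= pos <= e:
                return "CDS"
        return "genic_noncoding"
    promoter = build_promoter(model, promoter_length)
    if promoter and promoter[0] <= pos <= promoter[1]:
        return "promoter"
    return "outside"


def make_reports(
    snps: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    promoter_length: int = PROMOTER_LENGTH,
) -> list[GeneVariantReport]:
    """Per-gene SNP category counts.

    A SNP hitting two genes (e.g. in the promoter of one and the body of
    a neighbour) is counted once per gene, independently.
    """
    reports = []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in snps:
        if v.type == "SNP":
            by_chrom.setdefault(v.chrom, []).append(v)
    for model in models:
        rep = GeneVariantReport(gene_id=model.gene_id)
        for snp in by_chrom.get(model.chrom, []):
            cat = categorize_snp(snp, model, promoter_length)
            if cat == "CDS":
                rep.n_snps_cds += 1
            elif cat == "genic_noncoding":
                rep.n_snps_genic_noncoding += 1
            elif cat == "promoter":
                rep.n_snps_promoter += 1
        reports.append(rep)
    return reports


def census_noncoding_only(
    reports: Sequence[GeneVariantReport],
) -> tuple[int, float]:
    """Count genes whose SNPs are all non-coding, over genes with ≥1 SNP.

    Returns the count and its percentage of the universe (genes with at
    least one SNP in gene body or promoter), rounded to one decimal.
    """
    universe = [r for r in reports if r.n_snps > 0]
    if not universe:
        raise ValueError("no genes with SNPs: census universe is empty")
    count = sum(r.noncoding_only for r in universe)
    return count, round(100.0 * count / len(universe), 1)


def _intervals_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def sv_overlap(
    svs: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    include_promoter: bool = True,
    promoter_length: int = PROMOTER_LENGTH,
) -> dict[str, set[str]]:
    """Flag genes intersected by structural variants.

    A gene is flagged for an SV type when the SV interval intersects the
    gene body, or the promoter when ``include_promoter`` is set
    (enabling the promoter can only add flags, never remove them).
    """
    flags: dict[str, set[str]] = {m.gene_id: set() for m in models}
    for model in models:
        spans = [(model.start, model.end)]
        if include_promoter:
            promoter = build_promoter(model, promoter_length)
            if promoter:
                spans.append(promoter)
        for sv in svs:
            if sv.type == "SNP" or sv.chrom != model.chrom:
                continue
            if any(_intervals_intersect((sv.start, sv.end), s) for s in spans):
                flags[model.gene_id].add(sv.type)
    return flags


def enrichment_test(
    subset_flagged: int,
    subset_total: int,
    background_flagged: int,
    background_total: int,
) -> tuple[float, float]:
    """Fisher exact test: is the subset enriched for flagged genes?

    The 2×2 table opposes the subset to the rest of the background
    (flagged vs not).  Returns (odds ratio, two-sided p-value).
    """
    rest_total = background_total - subset_total
    rest_flagged = background_flagged - subset_flagged
    cells = [
        subset_flagged,
        subset_total - subset_flagged,
        rest_flagged,
        rest_total - rest_flagged,
    ]
    if any(c < 0 for c in cells):
        raise ValueError("inconsistent contingency counts")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    res = scipy.stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
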