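"""Readers and writers for the pipeline's file interfaces.

Tables are TSV with header rows; gene models come from GFF3 (gene +
CDS features) via gffutils; variants from VCF (SNPs, and SVs through
SVTYPE/END) via cyvcf2 or from a minimal TSV; protein isoforms from
FASTA via Biopython.  Floats are serialised with six significant
digits so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from orthoflora.og_assignment import AnnotationLink
from orthoflora.records import GeneRecord
from orthoflora.variants import GeneModel, VariantRecord

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_links(path: str | os.PathLike) -> list[AnnotationLink]:
    """Annotation-link TSV: target_gene <TAB> reference_gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        AnnotationLink(target_gene=row.target_gene, reference_gene=row.reference_gene)
        for row in df.itertuples()
    ]


def read_memberships(path: str | os.PathLike) -> dict[str, str]:
    """Membership TSV: gene_id <TAB> og_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["og_id"]))


def read_flowering_list(path: str | os.PathLike) -> set[str]:
    """Flowering-gene list TSV: gene_id [<TAB> symbol]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(df["gene_id"])


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Expression TSV: gene_id column then one column per condition."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_gene_coords_tsv(path: str | os.PathLike) -> list[GeneRecord]:
    """Gene coordinate TSV: gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneRecord(
            gene_id=row.gene_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=getattr(row, "strand", None),
        )
        for row in df.itertuples()
    ]


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """FASTA records as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Gene models (gene + CDS features) from a GFF3 file.

    CDS features attach to the enclosing gene via their Parent chain
    (gene → mRNA → CDS) or directly when nested transcripts are absent.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = [
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS", order_by="start")
        ]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds=cds,
            )
        )
    return models


def write_gene_models_gff3(
    models: Sequence[GeneModel], path: str | os.PathLike
) -> None:
    """Serialise gene models as GFF3 (gene, mRNA and CDS features)."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.chrom, m.start)):
        lines.append(
            f"{m.chrom}\torthoflora\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t."
            f"\tID={m.gene_id}"
        )
        mrna_id = f"{m.gene_id}.1"
        lines.append(
            f"{m.chrom}\torthoflora\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t."
            f"\tID={mrna_id};Parent={m.gene_id}"
        )
        for i, (s, e) in enumerate(m.cds, 1):
            lines.append(
                f"{m.chrom}\torthoflora\tCDS\t{s}\t{e}\t.\t{m.strand}\t0"
                f"\tID={mrna_id}.cds{i};Parent={mrna_id}"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Variants: VCF and minimal TSV
# ---------------------------------------------------------------------------

_SVTYPE_MAP = {"DEL": "deletion", "INS": "insertion", "INV": "inversion"}


def read_variants_vcf(path: str | os.PathLike) -> list[VariantRecord]:
    """SNPs and SVs from a VCF; SV type and extent via SVTYPE/END."""
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        svtype = v.INFO.get("SVTYPE")
        vid = v.ID or "."
        if svtype is not None:
            end = v.INFO.get("END", v.end)
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    start=v.POS,
                    end=int(end),
                    type=_SVTYPE_MAP.get(svtype, svtype.lower()),
                    id=vid,
                )
            )
        elif v.is_snp:
            records.append(
                VariantRecord(
                    chrom=v.CHROM, start=v.POS, end=v.POS, type="SNP", id=vid
                )
            )
    return records


def read_variants_tsv(path: str | os.PathLike) -> list[VariantRecord]:
    """Minimal variant TSV: chrom, start, end, type[, id]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "type": str})
    return [
        VariantRecord(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            type=row.type,
            id=str(getattr(row, "id", ".")),
        )
        for row in df.itertuples()
    ]


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Dispatch on extension: .vcf[.gz] → VCF reader, else TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_variants_vcf(path)
    return read_variants_tsv(path)


def write_variants_vcf(
    variants: Sequence[VariantRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write variants as a minimal VCF 4.2 text file."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
    ]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rev = {v: k for k, v in _SVTYPE_MAP.items()}
    for v in sorted(variants, key=lambda v: (v.chrom, v.start)):
        if v.type == "SNP":
            lines.append(f"{v.chrom}\t{v.start}\t{v.id}\tA\tG\t.\t.\t.")
        else:
            code = rev[v.type]
            lines.append(
                f"{v.chrom}\t{v.start}\t{v.id}\tN\t<{code}>\t.\t.\t"
                f"SVTYPE={code};END={v.end}"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Newick trees per OG
# ---------------------------------------------------------------------------

def read_og_trees(directory: str | os.PathLike) -> dict[str, str]:
    """Newick text per OG from ``<og_id>.nwk`` files in a directory."""
    trees: dict[str, str] = {}
    for p in sorted(Path(directory).glob("*.nwk")):
        trees[p.stem] = p.read_text().strip()
    return trees
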