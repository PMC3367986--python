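"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the structure of the real inputs without any
sequence content:

* an OG universe whose per-OG log2(target/reference) count ratios are
  normal (defaults: mean 1.03, sd 0.88 over 11,344 OGs — the observed
  genome-wide distribution), with the generating ratio recorded as each
  OG's true paralogue class;
* per-OG gene trees built from an explicit duplication history
  (pre-speciation duplications create subfamilies; the speciation node
  separates reference from target lineages), ultrametric before a
  configurable multiplicative branch-length noise, with each target
  leaf's true closest reference gene recorded from the noiseless tree;
* negative-binomial expression counts around planted cluster templates,
  with a fraction of all-zero genes to exercise inactivity calls;
* uniform gene placement on chromosomes with one planted cluster of
  flagged genes condensed in a short span;
* SNPs placed with known per-category counts (CDS / genic non-coding /
  promoter / intergenic) and SVs with known gene overlaps.

A single root seed derives an independent, reproducible stream per
stage, so stages can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from orthoflora.expression import ExpressionMatrix
from orthoflora.records import GeneRecord
from orthoflora.variants import GeneModel, VariantRecord, build_promoter

_STREAMS = {
    "og_universe": 1,
    "trees": 2,
    "expression": 3,
    "genome": 4,
    "variants": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one simulation stage."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic universe; the seed fixes every stream."""

    seed: int = 42
    # OG universe
    n_ogs: int = 11344
    log2_ratio_mean: float = 1.03
    log2_ratio_sd: float = 0.88
    reference_count_rate: float = 1.5  # reference counts ~ 1 + Poisson(rate)
    k_sd: float = 2.0
    flowering_og_fraction: float = 0.01
    # gene trees
    pre_speciation_dup_rate: float = 0.4
    branch_noise_sd: float = 0.0
    # expression
    n_conditions: int = 14
    n_flower_conditions: int = 3
    n_expression_clusters: int = 4
    nb_mean: float = 50.0
    nb_dispersion: float = 0.3
    zero_gene_fraction: float = 0.05
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 50_000_000
    n_background_genes: int = 1000
    gene_length: int = 3000
    cluster_span: int = 1_000_000
    cluster_size: int = 60
    n_scattered_flagged: int = 40
    # variants
    n_snps_cds: int = 60
    n_snps_genic_noncoding: int = 50
    n_snps_promoter: int = 40
    n_snps_intergenic: int = 30
    n_svs: int = 30
    promoter_length: int = 1000

    def __post_init__(self) -> None:
        if self.log2_ratio_sd < 0:
            raise ValueError("log2_ratio_sd must be non-negative")
        if self.n_ogs < 2:
            raise ValueError("need at least two OGs")


# ---------------------------------------------------------------------------
# OG universe
# ---------------------------------------------------------------------------

def generate_og_universe(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an OG count universe with normal log2 count ratios.

    Reference counts are 1 + Poisson; target counts round the reference
    count times 2^z (z normal) on the linear scale, clipped at one so
    both species stay represented.  The truth table records the
    generating ratio and the class it implies under the k·SD rule at
    the generator parameters.

    Returns
    -------
    (count_table, truth)
        ``count_table``: og_id, n_reference, n_target;
        ``truth`` adds ``true_log2`` and ``true_class``.
    """
    rng = stream_rng(config.seed, "og_universe")
    n = config.n_ogs
    n_ref = 1 + rng.poisson(config.reference_count_rate, n)
    z = rng.normal(config.log2_ratio_mean, config.log2_ratio_sd, n)
    n_target = np.maximum(np.rint(n_ref * 2.0**z), 1).astype(int)
    og_ids = [f"OG5_{100000 + i}" for i in range(n)]
    upper = config.log2_ratio_mean + config.k_sd * config.log2_ratio_sd
    lower = config.log2_ratio_mean - config.k_sd * config.log2_ratio_sd
    true_class = np.where(z > upper, "rich", np.where(z < lower, "less", "typical"))
    count_table = pd.DataFrame(
        {"og_id": og_ids, "n_reference": n_ref, "n_target": n_target}
    )
    truth = count_table.assign(true_log2=z, true_class=true_class)
    return count_table, truth


def og_gene_catalogue(count_table: pd.DataFrame) -> pd.DataFrame:
    """Expand a count table into per-gene rows with synthetic IDs."""
    rows = []
    ref_i = target_i = 0
    for row in count_table.itertuples():
        for _ in range(row.n_reference):
            ref_i += 1
            rows.append(
                {
                    "gene_id": f"AT{1 + ref_i % 5}G{ref_i:05d}",
                    "species": "reference",
                    "og_id": row.og_id,
                }
            )
        for _ in range(row.n_target):
            target_i += 1
            rows.append(
                {
                    "gene_id": f"Glyma{1 + target_i % 20:02d}g{target_i:05d}",
                    "species": "target",
                    "og_id": row.og_id,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "species", "og_id"])


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "height", "children")

    def __init__(self, name: str | None, height: float, children: list):
        self.name = name
        self.height = height
        self.children = children  # list of _Node


def _ultrametric(leaves: list[str], height: float, rng: np.random.Generator) -> _Node:
    if len(leaves) == 1:
        return _Node(leaves[0], 0.0, [])
    order = rng.permutation(len(leaves))
    split = int(rng.integers(1, len(leaves)))
    left = [leaves[i] for i in order[:split]]
    right = [leaves[i] for i in order[split:]]
    h_left = height * rng.uniform(0.3, 0.9) if len(left) > 1 else 0.0
    h_right = height * rng.uniform(0.3, 0.9) if len(right) > 1 else 0.0
    return _Node(
        None, height, [_ultrametric(left, h_left, rng), _ultrametric(right, h_right, rng)]
    )


def _pair_distances(node: _Node, dist: dict[tuple[str, str], float]) -> list[str]:
    """Fill 2·MRCA-height distances for all cross-child leaf pairs."""
    if not node.children:
        return [node.name]
    sets = [_pair_distances(c, dist) for c in node.children]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            for a in sets[i]:
                for b in sets[j]:
                    d = 2.0 * node.height
                    dist[(a, b)] = d
                    dist[(b, a)] = d
    return [leaf for s in sets for leaf in s]


def _to_newick(node: _Node, parent_height: float, rng, noise_sd: float) -> str:
    blen = parent_height - node.height
    if noise_sd > 0:
        blen *= float(np.exp(rng.normal(0.0, noise_sd)))
    if not node.children:
        return f"{node.name}:{blen:.8f}"
    inner = ",".join(
        _to_newick(c, node.height, rng, noise_sd) for c in node.children
    )
    return f"({inner}):{blen:.8f}"


def generate_gene_tree(
    reference_genes: Sequence[str],
    target_genes: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, dict[str, list[str]]]:
    """Simulate one OG gene tree with a known duplication history.

    Pre-speciation duplications split the family into subfamilies; each
    subfamily speciates into a reference clade and a target clade (one
    side may be lost).  The emitted Newick carries noisy branch lengths;
    the true closest reference gene(s) per target leaf come from the
    noiseless ultrametric history.

    Returns
    -------
    (newick, truth)
        ``truth`` maps each target leaf to the list of reference leaves
        at minimal noiseless patristic distance.
    """
    refs, targets = list(reference_genes), list(target_genes)
    if len(refs) + len(targets) < 2:
        raise ValueError("a tree needs at least two members")
    if rng is None:
        rng = stream_rng(config.seed, "trees")

    n_sub = 1 + int(rng.poisson(config.pre_speciation_dup_rate))
    ref_sub = rng.integers(0, n_sub, len(refs))
    tgt_sub = rng.integers(0, n_sub, len(targets))

    subtrees: list[_Node] = []
    for s in range(n_sub):
        sub_refs = [g for g, a in zip(refs, ref_sub) if a == s]
        sub_tgts = [g for g, a in zip(targets, tgt_sub) if a == s]
        sides = []
        if sub_refs:
            h = float(rng.uniform(0.2, 0.8)) if len(sub_refs) > 1 else 0.0
            sides.append(_ultrametric(sub_refs, h, rng))
        if sub_tgts:
            h = float(rng.uniform(0.2, 0.8)) if len(sub_tgts) > 1 else 0.0
            sides.append(_ultrametric(sub_tgts, h, rng))
        if not sides:
            continue
        if len(sides) == 2:
            subtrees.append(_Node(None, 1.0, sides))  # speciation at height 1
        else:
            subtrees.append(sides[0])

    root = subtrees[0]
    join_height = 1.3
    for sub in subtrees[1:]:
        root = _Node(None, join_height, [root, sub])
        join_height += 0.3

    dist: dict[tuple[str, str], float] = {}
    _pair_distances(root, dist)
    truth: dict[str, list[str]] = {}
    for t in targets:
        dists = {r: dist[(t, r)] for r in refs} if refs else {}
        if dists:
            dmin = min(dists.values())
            truth[t] = sorted(r for r, d in dists.items() if d <= dmin + 1e-12)
        else:
            truth[t] = []

    if root.children:
        inner = ",".join(
            _to_newick(c, root.height, rng, config.branch_noise_sd)
            for c in root.children
        )
        newick = f"({inner});"
    else:
        newick = f"{root.name};"
    return newick, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    genes: Sequence[str],
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Negative-binomial counts around planted cluster templates.

    Each planted cluster expresses a distinct block of conditions;
    dispersion 0 returns the integer templates exactly.  A configured
    fraction of genes is forced all-zero (label ``-1``) to exercise the
    inactivity path.
    """
    if config.n_expression_clusters > len(genes):
        raise ValueError("more clusters than genes")
    rng = stream_rng(config.seed, "expression")
    n_genes, n_cond = len(genes), config.n_conditions
    k = config.n_expression_clusters
    conditions = [f"cond{i + 1}" for i in range(n_cond - config.n_flower_conditions)]
    conditions += [f"flower{i + 1}" for i in range(config.n_flower_conditions)]

    labels = rng.integers(0, k, n_genes)
    n_zero = int(round(config.zero_gene_fraction * n_genes))
    zero_idx = rng.choice(n_genes, size=n_zero, replace=False)
    labels[zero_idx] = -1

    block = max(1, n_cond // k)
    templates = np.full((k, n_cond), 2.0)
    for c in range(k):
        lo = (c * block) % n_cond
        templates[c, lo : lo + block] = config.nb_mean
    templates = np.rint(templates)

    counts = np.zeros((n_genes, n_cond), dtype=int)
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        mean = templates[lab]
        if config.nb_dispersion <= 0:
            counts[i] = mean.astype(int)
        else:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
            counts[i] = rng.poisson(lam)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=list(genes), columns=conditions),
        rule_tag="raw_reads",
        flower_conditions=tuple(
            c for c in conditions if c.startswith("flower")
        ),
    )
    return matrix, pd.Series(labels, index=list(genes), name="planted_cluster")


# ---------------------------------------------------------------------------
# Genome and variants
# ---------------------------------------------------------------------------

def generate_genome_and_variants(
    genes: Sequence[str],
    config: SimulationConfig,
) -> dict:
    """Place genes on chromosomes and scatter variants with known truth.

    The first ``cluster_size`` genes are flagged and condensed in one
    ``cluster_span`` region of chromosome 1; ``n_scattered_flagged``
    further flagged genes and the remaining background genes are placed
    uniformly.  SNPs are then planted with known per-category counts and
    SVs with known gene overlaps.

    Returns a dict with gene records, gene models, flagged IDs, variant
    records, the planted cluster interval, per-SNP truth rows and
    per-gene true SV overlap types.
    """
    rng = stream_rng(config.seed, "genome")
    gene_ids = list(genes)
    need = config.cluster_size + config.n_scattered_flagged
    if len(gene_ids) < need:
        raise ValueError(
            f"need at least {need} genes for the configured flagged sets"
        )
    glen = config.gene_length
    if config.cluster_size * (glen + 10) > config.cluster_span:
        raise ValueError("planted cluster does not fit its span")

    cluster_genes = gene_ids[: config.cluster_size]
    scattered = gene_ids[config.cluster_size : need]
    background = gene_ids[need:]
    flagged = set(cluster_genes) | set(scattered)

    span_start = int(
        rng.integers(1, config.chromosome_length - config.cluster_span - glen)
    )
    cluster_interval = (span_start, span_start + config.cluster_span - 1)

    records: list[GeneRecord] = []
    models: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    def place(gene_id: str, chrom: str, lo: int, hi: int) -> None:
        taken = occupied.setdefault(chrom, [])
        for _ in range(200):
            start = int(rng.integers(lo, hi - glen))
            end = start + glen - 1
            if all(not (start <= e and s <= end) for s, e in taken):
                break
        else:
            raise ValueError(f"cannot pack gene {gene_id} on {chrom}")
        taken.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand)
        )
        # two CDS blocks framing an intron in the middle of the gene
        cds = [
            (start + 200, start + glen // 2 - 200),
            (start + glen // 2 + 200, end - 200),
        ]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                cds=cds,
                chrom_length=config.chromosome_length,
            )
        )

    for g in cluster_genes:
        place(g, "Chr01", cluster_interval[0], cluster_interval[1] - glen)
    rest = scattered + background
    for g in rest:
        chrom = f"Chr{1 + int(rng.integers(0, config.n_chromosomes)):02d}"
        place(g, chrom, config.promoter_length + 1, config.chromosome_length)

    # --- variants -------------------------------------------------------
    vrng = stream_rng(config.seed, "variants")
    snps: list[VariantRecord] = []
    snp_truth: list[dict] = []

    def plant_snp(category: str, idx: int) -> None:
        model = models[int(vrng.integers(0, len(models)))]
        if category == "CDS":
            s, e = model.cds[int(vrng.integers(0, len(model.cds)))]
            pos = int(vrng.integers(s, e + 1))
        elif category == "genic_noncoding":
            # the planted intron between the two CDS blocks
            pos = int(
                vrng.integers(model.cds[0][1] + 1, model.cds[1][0])
            )
        elif category == "promoter":
            promoter = build_promoter(model, config.promoter_length)
            if promoter is None:
                return
            pos = int(vrng.integers(promoter[0], promoter[1] + 1))
        else:  # intergenic: rejection-sample clear of bodies and promoters
            chrom = model.chrom
            spans = []
            for m in models:
                if m.chrom != chrom:
                    continue
                spans.append((m.start - config.promoter_length, m.end + config.promoter_length))
            for _ in range(200):
                pos = int(vrng.integers(1, config.chromosome_length))
                if all(not (s <= pos <= e) for s, e in spans):
                    break
            else:
                return
        snp = VariantRecord(
            chrom=model.chrom, start=pos, end=pos, type="SNP",
            id=f"snp_{category}_{idx}",
        )
        snps.append(snp)
        snp_truth.append(
            {"snp_id": snp.id, "gene_id": model.gene_id, "true_category": category}
        )

    for cat, count in (
        ("CDS", config.n_snps_cds),
        ("genic_noncoding", config.n_snps_genic_noncoding),
        ("promoter", config.n_snps_promoter),
        ("intergenic", config.n_snps_intergenic),
    ):
        for i in range(count):
            plant_snp(cat, i)

    sv_types = ("deletion", "insertion", "inversion")
    svs: list[VariantRecord] = []
    sv_truth: dict[str, set[str]] = {m.gene_id: set() for m in models}
    for i in range(config.n_svs):
        model = models[int(vrng.integers(0, len(models)))]
        sv_type = sv_types[i % len(sv_types)]
        mid = (model.start + model.end) // 2
        half = int(vrng.integers(100, 2000))
        sv = VariantRecord(
            chrom=model.chrom,
            start=max(1, mid - half),
            end=mid + half,
            type=sv_type,
            id=f"sv_{i}",
        )
        svs.append(sv)
        for m in models:
            if m.chrom == sv.chrom and sv.start <= m.end and m.start <= sv.end:
                sv_truth[m.gene_id].add(sv_type)

    return {
        "gene_records": records,
        "gene_models": models,
        "flagged": flagged,
        "snps": snps,
        "svs": svs,
        "cluster_interval": cluster_interval,
        "cluster_chrom": "Chr01",
        "snp_truth": pd.DataFrame(snp_truth),
        "sv_truth": sv_truth,
    }


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------

def generate_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Emit a complete input bundle plus ground truth for a pipeline run.

    Writes links/memberships/flowering TSVs, one Newick per multi-member
    flowering OG, an expression TSV, gene models as GFF3, variants as
    VCF, and ground-truth TSVs under ``truth/``.
    """
    from orthoflora import io as ofio

    out = Path(outdir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    count_table, truth = generate_og_universe(config)
    catalogue = og_gene_catalogue(count_table)
    rng = stream_rng(config.seed, "og_universe")

    # flowering list: a fraction of OGs contribute all their reference
    # genes; small universes keep at least a handful so every downstream
    # stage has work to do
    og_ids = list(count_table["og_id"])
    n_flowering = max(
        min(5, len(og_ids)),
        int(round(config.flowering_og_fraction * len(og_ids))),
    )
    flowering_ogs = set(og_ids[:n_flowering])
    ref_rows = catalogue[catalogue["species"] == "reference"]
    flowering_genes = set(
        ref_rows.loc[ref_rows["og_id"].isin(flowering_ogs), "gene_id"]
    )

    # memberships for all reference genes and ~80% of target genes;
    # the rest are covered by annotation links instead
    target_rows = catalogue[catalogue["species"] == "target"]
    keep = rng.random(len(target_rows)) < 0.8
    memberships = pd.concat(
        [ref_rows, target_rows.loc[keep]], ignore_index=True
    )[["gene_id", "og_id"]]

    ref_by_og = ref_rows.groupby("og_id")["gene_id"].first()
    linked = target_rows.loc[~keep]
    links = pd.DataFrame(
        {
            "target_gene": linked["gene_id"],
            "reference_gene": [ref_by_og[og] for og in linked["og_id"]],
        }
    )

    ofio.write_tsv(memberships, out / "memberships.tsv")
    ofio.write_tsv(links, out / "links.tsv")
    ofio.write_tsv(
        pd.DataFrame({"gene_id": sorted(flowering_genes)}), out / "flowering.tsv"
    )
    ofio.write_tsv(count_table, out / "counts.tsv")
    ofio.write_tsv(truth, out / "truth" / "og_classes.tsv")

    # trees + orthology truth for flowering OGs with >= 4 sequences
    trng = stream_rng(config.seed, "trees")
    anchor_rows = []
    for og_id in sorted(flowering_ogs):
        sub = catalogue[catalogue["og_id"] == og_id]
        refs = list(sub.loc[sub["species"] == "reference", "gene_id"])
        tgts = list(sub.loc[sub["species"] == "target", "gene_id"])
        if len(refs) + len(tgts) < 4:
            continue
        newick, tree_truth = generate_gene_tree(refs, tgts, config, trng)
        (out / "trees" / f"{og_id}.nwk").write_text(newick + "\n")
        for t, anchors in tree_truth.items():
            anchor_rows.append(
                {"og_id": og_id, "target_gene": t, "true_anchors": ",".join(anchors)}
            )
    ofio.write_tsv(pd.DataFrame(anchor_rows), out / "truth" / "anchors.tsv")

    # expression over the flowering-OG target genes
    flowering_targets = list(
        target_rows.loc[target_rows["og_id"].isin(flowering_ogs), "gene_id"]
    )
    expr_config = replace(
        config,
        n_expression_clusters=min(
            config.n_expression_clusters, max(1, len(flowering_targets))
        ),
    )
    matrix, planted = generate_expression(flowering_targets, expr_config)
    expr = matrix.values.copy()
    expr.insert(0, "gene_id", expr.index)
    ofio.write_tsv(expr, out / "expression.tsv")
    ofio.write_tsv(
        planted.rename_axis("gene_id").reset_index(), out / "truth" / "expression_clusters.tsv"
    )

    # genome + variants over target genes (flagged = planted cluster genes)
    rich_targets = list(
        target_rows.loc[
            target_rows["og_id"].isin(
                set(truth.loc[truth["true_class"] == "rich", "og_id"])
            ),
            "gene_id",
        ]
    )
    other_targets = [g for g in target_rows["gene_id"] if g not in set(rich_targets)]
    placed = (rich_targets + other_targets)[
        : config.cluster_size + config.n_scattered_flagged + config.n_background_genes
    ]
    genome = generate_genome_and_variants(placed, config)
    ofio.write_gene_models_gff3(genome["gene_models"], out / "genes.gff3")
    ofio.write_variants_vcf(
        genome["snps"] + genome["svs"],
        out / "variants.vcf",
        contigs={
            f"Chr{i + 1:02d}": config.chromosome_length
            for i in range(config.n_chromosomes)
        },
    )
    ofio.write_tsv(
        pd.DataFrame({"gene_id": sorted(genome["flagged"])}), out / "flagged.tsv"
    )
    ofio.write_tsv(genome["snp_truth"], out / "truth" / "snp_categories.tsv")
    genome["count_table"] = count_table
    genome["truth"] = truth
    genome["catalogue"] = catalogue
    genome["flowering_genes"] = flowering_genes
    genome["expression"] = matrix
    genome["planted_expression"] = planted
    return genome
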