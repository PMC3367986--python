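"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: assign → classify → express / paralogue
→ distribute → variants.  The run manifest records package version,
parameters, input checksums and per-stage row counts; identical config
and inputs reproduce byte-identical TSV outputs (floats are written at
six significant digits).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import orthoflora
from orthoflora import io as ofio
from orthoflora.clade import assignments_to_rows, classify_og, parse_newick
from orthoflora.distribution import per_chromosome_fraction, window_scan
from orthoflora.expression import (
    ExpressionMatrix,
    call_active,
    flag_flower_expressed,
    hierarchical_cluster,
    summarize_activity,
    zscore_rows,
)
from orthoflora.og_assignment import (
    assignments_frame,
    build_ogs,
    flag_flowering_ogs,
    merge_og_assignments,
    og_count_table,
)
from orthoflora.paralogue import (
    classify_ratio_table,
    compute_ratios,
    distribution_summary,
    summary_frame,
)
from orthoflora.variants import (
    census_noncoding_only,
    make_reports,
    sv_overlap,
)

log = logging.getLogger("orthoflora.pipeline")

ALL_STAGES = ("assign", "classify", "express", "paralogue", "distribute", "variants")
_STAGE_INPUTS = {
    "assign": ("links", "memberships", "flowering"),
    "classify": ("trees", "flowering"),
    "express": ("expression",),
    "paralogue": (),
    "distribute": ("genes",),
    "variants": ("genes", "variants"),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    """Paths, stage toggles and parameters for one pipeline run."""

    out_dir: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    tolerance: float = 1e-9
    k: float = 2.0
    window: int = 1_400_000
    step: int = 100_000
    promoter_length: int = 1000
    expression_rule: str = "raw_reads"
    flower_conditions: tuple[str, ...] = ()
    distance: str = "pearson_correlation"
    linkage: str = "average"
    cut_height: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        inputs = {k: Path(v) for k, v in raw.pop("inputs", {}).items()}
        out_dir = Path(raw.pop("out_dir", "orthoflora_out"))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        flower = tuple(raw.pop("flower_conditions", ()))
        known = {
            "seed", "tolerance", "k", "window", "step", "promoter_length",
            "expression_rule", "distance", "linkage", "cut_height",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            out_dir=out_dir,
            inputs=inputs,
            stages=stages,
            flower_conditions=flower,
            **raw,
        )

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        for stage in self.stages:
            for key in _STAGE_INPUTS[stage]:
                if key not in self.inputs:
                    raise ConfigError(
                        f"stage {stage!r} enabled but input {key!r} not configured"
                    )
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(
                        f"stage {stage!r}: input {key!r} missing at "
                        f"{self.inputs[key]}"
                    )
        if not (0 < self.step <= self.window):
            raise ConfigError("need 0 < step <= window")
        enabled = set(self.stages)
        if "classify" in enabled and "assign" not in enabled:
            raise ConfigError("stage 'classify' needs the 'assign' stage")
        if "paralogue" in enabled and "assign" not in enabled and "counts" not in self.inputs:
            raise ConfigError("stage 'paralogue' needs 'assign' or a counts input")
        if "distribute" in enabled and "flags" not in self.inputs and not (
            {"assign", "paralogue"} <= enabled
        ):
            raise ConfigError(
                "stage 'distribute' needs a flags input or the assign+paralogue stages"
            )


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": orthoflora.__version__,
        "parameters": {
            "seed": config.seed,
            "tolerance": config.tolerance,
            "k": config.k,
            "window": config.window,
            "step": config.step,
            "promoter_length": config.promoter_length,
            "expression_rule": config.expression_rule,
            "distance": config.distance,
            "linkage": config.linkage,
        },
        "inputs": {
            k: _checksum(Path(v)) for k, v in sorted(config.inputs.items())
        },
        "stages": {},
    }

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        rows = _STAGE_RUNNERS[stage](config, out, state)
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"rows": rows, "seconds": round(dt, 3)}
        log.info("stage %s: %s rows in %.2fs", stage, rows, dt)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# --- stage runners ---------------------------------------------------------

def _run_assign(config: PipelineConfig, out: Path, state: dict) -> int:
    links = ofio.read_links(config.inputs["links"])
    memberships = ofio.read_memberships(config.inputs["memberships"])
    flowering = ofio.read_flowering_list(config.inputs["flowering"])
    assignments, synthesized, unassigned = merge_og_assignments(links, memberships)
    ogs = build_ogs(assignments)
    ogs, summary, orphans = flag_flowering_ogs(ogs, flowering)
    frame = assignments_frame(assignments)
    ofio.write_tsv(frame, out / "og_map.tsv")
    counts = og_count_table(ogs)
    ofio.write_tsv(counts, out / "og_counts.tsv")
    ofio.write_tsv(
        pd.DataFrame([summary]).assign(
            n_synthesized=len(synthesized), n_unassigned=len(unassigned),
            n_orphans=len(orphans),
        ),
        out / "flowering_summary.tsv",
    )
    state["ogs"] = {og.og_id: og for og in ogs}
    state["flowering"] = flowering
    state["counts"] = counts
    return len(frame)


def _run_classify(config: PipelineConfig, out: Path, state: dict) -> int:
    flowering = state.get("flowering") or ofio.read_flowering_list(
        config.inputs["flowering"]
    )
    trees = ofio.read_og_trees(config.inputs["trees"])
    if "ogs" not in state:
        raise ConfigError("classify requires the assign stage (no OG map)")
    rows: list[dict] = []
    for og_id, og in sorted(state["ogs"].items()):
        if not og.contains_flowering:
            continue
        tree_text = trees.get(og_id)
        if og.n_sequences >= 4 and tree_text is None:
            continue  # no tree supplied for this OG; skip rather than abort
        tree = parse_newick(tree_text) if tree_text else None
        assignments = classify_og(og, tree, flowering, config.tolerance)
        rows.extend(assignments_to_rows(og_id, assignments))
    df = pd.DataFrame(
        rows,
        columns=[
            "og_id", "target_gene", "status", "anchor_genes",
            "d_flowering", "d_other", "via_small_og_rule",
        ],
    )
    ofio.write_tsv(df, out / "clade_assignments.tsv")
    state["clades"] = df
    return len(df)


def _run_express(config: PipelineConfig, out: Path, state: dict) -> int:
    values = ofio.read_expression_tsv(config.inputs["expression"])
    matrix = ExpressionMatrix(
        values=values,
        rule_tag=config.expression_rule,
        flower_conditions=tuple(
            c for c in config.flower_conditions if c in values.columns
        ),
    )
    calls = call_active(matrix)
    calls = flag_flower_expressed(calls, matrix)
    ofio.write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "active_raw": c.active_raw,
                    "active_normalized": c.active_normalized,
                    "active_any": c.active_any,
                    "flower_expressed": c.flower_expressed,
                }
                for c in calls
            ]
        ),
        out / "activity.tsv",
    )
    ofio.write_tsv(
        pd.DataFrame([summarize_activity(calls)]), out / "activity_summary.tsv"
    )
    z = zscore_rows(matrix)
    zt = z.copy()
    zt.insert(0, "gene_id", zt.index)
    ofio.write_tsv(zt, out / "zscores.tsv")
    dendro = hierarchical_cluster(z, config.distance, config.linkage)
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    flat = dendro.cut(config.cut_height)
    ofio.write_tsv(
        pd.DataFrame(
            {"gene_id": list(flat), "cluster": list(flat.values())}
        ).sort_values("gene_id", ignore_index=True),
        out / "flat_clusters.tsv",
    )
    return len(calls)


def _run_paralogue(config: PipelineConfig, out: Path, state: dict) -> int:
    if "counts" in state:
        counts = state["counts"]
    elif "counts" in config.inputs:
        counts = pd.read_csv(config.inputs["counts"], sep="\t")
    else:
        raise ConfigError("paralogue stage needs the assign stage or a counts input")
    ratios, excluded = compute_ratios(counts)
    summary = distribution_summary(ratios, k=config.k)
    classified = classify_ratio_table(ratios, summary)
    ofio.write_tsv(classified, out / "ratios.tsv")
    ofio.write_tsv(excluded, out / "ratios_excluded.tsv")
    ofio.write_tsv(summary_frame(summary), out / "ratio_summary.tsv")
    state["rich_ogs"] = set(
        classified.loc[classified["paralogue_class"] == "rich", "og_id"]
    )
    return len(classified)


def _load_genes(config: PipelineConfig):
    path = str(config.inputs["genes"])
    if path.endswith((".gff3", ".gff")):
        models = ofio.read_gene_models(path)
        from orthoflora.records import GeneRecord

        records = [
            GeneRecord(
                gene_id=m.gene_id, chrom=m.chrom, start=m.start, end=m.end,
                strand=m.strand,
            )
            for m in models
        ]
        return records, models
    return ofio.read_gene_coords_tsv(path), None


def _run_distribute(config: PipelineConfig, out: Path, state: dict) -> int:
    records, _ = _load_genes(config)
    if "flags" in config.inputs:
        flagged = set(
            pd.read_csv(config.inputs["flags"], sep="\t", dtype=str)["gene_id"]
        )
    elif "rich_ogs" in state and "ogs" in state:
        flagged = {
            g
            for og_id in state["rich_ogs"]
            for g in state["ogs"][og_id].members.get("target", set())
        }
    else:
        raise ConfigError("distribute stage needs a flags input or upstream stages")
    known = {r.gene_id for r in records}
    flagged &= known
    summary = per_chromosome_fraction(records, flagged)
    ofio.write_tsv(summary, out / "chromosome_summary.tsv")
    hits = window_scan(records, flagged, config.window, config.step)
    ofio.write_tsv(hits, out / "window_hits.tsv")
    return len(hits)


def _run_variants(config: PipelineConfig, out: Path, state: dict) -> int:
    _, models = _load_genes(config)
    if models is None:
        raise ConfigError("variants stage needs gene models in GFF3")
    variants = ofio.read_variants(config.inputs["variants"])
    snps = [v for v in variants if v.type == "SNP"]
    svs = [v for v in variants if v.type != "SNP"]
    reports = make_reports(snps, models, config.promoter_length)
    flags = sv_overlap(svs, models, True, config.promoter_length)
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_snps_cds": r.n_snps_cds,
                "n_snps_genic_noncoding": r.n_snps_genic_noncoding,
                "n_snps_promoter": r.n_snps_promoter,
                "sv_overlap_types": ",".join(sorted(flags.get(r.gene_id, set()))),
                "noncoding_only": r.noncoding_only,
            }
            for r in reports
        ]
    )
    ofio.write_tsv(df, out / "gene_variant_report.tsv")
    with_snps = [r for r in reports if r.n_snps > 0]
    if with_snps:
        count, pct = census_noncoding_only(reports)
        census = pd.DataFrame(
            [
                {
                    "n_genes_with_snps": len(with_snps),
                    "n_noncoding_only": count,
                    "pct_noncoding_only": pct,
                }
            ]
        )
        ofio.write_tsv(census, out / "census.tsv")
    return len(df)


_STAGE_RUNNERS = {
    "assign": _run_assign,
    "classify": _run_classify,
    "express": _run_express,
    "paralogue": _run_paralogue,
    "distribute": _run_distribute,
    "variants": _run_variants,
}
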