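"""Genomic distribution of flagged (paralogue-rich-OG) genes.

Per-chromosome fractions of flagged genes, their correlation with the
percentage of recently duplicated segments (an input column from the
genome resource, never computed here), and a sliding-window scan that
finds chromosomal regions where flagged genes condense — e.g. a ~1.4 Mb
stretch of one chromosome holding dozens of members of just two OGs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from orthoflora.records import GeneRecord

DEFAULT_WINDOW = 1_400_000
DEFAULT_STEP = 100_000


def per_chromosome_fraction(
    genes: Sequence[GeneRecord],
    flagged: set[str],
    pct_duplicated: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fraction of flagged genes per chromosome.

    Every gene must carry a chromosome; every flagged ID must be a known
    gene.  ``pct_duplicated`` optionally joins the duplicated-segment
    percentage column for downstream correlation.
    """
    known = {g.gene_id for g in genes}
    missing = flagged - known
    if missing:
        raise ValueError(f"flagged IDs not in gene set: {sorted(missing)[:5]}")
    rows: dict[str, list[int]] = {}
    for g in genes:
        if g.chrom is None:
            raise ValueError(f"gene {g.gene_id} has no chromosome")
        n, k = rows.setdefault(g.chrom, [0, 0])
        rows[g.chrom][0] = n + 1
        rows[g.chrom][1] = k + (g.gene_id in flagged)
    out = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "n_genes": n,
                "n_flagged": k,
                "fraction": k / n,
                "pct_duplicated": (
                    pct_duplicated.get(chrom) if pct_duplicated else None
                ),
            }
            for chrom, (n, k) in rows.items()
        ]
    )
    return out.sort_values("chrom", ignore_index=True)


def pearson_r(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    for name, v in (("x", xa), ("y", ya)):
        if np.allclose(v, v[0]):
            raise ValueError(f"vector {name} has zero variance")
    return float(scipy.stats.pearsonr(xa, ya).statistic)


def window_scan(
    genes: Sequence[GeneRecord],
    flagged: set[str],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    og_of: Mapping[str, str] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window census of flagged genes along each chromosome.

    A gene belongs to a window iff its start coordinate lies inside it
    (unambiguous for boundary-straddling genes).  Windows tile each
    chromosome from position 1 at the given step; hits are ranked by
    flagged count descending, ties by (chrom, start).  ``og_of``
    optionally annotates each window with the contributing OG IDs.

    Returns a table with both 1-based inclusive coordinates and BED-style
    0-based half-open ones.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if step > window_size:
        raise ValueError("step must not exceed window_size")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.gene_id in flagged:
            if g.chrom is None or g.start is None:
                raise ValueError(f"flagged gene {g.gene_id} lacks coordinates")
            by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: g.start)
        starts = np.array([g.start for g in chrom_genes])
        extent = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(starts.max())
        )
        w_start = 1
        while True:
            w_end = w_start + window_size - 1
            lo = int(np.searchsorted(starts, w_start, side="left"))
            hi = int(np.searchsorted(starts, w_end, side="right"))
            in_window = chrom_genes[lo:hi]
            ogs = (
                sorted({og_of[g.gene_id] for g in in_window if g.gene_id in og_of})
                if og_of
                else []
            )
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": w_start,
                    "window_end": w_end,
                    "bed_start": w_start - 1,
                    "bed_end": w_end,
                    "n_flagged_in_window": len(in_window),
                    "contributing_ogs": ",".join(ogs),
                }
            )
            if w_end >= extent:
                break
            w_start += step
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "window_start", "window_end", "bed_start", "bed_end",
            "n_flagged_in_window", "contributing_ogs",
        ],
    )
    if df.empty:
        return df
    return df.sort_values(
        ["n_flagged_in_window", "chrom", "window_start"],
        ascending=[False, True, True],
        ignore_index=True,
    )
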