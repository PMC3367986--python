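"""Transcriptional-activity calls and expression-profile clustering.

Two public transcriptome resources back the activity calls, each with
its own rule: for raw sequence-read data a gene is transcriptionally
active when it has at least two reads in at least one tissue or
developmental stage; for normalized counts any value greater than zero
in at least one condition suffices.  Genes active in flower conditions
are flagged separately.  Profiles are standardised to per-gene Z-scores
and clustered hierarchically (correlation distance, average linkage by
default), and flat clusters can be compared against the OG partition
with the adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

RAW_READS_MIN = 2  # reads in ≥1 condition ⇒ active (raw-read datasets)


@dataclass
class ExpressionMatrix:
    """Genes × conditions of non-negative expression values.

    ``rule_tag`` selects the activity rule (``raw_reads`` or
    ``normalized``); ``flower_conditions`` names the subset of columns
    sampled from flowers.
    """

    values: pd.DataFrame
    rule_tag: str = "raw_reads"
    flower_conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rule_tag not in ("raw_reads", "normalized"):
            raise ValueError(f"unknown rule_tag {self.rule_tag!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or condition labels")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        unknown = set(self.flower_conditions) - set(self.values.columns)
        if unknown:
            raise ValueError(f"unknown flower conditions: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ActivityCall:
    """Per-gene activity verdict under the dataset rule(s)."""

    gene_id: str
    active_raw: bool | None = None
    active_normalized: bool | None = None
    flower_expressed: bool = False

    @property
    def active_any(self) -> bool:
        return bool(self.active_raw) or bool(self.active_normalized)


def _active_mask(values: pd.DataFrame, rule_tag: str) -> pd.Series:
    if rule_tag == "raw_reads":
        return (values >= RAW_READS_MIN).any(axis=1)
    return (values > 0).any(axis=1)


def call_active(matrix: ExpressionMatrix) -> list[ActivityCall]:
    """Call transcriptional activity for every gene under the matrix rule."""
    mask = _active_mask(matrix.values, matrix.rule_tag)
    key = "active_raw" if matrix.rule_tag == "raw_reads" else "active_normalized"
    return [
        ActivityCall(gene_id=g, **{key: bool(mask[g])}) for g in matrix.genes
    ]


def combine_calls(
    per_dataset: Sequence[Sequence[ActivityCall]],
) -> list[ActivityCall]:
    """OR per-dataset calls into one call per gene (union of gene sets)."""
    merged: dict[str, ActivityCall] = {}
    for calls in per_dataset:
        for c in calls:
            m = merged.setdefault(c.gene_id, ActivityCall(gene_id=c.gene_id))
            if c.active_raw is not None:
                m.active_raw = bool(m.active_raw) or c.active_raw
            if c.active_normalized is not None:
                m.active_normalized = (
                    bool(m.active_normalized) or c.active_normalized
                )
            m.flower_expressed = m.flower_expressed or c.flower_expressed
    return list(merged.values())


def flag_flower_expressed(
    calls: Sequence[ActivityCall],
    matrix: ExpressionMatrix,
    flower_conditions: Sequence[str] | None = None,
) -> list[ActivityCall]:
    """Set ``flower_expressed`` from the activity rule restricted to flowers."""
    conditions = tuple(flower_conditions or matrix.flower_conditions)
    unknown = set(conditions) - set(matrix.conditions)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    sub = matrix.values.loc[:, list(conditions)]
    mask = _active_mask(sub, matrix.rule_tag) if conditions else None
    for c in calls:
        if mask is not None and c.gene_id in mask.index:
            c.flower_expressed = c.flower_expressed or bool(mask[c.gene_id])
    return list(calls)


def summarize_activity(calls: Sequence[ActivityCall]) -> dict:
    """Headline activity summary: totals and percentage (1 decimal)."""
    n = len(calls)
    n_active = sum(c.active_any for c in calls)
    n_flower = sum(c.flower_expressed for c in calls)
    return {
        "n_genes": n,
        "n_active": n_active,
        "pct_active": round(100.0 * n_active / n, 1) if n else 0.0,
        "n_flower_expressed": n_flower,
    }


def zscore_rows(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Standardise each gene's profile to mean 0, unit population SD.

    Zero-variance rows map to all-zeros rather than NaN.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("Z-scoring needs at least two conditions")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (divide-by-n)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns)


@dataclass
class Dendrogram:
    """Average/complete-linkage merge tree over genes.

    ``linkage_matrix`` is in scipy's standard (n−1)×4 form; leaf order
    and merge heights are deterministic for a fixed input.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    distance: str
    linkage: str
    zero_variance_rows: list[str] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, height: float) -> dict[str, int]:
        """Flat clusters at a height threshold (cluster IDs from 1)."""
        flat = sch.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return dict(zip(self.labels, (int(i) for i in flat)))

    def cut_k(self, k: int) -> dict[str, int]:
        flat = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(i) for i in flat)))

    def to_newick(self) -> str:
        """Serialise the merge tree as Newick with merge-height branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def render(i: int) -> str:
            if i < n:
                return self.labels[i]
            row = self.linkage_matrix[i - n]
            a, b, h = int(row[0]), int(row[1]), float(row[2])
            heights[i] = h
            return "({}:{:.6g},{}:{:.6g})".format(
                render(a), h - heights[a], render(b), h - heights[b]
            )

        # children rendered before parents: recurse from the final merge
        return render(2 * n - 2) + ";"


def correlation_distance_matrix(values: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Pairwise 1−Pearson distances; zero-variance pairs set to 1."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    d = 1.0 - r
    d[degenerate, :] = 1.0
    d[:, degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    zero_rows = [g for g, bad in zip(values.index, degenerate) if bad]
    return d, zero_rows


def hierarchical_cluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    distance: str = "pearson_correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Hierarchically cluster gene expression profiles.

    Distances: ``pearson_correlation`` (d = 1 − r; zero-variance rows at
    distance 1 from everything, with a warning) or ``euclidean``.
    Linkage: ``average`` or ``complete``.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least two genes")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    zero_rows: list[str] = []
    if distance == "pearson_correlation":
        dmat, zero_rows = correlation_distance_matrix(values)
        if zero_rows:
            warnings.warn(
                f"{len(zero_rows)} zero-variance rows: correlation distance "
                "set to 1 for their pairs",
                stacklevel=2,
            )
        condensed = squareform(dmat, checks=False)
        Z = sch.linkage(condensed, method=linkage)
    elif distance == "euclidean":
        Z = sch.linkage(values.to_numpy(dtype=float), method=linkage)
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    return Dendrogram(
        linkage_matrix=Z,
        labels=list(values.index),
        distance=distance,
        linkage=linkage,
        zero_variance_rows=zero_rows,
    )


def cluster_og_concordance(
    flat_clusters: Mapping[str, int | str],
    og_membership: Mapping[str, str],
) -> float:
    """Adjusted Rand index between an expression partition and the OG map.

    Both partitions must cover exactly the same genes.
    """
    if set(flat_clusters) != set(og_membership):
        raise ValueError("partitions cover different gene sets")
    genes = sorted(flat_clusters)
    a = [flat_clusters[g] for g in genes]
    b = [og_membership[g] for g in genes]
    return float(adjusted_rand_score(a, b))
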