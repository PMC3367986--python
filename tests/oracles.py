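"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library routines the implementation uses:
patristic distances come from explicit root-path walks, linkage from a
naive O(n^3) re-merge, the adjusted Rand index from the contingency
formula, and Fisher p-values from exact hypergeometric enumeration.
"""

from __future__ import annotations

import math

import numpy as np


def brute_patristic(tree, a: str, b: str) -> float:
    """Branch-length sum along the a-b path via root-path walks."""
    dtree = tree.dendropy_tree
    leaves = {lf.taxon.label: lf for lf in dtree.leaf_node_iter()}

    def path(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    pa, pb = path(leaves[a]), path(leaves[b])
    set_a = {id(n) for n in pa}
    mrca = next(n for n in pb if id(n) in set_a)

    def climb(node, stop):
        total = 0.0
        while node is not stop:
            total += node.edge.length or 0.0
            node = node.parent_node
        return total

    return climb(leaves[a], mrca) + climb(leaves[b], mrca)


def brute_informative_clade_leaves(tree, leaf: str) -> set[str]:
    """Leaf set of the smallest clade holding *leaf* and a reference leaf,
    by enumerating every clade of the (rooted) tree."""
    tree.ensure_rooted()
    dtree = tree.dendropy_tree
    best = None
    for node in dtree.preorder_node_iter():
        names = {lf.taxon.label for lf in node.leaf_iter()}
        if leaf in names and any(
            tree.species(n) == "reference" for n in names - {leaf}
        ):
            if best is None or len(names) < len(best):
                best = names
    return best


def brute_classify(tree, leaf: str, flowering: set[str], tol: float = 1e-9) -> str:
    """Re-derive the clade-rule status from a full distance matrix."""
    refs = [n for n in tree.leaf_names if tree.species(n) == "reference"]
    if not refs:
        return "unresolved"
    clade = brute_informative_clade_leaves(tree, leaf)
    clade_flowering = [n for n in clade if n in flowering]
    non_flowering = [n for n in refs if n not in flowering]
    d_other = (
        min(brute_patristic(tree, leaf, n) for n in non_flowering)
        if non_flowering
        else None
    )
    if not clade_flowering:
        return "other_orthologue"
    d_f = min(brute_patristic(tree, leaf, n) for n in clade_flowering)
    if d_other is None or d_f < d_other - tol:
        return "flowering_orthologue"
    return "other_orthologue"


def naive_linkage_cophenetic(d: np.ndarray, method: str) -> np.ndarray:
    """Cophenetic distance matrix from a naive agglomerative re-merge.

    Recomputes the full inter-cluster distance at every step (average or
    complete linkage) and records, for every leaf pair, the height of
    the merge that first unites them.
    """
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                pair_d = [d[a, b] for a in clusters[i] for b in clusters[j]]
                dist = (
                    float(np.mean(pair_d))
                    if method == "average"
                    else float(np.max(pair_d))
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dist
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return coph


def ari_formula(labels_a, labels_b) -> float:
    """Adjusted Rand index straight from the contingency-table formula."""
    table: dict[tuple, int] = {}
    ca: dict[object, int] = {}
    cb: dict[object, int] = {}
    for x, y in zip(labels_a, labels_b):
        table[(x, y)] = table.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    n = len(labels_a)
    sum_ij = sum(math.comb(v, 2) for v in table.values())
    sum_a = sum(math.comb(v, 2) for v in ca.values())
    sum_b = sum(math.comb(v, 2) for v in cb.values())
    total = math.comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Table [[a, b], [c, d]]; margins fixed; sums the probabilities of all
    tables at most as probable as the observed one.
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(
        prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7)
    )


def snp_category_by_scan(pos: int, model, promoter_length: int = 1000) -> str:
    """Exhaustive per-base interval membership for one gene model."""
    in_cds = any(s <= pos <= e for s, e in model.cds)
    in_body = model.start <= pos <= model.end
    if model.strand == "+":
        prom = (max(1, model.start - promoter_length), model.start - 1)
    else:
        prom = (model.end + 1, model.end + promoter_length)
        if model.chrom_length is not None:
            prom = (prom[0], min(prom[1], model.chrom_length))
    in_prom = prom[0] <= pos <= prom[1]
    if in_body and in_cds:
        return "CDS"
    if in_body:
        return "genic_noncoding"
    if in_prom:
        return "promoter"
    return "outside"
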