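"""Clade-based orthologue refinement from per-OG gene trees.

Membership in an OG is coarse: a paleopolyploid target genome often
contributes many paralogues per OG, only some of which are close
orthologues of the reference flowering gene(s).  The refinement rule:
a target gene is a flowering orthologue when it sits in the same clade
as a flowering reference gene, unless some other (non-flowering)
reference gene is equally close or closer.  "Same clade" is
operationalised as the smallest clade containing the target leaf and at
least one reference-species leaf (after midpoint-rooting unrooted
inputs); "closer" is measured by patristic distance, with an absolute
tolerance for equality because branch lengths are floating point.

OGs with fewer than four sequences have no tree (four sequences is the
minimum for tree building); for those, all target members are accepted
as flowering orthologues when the OG's reference members are all listed
flowering genes, and left unresolved otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

from orthoflora.og_assignment import OrthologueGroup
from orthoflora.records import DEFAULT_SPECIES_PREFIXES, infer_species

SMALL_OG_LIMIT = 4
DEFAULT_TOLERANCE = 1e-9


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate leaves...)."""


@dataclass(frozen=True)
class CladeAssignment:
    """Orthology verdict for one target-species gene."""

    target_gene: str
    status: str  # flowering_orthologue | other_orthologue | unresolved
    anchor_reference_genes: frozenset[str] = frozenset()
    min_distance_flowering: float | None = None
    min_distance_other: float | None = None
    via_small_og_rule: bool = False


class PhyloTree:
    """A gene tree with species-labelled leaves and patristic distances.

    Wraps a :class:`dendropy.Tree`.  Missing branch lengths default to 0
    (with a warning), so topology-only trees degrade to clade membership
    without distance tie-breaking.  Internal node labels (bootstrap
    support, out of 1000 replicates in the source trees) are retained
    but never used in classification.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        species_prefixes: Mapping[str, str] | None = None,
    ) -> None:
        self._tree = tree
        self._prefixes = dict(species_prefixes or DEFAULT_SPECIES_PREFIXES)
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NewickParseError(f"duplicate leaf names: {', '.join(dup)}")
        self.leaf_names: list[str] = names
        missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                missing += 1
            elif edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {edge.length} in tree"
                )
        if missing:
            warnings.warn(
                f"{missing} branch lengths missing; defaulting to 0 "
                "(topology-only classification)",
                stacklevel=3,
            )
        self._rooted_for_clades = False
        self._pdm: dendropy.PhylogeneticDistanceMatrix | None = None
        self._leaf_index = {
            lf.taxon.label: lf for lf in tree.leaf_node_iter()
        }

    # -- species -----------------------------------------------------------
    def species(self, leaf_name: str) -> str:
        return infer_species(leaf_name, self._prefixes)

    def leaves_of_species(self, species: str) -> list[str]:
        return [n for n in self.leaf_names if self.species(n) == species]

    # -- structure ---------------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def _node(self, leaf_name: str) -> dendropy.Node:
        try:
            return self._leaf_index[leaf_name]
        except KeyError:
            raise KeyError(f"leaf {leaf_name!r} not in tree") from None

    def support_labels(self) -> dict[int, float]:
        """Internal-node support labels keyed by node id (reporting only)."""
        out: dict[int, float] = {}
        for i, node in enumerate(self._tree.preorder_node_iter()):
            if node.is_leaf():
                continue
            label = node.label
            if label not in (None, ""):
                try:
                    out[i] = float(label)
                except ValueError:
                    pass
        return out

    def ensure_rooted(self) -> None:
        """Midpoint-root if the tree looks unrooted (basal polytomy)."""
        if self._rooted_for_clades:
            return
        root = self._tree.seed_node
        if len(root.child_nodes()) > 2 and len(self.leaf_names) > 2:
            self._tree.reroot_at_midpoint(update_bipartitions=False)
            self._pdm = None
            self._leaf_index = {
                lf.taxon.label: lf for lf in self._tree.leaf_node_iter()
            }
        self._rooted_for_clades = True

    def distance(self, a: str, b: str) -> float:
        """Patristic distance: branch-length sum along the a–b path."""
        if a == b:
            self._node(a)
            return 0.0
        node_a, node_b = self._node(a), self._node(b)
        if self._pdm is None:
            self._pdm = self._tree.phylogenetic_distance_matrix()
        return float(self._pdm.patristic_distance(node_a.taxon, node_b.taxon))


def parse_newick(
    text: str,
    species_prefixes: Mapping[str, str] | None = None,
) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Raises :class:`NewickParseError` on malformed input; the dendropy
    error message carries the offending position.
    """
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick statement must end in ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failure: {exc}") from exc
    return PhyloTree(tree, species_prefixes)


def patristic_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between leaves *a*, *b*."""
    return tree.distance(a, b)


def smallest_informative_clade(tree: PhyloTree, leaf: str) -> dendropy.Node:
    """Smallest clade containing *leaf* and ≥1 reference-species leaf.

    Unrooted inputs are midpoint-rooted first so "clade" is well defined.
    Raises ``ValueError`` when the tree has no reference leaf at all.
    """
    tree.ensure_rooted()
    node = tree._node(leaf)
    while node is not None:
        for lf in node.leaf_iter():
            name = lf.taxon.label
            if name != leaf and tree.species(name) == "reference":
                return node
        node = node.parent_node
    raise ValueError("tree contains no reference-species leaf")


def _clade_leaves(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def classify_target_gene(
    tree: PhyloTree,
    leaf: str,
    flowering_set: set[str],
    tolerance: float = DEFAULT_TOLERANCE,
) -> CladeAssignment:
    """Apply the clade rule to one target-species leaf.

    The leaf is a flowering orthologue when its informative clade holds
    at least one flowering reference leaf strictly closer (beyond
    *tolerance*) than every non-flowering reference leaf anywhere in the
    tree; a non-flowering reference equally close or closer demotes it
    to ``other_orthologue``.  A tree without reference leaves yields
    ``unresolved``.
    """
    if tree.species(leaf) != "target":
        raise ValueError(f"{leaf!r} is not a target-species leaf")
    ref_leaves = tree.leaves_of_species("reference")
    if not ref_leaves:
        return CladeAssignment(target_gene=leaf, status="unresolved")

    clade = smallest_informative_clade(tree, leaf)
    clade_refs = [
        n for n in _clade_leaves(clade) if tree.species(n) == "reference"
    ]
    clade_flowering = [n for n in clade_refs if n in flowering_set]
    nonflowering_all = [n for n in ref_leaves if n not in flowering_set]

    d_other = (
        min(tree.distance(leaf, n) for n in nonflowering_all)
        if nonflowering_all
        else None
    )
    if not clade_flowering:
        return CladeAssignment(
            target_gene=leaf,
            status="other_orthologue",
            min_distance_other=d_other,
        )

    dists = {n: tree.distance(leaf, n) for n in clade_flowering}
    d_flowering = min(dists.values())
    anchors = frozenset(
        n for n, d in dists.items() if d <= d_flowering + tolerance
    )
    if d_other is None or d_flowering < d_other - tolerance:
        status = "flowering_orthologue"
    else:
        status = "other_orthologue"
    return CladeAssignment(
        target_gene=leaf,
        status=status,
        anchor_reference_genes=anchors,
        min_distance_flowering=d_flowering,
        min_distance_other=d_other,
    )


def classify_og(
    og: OrthologueGroup,
    tree: PhyloTree | None,
    flowering_set: set[str],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[CladeAssignment]:
    """Classify every target member of an OG.

    Small OGs (<4 sequences) cannot have trees; their target members are
    all accepted when the OG's reference members are a non-empty subset
    of the flowering list, and all left unresolved otherwise.  Larger
    OGs delegate to :func:`classify_target_gene` per target leaf.
    """
    targets = sorted(og.members.get("target", set()))
    if og.n_sequences < SMALL_OG_LIMIT:
        refs = og.members.get("reference", set())
        if refs and refs <= flowering_set:
            return [
                CladeAssignment(
                    target_gene=g,
                    status="flowering_orthologue",
                    anchor_reference_genes=frozenset(refs),
                    via_small_og_rule=True,
                )
                for g in targets
            ]
        return [
            CladeAssignment(target_gene=g, status="unresolved") for g in targets
        ]
    if tree is None:
        raise ValueError(
            f"OG {og.og_id} has {og.n_sequences} sequences but no tree"
        )
    leaf_set = set(tree.leaf_names)
    return [
        classify_target_gene(tree, g, flowering_set, tolerance)
        for g in targets
        if g in leaf_set
    ]


def assignments_to_rows(
    og_id: str, assignments: Iterable[CladeAssignment]
) -> list[dict]:
    """Flatten assignments for TSV output."""
    return [
        {
            "og_id": og_id,
            "target_gene": a.target_gene,
            "status": a.status,
            "anchor_genes": ",".join(sorted(a.anchor_reference_genes)),
            "d_flowering": a.min_distance_flowering,
            "d_other": a.min_distance_other,
            "via_small_og_rule": a.via_small_og_rule,
        }
        for a in assignments
    ]
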