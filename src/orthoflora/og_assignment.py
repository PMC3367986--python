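"""Orthologue-group (OG) unification.

Two sources of homology are merged into one OG map:

1. the target-species genome annotation, which links each target gene to
   its closest reference-species gene ("annotation links"), and
2. a pre-computed multi-species OG membership table (OrthoMCL-DB style
   ``OG5_*`` identifiers).

A target gene that is annotation-linked to a reference gene inherits
that reference gene's OG; only unlinked genes fall back to their own
membership OG.  A reference gene that has linked target genes but no
membership OG receives a synthesized ID ``OG5_<locus>`` so its linked
genes still form a group.  OGs containing at least one listed flowering
gene are flagged, and reference members not on the list are reported as
"additional" genes riding along in flowering OGs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from orthoflora.records import infer_species

SYNTHESIZED_PREFIX = "OG5_"
_SOURCE_ORDER = ("link", "membership", "synthesized")


@dataclass(frozen=True)
class AnnotationLink:
    """A target gene's annotation link to its closest reference gene."""

    target_gene: str
    reference_gene: str


@dataclass
class OrthologueGroup:
    """An OG ID with per-species member sets and flowering annotation."""

    og_id: str
    members: dict[str, set[str]] = field(default_factory=dict)
    is_synthetic_id: bool = False
    contains_flowering: bool = False
    additional_reference_genes: set[str] = field(default_factory=set)

    def species_count(self, species: str) -> int:
        return len(self.members.get(species, set()))

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self.members.values())


class AssignmentError(ValueError):
    """Raised on malformed link tables or ID collisions."""


def select_longest_isoform(
    isoforms_by_locus: Mapping[str, Sequence[tuple[str, str]]],
) -> dict[str, tuple[str, str]]:
    """Pick one protein isoform per locus: the longest sequence.

    Length ties are broken by the lexicographically smallest isoform ID,
    so the selection is deterministic.

    Parameters
    ----------
    isoforms_by_locus
        Locus → list of ``(isoform_id, sequence)`` pairs.

    Returns
    -------
    dict
        Locus → the selected ``(isoform_id, sequence)`` pair.
    """
    selected: dict[str, tuple[str, str]] = {}
    for locus, isoforms in isoforms_by_locus.items():
        if not isoforms:
            raise AssignmentError(f"locus {locus!r} has no isoforms")
        selected[locus] = min(isoforms, key=lambda it: (-len(it[1]), it[0]))
    return selected


def group_isoforms(records: Iterable[tuple[str, str]]) -> dict[str, list[tuple[str, str]]]:
    """Group ``(sequence_id, sequence)`` pairs by locus.

    The locus is the sequence ID up to the last ``.``; IDs without a dot
    are their own locus (the convention of the source proteomes, where
    splice variants are ``<locus>.1``, ``<locus>.2`` ...).
    """
    by_locus: dict[str, list[tuple[str, str]]] = {}
    for seq_id, seq in records:
        locus = seq_id.rsplit(".", 1)[0] if "." in seq_id else seq_id
        by_locus.setdefault(locus, []).append((seq_id, seq))
    return by_locus


def merge_og_assignments(
    links: Sequence[AnnotationLink],
    memberships: Mapping[str, str],
    known_genes: Iterable[str] | None = None,
) -> tuple[dict[str, tuple[str, str]], list[str], list[str]]:
    """Unify annotation links with membership OGs into one OG map.

    Precedence: a linked target gene inherits its reference gene's OG
    (source ``link``) even when it has its own membership; unlinked genes
    keep their membership OG (source ``membership``).  A reference gene
    with links but no membership is assigned the synthesized ID
    ``OG5_<locus>`` (source ``synthesized``) and its linked genes join it.

    Parameters
    ----------
    links
        Annotation links; at most one per target gene.
    memberships
        Gene ID → OG ID from the pre-computed membership table.
    known_genes
        Optional gene universe.  When given, genes in it with neither a
        link nor a membership are reported unassigned, and a link naming
        a gene outside it is an error.

    Returns
    -------
    (assignments, synthesized, unassigned)
        ``assignments``: gene ID → ``(og_id, source)``;
        ``synthesized``: the synthesized OG IDs, sorted;
        ``unassigned``: known genes with neither link nor membership.
    """
    universe = set(known_genes) if known_genes is not None else None
    seen_targets: set[str] = set()
    for link in links:
        if link.target_gene in seen_targets:
            raise AssignmentError(
                f"target gene {link.target_gene} has more than one link"
            )
        seen_targets.add(link.target_gene)
        if universe is not None:
            for gid in (link.target_gene, link.reference_gene):
                if gid not in universe:
                    raise AssignmentError(f"link names unknown gene {gid}")

    assignments: dict[str, tuple[str, str]] = {
        gid: (og, "membership") for gid, og in memberships.items()
    }
    synthesized: set[str] = set()
    existing_ogs = set(memberships.values())

    for link in links:
        ref_og = memberships.get(link.reference_gene)
        if ref_og is None:
            ref_og = SYNTHESIZED_PREFIX + link.reference_gene
            if ref_og in existing_ogs:
                raise AssignmentError(
                    f"synthesized OG ID {ref_og} collides with an input OG ID"
                )
            synthesized.add(ref_og)
            assignments[link.reference_gene] = (ref_og, "synthesized")
        assignments[link.target_gene] = (ref_og, "link")

    unassigned: list[str] = []
    if universe is not None:
        unassigned = sorted(universe - assignments.keys())
    return assignments, sorted(synthesized), unassigned


def build_ogs(
    assignments: Mapping[str, tuple[str, str]],
    species_of: Mapping[str, str] | None = None,
) -> list[OrthologueGroup]:
    """Group an assignment map into :class:`OrthologueGroup` objects.

    Species defaults to prefix inference when *species_of* is omitted.
    """
    by_og: dict[str, OrthologueGroup] = {}
    for gene_id, (og_id, _source) in assignments.items():
        og = by_og.setdefault(og_id, OrthologueGroup(og_id=og_id))
        species = (
            species_of[gene_id] if species_of is not None else infer_species(gene_id)
        )
        og.members.setdefault(species, set()).add(gene_id)
    for og in by_og.values():
        og.is_synthetic_id = bool(
            re.fullmatch(re.escape(SYNTHESIZED_PREFIX) + r"AT\w+", og.og_id)
        )
    return sorted(by_og.values(), key=lambda og: og.og_id)


def flag_flowering_ogs(
    ogs: Sequence[OrthologueGroup],
    flowering_list: set[str],
) -> tuple[list[OrthologueGroup], dict[str, int], list[str]]:
    """Flag OGs containing listed flowering genes; tabulate the summary.

    An OG is flagged when at least one of its reference-species members
    is on the flowering list; its other reference members become
    ``additional_reference_genes``.  Listed genes found in no OG are
    returned as orphans (not an error — the membership table does not
    cover every reference gene).

    Returns
    -------
    (ogs, summary, orphans)
        The OGs annotated in place; summary counts
        (``n_flowering_genes``, ``n_flowering_ogs``,
        ``n_additional_genes``, ``n_target_genes``); orphan listed genes.
    """
    found: set[str] = set()
    n_additional = 0
    n_target = 0
    for og in ogs:
        refs = og.members.get("reference", set())
        listed = refs & flowering_list
        og.contains_flowering = bool(listed)
        og.additional_reference_genes = (refs - flowering_list) if listed else set()
        if listed:
            found |= listed
            n_additional += len(og.additional_reference_genes)
            n_target += og.species_count("target")
    orphans = sorted(flowering_list - found)
    summary = {
        "n_flowering_genes": len(found),
        "n_flowering_ogs": sum(og.contains_flowering for og in ogs),
        "n_additional_genes": n_additional,
        "n_target_genes": n_target,
    }
    return list(ogs), summary, orphans


def og_count_table(ogs: Sequence[OrthologueGroup]) -> pd.DataFrame:
    """Per-OG reference/target member counts, sorted by OG ID."""
    rows = [
        {
            "og_id": og.og_id,
            "n_reference": og.species_count("reference"),
            "n_target": og.species_count("target"),
        }
        for og in ogs
    ]
    df = pd.DataFrame(rows, columns=["og_id", "n_reference", "n_target"])
    return df.sort_values("og_id", ignore_index=True)


def assignments_frame(
    assignments: Mapping[str, tuple[str, str]],
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assignment map as a tidy table (gene_id, species, og_id, source)."""
    rows = [
        {
            "gene_id": gid,
            "species": species_of[gid] if species_of else infer_species(gid),
            "og_id": og,
            "source": source,
        }
        for gid, (og, source) in assignments.items()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "species", "og_id", "source"])
    df["source"] = pd.Categorical(df["source"], categories=list(_SOURCE_ORDER))
    return df.sort_values(["og_id", "gene_id"], ignore_index=True)
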