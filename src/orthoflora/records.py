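"""Gene records and species inference from gene-ID prefixes.

Gene identifiers in the source annotations are species-stable: Arabidopsis
loci start with ``AT`` (the reference species here), soybean loci with
``Glyma`` (the target species), and the outgroup genomes carry their own
prefixes (``Alyr_`` for A. lyrata, ``Bradi`` for Brachypodium, ``Medtr``
and ``AC`` for Medicago).  Species is therefore inferable from the ID when
not given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default prefix table; longest prefix wins, matching is case-sensitive.
DEFAULT_SPECIES_PREFIXES: dict[str, str] = {
    "AT": "reference",
    "Glyma": "target",
    "Alyr_": "other:lyrata",
    "Bradi": "other:brachypodium",
    "Medtr": "other:medicago",
    "AC": "other:medicago",
}


def infer_species(gene_id: str, prefixes: dict[str, str] | None = None) -> str:
    """Infer the species label of *gene_id* from its prefix.

    Parameters
    ----------
    gene_id
        Gene identifier, e.g. ``AT2G33835`` or ``Glyma16g32080``.
    prefixes
        Prefix → species map; defaults to :data:`DEFAULT_SPECIES_PREFIXES`.
        The longest matching prefix wins (so ``AT`` never shadows a longer
        user-supplied prefix), and matching is case-sensitive.

    Returns
    -------
    str
        ``"reference"``, ``"target"`` or an ``"other:<label>"`` tag.

    Raises
    ------
    ValueError
        If no prefix matches.
    """
    table = DEFAULT_SPECIES_PREFIXES if prefixes is None else prefixes
    best: str | None = None
    best_len = -1
    for prefix, species in table.items():
        if gene_id.startswith(prefix) and len(prefix) > best_len:
            best, best_len = species, len(prefix)
    if best is None:
        raise ValueError(f"cannot infer species for gene ID {gene_id!r}")
    return best


@dataclass
class GeneRecord:
    """One gene: identifier, species, optional chromosomal interval.

    Coordinates are 1-based inclusive (GFF3 convention).  The flags mark
    membership in the reference flowering-gene list and in a
    paralogue-rich OG respectively.
    """

    gene_id: str
    species: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    is_flowering_listed: bool = False
    is_paralogue_rich: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.species is None:
            self.species = infer_species(self.gene_id)
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
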