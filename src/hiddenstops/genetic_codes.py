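"""NCBI genetic code tables and derived structures.

Every analysis in this package is parameterised by a genetic code: the set
of stop codons differs between codes (the vertebrate mitochondrial code,
for instance, reads AGA/AGG as stops), and with it every downstream
quantity — which off-frame triplets count as hidden stops, which codons
form synonymous families, which codons are excluded from adaptation
indices.

Tables are sourced from Biopython's bundled copy of the NCBI translation
tables (``Bio.Data.CodonTable``); no network access is involved. The
shipped subset covers the nuclear and organellar codes in common use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STOP_SYMBOL",
    "BASES",
    "ALL_CODONS",
    "SHIPPED_TABLE_IDS",
    "GeneticCodeTable",
    "get_genetic_code",
    "available_tables",
    "synonymous_families",
    "sense_codons",
]

STOP_SYMBOL = "*"
BASES = "ACGT"
#: All 64 DNA codons in lexicographic order (the canonical ordering used
#: by every tabular output in this package).
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

#: NCBI translation-table identifiers shipped with this package.
SHIPPED_TABLE_IDS: tuple[int, ...] = (
    1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 13, 14, 15, 16, 21, 22, 23, 24, 25,
)


@dataclass(frozen=True)
class GeneticCodeTable:
    """One NCBI translation table, with the structures analyses need.

    Attributes
    ----------
    table_id : int
        NCBI translation-table number.
    name : str
        NCBI's descriptive name for the table.
    codon_map : Mapping[str, str]
        All 64 DNA codons (uppercase, ``T`` not ``U``) mapped to a
        single-letter amino acid, or ``"*"`` for stop codons.
    stop_set : frozenset[str]
        The stop codons of this table (the preimage of ``"*"``).
    start_set : frozenset[str]
        Initiation codons; informational only. May overlap ``stop_set``
        in some tables — no disjointness is assumed anywhere.
    """

    table_id: int
    name: str
    codon_map: Mapping[str, str]
    stop_set: frozenset[str]
    start_set: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValueError(
                f"codon_map must cover all 64 codons, got {len(self.codon_map)}"
            )
        preimage = frozenset(
            c for c, aa in self.codon_map.items() if aa == STOP_SYMBOL
        )
        if preimage != self.stop_set:
            raise ValueError("stop_set must equal the preimage of the stop symbol")
        if not self.stop_set:
            raise ValueError("stop_set must be non-empty")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_set

    def translate_codon(self, codon: str) -> str:
        """Amino acid (or ``"*"``) for one uppercase DNA codon."""
        return self.codon_map[codon]


@lru_cache(maxsize=None)
def get_genetic_code(table_id: int) -> GeneticCodeTable:
    """Return the shipped :class:`GeneticCodeTable` for an NCBI table id.

    Raises
    ------
    ValueError
        If ``table_id`` is not among :data:`SHIPPED_TABLE_IDS`; the message
        lists the available identifiers.
    """
    if table_id not in SHIPPED_TABLE_IDS:
        raise ValueError(
            f"unknown translation table {table_id!r}; "
            f"available tables: {', '.join(map(str, SHIPPED_TABLE_IDS))}"
        )
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    codon_map = {c: bio.forward_table.get(c, STOP_SYMBOL) for c in ALL_CODONS}
    return GeneticCodeTable(
        table_id=table_id,
        name=bio.names[0] if bio.names else f"table {table_id}",
        codon_map=MappingProxyType(codon_map),
        stop_set=frozenset(bio.stop_codons),
        start_set=frozenset(bio.start_codons),
    )


def available_tables() -> list[GeneticCodeTable]:
    """All shipped tables, ordered by table id."""
    return [get_genetic_code(i) for i in SHIPPED_TABLE_IDS]


def synonymous_families(code: GeneticCodeTable) -> dict[str, frozenset[str]]:
    """Partition the 64 codons into synonymous families.

    Returns a map amino-acid letter -> frozenset of codons; the stop
    codons form their own family under the key ``"*"``. The family sets
    partition the codon space exactly.
    """
    fams: dict[str, set[str]] = {}
    for codon, aa in code.codon_map.items():
        fams.setdefault(aa, set()).add(codon)
    return {aa: frozenset(cs) for aa, cs in fams.items()}


def sense_codons(code: GeneticCodeTable) -> tuple[str, ...]:
    """The non-stop codons of ``code``, in lexicographic order."""
    return tuple(c for c in ALL_CODONS if c not in code.stop_set)
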