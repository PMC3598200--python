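"""Reading and validating coding DNA sequences.

Input is one or more coding sequences (CDSs), from FASTA files/streams or
raw strings. Sequences are normalised on construction: whitespace
stripped, case folded to upper, RNA ``U`` transliterated to ``T``. The
alphabet is the IUPAC nucleotide set; anything else is rejected with its
position. Validation of a CDS against a genetic code never rejects — it
only flags (length not divisible by 3, internal in-frame stops, ambiguity
codes), because users legitimately submit partial CDSs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .genetic_codes import BASES, GeneticCodeTable

__all__ = [
    "IUPAC_NUCLEOTIDES",
    "CodingSequence",
    "coding_sequence",
    "read_fasta",
    "write_fasta",
    "validate_cds",
    "ValidationReport",
    "validation_table",
]

#: IUPAC nucleotide one-letter codes (DNA alphabet plus ambiguity letters).
IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHV")

_ACGT = frozenset(BASES)


def _normalise(raw: str, seq_id: str) -> str:
    seq = "".join(raw.split()).upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_NUCLEOTIDES:
            raise ValueError(
                f"sequence {seq_id!r}: invalid character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding DNA sequence with its in-frame codon split.

    ``codons`` are the complete triplets starting at nucleotide 0;
    ``trailing_len`` (0-2) nucleotides are retained in ``sequence`` but
    excluded from ``codons``. All coordinates in this package are 0-based,
    half-open.
    """

    seq_id: str
    sequence: str

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3))

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def trailing_len(self) -> int:
        return len(self.sequence) % 3

    @property
    def has_trailing(self) -> bool:
        """True when a partial codon trails the in-frame decomposition."""
        return self.trailing_len != 0

    def clean_codons(self) -> tuple[str, ...]:
        """In-frame codons containing only A/C/G/T (masked codons dropped)."""
        return tuple(c for c in self.codons if set(c) <= _ACGT)

    def __len__(self) -> int:
        return len(self.sequence)


def coding_sequence(sequence: str, seq_id: str = "seq") -> CodingSequence:
    """Build a :class:`CodingSequence` from a raw string, normalising it."""
    seq = _normalise(sequence, seq_id)
    if not seq:
        raise ValueError(f"sequence {seq_id!r} is empty")
    return CodingSequence(seq_id=seq_id, sequence=seq)


def read_fasta(source: Union[str, PathLike, TextIO]) -> list[CodingSequence]:
    """Read all records of a FASTA file or text stream, order preserved.

    Raises on empty input, on a record with an empty sequence, and on
    characters outside the IUPAC nucleotide codes (with position).
    """
    if isinstance(source, (str, PathLike)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("no FASTA records found in input")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        out.append(coding_sequence(str(rec.seq), seq_id=rec.id))
    return out


def write_fasta(seqs: Iterable[CodingSequence], dest: Union[str, PathLike, TextIO],
                width: int = 60) -> None:
    """Write sequences as FASTA (fixed line wrapping, uppercase DNA)."""
    if isinstance(dest, (str, PathLike)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for s in seqs:
            handle.write(f">{s.seq_id}\n")
            for i in range(0, len(s.sequence), width):
                handle.write(s.sequence[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


@dataclass(frozen=True)
class ValidationReport:
    """Flags-only report for one CDS under one genetic code."""

    seq_id: str
    length: int
    n_codons: int
    divisible_by_3: bool
    internal_stops: tuple[tuple[int, str], ...]  # (codon index, codon)
    ambiguity_count: int
    masked_codons: int


def validate_cds(seq: CodingSequence, code: GeneticCodeTable) -> ValidationReport:
    """Check a CDS against a genetic code; flags only, never rejects.

    Internal in-frame stops are stops at codon indices 0..n-2; a terminal
    stop (the last codon) is the expected CDS terminator and is not
    flagged. Ambiguity letters are counted per nucleotide; codons
    containing any are tallied as masked (they are excluded from every
    counting operation downstream).
    """
    codons = seq.codons
    internal = tuple(
        (i, c) for i, c in enumerate(codons[:-1]) if c in code.stop_set
    )
    ambiguity = sum(1 for ch in seq.sequence if ch not in _ACGT)
    masked = sum(1 for c in codons if not set(c) <= _ACGT)
    return ValidationReport(
        seq_id=seq.seq_id,
        length=len(seq.sequence),
        n_codons=len(codons),
        divisible_by_3=seq.trailing_len == 0,
        internal_stops=internal,
        ambiguity_count=ambiguity,
        masked_codons=masked,
    )


def validation_table(reports: Iterable[ValidationReport]) -> pd.DataFrame:
    """Tabulate validation reports (one row per sequence) for TSV output."""
    rows = [
        {
            "seq_id": r.seq_id,
            "length": r.length,
            "n_codons": r.n_codons,
            "divisible_by_3": int(r.divisible_by_3),
            "internal_stops": len(r.internal_stops),
            "internal_stop_positions": ";".join(
                f"{i}:{c}" for i, c in r.internal_stops
            ),
            "ambiguity_count": r.ambiguity_count,
            "masked_codons": r.masked_codons,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
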