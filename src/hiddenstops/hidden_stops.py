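"""Hidden stop codon scanning and per-codon contribution scores.

A hidden stop codon (HSC, also "off-frame stop") is a stop-codon triplet
read in the +1 or -1 shifted register of a coding sequence. Under the
ambush hypothesis these triplets terminate accidentally frameshifted
ribosomes early, so their abundance is of evolutionary interest.

Frame conventions for a bare linear CDS (no upstream context available):

* +1 frame: triplets starting at nucleotide offsets 1, 4, 7, ...
* -1 frame: realised as offset +2 within the same linear sequence
  (offsets 2, 5, 8, ...), the standard surrogate for the -1 register.

Only complete triplets inside the sequence are scanned, and triplets
containing non-ACGT letters are masked out of both the stop count and the
position denominator, so ``hsc_frequency`` is a rate per scanned
off-frame position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .genetic_codes import ALL_CODONS, GeneticCodeTable
from .sequence_io import CodingSequence

__all__ = [
    "Frame",
    "HiddenStop",
    "HiddenStopReport",
    "find_hidden_stops",
    "count_offframe_positions",
    "half_gene_analysis",
    "codon_contribution_scores",
    "hidden_stop_report",
    "hsc_summary",
    "summary_table",
    "records_table",
    "contribution_table",
]

Frame = Literal[1, -1]
FRAMES: tuple[Frame, ...] = (1, -1)

_ACGT = frozenset("ACGT")

#: Nucleotide offset at which each shifted frame's triplets start.
_FRAME_OFFSET: dict[int, int] = {1: 1, -1: 2}


@dataclass(frozen=True)
class HiddenStop:
    """One off-frame stop triplet: 0-based start offset, triplet, frame."""

    start_nt: int
    triplet: str
    frame: Frame


def _scan(sequence: str, code: GeneticCodeTable, frame: Frame):
    """Yield (records, n_clean_positions) for one shifted frame."""
    offset = _FRAME_OFFSET[frame]
    records: list[HiddenStop] = []
    n_positions = 0
    for start in range(offset, len(sequence) - 2, 3):
        triplet = sequence[start : start + 3]
        if not set(triplet) <= _ACGT:
            continue
        n_positions += 1
        if triplet in code.stop_set:
            records.append(HiddenStop(start_nt=start, triplet=triplet, frame=frame))
    return records, n_positions


def find_hidden_stops(
    seq: CodingSequence, code: GeneticCodeTable, frame: Frame
) -> list[HiddenStop]:
    """All hidden stops of ``seq`` in one shifted frame, sorted by start.

    A sequence shorter than 4 nt has no complete off-frame triplet and
    yields an empty list (not an error).
    """
    if frame not in _FRAME_OFFSET:
        raise ValueError(f"frame must be +1 or -1, got {frame!r}")
    records, _ = _scan(seq.sequence, code, frame)
    return records


def count_offframe_positions(seq: CodingSequence, frame: Frame) -> int:
    """Number of complete, ACGT-clean triplets scanned in one frame."""
    offset = _FRAME_OFFSET[frame]
    return sum(
        1
        for start in range(offset, len(seq.sequence) - 2, 3)
        if set(seq.sequence[start : start + 3]) <= _ACGT
    )


@dataclass(frozen=True)
class HiddenStopReport:
    """Per-sequence hidden-stop summary across both shifted frames."""

    seq_id: str
    records: Mapping[Frame, tuple[HiddenStop, ...]]
    n_offframe_positions: Mapping[Frame, int]
    half_gene: Mapping[Frame, tuple[int, int]] | None

    def count(self, frame: Frame) -> int:
        return len(self.records[frame])

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.records.values())

    def hsc_frequency(self, frame: Frame) -> float:
        n = self.n_offframe_positions[frame]
        return len(self.records[frame]) / n if n else 0.0

    @property
    def total_frequency(self) -> float:
        """Both-frame stop count per scanned off-frame position."""
        n = sum(self.n_offframe_positions.values())
        return self.total / n if n else 0.0


def half_gene_analysis(
    seq: CodingSequence, code: GeneticCodeTable
) -> dict[Frame, tuple[int, int]]:
    """Hidden-stop counts split between the two halves of the gene.

    The gene is divided into codons; the first half is codons
    ``[0, n//2)`` and the second half the rest. Each hidden stop is
    assigned to the half containing its starting nucleotide. Returns
    ``{frame: (first_half, second_half)}``.
    """
    n = seq.n_codons
    if n < 2:
        raise ValueError("sequence too short for half-gene analysis (need >= 2 codons)")
    boundary_nt = 3 * (n // 2)
    out: dict[Frame, tuple[int, int]] = {}
    for frame in FRAMES:
        stops = find_hidden_stops(seq, code, frame)
        first = sum(1 for s in stops if s.start_nt < boundary_nt)
        out[frame] = (first, len(stops) - first)
    return out


def codon_contribution_scores(code: GeneticCodeTable) -> dict[str, int]:
    """How many ways each codon can supply part of an off-frame stop.

    Consider a dicodon junction (two adjacent in-frame codons). A shifted
    stop triplet ``S`` straddles the junction in one of four ways, and a
    codon ``c = n1 n2 n3`` contributes when:

    * left partner, +1 frame: ``n2 n3 == S[0:2]``
    * right partner, +1 frame: ``n1 == S[2]``
    * left partner, -1 frame: ``n3 == S[0]``
    * right partner, -1 frame: ``n1 n2 == S[1:3]``

    The score of ``c`` is the number of (stop, role) pairs it matches —
    an operationalisation of the "contribution of codons to hidden stops"
    idea; the score depends only on the code's stop set.
    """
    scores: dict[str, int] = {}
    for c in ALL_CODONS:
        n = 0
        for s in sorted(code.stop_set):
            if c[1:3] == s[0:2]:
                n += 1
            if c[0] == s[2]:
                n += 1
            if c[2] == s[0]:
                n += 1
            if c[0:2] == s[1:3]:
                n += 1
        scores[c] = n
    return scores


def hidden_stop_report(
    seq: CodingSequence, code: GeneticCodeTable, half_gene: bool = True
) -> HiddenStopReport:
    """Full hidden-stop report for one sequence (both frames)."""
    records = {}
    n_pos = {}
    for frame in FRAMES:
        recs, npos = _scan(seq.sequence, code, frame)
        records[frame] = tuple(recs)
        n_pos[frame] = npos
    halves = None
    if half_gene and seq.n_codons >= 2:
        halves = half_gene_analysis(seq, code)
    return HiddenStopReport(
        seq_id=seq.seq_id,
        records=records,
        n_offframe_positions=n_pos,
        half_gene=halves,
    )


def hsc_summary(
    seqs: Iterable[CodingSequence], code: GeneticCodeTable, half_gene: bool = True
) -> list[HiddenStopReport]:
    """One report per sequence, input order preserved."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("hsc_summary requires at least one sequence")
    return [hidden_stop_report(s, code, half_gene=half_gene) for s in seqs]


def summary_table(reports: Iterable[HiddenStopReport]) -> pd.DataFrame:
    """Per-sequence summary rows plus a TOTAL aggregate row."""
    rows = []
    for r in reports:
        row = {
            "seq_id": r.seq_id,
            "hsc_plus1": r.count(1),
            "hsc_minus1": r.count(-1),
            "hsc_total": r.total,
            "n_pos_plus1": r.n_offframe_positions[1],
            "n_pos_minus1": r.n_offframe_positions[-1],
            "freq_plus1": r.hsc_frequency(1),
            "freq_minus1": r.hsc_frequency(-1),
        }
        if r.half_gene is not None:
            row.update(
                first_half_plus1=r.half_gene[1][0],
                second_half_plus1=r.half_gene[1][1],
                first_half_minus1=r.half_gene[-1][0],
                second_half_minus1=r.half_gene[-1][1],
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"seq_id": "TOTAL"}
    for col in df.columns:
        if col.startswith(("hsc_", "n_pos_", "first_half", "second_half")):
            total[col] = df[col].sum()
    if total.get("n_pos_plus1"):
        total["freq_plus1"] = total["hsc_plus1"] / total["n_pos_plus1"]
    if total.get("n_pos_minus1"):
        total["freq_minus1"] = total["hsc_minus1"] / total["n_pos_minus1"]
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def records_table(reports: Iterable[HiddenStopReport]) -> pd.DataFrame:
    """Flat per-stop table: seq_id, frame, start_nt, triplet."""
    rows = [
        {"seq_id": r.seq_id, "frame": frame, "start_nt": s.start_nt,
         "triplet": s.triplet}
        for r in reports
        for frame in FRAMES
        for s in r.records[frame]
    ]
    return pd.DataFrame(rows, columns=["seq_id", "frame", "start_nt", "triplet"])


def contribution_table(code: GeneticCodeTable) -> pd.DataFrame:
    """Codon-contribution scores as a two-column table."""
    scores = codon_contribution_scores(code)
    return pd.DataFrame(
        {"codon": list(ALL_CODONS), "contribution": [scores[c] for c in ALL_CODONS]}
    )
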