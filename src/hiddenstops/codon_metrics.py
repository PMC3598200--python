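"""Codon usage frequencies, RSCU, relative adaptiveness and CAI.

Definitions (the Sharp & Li conventions):

* codon usage frequency (CUF): the fraction of counted in-frame codon
  occurrences attributable to each codon;
* RSCU(c) = count(c) / mean count over c's synonymous family — 1 means no
  bias within the family;
* relative adaptiveness w(c) = count(c) / max count in c's family, so the
  preferred codon of every family has w = 1;
* CAI of a gene = geometric mean of w over its codons, in (0, 1], higher
  meaning closer conformance to the reference usage.

CAI excludes stop codons and single-codon families (Met/Trp under the
standard code carry no choice and would only dilute the index), and is
computed in log space so long genes do not underflow. Codons absent from
the reference receive a small floor w (default 0.01) rather than zero,
which would annihilate the geometric mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Iterable, Mapping, Union

import pandas as pd

from .genetic_codes import (
    ALL_CODONS,
    STOP_SYMBOL,
    GeneticCodeTable,
    synonymous_families,
)
from .sequence_io import CodingSequence

__all__ = [
    "CodonUsageTable",
    "codon_usage",
    "rscu",
    "relative_adaptiveness",
    "cai",
    "read_usage_tsv",
    "write_usage_tsv",
    "usage_metrics_table",
]

#: Default relative-adaptiveness floor for zero-count codons.
W_FLOOR = 0.01


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon counts with derived frequencies and optional w scores.

    ``frequencies`` sum to 1 over codons with positive count;
    ``w`` is filled by :func:`relative_adaptiveness` (it needs a genetic
    code to define the synonymous families).
    """

    counts: Mapping[str, float]
    source: str = ""
    w: Mapping[str, float] | None = None

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            raise ValueError("usage table has no counts")
        return {c: self.counts.get(c, 0.0) / tot for c in ALL_CODONS}

    def frequency(self, codon: str) -> float:
        return self.counts.get(codon, 0.0) / self.total

    def with_w(self, code: GeneticCodeTable, floor: float = W_FLOOR
               ) -> "CodonUsageTable":
        """Copy of the table with relative adaptiveness attached."""
        return replace(self, w=relative_adaptiveness(self, code, floor=floor))


def codon_usage(
    seqs: Iterable[CodingSequence],
    code: GeneticCodeTable,
    exclude_terminal_stop: bool = True,
) -> CodonUsageTable:
    """Pooled in-frame codon counts over one or more sequences.

    Masked codons (containing non-ACGT letters) are never counted. When
    ``exclude_terminal_stop`` is set (the default), the final codon of a
    sequence is dropped if it is a stop of ``code`` — the CDS terminator
    is not "usage".
    """
    counts: dict[str, int] = {}
    n_seqs = 0
    for seq in seqs:
        n_seqs += 1
        codons = list(seq.codons)
        if exclude_terminal_stop and codons and codons[-1] in code.stop_set:
            codons = codons[:-1]
        for c in codons:
            if set(c) <= frozenset("ACGT"):
                counts[c] = counts.get(c, 0) + 1
    if n_seqs == 0:
        raise ValueError("codon_usage requires at least one sequence")
    if not counts:
        raise ValueError("no countable codons in input sequences")
    return CodonUsageTable(counts=counts, source=f"pooled from {n_seqs} sequence(s)")


def rscu(table: CodonUsageTable, code: GeneticCodeTable) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    Families whose total count is zero have undefined RSCU and are simply
    absent from the result.
    """
    out: dict[str, float] = {}
    for aa, fam in synonymous_families(code).items():
        fam_counts = {c: table.counts.get(c, 0.0) for c in fam}
        tot = sum(fam_counts.values())
        if tot == 0:
            continue
        mean = tot / len(fam)
        for c, n in fam_counts.items():
            out[c] = n / mean
    return out


def relative_adaptiveness(
    table: CodonUsageTable, code: GeneticCodeTable, floor: float = W_FLOOR
) -> dict[str, float]:
    """w(c) = count(c) / max count in c's synonymous family.

    Stop codons are excluded. Zero-count codons are floored at ``floor``
    so a downstream geometric mean cannot collapse to zero; a family with
    no counts at all gets the floor throughout, with a warning.
    """
    if not 0 < floor <= 1:
        raise ValueError("floor must be in (0, 1]")
    out: dict[str, float] = {}
    empty_families: list[str] = []
    for aa, fam in synonymous_families(code).items():
        if aa == STOP_SYMBOL:
            continue
        fam_counts = {c: table.counts.get(c, 0.0) for c in fam}
        m = max(fam_counts.values())
        if m == 0:
            empty_families.append(aa)
            for c in fam:
                out[c] = floor
            continue
        for c, n in fam_counts.items():
            out[c] = max(n / m, floor)
    if empty_families:
        warnings.warn(
            f"synonymous families {sorted(empty_families)} have zero total "
            f"count; all their codons get the floor w = {floor}",
            stacklevel=2,
        )
    return out


def cai(
    gene: CodingSequence,
    reference: CodonUsageTable,
    code: GeneticCodeTable,
    floor: float = W_FLOOR,
) -> float:
    """Codon adaptation index of ``gene`` against a reference usage table.

    Geometric mean (computed in log space) of w over the gene's eligible
    codons: in-frame, ACGT-clean, not a stop codon, and not a member of a
    single-codon family. Raises if no codon is eligible.
    """
    w = reference.w if reference.w is not None else relative_adaptiveness(
        reference, code, floor=floor
    )
    fams = synonymous_families(code)
    singletons = {
        next(iter(f)) for aa, f in fams.items()
        if aa != STOP_SYMBOL and len(f) == 1
    }
    log_sum = 0.0
    n = 0
    for c in gene.clean_codons():
        if c in code.stop_set or c in singletons:
            continue
        log_sum += math.log(w[c])
        n += 1
    if n == 0:
        raise ValueError(
            f"gene {gene.seq_id!r} has no eligible codons for CAI"
        )
    return math.exp(log_sum / n)


def read_usage_tsv(source: Union[str, PathLike]) -> CodonUsageTable:
    """Read a codon/count TSV: two columns ``codon<TAB>count``.

    A header row is optional; RNA letters (U) are accepted and folded to
    DNA. Counts must be non-negative numbers.
    """
    counts: dict[str, float] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected 'codon<TAB>count'")
            codon = parts[0].upper().replace("U", "T")
            if lineno == 1 and codon not in ALL_CODONS:
                continue  # header row
            if codon not in ALL_CODONS:
                raise ValueError(f"line {lineno}: {parts[0]!r} is not a codon")
            value = float(parts[1])
            if value < 0:
                raise ValueError(f"line {lineno}: negative count {value}")
            counts[codon] = counts.get(codon, 0.0) + value
    if not counts:
        raise ValueError("usage TSV contains no codon counts")
    return CodonUsageTable(counts=counts, source=str(source))


def write_usage_tsv(table: CodonUsageTable, dest: Union[str, PathLike]) -> None:
    with open(dest, "w") as fh:
        fh.write("codon\tcount\n")
        for c in ALL_CODONS:
            fh.write(f"{c}\t{table.counts.get(c, 0)}\n")


def usage_metrics_table(
    table: CodonUsageTable, code: GeneticCodeTable, floor: float = W_FLOOR
) -> pd.DataFrame:
    """Per-codon table of count, frequency, RSCU and w (64 rows)."""
    freqs = table.frequencies
    r = rscu(table, code)
    w = relative_adaptiveness(table, code, floor=floor)
    return pd.DataFrame(
        {
            "codon": list(ALL_CODONS),
            "amino_acid": [code.codon_map[c] for c in ALL_CODONS],
            "count": [table.counts.get(c, 0) for c in ALL_CODONS],
            "frequency": [freqs[c] for c in ALL_CODONS],
            "rscu": [r.get(c, float("nan")) for c in ALL_CODONS],
            "w": [w.get(c, float("nan")) for c in ALL_CODONS],
        }
    )
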