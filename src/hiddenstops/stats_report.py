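"""Correlation analyses and report assembly.

Two correlations are of biological interest:

* codon usage frequency (CUF) vs per-codon hidden-stop contribution —
  under the ambush hypothesis, usage should favour stop-prone codons, so
  the test is one-tailed for a POSITIVE correlation by default;
* G+C content vs hidden-stop frequency across a set of genes — stop
  codons are A/T-rich, so the default test is one-tailed for a NEGATIVE
  correlation. This analysis requires five or more sequences.

Significance uses the t transform of Pearson's r,
t = r * sqrt(n-2) / sqrt(1-r^2), with n-2 degrees of freedom, at
alpha = 0.05 one-tailed. Spearman rank correlation is available as an
option for the usage analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .codon_metrics import CodonUsageTable, cai, codon_usage, usage_metrics_table
from .genetic_codes import GeneticCodeTable, sense_codons
from .hidden_stops import (
    codon_contribution_scores,
    contribution_table,
    hsc_summary,
    records_table,
    summary_table,
)
from .markov import NullComparison, hsc_null_comparison
from .sequence_io import CodingSequence, validate_cds, validation_table

__all__ = [
    "ALPHA",
    "CorrelationResult",
    "pearson",
    "one_tailed_t",
    "cuf_contribution_correlation",
    "gc_hsc_correlation",
    "gc_content",
    "run_analyses",
    "build_report",
]

#: Significance level used throughout (one-tailed).
ALPHA = 0.05

Direction = Literal["greater", "less"]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises on length mismatch, n < 3, or zero variance in either vector
    ("undefined correlation").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    return float(_st.pearsonr(x, y).statistic)


def one_tailed_t(
    r: float, n: int, direction: Direction = "greater"
) -> tuple[float, float]:
    """t statistic and one-tailed p for a correlation coefficient.

    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom. ``direction``
    selects the tested tail: "greater" for positive correlation,
    "less" for negative. |r| = 1 gives an infinite t with p = 0 (when the
    sign matches the tested tail) or 1.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1 <= r <= 1:
        raise ValueError("r must be in [-1, 1]")
    df = n - 2
    if abs(r) == 1:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    if direction == "greater":
        p = float(_st.t.sf(t, df)) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    elif direction == "less":
        p = float(_st.t.cdf(t, df)) if math.isfinite(t) else (0.0 if t < 0 else 1.0)
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return t, p


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation with its one-tailed significance assessment."""

    analysis: str
    r: float
    n: int
    t_value: float  # +/-inf when |r| = 1; see infinite_t
    p_one_tailed: float
    direction: Direction
    significant: bool

    @property
    def infinite_t(self) -> bool:
        return not math.isfinite(self.t_value)


def _correlate(
    analysis: str, x, y, direction: Direction, method: str = "pearson"
) -> CorrelationResult:
    if method == "pearson":
        r = pearson(x, y)
    elif method == "spearman":
        res = _st.spearmanr(x, y)
        r = float(res.statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    t, p = one_tailed_t(r, len(x), direction=direction)
    return CorrelationResult(
        analysis=analysis, r=r, n=len(x), t_value=t, p_one_tailed=p,
        direction=direction, significant=p < ALPHA,
    )


def cuf_contribution_correlation(
    seqs: Iterable[CodingSequence],
    code: GeneticCodeTable,
    direction: Direction = "greater",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation of pooled codon usage with hidden-stop contribution.

    Pairs, over the sense codons of ``code``, the pooled usage frequency
    (codons never observed keep frequency 0 — they are not dropped) with
    the per-codon contribution score. One-tailed for positive correlation
    by default: the hypothesis is that usage favours stop-prone codons.
    """
    seqs = list(seqs)
    usage = codon_usage(seqs, code)
    freqs = usage.frequencies
    scores = codon_contribution_scores(code)
    codons = sense_codons(code)
    x = [freqs[c] for c in codons]
    y = [float(scores[c]) for c in codons]
    return _correlate("cuf_vs_contribution", x, y, direction, method)


def gc_content(seq: CodingSequence) -> float:
    """G+C fraction over unambiguous (ACGT) bases."""
    counts = {b: seq.sequence.count(b) for b in "ACGT"}
    tot = sum(counts.values())
    if tot == 0:
        raise ValueError(f"sequence {seq.seq_id!r} has no unambiguous bases")
    return (counts["G"] + counts["C"]) / tot


def gc_hsc_correlation(
    seqs: Iterable[CodingSequence],
    code: GeneticCodeTable,
    direction: Direction = "less",
    method: str = "pearson",
) -> CorrelationResult:
    """Across-gene correlation of G+C content with hidden-stop frequency.

    Requires 5 or more sequences. Per sequence, x is the G+C fraction of
    unambiguous bases and y the total hidden-stop count (both frames) per
    scanned off-frame position. One-tailed for negative correlation by
    default (stop triplets are A/T-rich).
    """
    seqs = list(seqs)
    if len(seqs) < 5:
        raise ValueError("gc_hsc_correlation requires 5 or more coding sequences")
    reports = hsc_summary(seqs, code, half_gene=False)
    x = [gc_content(s) for s in seqs]
    y = [r.total_frequency for r in reports]
    return _correlate("gc_vs_hsc", x, y, direction, method)


def _correlation_table(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": r.analysis,
                "r": r.r,
                "n": r.n,
                "t_value": r.t_value,
                "p_one_tailed": r.p_one_tailed,
                "direction": r.direction,
                "significant_at_0.05": int(r.significant),
            }
            for r in results
        ]
    )


def _null_table(comparisons: Iterable[NullComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": c.seq_id,
                "order": c.order,
                "observed_hsc": c.observed_hsc,
                "n_sim": c.n_sim,
                "sim_mean": c.sim_mean,
                "sim_sd": c.sim_sd,
                "z_score": "" if c.z_score is None else c.z_score,
                "degenerate_sd": int(c.z_score is None),
                "empirical_p": c.empirical_p,
                "seed": c.seed,
            }
            for c in comparisons
        ]
    )


def run_analyses(
    seqs: Sequence[CodingSequence],
    code: GeneticCodeTable,
    cai_reference: CodonUsageTable | None = None,
    markov_order: int | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    half_gene: bool = True,
    gc_corr: bool = False,
    correlation_direction: Direction = "greater",
    gc_direction: Direction = "less",
) -> dict[str, pd.DataFrame]:
    """Run the full analysis battery; returns named tables.

    Always produced: validation, hidden-stop records and summary,
    contribution scores, usage metrics, the CUF-contribution correlation.
    Optional: per-gene CAI (needs a reference usage table), GC-HSC
    correlation (needs >= 5 sequences), Markov null comparisons.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to analyse")
    reports = hsc_summary(seqs, code, half_gene=half_gene)
    usage = codon_usage(seqs, code)
    tables: dict[str, pd.DataFrame] = {
        "validation": validation_table(validate_cds(s, code) for s in seqs),
        "hsc_records": records_table(reports),
        "hsc_summary": summary_table(reports),
        "contribution": contribution_table(code),
        "codon_usage": usage_metrics_table(usage, code),
    }
    correlations = [
        cuf_contribution_correlation(seqs, code, direction=correlation_direction)
    ]
    if gc_corr:
        correlations.append(gc_hsc_correlation(seqs, code, direction=gc_direction))
    tables["correlations"] = _correlation_table(correlations)
    if cai_reference is not None:
        tables["cai"] = pd.DataFrame(
            [
                {"seq_id": s.seq_id, "cai": cai(s, cai_reference, code)}
                for s in seqs
            ]
        )
    if markov_order is not None:
        comparisons = [
            hsc_null_comparison(
                s, code, order=markov_order, n_sim=n_sim, seed=seed + i
            )
            for i, s in enumerate(seqs)
        ]
        tables["null_comparison"] = _null_table(comparisons)
    return tables


def build_report(tables: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write the table bundle as TSVs plus a manifest; returns filenames.

    Output is deterministic: fixed table order, fixed float formatting,
    so identical inputs give byte-identical files.
    """
    if not tables:
        raise ValueError("no analyses selected: nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        tables[name].to_csv(
            out / fname, sep="\t", index=False, float_format="%.10g",
            lineterminator="\n",
        )
        written.append(fname)
    manifest = out / "MANIFEST.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tn_rows\n")
        for name in sorted(tables):
            fh.write(f"{name}.tsv\t{len(tables[name])}\n")
    written.append("MANIFEST.tsv")
    return written
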