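"""Coding-phase probability profiles from codon usage.

In a window of a nucleotide sequence, each of the three reading registers
(phase 1 = window offset 0, phase 2 = offset 1, phase 3 = offset 2)
yields a run of complete codons. The likelihood of each phase is the
product of the reference usage frequencies of its codons,

    f_k = prod_i freq(codon_i in phase k),

and Bayes' formula with a uniform phase prior turns these into posterior
phase probabilities p_k = f_k / (f_1 + f_2 + f_3). Sliding the window
along a sequence traces p_1/p_2/p_3 profiles whose peaks mark regions
whose codon statistics match the reference — a classic descriptive aid
for locating protein-coding regions.

All products are accumulated as log sums and normalised with a stable
log-sum-exp, so windows of hundreds of codons do not underflow. Codons
with zero reference frequency are floored (default 1e-6) before the log;
window codons containing non-ACGT letters are skipped, as are incomplete
trailing codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .codon_metrics import CodonUsageTable

__all__ = [
    "FREQ_FLOOR",
    "DEFAULT_WINDOW_CODONS",
    "DEFAULT_STEP_NT",
    "PhaseWindow",
    "PhaseProfile",
    "window_phase_probabilities",
    "phase_profile",
    "profile_table",
]

#: Floor applied to zero usage frequencies before taking logs.
FREQ_FLOOR = 1e-6
#: Default window length in codons and default slide step in nucleotides.
DEFAULT_WINDOW_CODONS = 40
DEFAULT_STEP_NT = 3

_ACGT = frozenset("ACGT")


def _log_phase_likelihoods(
    window: str, freqs: dict[str, float], floor: float
) -> np.ndarray:
    """ln f_k for the three phases (offsets 0, 1, 2) of one window."""
    logf = np.zeros(3)
    for k in range(3):
        total = 0.0
        for start in range(k, len(window) - 2, 3):
            codon = window[start : start + 3]
            if not set(codon) <= _ACGT:
                continue
            total += math.log(max(freqs.get(codon, 0.0), floor))
        logf[k] = total
    return logf


def window_phase_probabilities(
    window: str, usage: CodonUsageTable, floor: float = FREQ_FLOOR
) -> tuple[float, float, float]:
    """Bayes posterior (p1, p2, p3) that each phase is the coding one.

    The window must be at least 5 nt so that all three phases contain a
    complete codon.
    """
    if len(window) < 5:
        raise ValueError("window must be at least 5 nt (one codon per phase)")
    window = window.upper().replace("U", "T")
    logf = _log_phase_likelihoods(window, usage.frequencies, floor)
    p = np.exp(logf - logsumexp(logf))
    p /= p.sum()  # guard residual rounding; p already sums to ~1
    return float(p[0]), float(p[1]), float(p[2])


@dataclass(frozen=True)
class PhaseWindow:
    """One profile record: window start, ln f per phase, p per phase."""

    start_nt: int
    log_f: tuple[float, float, float]
    p: tuple[float, float, float]


@dataclass(frozen=True)
class PhaseProfile:
    window_len_codons: int
    step_nt: int
    records: tuple[PhaseWindow, ...]


def phase_profile(
    seq: str,
    usage: CodonUsageTable,
    window_len_codons: int = DEFAULT_WINDOW_CODONS,
    step_nt: int = DEFAULT_STEP_NT,
    floor: float = FREQ_FLOOR,
) -> PhaseProfile:
    """Sliding-window phase-probability profile of a nucleotide string.

    The window spans ``3*N + 2`` nt (N codons in every phase); windows
    start at 0, len-window inclusive, stepping by ``step_nt``.
    """
    if window_len_codons < 1:
        raise ValueError("window_len_codons must be >= 1")
    if step_nt < 1:
        raise ValueError("step_nt must be >= 1")
    seq = "".join(seq.split()).upper().replace("U", "T")
    span = 3 * window_len_codons + 2
    if len(seq) < span:
        raise ValueError(
            f"sequence of {len(seq)} nt is shorter than the minimum window "
            f"span of {span} nt ({window_len_codons} codons)"
        )
    freqs = usage.frequencies
    records = []
    for start in range(0, len(seq) - span + 1, step_nt):
        logf = _log_phase_likelihoods(seq[start : start + span], freqs, floor)
        p = np.exp(logf - logsumexp(logf))
        p /= p.sum()
        records.append(
            PhaseWindow(start_nt=start, log_f=tuple(logf), p=tuple(p))
        )
    return PhaseProfile(
        window_len_codons=window_len_codons,
        step_nt=step_nt,
        records=tuple(records),
    )


def profile_table(profile: PhaseProfile) -> pd.DataFrame:
    """Profile as a table: window_start, p1, p2, p3 (plus ln f columns)."""
    return pd.DataFrame(
        {
            "window_start": [r.start_nt for r in profile.records],
            "p1": [r.p[0] for r in profile.records],
            "p2": [r.p[1] for r in profile.records],
            "p3": [r.p[2] for r in profile.records],
            "log_f1": [r.log_f[0] for r in profile.records],
            "log_f2": [r.log_f[1] for r in profile.records],
            "log_f3": [r.log_f[2] for r in profile.records],
        }
    )


def plot_profile(profile: PhaseProfile, path) -> None:
    """Write a PNG of the three phase-probability traces (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    xs = [r.start_nt for r in profile.records]
    for k, label in enumerate(["p1", "p2", "p3"]):
        ax.plot(xs, [r.p[k] for r in profile.records], label=label, lw=1)
    ax.set_xlabel("window start (nt)")
    ax.set_ylabel("phase probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
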