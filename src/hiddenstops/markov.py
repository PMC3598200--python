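"""Markov-chain nucleotide null models and synthetic-sequence generation.

Order-k chains (k in {0, 1, 2}) capture the mono-, di- and tri-nucleotide
composition of a sequence. Trained on an input CDS and resimulated, they
give composition-matched null sequences against which the observed
hidden-stop count can be scored: a z-score and an empirical p-value say
whether the real gene carries more (or fewer) off-frame stops than its
nucleotide statistics alone predict.

Estimation is maximum likelihood with an additive pseudocount (default 1)
per transition; contexts never observed in training fall back to the
uniform distribution. Simulation seeds its initial context from the
empirical context distribution of the training data and is bit-for-bit
reproducible given a seed.

The module also provides the synthetic-CDS generator used throughout the
test suite: codons drawn i.i.d. from prescribed weights, optionally
constrained stop-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .genetic_codes import ALL_CODONS, BASES, GeneticCodeTable
from .hidden_stops import FRAMES, count_offframe_positions, find_hidden_stops
from .sequence_io import CodingSequence, coding_sequence

__all__ = [
    "MarkovModel",
    "NullComparison",
    "train_markov",
    "simulate",
    "hsc_null_comparison",
    "generate_synthetic_cds",
    "save_model_tsv",
    "load_model_tsv",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_ACGT = frozenset(BASES)


def _all_contexts(order: int) -> list[str]:
    if order == 0:
        return [""]
    ctxs = [""]
    for _ in range(order):
        ctxs = [c + b for c in ctxs for b in BASES]
    return ctxs


@dataclass(frozen=True)
class MarkovModel:
    """Order-k nucleotide chain: per-context next-base distributions.

    ``context_probs`` maps every length-``order`` context over ACGT to a
    probability 4-vector (A, C, G, T order); ``initial_probs`` is the
    empirical distribution of contexts in the training data, used to seed
    simulation.
    """

    order: int
    context_probs: Mapping[str, tuple[float, float, float, float]]
    initial_probs: Mapping[str, float]
    pseudocount: float
    trained_on_len: int

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        expected = set(_all_contexts(self.order))
        if set(self.context_probs) != expected:
            raise ValueError(
                f"context_probs must cover all {len(expected)} contexts of "
                f"order {self.order}"
            )
        for ctx, p in self.context_probs.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1) > 1e-9:
                raise ValueError(f"invalid probability vector for context {ctx!r}")


def train_markov(
    seqs: Union[CodingSequence, Iterable[CodingSequence]],
    order: int,
    pseudocount: float = 1.0,
) -> MarkovModel:
    """Maximum-likelihood order-k chain with additive smoothing.

    Transitions are counted within each sequence (never across sequence
    boundaries) and only over ACGT-clean stretches. Contexts with no
    observations get the uniform next-base distribution.
    """
    if isinstance(seqs, CodingSequence):
        seqs = [seqs]
    seqs = list(seqs)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts: dict[str, np.ndarray] = {
        ctx: np.zeros(4) for ctx in _all_contexts(order)
    }
    ctx_counts: dict[str, float] = {ctx: 0.0 for ctx in counts}
    total_len = 0
    for seq in seqs:
        s = seq.sequence
        total_len += len(s)
        # split on non-ACGT so ambiguity letters break the chain
        start = 0
        for end in range(len(s) + 1):
            if end == len(s) or s[end] not in _ACGT:
                run = s[start:end]
                if len(run) > order:
                    for i in range(order, len(run)):
                        ctx = run[i - order : i] if order else ""
                        counts[ctx][_BASE_INDEX[run[i]]] += 1
                        ctx_counts[ctx] += 1
                start = end + 1
    if total_len == 0 or sum(ctx_counts.values()) == 0:
        raise ValueError(
            f"no training transitions: need clean runs longer than order {order}"
        )
    probs: dict[str, tuple[float, ...]] = {}
    for ctx, vec in counts.items():
        smoothed = vec + pseudocount
        tot = smoothed.sum()
        if tot == 0:  # pseudocount 0 and unseen context
            probs[ctx] = (0.25, 0.25, 0.25, 0.25)
        else:
            probs[ctx] = tuple(smoothed / tot)
    ctx_total = sum(ctx_counts.values())
    initial = {ctx: n / ctx_total for ctx, n in ctx_counts.items()}
    return MarkovModel(
        order=order,
        context_probs=probs,
        initial_probs=initial,
        pseudocount=pseudocount,
        trained_on_len=total_len,
    )


def simulate(
    model: MarkovModel, length: int, n_seqs: int, seed: int
) -> list[str]:
    """Generate ``n_seqs`` strings of exactly ``length`` nt from the chain.

    The first ``order`` bases of each string are the initial context,
    drawn from the model's empirical context distribution; subsequent
    bases follow the transition distributions. Identical arguments give
    identical output.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(seed)
    contexts = sorted(model.initial_probs)
    init_p = np.array([model.initial_probs[c] for c in contexts])
    init_p = init_p / init_p.sum()
    # inverse-CDF sampling: one uniform draw per emitted base
    cum = {c: np.cumsum(model.context_probs[c]) for c in model.context_probs}
    bases = BASES
    out: list[str] = []
    for _ in range(n_seqs):
        if model.order == 0:
            u = rng.random(length)
            draws = np.searchsorted(cum[""], u, side="right")
            np.clip(draws, 0, 3, out=draws)
            out.append("".join(bases[i] for i in draws))
            continue
        ctx = contexts[rng.choice(len(contexts), p=init_p)]
        chars = list(ctx[:length])
        u = rng.random(length)
        for i in range(len(chars), length):
            context = "".join(chars[i - model.order : i])
            j = min(int(np.searchsorted(cum[context], u[i], side="right")), 3)
            chars.append(bases[j])
        out.append("".join(chars))
    return out


@dataclass(frozen=True)
class NullComparison:
    """Observed hidden-stop count against a Markov-simulated null."""

    seq_id: str
    order: int
    observed_hsc: int
    n_sim: int
    sim_mean: float
    sim_sd: float
    z_score: float | None  # None when sim_sd == 0 (degenerate null)
    empirical_p: float
    seed: int

    @property
    def degenerate(self) -> bool:
        return self.z_score is None


def _total_hsc(sequence: str, code: GeneticCodeTable) -> int:
    cs = CodingSequence(seq_id="sim", sequence=sequence)
    return sum(len(find_hidden_stops(cs, code, f)) for f in FRAMES)


def hsc_null_comparison(
    seq: CodingSequence,
    code: GeneticCodeTable,
    order: int,
    n_sim: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> NullComparison:
    """Score a gene's hidden-stop count against a composition-matched null.

    Trains an order-``order`` chain on the sequence itself, simulates
    ``n_sim`` length-matched sequences, and compares the observed total
    hidden-stop count (both frames) with the simulated distribution.
    The empirical p is two-sided with the add-one correction
    (p = min(1, 2*min(p_le, p_ge)) with each tail computed as
    (1 + #extreme)/(n_sim + 1)), hence always positive.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable empirical p")
    model = train_markov(seq, order=order, pseudocount=pseudocount)
    observed = sum(len(find_hidden_stops(seq, code, f)) for f in FRAMES)
    sims = simulate(model, length=len(seq.sequence), n_seqs=n_sim, seed=seed)
    sim_counts = np.array([_total_hsc(s, code) for s in sims])
    mean = float(sim_counts.mean())
    sd = float(sim_counts.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else None
    p_le = (1 + int((sim_counts <= observed).sum())) / (n_sim + 1)
    p_ge = (1 + int((sim_counts >= observed).sum())) / (n_sim + 1)
    p = min(1.0, 2 * min(p_le, p_ge))
    return NullComparison(
        seq_id=seq.seq_id,
        order=order,
        observed_hsc=observed,
        n_sim=n_sim,
        sim_mean=mean,
        sim_sd=sd,
        z_score=z,
        empirical_p=p,
        seed=seed,
    )


def generate_synthetic_cds(
    n_codons: int,
    codon_weights: Mapping[str, float],
    code: GeneticCodeTable,
    forbid_internal_stops: bool = True,
    seed: int = 0,
    seq_id: str | None = None,
) -> CodingSequence:
    """Synthetic CDS of ``n_codons`` codons drawn i.i.d. from weights.

    With ``forbid_internal_stops`` (default), stop-codon weights are
    dropped before normalisation — equivalent to redrawing every stop —
    so the construction guarantees a stop-free codon sequence. Output is
    deterministic per seed.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    weights = {c: float(w) for c, w in codon_weights.items() if w > 0}
    if any(w < 0 for w in codon_weights.values()):
        raise ValueError("codon weights must be non-negative")
    for c in weights:
        if c.upper().replace("U", "T") not in ALL_CODONS:
            raise ValueError(f"{c!r} is not a codon")
    weights = {c.upper().replace("U", "T"): w for c, w in weights.items()}
    if forbid_internal_stops:
        weights = {c: w for c, w in weights.items() if c not in code.stop_set}
    if not weights:
        raise ValueError("no positive-weight codon available")
    codons = sorted(weights)
    p = np.array([weights[c] for c in codons])
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(codons), size=n_codons, p=p)
    sequence = "".join(codons[i] for i in draws)
    return coding_sequence(sequence, seq_id=seq_id or f"synthetic_seed{seed}")


def save_model_tsv(model: MarkovModel, dest: Union[str, PathLike]) -> None:
    """Persist a model as plain TSV: context, P(A), P(C), P(G), P(T)."""
    with open(dest, "w") as fh:
        fh.write(f"# order={model.order}\tpseudocount={model.pseudocount}"
                 f"\ttrained_on_len={model.trained_on_len}\n")
        fh.write("context\tA\tC\tG\tT\tinitial\n")
        for ctx in sorted(model.context_probs):
            p = model.context_probs[ctx]
            init = model.initial_probs.get(ctx, 0.0)
            fh.write(
                f"{ctx or '.'}\t{p[0]:.12g}\t{p[1]:.12g}\t{p[2]:.12g}"
                f"\t{p[3]:.12g}\t{init:.12g}\n"
            )


def load_model_tsv(source: Union[str, PathLike]) -> MarkovModel:
    """Load a model written by :func:`save_model_tsv`."""
    order = None
    pseudocount = 0.0
    trained_on_len = 0
    probs: dict[str, tuple[float, ...]] = {}
    initial: dict[str, float] = {}
    with open(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for kv in line.lstrip("# ").split("\t"):
                    k, _, v = kv.partition("=")
                    if k == "order":
                        order = int(v)
                    elif k == "pseudocount":
                        pseudocount = float(v)
                    elif k == "trained_on_len":
                        trained_on_len = int(v)
                continue
            if not line or line.startswith("context\t"):
                continue
            parts = line.split("\t")
            ctx = "" if parts[0] == "." else parts[0]
            probs[ctx] = tuple(float(x) for x in parts[1:5])
            initial[ctx] = float(parts[5]) if len(parts) > 5 else 0.0
    if order is None:
        order = len(next(iter(probs)))
    tot = sum(initial.values())
    if tot > 0:
        initial = {c: v / tot for c, v in initial.items()}
    else:
        initial = {c: 1 / len(probs) for c in probs}
    return MarkovModel(
        order=order,
        context_probs=probs,
        initial_probs=initial,
        pseudocount=pseudocount,
        trained_on_len=trained_on_len,
    )
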