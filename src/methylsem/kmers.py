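"""Kmer universe enumeration from a PWM under a p-value score threshold.

The kmer universe is the set of length-L sequences whose log2-odds PWM
score meets a cutoff chosen so that a random background sequence scores at
least that high with probability ~p. The cutoff is found by column-wise
dynamic programming over the discretized score distribution, then the
universe is enumerated by branch-and-bound over the motif columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io import Motif

BASES = "ACGT"

#: Default motif-scan p-value for the kmer universe.
DEFAULT_PVALUE = 4e-4
#: Column scores are rounded to this granularity (bits) in the cutoff DP.
DEFAULT_GRANULARITY = 1e-3
#: Refuse to materialize universes larger than this (advise a smaller p).
DEFAULT_MAX_KMERS = 4**12


@dataclass(frozen=True)
class ScoreThreshold:
    """A log2-odds cutoff and the background p-value that produced it."""

    cutoff: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 < self.pvalue <= 1:
            raise ValueError("p-value must be in (0, 1]")


def _score_columns(motif: Motif, background) -> np.ndarray:
    """(L, 4) matrix of per-column log2-odds scores."""
    background = np.asarray(background, dtype=float)
    if background.shape != (4,):
        raise ValueError("background must have 4 entries")
    if not np.isclose(background.sum(), 1.0, atol=1e-9):
        raise ValueError("background must sum to 1")
    if not (background > 0).all():
        raise ValueError("background probabilities must be positive")
    return np.log2(motif.probs / background)


def score_kmer(motif: Motif, kmer: str, background=(0.25, 0.25, 0.25, 0.25)) -> float:
    """Log2-odds PWM score: sum over columns of log2(p[i][b] / bg[b])."""
    if len(kmer) != motif.length:
        raise ValueError(f"kmer length {len(kmer)} != motif length {motif.length}")
    cols = _score_columns(motif, background)
    try:
        idx = [BASES.index(b) for b in kmer]
    except ValueError as exc:
        raise ValueError(f"kmer contains a non-ACGT letter: {kmer!r}") from exc
    return float(cols[np.arange(motif.length), idx].sum())


def pvalue_cutoff(
    motif: Motif,
    p: float = DEFAULT_PVALUE,
    background=(0.25, 0.25, 0.25, 0.25),
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreThreshold:
    """Largest score s with P_background(score >= s) >= p.

    The exact background score distribution is built column by column on an
    integer lattice (column scores rounded to ``granularity`` bits), then
    the survival function is scanned for the largest admissible cutoff.
    The returned cutoff is on the rounded lattice; enumeration uses the
    same rounding so cutoff and universe are mutually consistent.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    cols = _score_columns(motif, background)
    background = np.asarray(background, dtype=float)
    icols = np.rint(cols / granularity).astype(np.int64)

    # dist: integer lattice score -> background probability mass
    dist: dict[int, float] = {0: 1.0}
    for i in range(motif.length):
        nxt: dict[int, float] = {}
        for s, mass in dist.items():
            for b in range(4):
                key = s + int(icols[i, b])
                nxt[key] = nxt.get(key, 0.0) + mass * background[b]
        dist = nxt

    scores = np.array(sorted(dist), dtype=np.int64)
    masses = np.array([dist[int(s)] for s in scores])
    # survival[i] = P(score >= scores[i])
    survival = masses[::-1].cumsum()[::-1]
    admissible = scores[survival >= p - 1e-12]
    cutoff_lattice = int(admissible.max()) if admissible.size else int(scores.min())
    return ScoreThreshold(cutoff=cutoff_lattice * granularity, pvalue=p)


def enumerate_kmers(
    motif: Motif,
    threshold: ScoreThreshold,
    background=(0.25, 0.25, 0.25, 0.25),
    granularity: float = DEFAULT_GRANULARITY,
    max_kmers: int = DEFAULT_MAX_KMERS,
) -> list[str]:
    """All kmers scoring >= the cutoff, in lexicographic order.

    Branch-and-bound: a prefix is pruned when even the best possible
    completion cannot reach the cutoff. Scores are compared on the same
    rounded lattice the cutoff was computed on, so ties at the cutoff are
    admitted consistently.
    """
    cols = _score_columns(motif, background)
    icols = np.rint(cols / granularity).astype(np.int64)
    icut = int(np.rint(threshold.cutoff / granularity))
    L = motif.length
    # best achievable lattice score from column i to the end
    suffix_best = np.zeros(L + 1, dtype=np.int64)
    for i in range(L - 1, -1, -1):
        suffix_best[i] = suffix_best[i + 1] + icols[i].max()

    out: list[str] = []
    stack: list[tuple[int, int, list[str]]] = [(0, 0, [])]
    while stack:
        i, acc, prefix = stack.pop()
        if i == L:
            out.append("".join(prefix))
            if len(out) > max_kmers:
                raise ValueError(
                    f"kmer universe exceeds {max_kmers} kmers; use a smaller p-value"
                )
            continue
        # reverse base order so the DFS pops lexicographically
        for b in (3, 2, 1, 0):
            nacc = acc + int(icols[i, b])
            if nacc + suffix_best[i + 1] >= icut:
                stack.append((i + 1, nacc, prefix + [BASES[b]]))
    out.sort()
    return out


def build_snp_lists(kmers) -> dict[tuple[int, str], frozenset[str]]:
    """Per-(position, base) in-silico variant lists.

    For each 1-based motif position i and base b, the list holds every
    universe kmer with position i replaced by b (the identity substitution
    maps a kmer to itself, so every list is non-empty). Returns 4*L lists.
    """
    kmers = sorted(set(kmers))
    if not kmers:
        raise ValueError("empty kmer set")
    lengths = {len(k) for k in kmers}
    if len(lengths) != 1:
        raise ValueError("kmers must have uniform length")
    L = lengths.pop()
    lists: dict[tuple[int, str], set[str]] = {
        (i, b): set() for i in range(1, L + 1) for b in BASES
    }
    for k in kmers:
        for i in range(1, L + 1):
            prefix, suffix = k[: i - 1], k[i:]
            for b in BASES:
                lists[(i, b)].add(prefix + b + suffix)
    return {key: frozenset(v) for key, v in lists.items()}


def scramble_kmers(kmers, seed: int) -> list[str]:
    """One composition-preserving scramble per kmer (seeded, deterministic).

    Each kmer's letters are permuted by a seeded RNG; the multiset of
    letters is preserved, only the positional structure is destroyed.
    Returns a sorted, deduplicated list.
    """
    rng = np.random.default_rng(seed)
    out = set()
    for k in sorted(set(kmers)):
        letters = list(k)
        rng.shuffle(letters)
        out.add("".join(letters))
    return sorted(out)


def all_kmers(L: int):
    """All 4^L kmers of length L (test/oracle helper)."""
    return ("".join(t) for t in itertools.product(BASES, repeat=L))
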