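"""Genome alignment of kmers within open chromatin and signal attachment.

Kmers are matched exactly, on both strands, with the full L-base footprint
required to lie inside an open-chromatin interval. Signal per alignment is
the mean (or max) per-base ChIP-seq track value over the footprint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .io import Genome, IntervalSet, Motif, SignalTrack, revcomp
from .kmers import BASES, DEFAULT_PVALUE, enumerate_kmers, pvalue_cutoff

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedObservation:
    """One genomic occurrence of one kmer.

    ``start`` is 0-based on the plus strand; for strand "-" the kmer equals
    the reverse complement of the plus-strand substring. ``signal`` is the
    ChIP-seq statistic over the footprint (attached later); ``methylation``
    is the WGBS fraction relevant to the observation's SNP list (NaN until
    annotated, and for A/T/baseline lists).
    """

    chrom: str
    start: int
    strand: str
    kmer: str
    signal: float = math.nan
    methylation: float = math.nan
    meth_measured: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.kmer)


def align_kmers(
    genome: Genome, kmers, regions: IntervalSet
) -> dict[str, list[AlignedObservation]]:
    """Exact occurrences of each kmer, both strands, inside the regions.

    Returns {kmer: observations}. A locus matching on both strands (a
    palindrome) yields one + and one - observation; duplicates are emitted
    once. Every kmer in the input appears as a key (possibly empty list).
    """
    kmers = sorted(set(kmers))
    if not kmers:
        return {}
    lengths = {len(k) for k in kmers}
    if len(lengths) != 1:
        raise ValueError("kmers must have uniform length")
    bad = [k for k in kmers if set(k) - set("ACGT")]
    if bad:
        raise ValueError(f"kmers must be over ACGT; got {bad[0]!r}")
    L = lengths.pop()
    fwd = set(kmers)
    rev = {revcomp(k): k for k in kmers}
    hits: dict[str, set[tuple[str, int, str]]] = {k: set() for k in kmers}
    n_windows = 0
    for chrom, intervals in regions.intervals.items():
        if chrom not in genome.sequences:
            continue
        seq = genome.sequences[chrom]
        for start, end in intervals:
            end = min(end, len(seq))
            for s in range(start, end - L + 1):
                window = seq[s : s + L]
                n_windows += 1
                if window in fwd:
                    hits[window].add((chrom, s, "+"))
                if window in rev:
                    hits[rev[window]].add((chrom, s, "-"))
    if n_windows == 0:
        logger.warning("no open-chromatin window can hold a %d-mer", L)
    return {
        k: [
            AlignedObservation(chrom=c, start=s, strand=st, kmer=k)
            for c, s, st in sorted(locs)
        ]
        for k, locs in hits.items()
    }


def attach_signal(
    observations, track: SignalTrack, stat: str = "mean"
) -> list[AlignedObservation]:
    """Attach the per-footprint ChIP-seq statistic to each observation."""
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    fn = track.mean if stat == "mean" else track.max
    return [replace(o, signal=fn(o.chrom, o.start, o.end)) for o in observations]


def average_list(observations) -> tuple[float, float, int]:
    """(mean signal, standard error, n) over one SNP list's observations.

    Standard error is sample-sd/sqrt(n) for n >= 2, NaN for n < 2; an empty
    list yields (NaN, NaN, 0).
    """
    values = np.array([o.signal for o in observations], dtype=float)
    n = values.size
    if n == 0:
        return math.nan, math.nan, 0
    mean = float(values.mean())
    stderr = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
    return mean, stderr, n


def _pool_signals(alignments: dict[str, list[AlignedObservation]]) -> list[float]:
    return [o.signal for obs in alignments.values() for o in obs]


def endogenous_baseline(signals) -> float:
    """Mean signal over all alignments of the unmutated kmer universe.

    Accepts an iterable of signal values or an align_kmers-style dict.
    """
    if isinstance(signals, dict):
        signals = _pool_signals(signals)
    values = np.array(list(signals), dtype=float)
    if values.size == 0:
        raise ValueError(
            "no alignment of any enumerated kmer inside open chromatin; "
            "cannot set the endogenous baseline"
        )
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError(
            "endogenous baseline is zero (no ChIP-seq signal over any aligned "
            "kmer); cannot normalize"
        )
    return mean


def scrambled_baseline(signals, endogenous: float, track: SignalTrack | None = None) -> float:
    """log2(mean scrambled-kmer signal / endogenous baseline).

    When no scrambled kmer aligns (or all aligned signal is zero), falls
    back to log2(eps / endogenous) with eps the smallest positive per-base
    value in the track, so the baseline stays finite and "below random".
    """
    if isinstance(signals, dict):
        signals = _pool_signals(signals)
    values = np.array(list(signals), dtype=float)
    mean = float(values.mean()) if values.size else 0.0
    if mean <= 0:
        eps = track.min_positive() if track is not None else None
        if eps is None:
            eps = endogenous / 1024.0
        logger.warning(
            "no scrambled-kmer signal; falling back to log2(%g / baseline)", eps
        )
        mean = eps
    return float(np.log2(mean / endogenous))


def raw_cell_matrix(
    snp_lists: dict[tuple[int, str], frozenset[str]],
    alignments: dict[str, list[AlignedObservation]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(L, 4) mean/stderr/totals matrices over the plain (non-split) lists."""
    L = max(i for i, _ in snp_lists)
    means = np.full((L, 4), np.nan)
    stderr = np.full((L, 4), np.nan)
    totals = np.zeros((L, 4), dtype=np.int64)
    for (i, b), members in snp_lists.items():
        obs = [o for k in sorted(members) for o in alignments.get(k, [])]
        m, se, n = average_list(obs)
        means[i - 1, BASES.index(b)] = m
        stderr[i - 1, BASES.index(b)] = se
        totals[i - 1, BASES.index(b)] = n
    return means, stderr, totals


def refine_iterate(
    motif: Motif,
    genome: Genome,
    regions: IntervalSet,
    track: SignalTrack,
    pvalue: float = DEFAULT_PVALUE,
    background=(0.25, 0.25, 0.25, 0.25),
    max_iter: int = 1,
    tol: float = 1e-3,
    signal_stat: str = "mean",
):
    """Optionally iterate motif refinement before the methylation step.

    Each iteration enumerates the kmer universe of the current motif,
    aligns the in-silico variant lists, and rebuilds the motif from the
    per-cell mean signals (each position's four means normalized to
    probabilities). Iteration stops when the Pearson r^2 between
    consecutive raw matrices (defined cells only) reaches 1 - tol, or at
    ``max_iter``. Returns (kmer universe, snp lists, alignments, raw
    (L,4) matrices, r^2 trace) from the last iteration.
    """
    from .kmers import build_snp_lists  # local to avoid import cycle noise

    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    current = motif
    prev_means = None
    r2_trace: list[float] = []
    best = None
    best_r2 = -np.inf
    for it in range(1, max_iter + 1):
        threshold = pvalue_cutoff(current, pvalue, background)
        universe = enumerate_kmers(current, threshold, background)
        lists = build_snp_lists(universe)
        aligned = align_kmers(genome, set().union(*lists.values()), regions)
        aligned = {k: attach_signal(v, track, stat=signal_stat) for k, v in aligned.items()}
        means, stderr, totals = raw_cell_matrix(lists, aligned)
        state = (universe, lists, aligned, (means, stderr, totals))
        if prev_means is not None:
            mask = ~(np.isnan(prev_means) | np.isnan(means))
            if mask.sum() >= 3 and np.std(means[mask]) > 0 and np.std(prev_means[mask]) > 0:
                r2 = float(np.corrcoef(prev_means[mask], means[mask])[0, 1] ** 2)
            else:
                r2 = 1.0
            r2_trace.append(r2)
            logger.info("refinement iteration %d: r^2 vs previous = %.6f", it, r2)
            if r2 > best_r2:
                best_r2, best = r2, state
            if r2 >= 1.0 - tol:
                return (*state, r2_trace)
        else:
            best, best_r2 = state, 0.0
        prev_means = means
        if it < max_iter:
            current = _motif_from_means(means, current)
    if max_iter > 1 and r2_trace and r2_trace[-1] < 1.0 - tol:
        logger.warning(
            "refinement did not converge in %d iterations; returning best r^2 %.4f",
            max_iter,
            best_r2,
        )
        return (*best, r2_trace)
    return (*state, r2_trace)


def _motif_from_means(means: np.ndarray, fallback: Motif) -> Motif:
    """Rebuild a motif by normalizing each position's four mean signals."""
    filled = np.where(np.isnan(means), 0.0, means)
    sums = filled.sum(axis=1, keepdims=True)
    bad = sums[:, 0] <= 0
    probs = np.where(sums > 0, filled / np.where(sums > 0, sums, 1.0), fallback.probs)
    if bad.any():
        probs[bad] = fallback.probs[bad]
    # pseudocount on the probability scale keeps entries strictly positive
    probs = probs + 1e-6
    probs /= probs.sum(axis=1, keepdims=True)
    return Motif(probs, pseudocount=fallback.pseudocount)
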