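"""WGBS integration: methylation annotation and the weighted signal split.

For a SNP list that plants a C (or G) at motif position i, each aligned
observation gets the methylation fraction of the corresponding genomic
cytosine: for C, the cytosine sits on the alignment's motif strand; for G,
it is the base-paired cytosine on the opposite strand — this realizes the
W letter ("G opposite a methylated C"). Only CpG-context cytosines are
considered; anything else counts as unmethylated (fraction 0) and is
tallied as unmeasured.

The per-list signal mean is then split into a methylated component
sum(M_k * S_k) / n and an unmethylated component sum((1 - M_k) * S_k) / n,
which conserve the plain mean: methylated + unmethylated = sum(S_k) / n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np

from .alignment import AlignedObservation, average_list
from .io import ALPHABET, Genome, MethylationTrack
from .kmers import BASES

logger = logging.getLogger(__name__)


def _cytosine_site(
    obs: AlignedObservation, position: int, base: str, L: int
) -> tuple[int, str]:
    """Genomic (plus-strand position, cytosine strand) for a motif C or G.

    ``position`` is 1-based along the motif (= along the kmer as written).
    For base C the cytosine is on the alignment strand; for base G it is
    the paired cytosine on the opposite strand, at the same genomic base.
    """
    if obs.strand == "+":
        pos = obs.start + (position - 1)
        cyt_strand = "+" if base == "C" else "-"
    else:
        pos = obs.start + (L - position)
        cyt_strand = "-" if base == "C" else "+"
    return pos, cyt_strand


def _in_cpg_context(genome: Genome, chrom: str, pos: int, cyt_strand: str) -> bool:
    """True when the cytosine at (pos, strand) is followed by G on its strand.

    A plus-strand cytosine at p is CpG iff the plus strand reads CG at
    (p, p+1); a minus-strand cytosine at p is CpG iff the plus strand reads
    CG at (p-1, p). The plus-strand base at the cytosine's position must
    actually be C (plus) or G (minus) for the site to be a cytosine at all.
    """
    seq = genome.sequences[chrom]
    if cyt_strand == "+":
        return pos + 1 < len(seq) and seq[pos] == "C" and seq[pos + 1] == "G"
    return pos - 1 >= 0 and seq[pos] == "G" and seq[pos - 1] == "C"


def annotate_methylation(
    observations,
    list_key: tuple[int, str],
    genome: Genome,
    meth: MethylationTrack,
    min_coverage: int = 0,
    missing: str = "zero",
) -> tuple[list[AlignedObservation], int]:
    """Attach the relevant WGBS fraction to each observation of a C/G list.

    Returns (annotated observations, unmeasured count). An observation is
    unmeasured when the site is not in CpG context, has no WGBS record, or
    has coverage below ``min_coverage``; with ``missing="zero"`` it is kept
    as unmethylated (fraction 0), with ``missing="drop"`` it is removed
    from the list. For A/T lists the observations pass through unchanged
    (fraction NaN).
    """
    if missing not in ("zero", "drop"):
        raise ValueError("missing must be 'zero' or 'drop'")
    position, base = list_key
    if base not in ("C", "G"):
        return list(observations), 0
    out: list[AlignedObservation] = []
    unmeasured = 0
    for obs in observations:
        L = len(obs.kmer)
        pos, cyt_strand = _cytosine_site(obs, position, base, L)
        fraction: float | None = None
        if _in_cpg_context(genome, obs.chrom, pos, cyt_strand):
            fraction = meth.lookup(obs.chrom, pos, cyt_strand, min_coverage)
        if fraction is None:
            unmeasured += 1
            if missing == "zero":
                out.append(replace(obs, methylation=0.0, meth_measured=False))
        else:
            out.append(replace(obs, methylation=fraction, meth_measured=True))
    return out, unmeasured


def split_signal(
    pairs, literal_formula: bool = False
) -> tuple[float, float, int]:
    """Split a list's signal into methylated and unmethylated means.

    ``pairs`` is an iterable of (M_k, S_k). Methylated mean =
    sum(M_k * S_k) / n; unmethylated mean = sum((1 - M_k) * S_k) / n, so the
    two components sum exactly to the plain mean signal. With
    ``literal_formula=True`` the unmethylated component is instead
    sum(1 - M_k * S_k) / n, a non-conserving variant kept for
    compatibility with the formula as sometimes printed.
    """
    pairs = list(pairs)
    n = len(pairs)
    if n == 0:
        return math.nan, math.nan, 0
    m = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)
    if np.isnan(m).any():
        raise ValueError("undefined methylation fraction; annotate first")
    methylated = float(np.sum(m * s) / n)
    if literal_formula:
        unmethylated = float(np.sum(1.0 - m * s) / n)
    else:
        unmethylated = float(np.sum((1.0 - m) * s) / n)
    return methylated, unmethylated, n


def _weighted_stderr(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(n))


def build_methylated_matrices(
    per_list_observations: dict[tuple[int, str], list[AlignedObservation]],
    literal_formula: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw L x 6 mean / stderr / totals matrices (A, C, G, T, M, W).

    A and T cells are plain list averages. The C (resp. G) cell is the
    unmethylated component of the (i, C) (resp. (i, G)) list and M (resp.
    W) its methylated component. Standard errors for the split cells are
    computed over the per-observation weighted contributions M_k*S_k and
    (1-M_k)*S_k. Totals count the observations actually contributing:
    n for A/T, #{M_k > 0} for M/W, #{M_k < 1} for C/G. Cells with zero
    totals are left NaN.
    """
    keys = set(per_list_observations)
    L = max(i for i, _ in keys)
    if keys != {(i, b) for i in range(1, L + 1) for b in BASES}:
        raise ValueError("expected all 4*L SNP lists")
    means = np.full((L, 6), np.nan)
    stderr = np.full((L, 6), np.nan)
    totals = np.zeros((L, 6), dtype=np.int64)
    col = {x: j for j, x in enumerate(ALPHABET)}
    for i in range(1, L + 1):
        for b in ("A", "T"):
            m, se, n = average_list(per_list_observations[(i, b)])
            means[i - 1, col[b]] = m
            stderr[i - 1, col[b]] = se
            totals[i - 1, col[b]] = n
        for b, meth_letter in (("C", "M"), ("G", "W")):
            obs = per_list_observations[(i, b)]
            n = len(obs)
            if n == 0:
                continue
            m = np.array([o.methylation for o in obs], dtype=float)
            s = np.array([o.signal for o in obs], dtype=float)
            meth_mean, unmeth_mean, _ = split_signal(
                zip(m, s), literal_formula=literal_formula
            )
            n_meth = int(np.sum(m > 0))
            n_unmeth = int(np.sum(m < 1))
            totals[i - 1, col[meth_letter]] = n_meth
            totals[i - 1, col[b]] = n_unmeth
            if n_meth > 0:
                means[i - 1, col[meth_letter]] = meth_mean
                stderr[i - 1, col[meth_letter]] = _weighted_stderr(m * s)
            if n_unmeth > 0:
                means[i - 1, col[b]] = unmeth_mean
                contrib = (1.0 - m * s) if literal_formula else (1.0 - m) * s
                stderr[i - 1, col[b]] = _weighted_stderr(contrib)
    return means, stderr, totals
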