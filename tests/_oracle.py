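"""Naive reference implementation used as an independent oracle.

Everything here is deliberately brute force and written with plain loops
and per-base arrays: all 4^L kmers are scored one by one, alignment is a
sliding-window scan, signal is expanded to a dense per-base vector, and
the methylation split is a direct sum. Only the seeded scramble choice is
shared with the package (it defines the input, not the measurement).
"""

from __future__ import annotations

import math

from methylsem.io import revcomp
from methylsem.kmers import scramble_kmers

BASES = "ACGT"
ALPHABET = ("A", "C", "G", "T", "M", "W")


def all_kmers(L):
    if L == 0:
        yield ""
        return
    for prefix in all_kmers(L - 1):
        for b in BASES:
            yield prefix + b


def lattice_scores(motif, background, granularity):
    cols = []
    for i in range(motif.length):
        row = []
        for j in range(4):
            row.append(
                int(round(math.log2(motif.probs[i][j] / background[j]) / granularity))
            )
        cols.append(row)
    return cols


def brute_force_cutoff(motif, p, background=(0.25, 0.25, 0.25, 0.25), granularity=1e-3):
    """Largest lattice score s with P_bg(score >= s) >= p, by full enumeration."""
    cols = lattice_scores(motif, background, granularity)
    scored = []
    for kmer in all_kmers(motif.length):
        s = sum(cols[i][BASES.index(b)] for i, b in enumerate(kmer))
        prob = 1.0
        for b in kmer:
            prob *= background[BASES.index(b)]
        scored.append((s, prob))
    scored.sort(reverse=True)
    cum = 0.0
    cutoff = min(s for s, _ in scored)
    for s, prob in scored:
        cum += prob
        if cum >= p - 1e-12:
            cutoff = s
            break
    return cutoff


def brute_force_universe(motif, p, background=(0.25, 0.25, 0.25, 0.25), granularity=1e-3):
    cols = lattice_scores(motif, background, granularity)
    cutoff = brute_force_cutoff(motif, p, background, granularity)
    out = []
    for kmer in all_kmers(motif.length):
        s = sum(cols[i][BASES.index(b)] for i, b in enumerate(kmer))
        if s >= cutoff:
            out.append(kmer)
    return sorted(out)


def snp_lists(universe):
    L = len(universe[0])
    lists = {}
    for i in range(1, L + 1):
        for b in BASES:
            members = set()
            for k in universe:
                members.add(k[: i - 1] + b + k[i:])
            lists[(i, b)] = sorted(members)
    return lists


def region_tuples(regions):
    return list(regions.to_tuples())


def find_occurrences(genome, kmer, regions):
    """Sliding-window scan: (chrom, start, strand) of every contained match."""
    hits = []
    L = len(kmer)
    rc = revcomp(kmer)
    for chrom, start, end in region_tuples(regions):
        seq = genome.sequences[chrom]
        end = min(end, len(seq))
        for s in range(start, end - L + 1):
            window = seq[s : s + L]
            if window == kmer:
                hits.append((chrom, s, "+"))
            if window == rc:
                hits.append((chrom, s, "-"))
    return sorted(set(hits))


def dense_signal(track):
    """Expand a SignalTrack to per-base python lists per chromosome."""
    dense = {}
    for chrom, (starts, ends, values) in track.data.items():
        size = int(ends[-1])
        arr = [0.0] * size
        for s, e, v in zip(starts, ends, values):
            for p in range(int(s), int(e)):
                arr[p] = float(v)
        dense[chrom] = arr
    return dense


def footprint_mean(dense, chrom, start, end):
    arr = dense.get(chrom, [])
    total = 0.0
    for p in range(start, end):
        total += arr[p] if p < len(arr) else 0.0
    return total / (end - start)


def methylation_fraction(genome, meth, chrom, start, strand, kmer, position, base,
                         min_coverage=0):
    """WGBS fraction for the in-silico C/G at a motif position, or None."""
    L = len(kmer)
    seq = genome.sequences[chrom]
    if strand == "+":
        pos = start + position - 1
        cyt_strand = "+" if base == "C" else "-"
    else:
        pos = start + L - position
        cyt_strand = "-" if base == "C" else "+"
    if cyt_strand == "+":
        if not (pos + 1 < len(seq) and seq[pos] == "C" and seq[pos + 1] == "G"):
            return None
    else:
        if not (pos - 1 >= 0 and seq[pos] == "G" and seq[pos - 1] == "C"):
            return None
    rec = meth.records.get((chrom, pos, cyt_strand))
    if rec is None or rec[1] < min_coverage:
        return None
    return rec[0]


def sample_stderr(values):
    n = len(values)
    if n < 2:
        return math.nan
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var) / math.sqrt(n)


def naive_sem(genome, regions, track, meth, motif, pvalue=4e-4, seed=0,
              background=(0.25, 0.25, 0.25, 0.25), granularity=1e-3,
              min_coverage=0, literal_formula=False):
    """Full naive pipeline; returns a dict of matrices and baselines.

    Matrices are lists of lists (L rows, 6 columns in A,C,G,T,M,W order).
    """
    L = motif.length
    universe = brute_force_universe(motif, pvalue, background, granularity)
    lists = snp_lists(universe)
    dense = dense_signal(track)

    def observations(kmer):
        return [
            (chrom, s, strand, footprint_mean(dense, chrom, s, s + L))
            for chrom, s, strand in find_occurrences(genome, kmer, regions)
        ]

    universe_obs = [o for k in universe for o in observations(k)]
    if not universe_obs:
        raise ValueError("no universe alignment")
    endogenous = sum(o[3] for o in universe_obs) / len(universe_obs)

    scrambles = scramble_kmers(universe, seed)
    scrambled_obs = [o for k in scrambles for o in observations(k)]
    scrambled_mean = (
        sum(o[3] for o in scrambled_obs) / len(scrambled_obs) if scrambled_obs else 0.0
    )
    if scrambled_mean <= 0:
        positives = [
            v
            for _, (_, _, values) in track.data.items()
            for v in values
            if v > 0
        ]
        eps = min(positives) if positives else endogenous / 1024.0
        scrambled_mean = eps
    scrambled = math.log2(scrambled_mean / endogenous)

    nan = math.nan
    means = [[nan] * 6 for _ in range(L)]
    stderr = [[nan] * 6 for _ in range(L)]
    totals = [[0] * 6 for _ in range(L)]
    col = {x: j for j, x in enumerate(ALPHABET)}
    for i in range(1, L + 1):
        for b in BASES:
            obs = [o for k in lists[(i, b)] for o in observations(k)]
            n = len(obs)
            if b in "AT":
                if n:
                    values = [o[3] for o in obs]
                    means[i - 1][col[b]] = sum(values) / n
                    stderr[i - 1][col[b]] = sample_stderr(values)
                    totals[i - 1][col[b]] = n
                continue
            if n == 0:
                continue
            ms_pairs = []
            for chrom, s, strand, signal in obs:
                kmer_here = (
                    genome.sequences[chrom][s : s + L]
                    if strand == "+"
                    else revcomp(genome.sequences[chrom][s : s + L])
                )
                frac = methylation_fraction(
                    genome, meth, chrom, s, strand, kmer_here, i, b, min_coverage
                )
                ms_pairs.append((0.0 if frac is None else frac, signal))
            meth_letter = "M" if b == "C" else "W"
            meth_vals = [m * sv for m, sv in ms_pairs]
            unmeth_vals = [
                (1.0 - m * sv) if literal_formula else (1.0 - m) * sv
                for m, sv in ms_pairs
            ]
            n_meth = sum(1 for m, _ in ms_pairs if m > 0)
            n_unmeth = sum(1 for m, _ in ms_pairs if m < 1)
            totals[i - 1][col[meth_letter]] = n_meth
            totals[i - 1][col[b]] = n_unmeth
            if n_meth:
                means[i - 1][col[meth_letter]] = sum(meth_vals) / n
                stderr[i - 1][col[meth_letter]] = sample_stderr(meth_vals)
            if n_unmeth:
                means[i - 1][col[b]] = sum(unmeth_vals) / n
                stderr[i - 1][col[b]] = sample_stderr(unmeth_vals)

    scores = [[nan] * 6 for _ in range(L)]
    for i in range(L):
        for j in range(6):
            m = means[i][j]
            if isinstance(m, float) and math.isnan(m):
                continue
            scores[i][j] = math.log2(m / endogenous) if m > 0 else scrambled - 1.0
    return {
        "universe": universe,
        "scores": scores,
        "stderr": stderr,
        "totals": totals,
        "endogenous": endogenous,
        "scrambled": scrambled,
        "means": means,
    }
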