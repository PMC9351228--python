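"""Self-contained synthetic fixtures with known per-position, per-letter effects.

The generator plants motif occurrences in a random genome and gives each
site a ChIP-seq signal that is an exact, multiplicative (log2-additive)
function of its letters and methylation state:

    signal = background * 2 ** sum_i [ (1 - m_i) * effect[i][base_i]
                                       + m_i * effect[i][M or W] ]

where m_i is the site's methylation fraction at CpG-capable positions and
the plain effect[i][base_i] elsewhere, times optional lognormal noise.
Because the pipeline's SEM is additive in log2, parameter recovery on
these fixtures is a well-posed identity test. The consensus letter at each
position has effect 0 (the endogenous anchor).

Planted-site padding is kept free of chance kmer matches (a configurable
forbidden set is scrubbed from peak regions), so every in-peak alignment
is a planted site and the expected SEM has a closed form.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ALPHABET, Genome, IntervalSet, MethylationTrack, Motif, SignalTrack, revcomp

logger = logging.getLogger(__name__)

_COL = {x: j for j, x in enumerate(ALPHABET)}
BASES = "ACGT"


@dataclass
class SyntheticTruth:
    """Ground truth behind a fixture.

    ``effect`` is L x 6 (A, C, G, T, M, W) in log2 units; the consensus
    letter at each position must have effect 0. ``meth_beta`` parameterizes
    the per-site, per-channel methylation fraction distribution (bimodal by
    default, mirroring the mostly-extreme but non-binary fractions WGBS
    reports); ``fixed_fractions`` maps (1-based position, "M" or "W") to a
    fixed fraction and overrides the Beta draw. ``noise_sd`` is the sigma
    of multiplicative lognormal noise (natural-log scale).
    """

    consensus: str
    effect: np.ndarray
    background: float = 10.0
    noise_sd: float = 0.0
    meth_beta: tuple[float, float] = (0.4, 0.4)
    bg_meth_beta: tuple[float, float] = (7.0, 3.0)
    fixed_fractions: dict[tuple[int, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=float)
        L = len(self.consensus)
        if self.effect.shape != (L, 6):
            raise ValueError(f"effect matrix must be {L} x 6")
        for i, letter in enumerate(self.consensus):
            if abs(self.effect[i, _COL[letter]]) > 1e-12:
                raise ValueError(
                    f"consensus letter {letter} at position {i + 1} must have "
                    "effect 0 (endogenous anchor)"
                )
        if self.background <= 0:
            raise ValueError("background signal must be > 0")

    @property
    def length(self) -> int:
        return len(self.consensus)

    def motif(self, sharpness: float = 0.91) -> Motif:
        """Sharp PWM concentrated on the consensus (off-letters uniform)."""
        L = self.length
        probs = np.full((L, 4), (1.0 - sharpness) / 3.0)
        for i, letter in enumerate(self.consensus):
            probs[i, BASES.index(letter)] = sharpness
        return Motif(probs)

    def to_json(self) -> str:
        payload = {
            "consensus": self.consensus,
            "effect": [[None if np.isnan(v) else v for v in row] for row in self.effect],
            "alphabet": list(ALPHABET),
            "background": self.background,
            "noise_sd": self.noise_sd,
            "meth_beta": list(self.meth_beta),
            "bg_meth_beta": list(self.bg_meth_beta),
            "fixed_fractions": (
                None
                if self.fixed_fractions is None
                else [[pos, ch, f] for (pos, ch), f in sorted(self.fixed_fractions.items())]
            ),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        fixed = d.get("fixed_fractions")
        return cls(
            consensus=d["consensus"],
            effect=np.array(
                [[np.nan if v is None else v for v in row] for row in d["effect"]]
            ),
            background=d["background"],
            noise_sd=d["noise_sd"],
            meth_beta=tuple(d["meth_beta"]),
            bg_meth_beta=tuple(d["bg_meth_beta"]),
            fixed_fractions=None if fixed is None else {(p, c): f for p, c, f in fixed},
            seed=d["seed"],
        )


@dataclass
class PlantedSite:
    """One planted motif occurrence (coordinates on the plus strand)."""

    chrom: str
    start: int
    strand: str
    kmer: str  # motif-strand letters
    n_subs: int
    # (1-based motif position, "M" or "W") -> methylation fraction
    fractions: dict[tuple[int, str], float] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + len(self.kmer)


def generate_genome(
    length: int, gc_fraction: float = 0.4, seed: int = 0, chrom: str = "chr1"
) -> Genome:
    """Random i.i.d. genome at the stated GC content (deterministic per seed)."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    return Genome({chrom: seq})


def _cpg_channels(kmer: str) -> list[tuple[int, str]]:
    """CpG-capable channels of a kmer: (i, "M") for each in-kmer CpG's C and
    (i+1, "W") for its G (1-based positions)."""
    out = []
    for i in range(len(kmer) - 1):
        if kmer[i] == "C" and kmer[i + 1] == "G":
            out.append((i + 1, "M"))
            out.append((i + 2, "W"))
    return out


def plant_sites(
    genome: Genome,
    truth: SyntheticTruth,
    n_sites: int,
    seed: int = 0,
    mode: str = "random",
    n_subs_probs: tuple[float, float, float] = (0.05, 0.20, 0.75),
    pad: int = 20,
    min_gap: int = 10,
    forbidden: set[str] | None = None,
    overlap_forbidden: set[str] | None = None,
) -> tuple[Genome, list[PlantedSite]]:
    """Plant non-overlapping motif occurrences and assign methylation.

    Each site is the consensus with 0-2 substitutions: ``mode="random"``
    draws the substitution count from ``n_subs_probs``; ``mode="cycle"``
    cycles deterministically through the consensus and every single
    variant, giving balanced per-cell coverage. Sites get a random strand,
    flanking bases forced to A (no CpG can form across a footprint edge),
    and a methylation fraction per in-kmer CpG channel (Beta draw or the
    truth's fixed fraction). Peak padding is then scrubbed of every
    ``forbidden`` kmer (default: the Hamming<=1 ball of the consensus, on
    either strand) so no chance alignment pollutes the planted lists;
    ``overlap_forbidden`` kmers (e.g. the scrambled-baseline set) are
    scrubbed only from windows that straddle a planted footprint, so their
    pure-padding (zero-signal) occurrences survive.
    """
    rng = np.random.default_rng(seed)
    L = truth.length
    chrom = next(iter(genome.sequences))
    seq = list(genome.sequences[chrom])
    n_chrom = len(seq)

    if mode not in ("random", "cycle"):
        raise ValueError("mode must be 'random' or 'cycle'")
    if forbidden is None:
        forbidden = {truth.consensus} | {
            truth.consensus[:i] + b + truth.consensus[i + 1 :]
            for i in range(L)
            for b in BASES
        }
    forbidden = set(forbidden) | {revcomp(k) for k in forbidden}
    if overlap_forbidden is None:
        overlap_forbidden = set()
    overlap_forbidden = set(overlap_forbidden) | {revcomp(k) for k in overlap_forbidden}

    # balanced cycle: consensus + all 3L single variants
    cycle = [truth.consensus] + [
        truth.consensus[:i] + b + truth.consensus[i + 1 :]
        for i in range(L)
        for b in BASES
        if b != truth.consensus[i]
    ]

    sites: list[PlantedSite] = []
    cursor = pad + 1
    for j in range(n_sites):
        start = cursor
        end = start + L
        if end + pad + 1 > n_chrom:
            raise ValueError(
                f"cannot place {n_sites} non-overlapping sites in a "
                f"{n_chrom} bp genome (placed {j})"
            )
        if mode == "cycle":
            kmer = cycle[j % len(cycle)]
            n_subs = 0 if kmer == truth.consensus else 1
        else:
            n_subs = int(rng.choice(3, p=n_subs_probs))
            kmer = truth.consensus
            positions = rng.choice(L, size=n_subs, replace=False)
            for p in positions:
                alts = [b for b in BASES if b != kmer[p]]
                kmer = kmer[:p] + alts[int(rng.integers(3))] + kmer[p + 1 :]
        strand = "+" if rng.random() < 0.5 else "-"
        written = kmer if strand == "+" else revcomp(kmer)
        seq[start:end] = list(written)
        # A flanks: no CpG across the footprint boundary, ever
        seq[start - 1] = "A"
        seq[end] = "A"
        fractions: dict[tuple[int, str], float] = {}
        for key in _cpg_channels(kmer):
            if truth.fixed_fractions is not None and key in truth.fixed_fractions:
                fractions[key] = float(truth.fixed_fractions[key])
            elif truth.fixed_fractions is not None:
                fractions[key] = 0.0
            else:
                fractions[key] = float(rng.beta(*truth.meth_beta))
        sites.append(
            PlantedSite(
                chrom=chrom, start=start, strand=strand, kmer=kmer,
                n_subs=n_subs, fractions=fractions,
            )
        )
        cursor = end + pad + min_gap + int(rng.integers(0, 11)) + pad

    _scrub_peaks(seq, sites, forbidden, L, pad, rng,
                 overlap_forbidden=overlap_forbidden)
    return Genome({chrom: "".join(seq)}), sites


def _scrub_peaks(
    seq: list[str],
    sites: list[PlantedSite],
    forbidden: set[str],
    L: int,
    pad: int,
    rng: np.random.Generator,
    max_passes: int = 30,
    overlap_forbidden: set[str] | None = None,
) -> None:
    """Rewrite padding bases until no forbidden kmer survives in any peak
    window other than a planted footprint."""
    footprints = {(s.start, s.start + L) for s in sites}
    in_footprint = np.zeros(len(seq), dtype=bool)
    for a, b in footprints:
        in_footprint[a:b] = True
    windows = []
    for s in sites:
        lo = max(0, s.start - pad)
        hi = min(len(seq), s.end + pad)
        windows.append((lo, hi))
    # rewrites are restricted to A/T so no CpG can appear next to a footprint;
    # a window sharing L-1 bases with a planted site may have no escaping
    # rewrite at all — such windows are left in place (their partial-footprint
    # alignments are diluted, not signal-free, and are counted by any oracle)
    overlap_forbidden = overlap_forbidden or set()
    stuck: set[int] = set()

    def offending(word: str, overlaps_footprint: bool) -> bool:
        if word in forbidden:
            return True
        return overlaps_footprint and word in overlap_forbidden

    for _ in range(max_passes):
        dirty = False
        for lo, hi in windows:
            for w in range(lo, hi - L + 1):
                if (w, w + L) in footprints or w in stuck:
                    continue
                word = list(seq[w : w + L])
                overlaps = bool(in_footprint[w : w + L].any())
                if not offending("".join(word), overlaps):
                    continue
                free = [p for p in range(w, w + L) if not in_footprint[p]]
                fixed = False
                # smallest rewrite first: single-base escapes, then pairs, ...;
                # a random choice among equal-size escapes avoids the
                # deterministic flip cycles overlapping windows can fall into
                for r in range(1, len(free) + 1):
                    escapes = []
                    for combo in itertools.combinations(free, r):
                        for letters in itertools.product("AT", repeat=r):
                            if any(seq[p] == x for p, x in zip(combo, letters)):
                                continue
                            for p, x in zip(combo, letters):
                                word[p - w] = x
                            if not offending("".join(word), overlaps):
                                escapes.append((combo, letters))
                            for p in combo:
                                word[p - w] = seq[p]
                    if escapes:
                        combo, letters = escapes[int(rng.integers(len(escapes)))]
                        for p, x in zip(combo, letters):
                            seq[p] = x
                        fixed = dirty = True
                        break
                if not fixed:
                    stuck.add(w)
        if not dirty:
            break
    else:
        logger.warning("padding scrub did not fully converge in %d passes", max_passes)
    if stuck:
        logger.info("%d peak windows could not be scrubbed (footprint overlap)", len(stuck))


def site_exponent(truth: SyntheticTruth, site: PlantedSite) -> float:
    """Closed-form log2 signal exponent of one planted site."""
    total = 0.0
    meth_pos = dict(site.fractions)
    for i, letter in enumerate(site.kmer, start=1):
        base_effect = truth.effect[i - 1, _COL[letter]]
        channel = "M" if letter == "C" else "W" if letter == "G" else None
        m = meth_pos.get((i, channel)) if channel else None
        if m is None:
            total += base_effect
        else:
            total += (1.0 - m) * base_effect + m * truth.effect[i - 1, _COL[channel]]
    return total


def generate_tracks(
    genome: Genome,
    sites: list[PlantedSite],
    truth: SyntheticTruth,
    seed: int = 0,
    pad: int = 20,
    coverage: int = 30,
) -> tuple[IntervalSet, SignalTrack, MethylationTrack]:
    """Peaks, ChIP-seq signal and bedMethyl-style methylation for the sites.

    Signal covers each site's exact footprint at
    ``background * 2**exponent`` times lognormal noise; peaks are the
    footprints padded by ``pad`` bp (merged); the methylation track records
    every planted CpG channel at its assigned fraction (coverage fixed at
    ``coverage``) plus every off-site genomic CpG at a background Beta
    fraction.
    """
    rng = np.random.default_rng(seed)
    peak_tuples = []
    signal_records = []
    meth_records: dict[tuple[str, int, str], tuple[float, int]] = {}
    L = truth.length
    for s in sites:
        chrom_len = len(genome.sequences[s.chrom])
        peak_tuples.append((s.chrom, max(0, s.start - pad), min(chrom_len, s.end + pad)))
        value = truth.background * 2.0 ** site_exponent(truth, s)
        if truth.noise_sd > 0:
            value *= float(np.exp(truth.noise_sd * rng.standard_normal()))
        signal_records.append((s.chrom, s.start, s.end, value))
        for (pos, channel), fraction in sorted(s.fractions.items()):
            if s.strand == "+":
                if channel == "M":
                    key = (s.chrom, s.start + pos - 1, "+")
                else:  # W: the C paired with this G sits on the minus strand
                    key = (s.chrom, s.start + pos - 1, "-")
            else:
                if channel == "M":
                    key = (s.chrom, s.start + L - pos, "-")
                else:
                    key = (s.chrom, s.start + L - pos, "+")
            meth_records[key] = (fraction, coverage)
    # off-site background CpGs (both strands of every genomic CG)
    footprint_mask: dict[str, set[int]] = {}
    for s in sites:
        footprint_mask.setdefault(s.chrom, set()).update(range(s.start, s.end))
    for chrom, seq in genome.sequences.items():
        occupied = footprint_mask.get(chrom, set())
        idx = 0
        while True:
            idx = seq.find("CG", idx)
            if idx == -1:
                break
            if idx not in occupied and (idx + 1) not in occupied:
                for key in ((chrom, idx, "+"), (chrom, idx + 1, "-")):
                    if key not in meth_records:
                        meth_records[key] = (float(rng.beta(*truth.bg_meth_beta)), coverage)
            idx += 1
    return (
        IntervalSet.from_tuples(peak_tuples),
        SignalTrack.from_records(signal_records),
        MethylationTrack(meth_records),
    )


def sites_table(sites: list[PlantedSite]) -> pd.DataFrame:
    """Site table as a DataFrame (fractions serialized as 'pos:channel=f')."""
    rows = []
    for s in sites:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "kmer": s.kmer,
                "n_subs": s.n_subs,
                "fractions": ";".join(
                    f"{p}:{c}={f:.6f}" for (p, c), f in sorted(s.fractions.items())
                ),
            }
        )
    return pd.DataFrame(rows)


def recover_truth(
    truth: SyntheticTruth,
    sem,
    min_totals: int = 20,
    sign_effect_floor: float = 1.0,
    sign_min_totals: int = 50,
) -> dict:
    """Compare a pipeline SEM against the planted effects.

    Reports per-cell signed error (SEM score minus true effect) for cells
    with at least ``min_totals`` observations, the mean absolute error over
    those cells, and the sign-agreement rate over the stricter subset
    (|true effect| >= ``sign_effect_floor`` and totals >=
    ``sign_min_totals``).
    """
    rows = []
    for i in range(truth.length):
        for x in ALPHABET:
            j = _COL[x]
            score = sem.scores[i, j]
            if np.isnan(score) or sem.totals[i, j] < min_totals:
                continue
            true = truth.effect[i, j]
            rows.append(
                {
                    "pos": i + 1,
                    "letter": x,
                    "true_effect": true,
                    "sem_score": score,
                    "error": score - true,
                    "totals": int(sem.totals[i, j]),
                }
            )
    if not rows:
        raise ValueError(f"no cell has totals >= {min_totals}")
    cells = pd.DataFrame(rows)
    strict = cells[
        (cells.true_effect.abs() >= sign_effect_floor)
        & (cells.totals >= sign_min_totals)
    ]
    sign_agreement = (
        float((np.sign(strict.sem_score) == np.sign(strict.true_effect)).mean())
        if len(strict)
        else float("nan")
    )
    return {
        "cells": cells,
        "mae": float(cells.error.abs().mean()),
        "n_cells": len(cells),
        "sign_agreement": sign_agreement,
        "n_sign_cells": len(strict),
    }


def hamming_ball(kmer: str, radius: int) -> set[str]:
    """All kmers within the given Hamming distance of ``kmer``."""
    ball = {kmer}
    for _ in range(radius):
        ball |= {
            k[:i] + b + k[i + 1 :] for k in ball for i in range(len(k)) for b in BASES
        }
    return ball


def demo_exact_truth(seed: int = 0) -> SyntheticTruth:
    """Noise-free truth with binary methylation for exact-recovery fixtures.

    Consensus ATCTG carries no CpG; the C variant at position 4 creates a
    CpG read through the M channel (fraction fixed at 1) and the G variant
    at position 4 creates one read through the W channel (fixed at 1), so
    every populated SEM cell equals its planted effect exactly when the
    kmer universe is the consensus alone and signal is noise-free.
    """
    consensus = "ATCTG"
    L = len(consensus)
    rng = np.random.default_rng(seed)
    effect = np.zeros((L, 6))
    for i in range(L):
        for b in BASES:
            if b != consensus[i]:
                effect[i, _COL[b]] = rng.uniform(-3.0, 0.5)
    effect[3, _COL["M"]] = rng.uniform(-2.0, 2.0)
    effect[3, _COL["W"]] = rng.uniform(-2.0, 2.0)
    return SyntheticTruth(
        consensus=consensus,
        effect=effect,
        noise_sd=0.0,
        fixed_fractions={(4, "M"): 1.0, (5, "W"): 0.0, (3, "M"): 0.0, (4, "W"): 1.0},
        seed=seed,
    )


def demo_noisy_truth(seed: int = 0, noise_sd: float = 0.3) -> SyntheticTruth:
    """Noisy truth with Beta-distributed methylation (consensus ATTCAG).

    Variant effects span [-2.5, 2.5] log2 units; M/W effects at every
    position span [-2, 2] (any CpG a variant kmer creates is covered).
    The consensus itself carries no CpG, so the endogenous baseline is
    methylation-free.
    """
    consensus = "ATTCAG"
    L = len(consensus)
    rng = np.random.default_rng(seed)
    effect = np.zeros((L, 6))
    for i in range(L):
        for b in BASES:
            if b != consensus[i]:
                effect[i, _COL[b]] = rng.uniform(-2.5, 2.5)
        effect[i, _COL["M"]] = rng.uniform(-2.0, 2.0)
        effect[i, _COL["W"]] = rng.uniform(-2.0, 2.0)
    return SyntheticTruth(
        consensus=consensus, effect=effect, noise_sd=noise_sd, seed=seed
    )


def build_fixture(
    truth: SyntheticTruth,
    n_sites: int,
    genome_length: int,
    seed: int = 0,
    gc_fraction: float = 0.25,
    mode: str = "random",
    n_subs_probs: tuple[float, float, float] = (0.05, 0.20, 0.75),
    forbidden_radius: int = 1,
    pvalue: float = 4e-4,
):
    """Generate a complete in-memory fixture.

    ``forbidden_radius`` is the Hamming radius around the consensus scrubbed
    from peak padding; it must cover every kmer the pipeline will align
    (universe radius + 1 for the in-silico variant lists). The
    scrambled-baseline kmers a pipeline run at this seed and ``pvalue``
    will use are scrubbed from footprint-straddling windows only, so the
    scrambled baseline measures genuine zero-signal padding. Returns
    (genome, sites, peaks, signal, methylation, motif).
    """
    from .kmers import enumerate_kmers, pvalue_cutoff, scramble_kmers

    genome = generate_genome(genome_length, gc_fraction, seed)
    forbidden = hamming_ball(truth.consensus, forbidden_radius)
    motif = truth.motif()
    universe = enumerate_kmers(motif, pvalue_cutoff(motif, pvalue))
    scrambles = set(scramble_kmers(universe, seed))
    genome, sites = plant_sites(
        genome,
        truth,
        n_sites,
        seed=seed,
        mode=mode,
        n_subs_probs=n_subs_probs,
        forbidden=forbidden,
        overlap_forbidden=scrambles,
    )
    peaks, signal, meth = generate_tracks(genome, sites, truth, seed=seed)
    return genome, sites, peaks, signal, meth, motif


def write_fixture(
    directory,
    genome: Genome,
    sites: list[PlantedSite],
    truth: SyntheticTruth,
    peaks: IntervalSet,
    signal: SignalTrack,
    meth: MethylationTrack,
    motif: Motif | None = None,
) -> dict[str, str]:
    """Write a complete fixture (FASTA/BED/bedGraph/bedMethyl/PFM/truth.json)."""
    import os

    from .io import write_bed, write_bedgraph, write_genome, write_methylation

    os.makedirs(directory, exist_ok=True)
    paths = {
        "genome": os.path.join(directory, "genome.fa"),
        "peaks": os.path.join(directory, "peaks.bed"),
        "signal": os.path.join(directory, "signal.bedGraph"),
        "methylation": os.path.join(directory, "methylation.bedMethyl"),
        "sites": os.path.join(directory, "sites.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_genome(genome, paths["genome"])
    write_bed(peaks, paths["peaks"])
    write_bedgraph(signal, paths["signal"])
    write_methylation(meth, paths["methylation"])
    sites_table(sites).to_csv(paths["sites"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    if motif is not None:
        paths["motif"] = os.path.join(directory, "motif.pfm")
        with open(paths["motif"], "w") as fh:
            fh.write(">synthetic motif\n")
            counts = np.round(motif.probs.T * 1000).astype(int)
            for b, row in zip(BASES, counts):
                fh.write(f"{b} [ " + " ".join(str(v) for v in row) + " ]\n")
    return paths
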