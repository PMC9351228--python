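"""Domain types and readers/writers for the external file formats.

Coordinate convention: everything in memory is 0-based, half-open, on the
plus strand of the reference. Motif positions are 1-based only in output
files and plots. The SEM file family written here is this package's own
plain-text dialect (tab-separated, documented per writer).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from pyfaidx import Fasta

#: Column order of every L x 6 matrix in the package.
ALPHABET = ("A", "C", "G", "T", "M", "W")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a plus-strand sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class Genome:
    """Uppercase nucleotide sequences keyed by chromosome name.

    Non-ACGT letters are stored as N and never match any kmer.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def __len__(self) -> int:
        return len(self.sequences)


_VALID = set("ACGT")


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


def read_genome(path: str | os.PathLike) -> Genome:
    """Read a FASTA file; uppercases and maps non-ACGT letters to N.

    pyfaidx builds (or reuses) a ``.fai`` index next to the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    try:
        with Fasta(str(path)) as fa:
            for rec in fa:
                seqs[rec.name] = _sanitize(str(rec))
    except ValueError as exc:  # pyfaidx duplicate_action="stop"
        raise ValueError(f"duplicate chromosome name in {path}: {exc}") from exc
    except Exception as exc:
        raise ValueError(f"unparseable FASTA {path}: {exc}") from exc
    if not seqs:
        raise ValueError(f"no records in FASTA {path}")
    return Genome(seqs)


def write_genome(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Intervals


@dataclass
class IntervalSet:
    """Sorted, merged, non-overlapping genomic intervals per chromosome."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples) -> "IntervalSet":
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if start >= end:
                raise ValueError(f"interval start >= end: {chrom}:{start}-{end}")
            raw.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: merge_intervals(v) for c, v in raw.items()})

    def to_tuples(self):
        for chrom in sorted(self.intervals):
            for start, end in self.intervals[chrom]:
                yield chrom, start, end

    def total_length(self) -> int:
        return sum(e - s for iv in self.intervals.values() for s, e in iv)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting intervals. Idempotent."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a merged IntervalSet."""
    tuples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            tuples.append((parts[0], start, end))
    return IntervalSet.from_tuples(tuples)


def write_bed(regions: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.to_tuples():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Signal track


@dataclass
class SignalTrack:
    """Sparse per-base signal: disjoint intervals with constant values.

    Bases not covered by any interval have signal 0. Values are finite and
    non-negative (arbitrary ChIP-seq track units).
    """

    # chrom -> (starts, ends, values), each a sorted numpy array
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "SignalTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"non-finite signal value at {chrom}:{start}-{end}")
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}-{end}")
            if start >= end:
                raise ValueError(f"signal interval start >= end at {chrom}:{start}-{end}")
            per.setdefault(chrom, []).append((int(start), int(end), value))
        data = {}
        for chrom, recs in per.items():
            recs.sort()
            for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping signal intervals on {chrom} near {s2}")
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            data[chrom] = (starts, ends, values)
        return cls(data)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal value covering a single base (0 if uncovered)."""
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty query window")
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]) / (end - start))

    def max(self, chrom: str, start: int, end: int) -> float:
        """Max per-base signal over [start, end); 0 for uncovered stretches."""
        if end <= start:
            raise ValueError("empty query window")
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        best = float(np.max(values[lo:hi]))
        covered = int(np.sum(np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)))
        if covered < end - start:
            best = max(best, 0.0)
        return best

    def min_positive(self) -> float | None:
        """Smallest strictly positive stored value, or None if all zero/empty."""
        best = None
        for _, (_, _, values) in self.data.items():
            pos = values[values > 0]
            if pos.size:
                m = float(pos.min())
                best = m if best is None else min(best, m)
        return best


def read_signal(path: str | os.PathLike) -> SignalTrack:
    """Read a bedGraph (or bigWig, if pyBigWig is importable) signal track."""
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        return _read_bigwig(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                value = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed value") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative signal value {value}")
            records.append((parts[0], int(parts[1]), int(parts[2]), value))
    return SignalTrack.from_records(records)


def _read_bigwig(path: str) -> SignalTrack:
    import pyBigWig  # optional; bedGraph is the text-native route

    records = []
    with pyBigWig.open(path) as bw:
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                records.append((chrom, start, end, value))
    return SignalTrack.from_records(records)


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Methylation track


@dataclass
class MethylationTrack:
    """Per-cytosine methylation fractions from WGBS.

    One record per (chromosome, 0-based position, strand): a methylation
    fraction in [0, 1] and a read coverage. The strand is the strand that
    carries the cytosine.
    """

    records: dict[tuple[str, int, str], tuple[float, int]] = field(default_factory=dict)

    def lookup(
        self, chrom: str, pos: int, strand: str, min_coverage: int = 0
    ) -> float | None:
        """Fraction at a cytosine, or None if absent / below min coverage."""
        rec = self.records.get((chrom, pos, strand))
        if rec is None:
            return None
        fraction, coverage = rec
        if coverage < min_coverage:
            return None
        return fraction


def read_methylation(
    path: str | os.PathLike, units: str = "percent"
) -> MethylationTrack:
    """Read a bedMethyl-style TSV.

    Columns: chrom, start, end, name, coverage, strand, fraction. The
    fraction column is a percent (0-100, ENCODE convention) unless
    ``units="fraction"``. Stored internally as a proportion in [0, 1].
    """
    if units not in ("percent", "fraction"):
        raise ValueError("units must be 'percent' or 'fraction'")
    hi = 100.0 if units == "percent" else 1.0
    records: dict[tuple[str, int, str], tuple[float, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 bedMethyl columns")
            chrom, start = parts[0], int(parts[1])
            coverage = int(parts[4])
            strand = parts[5]
            raw = float(parts[6])
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            if not 0.0 <= raw <= hi:
                raise ValueError(
                    f"{path}:{lineno}: methylation value {raw} outside [0, {hi:g}]"
                )
            if coverage < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage")
            key = (chrom, start, strand)
            if key in records:
                raise ValueError(f"{path}:{lineno}: duplicate record for {key}")
            records[key] = (raw / hi, coverage)
    return MethylationTrack(records)


def write_methylation(
    track: MethylationTrack, path: str | os.PathLike, units: str = "percent"
) -> None:
    scale = 100.0 if units == "percent" else 1.0
    with open(path, "w") as fh:
        for (chrom, pos, strand), (fraction, coverage) in sorted(track.records.items()):
            fh.write(
                f"{chrom}\t{pos}\t{pos + 1}\tCpG\t{coverage}\t{strand}\t"
                f"{fraction * scale:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Motif


@dataclass
class Motif:
    """Per-position nucleotide probabilities of a binding motif.

    ``probs`` has shape (L, 4) in A, C, G, T order; every row sums to 1 and
    every entry is strictly positive (a pseudocount is added on the count
    scale before normalization).
    """

    probs: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("motif matrix must be L x 4")
        if self.length < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif rows must sum to 1")
        if not (self.probs > 0).all():
            raise ValueError("motif probabilities must be strictly positive")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25) -> "Motif":
        counts = np.asarray(counts, dtype=float) + pseudocount
        sums = counts.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise ValueError("zero-sum motif column")
        return cls(counts / sums, pseudocount=pseudocount)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=1))


def read_motif(path: str | os.PathLike, pseudocount: float = 0.25) -> Motif:
    """Read a JASPAR-style PFM (4 rows A/C/G/T, counts or frequencies).

    Accepts both the bracketed JASPAR layout (``A [ 10 2 0 ]``) and bare
    whitespace-separated rows, with an optional ``>`` header line.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            line = line.replace("[", " ").replace("]", " ")
            fields = line.split()
            if fields and fields[0].upper() in "ACGT" and len(fields[0]) == 1:
                fields = fields[1:]
            if fields:
                rows.append([float(x) for x in fields])
    if len(rows) != 4:
        raise ValueError(f"expected 4 PFM rows (A/C/G/T), found {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("unequal PFM row lengths")
    counts = np.array(rows, dtype=float).T  # (L, 4)
    return Motif.from_counts(counts, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# SEM result + file family


@dataclass
class SEMResult:
    """The final SNP effect matrix and its companions.

    ``scores`` is L x 6 (A, C, G, T, M, W) in log2 units relative to the
    endogenous baseline (NaN where no observations exist); ``stderr`` is in
    linear signal units; ``totals`` counts the observations behind each
    cell. ``scrambled_baseline`` is log2 relative to the endogenous
    baseline; ``qc_statistic`` is a -log10 mean p-value (None before QC).
    """

    scores: np.ndarray
    stderr: np.ndarray
    totals: np.ndarray
    endogenous_baseline: float
    scrambled_baseline: float
    qc_statistic: float | None = None
    qc_threshold: float = 3.15

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        shape = self.scores.shape
        if shape != self.stderr.shape or shape != self.totals.shape:
            raise ValueError("scores/stderr/totals shapes differ")
        if shape[1] != len(ALPHABET):
            raise ValueError("matrices must have 6 columns (A,C,G,T,M,W)")
        if not self.endogenous_baseline > 0:
            raise ValueError("endogenous baseline must be > 0")
        defined = ~np.isnan(self.scores)
        if (self.totals[defined] < 1).any():
            raise ValueError("defined score cell with zero observations")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def qc_pass(self) -> bool | None:
        if self.qc_statistic is None:
            return None
        return self.qc_statistic >= self.qc_threshold


def _write_matrix(path, matrix, fmt, baseline_line=None) -> None:
    with open(path, "w") as fh:
        if baseline_line is not None:
            fh.write(baseline_line)
        fh.write("pos\t" + "\t".join(ALPHABET) + "\n")
        for i, row in enumerate(matrix, start=1):
            cells = ["NA" if (isinstance(v, float) and math.isnan(v)) else fmt(v) for v in row]
            fh.write(f"{i}\t" + "\t".join(cells) + "\n")


def write_sem(result: SEMResult, prefix: str | os.PathLike) -> dict[str, str]:
    """Write the SEM file family; returns {kind: path}.

    Files: ``<prefix>.me.sem`` (log2 scores, 6 dp, ``#BASELINE`` first
    line), ``<prefix>.sterr``, ``<prefix>.me.totals`` (integer counts),
    ``<prefix>.me.baseline`` and ``<prefix>.qc``.
    """
    prefix = str(prefix)
    paths = {
        "sem": prefix + ".me.sem",
        "sterr": prefix + ".sterr",
        "totals": prefix + ".me.totals",
        "baseline": prefix + ".me.baseline",
        "qc": prefix + ".qc",
    }
    _write_matrix(
        paths["sem"],
        result.scores,
        lambda v: f"{v:.6f}",
        baseline_line=f"#BASELINE\t{result.scrambled_baseline:.6f}\n",
    )
    _write_matrix(paths["sterr"], result.stderr, lambda v: f"{v:.6f}")
    _write_matrix(paths["totals"], result.totals.astype(float), lambda v: str(int(v)))
    with open(paths["baseline"], "w") as fh:
        fh.write(f"endogenous\t{result.endogenous_baseline:.6f}\n")
        fh.write(f"scrambled\t{result.scrambled_baseline:.6f}\n")
    stat = result.qc_statistic if result.qc_statistic is not None else 0.0
    verdict = "PASS" if stat >= result.qc_threshold else "FAIL"
    with open(paths["qc"], "w") as fh:
        fh.write(f"{stat:.4f}\t{verdict}\n")
    return paths


def _read_matrix(path, baseline=False):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    base_val = None
    if baseline:
        if not lines[0].startswith("#BASELINE\t"):
            raise ValueError(f"{path}: missing #BASELINE line")
        base_val = float(lines[0].split("\t")[1])
        lines = lines[1:]
    header = lines[0].split("\t")
    if header != ["pos", *ALPHABET]:
        raise ValueError(f"{path}: unexpected header {header}")
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        rows.append([math.nan if v == "NA" else float(v) for v in parts[1:]])
    return np.array(rows, dtype=float), base_val


def read_sem(prefix: str | os.PathLike) -> SEMResult:
    """Read back a SEM file family written by :func:`write_sem`."""
    prefix = str(prefix)
    scores, scrambled = _read_matrix(prefix + ".me.sem", baseline=True)
    stderr, _ = _read_matrix(prefix + ".sterr")
    totals, _ = _read_matrix(prefix + ".me.totals")
    with open(prefix + ".me.baseline") as fh:
        endo = float(fh.readline().split("\t")[1])
        scrambled = float(fh.readline().split("\t")[1])
    qc_statistic = None
    qc_path = prefix + ".qc"
    if os.path.exists(qc_path):
        with open(qc_path) as fh:
            qc_statistic = float(fh.readline().split("\t")[0])
    stderr = np.where(np.isnan(scores) & np.isnan(stderr), np.nan, stderr)
    return SEMResult(
        scores=scores,
        stderr=stderr,
        totals=np.nan_to_num(totals, nan=0.0).astype(np.int64),
        endogenous_baseline=endo,
        scrambled_baseline=scrambled,
        qc_statistic=qc_statistic,
    )
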