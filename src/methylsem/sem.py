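"""Final SEM normalization, QC, sequence scoring and matrix analytics."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ALPHABET, SEMResult

logger = logging.getLogger(__name__)

#: QC pass threshold on the -log10 mean p-value statistic.
QC_THRESHOLD = 3.15


def normalize(
    raw_means: np.ndarray,
    raw_stderr: np.ndarray,
    totals: np.ndarray,
    endogenous: float,
    scrambled: float,
    qc_statistic: float | None = None,
) -> SEMResult:
    """log2-normalize raw mean signal to the endogenous baseline.

    score[i][x] = log2(raw[i][x] / endogenous); the baseline itself maps to
    0. Cells with raw mean 0 (log2 = -inf) are floored at
    ``scrambled - 1`` so "no signal at all" plots below the random-sequence
    reference; NaN (no observations) propagates.
    """
    if not endogenous > 0:
        raise ValueError("endogenous baseline must be > 0")
    raw = np.asarray(raw_means, dtype=float)
    if np.nanmin(raw, initial=0.0) < 0:
        raise ValueError("raw means must be >= 0")
    with np.errstate(divide="ignore"):
        scores = np.log2(raw / endogenous)
    floored = raw == 0
    scores = np.where(floored, scrambled - 1.0, scores)
    n_floor = int(np.sum(floored & ~np.isnan(raw)))
    if n_floor:
        logger.info("floored %d zero-signal cells at scrambled baseline - 1", n_floor)
    return SEMResult(
        scores=scores,
        stderr=np.asarray(raw_stderr, dtype=float),
        totals=np.asarray(totals),
        endogenous_baseline=endogenous,
        scrambled_baseline=scrambled,
        qc_statistic=qc_statistic,
    )


def denormalize(sem: SEMResult) -> np.ndarray:
    """Invert :func:`normalize` for un-floored cells (raw linear means)."""
    return sem.endogenous_baseline * np.exp2(sem.scores)


@dataclass(frozen=True)
class QCReport:
    """Signal-vs-scrambled discrimination report.

    ``statistic`` is -log10 of the mean p-value over ``n_tests`` repeated
    two-sample Welch t-tests, each drawing ``kmers_per_test`` signal values
    (with replacement) from the real and the scrambled alignments.
    """

    statistic: float
    n_tests: int
    kmers_per_test: int
    seed: int
    threshold: float = QC_THRESHOLD

    @property
    def passed(self) -> bool:
        return self.statistic >= self.threshold


def qc_statistic(
    signal_values,
    scrambled_values,
    n_tests: int = 100,
    kmers_per_test: int = 1000,
    seed: int = 0,
    threshold: float = QC_THRESHOLD,
) -> QCReport:
    """-log10 of the mean p-value of repeated signal-vs-scrambled t-tests.

    Each repeat samples ``kmers_per_test`` values with replacement from
    each side and runs a two-sided Welch t-test. Degenerate repeats (both
    samples constant) contribute p = 1. Pass requires the statistic to
    reach ``threshold``.
    """
    signal = np.asarray(list(signal_values), dtype=float)
    scrambled = np.asarray(list(scrambled_values), dtype=float)
    if signal.size == 0 or scrambled.size == 0:
        raise ValueError("both signal and scrambled samples must be non-empty")
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_tests)
    warned = False
    for t in range(n_tests):
        a = rng.choice(signal, size=kmers_per_test, replace=True)
        b = rng.choice(scrambled, size=kmers_per_test, replace=True)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate: identical constants are indistinguishable (p = 1);
            # different constants are perfectly separated (p = 0)
            pvals[t] = 1.0 if a[0] == b[0] else 0.0
            if not warned:
                logger.warning("zero-variance QC resample; degenerate p used")
                warned = True
            continue
        pvals[t] = stats.ttest_ind(a, b, equal_var=False).pvalue
    mean_p = float(pvals.mean())
    statistic = -math.log10(mean_p) if mean_p > 0 else math.inf
    return QCReport(
        statistic=statistic,
        n_tests=n_tests,
        kmers_per_test=kmers_per_test,
        seed=seed,
        threshold=threshold,
    )


_COL = {x: j for j, x in enumerate(ALPHABET)}


def score_sequence(sem: SEMResult, seq: str) -> tuple[float, list[int]]:
    """Additive log2 score of a sequence over the 6-letter alphabet.

    Returns (score, undefined positions). The score is the sum of the
    matrix cell for each letter at each position; if any cell is NaN the
    score is NaN and the offending 1-based positions are listed.
    """
    if len(seq) != sem.length:
        raise ValueError(f"sequence length {len(seq)} != motif length {sem.length}")
    total = 0.0
    undefined: list[int] = []
    for i, letter in enumerate(seq.upper()):
        if letter not in _COL:
            raise ValueError(f"illegal letter {letter!r} at position {i + 1}")
        cell = sem.scores[i, _COL[letter]]
        if math.isnan(cell):
            undefined.append(i + 1)
        else:
            total += cell
    if undefined:
        return math.nan, undefined
    return total, []


def sensitivity_profile(sem: SEMResult) -> pd.DataFrame:
    """Per-position methylation sensitivity: |C - M| and |G - W|.

    A position is flagged sensitive on a channel when the absolute log2
    difference exceeds twice the pooled standard error of the two cells
    (expressed in log2 units via each cell's linear stderr / mean). The
    returned frame has columns pos, cm_diff, gw_diff, cm_sensitive,
    gw_sensitive; the .attrs carry channel means and sensitive proportions.
    """
    rows = []
    for i in range(sem.length):
        row = {"pos": i + 1}
        for a, b, name in (("C", "M", "cm"), ("G", "W", "gw")):
            sa, sb = sem.scores[i, _COL[a]], sem.scores[i, _COL[b]]
            if math.isnan(sa) or math.isnan(sb):
                row[f"{name}_diff"] = math.nan
                row[f"{name}_sensitive"] = False
                continue
            diff = abs(sa - sb)
            row[f"{name}_diff"] = diff
            pooled = _pooled_log2_stderr(sem, i, a, b)
            row[f"{name}_sensitive"] = bool(
                not math.isnan(pooled) and diff > 2.0 * pooled
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    for name in ("cm", "gw"):
        diffs = frame[f"{name}_diff"].dropna()
        frame.attrs[f"{name}_mean_diff"] = float(diffs.mean()) if len(diffs) else math.nan
        frame.attrs[f"{name}_prop_sensitive"] = (
            float(frame.loc[diffs.index, f"{name}_sensitive"].mean()) if len(diffs) else math.nan
        )
    return frame


def _pooled_log2_stderr(sem: SEMResult, i: int, a: str, b: str) -> float:
    """Pooled stderr of two cells on the log2 scale (delta-method)."""
    ln2 = math.log(2.0)
    parts = []
    for letter in (a, b):
        se = sem.stderr[i, _COL[letter]]
        raw = sem.endogenous_baseline * 2.0 ** sem.scores[i, _COL[letter]]
        if math.isnan(se) or raw <= 0:
            return math.nan
        parts.append((se / (raw * ln2)) ** 2)
    return math.sqrt(sum(parts))


def compare_sems(
    sem_a: SEMResult, sem_b: SEMResult, subset: str = "all"
) -> dict[str, float]:
    """Squared Pearson correlation between two SEMs over shared cells.

    ``subset`` is "all" (all six columns) or "MW" (the methylated-letter
    columns only). Also reports a one-tailed Fisher r-to-z test of whether
    the correlation exceeds zero. Requires >= 3 jointly defined cells.
    """
    if sem_a.length != sem_b.length:
        raise ValueError("SEM lengths differ")
    if subset == "all":
        cols = list(range(6))
    elif subset.upper() == "MW":
        cols = [_COL["M"], _COL["W"]]
    else:
        raise ValueError("subset must be 'all' or 'MW'")
    x = sem_a.scores[:, cols].ravel()
    y = sem_b.scores[:, cols].ravel()
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} jointly defined cells; need >= 3")
    r = float(np.corrcoef(x[mask], y[mask])[0, 1])
    return {"r": r, "r2": r * r, "n": n, "p_greater_zero": _fisher_p(r, n)}


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """One-tailed Fisher r-to-z p-value that r1 > r2 (independent samples)."""
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(stats.norm.sf((z1 - z2) / se))


def _fisher_p(r: float, n: int) -> float:
    if n <= 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else 1.0
    z = np.arctanh(r) * math.sqrt(n - 3)
    return float(stats.norm.sf(z))


def kmer_score_vs_signal(
    sem: SEMResult,
    kmer_observations: dict[str, list],
    min_occurrences: int = 50,
) -> tuple[pd.DataFrame, float]:
    """Per-kmer predicted score vs mean observed ChIP-seq signal.

    Keeps kmers with at least ``min_occurrences`` alignments; x is the
    SEM score of the kmer (methylation-aware letters allowed), clamped
    below at the scrambled baseline; y is the mean aligned signal. Returns
    (table, r^2 between x and log2(y / endogenous) on positive-signal rows).
    """
    rows = []
    for kmer, obs in sorted(kmer_observations.items()):
        if len(obs) < min_occurrences:
            continue
        values = np.array([o.signal for o in obs], dtype=float)
        score, undefined = score_sequence(sem, kmer)
        if undefined:
            continue
        score = max(score, sem.scrambled_baseline)
        rows.append(
            {
                "kmer": kmer,
                "n": len(obs),
                "score": score,
                "mean_signal": float(values.mean()),
                "stderr": float(values.std(ddof=1) / math.sqrt(len(values)))
                if len(values) > 1
                else math.nan,
            }
        )
    if not rows:
        raise ValueError(f"no kmer has >= {min_occurrences} occurrences")
    table = pd.DataFrame(rows)
    positive = table[table.mean_signal > 0]
    if len(positive) >= 3 and positive.score.std() > 0:
        y = np.log2(positive.mean_signal / sem.endogenous_baseline)
        r = float(np.corrcoef(positive.score, y)[0, 1])
        r2 = r * r
    else:
        r2 = math.nan
    return table, r2
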