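"""End-to-end pipeline: motif -> kmer universe -> aligned signal -> SEM."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import alignment as al
from . import methylation as me
from .io import Genome, IntervalSet, MethylationTrack, Motif, SEMResult, SignalTrack
from .kmers import DEFAULT_PVALUE, scramble_kmers
from .sem import QC_THRESHOLD, QCReport, normalize, qc_statistic

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a run produces, for downstream analytics and file output."""

    sem: SEMResult
    qc: QCReport
    universe: list[str]
    snp_lists: dict[tuple[int, str], frozenset[str]]
    per_list_observations: dict[tuple[int, str], list]
    kmer_alignments: dict[str, list]
    unmeasured: dict[tuple[int, str], int] = field(default_factory=dict)
    r2_trace: list[float] = field(default_factory=list)


def run_pipeline(
    genome: Genome,
    regions: IntervalSet,
    track: SignalTrack,
    meth: MethylationTrack,
    motif: Motif,
    pvalue: float = DEFAULT_PVALUE,
    background=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    iterations: int = 1,
    refine_tol: float = 1e-3,
    min_meth_coverage: int = 0,
    missing_meth: str = "zero",
    signal_stat: str = "mean",
    literal_formula: bool = False,
    qc_n_tests: int = 100,
    qc_kmers_per_test: int = 1000,
    qc_threshold: float = QC_THRESHOLD,
) -> PipelineResult:
    """Run the full methylation-aware SNP-effect-matrix pipeline.

    Stages: PWM score cutoff at ``pvalue`` -> kmer universe (optionally
    refined for ``iterations`` > 1) -> 4L in-silico variant lists ->
    exact both-strand alignment inside open chromatin -> per-footprint
    ChIP-seq signal -> endogenous and scrambled baselines -> WGBS
    annotation of C/G lists -> methylated/unmethylated signal split ->
    log2 normalization -> QC t-test statistic.
    """
    universe, snp_lists, aligned, raw4, r2_trace = al.refine_iterate(
        motif,
        genome,
        regions,
        track,
        pvalue=pvalue,
        background=background,
        max_iter=iterations,
        tol=refine_tol,
        signal_stat=signal_stat,
    )
    logger.info("kmer universe: %d kmers of length %d", len(universe), motif.length)

    # endogenous baseline over the unmutated universe
    endo_aligned = {k: aligned[k] for k in universe if k in aligned}
    missing = [k for k in universe if k not in aligned]
    if missing:
        # universe kmers are a subset of every union of SNP lists, so any
        # miss means the kmer simply never occurred in open chromatin
        endo_aligned.update({k: [] for k in missing})
    endogenous = al.endogenous_baseline(endo_aligned)

    scrambled_set = scramble_kmers(universe, seed)
    scrambled_aligned = al.align_kmers(genome, scrambled_set, regions)
    scrambled_aligned = {
        k: al.attach_signal(v, track, stat=signal_stat)
        for k, v in scrambled_aligned.items()
    }
    scrambled = al.scrambled_baseline(scrambled_aligned, endogenous, track)

    per_list: dict[tuple[int, str], list] = {}
    unmeasured: dict[tuple[int, str], int] = {}
    for key, members in snp_lists.items():
        obs = [o for k in sorted(members) for o in aligned.get(k, [])]
        annotated, n_unmeasured = me.annotate_methylation(
            obs, key, genome, meth,
            min_coverage=min_meth_coverage, missing=missing_meth,
        )
        per_list[key] = annotated
        if key[1] in ("C", "G"):
            unmeasured[key] = n_unmeasured
    total_cg = sum(len(per_list[k]) for k in unmeasured)
    if total_cg:
        logger.info(
            "methylation unmeasured for %d / %d C/G-list observations",
            sum(unmeasured.values()),
            total_cg,
        )

    raw_means, raw_stderr, totals = me.build_methylated_matrices(
        per_list, literal_formula=literal_formula
    )

    signal_values = [o.signal for obs in endo_aligned.values() for o in obs]
    scrambled_values = [o.signal for obs in scrambled_aligned.values() for o in obs]
    if scrambled_values:
        qc = qc_statistic(
            signal_values,
            scrambled_values,
            n_tests=qc_n_tests,
            kmers_per_test=qc_kmers_per_test,
            seed=seed,
            threshold=qc_threshold,
        )
    else:
        # nothing scrambled aligned: no evidence of enrichment over random
        logger.warning("no scrambled alignment; QC statistic set to 0 (FAIL)")
        qc = QCReport(
            statistic=0.0,
            n_tests=qc_n_tests,
            kmers_per_test=qc_kmers_per_test,
            seed=seed,
            threshold=qc_threshold,
        )

    sem = normalize(
        raw_means, raw_stderr, totals, endogenous, scrambled, qc_statistic=qc.statistic
    )
    sem.qc_threshold = qc_threshold
    return PipelineResult(
        sem=sem,
        qc=qc,
        universe=universe,
        snp_lists=snp_lists,
        per_list_observations=per_list,
        kmer_alignments=aligned,
        unmeasured=unmeasured,
        r2_trace=r2_trace,
    )


def write_alignment_dump(result: PipelineResult, path: str) -> None:
    """TSV dump of every per-list observation (the `.me` alignment file)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tkmer\tposition\tbase\tsignal\tmethylation\n")
        for (i, b), obs_list in sorted(result.per_list_observations.items()):
            for o in obs_list:
                m = "NA" if np.isnan(o.methylation) else f"{o.methylation:.6f}"
                fh.write(
                    f"{o.chrom}\t{o.start}\t{o.end}\t{o.strand}\t{o.kmer}\t"
                    f"{i}\t{b}\t{o.signal:.6f}\t{m}\n"
                )
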