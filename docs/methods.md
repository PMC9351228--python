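# Methods

## Model

`methylsem` treats transcription factor binding affinity as log-additive
over motif positions. A site's expected ChIP-seq signal is the endogenous
level times 2 to the sum of per-position, per-letter effects; the SEM is
the inverse readout of that model from averaged signal. The extended
alphabet separates the two cytosines of a CpG: M is the methylated
cytosine read on the motif strand (it shares an in-silico SNP list with
C), W is the guanine whose *paired* cytosine on the opposite strand is
methylated (it shares a list with G). Hemimethylation is therefore
representable as M-without-W or W-without-M; no further hemimethylation
state is modelled, and non-CpG methylation is out of scope — a cytosine
outside CpG context is treated as unmethylated and counted in an
"unmeasured" tally that the pipeline logs.

Assumptions inherited from the measurement design:

- ChIP-seq signal at a locus reflects occupancy of the kmer at that locus;
  per-footprint averaging (the default `--signal-stat mean`) is the
  minimal reading of "signal for an alignment". `--signal-stat max` is
  available for narrow, spiky tracks.
- A binding site contributes only if its full L-base footprint lies inside
  an open-chromatin interval (binary containment; accessibility magnitude
  is not used as a weight).
- Motifs are strandless: both orientations of every kmer are matched, and
  a palindromic match yields one observation per strand.

## The methylation split

For each C or G list the mean signal is decomposed as

    methylated   = Σ M_k·S_k / n        unmethylated = Σ (1−M_k)·S_k / n

with M_k the WGBS fraction and n the full list size. The two components
conserve the plain mean exactly; this conservation is asserted to 1e-9 in
the test suite. The formula for the unmethylated part is sometimes printed
as Σ(1 − M_k·S_k)/n; that form mixes a dimensionless constant with signal
units and breaks conservation, so the conserving form is the default and
the literal one is kept behind `--literal-formula` for comparison only.

Because both components divide by the full list size n, the C and M cells
of one list partition its signal rather than re-estimating two independent
means. With fractional methylation the M column therefore reads "signal
share attributable to methylated copies", which equals the per-copy
methylated affinity only when site fractions are near 0/1 — one reason
WGBS's mostly-extreme fractions matter for interpretability.

`.me.totals` bookkeeping: A/T cells count all observations; M (resp. W)
counts observations with M_k > 0; C (resp. G) counts M_k < 1. A cell with
zero count is NA everywhere downstream.

## Kmer universe and threshold

The universe is every kmer with PWM log2-odds score ≥ a cutoff chosen so
the background (uniform by default, genome-derived compositions accepted)
exceeds it with probability ~p (default 4e-4, a conventional motif-scan
threshold). Column scores are rounded to 1/1000 bit and the exact rounded
score distribution is built by a column-by-column convolution; the cutoff
is the largest lattice score whose survival probability is ≥ p, ties at
the cutoff included. Enumeration is branch-and-bound on the same lattice,
so the threshold and the enumerated set are consistent by construction;
the rounding bounds the cutoff error by L/1000 bits. Universes larger
than 4^12 kmers are refused with advice to lower p.

Scrambles (for the null baseline) are per-kmer seeded letter permutations:
composition is preserved and only positional structure is destroyed.

## Refinement iteration

The optional pre-methylation refinement (`--iterations` > 1) alternates:
enumerate → align → average → rebuild the motif by normalizing each
position's four mean signals to probabilities → re-enumerate. It stops
when consecutive raw matrices reach Pearson r² ≥ 1 − tol on jointly
defined cells, and otherwise returns the best-r² iteration with a
warning. This is a deliberately simplified stand-in for a full
expectation–maximization refinement; the default is a single pass, which
makes the pipeline a pure post-processing of the starting motif's kmer
set. When a variant truly out-binds the consensus the rebuilt motif can
flip its optimum and the iteration may oscillate between two states —
that is a property of the coarse rebuild rule, and the oscillation path is
exercised in the tests.

## Normalization, QC and analytics

Scores are log2(mean / endogenous). Cells whose raw mean is exactly 0 are
floored at (scrambled baseline − 1) so they plot below the random-sequence
line instead of at −∞. The QC statistic resamples (with replacement) 1000
signal and 1000 scrambled per-alignment values, Welch-tests them, repeats
100 times, and reports −log10 of the mean p-value with a pass threshold
of 3.15. Degenerate resamples (both sides constant) count p = 1 when the
constants agree and p = 0 when they differ. Whether the t-tests should
compare per-kmer means or per-alignment values is not fixed by the
method's description; per-alignment values are used.

Sequence scoring is the sum of per-position cells, with M/W letters legal
at any position; an NA cell makes the score undefined and the offending
positions are reported. The sensitivity profile is |C−M| and |G−W| per
position; a position is called sensitive when the difference exceeds twice
the pooled standard error of the two cells (delta-method transfer of the
linear-scale stderr to log2 units) — this cutoff is this package's own
operational rule, configurable by the caller. SEM–SEM comparisons report
r² over jointly defined cells (all six columns or the M/W subset) with a
one-tailed Fisher r-to-z test; the per-kmer score-vs-signal table keeps
kmers with ≥ 50 alignments and clamps predicted scores below at the
scrambled baseline.

## Synthetic fixtures

The generator is first-class code: it emulates all five inputs with a
known truth. A random i.i.d. genome (default GC 0.4; the test fixtures
use 0.25 to thin out chance motif hits) receives non-overlapping planted
sites — consensus plus 0–2 substitutions, random strand, flanking bases
forced to A so no CpG spans a footprint edge. Each in-kmer CpG gets a
methylation fraction per strand-channel, drawn Beta(0.4, 0.4) (bimodal,
mirroring the mostly-extreme but non-binary fractions WGBS reports) or
fixed per position for exactness fixtures. Site signal is
`background · 2^Σ effects` — the same log-additive model the SEM assumes,
with the methylated-letter effect weighted by the site's fraction — times
optional lognormal noise (σ on the natural-log scale); the signal track
covers exactly the footprints, peaks are footprints ± 20 bp, and the
bedMethyl track records every planted CpG channel (coverage fixed at 30,
coverage realism being irrelevant to the method under test) plus
background genomic CpGs at Beta(7, 3) fractions.

Peak padding is scrubbed of a configurable forbidden kmer set (both
strands) by minimal A/T rewrites, so chance occurrences of list members
cannot dilute the planted averages; windows sharing L−1 bases with a
planted footprint occasionally admit no rewrite and are left (their
partial-signal alignments are seen identically by any reimplementation).
The scrambled kmers a given run seed will draw are additionally scrubbed
from footprint-straddling windows only, so the scrambled baseline measures
genuine zero-signal background rather than bleed-through from sites.

Two packaged presets define the study conditions used by the tests and
the acceptance script:

- **exact** (`demo_exact_truth`): L=5 consensus ATCTG, singleton kmer
  universe at the default p-value, balanced "cycle" planting (consensus +
  every single variant), zero noise, binary fixed methylation. Under
  these conditions every populated SEM cell equals its planted effect
  identically, which the tests verify to ~1e-16. 400 sites in a 30 kb
  genome by default; the oracle-equivalence runs use 150 sites in 12 kb.
- **noisy** (`demo_noisy_truth`): L=6 consensus ATTCAG, Hamming≤1
  universe, 500 random-mode sites (5% consensus / 15% singles / 80%
  doubles — doubles dominate, as weak near-motif sequences do in real
  peaks, and they give the variant lists enough depth for the
  50-observation analyses), lognormal noise σ=0.3, Beta methylation, in a
  42 kb genome.

What passing on these fixtures does **not** show: robustness to mapping
artefacts, fragment-size peak shape, accessibility-correlated signal,
non-CpG methylation, or motif misspecification — none of which the
generator emulates. Recovery there is an internal-consistency check of
the estimator under its own model, not a validation on real data.

## Numerical choices and degenerate inputs

- Coordinates 0-based half-open internally; motif positions 1-based in
  all outputs. ENCODE-style percent methylation is the file default
  (`--meth-units fraction` for proportions).
- Standard errors are sample SD / √n, NA below n=2; split-cell standard
  errors are taken over the weighted per-observation contributions.
- Endogenous baseline of 0 or an empty universe alignment is a fatal,
  named error; an unaligned scrambled set falls back to the smallest
  positive track value (with a warning) so the baseline stays finite.
- Missing/low-coverage/non-CpG methylation defaults to unmethylated
  (`--min-meth-coverage` defaults to 0 — no coverage filter);
  `--missing-meth drop` removes such observations from the C/G lists
  instead of zero-filling them.
- All randomness (scrambles, QC resampling, generator) flows from one
  integer seed; equal seeds give byte-identical output files.

## Problem sizes

Test and acceptance fixtures use 12–150 kb genomes, motifs of length 4–6
and 150–2000 planted sites; at these sizes the full suite runs in well
under a minute and the acceptance script in ~10 seconds on one CPU, while
exercising every stage at depths (≥ 20–50 observations per matrix cell)
where the averaging behaviour is already representative.
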