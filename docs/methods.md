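# Methods

This note documents the models, parameter choices and numerical conventions
behind `estmine`, and what the synthetic-data validation does and does not
demonstrate.

## Read QC

Adapter trimming removes the longest terminal overlap of any supplied
adapter, ungapped: a suffix of the adapter against the read's 5' end or a
prefix against the 3' end, requiring at least 8 overlapping bases with at
most `floor(0.1 × overlap)` mismatches.  Interior adapter copies are left
alone — terminal contamination is the 454 library artifact being modelled,
and removing interior matches would destroy real sequence on chimera-free
reads.  Both the minimum overlap and the mismatch rate are parameters;
adapter sequences are always user-supplied.  Trimming runs before length
filtering.  The length cutoff is strict (*shorter than* 50 bp is removed), so
a 50-bp read survives; 50 bp is also the smallest admissible simulated read.

## miRNA discovery

**Homology scan.**  Mature miRNAs are conserved; precursors are not.  Each
mature reference sequence (RNA, 19–25 nt) is placed ungapped and full-length
at every offset of every read, on both strands, in DNA space; placements
with Hamming distance ≤ 2 are kept.  "Mismatch" here means substitution
only — indel-tolerant matching would blur the conservation signal the method
relies on — and G:U wobble is *not* honoured at this stage, since the scan
compares cDNA sequence, not an RNA duplex.  Windows containing N are
suppressed.  The scanner is vectorized (numpy sliding windows); the suite
checks it against a brute-force enumeration, position by position.

**Noncoding filter.**  Candidate reads must look noncoding.  Three signals
apply in a fixed precedence: an externally supplied table of
protein-homology hits (the strongest evidence, e.g. BLASTX results), a
six-frame ORF heuristic (coding if some ATG→stop frame reaches 100 codons),
then a repeat-coverage fraction (bases under homopolymers ≥ 10 nt or
default-threshold SSRs; reads above 0.5 are dropped).  The 0.5 ceiling is
deliberately permissive because genuine precursor hairpins contain inverted
repeats.  ORFs still open at the read end are not counted: a truncated CDS
leaves no stop-pattern evidence either way on a single-pass fragment, and
the external-hit route is the proper detector for those.

**Precursor windows.**  Around each match, windows are excised at a flank
ladder of 20/40/60/90/130 nt on each side (clipped at read ends; minus-strand
matches reverse-complemented so the mature reads in sense).  The ladder
spans achievable precursor lengths of roughly 57–282 nt around a 21-mer,
bracketing the 68–294 nt range typical of plant pre-miRNAs.  Windows
shorter than mature + 16 nt cannot hold a star arm plus loop and are
dropped.

**Hairpin assessment.**  Structures come from a pluggable engine: ViennaRNA
(`RNA.fold`, default) or precomputed dot-bracket fixtures for folding-free
runs.  From the pair table, the mature's paired bases must all point to one
side: downstream partners → 5' arm, upstream → 3' arm; mixed directions,
pairing within the mature itself, or a fully unpaired mature make the
candidate "spanning" and reject it.  Up to 6 unpaired mature bases are
tolerated, of which the interior ones (bulges/internal loops between the
first and last paired mature position) are counted as mature/star
mismatches, also capped at 6.  These caps follow the conventional criterion
set used with the MFEI screen; all are parameters.

**MFEI screen.**  MFEI = (|MFE|/L × 100) / GC%, with GC% a percentage
*number* (22, not 0.22) — the convention is forced by the arithmetic of the
published candidate table, every row of which the suite reproduces at two
decimals.  Candidates with MFEI ≥ 0.85 pass; the threshold is inclusive and
guarded by a 1e-9 epsilon so an exactly-boundary value cannot be lost to
float round-trip.  Per read × mature family (miRBase name minus species
prefix), the passing window with the greatest MFEI is kept; ties prefer the
shorter precursor, then the lower mature start, making output independent of
candidate order.  MFE is stored signed; reports print magnitudes, matching
the table convention.

**Summary statistics.**  Means and dispersions over mature length, |MFE|,
precursor length and MFEI; SD uses the sample (n−1) convention, with the
caveat that published "±" values rarely state one — assertions are made
only on means, counts and ranges.  Rounding is half-up and happens only at
the report boundary.

## Target prediction

Plant miRNAs pair near-perfectly with their mRNA targets, so scanning is
ungapped: each mature-length window on the unigene *sense* strand (targets
are mRNAs) is scored antiparallel against the mature — Watson–Crick pair 0,
G:U wobble 0.5, anything else 1.0, N always 1.0.  Sites with total penalty
≤ 4.0 are reported; the cutoff is the standard EST-complementarity budget,
is configurable, and is echoed in every report header.  Overlapping windows
of one miRNA on one unigene collapse to the minimum-penalty window
(leftmost on ties).  A zero penalty is equivalent to the site being the
exact reverse complement of the mature, a biconditional the suite tests on
random inputs.  Bulged (gapped) sites are out of scope; the ungapped scheme
keeps the scoring exactly checkable against a lookup-table oracle.

## SSR detection and primers

A perfect SSR is a maximal tandem run of a primitive motif (2–6 nt) meeting
the per-length minimum repeat count {2:6, 3:5, 4:4, 5:4, 6:4}.  Runs are
attributed to the primitive motif at the leftmost position of the maximal
run — (AT)×6 is never reported as (ATAT)×3 or from a mid-run offset — and
partial trailing copies do not increase the count.  Runs containing N are
excluded; mononucleotides are not searched.  Interrupted ("compound")
repeats count as their component perfect runs, a deliberate dialect
difference from full MISA output that matches a matrix organized purely by
motif length × repeat number.  Motif classes are canonical over rotation
and strand (label "X/Y", X the smallest rotation over both strands); the
di-nucleotide rows of any summary have structurally empty 4- and 5-repeat
bins because the di threshold is 6.  Density is SSRs per Mb of summed
sequence at one decimal.

Primer design is a reduced, deterministic Primer3-style search: every
left/right placement satisfying the hard constraints (product 100–300 nt
spanning the repeat, primer 18–24 nt, GC 40–65%, no N) is enumerated and
scored with explicit weights — 1.0 per nt from the 20-nt optimum, 1.0 per °C
from 60 °C, 0.1 per GC-point from 50%, plus 2.0 per °C of pair Tm
difference.  Tm is the basic long-oligo formula 64.9 + 41(GC−16.4)/L.
Ties prefer the smaller product, then the leftmost pair.  There are no
dimer/hairpin or specificity checks: the constraint set is the point, and a
test re-validates every returned pair against an independent checker and a
brute-force optimum on small inputs.

## Collection reports

Length summaries are exact integer tallies (count, bases, mean at 1 dp,
range, percent of sequences strictly over 400 bp).  The four-set Venn
partition assigns each id to exactly one of 15 membership regions;
"private to X" always means the singleton region, never X's marginal total,
and the report headers say so.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a 454-style EST survey: background reads of
50–700 bp with i.i.d. bases at a configurable GC fraction (default 0.45),
plus carrier reads for planted features, one feature per read so truth is
unambiguous.  Planted pre-miRNAs are genuine extended stem-loops:
[flank][mature][loop][star][flank'], star the reverse complement of the
mature with k substitutions at non-terminal positions, flank' the reverse
complement of flank — real pre-miRNA stems extend past the mature duplex,
and the continued stem is also what makes ViennaRNA recover the intended
topology robustly.  Each hairpin ships with a declared structure under a
stub energy model of −2.0 kcal/mol per paired base, so hairpin topology and
MFEI arithmetic are testable bit-exactly without a folding engine.  Planted
target sites are built by editing an exact complement with wobbles (0.5)
and mismatches (1.0) to hit a requested penalty budget exactly; budgets
must be multiples of 0.5 and half-units need a G/U in the mature.  Coding
reads carry one ATG→stop ORF of 100–159 codons.  Planted SSRs are embedded
with boundary bases chosen so the maximal run is exactly the planted one.

To make detector *precision* measurable against the truth table, every
generated read — background, contexts, hairpin, coding and target carriers —
is rejection-sampled until it contains no chance default-threshold SSR:
any SSR present in a collection is therefore a recorded planting.  The
default reference conditions (`default_study_config`) are 500 background
reads, eight hairpins using non-repetitive published mature sequences
(repeat-rich matures like miR5658/miR5021 are excluded because their mature
sequences are themselves SSRs), an SSR ladder across motif lengths 2–6,
target budgets 0–3, and 20 coding reads.  All randomness flows from a
single integer seed through numpy's PCG64; a fixed seed reproduces the
collection byte for byte, and sub-seeds stay below 2³¹.

What passing these tests shows: the detectors recover exactly what the
models say they should, at the stated thresholds, on data matching the
models' assumptions.  What it does not show: robustness to 454 homopolymer
errors, quality artifacts, chimeras, assembly errors, Markovian base
composition, overlapping features, or diverged (rather than planted)
homology — none of which the generator emulates.

## Problem sizes

The suite and the analysis scripts run the full pipeline on one seeded
collection of ~550 reads (500 background + 53 carriers), which exercises
every stage including ~40 ViennaRNA folds, and the oracle-equivalence
checks use 100–500 randomized small instances per operation.  These sizes
were chosen so the entire validation completes in seconds while every
planted configuration (arm, mismatch count, motif length, penalty budget)
appears at least once.

## Known limitations

* The coding filter's ORF heuristic is a desk-scale stand-in for database
  homology; with no external hit table, truncated CDS fragments shorter
  than 100 codons pass as noncoding.
* Ungapped matching throughout (homology scan and target scan): bulged
  duplexes are invisible.
* The MISA dialect differences above (compound repeats, mononucleotides).
* Primer Tm ignores salt and thermodynamic nearest-neighbour effects, and
  no cross-dimer screening is done.
* `venn_partition` is fixed at four sets; other arities are out of scope.
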