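# Methods

## The screening model

A clonal cell line edited by CRISPR-Cas9 is genotyped from a single pooled
sequencing run of per-well barcoded amplicons.  The method assumes:

* one plate, one pooled library, single-end reads long enough to reach both
  in-line barcodes (hence the ~200 bp amplicon: the guide site with ~100 bp
  flanks, short enough for full-length single-end reads, long enough to
  catch deletions of tens of bases);
* well identity is carried by the *pair* of a column (forward) and row
  (reverse) barcode, so c + r oligos index c × r wells;
* the clone is diploid: at most two true alleles per well; more called
  alleles imply a non-clonal well (MIXED);
* NHEJ places real edits at the cut site, so only variants within a window
  of the expected cut define alleles; distal variants are artifact
  candidates.

## Demultiplexing

Barcode matching is anchored (5′ prefix for the leading barcode; 3′ suffix
with a 0–2 base slop for the trailing one) rather than scanned, because the
library structure is fixed.  Both orientations are tried; the orientation in
which the column barcode leads is "plus".  Tolerance is 1 mismatch per
barcode by default; equal-distance ties between distinct barcodes are
discarded rather than broken, since a silently misassigned read corrupts a
genotype downstream.  With the packaged barcode set (pairwise edit distance
≥ 5, including against reverse complements) a misassignment under 1-mismatch
tolerance would require four coincident in-barcode errors, i.e. it is
effectively impossible; the distance-5 margin was chosen for exactly this
head-room over the validator's default minimum of 3 (which guarantees safety
only for error-free reads).

## Alignment

The aligner is a three-state (Gotoh) affine-gap dynamic program, glocal:
the trimmed read must align end to end, reference overhangs are free.  A
gap of length k costs `open + k·extend`; the defaults (match +2, mismatch
−4, open 5, extend 1) keep a 13 bp deletion at cost 18 versus 52+ for a
mismatch run, which is what preserves CRISPR deletions as single CIGAR `D`
blocks.  The DP kernel is numba-compiled and releases the GIL (thread-based
per-well parallelism stays byte-identical to serial execution).  Traceback
ties prefer matches over gaps and gap extension over opening; emitted indels
are then left-normalized per variant (shifted maximally left within repeats,
guarded so a deletion never reaches the alignment's first reference column)
and the CIGAR is rebuilt from the normalized variants.  This makes allele
representations canonical: the same physical indel in a homopolymer always
yields the same signature.  Reads scoring below `0.4 × match × read length`
are unalignable and counted per well.

Correctness is checked two independent ways in the test suite: a cubic
gap-cost-function DP (a structurally different algorithm from the Gotoh
recurrence) and Biopython's `PairwiseAligner` configured with the same
model; scores agree on hundreds of randomized instances.

## Artifact discrimination

Two signals separate sequencing errors from true alleles, automating what
is otherwise a visual browser call:

* **Strand bias.**  A true allele is amplified from both template strands
  and should appear in plus- and minus-oriented reads at roughly the well's
  overall orientation balance.  Each distinct variant gets an exact
  two-sided binomial test of its plus count against the well's plus
  fraction; it is *biased* only if p < α (default 0.01) **and** its plus
  fraction is extreme (≥ 0.9 or ≤ 0.1).  The extremity guard supplies the
  specificity — the filter is a screen, not an inference, so α is left
  uncorrected.  At screen-scale depths (hundreds of reads per artifact)
  the binomial p-value is astronomically small, giving the observed 100%
  sensitivity; the guard keeps balanced alleles at any fraction ≥ 0.2 from
  ever being flagged (P(≥90% one strand) is negligible at ≥ 60 reads).
* **Recurrence.**  Platform artifacts repeat at the same reference position
  across wells.  Out-of-window, strand-biased variants observed at the same
  (position, kind) in ≥ 3 wells are blacklisted plate-wide; 3 is chosen so
  a true allele shared by duplicate clones can never be blacklisted, and
  in-window strand-balanced variants are excluded from the blacklist by
  construction.

Substitutions within the window may define alleles (point edits are real
outcomes), but a substitution-only allele must additionally clear a
stricter gate — fraction ≥ 0.25 and non-extreme strand balance — because
single-base errors dominate the platform's noise; failures fold back into
the wildtype signature and are flagged (`strand_bias` if one-stranded,
`low_support` otherwise).

## Allele calling and zygosity

Variants are collected within ±25 nt of the cut site (covers every edit a
200 bp amplicon is designed to catch while excluding distal artifact
hot-spots).  Identical filtered signatures collapse; signatures at fraction
≥ 0.20 are called alleles, fractions in [0.05, 0.20) are reported as
minor-allele evidence (actionable — re-streak the clone — without
overcalling MIXED), and smaller ones are dropped as noise.  The 0.20
threshold tolerates binomial depth noise at the ~300× minimum depth the
coverage gate implies.  Wells with fewer than 100 aligned reads are
NO_CALL.  Classification then follows the diploid composition rules, with
wildtype counted as an allele when judging "more than two alleles": a
wt + two-mutant well is MIXED, not compound heterozygous, because a true
diploid clone cannot carry three alleles.  Cohort summaries report both
mutation-rate conventions (excluding NO_CALL wells, and counting them as
insult), since screens quote either.

Frameshift annotation is the net indel length mod 3 per allele, available
when the layout provides the amplicon's coding-frame offset.

## The simulator

The generator emulates the screen's study conditions: per-well allele
mixtures built by editing the reference amplicon's interior; read structure
`barcodeF + fwd primer + core + rc(rev primer) + rc(barcodeR)`; orientation
Bernoulli(0.5); lognormal per-well depth with mean 2455× and σ = 0.6
(reproducing a ~300–6600× spread over 67 wells); substitution errors at
0.2%/base; homopolymer ±1 indels at `0.005 × (L − 2)` per run of length
L ≥ 3, capped at 0.1 (the platform's dominant, length-dependent error
mode); optional strand-restricted recurrent artifacts at fixed positions;
optional elevated barcode-region error rate.  `make_paper_cohort` builds a
67-well plate whose true classes follow the reference tally
(10 homozygous / 27 compound het / 4 het / 2 wildtype / 21 mixed /
3 forced-NO_CALL wells staged at depth 30, below the gate), with mutant
indel sizes drawn 1–30 nt and kept distinct within a well; mixed wells get
three alleles at ~1/3 each, half of them retaining a wildtype allele.

What the simulator does **not** model: flow-space signal and proper quality
scores (all bases Q40), chimeric PCR products, primer-dimer, index hopping,
coverage gradients along the amplicon, or contamination between wells.
Passing tests therefore demonstrate the algorithmic correctness of
demultiplexing, alignment, filtering and classification under a realistic
error budget — not robustness to every failure mode of real libraries.

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based in every report and
  config file; report positions are cut-site-relative with no position 0.
* Alignment tie-breaks and allele sort order are fully deterministic, so
  identical inputs reproduce identical reports (asserted in tests).
* QC bounds are closed intervals; the mean is taken over wells with ≥ 1
  read.
* The end-to-end recovery suite runs at depth 1000 per well and the worked
  example at 400× — comfortably above the 100-read coverage gate while
  keeping the default test run fast; recovery is class-exact at these
  depths.
* Barcode-set validation uses Hamming distance for equal lengths and edit
  distance otherwise (barcode sets of slightly varying length are common);
  the layout stores per-barcode lengths rather than assuming 10 nt.
* Plate geometry is fixed at rows A–H × columns 1–12; smaller (partial)
  plates are allowed, larger rejected.

## Known limitations

* Zygosity classes assume diploidy; polyploid lines will surface as MIXED
  whenever more than two alleles are real, and allele counts should be read
  directly in that case.
* Large structural outcomes (whole-amplicon loss, insertions beyond the
  read length, inversions) are invisible: an allele must amplify and align
  to be counted, and homozygous whole-amplicon deletion manifests only as
  missing coverage (NO_CALL).
* The strand-bias filter needs both orientations present; a well with
  extremely skewed orientation balance (or paired-end data reduced to one
  mate) weakens it, though the binomial test conditions on the well's own
  balance.
* Alignment is to the amplicon only; off-target integrations or
  pseudogene co-amplification would demand genome-scale mapping, which is
  out of scope.
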