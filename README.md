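# ampliclone

Genotyping CRISPR-Cas9 edited cell clones from one pooled amplicon
sequencing run.

After transfecting cells with Cas9 and a guide RNA, every clonal line must
be screened for the indels that non-homologous end joining left at the cut
site — and for whether *both* alleles were hit, and whether the "clone" is
actually a mixture of several founder cells.  `ampliclone` implements a
plate-scale screening strategy built on combinatorial barcoding: a ~200 bp
amplicon spanning the guide site is amplified in each well of a 96-well
plate with fusion primers carrying a **column** barcode on the forward
primer and a **row** barcode on the reverse primer, so 12 + 8 = 20 oligos
uniquely label 12 × 8 = 96 clones.  The products are pooled, sequenced
single-ended (Ion-Torrent-style), and this package does the rest in silico:

1. **demux** — each read is assigned to a well by its (column, row) barcode
   pair, tried in both orientations (reads enter from either adaptor); the
   orientation is the per-read strand label used later.
2. **align** — the trimmed read is aligned glocally (read-global,
   reference-local) to the amplicon under an affine gap model in which a
   gap of length *k* costs `open + k·extend` (default 5 + k), so a 30 bp
   CRISPR deletion survives as one CIGAR `D` block instead of being
   shredded.
3. **variants** — per-read variants within ±25 nt of the cut site define
   indel *allele signatures* (left-normalized so homopolymer-equivalent
   indels collapse); sequencing artifacts are removed automatically by an
   exact binomial **strand-bias test** (true alleles appear on both read
   orientations; artifacts on one) and a **cross-sample recurrence**
   blacklist (artifacts recur at the same position in many wells).
4. **genotype** — each well's called alleles map to
   WILDTYPE / HETEROZYGOUS / HOMOZYGOUS / COMPOUND_HETEROZYGOUS / MIXED
   (more than two alleles, wildtype included ⇒ the well is not clonal),
   with NO_CALL below the coverage gate; cohort summaries include the
   biallelic-disruption count (homozygous + compound heterozygous).
5. **qc** — the pooling-uniformity rule: wells outside
   [mean/5, 5 × mean] depth are flagged.
6. **simulate** — a ground-truth generator (allele mixtures, lognormal
   depth, substitution + homopolymer-indel errors, strand-restricted
   recurrent artifacts) that makes every stage testable end to end.

The published barcode subset and amplicon sequence of the screen this
models are not available, so the packaged example layout is synthetic
(deterministically generated; barcodes have pairwise edit distance ≥ 5).

## Worked example

Simulate the screen's worked clone — a compound heterozygote carrying a
1 bp deletion on one allele and a 13 bp deletion on the other, 50/50 at
400× depth — then genotype it:

```sh
ampliclone simulate --cohort a6 --depth 400 --seed 1 --out pool.fastq
ampliclone genotype --fastq pool.fastq --out reports/
```

which prints:

```
wells analysed: 1
  wildtype:               0
  heterozygous:           0
  homozygous:             0
  compound heterozygous:  1
  mixed (>2 alleles):     0
  no call:                0
biallelic disrupted (hom + compound het): 1
mutated: 1/1 of called wells (100.0%)
mutated incl. no-call: 1/1 (100.0%)
```

and `reports/allele_table.tsv` lists the two alleles with their
strand-split support (positions are 1-based relative to the cut site):

```
well  rank  allele     read_count  plus  minus  fraction  frameshift
A6    1     del1@-2    186         86    100    0.4709    frameshift
A6    2     del13@-7   173         92    81     0.438     frameshift
```

Both deletions sit at ~50% with balanced plus/minus support — the
hallmark of real alleles rather than strand-biased sequencing errors —
so the clone is called `COMPOUND_HETEROZYGOUS` with both alleles
frameshifting.  A full-plate run works the same way via
`ampliclone run --fastq pooled.fastq --layout layout.yaml --out reports/`
(optionally `--sam-out` for per-well SAM + reference FASTA loadable in
IGV).

## Layout of the code

```
src/ampliclone/
  plate.py      barcodes, plate geometry, combinatorial well enumeration
  demux.py      anchored dual-barcode read assignment and binning
  align.py      affine-gap glocal aligner (numba kernel), SAM output
  variants.py   allele signatures, strand-bias + recurrence filters
  genotype.py   zygosity classes, frameshift annotation, cohort summary
  qc.py         coverage-uniformity rule
  simulate.py   ground-truth read simulator and cohort builder
  io.py         FASTQ/FASTA/YAML/TSV round-tripping
  pipeline.py   end-to-end workflow + reports + run manifest
  cli.py        ampliclone {design,simulate,demux,genotype,qc,run}
```

See `docs/methods.md` for the model and parameter rationale and
`docs/FORMATS.md` for every file format written.
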