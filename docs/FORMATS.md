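# File formats

All positions in user-facing files are **1-based**; allele notations are
relative to the cut site with no position 0 (−1 is the base left of the
cut, +1 the base right of it).  Internally the package is 0-based
half-open.

## Layout config (YAML)

```yaml
column_barcodes:            # <=12, forward/column role
  - {id: COL01, sequence: ACGTACGTAC}
row_barcodes:               # <=8, reverse/row role
  - {id: ROW01, sequence: TTGCAATGGC}
fwd_target_primer: ...      # must equal the reference prefix
rev_target_primer: ...      # its reverse complement must equal the suffix
reference_amplicon: ...     # inline; or reference_fasta: path/to.fasta
cut_site: 101               # 1-based position of the expected cut
flank: 100                  # optional bookkeeping
frame_offset: 0             # optional; enables frameshift annotation
```

## Demultiplexing outputs

* `<run>_<well>.fastq` — raw (untrimmed) reads per well, e.g.
  `run1_A6.fastq`; plus `<run>_unassigned.fastq`.
* `demux_summary.tsv` — columns `well`, `reads`, `fraction` (of total
  input reads); final row `unassigned`.

## Report TSVs

Every report starts with the comment line `# manifest: manifest.json`
naming the manifest that produced it; read them with
`pandas.read_csv(..., sep="\t", comment="#")`.

* `allele_table.tsv` — `well, rank, allele, read_count, plus, minus,
  fraction, frameshift`.  Allele notation: `del13@-7`, `ins3@+1(ACG)`,
  `sub@-40(A>G)`, `WT`; multiple variants join with `;`.
* `genotype_report.tsv` — `well, class, n_reads, n_aligned, n_unmapped,
  alleles, fractions, minor_allele_evidence`.
* `cohort_summary.tsv` / `.txt` — per-class tallies, biallelic-disrupted
  count, both mutation-rate conventions.
* `qc_report.tsv` — `well, depth, flagged` under the [mean/5, 5×mean]
  rule.
* `artifacts.tsv` — `well, variant, reason, evidence` (reason one of
  `strand_bias`, `recurrent_across_wells`, `low_support`; `well = *` rows
  are plate-wide blacklist entries).
* `manifest.json` — tool version, layout hash, every effective parameter,
  input paths, timestamp, report list.

## SAM output (`--sam-out`)

One SAM per well against the single `amplicon` reference (written
alongside as `amplicon.fasta`), suitable for IGV.  Minus-orientation reads
carry flag 16 with SEQ stored in reference frame.  MAPQ is fixed at 60.

## Simulator truth tables

* `<prefix>_reads.tsv` — `read_id, well, orientation, allele_index,
  allele`.
* `<prefix>_wells.tsv` — `well, true_class, depth, alleles, fractions`.
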