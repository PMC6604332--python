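# chromwalk

Targeted local assembly of homologous gene loci from short sequencing
reads by recursive *in silico* chromosome walking.

Given a probe — a protein or cDNA sequence from a related species — and
one or more unassembled short-read libraries, `chromwalk` iteratively
recruits reads that match the current query set, completes read pairs,
locally assembles the recruited pool into contigs, and uses those contigs
(low-complexity-masked) as the next round's queries. Each round extends
the contigs outward from the probe's exons into introns and flanking
sequence, until a *hit contig* emerges — one whose spliced alignment to
the probe reaches the length, similarity and query-coverage thresholds —
or another stopping criterion fires. Whole-genome assembly of the library
is never required: only the reads relevant to the locus of interest are
ever assembled, so a single gene can be recovered from raw read deposits
in minutes.

Who it is for: anyone with unassembled (or poorly assembled) genome or
RNA-seq read sets who needs specific gene loci — orthologs, paralogs,
promoter regions — rather than a genome: population-genomics read
collections, pilot sequencing runs, coverage triage before committing to
a full assembly.

## Method

One walking round, starting from query set *Q* (the probe in round 1):

1. **Recruit.** Find every read sharing an exact substring of at least
   *m* characters with some query (*m* = 20 nt in DNA space; for protein
   probes, 8 aa against all six reading-frame translations of the reads).
   Reads are pre-indexed by k-mer (k = 15 nt / 5 aa) in chunks that are
   searched independently, so results are identical for any worker count.
2. **Complete pairs.** If either mate of a pair matched, both are kept.
3. **Assemble.** The entire found pool (error-corrected against its own
   k-mer spectrum) is assembled with a canonical-k-mer de Bruijn graph at
   each k in {15, 25, 35, 45}; tips are clipped, bubbles popped, pieces
   split at k-specific junctions re-joined on unambiguous end overlaps.
   The assembly whose best contig yields the greatest spliced-alignment
   length to the probe wins the sweep (ties to larger k).
4. **Mask and re-query.** Surviving contigs (>= 200 bp) are DUST-masked
   and become the next round's queries. Contigs above 10 kb are retired;
   every fourth round (or above 500 contigs) non-matching contigs and
   their reads are culled.

Stopping criteria: (1) a hit contig exists — length >= 200 bp, spliced
alignment similarity >= 0.5 and probe coverage >= 0.8; (2) no new reads
were recruited; (3) the round limit is reached; (4) every contig reached
the maximum length. `-f` ignores criterion 1; `-E n` runs n extra rounds
after the first hit.

The spliced aligner maps the probe onto genomic contigs with intron-scale
gaps on the contig axis only (free when flanked by GT...AG), reporting
similarity (identities / aligned probe positions) and probe coverage.

A synthetic-data module generates genomes with planted multi-exon genes,
cross-species probes diverged to a target protein identity, and
wgsim-style paired-end reads (70 bp, insert 340 +/- 50, 2% base error,
10% of errors as 1 bp indels), so the entire workflow is testable without
any external data.

## Worked example

```bash
# a 60 kb genome with one 3-exon gene at 20 kb, 20X paired-end reads,
# and a protein probe diverged to 85% identity
chromwalk simulate --length 60000 --coverage 20 --gene-start 20000 \
    --exons 300,300,300 --introns 200,250 --seed 3 -o demo

# walk: protein probe against the simulated library
chromwalk walk -q demo_probe.faa -t protein -1 demo_1.fastq -2 demo_2.fastq \
    -n 8 -o demo_out
```

which prints:

```
stop=hit rounds=1 contigs=1 hits=1
  round 1: +312 reads (312 total), 1 contigs, best k=45, coverage=1.00
```

Round 1 recruits the 312 reads matching the probe's exons (plus their
mates, which spill into the introns); at 20X that pool already assembles
into a single contig spanning the whole gene, the spliced alignment
covers 100% of the probe, and the recursion stops on the hit criterion.
At lower coverage the same walk takes several rounds, each extending the
contigs further outward. `demo_out/` contains `all_contigs.fasta`,
`hit_contigs.fasta`, the per-contig spliced-alignment report
`output.aln`, exon structures in `hits.gff3`, and the per-round history
table `history.tsv`.

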