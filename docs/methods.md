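# Methods

## The walking model

`chromwalk` recovers one genomic locus homologous to a probe sequence
from unassembled short reads. The model is iterative read baiting plus
local assembly: reads that share sufficient exact sequence with the
current query set are presumed to originate at or near the target locus;
assembling all reads recruited so far produces contigs whose ends reach
beyond the previous query boundary, so each round's queries cover more of
the locus and its flanks. The recursion is anchored by the probe: a
protein or cDNA from a related species whose exonic sequence is
conserved well enough (roughly >= 70-80% amino-acid identity) for exact
substring seeds to exist.

Assumptions worth making explicit:

* reads are short (tens of bp) and approximately uniformly drawn, with a
  substitution-dominated error process;
* the target locus is essentially single-copy in the recruited
  neighbourhood — heavy segmental duplication defeats both recruitment
  specificity and de Bruijn assembly, which is why periodic cleaning and
  the contig cap exist;
* introns are bounded by a few kb, so exon-anchored islands merge within
  a few rounds of mate-pair spillover and walking.

## Recruitment (exact-substring matching)

Reads are chunked (500,000 per chunk by default), uppercased, and indexed
by DNA 15-mers on both strands plus amino-acid 5-mers over all six frame
translations (translations break at stop codons and non-ACGT bases).
Matching extends an index seed to a maximal exact match and accepts the
read when the match reaches `min_match`.

Defaults: `min_match_dna = 20` nt, `min_match_prot = 8` aa. These floors
balance two failure modes. Too low, and random collisions recruit
background reads (at 20 nt the expected number of chance 20-mer matches
between a 10 kb query set and millions of 70 bp reads is far below one
read per round; at 8 aa likewise). Too high, and genuine frontier reads
are rejected: with a 2% per-base error rate the probability that a read
overlapping a contig end by 30 bp presents an error-free 30-mer is only
~0.55, which measurably starves the walking frontier and, for diverged
probes, misses exon ends where identity runs are short (at 85% protein
identity a 10-aa exact run occurs in only ~20% of windows). Lowercase
(DUST-masked) query positions seed nothing but may be crossed by
extension, so repeats recruit nothing on their own.

Chunks are searched independently and the union taken; output is
byte-identical for any worker count.

## Assembly

The found pool is reassembled from scratch each round:

1. **Error correction.** Substitution errors are corrected against the
   pool's own k-mer spectrum (k = 15): a k-mer observed >= 2 times is
   trusted; scanning each read, the first weak k-mer after a solid one
   implicates its final base, and the substitution that restores a solid
   window is applied (at most 4 per read; the reverse complement is
   scanned to catch read-start errors). Regions without redundancy are
   left untouched. Indels are not corrected.
2. **Graph.** Canonical k-mers (lexicographic minimum of k-mer and
   reverse complement; k odd, so never self-complementary) with counts;
   N-containing k-mers excluded.
3. **Cleanup.** Three error signatures: count-1 k-mers competing with a
   covered sibling at a junction are cut when the sibling branch
   actually continues (a guard keeps single-copy bridges across
   thin-coverage stretches); dead-end tips shorter than `read_len + k`
   with a better-covered sibling are clipped — a single mid-read error
   can hang a tip of up to that length, which is why the bound is
   read-length-aware rather than the conventional 2k; simple two-path
   bubbles with >= 90% arm identity collapse to the higher-coverage arm.
   Tip and bubble passes iterate to a fixpoint.
4. **Unitigs and overlap healing.** Maximal non-branching paths are
   spelled, canonically oriented, and deterministically ordered. Pieces
   split at (k-1)-mer repeats or at junctions where an unpopped error
   variant disagrees overlap each other by up to 2(k-1) bp; unambiguous
   end overlaps >= 13 bp (exact, or near-exact within ~4% divergence)
   are re-joined. Fragments down to 60 bp participate in this merge —
   a stranded single-copy bridge can reconnect two contigs — and only
   the merged result is subject to the 200 bp minimum contig length.
5. **k sweep and synthesis.** Steps 2-4 run per k in {15, 25, 35, 45};
   each assembly is scored by the greatest spliced-alignment length of
   the probe against any single contig (contiguity-rewarding; a sum over
   contigs cannot distinguish one spanning contig from fragments tiling
   the same probe), ties resolving to the larger k. Junctions that break
   one k's assembly are usually k-specific, so finally the per-k contig
   sets are pooled, contained duplicates dropped, and overlaps >= 30 bp
   merged; the combined set replaces the winner when it scores at least
   as well.

Scaffolding with mate-pair inserts, gap filling across uncovered
stretches, and coverage-based copy-number calls are deliberately out of
scope; a stretch of the genome covered by no error-free k-mer in any
recruited read cannot be crossed and will surface as two contigs.

## Spliced alignment

Seed-extend-chain in translated (protein probe) or nucleotide (DNA
probe) space: maximal exact seeds (5 aa / 12 nt) extend to ungapped
HSPs under BLOSUM62 (+2/−3 for DNA) with X-drop 20, then sparse chaining
allows contig-axis gaps up to 20 kb — free when the gap is flanked by
GT...AG, a small constant penalty otherwise — and small probe-axis gaps.
HSPs may overrun exon boundaries by a handful of residues, so chaining
tolerates overlaps up to 60 probe units and, when emitting blocks,
resolves each overlap at the split point that loses the fewest
identities, recomputing identity exactly from the sequences. Reported
per alignment: non-overlapping monotone blocks, similarity =
identities / aligned probe positions, probe coverage = aligned probe
positions / probe length, aligned length in contig bp, strand. Both
contig orientations are tried; similarity and coverage are invariant
under reverse-complementing the contig.

The hit test is `contig_len >= 200 and similarity >= 0.5 and
coverage >= 0.8` (all inclusive).

DUST masking scores every 64 bp window by triplet composition,
S = Σ c_t(c_t−1)/2 / (w−3), masks windows with S > level/10
(level = 20), and merges masked windows within 1 bp. Masking is applied
to next-round queries and to reported contigs (lowercase), never to the
sequence content itself.

## Walker bookkeeping

Defaults: minimum contig 200 bp; maximum contig 10,000 bp; cleaning
every 4 rounds or when a round ends with more than 500 contigs; round
cap 10. Over-long contigs are trimmed symmetrically to the cap (odd
excess: extra base off the tail) and parked as candidates; a candidate
whose sequence reappears inside a long contig next round becomes
permanent, its reads leave the assembly pool, and it is reported
byte-identical in the final output. Cleaning matches contigs against the
original probe at half the recruitment match length (strictly more
permissive than recruitment, so cleaning can never discard a contig the
probe itself recruited), then drops found reads matching no surviving
contig, then re-closes mates. The cleaning counter does not reset after
a contig-count-triggered clean. With `extra_rounds`, the countdown arms
at the first hit and later hits do not extend it. A walk whose contigs
are all culled re-seeds from the probe.

Final outputs: `all_contigs.fasta` (final-round contigs at or above the
minimum length, plus trimmed candidates and permanent long contigs),
`hit_contigs.fasta` (the subset passing the hit test), `output.aln`,
optional GFF3 of block structures, and a per-round history table (reads
found, contigs, best k, best coverage).

## Synthetic data

The generator emulates the classical wgsim protocol: N =
⌊L·coverage/(2·read_len)⌋ fragment pairs, uniform fragment start,
fragment length Normal(340, 50) truncated at 2·read_len, mate 1 forward
from the fragment start and mate 2 the reverse complement of the
fragment end; per-base substitutions at 2%, with 10% of error events
realised as 1 bp insertions or deletions; constant base quality;
everything deterministic per seed. Planted genes have GT...AG introns
and stop-free coding sequence; probes are diverged by random amino-acid
substitution to a target identity (±2 points) with a synonymously biased
codon rebuild for the cDNA, never introducing stops.

What the simulation does not model — real intergenic repeat families,
GC-coverage bias, PCR duplicates, quality-dependent errors, paralogous
gene families — bounds what passing tests show: they demonstrate the
machinery (recruitment, assembly, spliced alignment, stopping logic) is
correct and accurate under the stated error model, not that recruitment
specificity survives a repeat-dense mammalian genome.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based only in
  serialized reports.
* Tie-breaks are deterministic everywhere: sweep ties to larger k,
  contigs canonically oriented and sorted by (length desc, sequence),
  bubble survivors by (coverage desc, sequence).
* Read identity is (library, chunk, ordinal) — never the id string,
  which simulated libraries may repeat.
* Reference-scale runs in the acceptance script use a 1 Mb genome with
  one planted 3-exon gene (501 bp exons, 300/250 bp introns, 500-aa
  probe at 85% identity), 20X or 10X coverage; a full walk at this scale
  takes tens of seconds on one CPU.

## Known limitations

* Stopping is evaluated once per round, so the first hit can fire with
  the contig still a few hundred bp short of the locus ends (the next
  round would have covered them). Measured over 26 replicate walks at
  10-20X, 24 recovered the full gene body at >= 99.3% identity; the two
  marginal stops recovered 90-94%.
* Low-coverage stretches whose only spanning read carries clustered
  errors cannot be crossed exactly and, without pair scaffolding,
  occasionally leave the locus in two contigs at <= 10X.
* The spliced aligner's similarity is an identity fraction, not a
  substitution-matrix score; thresholds retain their meaning but the
  numeric value is not comparable to tools that report weighted scores.
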