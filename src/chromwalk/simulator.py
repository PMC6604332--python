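"""Synthetic genomes with planted multi-exon genes, diverged probes, and
wgsim-style paired-end read simulation.

The read model follows the common whole-genome shotgun simulation recipe:
fragments of truncated-normal length are drawn uniformly from the genome,
the first ``read_len`` bases become mate 1 and the reverse complement of
the last ``read_len`` bases becomes mate 2. Sequencing errors are
per-base substitutions at ``base_error``, with a fraction
``indel_fraction`` of error events realised as 1 bp insertions or
deletions instead. Defaults (70 bp reads, 340 +/- 50 insert, 2% error,
10% indel fraction) describe a typical older Illumina paired-end library.

Everything is deterministic per seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._kmers import _CODON_STR, translate
from .readstore import LibrarySpec, ReadChunk, ReadLibrary, ReadStore
from .seqio import SeqRecord, revcomp

__all__ = [
    "GeneSpec",
    "PlantedGene",
    "SimParams",
    "make_genome",
    "diverge_probe",
    "simulate_reads",
    "simulate_store",
    "write_truth_table",
]

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(c for c in _CODON_STR if c not in _STOPS)
_AA_CODONS: Dict[str, List[str]] = {}
for _c, _a in _CODON_STR.items():
    if _a != "*":
        _AA_CODONS.setdefault(_a, []).append(_c)
for _a in _AA_CODONS:
    _AA_CODONS[_a].sort()
_AA_LIST = sorted(_AA_CODONS)


@dataclass
class GeneSpec:
    """Requested layout of one planted gene.

    Exon lengths must sum to a multiple of three (the coding sequence);
    introns are generated with canonical GT...AG boundaries.
    """

    start: int
    exon_lengths: Sequence[int]
    intron_lengths: Sequence[int]
    strand: str = "+"
    gene_id: str = "gene1"

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one fewer intron than exons")
        if sum(self.exon_lengths) % 3 != 0 or sum(self.exon_lengths) < 9:
            raise ValueError("CDS length must be a multiple of 3 and >= 9")
        if any(l < 10 for l in self.intron_lengths):
            raise ValueError("introns must be >= 10 bp")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass
class PlantedGene:
    """Ground truth of one planted gene, in genome coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]]
    cds: str
    protein: str


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + stop; translates without internal
    stops by construction."""
    ncodons = length // 3
    body = [_NONSTOP_CODONS[i] for i in
            rng.integers(0, len(_NONSTOP_CODONS), ncodons - 2)]
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _random_intron(rng: np.random.Generator, length: int) -> str:
    return "GT" + _random_dna(rng, length - 4) + "AG"


def make_genome(length: int, genes: Sequence[GeneSpec],
                seed: int) -> Tuple[SeqRecord, List[PlantedGene]]:
    """Uniform-random genome with the requested genes embedded.

    Returns the genome record plus the ground-truth table. Overlapping
    gene layouts are rejected.
    """
    spans = sorted((g.start, g.start + g.span, g) for g in genes)
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if e1 > s2:
            raise ValueError("planted genes overlap")
    if spans and spans[-1][1] > length:
        raise ValueError("genes do not fit within the genome length")

    rng = np.random.default_rng(seed)
    base = list(_random_dna(rng, length))
    truth: List[PlantedGene] = []
    for spec in genes:
        cds = _random_cds(rng, sum(spec.exon_lengths))
        pieces = []
        exon_local: List[Tuple[int, int]] = []
        pos = 0
        cpos = 0
        for i, elen in enumerate(spec.exon_lengths):
            pieces.append(cds[cpos : cpos + elen])
            exon_local.append((pos, pos + elen))
            pos += elen
            cpos += elen
            if i < len(spec.intron_lengths):
                pieces.append(_random_intron(rng, spec.intron_lengths[i]))
                pos += spec.intron_lengths[i]
        gene_seq = "".join(pieces)
        if spec.strand == "-":
            gene_seq = revcomp(gene_seq)
            exon_local = [(spec.span - e, spec.span - s) for s, e in exon_local]
            exon_local.reverse()
        base[spec.start : spec.start + spec.span] = gene_seq
        exons = [(spec.start + s, spec.start + e) for s, e in exon_local]
        protein = translate(cds)[:-1]  # drop the stop
        truth.append(PlantedGene(
            gene_id=spec.gene_id, start=spec.start,
            end=spec.start + spec.span, strand=spec.strand,
            exons=exons, cds=cds, protein=protein,
        ))
    return SeqRecord(id="synthetic_genome", seq="".join(base)), truth


def diverge_probe(gene: PlantedGene, target_protein_identity: float,
                  seed: int) -> Tuple[SeqRecord, SeqRecord]:
    """Emulate a cross-species probe: substitute residues to reach the
    target protein identity, and rebuild a codon sequence with a
    synonymously biased nucleotide divergence. Never introduces stops.

    Returns (protein probe, cDNA probe).
    """
    if not 0.5 <= target_protein_identity <= 1.0:
        raise ValueError("target identity must be in [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    prot = list(gene.protein)
    n_sub = int(round((1.0 - target_protein_identity) * len(prot)))
    positions = rng.choice(len(prot), size=n_sub, replace=False)
    for p in positions:
        choices = [a for a in _AA_LIST if a != prot[p]]
        prot[p] = choices[rng.integers(0, len(choices))]
    sub_set = set(int(p) for p in positions)

    codons = [gene.cds[i : i + 3] for i in range(0, len(gene.cds) - 3, 3)]
    p_syn = 1.0 - target_protein_identity  # correlated silent divergence
    new_codons = []
    for i, codon in enumerate(codons):
        if i in sub_set:
            opts = _AA_CODONS[prot[i]]
            new_codons.append(opts[rng.integers(0, len(opts))])
        elif rng.random() < p_syn:
            opts = _AA_CODONS[_CODON_STR[codon]]
            new_codons.append(opts[rng.integers(0, len(opts))])
        else:
            new_codons.append(codon)
    cdna = "".join(new_codons) + gene.cds[-3:]
    probe_prot = SeqRecord(id=f"{gene.gene_id}_probe", seq="".join(prot),
                           alphabet="protein")
    probe_cdna = SeqRecord(id=f"{gene.gene_id}_probe_cdna", seq=cdna,
                           alphabet="dna")
    return probe_prot, probe_cdna


@dataclass
class SimParams:
    """wgsim-style paired-end simulation parameters."""

    read_len: int = 70
    insert_mean: int = 340
    insert_sd: int = 50
    base_error: float = 0.02
    mutation_rate: float = 0.0
    indel_fraction: float = 0.10
    coverage: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.base_error, self.mutation_rate, self.indel_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must be <= insert_mean")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _apply_indels(seq: str, template_ext: str, idx: np.ndarray,
                  rng: np.random.Generator) -> str:
    """Re-realise 1 bp indel error events at read positions *idx*."""
    out = []
    t = 0
    ins_del = rng.random(len(idx)) < 0.5
    events = {int(i): bool(d) for i, d in zip(idx, ins_del)}
    rl = len(seq)
    while len(out) < rl:
        pos = len(out)
        if pos in events and t < len(template_ext):
            if events[pos]:  # insertion of a random base
                out.append("ACGT"[rng.integers(0, 4)])
            else:  # deletion: skip one template base
                t += 1
                if t < len(template_ext):
                    out.append(template_ext[t])
                    t += 1
                else:
                    out.append("ACGT"[rng.integers(0, 4)])
            del events[pos]
        else:
            out.append(template_ext[t] if t < len(template_ext)
                       else "ACGT"[rng.integers(0, 4)])
            t += 1
    return "".join(out[:rl])


def _simulate_pairs(genome: str, params: SimParams
                    ) -> Tuple[List[str], List[str]]:
    """Mate-1 and mate-2 sequence lists (ids are positional)."""
    if params.coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(genome)
    rl = params.read_len
    if L <= params.insert_mean + 4 * params.insert_sd:
        raise ValueError("genome too short for the insert distribution")
    n_pairs = int(L * params.coverage // (rl * 2))
    rng = np.random.default_rng(params.seed)

    frag = np.rint(rng.normal(params.insert_mean, params.insert_sd,
                              n_pairs)).astype(np.int64)
    frag = np.clip(frag, 2 * rl, L)  # truncate: fragments hold both mates
    start = (rng.random(n_pairs) * (L - frag + 1)).astype(np.int64)
    end = start + frag

    g = _CODE[np.frombuffer(genome.upper().encode(), dtype=np.uint8)]
    col = np.arange(rl)
    m1 = g[start[:, None] + col]
    m2 = 3 - g[end[:, None] - 1 - col]  # reverse complement of fragment end

    reads = np.concatenate([m1, m2], axis=0)
    err = rng.random(reads.shape) < params.base_error
    is_indel = err & (rng.random(reads.shape) < params.indel_fraction)
    subs = err & ~is_indel
    shift = rng.integers(1, 4, reads.shape, dtype=np.uint8)
    reads = np.where(subs, (reads + shift) % 4, reads)

    chars = _BASES[reads]
    seqs1 = [chars[i].tobytes().decode() for i in range(n_pairs)]
    seqs2 = [chars[n_pairs + i].tobytes().decode() for i in range(n_pairs)]

    # rebuild the few reads that drew indel events
    indel_rows = np.nonzero(is_indel.any(axis=1))[0]
    for row in indel_rows:
        idx = np.nonzero(is_indel[row])[0]
        p = int(row) if row < n_pairs else int(row) - n_pairs
        if row < n_pairs:
            tmpl = genome[start[p] : min(start[p] + rl + len(idx) + 2, L)].upper()
        else:
            tmpl = revcomp(genome[max(end[p] - rl - len(idx) - 2, 0) : end[p]].upper())
        base = seqs1[p] if row < n_pairs else seqs2[p]
        rebuilt = _apply_indels(base, tmpl, idx, rng)
        # substitutions already applied positionally; re-apply on rebuilt
        sub_idx = np.nonzero(subs[row])[0]
        rb = list(rebuilt)
        for si in sub_idx:
            cur = rb[si]
            rb[si] = "ACGT"[(("ACGT".index(cur) if cur in "ACGT" else 0)
                             + int(shift[row, si])) % 4]
        if row < n_pairs:
            seqs1[p] = "".join(rb)
        else:
            seqs2[p] = "".join(rb)
    return seqs1, seqs2


_QUAL_CHAR = "2"  # constant Phred+33 quality (Q17 ~ 2% error)


def simulate_reads(genome: SeqRecord, params: SimParams, out_prefix: str
                   ) -> LibrarySpec:
    """Simulate a paired library and write ``<prefix>_1.fastq`` and
    ``<prefix>_2.fastq``; returns the library spec pointing at them."""
    seqs1, seqs2 = _simulate_pairs(genome.seq, params)
    files = (f"{out_prefix}_1.fastq", f"{out_prefix}_2.fastq")
    for fname, seqs, mate in ((files[0], seqs1, 1), (files[1], seqs2, 2)):
        with open(fname, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@sim{i}/{mate}\n{s}\n+\n{_QUAL_CHAR * len(s)}\n")
    return LibrarySpec(files=files, insert_size=params.insert_mean)


def simulate_store(genome: SeqRecord, params: SimParams,
                   split_size: int = 500_000) -> ReadStore:
    """Simulate a paired library directly into an in-memory read store
    (interleaved mates), skipping FASTQ round-tripping."""
    seqs1, seqs2 = _simulate_pairs(genome.seq, params)
    records = []
    for i, (a, b) in enumerate(zip(seqs1, seqs2)):
        records.append((f"sim{i}/1", a))
        records.append((f"sim{i}/2", b))
    spec = LibrarySpec(files=("<memory>_1", "<memory>_2"),
                       insert_size=params.insert_mean)
    step = max(split_size - (split_size % 2), 2)
    chunks = []
    for c0 in range(0, len(records), step):
        part = records[c0 : c0 + step]
        chunks.append(ReadChunk(len(chunks), [r[0] for r in part],
                                [r[1] for r in part], paired=True))
    return ReadStore([ReadLibrary(0, spec, chunks)])


def pair_positions(genome_len: int, params: SimParams) -> List[Tuple[int, int]]:
    """Ground-truth genome interval of each simulated read, replayed from
    the generator's deterministic draw stream. Entry 2*i is mate 1 of pair
    i, entry 2*i + 1 is mate 2 (matching the interleaved store layout)."""
    L = genome_len
    rl = params.read_len
    n_pairs = int(L * params.coverage // (rl * 2))
    rng = np.random.default_rng(params.seed)
    frag = np.rint(rng.normal(params.insert_mean, params.insert_sd,
                              n_pairs)).astype(np.int64)
    frag = np.clip(frag, 2 * rl, L)
    start = (rng.random(n_pairs) * (L - frag + 1)).astype(np.int64)
    end = start + frag
    out: List[Tuple[int, int]] = []
    for s, e in zip(start, end):
        out.append((int(s), int(s) + rl))
        out.append((int(e) - rl, int(e)))
    return out


def write_truth_table(genes: Sequence[PlantedGene], path: str) -> None:
    """Plain TSV ground truth: id, coordinates, strand, exons, protein."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\texons\tprotein\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t"
                     f"{exons}\t{g.protein}\n")
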