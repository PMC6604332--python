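"""Chunked, indexed short-read libraries and exact-substring read recruitment.

Read libraries (single- or paired-end, FASTA or FASTQ) are preprocessed
into chunks of at most ``split_size`` reads. Each chunk carries a k-mer
index covering both DNA strands and, for translated matching of protein
probes, all six reading frames. Recruitment ("baiting") finds every read
that shares an exact substring of at least ``min_match`` characters with
some query sequence — nucleotides against DNA queries, amino acids against
protein queries. Chunks are searched independently and results unioned, so
the outcome is identical for any degree of chunk-level parallelism.

Paired libraries store mates interleaved within a chunk (mate of ordinal
``o`` is ``o ^ 1``), which keeps mate completion a constant-time rule.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np

from . import _kmers
from .seqio import ParseError, SeqRecord, iter_sequences, revcomp

__all__ = [
    "ReadRef",
    "LibrarySpec",
    "ReadChunk",
    "ReadLibrary",
    "ReadStore",
    "KmerIndex",
    "preprocess",
    "build_index",
    "find_matching_reads",
    "complete_pairs",
]

DEFAULT_SPLIT_SIZE = 500_000
DEFAULT_K_DNA = 15
DEFAULT_K_PROT = 5
DEFAULT_MIN_MATCH_DNA = 20
DEFAULT_MIN_MATCH_PROT = 8


class ReadRef(NamedTuple):
    """Identity of one read: (library index, chunk id, ordinal in chunk)."""

    lib: int
    chunk: int
    ordinal: int


@dataclass
class LibrarySpec:
    """One input library: a single file, or two mate files for paired-end."""

    files: Tuple[str, ...]
    insert_size: Optional[int] = None
    fmt: Optional[str] = None  # autodetected from extension when None

    @property
    def paired(self) -> bool:
        return len(self.files) == 2

    def detect_format(self, path: str) -> str:
        if self.fmt:
            return self.fmt
        base = path[:-3] if path.endswith(".gz") else path
        ext = os.path.splitext(base)[1].lower()
        return "fastq" if ext in (".fq", ".fastq") else "fasta"


class KmerIndex:
    """Exact-substring index of one chunk.

    Postings are stored as parallel arrays sorted by k-mer hash:
    DNA postings (ordinal, offset, strand) on both strands, protein
    postings (ordinal, aa offset, frame in ±1..±3) over all six frame
    translations. Translations break at stop codons and at non-ACGT bases,
    so no amino-acid k-mer spans them.
    """

    def __init__(self, seqs: Sequence[str], k_dna: int = DEFAULT_K_DNA,
                 k_prot: int = DEFAULT_K_PROT):
        if k_dna < 11:
            raise ValueError("k_dna must be >= 11")
        if k_prot < 4:
            raise ValueError("k_prot must be >= 4")
        self.k_dna = k_dna
        self.k_prot = k_prot
        mat, lengths = _kmers.pack_dna([s.upper() for s in seqs])
        rc = _kmers.revcomp_codes(mat, lengths)
        self._build_dna(mat, rc)
        self._build_prot(mat, rc)

    def _build_dna(self, mat: np.ndarray, rc: np.ndarray) -> None:
        parts = []
        for strand, codes in ((0, mat), (1, rc)):
            h = _kmers.dna_window_hashes(codes, self.k_dna)
            ords, offs = np.nonzero(h != _kmers.INVALID_HASH)
            parts.append((h[ords, offs], ords, offs,
                          np.full(len(ords), strand, dtype=np.int8)))
        hashes = np.concatenate([p[0] for p in parts])
        order = np.argsort(hashes, kind="stable")
        self.d_hash = hashes[order]
        self.d_ord = np.concatenate([p[1] for p in parts]).astype(np.int32)[order]
        self.d_off = np.concatenate([p[2] for p in parts]).astype(np.int32)[order]
        self.d_strand = np.concatenate([p[3] for p in parts])[order]

    def _build_prot(self, mat: np.ndarray, rc: np.ndarray) -> None:
        parts = []
        for sign, codes in ((1, mat), (-1, rc)):
            for f in range(3):
                aa = _kmers.translate_codes(codes, f)
                h = _kmers.aa_window_hashes(aa, self.k_prot)
                ords, offs = np.nonzero(h != _kmers.INVALID_HASH)
                parts.append((h[ords, offs], ords, offs,
                              np.full(len(ords), sign * (f + 1), dtype=np.int8)))
        hashes = np.concatenate([p[0] for p in parts])
        order = np.argsort(hashes, kind="stable")
        self.p_hash = hashes[order]
        self.p_ord = np.concatenate([p[1] for p in parts]).astype(np.int32)[order]
        self.p_off = np.concatenate([p[2] for p in parts]).astype(np.int32)[order]
        self.p_frame = np.concatenate([p[3] for p in parts])[order]

    # -- query interfaces -------------------------------------------------

    def dna_ranges(self, qhashes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return (np.searchsorted(self.d_hash, qhashes, "left"),
                np.searchsorted(self.d_hash, qhashes, "right"))

    def prot_ranges(self, qhashes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return (np.searchsorted(self.p_hash, qhashes, "left"),
                np.searchsorted(self.p_hash, qhashes, "right"))

    def postings_dna(self, kmer: str) -> List[Tuple[int, int, str]]:
        """All (ordinal, offset, strand) postings of one DNA k-mer.

        Reverse-strand offsets are coordinates on the reverse complement
        of the read.
        """
        h = np.uint64(_kmers.hash_dna_kmer(kmer))
        lo = int(np.searchsorted(self.d_hash, h, "left"))
        hi = int(np.searchsorted(self.d_hash, h, "right"))
        return [(int(self.d_ord[i]), int(self.d_off[i]),
                 "+" if self.d_strand[i] == 0 else "-") for i in range(lo, hi)]

    def postings_prot(self, kmer: str) -> List[Tuple[int, int, int]]:
        """All (ordinal, aa offset, frame) postings of one amino-acid k-mer."""
        h = np.uint64(_kmers.hash_aa_kmer(kmer))
        lo = int(np.searchsorted(self.p_hash, h, "left"))
        hi = int(np.searchsorted(self.p_hash, h, "right"))
        return [(int(self.p_ord[i]), int(self.p_off[i]), int(self.p_frame[i]))
                for i in range(lo, hi)]


@dataclass
class ReadChunk:
    """One chunk of reads (stored as uppercase DNA, qualities dropped)."""

    chunk_id: int
    ids: List[str]
    seqs: List[str]
    paired: bool
    index: Optional[KmerIndex] = None
    _rc_cache: Dict[int, str] = field(default_factory=dict, repr=False)
    _tr_cache: Dict[Tuple[int, int], str] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.seqs)

    def mate_ordinal(self, ordinal: int) -> Optional[int]:
        return (ordinal ^ 1) if self.paired else None

    def oriented(self, ordinal: int, strand: str) -> str:
        if strand == "+":
            return self.seqs[ordinal]
        rc = self._rc_cache.get(ordinal)
        if rc is None:
            rc = revcomp(self.seqs[ordinal])
            self._rc_cache[ordinal] = rc
        return rc

    def translation(self, ordinal: int, frame: int) -> str:
        key = (ordinal, frame)
        t = self._tr_cache.get(key)
        if t is None:
            src = self.oriented(ordinal, "+" if frame > 0 else "-")
            t = _kmers.translate(src, abs(frame) - 1)
            self._tr_cache[key] = t
        return t

    def ensure_index(self, k_dna: int, k_prot: int) -> KmerIndex:
        if (self.index is None or self.index.k_dna != k_dna
                or self.index.k_prot != k_prot):
            self.index = KmerIndex(self.seqs, k_dna, k_prot)
        return self.index


@dataclass
class ReadLibrary:
    lib_id: int
    spec: LibrarySpec
    chunks: List[ReadChunk] = field(default_factory=list)

    @property
    def paired(self) -> bool:
        return self.spec.paired

    @property
    def n_reads(self) -> int:
        return sum(len(c) for c in self.chunks)


class ReadStore:
    """All read libraries of a run, plus convenience lookups by ReadRef."""

    def __init__(self, libraries: List[ReadLibrary]):
        self.libraries = libraries

    @property
    def n_reads(self) -> int:
        return sum(lib.n_reads for lib in self.libraries)

    def iter_chunks(self) -> Iterable[Tuple[int, ReadChunk]]:
        for lib in self.libraries:
            for chunk in lib.chunks:
                yield lib.lib_id, chunk

    def get_read(self, ref: ReadRef) -> SeqRecord:
        chunk = self.libraries[ref.lib].chunks[ref.chunk]
        return SeqRecord(id=chunk.ids[ref.ordinal], seq=chunk.seqs[ref.ordinal])

    def get_reads(self, refs: Iterable[ReadRef]) -> List[SeqRecord]:
        return [self.get_read(r) for r in sorted(refs)]


# ---------------------------------------------------------------------------
# preprocessing


def _chunk_records(records: Iterable[Tuple[str, str]], split_size: int,
                   paired: bool) -> List[ReadChunk]:
    """Split an iterable of (id, seq) into chunks; pairs are kept adjacent."""
    step = split_size - (split_size % 2) if paired else split_size
    step = max(step, 2 if paired else 1)
    chunks: List[ReadChunk] = []
    ids: List[str] = []
    seqs: List[str] = []
    for rid, seq in records:
        ids.append(rid)
        seqs.append(seq.upper())
        if len(seqs) >= step:
            chunks.append(ReadChunk(len(chunks), ids, seqs, paired))
            ids, seqs = [], []
    if seqs:
        chunks.append(ReadChunk(len(chunks), ids, seqs, paired))
    return chunks


def _iter_library_records(spec: LibrarySpec) -> Iterable[Tuple[str, str]]:
    if not spec.paired:
        for rec in iter_sequences(spec.files[0], spec.detect_format(spec.files[0])):
            yield rec.id, rec.seq
        return
    it1 = iter_sequences(spec.files[0], spec.detect_format(spec.files[0]))
    it2 = iter_sequences(spec.files[1], spec.detect_format(spec.files[1]))
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise ParseError(
                f"paired files {spec.files[0]} / {spec.files[1]} have "
                "unequal read counts"
            )
        yield r1.id, r1.seq
        yield r2.id, r2.seq


def _manifest_path(workdir: str) -> str:
    return os.path.join(workdir, "chunks.manifest.tsv")


def _manifest_key(specs: Sequence[LibrarySpec], split_size: int) -> List[str]:
    lines = [f"#split_size\t{split_size}"]
    for i, spec in enumerate(specs):
        lines.append(f"#library\t{i}\t{int(spec.paired)}\t" +
                     "\t".join(os.path.basename(f) for f in spec.files))
    return lines


def preprocess(specs: Sequence[LibrarySpec],
               split_size: int = DEFAULT_SPLIT_SIZE,
               workdir: Optional[str] = None) -> ReadStore:
    """Convert read libraries into chunked FASTA-style in-memory stores.

    Qualities are dropped, sequences uppercased. When *workdir* is given the
    chunks are persisted (FASTA per chunk plus a plain-text manifest) and a
    rerun over the same inputs loads the persisted chunks instead of
    re-reading the original libraries.
    """
    if not specs:
        raise ValueError("at least one read library is required")
    if workdir is not None:
        os.makedirs(workdir, exist_ok=True)
        manifest = _manifest_path(workdir)
        key = _manifest_key(specs, split_size)
        if os.path.exists(manifest):
            with open(manifest) as fh:
                lines = fh.read().splitlines()
            if lines[: len(key)] == key:
                return _load_persisted(specs, workdir, lines[len(key):])
    libraries = []
    for i, spec in enumerate(specs):
        chunks = _chunk_records(_iter_library_records(spec), split_size,
                                spec.paired)
        libraries.append(ReadLibrary(i, spec, chunks))
    store = ReadStore(libraries)
    if workdir is not None:
        _persist(store, workdir, _manifest_key(specs, split_size))
    return store


def _chunk_file(workdir: str, lib_id: int, chunk_id: int) -> str:
    return os.path.join(workdir, f"lib{lib_id}_chunk{chunk_id}.fasta")


def _persist(store: ReadStore, workdir: str, key: List[str]) -> None:
    rows = []
    for lib in store.libraries:
        for chunk in lib.chunks:
            path = _chunk_file(workdir, lib.lib_id, chunk.chunk_id)
            with open(path, "w") as fh:
                for rid, seq in zip(chunk.ids, chunk.seqs):
                    fh.write(f">{rid}\n{seq}\n")
            rows.append(f"{lib.lib_id}\t{chunk.chunk_id}\t"
                        f"{os.path.basename(path)}\t{len(chunk)}")
    with open(_manifest_path(workdir), "w") as fh:
        fh.write("\n".join(key + rows) + "\n")


def _load_persisted(specs: Sequence[LibrarySpec], workdir: str,
                    rows: List[str]) -> ReadStore:
    libraries = [ReadLibrary(i, spec) for i, spec in enumerate(specs)]
    for row in rows:
        if not row.strip():
            continue
        lib_id_s, chunk_id_s, fname, _count = row.split("\t")
        lib = libraries[int(lib_id_s)]
        ids, seqs = [], []
        for rec in iter_sequences(os.path.join(workdir, fname), "fasta"):
            ids.append(rec.id)
            seqs.append(rec.seq)
        lib.chunks.append(ReadChunk(int(chunk_id_s), ids, seqs, lib.paired))
    return ReadStore(libraries)


def build_index(chunk: ReadChunk, k_dna: int = DEFAULT_K_DNA,
                k_prot: int = DEFAULT_K_PROT) -> KmerIndex:
    """Build (and attach) the k-mer index of one chunk."""
    return chunk.ensure_index(k_dna, k_prot)


# ---------------------------------------------------------------------------
# matching


def _extend_match(q: str, r: str, qi: int, ri: int, k: int) -> int:
    """Length of the maximal exact match around an aligned k-seed."""
    a, b = qi, ri
    while a > 0 and b > 0 and q[a - 1] == r[b - 1]:
        a -= 1
        b -= 1
    c, d = qi + k, ri + k
    nq, nr = len(q), len(r)
    while c < nq and d < nr and q[c] == r[d]:
        c += 1
        d += 1
    return c - a


def _match_dna_chunk(lib_id: int, chunk: ReadChunk, queries_upper: List[str],
                     qhash_list: List[np.ndarray], min_match: int,
                     out: Set[ReadRef]) -> None:
    idx = chunk.index
    k = idx.k_dna
    strand_char = ("+", "-")
    for qu, qh in zip(queries_upper, qhash_list):
        if qh.size == 0:
            continue
        lo, hi = idx.dna_ranges(qh)
        hit_cols = np.nonzero(hi > lo)[0]
        for col in hit_cols:
            for i in range(lo[col], hi[col]):
                ordinal = int(idx.d_ord[i])
                ref = ReadRef(lib_id, chunk.chunk_id, ordinal)
                if ref in out:
                    continue
                r = chunk.oriented(ordinal, strand_char[idx.d_strand[i]])
                if _extend_match(qu, r, int(col), int(idx.d_off[i]), k) >= min_match:
                    out.add(ref)


def _match_prot_chunk(lib_id: int, chunk: ReadChunk, probes: List[str],
                      qhash_list: List[np.ndarray], min_match: int,
                      out: Set[ReadRef]) -> None:
    idx = chunk.index
    k = idx.k_prot
    for probe, qh in zip(probes, qhash_list):
        if qh.size == 0:
            continue
        lo, hi = idx.prot_ranges(qh)
        hit_cols = np.nonzero(hi > lo)[0]
        for col in hit_cols:
            for i in range(lo[col], hi[col]):
                ordinal = int(idx.p_ord[i])
                ref = ReadRef(lib_id, chunk.chunk_id, ordinal)
                if ref in out:
                    continue
                t = chunk.translation(ordinal, int(idx.p_frame[i]))
                if _extend_match(probe, t, int(col), int(idx.p_off[i]), k) >= min_match:
                    out.add(ref)


def find_matching_reads(store: ReadStore, queries: Sequence[SeqRecord],
                        min_match_dna: int = DEFAULT_MIN_MATCH_DNA,
                        min_match_prot: int = DEFAULT_MIN_MATCH_PROT,
                        k_dna: int = DEFAULT_K_DNA,
                        k_prot: int = DEFAULT_K_PROT) -> Set[ReadRef]:
    """Every read sharing an exact substring of length >= min_match with a
    query: DNA space for DNA queries, translated (six-frame) space for
    protein queries. Lowercase-masked query regions seed nothing but may be
    spanned by match extension.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    if min_match_dna < k_dna or min_match_prot < k_prot:
        raise ValueError("min_match must be >= the index k for its space")
    dna_q = [q for q in queries if q.alphabet == "dna"]
    prot_q = [q for q in queries if q.alphabet == "protein"]

    dna_hashes = []
    dna_upper = []
    for q in dna_q:
        mat, _ = _kmers.pack_dna([q.seq])  # lowercase -> invalid: no seeds
        dna_hashes.append(_kmers.dna_window_hashes(mat, k_dna)[0]
                          if len(q.seq) >= k_dna else np.zeros(0, np.uint64))
        dna_upper.append(q.seq.upper())
    prot_hashes = []
    prot_upper = []
    for q in prot_q:
        mat, _ = _kmers.pack_aa([q.seq.upper()])
        prot_hashes.append(_kmers.aa_window_hashes(mat, k_prot)[0]
                           if len(q.seq) >= k_prot else np.zeros(0, np.uint64))
        prot_upper.append(q.seq.upper())

    found: Set[ReadRef] = set()
    for lib_id, chunk in store.iter_chunks():
        chunk.ensure_index(k_dna, k_prot)
        if dna_q:
            _match_dna_chunk(lib_id, chunk, dna_upper, dna_hashes,
                             min_match_dna, found)
        if prot_q:
            _match_prot_chunk(lib_id, chunk, prot_upper, prot_hashes,
                              min_match_prot, found)
    return found


def complete_pairs(found: Set[ReadRef], store: ReadStore) -> Set[ReadRef]:
    """Close a read set under mate inclusion (single-end reads unaffected)."""
    out = set(found)
    for ref in found:
        chunk = store.libraries[ref.lib].chunks[ref.chunk]
        mate = chunk.mate_ordinal(ref.ordinal)
        if mate is not None and mate < len(chunk):
            out.add(ReadRef(ref.lib, ref.chunk, mate))
    return out
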