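"""Chunking, k-mer index postings, exact-substring recruitment (checked
against a quadratic brute-force oracle), and mate completion."""

import numpy as np
import pytest

from chromwalk._kmers import translate
from chromwalk.readstore import (KmerIndex, LibrarySpec, ReadRef,
                                 complete_pairs, find_matching_reads,
                                 preprocess)
from chromwalk.seqio import ParseError, SeqRecord, revcomp

from conftest import random_dna, store_from_reads


# ---------------------------------------------------------------------------
# preprocessing / chunking


def _write_reads(path, n, rng, fmt="fastq", length=40, prefix="r"):
    with open(path, "w") as fh:
        for i in range(n):
            s = random_dna(rng, length)
            if fmt == "fastq":
                fh.write(f"@{prefix}{i}\n{s}\n+\n{'I' * length}\n")
            else:
                fh.write(f">{prefix}{i}\n{s}\n")


def test_chunk_sizes_are_ceiling_division(tmp_path, rng):
    p = tmp_path / "se.fasta"
    _write_reads(p, 1200, rng, fmt="fasta")
    store = preprocess([LibrarySpec(files=(str(p),))], split_size=500)
    sizes = [len(c) for c in store.libraries[0].chunks]
    assert sizes == [500, 500, 200]
    assert [c.chunk_id for c in store.libraries[0].chunks] == [0, 1, 2]


def test_paired_unequal_counts_is_error(tmp_path, rng):
    p1, p2 = tmp_path / "a_1.fq", tmp_path / "a_2.fq"
    _write_reads(p1, 10, rng)
    _write_reads(p2, 9, rng)
    with pytest.raises(ParseError):
        preprocess([LibrarySpec(files=(str(p1), str(p2)))])


def test_rerun_reuses_persisted_chunks(tmp_path, rng):
    p = tmp_path / "se.fastq"
    _write_reads(p, 30, rng)
    wd = tmp_path / "work"
    store1 = preprocess([LibrarySpec(files=(str(p),))], split_size=10,
                        workdir=str(wd))
    p.unlink()  # original gone: a rerun must load the persisted chunks
    store2 = preprocess([LibrarySpec(files=(str(p),))], split_size=10,
                        workdir=str(wd))
    assert [c.chunk_id for c in store2.libraries[0].chunks] == [0, 1, 2]
    assert [c.seqs for c in store2.libraries[0].chunks] == \
           [c.seqs for c in store1.libraries[0].chunks]


def test_paired_reads_interleave_and_mate_rule(tmp_path, rng):
    p1, p2 = tmp_path / "a_1.fq", tmp_path / "a_2.fq"
    _write_reads(p1, 6, rng, prefix="m")
    _write_reads(p2, 6, rng, prefix="m")
    store = preprocess([LibrarySpec(files=(str(p1), str(p2)))], split_size=4)
    chunk = store.libraries[0].chunks[0]
    assert chunk.paired and chunk.mate_ordinal(0) == 1
    assert chunk.mate_ordinal(3) == 2


# ---------------------------------------------------------------------------
# index postings


def test_dna_postings_cover_both_strands():
    read = "ACGTACGTACGTACG"
    idx = KmerIndex([read], k_dna=12, k_prot=4)
    # L - k + 1 = 4 postings per strand
    assert int((idx.d_strand == 0).sum()) == 4
    assert int((idx.d_strand == 1).sum()) == 4
    # each forward posting's k-mer is the read substring at its offset
    for off in range(4):
        assert (0, off, "+") in idx.postings_dna(read[off : off + 12])
    # reverse strand postings index the reverse complement
    rc = revcomp(read)
    assert (0, 0, "-") in idx.postings_dna(rc[:12])


def test_protein_postings_sliding_window():
    # frame +1 translation MAMAPK
    read = "ATGGCCATGGCTCCTAAG"
    assert translate(read, 0) == "MAMAPK"
    idx = KmerIndex([read], k_dna=11, k_prot=4)
    for i, kmer in enumerate(["MAMA", "AMAP", "MAPK"]):
        assert (0, i, 1) in idx.postings_prot(kmer)


def test_no_protein_posting_spans_stop_codon():
    # frame +1: MA*KL -- no 4-mer may span the stop
    read = "ATGGCCTAAAAACTG"
    idx = KmerIndex([read], k_dna=11, k_prot=4)
    assert translate(read, 0) == "MA*KL"
    assert idx.postings_prot("MA*K") == []
    # and the hash space has no posting overlapping aa positions 0..3 in +1
    assert all(not (p[2] == 1 and p[1] <= 2) for kmer in ["AKLX"]
               for p in idx.postings_prot(kmer))


def test_postings_verify_against_read_substrings(rng):
    """Spot-check random postings: the k-mer equals the read substring (or
    its frame translation) at the recorded offset."""
    seqs = [random_dna(rng, 70) for _ in range(30)]
    k_dna, k_prot = 15, 5
    idx = KmerIndex(seqs, k_dna, k_prot)
    n = len(idx.d_hash)
    for i in rng.integers(0, n, 100):
        ordinal, off = int(idx.d_ord[i]), int(idx.d_off[i])
        s = seqs[ordinal] if idx.d_strand[i] == 0 else revcomp(seqs[ordinal])
        kmer = s[off : off + k_dna]
        assert np.uint64(idx.d_hash[i]) == np.uint64(
            sum("ACGT".index(c) * 4 ** (k_dna - 1 - j)
                for j, c in enumerate(kmer)))
    m = len(idx.p_hash)
    for i in rng.integers(0, m, 100):
        ordinal, off = int(idx.p_ord[i]), int(idx.p_off[i])
        frame = int(idx.p_frame[i])
        src = seqs[ordinal] if frame > 0 else revcomp(seqs[ordinal])
        t = translate(src, abs(frame) - 1)
        window = t[off : off + k_prot]
        assert "*" not in window and "X" not in window


# ---------------------------------------------------------------------------
# matching vs brute force


def brute_force_dna_matches(seqs, queries, min_match):
    """Quadratic longest-common-substring oracle (DNA, both strands)."""
    out = set()
    for qi, q in enumerate(queries):
        qU = q.upper()
        subs = {qU[i : i + min_match] for i in range(len(qU) - min_match + 1)}
        for ri, r in enumerate(seqs):
            for oriented in (r, revcomp(r)):
                if any(oriented[i : i + min_match] in subs
                       for i in range(len(oriented) - min_match + 1)):
                    out.add(ri)
                    break
    return out


def brute_force_prot_matches(seqs, probe, min_match):
    out = set()
    windows = {probe[i : i + min_match]
               for i in range(len(probe) - min_match + 1)}
    for ri, r in enumerate(seqs):
        frames = [translate(r, f) for f in range(3)] + \
                 [translate(revcomp(r), f) for f in range(3)]
        for t in frames:
            if any(t[i : i + min_match] in windows and
                   "*" not in t[i : i + min_match] and
                   "X" not in t[i : i + min_match]
                   for i in range(len(t) - min_match + 1)):
                out.add(ri)
                break
    return out


def test_dna_matcher_equals_brute_force(rng):
    tmpl = random_dna(rng, 600)
    seqs = []
    for i in range(60):
        start = int(rng.integers(0, 530))
        s = tmpl[start : start + 70]
        if rng.random() < 0.5:
            s = revcomp(s)
        seqs.append(s)
    seqs += [random_dna(rng, 70) for _ in range(60)]  # unrelated
    query = SeqRecord(id="q", seq=tmpl[100:400])
    store = store_from_reads(seqs)
    got = {r.ordinal for r in find_matching_reads(store, [query],
                                                  min_match_dna=30)}
    assert got == brute_force_dna_matches(seqs, [query.seq], 30)


def test_protein_matcher_equals_brute_force(rng):
    cds = "ATG" + "".join(
        ["GCT", "GAA", "TTC", "GGT", "CAT", "ATC", "AAA", "CTG", "ATG",
         "AAC", "CCA", "CAG", "CGT", "TCT", "ACC", "GTT", "TGG", "TAC"] * 3)
    probe = translate(cds, 0)
    seqs = []
    for start in range(0, len(cds) - 45, 7):
        s = cds[start : start + 45]
        seqs.append(s if start % 2 == 0 else revcomp(s))
    seqs += [random_dna(rng, 45) for _ in range(40)]
    store = store_from_reads(seqs)
    q = SeqRecord(id="p", seq=probe, alphabet="protein")
    got = {r.ordinal for r in find_matching_reads(store, [q],
                                                  min_match_prot=10)}
    assert got == brute_force_prot_matches(seqs, probe, 10)


def test_masked_query_regions_seed_nothing(rng):
    read = random_dna(rng, 70)
    store = store_from_reads([read])
    masked = SeqRecord(id="q", seq=read.lower())
    assert find_matching_reads(store, [masked]) == set()
    partially = SeqRecord(id="q", seq=read[:40] + read[40:].lower())
    assert find_matching_reads(store, [partially]) == \
        {ReadRef(0, 0, 0)}  # extension spans the masked tail


def test_min_match_below_k_is_config_error(rng):
    store = store_from_reads([random_dna(rng, 70)])
    with pytest.raises(ValueError):
        find_matching_reads(store, [SeqRecord(id="q", seq="ACGT" * 10)],
                            min_match_dna=10)


# ---------------------------------------------------------------------------
# mate completion


def test_complete_pairs_adds_mates_and_is_idempotent(rng):
    store = store_from_reads([random_dna(rng, 40) for _ in range(6)],
                             paired=True)
    found = {ReadRef(0, 0, 2)}
    closed = complete_pairs(found, store)
    assert closed == {ReadRef(0, 0, 2), ReadRef(0, 0, 3)}
    assert complete_pairs(closed, store) == closed  # idempotent
    assert closed >= found  # monotone


def test_complete_pairs_single_end_unaffected(rng):
    store = store_from_reads([random_dna(rng, 40) for _ in range(3)])
    found = {ReadRef(0, 0, 1)}
    assert complete_pairs(found, store) == found
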