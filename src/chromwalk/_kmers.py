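"""Vectorized k-mer encoding shared by the read index and the matcher.

Sequences are packed into numpy code matrices (A,C,G,T -> 0..3; anything
else, including N and lowercase masking, -> the invalid code 4). Window
hashes are polynomial codes: base 4 for DNA (k <= 31 fits in uint64) and
base 25 for amino acids (k <= 13). Windows touching an invalid code hash
to ``INVALID_HASH`` and are dropped by callers.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

INVALID_HASH = np.uint64(0xFFFFFFFFFFFFFFFF)

_DNA_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _DNA_CODE[ord(_b)] = _i  # uppercase only: lowercase = masked = invalid

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INVALID = 24  # stop codons, X, N-containing codons
_AA_CODE = np.full(256, AA_INVALID, dtype=np.uint8)
for _i, _a in enumerate(_AA_ALPHABET):
    _AA_CODE[ord(_a)] = _i

# codon id c0*16 + c1*4 + c2 -> aa code (stops stay invalid)
_CODON_AA = np.full(64, AA_INVALID, dtype=np.uint8)
for _i0, _b0 in enumerate("ACGT"):
    for _i1, _b1 in enumerate("ACGT"):
        for _i2, _b2 in enumerate("ACGT"):
            _aa = str(Seq(_b0 + _b1 + _b2).translate())
            _CODON_AA[_i0 * 16 + _i1 * 4 + _i2] = _AA_CODE[ord(_aa)]


_CODON_STR = {
    b0 + b1 + b2: str(Seq(b0 + b1 + b2).translate())
    for b0 in "ACGT" for b1 in "ACGT" for b2 in "ACGT"
}


def translate(seq: str, frame: int = 0) -> str:
    """Translate DNA in reading frame offset *frame* (0,1,2); stops as '*',
    codons with non-ACGT characters as 'X'."""
    s = seq.upper()
    get = _CODON_STR.get
    return "".join(get(s[i : i + 3], "X") for i in range(frame, len(s) - 2, 3))


def pack_dna(seqs: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Pack DNA strings into an (n, Lmax) uint8 code matrix plus lengths."""
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    lmax = int(lengths.max()) if n else 0
    mat = np.full((n, lmax), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = _DNA_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    return mat, lengths


def revcomp_codes(mat: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse-complement a code matrix row-wise, honouring row lengths."""
    n, lmax = mat.shape
    comp = np.where(mat < 4, 3 - mat, 4).astype(np.uint8)
    col = np.arange(lmax)
    src = lengths[:, None] - 1 - col
    valid = src >= 0
    src_c = np.clip(src, 0, max(lmax - 1, 0))
    out = np.where(valid, comp[np.arange(n)[:, None], src_c], 4)
    return out.astype(np.uint8)


def window_hashes(codes: np.ndarray, k: int, base: int, invalid_code: int) -> np.ndarray:
    """Hash every length-k window of each row; invalid windows -> INVALID_HASH.

    Returns an (n, L-k+1) uint64 array (empty second axis if rows are short).
    """
    n, lmax = codes.shape
    nwin = lmax - k + 1
    if n == 0 or nwin <= 0:
        return np.zeros((n, max(nwin, 0)), dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    h = np.zeros((n, nwin), dtype=np.uint64)
    b = np.uint64(base)
    for j in range(k):
        h = h * b + c64[:, j : j + nwin]
    bad = (codes >= invalid_code).astype(np.int32)
    cbad = np.zeros((n, lmax + 1), dtype=np.int32)
    np.cumsum(bad, axis=1, out=cbad[:, 1:])
    anybad = (cbad[:, k:] - cbad[:, :nwin]) > 0
    h[anybad] = INVALID_HASH
    return h


def dna_window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    return window_hashes(codes, k, base=4, invalid_code=4)


def translate_codes(mat: np.ndarray, frame: int) -> np.ndarray:
    """Amino-acid code matrix for one forward reading frame of a DNA code
    matrix. Stops and codons containing invalid bases become AA_INVALID."""
    n, lmax = mat.shape
    naa = (lmax - frame) // 3
    if naa <= 0:
        return np.zeros((n, 0), dtype=np.uint8)
    c0 = mat[:, frame : frame + 3 * naa : 3].astype(np.int32)
    c1 = mat[:, frame + 1 : frame + 1 + 3 * naa : 3].astype(np.int32)
    c2 = mat[:, frame + 2 : frame + 2 + 3 * naa : 3].astype(np.int32)
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4)
    codon = np.where(valid, c0 * 16 + c1 * 4 + c2, 0)
    aa = np.where(valid, _CODON_AA[codon], AA_INVALID)
    return aa.astype(np.uint8)


def aa_window_hashes(aa_codes: np.ndarray, k: int) -> np.ndarray:
    return window_hashes(aa_codes, k, base=25, invalid_code=20)


def pack_aa(seqs: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Pack amino-acid strings into an (n, Lmax) code matrix plus lengths."""
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    lmax = int(lengths.max()) if n else 0
    mat = np.full((n, lmax), AA_INVALID, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = _AA_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    return mat, lengths


def hash_dna_kmer(kmer: str) -> int:
    """Hash one DNA k-mer string; returns None-like INVALID on bad chars."""
    h = 0
    for ch in kmer:
        c = _DNA_CODE[ord(ch)]
        if c >= 4:
            return int(INVALID_HASH)
        h = h * 4 + int(c)
    return h


def hash_aa_kmer(kmer: str) -> int:
    h = 0
    for ch in kmer:
        c = _AA_CODE[ord(ch)]
        if c >= 20:
            return int(INVALID_HASH)
        h = h * 25 + int(c)
    return h
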