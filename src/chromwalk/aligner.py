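"""Spliced alignment of a probe to genomic contigs, plus DUST masking.

The spliced aligner maps a protein or cDNA probe onto a genomic contig
allowing intron-scale gaps on the contig axis only. It is a classical
seed-extend-chain design: exact seeds (>=5 aa in translated space, >=12 nt
in DNA space) are extended into ungapped high-scoring pairs (BLOSUM62 for
protein, +2/-3 for DNA, X-drop termination), and the pairs are chained by
dynamic programming with free intron gaps when the contig gap is flanked by
GT...AG and a small constant penalty otherwise. Both contig orientations
are tried and the better one kept.

Reported quantities:

* ``similarity`` — identities / aligned probe positions, in [0, 1];
* ``probe_coverage`` — probe positions inside alignment blocks / probe
  length, in [0, 1];
* ``aligned_length`` — total contig bp inside blocks, the quantity the
  assembler's k-mer sweep maximises.

DUST masking scores every 64 bp window by its triplet composition,
S = sum_t c_t (c_t - 1) / 2 / (w - 3), and lowercases windows whose score
exceeds ``level / 10`` (defaults follow the published DustMasker
parameters: window 64, level 20, linker 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
from Bio.Align import substitution_matrices

from ._kmers import translate
from .seqio import SeqRecord, revcomp

__all__ = [
    "DustParams",
    "dust_mask",
    "SplicedAlignment",
    "splice_align",
    "is_hit",
    "percent_identity",
    "write_alignment_report",
    "write_gff3",
]


# ---------------------------------------------------------------------------
# DUST low-complexity masking


@dataclass
class DustParams:
    window: int = 64
    level: int = 20
    linker: int = 1

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("DUST window must be >= 3")


def _merge_intervals(intervals: List[Tuple[int, int]], linker: int) -> List[Tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le + linker:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def dust_mask(seq: str, params: Optional[DustParams] = None) -> str:
    """Lowercase low-complexity runs of a DNA string (length preserved).

    A window is masked when its triplet-composition score exceeds
    ``level / 10``; masked windows within ``linker`` bp of each other merge.
    """
    params = params or DustParams()
    n = len(seq)
    s = seq.upper()
    w = min(params.window, n)
    if n < 4:
        return seq
    threshold = params.level / 10.0

    # triplet id per position, -1 where the triplet has a non-ACGT base
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    trip = [-1] * (n - 2)
    for i in range(n - 2):
        try:
            trip[i] = (code[s[i]] * 16 + code[s[i + 1]] * 4 + code[s[i + 2]])
        except KeyError:
            trip[i] = -1

    counts = [0] * 64
    numer = 0  # sum c(c-1)/2, updated incrementally

    def add(t: int, sign: int) -> int:
        nonlocal numer
        if t < 0:
            return 0
        c = counts[t]
        if sign > 0:
            numer += c
            counts[t] = c + 1
        else:
            counts[t] = c - 1
            numer -= counts[t]
        return 0

    masked: List[Tuple[int, int]] = []
    ntrip = w - 2
    for i in range(ntrip):
        add(trip[i], +1)
    denom = max(w - 3, 1)
    if numer / denom > threshold:
        masked.append((0, w))
    for start in range(1, n - w + 1):
        add(trip[start - 1], -1)
        add(trip[start + ntrip - 1], +1)
        if numer / denom > threshold:
            masked.append((start, start + w))
    out = list(seq)
    for s0, e0 in _merge_intervals(masked, params.linker):
        for i in range(s0, e0):
            out[i] = out[i].lower()
    return "".join(out)


# ---------------------------------------------------------------------------
# spliced alignment


@dataclass
class SplicedAlignment:
    """Probe-to-contig spliced alignment.

    Blocks are half-open (probe_start, probe_end, contig_start, contig_end)
    with probe coordinates in residues (protein) or bases (DNA) and contig
    coordinates in bp on the aligned orientation; they are non-overlapping
    and monotone on both axes.
    """

    probe_id: str
    contig_id: str
    blocks: List[Tuple[int, int, int, int]] = field(default_factory=list)
    similarity: float = 0.0
    probe_coverage: float = 0.0
    aligned_length: int = 0
    strand: str = "+"
    score: float = 0.0


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _blosum_lookup() -> Dict[Tuple[str, str], int]:
    tab: Dict[Tuple[str, str], int] = {}
    alpha = _BLOSUM62.alphabet
    for a in alpha:
        for b in alpha:
            tab[(a, b)] = int(_BLOSUM62[a, b])
    return tab


_B62 = _blosum_lookup()


def _aa_score(a: str, b: str) -> int:
    return _B62.get((a, b), -4)


def _nt_score(a: str, b: str) -> int:
    return 2 if a == b and a in "ACGT" else -3


@dataclass
class _Hsp:
    ps: int
    pe: int
    cs: int  # contig bp
    ce: int
    score: int
    identities: int


def _find_seeds(probe: str, text: str, k: int) -> List[Tuple[int, int, int]]:
    """Maximal exact matches >= k between probe and text as
    (probe_pos, text_pos, length), deduplicated per diagonal."""
    kmap: Dict[str, List[int]] = {}
    for i in range(len(probe) - k + 1):
        kmap.setdefault(probe[i : i + k], []).append(i)
    seen: Dict[int, int] = {}  # diagonal -> rightmost text end covered
    seeds = []
    for j in range(len(text) - k + 1):
        hits = kmap.get(text[j : j + k])
        if not hits:
            continue
        for i in hits:
            diag = j - i
            if seen.get(diag, -1) >= j + k:
                continue
            a, b = i, j
            while a > 0 and b > 0 and probe[a - 1] == text[b - 1]:
                a -= 1
                b -= 1
            c, d = i + k, j + k
            while c < len(probe) and d < len(text) and probe[c] == text[d]:
                c += 1
                d += 1
            seen[diag] = d
            seeds.append((a, b, c - a))
    return seeds


def _extend_hsp(probe: str, text: str, ps: int, ts: int, length: int,
                score_fn, xdrop: int) -> Tuple[int, int, int, int]:
    """Ungapped X-drop extension of an exact seed.

    Returns (probe_start, probe_end, score, identities); text coordinates
    follow the same diagonal.
    """
    best_score = sum(score_fn(probe[ps + i], text[ts + i]) for i in range(length))
    ident = length
    # right
    score = best_score
    best_right = ps + length
    ident_at_best_r = ident
    run_ident = ident
    i, j = ps + length, ts + length
    while i < len(probe) and j < len(text):
        score += score_fn(probe[i], text[j])
        if probe[i] == text[j]:
            run_ident += 1
        i += 1
        j += 1
        if score > best_score:
            best_score = score
            best_right = i
            ident_at_best_r = run_ident
        elif best_score - score > xdrop:
            break
    # left
    score = best_score
    best_left = ps
    ident = ident_at_best_r
    run_ident = ident
    i, j = ps - 1, ts - 1
    while i >= 0 and j >= 0:
        score += score_fn(probe[i], text[j])
        if probe[i] == text[j]:
            run_ident += 1
        if score > best_score:
            best_score = score
            best_left = i
            ident = run_ident
        elif best_score - score > xdrop:
            break
        i -= 1
        j -= 1
    return best_left, best_right, best_score, ident


_INTRON_MIN = 30
_INTRON_MAX = 20_000
_INTRON_PENALTY_NONCANON = 10
_PROBE_GAP_PENALTY = 2  # per probe unit skipped between chained blocks
_MAX_OVERLAP = 60  # probe units: X-drop overrun past an exon boundary


def _chain(hsps: List[_Hsp], contig: str, unit: int) -> Tuple[float, List[_Hsp]]:
    """Sparse chaining of HSPs, colinear on both axes; contig gaps of
    intron scale are free when flanked by GT...AG. Small overlaps (X-drop
    overruns across exon boundaries) are tolerated and trimmed away when
    the chained blocks are emitted. *unit* is contig bp per probe unit
    (3 for protein, 1 for DNA)."""
    if not hsps:
        return 0.0, []
    hsps = sorted(hsps, key=lambda h: (h.ps, h.cs))
    n = len(hsps)
    best = [float(h.score) for h in hsps]
    prev = [-1] * n
    for i in range(n):
        hi = hsps[i]
        for j in range(i):
            hj = hsps[j]
            if hj.ps >= hi.ps or hj.cs >= hi.cs:
                continue
            ov_p = max(0, hj.pe - hi.ps)
            ov_c = max(0, hj.ce - hi.cs)
            ov = max(ov_p, (ov_c + unit - 1) // unit)
            if ov > _MAX_OVERLAP:
                continue
            gc = hi.cs - hj.ce
            if gc > _INTRON_MAX:
                continue
            gp = max(0, hi.ps - hj.pe)
            penalty = gp * _PROBE_GAP_PENALTY + ov * 3
            if gc > _INTRON_MIN:
                if not (contig[hj.ce : hj.ce + 2] == "GT"
                        and contig[hi.cs - 2 : hi.cs] == "AG"):
                    penalty += _INTRON_PENALTY_NONCANON
            elif gc > 0:
                penalty += gc * 0.5
            cand = best[j] + hi.score - penalty
            if cand > best[i]:
                best[i] = cand
                prev[i] = j
        # chains may also start fresh at hi (handled by initialisation)
    end = max(range(n), key=lambda i: best[i])
    chain = []
    i = end
    while i != -1:
        chain.append(hsps[i])
        i = prev[i]
    chain.reverse()
    return best[end], chain


def _block_matches(probe: str, cseq: str, ps: int, pe: int, cs: int,
                   unit: int) -> List[bool]:
    """Per-probe-unit identity vector of a gapless block."""
    if unit == 3:
        t = translate(cseq[cs : cs + 3 * (pe - ps)], 0)
        return [i < len(t) and probe[ps + i] == t[i] for i in range(pe - ps)]
    return [probe[ps + i] == cseq[cs + i] for i in range(pe - ps)]


def _resolve_overlaps(chain: List[_Hsp], probe: str, cseq: str,
                      unit: int) -> List[Tuple[Tuple[int, int, int, int], int]]:
    """Turn a chained HSP list into strictly non-overlapping blocks with
    exact identity counts. Where adjacent blocks overlap (X-drop overruns
    across an exon boundary), the split point that loses the fewest
    identities is chosen."""
    blocks: List[List[int]] = [[h.ps, h.pe, h.cs, h.ce] for h in chain]
    out: List[List[int]] = []
    for cur in blocks:
        while out:
            prv = out[-1]
            ov_p = max(0, prv[1] - cur[0])
            ov_c = max(0, prv[3] - cur[2])
            d = max(ov_p, (ov_c + unit - 1) // unit)
            if d <= 0:
                break
            len_prv = prv[1] - prv[0]
            len_cur = cur[1] - cur[0]
            if d >= len_prv:
                out.pop()
                continue
            if d >= len_cur:
                cur[0] = cur[1]  # cur collapses; dropped below
                break
            m_prv = _block_matches(probe, cseq, prv[0], prv[1], prv[2], unit)
            m_cur = _block_matches(probe, cseq, cur[0], cur[1], cur[2], unit)
            best_x, best_lost = 0, None
            for x in range(0, d + 1):
                if x >= len_prv or (d - x) >= len_cur:
                    continue
                lost = sum(m_prv[len_prv - x:]) + sum(m_cur[: d - x])
                if best_lost is None or lost < best_lost:
                    best_x, best_lost = x, lost
            prv[1] -= best_x
            prv[3] -= best_x * unit
            cur[0] += d - best_x
            cur[2] += (d - best_x) * unit
            break
        if cur[1] > cur[0]:
            out.append(cur)
    result = []
    for b in out:
        ident = sum(_block_matches(probe, cseq, b[0], b[1], b[2], unit))
        result.append(((b[0], b[1], b[2], b[3]), ident))
    return result


def _hsps_protein(probe: str, contig: str, seed_len: int, xdrop: int) -> List[_Hsp]:
    hsps = []
    for frame in range(3):
        t = translate(contig, frame)
        for ps, ts, length in _find_seeds(probe, t, seed_len):
            a, b, score, ident = _extend_hsp(probe, t, ps, ts, length,
                                             _aa_score, xdrop)
            tstart = ts - (ps - a)
            hsps.append(_Hsp(ps=a, pe=b,
                             cs=frame + 3 * tstart,
                             ce=frame + 3 * (tstart + (b - a)),
                             score=score, identities=ident))
    return _dedupe(hsps)


def _hsps_dna(probe: str, contig: str, seed_len: int, xdrop: int) -> List[_Hsp]:
    hsps = []
    for ps, ts, length in _find_seeds(probe, contig, seed_len):
        a, b, score, ident = _extend_hsp(probe, contig, ps, ts, length,
                                         _nt_score, xdrop)
        tstart = ts - (ps - a)
        hsps.append(_Hsp(ps=a, pe=b, cs=tstart, ce=tstart + (b - a),
                         score=score, identities=ident))
    return _dedupe(hsps)


def _dedupe(hsps: List[_Hsp]) -> List[_Hsp]:
    seen: Dict[Tuple[int, int, int], _Hsp] = {}
    for h in hsps:
        key = (h.ps, h.pe, h.cs)
        if key not in seen or h.score > seen[key].score:
            seen[key] = h
    return list(seen.values())


def splice_align(probe: SeqRecord, contig: SeqRecord,
                 seed_len_prot: int = 5, seed_len_dna: int = 12,
                 xdrop: int = 20) -> SplicedAlignment:
    """Best spliced alignment of *probe* (protein or DNA) to *contig* (DNA).

    Both contig orientations are tried; block coordinates refer to the
    reported orientation. A probe with no seed match yields an empty
    alignment (similarity 0, coverage 0).
    """
    p = probe.seq.upper()
    is_protein = probe.alphabet == "protein"
    best: Optional[SplicedAlignment] = None
    for strand, cseq in (("+", contig.seq.upper()),
                         ("-", revcomp(contig.seq.upper()))):
        if is_protein:
            hsps = _hsps_protein(p, cseq, seed_len_prot, xdrop)
            unit = 3
        else:
            hsps = _hsps_dna(p, cseq, seed_len_dna, xdrop)
            unit = 1
        score, chain = _chain(hsps, cseq, unit)
        if not chain:
            continue
        resolved = _resolve_overlaps(chain, p, cseq, unit)
        if not resolved:
            continue
        blocks = [b for b, _ in resolved]
        aligned_probe = sum(b[1] - b[0] for b in blocks)
        identities = sum(i for _, i in resolved)
        aln = SplicedAlignment(
            probe_id=probe.id,
            contig_id=contig.id,
            blocks=blocks,
            similarity=identities / aligned_probe if aligned_probe else 0.0,
            probe_coverage=aligned_probe / len(p) if p else 0.0,
            aligned_length=sum(b[3] - b[2] for b in blocks),
            strand=strand,
            score=score,
        )
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        return SplicedAlignment(probe_id=probe.id, contig_id=contig.id)
    return best


def is_hit(aln: SplicedAlignment, contig_len: int, min_len: int = 200,
           min_sim: float = 0.5, min_cov: float = 0.8) -> bool:
    """Hit-contig test: length, similarity and probe coverage thresholds."""
    return (contig_len >= min_len and aln.similarity >= min_sim
            and aln.probe_coverage >= min_cov)


def percent_identity(query: str, target: str, mode: str = "HW",
                     try_revcomp: bool = True) -> float:
    """Percent identity of *query* against its best edit-distance placement
    in *target* (mode HW = semi-global: query inside target). Both target
    orientations are tried by default."""
    if not query:
        return 0.0
    d = edlib.align(query.upper(), target.upper(), mode=mode, task="distance")
    dist = d["editDistance"]
    if try_revcomp:
        d2 = edlib.align(query.upper(), revcomp(target.upper()), mode=mode,
                         task="distance")
        if 0 <= d2["editDistance"] < dist or dist < 0:
            dist = d2["editDistance"]
    if dist < 0:
        return 0.0
    return 100.0 * (len(query) - dist) / len(query)


# ---------------------------------------------------------------------------
# reports


def write_alignment_report(alignments: Sequence[SplicedAlignment],
                           path: str) -> None:
    """Plain-text alignment report (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f"## probe={aln.probe_id} contig={aln.contig_id} "
                     f"strand={aln.strand} similarity={aln.similarity:.3f} "
                     f"coverage={aln.probe_coverage:.3f} "
                     f"aligned_bp={aln.aligned_length}\n")
            for ps, pe, cs, ce in aln.blocks:
                fh.write(f"block\tprobe:{ps + 1}-{pe}\tcontig:{cs + 1}-{ce}\n")


def write_gff3(alignments: Sequence[SplicedAlignment], path: str,
               source: str = "chromwalk") -> None:
    """Emit hit gene structures as GFF3 (blocks as exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, aln in enumerate(alignments, 1):
            if not aln.blocks:
                continue
            gstart = min(b[2] for b in aln.blocks) + 1
            gend = max(b[3] for b in aln.blocks)
            gid = f"match{i}"
            fh.write(f"{aln.contig_id}\t{source}\tmatch\t{gstart}\t{gend}\t"
                     f"{aln.similarity:.3f}\t{aln.strand}\t.\t"
                     f"ID={gid};Target={aln.probe_id}\n")
            for ps, pe, cs, ce in aln.blocks:
                fh.write(f"{aln.contig_id}\t{source}\tmatch_part\t{cs + 1}\t"
                         f"{ce}\t.\t{aln.strand}\t.\tParent={gid};"
                         f"Target={aln.probe_id} {ps + 1} {pe}\n")
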