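"""Local de Bruijn assembly of the found-read pool, with a k-mer sweep.

The graph stores canonical k-mers (the lexicographically smaller of a
k-mer and its reverse complement; k is odd so no k-mer is its own reverse
complement) with occurrence counts. Cleanup removes short low-coverage
tips and pops near-identical two-path bubbles, then maximal non-branching
paths are spelled as unitig contigs.

``assemble_sweep`` runs the whole build-simplify-spell pipeline once per k
in the sweep list (default 15, 25, 35, 45) and keeps the assembly whose
best contig gives the greatest spliced-alignment length against the
probe; ties go to the larger k, which resolves repeats better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib

from .aligner import SplicedAlignment, splice_align
from .seqio import SeqRecord, revcomp

__all__ = [
    "DeBruijnGraph",
    "Assembly",
    "build_graph",
    "simplify",
    "unitigs",
    "merge_overlaps",
    "correct_reads",
    "assemble_sweep",
    "DEFAULT_K_LIST",
]

DEFAULT_K_LIST = (15, 25, 35, 45)
_ACGT = "ACGT"


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class DeBruijnGraph:
    """Canonical-k-mer de Bruijn graph with coverage counts.

    Adjacency is implicit: oriented k-mers are linked when they overlap by
    k-1 and both canonical forms are stored.
    """

    def __init__(self, k: int):
        if k % 2 == 0 or not (11 <= k <= 63):
            raise ValueError("k must be odd and in [11, 63]")
        self.k = k
        self.counts: Dict[str, int] = {}

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return _canon(kmer) in self.counts

    def coverage(self, kmer: str) -> int:
        return self.counts.get(_canon(kmer), 0)

    def add(self, kmer: str, n: int = 1) -> None:
        c = _canon(kmer)
        self.counts[c] = self.counts.get(c, 0) + n

    def remove(self, kmers) -> None:
        for km in kmers:
            self.counts.pop(_canon(km), None)

    def successors(self, kmer: str) -> List[str]:
        suf = kmer[1:]
        return [suf + b for b in _ACGT if _canon(suf + b) in self.counts]

    def predecessors(self, kmer: str) -> List[str]:
        pre = kmer[:-1]
        return [b + pre for b in _ACGT if _canon(b + pre) in self.counts]


def build_graph(reads: Sequence[SeqRecord], k: int) -> DeBruijnGraph:
    """Count canonical k-mers of the reads (both strands collapse onto the
    canonical form); k-mers containing non-ACGT characters are skipped."""
    g = DeBruijnGraph(k)
    counts = g.counts
    for rec in reads:
        s = rec.seq.upper()
        n = len(s)
        # positions of invalid characters bound the valid windows
        bad = [i for i, ch in enumerate(s) if ch not in _ACGT]
        segments = []
        prev = 0
        for b in bad:
            if b - prev >= k:
                segments.append((prev, b))
            prev = b + 1
        if n - prev >= k:
            segments.append((prev, n))
        for s0, s1 in segments:
            for i in range(s0, s1 - k + 1):
                km = s[i : i + k]
                c = _canon(km)
                counts[c] = counts.get(c, 0) + 1
    return g


@dataclass
class _Unitig:
    path: List[str]  # oriented k-mers
    seq: str
    mean_cov: float
    preds: List[str]  # oriented predecessors of path[0]
    succs: List[str]  # oriented successors of path[-1]


def _walk_unitigs(g: DeBruijnGraph) -> List[_Unitig]:
    """Maximal non-branching paths; every canonical k-mer is covered by
    exactly one unitig (in one of its two orientations)."""
    visited: Set[str] = set()
    out: List[_Unitig] = []

    def is_internal_step(a: str, b: str) -> bool:
        # the edge a->b extends a unitig iff it is the only way in and out
        return len(g.successors(a)) == 1 and len(g.predecessors(b)) == 1

    def walk_from(start: str) -> List[str]:
        path = [start]
        visited.add(_canon(start))
        cur = start
        while True:
            nxt = g.successors(cur)
            if len(nxt) != 1:
                break
            nx = nxt[0]
            if len(g.predecessors(nx)) != 1 or _canon(nx) in visited:
                break
            path.append(nx)
            visited.add(_canon(nx))
            cur = nx
        return path

    # deterministic order: sorted canonical k-mers
    for ckm in sorted(g.counts):
        if ckm in visited:
            continue
        # orient so we start at a path beginning when one exists
        start = ckm
        preds = g.predecessors(start)
        if not (len(preds) == 1 and len(g.successors(preds[0])) == 1):
            path = walk_from(start)
        else:
            rc = revcomp(start)
            preds_rc = g.predecessors(rc)
            if not (len(preds_rc) == 1 and len(g.successors(preds_rc[0])) == 1):
                path = walk_from(rc)
            else:
                # internal k-mer: walk back to the beginning first
                cur = start
                seen_local = {_canon(cur)}
                while True:
                    pr = g.predecessors(cur)
                    if len(pr) != 1 or len(g.successors(pr[0])) != 1:
                        break
                    p = pr[0]
                    if _canon(p) in seen_local or _canon(p) in visited:
                        break  # cycle
                    seen_local.add(_canon(p))
                    cur = p
                path = walk_from(cur)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(g.counts[_canon(p)] for p in path) / len(path)
        out.append(_Unitig(
            path=path, seq=seq, mean_cov=cov,
            preds=g.predecessors(path[0]),
            succs=g.successors(path[-1]),
        ))
    return out


def _best_sibling_cov(g: DeBruijnGraph, junction: str, exclude: str) -> float:
    """Highest coverage among the branches out of *junction* other than the
    branch starting at *exclude*."""
    best = 0.0
    for s in g.successors(junction):
        if s == exclude:
            continue
        best = max(best, float(g.coverage(s)))
    return best


def _cut_singleton_error_paths(g: DeBruijnGraph, max_walk: int = 130) -> None:
    """Remove count-1 k-mers that compete with a count>=2 sibling for the
    same junction; they are the entry/exit points of sequencing-error
    paths. Linear count-1 stretches (no competing sibling) survive.

    One guard prevents disconnection: if every competing sibling branch
    itself dead-ends within *max_walk* k-mers, the count-1 k-mer may be
    the only through-route across a thin-coverage stretch (the "sibling"
    being a doomed stub), so it is kept; the stub falls to tip clipping
    and the surviving pieces to contig-level overlap merging.
    """
    def branch_continues(start: str) -> bool:
        cur = start
        seen = {_canon(cur)}
        for _ in range(max_walk):
            succs = g.successors(cur)
            if not succs:
                return False  # dead end
            if len(succs) > 1:
                return True  # joins wider structure: treat as through
            cur = succs[0]
            if _canon(cur) in seen:
                return True  # cycle
            seen.add(_canon(cur))
        return True

    doomed = []
    for ckm, n in g.counts.items():
        if n >= 2:
            continue
        cut = False
        for o in (ckm, revcomp(ckm)):
            for p in g.predecessors(o):
                for s in g.successors(p):
                    if s != o and g.coverage(s) >= 2 and branch_continues(s):
                        cut = True
                        break
                if cut:
                    break
            if cut:
                break
        if cut:
            doomed.append(ckm)
    for ckm in doomed:
        g.counts.pop(ckm, None)


def simplify(g: DeBruijnGraph, tip_len: Optional[int] = None,
             bubble_identity: float = 0.9, max_rounds: int = 30) -> DeBruijnGraph:
    """Clean sequencing errors out of the graph in place.

    Three error signatures are targeted. (1) Single-copy error paths
    rooted at a junction with a covered sibling are excised when they are
    provably redundant (an alternative route exists) or dead-ended; a
    count-1 chain that is the only bridge across a thin stretch is kept. (2) Short dead-end tips with a better-covered sibling branch
    (read-end errors) are clipped. (3) Near-identical two-path bubbles
    (mid-read errors, or the same error in two reads) are popped to the
    higher-coverage path. Stages 2-3 iterate to a fixpoint (or
    *max_rounds*). Thin LINEAR stretches — e.g. regions covered by a
    single read at a recruitment frontier — have no competing sibling and
    are deliberately preserved. tip_len defaults to 2k bp.
    """
    tip_len = tip_len if tip_len is not None else 2 * g.k
    _cut_singleton_error_paths(g)
    for _ in range(max_rounds):
        changed = False
        units = _walk_unitigs(g)
        # --- tips: dead-ended short unitigs with a better sibling branch
        for u in units:
            if len(u.seq) >= tip_len:
                continue
            dead_front = not u.preds
            dead_back = not u.succs
            if dead_front and dead_back:
                # stranded fragment of a cut error path
                g.remove(u.path)
                changed = True
                continue
            if not dead_front and not dead_back:  # internal: keep
                continue
            junction = u.preds[0] if dead_back else revcomp(u.succs[0])
            entry = u.path[0] if dead_back else revcomp(u.path[-1])
            if _best_sibling_cov(g, junction, entry) >= u.mean_cov:
                g.remove(u.path)
                changed = True
        if changed:
            units = _walk_unitigs(g)
        # --- bubbles: two unitigs with identical flanks, similar sequence
        groups: Dict[Tuple[str, str], List[_Unitig]] = {}
        for u in units:
            if len(u.preds) != 1 or len(u.succs) != 1:
                continue
            key_f = (u.preds[0], u.succs[0])
            key_r = (revcomp(u.succs[0]), revcomp(u.preds[0]))
            groups.setdefault(min(key_f, key_r), []).append(u)
        for members in groups.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda u: (-u.mean_cov, u.seq))
            keeper = members[0]
            for other in members[1:]:
                limit = int(max(len(keeper.seq), len(other.seq))
                            * (1.0 - bubble_identity)) + 1
                d1 = edlib.align(other.seq, keeper.seq, mode="NW",
                                 task="distance", k=limit)["editDistance"]
                d2 = edlib.align(revcomp(other.seq), keeper.seq, mode="NW",
                                 task="distance", k=limit)["editDistance"]
                dists = [d for d in (d1, d2) if d >= 0]
                if not dists:
                    continue
                ident = 1.0 - min(dists) / max(len(keeper.seq), len(other.seq))
                if ident >= bubble_identity:
                    g.remove(other.path)
                    changed = True
        if not changed:
            break
    return g


def unitigs(g: DeBruijnGraph, min_len: int = 200) -> List[SeqRecord]:
    """Spell maximal non-branching paths; drop contigs shorter than
    *min_len*; canonical orientation (lexicographically smaller strand);
    sorted by (length desc, sequence asc) for determinism."""
    seqs = []
    for u in _walk_unitigs(g):
        if len(u.seq) < min_len:
            continue
        rc = revcomp(u.seq)
        seqs.append(u.seq if u.seq <= rc else rc)
    seqs.sort(key=lambda s: (-len(s), s))
    return [SeqRecord(id=f"c{i + 1}", seq=s) for i, s in enumerate(seqs)]


def _best_overlap(a: str, b: str, min_overlap: int,
                  max_divergence: float = 0.04, seed_len: int = 15,
                  window: int = 400) -> int:
    """Longest suffix(a)-prefix(b) overlap >= min_overlap bp (0 if none).

    Exact overlaps are found by locating a's terminal seed inside b.
    Failing that, near-exact overlaps (unpopped error variants at a graph
    junction) are recovered from any shared seed near the facing ends and
    verified by edit distance <= max_divergence of the overlap length.
    """
    seed = a[-min_overlap:]
    best = 0
    start = 0
    limit = min(len(a), len(b)) - 1
    while True:
        pos = b.find(seed, start)
        if pos < 0:
            break
        olen = pos + min_overlap
        if olen <= limit and olen > best and a[-olen:] == b[:olen]:
            best = olen
        start = pos + 1
    if best:
        return best
    # fuzzy rescue: diagonal estimates from shared seeds in the end windows
    tail = a[-window:]
    head = b[: window]
    kmap = {}
    for i in range(len(tail) - seed_len + 1):
        kmap.setdefault(tail[i : i + seed_len], i)
    cands = set()
    for j in range(len(head) - seed_len + 1):
        i = kmap.get(head[j : j + seed_len])
        if i is not None:
            cands.add((len(tail) - i) + j)  # implied overlap length
    for olen in sorted(cands, reverse=True):
        if not (min_overlap <= olen <= limit):
            continue
        tol = max(1, int(max_divergence * olen))
        d = edlib.align(a[-olen:], b[:olen], mode="NW", task="distance",
                        k=tol)["editDistance"]
        if d >= 0:
            return olen
    # short overlaps with a mid-overlap mismatch defeat seeding: scan the
    # candidate lengths directly with a Hamming tolerance
    for olen in range(min(limit, 4 * seed_len), min_overlap - 1, -1):
        tol = max(1, int(max_divergence * olen))
        mism = 0
        tail_s = a[-olen:]
        head_s = b[:olen]
        for x, y in zip(tail_s, head_s):
            if x != y:
                mism += 1
                if mism > tol:
                    break
        if mism <= tol:
            return olen
    return 0


def merge_overlaps(contigs: List[SeqRecord],
                   min_overlap: int = 20) -> List[SeqRecord]:
    """Merge contigs joined by an unambiguous exact end overlap.

    A de Bruijn graph breaks paths at (k-1)-mer repeats and the resulting
    pieces overlap by up to 2(k-1) bp; an exact overlap of *min_overlap*
    bp or more is essentially unique at these scales, so joining on it
    resolves what the graph could not. A contig end with two candidate
    partners is ambiguous and left alone. Output is re-canonicalised and
    deterministically ordered.
    """
    from collections import Counter

    seqs = [c.seq.upper() for c in contigs]
    changed = True
    while changed and len(seqs) > 1:
        changed = False
        n = len(seqs)
        # every physical junction once: pairs i<j, all orientation combos
        joins: List[Tuple[int, int, bool, int, bool]] = []
        for i in range(n):
            for j in range(i + 1, n):
                for oi in (False, True):
                    a = revcomp(seqs[i]) if oi else seqs[i]
                    for oj in (False, True):
                        b = revcomp(seqs[j]) if oj else seqs[j]
                        ov = _best_overlap(a, b, min_overlap)
                        if ov:
                            joins.append((ov, i, oi, j, oj))
        # a physical contig end taking part in >1 junction is ambiguous
        ends = Counter()
        for _, i, oi, j, oj in joins:
            ends[(i, "L" if oi else "R")] += 1  # tail end of orient(i)
            ends[(j, "R" if oj else "L")] += 1  # head end of orient(j)
        for ov, i, oi, j, oj in sorted(joins, reverse=True):
            if ends[(i, "L" if oi else "R")] == 1 and \
                    ends[(j, "R" if oj else "L")] == 1:
                a = revcomp(seqs[i]) if oi else seqs[i]
                b = revcomp(seqs[j]) if oj else seqs[j]
                merged = a + b[ov:]
                seqs = [s for idx, s in enumerate(seqs)
                        if idx not in (i, j)] + [merged]
                changed = True
                break
    out = []
    for s in seqs:
        rc = revcomp(s)
        out.append(s if s <= rc else rc)
    out.sort(key=lambda s: (-len(s), s))
    return [SeqRecord(id=f"c{i + 1}", seq=s) for i, s in enumerate(out)]


def correct_reads(reads: Sequence[SeqRecord], k: int = 15,
                  min_solid: int = 2, max_corrections: int = 4
                  ) -> List[SeqRecord]:
    """k-mer-spectrum substitution error correction of a read pool.

    A k-mer seen at least *min_solid* times in the pool is trusted. While
    scanning a read left to right, the first weak k-mer after a solid one
    implicates its final base; the substitution that turns the following
    window solid again is applied. The reverse complement is scanned the
    same way to catch errors near read starts. Reads in regions with no
    redundancy (nothing solid nearby) are left untouched, and at most
    *max_corrections* changes are made per read. Indel errors are not
    corrected; downstream graph cleanup owns those.
    """
    counts: Dict[str, int] = {}
    for rec in reads:
        s = rec.seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            c = _canon(km)
            counts[c] = counts.get(c, 0) + 1

    def solid(km: str) -> bool:
        return counts.get(_canon(km), 0) >= min_solid

    def window_score(s: str, i: int, span: int) -> int:
        hi = min(i + span, len(s) - k + 1)
        return sum(1 for j in range(i, hi) if solid(s[j : j + k]))

    def correct_one_pass(s: str, budget: int) -> Tuple[str, int]:
        i = 0
        prev_solid = False
        while budget > 0 and i + k <= len(s):
            if solid(s[i : i + k]):
                prev_solid = True
                i += 1
                continue
            if not prev_solid:
                i += 1
                continue
            j = i + k - 1  # last base of the first weak k-mer
            base_score = window_score(s, i, k)
            best = None
            for b in _ACGT:
                if b == s[j]:
                    continue
                cand = s[:j] + b + s[j + 1 :]
                sc = window_score(cand, i, k)
                if sc > base_score and (best is None or sc > best[0]):
                    best = (sc, cand)
            if best is not None:
                s = best[1]
                budget -= 1
            else:
                prev_solid = False
            i += 1
        return s, budget

    out = []
    for rec in reads:
        s = rec.seq.upper()
        if len(s) < k:
            out.append(rec)
            continue
        s, budget = correct_one_pass(s, max_corrections)
        if budget > 0:
            rc, budget = correct_one_pass(revcomp(s), budget)
            s = revcomp(rc)
        out.append(SeqRecord(id=rec.id, seq=s) if s != rec.seq.upper()
                   else rec)
    return out


@dataclass
class Assembly:
    """Result of one k-mer sweep: the winning k, its contigs, and the
    greatest single-contig spliced-alignment length that selected it."""

    k_used: int = 0
    contigs: List[SeqRecord] = field(default_factory=list)
    metric: int = 0
    alignments: Dict[str, SplicedAlignment] = field(default_factory=dict)


def assemble_sweep(reads: Sequence[SeqRecord], k_list: Sequence[int],
                   query_probe: SeqRecord, min_contig: int = 200,
                   bubble_identity: float = 0.9,
                   tip_len_factor: int = 2) -> Assembly:
    """Assemble the pool at each k and keep the assembly whose best contig
    gives the greatest spliced-alignment length to the probe.

    Equal metrics resolve to the larger k. If no k yields contigs, an
    empty Assembly (metric 0) is returned for the caller to handle.
    """
    if not k_list:
        raise ValueError("k_list must be non-empty")
    best = Assembly()
    have_any = False
    per_k_contigs: List[SeqRecord] = []
    max_read = max((len(r.seq) for r in reads), default=0)
    reads = correct_reads(reads, k=min(k_list))
    for k in sorted(k_list):
        if k > max_read:
            continue
        g = build_graph(reads, k)
        # a single read error can hang a tip of up to read_len + k - 1 bp
        tip_len = max(tip_len_factor * k, max_read + k)
        simplify(g, tip_len=tip_len, bubble_identity=bubble_identity)
        # sub-min_contig fragments join the merge: a stranded single-copy
        # bridge can reconnect two contigs across a thin stretch
        raw = unitigs(g, min_len=min(60, min_contig))
        merged = merge_overlaps(raw, min_overlap=13)
        contigs = [SeqRecord(id=f"k{k}_{c.id}", seq=c.seq)
                   for c in merged if len(c.seq) >= min_contig]
        if not contigs:
            continue
        per_k_contigs.extend(contigs)
        alns = {c.id: splice_align(query_probe, c) for c in contigs}
        # greatest single spliced-alignment length: rewards contiguity,
        # unlike a sum over contigs which cannot tell one spanning contig
        # from several fragments tiling the same probe
        metric = max(a.aligned_length for a in alns.values())
        if not have_any or metric >= best.metric:
            best = Assembly(k_used=k, contigs=contigs, metric=metric,
                            alignments=alns)
            have_any = True
    if not have_any:
        return best
    # sweep synthesis: a junction that breaks the winning assembly is
    # often k-specific, and the pieces of the other assemblies overlap it
    # by hundreds of bases; merging across the sweep and dropping
    # contained duplicates heals those breaks
    combined = merge_overlaps(_dedupe_contained(per_k_contigs),
                              min_overlap=30)
    combined = [c for c in combined if len(c.seq) >= min_contig]
    if combined:
        alns = {c.id: splice_align(query_probe, c) for c in combined}
        metric = max(a.aligned_length for a in alns.values())
        if metric >= best.metric:
            best = Assembly(k_used=best.k_used, contigs=combined,
                            metric=metric, alignments=alns)
    return best


def _dedupe_contained(contigs: List[SeqRecord],
                      max_divergence: float = 0.05) -> List[SeqRecord]:
    """Drop contigs essentially contained in a longer one (either
    orientation, small edit tolerance)."""
    ordered = sorted(contigs, key=lambda c: (-len(c.seq), c.seq))
    kept: List[SeqRecord] = []
    for c in ordered:
        s = c.seq.upper()
        tol = max(2, int(max_divergence * len(s)))
        contained = False
        for big in kept:
            t = big.seq.upper()
            if len(t) < len(s):
                continue
            d = edlib.align(s, t, mode="HW", task="distance",
                            k=tol)["editDistance"]
            if d < 0:
                d = edlib.align(revcomp(s), t, mode="HW", task="distance",
                                k=tol)["editDistance"]
            if d >= 0:
                contained = True
                break
        if not contained:
            kept.append(c)
    return [SeqRecord(id=f"c{i + 1}", seq=c.seq)
            for i, c in enumerate(kept)]
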