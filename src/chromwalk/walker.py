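"""The recursion engine: rounds of read recruitment, mate completion and
reassembly that extend contigs outward from the probe ("in silico
chromosome walking"), with periodic cleaning of non-matching contigs and
reads, retirement of contigs that reach the maximum length, and the four
stopping criteria:

1. a hit contig exists (length, similarity and probe-coverage thresholds);
2. no new reads were recruited, so nothing can be extended;
3. the maximum number of rounds is reached;
4. every assembled contig has reached the maximum contig length.

Criterion 1 can be ignored (``force_max_rounds``) or deferred by a fixed
number of extra rounds (``extra_rounds``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import aligner as _aligner
from ._kmers import translate as _translate
from .aligner import (SplicedAlignment, dust_mask, is_hit, splice_align,
                      write_alignment_report, write_gff3)
from .assembler import Assembly, DEFAULT_K_LIST, assemble_sweep
from .readstore import (DEFAULT_K_DNA, DEFAULT_K_PROT, DEFAULT_MIN_MATCH_DNA,
                        DEFAULT_MIN_MATCH_PROT, ReadRef, ReadStore,
                        complete_pairs, find_matching_reads)
from .seqio import SeqRecord, revcomp, write_sequences

__all__ = [
    "WalkParams",
    "WalkState",
    "WalkResult",
    "run_round",
    "clean",
    "handle_long_contigs",
    "check_stop",
    "finalize",
    "walk",
]


@dataclass
class WalkParams:
    """All tunables of a walk (defaults are the tool's standard settings)."""

    max_rounds: int = 10
    min_contig: int = 200
    max_contig: int = 10_000
    min_similarity: float = 0.5
    min_query_coverage: float = 0.8
    clean_period: int = 4
    contig_limit: int = 500
    k_list: Tuple[int, ...] = DEFAULT_K_LIST
    assembly_start_round: int = 1  # "-a": first round that assembles
    force_max_rounds: bool = False  # "-f": ignore the hit criterion
    extra_rounds: int = 0  # "-E": countdown of rounds after the first hit
    split_size: int = 500_000
    min_match_dna: int = DEFAULT_MIN_MATCH_DNA
    min_match_prot: int = DEFAULT_MIN_MATCH_PROT
    k_dna: int = DEFAULT_K_DNA
    k_prot: int = DEFAULT_K_PROT

    def __post_init__(self) -> None:
        if self.max_contig <= self.min_contig:
            raise ValueError("max_contig must exceed min_contig")
        for f in (self.min_similarity, self.min_query_coverage):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.force_max_rounds and self.extra_rounds:
            raise ValueError("force_max_rounds and extra_rounds are exclusive")


@dataclass
class RoundRecord:
    round: int
    new_reads: int
    total_reads: int
    n_contigs: int
    best_k: int
    best_coverage: float
    best_similarity: float


@dataclass
class WalkState:
    """Full recursion state between rounds."""

    probe: SeqRecord
    round: int = 0
    query_set: List[SeqRecord] = field(default_factory=list)
    found: Set[ReadRef] = field(default_factory=set)
    retired: Set[ReadRef] = field(default_factory=set)
    candidate_long: List[SeqRecord] = field(default_factory=list)
    permanent_long: List[SeqRecord] = field(default_factory=list)
    last_assembly: Assembly = field(default_factory=Assembly)
    last_new_reads: int = 0
    stop: Optional[str] = None
    extra_countdown: Optional[int] = None
    history: List[RoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.query_set:
            self.query_set = [self.probe]


def _contig_alignment(state: WalkState, contig: SeqRecord) -> SplicedAlignment:
    aln = state.last_assembly.alignments.get(contig.id)
    if aln is None or aln.contig_id != contig.id:
        aln = splice_align(state.probe, contig)
    return aln


def run_round(state: WalkState, store: ReadStore, params: WalkParams) -> WalkState:
    """One walking round: recruit reads matching the query set, complete
    mates, and (from ``assembly_start_round`` on) reassemble the whole
    found pool; the winning contigs, DUST-masked, become the next queries.
    Before that round the newly found reads themselves are the queries.
    """
    if state.stop is not None:
        raise RuntimeError("walk already stopped")
    state.round += 1
    new = find_matching_reads(
        store, state.query_set,
        min_match_dna=params.min_match_dna,
        min_match_prot=params.min_match_prot,
        k_dna=params.k_dna, k_prot=params.k_prot,
    )
    new = complete_pairs(new, store)
    state.last_new_reads = len(new - state.found)
    state.found |= new

    if state.round >= params.assembly_start_round:
        pool = state.found - state.retired
        reads = store.get_reads(pool)
        state.last_assembly = assemble_sweep(
            reads, params.k_list, state.probe, min_contig=params.min_contig)
        handle_long_contigs(state, store, params)
        queries = [SeqRecord(id=c.id, seq=dust_mask(c.seq))
                   for c in state.last_assembly.contigs]
        state.query_set = queries if queries else [state.probe]
    else:
        fresh = store.get_reads(new)
        state.query_set = fresh if fresh else [state.probe]
        state.last_assembly = Assembly()

    best_cov = 0.0
    best_sim = 0.0
    for c in state.last_assembly.contigs:
        aln = _contig_alignment(state, c)
        if aln.probe_coverage > best_cov:
            best_cov = aln.probe_coverage
            best_sim = aln.similarity
    state.history.append(RoundRecord(
        round=state.round, new_reads=state.last_new_reads,
        total_reads=len(state.found),
        n_contigs=len(state.last_assembly.contigs),
        best_k=state.last_assembly.k_used,
        best_coverage=best_cov, best_similarity=best_sim,
    ))
    return state


def _contains_either_orientation(haystack: str, needle: str) -> bool:
    h = haystack.upper()
    n = needle.upper()
    return n in h or revcomp(n) in h


def handle_long_contigs(state: WalkState, store: ReadStore,
                        params: WalkParams) -> WalkState:
    """Retire contigs that reached the maximum length.

    Over-long contigs are trimmed symmetrically to ``max_contig`` (odd
    excess: the extra base comes off the tail) and parked as candidates; a
    candidate whose sequence is reassembled inside a long contig of the
    next round is promoted to permanent, its reads leave the assembly
    pool, and it never serves as a query again.
    """
    contigs = state.last_assembly.contigs
    long_c = [c for c in contigs if len(c.seq) > params.max_contig]
    short_c = [c for c in contigs if len(c.seq) <= params.max_contig]

    promoted = []
    for cand in state.candidate_long:
        for c in long_c:
            if len(c.seq) >= params.max_contig and \
                    _contains_either_orientation(c.seq, cand.seq):
                promoted.append(cand)
                break
    if promoted:
        state.permanent_long.extend(promoted)
        retired = find_matching_reads(
            store, promoted,
            min_match_dna=params.min_match_dna,
            min_match_prot=params.min_match_prot,
            k_dna=params.k_dna, k_prot=params.k_prot)
        state.retired |= complete_pairs(retired, store)

    new_candidates = []
    for i, c in enumerate(long_c):
        excess = len(c.seq) - params.max_contig
        head = excess // 2
        trimmed = c.seq[head : head + params.max_contig]
        new_candidates.append(SeqRecord(id=f"long_r{state.round}_{i + 1}",
                                        seq=trimmed))
    state.candidate_long = new_candidates
    state.last_assembly.contigs = short_c
    return state


def _probe_partial_match(probe: SeqRecord, contig: SeqRecord,
                         params: WalkParams) -> bool:
    """Cleaning test: does the contig share an exact substring with the
    original probe at half the recruitment match length? Halving keeps
    cleaning strictly more permissive than recruitment."""
    cseq = contig.seq.upper()
    p = probe.seq.upper()
    if probe.alphabet == "protein":
        need = max(params.min_match_prot // 2, 3)
        for strand_seq in (cseq, revcomp(cseq)):
            for f in range(3):
                if _aligner._find_seeds(p, _translate(strand_seq, f), need):
                    return True
        return False
    need = max(params.min_match_dna // 2, 8)
    return bool(_aligner._find_seeds(p, cseq, need)
                or _aligner._find_seeds(p, revcomp(cseq), need))


def clean(state: WalkState, store: ReadStore, params: WalkParams) -> WalkState:
    """Cull contigs without a partial probe match, then cull found reads
    that match none of the surviving contigs (mates re-closed afterwards).
    If everything is culled the probe again becomes the query so the walk
    can re-seed.
    """
    contigs = state.last_assembly.contigs
    survivors = [c for c in contigs
                 if _probe_partial_match(state.probe, c, params)]
    state.last_assembly.contigs = survivors
    if not survivors:
        state.query_set = [state.probe]
        state.found = set()
        state.retired = set()
        return state
    matching = find_matching_reads(
        store, survivors,
        min_match_dna=params.min_match_dna,
        min_match_prot=params.min_match_prot,
        k_dna=params.k_dna, k_prot=params.k_prot)
    state.found = complete_pairs(state.found & matching, store)
    state.retired &= state.found
    state.query_set = [SeqRecord(id=c.id, seq=dust_mask(c.seq))
                       for c in survivors]
    return state


def _clean_due(state: WalkState, params: WalkParams) -> bool:
    if state.round < params.assembly_start_round:
        return False
    if params.clean_period and state.round % params.clean_period == 0:
        return True
    return len(state.last_assembly.contigs) > params.contig_limit


def check_stop(state: WalkState, params: WalkParams) -> WalkState:
    """Evaluate the stopping criteria after a round (possibly arming or
    draining the extra-rounds countdown)."""
    # criterion 1: hit contig
    hit_found = False
    if state.round >= params.assembly_start_round:
        for c in (state.last_assembly.contigs + state.candidate_long
                  + state.permanent_long):
            aln = _contig_alignment(state, c)
            if is_hit(aln, len(c.seq), params.min_contig,
                      params.min_similarity, params.min_query_coverage):
                hit_found = True
                break
    if hit_found and not params.force_max_rounds:
        if params.extra_rounds > 0:
            if state.extra_countdown is None:
                state.extra_countdown = params.extra_rounds
        else:
            state.stop = "hit"
            return state
    if state.extra_countdown is not None and state.extra_countdown <= 0:
        state.stop = "hit"
        return state

    # criterion 2: nothing new to extend with
    if state.last_new_reads == 0:
        state.stop = "no_new_reads"
        return state

    # criterion 3: iteration cap (an armed countdown may extend it)
    cap = params.max_rounds
    if state.extra_countdown is not None:
        cap += params.extra_rounds
    if state.round >= cap:
        state.stop = "max_rounds"
        return state

    # criterion 4: every contig reached the maximum length
    if (state.round >= params.assembly_start_round
            and not state.last_assembly.contigs
            and (state.candidate_long or state.permanent_long)):
        state.stop = "all_long"
        return state

    if state.extra_countdown is not None:
        state.extra_countdown -= 1
    return state


@dataclass
class WalkResult:
    state: WalkState
    all_contigs: List[SeqRecord]
    hit_contigs: List[SeqRecord]
    alignments: List[SplicedAlignment]

    @property
    def success(self) -> bool:
        return bool(self.hit_contigs)


def finalize(state: WalkState, params: WalkParams) -> WalkResult:
    """Produce the final outputs: every final-round contig at or above the
    minimum length (plus retired long contigs), the subset passing the hit
    thresholds, and an alignment report for everything with nonzero
    coverage. Output sequences carry DUST lowercase masking."""
    if state.stop is None:
        raise RuntimeError("finalize requires a stopped walk")
    pool = [(c, True) for c in state.last_assembly.contigs
            if len(c.seq) >= params.min_contig]
    pool += [(c, True) for c in state.candidate_long
             if len(c.seq) >= params.min_contig]
    # retired long contigs are reported byte-identical (never re-masked)
    pool += [(c, False) for c in state.permanent_long]
    all_contigs = []
    hits = []
    alignments = []
    for i, (c, mask) in enumerate(pool, 1):
        aln = _contig_alignment(state, c)
        out = SeqRecord(id=f"contig{i}", seq=dust_mask(c.seq) if mask else c.seq)
        all_contigs.append(out)
        if aln.probe_coverage > 0:
            aln.contig_id = out.id
            alignments.append(aln)
        if is_hit(aln, len(c.seq), params.min_contig,
                  params.min_similarity, params.min_query_coverage):
            hits.append(out)
    return WalkResult(state=state, all_contigs=all_contigs,
                      hit_contigs=hits, alignments=alignments)


def walk(probe: SeqRecord, store: ReadStore, params: Optional[WalkParams] = None,
         output_dir: Optional[str] = None) -> WalkResult:
    """Run the full recursion until a stopping criterion fires, then write
    (optionally) all_contigs.fasta, hit_contigs.fasta, output.aln and the
    per-round history table."""
    params = params or WalkParams()
    state = WalkState(probe=probe)
    while state.stop is None:
        run_round(state, store, params)
        if _clean_due(state, params):
            clean(state, store, params)
        check_stop(state, params)
    result = finalize(state, params)
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        write_sequences(result.all_contigs,
                        os.path.join(output_dir, "all_contigs.fasta"))
        write_sequences(result.hit_contigs,
                        os.path.join(output_dir, "hit_contigs.fasta"))
        write_alignment_report(result.alignments,
                               os.path.join(output_dir, "output.aln"))
        write_gff3(result.alignments, os.path.join(output_dir, "hits.gff3"))
        with open(os.path.join(output_dir, "history.tsv"), "w") as fh:
            fh.write("round\tnew_reads\ttotal_reads\tcontigs\tbest_k\t"
                     "best_coverage\tbest_similarity\n")
            for r in state.history:
                fh.write(f"{r.round}\t{r.new_reads}\t{r.total_reads}\t"
                         f"{r.n_contigs}\t{r.best_k}\t"
                         f"{r.best_coverage:.3f}\t{r.best_similarity:.3f}\n")
    return result
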