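"""Stopping criteria, cleaning triggers, long-contig retirement, and a
miniature end-to-end walk on the planted-gene fixture."""

import pytest

from chromwalk.aligner import SplicedAlignment
from chromwalk.assembler import Assembly
from chromwalk.readstore import ReadRef
from chromwalk.seqio import SeqRecord, revcomp
from chromwalk.walker import (WalkParams, WalkState, check_stop, clean,
                              finalize, handle_long_contigs, run_round, walk)

from conftest import random_dna, store_from_reads


PROBE = SeqRecord(id="p", seq="M" * 120, alphabet="protein")


def state_with_contigs(contigs, alns=None, new_reads=5, round_=1):
    st = WalkState(probe=PROBE)
    st.round = round_
    st.last_new_reads = new_reads
    st.last_assembly = Assembly(k_used=25, contigs=list(contigs),
                                metric=1, alignments=alns or {})
    return st


def aln_for(c, sim, cov):
    return SplicedAlignment(probe_id="p", contig_id=c.id, similarity=sim,
                            probe_coverage=cov,
                            blocks=[(0, 1, 0, 3)], aligned_length=3)


# ---------------------------------------------------------------------------
# check_stop


def test_stop_hit_when_contig_passes_thresholds():
    c = SeqRecord(id="c1", seq="A" * 1500)
    st = state_with_contigs([c], {"c1": aln_for(c, 0.92, 0.95)})
    check_stop(st, WalkParams())
    assert st.stop == "hit"


def test_no_stop_when_coverage_below_threshold():
    c = SeqRecord(id="c1", seq="A" * 1500)
    st = state_with_contigs([c], {"c1": aln_for(c, 0.92, 0.79)})
    check_stop(st, WalkParams())
    assert st.stop is None


def test_stop_no_new_reads():
    c = SeqRecord(id="c1", seq="A" * 300)
    st = state_with_contigs([c], {"c1": aln_for(c, 0.9, 0.1)}, new_reads=0)
    check_stop(st, WalkParams())
    assert st.stop == "no_new_reads"


def test_stop_max_rounds():
    c = SeqRecord(id="c1", seq="A" * 300)
    st = state_with_contigs([c], {"c1": aln_for(c, 0.9, 0.1)}, round_=10)
    check_stop(st, WalkParams(max_rounds=10))
    assert st.stop == "max_rounds"


def test_stop_all_long_when_every_contig_reached_cap():
    st = state_with_contigs([])
    st.candidate_long = [SeqRecord(id="L1", seq="A" * 10_000)]
    check_stop(st, WalkParams())
    assert st.stop == "all_long"


def test_force_max_rounds_ignores_hits():
    c = SeqRecord(id="c1", seq="A" * 1500)
    params = WalkParams(force_max_rounds=True, max_rounds=10)
    st = state_with_contigs([c], {"c1": aln_for(c, 0.92, 0.95)}, round_=3)
    check_stop(st, params)
    assert st.stop is None
    st.round = 10
    check_stop(st, params)
    assert st.stop == "max_rounds"


def test_extra_rounds_countdown_after_first_hit():
    c = SeqRecord(id="c1", seq="A" * 1500)
    params = WalkParams(extra_rounds=2, max_rounds=10)
    st = state_with_contigs([c], {"c1": aln_for(c, 0.92, 0.95)}, round_=3)
    check_stop(st, params)  # arming round
    assert st.stop is None
    st.round = 4
    check_stop(st, params)
    assert st.stop is None
    st.round = 5
    check_stop(st, params)
    assert st.stop == "hit"


def test_force_and_extra_rounds_are_exclusive():
    with pytest.raises(ValueError):
        WalkParams(force_max_rounds=True, extra_rounds=2)


# ---------------------------------------------------------------------------
# long contigs


def test_overlong_contig_trimmed_symmetrically(rng):
    seq = random_dna(rng, 12_000)
    store = store_from_reads([random_dna(rng, 70)])
    st = state_with_contigs([SeqRecord(id="big", seq=seq)])
    handle_long_contigs(st, store, WalkParams())
    assert st.last_assembly.contigs == []
    (cand,) = st.candidate_long
    assert len(cand.seq) == 10_000
    assert cand.seq == seq[1000:11_000]  # 1000 bp off each end


def test_odd_excess_takes_extra_base_off_tail(rng):
    seq = random_dna(rng, 10_001)
    store = store_from_reads([random_dna(rng, 70)])
    st = state_with_contigs([SeqRecord(id="big", seq=seq)])
    handle_long_contigs(st, store, WalkParams())
    (cand,) = st.candidate_long
    assert cand.seq == seq[0:10_000]


def test_under_cap_contig_untouched(rng):
    seq = random_dna(rng, 9_999)
    store = store_from_reads([random_dna(rng, 70)])
    st = state_with_contigs([SeqRecord(id="ok", seq=seq)])
    handle_long_contigs(st, store, WalkParams())
    assert st.candidate_long == []
    assert [c.seq for c in st.last_assembly.contigs] == [seq]


def test_candidate_promoted_when_reassembled(rng):
    genome = random_dna(rng, 14_000)
    reads = [genome[i : i + 70] for i in range(5000, 5200, 40)]
    store = store_from_reads(reads)
    st = state_with_contigs([SeqRecord(id="big", seq=genome[:12_000])])
    params = WalkParams()
    handle_long_contigs(st, store, params)
    (cand,) = st.candidate_long
    # next round reassembles a long contig containing the candidate
    st.last_assembly = Assembly(k_used=25,
                                contigs=[SeqRecord(id="big2",
                                                   seq=genome[500:12_500])])
    handle_long_contigs(st, store, params)
    assert [c.seq for c in st.permanent_long] == [cand.seq]
    # reads matching the promoted contig leave the assembly pool
    assert st.retired, "reads overlapping the permanent contig are retired"
    # a permanent contig never re-enters the candidate list
    assert all(c.seq != cand.seq for c in st.candidate_long)


# ---------------------------------------------------------------------------
# cleaning


def _dna_probe_state(rng, probe_seq, contigs, found=()):
    probe = SeqRecord(id="p", seq=probe_seq, alphabet="dna")
    st = WalkState(probe=probe)
    st.round = 4
    st.last_assembly = Assembly(k_used=25, contigs=list(contigs))
    st.found = set(found)
    return st


def _unrelated_dna(rng, n, probe_seq, word=10):
    """Random DNA sharing no length-`word` substring with the probe in
    either orientation (so a partial-match cull test is deterministic)."""
    words = {probe_seq[i : i + word] for i in range(len(probe_seq) - word + 1)}
    while True:
        s = random_dna(rng, n)
        rc = revcomp(s)
        if not any(s[i : i + word] in words or rc[i : i + word] in words
                   for i in range(n - word + 1)):
            return s


def test_clean_drops_non_matching_contigs_and_their_reads(rng):
    probe_seq = random_dna(rng, 300)
    good = SeqRecord(id="good", seq=probe_seq[50:250] + random_dna(rng, 100))
    bad = SeqRecord(id="bad", seq=_unrelated_dna(rng, 300, probe_seq))
    reads = [good.seq[10:80], bad.seq[100:170]]
    store = store_from_reads(reads)
    st = _dna_probe_state(rng, probe_seq, [good, bad],
                          found={ReadRef(0, 0, 0), ReadRef(0, 0, 1)})
    clean(st, store, WalkParams())
    assert [c.id for c in st.last_assembly.contigs] == ["good"]
    assert st.found == {ReadRef(0, 0, 0)}


def test_clean_keeps_everything_when_all_contigs_match(rng):
    probe_seq = random_dna(rng, 300)
    c1 = SeqRecord(id="c1", seq=probe_seq[:200])
    c2 = SeqRecord(id="c2", seq=probe_seq[100:300])
    reads = [probe_seq[20:90], probe_seq[150:220]]
    store = store_from_reads(reads)
    st = _dna_probe_state(rng, probe_seq, [c1, c2],
                          found={ReadRef(0, 0, 0), ReadRef(0, 0, 1)})
    clean(st, store, WalkParams())
    assert len(st.last_assembly.contigs) == 2
    assert st.found == {ReadRef(0, 0, 0), ReadRef(0, 0, 1)}


def test_clean_reseeds_probe_when_all_contigs_culled(rng):
    probe_seq = random_dna(rng, 300)
    bad = SeqRecord(id="bad", seq=_unrelated_dna(rng, 300, probe_seq))
    store = store_from_reads([bad.seq[10:80]])
    st = _dna_probe_state(rng, probe_seq, [bad], found={ReadRef(0, 0, 0)})
    clean(st, store, WalkParams())
    assert st.last_assembly.contigs == []
    assert st.query_set == [st.probe]


def test_contig_limit_triggers_early_clean(rng):
    from chromwalk.walker import _clean_due
    st = _dna_probe_state(rng, random_dna(rng, 300),
                          [SeqRecord(id=f"c{i}", seq="ACGT" * 60)
                           for i in range(501)])
    st.round = 2
    assert _clean_due(st, WalkParams(clean_period=4))
    st.last_assembly.contigs = st.last_assembly.contigs[:10]
    assert not _clean_due(st, WalkParams(clean_period=4))
    st.round = 4
    assert _clean_due(st, WalkParams(clean_period=4))


# ---------------------------------------------------------------------------
# finalize & end-to-end


def test_finalize_filters_hits_and_requires_stop():
    c1 = SeqRecord(id="c1", seq="ACGT" * 100)
    c2 = SeqRecord(id="c2", seq="ACGT" * 100)
    st = state_with_contigs([c1, c2], {"c1": aln_for(c1, 0.9, 0.9),
                                       "c2": aln_for(c2, 0.9, 0.1)})
    with pytest.raises(RuntimeError):
        finalize(st, WalkParams())
    st.stop = "hit"
    res = finalize(st, WalkParams())
    assert len(res.all_contigs) == 2
    assert len(res.hit_contigs) == 1
    assert res.success


def test_finalize_empty_on_failed_walk():
    st = state_with_contigs([])
    st.stop = "no_new_reads"
    res = finalize(st, WalkParams())
    assert res.all_contigs == [] and res.hit_contigs == []
    assert not res.success


def test_permanent_long_reported_byte_identical(rng):
    seq = random_dna(rng, 10_000)
    st = state_with_contigs([])
    st.permanent_long = [SeqRecord(id="L", seq=seq)]
    st.stop = "all_long"
    res = finalize(st, WalkParams())
    assert any(c.seq == seq for c in res.all_contigs)


def test_walk_on_planted_gene_reaches_hit(small_locus):
    """Error-prone 20X reads over a 60 kb genome: the recursion must stop
    on the hit criterion and the hit contig must recover the gene body at
    high identity."""
    from chromwalk.aligner import percent_identity
    res = walk(small_locus["probe"], small_locus["store"],
               WalkParams(max_rounds=8))
    assert res.state.stop == "hit"
    assert res.success
    gene = small_locus["gene"]
    body = small_locus["genome"].seq[gene.start:gene.end]
    best = max(percent_identity(body, c.seq) for c in res.hit_contigs)
    assert best >= 98.0


def test_delayed_assembly_uses_reads_as_queries(small_locus):
    from chromwalk.walker import run_round
    st = WalkState(probe=small_locus["probe"])
    params = WalkParams(assembly_start_round=3)
    run_round(st, small_locus["store"], params)
    assert st.round == 1
    assert st.last_assembly.contigs == []
    # queries are now the recruited reads themselves
    assert len(st.query_set) == len(st.found)
    assert all(len(q.seq) == 70 for q in st.query_set)


def test_walk_writes_output_files(small_locus, tmp_path):
    out = tmp_path / "out"
    res = walk(small_locus["probe"], small_locus["store"],
               WalkParams(max_rounds=8), output_dir=str(out))
    assert (out / "all_contigs.fasta").exists()
    assert (out / "hit_contigs.fasta").exists()
    assert (out / "output.aln").exists()
    history = (out / "history.tsv").read_text().splitlines()
    assert len(history) == res.state.round + 1  # header + one per round
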