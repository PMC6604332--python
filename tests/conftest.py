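"""Shared fixtures: small deterministic genomes, read pools and stores."""

from __future__ import annotations

import numpy as np
import pytest

from chromwalk.readstore import LibrarySpec, ReadChunk, ReadLibrary, ReadStore
from chromwalk.seqio import SeqRecord
from chromwalk.simulator import (GeneSpec, SimParams, diverge_probe,
                                 make_genome, simulate_store)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def store_from_reads(seqs, paired=False) -> ReadStore:
    """Build a single-chunk in-memory store from raw sequences."""
    ids = [f"r{i}" for i in range(len(seqs))]
    chunk = ReadChunk(0, ids, [s.upper() for s in seqs], paired)
    spec = LibrarySpec(files=("mem_1", "mem_2") if paired else ("mem",))
    return ReadStore([ReadLibrary(0, spec, [chunk])])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_locus():
    """A 60 kb genome with one 3-exon gene, its diverged probe, and 20X
    paired reads: the planted-gene walking fixture at miniature scale."""
    spec = GeneSpec(start=20_000, exon_lengths=[300, 300, 300],
                    intron_lengths=[200, 250], gene_id="g1")
    genome, truth = make_genome(60_000, [spec], seed=3)
    probe, cdna = diverge_probe(truth[0], 0.85, seed=5)
    store = simulate_store(genome, SimParams(coverage=20, seed=7))
    return {"genome": genome, "gene": truth[0], "probe": probe,
            "cdna": cdna, "store": store}
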