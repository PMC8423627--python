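"""Shared synthetic fixtures: one mid-sized genome pair with implanted SVs
and simulated reads, reused across test modules (session scope keeps the
suite fast)."""
from __future__ import annotations

import pytest

import anchorsv as asv


@pytest.fixture(scope="session")
def genome_and_genes():
    spec = asv.GenomeSpec([("A01", 400_000, "A"), ("D01", 300_000, "D")],
                          seed=1)
    return asv.generate_reference(spec)


@pytest.fixture(scope="session")
def genome(genome_and_genes):
    return genome_and_genes[0]


@pytest.fixture(scope="session")
def genes(genome_and_genes):
    return genome_and_genes[1]


@pytest.fixture(scope="session")
def implanted(genome):
    """Derived genome with a mixed truth set (all five SV types)."""
    svspec = asv.SVSpec(counts={"INS": 20, "DEL": 15, "INV": 3, "TRA": 2,
                                "DUP": 2}, seed=2)
    derived, truth, segments = asv.implant_variants(genome, svspec)
    return derived, truth, segments


@pytest.fixture(scope="session")
def comparison(genome, genes, implanted):
    derived, _, _ = implanted
    return asv.compare_genomes(genome, derived, genes)


@pytest.fixture(scope="session")
def reads_ref(genome, implanted):
    derived, _, segments = implanted
    cfg = asv.ReadSimConfig(seed=3)
    return asv.simulate_alignments(genome, derived, segments, cfg)


@pytest.fixture(scope="session")
def reads_query(implanted):
    derived, _, _ = implanted
    cfg = asv.ReadSimConfig(seed=4)
    return asv.simulate_alignments(derived, derived,
                                   asv.identity_map(derived), cfg)


@pytest.fixture(scope="session")
def index_ref(reads_ref):
    return asv.RecordIndex(reads_ref)


@pytest.fixture(scope="session")
def index_query(reads_query):
    return asv.RecordIndex(reads_query)
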