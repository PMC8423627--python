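"""Reference study scenarios and scoring helpers.

These functions pin down the synthetic study conditions used to exercise
the pipeline end to end — a tetraploid-like four-chromosome genome pair
with a mixed truth set for SV discovery, and a two-branch validation
scenario with truth SVs on both sides of the filters' length split — plus
truth-vs-call matching and precision/recall scoring.
"""
from __future__ import annotations

import numpy as np

from .simulate import GenomeSpec, LengthSampler, ReadSimConfig, SVSpec
from .variants import StructuralVariant

#: INS/DEL length mixture for discovery benchmarks: point-scale indels plus
#: a tail up to 5 kb, so chain-gap calling is exercised across block splits.
DISCOVERY_COUNTS = {"INS": 100, "DEL": 60, "INV": 20, "TRA": 10, "DUP": 10}


def discovery_genome_spec(seed: int) -> GenomeSpec:
    """5-Mb, four-chromosome (2 A + 2 D) genome."""
    return GenomeSpec([("A01", 1_250_000, "A"), ("A02", 1_250_000, "A"),
                       ("D01", 1_250_000, "D"), ("D02", 1_250_000, "D")],
                      seed=seed)


def discovery_sv_spec(seed: int) -> SVSpec:
    sampler = LengthSampler("mixture", components=[
        (0.7, LengthSampler("geometric", p=0.3, max=10)),
        (0.3, LengthSampler("uniform", lo=11, hi=5000))])
    return SVSpec(counts=dict(DISCOVERY_COUNTS), length_sampler=sampler,
                  large_sampler=LengthSampler("uniform", lo=2000, hi=5000),
                  min_separation=3000, seed=seed)


def validation_genome_spec(seed: int) -> GenomeSpec:
    return GenomeSpec([("A01", 700_000, "A"), ("D01", 700_000, "D")],
                      gene_density=0, seed=seed)


def validation_sv_spec(seed: int) -> SVSpec:
    """Truth lengths span both validation branches while staying out of
    the structural dead zone of the large branch (50 < L <= 3 x insert
    s.d. can never be accepted by the published rule).

    The composition is exact per run: of 60 events per type, 50 are
    short (geometric, <= 10 bp), 5 mid-sized (11-50 bp) and 5 large
    (151-2000 bp), so both branches are always exercised.
    """
    rng = np.random.default_rng(seed)
    lengths: list[int] = []
    for _ in range(2):  # one block per SV type (INS then DEL)
        block = [int(min(rng.geometric(0.45), 10)) for _ in range(50)]
        block += [int(rng.integers(11, 51)) for _ in range(5)]
        block += [int(rng.integers(151, 2001)) for _ in range(5)]
        lengths.extend(block)
    return SVSpec(counts={"INS": 60, "DEL": 60},
                  length_sampler=LengthSampler("fixed", lengths=lengths),
                  min_separation=2000, seed=seed)


def validation_read_config(seed: int) -> ReadSimConfig:
    return ReadSimConfig(coverage=30.0, seed=seed)


def make_decoys(genome, truth, n: int, seed: int,
                clearance: int = 6000) -> list[StructuralVariant]:
    """Randomly placed decoy candidates with the truth length spectrum,
    kept clear of implanted SV neighbourhoods so every decoy is genuinely
    false."""
    rng = np.random.default_rng(seed)
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        spans.setdefault(t.ref_chrom, []).append(
            (t.ref_start - clearance,
             max(t.ref_end, t.ref_start) + clearance))
    decoys: list[StructuralVariant] = []
    while len(decoys) < n:
        cid = genome.ids[int(rng.integers(len(genome)))]
        pos = int(rng.integers(clearance, len(genome[cid]) - clearance))
        if any(s < pos < e for s, e in spans.get(cid, [])):
            continue
        u = rng.random()
        if u < 0.9434:
            length = min(10, int(rng.geometric(0.45)))
        elif u < 0.9734:
            length = int(rng.integers(11, 51))
        else:
            length = int(rng.integers(151, 2001))
        typ = "DEL" if rng.random() < 0.5 else "INS"
        decoys.append(StructuralVariant(
            typ, cid, pos, pos + length if typ == "DEL" else pos,
            length=length))
    return decoys


def precision_recall(truth: list[StructuralVariant],
                     calls: list[StructuralVariant], svtype: str,
                     tol: int = 0) -> tuple[float, float]:
    """Breakpoint-matched precision and recall for one SV type.

    ``tol`` is the allowed distance on both breakpoints (0 = exact).
    Tandem-duplication calls count as insertions when scoring INS against
    a truth set that distinguishes the two is not requested.
    """
    want = [t for t in truth if t.type == svtype]
    got = [c for c in calls if c.type == svtype]
    if not want and not got:
        return 1.0, 1.0

    def match(t, c):
        if t.ref_chrom != c.ref_chrom:
            return False
        if tol == 0:
            return (t.ref_start, t.ref_end, t.length) == \
                (c.ref_start, c.ref_end, c.length)
        return abs(t.ref_start - c.ref_start) <= tol and \
            abs(max(t.ref_end, t.ref_start) - max(c.ref_end, c.ref_start)) <= tol

    used: set[int] = set()
    hits = 0
    for t in want:
        for i, c in enumerate(got):
            if i not in used and match(t, c):
                used.add(i)
                hits += 1
                break
    recall = hits / len(want) if want else 1.0
    precision = len(used) / len(got) if got else 1.0
    return precision, recall
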