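"""Synthetic genome pairs with implanted structural variants and simulated
read-alignment evidence.

This module generates everything the analysis stages consume, so the whole
pipeline is testable offline: a multi-chromosome "tetraploid-like" genome
(chromosomes carry A/D subgenome labels), protein-coding gene models, a
derived genome carrying a truth set of insertions, deletions, inversions,
translocations and tandem duplications, and paired-end read placements with
the statistical structure the validation filters assume — gapped alignments
over small indels, and single-end / aberrant-insert mates around large-SV
breakpoints, with insert sizes drawn from a truncated normal distribution.

Reads are *assigned* placements through the known derived-to-reference
coordinate map rather than mapped by an aligner; the simulator therefore
controls exactly which reads are gapped, dropped at unmappable junctions,
or left single-end.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignments import AlignmentRecord, write_sam
from .genome import Chromosome, GeneModel, Genome, revcomp, write_gff3
from .variants import StructuralVariant, left_align, write_bed, write_vcf

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# Junctions whose event size exceeds this are "large": reads crossing them
# are unmappable and their mates are emitted single-end.
SMALL_INDEL_MAX = 50


# --------------------------------------------------------------- specs


@dataclass
class GenomeSpec:
    """Chromosome layout for a synthetic reference.

    ``chromosomes`` lists (id, length bp, subgenome label in {A, D}).
    ``gene_density`` is genes per Mb; gene models are optional scaffolding
    for the annotation stage and can be disabled with density 0.
    """

    chromosomes: Sequence[tuple[str, int, str]]
    gc_fraction: float = 0.35
    gene_density: float = 30.0
    seed: int = 0

    def __post_init__(self):
        ids = [c[0] for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids must be unique")
        for cid, length, sub in self.chromosomes:
            if length < 10_000:
                raise ValueError(f"{cid}: length must be >= 10 kb")
            if sub not in ("A", "D"):
                raise ValueError(f"{cid}: subgenome must be 'A' or 'D'")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


class LengthSampler:
    """Named SV length distribution.

    Kinds: ``geometric`` (params p, optional max), ``uniform`` (lo, hi),
    ``mixture`` (components: list of (weight, LengthSampler)), and
    ``fixed`` (lengths: an explicit list consumed in order, wrapping
    around — for scenarios that need an exact length composition).
    Sampled lengths are always >= 1.
    """

    def __init__(self, kind: str, **params):
        self.kind = kind
        self.params = params
        if kind == "mixture":
            comps = params["components"]
            total = sum(w for w, _ in comps)
            self._weights = [w / total for w, _ in comps]
            self._samplers = [s for _, s in comps]
        elif kind == "fixed":
            if not params["lengths"]:
                raise ValueError("fixed sampler needs at least one length")
            self._cursor = 0
        elif kind not in ("geometric", "uniform"):
            raise ValueError(f"unknown length sampler {kind!r}")

    @property
    def max_length(self) -> int:
        if self.kind == "geometric":
            return int(self.params.get("max", 1000))
        if self.kind == "uniform":
            return int(self.params["hi"])
        if self.kind == "fixed":
            return int(max(self.params["lengths"]))
        return max(s.max_length for s in self._samplers)

    @property
    def mean_length(self) -> float:
        if self.kind == "geometric":
            return min(1.0 / self.params["p"], float(self.max_length))
        if self.kind == "uniform":
            return (self.params["lo"] + self.params["hi"]) / 2
        if self.kind == "fixed":
            return float(np.mean(self.params["lengths"]))
        return sum(w * s.mean_length
                   for w, s in zip(self._weights, self._samplers))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "geometric":
            cap = self.max_length
            out = rng.geometric(self.params["p"], size=n)
            while (mask := out > cap).any():
                out[mask] = rng.geometric(self.params["p"], size=int(mask.sum()))
            return out
        if self.kind == "uniform":
            return rng.integers(self.params["lo"], self.params["hi"] + 1, size=n)
        if self.kind == "fixed":
            lengths = self.params["lengths"]
            out = np.array([lengths[(self._cursor + i) % len(lengths)]
                            for i in range(n)], dtype=np.int64)
            self._cursor = (self._cursor + n) % len(lengths)
            return out
        which = rng.choice(len(self._samplers), size=n, p=self._weights)
        out = np.empty(n, dtype=np.int64)
        for i, s in enumerate(self._samplers):
            idx = np.flatnonzero(which == i)
            if idx.size:
                out[idx] = s.sample(rng, idx.size)
        return out

    @classmethod
    def study_like(cls) -> "LengthSampler":
        """Default indel length mixture: a heavy mass on short (<=10 bp)
        events and a long geometric tail, emulating the size spectrum of
        indels between closely related cotton genomes."""
        short = cls("geometric", p=0.45, max=10)
        long = cls("uniform", lo=11, hi=250)
        return cls("mixture", components=[(0.9434, short), (0.0566, long)])


@dataclass
class SVSpec:
    """How many SVs of each type to implant and how long they are.

    ``counts`` maps type (INS/DEL/INV/TRA/DUP) to a non-negative count.
    ``length_sampler`` drives INS/DEL/DUP lengths; ``large_sampler`` drives
    INV/TRA lengths (these must exceed the chaining cluster size to be
    classifiable from synteny blocks).  ``min_separation`` is the guard
    distance between implant sites; placement also stays clear of
    chromosome ends so every event is recoverable.
    """

    counts: dict[str, int]
    length_sampler: LengthSampler = field(default_factory=LengthSampler.study_like)
    large_sampler: LengthSampler = field(
        default_factory=lambda: LengthSampler("uniform", lo=2000, hi=5000))
    min_separation: int = 2000
    telomere_guard: int = 2000
    seed: int = 0

    def __post_init__(self):
        for t, n in self.counts.items():
            if t not in ("INS", "DEL", "INV", "TRA", "DUP"):
                raise ValueError(f"unknown SV type {t!r}")
            if n < 0:
                raise ValueError("counts must be non-negative")


@dataclass
class ReadSimConfig:
    """Paired-end library model.

    Insert sizes ~ Normal(insert_mean, insert_sd) truncated below at
    2 x read_length.  ``min_overlap`` is the flank a read must have on each
    side of a small indel to be emitted as a gapped alignment.
    ``background_single`` is the rate at which otherwise-mappable reads are
    emitted as randomly placed single-end records (the nonzero null the
    validation filters face).
    """

    read_length: int = 100
    insert_mean: int = 350
    insert_sd: int = 50
    coverage: float = 30.0
    min_overlap: int = 10
    background_single: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed 2 x read_length")
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


# ----------------------------------------------------- reference generation


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _make_gene(rng: np.random.Generator, gid: str, chrom: str, start: int,
               strand: str) -> tuple[GeneModel, str]:
    """Build one gene model and its genomic sequence starting at ``start``.

    Transcript layout (5' to 3'): 5'UTR, >=2 CDS exons separated by GT..AG
    introns, 3'UTR.  The CDS begins with ATG, ends with a stop codon and
    contains no internal stop.
    """
    n_codons = int(rng.integers(60, 301))
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    cds = "ATG" + "".join(SENSE_CODONS[i] for i in codons) + \
        STOP_CODONS[int(rng.integers(3))]
    n_exons = int(rng.integers(2, 5))
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3), size=n_exons - 1,
                             replace=False).tolist())
    chunks = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]
    utr5 = _random_sequence(rng, int(rng.integers(50, 201)), 0.4)
    utr3 = _random_sequence(rng, int(rng.integers(50, 201)), 0.4)

    # assemble in transcript orientation, tracking relative intervals
    seq_parts: list[str] = []
    rel = 0
    rel_utr5: list[tuple[int, int]] = []
    rel_utr3: list[tuple[int, int]] = []
    rel_cds: list[tuple[int, int]] = []
    rel_exons: list[tuple[int, int]] = []

    seq_parts.append(utr5)
    rel_utr5.append((rel, rel + len(utr5)))
    exon_open = rel  # first exon starts with the 5'UTR
    rel += len(utr5)
    for i, chunk in enumerate(chunks):
        rel_cds.append((rel, rel + len(chunk)))
        seq_parts.append(chunk)
        rel += len(chunk)
        if i < len(chunks) - 1:
            rel_exons.append((exon_open, rel))
            intron = "GT" + _random_sequence(rng, int(rng.integers(56, 497)), 0.3) + "AG"
            seq_parts.append(intron)
            rel += len(intron)
            exon_open = rel
    rel_utr3.append((rel, rel + len(utr3)))
    seq_parts.append(utr3)
    rel += len(utr3)
    rel_exons.append((exon_open, rel))

    gene_seq = "".join(seq_parts)
    length = len(gene_seq)
    assert rel == length

    def place(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        if strand == "+":
            return [(start + a, start + b) for a, b in ivs]
        return sorted((start + length - b, start + length - a) for a, b in ivs)

    if strand == "-":
        gene_seq = revcomp(gene_seq)
    gene = GeneModel(
        id=gid, chrom=chrom, strand=strand, start=start, end=start + length,
        exons=place(rel_exons), cds=place(rel_cds),
        utr5=place(rel_utr5), utr3=place(rel_utr3))
    return gene, gene_seq


def generate_reference(spec: GenomeSpec) -> tuple[Genome, list[GeneModel]]:
    """Generate a random reference genome and non-overlapping gene models.

    Deterministic for a fixed seed.  Raises if the requested gene density
    cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    genome = Genome()
    genes: list[GeneModel] = []
    for cid, length, sub in spec.chromosomes:
        seq = list(_random_sequence(rng, length, spec.gc_fraction))
        n_genes = int(round(spec.gene_density * length / 1e6))
        if n_genes:
            # lay genes left to right with random intergenic gaps
            max_gene = 6500  # upper bound on one gene's genomic footprint
            if n_genes * (max_gene + 200) > length - 2000:
                raise ValueError(
                    f"{cid}: cannot place {n_genes} genes without overlap "
                    f"on {length} bp")
            slot = (length - 2000) // n_genes
            for i in range(n_genes):
                strand = "+" if rng.random() < 0.5 else "-"
                offset = int(rng.integers(0, max(1, slot - max_gene)))
                start = 1000 + i * slot + offset
                gene, gseq = _make_gene(rng, f"{cid}.g{i + 1}", cid, start, strand)
                if gene.end > length - 1000:
                    raise ValueError(f"{cid}: gene {gene.id} exceeds bounds")
                seq[gene.start:gene.end] = gseq
                genes.append(gene)
        genome.add(Chromosome(cid, "".join(seq), sub))
    return genome, genes


# ------------------------------------------------------- variant implanting


@dataclass
class _Edit:
    """One reference-frame edit: delete ``del_len`` at ``pos``, then insert
    ``ins_seq``.  ``kind`` tags the originating SV for the coordinate map."""

    pos: int
    del_len: int
    ins_seq: str
    kind: str            # INS / DEL / INV / DUP / TRA_SRC / TRA_DST
    truth_idx: int


@dataclass
class MapSegment:
    """A derived-to-reference mapping segment (both 0-based half-open).

    kind: 'colinear' (strand +), 'inv' (strand -, reversed), 'tra'/'dup'
    (segment maps to its reference source elsewhere), 'novel' (inserted
    sequence with no reference image).
    """

    derived_chrom: str
    derived_start: int
    derived_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    kind: str


def implant_variants(genome: Genome, svspec: SVSpec
                     ) -> tuple[Genome, list[StructuralVariant], list[MapSegment]]:
    """Implant the requested SVs into a copy of ``genome``.

    Returns the derived genome, the truth set (``query_*`` fields hold
    derived-frame coordinates) and the derived-to-reference coordinate map
    used by the read simulator.  Truth indel breakpoints are left-aligned,
    matching the normalization applied by the caller.

    Raises when the genome cannot host the requested counts at the guard
    separation.
    """
    rng = np.random.default_rng(svspec.seed)
    counts = {t: svspec.counts.get(t, 0) for t in ("INS", "DEL", "INV", "TRA", "DUP")}
    n_events = sum(counts.values())
    n_sites = n_events + counts["TRA"]  # TRA needs a destination site too

    chrom_ids = genome.ids
    lengths = np.array([len(genome[c]) for c in chrom_ids])
    guard = svspec.telomere_guard
    usable = (lengths - 2 * guard).clip(min=0)
    n_indel = counts["INS"] + counts["DEL"]
    n_large = counts["INV"] + counts["TRA"] + counts["DUP"]
    need = (n_indel * svspec.length_sampler.mean_length
            + n_large * svspec.large_sampler.mean_length
            + n_sites * svspec.min_separation)
    if usable.sum() < 1.5 * need:
        raise ValueError(
            f"genome too small for {n_sites} implant sites at "
            f"min_separation {svspec.min_separation}")

    # guard-separated site placement: each event reserves its reference
    # footprint plus min_separation of clean flank on either side
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ids}
    p = usable / usable.sum()
    attempts = 0

    def place(footprint: int) -> tuple[str, int]:
        nonlocal attempts
        sep = svspec.min_separation
        while True:
            attempts += 1
            if attempts > 2000 * max(n_sites, 1):
                raise ValueError(
                    "cannot place implant sites at requested separation")
            ci = int(rng.choice(len(chrom_ids), p=p))
            cid = chrom_ids[ci]
            hi = int(lengths[ci]) - guard - footprint
            if hi <= guard:
                continue
            pos = int(rng.integers(guard, hi))
            iv = (pos - sep, pos + footprint + sep)
            occ = occupied[cid]
            i = bisect.bisect_left(occ, iv)
            if i > 0 and occ[i - 1][1] > iv[0]:
                continue
            if i < len(occ) and occ[i][0] < iv[1]:
                continue
            occ.insert(i, iv)
            return cid, pos

    truth: list[StructuralVariant] = []
    edits: dict[str, list[_Edit]] = {c: [] for c in chrom_ids}

    def indel_len() -> int:
        return int(svspec.length_sampler.sample(rng, 1)[0])

    def large_len() -> int:
        return int(svspec.large_sampler.sample(rng, 1)[0])

    for _ in range(counts["INS"]):
        length = indel_len()
        cid, site = place(0)
        # redraw sequences that tandem-duplicate the flanking reference;
        # those are DUP by definition and would make the truth ambiguous
        while True:
            seq = _random_sequence(rng, length, 0.5)
            pos, seq = left_align(site, seq, genome[cid].seq)
            ref_seq = genome[cid].seq
            if ref_seq[pos:pos + length] != seq and \
                    ref_seq[max(0, pos - length):pos] != seq:
                break
        ti = len(truth)
        truth.append(StructuralVariant("INS", cid, pos, pos, length=length,
                                       sequence=seq, source="truth"))
        edits[cid].append(_Edit(pos, 0, seq, "INS", ti))

    for _ in range(counts["DEL"]):
        length = indel_len()
        cid, pos = place(length)
        seq = genome[cid].seq[pos:pos + length]
        pos, seq = left_align(pos, seq, genome[cid].seq)
        ti = len(truth)
        truth.append(StructuralVariant("DEL", cid, pos, pos + length,
                                       length=length, sequence=seq,
                                       source="truth"))
        edits[cid].append(_Edit(pos, length, "", "DEL", ti))

    for _ in range(counts["INV"]):
        length = large_len()
        cid, pos = place(length)
        segment = genome[cid].seq[pos:pos + length]
        ti = len(truth)
        truth.append(StructuralVariant("INV", cid, pos, pos + length,
                                       length=length, source="truth"))
        edits[cid].append(_Edit(pos, length, revcomp(segment), "INV", ti))

    for _ in range(counts["DUP"]):
        length = large_len()
        cid, pos = place(length)
        segment = genome[cid].seq[pos:pos + length]
        # a tandem copy inserted after the template left-aligns to the
        # template start (and further through any upstream repeat context)
        pos, segment = left_align(pos, segment, genome[cid].seq)
        ti = len(truth)
        truth.append(StructuralVariant("DUP", cid, pos, pos + length,
                                       length=length, sequence=segment,
                                       source="truth"))
        edits[cid].append(_Edit(pos, 0, segment, "DUP", ti))

    for _ in range(counts["TRA"]):
        length = large_len()
        src_cid, src_pos = place(length)
        dst_cid, dst_pos = place(0)
        segment = genome[src_cid].seq[src_pos:src_pos + length]
        ti = len(truth)
        truth.append(StructuralVariant(
            "TRA", src_cid, src_pos, src_pos + length, length=length,
            query_chrom=dst_cid, inter_chromosomal=src_cid != dst_cid,
            source="truth"))
        edits[src_cid].append(_Edit(src_pos, length, "", "TRA_SRC", ti))
        edits[dst_cid].append(_Edit(dst_pos, 0, segment, "TRA_DST", ti))

    # stitch each chromosome, building the coordinate map
    derived = Genome()
    segments: list[MapSegment] = []
    for cid in chrom_ids:
        ref_seq = genome[cid].seq
        parts: list[str] = []
        dpos = 0
        cursor = 0

        def emit_colinear(upto: int):
            nonlocal dpos, cursor
            if upto > cursor:
                parts.append(ref_seq[cursor:upto])
                segments.append(MapSegment(cid, dpos, dpos + upto - cursor,
                                           cid, cursor, upto, "colinear"))
                dpos += upto - cursor
                cursor = upto

        for ed in sorted(edits[cid], key=lambda e: e.pos):
            if ed.pos < cursor:
                raise ValueError(f"overlapping edits on {cid} at {ed.pos}")
            emit_colinear(ed.pos)
            tv = truth[ed.truth_idx]
            if ed.kind == "DEL":
                cursor += ed.del_len
                tv.query_chrom, tv.query_start, tv.query_end = cid, dpos, dpos
            elif ed.kind == "INS":
                parts.append(ed.ins_seq)
                segments.append(MapSegment(cid, dpos, dpos + len(ed.ins_seq),
                                           cid, ed.pos, ed.pos, "novel"))
                tv.query_chrom = cid
                tv.query_start, tv.query_end = dpos, dpos + len(ed.ins_seq)
                dpos += len(ed.ins_seq)
            elif ed.kind == "INV":
                parts.append(ed.ins_seq)
                segments.append(MapSegment(cid, dpos, dpos + ed.del_len,
                                           cid, ed.pos, ed.pos + ed.del_len,
                                           "inv"))
                tv.query_chrom = cid
                tv.query_start, tv.query_end = dpos, dpos + ed.del_len
                cursor += ed.del_len
                dpos += ed.del_len
            elif ed.kind == "DUP":
                parts.append(ed.ins_seq)
                segments.append(MapSegment(cid, dpos, dpos + len(ed.ins_seq),
                                           cid, ed.pos, ed.pos + len(ed.ins_seq),
                                           "dup"))
                tv.query_chrom = cid
                tv.query_start, tv.query_end = dpos, dpos + len(ed.ins_seq)
                dpos += len(ed.ins_seq)
            elif ed.kind == "TRA_SRC":
                cursor += ed.del_len
            elif ed.kind == "TRA_DST":
                parts.append(ed.ins_seq)
                segments.append(MapSegment(cid, dpos, dpos + len(ed.ins_seq),
                                           tv.ref_chrom, tv.ref_start,
                                           tv.ref_end, "tra"))
                tv.query_start, tv.query_end = dpos, dpos + len(ed.ins_seq)
                dpos += len(ed.ins_seq)
        emit_colinear(len(ref_seq))
        derived.add(Chromosome(cid, "".join(parts), genome[cid].subgenome))
    return derived, truth, segments


# ---------------------------------------------------------- read simulation


class _ChromMap:
    """Per-derived-chromosome segment lookup."""

    def __init__(self, segments: list[MapSegment]):
        self.segs = sorted(segments, key=lambda s: s.derived_start)
        self.starts = [s.derived_start for s in self.segs]

    def overlapping(self, a: int, b: int) -> list[MapSegment]:
        i = bisect.bisect_right(self.starts, a) - 1
        out = []
        while i < len(self.segs) and (i < 0 or self.segs[i].derived_start < b):
            if i >= 0 and self.segs[i].derived_end > a:
                out.append(self.segs[i])
            i += 1
        return out


def _map_read(cmap: _ChromMap, a: int, b: int, min_overlap: int
              ) -> tuple[str, int, list[tuple[str, int, int]]] | None:
    """Assign one read interval [a, b) a reference placement, or None.

    Reads inside one mapped segment place gaplessly; reads crossing small
    indel junctions (<= SMALL_INDEL_MAX) with sufficient flank place with a
    gap op; everything else is unmappable.
    """
    segs = cmap.overlapping(a, b)
    if not segs:
        return None
    if len(segs) == 1:
        s = segs[0]
        if s.derived_start <= a and b <= s.derived_end:
            if s.kind == "novel":
                return None
            if s.kind == "inv":
                return s.ref_chrom, s.ref_start + (s.derived_end - b), []
            return s.ref_chrom, s.ref_start + (a - s.derived_start), []
        return None
    if not (segs[0].derived_start <= a and b <= segs[-1].derived_end):
        return None
    # multi-segment: only colinear/novel chains over small events map
    for prev, cur in zip(segs, segs[1:]):
        if prev.derived_end != cur.derived_start:
            return None
    if segs[0].derived_end - a < min_overlap or b - segs[-1].derived_start < min_overlap:
        return None
    if segs[0].kind != "colinear" or segs[-1].kind != "colinear":
        return None
    gap_ops: list[tuple[str, int, int]] = []
    first = segs[0]
    pos = first.ref_start + (a - first.derived_start)
    ref_off = first.derived_end - a
    for cur in segs[1:]:
        if cur.kind == "novel":
            ins_len = cur.derived_end - cur.derived_start
            if ins_len > SMALL_INDEL_MAX:
                return None
            gap_ops.append(("I", ins_len, ref_off))
        elif cur.kind == "colinear":
            d = cur.ref_start - (pos + ref_off)
            if cur.ref_chrom != first.ref_chrom or d < 0 or d > SMALL_INDEL_MAX:
                return None
            if d > 0:
                gap_ops.append(("D", d, ref_off))
            ref_off += d + min(cur.derived_end, b) - cur.derived_start
        else:
            return None
    return first.ref_chrom, pos, gap_ops


def simulate_alignments(ref: Genome, derived: Genome,
                        segments: list[MapSegment], cfg: ReadSimConfig
                        ) -> list[AlignmentRecord]:
    """Simulate paired-end reads from ``derived`` and place them on ``ref``.

    For self-alignment (reads placed back on the genome they were drawn
    from) pass ``derived`` as both genomes with an identity map (see
    :func:`identity_map`).
    """
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    maps = {c: _ChromMap([s for s in segments if s.derived_chrom == c])
            for c in derived.ids}
    records: list[AlignmentRecord] = []
    ref_lengths = {c.id: len(c) for c in ref}
    for chrom in derived:
        L = len(chrom)
        n_frags = int(round(cfg.coverage * L / (2 * rl)))
        inserts = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frags)
        inserts = np.clip(np.rint(inserts), 2 * rl, None).astype(np.int64)
        starts = rng.integers(0, np.maximum(1, L - inserts), size=n_frags)
        noise = rng.random(size=(n_frags, 2)) < cfg.background_single
        cmap = maps[chrom.id]
        for fi in range(n_frags):
            f, ins = int(starts[fi]), int(inserts[fi])
            placements = [
                _map_read(cmap, f, f + rl, cfg.min_overlap),
                _map_read(cmap, f + ins - rl, f + ins, cfg.min_overlap),
            ]
            # background: replace a mate with a random single-end placement
            improper = False
            for mi in range(2):
                if noise[fi, mi] and placements[mi] is not None:
                    rc = ref.ids[int(rng.integers(len(ref)))]
                    rp = int(rng.integers(0, max(1, ref_lengths[rc] - rl)))
                    placements[mi] = (rc, rp, [])
                    improper = True  # mate loses its proper pairing too
            p1, p2 = placements
            proper = False
            tlen = 0
            if p1 is not None and p2 is not None and not improper:
                c1, s1, _ = p1
                c2, s2, _ = p2
                if c1 == c2:
                    lo = min(s1, s2)
                    hi = max(s1 + rl, s2 + rl)
                    tlen = hi - lo
                    if 2 * rl <= tlen <= cfg.insert_mean + 5 * cfg.insert_sd:
                        proper = True
            for mi, pl in enumerate(placements):
                if pl is None:
                    continue
                c, s, ops = pl
                records.append(AlignmentRecord(
                    read_id=f"{chrom.id}.f{fi}/{mi + 1}", chrom=c, pos=s,
                    read_length=rl, gap_ops=ops,
                    properly_paired=proper,
                    insert_size=tlen if proper else 0))
    return records


def identity_map(genome: Genome) -> list[MapSegment]:
    """A trivial colinear map of a genome onto itself."""
    return [MapSegment(c.id, 0, len(c), c.id, 0, len(c), "colinear")
            for c in genome]


# ------------------------------------------------------------------ outputs


def write_outputs(outdir: str | Path, genome: Genome,
                  genes: Sequence[GeneModel] = (),
                  truth: Sequence[StructuralVariant] = (),
                  records: Sequence[AlignmentRecord] = (),
                  prefix: str = "ref") -> dict[str, Path]:
    """Write FASTA/GFF3/truth BED+VCF/SAM into ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = [(c.id, len(c)) for c in genome]
    paths["fasta"] = outdir / f"{prefix}.fa"
    genome.to_fasta(paths["fasta"])
    if genes:
        paths["gff3"] = outdir / f"{prefix}.gff3"
        write_gff3(genes, paths["gff3"])
    if truth:
        paths["bed"] = outdir / f"{prefix}.truth.bed"
        write_bed(truth, paths["bed"])
        paths["vcf"] = outdir / f"{prefix}.truth.vcf"
        write_vcf(truth, paths["vcf"], contigs)
    if records:
        paths["sam"] = outdir / f"{prefix}.sam"
        write_sam(records, paths["sam"], contigs)
    return paths
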