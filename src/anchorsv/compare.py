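"""Synteny-block chaining and structural-variant classification.

Anchors are chained into colinear same-strand blocks under a gap cap
(``max_gap``, default 500 bp) and a minimum anchored-length cluster size
(``min_cluster``, default 1 kb).  Insertions and deletions are read off
the gaps between consecutive anchors along the order-consistent backbone;
inversions come from reverse-pattern (minus-strand) blocks; translocations
from nonsequential blocks — blocks that fall off the length-weighted
longest increasing subsequence of query order over reference order, or
that pair with a non-dominant chromosome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .anchors import Anchor, find_anchors
from .genome import GeneModel, Genome
from .variants import StructuralVariant, left_align


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str
    anchor_bp: int
    rank_ref: int = -1
    rank_query: int = -1

    @property
    def identity(self) -> float:
        span = max(self.ref_end - self.ref_start, 1)
        return min(1.0, self.anchor_bp / span)

    @property
    def gap_count(self) -> int:
        return len(self.anchors) - 1

    @property
    def ref_mid(self) -> float:
        return (self.ref_start + self.ref_end) / 2

    @property
    def query_mid(self) -> float:
        return (self.query_start + self.query_end) / 2


def chain_anchors(anchors: list[Anchor], max_gap: int = 500,
                  min_cluster: int = 1000) -> list[SyntenyBlock]:
    """Chain anchors into maximal colinear same-strand blocks.

    Adjacent in-block anchors have reference and query gaps <= ``max_gap``
    (small overlaps up to ``max_gap`` are tolerated; exact repeats at a
    junction can make maximal matches overlap).  Blocks whose summed anchor
    length falls below ``min_cluster`` are discarded.  Surviving blocks get
    rank indices by midpoint order along each genome.
    """
    groups: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.query_chrom, a.strand), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (rc, qc, strand), grp in groups.items():
        grp.sort(key=lambda a: (a.ref_start, a.ref_end))
        chain: list[Anchor] = []

        def flush():
            if not chain:
                return
            bp = sum(a.length for a in chain)
            if bp >= min_cluster:
                blocks.append(SyntenyBlock(
                    anchors=list(chain), ref_chrom=rc,
                    ref_start=min(a.ref_start for a in chain),
                    ref_end=max(a.ref_end for a in chain),
                    query_chrom=qc,
                    query_start=min(a.query_start for a in chain),
                    query_end=max(a.query_end for a in chain),
                    strand=strand, anchor_bp=bp))
            chain.clear()

        for a in grp:
            if chain:
                prev = chain[-1]
                ref_gap = a.ref_start - prev.ref_end
                if strand == "+":
                    q_gap = a.query_start - prev.query_end
                    mono = a.query_start > prev.query_start
                else:
                    q_gap = prev.query_start - a.query_end
                    mono = a.query_start < prev.query_start
                if not (mono and -max_gap <= ref_gap <= max_gap
                        and -max_gap <= q_gap <= max_gap):
                    flush()
            chain.append(a)
        flush()

    for key_attr, rank_attr in (("ref", "rank_ref"), ("query", "rank_query")):
        by_chrom: dict[str, list[SyntenyBlock]] = {}
        for b in blocks:
            by_chrom.setdefault(getattr(b, f"{key_attr}_chrom"), []).append(b)
        for chrom_blocks in by_chrom.values():
            chrom_blocks.sort(key=lambda b: getattr(b, f"{key_attr}_mid"))
            for i, b in enumerate(chrom_blocks):
                setattr(b, rank_attr, i)
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return blocks


def weighted_lis(values: list[float], weights: list[float]) -> list[int]:
    """Indices of the maximum-weight strictly increasing subsequence."""
    n = len(values)
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    if n == 0:
        return []
    i = max(range(n), key=lambda x: best[x])
    out = []
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def _dominant_partner(blocks: list[SyntenyBlock]) -> dict[str, str]:
    """Per reference chromosome, the query chromosome with most anchored bp."""
    weight: dict[tuple[str, str], int] = {}
    for b in blocks:
        key = (b.ref_chrom, b.query_chrom)
        weight[key] = weight.get(key, 0) + b.anchor_bp
    dom: dict[str, str] = {}
    for (rc, qc), w in weight.items():
        if rc not in dom or w > weight[(rc, dom[rc])]:
            dom[rc] = qc
    return dom


def backbone_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Order-consistent plus-strand backbone per reference chromosome:
    blocks pairing with the dominant partner whose query midpoints form the
    length-weighted LIS over reference order."""
    dom = _dominant_partner(blocks)
    out: list[SyntenyBlock] = []
    by_ref: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        if b.strand == "+" and dom.get(b.ref_chrom) == b.query_chrom:
            by_ref.setdefault(b.ref_chrom, []).append(b)
    for rc, grp in by_ref.items():
        grp.sort(key=lambda b: b.ref_mid)
        keep = weighted_lis([b.query_mid for b in grp],
                            [float(b.anchor_bp) for b in grp])
        out.extend(grp[i] for i in keep)
    out.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return out


# ------------------------------------------------------------ indel calling

_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -2
_ALIGNER.extend_gap_score = -1

MAX_GAP_ALIGN = 20_000  # both-sided gaps beyond this are left uncalled


def _gap_indels(ref_gap: str, q_gap: str, ref_pos: int, q_pos: int
                ) -> list[tuple[str, int, int, str]]:
    """Net indels from a both-sided gap via end-anchored global alignment.

    Returns (type, ref offset position, query offset position, sequence).
    """
    if not ref_gap and not q_gap:
        return []
    if not ref_gap:
        return [("INS", ref_pos, q_pos, q_gap)]
    if not q_gap:
        return [("DEL", ref_pos, q_pos, ref_gap)]
    if len(ref_gap) > MAX_GAP_ALIGN or len(q_gap) > MAX_GAP_ALIGN:
        return []
    aln = _ALIGNER.align(ref_gap, q_gap)[0]
    rsegs, qsegs = aln.aligned
    out: list[tuple[str, int, int, str]] = []
    r_cursor, q_cursor = 0, 0
    for (r0, r1), (q0, q1) in zip(rsegs, qsegs):
        if r0 > r_cursor:
            out.append(("DEL", ref_pos + r_cursor, q_pos + q_cursor,
                        ref_gap[r_cursor:r0]))
        if q0 > q_cursor:
            out.append(("INS", ref_pos + r0, q_pos + q_cursor,
                        q_gap[q_cursor:q0]))
        r_cursor, q_cursor = r1, q1
    if len(ref_gap) > r_cursor:
        out.append(("DEL", ref_pos + r_cursor, q_pos + q_cursor,
                    ref_gap[r_cursor:]))
    if len(q_gap) > q_cursor:
        out.append(("INS", ref_pos + len(ref_gap), q_pos + q_cursor,
                    q_gap[q_cursor:]))
    return out


def _overlaps(iv: tuple[int, int], regions: list[tuple[int, int]]) -> bool:
    return any(s < iv[1] and iv[0] < e for s, e in regions)


def call_indels(blocks: list[SyntenyBlock], ref: Genome, query: Genome,
                exclude_ref: dict[str, list[tuple[int, int]]] | None = None,
                exclude_query: dict[str, list[tuple[int, int]]] | None = None,
                classify_dup: bool = True) -> list[StructuralVariant]:
    """Call INS/DEL (and tandem DUP) from gaps along the block backbone.

    Gaps between consecutive anchors — within a block or between adjacent
    backbone blocks — yield an INS where only query sequence is unaligned,
    a DEL where only reference sequence is, and net indels from pairwise
    alignment where both are.  Breakpoints are left-aligned.  An insertion
    whose sequence tandem-duplicates the adjacent reference sequence is
    reclassified as DUP.  ``exclude_*`` regions (e.g. spans already
    explained by inversion or translocation calls) suppress gap calls.
    """
    exclude_ref = exclude_ref or {}
    exclude_query = exclude_query or {}
    out: list[StructuralVariant] = []
    bb = backbone_blocks(blocks)
    by_ref: dict[str, list[SyntenyBlock]] = {}
    for b in bb:
        by_ref.setdefault(b.ref_chrom, []).append(b)
    for rc, grp in by_ref.items():
        anchors: list[Anchor] = []
        for b in grp:
            anchors.extend(sorted(b.anchors, key=lambda a: a.ref_start))
        for prev, cur in zip(anchors, anchors[1:]):
            if cur.ref_start < prev.ref_start or cur.query_start < prev.query_start:
                raise ValueError(f"non-monotone anchors in backbone of {rc}")
            ref_gap = cur.ref_start - prev.ref_end
            q_gap = cur.query_start - prev.query_end
            trim = max(0, -ref_gap, -q_gap)
            r0, r1 = prev.ref_end, cur.ref_start + trim
            q0, q1 = prev.query_end, cur.query_start + trim
            if r1 - r0 <= 0 and q1 - q0 <= 0:
                continue
            if _overlaps((r0, r1), exclude_ref.get(rc, [])):
                continue
            if _overlaps((q0, q1), exclude_query.get(cur.query_chrom, [])):
                continue
            ref_seq = ref[rc].seq
            q_seq = query[cur.query_chrom].seq
            for kind, rpos, qpos, seq in _gap_indels(
                    ref_seq[r0:r1], q_seq[q0:q1], r0, q0):
                pos, seq = left_align(rpos, seq, ref_seq)
                svtype = kind
                if kind == "INS" and classify_dup:
                    L = len(seq)
                    if ref_seq[pos:pos + L] == seq or ref_seq[pos - L:pos] == seq:
                        svtype = "DUP"
                if kind == "DEL":
                    sv = StructuralVariant(
                        "DEL", rc, pos, pos + len(seq),
                        query_chrom=cur.query_chrom, query_start=qpos,
                        query_end=qpos, length=len(seq), sequence=seq,
                        source="chain-gap")
                else:
                    sv = StructuralVariant(
                        svtype, rc, pos, pos if svtype == "INS" else pos + len(seq),
                        query_chrom=cur.query_chrom, query_start=qpos,
                        query_end=qpos + len(seq), length=len(seq),
                        sequence=seq, source="chain-gap")
                out.append(sv)
    out.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    return out


# --------------------------------------------------------- INV / TRA calls


def classify_inversions(blocks: list[SyntenyBlock], max_gap: int = 500
                        ) -> list[StructuralVariant]:
    """Reverse-pattern blocks -> inversions.

    Minus-strand blocks are inversion evidence; runs of minus-strand blocks
    within ``max_gap`` of each other on both genomes merge into one call.
    """
    out: list[StructuralVariant] = []
    by_chrom: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in blocks:
        if b.strand == "-":
            by_chrom.setdefault((b.ref_chrom, b.query_chrom), []).append(b)
    for (rc, qc), grp in by_chrom.items():
        grp.sort(key=lambda b: b.ref_start)
        run: list[SyntenyBlock] = [grp[0]]
        runs: list[list[SyntenyBlock]] = [run]
        for b in grp[1:]:
            if b.ref_start - run[-1].ref_end <= max_gap:
                run.append(b)
            else:
                run = [b]
                runs.append(run)
        for run in runs:
            rs = min(b.ref_start for b in run)
            re = max(b.ref_end for b in run)
            qs = min(b.query_start for b in run)
            qe = max(b.query_end for b in run)
            out.append(StructuralVariant(
                "INV", rc, rs, re, query_chrom=qc, query_start=qs,
                query_end=qe, length=re - rs, source="reverse-pattern"))
    out.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    return out


def classify_translocations(blocks: list[SyntenyBlock]
                            ) -> list[StructuralVariant]:
    """Nonsequential blocks -> translocations.

    A block pairing with a non-dominant chromosome is an inter-chromosomal
    translocation.  Among dominant-partner blocks, those off the
    length-weighted LIS backbone of query order over reference order are
    intra-chromosomal translocations.  Rank-consistent minus-strand blocks
    are inversions, not translocations.
    """
    dom = _dominant_partner(blocks)
    out: list[StructuralVariant] = []
    by_ref: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_chrom, []).append(b)
    for rc, grp in by_ref.items():
        for b in grp:
            if b.query_chrom != dom.get(rc):
                out.append(StructuralVariant(
                    "TRA", rc, b.ref_start, b.ref_end,
                    query_chrom=b.query_chrom, query_start=b.query_start,
                    query_end=b.query_end, length=b.ref_end - b.ref_start,
                    inter_chromosomal=True, source="nonsequential"))
        same = sorted((b for b in grp if b.query_chrom == dom.get(rc)),
                      key=lambda b: b.ref_mid)
        keep = set(weighted_lis([b.query_mid for b in same],
                                [float(b.anchor_bp) for b in same]))
        for i, b in enumerate(same):
            if i not in keep:
                out.append(StructuralVariant(
                    "TRA", rc, b.ref_start, b.ref_end,
                    query_chrom=b.query_chrom, query_start=b.query_start,
                    query_end=b.query_end, length=b.ref_end - b.ref_start,
                    inter_chromosomal=False, source="nonsequential"))
    out.sort(key=lambda s: (s.ref_chrom, s.ref_start))
    return out


# ------------------------------------------- identical blocks, ordered genes


def identical_blocks(blocks: list[SyntenyBlock], ref: Genome, query: Genome,
                     min_len: int = 1000) -> list[SyntenyBlock]:
    """Gap-free, mismatch-free, order-consistent blocks of >= ``min_len``.

    Each anchor on the order-consistent backbone is a maximal exact match;
    anchors of sufficient length are verified byte-identical and returned
    as single-anchor blocks.
    """
    out: list[SyntenyBlock] = []
    for b in backbone_blocks(blocks):
        for a in b.anchors:
            if a.length < min_len:
                continue
            if ref[a.ref_chrom].seq[a.ref_start:a.ref_end] != \
                    query[a.query_chrom].seq[a.query_start:a.query_end]:
                continue
            out.append(SyntenyBlock(
                anchors=[a], ref_chrom=a.ref_chrom, ref_start=a.ref_start,
                ref_end=a.ref_end, query_chrom=a.query_chrom,
                query_start=a.query_start, query_end=a.query_end,
                strand="+", anchor_bp=a.length))
    out.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    for i, b in enumerate(out):
        b.rank_ref = b.rank_query = i
    return out


def ordered_genes(identical: list[SyntenyBlock], genes: list[GeneModel]
                  ) -> list[str]:
    """Genes whose full transcript span (UTRs included) lies inside one
    identical block."""
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in identical:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    out = []
    for g in genes:
        for b in by_chrom.get(g.chrom, []):
            if b.ref_start <= g.start and g.end <= b.ref_end:
                out.append(g.id)
                break
    return out


# --------------------------------------------------------------- pipeline


@dataclass
class ComparisonResult:
    blocks: list[SyntenyBlock]
    svs: list[StructuralVariant] = field(default_factory=list)
    identical: list[SyntenyBlock] = field(default_factory=list)
    ordered_gene_ids: list[str] = field(default_factory=list)

    def of_type(self, svtype: str) -> list[StructuralVariant]:
        return [s for s in self.svs if s.type == svtype]


def compare_genomes(ref: Genome, query: Genome,
                    genes: list[GeneModel] | None = None,
                    min_anchor: int = 20, max_gap: int = 500,
                    min_cluster: int = 1000,
                    min_identical: int = 1000) -> ComparisonResult:
    """Full anchor -> chain -> classify pipeline for one genome pair.

    Inversions and translocations are classified first; their spans then
    mask the gap-derived indel calls so one event is reported once.
    """
    anchors = find_anchors(ref, query, min_anchor)
    blocks = chain_anchors(anchors, max_gap=max_gap, min_cluster=min_cluster)
    invs = classify_inversions(blocks, max_gap=max_gap)
    tras = classify_translocations(blocks)
    exclude_ref: dict[str, list[tuple[int, int]]] = {}
    exclude_query: dict[str, list[tuple[int, int]]] = {}
    pad = max_gap
    for sv in invs + tras:
        exclude_ref.setdefault(sv.ref_chrom, []).append(
            (sv.ref_start - pad, sv.ref_end + pad))
        exclude_query.setdefault(sv.query_chrom, []).append(
            (sv.query_start - pad, sv.query_end + pad))
    indels = call_indels(blocks, ref, query, exclude_ref, exclude_query)
    ident = identical_blocks(blocks, ref, query, min_len=min_identical)
    gene_ids = ordered_genes(ident, genes) if genes else []
    return ComparisonResult(blocks=blocks, svs=indels + invs + tras,
                            identical=ident, ordered_gene_ids=gene_ids)
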