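"""Two-branch SV candidate validation from read-alignment evidence.

Candidates <= 50 bp (the *small* branch) are accepted when more than three
gapped aligned reads support them with consistent breakpoints and lengths.
Larger candidates (the *large* branch) are accepted when the ratio of
single-end-aligned (S) to properly-paired (P) reads around the breakpoint
differs significantly between the alignments to the two genomes (two-sided
Fisher's exact test, p < 0.05) AND the candidate is longer than three times
the standard deviation of the library insert size.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignments import AlignmentRecord
from .variants import StructuralVariant

SMALL_MAX = 50


@dataclass
class SupportSummary:
    sv_id: str
    branch: str                 # 'small' | 'large'
    verdict: str                # 'ACCEPT' | 'REJECT'
    gapped_support: int = 0
    s_ref: int = 0
    p_ref: int = 0
    s_query: int = 0
    p_query: int = 0
    fisher_p: float = 1.0
    length_over_3sd: bool = False


class RecordIndex:
    """Alignment records sorted per chromosome for region queries."""

    def __init__(self, records: list[AlignmentRecord]):
        self._by_chrom: dict[str, list[AlignmentRecord]] = {}
        for r in records:
            self._by_chrom.setdefault(r.chrom, []).append(r)
        self._starts: dict[str, list[int]] = {}
        self._max_span: dict[str, int] = {}
        for c, recs in self._by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            self._starts[c] = [r.pos for r in recs]
            self._max_span[c] = max(r.ref_end - r.pos for r in recs)

    def overlapping(self, chrom: str, start: int, end: int
                    ) -> list[AlignmentRecord]:
        recs = self._by_chrom.get(chrom, [])
        if not recs:
            return []
        starts = self._starts[chrom]
        lo = bisect.bisect_left(starts, start - self._max_span[chrom])
        hi = bisect.bisect_right(starts, end)
        return [r for r in recs[lo:hi] if r.ref_end > start and r.pos < end]


def count_gapped_support(sv: StructuralVariant, index: RecordIndex,
                         match_tol: int = 10) -> int:
    """Count gapped reads consistent with a small (<= 50 bp) indel.

    A read supports the SV when it carries a gap op of the matching kind
    (I for INS/DUP, D for DEL) whose implied reference breakpoint is within
    ``match_tol`` bp of the SV breakpoint and whose length differs by at
    most ``match_tol`` bp.
    """
    if sv.length > SMALL_MAX:
        raise ValueError("gapped support applies to the <= 50 bp branch only")
    want = "D" if sv.type == "DEL" else "I"
    n = 0
    for rec in index.overlapping(sv.ref_chrom, sv.ref_start - match_tol,
                                 sv.ref_start + sv.length + match_tol):
        for kind, length, offset in rec.gap_ops:
            if kind != want:
                continue
            if abs(length - sv.length) > match_tol:
                continue
            if abs((rec.pos + offset) - sv.ref_start) <= match_tol:
                n += 1
                break
    return n


def sp_counts(index: RecordIndex, chrom: str, start: int, end: int,
              chrom_length: int | None = None) -> tuple[int, int]:
    """(single-end, properly-paired) read counts over a region."""
    if end <= start:
        return 0, 0
    if chrom_length is not None and (start >= chrom_length or end <= 0):
        warnings.warn(f"region {chrom}:{start}-{end} beyond chromosome end")
        return 0, 0
    s = p = 0
    for rec in index.overlapping(chrom, start, end):
        if rec.properly_paired:
            p += 1
        else:
            s += 1
    return s, p


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities <= that of the observed table at
    fixed margins.  Any zero margin means no association is testable and
    returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 table margin; p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def estimate_insert_sd(records: list[AlignmentRecord]) -> float:
    """Insert-size s.d. over properly-paired records, trimmed at the
    1st/99th percentiles."""
    sizes = np.array([abs(r.insert_size) for r in records
                      if r.properly_paired and r.insert_size != 0], dtype=float)
    if sizes.size < 2:
        raise ValueError("not enough properly-paired records to estimate s.d.")
    lo, hi = np.percentile(sizes, [1, 99])
    kept = sizes[(sizes >= lo) & (sizes <= hi)]
    return float(kept.std(ddof=1))


def validate_sv(sv: StructuralVariant, index_ref: RecordIndex,
                index_query: RecordIndex | None = None, *,
                insert_sd: float, insert_mean: int = 350,
                match_tol: int = 10, alpha: float = 0.05,
                min_gapped: int = 3,
                sv_id: str | None = None) -> SupportSummary:
    """Validate one SV candidate through the branch its length selects.

    Small branch (length <= 50): ACCEPT iff gapped support strictly exceeds
    ``min_gapped``.  Large branch: ACCEPT iff the S/P contrast between the
    two genome alignments is significant (Fisher p < ``alpha``) and length
    > 3 x ``insert_sd``.  The S/P window is one ``insert_mean`` each side
    of each breakpoint.
    """
    sid = sv_id or f"{sv.type}:{sv.ref_chrom}:{sv.ref_start}"
    if sv.length <= SMALL_MAX:
        support = count_gapped_support(sv, index_ref, match_tol)
        verdict = "ACCEPT" if support > min_gapped else "REJECT"
        return SupportSummary(sid, "small", verdict, gapped_support=support)
    if index_query is None:
        raise ValueError("large-branch validation needs both record streams")
    w = insert_mean
    r0 = sv.ref_start - w
    r1 = (sv.ref_end if sv.ref_end > sv.ref_start else sv.ref_start) + w
    s_ref, p_ref = sp_counts(index_ref, sv.ref_chrom, r0, r1)
    if sv.query_chrom and sv.query_start >= 0:
        q0, q1 = sv.query_start - w, max(sv.query_end, sv.query_start) + w
        s_q, p_q = sp_counts(index_query, sv.query_chrom, q0, q1)
    else:  # fall back to the same coordinates on the query alignment
        s_q, p_q = sp_counts(index_query, sv.ref_chrom, r0, r1)
    p_val = fisher_exact(s_ref, p_ref, s_q, p_q)
    long_enough = sv.length > 3 * insert_sd
    verdict = "ACCEPT" if (p_val < alpha and long_enough) else "REJECT"
    return SupportSummary(sid, "large", verdict, s_ref=s_ref, p_ref=p_ref,
                          s_query=s_q, p_query=p_q, fisher_p=p_val,
                          length_over_3sd=long_enough)


def validate_all(svs: list[StructuralVariant], records_ref: list[AlignmentRecord],
                 records_query: list[AlignmentRecord] | None = None,
                 **kwargs) -> list[SupportSummary]:
    index_ref = RecordIndex(records_ref)
    index_query = RecordIndex(records_query) if records_query else None
    return [validate_sv(sv, index_ref, index_query, sv_id=f"sv{i}", **kwargs)
            for i, sv in enumerate(svs)]
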