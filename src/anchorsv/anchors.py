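"""Maximal unique match (MUM) anchors between two genomes.

An anchor is an exact match that is unique in both genomes and cannot be
extended on either side.  Anchors are found by seeding with k-mers that
occur exactly once in each genome (k = ``min_anchor_len``), merging seeds
that lie on the same alignment diagonal, and extending each merged run to
its maximal extent.  Any match containing a both-genomes-unique k-mer is
itself unique, so every reported anchor satisfies MUM semantics; matches
of length >= k none of whose k-mers are unique are not reported.  Both
query strands are searched.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import Genome, revcomp

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[b + 32] = i  # lower case


@dataclass(frozen=True)
class Anchor:
    """One maximal unique exact match.

    On strand '+', ref[ref_start:ref_end] == query[query_start:query_end];
    on strand '-', ref[ref_start:ref_end] == revcomp(query slice).
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit k-mer codes (k <= 31); positions with non-ACGT -> invalid
    sentinel (max uint64)."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = enc[i:i + n]
        codes = (codes << np.uint64(2)) | window.astype(np.uint64)
        bad |= window > 3
    codes[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return codes


class _GenomeIndex:
    """Concatenated k-mer codes over all chromosomes of one genome side."""

    def __init__(self, seqs: list[tuple[str, str]], k: int):
        self.k = k
        self.chrom_ids = [cid for cid, _ in seqs]
        self.enc = {cid: _encode(s) for cid, s in seqs}
        parts, owners, offsets = [], [], []
        for ci, (cid, s) in enumerate(seqs):
            c = _kmer_codes(self.enc[cid], k)
            parts.append(c)
            owners.append(np.full(c.size, ci, dtype=np.int32))
            offsets.append(np.arange(c.size, dtype=np.int64))
        self.codes = np.concatenate(parts) if parts else np.empty(0, np.uint64)
        self.owner = np.concatenate(owners) if owners else np.empty(0, np.int32)
        self.offset = np.concatenate(offsets) if offsets else np.empty(0, np.int64)

    def unique(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, flat positions) of k-mers occurring exactly once."""
        valid = self.codes != np.uint64(0xFFFFFFFFFFFFFFFF)
        codes = self.codes[valid]
        idx = np.flatnonzero(valid)
        if codes.size == 0:
            return codes, idx
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        is_first = np.empty(sorted_codes.size, dtype=bool)
        is_first[0] = True
        np.not_equal(sorted_codes[1:], sorted_codes[:-1], out=is_first[1:])
        is_last = np.empty_like(is_first)
        is_last[-1] = True
        np.not_equal(sorted_codes[1:], sorted_codes[:-1], out=is_last[:-1])
        singleton = is_first & is_last
        return sorted_codes[singleton], idx[order[singleton]]


def _extend(renc: np.ndarray, qenc: np.ndarray, rs: int, re: int, qs: int
            ) -> tuple[int, int, int]:
    """Maximally extend an exact match renc[rs:re] == qenc[qs:qs+(re-rs)]."""
    # left
    lim = min(rs, qs)
    if lim:
        eq = renc[rs - lim:rs][::-1] == qenc[qs - lim:qs][::-1]
        ext = int(np.argmin(eq)) if not eq.all() else lim
        rs -= ext
        qs -= ext
        re = re  # unchanged
    length = re - rs
    # right
    lim = min(renc.size - re, qenc.size - (qs + length))
    if lim:
        eq = renc[re:re + lim] == qenc[qs + length:qs + length + lim]
        ext = int(np.argmin(eq)) if not eq.all() else lim
        re += ext
    return rs, re, qs


def find_anchors(ref: Genome, query: Genome, min_anchor_len: int = 20
                 ) -> list[Anchor]:
    """Find MUM anchors between two genomes, both query strands.

    ``min_anchor_len`` (>= 15) is the seed k-mer size; every anchor is at
    least this long.  Uniqueness is enforced genome-wide per searched
    orientation.
    """
    if min_anchor_len < 15 or min_anchor_len > 31:
        raise ValueError("min_anchor_len must be in [15, 31]")
    k = min_anchor_len
    ref_seqs = [(c.id, c.seq) for c in ref]
    if not ref_seqs or all(len(s) == 0 for _, s in ref_seqs):
        warnings.warn("empty reference; no anchors")
        return []
    rindex = _GenomeIndex(ref_seqs, k)
    r_codes, r_pos = rindex.unique()

    anchors: list[Anchor] = []
    for strand in ("+", "-"):
        if strand == "+":
            q_seqs = [(c.id, c.seq) for c in query]
        else:
            q_seqs = [(c.id, revcomp(c.seq)) for c in query]
        if not q_seqs or all(len(s) == 0 for _, s in q_seqs):
            warnings.warn("empty query; no anchors")
            return []
        qindex = _GenomeIndex(q_seqs, k)
        q_codes, q_pos = qindex.unique()
        common, ri, qi = np.intersect1d(r_codes, q_codes,
                                        assume_unique=True,
                                        return_indices=True)
        if common.size == 0:
            continue
        rp, qp = r_pos[ri], q_pos[qi]
        r_owner, r_off = rindex.owner[rp], rindex.offset[rp]
        q_owner, q_off = qindex.owner[qp], qindex.offset[qp]
        # group seeds by (ref chrom, query chrom, diagonal) and merge runs
        diag = r_off - q_off
        order = np.lexsort((r_off, diag, q_owner, r_owner))
        r_owner, q_owner = r_owner[order], q_owner[order]
        r_off, q_off, diag = r_off[order], q_off[order], diag[order]
        new_run = np.ones(r_off.size, dtype=bool)
        if r_off.size > 1:
            same = ((r_owner[1:] == r_owner[:-1]) &
                    (q_owner[1:] == q_owner[:-1]) &
                    (diag[1:] == diag[:-1]) &
                    (r_off[1:] <= r_off[:-1] + k))
            new_run[1:] = ~same
        run_starts = np.flatnonzero(new_run)
        run_ends = np.append(run_starts[1:], r_off.size)
        seen: set[tuple] = set()
        for s, e in zip(run_starts, run_ends):
            rcid = rindex.chrom_ids[r_owner[s]]
            qcid = qindex.chrom_ids[q_owner[s]]
            rs, re = int(r_off[s]), int(r_off[e - 1]) + k
            qs = int(q_off[s])
            rs, re, qs = _extend(rindex.enc[rcid], qindex.enc[qcid], rs, re, qs)
            if re - rs < min_anchor_len:
                continue
            key = (rcid, qcid, rs, re, qs, strand)
            if key in seen:
                continue
            seen.add(key)
            qlen_chrom = len(query[qcid].seq)
            if strand == "+":
                q0, q1 = qs, qs + (re - rs)
            else:  # positions were on the reverse-complemented query
                q1 = qlen_chrom - qs
                q0 = q1 - (re - rs)
            anchors.append(Anchor(rcid, rs, re, qcid, q0, q1, strand))
    anchors.sort(key=lambda a: (a.ref_chrom, a.ref_start, a.query_chrom,
                                a.query_start, a.strand))
    return anchors
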