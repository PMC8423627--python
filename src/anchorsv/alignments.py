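"""Read-placement records and minimal SAM I/O.

An :class:`AlignmentRecord` is one read's placement on a genome: leftmost
position, gap operations relative to that position, whether the read is in
a properly-paired configuration, and the signed insert size (0 when the
mate is unplaced).  This is the evidence consumed by the SV validation
filters; base sequences and qualities are not carried.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    read_length: int
    gap_ops: list[tuple[str, int, int]] = field(default_factory=list)
    # each op: (kind 'I'|'D', length bp, reference offset bp from pos)
    properly_paired: bool = False
    insert_size: int = 0

    def __post_init__(self):
        for kind, length, offset in self.gap_ops:
            if kind not in ("I", "D"):
                raise ValueError(f"gap op kind {kind!r}")
            if offset < 0 or length < 1:
                raise ValueError("gap op offset/length out of range")

    @property
    def ref_end(self) -> int:
        """End of the reference span covered by this read."""
        consumed = self.read_length
        for kind, length, _ in self.gap_ops:
            consumed += length if kind == "D" else -length
        return self.pos + consumed

    def cigar(self) -> str:
        """CIGAR string; gap offsets are in reference coordinates."""
        if not self.gap_ops:
            return f"{self.read_length}M"
        parts = []
        ref_off = 0     # reference bases consumed so far
        read_off = 0    # read bases consumed so far
        for kind, length, offset in sorted(self.gap_ops, key=lambda o: o[2]):
            m = offset - ref_off
            if m > 0:
                parts.append(f"{m}M")
                read_off += m
                ref_off += m
            parts.append(f"{length}{kind}")
            if kind == "D":
                ref_off += length
            else:
                read_off += length
        tail = self.read_length - read_off
        if tail > 0:
            parts.append(f"{tail}M")
        return "".join(parts)


def write_sam(records: Iterable[AlignmentRecord], path: str | Path,
              contigs: Iterable[tuple[str, int]]) -> None:
    """Minimal SAM: @SQ header, placeholder sequence, flags encode pairing."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, length in contigs:
            fh.write(f"@SQ\tSN:{cid}\tLN:{length}\n")
        for rec in records:
            flag = 0x1  # paired library
            if rec.properly_paired:
                flag |= 0x2
            fh.write("\t".join([
                rec.read_id, str(flag), rec.chrom, str(rec.pos + 1), "60",
                rec.cigar(), "*", "0", str(rec.insert_size), "*", "*",
            ]) + "\n")


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse a SAM file back into alignment records (via pysam)."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            gap_ops: list[tuple[str, int, int]] = []
            ref_off = 0
            read_len = 0
            for op, length in aln.cigartuples:
                if op == 0:      # M
                    ref_off += length
                    read_len += length
                elif op == 1:    # I
                    gap_ops.append(("I", length, ref_off))
                    read_len += length
                elif op == 2:    # D
                    gap_ops.append(("D", length, ref_off))
                    ref_off += length
            out.append(AlignmentRecord(
                read_id=aln.query_name, chrom=aln.reference_name,
                pos=aln.reference_start, read_length=read_len,
                gap_ops=gap_ops, properly_paired=aln.is_proper_pair,
                insert_size=aln.template_length))
    return out
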