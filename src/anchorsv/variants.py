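"""Structural-variant records, breakpoint normalization and VCF/BED I/O.

SV semantics follow the query-versus-reference convention used throughout
the package: an insertion (INS) is sequence present in the query genome and
absent from the reference; a deletion (DEL) is the converse.  Inversions
(INV) span equal lengths on both genomes; translocations (TRA) carry a
source span on the reference and a destination point; duplications (DUP)
are tandem copies, represented with the inserted copy as their sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

SV_TYPES = ("INS", "DEL", "INV", "TRA", "DUP")


@dataclass
class StructuralVariant:
    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str = ""
    query_start: int = -1
    query_end: int = -1
    length: int = 0
    sequence: str = ""
    inter_chromosomal: bool = False
    source: str = ""
    validation: str = ""
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.length < 1:
            raise ValueError("SV length must be >= 1")

    @property
    def breakpoint(self) -> int:
        """Left breakpoint on the reference."""
        return self.ref_start


def left_align(pos: int, seq: str, ref_seq: str) -> tuple[int, str]:
    """Left-shift an indel through repetitive context (VCF convention).

    ``pos`` is the 0-based reference position where ``seq`` is inserted
    (INS) or where the deleted bases start (DEL); ``ref_seq`` is the
    chromosome sequence.  The indel may be shifted left one base at a time
    while the base preceding it equals the last base of the event sequence.
    """
    seq = list(seq)
    while pos > 0 and ref_seq[pos - 1] == seq[-1]:
        seq.insert(0, seq.pop())
        pos -= 1
    return pos, "".join(seq)


def apply_indels(ref_seq: str, svs: Iterable[StructuralVariant]) -> str:
    """Apply INS/DEL/DUP calls for one chromosome to its reference sequence.

    Returns the reconstructed query sequence.  Calls must not overlap.
    """
    ordered = sorted(svs, key=lambda s: (s.ref_start, 0 if s.type == "DEL" else 1))
    out: list[str] = []
    cursor = 0
    for sv in ordered:
        if sv.ref_start < cursor:
            raise ValueError(f"overlapping calls at {sv.ref_chrom}:{sv.ref_start}")
        out.append(ref_seq[cursor:sv.ref_start])
        if sv.type == "DEL":
            cursor = sv.ref_start + sv.length
        elif sv.type in ("INS", "DUP"):
            out.append(sv.sequence)
            cursor = sv.ref_start
        else:
            raise ValueError(f"apply_indels cannot apply {sv.type}")
    out.append(ref_seq[cursor:])
    return "".join(out)


# ----------------------------------------------------------------- VCF/BED

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position on reference">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Destination chromosome (TRA)">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=DUP,Description="Tandem duplication">
##ALT=<ID=TRA,Description="Translocation">
"""


def write_vcf(svs: Iterable[StructuralVariant], path: str | Path,
              contigs: Iterable[tuple[str, int]] = ()) -> None:
    """Write SVs as VCF 4.2 with symbolic ALTs (1-based POS)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for cid, length in contigs:
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, sv in enumerate(sorted(svs, key=lambda s: (s.ref_chrom, s.ref_start))):
            svlen = sv.length if sv.type in ("INS", "DUP") else (
                -sv.length if sv.type == "DEL" else sv.length)
            end = sv.ref_end if sv.ref_end > sv.ref_start else sv.ref_start
            info = f"SVTYPE={sv.type};SVLEN={svlen};END={end}"
            if sv.type == "TRA" and sv.query_chrom:
                info += f";CHR2={sv.query_chrom}"
            fh.write(f"{sv.ref_chrom}\t{sv.ref_start + 1}\tsv{i}\tN\t"
                     f"<{sv.type}>\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path) -> list[StructuralVariant]:
    """Read symbolic-ALT SV records back from a VCF written by this package
    (or any VCF carrying SVTYPE/SVLEN/END INFO keys), via pysam."""
    import pysam

    out: list[StructuralVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            alt = rec.alts[0] if rec.alts else ""
            svtype = info.get("SVTYPE", alt.strip("<>"))
            svlen = abs(int(info.get("SVLEN", 0)))
            end = int(info.get("END", rec.stop))
            out.append(StructuralVariant(
                type=svtype, ref_chrom=rec.chrom, ref_start=rec.pos - 1,
                ref_end=end, length=max(svlen, 1),
                query_chrom=info.get("CHR2", "")))
    return out


def write_bed(svs: Iterable[StructuralVariant], path: str | Path) -> None:
    """0-based half-open BED: chrom, start, end, type, length."""
    with open(path, "w") as fh:
        for sv in sorted(svs, key=lambda s: (s.ref_chrom, s.ref_start)):
            end = sv.ref_end if sv.ref_end > sv.ref_start else sv.ref_start + sv.length
            fh.write(f"{sv.ref_chrom}\t{sv.ref_start}\t{end}\t{sv.type}\t{sv.length}\n")
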