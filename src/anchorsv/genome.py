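"""Genome, chromosome and gene-model containers plus FASTA/GFF3 I/O.

All coordinates are 0-based half-open internally.  GFF3 is emitted and read
1-based inclusive per the format standard.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Chromosome:
    """One chromosome: identifier, sequence and subgenome label (A or D)."""

    id: str
    seq: str
    subgenome: str = "A"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A protein-coding gene model on the reference coordinate frame.

    ``exons``, ``cds``, ``utr5`` and ``utr3`` are lists of 0-based half-open
    intervals in genome order (ascending start), regardless of strand.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    def cds_sequence(self, genome: "Genome") -> str:
        """Spliced CDS in translation order (reverse-complemented on minus)."""
        chrom = genome[self.chrom]
        parts = [chrom.seq[s:e] for s, e in self.cds]
        spliced = "".join(parts)
        return revcomp(spliced) if self.strand == "-" else spliced


class Genome:
    """An ordered collection of chromosomes, indexable by id."""

    def __init__(self, chromosomes: Iterable[Chromosome] = ()):
        self._chroms: dict[str, Chromosome] = {}
        for c in chromosomes:
            self.add(c)

    def add(self, chrom: Chromosome) -> None:
        if chrom.id in self._chroms:
            raise ValueError(f"duplicate chromosome id {chrom.id!r}")
        self._chroms[chrom.id] = chrom

    def __getitem__(self, cid: str) -> Chromosome:
        return self._chroms[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._chroms

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def ids(self) -> list[str]:
        return list(self._chroms)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def chrom_table(self) -> list[tuple[str, int, str]]:
        """(id, length, subgenome) rows, the frame for window statistics."""
        return [(c.id, len(c), c.subgenome) for c in self]

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        records = [
            SeqRecord(Seq(c.seq), id=c.id, description=f"subgenome={c.subgenome}")
            for c in self
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        genome = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            sub = "A"
            for tok in rec.description.split():
                if tok.startswith("subgenome="):
                    sub = tok.split("=", 1)[1]
            genome.add(Chromosome(rec.id, str(rec.seq).upper(), sub))
        return genome


# ---------------------------------------------------------------- GFF3 I/O


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            cols = [g.chrom, "anchorsv", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.id}"]
            fh.write("\t".join(cols) + "\n")
            mrna = f"{g.id}.t1"
            fh.write("\t".join([g.chrom, "anchorsv", "mRNA", str(g.start + 1),
                                str(g.end), ".", g.strand, ".",
                                f"ID={mrna};Parent={g.id}"]) + "\n")
            for kind, ivs in (("exon", g.exons), ("five_prime_UTR", g.utr5),
                              ("CDS", g.cds), ("three_prime_UTR", g.utr3)):
                for s, e in ivs:
                    fh.write("\t".join([g.chrom, "anchorsv", kind, str(s + 1),
                                        str(e), ".", g.strand,
                                        "0" if kind == "CDS" else ".",
                                        f"Parent={mrna}"]) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 via gffutils (any GFF3 with
    gene/mRNA/exon/CDS/UTR rows and ID/Parent links)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                            keep_order=True)
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    for feat in db.all_features(featuretype="gene"):
        gid = feat.id
        genes[gid] = GeneModel(gid, feat.seqid, feat.strand,
                               feat.start - 1, feat.end)
    for feat in db.all_features(featuretype="mRNA"):
        mrna_to_gene[feat.id] = feat.attributes["Parent"][0]
    for kind, attr in (("exon", "exons"), ("CDS", "cds"),
                       ("five_prime_UTR", "utr5"),
                       ("three_prime_UTR", "utr3")):
        for feat in db.all_features(featuretype=kind):
            parent = feat.attributes["Parent"][0]
            gid = mrna_to_gene.get(parent, parent)
            g = genes.get(gid)
            if g is not None:
                getattr(g, attr).append((feat.start - 1, feat.end))
    for g in genes.values():
        for ivs in (g.exons, g.cds, g.utr5, g.utr3):
            ivs.sort()
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start))
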