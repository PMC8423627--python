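"""Functional placement of SVs against gene models and coding-consequence
calls.

Regions follow the precedence exonic-CDS > 5'UTR > 3'UTR > intronic >
upstream1kb > downstream1kb > intergenic, with the up/downstream flanks
(default +-1 kb) measured strand-aware from the transcript ends.  Coding
indels are classified frameshift / inframe / stop_gain / stop_loss by
splicing the variant into the CDS and translating both versions.
Variant-gene pairs may additionally be flagged with expression change
(|log2 fold-change| >= 1 and p <= 0.05, both boundaries inclusive).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import GeneModel, Genome, revcomp
from .variants import StructuralVariant

REGION_ORDER = ("exonic-CDS", "5'UTR", "3'UTR", "intronic",
                "upstream1kb", "downstream1kb", "intergenic")
SPLICE_PAD = 2  # bp around intron boundaries tagged splice_region


@dataclass
class SVAnnotation:
    sv_id: str
    gene_id: str | None
    region: str
    coding_effect: str = "none"      # frameshift/inframe/stop_gain/stop_loss/none
    expression_flag: str = "NA"      # up/down/unchanged/NA
    tags: list[str] = field(default_factory=list)


class GeneIndex:
    """Interval lookup of gene models including their flanks."""

    def __init__(self, genes: list[GeneModel], flank: int = 1000):
        self.flank = flank
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self.trees.setdefault(g.chrom, IntervalTree())
            tree[max(0, g.start - flank):g.end + flank] = g

    def near(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[start:end]),
                      key=lambda g: g.start)


def _sv_interval(sv: StructuralVariant) -> tuple[int, int]:
    """Reference footprint; an insertion is a point between two bases."""
    end = sv.ref_end if sv.ref_end > sv.ref_start else sv.ref_start + 1
    return sv.ref_start, end


def _hits(iv: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    return any(s < iv[1] and iv[0] < e for s, e in intervals)


def region_for_gene(sv: StructuralVariant, gene: GeneModel,
                    flank: int = 1000) -> str:
    """Region of one SV relative to one gene, by precedence."""
    iv = _sv_interval(sv)
    if _hits(iv, gene.cds):
        return "exonic-CDS"
    if _hits(iv, gene.utr5):
        return "5'UTR"
    if _hits(iv, gene.utr3):
        return "3'UTR"
    if iv[0] < gene.end and gene.start < iv[1]:
        return "intronic"
    upstream = (gene.start - flank, gene.start) if gene.strand == "+" \
        else (gene.end, gene.end + flank)
    downstream = (gene.end, gene.end + flank) if gene.strand == "+" \
        else (gene.start - flank, gene.start)
    if _hits(iv, [upstream]):
        return "upstream1kb"
    if _hits(iv, [downstream]):
        return "downstream1kb"
    return "intergenic"


def classify_location(sv: StructuralVariant, index: GeneIndex,
                      genome: Genome | None = None,
                      sv_id: str = "") -> list[SVAnnotation]:
    """One annotation per overlapping gene; a single intergenic record when
    no gene is within reach."""
    if genome is not None:
        if sv.ref_chrom not in genome:
            raise ValueError(f"SV on unknown chromosome {sv.ref_chrom}")
        if sv.ref_start < 0 or _sv_interval(sv)[1] > len(genome[sv.ref_chrom]):
            raise ValueError(f"SV beyond bounds of {sv.ref_chrom}")
    iv = _sv_interval(sv)
    out: list[SVAnnotation] = []
    for gene in index.near(sv.ref_chrom, *iv):
        region = region_for_gene(sv, gene, index.flank)
        if region == "intergenic":
            continue
        ann = SVAnnotation(sv_id, gene.id, region)
        if iv[0] <= gene.start and iv[1] >= gene.end:
            ann.tags.append("gene_loss")
        for a, b in zip(sorted(gene.exons), sorted(gene.exons)[1:]):
            for edge in (a[1], b[0]):  # intron boundaries
                if iv[0] < edge + SPLICE_PAD and edge - SPLICE_PAD < iv[1]:
                    if "splice_region" not in ann.tags:
                        ann.tags.append("splice_region")
        out.append(ann)
    if not out:
        out.append(SVAnnotation(sv_id, None, "intergenic"))
    return out


def coding_effect(sv: StructuralVariant, gene: GeneModel,
                  genome: Genome) -> str:
    """Coding consequence of an INS/DEL/DUP overlapping the CDS.

    A net CDS length change not divisible by 3 is a frameshift.  Otherwise
    the variant is spliced into the CDS and both versions are translated:
    a premature stop is stop_gain, a lost terminal stop with readthrough is
    stop_loss, anything else is inframe.
    """
    if sv.type not in ("INS", "DEL", "DUP"):
        raise ValueError("coding effects are defined for INS/DEL/DUP")
    cds_ivs = sorted(gene.cds)
    chrom_seq = genome[gene.chrom].seq
    pieces: list[str] = []
    net = 0
    if sv.type == "DEL":
        for s, e in cds_ivs:
            ov0, ov1 = max(s, sv.ref_start), min(e, sv.ref_end)
            if ov1 > ov0:
                pieces.append(chrom_seq[s:ov0] + chrom_seq[ov1:e])
                net -= ov1 - ov0
            else:
                pieces.append(chrom_seq[s:e])
    else:  # INS / DUP insert at a point
        at = sv.ref_start
        for s, e in cds_ivs:
            if s < at < e:
                pieces.append(chrom_seq[s:at] + sv.sequence + chrom_seq[at:e])
                net += len(sv.sequence)
            else:
                pieces.append(chrom_seq[s:e])
        if net == 0:
            return "none"  # insertion point outside the CDS
    if net == 0 and sv.type == "DEL":
        return "none"
    if net % 3 != 0:
        return "frameshift"
    mutated = "".join(pieces)
    if gene.strand == "-":
        mutated = revcomp(mutated)
    original = gene.cds_sequence(genome)
    prot_orig = str(Seq(original).translate())
    prot_mut = str(Seq(mutated).translate())
    interior_orig = prot_orig.rstrip("*")
    interior_mut = prot_mut.rstrip("*") if prot_mut.endswith("*") else prot_mut
    if "*" in interior_mut and "*" not in interior_orig:
        return "stop_gain"
    if prot_orig.endswith("*") and not prot_mut.endswith("*"):
        return "stop_loss"
    return "inframe"


def variant_gene_pairs(svs: list[StructuralVariant], genes: list[GeneModel],
                       flank: int = 1000,
                       genome: Genome | None = None
                       ) -> list[SVAnnotation]:
    """All deduplicated (SV, gene) pairs with region != intergenic."""
    index = GeneIndex(genes, flank)
    pairs: dict[tuple[str, str], SVAnnotation] = {}
    for i, sv in enumerate(svs):
        for ann in classify_location(sv, index, genome, sv_id=f"sv{i}"):
            if ann.gene_id is None:
                continue
            pairs.setdefault((ann.sv_id, ann.gene_id), ann)
    return list(pairs.values())


def expression_change(pairs: list[SVAnnotation], expr_table: pd.DataFrame
                      ) -> tuple[list[SVAnnotation], int]:
    """Flag pairs whose gene changed expression (|log2FC| >= 1, p <= 0.05).

    ``expr_table`` columns: gene_id, log2fc, pvalue.  Returns the flagged
    pairs and the number of malformed rows skipped.
    """
    skipped = 0
    table: dict[str, tuple[float, float]] = {}
    for _, row in expr_table.iterrows():
        try:
            table[str(row["gene_id"])] = (float(row["log2fc"]),
                                          float(row["pvalue"]))
        except (KeyError, TypeError, ValueError):
            skipped += 1
    for ann in pairs:
        entry = table.get(ann.gene_id)
        if entry is None:
            ann.expression_flag = "NA"
            continue
        lfc, p = entry
        if abs(lfc) >= 1.0 and p <= 0.05:
            ann.expression_flag = "up" if lfc > 0 else "down"
        else:
            ann.expression_flag = "unchanged"
    return pairs, skipped
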