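"""Gene-relative SV placement, coding consequences (with an independent
apply-and-translate oracle), variant-gene pairing and expression flags."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import anchorsv as asv
from anchorsv.annotate import (GeneIndex, classify_location, coding_effect,
                               expression_change, region_for_gene,
                               variant_gene_pairs)
from anchorsv.genome import Chromosome, Genome, revcomp
from anchorsv.simulate import _make_gene, _random_sequence


@pytest.fixture(scope="module")
def toy():
    """One isolated plus-strand and one minus-strand gene on a 60-kb
    chromosome."""
    rng = np.random.default_rng(3)
    seq = list(_random_sequence(rng, 60_000, 0.4))
    gplus, s1 = _make_gene(rng, "gp", "c", 10_000, "+")
    gminus, s2 = _make_gene(rng, "gm", "c", 40_000, "-")
    seq[gplus.start:gplus.end] = s1
    seq[gminus.start:gminus.end] = s2
    genome = Genome([Chromosome("c", "".join(seq), "A")])
    return genome, [gplus, gminus]


def _ins(pos, seq="T"):
    return asv.StructuralVariant("INS", "c", pos, pos, length=len(seq),
                                 sequence=seq)


def _del(pos, length):
    return asv.StructuralVariant("DEL", "c", pos, pos + length,
                                 length=length)


class TestRegions:
    def test_intron_insertion(self, toy):
        _, genes = toy
        g = genes[0]
        exons = sorted(g.exons)
        intron_mid = (exons[0][1] + exons[1][0]) // 2
        assert region_for_gene(_ins(intron_mid), g) == "intronic"

    def test_utrs(self, toy):
        _, genes = toy
        g = genes[0]  # plus strand: utr5 at the left end
        assert region_for_gene(_ins(g.utr5[0][0] + 5), g) == "5'UTR"
        assert region_for_gene(_ins(g.utr3[0][0] + 5), g) == "3'UTR"

    def test_cds_takes_precedence(self, toy):
        _, genes = toy
        g = genes[0]
        cds0 = sorted(g.cds)[0]
        assert region_for_gene(_ins(cds0[0] + 3), g) == "exonic-CDS"

    def test_strand_aware_flanks(self, toy):
        _, genes = toy
        gm = genes[1]  # minus strand: downstream is left of gene start
        assert region_for_gene(_ins(gm.start - 500), gm) == "downstream1kb"
        assert region_for_gene(_ins(gm.end + 500), gm) == "upstream1kb"
        gp = genes[0]
        assert region_for_gene(_ins(gp.start - 500), gp) == "upstream1kb"
        assert region_for_gene(_ins(gp.end + 500), gp) == "downstream1kb"

    def test_flank_boundary_exclusive_beyond_1kb(self, toy):
        _, genes = toy
        g = genes[0]
        assert region_for_gene(_ins(g.end + 999), g) == "downstream1kb"
        assert region_for_gene(_ins(g.end + 1001), g) == "intergenic"

    def test_classify_location_bounds_check(self, toy):
        genome, genes = toy
        index = GeneIndex(genes)
        with pytest.raises(ValueError):
            classify_location(_ins(70_000), index, genome)

    def test_splice_region_tagged(self, toy):
        genome, genes = toy
        g = genes[0]
        edge = sorted(g.exons)[0][1]  # first intron start
        index = GeneIndex(genes)
        anns = classify_location(_ins(edge + 1), index, genome)
        assert any("splice_region" in a.tags for a in anns)


def _cds_offset_to_genomic(gene, offset):
    """Genomic coordinate of a plus-strand CDS offset."""
    for s, e in sorted(gene.cds):
        if offset < e - s:
            return s + offset
        offset -= e - s
    raise AssertionError("offset beyond CDS")


class TestCodingEffect:
    def test_two_bp_deletion_frameshifts(self, toy):
        genome, genes = toy
        g = genes[0]
        pos = _cds_offset_to_genomic(g, 30)
        assert coding_effect(_del(pos, 2), g, genome) == "frameshift"

    def test_full_codon_deletion_inframe(self, toy):
        genome, genes = toy
        g = genes[0]
        pos = _cds_offset_to_genomic(g, 15)  # codon 6 boundary
        assert coding_effect(_del(pos, 3), g, genome) == "inframe"

    def test_taa_insertion_stop_gain(self, toy):
        """In-frame TAA inserted at codon 11: translation oracle confirms a
        premature stop."""
        genome, genes = toy
        g = genes[0]
        pos = _cds_offset_to_genomic(g, 30)
        sv = _ins(pos, "TAA")
        assert coding_effect(sv, g, genome) == "stop_gain"
        # oracle: mutate CDS directly and translate
        cds = g.cds_sequence(genome)
        mutated = cds[:30] + "TAA" + cds[30:]
        assert "*" in str(Seq(mutated).translate())[:-1]

    def test_stop_loss_on_terminal_stop_deletion(self, toy):
        genome, genes = toy
        g = genes[0]
        cds_len = sum(e - s for s, e in g.cds)
        pos = _cds_offset_to_genomic(g, cds_len - 3)
        assert coding_effect(_del(pos, 3), g, genome) == "stop_loss"

    def test_minus_strand_frameshift(self, toy):
        genome, genes = toy
        gm = genes[1]
        cds0 = sorted(gm.cds)[0]
        pos = cds0[0] + 4
        assert coding_effect(_del(pos, 1), gm, genome) == "frameshift"

    def test_oracle_agreement_on_random_indels(self, toy):
        """Apply-and-translate oracle: mutate the chromosome, re-extract
        the CDS with shifted coordinates, translate, and derive the label
        independently (200 random cases; the full 1,000-case sweep runs in
        the acceptance suite)."""
        genome, genes = toy
        rng = np.random.default_rng(5)
        agree = 0
        for _ in range(200):
            g = genes[int(rng.integers(2))]
            got, want = _random_indel_effect_pair(rng, g, genome)
            assert got == want
            agree += 1
        assert agree == 200


def _random_indel_effect_pair(rng, gene, genome):
    """(implementation label, oracle label) for one random coding indel
    placed strictly inside one CDS interval."""
    ivs = sorted(gene.cds)
    s, e = ivs[int(rng.integers(len(ivs)))]
    if rng.random() < 0.5 and e - s > 8:
        length = int(rng.integers(1, 7))
        pos = int(rng.integers(s + 1, e - length))
        sv = asv.StructuralVariant("DEL", gene.chrom, pos, pos + length,
                                   length=length)
        mutated_chrom = genome[gene.chrom].seq[:pos] + \
            genome[gene.chrom].seq[pos + length:]
        shift_at, net = pos, -length
    else:
        length = int(rng.integers(1, 7))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        pos = int(rng.integers(s + 1, e))
        sv = asv.StructuralVariant("INS", gene.chrom, pos, pos,
                                   length=length, sequence=seq)
        mutated_chrom = genome[gene.chrom].seq[:pos] + seq + \
            genome[gene.chrom].seq[pos:]
        shift_at, net = pos, length
    got = coding_effect(sv, gene, genome)
    # oracle: shift downstream CDS coordinates and re-extract
    new_ivs = []
    for a, b in ivs:
        a2 = a + net if a >= shift_at else a
        b2 = b + net if b > shift_at else b
        new_ivs.append((a2, b2))
    spliced = "".join(mutated_chrom[a:b] for a, b in new_ivs)
    if gene.strand == "-":
        spliced = revcomp(spliced)
    if net % 3 != 0:
        want = "frameshift"
    else:
        orig = str(Seq(gene.cds_sequence(genome)).translate())
        mut = str(Seq(spliced).translate())
        if "*" in (mut[:-1] if mut.endswith("*") else mut):
            want = "stop_gain"
        elif orig.endswith("*") and not mut.endswith("*"):
            want = "stop_loss"
        else:
            want = "inframe"
    return got, want


class TestPairsAndExpression:
    def test_pair_counting(self, toy):
        genome, genes = toy
        gp, gm = genes
        svs = [_ins(gp.start + 10),                  # in gene body -> 1 pair
               _ins(gp.end + 2_000)]                 # 2 kb away -> 0 pairs
        pairs = variant_gene_pairs(svs, genes, genome=genome)
        assert {(p.sv_id, p.gene_id) for p in pairs} == {("sv0", "gp")}

    def test_sv_between_two_genes_pairs_with_both(self):
        rng = np.random.default_rng(9)
        seq = list(_random_sequence(rng, 30_000, 0.4))
        g1, s1 = _make_gene(rng, "g1", "c", 5_000, "+")
        # place the second gene so that a midpoint SV is within 1 kb of both
        start2 = g1.end + 1_600
        g2, s2 = _make_gene(rng, "g2", "c", start2, "+")
        seq[g1.start:g1.end] = s1
        seq[g2.start:g2.end] = s2
        genome = Genome([Chromosome("c", "".join(seq), "A")])
        mid = g1.end + 800
        pairs = variant_gene_pairs([_ins(mid)], [g1, g2], genome=genome)
        assert {(p.sv_id, p.gene_id) for p in pairs} == {("sv0", "g1"),
                                                         ("sv0", "g2")}

    def test_expression_boundaries_inclusive(self, toy):
        genome, genes = toy
        gp = genes[0]
        pairs = variant_gene_pairs([_ins(gp.start + 10)], genes,
                                   genome=genome)
        table = pd.DataFrame([{"gene_id": "gp", "log2fc": 1.0,
                               "pvalue": 0.05}])
        flagged, skipped = expression_change(pairs, table)
        assert flagged[0].expression_flag == "up" and skipped == 0
        table = pd.DataFrame([{"gene_id": "gp", "log2fc": -0.9,
                               "pvalue": 0.01}])
        flagged, _ = expression_change(pairs, table)
        assert flagged[0].expression_flag == "unchanged"
        table = pd.DataFrame([{"gene_id": "other", "log2fc": 2.0,
                               "pvalue": 0.001}])
        flagged, _ = expression_change(pairs, table)
        assert flagged[0].expression_flag == "NA"

    def test_malformed_rows_skipped_and_counted(self, toy):
        genome, genes = toy
        pairs = variant_gene_pairs([_ins(genes[0].start + 10)], genes,
                                   genome=genome)
        table = pd.DataFrame([{"gene_id": "gp", "log2fc": "bad",
                               "pvalue": 0.01},
                              {"gene_id": "gp", "log2fc": -2.0,
                               "pvalue": 0.01}])
        flagged, skipped = expression_change(pairs, table)
        assert skipped == 1
        assert flagged[0].expression_flag == "down"
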