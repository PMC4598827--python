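"""Repeat/genic classification and coding consequences vs exhaustive
oracles."""

import itertools

import numpy as np
import pytest

from helpers import STANDARD_CODE, random_genome
from inosinome.annotation import (
    CDS,
    INTERGENIC,
    INTRON,
    NCRNA_EXON,
    NONSYN,
    SYN,
    UTR3,
    UTR5,
    classify_genic,
    classify_repeat,
    codon_effect,
    flag_retrogene,
    is_known_variant,
)
from inosinome.calling import ALU, NONREP, REP_NON_ALU
from inosinome.io_formats import (
    Genome,
    IntervalIndex,
    KnownVariantIndex,
    SiteRecord,
    TranscriptModel,
    reverse_complement,
)


def _index(rows):
    index = IntervalIndex()
    for row in rows:
        index.add(*row)
    return index


class TestRepeatClass:
    def test_alu_label(self):
        index = _index([("c", 10, 40, "AluSx", "+")])
        assert classify_repeat("c", 20, index) == ALU

    def test_rep_non_alu(self):
        index = _index([("c", 10, 40, "L1PA3", "+")])
        assert classify_repeat("c", 20, index) == REP_NON_ALU

    def test_nonrep_and_alu_precedence_when_nested(self):
        index = _index([("c", 10, 40, "L1PA3", "+"),
                        ("c", 15, 35, "AluY", "+")])
        assert classify_repeat("c", 20, index) == ALU
        assert classify_repeat("c", 50, index) == NONREP


def _mrna(strand="+"):
    # exons [10,40) [60,100); CDS [20,40)+[60,80); UTRs on both sides
    return TranscriptModel("t1", "g1", "c", strand,
                           exons=[(10, 40), (60, 100)],
                           cds=[(20, 40), (60, 80)])


class TestGenicContext:
    def test_utr5_plus_strand(self):
        assert classify_genic("c", 15, [_mrna()]).context == UTR5

    def test_utr5_minus_strand_is_right_of_cds(self):
        assert classify_genic("c", 90, [_mrna("-")]).context == UTR5
        assert classify_genic("c", 15, [_mrna("-")]).context == UTR3

    def test_cds_intron_utr3_intergenic(self):
        model = _mrna()
        assert classify_genic("c", 25, [model]).context == CDS
        assert classify_genic("c", 50, [model]).context == INTRON
        assert classify_genic("c", 90, [model]).context == UTR3
        assert classify_genic("c", 500, [model]).context == INTERGENIC

    def test_ncrna_exon_beats_intron(self):
        nc = TranscriptModel("nc", "gn", "c", "+", exons=[(45, 55)],
                             biotype="lincRNA")
        ctx = classify_genic("c", 50, [_mrna(), nc])
        assert ctx.context == NCRNA_EXON
        assert ctx.gene_id == "gn"

    def test_random_sites_match_bruteforce(self, small_dataset, rng):
        """Independent per-transcript scan over 2,000 random positions."""
        models = small_dataset.sim_genome.models
        rank = {CDS: 0, UTR5: 1, UTR3: 1, NCRNA_EXON: 2, INTRON: 3,
                INTERGENIC: 4}

        def oracle(chrom, pos):
            best = INTERGENIC
            for t in models:
                if t.chrom != chrom or not t.start <= pos < t.end:
                    continue
                exonic = any(s <= pos < e for s, e in t.exons)
                if not exonic:
                    ctx = INTRON
                elif t.cds and any(s <= pos < e for s, e in t.cds):
                    ctx = CDS
                elif t.cds:
                    left_of_cds = pos < t.cds[0][0]
                    if t.strand == "+":
                        ctx = UTR5 if left_of_cds else UTR3
                    else:
                        ctx = UTR3 if left_of_cds else UTR5
                else:
                    ctx = NCRNA_EXON
                if rank[ctx] < rank[best]:
                    best = ctx
            return best

        chroms = sorted(small_dataset.genome.sequences)
        for _ in range(2000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, small_dataset.genome.lengths[chrom]))
            assert classify_genic(chrom, pos, models).context == \
                oracle(chrom, pos)


class TestCodonEffect:
    def _model_for(self, codon):
        genome = Genome({"c": "TT" + "ATG" + codon + "TAA" + "TT"})
        model = TranscriptModel("t", "g", "c", "+", exons=[(0, 13)],
                                cds=[(2, 11)])
        return genome, model

    def test_k_to_r(self):
        genome, model = self._model_for("AAA")
        eff = codon_effect("c", 6, model, genome)  # middle codon, offset 1
        assert (eff.ref_codon, eff.alt_codon) == ("AAA", "AGA")
        assert (eff.ref_aa, eff.alt_aa, eff.consequence) == \
            ("K", "R", NONSYN)

    def test_t_to_a(self):
        genome, model = self._model_for("ACA")
        eff = codon_effect("c", 5, model, genome)
        assert (eff.ref_codon, eff.alt_codon) == ("ACA", "GCA")
        assert (eff.ref_aa, eff.alt_aa, eff.consequence) == \
            ("T", "A", NONSYN)

    def test_wobble_synonymous(self):
        genome, model = self._model_for("GCA")
        eff = codon_effect("c", 7, model, genome)
        assert eff.alt_codon == "GCG"
        assert eff.consequence == SYN

    def test_outside_cds_is_contract_violation(self):
        genome, model = self._model_for("AAA")
        with pytest.raises(ValueError):
            codon_effect("c", 0, model, genome)

    def test_incomplete_cds_skipped(self):
        genome = Genome({"c": "TTATGAAAT"})
        model = TranscriptModel("t", "g", "c", "+", exons=[(0, 9)],
                                cds=[(2, 9)])  # length 7, not codon-aligned
        assert not model.cds_complete
        assert codon_effect("c", 5, model, genome) is None

    def test_all_codons_and_positions_vs_translation_table(self):
        """Exhaustive 64 x 3 enumeration against a literal codon table."""
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            genome, model = self._model_for(codon)
            for offset in range(3):
                eff = codon_effect("c", 5 + offset, model, genome)
                alt = codon[:offset] + "G" + codon[offset + 1:]
                ref_aa = STANDARD_CODE[codon.replace("U", "T")]
                alt_aa = STANDARD_CODE[alt]
                assert eff.ref_aa == ref_aa
                assert eff.alt_aa == alt_aa
                assert eff.consequence == (SYN if ref_aa == alt_aa
                                           else NONSYN)

    def test_minus_strand_consistent_with_mirrored_fixture(self, rng):
        """A CDS site on a minus-strand model gives the same consequence
        as the mirrored plus-strand construction."""
        seq = "".join(rng.choice(list("ACGT"), 60))
        genome_fwd = Genome({"c": seq})
        # minus-strand model: CDS read right-to-left on the complement
        minus = TranscriptModel("t", "g", "c", "-", exons=[(5, 53)],
                                cds=[(10, 46)])
        genome_mirror = Genome({"c": reverse_complement(seq)})
        n = len(seq)
        plus = TranscriptModel("t", "g", "c", "+",
                               exons=[(n - 53, n - 5)],
                               cds=[(n - 46, n - 10)])
        for pos in range(10, 46):
            eff_minus = codon_effect("c", pos, minus, genome_fwd)
            eff_plus = codon_effect("c", n - 1 - pos, plus, genome_mirror)
            assert (eff_minus.ref_aa, eff_minus.alt_aa) == \
                (eff_plus.ref_aa, eff_plus.alt_aa)
            assert eff_minus.codon_index == eff_plus.codon_index


def _site(chrom="c", pos0=50, strand="+", substitution="AG"):
    ref = substitution[0]
    return SiteRecord(chrom=chrom, pos0=pos0, strand=strand, ref_base=ref,
                      dna_depth=20, dna_genotype=ref, rna_depth=10,
                      base_counts={"A": 7, "C": 0, "G": 3, "T": 0},
                      editing_level=0.3, substitution=substitution)


class TestKnownVariants:
    def test_allele_aware_match(self):
        index = KnownVariantIndex()
        index.add("c", 50, "A", "G")
        assert is_known_variant(_site(), index)
        other = KnownVariantIndex()
        other.add("c", 50, "A", "C")
        assert not is_known_variant(_site(), other)

    def test_minus_strand_site_matches_genomic_alleles(self):
        # transcript-space A>G on minus strand is genomic T>C
        index = KnownVariantIndex()
        index.add("c", 50, "T", "C")
        assert is_known_variant(_site(strand="-"), index)

    def test_random_sites_vs_linear_scan(self, rng):
        entries = [(f"c{rng.integers(1, 3)}", int(rng.integers(0, 500)),
                    rng.choice(list("ACGT")), rng.choice(list("ACGT")))
                   for _ in range(200)]
        index = KnownVariantIndex()
        for chrom, pos, ref, alt in entries:
            if ref != alt:
                index.add(chrom, pos, ref, alt)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(500):
            chrom = f"c{rng.integers(1, 3)}"
            pos = int(rng.integers(0, 500))
            strand = rng.choice(["+", "-"])
            site = _site(chrom=chrom, pos0=pos, strand=strand)
            ref_g, alt_g = ("A", "G") if strand == "+" else ("T", "C")
            expected = any(c == chrom and p == pos and r == ref_g
                           and a == alt_g
                           for c, p, r, a in entries if r != a)
            assert is_known_variant(site, index) == expected


def test_flag_retrogene_membership():
    index = _index([("c", 10, 60, "retro1", "+")])
    assert flag_retrogene("c", 30, index)
    assert not flag_retrogene("c", 60, index)
    assert not flag_retrogene("c", 30, IntervalIndex())
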