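"""Pileup construction, genotyping, candidate detection and cascade
invariants, checked against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from helpers import (
    make_column,
    make_obs,
    make_record,
    maximal_run_lengths,
    random_genome,
    recount_sam_text,
)
from inosinome.calling import (
    FilterConfig,
    GenotypeCall,
    HET,
    HOM,
    LOW_COV,
    assign_transcript_strand,
    build_pileup,
    call_dna_genotype,
    call_sites,
    detect_candidate,
    homopolymer_run_length,
    mark_duplicates,
)
from inosinome.io_formats import Genome, write_sam

CONFIG = FilterConfig()


class TestStrandAssignment:
    @pytest.mark.parametrize("is_read2,is_reverse,expected", [
        (True, False, "+"), (True, True, "-"),
        (False, False, "-"), (False, True, "+"),
    ])
    def test_dutp_rules(self, is_read2, is_reverse, expected):
        rec = make_record(is_read2=is_read2, is_reverse=is_reverse)
        assert assign_transcript_strand(rec, "dUTP-RF") == expected
        # FR is the mirror image
        assert assign_transcript_strand(rec, "FR") == \
            ("-" if expected == "+" else "+")

    def test_unstranded_returns_none(self):
        assert assign_transcript_strand(make_record(), "unstranded") is None

    def test_unmapped_rejected(self):
        rec = make_record(seq="AC", quals=[30, 30], cigar=[("M", 2)])
        rec.is_unmapped = True
        with pytest.raises(ValueError):
            assign_transcript_strand(rec)

    def test_simulated_pairs_match_gene_strand(self, small_dataset,
                                               small_sample):
        strand_of = {}
        for m in small_dataset.sim_genome.models:
            for s, e in m.exons:
                strand_of[(m.chrom, s)] = m.strand
        gene_strand = {m.transcript_id: m.strand
                       for m in small_dataset.sim_genome.models}
        checked = 0
        for rec in small_sample.rna_records[:2000]:
            model = next(m for m in small_dataset.sim_genome.models
                         if m.chrom == rec.chrom
                         and m.start <= rec.start < m.end)
            assert assign_transcript_strand(rec, "dUTP-RF") == model.strand
            checked += 1
        assert checked == 2000


class TestPileup:
    def test_mapq_floor_excludes(self):
        genome = Genome({"chrT": "A" * 100})
        records = [make_record(read_id=f"r{i}", start=0) for i in range(4)]
        records.append(make_record(read_id="low", start=0, mapq=10))
        col = build_pileup(records, "chrT", 10, genome, CONFIG)
        assert col.depth == 4
        assert len(col.low_mapq_observations) == 1

    def test_read_cycle_orientation(self):
        genome = Genome({"chrT": "A" * 100})
        fwd = make_record(start=0, is_reverse=False)
        rev = make_record(start=0, is_reverse=True)
        col = build_pileup([fwd], "chrT", 2, genome, CONFIG)
        assert col.observations[0].read_cycle == 3
        col = build_pileup([rev], "chrT", 2, genome, CONFIG)
        assert col.observations[0].read_cycle == 48  # 50-mer, 3' counted

    def test_overlapping_mates_counted_once(self):
        genome = Genome({"chrT": "A" * 100})
        r1 = make_record(read_id="p", start=0, is_read2=False,
                         quals=[20] * 50)
        r2 = make_record(read_id="p", start=20, is_read2=True,
                         quals=[39] * 50)
        col = build_pileup([r1, r2], "chrT", 30, genome, CONFIG)
        assert col.depth == 1
        assert col.observations[0].qual == 39

    def test_deletion_spanning_read_skips_position(self):
        genome = Genome({"chrT": "A" * 100})
        rec = make_record(start=0, cigar=[("M", 20), ("D", 5), ("M", 30)])
        col = build_pileup([rec], "chrT", 22, genome, CONFIG)
        assert col.depth == 0
        col = build_pileup([rec], "chrT", 19, genome, CONFIG)
        assert col.depth == 1
        assert col.observations[0].dist_to_indel == 1

    def test_counts_match_sam_text_recount(self, tmp_path, rng):
        genome = random_genome(rng, {"chrS": 500})
        records = []
        for i in range(300):
            start = int(rng.integers(0, 440))
            length = int(rng.integers(20, 60))
            seq = "".join(rng.choice(list("ACGT"), length))
            records.append(make_record(
                read_id=f"r{i % 250}", chrom="chrS", start=start, seq=seq,
                quals=[int(q) for q in rng.integers(25, 41, length)],
                mapq=int(rng.choice([60, 10])), mate_start=start))
        records.sort(key=lambda r: r.start)
        path = tmp_path / "fixture.sam"
        write_sam(records, {"chrS": 500}, str(path))
        for pos0 in rng.integers(0, 500, 40):
            col = build_pileup(records, "chrS", int(pos0), genome, CONFIG)
            ours = {}
            for o in col.observations:
                ours[o.base] = ours.get(o.base, 0) + 1
            theirs = recount_sam_text(str(path), "chrS", int(pos0))
            assert ours == theirs


class TestGenotyping:
    def test_reference_examples(self):
        hom = call_dna_genotype(
            make_column("c", 0, "A", [make_obs("A", read_id=f"r{i}")
                                      for i in range(12)]), CONFIG)
        assert (hom.status, hom.base, hom.depth) == (HOM, "A", 12)
        low = call_dna_genotype(
            make_column("c", 0, "A", [make_obs("A", read_id=f"r{i}")
                                      for i in range(9)]), CONFIG)
        assert low.status == LOW_COV
        het = call_dna_genotype(
            make_column("c", 0, "A",
                        [make_obs("A", read_id=f"r{i}") for i in range(11)]
                        + [make_obs("G", read_id="g")]), CONFIG)
        assert het.status == HET
        assert het.base == "A/G"

    def test_rule_over_all_count_splits(self):
        """Enumerate (n_ref, n_alt) splits: HOM iff deep and pure."""
        for n_ref, n_alt in itertools.product(range(16), range(4)):
            obs = [make_obs("A", read_id=f"a{i}") for i in range(n_ref)] + \
                  [make_obs("G", read_id=f"g{i}") for i in range(n_alt)]
            call = call_dna_genotype(make_column("c", 0, "A", obs), CONFIG)
            depth = n_ref + n_alt
            if depth < 10:
                assert call.status == LOW_COV
            elif n_alt == 0 or n_ref == 0:
                assert call.status == HOM
            else:
                assert call.status == HET

    def test_quality_floor_applies(self):
        obs = [make_obs("A", read_id=f"a{i}") for i in range(12)] + \
              [make_obs("G", qual=20, read_id="g")]
        assert call_dna_genotype(make_column("c", 0, "A", obs),
                                 CONFIG).status == HOM


class TestCandidateDetection:
    def test_plus_strand_ag(self):
        obs = [make_obs("A", read_id=f"a{i}") for i in range(8)] + \
              [make_obs("G", read_id=f"g{i}") for i in range(2)]
        cand = detect_candidate(make_column("c", 5, "A", obs),
                                GenotypeCall("A", 20, HOM), CONFIG)
        assert cand.substitution == "AG"
        assert cand.level == pytest.approx(0.2)
        assert cand.strand == "+"

    def test_no_mismatch_returns_none(self):
        obs = [make_obs("A", read_id=f"a{i}") for i in range(10)]
        assert detect_candidate(make_column("c", 5, "A", obs),
                                GenotypeCall("A", 20, HOM), CONFIG) is None

    def test_het_genotype_is_contract_violation(self):
        obs = [make_obs("A", read_id="a")]
        with pytest.raises(ValueError):
            detect_candidate(make_column("c", 5, "A", obs),
                             GenotypeCall("A/G", 20, HET), CONFIG)

    @pytest.mark.parametrize("ref,alt",
                             list(itertools.permutations("ACGT", 2)))
    def test_complementation_over_all_substitutions(self, ref, alt):
        """Minus-strand evidence reports the complemented substitution."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        obs = [make_obs(ref, strand="-", read_id=f"a{i}")
               for i in range(7)] + \
              [make_obs(alt, strand="-", read_id=f"g{i}") for i in range(3)]
        cand = detect_candidate(make_column("c", 5, ref, obs),
                                GenotypeCall(ref, 20, HOM), CONFIG)
        assert cand.strand == "-"
        assert cand.substitution == comp[ref] + comp[alt]
        assert cand.level == pytest.approx(0.3)

    def test_multiallelic_tie_break(self):
        obs = [make_obs("A", read_id=f"a{i}") for i in range(10)] + \
              [make_obs("C", read_id="c0"), make_obs("G", read_id="g0")]
        cand = detect_candidate(make_column("c", 5, "A", obs),
                                GenotypeCall("A", 20, HOM), CONFIG)
        assert cand.alt_t == "C"  # tie broken by base order
        assert cand.multiallelic


class TestHomopolymer:
    def test_reference_examples(self):
        genome = Genome({"c": "CCAAAAAACC"})
        for pos in range(2, 8):
            assert homopolymer_run_length(genome, "c", pos) == 6
        genome5 = Genome({"c": "CCAAAAACC"})
        assert homopolymer_run_length(genome5, "c", 4) == 5

    def test_all_positions_match_regex_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        genome = Genome({"c": seq})
        expected = maximal_run_lengths(seq)
        for pos in range(len(seq)):
            assert homopolymer_run_length(genome, "c", pos) == expected[pos]


class TestDuplicates:
    def test_marks_identical_placement_keeps_best(self):
        a = make_record(read_id="a", start=5, quals=[30] * 50, mate_start=9)
        b = make_record(read_id="b", start=5, quals=[38] * 50, mate_start=9)
        c = make_record(read_id="c", start=6, quals=[30] * 50, mate_start=9)
        out = {r.read_id: r.is_duplicate for r in mark_duplicates([a, b, c])}
        assert out == {"a": True, "b": False, "c": False}

    def test_existing_flags_respected(self):
        a = make_record(read_id="a", start=5, is_duplicate=True)
        b = make_record(read_id="b", start=5)
        assert mark_duplicates([a, b]) == [a, b]


class TestCallSitesInvariants:
    def test_counts_conservation(self, small_callset):
        for site in small_callset:
            assert sum(site.base_counts.values()) == site.rna_depth

    def test_minus_strand_sites_report_ag(self, small_dataset,
                                          small_callset):
        truth = {(e.chrom, e.pos0): e for e in small_dataset.truth.edits}
        minus_pass = [s for s in small_callset
                      if s.passed and (s.chrom, s.pos0) in truth
                      and truth[(s.chrom, s.pos0)].strand == "-"]
        assert minus_pass, "no minus-strand sites recovered"
        for s in minus_pass:
            assert (s.strand, s.substitution) == ("-", "AG")

    def test_threshold_monotonicity(self, small_dataset, small_sample,
                                    small_annotations):
        """Raising any threshold never increases the PASS count."""
        def n_pass(config):
            sites = call_sites(small_sample.rna_records, small_dataset.dna,
                               small_dataset.genome, small_annotations,
                               config)
            return len(sites)

        base = n_pass(FilterConfig())
        for stricter in (
                FilterConfig(min_alt_reads_nonalu=5),
                FilterConfig(min_alt_reads_alu=4),
                FilterConfig(min_freq_nonalu=0.3),
                FilterConfig(stringent_min_basequal=37),
                FilterConfig(loose_min_basequal=33),
                FilterConfig(read_end_trim=20),
                FilterConfig(min_dna_depth=25),
                FilterConfig(max_homopolymer=0),
        ):
            assert n_pass(stricter) <= base

    def test_unknown_chromosome_is_fatal(self, small_dataset):
        rec = make_record(chrom="chrMissing")
        with pytest.raises(ValueError, match="chrMissing"):
            call_sites([rec], small_dataset.dna, small_dataset.genome)

    def test_deterministic_output(self, small_dataset, small_sample,
                                  small_annotations):
        a = call_sites(small_sample.rna_records, small_dataset.dna,
                       small_dataset.genome, small_annotations,
                       FilterConfig())
        b = call_sites(small_sample.rna_records, small_dataset.dna,
                       small_dataset.genome, small_annotations,
                       FilterConfig())
        assert a == b
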