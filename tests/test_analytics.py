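"""Downstream statistics vs closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from helpers import (
    bh_stepup,
    hypergeom_tail,
    naive_average_linkage,
    random_genome,
)
from inosinome.analytics import (
    bh_adjust,
    cluster_samples,
    context_matrix,
    correlate_editing_expression,
    differential_editing,
    editing_level,
    events_per_gene_vs_alu,
    geneset_enrichment,
    paired_t_table,
    sample_profile,
    spearman,
    tissue_specific_sites,
)
from inosinome.io_formats import Genome, IntervalIndex, SiteRecord


def _site(pos0, level, chrom="c", strand="+", depth=30, source="MAIN",
          gene="", sample_id="s", flags=frozenset()):
    g = int(round(level * depth))
    return SiteRecord(
        chrom=chrom, pos0=pos0, strand=strand, ref_base="A",
        dna_depth=30, dna_genotype="A", rna_depth=depth,
        base_counts={"A": depth - g, "C": 0, "G": g, "T": 0},
        editing_level=level, substitution="AG",
        genic_context=f"UTR3:{gene}" if gene else "",
        filter_flags=flags, source=source, sample_id=sample_id)


def test_editing_level_arithmetic():
    assert editing_level(10, 0) == 0.0
    assert editing_level(0, 10) == 1.0
    assert editing_level(7, 3) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        editing_level(0, 0)


class TestSampleProfile:
    def test_closed_form(self):
        table = [_site(i, lv) for i, lv in enumerate((0.1, 0.2, 0.3))]
        p = sample_profile(table)
        assert p.median_level == pytest.approx(0.2)
        assert p.mean_level == pytest.approx(0.2)
        assert p.cv == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1) / 0.2)
        assert p.global_editing == pytest.approx(0.6)
        assert p.n_sites == 3

    def test_degenerate_cases(self):
        single = sample_profile([_site(0, 0.4)])
        assert single.median_level == pytest.approx(0.4)
        assert single.cv == 0.0
        equal = sample_profile([_site(i, 0.25) for i in range(5)])
        assert equal.cv == 0.0
        empty = sample_profile([])
        assert empty.n_sites == 0 and math.isnan(empty.median_level)

    def test_only_pass_sites_and_hyper_counted(self):
        table = [_site(0, 0.5), _site(1, 0.9, flags=frozenset({"LOW_FREQ"})),
                 _site(2, 0.2, source="HYPER")]
        p = sample_profile(table)
        assert p.n_sites == 2
        assert p.n_hyper == 1


class TestContextMatrix:
    def test_manual_window_indexing(self):
        #                0123456789012
        genome = Genome({"c": "CCTAGAGGGTTCC"})
        site = _site(5, 0.3)  # base at 5 is 'A'
        m = context_matrix([site], genome, flank=5,
                           rng=np.random.default_rng(0))
        window = "CCTAGAGGGTT"  # positions -5..+5 around index 5
        for i, b in enumerate(window):
            assert m.foreground[i, "ACGT".index(b)] == 1
        assert m.foreground[5, 0] == 1  # position 0 is the edited A

    def test_minus_strand_is_reverse_complement(self):
        genome = Genome({"c": "CCTAGTGGGTTCC"})
        site = _site(5, 0.3, strand="-")  # genomic T at 5 -> transcript A
        m = context_matrix([site], genome, flank=5,
                           rng=np.random.default_rng(0))
        window = "AACCCACTAGG"  # revcomp of CCTAGTGGGTT
        for i, b in enumerate(window):
            assert m.foreground[i, "ACGT".index(b)] == 1

    def test_conservation_and_background_size(self, rng):
        genome = random_genome(rng, {"c": 4000})
        sites = []
        for pos in range(100, 3900, 40):
            if genome.base("c", pos) == "A":
                sites.append(_site(pos, 0.2))
        m = context_matrix(sites, genome, rng=np.random.default_rng(1))
        n = len(sites)
        assert (m.foreground.sum(axis=1) == n).all()
        assert (m.background.sum(axis=1) == n).all()
        assert m.foreground[5, 0] == n  # all A at position 0
        assert m.background[5, 0] == n

    def test_contig_edge_sites_skipped(self):
        genome = Genome({"c": "A" * 20})
        m = context_matrix([_site(2, 0.1), _site(10, 0.1)], genome,
                           rng=np.random.default_rng(0))
        assert m.n_skipped == 1


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_degenerate_flagged(self):
        assert not spearman([1, 2, 3], [5, 5, 5]).defined

    def test_matches_rank_formula_oracle(self, rng):
        """Midrank + Pearson-on-ranks evaluation, written independently."""
        def midranks(x):
            order = sorted(range(len(x)), key=lambda i: x[i])
            ranks = [0.0] * len(x)
            i = 0
            while i < len(x):
                j = i
                while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        for _ in range(25):
            x = rng.integers(0, 10, 20).astype(float).tolist()
            y = (rng.integers(0, 10, 20).astype(float)).tolist()
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rx, ry = midranks(x), midranks(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)


class TestBH:
    def test_reference_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]).tolist() == \
            pytest.approx([0.03, 0.03, 0.04])
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_stepup_oracle_and_permutation_invariance(self, rng):
        for _ in range(30):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert q.tolist() == pytest.approx(bh_stepup(p.tolist()))
            assert ((q >= 0) & (q <= 1)).all()
            perm = rng.permutation(len(p))
            assert bh_adjust(p[perm]).tolist() == \
                pytest.approx(q[perm].tolist())

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        table = [_site(i, lv) for i, lv in
                 enumerate(np.linspace(0.05, 0.8, 12))]
        tree = cluster_samples({"a": table, "b": table,
                                "c": [_site(i, lv) for i, lv in
                                      enumerate(
                                          np.linspace(0.8, 0.05, 12))]})
        assert tree.distances.loc["a", "b"] == pytest.approx(0.0)
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_average_linkage_matches_bruteforce_on_four(self, rng):
        tables = {}
        for name in "abcd":
            levels = rng.random(15)
            tables[name] = [_site(i, float(lv))
                            for i, lv in enumerate(levels)]
        tree = cluster_samples(tables)
        heights = sorted(tree.linkage[:, 2].tolist())
        oracle = naive_average_linkage(tree.distances.values)
        assert heights == pytest.approx(oracle)

    def test_too_few_shared_sites_is_fatal(self):
        a = [_site(0, 0.1)]
        b = [_site(100, 0.1)]
        with pytest.raises(ValueError, match="share"):
            cluster_samples({"a": a, "b": b})

    def test_newick_contains_all_leaves(self, rng):
        tables = {name: [_site(i, float(lv)) for i, lv in
                         enumerate(rng.random(10))] for name in "abcd"}
        nw = cluster_samples(tables).newick()
        assert nw.endswith(";")
        for name in "abcd":
            assert name in nw


class TestDifferential:
    def test_closed_form_paired_t(self):
        a = np.array([[0.30, 0.32, 0.28]])
        b = np.array([[0.60, 0.62, 0.58]])
        table = paired_t_table(a, b)
        d = (a - b)[0]
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert table["t"][0] == pytest.approx(t_expected)
        assert table["pvalue"][0] < 0.01

    def test_identical_levels_null(self):
        a = np.array([[0.3, 0.4, 0.5]])
        table = paired_t_table(a, a.copy())
        assert table["t"][0] == 0.0
        assert table["pvalue"][0] == 1.0

    def test_site_eligibility_and_pairing(self):
        # site 0 deep everywhere; site 1 shallow in one sample of tissue B
        def tbl(sample, levels, depths):
            return [_site(i, lv, depth=d, sample_id=sample)
                    for i, (lv, d) in enumerate(zip(levels, depths))]

        ta = {"a1": tbl("a1", [0.2, 0.3], [40, 40]),
              "a2": tbl("a2", [0.25, 0.3], [40, 40])}
        tb = {"b1": tbl("b1", [0.6, 0.3], [40, 40]),
              "b2": tbl("b2", [0.65, 0.3], [40, 5])}
        pairing = {"a1": "i1", "a2": "i2", "b1": "i1", "b2": "i2"}
        results = differential_editing(ta, tb, pairing)
        assert [r.site[1] for r in results] == [0]
        assert results[0].mean_level_a == pytest.approx(0.225)
        assert results[0].mean_level_b == pytest.approx(0.625)


class TestEnrichment:
    def test_hypergeometric_matches_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = {"S": universe[:20]}
        query = universe[10:40]
        res = geneset_enrichment(query, universe, gene_set)[0]
        assert res.k_overlap == 10
        assert res.pvalue == pytest.approx(hypergeom_tail(10, 100, 20, 30))

    def test_independence_gives_large_p(self, rng):
        universe = [f"g{i}" for i in range(200)]
        gene_set = {"S": universe[:40]}
        query = universe[::5]  # 40 genes, overlap 8 = expectation
        res = geneset_enrichment(query, universe, gene_set)[0]
        assert res.pvalue > 0.3
        assert 0.3 < res.odds_ratio < 3.5

    def test_query_equals_set_is_minimal_p(self):
        universe = [f"g{i}" for i in range(50)]
        gene_set = {"S": universe[:10]}
        res = geneset_enrichment(universe[:10], universe, gene_set)[0]
        assert res.pvalue == pytest.approx(
            hypergeom_tail(10, 50, 10, 10))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment(["a"], [], {"S": ["a"]})


class TestTissueSpecific:
    def _tables(self):
        brain = {"b1": [_site(0, 0.3, gene="g1", sample_id="b1"),
                        _site(5, 0.3, gene="g2", sample_id="b1"),
                        _site(9, 0.3, sample_id="b1")]}
        lung = {"l1": [_site(5, 0.2, gene="g2", sample_id="l1")]}
        return {"brain": brain, "lung": lung}

    def test_rules(self):
        expression = pd.DataFrame({"b1": [5.0, 2.0], "l1": [1.5, 2.0]},
                                  index=["g1", "g2"])
        specific, n_unann = tissue_specific_sites(self._tables(),
                                                  expression)
        assert specific["brain"] == {("c", 0, "+")}  # g1 FPKM 5 in brain
        assert specific["lung"] == set()  # site 5 edited in both tissues
        assert n_unann == 1  # the unannotated brain site

    def test_fpkm_threshold(self):
        expression = pd.DataFrame({"b1": [0.5, 2.0], "l1": [1.5, 2.0]},
                                  index=["g1", "g2"])
        specific, _ = tissue_specific_sites(self._tables(), expression)
        assert specific["brain"] == set()


def test_events_per_gene_vs_alu_counts_match_bruteforce(rng):
    from inosinome.io_formats import TranscriptModel
    models = [TranscriptModel(f"t{i}", f"g{i}", "c",
                              "+", exons=[(i * 1000, i * 1000 + 600)])
              for i in range(8)]
    repeat_index = IntervalIndex()
    alu_rows = []
    for i in range(8):
        for j in range(i):  # gene i hosts i Alu copies
            s = i * 1000 + j * 60
            repeat_index.add("c", s, s + 50, f"AluS{i}{j}", "+")
            alu_rows.append(("c", s, s + 50))
    sites = []
    for i in range(8):
        for j in range(max(1, i)):  # edited positions scale with Alu count
            sites.append(_site(i * 1000 + j * 60 + 5, 0.2,
                               gene=f"g{i}"))
    result, frame = events_per_gene_vs_alu(sites, models, repeat_index)
    for row in frame.itertuples():
        gene_idx = int(row.gene_id[1:])
        span = (gene_idx * 1000, gene_idx * 1000 + 600)
        expected = sum(1 for c, s, e in alu_rows
                       if s < span[1] and e > span[0])
        assert row.n_alu == expected
    assert result.rho > 0.9


def test_correlate_editing_expression_monotone_and_degenerate(rng):
    from inosinome.analytics import SampleProfile
    profiles = []
    fpkm = {}
    for i in range(8):
        profiles.append(SampleProfile(f"s{i}", "t", n_sites=50 + i * 9,
                                      n_hyper=0, median_level=0.2,
                                      mean_level=0.2, cv=0.5,
                                      global_editing=3.0 + i))
        fpkm[f"s{i}"] = [10.0 + 2 * i]
    expression = pd.DataFrame(fpkm, index=["ADAR"])
    out = correlate_editing_expression(profiles, expression)
    assert out["global_editing"].rho == pytest.approx(1.0)
    assert out["n_sites"].rho == pytest.approx(1.0)
    constant = expression * 0 + 1.0
    res = correlate_editing_expression(profiles, constant)
    assert not res["global_editing"].defined

    with pytest.warns(UserWarning):
        correlate_editing_expression(
            profiles, expression.drop(columns=["s7"]))
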