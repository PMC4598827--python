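"""Hand-built pileup fixtures: one per filter failure code.

Each case evaluates a constructed column through the real cascade and
records the verdict together with a boundary variant where the code must
clear (6 bp read-end limit, homopolymer 5 vs 6, indel +/-10, support 2 vs 3,
frequency 0.1, quality 30, duplicate-only support, multi-mapping tie).
Shared between the filter unit tests and the acceptance suite.
"""

from __future__ import annotations

import math

import numpy as np

from helpers import make_obs, make_column, make_record
from inosinome.calling import (
    ALU,
    CallContext,
    FilterConfig,
    GenotypeCall,
    HET,
    HOM,
    LOW_COV,
    NONREP,
    evaluate_position,
)
from inosinome.io_formats import Genome, IntervalIndex, KnownVariantIndex
from inosinome.realign import SeedIndex

_seq = list(("CGT" * 140)[:400])
_seq[100] = "A"
for _i in range(200, 206):   # homopolymer run of 6
    _seq[_i] = "A"
for _i in range(220, 225):   # run of exactly 5
    _seq[_i] = "A"
GENOME = Genome({"chrT": "".join(_seq)})

HOM_A = GenotypeCall("A", 12, HOM)
CONFIG = FilterConfig()


def _obs(n, base, start_id=0, **kw):
    return [make_obs(base=base, read_id=f"{base}{start_id + i}", **kw)
            for i in range(n)]


def _ctx(repeat_class=NONREP, **kw):
    return CallContext(genome=GENOME, repeat_class=repeat_class, **kw)


def _flags(observations, genotype=HOM_A, pos0=100, low_mapq=(),
           context=None, config=CONFIG):
    column = make_column("chrT", pos0, GENOME.base("chrT", pos0),
                         observations, low_mapq)
    site = evaluate_position(column, genotype, context or _ctx(), config)
    assert site is not None
    return set(site.filter_flags)


def case_low_mapq():
    fired = _flags(_obs(10, "A"), low_mapq=_obs(3, "G", mapq=10))
    clear = _flags(_obs(10, "A") + _obs(3, "G"))
    return fired, clear


def case_low_basequal():
    # loose floor: mismatches only below q25 never become candidates
    fired = _flags(_obs(10, "A") + _obs(3, "G", qual=24))
    # stringent floor: q29 variant reads survive loosely but fail at 30
    stringent = _flags(_obs(10, "A") + _obs(3, "G", qual=29))
    assert "LOW_BASEQUAL" in stringent
    clear = _flags(_obs(10, "A") + _obs(3, "G", qual=30))
    return fired, clear


def case_read_end():
    fired = _flags(_obs(17, "A") + _obs(3, "G", cycle=6))
    assert fired == {"READ_END", "LOW_ALT_SUPPORT"}
    tail = _flags(_obs(17, "A") + _obs(3, "G", cycle=95))
    assert "READ_END" in tail
    clear = _flags(_obs(17, "A") + _obs(3, "G", cycle=7))
    return fired, clear


def case_homopolymer():
    fired = _flags(_obs(10, "A") + _obs(3, "G"), pos0=202)
    clear = _flags(_obs(10, "A") + _obs(3, "G"), pos0=222)
    return fired, clear


def case_near_indel():
    fired = _flags(_obs(10, "A") + _obs(3, "G", dist=10))
    near = _flags(_obs(10, "A") + _obs(3, "G"),
                  context=_ctx(nearby_indel_positions=[110]))
    assert near == {"NEAR_INDEL"}
    clear = _flags(_obs(10, "A") + _obs(3, "G", dist=11),
                   context=_ctx(nearby_indel_positions=[111]))
    return fired, clear


def case_near_splice():
    splice = IntervalIndex()
    splice.add("chrT", 98, 102, "splice", "+")
    fired = _flags(_obs(10, "A") + _obs(3, "G"),
                   context=_ctx(splice_index=splice))
    far = IntervalIndex()
    far.add("chrT", 102, 106, "splice", "+")
    clear = _flags(_obs(10, "A") + _obs(3, "G"),
                   context=_ctx(splice_index=far))
    return fired, clear


def case_low_alt_support():
    fired = _flags(_obs(18, "A") + _obs(2, "G"))  # freq 0.1 exactly: no LOW_FREQ
    assert fired == {"LOW_ALT_SUPPORT"}
    alu_fired = _flags(_obs(10, "A") + _obs(1, "G"),
                       context=_ctx(repeat_class=ALU))
    assert alu_fired == {"LOW_ALT_SUPPORT"}
    alu_clear = _flags(_obs(10, "A") + _obs(2, "G", qual=25),
                       context=_ctx(repeat_class=ALU))
    assert alu_clear == set()
    clear = _flags(_obs(17, "A") + _obs(3, "G"))
    return fired, clear


def case_low_freq():
    fired = _flags(_obs(37, "A") + _obs(3, "G"))
    clear = _flags(_obs(27, "A") + _obs(3, "G"))
    return fired, clear


def case_dna_not_hom():
    fired = _flags(_obs(8, "A") + _obs(4, "G"),
                   genotype=GenotypeCall("A/G", 30, HET))
    clear = _flags(_obs(8, "A") + _obs(4, "G"))
    return fired, clear


def case_dna_low_cov():
    fired = _flags(_obs(10, "A") + _obs(3, "G"),
                   genotype=GenotypeCall("A", 9, LOW_COV))
    clear = _flags(_obs(10, "A") + _obs(3, "G"),
                   genotype=GenotypeCall("A", 10, HOM))
    return fired, clear


def case_known_snp():
    known = KnownVariantIndex()
    known.add("chrT", 100, "A", "G")
    fired = _flags(_obs(10, "A") + _obs(3, "G"),
                   context=_ctx(known_variants=known))
    other = KnownVariantIndex()
    other.add("chrT", 100, "A", "C")
    clear = _flags(_obs(10, "A") + _obs(3, "G"),
                   context=_ctx(known_variants=other))
    return fired, clear


def case_retrogene():
    retro = IntervalIndex()
    retro.add("chrT", 90, 120, "retro1", "+")
    fired = _flags(_obs(10, "A") + _obs(3, "G"),
                   context=_ctx(retro_index=retro))
    clear = _flags(_obs(10, "A") + _obs(3, "G"),
                   context=_ctx(retro_index=IntervalIndex()))
    return fired, clear


def _multimap_fixture(duplicated: bool):
    rng = np.random.default_rng(99)
    seq = list("".join(rng.choice(list("ACGT"), 1200)))
    seq[175] = "A"
    if duplicated:
        seq[700:1000] = seq[100:400]
    genome = Genome({"chrM": "".join(seq)})
    variant_reads = []
    observations = [make_obs(base="A", read_id=f"ref{i}")
                    for i in range(10)]
    for k, start in enumerate((150, 155, 160)):
        rseq = list(genome.subsequence("chrM", start, start + 50))
        rseq[175 - start] = "G"
        rid = f"var{k}"
        variant_reads.append(make_record(
            read_id=rid, chrom="chrM", start=start, seq="".join(rseq),
            quals=[35] * 50))
        observations.append(make_obs(base="G", read_id=rid,
                                     cycle=175 - start + 1,
                                     read_length=50))
    context = CallContext(
        genome=genome, repeat_class=NONREP,
        seed_index=SeedIndex(genome, k=11),
        read_lookup={r.read_id: [r] for r in variant_reads})
    column = make_column("chrM", 175, "A", observations)
    site = evaluate_position(column, HOM_A, context, CONFIG)
    return set(site.filter_flags)


def case_multimap():
    return _multimap_fixture(True), _multimap_fixture(False)


def case_duplicate_only():
    fired = _flags(_obs(15, "A") + _obs(3, "G", dup=True))
    assert fired == {"DUPLICATE_ONLY", "LOW_ALT_SUPPORT"}
    clear = _flags(_obs(15, "A") + _obs(3, "G"))
    return fired, clear


CASES = {
    "LOW_MAPQ": case_low_mapq,
    "LOW_BASEQUAL": case_low_basequal,
    "READ_END": case_read_end,
    "HOMOPOLYMER": case_homopolymer,
    "NEAR_INDEL": case_near_indel,
    "NEAR_SPLICE": case_near_splice,
    "LOW_ALT_SUPPORT": case_low_alt_support,
    "LOW_FREQ": case_low_freq,
    "DNA_NOT_HOM": case_dna_not_hom,
    "DNA_LOW_COV": case_dna_low_cov,
    "KNOWN_SNP": case_known_snp,
    "RETROGENE": case_retrogene,
    "MULTIMAP": case_multimap,
    "DUPLICATE_ONLY": case_duplicate_only,
}

# codes expected to fire alone in their dedicated fixture
EXACT_SINGLE = {
    "LOW_MAPQ", "LOW_BASEQUAL", "HOMOPOLYMER", "NEAR_INDEL", "NEAR_SPLICE",
    "LOW_FREQ", "DNA_NOT_HOM", "DNA_LOW_COV", "KNOWN_SNP", "RETROGENE",
    "MULTIMAP",
}
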