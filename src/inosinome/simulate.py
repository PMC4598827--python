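"""Synthetic matched DNA/RNA datasets with known editing truth.

The generator emulates the study design the caller is built for: a genome
carrying Alu-like inverted repeats, multi-exon genes on both strands,
strand-oriented (dUTP) paired RNA-Seq sampled from mature transcripts,
whole-genome DNA reads carrying germline SNPs but never editing, clusters of
hyper-edited reads, and an FPKM expression table — all with a truth table,
so every downstream claim can be checked against planted values.

Deliberate simplifications (see the methods note): reads are emitted
pre-aligned with exact CIGARs, so no external aligner is needed; the error
model is phred-consistent uniform substitution; editing is planted in
exonic sequence because fragments are drawn from mature transcripts; per-gene
abundances are narrowly spread so planted sites are comparably powered.
Fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import (
    FilterConfig,
    GenotypeCall,
    call_dna_genotype,
    PileupColumn,
    ReadObservation,
    splice_window_index,
)
from .hyperediting import UnalignedRead
from .io_formats import (
    AlignmentRecord,
    Genome,
    IntervalIndex,
    TranscriptModel,
    reverse_complement,
    write_sam,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# Phred qualities are drawn from this discrete distribution; the error
# probability of each base is 10^(-q/10) scaled so that the average matches
# the configured error rate, keeping errors concentrated at low qualities
# as in real base calling.
QUAL_VALUES = np.array([40, 37, 33, 30, 27, 24, 20, 15])
QUAL_PROBS = np.array([0.45, 0.20, 0.12, 0.08, 0.05, 0.04, 0.04, 0.02])
_MEAN_ERR = float((QUAL_PROBS * 10.0 ** (-QUAL_VALUES / 10.0)).sum())


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the toy configuration used throughout the test suite:
    a 2 Mb genome over two chromosomes, 300 planted sites with a low-level
    Alu mixture, 30x stranded RNA and 40x DNA coverage, 0.1% sequencing
    error, paired 100 nt reads.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 800_000})
    n_genes: int = 24
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (250, 600)
    intron_length: tuple[int, int] = (300, 1500)
    utr3_alu_fraction: float = 0.5   # genes with an inverted Alu pair in 3'UTR
    intron_alu_fraction: float = 0.3
    alu_length: int = 300
    alu_divergence: float = 0.08
    alu_spacer: int = 60
    n_rep_nonalu: int = 12
    rep_nonalu_length: int = 400
    n_retro: int = 4
    retro_length: int = 500
    n_edit_sites: int = 300
    alu_site_fraction: float = 0.7
    alu_level_beta: tuple[float, float] = (1.2, 12.0)  # mode < 0.1
    alu_level_uniform_weight: float = 0.3
    n_hom_snps: int = 15
    n_het_snps: int = 15
    coverage_rna: float = 30.0
    coverage_dna: float = 40.0
    read_length: int = 100
    fragment_range: tuple[int, int] = (180, 400)
    error_rate: float = 0.001
    protocol: str = "dUTP-RF"
    duplicate_fraction: float = 0.02
    abundance_sigma: float = 0.15
    n_hyper_clusters: int = 10
    edits_per_cluster: tuple[int, int] = (6, 12)
    reads_per_cluster: int = 3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_edit_sites", "n_hom_snps", "n_het_snps",
                     "n_hyper_clusters", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class PlantedEdit:
    chrom: str
    pos0: int
    strand: str
    level: float
    in_alu: bool
    hyper: bool = False
    cluster_id: int = -1


@dataclass
class PlantedSnp:
    chrom: str
    pos0: int
    ref: str
    alt: str
    genotype: str  # HOM | HET


@dataclass
class TruthTable:
    edits: list[PlantedEdit] = field(default_factory=list)
    snps: list[PlantedSnp] = field(default_factory=list)

    def edit_positions(self) -> set[tuple[str, int]]:
        return {(e.chrom, e.pos0) for e in self.edits}


def write_truth_table(truth: TruthTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tchrom\tpos\tstrand\tlevel\tin_alu\thyper\t"
                 "cluster\tref\talt\tgenotype\n")
        for e in truth.edits:
            fh.write(f"EDIT\t{e.chrom}\t{e.pos0 + 1}\t{e.strand}\t"
                     f"{e.level!r}\t{int(e.in_alu)}\t{int(e.hyper)}\t"
                     f"{e.cluster_id}\t.\t.\t.\n")
        for s in truth.snps:
            fh.write(f"SNP\t{s.chrom}\t{s.pos0 + 1}\t.\t0.0\t0\t0\t-1\t"
                     f"{s.ref}\t{s.alt}\t{s.genotype}\n")


def read_truth_table(path: str) -> TruthTable:
    truth = TruthTable()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[0] == "EDIT":
                truth.edits.append(PlantedEdit(
                    f[1], int(f[2]) - 1, f[3], float(f[4]), bool(int(f[5])),
                    bool(int(f[6])), int(f[7])))
            else:
                truth.snps.append(PlantedSnp(f[1], int(f[2]) - 1, f[8],
                                             f[9], f[10]))
    return truth


# ---------------------------------------------------------------------------
# Genome construction


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _diverge(seq: np.ndarray, rate: float,
             rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    idx = np.nonzero(mask)[0]
    shift = rng.integers(1, 4, len(idx))
    codes = _CODE[out[idx]]
    out[idx] = _BASES[(codes + shift) % 4]
    return out


def _revcomp_array(seq: np.ndarray) -> np.ndarray:
    comp = _BASES[3 - _CODE[seq]]
    return comp[::-1]


def transcript_interval_to_genomic(model: TranscriptModel, t0: int,
                                   t1: int) -> list[tuple[int, int]]:
    """Genomic intervals (sorted) covered by transcript coords [t0, t1)."""
    if not 0 <= t0 < t1 <= model.exonic_length:
        raise IndexError("transcript interval out of range")
    exons = model.exons if model.strand == "+" else model.exons[::-1]
    out = []
    off = 0
    for s, e in exons:
        length = e - s
        a, b = max(t0, off), min(t1, off + length)
        if a < b:
            if model.strand == "+":
                out.append((s + (a - off), s + (b - off)))
            else:
                out.append((e - (b - off), e - (a - off)))
        off += length
    return sorted(out)


@dataclass
class SimulatedGenome:
    genome: Genome
    repeats: list[tuple[str, int, int, str, str]]  # BED-style rows
    retro: list[tuple[str, int, int, str, str]]
    models: list[TranscriptModel]

    def repeat_index(self) -> IntervalIndex:
        index = IntervalIndex()
        for chrom, s, e, label, strand in self.repeats:
            index.add(chrom, s, e, label, strand)
        return index

    def retro_index(self) -> IntervalIndex:
        index = IntervalIndex()
        for chrom, s, e, label, strand in self.retro:
            index.add(chrom, s, e, label, strand)
        return index


def make_genome(config: SimConfig) -> SimulatedGenome:
    """Random genome with genes, inverted Alu-like pairs and decoy repeats.

    Alu pairs are placed in inverted orientation either inside an enlarged
    3'UTR exon (where mature-transcript reads cover them) or inside an
    intron; each copy diverges from a per-run consensus by the configured
    rate.  Gene models are written with complete CDS (multiple of 3) and
    UTRs on both strands.
    """
    rng = np.random.default_rng([config.seed, 101])
    arrays = {name: _random_bases(rng, length)
              for name, length in config.chrom_lengths.items()}
    consensus = _random_bases(rng, config.alu_length)
    l1_consensus = _random_bases(rng, config.rep_nonalu_length)
    repeats: list[tuple[str, int, int, str, str]] = []
    retro: list[tuple[str, int, int, str, str]] = []
    models: list[TranscriptModel] = []

    chroms = list(config.chrom_lengths)
    genes_per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        genes_per_chrom[i] += 1

    gene_no = 0
    alu_no = 0
    for chrom, n_genes in zip(chroms, genes_per_chrom):
        arr = arrays[chrom]
        cursor = int(rng.integers(2000, 6000))
        for _ in range(n_genes):
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            exon_lengths = [int(rng.integers(*config.exon_length))
                            for _ in range(n_exons)]
            with_utr3_alu = rng.random() < config.utr3_alu_fraction
            alu_block = 2 * config.alu_length + config.alu_spacer
            utr3_exon = n_exons - 1 if strand == "+" else 0
            if with_utr3_alu:
                exon_lengths[utr3_exon] += alu_block + 80
            intron_lengths = [int(rng.integers(*config.intron_length))
                              for _ in range(n_exons - 1)]
            with_intron_alu = n_exons > 1 and \
                rng.random() < config.intron_alu_fraction
            intron_for_alu = int(rng.integers(0, n_exons - 1)) \
                if with_intron_alu else -1
            if with_intron_alu:
                intron_lengths[intron_for_alu] = max(
                    intron_lengths[intron_for_alu], alu_block + 200)
            span = sum(exon_lengths) + sum(intron_lengths)
            if cursor + span + 2000 > len(arr):
                break
            exons = []
            pos = cursor
            for k, el in enumerate(exon_lengths):
                exons.append((pos, pos + el))
                pos += el
                if k < n_exons - 1:
                    pos += intron_lengths[k]
            gene_end = pos

            def plant_alu_pair(lo: int) -> None:
                nonlocal alu_no
                copy_a = _diverge(consensus, config.alu_divergence, rng)
                copy_b = _revcomp_array(
                    _diverge(consensus, config.alu_divergence, rng))
                start_a = lo
                start_b = lo + config.alu_length + config.alu_spacer
                arr[start_a:start_a + config.alu_length] = copy_a
                arr[start_b:start_b + config.alu_length] = copy_b
                alu_no += 1
                repeats.append((chrom, start_a,
                                start_a + config.alu_length,
                                f"AluSim{alu_no}a", "+"))
                repeats.append((chrom, start_b,
                                start_b + config.alu_length,
                                f"AluSim{alu_no}b", "-"))

            if with_utr3_alu:
                s, e = exons[utr3_exon]
                # keep the pair away from the exon edges (splice windows)
                plant_alu_pair(s + 40)
            if with_intron_alu:
                intron_start = exons[intron_for_alu][1]
                plant_alu_pair(intron_start + 60)

            # CDS: leave a 5'UTR of ~90 nt and a 3'UTR covering the Alu block
            exonic = sum(e - s for s, e in exons)
            utr3_reserve = (alu_block + 120) if with_utr3_alu else 120
            utr5 = 90
            cds_len = exonic - utr5 - utr3_reserve
            cds_len -= cds_len % 3
            cds_intervals: list[tuple[int, int]] = []
            gene_id = f"gene{gene_no}"
            tid = f"tx{gene_no}"
            model = TranscriptModel(tid, gene_id, chrom, strand, exons)
            if cds_len >= 60:
                cds_intervals = transcript_interval_to_genomic(
                    model, utr5, utr5 + cds_len)
            models.append(TranscriptModel(tid, gene_id, chrom, strand,
                                          exons, cds_intervals))
            cursor = gene_end + int(rng.integers(2000, 8000))

    # decoy repeats and retrogene intervals in intergenic space
    def intergenic_spot(chrom: str, length: int) -> int | None:
        arr_len = config.chrom_lengths[chrom]
        spans = [(m.start - 200, m.end + 200) for m in models
                 if m.chrom == chrom]
        for _ in range(50):
            start = int(rng.integers(0, arr_len - length))
            if all(start + length <= s or start >= e for s, e in spans):
                return start
        return None

    for j in range(config.n_rep_nonalu):
        chrom = chroms[j % len(chroms)]
        start = intergenic_spot(chrom, config.rep_nonalu_length)
        if start is None:
            continue
        arrays[chrom][start:start + config.rep_nonalu_length] = _diverge(
            l1_consensus, 0.15, rng)
        repeats.append((chrom, start, start + config.rep_nonalu_length,
                        f"L1Sim{j + 1}", "+"))
    for j in range(config.n_retro):
        chrom = chroms[j % len(chroms)]
        start = intergenic_spot(chrom, config.retro_length)
        if start is None:
            continue
        retro.append((chrom, start, start + config.retro_length,
                      f"retro{j + 1}", "+"))

    genome = Genome({name: arr.tobytes().decode()
                     for name, arr in arrays.items()})
    repeats.sort()
    retro.sort()
    return SimulatedGenome(genome, repeats, retro, models)


# ---------------------------------------------------------------------------
# Truth planting


def plant_truth(config: SimConfig, sim: SimulatedGenome) -> TruthTable:
    """Plant edit sites, SNPs and hyper clusters on exonic positions.

    Edits sit at transcript-space A's (genomic A on plus-strand genes,
    genomic T on minus-strand genes).  Alu-resident sites draw levels from a
    low-mode Beta/uniform mixture; other sites draw uniform levels.  Planted
    positions avoid annotated splice windows and homopolymer runs so the
    truth set represents the detectable inosinome; the exclusion rules
    themselves are exercised by dedicated fixtures.
    """
    rng = np.random.default_rng([config.seed, 202])
    genome = sim.genome
    repeat_index = sim.repeat_index()
    splice = splice_window_index(sim.models, window=4)

    def homopolymer_ok(chrom: str, pos0: int) -> bool:
        seq = genome.sequences[chrom]
        base = seq[pos0]
        left = pos0
        while left > 0 and seq[left - 1] == base:
            left -= 1
        right = pos0
        while right + 1 < len(seq) and seq[right + 1] == base:
            right += 1
        return right - left + 1 <= 5

    # paired fragments cannot deliver nominal coverage within roughly one
    # fragment length of a transcript's ends, so truth is planted only in
    # the uniformly covered interior
    end_margin = max(0, config.fragment_range[1] - config.read_length)

    alu_pool: list[tuple[str, int, str]] = []
    nonalu_pool: list[tuple[str, int, str]] = []
    exonic_pool: list[tuple[str, int]] = []
    for m in sim.models:
        want = "A" if m.strand == "+" else "T"
        margin = min(end_margin, max(0, (m.exonic_length - 50) // 2))
        offset = 0
        for s, e in m.exons:
            seq = genome.subsequence(m.chrom, s, e)
            for i, b in enumerate(seq):
                pos0 = s + i
                exonic_pool.append((m.chrom, pos0))
                t_off = offset + i
                if not margin <= t_off < m.exonic_length - margin:
                    continue
                if b != want:
                    continue
                if splice.at(m.chrom, pos0) or \
                        not homopolymer_ok(m.chrom, pos0):
                    continue
                labels = [lab for _, _, lab, _ in
                          repeat_index.at(m.chrom, pos0)]
                entry = (m.chrom, pos0, m.strand)
                if any(lab.startswith("Alu") for lab in labels):
                    alu_pool.append(entry)
                elif not labels:
                    nonalu_pool.append(entry)
            offset += e - s

    n_alu = round(config.n_edit_sites * config.alu_site_fraction)
    n_non = config.n_edit_sites - n_alu
    if n_alu > len(alu_pool) or n_non > len(nonalu_pool):
        raise ValueError("not enough A positions to plant the requested "
                         "number of edit sites")
    taken: set[tuple[str, int]] = set()
    truth = TruthTable()

    def sample_sites(pool: list[tuple[str, int, str]], n: int,
                     in_alu: bool) -> None:
        order = rng.permutation(len(pool))
        planted = 0
        for idx in order:
            if planted == n:
                break
            chrom, pos0, strand = pool[idx]
            if (chrom, pos0) in taken:
                continue
            taken.add((chrom, pos0))
            if in_alu:
                if rng.random() < config.alu_level_uniform_weight:
                    level = float(rng.uniform(0.0, 1.0))
                else:
                    level = float(rng.beta(*config.alu_level_beta))
            else:
                level = float(rng.uniform(0.0, 1.0))
            truth.edits.append(PlantedEdit(chrom, pos0, strand, level,
                                           in_alu))
            planted += 1
        if planted < n:
            raise ValueError("insufficient distinct positions for edits")

    sample_sites(alu_pool, n_alu, True)
    sample_sites(nonalu_pool, n_non, False)

    # hyper clusters: one read-length window inside a single exon (dense
    # editing arises in contiguous dsRNA, so clusters never straddle
    # splice junctions)
    cluster_id = 0
    rl = config.read_length
    wide_exons = [(m, s, e) for m in sim.models
                  for s, e in m.exons if e - s >= rl]
    attempts = 0
    while cluster_id < config.n_hyper_clusters and attempts < 500 and \
            wide_exons:
        attempts += 1
        m, es, ee = wide_exons[int(rng.integers(0, len(wide_exons)))]
        w = int(rng.integers(es, ee - rl + 1))
        want = "A" if m.strand == "+" else "T"
        seq = genome.subsequence(m.chrom, w, w + rl)
        usable = [w + i for i, b in enumerate(seq)
                  if b == want and (m.chrom, w + i) not in taken]
        lo, hi = config.edits_per_cluster
        if len(usable) < lo:
            continue
        k = int(rng.integers(lo, min(hi, len(usable)) + 1))
        chosen = rng.permutation(len(usable))[:k]
        cluster_id += 1
        for ci in sorted(chosen):
            g = usable[ci]
            taken.add((m.chrom, g))
            truth.edits.append(PlantedEdit(m.chrom, g, m.strand, 1.0,
                                           in_alu=False, hyper=True,
                                           cluster_id=cluster_id))

    # SNPs at exonic positions clear of edits
    free = [p for p in exonic_pool if p not in taken]
    order = rng.permutation(len(free))
    n_snps = config.n_hom_snps + config.n_het_snps
    picked = []
    for idx in order:
        if len(picked) == n_snps:
            break
        chrom, pos0 = free[idx]
        if (chrom, pos0) in taken:
            continue
        taken.add((chrom, pos0))
        picked.append((chrom, pos0))
    for j, (chrom, pos0) in enumerate(picked):
        ref = genome.base(chrom, pos0)
        alt = "ACGT"[(_CODE[ord(ref)] + int(rng.integers(1, 4))) % 4]
        genotype = "HOM" if j < config.n_hom_snps else "HET"
        truth.snps.append(PlantedSnp(chrom, pos0, ref, alt, genotype))
    truth.edits.sort(key=lambda e: (e.chrom, e.pos0))
    truth.snps.sort(key=lambda s: (s.chrom, s.pos0))
    return truth


def truth_vcf_entries(truth: TruthTable) \
        -> list[tuple[str, int, str, str]]:
    """dbSNP-style entries: every planted germline SNP."""
    return [(s.chrom, s.pos0, s.ref, s.alt) for s in truth.snps]


# ---------------------------------------------------------------------------
# Read simulation


_QUAL_CUM = np.cumsum(QUAL_PROBS).astype(np.float64)
_QUAL_U8 = QUAL_VALUES.astype(np.uint8)
_ERR_BY_QUAL = np.zeros(64, dtype=np.float32)
_ERR_BY_QUAL[QUAL_VALUES] = 10.0 ** (-QUAL_VALUES / 10.0)


# 16-bit quantized inverse CDF: one table lookup per drawn quality
_QUAL_TABLE16 = _QUAL_U8[np.minimum(
    np.searchsorted(_QUAL_CUM, (np.arange(65536) + 0.5) / 65536,
                    side="right"), len(QUAL_VALUES) - 1)]


def _draw_quals(rng: np.random.Generator, shape) -> np.ndarray:
    u = rng.integers(0, 65536, size=shape, dtype=np.uint16)
    return _QUAL_TABLE16[u]


def _apply_errors(seqs: np.ndarray, quals: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute bases with probability scaled from their phred quality."""
    scale = np.float32(error_rate / _MEAN_ERR)
    p_err = _ERR_BY_QUAL[quals] * scale
    mask = rng.random(seqs.shape, dtype=np.float32) < p_err
    idx = np.nonzero(mask)
    if idx[0].size:
        codes = _CODE[seqs[idx]]
        shift = rng.integers(1, 4, idx[0].size)
        seqs[idx] = _BASES[(codes + shift) % 4]
    return mask


class DnaReadSet:
    """Vectorized single-end DNA reads with on-demand genotyping.

    Genotyping needs depth and allele purity, not pairing, so genomic reads
    are stored as packed arrays per chromosome; full AlignmentRecords or a
    SAM file can be materialized when an interface requires them.
    """

    def __init__(self, read_length: int) -> None:
        self.read_length = read_length
        self.chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] \
            = {}

    def genotype(self, chrom: str, pos0: int,
                 config: FilterConfig | None = None) -> GenotypeCall:
        config = config or FilterConfig()
        column = self.pileup(chrom, pos0)
        return call_dna_genotype(column, config)

    def pileup(self, chrom: str, pos0: int) -> PileupColumn:
        starts, seqs, quals = self.chroms[chrom]
        lo = np.searchsorted(starts, pos0 - self.read_length + 1, "left")
        hi = np.searchsorted(starts, pos0, "right")
        column = PileupColumn(chrom, pos0, "N")
        for i in range(lo, hi):
            off = pos0 - int(starts[i])
            column.observations.append(ReadObservation(
                base=chr(seqs[i, off]), qual=int(quals[i, off]),
                read_cycle=off + 1, read_length=self.read_length,
                mate="R1", transcript_strand=None, dist_to_indel=math.inf,
                is_duplicate=False, mapq=60, read_id=f"dna.{chrom}.{i}"))
        return column

    def to_records(self, chrom: str, start: int,
                   end: int) -> list[AlignmentRecord]:
        starts, seqs, quals = self.chroms[chrom]
        lo = np.searchsorted(starts, start - self.read_length + 1, "left")
        hi = np.searchsorted(starts, end, "right")
        out = []
        for i in range(lo, hi):
            out.append(AlignmentRecord(
                read_id=f"dna.{chrom}.{i}", chrom=chrom,
                start=int(starts[i]),
                cigar=[("M", self.read_length)],
                seq=seqs[i].tobytes().decode(),
                quals=[int(q) for q in quals[i]],
                mapq=60, is_paired=False, is_read1=True, is_read2=False))
        return out

    def to_sam(self, lengths: dict[str, int], path: str) -> None:
        def records():
            for chrom in self.chroms:
                yield from self.to_records(chrom, 0, lengths[chrom])
        write_sam(records(), lengths, path)


def simulate_dna(sim: SimulatedGenome, truth: TruthTable,
                 config: SimConfig,
                 rng: np.random.Generator | None = None) -> DnaReadSet:
    """Whole-genome single-end reads carrying SNP genotypes, no editing."""
    rng = rng or np.random.default_rng([config.seed, 303])
    rl = config.read_length
    reads = DnaReadSet(rl)
    hom = {(s.chrom, s.pos0): s for s in truth.snps if s.genotype == "HOM"}
    het = [s for s in truth.snps if s.genotype == "HET"]
    for chrom, length in config.chrom_lengths.items():
        arr = np.frombuffer(sim.genome.sequences[chrom].encode(),
                            dtype=np.uint8).copy()
        for (c, p), s in hom.items():
            if c == chrom:
                arr[p] = ord(s.alt)
        n = int(round(config.coverage_dna * length / rl))
        if n == 0:
            warnings.warn(f"zero DNA coverage on {chrom}", stacklevel=2)
            reads.chroms[chrom] = (np.empty(0, np.int64),
                                   np.empty((0, rl), np.uint8),
                                   np.empty((0, rl), np.uint8))
            continue
        starts = np.sort(rng.integers(0, length - rl + 1, n))
        seqs = arr[starts[:, None] + np.arange(rl)[None, :]].copy()
        for s in het:
            if s.chrom != chrom:
                continue
            lo = np.searchsorted(starts, s.pos0 - rl + 1, "left")
            hi = np.searchsorted(starts, s.pos0, "right")
            for i in range(lo, hi):
                if rng.random() < 0.5:
                    seqs[i, s.pos0 - starts[i]] = ord(s.alt)
        quals = _draw_quals(rng, seqs.shape)
        _apply_errors(seqs, quals, config.error_rate, rng)
        reads.chroms[chrom] = (starts, seqs, quals)
    return reads


@dataclass
class SimulatedSample:
    sample_id: str
    rna_records: list[AlignmentRecord]
    hyper_reads: list[UnalignedRead]
    fpkm: pd.Series
    fragment_counts: pd.Series


def _cigar_for(intervals: list[tuple[int, int]]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        cigar.append(("M", e1 - s1))
        cigar.append(("N", s2 - e1))
    cigar.append(("M", intervals[-1][1] - intervals[-1][0]))
    return cigar


def simulate_sample(sim: SimulatedGenome, truth: TruthTable,
                    config: SimConfig, sample_id: str = "s1",
                    multiplier: float = 1.0,
                    stream: int = 0) -> SimulatedSample:
    """Strand-oriented paired RNA alignments plus hyper reads for a sample.

    Per planted site, each fragment carries G (transcript space) with
    probability ``level * multiplier`` capped at 1; heterozygous SNP alleles
    are drawn per fragment; errors follow the phred-consistent model;
    a configurable fraction of fragments is re-emitted to create duplicates.
    """
    rng = np.random.default_rng([config.seed, 404, stream])
    genome = sim.genome
    rl = config.read_length
    hom = {(s.chrom, s.pos0): s for s in truth.snps if s.genotype == "HOM"}
    het = {(s.chrom, s.pos0): s for s in truth.snps
           if s.genotype == "HET"}
    edits = {(e.chrom, e.pos0): e for e in truth.edits if not e.hyper}
    mutated = {}
    for chrom in config.chrom_lengths:
        arr = np.frombuffer(genome.sequences[chrom].encode(),
                            dtype=np.uint8).copy()
        for (c, p), s in hom.items():
            if c == chrom:
                arr[p] = ord(s.alt)
        mutated[chrom] = arr

    models = sim.models
    total_exonic = sum(m.exonic_length for m in models)
    total_frags = config.coverage_rna * total_exonic / (2 * rl)
    weights = np.exp(rng.normal(0.0, config.abundance_sigma, len(models)))
    weights *= np.array([m.exonic_length for m in models]) / total_exonic
    weights /= weights.sum()
    frag_counts = np.maximum(
        1, np.round(total_frags * weights)).astype(int) \
        if total_frags >= 1 else np.zeros(len(models), int)
    if total_frags < 1:
        warnings.warn("zero RNA coverage requested; no fragments emitted",
                      stacklevel=2)

    records: list[AlignmentRecord] = []
    seq_rows: list[np.ndarray] = []
    frag_no = 0
    for m, n_frag in zip(models, frag_counts):
        arr = mutated[m.chrom]
        gene_edits = [edits[(m.chrom, p)]
                      for (c, p) in edits if c == m.chrom
                      and any(s <= p < e for s, e in m.exons)]
        gene_hets = [het[(m.chrom, p)]
                     for (c, p) in het if c == m.chrom
                     and any(s <= p < e for s, e in m.exons)]
        L = m.exonic_length
        if L < rl:
            continue
        for _ in range(int(n_frag)):
            frag_no += 1
            flen = int(rng.integers(*config.fragment_range))
            flen = min(flen, L)
            t0 = int(rng.integers(0, L - flen + 1))
            g_intervals = transcript_interval_to_genomic(m, t0, t0 + flen)
            g_lo, g_hi = g_intervals[0][0], g_intervals[-1][1]
            overrides: dict[int, int] = {}
            for e in gene_edits:
                if g_lo <= e.pos0 < g_hi and \
                        any(s <= e.pos0 < en for s, en in g_intervals):
                    p_edit = min(1.0, e.level * multiplier)
                    if rng.random() < p_edit:
                        edited_base = "G" if e.strand == "+" else "C"
                        overrides[e.pos0] = ord(edited_base)
            for s in gene_hets:
                if g_lo <= s.pos0 < g_hi and rng.random() < 0.5:
                    overrides[s.pos0] = ord(s.alt)

            def read_record(t_read: int, is_read2: bool,
                            dup_tag: str = "") -> None:
                intervals = transcript_interval_to_genomic(
                    m, t_read, t_read + rl)
                seq = np.concatenate([arr[s:e] for s, e in intervals])
                if overrides:
                    off = 0
                    for s, e in intervals:
                        for p, b in overrides.items():
                            if s <= p < e:
                                seq[off + p - s] = b
                        off += e - s
                if m.strand == "+":
                    is_reverse = not is_read2
                else:
                    is_reverse = is_read2
                rid = f"{sample_id}.frag{frag_no}{dup_tag}"
                records.append(AlignmentRecord(
                    read_id=rid, chrom=m.chrom, start=intervals[0][0],
                    cigar=_cigar_for(intervals),
                    seq="N" * rl,  # filled after vectorized error pass
                    quals=[0] * rl, mapq=60, is_paired=True,
                    is_read1=not is_read2, is_read2=is_read2,
                    is_reverse=is_reverse, is_proper_pair=True,
                    mate_start=-2))
                seq_rows.append(seq)

            t_r2 = t0
            t_r1 = t0 + flen - rl
            read_record(t_r2, True)
            read_record(max(0, t_r1), False)
            records[-2].mate_start = records[-1].start
            records[-1].mate_start = records[-2].start
            if rng.random() < config.duplicate_fraction:
                read_record(t_r2, True, ".dup")
                read_record(max(0, t_r1), False, ".dup")
                records[-2].mate_start = records[-1].start
                records[-1].mate_start = records[-2].start

    if seq_rows:
        seqs = np.vstack(seq_rows)
        quals = _draw_quals(rng, seqs.shape)
        _apply_errors(seqs, quals, config.error_rate, rng)
        for rec, srow, qrow in zip(records, seqs, quals):
            rec.seq = srow.tobytes().decode()
            rec.quals = [int(q) for q in qrow]

    # hyper-edited reads: every read of a cluster carries all cluster edits
    hyper_reads: list[UnalignedRead] = []
    clusters: dict[int, list[PlantedEdit]] = {}
    for e in truth.edits:
        if e.hyper:
            clusters.setdefault(e.cluster_id, []).append(e)
    for cid in sorted(clusters):
        sites = sorted(clusters[cid], key=lambda e: e.pos0)
        chrom = sites[0].chrom
        strand = sites[0].strand
        m = next(mm for mm in models
                 if mm.chrom == chrom and any(
                     s <= sites[0].pos0 < e for s, e in mm.exons))
        es, ee = next((s, e) for s, e in m.exons
                      if s <= sites[0].pos0 < e)
        p_min, p_max = sites[0].pos0, sites[-1].pos0
        w0 = p_min - (rl - (p_max - p_min) - 1) // 2
        w0 = max(max(es, p_max - rl + 1), min(w0, min(p_min, ee - rl)))
        window = list(genome.subsequence(chrom, w0, w0 + rl))
        for site in sites:
            window[site.pos0 - w0] = "G" if strand == "+" else "C"
        base_seq = "".join(window)
        if strand == "-":  # read sequenced on the transcript strand
            base_seq = reverse_complement(base_seq)
        for r in range(config.reads_per_cluster):
            seq_arr = np.frombuffer(base_seq.encode(), np.uint8).copy()
            quals = _draw_quals(rng, (rl,))
            _apply_errors(seq_arr.reshape(1, -1), quals.reshape(1, -1),
                          config.error_rate, rng)
            seq = seq_arr.tobytes().decode()
            if r % 2 == 1:
                seq = reverse_complement(seq)
                quals = quals[::-1]
            hyper_reads.append(UnalignedRead(
                read_id=f"{sample_id}.hyper{cid}.{r}", seq=seq,
                quals=[int(q) for q in quals]))

    gene_ids = [m.gene_id for m in models]
    counts = pd.Series(frag_counts, index=gene_ids, dtype=float)
    exonic_kb = pd.Series([m.exonic_length / 1000 for m in models],
                          index=gene_ids)
    million = max(counts.sum(), 1.0) / 1e6
    fpkm = counts / exonic_kb / million
    return SimulatedSample(sample_id=sample_id, rna_records=records,
                           hyper_reads=hyper_reads, fpkm=fpkm,
                           fragment_counts=counts)


@dataclass
class SimulatedDataset:
    config: SimConfig
    sim_genome: SimulatedGenome
    truth: TruthTable
    dna: DnaReadSet

    @property
    def genome(self) -> Genome:
        return self.sim_genome.genome

    def sample(self, sample_id: str = "s1", multiplier: float = 1.0,
               stream: int = 0) -> SimulatedSample:
        return simulate_sample(self.sim_genome, self.truth, self.config,
                               sample_id=sample_id, multiplier=multiplier,
                               stream=stream)


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Genome + truth + DNA reads for one individual under ``config``."""
    config = config or SimConfig()
    sim = make_genome(config)
    truth = plant_truth(config, sim)
    dna = simulate_dna(sim, truth, config)
    return SimulatedDataset(config, sim, truth, dna)


def write_fastq(reads: Sequence[UnalignedRead] | Sequence[AlignmentRecord],
                path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            rid = getattr(r, "read_id")
            seq = r.seq
            quals = r.quals
            fh.write(f"@{rid}\n{seq}\n+\n"
                     + "".join(chr(q + 33) for q in quals) + "\n")
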