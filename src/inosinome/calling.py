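"""Matched DNA/RNA editing-site calling with a two-stage filter cascade.

The detection logic mirrors the established DNA/RNA comparative strategy for
A-to-I discovery: candidates are gathered under loose evidence thresholds
(mapping quality >= 20, base quality >= 25, any variant read), required to sit
on a deeply covered and completely homozygous genomic position, and then
pushed through a region-dependent stringent stage.  Sites inside Alu elements
keep the loose rules plus a minimal variant-support floor; sites in other
repeats and in unique sequence additionally require high base quality,
distance from read ends, non-duplicate support, a minimum variant frequency,
and clearance of homopolymer, splice-vicinity, indel-vicinity and
multi-mapping checks.

Counts and substitutions are reported in transcript space: evidence from a
minus-strand transcript is complemented, so genomic T->C on the minus strand
is reported as the canonical A-to-G.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol

import numpy as np

from .io_formats import (
    AlignmentRecord,
    Genome,
    IntervalIndex,
    KnownVariantIndex,
    SiteRecord,
    TranscriptModel,
    natural_chrom_key,
)
from .realign import SeedIndex, make_aligner, realignment_unique

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Filter failure codes
LOW_MAPQ = "LOW_MAPQ"
LOW_BASEQUAL = "LOW_BASEQUAL"
READ_END = "READ_END"
HOMOPOLYMER = "HOMOPOLYMER"
NEAR_INDEL = "NEAR_INDEL"
NEAR_SPLICE = "NEAR_SPLICE"
LOW_ALT_SUPPORT = "LOW_ALT_SUPPORT"
LOW_FREQ = "LOW_FREQ"
DNA_NOT_HOM = "DNA_NOT_HOM"
DNA_LOW_COV = "DNA_LOW_COV"
KNOWN_SNP = "KNOWN_SNP"
RETROGENE = "RETROGENE"
MULTIMAP = "MULTIMAP"
DUPLICATE_ONLY = "DUPLICATE_ONLY"

ALL_FILTER_CODES = frozenset({
    LOW_MAPQ, LOW_BASEQUAL, READ_END, HOMOPOLYMER, NEAR_INDEL, NEAR_SPLICE,
    LOW_ALT_SUPPORT, LOW_FREQ, DNA_NOT_HOM, DNA_LOW_COV, KNOWN_SNP,
    RETROGENE, MULTIMAP, DUPLICATE_ONLY,
})


@dataclass
class FilterConfig:
    """Thresholds of the calling cascade.

    Defaults implement the reference cascade: mapping quality floor 20, loose
    base-quality floor 25 and stringent floor 30, 6 bp read-end trim,
    homopolymer runs longer than 5 excluded, indel vicinity of 10 bp, at
    least 10 homozygous genomic reads, variant support of at least 2 reads in
    Alu and 3 elsewhere with frequency at least 0.1 outside Alu.
    """

    min_mapq: int = 20
    loose_min_basequal: int = 25
    stringent_min_basequal: int = 30
    read_end_trim: int = 6
    max_homopolymer: int = 5
    indel_window: int = 10
    min_dna_depth: int = 10
    min_alt_reads_alu: int = 2
    min_alt_reads_nonalu: int = 3
    min_freq_nonalu: float = 0.1
    splice_window: int = 4
    strand_protocol: str = "dUTP-RF"
    dedup: bool = True
    realign_k: int = 11
    realign_score_ratio: float = 0.95
    # whether the 0.1 frequency floor also applies in Alu (off: the stringent
    # branch is non-Alu only)
    apply_freq_to_alu: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_freq_nonalu <= 1.0:
            raise ValueError("min_freq_nonalu must be in [0, 1]")
        for name in ("min_mapq", "loose_min_basequal",
                     "stringent_min_basequal", "read_end_trim",
                     "max_homopolymer", "indel_window", "min_dna_depth",
                     "min_alt_reads_alu", "min_alt_reads_nonalu",
                     "splice_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.strand_protocol not in ("dUTP-RF", "FR", "unstranded"):
            raise ValueError(
                f"unknown strand protocol {self.strand_protocol!r}")


@dataclass
class ReadObservation:
    """One read's evidence at one position."""

    base: str
    qual: int
    read_cycle: int
    read_length: int
    mate: str  # R1 | R2
    transcript_strand: str | None
    dist_to_indel: float
    is_duplicate: bool
    mapq: int
    read_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.read_cycle <= self.read_length:
            raise ValueError(
                f"read_cycle {self.read_cycle} outside 1..{self.read_length}")
        if self.base not in "ACGTN":
            raise ValueError(f"invalid base {self.base!r}")


@dataclass
class PileupColumn:
    chrom: str
    pos0: int
    ref_base: str
    observations: list[ReadObservation] = field(default_factory=list)
    low_mapq_observations: list[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


HOM = "HOM"
HET = "HET"
LOW_COV = "LOW_COV"


@dataclass
class GenotypeCall:
    base: str  # single base for HOM, "X/Y" for HET, majority base otherwise
    depth: int
    status: str


@dataclass
class CandidateSite:
    """A loose-stage DNA/RNA mismatch, expressed in transcript space."""

    chrom: str
    pos0: int
    strand: str
    ref_genomic: str       # genome reference base (genomic space)
    genotype: GenotypeCall
    alt_t: str             # top alternative base, transcript space
    counts_t: dict[str, int]
    level: float
    substitution: str      # e.g. "AG", transcript space
    multiallelic: bool
    column: PileupColumn
    variant_obs: list[ReadObservation]

    @property
    def ref_t(self) -> str:
        return self.substitution[0]


@dataclass
class FilterVerdict:
    site: CandidateSite
    failures: frozenset[str]

    @property
    def passed(self) -> bool:
        return not self.failures


# ---------------------------------------------------------------------------
# Strand assignment


def assign_transcript_strand(record: AlignmentRecord,
                             protocol: str = "dUTP-RF") -> str | None:
    """Transcript strand of the fragment a read came from.

    dUTP-RF (TruSeq stranded): read 2 maps on the transcript strand, so a
    forward-mapped R2 means '+' and its R1 mate the complement.  FR is the
    mirror image.  Unstranded returns None (strand imputed downstream from
    the mismatch pattern).
    """
    if record.is_unmapped:
        raise ValueError("cannot assign strand to an unmapped record")
    if protocol == "unstranded":
        return None
    if protocol not in ("dUTP-RF", "FR"):
        raise ValueError(f"unknown protocol {protocol!r}")
    second = record.is_read2
    forward = not record.is_reverse
    if protocol == "dUTP-RF":
        return "+" if second == forward else "-"
    return "+" if (not second) == forward else "-"


def read_cycle_of(record: AlignmentRecord, query_index: int) -> int:
    """1-based cycle in original sequencing orientation."""
    if record.is_reverse:
        return len(record.seq) - query_index
    return query_index + 1


def dist_to_indel_of(record: AlignmentRecord, pos0: int) -> float:
    positions = record.indel_ref_positions()
    if not positions:
        return math.inf
    return min(abs(pos0 - p) for p in positions)


# ---------------------------------------------------------------------------
# Duplicate marking


def mark_duplicates(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag duplicates when the input carries no duplicate flags.

    Duplicates share (chrom, start, orientation, mate start); within a group
    the read with the highest summed base quality is kept, deterministic
    tie-break on read id.  Records already flagged anywhere are returned
    unchanged.
    """
    if any(r.is_duplicate for r in records):
        return records
    groups: dict[tuple, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        groups[(r.chrom, r.start, r.is_reverse, r.is_read2,
                r.mate_start)].append(r)
    out = []
    for group in groups.values():
        group.sort(key=lambda r: (-sum(r.quals), r.read_id))
        out.append(group[0])
        for r in group[1:]:
            out.append(replace(r, is_duplicate=True))
    out.sort(key=lambda r: (natural_chrom_key(r.chrom), r.start, r.read_id))
    return out


# ---------------------------------------------------------------------------
# Pileup


def build_pileup(records: Iterable[AlignmentRecord], chrom: str, pos0: int,
                 genome: Genome, config: FilterConfig) -> PileupColumn:
    """Collect per-read observations M-aligned over one position.

    Records below the mapping-quality floor are kept apart (they may still
    explain a rejected candidate); overlapping mates contribute a single
    observation, keeping the mate with the higher base quality at the
    position (ties keep read 2, which lies on the transcript strand).
    """
    ref_base = genome.base(chrom, pos0)
    column = PileupColumn(chrom, pos0, ref_base)
    by_read: dict[str, ReadObservation] = {}
    low_by_read: dict[str, ReadObservation] = {}
    for rec in records:
        if rec.is_unmapped or rec.chrom != chrom:
            continue
        if not rec.start <= pos0 < rec.end:
            continue
        qi = rec.query_index_at(pos0)
        if qi is None:
            continue
        obs = ReadObservation(
            base=rec.seq[qi],
            qual=rec.quals[qi],
            read_cycle=read_cycle_of(rec, qi),
            read_length=len(rec.seq),
            mate="R2" if rec.is_read2 else "R1",
            transcript_strand=assign_transcript_strand(
                rec, config.strand_protocol),
            dist_to_indel=dist_to_indel_of(rec, pos0),
            is_duplicate=rec.is_duplicate,
            mapq=rec.mapq,
            read_id=rec.read_id,
        )
        target = by_read if rec.mapq >= config.min_mapq else low_by_read
        prev = target.get(rec.read_id)
        if prev is None or (obs.qual, obs.mate == "R2") > (prev.qual,
                                                           prev.mate == "R2"):
            target[rec.read_id] = obs
    column.observations = list(by_read.values())
    column.low_mapq_observations = list(low_by_read.values())
    return column


# ---------------------------------------------------------------------------
# Genotyping


def call_dna_genotype(column: PileupColumn,
                      config: FilterConfig) -> GenotypeCall:
    """Genotype a genomic pileup: >= 10 reads and completely homozygous.

    Homozygosity is strict: any second allele among quality-passing reads
    makes the call HET.  Depth below ``min_dna_depth`` is LOW_COV.
    """
    obs = [o for o in column.observations
           if o.qual >= config.loose_min_basequal and o.base != "N"]
    depth = len(obs)
    counts = Counter(o.base for o in obs)
    if depth < config.min_dna_depth:
        base = counts.most_common(1)[0][0] if counts else column.ref_base
        return GenotypeCall(base, depth, LOW_COV)
    if len(counts) == 1:
        return GenotypeCall(next(iter(counts)), depth, HOM)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
    return GenotypeCall("/".join(sorted(b for b, _ in top)), depth, HET)


class GenotypeSource(Protocol):
    def genotype(self, chrom: str, pos0: int) -> GenotypeCall: ...


class AlignmentGenotypeSource:
    """Genotypes computed on demand from DNA alignment records."""

    def __init__(self, records: list[AlignmentRecord], genome: Genome,
                 config: FilterConfig | None = None,
                 bucket: int = 1024) -> None:
        self.genome = genome
        self.config = config or FilterConfig()
        self._bucket = bucket
        self._index: dict[tuple[str, int], list[AlignmentRecord]] = \
            defaultdict(list)
        for r in records:
            for b in range(r.start // bucket, (r.end - 1) // bucket + 1):
                self._index[(r.chrom, b)].append(r)

    def fetch(self, chrom: str, pos0: int) -> list[AlignmentRecord]:
        return [r for r in self._index.get((chrom, pos0 // self._bucket), [])
                if r.start <= pos0 < r.end]

    def genotype(self, chrom: str, pos0: int) -> GenotypeCall:
        column = build_pileup(self.fetch(chrom, pos0), chrom, pos0,
                              self.genome, self.config)
        return call_dna_genotype(column, self.config)


class TableGenotypeSource:
    """Genotypes from a precomputed table; absent positions are LOW_COV."""

    def __init__(self, table: dict[tuple[str, int],
                                   tuple[str, int, str]]) -> None:
        self._table = table

    @classmethod
    def from_tsv(cls, path: str) -> "TableGenotypeSource":
        table = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["chrom", "pos", "genotype", "depth", "status"]:
                raise ValueError(f"{path}: unexpected genotype-table header")
            for line in fh:
                chrom, pos, base, depth, status = \
                    line.rstrip("\n").split("\t")
                table[(chrom, int(pos) - 1)] = (base, int(depth), status)
        return cls(table)

    def genotype(self, chrom: str, pos0: int) -> GenotypeCall:
        entry = self._table.get((chrom, pos0))
        if entry is None:
            return GenotypeCall("N", 0, LOW_COV)
        return GenotypeCall(*entry)


def write_genotype_table(table: dict[tuple[str, int], tuple[str, int, str]],
                         path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tgenotype\tdepth\tstatus\n")
        for (chrom, pos0), (base, depth, status) in sorted(table.items()):
            fh.write(f"{chrom}\t{pos0 + 1}\t{base}\t{depth}\t{status}\n")


# ---------------------------------------------------------------------------
# Candidate detection


def _transcript_base(base: str, strand: str) -> str:
    return _COMP[base] if strand == "-" else base


def detect_candidate(rna_column: PileupColumn, genotype: GenotypeCall,
                     config: FilterConfig) -> CandidateSite | None:
    """Loose-stage candidate at a homozygous position, in transcript space.

    Counts are tallied on the transcript strand (minus-strand evidence is
    complemented, so genomic T->C becomes A-to-G).  A candidate needs at
    least one non-genotype base at loose base quality.
    """
    if genotype.status != HOM:
        raise ValueError("detect_candidate requires a HOM genotype "
                         "(pre-filter HET/LOW_COV positions)")
    obs = [o for o in rna_column.observations
           if o.qual >= config.loose_min_basequal and o.base != "N"]
    if not obs:
        return None
    strand_votes = Counter(o.transcript_strand for o in obs
                           if o.transcript_strand is not None)
    if strand_votes:
        strand = max(strand_votes.items(), key=lambda kv: (kv[1],
                                                           kv[0]))[0]
        obs = [o for o in obs if o.transcript_strand in (strand, None)]
    else:
        # unstranded: impute from the mismatch pattern (an excess of C over
        # the genotype T reads as A-to-G on the minus strand)
        counts_g = Counter(o.base for o in obs)
        counts_g.pop(genotype.base, None)
        top = max(counts_g.items(), key=lambda kv: (kv[1], kv[0]),
                  default=None)
        strand = "-" if top and (genotype.base, top[0]) in (
            ("T", "C"), ("G", "A"), ("C", "T"), ("A", "G")) and \
            genotype.base in "TG" else "+"
    counts_t: dict[str, int] = {"A": 0, "C": 0, "G": 0, "T": 0}
    for o in obs:
        counts_t[_transcript_base(o.base, strand)] += 1
    ref_t = _transcript_base(genotype.base, strand)
    alts = [(b, c) for b, c in counts_t.items() if b != ref_t and c > 0]
    if not alts:
        return None
    alts.sort(key=lambda bc: (-bc[1], bc[0]))
    alt_t = alts[0][0]
    denom = counts_t[ref_t] + counts_t[alt_t]
    level = counts_t[alt_t] / denom if denom else 0.0
    alt_genomic = _transcript_base(alt_t, strand)
    variant_obs = [o for o in obs if o.base == alt_genomic]
    return CandidateSite(
        chrom=rna_column.chrom,
        pos0=rna_column.pos0,
        strand=strand,
        ref_genomic=rna_column.ref_base,
        genotype=genotype,
        alt_t=alt_t,
        counts_t=counts_t,
        level=level,
        substitution=ref_t + alt_t,
        multiallelic=len(alts) > 1,
        column=rna_column,
        variant_obs=variant_obs,
    )


# ---------------------------------------------------------------------------
# Individual filters


def homopolymer_run_length(genome: Genome, chrom: str, pos0: int) -> int:
    """Length of the maximal single-base run containing ``pos0``."""
    seq = genome.sequences[chrom]
    base = seq[pos0]
    left = pos0
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos0
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1


def splice_window_index(transcripts: Iterable[TranscriptModel],
                        window: int = 4) -> IntervalIndex:
    """Intronic windows of ``window`` nt flanking every annotated junction."""
    index = IntervalIndex()
    for t in transcripts:
        for intron_start, intron_end in t.introns():
            donor_end = min(intron_start + window, intron_end)
            index.add(t.chrom, intron_start, donor_end, "splice", t.strand)
            acceptor_start = max(intron_end - window, intron_start)
            if acceptor_start > donor_end:
                index.add(t.chrom, acceptor_start, intron_end, "splice",
                          t.strand)
    return index


ALU = "ALU"
REP_NON_ALU = "REP_NON_ALU"
NONREP = "NONREP"


@dataclass
class CallContext:
    """Everything apply_filters needs beyond the candidate itself."""

    genome: Genome
    repeat_class: str = NONREP
    known_variants: KnownVariantIndex | None = None
    retro_index: IntervalIndex | None = None
    splice_index: IntervalIndex | None = None
    seed_index: SeedIndex | None = None
    read_lookup: dict[str, list[AlignmentRecord]] | None = None
    nearby_indel_positions: list[int] = field(default_factory=list)
    uniqueness_cache: dict[str, bool] = field(default_factory=dict)

    def pair_unique(self, read_id: str, config: FilterConfig) -> bool:
        """Both mates of the pair place uniquely (cached per read id)."""
        if read_id in self.uniqueness_cache:
            return self.uniqueness_cache[read_id]
        records = (self.read_lookup or {}).get(read_id, [])
        if not records or self.seed_index is None:
            verdict = True
        else:
            aligner = make_aligner()
            verdict = all(
                realignment_unique(r, self.genome, self.seed_index,
                                   score_ratio=config.realign_score_ratio,
                                   aligner=aligner)
                for r in records)
        self.uniqueness_cache[read_id] = verdict
        return verdict


def apply_filters(candidate: CandidateSite, context: CallContext,
                  config: FilterConfig) -> FilterVerdict:
    """Region-dependent stringent cascade on a loose-stage candidate.

    All regions: indel vicinity, known SNP, retrogene, minimal variant
    support, and (when everything else passes) the realignment-uniqueness
    check.  Non-Alu regions additionally restrict variant evidence to
    quality >= 30, cycles outside the first/last 6, non-duplicate reads, and
    require >= 3 variant reads at frequency >= 0.1 away from homopolymers
    and splice junctions.
    """
    if not context.repeat_class:
        raise ValueError("candidate has no repeat class")
    failures: set[str] = set()
    chrom, pos0 = candidate.chrom, candidate.pos0

    if candidate.genotype.status == LOW_COV:
        failures.add(DNA_LOW_COV)
    elif candidate.genotype.status == HET:
        failures.add(DNA_NOT_HOM)

    alt_genomic = _transcript_base(candidate.alt_t, candidate.strand)
    if context.known_variants is not None and (
            candidate.ref_genomic, alt_genomic) in \
            context.known_variants.alleles_at(chrom, pos0):
        failures.add(KNOWN_SNP)
    if context.retro_index is not None and context.retro_index.at(chrom,
                                                                  pos0):
        failures.add(RETROGENE)

    variant_obs = candidate.variant_obs
    if any(o.dist_to_indel <= config.indel_window for o in variant_obs) or \
            any(abs(pos0 - p) <= config.indel_window
                for p in context.nearby_indel_positions):
        failures.add(NEAR_INDEL)

    in_alu = context.repeat_class == ALU

    if in_alu:
        restricted = variant_obs
        if len(restricted) < config.min_alt_reads_alu:
            failures.add(LOW_ALT_SUPPORT)
        if config.apply_freq_to_alu and candidate.column.depth and \
                len(restricted) / candidate.column.depth < \
                config.min_freq_nonalu:
            failures.add(LOW_FREQ)
    else:
        q30 = [o for o in variant_obs
               if o.qual >= config.stringent_min_basequal]
        if variant_obs and not q30:
            failures.add(LOW_BASEQUAL)
        trim = config.read_end_trim

        def mid_read(o: ReadObservation) -> bool:
            return trim < o.read_cycle <= o.read_length - trim

        ends = [o for o in variant_obs if mid_read(o)]
        if variant_obs and not ends:
            failures.add(READ_END)
        nondup = [o for o in variant_obs if not o.is_duplicate]
        if variant_obs and not nondup:
            failures.add(DUPLICATE_ONLY)
        restricted = [o for o in q30 if mid_read(o) and not o.is_duplicate]
        if len(restricted) < config.min_alt_reads_nonalu:
            failures.add(LOW_ALT_SUPPORT)
        stringent_depth = sum(
            1 for o in candidate.column.observations
            if o.qual >= config.stringent_min_basequal and mid_read(o)
            and not o.is_duplicate and o.base != "N")
        if restricted and stringent_depth and \
                len(restricted) / stringent_depth < config.min_freq_nonalu:
            failures.add(LOW_FREQ)
        if homopolymer_run_length(context.genome, chrom, pos0) > \
                config.max_homopolymer:
            failures.add(HOMOPOLYMER)
        if context.splice_index is not None and context.splice_index.at(
                chrom, pos0):
            failures.add(NEAR_SPLICE)

    # The realignment check is the most expensive filter, so it runs last and
    # only when the candidate would otherwise pass (sequential cascade, as in
    # the reference pipeline).
    if not failures and restricted:
        surviving = [o for o in restricted
                     if context.pair_unique(o.read_id, config)]
        if not surviving:
            failures.add(MULTIMAP)

    return FilterVerdict(candidate, frozenset(failures))


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class CallAnnotations:
    """Annotation bundle for a calling run."""

    repeat_index: IntervalIndex | None = None
    known_variants: KnownVariantIndex | None = None
    retro_index: IntervalIndex | None = None
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def repeat_class_at(self, chrom: str, pos0: int) -> str:
        if self.repeat_index is None:
            return NONREP
        labels = [label for _, _, label, _ in
                  self.repeat_index.at(chrom, pos0)]
        if any(label.startswith("Alu") for label in labels):
            return ALU
        if labels:
            return REP_NON_ALU
        return NONREP


def _genome_arrays(genome: Genome) -> dict[str, np.ndarray]:
    return {name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in genome.sequences.items()}


def find_mismatch_positions(records: Iterable[AlignmentRecord],
                            genome: Genome) -> set[tuple[str, int]]:
    """Positions where any M-aligned read base differs from the reference."""
    arrays = _genome_arrays(genome)
    out: set[tuple[str, int]] = set()
    for rec in records:
        if rec.is_unmapped or rec.chrom not in arrays:
            continue
        ref = arrays[rec.chrom]
        q, r = 0, rec.start
        seq = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
        for op, n in rec.cigar:
            if op == "M":
                diff = np.nonzero(seq[q:q + n] != ref[r:r + n])[0]
                for d in diff:
                    out.add((rec.chrom, r + int(d)))
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n
    return out


class _ReadIndex:
    """Bucketed interval lookup over alignment records."""

    def __init__(self, records: list[AlignmentRecord],
                 bucket: int = 1024) -> None:
        self._bucket = bucket
        self._buckets: dict[tuple[str, int], list[AlignmentRecord]] = \
            defaultdict(list)
        for r in records:
            if r.is_unmapped:
                continue
            for b in range(r.start // bucket, max(r.start, r.end - 1)
                           // bucket + 1):
                self._buckets[(r.chrom, b)].append(r)

    def fetch(self, chrom: str, start: int, end: int) \
            -> list[AlignmentRecord]:
        seen: set[int] = set()
        out = []
        for b in range(start // self._bucket, max(start, end - 1)
                       // self._bucket + 1):
            for r in self._buckets.get((chrom, b), ()):
                if id(r) not in seen and r.start < end and r.end > start:
                    seen.add(id(r))
                    out.append(r)
        return out


def evaluate_position(column: PileupColumn, genotype: GenotypeCall,
                      context: CallContext, config: FilterConfig,
                      sample_id: str = "") -> SiteRecord | None:
    """Run genotype gate, candidate detection and filters at one position.

    Returns a SiteRecord (PASS or carrying failure codes) or None when the
    position shows no variant evidence at all.
    """
    def rejected(code: str, strand: str = "+", substitution: str = "",
                 counts: dict[str, int] | None = None,
                 level: float = 0.0) -> SiteRecord:
        counts = counts or {"A": 0, "C": 0, "G": 0, "T": 0}
        return SiteRecord(
            chrom=column.chrom, pos0=column.pos0, strand=strand,
            ref_base=_transcript_base(column.ref_base, strand),
            dna_depth=genotype.depth, dna_genotype=genotype.base,
            rna_depth=sum(counts.values()), base_counts=counts,
            editing_level=level, substitution=substitution or ".",
            filter_flags=frozenset({code}), source="MAIN",
            sample_id=sample_id)

    if genotype.status in (HET, LOW_COV):
        # the traversal only reaches positions with RNA/reference mismatch
        # evidence, so a non-homozygous or shallow genomic position is
        # reported with its failure code
        code = DNA_NOT_HOM if genotype.status == HET else DNA_LOW_COV
        return rejected(code)

    candidate = detect_candidate(column, genotype, config)
    if candidate is None:
        low_mapq_mismatch = [o for o in column.low_mapq_observations
                             if o.base not in (genotype.base, "N")]
        low_qual_mismatch = [o for o in column.observations
                             if o.base not in (genotype.base, "N")
                             and o.qual < config.loose_min_basequal]
        if low_mapq_mismatch:
            return rejected(LOW_MAPQ)
        if low_qual_mismatch:
            return rejected(LOW_BASEQUAL)
        return None

    verdict = apply_filters(candidate, context, config)
    flags = verdict.failures
    return SiteRecord(
        chrom=candidate.chrom, pos0=candidate.pos0, strand=candidate.strand,
        ref_base=candidate.ref_t, dna_depth=genotype.depth,
        dna_genotype=genotype.base, rna_depth=sum(
            candidate.counts_t.values()),
        base_counts=dict(candidate.counts_t),
        editing_level=candidate.level, substitution=candidate.substitution,
        repeat_class=context.repeat_class,
        filter_flags=flags, source="MAIN", sample_id=sample_id)


def call_sites(rna_records: list[AlignmentRecord],
               dna_source: GenotypeSource | list[AlignmentRecord],
               genome: Genome,
               annotations: CallAnnotations | None = None,
               config: FilterConfig | None = None,
               emit_rejected: bool = False,
               sample_id: str = "",
               seed_index: SeedIndex | None = None) -> list[SiteRecord]:
    """End-to-end calling: pileup -> genotype -> candidate -> filters.

    ``dna_source`` may be DNA alignment records or any object with a
    ``genotype(chrom, pos0)`` method (e.g. a precomputed table).  Output is
    deterministic: positions are traversed in natural chromosome order.
    """
    config = config or FilterConfig()
    annotations = annotations or CallAnnotations()
    for rec in rna_records:
        if rec.chrom not in genome:
            raise ValueError(f"alignment on unknown chromosome "
                             f"{rec.chrom!r}; reference mismatch?")
    if isinstance(dna_source, list):
        dna_source = AlignmentGenotypeSource(dna_source, genome, config)
    if config.dedup:
        rna_records = mark_duplicates(rna_records)

    candidates = sorted(find_mismatch_positions(rna_records, genome),
                        key=lambda cp: (natural_chrom_key(cp[0]), cp[1]))
    read_index = _ReadIndex(rna_records)
    read_lookup: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in rna_records:
        read_lookup[r.read_id].append(r)
    if seed_index is None and candidates:
        seed_index = SeedIndex(genome, k=config.realign_k)
    splice_index = splice_window_index(annotations.transcripts,
                                       config.splice_window) \
        if annotations.transcripts else None
    uniqueness_cache: dict[str, bool] = {}

    out: list[SiteRecord] = []
    tallies: Counter[str] = Counter()
    for chrom, pos0 in candidates:
        reads_here = read_index.fetch(chrom, pos0, pos0 + 1)
        column = build_pileup(reads_here, chrom, pos0, genome, config)
        genotype = dna_source.genotype(chrom, pos0)
        nearby = read_index.fetch(chrom, max(0, pos0 - config.indel_window),
                                  pos0 + config.indel_window + 1)
        indel_positions = sorted({p for r in nearby
                                  for p in r.indel_ref_positions()})
        context = CallContext(
            genome=genome,
            repeat_class=annotations.repeat_class_at(chrom, pos0),
            known_variants=annotations.known_variants,
            retro_index=annotations.retro_index,
            splice_index=splice_index,
            seed_index=seed_index,
            read_lookup=read_lookup,
            nearby_indel_positions=indel_positions,
            uniqueness_cache=uniqueness_cache,
        )
        site = evaluate_position(column, genotype, context, config,
                                 sample_id=sample_id)
        if site is None:
            continue
        site.repeat_class = site.repeat_class or context.repeat_class
        if site.passed:
            tallies["PASS"] += 1
            out.append(site)
        else:
            for code in site.filter_flags:
                tallies[code] += 1
            if emit_rejected:
                out.append(site)
    logger.info("call_sites: %d candidate positions, tallies: %s",
                len(candidates), dict(sorted(tallies.items())))
    return out
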