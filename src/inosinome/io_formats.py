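"""Domain types and readers/writers for the standard formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  The only 1-based surfaces are
serialized site tables and log messages, converted at a single point
(:func:`write_site_table` / :func:`read_site_table`), so that coordinate
arithmetic everywhere else never mixes conventions.
"""

from __future__ import annotations

import re
import sys
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

_IUPAC_AMBIGUITY = set("RYSWKMBDHV")
_VALID_BASES = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class Genome:
    """Reference sequences, uppercase, keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def subsequence(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)``; out-of-range is an error."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"{chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def base(self, chrom: str, pos0: int) -> str:
        return self.subsequence(chrom, pos0, pos0 + 1)


def read_fasta(path: str) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Sequences are uppercased; the chromosome name is the header token before
    the first whitespace.  IUPAC ambiguity codes are collapsed to ``N``; any
    other character is a :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad - _IUPAC_AMBIGUITY:
            raise FormatError(
                f"record {record.id!r} contains non-IUPAC characters "
                f"{sorted(bad - _IUPAC_AMBIGUITY)}"
            )
        if bad:
            seq = re.sub(f"[{''.join(sorted(_IUPAC_AMBIGUITY))}]", "N", seq)
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class AlignmentRecord:
    """One aligned read — the unit of evidence for calling.

    ``cigar`` is a list of ``(op, length)`` with op in ``MIDNSH``; ``start`` is
    the 0-based leftmost reference position.  ``seq``/``quals`` are stored in
    reference orientation, as in SAM.
    """

    read_id: str
    chrom: str
    start: int
    cigar: list[tuple[str, int]]
    seq: str
    quals: list[int]
    mapq: int = 60
    is_paired: bool = True
    is_read1: bool = True
    is_read2: bool = False
    is_reverse: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False
    is_proper_pair: bool = True
    mate_start: int = -1

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            qlen = sum(n for op, n in self.cigar if op in "MIS")
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.read_id}: CIGAR query length {qlen} != seq length "
                    f"{len(self.seq)}"
                )
        if len(self.quals) != len(self.seq):
            raise ValueError(f"{self.read_id}: {len(self.quals)} quals for "
                             f"{len(self.seq)} bases")
        if self.start < 0 and not self.is_unmapped:
            raise ValueError(f"{self.read_id}: negative start")

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + sum(n for op, n in self.cigar if op in "MDN")

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield ``(query_index, ref_pos)`` for every M-aligned base."""
        q, r = 0, self.start
        for op, n in self.cigar:
            if op == "M":
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n
            # H consumes neither

    def query_index_at(self, pos0: int) -> int | None:
        """Query index of the base M-aligned to ``pos0``, or None."""
        q, r = 0, self.start
        for op, n in self.cigar:
            if op == "M":
                if r <= pos0 < r + n:
                    return q + (pos0 - r)
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                if op == "D" and r <= pos0 < r + n:
                    return None
                r += n
        return None

    def indel_ref_positions(self) -> list[int]:
        """Reference positions adjacent to I/D operations in this alignment."""
        out: list[int] = []
        r = self.start
        for op, n in self.cigar:
            if op == "I":
                out.append(r)  # insertion sits between r-1 and r
            elif op == "D":
                out.extend((r, r + n - 1))
                r += n
            elif op in "MN":
                r += n
        return out


_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_DUP = 0x400

_CIGAR_OPS = "MIDNSHP=X"


def _from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [(_CIGAR_OPS[op], n) for op, n in (a.cigartuples or [])]
    return AlignmentRecord(
        read_id=a.query_name,
        chrom=a.reference_name or "*",
        start=a.reference_start if a.reference_start is not None else 0,
        cigar=cigar,
        seq=a.query_sequence or "",
        quals=list(a.query_qualities or []),
        mapq=a.mapping_quality,
        is_paired=a.is_paired,
        is_read1=a.is_read1 or not a.is_paired,
        is_read2=a.is_read2,
        is_reverse=a.is_reverse,
        is_duplicate=a.is_duplicate,
        is_unmapped=a.is_unmapped,
        is_proper_pair=a.is_proper_pair,
        mate_start=a.next_reference_start if a.is_paired else -1,
    )


def read_sam(path: str) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into in-memory records (mapped records only)."""
    records = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            records.append(_from_pysam(a))
    return records


def write_sam(records: Iterable[AlignmentRecord], lengths: dict[str, int],
              path: str) -> None:
    """Write records as plain-text SAM with an @SQ header from ``lengths``."""
    names = list(lengths)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": lengths[n]} for n in names]}
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals))
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            flag = 0
            if r.is_paired:
                flag |= _FLAG_PAIRED
                flag |= _FLAG_READ1 if r.is_read1 else 0
                flag |= _FLAG_READ2 if r.is_read2 else 0
                if r.is_proper_pair:
                    flag |= _FLAG_PROPER
            if r.is_reverse:
                flag |= _FLAG_REVERSE
            if r.is_duplicate:
                flag |= _FLAG_DUP
            a.flag = flag
            if r.is_paired and r.mate_start >= 0:
                a.next_reference_id = tid[r.chrom]
                a.next_reference_start = r.mate_start
            out.write(a)


# ---------------------------------------------------------------------------
# Intervals


@dataclass
class IntervalIndex:
    """Per-chromosome interval sets with stabbing/overlap queries.

    Intervals are 0-based half-open; each carries ``(label, strand)``.
    Backed by :mod:`intervaltree`; equivalence with a brute-force linear scan
    is asserted in the test suite.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, label: str,
            strand: str = ".") -> None:
        if start > end:
            raise FormatError(f"{chrom}:{start}-{end}: start > end")
        if start == end:
            return
        self.trees.setdefault(chrom, IntervalTree()).addi(
            start, end, (label, strand))

    def at(self, chrom: str, pos0: int) -> list[tuple[int, int, str, str]]:
        """Intervals with ``start <= pos0 < end``."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data[0], iv.data[1])
                      for iv in tree.at(pos0))

    def overlapping(self, chrom: str, start: int,
                    end: int) -> list[tuple[int, int, str, str]]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data[0], iv.data[1])
                      for iv in tree.overlap(start, end))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def read_intervals(path: str, fmt: str = "BED",
                   genome: Genome | None = None) -> IntervalIndex:
    """Read a BED file or the feature rows of a GTF into an IntervalIndex.

    BED is taken as 0-based half-open; GTF rows are 1-based inclusive and are
    converted on read.  GTF intervals are labelled ``feature`` and carry the
    attribute string's gene_id/transcript_id appended as ``feature:gene_id``.
    Intervals on chromosomes absent from ``genome`` (when given) are skipped
    with a warning, since real annotation files carry alt contigs.
    """
    if fmt not in ("BED", "GTF"):
        raise ValueError(f"unknown interval format {fmt!r}")
    index = IntervalIndex()
    skipped: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "BED":
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else "."
                strand = fields[5] if len(fields) > 5 else "."
            else:
                chrom = fields[0]
                feature = fields[2]
                start, end = int(fields[3]) - 1, int(fields[4])
                strand = fields[6]
                attrs = parse_gtf_attributes(fields[8]) if len(fields) > 8 else {}
                label = feature
                if "gene_id" in attrs:
                    label = f"{feature}:{attrs['gene_id']}"
            if genome is not None and chrom not in genome:
                skipped.add(chrom)
                continue
            index.add(chrom, start, end, label, strand)
    if skipped:
        warnings.warn(
            f"{path}: skipped intervals on unknown chromosomes "
            f"{sorted(skipped)}", stacklevel=2)
    return index


def write_bed(intervals: Iterable[tuple[str, int, int, str, str]],
              path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Gene models


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


@dataclass
class TranscriptModel:
    """One transcript: sorted non-overlapping exons, optional CDS."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise FormatError(
                    f"{self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def cds_complete(self) -> bool:
        """True when the CDS length is a whole number of codons."""
        return bool(self.cds) and self.cds_length % 3 == 0

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons,
                                                     self.exons[1:])]

    def genomic_to_transcript(self, pos0: int) -> int | None:
        """Transcript-space offset (5'->3') of a genomic position, or None."""
        off = 0
        for s, e in self.exons:
            if s <= pos0 < e:
                t = off + (pos0 - s)
                if self.strand == "-":
                    return self.exonic_length - 1 - t
                return t
            off += e - s
        return None

    def transcript_to_genomic(self, t: int) -> int:
        if not 0 <= t < self.exonic_length:
            raise IndexError(f"{self.transcript_id}: offset {t} out of range")
        if self.strand == "-":
            t = self.exonic_length - 1 - t
        for s, e in self.exons:
            if t < e - s:
                return s + t
            t -= e - s
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: Genome) -> str:
        seq = "".join(genome.subsequence(self.chrom, s, e)
                      for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def cds_sequence(self, genome: Genome) -> str:
        seq = "".join(genome.subsequence(self.chrom, s, e)
                      for s, e in self.cds)
        return reverse_complement(seq) if self.strand == "-" else seq


def read_transcripts(path: str,
                     genome: Genome | None = None) -> list[TranscriptModel]:
    """Build transcript models from the exon/CDS rows of a GTF file."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    skipped: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attr = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            if genome is not None and chrom not in genome:
                skipped.add(chrom)
                continue
            attrs = parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id", "")
            if not tid:
                raise FormatError(f"{path}: {feature} row without "
                                  "transcript_id")
            meta.setdefault(tid, (attrs.get("gene_id", tid), chrom, strand,
                                  attrs.get("gene_biotype",
                                            attrs.get("transcript_biotype",
                                                      "protein_coding"))))
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
    if skipped:
        warnings.warn(f"{path}: skipped features on unknown chromosomes "
                      f"{sorted(skipped)}", stacklevel=2)
    models = []
    for tid, ex in exons.items():
        gene_id, chrom, strand, biotype = meta[tid]
        models.append(TranscriptModel(tid, gene_id, chrom, strand, ex,
                                      cds.get(tid, []), biotype))
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def write_transcripts_gtf(models: Iterable[TranscriptModel],
                          path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (f'gene_id "{m.gene_id}"; transcript_id '
                     f'"{m.transcript_id}"; gene_biotype "{m.biotype}";')
            rows = [("exon", s, e) for s, e in m.exons]
            rows += [("CDS", s, e) for s, e in m.cds]
            for feature, s, e in rows:
                fh.write("\t".join([m.chrom, "inosinome", feature,
                                    str(s + 1), str(e), ".", m.strand, ".",
                                    attrs]) + "\n")


# ---------------------------------------------------------------------------
# Known variants (VCF, read-only, CHROM/POS/REF/ALT)


class KnownVariantIndex:
    """Known germline variants keyed by (chrom, pos0) -> {(ref, alt), ...}."""

    def __init__(self) -> None:
        self._sites: dict[tuple[str, int], set[tuple[str, str]]] = {}

    def add(self, chrom: str, pos0: int, ref: str, alt: str) -> None:
        self._sites.setdefault((chrom, pos0), set()).add((ref, alt))

    def alleles_at(self, chrom: str, pos0: int) -> set[tuple[str, str]]:
        return self._sites.get((chrom, pos0), set())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._sites

    def __len__(self) -> int:
        return len(self._sites)


def read_vcf(path: str) -> KnownVariantIndex:
    """Read SNV records from a VCF into a :class:`KnownVariantIndex`.

    Only CHROM/POS/REF/ALT are used; multi-allelic rows contribute one entry
    per ALT; non-SNV alleles are ignored.
    """
    index = KnownVariantIndex()
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt != ".":
                    index.add(rec.chrom, rec.pos - 1, rec.ref, alt)
    return index


def write_vcf(variants: Iterable[tuple[str, int, str, str]],
              lengths: dict[str, int], path: str) -> None:
    """Write SNVs as a minimal VCF (pos0 converted to 1-based POS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, ln in lengths.items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in sorted(variants):
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Site tables


@dataclass
class SiteRecord:
    """One called editing site with evidence, verdicts and annotations."""

    chrom: str
    pos0: int
    strand: str
    ref_base: str
    dna_depth: int
    dna_genotype: str
    rna_depth: int
    base_counts: dict[str, int]
    editing_level: float
    substitution: str
    repeat_class: str = ""
    genic_context: str = ""
    filter_flags: frozenset[str] = frozenset()
    source: str = "MAIN"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError("negative position")
        self.filter_flags = frozenset(self.filter_flags)

    @property
    def pos_1based(self) -> int:
        return self.pos0 + 1

    @property
    def passed(self) -> bool:
        return not self.filter_flags

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos0, self.strand)


SITE_TABLE_COLUMNS = [
    "chrom", "pos", "strand", "ref", "dna_depth", "dna_genotype",
    "rna_depth", "counts_A", "counts_C", "counts_G", "counts_T",
    "editing_level", "substitution", "repeat_class", "genic_context",
    "filters", "source", "sample_id",
]


def write_site_table(records: Iterable[SiteRecord], path: str) -> None:
    """Serialize site records as TSV with 1-based positions.

    The filters column is ``PASS`` for an empty flag set, otherwise the
    comma-joined sorted failure codes.  Floats use repr precision so the
    round trip is lossless.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for r in records:
            filters = ",".join(sorted(r.filter_flags)) or "PASS"
            row = [
                r.chrom, str(r.pos_1based), r.strand, r.ref_base,
                str(r.dna_depth), r.dna_genotype, str(r.rna_depth),
                str(r.base_counts.get("A", 0)), str(r.base_counts.get("C", 0)),
                str(r.base_counts.get("G", 0)), str(r.base_counts.get("T", 0)),
                repr(float(r.editing_level)), r.substitution,
                r.repeat_class or ".", r.genic_context or ".", filters,
                r.source, r.sample_id or ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_site_table(path: str) -> list[SiteRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_TABLE_COLUMNS:
            raise FormatError(f"{path}: unexpected site-table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            row = dict(zip(SITE_TABLE_COLUMNS, f))
            flags = (frozenset() if row["filters"] == "PASS"
                     else frozenset(row["filters"].split(",")))
            records.append(SiteRecord(
                chrom=row["chrom"],
                pos0=int(row["pos"]) - 1,
                strand=row["strand"],
                ref_base=row["ref"],
                dna_depth=int(row["dna_depth"]),
                dna_genotype=row["dna_genotype"],
                rna_depth=int(row["rna_depth"]),
                base_counts={b: int(row[f"counts_{b}"]) for b in "ACGT"},
                editing_level=float(row["editing_level"]),
                substitution=row["substitution"],
                repeat_class="" if row["repeat_class"] == "." else
                row["repeat_class"],
                genic_context="" if row["genic_context"] == "." else
                row["genic_context"],
                filter_flags=flags,
                source=row["source"],
                sample_id="" if row["sample_id"] == "." else row["sample_id"],
            ))
    return records


def export_site_table_sqlite(records: Iterable[SiteRecord],
                             path: str, table: str = "sites") -> None:
    """Optional single-file SQL export of a site table (same columns)."""
    import sqlite3

    conn = sqlite3.connect(path)
    try:
        cols = ", ".join(f'"{c}"' for c in SITE_TABLE_COLUMNS)
        conn.execute(f'DROP TABLE IF EXISTS "{table}"')
        conn.execute(f'CREATE TABLE "{table}" ({cols})')
        rows = []
        for r in records:
            rows.append((
                r.chrom, r.pos_1based, r.strand, r.ref_base, r.dna_depth,
                r.dna_genotype, r.rna_depth, r.base_counts.get("A", 0),
                r.base_counts.get("C", 0), r.base_counts.get("G", 0),
                r.base_counts.get("T", 0), float(r.editing_level),
                r.substitution, r.repeat_class or ".",
                r.genic_context or ".",
                ",".join(sorted(r.filter_flags)) or "PASS", r.source,
                r.sample_id or "."))
        conn.executemany(
            f'INSERT INTO "{table}" VALUES ({",".join("?" * 18)})', rows)
        conn.commit()
    finally:
        conn.close()


def natural_chrom_key(chrom: str):
    """Natural sort key: chr2 before chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)
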