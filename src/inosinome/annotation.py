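"""Site annotation: repeat context, genic context, coding consequence.

Repeat classes partition every site into ALU / REP_NON_ALU / NONREP (Alu
wins over other repeats when annotations nest).  Genic context applies the
precedence CDS > UTR > ncRNA-exon > intron > intergenic across all
overlapping transcripts.  Coding consequences substitute G at the edited A
(transcript space) and translate with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import Seq

from .calling import ALU, NONREP, REP_NON_ALU
from .io_formats import (
    Genome,
    IntervalIndex,
    KnownVariantIndex,
    SiteRecord,
    TranscriptModel,
)

CDS = "CDS"
UTR5 = "UTR5"
UTR3 = "UTR3"
NCRNA_EXON = "NCRNA_EXON"
INTRON = "INTRON"
INTERGENIC = "INTERGENIC"

_PRECEDENCE = {CDS: 0, UTR5: 1, UTR3: 1, NCRNA_EXON: 2, INTRON: 3,
               INTERGENIC: 4}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_ALU_PREFIXES = ("Alu",)


def classify_repeat(chrom: str, pos0: int, repeat_index: IntervalIndex,
                    alu_prefixes: tuple[str, ...] = DEFAULT_ALU_PREFIXES,
                    ) -> str:
    """ALU / REP_NON_ALU / NONREP by repeat-label prefix; Alu wins nesting."""
    labels = [label for _, _, label, _ in repeat_index.at(chrom, pos0)]
    if any(label.startswith(alu_prefixes) for label in labels):
        return ALU
    if labels:
        return REP_NON_ALU
    return NONREP


@dataclass
class GenicContext:
    context: str
    gene_id: str = ""
    transcript_id: str = ""


def _context_in_transcript(pos0: int, t: TranscriptModel) -> str | None:
    if not t.start <= pos0 < t.end:
        return None
    in_exon = any(s <= pos0 < e for s, e in t.exons)
    if not in_exon:
        return INTRON
    if t.biotype != "protein_coding" or not t.cds:
        return NCRNA_EXON
    if any(s <= pos0 < e for s, e in t.cds):
        return CDS
    cds_start, cds_end = t.cds[0][0], t.cds[-1][1]
    if pos0 < cds_start:
        return UTR5 if t.strand == "+" else UTR3
    return UTR3 if t.strand == "+" else UTR5


def classify_genic(chrom: str, pos0: int,
                   transcripts: Iterable[TranscriptModel]) -> GenicContext:
    """Winning genic context over all overlapping transcripts.

    Precedence CDS > UTR > ncRNA exon > intron > intergenic; within a rank,
    protein-coding transcripts are preferred, then the longest CDS, then the
    transcript id (deterministic).
    """
    best: tuple[int, int, int, str] | None = None
    best_ctx: GenicContext | None = None
    for t in transcripts:
        if t.chrom != chrom:
            continue
        ctx = _context_in_transcript(pos0, t)
        if ctx is None:
            continue
        rank = (_PRECEDENCE[ctx], 0 if t.biotype == "protein_coding" else 1,
                -t.cds_length, t.transcript_id)
        if best is None or rank < best:
            best = rank
            best_ctx = GenicContext(ctx, t.gene_id, t.transcript_id)
    return best_ctx or GenicContext(INTERGENIC)


SYN = "SYN"
NONSYN = "NONSYN"


@dataclass
class CodonEffect:
    transcript_id: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str


def _cds_offset(t: TranscriptModel, pos0: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS."""
    off = 0
    for s, e in t.cds:
        if s <= pos0 < e:
            idx = off + (pos0 - s)
            return t.cds_length - 1 - idx if t.strand == "-" else idx
        off += e - s
    return None


def codon_effect(chrom: str, pos0: int, transcript: TranscriptModel,
                 genome: Genome, alt_base: str = "G") -> CodonEffect | None:
    """Consequence of substituting ``alt_base`` (transcript space) at a CDS
    position: the codon is rebuilt from the spliced CDS in transcript
    orientation and translated with the standard code.

    Returns None (effect skipped) for transcripts whose CDS is not a whole
    number of codons; raises for positions outside the CDS.
    """
    if transcript.chrom != chrom:
        raise ValueError("site and transcript on different chromosomes")
    offset = _cds_offset(transcript, pos0)
    if offset is None:
        raise ValueError(
            f"{chrom}:{pos0 + 1} is not in the CDS of "
            f"{transcript.transcript_id}")
    if not transcript.cds_complete:
        return None
    cds_seq = transcript.cds_sequence(genome)
    codon_index = offset // 3
    in_codon = offset % 3
    ref_codon = cds_seq[codon_index * 3 : codon_index * 3 + 3]
    alt_codon = (ref_codon[:in_codon] + alt_base
                 + ref_codon[in_codon + 1 :])
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodonEffect(
        transcript_id=transcript.transcript_id,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=SYN if ref_aa == alt_aa else NONSYN,
    )


def is_known_variant(site: SiteRecord,
                     vcf_index: KnownVariantIndex) -> bool:
    """True iff the site's genomic-space substitution is a known variant."""
    if len(site.substitution) != 2:
        return False
    ref_t, alt_t = site.substitution
    if site.strand == "-":
        ref_g, alt_g = _COMP[ref_t], _COMP[alt_t]
    else:
        ref_g, alt_g = ref_t, alt_t
    return (ref_g, alt_g) in vcf_index.alleles_at(site.chrom, site.pos0)


def flag_retrogene(chrom: str, pos0: int,
                   retrogene_index: IntervalIndex) -> bool:
    return bool(retrogene_index.at(chrom, pos0))


def overlaps_targets(chrom: str, pos0: int,
                     target_index: IntervalIndex) -> bool:
    """Generic interval membership, e.g. against a predicted-target BED."""
    return bool(target_index.at(chrom, pos0))


def annotate_sites(sites: Iterable[SiteRecord],
                   repeat_index: IntervalIndex | None = None,
                   transcripts: Iterable[TranscriptModel] | None = None,
                   alu_prefixes: tuple[str, ...] = DEFAULT_ALU_PREFIXES,
                   ) -> list[SiteRecord]:
    """Fill repeat_class and genic_context on site records, in place."""
    transcripts = list(transcripts or [])
    out = []
    for site in sites:
        if repeat_index is not None:
            site.repeat_class = classify_repeat(site.chrom, site.pos0,
                                                repeat_index, alu_prefixes)
        if transcripts:
            ctx = classify_genic(site.chrom, site.pos0, transcripts)
            site.genic_context = ctx.context if not ctx.gene_id else \
                f"{ctx.context}:{ctx.gene_id}"
        out.append(site)
    return out
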