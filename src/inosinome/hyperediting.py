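"""Rescue of hyper-edited reads via transformed-reference realignment.

Reads carrying dense A-to-G edit clusters defeat ordinary alignment (too many
mismatches), so they never reach the main caller.  The rescue collapses the
edited base out of the problem: all A are rewritten to G in both the read and
the reference, the transformed read is placed with the internal seeded
aligner, and the original read is then re-threaded onto the untransformed
reference so that the A->G mismatches reappear as recovered edits.  The
minus-strand case (genomic T->C under a minus-strand transcript) uses the
symmetric T->C transformation, so both orientations funnel into one A->G
transcript-space representation.

Acceptance of a rescued read requires a minimum number of edits, an edit
fraction within plausible bounds, near-perfect purity (at most one non-edit
mismatch), adequate base quality at edited positions, and edits not confined
to the read ends.  These thresholds are declared in :class:`HyperConfig`;
they reconstruct the published screen rather than quote it, and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .calling import HOM, GenotypeSource
from .io_formats import (
    Genome,
    KnownVariantIndex,
    SiteRecord,
    natural_chrom_key,
    reverse_complement,
)
from .realign import SeedIndex, place_read


@dataclass(frozen=True)
class TransformScheme:
    """A one-way base collapse, e.g. A->G for plus-orientation rescue."""

    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if self.from_base not in "ACGT" or self.to_base not in "ACGT":
            raise ValueError("transform bases must be in ACGT")


PLUS_SCHEME = TransformScheme("A", "G")   # edits appear as genomic A->G
MINUS_SCHEME = TransformScheme("T", "C")  # minus-strand transcripts


def transform_sequence(seq: str, scheme: TransformScheme) -> str:
    """Replace every occurrence of the scheme's source base (idempotent)."""
    return seq.replace(scheme.from_base, scheme.to_base)


def build_transformed_reference(genome: Genome) -> dict[str, Genome]:
    """A->G and T->C collapsed copies of the genome (same names/lengths)."""
    return {
        "plus": Genome({name: transform_sequence(seq, PLUS_SCHEME)
                        for name, seq in genome.sequences.items()}),
        "minus": Genome({name: transform_sequence(seq, MINUS_SCHEME)
                         for name, seq in genome.sequences.items()}),
    }


@dataclass
class HyperConfig:
    min_edits: int = 5
    min_edit_fraction: float = 0.05
    max_edit_fraction: float = 0.6
    max_other_mismatches: int = 1
    min_edit_qual_mean: float = 25.0
    end_exclusion_fraction: float = 0.10
    min_seed_votes: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.min_edit_fraction <= self.max_edit_fraction <= 1:
            raise ValueError("edit fraction bounds must satisfy "
                             "0 <= min <= max <= 1")


@dataclass
class UnalignedRead:
    """A read that failed (or skipped) normal alignment."""

    read_id: str
    seq: str
    quals: list[int]


@dataclass
class HyperAlignment:
    """One rescued read with its recovered edits in genomic space."""

    read_id: str
    chrom: str
    start0: int
    strand: str  # transcript strand of the recovered cluster
    recovered_mismatches: list[tuple[int, str, str]]
    n_edits: int
    edit_fraction: float


@dataclass
class HyperSite(SiteRecord):
    supporting_reads: int = 0


class HyperAligner:
    """Seeded placement of transformed reads on transformed references."""

    def __init__(self, genome: Genome, k: int = 11) -> None:
        self.genome = genome
        refs = build_transformed_reference(genome)
        self.index = {name: SeedIndex(ref, k=k)
                      for name, ref in refs.items()}

    def place(self, seq: str, orientation: str,
              min_votes: int) -> tuple[str, int, int] | None:
        scheme = PLUS_SCHEME if orientation == "plus" else MINUS_SCHEME
        transformed = transform_sequence(seq, scheme)
        return place_read(transformed, self.index[orientation],
                          min_votes=min_votes)


def _evaluate_placement(seq: str, quals: list[int], chrom: str, start: int,
                        genome: Genome, orientation: str,
                        config: HyperConfig) -> HyperAlignment | None:
    length = len(seq)
    if start + length > genome.lengths[chrom]:
        return None
    ref = genome.subsequence(chrom, start, start + length)
    scheme = PLUS_SCHEME if orientation == "plus" else MINUS_SCHEME
    edits: list[tuple[int, str, str]] = []
    edit_quals: list[int] = []
    others = 0
    for i, (rb, gb) in enumerate(zip(seq, ref)):
        if rb == gb or rb == "N" or gb == "N":
            continue
        if gb == scheme.from_base and rb == scheme.to_base:
            edits.append((start + i, gb, rb))
            edit_quals.append(quals[i])
        else:
            others += 1
    n = len(edits)
    if n < config.min_edits:
        return None
    fraction = n / length
    if not config.min_edit_fraction <= fraction <= \
            config.max_edit_fraction:
        return None
    if others > config.max_other_mismatches:
        return None
    if sum(edit_quals) / n < config.min_edit_qual_mean:
        return None
    lo = config.end_exclusion_fraction * length
    hi = length - lo
    if all(not lo <= (p - start) < hi for p, _, _ in edits):
        return None
    strand = "+" if orientation == "plus" else "-"
    return HyperAlignment(read_id="", chrom=chrom, start0=start,
                          strand=strand, recovered_mismatches=edits,
                          n_edits=n, edit_fraction=fraction)


def rescue_reads(candidate_reads: Iterable[UnalignedRead], genome: Genome,
                 config: HyperConfig | None = None,
                 aligner: HyperAligner | None = None,
                 ) -> list[HyperAlignment]:
    """Rescue hyper-edited reads against the transformed references.

    Each read is tried in both sequencing orientations against both the
    A->G (plus-transcript) and T->C (minus-transcript) references; the
    highest-voted placement that satisfies the acceptance rules wins.
    Unrescuable reads are silently dropped.
    """
    config = config or HyperConfig()
    if aligner is None:
        aligner = HyperAligner(genome)
    rescued: list[HyperAlignment] = []
    for read in candidate_reads:
        attempts = []
        for seq, quals, tag in (
                (read.seq, read.quals, "fwd"),
                (reverse_complement(read.seq), read.quals[::-1], "rev")):
            for orientation in ("plus", "minus"):
                placement = aligner.place(seq, orientation,
                                          config.min_seed_votes)
                if placement is not None:
                    chrom, start, votes = placement
                    attempts.append((votes, tag, orientation, seq, quals,
                                     chrom, start))
        best: HyperAlignment | None = None
        best_votes = -1
        for votes, _, orientation, seq, quals, chrom, start in \
                sorted(attempts, key=lambda a: -a[0]):
            if votes <= best_votes:
                break
            hit = _evaluate_placement(seq, quals, chrom, start, genome,
                                      orientation, config)
            if hit is not None:
                hit.read_id = read.read_id
                best, best_votes = hit, votes
        if best is not None:
            rescued.append(best)
    return rescued


def call_hyper_sites(hyper_alignments: Iterable[HyperAlignment],
                     dna_source: GenotypeSource,
                     known_variants: KnownVariantIndex | None = None,
                     main_counts: Callable[[str, int],
                                           dict[str, int] | None] | None
                     = None,
                     sample_id: str = "") -> list[HyperSite]:
    """Aggregate recovered edits into per-position hyper sites.

    Positions that are heterozygous (or too shallow) in the genomic DNA, or
    that match a known variant, are discarded.  The editing level counts the
    rescued reads as G evidence on top of whatever main-caller coverage is
    supplied through ``main_counts`` (transcript-space base counts per
    position); without it the level is computed over rescued reads alone.
    """
    support: dict[tuple[str, int, str], int] = {}
    for aln in hyper_alignments:
        for pos0, _, _ in aln.recovered_mismatches:
            key = (aln.chrom, pos0, aln.strand)
            support[key] = support.get(key, 0) + 1
    sites: list[HyperSite] = []
    for (chrom, pos0, strand) in sorted(
            support, key=lambda k: (natural_chrom_key(k[0]), k[1], k[2])):
        n = support[(chrom, pos0, strand)]
        genotype = dna_source.genotype(chrom, pos0)
        if genotype.status != HOM:
            continue
        ref_genomic = "A" if strand == "+" else "T"
        if genotype.base != ref_genomic:
            continue
        if known_variants is not None and \
                known_variants.alleles_at(chrom, pos0):
            continue
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        if main_counts is not None:
            existing = main_counts(chrom, pos0)
            if existing:
                counts.update(existing)
        counts["G"] += n
        denom = counts["A"] + counts["G"]
        level = counts["G"] / denom if denom else 0.0
        sites.append(HyperSite(
            chrom=chrom, pos0=pos0, strand=strand, ref_base="A",
            dna_depth=genotype.depth, dna_genotype=genotype.base,
            rna_depth=sum(counts.values()), base_counts=counts,
            editing_level=level, substitution="AG", source="HYPER",
            sample_id=sample_id, supporting_reads=n))
    return sites


def merge_catalogues(main_sites: Iterable[SiteRecord],
                     hyper_sites: Iterable[SiteRecord]) -> list[SiteRecord]:
    """Union of main and hyper catalogues, unique (chrom, pos, strand) keys.

    When a position appears in both, the main-caller record wins (its
    evidence is quantitative) and is kept with source MAIN.
    """
    merged: dict[tuple[str, int, str], SiteRecord] = {}
    for site in hyper_sites:
        merged[site.key] = site
    for site in main_sites:
        merged[site.key] = site
    return sorted(merged.values(),
                  key=lambda s: (natural_chrom_key(s.chrom), s.pos0,
                                 s.strand))
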