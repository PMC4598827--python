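# Methods

## Detection model

A-to-I editing is observed as an A→G mismatch between a sample's RNA reads
and its own genomic DNA, in transcript orientation. The caller treats each
genomic position independently and conditions on the DNA genotype: a site
is considered only where the genome is deeply covered and completely
homozygous — at least `min_dna_depth` (10) reads after a base-quality
floor of 25, and *zero* reads supporting a second allele. Strictness here
is asymmetric by design: a lost heterozygous-looking position costs
recall, never specificity. Positions failing the gate are reported with
`DNA_LOW_COV` / `DNA_NOT_HOM` codes when rejected-site emission is on.

RNA evidence is collected per read (base, quality, read cycle in original
sequencing orientation, distance to the nearest indel in the alignment,
duplicate flag, inferred transcript strand). Overlapping mates contribute
one observation (higher base quality wins; ties keep read 2, which lies on
the transcript strand under the dUTP protocol). Transcript strand follows
the dUTP rule — a forward-mapped read 2 implies a plus-strand transcript —
with `FR` and `unstranded` alternatives; under `unstranded` the strand is
imputed from the mismatch pattern. Counts at a site are complemented onto
the transcript strand, so the editing level is always
`G/(A+G)` and minus-strand editing is reported as `AG` with strand `-`.

The stringent stage is region-dependent, reflecting where errors
concentrate:

| rule | Alu | non-Alu (repetitive non-Alu and unique) |
|---|---|---|
| variant support | ≥2 reads | ≥3 reads after restriction |
| variant base quality | ≥25 | ≥30 |
| read-end trim | — | cycles within first/last 6 excluded |
| duplicates | counted | excluded |
| variant frequency | — | ≥0.1 of stringent depth |
| homopolymer | — | run >5 nt rejected |
| splice vicinity | — | within 4 nt intronic of a junction rejected |
| indel vicinity | ±10 bp | ±10 bp |
| known variant / retrogene | rejected | rejected |
| multi-mapping | rejected | rejected |

The frequency code fires only when restricted variant support is nonzero;
a site whose variant reads were entirely removed by a restriction reports
the restriction's code (`READ_END`, `LOW_BASEQUAL`, `DUPLICATE_ONLY`) plus
`LOW_ALT_SUPPORT`, not a meaningless zero-frequency failure.

The multi-mapping check replaces an external realigner with a
k-mer-seeded (k=11) affine-gap local alignment (match 1, mismatch −1, gap
open −2, extend −1) of each variant-supporting read against every genomic
window reachable by exact seeding: the pair is discarded when any
alternative window scores ≥ `score_ratio` (0.95) of the primary placement,
and both mates must be unique. Because it is by far the most expensive
filter, it runs last and only on candidates that survive everything else,
mirroring the sequential structure of reference pipelines; consequently a
site can carry `MULTIMAP` only as its sole code.

Reported per-site counts are the loose-stage transcript-space tallies
(MAPQ ≥20, base quality ≥25, mates collapsed); the stringent restrictions
gate the verdict but do not redefine the level estimate. Traversal is
natural-sorted by chromosome then position, making output byte-identical
across runs.

## Hyper-editing rescue

Reads with many clustered edits never survive normal alignment, so they
are recovered by base-collapsed realignment: read and reference are both
rewritten A→G (plus orientation) or T→C (minus orientation, i.e. a
minus-strand transcript seen in genomic space), the transformed read is
placed by diagonal-voted exact k-mer seeding, and the original read is
compared ungapped against the untransformed reference at that placement.
Both sequencing orientations are tried. Acceptance requires ≥5 recovered
edits, an edit fraction in [0.05, 0.6], ≤1 non-edit mismatch, mean quality
≥25 at edited bases, and at least one edit outside the outer 10% of the
read. These thresholds reconstruct the published hyper-editing screen
rather than quote it; all are configurable in `HyperConfig`. Recovered
positions heterozygous in DNA or matching a known variant are dropped;
the merged catalogue keeps the main caller's record when both sources
contain a position, since its evidence is quantitative.

The rescue alignment is ungapped by construction, so reads spanning an
indel or a splice junction are not rescuable — consistent with treating
hyper-edited clusters as arising in contiguous dsRNA (inverted-repeat)
regions.

## Annotation

Repeat class partitions every site into `ALU` / `REP_NON_ALU` / `NONREP`
by repeat-label prefix (default `Alu`), with Alu winning nested
annotations. Genic context applies the precedence CDS > UTR > ncRNA exon >
intron > intergenic over all overlapping transcripts; within a rank,
protein-coding transcripts are preferred, then the longest CDS, then the
transcript id, so classification is deterministic. Coding consequences
substitute G at the edited A's offset in the spliced CDS (transcript
orientation) and translate with the standard code; transcripts whose CDS
is not a whole number of codons are flagged and skipped.

## Downstream statistics

* Per-sample profile: median/mean editing level over PASS sites, CV using
  the sample (n−1) standard deviation, global editing as the plain sum of
  levels, hyper-site count by source.
* Context matrices count bases at −5..+5 around the edited A in transcript
  orientation (−k is 5′); the background draws an equal number of random
  genomic A's (or T's read as minus-strand A's). The two-sample comparison
  reports per-position log2 enrichment with a pooled two-proportion z.
* Sample clustering: pairwise Spearman ρ on editing levels of sites
  covered by more than 10 reads in both samples; distance 1−ρ;
  agglomerative linkage (average by default, single/complete selectable).
* Differential editing: eligibility demands a PASS call with more than 10
  reads in *every* sample of both tissues; levels are paired by individual
  and tested with a paired t-test, BH-adjusted across eligible sites.
  Zero-variance differences yield t=0, p=1.
* Tissue specificity: a site is specific to tissue T when edited only in
  T's samples and its gene exceeds FPKM 1 (mean over T's samples).
* Gene-set enrichment: hypergeometric upper tail against a user-supplied
  universe, BH across sets, odds ratio from the 2×2 table.

Statistical primitives are library calls (scipy, statsmodels); the test
suite pins each one to an independent brute-force oracle (midrank formula,
step-up evaluation, exact hypergeometric enumeration, naive agglomeration)
on small instances.

## Synthetic data

The generator emulates the study design end to end: a random genome (2 Mb
over two chromosomes by default) carrying inverted Alu-like pairs (~300 bp
copies, 8% divergence from a per-run consensus) inside enlarged 3′UTR
exons and introns, decoy non-Alu repeats and retrogene intervals;
multi-exon genes on both strands with complete CDS; 300 edit sites planted
at exonic transcript-A positions (70% in Alu, levels from a Beta(1.2,12)
low mode mixed with a uniform component; non-Alu levels uniform);
homozygous-alt and heterozygous SNPs listed in a dbSNP-style VCF; paired
100 nt dUTP reads at 30× with per-fragment edit draws (each fragment
carries G with probability level × sample multiplier); single-end 40× DNA
reads carrying genotypes but never editing; hyper clusters of 6–12 edits
confined to single exons, emitted as dedicated reads; and an FPKM table
recomputable from the fragment tallies.

Base qualities are drawn from a fixed discrete distribution and errors
occur with probability 10^(−q/10) scaled so the mean matches the
configured error rate (0.1%), concentrating errors at low quality as in
real base calling. Truth is planted only where the stated coverage is
actually delivered: positions within one maximal fragment length of a
transcript's ends (the paired-fragment edge falloff), inside splice
windows, or in homopolymer runs are excluded from planting — those
exclusion rules are exercised by dedicated hand-built fixtures instead.
Per-gene abundances are narrowly spread (lognormal σ=0.15) so planted
sites are comparably powered.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: spliced-alignment errors (reads are
emitted pre-aligned with exact CIGARs), GC and fragment-length bias,
indel sequencing errors (indel-bearing reads are planted explicitly in
fixtures), real Alu consensus sequences and their mappability structure,
intronic/pre-mRNA editing, allele-specific expression, and
quality-recalibration artifacts. FASTQ output is provided for optional
integration with a real aligner.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; only serialized
  tables are 1-based, converted at the single read/write point.
* Multiallelic candidates report the highest-count alternative (ties by
  A<C<G<T) and are flagged.
* Duplicate flags are honored when present; otherwise duplicates are
  defined by identical (chromosome, start, orientation, mate start),
  keeping the highest-summed-quality read.
* The splice window (4 nt into the intron) and the Alu frequency floor
  (off by default) are configurable because the underlying conventions
  vary between pipelines.
* Genotype sources are pluggable: DNA alignments, packed array sets from
  the simulator, or a precomputed genotype table.
* All simulation RNG streams derive from a single seed
  (`numpy.random.default_rng([seed, component, stream])`), giving
  byte-identical outputs for fixed seed across platforms.

Problem sizes used by the test suite and the acceptance script — a 2 Mb
genome, 300 planted sites, 30×/40× coverage, 10 specificity seeds, 200
calibration replicates, 100 clustering runs — are the package's default
desk-scale study conditions; they complete in a few minutes on one CPU.

## Known limitations

Single-nucleotide substitutions only (no C-to-U calling beyond diagnostic
substitution counts, no indel editing); ungapped hyper-rescue; the
Blat-surrogate uniqueness check seeds on exact k-mers and can miss
alternative placements more diverged than ~2 mismatches per k-mer window;
annotation assumes non-overlapping exons per transcript; the analytics
layer assumes editing levels are comparable across samples without further
normalization.
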