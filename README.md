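# inosinome

Detection and tissue profiling of A-to-I RNA editing from matched RNA-Seq
and whole-genome DNA sequencing.

Adenosine deaminases (ADAR enzymes) convert adenosine to inosine in
double-stranded RNA; sequencers read inosine as guanosine, so editing
appears as A→G mismatches between a sample's RNA reads and its own genomic
DNA. Separating true editing from sequencing errors, misalignment and
germline variation requires matched DNA, strand-oriented RNA libraries and
an aggressive filter cascade. This package is for people who want that
cascade as a tested, scriptable library: it calls editing sites from
matched alignments, rescues hyper-edited reads that defeat ordinary
aligners, annotates sites by repeat/genic/codon context, and provides the
downstream statistics used to profile the *inosinome* — the genome-wide
set of edited positions — across samples and tissues. A synthetic-data
generator with a truth table makes every stage testable end to end without
any controlled-access data.

## The method

**Calling.** At each RNA/DNA mismatch position the caller demands a deeply
covered, completely homozygous genomic genotype (≥10 DNA reads, zero
second-allele reads at base quality ≥25), then gathers loose RNA evidence
(MAPQ ≥20, base quality ≥25, ≥1 variant read). Counts are tallied on the
transcript strand inferred from the dUTP protocol (read 2 lies on the
transcript strand), so minus-strand editing reports as A→G, never T→C. The
editing level at a site is

  level = n(G) / (n(A) + n(G))

in transcript space. Candidates then face a region-dependent stringent
stage: sites in Alu elements keep the loose rules plus ≥2 variant reads;
sites in other repeats and unique sequence additionally restrict variant
evidence to quality ≥30, read cycles outside the first/last 6, and
non-duplicate reads, then require ≥3 variant reads at frequency ≥0.1,
clear of homopolymer runs >5 nt, annotated splice windows, indels within
±10 bp, known germline variants, retrogene intervals, and a
realignment-uniqueness check (k-mer-seeded affine local alignment; a read
pair is discarded when an alternative placement scores ≥0.95 of its
primary placement).

**Hyper-editing rescue.** Reads with dense edit clusters never align in the
first place. Both read and reference are collapsed A→G (T→C for
minus-strand transcripts), the transformed read is placed by seeded
alignment, and the original read is re-threaded onto the untransformed
reference; a rescued read needs ≥5 recovered A→G edits at 5–60% of its
length, at most one non-A→G mismatch, mean edit quality ≥25, and edits not
confined to the read ends. Per-position clusters with heterozygous DNA are
discarded.

**Analytics.** Per-sample profiles (median/mean level, CV = sd/mean, global
editing = Σ levels), flanking-context matrices (−5..+5 around the edited
A), sample clustering on 1 − Spearman ρ of shared editing levels,
correlation of editing output with deaminase (ADAR) expression, paired
t-tests with Benjamini–Hochberg correction for differential editing,
FPKM>1-gated tissue-specific site selection, and hypergeometric gene-set
enrichment.

## Worked example

`python examples/01_simulate_and_call.py` simulates a 250 kb genome with 60
planted editing sites, sequences 30× stranded RNA and 40× DNA, and runs the
caller:

```
planted sites: 60 (24 with level >= 0.2)
PASS calls: 41, all A-to-G: True
recall on level >= 0.2 sites: 23/24

first calls (true level vs estimated G/(A+G)):
  chr1:6572 + NONREP       true=0.13 est=0.17 depth=30
  chr1:11010 + NONREP       true=0.45 est=0.34 depth=32
  chr1:11401 + NONREP       true=0.85 est=0.94 depth=32
```

Every PASS call is A-to-G (the hallmark of genuine A-to-I detection), the
recall counts planted sites at level ≥0.2 recovered by the cascade, and the
estimated levels are binomial draws around the planted truth at the local
read depth. Low-level sites (<0.2) in non-repetitive sequence are
deliberately sacrificed by the frequency and support floors — specificity
over sensitivity. The other examples cover hyper-editing rescue
(`02`), tissue profiles, clustering and ADAR correlation (`03`), and
differential editing plus sequence context (`04`).

A thin CLI wraps the same library: `inosinome simulate|call|hyper|annotate|analyze`
(see `inosinome --help`).

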