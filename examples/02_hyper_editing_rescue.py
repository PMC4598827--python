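"""Rescue hyper-edited reads that ordinary alignment would discard.

Reads carrying 6-12 clustered A-to-G edits are realigned after collapsing
A to G in both read and reference; the recovered mismatches are aggregated
into hyper-editing sites and merged with the main catalogue.
"""

from inosinome.hyperediting import call_hyper_sites, rescue_reads
from inosinome.io_formats import KnownVariantIndex
from inosinome.simulate import SimConfig, simulate_dataset

config = SimConfig(seed=4, chrom_lengths={"chr1": 250_000}, n_genes=10,
                   n_edit_sites=40, n_hyper_clusters=6,
                   reads_per_cluster=4)
dataset = simulate_dataset(config)
sample = dataset.sample("s1")

rescued = rescue_reads(sample.hyper_reads, dataset.genome)
print(f"hyper-edited reads in: {len(sample.hyper_reads)}, "
      f"rescued: {len(rescued)}")
for aln in rescued[:3]:
    print(f"  {aln.read_id}: {aln.n_edits} edits "
          f"({aln.edit_fraction:.0%} of the read) at "
          f"{aln.chrom}:{aln.start0 + 1} strand {aln.strand}")

known = KnownVariantIndex()
for snp in dataset.truth.snps:
    known.add(snp.chrom, snp.pos0, snp.ref, snp.alt)
sites = call_hyper_sites(rescued, dataset.dna, known_variants=known)

planted = {(e.chrom, e.pos0) for e in dataset.truth.edits if e.hyper}
found = {(s.chrom, s.pos0) for s in sites}
print(f"\nplanted cluster positions: {len(planted)}, "
      f"recovered as hyper sites: {len(found & planted)}")
print("every hyper site is A-to-G with HOM genomic DNA:",
      all(s.substitution == "AG" for s in sites))
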