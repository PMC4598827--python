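"""Hand-built fixtures and independent brute-force oracles for the suite."""

from __future__ import annotations

import math
import re

import numpy as np

from inosinome.calling import FilterConfig, PileupColumn, ReadObservation
from inosinome.io_formats import AlignmentRecord, Genome


def make_record(read_id="r1", chrom="chrT", start=0, cigar=None, seq=None,
                quals=None, mapq=60, is_read2=True, is_reverse=False,
                is_duplicate=False, mate_start=-1, is_paired=True):
    seq = seq if seq is not None else "A" * 50
    cigar = cigar or [("M", len(seq))]
    quals = quals if quals is not None else [35] * len(seq)
    return AlignmentRecord(
        read_id=read_id, chrom=chrom, start=start, cigar=cigar, seq=seq,
        quals=quals, mapq=mapq, is_paired=is_paired,
        is_read1=not is_read2, is_read2=is_read2, is_reverse=is_reverse,
        is_duplicate=is_duplicate, mate_start=mate_start)


def make_obs(base="A", qual=35, cycle=50, read_length=100, mate="R2",
             strand="+", dist=math.inf, dup=False, mapq=60, read_id="r"):
    return ReadObservation(base=base, qual=qual, read_cycle=cycle,
                           read_length=read_length, mate=mate,
                           transcript_strand=strand, dist_to_indel=dist,
                           is_duplicate=dup, mapq=mapq, read_id=read_id)


def make_column(chrom, pos0, ref_base, observations, low_mapq=()):
    return PileupColumn(chrom, pos0, ref_base, list(observations),
                        list(low_mapq))


def random_genome(rng, lengths):
    return Genome({name: "".join(rng.choice(list("ACGT"), n))
                   for name, n in lengths.items()})


# --- independent oracles ---------------------------------------------------

def linear_scan_at(intervals, chrom, pos):
    """Brute-force stabbing query over (chrom, start, end, label, strand)."""
    return sorted((s, e, label, st) for c, s, e, label, st in intervals
                  if c == chrom and s <= pos < e)


def maximal_run_lengths(seq):
    """Per-position maximal homopolymer run length via regex scan."""
    out = [0] * len(seq)
    for m in re.finditer(r"(.)\1*", seq):
        for i in range(m.start(), m.end()):
            out[i] = m.end() - m.start()
    return out


def bh_stepup(pvalues):
    """Direct Benjamini-Hochberg step-up evaluation."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def hypergeom_tail(k, big_n, big_k, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    total = math.comb(big_n, n)
    upper = min(big_k, n)
    return sum(math.comb(big_k, j) * math.comb(big_n - big_k, n - j)
               for j in range(k, upper + 1)) / total


def naive_average_linkage(dist):
    """All-merge average-linkage agglomeration; returns sorted merge heights.

    ``dist`` is a symmetric numpy matrix.  Average linkage between clusters
    is the mean of all inter-point distances.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def recount_sam_text(sam_path, chrom, pos0, min_mapq=20):
    """Base counts at a position from a raw SAM text re-parse.

    Deliberately independent of the package: walks CIGAR strings with a
    regex and tallies every M-aligned base of sufficiently mapped reads,
    one observation per read id (mate overlaps collapse arbitrarily to the
    higher-quality base, mirroring the documented pileup rule).
    """
    per_read = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 0x4 or f[2] != chrom or int(f[4]) < min_mapq:
                continue
            start = int(f[3]) - 1
            seq, qual = f[9], f[10]
            q = 0
            r = start
            for num, op in re.findall(r"(\d+)([MIDNSHP=X])", f[5]):
                num = int(num)
                if op in "M=X":
                    if r <= pos0 < r + num:
                        idx = q + pos0 - r
                        b, bq = seq[idx], ord(qual[idx]) - 33
                        prev = per_read.get(f[0])
                        if prev is None or bq > prev[1]:
                            per_read[f[0]] = (b, bq)
                    q += num
                    r += num
                elif op in "IS":
                    q += num
                elif op in "DN":
                    r += num
    counts = {}
    for b, _ in per_read.values():
        counts[b] = counts.get(b, 0) + 1
    return counts


STANDARD_CODE = {}
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG")
for _i, _a in enumerate(_AAS):
    STANDARD_CODE[_BASES[_i // 16] + _BASES[(_i // 4) % 4]
                  + _BASES[_i % 4]] = _a


def default_filter_config(**kwargs):
    return FilterConfig(**kwargs)
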