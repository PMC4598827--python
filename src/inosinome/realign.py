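"""k-mer-seeded local realignment.

Two consumers:

* the multi-mapping check in the calling cascade — a read (pair) carrying a
  candidate mismatch is realigned against every genomic window reachable by
  exact k-mer seeding, and discarded when an alternative placement scores
  within ``score_ratio`` of its primary placement;
* hyper-editing rescue, which needs fast placement of base-transformed reads
  on a transformed reference.

Seeding is exact k-mer lookup (default k=11) over a numpy-packed index;
scoring is affine-gap local alignment via :class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io_formats import AlignmentRecord, Genome

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def make_aligner(match: int = 1, mismatch: int = -1, gap_open: int = -2,
                 gap_extend: int = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


class SeedIndex:
    """Exact k-mer index over a genome, kmer code -> sorted positions."""

    def __init__(self, genome: Genome, k: int = 11) -> None:
        if k < 4 or k > 15:
            raise ValueError("k must be in [4, 15]")
        self.k = k
        self.genome = genome
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in genome.sequences.items():
            n = len(seq) - k + 1
            if n <= 0:
                continue
            enc = _encode(seq)
            codes = np.zeros(n, dtype=np.int64)
            valid = np.ones(n, dtype=bool)
            for j in range(k):
                cj = enc[j : j + n]
                valid &= cj != 255
                codes = codes * 4 + cj
            positions = np.nonzero(valid)[0]
            codes = codes[positions]
            order = np.argsort(codes, kind="stable")
            self._chrom[name] = (codes[order],
                                 positions[order].astype(np.int64))

    def kmer_codes(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Codes and offsets of every valid k-mer of ``seq``."""
        k = self.k
        n = len(seq) - k + 1
        if n <= 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        enc = _encode(seq)
        codes = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            cj = enc[j : j + n]
            valid &= cj != 255
            codes = codes * 4 + cj
        offsets = np.nonzero(valid)[0]
        return codes[offsets], offsets.astype(np.int64)

    def hits(self, code: int) -> list[tuple[str, np.ndarray]]:
        out = []
        for name, (codes, positions) in self._chrom.items():
            lo = np.searchsorted(codes, code, "left")
            hi = np.searchsorted(codes, code, "right")
            if hi > lo:
                out.append((name, positions[lo:hi]))
        return out


@dataclass
class SeedWindow:
    chrom: str
    start: int
    end: int
    votes: int


def find_windows(seq: str, index: SeedIndex, step: int = 4,
                 max_hits_per_kmer: int = 64, merge_gap: int = 16,
                 pad: int = 15) -> list[SeedWindow]:
    """Candidate genomic windows for ``seq`` from diagonal-clustered seeds.

    Seeds sampled every ``step`` bases vote on (chrom, diagonal); diagonals
    closer than ``merge_gap`` are merged into one window padded by ``pad``.
    Windows are returned sorted by decreasing vote count.
    """
    codes, offsets = index.kmer_codes(seq)
    if codes.size == 0:
        return []
    take = np.arange(0, codes.size, step)
    diags: dict[str, list[int]] = {}
    for code, off in zip(codes[take], offsets[take]):
        for chrom, positions in index.hits(int(code)):
            if positions.size > max_hits_per_kmer:
                continue
            diags.setdefault(chrom, []).extend(
                int(p) - int(off) for p in positions)
    windows: list[SeedWindow] = []
    read_len = len(seq)
    for chrom, ds in diags.items():
        ds.sort()
        run = [ds[0]]
        for d in ds[1:] + [ds[-1] + merge_gap + 1]:
            if d - run[-1] <= merge_gap:
                run.append(d)
            else:
                lo, hi = run[0], run[-1]
                chrom_len = index.genome.lengths[chrom]
                start = max(0, lo - pad)
                end = min(chrom_len, hi + read_len + pad)
                windows.append(SeedWindow(chrom, start, end, len(run)))
                run = [d]
    windows.sort(key=lambda w: (-w.votes, w.chrom, w.start))
    return windows


def place_read(seq: str, index: SeedIndex, step: int = 3,
               min_votes: int = 2) -> tuple[str, int, int] | None:
    """Best ungapped placement (chrom, start0, votes) by diagonal voting."""
    codes, offsets = index.kmer_codes(seq)
    if codes.size == 0:
        return None
    take = np.arange(0, codes.size, step)
    votes: dict[tuple[str, int], int] = {}
    for code, off in zip(codes[take], offsets[take]):
        for chrom, positions in index.hits(int(code)):
            if positions.size > 64:
                continue
            for p in positions:
                key = (chrom, int(p) - int(off))
                votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    (chrom, start), n = max(votes.items(), key=lambda kv: (kv[1], kv[0][0],
                                                           -kv[0][1]))
    if n < min_votes or start < 0:
        return None
    if start + len(seq) > index.genome.lengths[chrom]:
        return None
    return chrom, start, n


def realignment_unique(record: AlignmentRecord, genome: Genome,
                       index: SeedIndex | None = None, k: int = 11,
                       score_ratio: float = 0.95,
                       aligner: Align.PairwiseAligner | None = None) -> bool:
    """True iff no alternative genomic placement rivals the primary one.

    The read is locally aligned to its mapped window and to every window
    reached by k-mer seeding; it is unique iff the best alternative score is
    strictly below ``score_ratio`` times the primary score.  Mated pairs are
    unique only if both mates are (enforced by the caller, which knows the
    pairing).
    """
    if record.is_unmapped:
        raise ValueError("realignment_unique requires a mapped record")
    if index is None:
        index = SeedIndex(genome, k=k)
    if aligner is None:
        aligner = make_aligner()
    pad = 25
    chrom_len = genome.lengths[record.chrom]
    p_start = max(0, record.start - pad)
    p_end = min(chrom_len, record.end + pad)
    primary_window = genome.subsequence(record.chrom, p_start, p_end)
    primary = aligner.score(primary_window, record.seq)
    if primary <= 0:
        return False
    for w in find_windows(record.seq, index):
        if w.chrom == record.chrom and w.start < p_end and w.end > p_start:
            continue
        alt_seq = genome.subsequence(w.chrom, w.start, w.end)
        if aligner.score(alt_seq, record.seq) >= score_ratio * primary:
            return False
    return True
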