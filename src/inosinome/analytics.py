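"""Downstream inosinome statistics.

Per-sample editing profiles, flanking sequence context, inter-sample
clustering of editing levels, correlation of editing with deaminase
expression, paired differential editing with FDR control, tissue-specific
site selection and gene-set enrichment.  Statistical primitives delegate to
scipy/statsmodels; the test suite checks them against independent
brute-force oracles on small instances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io_formats import Genome, IntervalIndex, SiteRecord, TranscriptModel

BASES = "ACGT"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def editing_level(count_a: int, count_g: int) -> float:
    """G / (A + G), transcript space."""
    denom = count_a + count_g
    if denom <= 0:
        raise ValueError("editing level undefined for A + G == 0")
    return count_g / denom


def site_gene(site: SiteRecord) -> str:
    """Gene id encoded in the genic_context field (``CTX:gene``), or ''."""
    if ":" in site.genic_context:
        return site.genic_context.split(":", 1)[1]
    return ""


# ---------------------------------------------------------------------------
# Per-sample profiles


@dataclass
class SampleProfile:
    sample_id: str
    tissue: str
    n_sites: int
    n_hyper: int
    median_level: float
    mean_level: float
    cv: float
    global_editing: float


def sample_profile(site_table: Sequence[SiteRecord], sample_id: str = "",
                   tissue: str = "") -> SampleProfile:
    """Summaries over PASS-site editing levels.

    The coefficient of variation uses the sample standard deviation (n-1);
    it is 0 by convention for a single site or a zero mean.  Global editing
    is the sum of levels over all sites.
    """
    passed = [s for s in site_table if s.passed]
    levels = np.array([s.editing_level for s in passed], dtype=float)
    n = len(levels)
    sample_id = sample_id or (passed[0].sample_id if passed else "")
    if n == 0:
        return SampleProfile(sample_id, tissue, 0, 0, math.nan, math.nan,
                             math.nan, 0.0)
    mean = float(levels.mean())
    sd = float(levels.std(ddof=1)) if n > 1 else 0.0
    cv = sd / mean if mean > 0 else 0.0
    return SampleProfile(
        sample_id=sample_id, tissue=tissue, n_sites=n,
        n_hyper=sum(1 for s in passed if s.source == "HYPER"),
        median_level=float(np.median(levels)), mean_level=mean, cv=cv,
        global_editing=float(levels.sum()))


# ---------------------------------------------------------------------------
# Sequence context


@dataclass
class ContextMatrix:
    """Base counts at positions -flank..+flank around edited A's.

    Position 0 is the edited A; -k is k nt 5' and +k is k nt 3' of it, in
    transcript orientation.  ``foreground`` counts come from edited sites,
    ``background`` from an equal-size random draw of genomic A's under the
    same strand convention.  Arrays are (2*flank+1, 4) over ACGT.
    """

    flank: int
    foreground: np.ndarray
    background: np.ndarray
    n_skipped: int = 0

    @property
    def positions(self) -> list[int]:
        return list(range(-self.flank, self.flank + 1))

    def frequency(self, which: str = "foreground") -> np.ndarray:
        counts = getattr(self, which).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return counts / totals


def _context_of(genome: Genome, chrom: str, pos0: int, strand: str,
                flank: int) -> str | None:
    if pos0 - flank < 0 or pos0 + flank + 1 > genome.lengths[chrom]:
        return None
    window = genome.subsequence(chrom, pos0 - flank, pos0 + flank + 1)
    if strand == "-":
        window = "".join(_COMP[b] for b in reversed(window))
    return window


def context_matrix(sites: Sequence[SiteRecord], genome: Genome,
                   flank: int = 5, rng: np.random.Generator | None = None,
                   ) -> ContextMatrix:
    """Foreground/background flanking-base counts around edited sites.

    Sites closer than ``flank`` to a contig end are skipped and counted.
    The background draws one unedited genomic A (or T read as a minus-strand
    A) per contributing site, uniformly over the genome.
    """
    rng = rng or np.random.default_rng(0)
    base_index = {b: i for i, b in enumerate(BASES)}
    width = 2 * flank + 1
    fg = np.zeros((width, 4), dtype=np.int64)
    skipped = 0
    site_keys = {(s.chrom, s.pos0) for s in sites}
    for s in sites:
        window = _context_of(genome, s.chrom, s.pos0, s.strand, flank)
        if window is None:
            skipped += 1
            continue
        for i, b in enumerate(window):
            if b in base_index:
                fg[i, base_index[b]] += 1
    n_fg = int(fg[flank].sum())
    bg = np.zeros_like(fg)
    chroms = sorted(genome.sequences)
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    drawn = 0
    attempts = 0
    while drawn < n_fg and attempts < 200 * max(n_fg, 1):
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos0 = int(rng.integers(0, genome.lengths[chrom]))
        if (chrom, pos0) in site_keys:
            continue
        base = genome.base(chrom, pos0)
        if base == "A":
            strand = "+"
        elif base == "T":
            strand = "-"
        else:
            continue
        window = _context_of(genome, chrom, pos0, strand, flank)
        if window is None:
            continue
        for i, b in enumerate(window):
            if b in base_index:
                bg[i, base_index[b]] += 1
        drawn += 1
    return ContextMatrix(flank=flank, foreground=fg, background=bg,
                         n_skipped=skipped)


def context_comparison(matrix: ContextMatrix) -> pd.DataFrame:
    """Per-position, per-base log2 enrichment and two-proportion z.

    Compares foreground against background frequencies with a pooled
    two-proportion z statistic per base and position (the counts behind a
    two-sample sequence logo).
    """
    rows = []
    fg, bg = matrix.foreground, matrix.background
    for pi, pos in enumerate(matrix.positions):
        n1 = fg[pi].sum()
        n2 = bg[pi].sum()
        for bi, base in enumerate(BASES):
            k1, k2 = int(fg[pi, bi]), int(bg[pi, bi])
            p1 = k1 / n1 if n1 else math.nan
            p2 = k2 / n2 if n2 else math.nan
            if n1 and n2 and 0 < k1 + k2 < n1 + n2:
                pooled = (k1 + k2) / (n1 + n2)
                se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
                z = (p1 - p2) / se if se else math.nan
            else:
                z = math.nan
            log2fc = math.log2(p1 / p2) if p1 and p2 else math.nan
            rows.append({"position": pos, "base": base, "fg_count": k1,
                         "bg_count": k2, "fg_freq": p1, "bg_freq": p2,
                         "log2_enrichment": log2fc, "z": z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation


@dataclass
class CorrelationResult:
    rho: float
    pvalue: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midrank ties, two-sided p."""
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if len(set(x)) < 2 or len(set(y)) < 2:
        return CorrelationResult(math.nan, math.nan, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), n)


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterTree:
    labels: list[str]
    linkage: np.ndarray
    distances: pd.DataFrame

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        assignment = hierarchy.fcluster(self.linkage, t=k,
                                        criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_dist) -> str:
            if node.is_leaf():
                return (f"{self.labels[node.id]}:"
                        f"{parent_dist - node.dist:.6f}")
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{parent_dist - node.dist:.6f}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def shared_levels(table_a: Sequence[SiteRecord],
                  table_b: Sequence[SiteRecord],
                  min_depth: int = 10) -> tuple[list[float], list[float]]:
    """Editing levels at PASS sites covered above ``min_depth`` in both."""
    a = {s.key: s for s in table_a
         if s.passed and s.rna_depth > min_depth}
    b = {s.key: s for s in table_b
         if s.passed and s.rna_depth > min_depth}
    keys = sorted(set(a) & set(b))
    return ([a[k].editing_level for k in keys],
            [b[k].editing_level for k in keys])


def cluster_samples(site_tables: dict[str, Sequence[SiteRecord]],
                    min_depth: int = 10,
                    linkage_method: str = "average") -> ClusterTree:
    """Hierarchical clustering of samples on 1 - Spearman rho distances.

    Each pairwise rho uses the editing levels of sites covered above
    ``min_depth`` in both samples of that pair.  Fewer than 2 shared sites
    in any pair is fatal (the distance would be undefined).
    """
    labels = sorted(site_tables)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if linkage_method not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xa, xb = shared_levels(site_tables[labels[i]],
                                   site_tables[labels[j]], min_depth)
            if len(xa) < 2:
                raise ValueError(
                    f"samples {labels[i]} and {labels[j]} share fewer than "
                    "2 usable sites")
            if len(xa) < 3 or len(set(xa)) < 2 or len(set(xb)) < 2:
                rho = 1.0 if xa == xb else 0.0
            else:
                rho = spearman(xa, xb).rho
            dist[i, j] = dist[j, i] = 1.0 - rho
    condensed = dist[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method=linkage_method)
    frame = pd.DataFrame(dist, index=labels, columns=labels)
    return ClusterTree(labels=labels, linkage=linkage, distances=frame)


def correlate_editing_expression(profiles: Sequence[SampleProfile],
                                 expression: pd.DataFrame,
                                 gene: str = "ADAR",
                                 ) -> dict[str, CorrelationResult]:
    """Spearman correlation of per-sample editing with a gene's expression.

    Two variants: global editing (sum of levels) vs FPKM and the number of
    sites vs FPKM.  Samples absent from the expression table are dropped
    with a warning.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not in expression table")
    kept = [p for p in profiles if p.sample_id in expression.columns]
    dropped = [p.sample_id for p in profiles
               if p.sample_id not in expression.columns]
    if dropped:
        warnings.warn(f"samples missing from expression table: {dropped}",
                      stacklevel=2)
    if len(kept) < 3:
        raise ValueError("need at least 3 overlapping samples")
    fpkm = [float(expression.at[gene, p.sample_id]) for p in kept]
    return {
        "global_editing": spearman([p.global_editing for p in kept], fpkm),
        "n_sites": spearman([p.n_sites for p in kept], fpkm),
    }


# ---------------------------------------------------------------------------
# Differential editing


@dataclass
class DifferentialResult:
    site: tuple[str, int, str]
    mean_level_a: float
    mean_level_b: float
    t_statistic: float
    pvalue: float
    qvalue: float = math.nan
    n_pairs: int = 0

    @property
    def significant(self) -> bool:
        return self.qvalue < 0.05


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t_table(levels_a: np.ndarray,
                   levels_b: np.ndarray) -> pd.DataFrame:
    """Per-row paired t-tests between two (sites x pairs) level matrices.

    Zero-variance differences give t = 0 and p = 1 (no evidence of change).
    q-values are BH-adjusted across rows.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("level matrices must have the same shape")
    if a.shape[1] < 2:
        raise ValueError("need at least 2 pairs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_rel(a, b, axis=1)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({
        "mean_a": a.mean(axis=1), "mean_b": b.mean(axis=1),
        "t": t, "pvalue": p, "qvalue": bh_adjust(p),
    })


def differential_editing(tables_a: dict[str, Sequence[SiteRecord]],
                         tables_b: dict[str, Sequence[SiteRecord]],
                         pairing: dict[str, str],
                         min_depth: int = 10,
                         ) -> list[DifferentialResult]:
    """Paired differential editing between two tissues.

    ``tables_a``/``tables_b`` map sample id -> site table; ``pairing`` maps
    sample id -> individual.  A site is eligible only when it is a PASS call
    supported by more than ``min_depth`` RNA reads in every sample of both
    tissues; levels are then paired by individual and tested with a paired
    t-test, BH-adjusted across all eligible sites.
    """
    ind_a = {pairing[s]: s for s in tables_a}
    ind_b = {pairing[s]: s for s in tables_b}
    individuals = sorted(set(ind_a) & set(ind_b))
    if len(individuals) < 2:
        return []
    maps_a = {s: {r.key: r for r in tables_a[s]
                  if r.passed and r.rna_depth > min_depth}
              for s in tables_a}
    maps_b = {s: {r.key: r for r in tables_b[s]
                  if r.passed and r.rna_depth > min_depth}
              for s in tables_b}
    eligible = set.intersection(*(set(m) for m in maps_a.values()),
                                *(set(m) for m in maps_b.values()))
    if not eligible:
        return []
    keys = sorted(eligible)
    la = np.array([[maps_a[ind_a[i]][k].editing_level
                    for i in individuals] for k in keys])
    lb = np.array([[maps_b[ind_b[i]][k].editing_level
                    for i in individuals] for k in keys])
    table = paired_t_table(la, lb)
    return [DifferentialResult(
        site=k, mean_level_a=row.mean_a, mean_level_b=row.mean_b,
        t_statistic=row.t, pvalue=row.pvalue, qvalue=row.qvalue,
        n_pairs=len(individuals))
        for k, row in zip(keys, table.itertuples(index=False))]


# ---------------------------------------------------------------------------
# Tissue specificity


def tissue_specific_sites(
        site_tables_by_tissue: dict[str, dict[str, Sequence[SiteRecord]]],
        expression: pd.DataFrame,
        fpkm_min: float = 1.0,
) -> tuple[dict[str, set[tuple[str, int, str]]], int]:
    """Sites edited in exactly one tissue whose gene is expressed there.

    A site is specific to tissue T iff it is a PASS call in at least one of
    T's samples, absent from every other tissue's tables, and its gene has
    mean FPKM > ``fpkm_min`` across T's samples.  Sites without a gene
    annotation are excluded; their number is returned alongside.
    """
    edited_in: dict[tuple[str, int, str], set[str]] = {}
    gene_of: dict[tuple[str, int, str], str] = {}
    for tissue, samples in site_tables_by_tissue.items():
        for table in samples.values():
            for s in table:
                if not s.passed:
                    continue
                edited_in.setdefault(s.key, set()).add(tissue)
                gene = site_gene(s)
                if gene:
                    gene_of[s.key] = gene
    n_unannotated = 0
    out: dict[str, set[tuple[str, int, str]]] = {
        t: set() for t in site_tables_by_tissue}
    for key, tissues in edited_in.items():
        if len(tissues) != 1:
            continue
        tissue = next(iter(tissues))
        gene = gene_of.get(key, "")
        if not gene:
            n_unannotated += 1
            continue
        samples = list(site_tables_by_tissue[tissue])
        cols = [c for c in samples if c in expression.columns]
        if gene not in expression.index or not cols:
            continue
        if float(expression.loc[gene, cols].mean()) > fpkm_min:
            out[tissue].add(key)
    return out, n_unannotated


# ---------------------------------------------------------------------------
# Events per gene vs Alu abundance


def events_per_gene_vs_alu(site_table: Sequence[SiteRecord],
                           transcript_models: Sequence[TranscriptModel],
                           repeat_index: IntervalIndex,
                           ) -> tuple[CorrelationResult, pd.DataFrame]:
    """Edited positions per gene vs Alu intervals overlapping the gene span.

    Only genes with at least one edited position enter; returns the Spearman
    result and the per-gene table behind it.
    """
    spans: dict[str, tuple[str, int, int]] = {}
    for t in transcript_models:
        chrom, start, end = spans.get(t.gene_id, (t.chrom, t.start, t.end))
        spans[t.gene_id] = (chrom, min(start, t.start), max(end, t.end))
    counts: dict[str, set[tuple[str, int, str]]] = {}
    for s in site_table:
        if not s.passed:
            continue
        gene = site_gene(s)
        if gene:
            counts.setdefault(gene, set()).add(s.key)
    rows = []
    for gene, keys in sorted(counts.items()):
        chrom, start, end = spans.get(gene, (None, 0, 0))
        if chrom is None:
            continue
        alus = [iv for iv in repeat_index.overlapping(chrom, start, end)
                if iv[2].startswith("Alu")]
        rows.append({"gene_id": gene, "n_sites": len(keys),
                     "n_alu": len(alus)})
    frame = pd.DataFrame(rows)
    if len(frame) < 3 or frame["n_sites"].nunique() < 2 or \
            frame["n_alu"].nunique() < 2:
        return CorrelationResult(math.nan, math.nan, len(frame)), frame
    result = spearman(frame["n_alu"].tolist(), frame["n_sites"].tolist())
    return result, frame


# ---------------------------------------------------------------------------
# Gene-set enrichment


@dataclass
class EnrichmentResult:
    name: str
    k_overlap: int
    set_size: int
    query_size: int
    universe_size: int
    odds_ratio: float
    pvalue: float
    qvalue: float = math.nan


def geneset_enrichment(query_genes: Iterable[str],
                       universe: Iterable[str],
                       gene_sets: dict[str, Iterable[str]],
                       ) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of a gene list in each set.

    Sets are intersected with the universe; p-values are BH-adjusted across
    sets; the odds ratio comes from the 2x2 contingency table.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes) & universe_set
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe_set
        k = len(query & members)
        big_k, n, big_n = len(members), len(query), len(universe_set)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        a, b = k, n - k
        c, d = big_k - k, big_n - big_k - (n - k)
        odds = (a * d) / (b * c) if b * c else math.inf
        results.append(EnrichmentResult(
            name=name, k_overlap=k, set_size=big_k, query_size=n,
            universe_size=big_n, odds_ratio=odds, pvalue=p))
    qvalues = bh_adjust([r.pvalue for r in results])
    for r, q in zip(results, qvalues):
        r.qvalue = float(q)
    return results


# ---------------------------------------------------------------------------
# Expression tables


def read_expression(path: str) -> pd.DataFrame:
    """TSV of FPKM values, genes as rows, samples as columns."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.values < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return frame


def write_expression(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path: str) -> dict[str, set[str]]:
    """Two-column TSV ``set_name<TAB>gene_id`` -> mapping."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, gene = line.rstrip("\n").split("\t")[:2]
            sets.setdefault(name, set()).add(gene)
    return sets
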