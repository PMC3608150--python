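"""Library- and cohort-level descriptive analyses.

Covers the standard battery of DGE library diagnostics: tag abundance
distributions, sequencing saturation (genes detected vs depth), pairwise
fold-change distributions of shared tags, Venn-style overlap partitions of
expressed-gene sets, hierarchical clustering of DEG fold-change profiles,
and generic hypergeometric term enrichment with BH correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

from .differential_expression import bh_fdr
from .tag_mapping import TagAssignment
from .tag_processing import TagLibrary

DEFAULT_ABUNDANCE_BINS: Tuple[Tuple[int, Optional[int]], ...] = (
    (2, 5),
    (6, 10),
    (11, 20),
    (21, 50),
    (51, 100),
    (101, None),
)

# fold-change bins over shared tags: [1,2), [2,3), [3,4), [4,5], (5, inf)
RATIO_BIN_LABELS = ("[1,2)", "[2,3)", "[3,4)", "[4,5]", ">5")


@dataclass
class AbundanceDistribution:
    """Distinct-tag and copy counts per copy-number bin for one library."""

    library_id: str
    bins: Tuple[Tuple[int, Optional[int]], ...]
    distinct: List[int]
    copies: List[int]

    @property
    def pct_distinct(self) -> List[float]:
        total = sum(self.distinct)
        return [100.0 * d / total if total else 0.0 for d in self.distinct]

    @property
    def pct_copies(self) -> List[float]:
        total = sum(self.copies)
        return [100.0 * c / total if total else 0.0 for c in self.copies]

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"[{lo},{hi}]" if hi is not None else f">{lo - 1}" for lo, hi in self.bins
        ]
        return pd.DataFrame(
            {
                "bin": labels,
                "distinct": self.distinct,
                "distinct_pct": self.pct_distinct,
                "copies": self.copies,
                "copies_pct": self.pct_copies,
            }
        )


def abundance_distribution(
    lib: TagLibrary,
    bin_edges: Sequence[Tuple[int, Optional[int]]] = DEFAULT_ABUNDANCE_BINS,
) -> AbundanceDistribution:
    """Bin distinct tags by copy number; bin sums equal library totals."""
    bins = tuple(bin_edges)
    for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
        if hi is None or lo2 <= hi:
            raise ValueError("bins must be ascending and non-overlapping")
    distinct = [0] * len(bins)
    copies = [0] * len(bins)
    for count in lib.counts.values():
        for i, (lo, hi) in enumerate(bins):
            if count >= lo and (hi is None or count <= hi):
                distinct[i] += 1
                copies[i] += count
                break
        else:
            raise ValueError(f"copy number {count} falls outside all bins")
    return AbundanceDistribution(lib.library_id, bins, distinct, copies)


@dataclass
class SaturationCurve:
    library_id: str
    seed: int
    points: List[Tuple[int, int]]  # (depth, genes detected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["depth", "genes_detected"])


def saturation_curve(
    lib: TagLibrary,
    assignments: Sequence[TagAssignment],
    step: int,
    seed: int,
    replicates: int = 1,
) -> SaturationCurve:
    """Genes detected vs sequencing depth, by subsampling without replacement.

    Depth counts all clean tag copies drawn; detection counts distinct genes
    carrying at least one unambiguous tag copy at that depth.  With
    ``replicates`` > 1 the detection counts are averaged over independent
    subsampling orders (rounded); the curve is non-decreasing by
    construction for each replicate.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    gene_of_tag = {
        a.tag: a.gene_id for a in assignments if a.category == "gene_unambiguous"
    }
    tags = sorted(lib.counts)
    gene_ids = sorted({g for g in gene_of_tag.values()})
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    per_copy = np.repeat(
        [gene_index.get(gene_of_tag.get(t, ""), -1) for t in tags],
        [lib.counts[t] for t in tags],
    ).astype(np.int64)
    total = per_copy.size
    depths = list(range(step, total + 1, step))
    if not depths or depths[-1] != total:
        depths.append(total)

    acc = np.zeros(len(depths), dtype=float)
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        perm = per_copy[rng.permutation(total)]
        mapped = perm >= 0
        # first occurrence position of each detected gene
        _, first_idx = np.unique(perm[mapped], return_index=True)
        first_positions = np.sort(np.flatnonzero(mapped)[first_idx])
        acc += np.searchsorted(first_positions, depths, side="left")
    detected = np.rint(acc / replicates).astype(int)
    return SaturationCurve(lib.library_id, seed, list(zip(depths, detected.tolist())))


@dataclass
class RatioDistribution:
    """Fold-change bins over distinct tags shared by two libraries."""

    library_a: str
    library_b: str
    fractions: Dict[str, float]  # over shared tags only; sums to 1
    n_shared: int
    n_a_only: int
    n_b_only: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"bin": k, "fraction": v} for k, v in self.fractions.items()]
        rows.append(
            {"bin": "library_specific",
             "fraction": float(self.n_a_only + self.n_b_only)}
        )
        return pd.DataFrame(rows)


def ratio_distribution(
    lib_a: TagLibrary, lib_b: TagLibrary, normalize: bool = True
) -> RatioDistribution:
    """Distribution of folded copy-number ratios for tags shared by a pair.

    Counts are per-million normalized by default (flag to use raw counts);
    the ratio is folded to >= 1.  Tags present in one library only go to a
    separate library-specific tally outside the shared-fraction denominator.
    """
    scale_a = 1e6 / lib_a.total if normalize and lib_a.total else 1.0
    scale_b = 1e6 / lib_b.total if normalize and lib_b.total else 1.0
    shared = set(lib_a.counts) & set(lib_b.counts)
    bins = {label: 0 for label in RATIO_BIN_LABELS}
    for tag in shared:
        va = lib_a.counts[tag] * scale_a
        vb = lib_b.counts[tag] * scale_b
        fold = max(va, vb) / min(va, vb)
        if fold < 2:
            bins["[1,2)"] += 1
        elif fold < 3:
            bins["[2,3)"] += 1
        elif fold < 4:
            bins["[3,4)"] += 1
        elif fold <= 5:
            bins["[4,5]"] += 1
        else:
            bins[">5"] += 1
    n_shared = len(shared)
    fractions = {
        k: (v / n_shared if n_shared else 0.0) for k, v in bins.items()
    }
    return RatioDistribution(
        lib_a.library_id,
        lib_b.library_id,
        fractions,
        n_shared,
        len(set(lib_a.counts) - shared),
        len(set(lib_b.counts) - shared),
    )


@dataclass
class OverlapSets:
    """Full Venn partition of 2-4 named gene sets."""

    names: Tuple[str, ...]
    regions: Dict[FrozenSet[str], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def region(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "genes": v}
            for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def expression_overlaps(gene_sets: Mapping[str, Set[str]]) -> OverlapSets:
    """Exact Venn region counts for 2-4 gene sets over a shared id space."""
    names = tuple(gene_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError(
            "expression_overlaps handles 2-4 sets; run larger designs pairwise"
        )
    regions: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            members = set.intersection(*(set(gene_sets[n]) for n in inside))
            for outside in names:
                if outside not in inside:
                    members -= set(gene_sets[outside])
            regions[frozenset(inside)] = len(members)
    return OverlapSets(names, regions)


@dataclass
class ClusterTree:
    """Agglomerative clustering of genes over comparison fold-change profiles."""

    merges: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # gene -> flat cluster label
    means: pd.DataFrame  # cluster -> mean log2-ratio per comparison

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def cluster_degs(
    log2_matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
    n_clusters: int = 12,
) -> ClusterTree:
    """Average-linkage hierarchical clustering of a gene x comparison matrix.

    Rows are DEGs (union or intersection over comparisons), cells are log2
    ratios with untested cells imputed as 0 upstream.  The flat partition
    cuts the tree at ``n_clusters`` (maxclust); merges are deterministic
    given the input (ties resolve to the lowest-index pair).
    """
    if log2_matrix.empty:
        raise ValueError("empty DEG matrix")
    values = log2_matrix.to_numpy(dtype=float)
    if values.shape[0] == 1:
        merges = np.empty((0, 4))
        labels = pd.Series([1], index=log2_matrix.index, name="cluster")
    else:
        merges = linkage(values, method=method, metric=metric)
        labels = pd.Series(
            fcluster(merges, t=n_clusters, criterion="maxclust"),
            index=log2_matrix.index,
            name="cluster",
        )
    means = log2_matrix.groupby(labels).mean()
    return ClusterTree(merges, labels, means)


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    k: int  # term genes in foreground
    K: int  # term genes in background
    n: int  # foreground size
    N: int  # background size
    p_value: float
    q_value: float

    @property
    def significant(self) -> bool:
        return self.q_value <= 0.05


def term_enrichment(
    foreground: Set[str],
    background: Set[str],
    gene_to_terms: Mapping[str, Set[str]],
) -> List[EnrichmentRecord]:
    """Hypergeometric upper-tail enrichment of terms in a foreground set.

    Only terms with at least one foreground gene are tested; BH q-values are
    computed across the tested terms.  Genes without annotation still count
    in N and n.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    term_bg: Dict[str, int] = {}
    term_fg: Dict[str, int] = {}
    for gene in background:
        for term in gene_to_terms.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in foreground:
                term_fg[term] = term_fg.get(term, 0) + 1
    tested = sorted(term_fg)
    N, n = len(background), len(foreground)
    pvals = [
        float(hypergeom.sf(term_fg[t] - 1, N, term_bg[t], n)) for t in tested
    ]
    qvals = bh_fdr(pvals)
    records = [
        EnrichmentRecord(t, term_fg[t], term_bg[t], n, N, p, float(q))
        for t, p, q in zip(tested, pvals, qvals)
    ]
    records.sort(key=lambda r: (r.p_value, r.term))
    return records
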