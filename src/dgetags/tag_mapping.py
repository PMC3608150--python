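"""Clean-tag categorization, library accounting, and per-gene TPM profiles.

Every distinct clean tag falls in exactly one category at its best matching
stratum (exact before single-mismatch):

* ``gene_unambiguous`` — hits exactly one gene; credited to that gene with
  an orientation (sense/antisense),
* ``gene_ambiguous``  — hits two or more genes; counted as gene-mapped but
  credited to none,
* ``genome_only``     — no gene hit but present in the genome-wide tag set,
* ``unknown``         — no match anywhere at <= 1 mismatch.

The three top-level categories (gene, genome, unknown) therefore partition
both the total and the distinct clean-tag counts of a library exactly.

Expression is the count of unambiguous tag copies per (gene, orientation),
normalized to TPM against the library's total clean-tag count (not the
mapped count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .reference_tags import ReferenceTagIndex
from .tag_processing import TagLibrary

logger = logging.getLogger(__name__)

CATEGORIES = ("gene_unambiguous", "gene_ambiguous", "genome_only", "unknown")


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """A printed percentage: 100*part/whole rounded to ``ndigits`` decimals."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, ndigits)


@dataclass(frozen=True)
class TagAssignment:
    """One distinct clean tag resolved against the reference index."""

    tag: str
    count: int
    category: str
    gene_id: Optional[str]
    orientation: Optional[str]
    stratum: str
    hit_genes: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category}")
        if (self.gene_id is not None) != (self.category == "gene_unambiguous"):
            raise ValueError("gene_id set iff category is gene_unambiguous")
        if self.category == "unknown" and self.stratum != "none":
            raise ValueError("unknown tags have stratum none")


@dataclass
class LibrarySummary:
    """Per-library accounting of tag categories and gene detection."""

    library_id: str
    clean_total: int
    clean_distinct: int
    gene_total: int
    gene_distinct: int
    unambiguous_total: int
    unambiguous_distinct: int
    genome_total: int
    genome_distinct: int
    unknown_total: int
    unknown_distinct: int
    tag_mapped_genes: int
    unambiguous_tag_mapped_genes: int
    both_strand_genes: int

    def check_partition(self) -> None:
        """The three categories must partition clean totals and distincts."""
        if self.gene_total + self.genome_total + self.unknown_total != self.clean_total:
            raise AssertionError("total partition identity violated")
        if (
            self.gene_distinct + self.genome_distinct + self.unknown_distinct
            != self.clean_distinct
        ):
            raise AssertionError("distinct partition identity violated")
        if self.unambiguous_total > self.gene_total:
            raise AssertionError("unambiguous exceeds gene-mapped total")
        if self.unambiguous_tag_mapped_genes > self.tag_mapped_genes:
            raise AssertionError("unambiguous genes exceed tag-mapped genes")


@dataclass
class GeneExpressionProfile:
    """Per-gene sense/antisense unambiguous tag counts and TPM for one library."""

    library_id: str
    clean_total: int
    sense: Dict[str, int] = field(default_factory=dict)
    antisense: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clean_total <= 0:
            raise ValueError("clean_total must be positive")

    @property
    def genes(self) -> Set[str]:
        return set(self.sense) | set(self.antisense)

    def sense_count(self, gene: str) -> int:
        return self.sense.get(gene, 0)

    def antisense_count(self, gene: str) -> int:
        return self.antisense.get(gene, 0)

    def tpm(self, count: int) -> float:
        return 1e6 * count / self.clean_total

    def sense_tpm(self, gene: str) -> float:
        return self.tpm(self.sense_count(gene))

    def antisense_tpm(self, gene: str) -> float:
        return self.tpm(self.antisense_count(gene))

    def to_frame(self) -> pd.DataFrame:
        lid = self.library_id
        rows = []
        for gene in sorted(self.genes):
            s, a = self.sense_count(gene), self.antisense_count(gene)
            rows.append(
                {
                    "gene": gene,
                    f"{lid}_sense_raw": s,
                    f"{lid}_antisense_raw": a,
                    f"{lid}_sense_norm": self.tpm(s),
                    f"{lid}_antisense_norm": self.tpm(a),
                }
            )
        return pd.DataFrame(rows)


def assign_tags(clean: TagLibrary, index: ReferenceTagIndex) -> List[TagAssignment]:
    """Resolve every distinct clean tag to its category at the best stratum."""
    if clean.stage != "clean":
        raise ValueError("assign_tags expects a clean library")
    assignments: List[TagAssignment] = []
    n_dual = 0
    for tag, count in clean.counts.items():
        hit = index.query(tag)
        if hit.gene_hits:
            gene_ids = frozenset(vt.gene_id for vt in hit.gene_hits)
            if len(gene_ids) == 1:
                gene_id = next(iter(gene_ids))
                orientations = {vt.orientation for vt in hit.gene_hits}
                if orientations == {"sense", "antisense"}:
                    # single gene matched on both strands at the same stratum:
                    # credit as sense (parsimonious transcriptional origin)
                    n_dual += 1
                orientation = "sense" if "sense" in orientations else "antisense"
                assignments.append(
                    TagAssignment(
                        tag, count, "gene_unambiguous", gene_id, orientation,
                        hit.stratum, gene_ids,
                    )
                )
            else:
                assignments.append(
                    TagAssignment(
                        tag, count, "gene_ambiguous", None, None, hit.stratum, gene_ids
                    )
                )
        elif hit.genome_hit:
            assignments.append(
                TagAssignment(tag, count, "genome_only", None, None, hit.stratum)
            )
        else:
            assignments.append(
                TagAssignment(tag, count, "unknown", None, None, "none")
            )
    if n_dual:
        logger.info(
            "%s: %d tags hit one gene in both orientations; credited as sense",
            clean.library_id, n_dual,
        )
    return assignments


def summarize_library(
    assignments: Sequence[TagAssignment], clean: TagLibrary
) -> LibrarySummary:
    """Category totals/distincts plus tag-mapped gene counts for one library.

    Gene detection counts genes reachable through ambiguous hit sets too;
    the unambiguous gene count and both-strand gene count use unambiguous
    tags only.
    """
    if {a.tag for a in assignments} != set(clean.counts):
        raise ValueError("assignments do not cover exactly the library's tags")
    totals = {c: 0 for c in CATEGORIES}
    distincts = {c: 0 for c in CATEGORIES}
    tag_mapped: Set[str] = set()
    unamb_sense: Set[str] = set()
    unamb_anti: Set[str] = set()
    for a in assignments:
        totals[a.category] += a.count
        distincts[a.category] += 1
        tag_mapped.update(a.hit_genes)
        if a.category == "gene_unambiguous":
            (unamb_sense if a.orientation == "sense" else unamb_anti).add(a.gene_id)
    gene_total = totals["gene_unambiguous"] + totals["gene_ambiguous"]
    gene_distinct = distincts["gene_unambiguous"] + distincts["gene_ambiguous"]
    summary = LibrarySummary(
        library_id=clean.library_id,
        clean_total=clean.total,
        clean_distinct=clean.distinct,
        gene_total=gene_total,
        gene_distinct=gene_distinct,
        unambiguous_total=totals["gene_unambiguous"],
        unambiguous_distinct=distincts["gene_unambiguous"],
        genome_total=totals["genome_only"],
        genome_distinct=distincts["genome_only"],
        unknown_total=totals["unknown"],
        unknown_distinct=distincts["unknown"],
        tag_mapped_genes=len(tag_mapped),
        unambiguous_tag_mapped_genes=len(unamb_sense | unamb_anti),
        both_strand_genes=len(unamb_sense & unamb_anti),
    )
    summary.check_partition()
    return summary


def compute_profile(
    assignments: Sequence[TagAssignment], clean_total: int, library_id: str
) -> GeneExpressionProfile:
    """Accumulate unambiguous tag copies per (gene, orientation) into a profile.

    A tag hitting the same gene at several sites is credited once (its copy
    count is not multiplied by the number of sites).
    """
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    profile = GeneExpressionProfile(library_id, clean_total)
    for a in assignments:
        if a.category != "gene_unambiguous":
            continue
        target = profile.sense if a.orientation == "sense" else profile.antisense
        target[a.gene_id] = target.get(a.gene_id, 0) + a.count
    return profile


# ---------------------------------------------------------------------------
# Tabular output


def summary_table(summaries: Sequence[LibrarySummary]) -> pd.DataFrame:
    """Library accounting in the conventional row layout, with percentages.

    Percentages of clean tags are printed to two decimals; gene percentages
    would need a reference gene count and are left to the caller.
    """
    rows = {}
    for s in summaries:
        rows[s.library_id] = {
            "clean_total": s.clean_total,
            "clean_distinct": s.clean_distinct,
            "gene_total": s.gene_total,
            "gene_distinct": s.gene_distinct,
            "unambiguous_total": s.unambiguous_total,
            "unambiguous_total_pct": percent(s.unambiguous_total, s.clean_total),
            "unambiguous_distinct": s.unambiguous_distinct,
            "unambiguous_distinct_pct": percent(s.unambiguous_distinct, s.clean_distinct),
            "genome_total": s.genome_total,
            "genome_total_pct": percent(s.genome_total, s.clean_total),
            "genome_distinct": s.genome_distinct,
            "unknown_total": s.unknown_total,
            "unknown_total_pct": percent(s.unknown_total, s.clean_total),
            "unknown_distinct": s.unknown_distinct,
            "tag_mapped_genes": s.tag_mapped_genes,
            "unambiguous_tag_mapped_genes": s.unambiguous_tag_mapped_genes,
            "both_strand_genes": s.both_strand_genes,
        }
    return pd.DataFrame(rows)


def expression_matrix(profiles: Sequence[GeneExpressionProfile]) -> pd.DataFrame:
    """Gene x library matrix of raw and normalized sense/antisense values."""
    frames = [p.to_frame().set_index("gene") for p in profiles]
    out = pd.concat(frames, axis=1).fillna(0)
    raw_cols = [c for c in out.columns if c.endswith("_raw")]
    out[raw_cols] = out[raw_cols].astype(int)
    return out.sort_index()
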