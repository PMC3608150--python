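"""End-to-end conveniences tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .differential_expression import ComparisonResult
from .reference_tags import ReferenceTagIndex, build_reference_index
from .tag_mapping import (
    GeneExpressionProfile,
    LibrarySummary,
    TagAssignment,
    assign_tags,
    compute_profile,
    summarize_library,
)
from .tag_processing import FilterReport, TagLibrary, build_raw_library, clean_library


@dataclass
class LibraryResult:
    """Everything the pipeline derives from one library's raw reads."""

    raw: TagLibrary
    clean: TagLibrary
    report: FilterReport
    assignments: List[TagAssignment]
    summary: LibrarySummary
    profile: Optional[GeneExpressionProfile]


def process_library(
    reads: Iterable[str],
    library_id: str,
    index: ReferenceTagIndex,
    adaptors: Sequence[str] = (),
) -> LibraryResult:
    """Raw reads -> raw library -> clean library -> assignments -> profile."""
    raw, n_empty = build_raw_library(reads, library_id)
    clean, report = clean_library(raw, adaptors=adaptors, n_empty=n_empty)
    assignments = assign_tags(clean, index)
    summary = summarize_library(assignments, clean)
    profile = (
        compute_profile(assignments, clean.total, library_id)
        if clean.total > 0
        else None
    )
    return LibraryResult(raw, clean, report, assignments, summary, profile)


def deg_log2_matrix(
    results: Sequence[ComparisonResult], mode: str = "union"
) -> pd.DataFrame:
    """Gene x comparison log2-ratio matrix over the union or intersection of DEGs.

    Cells for genes not tested in a comparison are imputed as 0 (no evidence
    of change).  Column names are "control vs experimental".
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    sig_sets = [r.significant_genes for r in results]
    genes = set.union(*sig_sets) if mode == "union" else set.intersection(*sig_sets)
    columns = {}
    for r in results:
        name = f"{r.control_id} vs {r.experimental_id}"
        lookup = {rec.gene_id: rec.log2_ratio for rec in r.records}
        columns[name] = [lookup.get(g, 0.0) for g in sorted(genes)]
    return pd.DataFrame(columns, index=sorted(genes))
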