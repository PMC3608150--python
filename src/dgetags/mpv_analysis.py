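"""Mid-parent-value (MPV) construction and non-additive expression calls.

The MPV is the expression a hybrid would show if it simply inherited the
sum of its parents' transcriptomes.  It is built in silico by pooling the
two parents' raw unambiguous tag counts and totals (an equal RNA mixture
sequenced at the combined depth); with near-equal parental library sizes
this equals the mean of the parental TPMs to first order.

A hybrid gene is called non-additive when hybrid-vs-MPV is significant
under the same screen as any library pair (conditional count test,
FDR <= 0.001, |log2 ratio| >= 1), partitioned into above/below MPV by the
sign of the ratio and cross-tabulated by parental bias (Br > Bo, Br < Bo,
with exact ties reported as their own row rather than merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .differential_expression import (
    FDR_THRESHOLD,
    LOG2_THRESHOLD,
    ComparisonResult,
    compare_libraries,
)
from .tag_mapping import GeneExpressionProfile, percent


def mid_parent_profile(
    br: GeneExpressionProfile, bo: GeneExpressionProfile, library_id: str = "MPV"
) -> GeneExpressionProfile:
    """Pool parental counts and totals into the in-silico mid-parent library."""
    sense: Dict[str, int] = dict(br.sense)
    for g, c in bo.sense.items():
        sense[g] = sense.get(g, 0) + c
    antisense: Dict[str, int] = dict(br.antisense)
    for g, c in bo.antisense.items():
        antisense[g] = antisense.get(g, 0) + c
    return GeneExpressionProfile(
        library_id, br.clean_total + bo.clean_total, sense, antisense
    )


@dataclass(frozen=True)
class GeneClass:
    gene_id: str
    regulation: str  # "additive" | "above_mpv" | "below_mpv"
    parental_bias: str  # "Br>Bo" | "Br<Bo" | "Br=Bo"
    log2_ratio: float
    fdr: float


@dataclass
class NonAdditiveSummary:
    """Counts of non-additive genes split by direction and parental bias.

    ``n_nonadditive`` (a) = ``n_above`` (b) + ``n_below`` (c).  Rows
    cross-tabulate by which parent expressed the gene more highly;
    percentages are recomputable from the counts.
    """

    n_nonadditive: int
    n_above: int
    n_below: int
    rows: Dict[str, Dict[str, int]]  # bias -> {total, above, below}

    @property
    def pct_above(self) -> float:
        return percent(self.n_above, self.n_nonadditive, 1)

    @property
    def pct_below(self) -> float:
        return percent(self.n_below, self.n_nonadditive, 1)

    def check_partition(self) -> None:
        if self.n_above + self.n_below != self.n_nonadditive:
            raise AssertionError("above + below != non-additive total")
        if sum(r["total"] for r in self.rows.values()) != self.n_nonadditive:
            raise AssertionError("bias rows do not partition the non-additive set")
        for r in self.rows.values():
            if r["above"] + r["below"] != r["total"]:
                raise AssertionError("bias row does not split into above + below")

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped summary: a / b / c counts with percentages to 1 decimal."""
        records = [
            {
                "row": "hybrid_vs_mpv",
                "a_total": self.n_nonadditive,
                "a_pct": "",
                "b_above": self.n_above,
                "b_pct": "",
                "b_over_a_pct": self.pct_above,
                "c_below": self.n_below,
                "c_pct": "",
                "c_over_a_pct": self.pct_below,
            }
        ]
        for bias in ("Br>Bo", "Br<Bo", "Br=Bo"):
            if bias not in self.rows:
                continue
            r = self.rows[bias]
            records.append(
                {
                    "row": bias,
                    "a_total": r["total"],
                    "a_pct": percent(r["total"], self.n_nonadditive, 1),
                    "b_above": r["above"],
                    "b_pct": percent(r["above"], self.n_above, 1),
                    "b_over_a_pct": percent(r["above"], r["total"], 1),
                    "c_below": r["below"],
                    "c_pct": percent(r["below"], self.n_below, 1),
                    "c_over_a_pct": percent(r["below"], r["total"], 1),
                }
            )
        return pd.DataFrame(records)


def summarize_nonadditive(
    n_above_by_bias: Dict[str, int], n_below_by_bias: Dict[str, int]
) -> NonAdditiveSummary:
    """Assemble and validate the summary from per-bias above/below counts."""
    biases = set(n_above_by_bias) | set(n_below_by_bias)
    rows = {}
    for bias in biases:
        above = n_above_by_bias.get(bias, 0)
        below = n_below_by_bias.get(bias, 0)
        if above + below:
            rows[bias] = {"total": above + below, "above": above, "below": below}
    n_above = sum(r["above"] for r in rows.values())
    n_below = sum(r["below"] for r in rows.values())
    summary = NonAdditiveSummary(n_above + n_below, n_above, n_below, rows)
    summary.check_partition()
    return summary


@dataclass
class NonAdditiveResult:
    comparison: ComparisonResult  # MPV (control) vs hybrid (experimental)
    classes: List[GeneClass]
    summary: NonAdditiveSummary


def classify_non_additive(
    hybrid: GeneExpressionProfile,
    mpv: GeneExpressionProfile,
    br: GeneExpressionProfile,
    bo: GeneExpressionProfile,
    fdr_threshold: float = FDR_THRESHOLD,
    log2_threshold: float = LOG2_THRESHOLD,
) -> NonAdditiveResult:
    """Call non-additive genes by testing the hybrid against the MPV library."""
    comparison = compare_libraries(
        mpv, hybrid, fdr_threshold=fdr_threshold, log2_threshold=log2_threshold
    )
    classes: List[GeneClass] = []
    above_by_bias: Dict[str, int] = {}
    below_by_bias: Dict[str, int] = {}
    for rec in comparison.records:
        br_tpm = br.sense_tpm(rec.gene_id)
        bo_tpm = bo.sense_tpm(rec.gene_id)
        if br_tpm > bo_tpm:
            bias = "Br>Bo"
        elif br_tpm < bo_tpm:
            bias = "Br<Bo"
        else:
            bias = "Br=Bo"
        if not rec.significant:
            regulation = "additive"
        elif rec.log2_ratio > 0:
            regulation = "above_mpv"
            above_by_bias[bias] = above_by_bias.get(bias, 0) + 1
        else:
            regulation = "below_mpv"
            below_by_bias[bias] = below_by_bias.get(bias, 0) + 1
        classes.append(GeneClass(rec.gene_id, regulation, bias, rec.log2_ratio, rec.fdr))
    summary = summarize_nonadditive(above_by_bias, below_by_bias)
    return NonAdditiveResult(comparison, classes, summary)


def write_gene_classes_tsv(result: NonAdditiveResult, path) -> None:
    pd.DataFrame(
        {
            "gene": [c.gene_id for c in result.classes],
            "regulation": [c.regulation for c in result.classes],
            "parental_bias": [c.parental_bias for c in result.classes],
            "log2_ratio": [c.log2_ratio for c in result.classes],
            "FDR": [c.fdr for c in result.classes],
        }
    ).to_csv(path, sep="\t", index=False)


def write_summary_tsv(result: NonAdditiveResult, path) -> None:
    result.summary.to_frame().to_csv(path, sep="\t", index=False)
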