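"""Pairwise count-based differential expression between tag libraries.

Single-library DGE data have no replicates, so significance comes from the
Audic–Claverie style conditional count model: given the pair total
``n = x + y`` of a gene's tag copies across libraries A (total ``n_a``) and
B (total ``n_b``), the count in B follows

    P(y) = r**y * (x+y)! / (x! * y! * (1+r)**(x+y)),   r = n_b / n_a,

which is the binomial pmf of ``y`` in ``n`` trials with success probability
q = n_b / (n_a + n_b).  Two-sided p-values double the smaller of the two
binomial tails and are capped at 1; the construction is exactly symmetric
under swapping the libraries, (x, n_a) <-> (y, n_b).

Significance uses the standard stringent screen for tag counts:
FDR <= 0.001 (Benjamini–Hochberg within the comparison) and
|log2 ratio| >= 1, with TPM floored at 0.001 for genes absent from one
library.  Testing is on sense counts; antisense profiles are reported
upstream but not tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .tag_mapping import GeneExpressionProfile

FDR_THRESHOLD = 0.001
LOG2_THRESHOLD = 1.0
TPM_FLOOR = 0.001


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    tpm_a: float
    tpm_b: float
    raw_a: int
    raw_b: int
    log2_ratio: float
    p_value: float
    fdr: float
    significant: bool
    direction: str  # "up" | "down" | "none"


@dataclass
class ComparisonResult:
    """All tested genes for one 'control vs experimental' library pair."""

    control_id: str
    experimental_id: str
    records: List[DEGRecord]

    @property
    def n_up(self) -> int:
        return sum(1 for r in self.records if r.direction == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for r in self.records if r.direction == "down")

    @property
    def significant(self) -> List[DEGRecord]:
        return [r for r in self.records if r.significant]

    @property
    def significant_genes(self) -> set:
        return {r.gene_id for r in self.records if r.significant}


def ac_pvalue(x: int, y: int, n_a: float, n_b: float) -> float:
    """Two-sided conditional-count p-value for the pair (x, y).

    Conditional on the pair total n = x + y, the experimental count is
    binomial with success probability q = n_b / (n_a + n_b); the smaller of
    the two tails at y is doubled and the result capped at 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")
    n = x + y
    if n == 0:
        return 1.0
    q = n_b / (n_a + n_b)
    lower = float(binom.cdf(y, n, q))
    upper = float(binom.sf(y - 1, n, q))
    return min(1.0, 2.0 * min(lower, upper))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, q >= p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_libraries(
    control: GeneExpressionProfile,
    experimental: GeneExpressionProfile,
    fdr_threshold: float = FDR_THRESHOLD,
    log2_threshold: float = LOG2_THRESHOLD,
) -> ComparisonResult:
    """Screen every sense-expressed gene of the pair for differential expression.

    Genes with zero sense counts in both libraries are excluded before the
    FDR correction (they carry no information and would inflate m).
    """
    if control.library_id == experimental.library_id:
        raise ValueError("control and experimental must be different libraries")
    genes = sorted(
        g
        for g in (set(control.sense) | set(experimental.sense))
        if control.sense_count(g) > 0 or experimental.sense_count(g) > 0
    )
    raw_a = [control.sense_count(g) for g in genes]
    raw_b = [experimental.sense_count(g) for g in genes]
    tpm_a = [control.sense_tpm(g) for g in genes]
    tpm_b = [experimental.sense_tpm(g) for g in genes]
    log2_ratio = [
        math.log2(max(tb, TPM_FLOOR) / max(ta, TPM_FLOOR))
        for ta, tb in zip(tpm_a, tpm_b)
    ]
    pvals = [
        ac_pvalue(xa, xb, control.clean_total, experimental.clean_total)
        for xa, xb in zip(raw_a, raw_b)
    ]
    fdrs = bh_fdr(pvals)
    records = []
    for i, g in enumerate(genes):
        sig = fdrs[i] <= fdr_threshold and abs(log2_ratio[i]) >= log2_threshold
        direction = "none"
        if sig:
            direction = "up" if log2_ratio[i] > 0 else "down"
        records.append(
            DEGRecord(
                g, tpm_a[i], tpm_b[i], raw_a[i], raw_b[i],
                log2_ratio[i], pvals[i], float(fdrs[i]), sig, direction,
            )
        )
    return ComparisonResult(control.library_id, experimental.library_id, records)


def top_k(result: ComparisonResult, k: int = 20) -> Tuple[List[DEGRecord], List[DEGRecord]]:
    """Top-k up- and down-regulated significant genes by |log2 ratio|.

    Genes expressed in only one library are excluded (their fold change is
    floor-driven).  Ties break by smaller FDR, then gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = [r for r in result.significant if r.raw_a > 0 and r.raw_b > 0]
    key = lambda r: (-abs(r.log2_ratio), r.fdr, r.gene_id)
    up = sorted((r for r in eligible if r.direction == "up"), key=key)[:k]
    down = sorted((r for r in eligible if r.direction == "down"), key=key)[:k]
    return up, down


def comparison_frame(result: ComparisonResult) -> pd.DataFrame:
    """Per-gene TSV-ready table for one comparison (control = A, experimental = B)."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in result.records],
            f"TPM_{result.control_id}": [r.tpm_a for r in result.records],
            f"TPM_{result.experimental_id}": [r.tpm_b for r in result.records],
            f"raw_{result.control_id}": [r.raw_a for r in result.records],
            f"raw_{result.experimental_id}": [r.raw_b for r in result.records],
            "log2Ratio": [r.log2_ratio for r in result.records],
            "p_value": [r.p_value for r in result.records],
            "FDR": [r.fdr for r in result.records],
            "significant": [r.significant for r in result.records],
            "direction": [r.direction for r in result.records],
        }
    )


def write_comparison_tsv(result: ComparisonResult, path) -> None:
    comparison_frame(result).to_csv(path, sep="\t", index=False)
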