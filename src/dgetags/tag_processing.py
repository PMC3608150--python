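"""Raw-read tag extraction and clean-tag filtering.

A 35-bp DGE read carries at most one informative 21-mer: the CATG anchor
plus 17 downstream nucleotides.  Extraction takes the first CATG with at
least 17 nt following.  Cleaning then removes, in a fixed order, adaptor
tags, tags containing N, and singleton tags (copy number 1), pooling all
reads of one library before the singleton rule is applied.  Each removed
copy is attributed to exactly one filter, so raw and clean totals satisfy
an exact conservation identity.

Quality strings in FASTQ input are parsed but otherwise unused; N bases in
the sequence are the only low-quality signal acted upon.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .reference_tags import ANCHOR, TAG_LENGTH


@dataclass
class TagLibrary:
    """Distinct tag sequences with copy counts for one library."""

    library_id: str
    counts: Dict[str, int]
    stage: str  # "raw" | "clean"

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "clean"):
            raise ValueError("stage must be 'raw' or 'clean'")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative tag count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return len(self.counts)


@dataclass
class FilterReport:
    """Fate accounting for every raw read/copy removed during cleaning.

    ``n_empty`` counts reads yielding no tag (no CATG with 17 nt after it);
    the remaining fields count tag *copies* removed by each filter, plus the
    number of distinct singleton tags.  Conservation:
    raw_reads = clean_total + n_empty + n_adaptor + n_lowquality + n_singleton_copies.
    """

    n_empty: int = 0
    n_adaptor: int = 0
    n_lowquality: int = 0
    n_singleton_tags: int = 0
    n_singleton_copies: int = 0

    @property
    def removed_copies(self) -> int:
        return self.n_empty + self.n_adaptor + self.n_lowquality + self.n_singleton_copies

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def extract_tag(read: str) -> Optional[str]:
    """The 21-mer at the first CATG site with >= 17 nt following, else None."""
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    limit = len(read) - TAG_LENGTH
    start = 0
    while True:
        i = read.find(ANCHOR, start)
        if i == -1 or i > limit:
            return None
        return read[i : i + TAG_LENGTH]


def build_raw_library(reads: Iterable[str], library_id: str) -> Tuple[TagLibrary, int]:
    """Count extracted tags over all reads; returns (raw library, n_empty reads)."""
    counts: Counter = Counter()
    n_empty = 0
    for read in reads:
        tag = extract_tag(read)
        if tag is None:
            n_empty += 1
        else:
            counts[tag] += 1
    return TagLibrary(library_id, dict(counts), stage="raw"), n_empty


def clean_library(
    raw: TagLibrary,
    adaptors: Sequence[str] = (),
    n_empty: int = 0,
) -> Tuple[TagLibrary, FilterReport]:
    """Apply the clean-tag filters: adaptor -> N -> singleton, in that order.

    Each tag is attributed to the first filter it triggers, so removed-copy
    categories are disjoint and the conservation identity is exact.
    ``n_empty`` (reads that produced no tag) is carried into the report so a
    single report accounts for every raw read.
    """
    adaptors = [a.upper() for a in adaptors]
    report = FilterReport(n_empty=n_empty)
    kept: Dict[str, int] = {}
    for tag, count in raw.counts.items():
        if any(a in tag for a in adaptors):
            report.n_adaptor += count
        elif "N" in tag:
            report.n_lowquality += count
        elif count == 1:
            report.n_singleton_tags += 1
            report.n_singleton_copies += 1
        else:
            kept[tag] = count
    return TagLibrary(raw.library_id, kept, stage="clean"), report


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path) -> Iterable[str]:
    """Yield read sequences from a FASTQ file (qualities parsed, unused)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


def write_library_tsv(lib: TagLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(lib.counts):
            fh.write(f"{tag}\t{lib.counts[tag]}\n")


def read_library_tsv(path, library_id: str, stage: str) -> TagLibrary:
    counts: Dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            tag, count = line.rstrip("\n").split("\t")
            counts[tag] = int(count)
    return TagLibrary(library_id, counts, stage=stage)
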