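"""Virtual CATG-anchored tag database built from gene models and a genome.

NlaIII-style digital gene expression (DGE) tags are 21-mers that begin at a
CATG restriction site and extend 17 nt downstream.  To annotate observed
tags we enumerate, for every gene, all CATG-anchored 21-mers of its spliced
transcript (sense tags) and of the transcript's reverse complement
(antisense tags), and separately the set of all CATG-anchored 21-mers
present anywhere in the genome on either strand.  Observed tags are then
looked up exactly first, and failing that against all 63 single-mismatch
variants.

All sites per transcript are indexed, not only the 3'-most (canonical
NlaIII) site; ``site_rank`` records the 3'-to-5' order so canonical-only
analyses can filter on ``site_rank == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio import SeqIO

ANCHOR = "CATG"
TAG_LENGTH = 21

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def anchored_offsets(seq: str) -> List[int]:
    """Offsets of CATG occurrences with >= 17 nt following (full 21-mer fits)."""
    out: List[int] = []
    limit = len(seq) - TAG_LENGTH
    start = 0
    while True:
        i = seq.find(ANCHOR, start)
        if i == -1 or i > limit:
            break
        out.append(i)
        start = i + 1
    return out


def anchored_tags(seq: str) -> List[Tuple[int, str]]:
    """All (offset, 21-mer) pairs of CATG-anchored tags fully inside ``seq``."""
    return [(o, seq[o : o + TAG_LENGTH]) for o in anchored_offsets(seq)]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its spliced transcript sequence, 5'->3' on the coding strand."""

    gene_id: str
    chrom: str
    strand: str
    transcript_seq: str

    def __post_init__(self) -> None:
        if not self.transcript_seq:
            raise ValueError(f"gene {self.gene_id}: empty transcript")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        seq = self.transcript_seq.upper()
        if set(seq) - _ALPHABET:
            bad = sorted(set(seq) - _ALPHABET)
            raise ValueError(f"gene {self.gene_id}: invalid bases {bad}")
        object.__setattr__(self, "transcript_seq", seq)


@dataclass(frozen=True, order=True)
class VirtualTag:
    """A reference tag: which gene it identifies, on which strand, at which site.

    ``site_rank`` is 1 for the 3'-most CATG site on that strand and increases
    towards the 5' end.
    """

    seq: str
    gene_id: str
    orientation: str  # "sense" | "antisense"
    site_rank: int


@dataclass(frozen=True)
class TagHit:
    """Result of a single tag query against the reference index.

    ``stratum`` is "exact" when the tag itself matched, "1MM" when only a
    Hamming-distance-1 variant matched, "none" otherwise.  ``gene_hits`` is
    the set of matching virtual tags at the best stratum; ``genome_hit``
    reports whether the genome-wide tag set matches at (or below) the same
    stratum.
    """

    stratum: str
    gene_hits: FrozenSet[VirtualTag]
    genome_hit: bool


def mismatch_variants(tag: str) -> Iterable[str]:
    """The 63 sequences at Hamming distance exactly 1 from a 21-mer (ACGT only)."""
    for i, base in enumerate(tag):
        for alt in "ACGT":
            if alt != base:
                yield tag[:i] + alt + tag[i + 1 :]


class ReferenceTagIndex:
    """Lookup from 21-mer tag to gene hits, plus the genome-wide tag set.

    Build with :func:`build_reference_index`.
    """

    def __init__(
        self,
        gene_tags: Mapping[str, FrozenSet[VirtualTag]],
        genome_tag_set: Set[str],
        genes_without_tags: Sequence[str] = (),
    ) -> None:
        self._gene_tags: Dict[str, FrozenSet[VirtualTag]] = dict(gene_tags)
        self.genome_tag_set: FrozenSet[str] = frozenset(genome_tag_set)
        self.genes_without_tags: Tuple[str, ...] = tuple(genes_without_tags)

    def __contains__(self, tag: str) -> bool:
        return tag in self._gene_tags

    def __len__(self) -> int:
        return len(self._gene_tags)

    @property
    def tags(self) -> FrozenSet[str]:
        return frozenset(self._gene_tags)

    def gene_hits_exact(self, tag: str) -> FrozenSet[VirtualTag]:
        return self._gene_tags.get(tag, frozenset())

    def query(self, tag: str) -> TagHit:
        """Resolve one observed tag: exact beats 1MM; N never matches."""
        if len(tag) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(tag)}")
        tag = tag.upper()
        if "N" in tag:
            return TagHit("none", frozenset(), False)

        exact = self._gene_tags.get(tag)
        if exact:
            return TagHit("exact", exact, tag in self.genome_tag_set)

        onemm: Set[VirtualTag] = set()
        genome_1mm = False
        for var in mismatch_variants(tag):
            hits = self._gene_tags.get(var)
            if hits:
                onemm.update(hits)
            if var in self.genome_tag_set:
                genome_1mm = True
        if onemm:
            genome_hit = tag in self.genome_tag_set or genome_1mm
            return TagHit("1MM", frozenset(onemm), genome_hit)
        if tag in self.genome_tag_set:
            return TagHit("exact", frozenset(), True)
        if genome_1mm:
            return TagHit("1MM", frozenset(), True)
        return TagHit("none", frozenset(), False)


def build_reference_index(
    genes: Sequence[GeneModel],
    genome: Optional[Mapping[str, str]] = None,
) -> ReferenceTagIndex:
    """Enumerate every CATG-anchored 21-mer of every gene and of the genome.

    Sense tags come from the transcript, antisense tags from its reverse
    complement; site ranks are assigned 3'->5' independently per strand.
    Tags containing N are never indexed (an N in the reference matches no
    observed base).  Genes yielding zero tags are recorded in
    ``genes_without_tags`` rather than raising.
    """
    if not genes:
        raise ValueError("gene list is empty")
    seen_ids: Set[str] = set()
    tag_map: Dict[str, Set[VirtualTag]] = {}
    tagless: List[str] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.gene_id in seen_ids:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        seen_ids.add(gene.gene_id)
        n_registered = 0
        for orientation, seq in (
            ("sense", gene.transcript_seq),
            ("antisense", reverse_complement(gene.transcript_seq)),
        ):
            sites = anchored_tags(seq)
            # highest offset = closest to that strand's 3' end = rank 1
            for rank, (_, tagseq) in enumerate(
                sorted(sites, key=lambda t: -t[0]), start=1
            ):
                if "N" in tagseq:
                    continue
                vt = VirtualTag(tagseq, gene.gene_id, orientation, rank)
                tag_map.setdefault(tagseq, set()).add(vt)
                n_registered += 1
        if n_registered == 0:
            tagless.append(gene.gene_id)

    genome_tags: Set[str] = set()
    if genome is not None:
        for chrom_seq in genome.values():
            chrom_seq = chrom_seq.upper()
            for strand_seq in (chrom_seq, reverse_complement(chrom_seq)):
                for _, tagseq in anchored_tags(strand_seq):
                    if "N" not in tagseq:
                        genome_tags.add(tagseq)

    frozen = {t: frozenset(v) for t, v in tag_map.items()}
    return ReferenceTagIndex(frozen, genome_tags, tagless)


# ---------------------------------------------------------------------------
# I/O


def load_genome_fasta(path) -> Dict[str, str]:
    """Read a genome (or any sequence collection) FASTA into {name: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def gene_models_from_transcripts_fasta(path) -> List[GeneModel]:
    """Treat each FASTA record as a pre-spliced transcript (one gene each)."""
    return [
        GeneModel(rec.id, chrom=".", strand="+", transcript_seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def load_gene_models(gff3_path, genome: Mapping[str, str]) -> List[GeneModel]:
    """Build spliced transcripts from GFF3 exon features, strand-aware.

    Exons are concatenated in genomic order and reverse-complemented for
    minus-strand genes.  GFF3 coordinates are 1-based inclusive; internal
    slices are 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = list(db.children(gene, featuretype="exon", order_by="start"))
        if not exons:
            exons = [gene]
        chrom_seq = genome[gene.seqid]
        spliced = "".join(chrom_seq[e.start - 1 : e.end] for e in exons)
        if gene.strand == "-":
            spliced = reverse_complement(spliced)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                transcript_seq=spliced,
            )
        )
    return models


def write_tag_database(index: ReferenceTagIndex, path) -> None:
    """Dump the virtual tag database as TSV: tag, gene_id, orientation, site_rank."""
    with open(path, "w") as fh:
        fh.write("tag\tgene_id\torientation\tsite_rank\n")
        for tag in sorted(index.tags):
            for vt in sorted(index.gene_hits_exact(tag)):
                fh.write(f"{vt.seq}\t{vt.gene_id}\t{vt.orientation}\t{vt.site_rank}\n")
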