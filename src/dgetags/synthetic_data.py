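"""Synthetic genomes, expression truths, and tag reads with known ground truth.

The generator emulates a seven-library allopolyploid DGE design: two
diploid parents (Br, Bo), four successive hybrid generations (F1-F4), and
an independently evolved "natural" allopolyploid (N).  Parental transcript
abundances are heavy-tailed (a few highly expressed genes, a long tail of
rare ones); the F1 is the mid-parent mixture with a planted fraction of
non-additive genes deviating from MPV by controlled log2 effects, and
F2-F4 attenuate those deviations back toward MPV generation by generation.

Reads are 35-mers anchored on a gene's CATG sites (3'-most site favoured),
drawn multinomially from the true abundances, with configurable per-base
substitution errors, N masking, and whole-read adaptor contamination.
Every stage is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .reference_tags import (
    GeneModel,
    anchored_offsets,
    reverse_complement,
)

LIBRARIES = ("Br", "Bo", "F1", "F2", "F3", "F4", "N")

# 17-nt adaptor; contaminated reads yield the tag CATG+adaptor, which the
# adaptor filter removes by substring match
DEFAULT_ADAPTOR = "TCGTATGCCGTCTTCTG"

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
READ_LENGTH = 35


@dataclass
class SimulationConfig:
    """All knobs of the simulated study; rates are per-base or per-read.

    Defaults model a desk-scale version of a seven-library Illumina DGE
    experiment: one million 35-bp raw reads per library over 2000 genes,
    light substitution noise, about a third of genes antisense-transcribed,
    a small fraction of gene pairs sharing an exact tag (mapping ambiguity),
    and 30% of genes non-additively regulated in the F1 with deviations of
    1-3 log2 units, attenuating by half each later generation.
    """

    seed: int
    n_genes: int = 2000
    gene_length: Tuple[int, int] = (300, 800)
    n_chromosomes: int = 5
    depth: int = 1_000_000
    error_rate: float = 0.001
    n_rate: float = 0.0002
    adaptor_rate: float = 0.005
    adaptor: str = DEFAULT_ADAPTOR
    antisense_fraction: float = 0.36
    antisense_share: float = 0.3
    shared_tag_fraction: float = 0.05
    parent_specific_fraction: float = 0.05
    nonadditive_fraction: float = 0.30
    effect_size_range: Tuple[float, float] = (1.0, 3.0)
    up_probability: float = 0.6
    attenuation: float = 0.5
    canonical_site_probability: float = 0.7

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "error_rate", "n_rate", "adaptor_rate", "antisense_fraction",
            "antisense_share", "shared_tag_fraction", "parent_specific_fraction",
            "nonadditive_fraction", "attenuation", "canonical_site_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.gene_length[0] < 21:
            raise ValueError("genes must be at least 21 nt")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


@dataclass
class ReferenceSet:
    """A simulated genome with gene models and their genomic coordinates."""

    genome: Dict[str, str]
    genes: List[GeneModel]
    coordinates: Dict[str, Tuple[str, int, int, str]]  # gene -> chrom,start,end,strand (1-based)
    ambiguity_pairs: List[Tuple[str, str]]

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.genes:
                chrom, start, end, strand = self.coordinates[gene.gene_id]
                gid = gene.gene_id
                fh.write(
                    f"{chrom}\tdgetags\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
                )
                fh.write(
                    f"{chrom}\tdgetags\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gid}.t1;Parent={gid}\n"
                )
                fh.write(
                    f"{chrom}\tdgetags\texon\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gid}.e1;Parent={gid}.t1\n"
                )


@dataclass
class SimulationTruth:
    """Ground truth backing one synthetic run."""

    gene_ids: List[str]
    abundance: pd.DataFrame  # genes x libraries, each column sums to 1
    log2_deviation: pd.Series  # planted F1 deviation from MPV
    regulation_class: pd.Series  # additive | nonadditive_above | nonadditive_below
    parental_bias: pd.Series  # Br>Bo | Br<Bo | Br=Bo
    antisense: pd.Series  # bool
    ambiguity_partner: Dict[str, str]

    def true_tpm(self, library: str) -> pd.Series:
        return self.abundance[library] * 1e6

    def to_tsv(self, path) -> None:
        out = self.abundance.copy()
        out["log2_deviation"] = self.log2_deviation
        out["regulation_class"] = self.regulation_class
        out["parental_bias"] = self.parental_bias
        out["antisense"] = self.antisense
        out["ambiguity_partner"] = [
            self.ambiguity_partner.get(g, "") for g in out.index
        ]
        out.to_csv(path, sep="\t", index_label="gene")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_reference(config: SimulationConfig) -> ReferenceSet:
    """Random genome and single-exon gene models with guaranteed CATG tags.

    Every gene carries at least one CATG site with 17 nt following; the
    configured fraction of gene *pairs* share one exact 21-mer (planted
    mapping ambiguity).  Transcripts are verbatim genome substrings (reverse
    complemented for minus-strand genes), so every gene tag also occurs in
    the genome-wide tag set.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.gene_length
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    seqs: Dict[str, str] = {}
    for gid in gene_ids:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if not anchored_offsets(seq):
            pos = length - 21
            seq = seq[:pos] + "CATG" + seq[pos + 4 :]
        seqs[gid] = seq

    n_pairs = round(config.shared_tag_fraction * config.n_genes / 2)
    pair_members = rng.choice(config.n_genes, size=2 * n_pairs, replace=False)
    pairs: List[Tuple[str, str]] = []
    for i in range(n_pairs):
        ga, gb = gene_ids[pair_members[2 * i]], gene_ids[pair_members[2 * i + 1]]
        donor = seqs[ga]
        site = anchored_offsets(donor)[0]
        shared = donor[site : site + 21]
        pos = int(rng.integers(0, len(seqs[gb]) - 21 + 1))
        seqs[gb] = seqs[gb][:pos] + shared + seqs[gb][pos + 21 :]
        pairs.append((ga, gb))

    strands = ["+" if s else "-" for s in rng.integers(0, 2, config.n_genes)]
    chrom_parts: Dict[str, List[str]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    chrom_pos: Dict[str, int] = {c: 0 for c in chrom_parts}
    coords: Dict[str, Tuple[str, int, int, str]] = {}
    genes: List[GeneModel] = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        spacer = _random_seq(rng, int(rng.integers(100, 301)))
        chrom_parts[chrom].append(spacer)
        chrom_pos[chrom] += len(spacer)
        transcript = seqs[gid]
        segment = transcript if strands[i] == "+" else reverse_complement(transcript)
        start = chrom_pos[chrom] + 1  # 1-based inclusive for GFF3
        chrom_parts[chrom].append(segment)
        chrom_pos[chrom] += len(segment)
        coords[gid] = (chrom, start, chrom_pos[chrom], strands[i])
        genes.append(GeneModel(gid, chrom, strands[i], transcript))
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    return ReferenceSet(genome, genes, coords, pairs)


def simulate_expression(
    config: SimulationConfig, reference: ReferenceSet
) -> SimulationTruth:
    """Seven-library abundance truth with planted non-additive regulation.

    Parental abundances are lognormal (heavy-tailed); the F1 is the MPV
    mixture with log2 deviations planted on a random gene subset, F2-F4
    shrink those deviations by the attenuation factor per generation, and
    the natural library is an independent draw near MPV.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_genes
    gene_ids = [g.gene_id for g in reference.genes]

    base = rng.lognormal(mean=0.0, sigma=2.0, size=n)
    br_w = base * rng.lognormal(0.0, 0.5, size=n)
    bo_w = base * rng.lognormal(0.0, 0.5, size=n)
    n_specific = round(config.parent_specific_fraction * n)
    specific = rng.choice(n, size=2 * n_specific, replace=False)
    bo_w[specific[:n_specific]] = 0.0  # Br-only genes
    br_w[specific[n_specific:]] = 0.0  # Bo-only genes
    br_w /= br_w.sum()
    bo_w /= bo_w.sum()
    mpv_w = (br_w + bo_w) / 2.0

    dev = np.zeros(n)
    n_nonadd = round(config.nonadditive_fraction * n)
    expressed = np.flatnonzero(mpv_w > 0)
    planted = rng.choice(expressed, size=n_nonadd, replace=False)
    lo, hi = config.effect_size_range
    magnitudes = rng.uniform(lo, hi, size=n_nonadd)
    signs = np.where(rng.random(n_nonadd) < config.up_probability, 1.0, -1.0)
    dev[planted] = signs * magnitudes

    def _mix(deviation: np.ndarray) -> np.ndarray:
        w = mpv_w * np.exp2(deviation)
        return w / w.sum()

    columns = {
        "Br": br_w,
        "Bo": bo_w,
        "F1": _mix(dev),
        "F2": _mix(dev * (1.0 - config.attenuation)),
        "F3": _mix(dev * (1.0 - config.attenuation) ** 2),
        "F4": _mix(dev * (1.0 - config.attenuation) ** 3),
    }
    natural = mpv_w * rng.lognormal(0.0, 0.2, size=n)
    columns["N"] = natural / natural.sum()
    abundance = pd.DataFrame(columns, index=gene_ids)

    regulation = np.where(
        dev > 0, "nonadditive_above", np.where(dev < 0, "nonadditive_below", "additive")
    )
    bias = np.where(br_w > bo_w, "Br>Bo", np.where(br_w < bo_w, "Br<Bo", "Br=Bo"))
    antisense = np.zeros(n, dtype=bool)
    n_anti = round(config.antisense_fraction * n)
    antisense[rng.choice(n, size=n_anti, replace=False)] = True

    partners: Dict[str, str] = {}
    for ga, gb in reference.ambiguity_pairs:
        partners[ga] = gb
        partners[gb] = ga

    return SimulationTruth(
        gene_ids=gene_ids,
        abundance=abundance,
        log2_deviation=pd.Series(dev, index=gene_ids),
        regulation_class=pd.Series(regulation, index=gene_ids),
        parental_bias=pd.Series(bias, index=gene_ids),
        antisense=pd.Series(antisense, index=gene_ids),
        ambiguity_partner=partners,
    )


def _encode(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGTN"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _build_templates(
    truth: SimulationTruth, reference: ReferenceSet, config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """35-mer read templates over (gene, strand, site) and their weights.

    The 3'-most CATG site takes ``canonical_site_probability`` of a gene's
    reads on its strand; internal sites split the remainder evenly.
    Antisense-flagged genes emit ``antisense_share`` of their reads from the
    reverse-complement strand when it has an anchored site.
    """
    templates: List[np.ndarray] = []
    weights: List[float] = []
    p_canon = config.canonical_site_probability
    for gene in reference.genes:
        templates_gene: List[Tuple[np.ndarray, float]] = []
        strands = [("sense", gene.transcript_seq, 1.0)]
        if truth.antisense[gene.gene_id]:
            rc = reverse_complement(gene.transcript_seq)
            if anchored_offsets(rc):
                strands = [
                    ("sense", gene.transcript_seq, 1.0 - config.antisense_share),
                    ("antisense", rc, config.antisense_share),
                ]
        for _, seq, w_strand in strands:
            offsets = anchored_offsets(seq)
            if not offsets:
                continue
            canonical = max(offsets)  # closest to the 3' end
            for o in offsets:
                if len(offsets) == 1:
                    w_site = 1.0
                elif o == canonical:
                    w_site = p_canon
                else:
                    w_site = (1.0 - p_canon) / (len(offsets) - 1)
                read = seq[o : o + READ_LENGTH]
                if len(read) < READ_LENGTH:
                    read += _random_seq(rng, READ_LENGTH - len(read))
                templates_gene.append((_encode(read), w_strand * w_site))
        total = sum(w for _, w in templates_gene)
        for arr, w in templates_gene:
            templates.append(arr)
            weights.append(w / total if total else 0.0)
    return np.stack(templates), np.asarray(weights)


def simulate_reads(
    truth: SimulationTruth,
    reference: ReferenceSet,
    config: SimulationConfig,
    libraries: Optional[Sequence[str]] = None,
) -> Dict[str, List[str]]:
    """Error-bearing 35-bp reads for each requested library.

    Reads are sampled multinomially over (gene, strand, site) templates in
    proportion to the library's true abundances, contaminated with whole
    adaptor reads, hit by per-base substitution errors and N masking, and
    shuffled.  All randomness derives from the configuration seed; a fixed
    seed gives byte-identical output.
    """
    libraries = list(libraries) if libraries is not None else list(LIBRARIES)
    template_rng = np.random.default_rng([config.seed, 2])
    templates, site_weights = _build_templates(truth, reference, config, template_rng)
    # map template rows back to genes in reference order
    gene_rows: List[int] = []
    row = 0
    rows_per_gene: Dict[str, slice] = {}
    for gene in reference.genes:
        n_rows = 0
        strands = 1
        if truth.antisense[gene.gene_id] and anchored_offsets(
            reverse_complement(gene.transcript_seq)
        ):
            strands = 2
        seqs = [gene.transcript_seq]
        if strands == 2:
            seqs.append(reverse_complement(gene.transcript_seq))
        for seq in seqs:
            n_rows += len(anchored_offsets(seq))
        rows_per_gene[gene.gene_id] = slice(row, row + n_rows)
        row += n_rows
    assert row == templates.shape[0]

    adaptor_read = _encode(
        ("CATG" + config.adaptor + "ACGT" * READ_LENGTH)[:READ_LENGTH]
    )
    out: Dict[str, List[str]] = {}
    for lib in libraries:
        rng = np.random.default_rng([config.seed, 3, LIBRARIES.index(lib)])
        weights = np.zeros(templates.shape[0])
        for gene in reference.genes:
            sl = rows_per_gene[gene.gene_id]
            weights[sl] = site_weights[sl] * float(
                truth.abundance.loc[gene.gene_id, lib]
            )
        weights /= weights.sum()
        counts = rng.multinomial(config.depth, weights)
        reads = np.repeat(templates, counts, axis=0)
        reads = reads[rng.permutation(reads.shape[0])]

        # rows are a random order now, so the first n form a uniform subset
        n_adaptor = rng.binomial(config.depth, config.adaptor_rate)
        if n_adaptor:
            reads[:n_adaptor] = adaptor_read

        flat = reads.reshape(-1)
        n_err = rng.binomial(flat.size, config.error_rate)
        if n_err:
            pos = rng.integers(0, flat.size, size=n_err)
            flat[pos] = (flat[pos] + rng.integers(1, 4, size=n_err)) % 4
        n_mask = rng.binomial(flat.size, config.n_rate)
        if n_mask:
            pos = rng.integers(0, flat.size, size=n_mask)
            flat[pos] = 4

        reads = reads[rng.permutation(reads.shape[0])]
        decoded = _BASES[reads].tobytes().decode()
        out[lib] = [
            decoded[i : i + READ_LENGTH]
            for i in range(0, len(decoded), READ_LENGTH)
        ]
    return out


def write_fastq(reads: Sequence[str], path, library_id: str) -> None:
    """Sanger-encoded FASTQ with constant qualities ('I'; '#' at N bases)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            qual = "".join("#" if b == "N" else "I" for b in seq)
            fh.write(f"@{library_id}_{i}\n{seq}\n+\n{qual}\n")
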