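"""Strand-aware gene-region index and PEUS classification of SNPs.

A PEUS SNP lies in a Promoter (1 kb upstream of the start codon by
default), Exon, Untranslated region, or Stop codon of a gene model.
Gene models come from GFF3; positions are classified with per-chromosome
interval trees, one per category. Categories may overlap (a 5'UTR base is
also exonic; a promoter may reach into the 5'UTR of its own transcript
because it is anchored at the start codon, not the TSS) and a site carries
every category that covers it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

PROMOTER = "PROMOTER"
EXON = "EXON"
UTR = "UTR"
STOP_CODON = "STOP_CODON"
CATEGORIES = (PROMOTER, EXON, UTR, STOP_CODON)

Interval1 = tuple[int, int]  # 1-based inclusive genomic interval


@dataclass
class Transcript:
    """One transcript's structure in 1-based inclusive genomic coordinates."""

    exons: list[Interval1]
    cds: list[Interval1]
    utr5: list[Interval1] = field(default_factory=list)
    utr3: list[Interval1] = field(default_factory=list)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for t in self.transcripts:
            exon_pos = set()
            for a, b in t.exons:
                if b < a:
                    raise ValueError(f"gene {self.gene_id}: empty exon interval")
                exon_pos.update(range(a, b + 1))
            for a, b in t.cds:
                if b < a or not exon_pos.issuperset(range(a, b + 1)):
                    raise ValueError(f"gene {self.gene_id}: CDS not contained in exons")


class RegionIndex:
    """Maps genomic position -> set of PEUS categories.

    Backed by one IntervalTree per (chromosome, category); intervals are
    stored 0-based half-open internally, queries take 1-based positions.
    """

    def __init__(self, promoter_len: int = 1000) -> None:
        self.promoter_len = promoter_len
        self._trees: dict[str, dict[str, IntervalTree]] = {}

    def add(self, chrom: str, category: str, start1: int, end1: int) -> None:
        """Add a 1-based inclusive interval under a category."""
        if end1 < start1:
            return
        trees = self._trees.setdefault(chrom, {c: IntervalTree() for c in CATEGORIES})
        trees[category].addi(start1 - 1, end1)

    def query(self, chrom: str, pos: int) -> set[str]:
        """Categories covering 1-based position pos (empty set if none)."""
        trees = self._trees.get(chrom)
        if trees is None:
            return set()
        return {c for c, t in trees.items() if t.overlaps_point(pos - 1)}

    def intervals(self, category: str) -> list[tuple[str, int, int]]:
        """All merged (chrom, start1, end1) intervals of a category."""
        out = []
        for chrom in sorted(self._trees):
            tree = IntervalTree(self._trees[chrom][category])
            tree.merge_overlaps(strict=False)
            for iv in sorted(tree):
                out.append((chrom, iv.begin + 1, iv.end))
        return out


def _stop_codon_intervals(cds: list[Interval1], strand: str) -> list[Interval1]:
    """Last 3 coding bases in transcript orientation; may span two CDS pieces."""
    pieces = sorted(cds)
    need = 3
    out: list[Interval1] = []
    if strand == "+":
        for a, b in reversed(pieces):
            take = min(need, b - a + 1)
            out.append((b - take + 1, b))
            need -= take
            if need == 0:
                break
    else:
        for a, b in pieces:
            take = min(need, b - a + 1)
            out.append((a, a + take - 1))
            need -= take
            if need == 0:
                break
    return out


def build_region_index(genes: list[GeneModel], promoter_len: int = 1000) -> RegionIndex:
    """Build the PEUS region index from gene models.

    Per transcript: PROMOTER = promoter_len bases 5' of the start codon in
    strand orientation (truncated at position 1); EXON = all exons; UTR =
    5' and 3' UTRs; STOP_CODON = final 3 coding bases in transcript
    orientation. Categories are unioned over transcripts and genes.
    Transcripts without CDS contribute EXON/UTR only.
    """
    idx = RegionIndex(promoter_len)
    n_no_cds = 0
    for gene in genes:
        for tr in gene.transcripts:
            for a, b in tr.exons:
                idx.add(gene.chrom, EXON, a, b)
            for a, b in list(tr.utr5) + list(tr.utr3):
                idx.add(gene.chrom, UTR, a, b)
            if not tr.cds:
                n_no_cds += 1
                continue
            if gene.strand == "+":
                start_codon = min(a for a, _ in tr.cds)
                idx.add(gene.chrom, PROMOTER, max(1, start_codon - promoter_len), start_codon - 1)
            else:
                cds_max = max(b for _, b in tr.cds)
                idx.add(gene.chrom, PROMOTER, cds_max + 1, cds_max + promoter_len)
            for a, b in _stop_codon_intervals(tr.cds, gene.strand):
                idx.add(gene.chrom, STOP_CODON, a, b)
    if n_no_cds:
        logger.info("build_region_index: %d transcripts without CDS (EXON/UTR only)", n_no_cds)
    return idx


def classify_position(idx: RegionIndex, chrom: str, pos: int) -> set[str]:
    """All PEUS categories covering (chrom, pos); deterministic."""
    return idx.query(chrom, pos)


@dataclass
class PeusAnnotation:
    """Per-site PEUS flags for a genotype matrix, aligned to its site order."""

    is_peus: np.ndarray  # bool, n_sites
    categories: list[frozenset]  # per-site category sets

    @property
    def n_peus(self) -> int:
        return int(self.is_peus.sum())

    def category_counts(self) -> dict[str, int]:
        """Sites per category; a site increments every category it carries."""
        counts = dict.fromkeys(CATEGORIES, 0)
        for cats in self.categories:
            for c in cats:
                counts[c] += 1
        return counts


def annotate_matrix(gm: GenotypeMatrix, idx: RegionIndex) -> PeusAnnotation:
    """Classify every site of a genotype matrix against the region index.

    A site is PEUS iff it carries at least one category; it is counted once
    in the PEUS total regardless of how many categories cover it.
    """
    cats = [
        frozenset(idx.query(c, int(p)))
        for c, p in zip(gm.sites["chrom"], gm.sites["pos"])
    ]
    is_peus = np.array([len(c) > 0 for c in cats], dtype=bool)
    return PeusAnnotation(is_peus=is_peus, categories=cats)


def read_gff3(path: str) -> list[GeneModel]:
    """Load gene models (gene/mRNA/exon/CDS/UTR features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA"):
            transcripts.append(
                Transcript(
                    exons=[(f.start, f.end) for f in db.children(t, featuretype="exon")],
                    cds=[(f.start, f.end) for f in db.children(t, featuretype="CDS")],
                    utr5=[(f.start, f.end) for f in db.children(t, featuretype="five_prime_UTR")],
                    utr3=[(f.start, f.end) for f in db.children(t, featuretype="three_prime_UTR")],
                )
            )
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand, transcripts=transcripts))
    return genes


def write_peus_bed(idx: RegionIndex, path: str) -> None:
    """Dump the index as BED (0-based half-open), one line per interval."""
    with open(path, "w") as fh:
        for cat in CATEGORIES:
            for chrom, s1, e1 in idx.intervals(cat):
                fh.write(f"{chrom}\t{s1 - 1}\t{e1}\t{cat}\n")
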