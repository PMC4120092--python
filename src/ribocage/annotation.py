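"""Annotation of CAGEscan clusters against gene models.

Three annotation routes, mirroring how paired-end 5' tag data links TSSs to
genes: *direct* (the seed peak itself intersects a gene in sense),
*cagescan* (only a downstream mate block does), and *rescue* (sense overlap
with a secondary model set, or position within a configurable window past a
primary gene's 3' end, i.e. a putative long 3' UTR).  Every cluster also
receives a positional category of its dominant CTSS (5' UTR, CDS exon,
intron, 3' UTR or intergenic) with precedence 5'UTR > CDS > 3'UTR > intron
when overlapping transcripts disagree.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

__all__ = [
    "GeneModelSet",
    "annotate",
    "rescue_annotation",
    "categorize_tss",
    "dominant_ctss",
    "representative_cluster",
]

CATEGORY_PRECEDENCE = ("five_prime_utr", "cds_exon", "three_prime_utr", "intron")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list  # sorted genomic half-open
    cds: list = field(default_factory=list)

    def regions(self, strand: str) -> dict:
        """Genomic intervals per category; UTRs only where a CDS exists."""
        out = {"cds_exon": list(self.cds), "five_prime_utr": [], "three_prime_utr": []}
        if self.cds:
            cds_lo = min(s for s, _ in self.cds)
            cds_hi = max(e for _, e in self.cds)
            for s, e in self.exons:
                lo_part = (s, min(e, cds_lo))
                hi_part = (max(s, cds_hi), e)
                if lo_part[0] < lo_part[1]:
                    key = "five_prime_utr" if strand == "+" else "three_prime_utr"
                    out[key].append(lo_part)
                if hi_part[0] < hi_part[1]:
                    key = "three_prime_utr" if strand == "+" else "five_prime_utr"
                    out[key].append(hi_part)
        return out


@dataclass
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: dict = field(default_factory=dict)


class GeneModelSet:
    """Gene models read from GTF with per-strand interval indexes."""

    def __init__(self, genes: dict, source: str = "primary"):
        self.genes = genes
        self.source = source
        self._gene_tree: dict[tuple, IntervalTree] = defaultdict(IntervalTree)
        for g in genes.values():
            self._gene_tree[(g.chrom, g.strand)].addi(g.start, g.end, g.gene_id)

    @classmethod
    def from_gtf(cls, path, source: str = "primary",
                 exclude_biotypes: tuple = ("pseudogene",)) -> "GeneModelSet":
        df = pr.read_gtf(str(path)).df
        genes: dict[str, Gene] = {}
        for _, row in df[df.Feature == "gene"].iterrows():
            genes[row.gene_id] = Gene(
                gene_id=row.gene_id,
                symbol=getattr(row, "gene_name", row.gene_id),
                chrom=str(row.Chromosome),
                strand=str(row.Strand),
                start=int(row.Start),
                end=int(row.End),
                biotype=str(getattr(row, "gene_biotype", "protein_coding")),
            )
        for _, row in df[df.Feature.isin(["exon", "CDS"])].iterrows():
            gene = genes.get(row.gene_id)
            if gene is None:
                continue
            tx = gene.transcripts.setdefault(
                row.transcript_id, Transcript(row.transcript_id, row.gene_id, [])
            )
            iv = (int(row.Start), int(row.End))
            (tx.exons if row.Feature == "exon" else tx.cds).append(iv)
        for gene in genes.values():
            for tx in gene.transcripts.values():
                tx.exons.sort()
                tx.cds.sort()
        kept = {
            gid: g for gid, g in genes.items() if g.biotype not in exclude_biotypes
        }
        return cls(kept, source=source)

    @property
    def chroms(self) -> set:
        return {g.chrom for g in self.genes.values()}

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> list:
        """Gene ids intersecting [start, end) in sense orientation."""
        hits = self._gene_tree[(chrom, strand)].overlap(start, end)
        return sorted(h.data for h in hits)

    def symbols(self, gene_ids) -> list:
        return sorted({self.genes[g].symbol for g in gene_ids})


def _check_chroms(clusters, models: GeneModelSet) -> None:
    missing = sorted({c.chrom for c in clusters} - models.chroms)
    if missing:
        raise ValueError(
            f"cluster chromosomes absent from gene models: {missing}; "
            "inputs are probably from different assemblies"
        )


def annotate(clusters, models: GeneModelSet) -> None:
    """Attach sense-overlap annotation in place.

    ``direct`` when the seed peak intersects a gene in sense; otherwise
    ``cagescan`` when any mate block does; otherwise the cluster stays
    unannotated (source ``none``).  All intersected gene symbols are kept.
    """
    _check_chroms(clusters, models)
    for c in clusters:
        seed_hits = models.overlapping(c.chrom, c.strand, c.seed.start, c.seed.end)
        if seed_hits:
            c.annotation = models.symbols(seed_hits)
            c.annotation_source = "direct"
            continue
        block_hits: set = set()
        for s, e in c.blocks:
            block_hits.update(models.overlapping(c.chrom, c.strand, s, e))
        if block_hits:
            c.annotation = models.symbols(block_hits)
            c.annotation_source = "cagescan"
        else:
            c.annotation = []
            c.annotation_source = "none"


def rescue_annotation(clusters, secondary: GeneModelSet | None,
                      primary: GeneModelSet, downstream_window: int = 10_000) -> list:
    """Second-chance annotation for unannotated clusters.

    A cluster is rescued when it sense-overlaps a secondary ("RefSeq-like")
    model, or lies within ``downstream_window`` bp past a primary gene's 3'
    end on the same strand (putative long 3' UTR).  Returns the rescued
    clusters; their source becomes ``rescue``.
    """
    rescued = []
    for c in clusters:
        if c.annotation_source != "none":
            continue
        symbols: list = []
        if secondary is not None:
            hits = set(secondary.overlapping(c.chrom, c.strand, c.seed.start, c.seed.end))
            for s, e in c.blocks:
                hits.update(secondary.overlapping(c.chrom, c.strand, s, e))
            symbols = secondary.symbols(hits)
        if not symbols:
            for g in primary.genes.values():
                if g.chrom != c.chrom or g.strand != c.strand:
                    continue
                if g.strand == "+":
                    window = (g.end, g.end + downstream_window)
                else:
                    window = (max(0, g.start - downstream_window), g.start)
                if c.seed.start < window[1] and window[0] < c.seed.end:
                    symbols.append(g.symbol)
            symbols = sorted(set(symbols))
        if symbols:
            c.annotation = symbols
            c.annotation_source = "rescue"
            rescued.append(c)
    return rescued


def dominant_ctss(cluster, ctss_track) -> int:
    """Modal CTSS position of the seed (leftmost on ties); cached on the
    cluster."""
    if cluster.dominant_ctss is not None:
        return cluster.dominant_ctss
    counter = ctss_track[(cluster.chrom, cluster.strand)]
    best_pos, best = None, -1
    for pos in range(cluster.seed.start, cluster.seed.end):
        n = counter.get(pos, 0)
        if n > best:
            best, best_pos = n, pos
    cluster.dominant_ctss = best_pos if best > 0 else cluster.seed.start
    return cluster.dominant_ctss


def categorize_tss(cluster, models: GeneModelSet, ctss_track=None) -> str:
    """Positional category of the cluster's dominant CTSS.

    The position is tested against every sense-overlapping transcript;
    disagreements resolve by precedence 5'UTR > CDS exon > 3'UTR > intron.
    No sense overlap at all gives ``intergenic``.
    """
    pos = (
        dominant_ctss(cluster, ctss_track)
        if ctss_track is not None
        else (cluster.dominant_ctss if cluster.dominant_ctss is not None else cluster.seed.start)
    )
    gene_ids = models.overlapping(cluster.chrom, cluster.strand, pos, pos + 1)
    if not gene_ids:
        cluster.category = "intergenic"
        return cluster.category
    seen: set = set()
    for gid in gene_ids:
        gene = models.genes[gid]
        for tx in gene.transcripts.values():
            regions = tx.regions(gene.strand)
            in_exon = any(s <= pos < e for s, e in tx.exons)
            hit = None
            for cat in ("five_prime_utr", "cds_exon", "three_prime_utr"):
                if any(s <= pos < e for s, e in regions[cat]):
                    hit = cat
                    break
            if hit is None and in_exon:
                # exon of a non-coding transcript counts with CDS-exon rank
                hit = "cds_exon"
            if hit is None:
                hit = "intron"
            seen.add(hit)
    for cat in CATEGORY_PRECEDENCE:
        if cat in seen:
            cluster.category = cat
            return cat
    cluster.category = "intron"
    return cluster.category


def representative_cluster(clusters_of_gene: list) -> "object":
    """The most representative cluster of one gene: promoter classification
    first (high-confidence preferred), then pooled expression, then leftmost
    start as the deterministic tie-break."""
    if not clusters_of_gene:
        raise ValueError("gene has no clusters")
    high = [c for c in clusters_of_gene if c.confidence == "high"]
    pool = high if high else list(clusters_of_gene)
    pool.sort(key=lambda c: (-c.total_count, c.seed.start, c.cluster_id))
    return pool[0]


def annotation_table(clusters) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "symbols": ",".join(c.annotation),
            "source": c.annotation_source,
            "category": c.category,
            "confidence": c.confidence,
            "score": c.classifier_score,
            "total_count": c.total_count,
        }
        for c in clusters
    ]
    return pd.DataFrame(rows).set_index("cluster_id")
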