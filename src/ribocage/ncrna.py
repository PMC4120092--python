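"""Triage of unannotated captured clusters and SINEUP candidate detection.

Unannotated clusters that survive the enrichment gate are screened for
three artifact classes before being considered candidate noncoding RNAs:

* template-switching artifacts — the genomic sequence immediately 5' of the
  dominant CTSS (sense strand) matches the terminal bases of the
  template-switching oligo tail (default ``GGG``), so the "cap signal" can
  be explained by strand invasion at a G-rich site;
* pseudogene overlap — sense or antisense overlap with a pseudogene model;
* multi-locus spans — clusters whose assembled blocks span more than
  ``max_span`` (default 100 kb) or intersect more than one annotated locus
  in sense.

A SINEUP candidate is a cluster that (a) overlaps a protein-coding gene on
the opposite strand with the two 5' ends facing each other (head-to-head)
and (b) overlaps a SINE repeat downstream of its own TSS in its own
transcriptional orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .annotation import GeneModelSet
from .simulate import revcomp

__all__ = ["TriageFlags", "triage", "sineup_candidates"]


@dataclass
class TriageFlags:
    cluster_id: str
    template_switch_artifact: bool
    pseudogene_overlap: bool
    multi_locus_span: bool
    span_bp: int
    high_confidence: bool

    @property
    def clean(self) -> bool:
        return not (
            self.template_switch_artifact
            or self.pseudogene_overlap
            or self.multi_locus_span
        )


def _upstream_sequence(genome, chrom: str, pos: int, strand: str, k: int) -> str:
    seq = genome[chrom]
    seq = str(seq[:]) if not isinstance(seq, str) else seq
    if strand == "+":
        return seq[max(0, pos - k) : pos]
    return revcomp(seq[pos + 1 : pos + 1 + k])


def triage(clusters, genome, pseudogene_models: GeneModelSet | None = None,
           max_span: int = 100_000, tso_tail: str = "GGG", k: int = 3,
           gene_models: GeneModelSet | None = None) -> dict:
    """Per-cluster :class:`TriageFlags` for unannotated enriched clusters.

    ``pseudogene_models`` may be empty/None (no pseudogene flags then);
    ``gene_models`` enables the sense multi-locus rule in addition to the
    span threshold.
    """
    tail = tso_tail[-k:].upper()
    flags: dict[str, TriageFlags] = {}
    for c in clusters:
        pos = c.dominant_ctss if c.dominant_ctss is not None else c.seed.start
        upstream = _upstream_sequence(genome, c.chrom, pos, c.strand, k).upper()
        is_ts = upstream == tail
        pg = False
        if pseudogene_models is not None:
            for strand in ("+", "-"):
                for s, e in c.blocks:
                    if pseudogene_models.overlapping(c.chrom, strand, s, e):
                        pg = True
        multi = c.span_bp > max_span
        if not multi and gene_models is not None:
            hit_genes: set = set()
            for s, e in c.blocks:
                hit_genes.update(gene_models.overlapping(c.chrom, c.strand, s, e))
            multi = len(hit_genes) > 1
        flags[c.cluster_id] = TriageFlags(
            cluster_id=c.cluster_id,
            template_switch_artifact=is_ts,
            pseudogene_overlap=pg,
            multi_locus_span=multi,
            span_bp=c.span_bp,
            high_confidence=c.confidence == "high",
        )
    return flags


def sineup_candidates(clusters, gene_models: GeneModelSet, repeats,
                      head_to_head_window: int = 5000) -> list:
    """Detect antisense clusters with SINEUP geometry.

    ``repeats`` is an iterable of (chrom, start, end, name[, strand]) SINE
    annotations and is required: without it, rule (b) is untestable.
    Head-to-head is operationalized as: the cluster's blocks overlap a
    protein-coding gene on the opposite strand, and the cluster's 5' end
    lies between ``head_to_head_window`` bp upstream of the partner's 5'
    end and the partner's 3' end.  Returns one geometry report per
    candidate (partner gene, overlap interval, repeat name).
    """
    repeats = list(repeats)
    if not repeats:
        raise ValueError("repeat annotation required for SINEUP detection")
    rep_tree: dict[str, IntervalTree] = {}
    for rec in repeats:
        chrom, start, end, name = rec[0], int(rec[1]), int(rec[2]), rec[3]
        rep_tree.setdefault(chrom, IntervalTree()).addi(start, end, name)

    out = []
    for c in clusters:
        tss = c.dominant_ctss if c.dominant_ctss is not None else c.seed.start
        anti = "-" if c.strand == "+" else "+"
        partner = None
        for s, e in c.blocks:
            for gid in gene_models.overlapping(c.chrom, anti, s, e):
                gene = gene_models.genes[gid]
                if gene.biotype != "protein_coding":
                    continue
                if gene.strand == "+":
                    lo = gene.start - head_to_head_window
                    ok = lo <= tss < gene.end
                else:
                    hi = gene.end - 1 + head_to_head_window
                    ok = gene.start <= tss <= hi
                if ok:
                    partner = gene
                    break
            if partner:
                break
        if partner is None:
            continue
        sine_hit = None
        for s, e in c.blocks:
            if c.chrom not in rep_tree:
                continue
            for iv in rep_tree[c.chrom].overlap(s, e):
                # repeat must lie downstream of the cluster's own TSS
                downstream = iv.end > tss if c.strand == "+" else iv.begin <= tss
                if downstream:
                    sine_hit = iv
                    break
            if sine_hit:
                break
        if sine_hit is None:
            continue
        out.append(
            {
                "cluster_id": c.cluster_id,
                "partner_gene": partner.gene_id,
                "partner_symbol": partner.symbol,
                "overlap": (max(c.span[0], partner.start), min(c.span[1], partner.end)),
                "repeat": sine_hit.data,
                "repeat_interval": (sine_hit.begin, sine_hit.end),
            }
        )
    return out
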