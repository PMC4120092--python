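"""CAGEscan cluster assembly and the cluster x library count matrix.

A filtered Paraclu peak becomes the *seed* of a CAGEscan cluster; every
deduplicated pair whose 5' end falls inside the seed (same chromosome and
strand) contributes its mate blocks, so the merged block structure of a
cluster traces the transcript body (including intron gaps) downstream of
the TSS.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paraclu import ParacluCluster
from .tagio import AlignedPair, merge_blocks

__all__ = ["CAGEscanCluster", "CountMatrix", "SeedIndex", "assemble_cagescan", "count_matrix"]


@dataclass
class CAGEscanCluster:
    cluster_id: str
    seed: ParacluCluster
    blocks: tuple = ()
    counts: dict = field(default_factory=dict)  # library_id -> pair count
    annotation: list = field(default_factory=list)  # gene symbols
    annotation_source: str = "none"  # direct | cagescan | rescue | none
    category: str | None = None
    dominant_ctss: int | None = None
    classifier_score: float | None = None
    confidence: str | None = None

    @property
    def chrom(self) -> str:
        return self.seed.chrom

    @property
    def strand(self) -> str:
        return self.seed.strand

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1]) if self.blocks else (
            self.seed.start,
            self.seed.end,
        )

    @property
    def span_bp(self) -> int:
        s, e = self.span
        return e - s

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


class SeedIndex:
    """Locate the unique seed containing a (chrom, strand, position)."""

    def __init__(self, seeds: list[ParacluCluster]):
        self._starts: dict[tuple, list[int]] = {}
        self._ends: dict[tuple, list[int]] = {}
        self._idx: dict[tuple, list[int]] = {}
        by_key: dict[tuple, list[tuple[int, int, int]]] = defaultdict(list)
        for k, s in enumerate(seeds):
            by_key[(s.chrom, s.strand)].append((s.start, s.end, k))
        for key, triples in by_key.items():
            triples.sort()
            for (s1, e1, _), (s2, _, _) in zip(triples, triples[1:]):
                if s2 < e1:
                    raise ValueError("seeds must be disjoint per strand")
            self._starts[key] = [t[0] for t in triples]
            self._ends[key] = [t[1] for t in triples]
            self._idx[key] = [t[2] for t in triples]

    def find(self, chrom: str, strand: str, pos: int) -> int | None:
        key = (chrom, strand)
        if key not in self._starts:
            return None
        i = bisect_right(self._starts[key], pos) - 1
        if i >= 0 and pos < self._ends[key][i]:
            return self._idx[key][i]
        return None


def assemble_cagescan(seeds: list[ParacluCluster], pairs) -> tuple[list[CAGEscanCluster], list[AlignedPair]]:
    """Assemble one CAGEscan cluster per seed from deduplicated pairs.

    Each pair is assigned to at most the single seed containing its 5' end
    on the matching strand; pairs hitting no seed are returned unassigned.
    Cluster blocks are the merged union of the seed interval and all
    assigned mate blocks.
    """
    index = SeedIndex(seeds)
    raw_blocks: list[list] = [[(s.start, s.end)] for s in seeds]
    counts: list[dict] = [defaultdict(int) for _ in seeds]
    unassigned: list[AlignedPair] = []
    for pair in pairs:
        k = index.find(pair.chrom, pair.strand, pair.pos5)
        if k is None:
            unassigned.append(pair)
            continue
        raw_blocks[k].extend(pair.mate_blocks)
        counts[k][pair.library_id] += 1
    clusters = []
    order = sorted(range(len(seeds)), key=lambda k: (seeds[k].chrom, seeds[k].start, seeds[k].strand))
    for serial, k in enumerate(order):
        clusters.append(
            CAGEscanCluster(
                cluster_id=f"CSC{serial:05d}",
                seed=seeds[k],
                blocks=merge_blocks(raw_blocks[k]),
                counts=dict(counts[k]),
            )
        )
    return clusters, unassigned


@dataclass
class CountMatrix:
    """Deduplicated pair counts per CAGEscan cluster and library, plus the
    library metadata (fraction / capture / compartment / pair id)."""

    counts: pd.DataFrame  # rows: cluster_id, columns: library_id
    meta: pd.DataFrame  # index: library_id
    unassigned: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count matrix columns must match metadata library ids")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def cpm(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return 1e6 * self.counts / totals

    def subset_libraries(self, library_ids) -> "CountMatrix":
        library_ids = list(library_ids)
        return CountMatrix(
            self.counts[library_ids],
            self.meta.loc[library_ids],
            {k: v for k, v in self.unassigned.items() if k in library_ids},
        )

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="cluster_id")


def count_matrix(clusters: list[CAGEscanCluster], pairs_by_library: dict,
                 meta: pd.DataFrame) -> CountMatrix:
    """Count, per library, the deduplicated pairs whose 5' end falls in each
    cluster seed.  Conservation holds per library: assigned + unassigned =
    total pairs.  Unknown library ids are a hard error."""
    unknown = set(pairs_by_library) - set(meta.index)
    if unknown:
        raise ValueError(f"libraries missing from metadata: {sorted(unknown)}")
    index = SeedIndex([c.seed for c in clusters])
    ids = [c.cluster_id for c in clusters]
    mat = pd.DataFrame(0, index=ids, columns=list(meta.index), dtype=np.int64)
    unassigned = {}
    for lib_id, pairs in pairs_by_library.items():
        miss = 0
        col = np.zeros(len(clusters), dtype=np.int64)
        for pair in pairs:
            k = index.find(pair.chrom, pair.strand, pair.pos5)
            if k is None:
                miss += 1
            else:
                col[k] += 1
        mat[lib_id] = col
        unassigned[lib_id] = miss
        assert col.sum() + miss == len(pairs)
    return CountMatrix(mat, meta.copy(), unassigned)


# ---------------------------------------------------------------------------
# exports


def seeds_to_bed6(seeds, path) -> None:
    with open(path, "w") as fh:
        for k, s in enumerate(seeds):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tseed{k}\t{s.tag_count}\t{s.strand}\n")


def clusters_to_bed12(clusters, path, score_from: str = "count") -> None:
    """BED12 export; score is the pooled count or a scaled classifier score."""
    with open(path, "w") as fh:
        for c in clusters:
            s, e = c.span
            if score_from == "score" and c.classifier_score is not None:
                score = int(np.clip(500 + 100 * c.classifier_score, 0, 1000))
            else:
                score = min(c.total_count, 1000)
            sizes = ",".join(str(be - bs) for bs, be in c.blocks)
            starts = ",".join(str(bs - s) for bs, be in c.blocks)
            fh.write(
                f"{c.chrom}\t{s}\t{e}\t{c.cluster_id}\t{score}\t{c.strand}\t{s}\t{s}\t"
                f"0,0,0\t{len(c.blocks)}\t{sizes}\t{starts}\n"
            )
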