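"""Reading aligned paired-end 5' tags, PCR-duplicate collapsing, and
single-nucleotide 5'-end (CTSS) count tracks.

All internal coordinates are 0-based half-open; SAM input (1-based) is
converted on read, BED is used natively.  For a minus-strand pair the 5'
position is the highest genomic coordinate covered by mate 1, i.e. the 5'
end on the transcript strand.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedPair",
    "CTSSTrack",
    "read_aligned_pairs",
    "write_pairs_sam",
    "write_pairs_bed12",
    "deduplicate",
    "ctss_counts",
    "dedup_stats",
]

Blocks = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class AlignedPair:
    """One deduplicatable paired-end tag.

    ``pos5`` is the strand-oriented 5'-most base of mate 1; ``mate_blocks``
    are the sorted, non-overlapping 0-based half-open genomic intervals
    covered by the pair.  ``multiplicity`` counts observed identical copies
    (1 before deduplication).
    """

    library_id: str
    chrom: str
    strand: str
    pos5: int
    mate_blocks: Blocks
    multiplicity: int = 1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        blocks = self.mate_blocks
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError(f"mate blocks not sorted/non-overlapping: {blocks}")
        if any(e <= s for s, e in blocks):
            raise ValueError(f"empty mate block in {blocks}")

    @property
    def span(self) -> tuple[int, int]:
        return self.mate_blocks[0][0], self.mate_blocks[-1][1]

    def key(self) -> tuple:
        return (self.chrom, self.strand, self.pos5, self.mate_blocks)


def merge_blocks(blocks) -> Blocks:
    """Sort and merge overlapping/adjacent half-open intervals."""
    blocks = sorted(blocks)
    out: list[list[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


# ---------------------------------------------------------------------------
# reading


def read_aligned_pairs(path, format: str = "sam", library_id: str | None = None,
                       mapq_min: int = 10) -> list[AlignedPair]:
    """Read proper pairs from a SAM or BED12 file into :class:`AlignedPair`.

    Secondary, supplementary and unmapped records are skipped; both mates
    are required (orphans are counted and skipped).  Records failing the
    block invariants raise with the offending line number.
    """
    path = str(path)
    if library_id is None:
        library_id = Path(path).stem
    if format == "sam":
        return _read_sam(path, library_id, mapq_min)
    if format == "bed12":
        return _read_bed12(path, library_id)
    raise ValueError(f"unknown format {format!r}")


def _read_sam(path: str, library_id: str, mapq_min: int) -> list[AlignedPair]:
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPair] = []
    n_orphan = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.mate_is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality < mapq_min
            ):
                continue
            if rec.query_name in pending:
                other = pending.pop(rec.query_name)
                r1, r2 = (rec, other) if rec.is_read1 else (other, rec)
                if not (r1.is_read1 and r2.is_read2):
                    n_orphan += 1
                    continue
                if r1.reference_name != r2.reference_name:
                    n_orphan += 1
                    continue
                strand = "-" if r1.is_reverse else "+"
                pos5 = r1.reference_end - 1 if r1.is_reverse else r1.reference_start
                blocks = merge_blocks(list(r1.get_blocks()) + list(r2.get_blocks()))
                pairs.append(
                    AlignedPair(library_id, r1.reference_name, strand, pos5, blocks)
                )
            else:
                pending[rec.query_name] = rec
    n_orphan += len(pending)
    if n_orphan:
        logger.info("%s: skipped %d orphan mates", path, n_orphan)
    return pairs


def _read_bed12(path: str, library_id: str) -> list[AlignedPair]:
    pairs: list[AlignedPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields, got {len(f)}")
            try:
                chrom, start, end, _name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed record: {err}") from None
            if len(sizes) != nblocks or len(starts) != nblocks:
                raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
            blocks = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if s2 < e1:
                    raise ValueError(f"{path}:{lineno}: blocks unsorted or overlapping")
            if blocks[0][0] != start or blocks[-1][1] != end:
                raise ValueError(f"{path}:{lineno}: blocks do not span chromStart..chromEnd")
            pos5 = start if strand == "+" else end - 1
            pairs.append(AlignedPair(library_id, chrom, strand, pos5, blocks))
    return pairs


# ---------------------------------------------------------------------------
# writing


def write_pairs_bed12(pairs, path, name_prefix: str = "pair") -> None:
    """One BED12 record per pair (blocks = covered fragments); duplicates
    are written ``multiplicity`` times so the file round-trips dedup."""
    with open(path, "w") as fh:
        for k, pair in enumerate(pairs):
            s, e = pair.span
            sizes = ",".join(str(be - bs) for bs, be in pair.mate_blocks)
            starts = ",".join(str(bs - s) for bs, be in pair.mate_blocks)
            line = (
                f"{pair.chrom}\t{s}\t{e}\t{name_prefix}{k}\t0\t{pair.strand}\t{s}\t{s}\t"
                f"0,0,0\t{len(pair.mate_blocks)}\t{sizes}\t{starts}\n"
            )
            fh.write(line * pair.multiplicity)


def write_pairs_sam(pairs, path, chrom_sizes: dict[str, int], read_len: int = 25) -> None:
    """Write pairs as properly-paired SAM records (text, uncompressed).

    Mate 1 covers ``read_len`` bases from the 5' end within the first (plus
    strand) or last (minus strand) block; mate 2 covers the opposite end of
    the fragment, with N-gaps reproducing the remaining block structure.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }

    def cigar_for(blocks):
        cig = []
        prev_end = None
        for s, e in blocks:
            if prev_end is not None:
                cig.append((3, s - prev_end))  # N
            cig.append((0, e - s))  # M
            prev_end = e
        return cig

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        serial = 0
        for pair in pairs:
            blocks = pair.mate_blocks
            span_len = sum(e - s for s, e in blocks)
            r1_len = min(read_len, span_len)
            if pair.strand == "+":
                r1_blocks = _take_blocks(blocks, r1_len, from_left=True)
                r2_blocks = _take_blocks(blocks, min(read_len, span_len), from_left=False)
            else:
                r1_blocks = _take_blocks(blocks, r1_len, from_left=False)
                r2_blocks = _take_blocks(blocks, min(read_len, span_len), from_left=True)
            for _copy in range(pair.multiplicity):
                qname = f"{pair.library_id}.{serial}"
                serial += 1
                for which, rblocks in ((1, r1_blocks), (2, r2_blocks)):
                    a = pysam.AlignedSegment()
                    a.query_name = qname
                    a.reference_id = list(chrom_sizes).index(pair.chrom)
                    a.reference_start = rblocks[0][0]
                    a.cigartuples = cigar_for(rblocks)
                    rlen = sum(e - s for s, e in rblocks)
                    a.query_sequence = "A" * rlen
                    a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                    a.mapping_quality = 60
                    a.flag = 0x1 | 0x2  # paired, proper pair
                    rev1 = pair.strand == "-"
                    if which == 1:
                        a.flag |= 0x40 | (0x10 if rev1 else 0x20)
                    else:
                        a.flag |= 0x80 | (0x20 if rev1 else 0x10)
                    mate = r2_blocks if which == 1 else r1_blocks
                    a.next_reference_id = a.reference_id
                    a.next_reference_start = mate[0][0]
                    a.template_length = 0
                    out.write(a)


def _take_blocks(blocks: Blocks, want: int, from_left: bool) -> Blocks:
    out = []
    if from_left:
        for s, e in blocks:
            take = min(want, e - s)
            out.append((s, s + take))
            want -= take
            if want == 0:
                break
    else:
        for s, e in reversed(blocks):
            take = min(want, e - s)
            out.append((e - take, e))
            want -= take
            if want == 0:
                break
        out.reverse()
    return tuple(out)


# ---------------------------------------------------------------------------
# dedup and CTSS


def deduplicate(pairs) -> list[AlignedPair]:
    """Collapse pairs identical in (chrom, strand, pos5, mate_blocks).

    The output multiplicity is the total observed copy count; the operation
    is idempotent and never increases the pair count.  Output order is
    deterministic (genomic sort).
    """
    agg: dict[tuple, int] = {}
    lib: dict[tuple, str] = {}
    for pair in pairs:
        k = pair.key()
        agg[k] = agg.get(k, 0) + pair.multiplicity
        lib.setdefault(k, pair.library_id)
    out = [
        AlignedPair(lib[k], k[0], k[1], k[2], k[3], mult) for k, mult in agg.items()
    ]
    out.sort(key=lambda p: (p.chrom, p.span, p.strand, p.pos5))
    return out


class CTSSTrack:
    """Per-nucleotide 5'-end tag counts, keyed by (chrom, strand)."""

    def __init__(self):
        self._data: dict[tuple[str, str], Counter] = defaultdict(Counter)

    def items(self):
        return self._data.items()

    def __getitem__(self, key):
        return self._data[key]

    def add_pair(self, pair: AlignedPair, weight: int | None = None):
        self._data[(pair.chrom, pair.strand)][pair.pos5] += (
            weight if weight is not None else 1
        )

    def add_track(self, other: "CTSSTrack"):
        for key, counter in other.items():
            self._data[key].update(counter)

    def total(self) -> int:
        return sum(sum(c.values()) for c in self._data.values())

    def to_bedgraph(self, prefix) -> list[str]:
        """Write one bedGraph per strand (``<prefix>.plus.bedgraph`` /
        ``.minus.bedgraph``); minus-strand counts are written negative by
        UCSC convention."""
        paths = []
        for strand, tag, sign in (("+", "plus", 1), ("-", "minus", -1)):
            path = f"{prefix}.{tag}.bedgraph"
            with open(path, "w") as fh:
                for (chrom, s), counter in sorted(self._data.items()):
                    if s != strand:
                        continue
                    for pos in sorted(counter):
                        fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sign * counter[pos]}\n")
            paths.append(path)
        return paths


def ctss_counts(pairs, count_duplicates: bool = False) -> CTSSTrack:
    """One count per pair at its (chrom, strand, pos5).

    With the default ``count_duplicates=False`` each deduplicated pair
    contributes 1, so the track total equals the number of pairs.
    """
    track = CTSSTrack()
    for pair in pairs:
        track.add_pair(pair, pair.multiplicity if count_duplicates else 1)
    return track


def dedup_stats(raw_pairs, unique_pairs) -> dict:
    """Per-library accounting of input pairs vs unique pairs."""
    raw = Counter()
    for p in raw_pairs:
        raw[p.library_id] += p.multiplicity
    uniq = Counter()
    for p in unique_pairs:
        uniq[p.library_id] += 1
    return {
        lib: {"input_pairs": raw[lib], "unique_pairs": uniq[lib]}
        for lib in sorted(raw | uniq)
    }
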