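"""Density-based clustering of CAGE 5' end signal (Paraclu-style peak calling).

A CTSS track is a set of genomic positions with positive tag counts on one
strand.  For a contiguous segment S of tag positions, define the density of
any sub-run as ``tags / (last - first + 1)`` in base pairs (a single position
has length 1).  A segment S is *admissible* at density ``d`` when every
prefix and every suffix of S (including S itself) has density >= d, and it
is *maximal* at ``d`` when no strict superset segment is also admissible.
The cluster family emitted here is the union over all densities d > 0 of the
maximal admissible segments; it is laminar (any two clusters are disjoint or
nested) and each cluster carries the density interval (d_min, d_max] over
which it is maximal.

Writing ``m(S)`` for the minimum prefix/suffix density of S, a segment is
emitted exactly when ``m(S)`` exceeds ``m(T)`` for every strict superset T,
with ``d_max = m(S)`` and ``d_min = max_T m(T)`` (0 for top-level clusters,
where the stability ratio d_max/d_min is taken as infinite).  The
implementation evaluates this rule for all O(n^2) segments with vectorized
running minima/maxima rather than by recursive splitting, which keeps it an
exact transcription of the definition above.

Exact density ties can make two overlapping, non-nested segments maximal at
the same density (e.g. three equal counts at evenly spaced positions); such
conflicts are resolved deterministically toward the leftmost segment so that
the emitted family is always laminar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParacluCluster", "paraclu", "paraclu_track", "filter_peaks"]


@dataclass
class ParacluCluster:
    """A density-stable TSS peak.

    Coordinates are 0-based half-open genomic intervals; ``d_min``/``d_max``
    bound the density range over which the segment is a maximal cluster.
    """

    chrom: str
    strand: str
    start: int
    end: int
    tag_count: int
    d_min: float
    d_max: float
    parent: "ParacluCluster | None" = None
    children: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        return self.tag_count / self.length

    @property
    def stability(self) -> float:
        return self.d_max / self.d_min if self.d_min > 0 else float("inf")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ParacluCluster({self.chrom}:{self.start}-{self.end}({self.strand}) "
            f"tags={self.tag_count} d=[{self.d_min:.3g},{self.d_max:.3g}])"
        )


def paraclu_track(positions: np.ndarray, counts: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Run the clustering on one sorted single-strand track.

    Parameters
    ----------
    positions : sorted, strictly increasing genomic positions (0-based).
    counts : positive tag counts aligned with ``positions``.

    Returns
    -------
    List of ``(start_index, end_index, d_min, d_max)`` tuples over the input
    arrays (end_index inclusive), in (start, -length) order.
    """
    p = np.asarray(positions, dtype=np.int64)
    c = np.asarray(counts, dtype=np.float64)
    n = p.size
    if n == 0:
        return []
    if np.any(np.diff(p) <= 0):
        raise ValueError("positions must be strictly increasing")
    if np.any(c <= 0):
        raise ValueError("counts must be positive")

    # density of segment [i..j]: (C[j+1]-C[i]) / (p[j]-p[i]+1)
    C = np.concatenate([[0.0], np.cumsum(c)])
    tags = C[np.newaxis, 1:] - C[:, np.newaxis][:n, :]  # tags[i, j]
    length = p[np.newaxis, :] - p[:, np.newaxis] + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = tags / length
    # invalidate lower triangle (j < i)
    ii, jj = np.tril_indices(n, k=-1)
    dens[ii, jj] = np.inf

    # m[i, j] = min over prefixes [i..k] and suffixes [k..j] of density
    prefmin = np.minimum.accumulate(dens, axis=1)
    sufmin = np.minimum.accumulate(dens[::-1, :], axis=0)[::-1, :]
    m = np.minimum(prefmin, sufmin)
    m[ii, jj] = -np.inf

    # B[i, j] = max over i' <= i, j' >= j of m  (superset running max)
    B = np.maximum.accumulate(m, axis=0)
    B = np.maximum.accumulate(B[:, ::-1], axis=1)[:, ::-1]

    # strict-superset max: supersets with a smaller start, or same start and
    # a larger end
    M = np.full((n, n), -np.inf)
    M[1:, :] = np.maximum(M[1:, :], B[:-1, :])
    M[:, :-1] = np.maximum(M[:, :-1], B[:, 1:])

    emit_i, emit_j = np.nonzero(m > M)
    emitted = [
        (i, j, max(float(M[i, j]), 0.0), float(m[i, j]))
        for i, j in zip(emit_i.tolist(), emit_j.tolist())
    ]
    out = _enforce_laminar(emitted)
    out.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    return out


def _enforce_laminar(emitted: list[tuple[int, int, float, float]]):
    """Drop tie-induced conflicts: process segments densest-first (then
    leftmost, then longest) and keep each only if nested in or disjoint from
    everything already kept."""
    kept: list[tuple[int, int, float, float]] = []
    for seg in sorted(emitted, key=lambda t: (-t[3], t[0], -(t[1] - t[0]))):
        i, j = seg[0], seg[1]
        ok = True
        for ki, kj, _, _ in kept:
            overlap = i <= kj and ki <= j
            nested = (ki <= i and j <= kj) or (i <= ki and kj <= j)
            if overlap and not nested:
                ok = False
                break
        if ok:
            kept.append(seg)
    return kept


def _link_family(clusters: list[ParacluCluster]) -> None:
    """Attach parent/children links to a laminar, (start, -length)-sorted list."""
    stack: list[ParacluCluster] = []
    for cl in clusters:
        while stack and not (stack[-1].start <= cl.start and cl.end <= stack[-1].end):
            stack.pop()
        if stack:
            cl.parent = stack[-1]
            stack[-1].children.append(cl)
        stack.append(cl)


def paraclu(ctss) -> list[ParacluCluster]:
    """Cluster a (pooled) CTSS track into the full laminar peak hierarchy.

    ``ctss`` is a :class:`ribocage.tagio.CTSSTrack` (or any object exposing
    ``items()`` yielding ``((chrom, strand), {position: count})``).  Returns
    all clusters, strand-separated, with parent/children links set.
    """
    clusters: list[ParacluCluster] = []
    for (chrom, strand), track in sorted(ctss.items()):
        if not track:
            continue
        pos = np.array(sorted(track), dtype=np.int64)
        cnt = np.array([track[x] for x in pos.tolist()], dtype=np.float64)
        per_track: list[ParacluCluster] = []
        for i, j, dmin, dmax in paraclu_track(pos, cnt):
            per_track.append(
                ParacluCluster(
                    chrom=chrom,
                    strand=strand,
                    start=int(pos[i]),
                    end=int(pos[j]) + 1,
                    tag_count=int(round(cnt[i : j + 1].sum())),
                    d_min=dmin,
                    d_max=dmax,
                )
            )
        _link_family(per_track)
        clusters.extend(per_track)
    return clusters


def filter_peaks(
    clusters: list[ParacluCluster],
    max_len: int = 100,
    min_stability: float = 2.0,
    min_tags: int = 1,
) -> list[ParacluCluster]:
    """Flatten the hierarchy into disjoint seed peaks.

    Keeps the outermost clusters that satisfy ``length <= max_len``,
    ``d_max/d_min >= min_stability`` and ``tag_count >= min_tags``;
    descendants of a kept cluster are dropped, so by laminarity the
    survivors on one strand are disjoint.  Any residual same-strand overlap
    (defensive; cannot arise from a laminar input) is resolved in favour of
    the denser cluster.
    """

    def passes(cl: ParacluCluster) -> bool:
        return (
            cl.length <= max_len
            and cl.stability >= min_stability
            and cl.tag_count >= min_tags
        )

    kept: list[ParacluCluster] = []
    roots = [cl for cl in clusters if cl.parent is None]

    def descend(cl: ParacluCluster) -> None:
        if passes(cl):
            kept.append(cl)
            return
        for ch in cl.children:
            descend(ch)

    for root in roots:
        descend(root)

    # defensive overlap resolution: highest density wins, leftmost on ties
    kept.sort(key=lambda cl: (-cl.density, -cl.tag_count, cl.chrom, cl.start))
    chosen: list[ParacluCluster] = []
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for cl in kept:
        key = (cl.chrom, cl.strand)
        if any(cl.start < e and s < cl.end for s, e in occupied.get(key, [])):
            continue
        occupied.setdefault(key, []).append((cl.start, cl.end))
        chosen.append(cl)
    chosen.sort(key=lambda cl: (cl.chrom, cl.start, cl.strand))
    return chosen
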