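"""Independent brute-force oracles shared by the test suite and the
acceptance script.  These deliberately re-derive expected values from first
principles (explicit loops, closed forms, Monte-Carlo) and never call the
implementation paths they check."""

from __future__ import annotations

import numpy as np


def brute_force_paraclu(positions, counts):
    """Enumerate all density-maximal segments of a single-strand tag track.

    Density of a run of tag positions is ``tags / (last - first + 1)``.
    A segment S (endpoints at tag positions) is admissible at density d when
    every prefix and every suffix of S has density >= d; it is emitted when
    for some d > 0 it is admissible and no strict superset segment is.
    Writing m(S) for the minimum prefix/suffix density, a superset T is
    admissible at d iff m(T) >= d, so S is emitted iff m(S) > max_T m(T):
    choosing any d in (max_T m(T), m(S)] witnesses it, and no d works
    otherwise.  Exact density ties can leave two overlapping non-nested
    segments both maximal; the convention is leftmost-wins (densest first,
    then leftmost, then longest), which restores laminarity.

    Returns a set of ``(start_pos, end_pos_inclusive, d_min, d_max)`` with
    densities rounded for comparison, d_min floored at 0.
    """
    p = [int(x) for x in positions]
    c = [float(x) for x in counts]
    n = len(p)
    m = [[None] * n for _ in range(n)]
    for i in range(n):
        # min density over prefixes [i..k], k = i..j, tracked as j grows
        running = None
        tot = 0.0
        for j in range(i, n):
            tot += c[j]
            d = tot / (p[j] - p[i] + 1)
            running = d if running is None else min(running, d)
            m[i][j] = running
    for j in range(n):
        # fold in min density over suffixes [k..j], k = j..i
        running = None
        tot = 0.0
        for i in range(j, -1, -1):
            tot += c[i]
            d = tot / (p[j] - p[i] + 1)
            running = d if running is None else min(running, d)
            m[i][j] = min(m[i][j], running)
    marr = np.array([[m[i][j] if j >= i else -np.inf for j in range(n)] for i in range(n)])
    emitted = []
    for i in range(n):
        for j in range(i, n):
            best = -np.inf
            if i > 0:
                best = max(best, float(marr[:i, j:].max()))
            if j < n - 1:
                best = max(best, float(marr[: i + 1, j + 1 :].max()))
            if marr[i, j] > best:
                emitted.append((i, j, max(best, 0.0), float(marr[i, j])))
    # leftmost-wins tie rule, independently coded
    out = set()
    kept_spans = []
    for i, j, dmin, dmax in sorted(emitted, key=lambda t: (-t[3], t[0], t[0] - t[1])):
        conflict = False
        for ki, kj in kept_spans:
            if i <= kj and ki <= j:
                if not ((ki <= i and j <= kj) or (i <= ki and kj <= j)):
                    conflict = True
                    break
        if not conflict:
            kept_spans.append((i, j))
            out.add((p[i], p[j], round(dmin, 9), round(dmax, 9)))
    return out


def brute_force_bh(pvalues):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(pvalues, dtype=float)
    mtests = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(mtests)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = mtests - rank_from_top
        running = min(running, p[idx] * mtests / rank)
        adj[idx] = running
    return adj


def richness_closed_form_smallN(counts, m):
    """Expected distinct categories when drawing m of N tags without
    replacement, via exact ratios of binomial coefficients (small N only)."""
    from math import comb

    counts = [int(x) for x in counts if x > 0]
    N = sum(counts)
    return sum(1.0 - comb(N - ni, m) / comb(N, m) for ni in counts)


def richness_monte_carlo(counts, m, reps, rng):
    """Monte-Carlo estimate of subsampling richness, with standard error."""
    counts = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    labels = np.repeat(np.arange(counts.size), counts)
    vals = np.empty(reps)
    for r in range(reps):
        take = rng.choice(labels, size=m, replace=False)
        vals[r] = np.unique(take).size
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(reps))
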