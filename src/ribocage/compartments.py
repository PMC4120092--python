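"""Compartment-level summary statistics of the translatome.

Covers the bespoke numeric operations used to compare subcellular
compartments: subsampling richness (expected distinct clusters in a
fixed-size tag draw), feature-level tags-per-million, marker-panel log-FC
summaries, moving-window rank/score curves against external per-gene
scores, the dendritic-presence upper-quartile rule, the dendritic
enrichment intersection, fragment-size comparisons, and subsampling
saturation of the enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import ttest_ind, ttest_rel

from .clustering import count_matrix
from .enrichment import estimate_dispersion, exact_test

__all__ = [
    "AnalysisConfig",
    "richness",
    "feature_tpm",
    "marker_panel_summary",
    "rank_score_curve",
    "dendritic_presence",
    "dendritic_enrichment",
    "saturation",
    "cdna_size_test",
]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the compartment analyses."""

    richness_subsample: int = 1000  # m tags drawn per library
    rank_window: int = 200  # genes per moving window
    dendrite_quantile: float = 0.75
    aba_score_levels: tuple = (0.0, 0.5, 1.0)
    saturation_fractions: tuple = (0.1, 0.25, 0.5, 0.75, 1.0)
    background_sample: int = 700
    seed: int = 0

    def __post_init__(self):
        if self.richness_subsample <= 0:
            raise ValueError("richness_subsample must be positive")
        if not 0 < self.dendrite_quantile < 1:
            raise ValueError("dendrite_quantile must be in (0, 1)")
        if any(not 0 < f <= 1 for f in self.saturation_fractions):
            raise ValueError("saturation fractions must be in (0, 1]")


def richness(counts, m: int = 1000) -> float:
    """Expected number of distinct clusters in a without-replacement draw of
    ``m`` tags: R = sum_i [1 - C(N - n_i, m) / C(N, m)].

    Evaluated in log-gamma space; a cluster with fewer than m tags missing
    from the pool (N - n_i < m) is certain to appear.  High values mean many
    clusters at similar abundance; low values mean a few dominant clusters.
    """
    n = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    N = int(n.sum())
    if N < m:
        raise ValueError(f"richness undefined: library holds {N} < m = {m} tags")

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        log_miss = logC(N - n, m) - logC(N, m)
    miss = np.where(N - n < m, 0.0, np.exp(log_miss))
    return float(np.sum(1.0 - miss))


def feature_tpm(pairs, features) -> float:
    """Tags-per-million of deduplicated pairs whose 5' end falls sense
    inside any feature interval.

    ``features`` is an iterable of (chrom, start, end, strand); strand '.'
    matches both.  The denominator is the library's deduplicated total.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty library: TPM undefined")
    feats = [tuple(f) for f in features]
    hits = 0
    for p in pairs:
        for chrom, start, end, strand in feats:
            if p.chrom == chrom and start <= p.pos5 < end and strand in (p.strand, "."):
                hits += 1
                break
    return 1e6 * hits / len(pairs)


def read_feature_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[5].strip() if len(f) > 5 else "."))
    return out


def marker_panel_summary(results, panels: dict, representative: dict) -> pd.DataFrame:
    """Mean +/- sd of representative-cluster logFC per marker panel.

    ``representative`` maps gene symbol -> cluster id (from the annotation
    module); genes whose representative cluster is absent from the DE table
    are reported in the ``missing`` column and excluded from the mean.
    """
    import warnings

    rows = []
    for name, genes in panels.items():
        if not genes:
            warnings.warn(f"panel {name!r} is empty; skipped", stacklevel=2)
            continue
        lfc, missing = [], []
        for g in genes:
            cid = representative.get(g)
            if cid is None or cid not in results.index:
                missing.append(g)
            else:
                lfc.append(float(results.loc[cid, "logFC"]))
        rows.append(
            {
                "panel": name,
                "n": len(lfc),
                "mean_logFC": float(np.mean(lfc)) if lfc else np.nan,
                "sd_logFC": float(np.std(lfc, ddof=0)) if lfc else np.nan,
                "missing": ",".join(missing),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["n", "mean_logFC", "sd_logFC", "missing"],
            index=pd.Index([], name="panel"),
        )
    return pd.DataFrame(rows).set_index("panel")


def rank_score_curve(ranked_ids, scores: dict, window: int = 200,
                     background_n: int = 700, rng=None) -> dict:
    """Moving mean +/- SEM of external scores along a ranked gene list.

    Window r covers ranks [r, r + window); the background level is the mean
    score of a seeded random sample from the score universe; the crossing
    rank is the first window whose mean drops below the background.
    """
    vals = np.array([scores[i] for i in ranked_ids], dtype=float)
    n = vals.size
    w = min(window, n)
    kernel = np.ones(w) / w
    means = np.convolve(vals, kernel, mode="valid")
    sq = np.convolve(vals**2, kernel, mode="valid")
    sd = np.sqrt(np.clip(sq - means**2, 0.0, None) * w / max(w - 1, 1))
    sem = sd / np.sqrt(w)
    universe = np.array(list(scores.values()), dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    take = min(background_n, universe.size)
    background = float(rng.choice(universe, size=take, replace=False).mean())
    below = np.nonzero(means < background)[0]
    crossing = int(below[0]) + 1 if below.size else None  # 1-based rank
    return {
        "rank": np.arange(1, means.size + 1),
        "mean": means,
        "sem": sem,
        "background": background,
        "crossing_rank": crossing,
    }


def dendritic_presence(matrix, q: float = 0.75, nonzero_only: bool = False) -> list:
    """Clusters present in dendrites: CPM at or above the q-quantile of
    cluster CPMs in BOTH the dendritic rER and cytoplasmic fractions.

    The quantile (type-7) is computed over all matrix clusters by default;
    ``nonzero_only`` restricts it to clusters with nonzero dendritic counts.
    Requires at least one dendrite library per fraction.
    """
    meta = matrix.meta
    dend = meta[meta["compartment"] == "dendrite"]
    fractions = sorted(dend["fraction"].unique())
    if not {"cytoplasm", "rER"} <= set(fractions):
        missing = {"cytoplasm", "rER"} - set(fractions)
        raise ValueError(f"dendrite libraries missing for fraction(s): {sorted(missing)}")
    present = None
    for frac in ("cytoplasm", "rER"):
        libs = dend.index[dend["fraction"] == frac]
        pooled = matrix.counts[libs].sum(axis=1)
        cpm = 1e6 * pooled / pooled.sum()
        ref = cpm[cpm > 0] if nonzero_only else cpm
        thr = float(np.quantile(ref.to_numpy(), q))  # numpy default = type 7
        ok = set(cpm.index[cpm >= thr]) if thr > 0 else set(cpm.index[cpm > 0])
        present = ok if present is None else (present & ok)
    return sorted(present)


def dendritic_enrichment(de_tables: dict, fdr_max: float = 0.1,
                         annotation: dict | None = None) -> dict:
    """Clusters enriched (FDR gate, positive logFC) in EVERY
    dendrite-vs-whole contrast, with their annotated gene symbols."""
    sets = []
    for name, tab in de_tables.items():
        sel = (tab["fdr"] <= fdr_max) & (tab["logFC"] > 0)
        sets.append(set(tab.index[sel]))
    clusters = sorted(set.intersection(*sets)) if sets else []
    genes = (
        sorted({s for c in clusters for s in annotation.get(c, [])})
        if annotation is not None
        else []
    )
    return {"clusters": clusters, "genes": genes}


def saturation(clusters, pairs_by_library, meta, group_a, group_b,
               fractions=(0.1, 0.25, 0.5, 0.75, 1.0), seed: int = 0,
               fdr_max: float = 0.1) -> pd.DataFrame:
    """Subsampling saturation of the enrichment analysis.

    Each library's deduplicated pairs are subsampled without replacement at
    every rate, the cluster counts and the two-group exact test rerun, and
    the number of significant clusters and median |logFC| among them
    recorded.  Rates that empty a library yield NA rows.
    """
    fractions = sorted(fractions)
    ss = np.random.SeedSequence((seed, 104729))
    rows = []
    for frac, child in zip(fractions, ss.spawn(len(fractions))):
        rng = np.random.default_rng(child)
        sub = {}
        empty = False
        for lib, pairs in pairs_by_library.items():
            k = int(round(frac * len(pairs)))
            if k == 0:
                empty = True
                break
            idx = rng.choice(len(pairs), size=k, replace=False)
            sub[lib] = [pairs[i] for i in sorted(idx)]
        if empty:
            rows.append({"fraction": frac, "n_significant": np.nan, "median_abs_logFC": np.nan})
            continue
        mat = count_matrix(clusters, sub, meta)
        design = np.column_stack(
            [np.ones(len(meta)), [1.0 if l in group_a else 0.0 for l in meta.index]]
        )
        disp = estimate_dispersion(mat.counts, design)
        res = exact_test(mat.counts, group_a, group_b, disp)
        sig = res[(res["fdr"] <= fdr_max) & (res["logFC"] > 0)]
        rows.append(
            {
                "fraction": frac,
                "n_significant": int(len(sig)),
                "median_abs_logFC": float(sig["logFC"].abs().median()) if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cdna_size_test(sizes_a, sizes_b, paired: bool = False) -> dict:
    """Compare mean cDNA fragment sizes between two compartments (paired or
    Welch t-test)."""
    a, b = np.asarray(sizes_a, float), np.asarray(sizes_b, float)
    res = ttest_rel(a, b) if paired else ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": float(res.statistic),
        "pvalue": float(res.pvalue),
    }
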