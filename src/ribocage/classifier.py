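"""Sequence-composition promoter classifier.

Clusters that resemble known promoters are separated from intragenic
background by a bag-of-4-mers naive Bayes model over a 2-kb window centred
on the dominant CTSS: two pseudocounted multinomial k-mer distributions
(promoter vs background) and a length-normalized log-odds score, with
``high`` confidence for scores strictly above the threshold ``tau``.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .simulate import revcomp

__all__ = ["KmerPromoterClassifier", "extract_window", "train", "score_and_classify",
           "build_training_windows"]

_BASES = "ACGT"


def _kmer_index(k: int) -> dict:
    return {"".join(t): i for i, t in enumerate(itertools.product(_BASES, repeat=k))}


def count_kmers(seq: str, k: int, index: dict) -> np.ndarray:
    """Overlapping k-mer counts; windows containing N (or any non-ACGT base)
    contribute only their unambiguous k-mers."""
    out = np.zeros(len(index))
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        j = index.get(seq[i : i + k])
        if j is not None:
            out[j] += 1
    return out


class KmerPromoterClassifier(ClassifierMixin, BaseEstimator):
    """Naive Bayes log-odds classifier on k-mer composition.

    Parameters
    ----------
    k : k-mer length (4 by convention).
    window : window size in bp centred on the TSS (metadata for extraction;
        the model itself accepts sequences of any length).
    alpha : pseudocount added to each k-mer count per class.
    tau : decision threshold on the per-k-mer mean log-odds; ``high``
        requires a score strictly greater than tau.

    Fitted attributes
    -----------------
    log_p_promoter_, log_p_background_ : log probability vectors over the
        4^k k-mers; each class sums to 1 in probability space.
    """

    def __init__(self, k: int = 4, window: int = 2000, alpha: float = 1.0, tau: float = 0.0):
        self.k = k
        self.window = window
        self.alpha = alpha
        self.tau = tau

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y):
        """Fit from sequences ``X`` and binary labels ``y`` (1 = promoter)."""
        y = np.asarray(y)
        index = _kmer_index(self.k)
        pos = np.zeros(len(index))
        neg = np.zeros(len(index))
        for seq, lab in zip(X, y):
            (pos if lab == 1 else neg).__iadd__(count_kmers(seq, self.k, index))
        if pos.sum() == 0 or neg.sum() == 0:
            raise ValueError("a class has zero usable k-mers; cannot fit")
        self.kmer_index_ = index
        self.log_p_promoter_ = np.log(pos + self.alpha) - np.log(
            pos.sum() + self.alpha * len(index)
        )
        self.log_p_background_ = np.log(neg + self.alpha) - np.log(
            neg.sum() + self.alpha * len(index)
        )
        self.classes_ = np.array([0, 1])
        return self

    def score_sequence(self, seq: str) -> float:
        """Mean per-k-mer log-odds log P(kmer|promoter)/P(kmer|background);
        NaN when the sequence holds no usable k-mer."""
        counts = count_kmers(seq, self.k, self.kmer_index_)
        n = counts.sum()
        if n == 0:
            return float("nan")
        return float(counts @ (self.log_p_promoter_ - self.log_p_background_) / n)

    def decision_function(self, X) -> np.ndarray:
        return np.array([self.score_sequence(s) for s in X]) - self.tau

    def predict(self, X) -> np.ndarray:
        scores = np.array([self.score_sequence(s) for s in X])
        with np.errstate(invalid="ignore"):
            return (scores > self.tau).astype(int)

    def calibrate_tau(self, negatives, specificity: float = 0.95) -> float:
        """Set tau from a target specificity on held-out negative windows."""
        scores = np.sort([self.score_sequence(s) for s in negatives])
        self.tau = float(np.quantile(scores, specificity))
        return self.tau

    def to_tsv(self, path) -> None:
        inv = sorted(self.kmer_index_, key=self.kmer_index_.get)
        with open(path, "w") as fh:
            fh.write("kmer\tlogP_promoter\tlogP_background\n")
            for kmer, lp, lb in zip(inv, self.log_p_promoter_, self.log_p_background_):
                fh.write(f"{kmer}\t{lp:.8f}\t{lb:.8f}\n")


def train(positive_windows, negative_windows, k: int = 4, window: int = 2000,
          alpha: float = 1.0, tau: float = 0.0, min_class_size: int = 50) -> KmerPromoterClassifier:
    """Fit the classifier from explicit window sequence sets."""
    if len(positive_windows) < min_class_size or len(negative_windows) < min_class_size:
        raise ValueError(
            f"need >= {min_class_size} windows per class, got "
            f"{len(positive_windows)}/{len(negative_windows)}"
        )
    X = list(positive_windows) + list(negative_windows)
    y = [1] * len(positive_windows) + [0] * len(negative_windows)
    return KmerPromoterClassifier(k=k, window=window, alpha=alpha, tau=tau).fit(X, y)


def extract_window(genome, chrom: str, pos: int, strand: str, window: int = 2000) -> str:
    """Sequence of the window/2-bp flanks around a TSS, on the transcript
    strand (reverse-complemented for minus-strand clusters), truncated at
    chromosome edges.

    ``genome`` is a mapping chrom -> sequence string (e.g. a pyfaidx.Fasta
    works via its string interface).
    """
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} absent from genome FASTA") from None
    seq = str(seq[:]) if not isinstance(seq, str) else seq
    half = window // 2
    if strand == "+":
        lo, hi = pos - half, pos + half
    else:
        # mirror-symmetric window so that reverse-complementing the genome
        # (which flips the strand) returns the same window sequence
        lo, hi = pos - half + 1, pos + half + 1
    lo_c, hi_c = max(0, lo), min(len(seq), hi)
    out = seq[lo_c:hi_c]
    return out if strand == "+" else revcomp(out)


def score_and_classify(clusters, model: KmerPromoterClassifier, genome,
                       ctss_track=None) -> None:
    """Attach classifier_score and confidence to clusters in place.

    Windows shorter than k yield an undefined score: confidence ``low``,
    score NaN.  Confidence is ``high`` only for score strictly above tau.
    """
    from .annotation import dominant_ctss

    for c in clusters:
        pos = dominant_ctss(c, ctss_track) if ctss_track is not None else (
            c.dominant_ctss if c.dominant_ctss is not None else c.seed.start
        )
        seq = extract_window(genome, c.chrom, pos, c.strand, model.window)
        score = model.score_sequence(seq) if len(seq) >= model.k else float("nan")
        c.classifier_score = score
        c.confidence = "high" if (score == score and score > model.tau) else "low"


def build_training_windows(clusters, models, genome, ctss_track, rng,
                           window: int = 2000, tss_tolerance: int = 100,
                           n_negatives: int | None = None) -> tuple[list, list]:
    """Training sets from the data itself: positives are windows of clusters
    whose dominant CTSS lies within ``tss_tolerance`` of an annotated
    transcript 5' end; negatives are windows at random intergenic positions,
    length-matched by construction."""
    from .annotation import dominant_ctss

    tss_by_key: dict = {}
    for gene in models.genes.values():
        tss = gene.start if gene.strand == "+" else gene.end - 1
        tss_by_key.setdefault((gene.chrom, gene.strand), []).append(tss)
    positives = []
    for c in clusters:
        pos = dominant_ctss(c, ctss_track)
        nearby = tss_by_key.get((c.chrom, c.strand), [])
        if any(abs(pos - t) <= tss_tolerance for t in nearby):
            positives.append(extract_window(genome, c.chrom, pos, c.strand, window))
    n_neg = n_negatives if n_negatives is not None else max(len(positives), 50)
    chroms = sorted(genome if isinstance(genome, dict) else genome.keys())
    occupied: dict = {}
    for gene in models.genes.values():
        occupied.setdefault(gene.chrom, []).append((gene.start - window, gene.end + window))
    negatives = []
    guard = 0
    while len(negatives) < n_neg and guard < 50 * n_neg:
        guard += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        seq = genome[chrom]
        clen = len(seq if isinstance(seq, str) else seq[:])
        pos = int(rng.integers(window, clen - window))
        if any(s <= pos < e for s, e in occupied.get(chrom, [])):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        negatives.append(extract_window(genome, chrom, pos, strand, window))
    return positives, negatives
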