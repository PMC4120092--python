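# Methods

This note documents the models implemented in `ribocage`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Coordinates and tag representation

All internal coordinates are 0-based half-open. SAM input (1-based) is
converted on read; BED is native. A paired-end tag is reduced to
`(chromosome, strand, pos5, mate_blocks)`: `pos5` is the 5′-most base of
mate 1 on the transcript strand (for minus-strand pairs, the highest
genomic coordinate of mate 1), and `mate_blocks` are the sorted,
non-overlapping intervals covered by both mates. PCR duplicates are pairs
identical in this whole tuple; deduplication sums their multiplicities and
is idempotent. A default mapping-quality floor of MAPQ ≥ 10 is applied on
SAM read (configurable; alignment pipelines differ in how they encode
multi-mappers, and 10 removes the common ambiguous class without touching
confident unique alignments).

## TSS peak calling

The caller operates per (chromosome, strand) on the pooled CTSS track. The
density of a run of tag positions is `tags / (last − first + 1)` in bp, so
a single position has length 1 and finite density. A segment *S* is
admissible at threshold *d* when every prefix and every suffix of *S*
(including *S* itself) has density ≥ *d*; it is emitted when it is maximal
(no admissible strict superset) at some *d* > 0. Writing *m(S)* for the
minimum prefix/suffix density, the emitted family is exactly
{*S* : *m(S)* > max over strict supersets *T* of *m(T)*}, each segment
carrying *d<sub>max</sub>* = *m(S)* and *d<sub>min</sub>* = the superset
maximum (0 for top-level segments, whose stability ratio is taken as
infinite). The implementation evaluates this rule for all O(n²) segments
with vectorized running minima/maxima; memory is O(n²) per track, which is
the intended regime for pooled tracks of up to a few thousand distinct
positions per chromosome and strand.

Two conventions deserve note. First, exact density ties (for example three
equal counts at evenly spaced positions) can make two overlapping,
non-nested segments simultaneously maximal; conflicts are resolved
deterministically toward the leftmost (densest first, then leftmost, then
longest), which restores laminarity. Second, peak filtering keeps the
*outermost* cluster in the laminar hierarchy that satisfies the filters
(length ≤ 100 bp, stability ≥ 2, tag count ≥
a configurable floor, default 1). Keeping outermost survivors rather than
the densest overlapping one matters: a 1-bp spike inside a sharp promoter
would otherwise win on density and strand the bulk of the promoter's tags
outside the seed, breaking the seed-level count accounting that downstream
statistics rely on. Survivors of the outermost rule are disjoint by
laminarity.

## CAGEscan assembly and counting

Each filtered peak seeds one cluster. A deduplicated pair is assigned to
the unique seed containing its `pos5` on the matching strand (seeds are
disjoint, so "at most one" is structural); unassigned pairs are reported.
Cluster blocks are the merged union of the seed interval and all assigned
mate blocks. The count matrix cell (cluster, library) is the number of that
library's deduplicated pairs with `pos5` in the seed; per library,
assigned + unassigned equals the library total.

## Annotation

Sense overlap of the seed with a gene gives source `direct`; otherwise
sense overlap of any mate block gives `cagescan`; otherwise the cluster is
unannotated. All intersected symbols are kept (a multi-gene cluster counts
toward every symbol). Rescue, applied to unannotated clusters that pass the
enrichment gate, annotates via a secondary ("RefSeq-like") model set or via
a window downstream of a primary gene's 3′ end on the same strand (putative
long 3′ UTR; default 10 kb — a deliberate compromise between documented
long 3′ UTRs and the risk of claiming unrelated downstream loci).
Pseudogene-biotype models are excluded from annotation (configurable) and
instead drive the pseudogene triage flag.

The positional category of a cluster is decided at its *dominant CTSS*
(modal position of the seed, leftmost on ties) against all
sense-overlapping transcripts, with precedence 5′UTR > CDS exon > 3′UTR >
intron; exons of non-coding transcripts rank with CDS exons, and no sense
overlap gives `intergenic`. The representative cluster of a gene prefers
high-confidence classification before expression, with a leftmost
tie-break.

## Promoter classifier

Two pseudocounted (α = 1) multinomial distributions over the 4⁴ = 256
4-mers — one for promoter windows, one for background — with the
length-normalized log-odds score

  s(w) = (1/K) Σ_k log P(k-mer | promoter) / P(k-mer | background)

over the K overlapping 4-mers of the 2-kb window centred on the dominant
CTSS (reverse-complemented for minus-strand clusters; windows are
truncated at chromosome edges; 4-mers containing non-ACGT bases are
skipped). Confidence is `high` iff s(w) > τ, default τ = 0 (the balance
point of the symmetric model); τ can instead be calibrated to a target
specificity on held-out negatives. Positives for training are clusters
whose dominant CTSS lies within ±100 bp of an annotated transcript start;
negatives are seeded random intergenic windows. A bag-of-k-mers model was
chosen as the simplest family consistent with modeling "the distribution
of all 4-mers" in a fixed window; it carries no positional information
within the window, which a real promoter model might exploit.

## Enrichment statistics

Counts are modeled NB: var = μ + φμ². The module re-implements the
edgeR-family computations rather than calling them; exact numeric
agreement with any external package is not a contract — calibration is
established by simulation — although the test suite does cross-check TMM
factors against Bioconductor edgeR on a small matrix.

* **TMM**: reference library chosen by the 75th-percentile rule; M-values
  trimmed 30% two-sided, A-values 5%; delta-method precision weights;
  factors rescaled to geometric mean 1. Clusters zero in either library are
  excluded.
* **Dispersion**: common φ maximizes the summed Cox–Reid adjusted profile
  likelihood (IRLS fit per candidate φ, penalty −½ log det XᵀWX); shrunk
  per-cluster values maximize the cluster's own APL plus `prior_weight`
  (default 10) times the average APL curve, on a log-spaced grid. Designs
  without residual degrees of freedom fall back to a floor (10⁻⁴) with a
  warning.
* **Exact test**: libraries are equalized to the geometric-mean effective
  size by NB quantile adjustment (average of normal and gamma
  quantile-to-quantile maps, preserving the mean–variance relation where
  plain scaling would distort it); group sums are compared conditionally on
  their total, with p = 2 × the one-sided conditional tail on the observed
  side, capped at 1. log2FC uses a prior count of 0.125.
* **GLM LRT**: log-link NB GLM fit by batched IRLS with offsets
  log(total × TMM factor); p from the likelihood-ratio χ²(1). The χ²
  reference is asymptotic in the counts: at per-library means below ~30 the
  null distribution is visibly discrete/conservative, which the test suite
  accounts for by checking uniformity on well-expressed clusters. Wald
  standard errors accompany each coefficient.
* **BH-FDR** is delegated to statsmodels and verified against the
  step-up definition; the gate FDR ≤ 0.1 is applied per contrast over all
  tested clusters with no independent filtering.

For dendrite-vs-soma contrasts the pipeline guards TMM: when fewer than
30% of the whole-fraction-expressed clusters are also expressed in the
dendritic group, the trimmed mean is dominated by the restricted
transcriptome itself and would absorb the biological signal, so the
contrast falls back to total-count normalization (logged).

## Compartment statistics

* **Richness**: R = Σᵢ [1 − C(N−nᵢ, m)/C(N, m)] with m = 1000, evaluated
  with log-gamma; clusters with N − nᵢ < m are certain to appear. This is
  the expected-species rarefaction of classical ecology, exact rather than
  sampled.
* **Feature TPM**: 10⁶ × (sense 5′ ends in the feature intervals) /
  (library deduplicated total); feature intervals supplied as BED.
* **Rank/score curves**: moving mean ± SEM over 200-gene windows of an
  external 0/0.5/1 score along the p-value-ranked gene list, with a seeded
  random background sample (default 700 genes) and the first
  below-background window reported as the crossing rank.
* **Dendritic presence**: a cluster is present iff its CPM is at or above
  the q-quantile (default 0.75, numpy type-7) of cluster CPMs in *both* the
  dendritic rER and cytoplasmic fractions. The quantile is computed over
  all matrix clusters (zeros included) by default: "upper quartile of total
  expression" is read as a quantile of the full cluster population, and
  with a strongly restricted dendritic transcriptome a nonzero-only
  quantile degenerates (the threshold lands inside the expressed group
  itself). A `nonzero_only` switch exposes the alternative reading; if the
  resulting threshold is 0, presence falls back to nonzero-in-both.
* **Dendritic enrichment**: FDR ≤ 0.1 and positive logFC in *every*
  dendrite-vs-whole contrast, intersected.
* **cDNA size**: the exported per-pair size is the genomic span of the pair
  (5′ end to mate end). This is a proxy — it includes intron gaps that the
  cDNA does not — so it is suited to within-genome comparisons between
  fractions (the planted rER < cytoplasm ordering is preserved), not to
  absolute fragment-length claims. Paired and Welch t-tests are provided.
* **Saturation**: each library's deduplicated pairs are subsampled without
  replacement at a ladder of rates (default ¼, ½, 1 in the pipeline),
  counting and the exact test rerun, and the number of significant clusters
  and median |logFC| recorded; rates that empty a library yield NA.

## ncRNA screen

Triage of unannotated enriched clusters: `template_switch_artifact` iff the
genomic sequence immediately 5′ of the dominant CTSS on the sense strand
equals the last k bases of the template-switching oligo tail (default
"GGG", k = 3 — the canonical strand-invasion signature; both are
configurable since protocols differ); `pseudogene_overlap` for sense or
antisense block overlap with a pseudogene model; `multi_locus_span` for
spans > 100 kb or blocks sense-intersecting more than one locus. A SINEUP
candidate must (a) overlap a protein-coding gene on the opposite strand
with its own 5′ end between 5 kb upstream of the partner's 5′ end and the
partner's 3′ end (the head-to-head operationalization; window configurable)
and (b) overlap a SINE repeat downstream of its own TSS in its own
orientation. Any SINE family is accepted; the family name is reported.

## The synthetic study

Defaults emulate a full ribosome-capture nanoCAGE study at desk scale: 10
libraries (three replicated IP pools × cytoplasm/rER, one supernatant pool
× both fractions, one dendritic pool × both fractions; a full-scale study
of this kind runs ~24 such libraries), ~12 000 expected baseline pairs per
library (against ~1.2 M unique tags at production depth), a two-chromosome
1.32-Mb genome with 60 genes (13–18 kb intergenic gaps, so that the 10-kb
rescue window behaves as it does on a mammalian genome), and NB unique-pair
counts with dispersion φ = 0.1.

Planted structure: lognormal baseline weights (σ = 0.8, capped at 4 to
keep the most abundant transcripts below the unique-pair key-space
ceiling); per-class capture log2 fold changes (+3 for the PC-enriched
class, −3 for glia-like, 0 otherwise); rER/cytoplasm log2 effects drawn
from {±1.5, 0}; four cytoplasm-dominant transcripts (composition bias and
lower cytoplasmic richness); sharp promoters as discretized Laplace
(scale 1 bp) and broad promoters uniform over 40 bp; gene-body noise
("capped processed transcripts") at up to two recurrent hotspots per gene,
placed ≥ 1.8 kb from the TSS so their 2-kb windows remain background-like,
with noise proportional to gene expression (12% by default); PCR
duplication 1 + Poisson(mean − 1) per unique pair; fraction-specific cDNA
fragment sizes (cytoplasm 700 ± 150, rER 300 ± 80 bp); CpG-island promoter
composition with tunable strength (0 = background, the null fixture); a
strictly restricted dendritic transcriptome (12 genes share the dendritic
depth, allocation including the capture fold change so dendrite-vs-whole
enrichment is uniform across classes); and one decoy of each screen class —
SINEUP (antisense inside a partner gene with a SINE/B2 planted downstream
of its TSS), a matched antisense locus without a repeat, an expressed
pseudogene, a sharp template-switching artifact with genomic GGG planted
immediately upstream (and the signature scrubbed from every other TSS), a
multi-hundred-kb multi-locus cluster anchored in intergenic gaps, an
annotated SRP-like small RNA with planted per-fraction abundance, and a
gene present only in the secondary models. Decoy loci get broad promoters
(except the artifact, which is deliberately sharp at its G-rich site) and
2–2.5 kb transcripts: unique-pair identity has a finite key space
(5′ position × fragment end), and short or extremely abundant transcripts
saturate it, compressing realized fold changes — a real library-complexity
phenomenon that the generator keeps out of the planted-truth regime by
construction.

What passing the end-to-end tests does *not* show about real data: the
simulation has no mapping errors or multi-mappers, no rRNA or adapter
contamination, no positional biases in fragment ends, promoter composition
reduced to GC/CpG content, uniform dispersion across clusters, and decoys
planted one per class with clean geometry. It validates the computational
contracts — exact deduplication, peak-caller correctness, calibration of
the NB tests, classifier behaviour under planted composition, and the
screen's decision rules — not biological discovery performance.

## Problem sizes and determinism

The default test-suite and acceptance runs use: 1000 random tracks (≤ 30
positions) for the peak-caller oracle; 50 random count vectors × 10⁵
Monte-Carlo replicates for richness; 5000-cluster simulations for the NB
calibration; 2000 clusters × 6 pairs for the paired GLM; 250 + 250
training and 200–250 + 200–250 held-out 2-kb windows for the classifier;
and the full 10-library synthetic study end to end. Every random draw
descends from a single seed through `numpy.random.SeedSequence`, and a
rerun with the same seed is byte-identical file for file.
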