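"""Synthetic nanoCAGE/CAGEscan data with a machine-readable planted truth.

The generator emits a toy genome (FASTA), gene models (primary and secondary
GTF), SINE repeat annotation (BED), per-library aligned pairs (SAM or
BED12), a library metadata table, and ``truth.json`` describing every
planted feature, so each downstream pipeline stage can be tested against
known ground truth.

What is emulated
----------------
* sharp (discretized Laplace, scale 1 bp) and broad (uniform over 40 bp)
  promoter tag-position distributions;
* intragenic "capped processed transcript" background noise at recurrent
  gene-body hotspots, scaling with gene expression;
* PCR duplication (1 + Poisson copies of each unique pair);
* spliced downstream mates respecting exon structure, with fraction-specific
  cDNA fragment sizes (cytoplasm longer than rER);
* per-library negative-binomial unique-pair counts with planted per-class
  log2 fold changes (ribosome-capture IP vs supernatant, rER vs cytoplasm)
  and a restricted, strongly concentrated dendritic transcriptome;
* composition bias (a few dominant transcripts in the cytoplasmic fraction);
* CpG-enriched promoter sequence composition, tunable down to a null;
* decoy loci: a head-to-head antisense SINEUP locus overlapping a SINE
  repeat, a matched antisense locus without a repeat, an expressed
  pseudogene, a template-switching artifact (genomic GGG immediately
  upstream of the TSS), a multi-hundred-kb multi-locus cluster, and a gene
  present only in the secondary ("RefSeq-like") models for annotation
  rescue.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .tagio import AlignedPair, merge_blocks, write_pairs_bed12, write_pairs_sam

__all__ = [
    "LibraryMeta",
    "SimConfig",
    "Unit",
    "Reference",
    "TruthTable",
    "generate_reference",
    "simulate_libraries",
    "write_outputs",
    "default_library_design",
    "SizingError",
]


class SizingError(ValueError):
    """Genome too small to place the requested features."""


@dataclass(frozen=True)
class LibraryMeta:
    library_id: str
    fraction: str  # cytoplasm | rER
    capture: str  # IP | supernatant
    compartment: str  # whole | dendrite
    pair_id: str
    target_pairs: int = 12000


def default_library_design(target_pairs: int = 12000) -> list[LibraryMeta]:
    """Scaled-down version of the study's 24-library design: three replicated
    IP pools and one supernatant pool, each split into cytoplasmic and
    rER-bound fractions, plus one dendritic pool (both fractions)."""
    libs = []
    for pool in ("P1", "P2", "P3"):
        for frac, tag in (("cytoplasm", "c"), ("rER", "r")):
            libs.append(LibraryMeta(f"{pool}{tag}", frac, "IP", "whole", pool, target_pairs))
    for frac, tag in (("cytoplasm", "c"), ("rER", "r")):
        libs.append(LibraryMeta(f"S1{tag}", frac, "supernatant", "whole", "S1", target_pairs))
    for frac, tag in (("cytoplasm", "c"), ("rER", "r")):
        libs.append(LibraryMeta(f"D1{tag}", frac, "IP", "dendrite", "D1", target_pairs))
    return libs


@dataclass
class SimConfig:
    """Study conditions for the simulation (defaults are the package's
    scaled-down emulation of a full ribosome-capture nanoCAGE study)."""

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 760_000, "chr2": 560_000})
    n_genes: int = 60
    intergenic_gap: tuple = (13_000, 18_000)  # realistic spacing >> rescue window
    class_fractions: dict = field(
        default_factory=lambda: {
            "pc_enriched": 10 / 60,
            "glia": 8 / 60,
            "other_neuron": 12 / 60,
            "background": 30 / 60,
        }
    )
    promoter_gc_bias: float = 0.6
    shape_mix: float = 0.5  # fraction of sharp promoters
    pcr_dup_mean: float = 2.0
    nb_dispersion: float = 0.1
    fold_changes: dict = field(
        default_factory=lambda: {
            "ip_vs_supernatant": {
                "pc_enriched": 3.0,
                "glia": -3.0,
                "other_neuron": 0.0,
                "background": 0.0,
            }
        }
    )
    rer_log2fc_choices: tuple = (1.5, -1.5, 0.0, 0.0, 0.0)
    noise_rate: float = 0.12
    n_dendritic: int = 12
    dendrite_concentration: bool = True
    n_sineup: int = 1
    with_decoys: bool = True
    srp_tpm: dict = field(default_factory=lambda: {"rER": 1800.0, "cytoplasm": 1000.0})
    cyto_dominant_genes: int = 4
    cyto_dominance: float = 4.0
    fragment_size: dict = field(
        default_factory=lambda: {"cytoplasm": (700.0, 150.0), "rER": (300.0, 80.0)}
    )
    read_len: int = 25
    weight_sigma: float = 0.8
    library_design: list = field(default_factory=default_library_design)
    seed: int = 0

    def validate(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for name in ("promoter_gc_bias", "shape_mix", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.pcr_dup_mean < 1:
            raise ValueError("pcr_dup_mean must be >= 1")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")


@dataclass
class Unit:
    """One transcription unit (gene or planted special locus).

    ``exons`` are gene-coordinate half-open intervals with 0 at the TSS and
    coordinates increasing downstream; genomic mapping depends on strand.
    """

    unit_id: str
    name: str
    chrom: str
    strand: str
    tss: int
    exons: list  # [(gs, ge), ...] in gene coordinates
    utr5_len: int = 0
    utr3_len: int = 0
    gene_class: str = "background"
    biotype: str = "protein_coding"
    sharp: bool = True
    dendritic: bool = False
    special: str | None = None
    in_primary: bool = True
    in_secondary: bool = True
    base_weight: float = 1.0
    rer_log2fc: float = 0.0
    noise_offsets: list = field(default_factory=list)  # transcript coords

    # -- coordinate helpers -------------------------------------------------
    @property
    def tx_len(self) -> int:
        return sum(ge - gs for gs, ge in self.exons)

    def gene_to_genomic(self, x: int) -> int:
        return self.tss + x if self.strand == "+" else self.tss - x

    def genomic_span(self) -> tuple[int, int]:
        lo = self.gene_to_genomic(self.exons[0][0])
        hi = self.gene_to_genomic(self.exons[-1][1] - 1)
        return (min(lo, hi), max(lo, hi) + 1)

    def genomic_blocks(self, gene_blocks) -> tuple:
        out = []
        for gs, ge in gene_blocks:
            if self.strand == "+":
                out.append((self.tss + gs, self.tss + ge))
            else:
                out.append((self.tss - ge + 1, self.tss - gs + 1))
        return merge_blocks(out)

    def exon_genomic_blocks(self) -> tuple:
        return self.genomic_blocks(self.exons)

    def tx_to_gene_blocks(self, a: int, b: int) -> list:
        """Map a transcript interval [a, b) to gene-coordinate blocks."""
        out = []
        cum = 0
        for gs, ge in self.exons:
            ln = ge - gs
            lo, hi = max(a, cum), min(b, cum + ln)
            if lo < hi:
                out.append((gs + lo - cum, gs + hi - cum))
            cum += ln
        return out

    def tx_to_genomic_blocks(self, a: int, b: int) -> tuple:
        return self.genomic_blocks(self.tx_to_gene_blocks(a, b))

    def cds_gene_interval(self) -> tuple[int, int] | None:
        if self.biotype != "protein_coding":
            return None
        tx = self.tx_len
        a, b = self.utr5_len, tx - self.utr3_len
        if b <= a:
            return None
        ga = self.tx_to_gene_blocks(a, a + 1)[0][0]
        gb = self.tx_to_gene_blocks(b - 1, b)[0][1]
        return ga, gb


@dataclass
class TruthTable:
    """Planted ground truth; the oracle for end-to-end tests."""

    classes: dict = field(default_factory=dict)  # unit_id -> class label
    true_log2fc: dict = field(default_factory=dict)  # contrast -> unit -> fc
    dendritic: list = field(default_factory=list)
    sineup: list = field(default_factory=list)  # [{id, partner, sine}]
    clean_ncrna: list = field(default_factory=list)
    artifact: list = field(default_factory=list)
    pseudogene: list = field(default_factory=list)
    multilocus: list = field(default_factory=list)
    rescue: list = field(default_factory=list)
    srp: list = field(default_factory=list)
    tss: dict = field(default_factory=dict)  # unit_id -> [chrom, strand, pos]
    unique_counts: dict = field(default_factory=dict)  # unit -> lib -> n (promoter pairs)
    noise_unique_counts: dict = field(default_factory=dict)
    library_unique_totals: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Reference:
    config: SimConfig
    sequences: dict  # chrom -> str
    units: list  # [Unit]
    repeats: list  # [(chrom, start, end, name, strand)]
    truth: TruthTable

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    def unit_by_id(self, uid: str) -> Unit:
        for u in self.units:
            if u.unit_id == uid:
                return u
        raise KeyError(uid)


# ---------------------------------------------------------------------------
# reference construction

_BACKGROUND_P = {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29}


def _background_seq(rng, n: int) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p = [_BACKGROUND_P[b] for b in "ACGT"]
    return rng.choice(bases, size=n, p=p)


def _promoter_seq(rng, n: int, bias: float) -> np.ndarray:
    """CpG-island-like sequence; bias 0 reduces to the background model."""
    gc = min(0.21 + 0.125 * bias, 0.45)
    p = np.array([0.5 - gc, gc, gc, 0.5 - gc])
    cpg_boost = 0.35 * bias
    out = np.empty(n, dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    u = rng.random(n)
    draws = rng.choice(bases, size=n, p=p)
    for i in range(n):
        if i > 0 and out[i - 1] == b"C" and u[i] < cpg_boost:
            out[i] = b"G"
        else:
            out[i] = draws[i]
    return out


def _make_gene_structure(rng, sharp: bool) -> tuple[list, int, int]:
    """Exons in gene coordinates, plus UTR lengths."""
    utr5 = int(rng.integers(100, 200))
    n_introns = int(rng.integers(1, 4))
    exons = []
    cursor = 0
    first_len = utr5 + int(rng.integers(250, 600))
    exons.append((cursor, cursor + first_len))
    cursor += first_len
    for _ in range(n_introns):
        cursor += int(rng.integers(400, 1500))  # intron
        ln = int(rng.integers(350, 800))
        exons.append((cursor, cursor + ln))
        cursor += ln
    utr3 = int(rng.integers(80, min(200, exons[-1][1] - exons[-1][0])))
    return exons, utr5, utr3


def generate_reference(config: SimConfig) -> Reference:
    """Build the toy genome, gene models, repeats and truth table."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_seq, rng_weights = [np.random.default_rng(s) for s in ss.spawn(3)]

    chroms = list(config.chrom_lengths)
    clens = config.chrom_lengths
    margin = 4000
    gap_lo, gap_hi = config.intergenic_gap

    # assign gene counts per chromosome proportional to length
    total_len = sum(clens.values())
    n_per_chrom = {c: max(1, int(round(config.n_genes * clens[c] / total_len))) for c in chroms}
    while sum(n_per_chrom.values()) > config.n_genes:
        n_per_chrom[max(n_per_chrom, key=n_per_chrom.get)] -= 1
    while sum(n_per_chrom.values()) < config.n_genes:
        n_per_chrom[min(n_per_chrom, key=n_per_chrom.get)] += 1

    class_names = list(config.class_fractions)
    n_by_class = {c: int(round(config.class_fractions[c] * config.n_genes)) for c in class_names}
    while sum(n_by_class.values()) > config.n_genes:
        n_by_class[max(n_by_class, key=n_by_class.get)] -= 1
    while sum(n_by_class.values()) < config.n_genes:
        n_by_class["background"] += 1
    class_pool = [c for c in class_names for _ in range(n_by_class[c])]
    rng_place.shuffle(class_pool)

    units: list[Unit] = []
    gidx = 0
    for chrom in chroms:
        cursor = margin
        for _ in range(n_per_chrom[chrom]):
            exons, utr5, utr3 = _make_gene_structure(rng_place, True)
            span = exons[-1][1]
            gap = int(rng_place.integers(gap_lo, gap_hi))
            if cursor + span + gap > clens[chrom] - margin:
                raise SizingError(
                    f"{chrom} ({clens[chrom]} bp) cannot hold {n_per_chrom[chrom]} genes; "
                    "increase chrom_lengths or decrease n_genes"
                )
            strand = "+" if rng_place.random() < 0.5 else "-"
            tss = cursor if strand == "+" else cursor + span - 1
            cls = class_pool[gidx]
            sharp = bool(rng_place.random() < config.shape_mix)
            unit = Unit(
                unit_id=f"G{gidx:03d}",
                name=f"Gene{gidx:03d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                exons=exons,
                utr5_len=utr5,
                utr3_len=utr3,
                gene_class=cls,
                sharp=sharp,
                base_weight=float(min(rng_weights.lognormal(0.0, config.weight_sigma), 4.0)),
                rer_log2fc=float(rng_place.choice(config.rer_log2fc_choices)),
            )
            # gene-body noise hotspots (transcript coordinates), kept well
            # clear of the promoter so their 2-kb sequence windows stay
            # background-like; short genes may host fewer or none
            tx = unit.tx_len
            cands: list[int] = []
            for _ in range(30):
                off = int(rng_place.integers(200, max(201, tx - 60)))
                gcoord = unit.tx_to_gene_blocks(off, off + 1)[0][0]
                if gcoord >= 1800 and off not in cands:
                    cands.append(off)
                if len(cands) == 2:
                    break
            unit.noise_offsets = sorted(cands)
            units.append(unit)
            cursor += span + gap
            gidx += 1

    # dendritic flags
    dend_ids = rng_place.choice(len(units), size=min(config.n_dendritic, len(units)), replace=False)
    for k in sorted(dend_ids.tolist()):
        units[k].dendritic = True

    repeats: list[tuple] = []
    truth = TruthTable()

    def intergenic_gaps(chrom: str) -> list[tuple[int, int]]:
        spans = sorted(u.genomic_span() for u in units if u.chrom == chrom)
        gaps, prev = [], margin
        for s, e in spans:
            if s - prev > 0:
                gaps.append((prev, s))
            prev = max(prev, e)
        gaps.append((prev, clens[chrom] - margin))
        return [(s + 200, e - 200) for s, e in gaps if e - s > 1200]

    def decoy_position(gaps: list, want_frac: float, clen: int) -> int:
        # keep planted intergenic TSSs > 10 kb past any gene 3' end so the
        # long-3'UTR rescue window cannot claim them
        wide = [g for g in gaps if g[1] - g[0] > 12_500] or gaps
        target = margin + want_frac * (clen - 2 * margin)
        best = min(wide, key=lambda gp: abs((gp[0] + gp[1]) / 2 - target))
        return best[0] + 10_600

    specials: list[Unit] = []
    if config.with_decoys:
        # --- SINEUP: antisense, head-to-head inside a partner gene's 5' region,
        # overlapping a SINE repeat downstream of its own TSS
        partners = [u for u in units if u.gene_class == "pc_enriched"]
        for k in range(config.n_sineup):
            partner = partners[k]
            offset = 1200  # antisense TSS this far into the partner, gene coords
            as_strand = "-" if partner.strand == "+" else "+"
            as_tss = partner.gene_to_genomic(offset)
            su = Unit(
                unit_id=f"SINEUP{k}",
                name=f"{partner.name}os",
                chrom=partner.chrom,
                strand=as_strand,
                tss=as_tss,
                exons=[(0, 1900)],  # runs back across the partner's 5' end
                sharp=False,
                biotype="ncRNA",
                gene_class="pc_enriched",
                special="sineup",
                in_primary=False,
                in_secondary=False,
                base_weight=2.0,
            )
            specials.append(su)
            s_lo = su.gene_to_genomic(150)
            s_hi = su.gene_to_genomic(270)
            sine = (su.chrom, min(s_lo, s_hi), max(s_lo, s_hi) + 1, "SINE/B2", su.strand)
            repeats.append(sine)
            truth.sineup.append(
                {"id": su.unit_id, "partner": partner.unit_id, "sine": list(sine[:3])}
            )

        # --- matched antisense locus WITHOUT a SINE (must not be a candidate)
        partner2 = [u for u in units if u.gene_class == "other_neuron"][0]
        cn = Unit(
            unit_id="NCRNA0",
            name=f"{partner2.name}os",
            chrom=partner2.chrom,
            strand="-" if partner2.strand == "+" else "+",
            tss=partner2.gene_to_genomic(1200),
            exons=[(0, 1900)],
            sharp=False,
            biotype="ncRNA",
            gene_class="pc_enriched",
            special="clean_ncrna",
            in_primary=False,
            in_secondary=False,
            base_weight=2.0,
        )
        specials.append(cn)
        truth.clean_ncrna.append({"id": cn.unit_id, "partner": partner2.unit_id})

        gaps1 = intergenic_gaps(chroms[0])
        if len(gaps1) < 6:
            raise SizingError("not enough intergenic space on chr1 for decoy loci")

        # --- template-switching artifact: genomic GGG immediately 5' of TSS
        art = Unit(
            unit_id="ART0",
            name="Artifact0",
            chrom=chroms[0],
            strand="+",
            tss=decoy_position(gaps1, 0.2, clens[chroms[0]]),
            exons=[(0, 2500)],
            sharp=True,  # template switching fires at one precise G-rich site
            biotype="ncRNA",
            gene_class="pc_enriched",
            special="artifact",
            in_primary=False,
            in_secondary=False,
            base_weight=1.2,
        )
        specials.append(art)
        truth.artifact.append({"id": art.unit_id})

        # --- expressed pseudogene (annotated with biotype pseudogene)
        pg = Unit(
            unit_id="PSG0",
            name="Pseudo0",
            chrom=chroms[0],
            strand="+",
            tss=decoy_position(gaps1, 0.45, clens[chroms[0]]),
            exons=[(0, 2500)],
            sharp=False,
            biotype="pseudogene",
            gene_class="pc_enriched",
            special="pseudogene",
            in_primary=True,
            in_secondary=True,
            base_weight=2.0,
        )
        specials.append(pg)
        truth.pseudogene.append({"id": pg.unit_id})

        # --- multi-locus artifact cluster: intergenic anchors spread over
        # hundreds of kb, so the assembled cluster spans multiple loci
        anchors = [decoy_position(gaps1, 0.06, clens[chroms[0]])]
        for frac in (0.35, 0.6, 0.85):
            target = margin + frac * (clens[chroms[0]] - 2 * margin)
            best = min(gaps1, key=lambda gp: abs((gp[0] + gp[1]) / 2 - target))
            anchors.append(int((best[0] + best[1]) / 2))
        anchors = sorted(set(anchors))
        anchors = [a for k, a in enumerate(anchors) if k == 0 or a - anchors[k - 1] > 20_000]
        first = anchors[0]
        ml_exons = [(a - first, a - first + 700) for a in anchors]
        ml = Unit(
            unit_id="MULTI0",
            name="Multi0",
            chrom=chroms[0],
            strand="+",
            tss=first,
            exons=ml_exons,
            sharp=False,
            biotype="ncRNA",
            gene_class="pc_enriched",
            special="multilocus",
            in_primary=False,
            in_secondary=False,
            base_weight=2.0,
        )
        specials.append(ml)
        truth.multilocus.append({"id": ml.unit_id, "span_bp": ml_exons[-1][1]})

        # --- SRP-like locus (annotated non-coding RNA, fraction-biased)
        gaps2 = intergenic_gaps(chroms[-1])
        srp = Unit(
            unit_id="SRP0",
            name="SrpRna",
            chrom=chroms[-1],
            strand="+",
            tss=decoy_position(gaps2, 0.1, clens[chroms[-1]]),
            exons=[(0, 300)],
            sharp=False,
            biotype="misc_RNA",
            gene_class="background",
            special="srp",
            in_primary=True,
            in_secondary=True,
            base_weight=0.0,  # expression set from srp_tpm, not weights
        )
        specials.append(srp)
        truth.srp.append({"id": srp.unit_id, "tpm": dict(config.srp_tpm)})

        # --- rescue gene: present only in the secondary models
        rescue = [u for u in units if u.gene_class == "pc_enriched"][-1]
        rescue.in_primary = False
        truth.rescue.append({"id": rescue.unit_id})

    units = units + specials

    # several decoys double as extra-contrast members; record all truths
    for u in units:
        truth.classes[u.unit_id] = u.gene_class
        truth.tss[u.unit_id] = [u.chrom, u.strand, int(u.tss)]
        if u.dendritic:
            truth.dendritic.append(u.unit_id)
    for contrast, fcs in config.fold_changes.items():
        truth.true_log2fc[contrast] = {
            u.unit_id: float(fcs.get(u.gene_class, 0.0)) for u in units
        }
    truth.true_log2fc["rer_vs_cytoplasm"] = {u.unit_id: u.rer_log2fc for u in units}

    # --- genome sequence: background, promoter windows, planted motifs
    sequences: dict[str, np.ndarray] = {}
    chrom_rngs = {c: np.random.default_rng(s) for c, s in zip(chroms, ss.spawn(len(chroms)))}
    for chrom in chroms:
        sequences[chrom] = _background_seq(chrom_rngs[chrom], clens[chrom])
    half = 1000
    for u in units:
        if u.special in ("artifact", "multilocus"):
            continue  # background composition at these TSSs
        chrom_seq = sequences[u.chrom]
        lo = max(0, u.tss - half)
        hi = min(len(chrom_seq), u.tss + half)
        win = _promoter_seq(chrom_rngs[u.chrom], hi - lo, config.promoter_gc_bias)
        if u.strand == "-":
            win = _revcomp_arr(win)
        chrom_seq[lo:hi] = win
    # plant the template-switching signature immediately 5' of the artifact TSS
    for entry in truth.artifact:
        u = next(x for x in units if x.unit_id == entry["id"])
        seq = sequences[u.chrom]
        if u.strand == "+":
            seq[u.tss - 3 : u.tss] = np.frombuffer(b"GGG", dtype="S1")
        else:
            seq[u.tss + 1 : u.tss + 4] = np.frombuffer(b"CCC", dtype="S1")
    # make sure no other TSS carries the artifact signature by chance
    for u in units:
        if u.special == "artifact":
            continue
        seq = sequences[u.chrom]
        if u.strand == "+":
            up = seq[max(0, u.tss - 3) : u.tss].tobytes().decode()
            if up.endswith("GG"):
                seq[u.tss - 1] = b"T"
        else:
            up = seq[u.tss + 1 : u.tss + 4].tobytes().decode()
            if up.startswith("CC"):
                seq[u.tss + 1] = b"T"

    # background SINE repeats in intergenic space (must not create candidates)
    for chrom in chroms:
        gaps = intergenic_gaps(chrom)
        for g in gaps[:: max(1, len(gaps) // 3)]:
            mid = (g[0] + g[1]) // 2
            repeats.append((chrom, mid, mid + 140, "SINE/ID", "+"))

    sequences_str = {c: arr.tobytes().decode() for c, arr in sequences.items()}
    return Reference(config=config, sequences=sequences_str, units=units,
                     repeats=sorted(repeats), truth=truth)


_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return np.frombuffer(arr.tobytes().translate(_COMP), dtype="S1")[::-1].copy()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# library simulation


def _unit_mean(unit: Unit, lib: LibraryMeta, config: SimConfig, sum_w: float,
               sum_w_dend: float, dominant: set) -> float:
    """Expected unique promoter-pair count for one unit in one library."""
    if unit.special == "srp":
        if lib.compartment == "dendrite":
            return 0.0
        return lib.target_pairs * config.srp_tpm[lib.fraction] / 1e6
    if lib.compartment == "dendrite":
        if not unit.dendritic or not config.dendrite_concentration:
            return 0.0 if config.dendrite_concentration else _whole_mean(
                unit, lib, config, sum_w, dominant
            )
        # restricted transcriptome: dendritic genes share the full depth.
        # Dendritic pools are IP captures, so the capture fold change enters
        # the allocation too; this keeps the dendrite-vs-whole enrichment
        # uniform across dendritic genes of different capture classes.
        fc = config.fold_changes.get("ip_vs_supernatant", {}).get(unit.gene_class, 0.0)
        w = unit.base_weight * 2.0 ** fc
        return lib.target_pairs * w / sum_w_dend
    return _whole_mean(unit, lib, config, sum_w, dominant)


def _whole_mean(unit, lib, config, sum_w, dominant) -> float:
    mu = lib.target_pairs * unit.base_weight / sum_w
    if lib.capture == "IP":
        fc = config.fold_changes.get("ip_vs_supernatant", {}).get(unit.gene_class, 0.0)
        if unit.special is not None:
            fc = max(fc, 3.0)  # planted decoys are all captured
        mu *= 2.0 ** fc
    if lib.fraction == "rER":
        mu *= 2.0 ** unit.rer_log2fc
    if lib.fraction == "cytoplasm" and unit.unit_id in dominant:
        mu *= config.cyto_dominance
    return mu


def expected_unique_counts(reference: Reference, lib: LibraryMeta) -> dict:
    """Planted NB means per unit for one library (promoter pairs, before
    noise); exposed so tests can check the count model's moments."""
    config = reference.config
    config_fc = config.fold_changes.get("ip_vs_supernatant", {})
    regular = [u for u in reference.units if u.special != "srp"]
    sum_w = sum(u.base_weight for u in regular)
    sum_w_dend = sum(
        u.base_weight * 2.0 ** config_fc.get(u.gene_class, 0.0)
        for u in regular if u.dendritic
    ) or 1.0
    dominant = _dominant_set(reference)
    return {
        u.unit_id: _unit_mean(u, lib, config, sum_w, sum_w_dend, dominant)
        for u in reference.units
    }


def _dominant_set(reference: Reference) -> set:
    config = reference.config
    regular = [u for u in reference.units if u.special is None]
    top = sorted(regular, key=lambda u: -u.base_weight)[: config.cyto_dominant_genes]
    return {u.unit_id for u in top}


def _draw_nb(rng, mu: float, phi: float) -> int:
    if mu <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mu))
    r = 1.0 / phi
    return int(rng.negative_binomial(r, r / (r + mu)))


def simulate_libraries(reference: Reference, config: SimConfig | None = None) -> dict:
    """Draw per-library aligned pairs (with PCR duplicates) and record the
    planted unique-pair counts in the truth table.

    Returns ``{library_id: [AlignedPair, ...]}`` where identical duplicates
    appear as repeated entries (multiplicity 1 each), ready for SAM/BED12
    emission and for exercising deduplication downstream.
    """
    config = config or reference.config
    libs = config.library_design
    captures = {l.capture for l in libs}
    if not {"IP", "supernatant"} <= captures:
        warnings.warn(
            "library design lacks both IP and supernatant libraries; the "
            "capture-enrichment contrast is infeasible",
            stacklevel=2,
        )
    ss = np.random.SeedSequence((config.seed, 7919))
    lib_rngs = {l.library_id: np.random.default_rng(s) for l, s in zip(libs, ss.spawn(len(libs)))}

    truth = reference.truth
    out: dict[str, list[AlignedPair]] = {}
    for lib in libs:
        rng = lib_rngs[lib.library_id]
        means = expected_unique_counts(reference, lib)
        pairs: list[AlignedPair] = []
        total_unique = 0
        for unit in reference.units:
            mu = means[unit.unit_id]
            n_prom = _draw_nb(rng, mu, config.nb_dispersion)
            noise_mu = (
                mu * config.noise_rate / max(1, len(unit.noise_offsets))
                if (unit.noise_offsets and lib.compartment == "whole")
                else 0.0
            )
            prom_pairs = _draw_unit_pairs(rng, unit, lib, config, n_prom, origin=None)
            noise_pairs = []
            for hot in unit.noise_offsets:
                n_noise = _draw_nb(rng, noise_mu, config.nb_dispersion)
                noise_pairs.extend(
                    _draw_unit_pairs(rng, unit, lib, config, n_noise, origin=hot)
                )
            # collapse accidental identical draws so "unique" is exact;
            # promoter identity wins on the (vanishingly rare) collision
            uniq: dict[tuple, AlignedPair] = {}
            n_prom_unique = 0
            for p in prom_pairs:
                if p.key() not in uniq:
                    uniq[p.key()] = p
                    n_prom_unique += 1
            n_noise_unique = 0
            for p in noise_pairs:
                if p.key() not in uniq:
                    uniq[p.key()] = p
                    n_noise_unique += 1
            truth.unique_counts.setdefault(unit.unit_id, {})[lib.library_id] = n_prom_unique
            truth.noise_unique_counts.setdefault(unit.unit_id, {})[lib.library_id] = n_noise_unique
            pairs.extend(uniq.values())
            total_unique += len(uniq)
        truth.library_unique_totals[lib.library_id] = total_unique
        # PCR duplication of each unique pair
        dup = []
        for p in pairs:
            copies = 1 + int(rng.poisson(config.pcr_dup_mean - 1.0))
            dup.extend([p] * copies)
        rng.shuffle(dup)
        out[lib.library_id] = dup
    return out


def _draw_unit_pairs(rng, unit: Unit, lib: LibraryMeta, config: SimConfig,
                     n: int, origin: int | None) -> list[AlignedPair]:
    """Draw ``n`` unique pairs for one unit; ``origin`` is None for promoter
    tags or a transcript coordinate for a noise hotspot."""
    if n == 0:
        return []
    pairs = []
    tx = unit.tx_len
    mean, sd = config.fragment_size[lib.fraction]
    rl = config.read_len
    for _ in range(n):
        if origin is None:
            if unit.sharp:
                off = int(np.rint(rng.laplace(0.0, 1.0)))
            else:
                off = int(rng.integers(0, 40))
            start_tx = max(off, 0)
        else:
            off = None
            start_tx = min(origin + int(np.rint(rng.laplace(0.0, 1.0))), tx - rl - 1)
            start_tx = max(start_tx, 0)
        frag = int(np.clip(rng.normal(mean, sd), rl + 10, max(rl + 11, tx - start_tx - 1)))
        end_tx = min(start_tx + frag, tx)
        mate_blocks = unit.tx_to_genomic_blocks(max(end_tx - rl, start_tx), end_tx)
        if origin is None:
            pos5 = unit.gene_to_genomic(off)
        else:
            pos5 = unit.tx_to_genomic_blocks(start_tx, start_tx + 1)[0][0]
        if unit.strand == "+":
            r1 = (pos5, pos5 + rl)
        else:
            r1 = (pos5 - rl + 1, pos5 + 1)
        blocks = merge_blocks(list(mate_blocks) + [r1])
        pairs.append(AlignedPair(lib.library_id, unit.chrom, unit.strand, pos5, blocks))
    return pairs


# ---------------------------------------------------------------------------
# serialization


def write_outputs(reference: Reference, libraries: dict | None, outdir,
                  pair_format: str = "sam") -> dict:
    """Write FASTA, GTFs, repeat BED, SRP BED, truth.json, libraries.tsv and
    (when ``libraries`` is given) one alignment file per library.  Returns a
    manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["genome"] = str(fasta)
    fai = Path(str(fasta) + ".fai")
    if fai.exists():
        fai.unlink()  # stale index invalidates determinism checks

    for tag, attr in (("primary", "in_primary"), ("secondary", "in_secondary")):
        gtf = outdir / f"models_{tag}.gtf"
        _write_gtf(reference, gtf, attr)
        paths[f"models_{tag}"] = str(gtf)

    rep = outdir / "repeats.bed"
    with open(rep, "w") as fh:
        for chrom, s, e, name, strand in reference.repeats:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
    paths["repeats"] = str(rep)

    srp_units = [reference.unit_by_id(e["id"]) for e in reference.truth.srp]
    srp = outdir / "srp.bed"
    with open(srp, "w") as fh:
        for u in srp_units:
            s, e = u.genomic_span()
            fh.write(f"{u.chrom}\t{s}\t{e}\t{u.unit_id}\t0\t{u.strand}\n")
    paths["srp"] = str(srp)

    libtsv = outdir / "libraries.tsv"
    with open(libtsv, "w") as fh:
        fh.write("library_id\tfraction\tcapture\tcompartment\tpair_id\ttarget_pairs\n")
        for l in reference.config.library_design:
            fh.write(
                f"{l.library_id}\t{l.fraction}\t{l.capture}\t{l.compartment}\t"
                f"{l.pair_id}\t{l.target_pairs}\n"
            )
    paths["libraries"] = str(libtsv)

    if libraries is not None:
        for lib_id, pairs in libraries.items():
            if pair_format == "sam":
                p = outdir / f"{lib_id}.sam"
                write_pairs_sam(pairs, p, reference.chrom_lengths, reference.config.read_len)
            else:
                p = outdir / f"{lib_id}.bed12"
                write_pairs_bed12(pairs, p, name_prefix=f"{lib_id}.")
            paths[f"library:{lib_id}"] = str(p)

    truthp = outdir / "truth.json"
    reference.truth.to_json(truthp)
    paths["truth"] = str(truthp)
    return paths


def _write_gtf(reference: Reference, path, attr: str) -> None:
    with open(path, "w") as fh:
        fh.write("##description: synthetic gene models\n")
        for u in reference.units:
            if not getattr(u, attr) or u.special in ("sineup", "clean_ncrna", "artifact", "multilocus"):
                continue
            s, e = u.genomic_span()
            common = (
                f'gene_id "{u.unit_id}"; transcript_id "{u.unit_id}.1"; '
                f'gene_name "{u.name}"; gene_biotype "{u.biotype}";'
            )
            fh.write(
                f"{u.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{u.strand}\t.\t"
                f'gene_id "{u.unit_id}"; gene_name "{u.name}"; gene_biotype "{u.biotype}";\n'
            )
            fh.write(f"{u.chrom}\tsim\ttranscript\t{s + 1}\t{e}\t.\t{u.strand}\t.\t{common}\n")
            for bs, be in u.exon_genomic_blocks():
                fh.write(f"{u.chrom}\tsim\texon\t{bs + 1}\t{be}\t.\t{u.strand}\t.\t{common}\n")
            cds = u.cds_gene_interval()
            if cds is not None:
                for bs, be in u.genomic_blocks(u.tx_to_gene_blocks(u.utr5_len, u.tx_len - u.utr3_len)):
                    fh.write(f"{u.chrom}\tsim\tCDS\t{bs + 1}\t{be}\t.\t{u.strand}\t0\t{common}\n")
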