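"""Staged pipeline orchestration over a workspace directory.

Stages (in dependency order): ``simulate`` -> ``dedup`` -> ``cluster`` ->
``annotate`` -> ``classify`` -> ``test`` -> ``compartments`` -> ``ncrna``.
Each stage reads the previous stage's files from the workspace, writes its
outputs atomically (temp file + rename) and drops a manifest (config hash,
seed, input checksums) as its completion marker; downstream stages refuse
to run with an actionable error when the marker is missing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as anno
from . import classifier as clf
from . import compartments as comp
from . import enrichment as enr
from . import ncrna as ncr
from .clustering import (CAGEscanCluster, assemble_cagescan, clusters_to_bed12,
                         count_matrix, seeds_to_bed6)
from .config import PipelineConfig
from .paraclu import ParacluCluster, filter_peaks, paraclu
from .simulate import (SimConfig, TruthTable, generate_reference,
                       simulate_libraries, write_outputs)
from .tagio import (ctss_counts, dedup_stats, deduplicate, read_aligned_pairs,
                    write_pairs_bed12)

logger = logging.getLogger("ribocage")

STAGES = ["simulate", "dedup", "cluster", "annotate", "classify", "test",
          "compartments", "ncrna"]


class MissingUpstream(RuntimeError):
    def __init__(self, stage: str, needed: str):
        super().__init__(
            f"stage '{stage}' needs outputs of stage '{needed}'; "
            f"run 'ribocage {needed}' first"
        )


class InfeasibleDesign(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# small helpers


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, stage: str, outputs: list) -> None:
    import ribocage

    manifest = {
        "stage": stage,
        "version": getattr(ribocage, "__version__", "0"),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "outputs": {str(p): _checksum(Path(p)) for p in outputs if Path(p).is_file()},
    }
    _atomic_write(cfg.path(f"{stage}.manifest.json"), json.dumps(manifest, indent=1, sort_keys=True))


def _require(cfg: PipelineConfig, stage: str, needed: str) -> None:
    if not cfg.path(f"{needed}.manifest.json").is_file():
        raise MissingUpstream(stage, needed)


def _load_meta(cfg: PipelineConfig) -> pd.DataFrame:
    path = cfg.libraries or cfg.path("sim", "libraries.tsv")
    return pd.read_csv(path, sep="\t").set_index("library_id")


def _genome(cfg: PipelineConfig) -> dict:
    from pyfaidx import Fasta

    path = cfg.genome or cfg.path("sim", "genome.fa")
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _truth(cfg: PipelineConfig) -> TruthTable | None:
    p = cfg.path("sim", "truth.json")
    return TruthTable.from_json(p) if p.is_file() else None


# ---------------------------------------------------------------------------
# cluster (de)serialization


def _dump_clusters(clusters, path: Path) -> None:
    recs = []
    for c in clusters:
        recs.append(
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "strand": c.strand,
                "seed": [c.seed.start, c.seed.end, c.seed.tag_count, c.seed.d_min, c.seed.d_max],
                "blocks": [list(b) for b in c.blocks],
                "counts": c.counts,
                "dominant_ctss": c.dominant_ctss,
                "annotation": c.annotation,
                "annotation_source": c.annotation_source,
                "category": c.category,
                "classifier_score": c.classifier_score,
                "confidence": c.confidence,
            }
        )
    _atomic_write(path, json.dumps(recs))


def _load_clusters(path: Path) -> list:
    out = []
    for r in json.loads(path.read_text()):
        seed = ParacluCluster(r["chrom"], r["strand"], r["seed"][0], r["seed"][1],
                              r["seed"][2], r["seed"][3], r["seed"][4])
        out.append(
            CAGEscanCluster(
                cluster_id=r["cluster_id"],
                seed=seed,
                blocks=tuple(tuple(b) for b in r["blocks"]),
                counts=r["counts"],
                dominant_ctss=r["dominant_ctss"],
                annotation=r["annotation"],
                annotation_source=r["annotation_source"],
                category=r["category"],
                classifier_score=r["classifier_score"],
                confidence=r["confidence"],
            )
        )
    return out


def _load_dedup_pairs(cfg: PipelineConfig) -> dict:
    meta = _load_meta(cfg)
    out = {}
    for lib in meta.index:
        out[lib] = read_aligned_pairs(cfg.path("dedup", f"{lib}.bed12"), "bed12", lib)
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> None:
    sim_kwargs = dict(cfg.sim)
    sim_kwargs.setdefault("seed", cfg.seed)
    simcfg = SimConfig(**sim_kwargs)
    ref = generate_reference(simcfg)
    libs = simulate_libraries(ref)
    paths = write_outputs(ref, libs, cfg.path("sim"), pair_format=cfg["pair_format"])
    _write_manifest(cfg, "simulate", list(paths.values()))
    logger.info("simulate: %d units, %d libraries", len(ref.units), len(libs))


def stage_dedup(cfg: PipelineConfig) -> None:
    if cfg.libraries is None:
        _require(cfg, "dedup", "simulate")
    meta = _load_meta(cfg)
    captures = set(meta["capture"])
    if not {"IP", "supernatant"} <= captures:
        raise InfeasibleDesign(
            "library design lacks IP and/or supernatant libraries; the "
            "capture contrast cannot be tested"
        )
    outdir = cfg.path("dedup")
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = cfg["pair_format"]
    stats = {}
    pooled_track = None
    outputs = []
    for lib in meta.index:
        src = cfg.path("sim", f"{lib}.{ 'sam' if fmt == 'sam' else 'bed12' }")
        raw = read_aligned_pairs(src, fmt, lib, mapq_min=cfg["mapq_min"])
        uniq = deduplicate(raw)
        stats.update(dedup_stats(raw, uniq))
        dst = outdir / f"{lib}.bed12"
        write_pairs_bed12(
            [p.__class__(p.library_id, p.chrom, p.strand, p.pos5, p.mate_blocks, 1) for p in uniq],
            dst, name_prefix=f"{lib}.",
        )
        outputs.append(dst)
        track = ctss_counts(uniq)
        track.to_bedgraph(str(outdir / f"{lib}.ctss"))
        if pooled_track is None:
            pooled_track = track
        else:
            pooled_track.add_track(track)
    pooled_track.to_bedgraph(str(outdir / "pooled.ctss"))
    stats_df = pd.DataFrame(stats).T
    stats_df.index.name = "library_id"
    stats_df.to_csv(outdir / "dedup_stats.tsv", sep="\t")
    outputs.append(outdir / "dedup_stats.tsv")
    _write_manifest(cfg, "dedup", outputs)
    logger.info("dedup: %s", {k: v["unique_pairs"] for k, v in stats.items()})


def stage_cluster(cfg: PipelineConfig) -> None:
    _require(cfg, "cluster", "dedup")
    pairs_by_lib = _load_dedup_pairs(cfg)
    meta = _load_meta(cfg)
    pooled = [p for pairs in pairs_by_lib.values() for p in pairs]
    track = ctss_counts(pooled)
    hierarchy = paraclu(track)
    seeds = filter_peaks(
        hierarchy,
        max_len=cfg["paraclu_max_len"],
        min_stability=cfg["paraclu_min_stability"],
        min_tags=cfg["paraclu_min_tags"],
    )
    clusters, unassigned = assemble_cagescan(seeds, pooled)
    for c in clusters:
        anno.dominant_ctss(c, track)
    mat = count_matrix(clusters, pairs_by_lib, meta)
    keep = mat.counts.sum(axis=1) >= cfg["min_pooled_count"]
    mat.counts = mat.counts[keep]
    clusters = [c for c in clusters if keep.get(c.cluster_id, False)]
    outdir = cfg.path("cluster")
    outdir.mkdir(parents=True, exist_ok=True)
    seeds_to_bed6(seeds, outdir / "seeds.bed")
    clusters_to_bed12(clusters, outdir / "clusters.bed12")
    mat.to_tsv(outdir / "counts.tsv")
    _dump_clusters(clusters, outdir / "clusters.json")
    _atomic_write(outdir / "unassigned.json",
                  json.dumps({"pooled_unassigned": len(unassigned), **mat.unassigned}))
    _write_manifest(cfg, "cluster", [outdir / "seeds.bed", outdir / "counts.tsv",
                                     outdir / "clusters.json"])
    logger.info("cluster: %d seeds, %d clusters, %d unassigned pooled pairs",
                len(seeds), len(clusters), len(unassigned))


def _load_models(cfg: PipelineConfig, which: str) -> anno.GeneModelSet | None:
    default = cfg.path("sim", f"models_{which}.gtf")
    path = getattr(cfg, f"models_{which}") or (default if default.is_file() else None)
    if path is None:
        return None
    return anno.GeneModelSet.from_gtf(path, source=which,
                                      exclude_biotypes=tuple(cfg["exclude_biotypes"]))


def stage_annotate(cfg: PipelineConfig) -> None:
    _require(cfg, "annotate", "cluster")
    clusters = _load_clusters(cfg.path("cluster", "clusters.json"))
    models = _load_models(cfg, "primary")
    anno.annotate(clusters, models)
    for c in clusters:
        anno.categorize_tss(c, models)
    outdir = cfg.path("annotate")
    outdir.mkdir(parents=True, exist_ok=True)
    anno.annotation_table(clusters).to_csv(outdir / "annotation.tsv", sep="\t")
    _dump_clusters(clusters, cfg.path("cluster", "clusters.json"))
    _write_manifest(cfg, "annotate", [outdir / "annotation.tsv"])
    src = pd.Series([c.annotation_source for c in clusters]).value_counts().to_dict()
    logger.info("annotate: %s", src)


def stage_classify(cfg: PipelineConfig) -> None:
    _require(cfg, "classify", "annotate")
    clusters = _load_clusters(cfg.path("cluster", "clusters.json"))
    genome = _genome(cfg)
    models = _load_models(cfg, "primary")
    pairs = _load_dedup_pairs(cfg)
    track = ctss_counts([p for ps in pairs.values() for p in ps])
    rng = np.random.default_rng((cfg.seed, 33))
    pos, neg = clf.build_training_windows(
        clusters, models, genome, track, rng,
        window=cfg["classifier_window"], tss_tolerance=cfg["classifier_tss_tolerance"],
    )
    model = clf.train(pos, neg, k=cfg["classifier_k"], window=cfg["classifier_window"],
                      alpha=cfg["classifier_alpha"], tau=cfg["classifier_tau"])
    clf.score_and_classify(clusters, model, genome)
    outdir = cfg.path("classify")
    outdir.mkdir(parents=True, exist_ok=True)
    model.to_tsv(outdir / "kmer_model.tsv")
    clusters_to_bed12(clusters, outdir / "clusters_scored.bed12", score_from="score")
    _dump_clusters(clusters, cfg.path("cluster", "clusters.json"))
    _write_manifest(cfg, "classify", [outdir / "kmer_model.tsv"])
    n_high = sum(1 for c in clusters if c.confidence == "high")
    logger.info("classify: %d high / %d low confidence", n_high, len(clusters) - n_high)


def _groups(meta: pd.DataFrame) -> dict:
    whole = meta[meta["compartment"] == "whole"]
    return {
        "ip": list(whole.index[whole["capture"] == "IP"]),
        "sn": list(whole.index[whole["capture"] == "supernatant"]),
        "dendrite": list(meta.index[meta["compartment"] == "dendrite"]),
        "whole_cyto_ip": list(
            whole.index[(whole["capture"] == "IP") & (whole["fraction"] == "cytoplasm")]
        ),
        "whole_rer_ip": list(
            whole.index[(whole["capture"] == "IP") & (whole["fraction"] == "rER")]
        ),
    }


def stage_test(cfg: PipelineConfig) -> None:
    """Enrichment statistics: IP-vs-supernatant exact test, paired rER-vs-
    cytoplasm GLM, and annotation rescue of enriched unannotated clusters."""
    _require(cfg, "test", "classify")
    meta = _load_meta(cfg)
    clusters = _load_clusters(cfg.path("cluster", "clusters.json"))
    counts = pd.read_csv(cfg.path("cluster", "counts.tsv"), sep="\t", index_col=0)
    groups = _groups(meta)
    if not groups["ip"] or not groups["sn"]:
        raise InfeasibleDesign("need both IP and supernatant whole-compartment libraries")
    outdir = cfg.path("test")
    outdir.mkdir(parents=True, exist_ok=True)

    whole = groups["ip"] + groups["sn"]
    sub = counts[whole]
    design = np.column_stack([np.ones(len(whole)), [1.0 if l in groups["ip"] else 0.0 for l in whole]])
    factors = enr.tmm_factors(sub, trim_m=cfg["tmm_trim_m"], trim_a=cfg["tmm_trim_a"])
    disp = enr.estimate_dispersion(sub, design, factors=factors,
                                   prior_weight=cfg["dispersion_prior_weight"])
    de_ip = enr.exact_test(sub, groups["ip"], groups["sn"], disp, factors=factors,
                           prior_count=cfg["prior_count"])
    de_ip.to_csv(outdir / "de_ip_vs_supernatant.tsv", sep="\t", index_label="cluster_id")

    # paired rER vs cytoplasm on replicated whole-compartment pools
    whole_meta = meta.loc[whole]
    pools = sorted(whole_meta["pair_id"].unique())
    paired_libs = [
        l for l in whole if (whole_meta.loc[l, "pair_id"], ) and
        (whole_meta["pair_id"] == whole_meta.loc[l, "pair_id"]).sum() == 2
    ]
    de_rer = None
    if len(paired_libs) >= 4:
        pm = whole_meta.loc[paired_libs]
        pools = sorted(pm["pair_id"].unique())
        cols = {"intercept": np.ones(len(paired_libs))}
        for p in pools[1:]:
            cols[f"pair_{p}"] = (pm["pair_id"] == p).astype(float).to_numpy()
        cols["fraction_rER"] = (pm["fraction"] == "rER").astype(float).to_numpy()
        design_p = pd.DataFrame(cols, index=paired_libs)
        subp = counts[paired_libs]
        fac_p = enr.tmm_factors(subp)
        disp_p = enr.estimate_dispersion(subp, design_p.to_numpy(), factors=fac_p)
        de_rer = enr.glm_lrt(subp, design_p, "fraction_rER", disp_p, factors=fac_p,
                             prior_count=cfg["prior_count"])
        de_rer.to_csv(outdir / "de_rer_vs_cytoplasm.tsv", sep="\t", index_label="cluster_id")

    # enriched sets and annotation rescue
    ann_map = {c.cluster_id: c.annotation for c in clusters}
    up = enr.enriched_set(de_ip, fdr_max=cfg["fdr_max"], direction="up", annotation=ann_map)
    down = enr.enriched_set(de_ip, fdr_max=cfg["fdr_max"], direction="down", annotation=ann_map)
    by_id = {c.cluster_id: c for c in clusters}
    enriched_unannotated = [
        by_id[cid] for cid in up["clusters"] if by_id[cid].annotation_source == "none"
    ]
    secondary = _load_models(cfg, "secondary")
    primary = _load_models(cfg, "primary")
    rescued = anno.rescue_annotation(enriched_unannotated, secondary, primary,
                                     downstream_window=cfg["downstream_window"])
    up = enr.enriched_set(de_ip, fdr_max=cfg["fdr_max"], direction="up",
                          annotation={c.cluster_id: c.annotation for c in clusters})
    summary = {
        "n_enriched_clusters": len(up["clusters"]),
        "enriched_genes": up["genes"],
        "n_depleted_clusters": len(down["clusters"]),
        "depleted_genes": down["genes"],
        "n_rescued": len(rescued),
        "rescued_clusters": [c.cluster_id for c in rescued],
        "enriched_unannotated": [
            c.cluster_id for c in clusters
            if c.cluster_id in set(up["clusters"]) and c.annotation_source == "none"
        ],
    }
    _atomic_write(outdir / "enriched.json", json.dumps(summary, indent=1, sort_keys=True))
    _dump_clusters(clusters, cfg.path("cluster", "clusters.json"))
    _write_manifest(cfg, "test", [outdir / "de_ip_vs_supernatant.tsv", outdir / "enriched.json"])
    logger.info("test: %d enriched clusters (%d genes), %d rescued",
                len(up["clusters"]), len(up["genes"]), len(rescued))


def stage_compartments(cfg: PipelineConfig) -> None:
    _require(cfg, "compartments", "test")
    meta = _load_meta(cfg)
    clusters = _load_clusters(cfg.path("cluster", "clusters.json"))
    counts = pd.read_csv(cfg.path("cluster", "counts.tsv"), sep="\t", index_col=0)
    pairs = _load_dedup_pairs(cfg)
    groups = _groups(meta)
    outdir = cfg.path("compartments")
    outdir.mkdir(parents=True, exist_ok=True)

    # richness per library
    rich = {
        lib: comp.richness(counts[lib].to_numpy(), cfg["richness_subsample"])
        for lib in counts.columns
        if counts[lib].sum() >= cfg["richness_subsample"]
    }
    pd.Series(rich, name="richness").to_csv(outdir / "richness.tsv", sep="\t",
                                            index_label="library_id")

    # SRP-like feature TPM per library
    srp_path = cfg.srp_features or cfg.path("sim", "srp.bed")
    srp_tpm = {}
    if Path(srp_path).is_file():
        feats = comp.read_feature_bed(srp_path)
        srp_tpm = {lib: comp.feature_tpm(pairs[lib], feats) for lib in meta.index}
        pd.Series(srp_tpm, name="tpm").to_csv(outdir / "srp_tpm.tsv", sep="\t",
                                              index_label="library_id")

    # cDNA size comparison (pair spans), paired by pool over IP whole libs
    spans = {lib: [p.span[1] - p.span[0] for p in ps] for lib, ps in pairs.items()}
    size_rows = [
        {"library_id": lib, "mean_span": float(np.mean(s)), "n": len(s)}
        for lib, s in spans.items()
    ]
    pd.DataFrame(size_rows).to_csv(outdir / "cdna_sizes.tsv", sep="\t", index=False)
    whole_meta = meta.loc[groups["ip"]]
    rer_means, cyto_means = [], []
    for pool in sorted(whole_meta["pair_id"].unique()):
        sel = whole_meta[whole_meta["pair_id"] == pool]
        r = sel.index[sel["fraction"] == "rER"]
        c = sel.index[sel["fraction"] == "cytoplasm"]
        if len(r) == 1 and len(c) == 1:
            rer_means.append(np.mean(spans[r[0]]))
            cyto_means.append(np.mean(spans[c[0]]))
    size_test = (
        comp.cdna_size_test(rer_means, cyto_means, paired=True)
        if len(rer_means) >= 2
        else None
    )

    # dendritic presence and enrichment
    dendritic = {}
    if groups["dendrite"]:
        from .clustering import CountMatrix

        mat = CountMatrix(counts, meta.loc[counts.columns])
        present = comp.dendritic_presence(
            mat, q=cfg["dendrite_quantile"],
            nonzero_only=cfg["dendrite_quantile_nonzero_only"],
        )
        de_tables = {}
        for frac, whole_libs in (("cytoplasm", groups["whole_cyto_ip"]),
                                 ("rER", groups["whole_rer_ip"])):
            libs = groups["dendrite"] + whole_libs
            sub = counts[libs]
            design = np.column_stack(
                [np.ones(len(libs)), [1.0 if l in groups["dendrite"] else 0.0 for l in libs]]
            )
            dd = pd.DataFrame(design, index=libs, columns=["intercept", "dendrite"])
            # TMM assumes the groups share a mostly non-changing transcriptome;
            # a strongly restricted dendritic transcriptome violates that, so
            # fall back to total-count normalization when composition overlap
            # is too small to trim meaningfully
            dend_pos = sub[groups["dendrite"]].sum(axis=1) > 0
            whole_pos = sub[whole_libs].sum(axis=1) > 0
            shared = float((dend_pos & whole_pos).sum()) / max(int(whole_pos.sum()), 1)
            if shared < 0.3:
                fac = pd.Series(1.0, index=sub.columns)
                logger.info(
                    "dendrite vs whole (%s): only %.0f%% shared composition; "
                    "using total-count normalization", frac, 100 * shared,
                )
            else:
                fac = enr.tmm_factors(sub)
            disp = enr.estimate_dispersion(sub, design, factors=fac)
            de_tables[f"dendrite_vs_whole_{frac}"] = enr.glm_lrt(sub, dd, "dendrite",
                                                                 disp, factors=fac)
        for name, tab in de_tables.items():
            tab.to_csv(outdir / f"de_{name}.tsv", sep="\t", index_label="cluster_id")
        ann_map = {c.cluster_id: c.annotation for c in clusters}
        enriched = comp.dendritic_enrichment(de_tables, fdr_max=cfg["fdr_max"],
                                             annotation=ann_map)
        dendritic = {"present": present, **enriched}

    # marker panels (planted classes when simulated truth is available)
    truth = _truth(cfg)
    panel_table = None
    if truth is not None:
        de_ip = pd.read_csv(cfg.path("test", "de_ip_vs_supernatant.tsv"), sep="\t", index_col=0)
        symbols_by_class: dict = {}
        id2sym: dict = {}
        for c in clusters:
            for s in c.annotation:
                id2sym.setdefault(s, []).append(c)
        panels = {}
        for cls in ("pc_enriched", "glia", "other_neuron"):
            uids = [u for u, k in truth.classes.items() if k == cls]
            syms = []
            for u in uids:
                # unit naming convention of the generator: GeneNNN symbols
                syms.append(f"Gene{u[1:]}" if u.startswith("G") and u[1:].isdigit() else u)
            panels[cls] = [s for s in syms if s in id2sym]
        rep = {
            sym: anno.representative_cluster(cl_list).cluster_id
            for sym, cl_list in id2sym.items()
        }
        panel_table = comp.marker_panel_summary(de_ip, panels, rep)
        panel_table.to_csv(outdir / "marker_panels.tsv", sep="\t")

    # optional external-score rank curve
    if cfg.aba_scores and Path(cfg.aba_scores).is_file():
        scores = pd.read_csv(cfg.aba_scores, sep="\t", header=None,
                             names=["gene", "score"]).set_index("gene")["score"].to_dict()
        de_ip = pd.read_csv(cfg.path("test", "de_ip_vs_supernatant.tsv"), sep="\t", index_col=0)
        ann_map = {c.cluster_id: c.annotation for c in clusters}
        ranked_genes = []
        seen = set()
        for cid in de_ip.sort_values("pvalue").index:
            for s in ann_map.get(cid, []):
                if s in scores and s not in seen:
                    ranked_genes.append(s)
                    seen.add(s)
        curve = comp.rank_score_curve(ranked_genes, scores, window=cfg["rank_window"],
                                      rng=np.random.default_rng((cfg.seed, 55)))
        pd.DataFrame({"rank": curve["rank"], "mean": curve["mean"], "sem": curve["sem"]}).to_csv(
            outdir / "rank_score_curve.tsv", sep="\t", index=False
        )

    # subsampling saturation of the capture contrast
    saturation_table = None
    if cfg["run_saturation"]:
        whole = groups["ip"] + groups["sn"]
        saturation_table = comp.saturation(
            clusters, {l: pairs[l] for l in whole}, meta.loc[whole],
            groups["ip"], groups["sn"],
            fractions=tuple(cfg["saturation_fractions"]), seed=cfg.seed,
            fdr_max=cfg["fdr_max"],
        )
        saturation_table.to_csv(outdir / "saturation.tsv", sep="\t", index=False)

    summary = {
        "richness": rich,
        "srp_tpm": srp_tpm,
        "cdna_size_test": size_test,
        "dendritic": dendritic,
    }
    _atomic_write(outdir / "compartments.json", json.dumps(summary, indent=1, sort_keys=True))
    _write_manifest(cfg, "compartments", [outdir / "compartments.json"])
    logger.info("compartments: richness %s", {k: round(v, 1) for k, v in rich.items()})


def stage_ncrna(cfg: PipelineConfig) -> None:
    _require(cfg, "ncrna", "test")
    clusters = _load_clusters(cfg.path("cluster", "clusters.json"))
    genome = _genome(cfg)
    enriched = json.loads(cfg.path("test", "enriched.json").read_text())
    by_id = {c.cluster_id: c for c in clusters}
    screen = [by_id[cid] for cid in enriched["enriched_unannotated"]]
    primary = _load_models(cfg, "primary")
    pseudo_path = cfg.models_primary or cfg.path("sim", "models_primary.gtf")
    pseudogenes = anno.GeneModelSet.from_gtf(pseudo_path, source="pseudogene",
                                             exclude_biotypes=())
    pseudogenes = anno.GeneModelSet(
        {g: v for g, v in pseudogenes.genes.items() if v.biotype == "pseudogene"},
        source="pseudogene",
    )
    flags = ncr.triage(screen, genome, pseudogenes, max_span=cfg["max_span"],
                       tso_tail=cfg["tso_tail"], k=cfg["tso_k"], gene_models=primary)
    clean = [c for c in screen if flags[c.cluster_id].clean]
    repeats_path = cfg.repeats or cfg.path("sim", "repeats.bed")
    repeats = []
    with open(repeats_path) as fh:
        for line in fh:
            f = line.split("\t")
            repeats.append((f[0], int(f[1]), int(f[2]), f[3]))
    candidates = ncr.sineup_candidates(clean, primary, repeats,
                                       head_to_head_window=cfg["head_to_head_window"])
    outdir = cfg.path("ncrna")
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [vars(flags[c.cluster_id]) for c in screen]
    pd.DataFrame(rows).to_csv(outdir / "triage.tsv", sep="\t", index=False)
    _atomic_write(outdir / "sineup_candidates.json", json.dumps(candidates, indent=1))
    _write_manifest(cfg, "ncrna", [outdir / "triage.tsv", outdir / "sineup_candidates.json"])
    logger.info("ncrna: screened %d, %d clean, %d SINEUP candidates",
                len(screen), len(clean), len(candidates))


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "dedup": stage_dedup,
    "cluster": stage_cluster,
    "annotate": stage_annotate,
    "classify": stage_classify,
    "test": stage_test,
    "compartments": stage_compartments,
    "ncrna": stage_ncrna,
}


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage, or every stage in order for ``all``."""
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    if stage == "all":
        for s in STAGES:
            STAGE_FUNCS[s](cfg)
    else:
        STAGE_FUNCS[stage](cfg)
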