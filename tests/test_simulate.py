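"""Synthetic-data generator: determinism, planted geometry, count model."""

import json
import warnings

import numpy as np
import pytest

from ribocage.simulate import (LibraryMeta, SimConfig, SizingError,
                               default_library_design, expected_unique_counts,
                               generate_reference, simulate_libraries,
                               write_outputs)
from ribocage.tagio import deduplicate


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chrom_lengths": {"chr1": -5}},
            {"promoter_gc_bias": 1.5},
            {"shape_mix": -0.1},
            {"nb_dispersion": -1},
            {"pcr_dup_mean": 0.5},
            {"class_fractions": {"pc_enriched": 1.0, "glia": 0.5,
                                 "other_neuron": 0.0, "background": 0.0}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()

    def test_genome_too_small(self):
        with pytest.raises(SizingError):
            generate_reference(SimConfig(chrom_lengths={"chr1": 30_000}, n_genes=40))


class TestDeterminism:
    def test_reference_byte_identical(self, mini_config, tmp_path):
        a = generate_reference(mini_config)
        b = generate_reference(mini_config)
        assert a.sequences == b.sequences
        assert [(u.unit_id, u.tss, u.exons) for u in a.units] == [
            (u.unit_id, u.tss, u.exons) for u in b.units
        ]
        da, db = tmp_path / "a", tmp_path / "b"
        write_outputs(a, None, da)
        write_outputs(b, None, db)
        for name in ("genome.fa", "models_primary.gtf", "models_secondary.gtf",
                     "repeats.bed"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_libraries_identical_across_reruns(self, mini_config):
        ref_a = generate_reference(mini_config)
        ref_b = generate_reference(mini_config)
        la = simulate_libraries(ref_a)
        lb = simulate_libraries(ref_b)
        for lib in la:
            assert [p.key() for p in la[lib]] == [p.key() for p in lb[lib]]


class TestPlantedGeometry:
    def test_sineup_locus(self, reference):
        entry = reference.truth.sineup[0]
        su = reference.unit_by_id(entry["id"])
        partner = reference.unit_by_id(entry["partner"])
        assert su.strand != partner.strand
        # antisense body reaches back across the partner's 5' region
        s, e = su.genomic_span()
        ps, pe = partner.genomic_span()
        assert s < pe and ps < e
        # exactly one antisense unit whose TSS region intersects a SINE record
        chrom, lo, hi = entry["sine"]
        assert su.chrom == chrom
        assert min(abs(su.tss - lo), abs(su.tss - hi)) <= 500
        sine_like = [
            u for u in reference.units
            if u.special == "sineup"
        ]
        assert len(sine_like) == reference.config.n_sineup == 1

    def test_pseudogene_and_artifact_planted(self, reference):
        assert len(reference.truth.pseudogene) == 1
        pg = reference.unit_by_id(reference.truth.pseudogene[0]["id"])
        assert pg.biotype == "pseudogene"
        art = reference.unit_by_id(reference.truth.artifact[0]["id"])
        seq = reference.sequences[art.chrom]
        assert seq[art.tss - 3 : art.tss] == "GGG"

    def test_multilocus_span_hundreds_of_kb(self, reference):
        ml = reference.unit_by_id(reference.truth.multilocus[0]["id"])
        s, e = ml.genomic_span()
        assert e - s > 150_000

    def test_promoter_composition_distinguishable(self, reference):
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        cpg = lambda s: s.count("CG") / len(s)
        g = next(u for u in reference.units if u.special is None and u.strand == "+")
        seq = reference.sequences[g.chrom]
        win = seq[g.tss - 900 : g.tss + 900]
        bg = seq[200:3200]
        assert gc(win) - gc(bg) > 0.08
        assert cpg(win) > 2 * cpg(bg)

    def test_null_bias_removes_composition_signal(self, mini_config):
        import dataclasses

        cfg = dataclasses.replace(mini_config, promoter_gc_bias=0.0)
        ref = generate_reference(cfg)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        g = next(u for u in ref.units if u.special is None and u.strand == "+")
        seq = ref.sequences[g.chrom]
        assert abs(gc(seq[g.tss - 900 : g.tss + 900]) - gc(seq[200:5000])) < 0.04


class TestCountModel:
    def test_pcr_duplication_rate_and_exact_dedup(self, mini_reference, mini_libraries):
        lib = "P1c"
        raw = mini_libraries[lib]
        uniq = deduplicate(raw)
        truth_n = mini_reference.truth.library_unique_totals[lib]
        assert len(uniq) == truth_n
        ratio = len(raw) / truth_n
        assert ratio == pytest.approx(mini_reference.config.pcr_dup_mean, rel=0.05)

    def test_nb_moments_match_planted_means(self, mini_config):
        """With the reference fixed, per-gene unique-count moments across
        replicate library draws match NB(mu, phi) within ~3 standard
        errors."""
        import dataclasses

        design = [
            LibraryMeta("IP1", "cytoplasm", "IP", "whole", "P1", 2000),
            LibraryMeta("SN1", "cytoplasm", "supernatant", "whole", "S1", 2000),
        ]
        base = dataclasses.replace(mini_config, library_design=design, seed=77)
        ref = generate_reference(base)
        n_rep = 50
        counts: dict = {}
        for r in range(n_rep):
            cfg = dataclasses.replace(base, seed=5000 + r)
            simulate_libraries(ref, cfg)
            for uid, per_lib in ref.truth.unique_counts.items():
                counts.setdefault(uid, []).append(per_lib["SN1"])
        mu = expected_unique_counts(ref, design[1])
        phi = base.nb_dispersion
        checked = 0
        for uid, obs in counts.items():
            m = mu[uid]
            if not 20 < m < 300:
                continue  # skip saturating or near-empty units
            obs = np.asarray(obs, float)
            var = m + phi * m * m
            se_mean = np.sqrt(var / n_rep)
            assert abs(obs.mean() - m) < 3.5 * se_mean, uid
            # variance within a generous band (chi-square spread at n=50)
            assert 0.4 * var < obs.var(ddof=1) < 2.5 * var, uid
            checked += 1
        assert checked >= 5

    def test_planted_fold_change_recovered_in_raw_means(self, mini_config):
        """IP-vs-supernatant mean unique counts reflect the planted 8x
        (log2FC = 3) for the capture-enriched class."""
        ref = generate_reference(mini_config)
        simulate_libraries(ref)
        truth = ref.truth
        ip = [l.library_id for l in mini_config.library_design
              if l.capture == "IP" and l.compartment == "whole"]
        sn = [l.library_id for l in mini_config.library_design
              if l.capture == "supernatant"]
        ratios = []
        for uid, cls in truth.classes.items():
            if cls != "pc_enriched" or not uid.startswith("G"):
                continue
            c = truth.unique_counts[uid]
            a = np.mean([c[l] for l in ip])
            b = np.mean([c[l] for l in sn])
            if b > 10:
                ratios.append(a / b)
        assert 5.0 < np.mean(ratios) < 9.5  # 8x planted, attenuated by key-space saturation

    def test_zero_noise_puts_all_5prime_ends_in_promoters(self, mini_config):
        import dataclasses

        cfg = dataclasses.replace(mini_config, noise_rate=0.0, with_decoys=False)
        ref = generate_reference(cfg)
        libs = simulate_libraries(ref)
        windows = {}
        for u in ref.units:
            lo = u.tss - 60 if u.strand == "+" else u.tss - 45
            hi = u.tss + 45 if u.strand == "+" else u.tss + 60
            windows.setdefault((u.chrom, u.strand), []).append((lo, hi))
        for pairs in libs.values():
            for p in pairs:
                assert any(lo <= p.pos5 <= hi
                           for lo, hi in windows.get((p.chrom, p.strand), [])), p

    def test_mate_blocks_respect_exons(self, mini_reference, mini_libraries):
        """Mate blocks of promoter pairs stay within the unit's exonic span
        plus the 5' read."""
        by_key = {}
        for u in mini_reference.units:
            by_key.setdefault((u.chrom, u.strand), []).append(u)
        for p in mini_libraries["P1r"][:2000]:
            units = [u for u in by_key.get((p.chrom, p.strand), [])
                     if u.genomic_span()[0] - 60 <= p.pos5 <= u.genomic_span()[1] + 60]
            assert units
            u = max(units, key=lambda x: -abs(x.tss))
            allowed = list(u.exon_genomic_blocks())
            s, e = p.span
            lo = min(b[0] for b in allowed)
            hi = max(b[1] for b in allowed)
            assert s >= lo - 60 and e <= hi + 60


def test_missing_supernatant_warns(mini_config):
    import dataclasses

    design = [l for l in default_library_design(2000) if l.capture == "IP"]
    cfg = dataclasses.replace(mini_config, library_design=design)
    ref = generate_reference(cfg)
    with pytest.warns(UserWarning, match="contrast is infeasible"):
        simulate_libraries(ref)


def test_truth_table_round_trip(mini_reference, tmp_path):
    path = tmp_path / "truth.json"
    mini_reference.truth.to_json(path)
    from ribocage.simulate import TruthTable

    back = TruthTable.from_json(path)
    assert back.classes == mini_reference.truth.classes
    assert back.sineup == mini_reference.truth.sineup


def test_sam_output_valid_against_fasta(mini_reference, mini_libraries, tmp_path):
    """Emitted SAM parses under its own header and every record stays within
    the FASTA chromosome bounds."""
    import pysam

    paths = write_outputs(mini_reference, {"S1r": mini_libraries["S1r"]}, tmp_path)
    fa = pysam.FastaFile(paths["genome"])
    with pysam.AlignmentFile(paths["library:S1r"], "r") as sam:
        assert set(sam.references) == set(fa.references)
        n = 0
        for rec in sam:
            assert 0 <= rec.reference_start
            assert rec.reference_end <= fa.get_reference_length(rec.reference_name)
            n += 1
    assert n == 2 * len(mini_libraries["S1r"])  # two mates per pair
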