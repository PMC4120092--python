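"""Compartment statistics: richness, feature TPM, rank curves, dendritic
rules, saturation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ribocage.clustering import CountMatrix
from ribocage.compartments import (AnalysisConfig, cdna_size_test,
                                   dendritic_enrichment, dendritic_presence,
                                   feature_tpm, marker_panel_summary,
                                   rank_score_curve, richness, saturation)
from ribocage.tagio import AlignedPair

from oracles import richness_closed_form_smallN, richness_monte_carlo


class TestAnalysisConfig:
    def test_defaults_and_validation(self):
        cfg = AnalysisConfig()
        assert cfg.richness_subsample == 1000
        assert cfg.rank_window == 200
        assert cfg.dendrite_quantile == 0.75
        with pytest.raises(ValueError):
            AnalysisConfig(dendrite_quantile=1.5)
        with pytest.raises(ValueError):
            AnalysisConfig(saturation_fractions=(0.0, 1.0))


class TestRichness:
    def test_single_cluster_gives_one(self):
        assert richness([5000], m=1000) == pytest.approx(1.0)

    def test_m_equals_N_gives_nonzero_count(self):
        counts = [3, 0, 7, 1, 0, 9]
        assert richness(counts, m=20) == pytest.approx(4.0)

    def test_undefined_below_m(self):
        with pytest.raises(ValueError, match="undefined"):
            richness([10, 20], m=1000)

    def test_matches_exact_combinatorial_oracle(self):
        counts = [500, 300, 200]
        got = richness(counts, m=2)
        expect = richness_closed_form_smallN(counts, 2)
        # 3 - [C(500,2)+C(700,2)+C(800,2)]/C(1000,2)
        from math import comb

        direct = 3 - (comb(500, 2) + comb(700, 2) + comb(800, 2)) / comb(1000, 2)
        assert got == pytest.approx(expect) == pytest.approx(direct)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 300, size=40)
        counts[0] += 1500  # ensure N >= m
        m = 500
        mc, se = richness_monte_carlo(counts, m, reps=4000, rng=rng)
        assert abs(richness(counts, m) - mc) < 3.5 * se

    def test_matches_vegan_rarefy(self, tmp_path):
        """Cross-check against the vegan R package's expected-species
        rarefaction."""
        rng = np.random.default_rng(12)
        counts = rng.integers(1, 400, size=30)
        script = tmp_path / "rarefy.R"
        script.write_text(
            textwrap.dedent(
                f"""\
                suppressMessages(library(vegan))
                x <- c({",".join(map(str, counts.tolist()))})
                cat(rarefy(x, 200), "\\n")
                """
            )
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        assert richness(counts, 200) == pytest.approx(float(out.stdout.split()[0]),
                                                      rel=1e-6)

    def test_splitting_invariants(self):
        counts = [100, 200, 300, 0]
        base = richness(counts, 150)
        assert richness(counts + [0], 150) == pytest.approx(base)
        split = [100, 200, 150, 150]
        assert richness(split, 150) > base


class TestFeatureTPM:
    def _pairs(self, positions, strand="+"):
        return [
            AlignedPair("L", "chr1", strand, p, ((p, p + 25),)) for p in positions
        ]

    def test_basic_rate(self):
        pairs = self._pairs(range(0, 10_000, 10))  # 1000 pairs
        feats = [("chr1", 0, 1000, "+")]
        assert feature_tpm(pairs, feats) == pytest.approx(1e6 * 100 / 1000)

    def test_no_overlap_zero(self):
        assert feature_tpm(self._pairs([5]), [("chr2", 0, 10, "+")]) == 0.0

    def test_sense_only(self):
        pairs = self._pairs([5], strand="-")
        assert feature_tpm(pairs, [("chr1", 0, 10, "+")]) == 0.0
        assert feature_tpm(pairs, [("chr1", 0, 10, ".")]) == 1e6

    def test_empty_library_error(self):
        with pytest.raises(ValueError, match="empty"):
            feature_tpm([], [("chr1", 0, 10, "+")])

    def test_planted_srp_abundance(self, workspace):
        """SRP-like locus TPM tracks the planted per-fraction abundance
        within sampling error, and is higher on the rER side."""
        import json

        comp = json.load(open(workspace.path("compartments", "compartments.json")))
        tpm = comp["srp_tpm"]
        rer = np.mean([tpm[l] for l in ("P1r", "P2r", "P3r")])
        cyto = np.mean([tpm[l] for l in ("P1c", "P2c", "P3c")])
        assert rer > cyto
        # supernatant libraries are closest to the planted rate (no capture
        # enrichment inflating the denominator)
        assert 0.4 * 1800 < tpm["S1r"] < 2.2 * 1800


class TestMarkerPanels:
    def test_single_gene_panel(self):
        de = pd.DataFrame({"logFC": [2.0]}, index=["c1"])
        out = marker_panel_summary(de, {"pc": ["GeneA"]}, {"GeneA": "c1"})
        assert out.loc["pc", "mean_logFC"] == 2.0
        assert out.loc["pc", "sd_logFC"] == 0.0

    def test_missing_gene_excluded_and_reported(self):
        de = pd.DataFrame({"logFC": [2.0]}, index=["c1"])
        out = marker_panel_summary(de, {"pc": ["GeneA", "GeneB"]}, {"GeneA": "c1"})
        assert out.loc["pc", "n"] == 1
        assert out.loc["pc", "missing"] == "GeneB"

    def test_empty_panel_warns_and_skips(self):
        de = pd.DataFrame({"logFC": [2.0]}, index=["c1"])
        with pytest.warns(UserWarning, match="empty"):
            out = marker_panel_summary(de, {"none": []}, {})
        assert len(out) == 0

    def test_fixture_panel_ordering(self, workspace):
        """Planted class panels order as capture-enriched > neutral, with
        the glia panel strongly negative."""
        panels = pd.read_csv(workspace.path("compartments", "marker_panels.tsv"),
                             sep="\t", index_col=0)
        assert panels.loc["pc_enriched", "mean_logFC"] > 1.0
        assert panels.loc["glia", "mean_logFC"] < -1.0
        assert (panels.loc["pc_enriched", "mean_logFC"]
                > panels.loc["other_neuron", "mean_logFC"]
                > panels.loc["glia", "mean_logFC"])


class TestRankScoreCurve:
    def test_constant_scores_flat(self):
        ids = [f"g{i}" for i in range(300)]
        scores = {i: 0.5 for i in ids}
        out = rank_score_curve(ids, scores, window=100)
        assert np.allclose(out["mean"], 0.5)
        assert np.allclose(out["sem"], 0.0)

    def test_step_input_linear_ramp(self):
        ids = [f"g{i}" for i in range(600)]
        scores = {f"g{i}": 1.0 if i < 300 else 0.0 for i in range(600)}
        out = rank_score_curve(ids, scores, window=200,
                               rng=np.random.default_rng(0))
        means = out["mean"]
        assert np.allclose(means[:101], 1.0)
        ramp = means[101:301]
        assert np.all(np.diff(ramp) < 0)  # strictly decreasing
        assert np.allclose(means[301:], 0.0)

    def test_shuffled_scores_hug_background(self, rng):
        ids = [f"g{i}" for i in range(1000)]
        vals = rng.choice([0.0, 0.5, 1.0], size=1000)
        scores = dict(zip(ids, vals))
        out = rank_score_curve(ids, scores, window=200, rng=rng)
        sem = np.maximum(out["sem"], 1e-9)
        frac_far = np.mean(np.abs(out["mean"] - out["background"]) > 3 * sem)
        assert frac_far < 0.1

    def test_window_longer_than_list(self):
        ids = ["a", "b", "c"]
        out = rank_score_curve(ids, {"a": 1.0, "b": 0.0, "c": 1.0}, window=200)
        assert len(out["mean"]) == 1


class TestDendriticPresence:
    def _matrix(self, counts: dict):
        libs = ["Dc", "Dr", "W1"]
        meta = pd.DataFrame(
            {
                "fraction": ["cytoplasm", "rER", "cytoplasm"],
                "capture": "IP",
                "compartment": ["dendrite", "dendrite", "whole"],
                "pair_id": ["D", "D", "P"],
            },
            index=pd.Index(libs, name="library_id"),
        )
        df = pd.DataFrame(counts)
        df.index = [f"c{i}" for i in range(len(df))]
        return CountMatrix(df, meta)

    def test_hand_enumerated_toy(self):
        # 8 clusters; only c1 and c2 are in the top quartile of BOTH fractions
        counts = {
            "Dc": [90, 80, 10, 5, 4, 3, 2, 1],
            "Dr": [85, 90, 4, 10, 3, 2, 1, 5],
            "W1": [10] * 8,
        }
        mat = self._matrix(counts)
        present = dendritic_presence(mat, q=0.75)
        assert present == ["c0", "c1"]

    def test_both_fractions_required_rule(self):
        counts = {
            "Dc": [90, 0, 10, 5, 4, 3, 2, 1],
            "Dr": [85, 90, 4, 10, 3, 2, 1, 5],
            "W1": [10] * 8,
        }
        mat = self._matrix(counts)
        present = dendritic_presence(mat, q=0.75)
        assert "c1" not in present  # top in rER, zero in cytoplasm

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(3)
        counts = {
            "Dc": rng.integers(0, 100, 30).tolist(),
            "Dr": rng.integers(0, 100, 30).tolist(),
            "W1": [10] * 30,
        }
        mat = self._matrix(counts)
        prev = None
        for q in (0.5, 0.65, 0.8, 0.9):
            cur = set(dendritic_presence(mat, q=q))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_missing_fraction_error(self):
        libs = ["Dc", "W1"]
        meta = pd.DataFrame(
            {"fraction": ["cytoplasm", "cytoplasm"], "capture": "IP",
             "compartment": ["dendrite", "whole"], "pair_id": ["D", "P"]},
            index=pd.Index(libs, name="library_id"),
        )
        mat = CountMatrix(pd.DataFrame({"Dc": [1], "W1": [1]}, index=["c0"]), meta)
        with pytest.raises(ValueError, match="rER"):
            dendritic_presence(mat)


class TestDendriticEnrichment:
    def _tab(self, fdr, lfc):
        return pd.DataFrame({"logFC": lfc, "fdr": fdr},
                            index=[f"c{i}" for i in range(len(fdr))])

    def test_intersection_rule(self):
        a = self._tab([0.01, 0.01, 0.5], [2.0, 2.0, 2.0])
        b = self._tab([0.01, 0.5, 0.01], [2.0, 2.0, 2.0])
        out = dendritic_enrichment({"a": a, "b": b}, fdr_max=0.1)
        assert out["clusters"] == ["c0"]

    def test_negative_lfc_excluded(self):
        a = self._tab([0.01], [-2.0])
        assert dendritic_enrichment({"a": a})["clusters"] == []

    def test_empty_when_nothing_significant(self):
        a = self._tab([0.9, 0.8], [1.0, 1.0])
        assert dendritic_enrichment({"a": a})["clusters"] == []


class TestSizesAndSaturation:
    def test_cdna_size_test_direction(self, rng):
        a = rng.normal(300, 30, 50)
        b = rng.normal(700, 60, 50)
        out = cdna_size_test(a, b, paired=True)
        assert out["mean_a"] < out["mean_b"]
        assert out["pvalue"] < 1e-6

    def test_fixture_rer_fragments_smaller(self, workspace):
        sizes = pd.read_csv(workspace.path("compartments", "cdna_sizes.tsv"),
                            sep="\t").set_index("library_id")
        assert sizes.loc["P1r", "mean_span"] < sizes.loc["P1c", "mean_span"]

    def test_saturation_monotone_and_deterministic(self, workspace):
        sat = pd.read_csv(workspace.path("compartments", "saturation.tsv"), sep="\t")
        n = sat["n_significant"].tolist()
        assert n == sorted(n)  # diminishing returns: no loss at higher depth
        # rerunning at f = 1.0 reproduces the full-depth analysis
        assert sat["fraction"].iloc[-1] == 1.0
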