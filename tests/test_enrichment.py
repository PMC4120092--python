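"""NB enrichment statistics: TMM, dispersion, exact test, GLM, BH."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from ribocage.enrichment import (Dispersion, bh_adjust, enriched_set,
                                 estimate_dispersion, exact_test, glm_lrt,
                                 tmm_factors)

from oracles import brute_force_bh


def nb_counts(rng, mu, phi, n):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.asarray(mu)[:, None]), size=(len(mu), n))


@pytest.fixture(scope="module")
def null_counts():
    rng = np.random.default_rng(41)
    mu = rng.lognormal(4.3, 1.0, 2000)
    Y = nb_counts(rng, mu, 0.1, 8)
    return pd.DataFrame(Y, columns=[f"L{j}" for j in range(8)])


TWO_GROUP = pd.DataFrame(
    {"intercept": [1.0] * 8, "grp": [1.0] * 6 + [0.0] * 2},
    index=[f"L{j}" for j in range(8)],
)


class TestTMM:
    def test_identical_libraries(self):
        c = pd.DataFrame({"A": [10, 20, 30] * 20, "B": [10, 20, 30] * 20})
        assert tmm_factors(c).tolist() == pytest.approx([1.0, 1.0])

    def test_pure_depth_scaling_absorbed_by_totals(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 500)
        c = pd.DataFrame({"A": a, "B": 2 * a})
        assert tmm_factors(c).tolist() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_composition_bias_matches_analytic_trimmed_mean(self):
        """10% of clusters 8x up in B: the B factor approaches the analytic
        trimmed mean of log ratios (the 8x block is trimmed away)."""
        rng = np.random.default_rng(1)
        n = 2000
        mu = rng.lognormal(4.5, 0.7, n)
        up = np.ones(n)
        up[: n // 10] = 8.0
        a = rng.poisson(mu)
        b = rng.poisson(mu * up)
        c = pd.DataFrame({"A": a, "B": b})
        f = tmm_factors(c, ref_library="A")
        # after trimming the shifted block, M approx log2(NA/NB-corrected 1)
        # analytic: non-DE clusters have ratio (1 / depth-ratio); factors are
        # rescaled to geometric mean 1, so B/A reflects the 8x block removal
        expect_ratio = 1.0 / (0.9 + 0.1 * 8.0) ** 0  # ratios normalized by totals
        depth_ratio = b.sum() / a.sum()
        analytic_b = 1.0 / depth_ratio * 1.0  # trimmed mean of non-DE = 1/depth
        ratio = f["B"] / f["A"]
        assert ratio == pytest.approx(np.sqrt(analytic_b) ** 2, rel=0.05)

    def test_all_zero_library_error(self):
        c = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(c)

    def test_matches_edger_oracle(self, tmp_path):
        """Cross-check against Bioconductor edgeR's calcNormFactors."""
        rng = np.random.default_rng(7)
        mu = rng.lognormal(4.0, 1.0, 800)
        up = np.ones(800)
        up[:80] = 6.0
        c = pd.DataFrame(
            {
                "A": rng.poisson(mu),
                "B": rng.poisson(mu * up),
                "C": rng.poisson(mu * 1.5),
            }
        )
        csv = tmp_path / "counts.tsv"
        c.to_csv(csv, sep="\t", index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            textwrap.dedent(
                f"""\
                suppressMessages(library(edgeR))
                x <- as.matrix(read.delim("{csv}"))
                f <- calcNormFactors(x, method="TMM")
                cat(f, sep="\\n")
                """
            )
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        edger = np.array([float(v) for v in out.stdout.split()])
        mine = tmm_factors(c).to_numpy()
        assert np.allclose(mine, edger, rtol=0.02)


class TestDispersion:
    def test_poisson_data_low_phi(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(4.3, 1.0, 2000)
        Y = rng.poisson(mu[:, None] * np.ones(8))
        d = estimate_dispersion(pd.DataFrame(Y, columns=TWO_GROUP.index),
                                TWO_GROUP.values)
        assert d.common <= 0.01

    def test_phi_point_two_recovered(self):
        rng = np.random.default_rng(4)
        mu = rng.lognormal(4.3, 1.0, 2000)
        Y = nb_counts(rng, mu, 0.2, 8)
        d = estimate_dispersion(pd.DataFrame(Y, columns=TWO_GROUP.index),
                                TWO_GROUP.values)
        assert 0.15 <= d.common <= 0.25

    def test_shrunk_between_cluster_and_common(self, null_counts):
        d = estimate_dispersion(null_counts, TWO_GROUP.values)
        assert d.per_cluster is not None
        # shrinkage keeps per-cluster values in a band around the common value
        assert np.median(np.abs(np.log(d.per_cluster / d.common))) < 1.0

    def test_no_replication_warns_and_floors(self):
        rng = np.random.default_rng(5)
        Y = nb_counts(rng, rng.lognormal(4, 1, 200), 0.1, 2)
        design = np.column_stack([np.ones(2), [1.0, 0.0]])
        with pytest.warns(UserWarning, match="residual degrees"):
            d = estimate_dispersion(pd.DataFrame(Y, columns=["a", "b"]), design)
        assert d.common == pytest.approx(1e-4)


class TestExactTest:
    def test_equal_counts_zero_logfc(self):
        c = pd.DataFrame({"A": [100, 50], "B": [100, 50], "C": [100, 50],
                          "D": [100, 50]})
        res = exact_test(c, ["A", "B"], ["C", "D"], 0.1)
        assert res["logFC"].abs().max() < 1e-9
        assert (res["pvalue"] == 1.0).all()

    def test_null_type_one_error(self, null_counts):
        d = estimate_dispersion(null_counts, TWO_GROUP.values)
        res = exact_test(null_counts, [f"L{j}" for j in range(6)], ["L6", "L7"], d)
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.065

    def test_planted_fold_change_power(self):
        rng = np.random.default_rng(6)
        G = 1500
        mu = rng.lognormal(4.3, 1.0, G)
        fc = np.ones(G)
        de = rng.choice(G, G // 10, replace=False)
        fc[de] = 4.0
        Y = np.column_stack([nb_counts(rng, mu * fc, 0.1, 6),
                             nb_counts(rng, mu, 0.1, 2)])
        c = pd.DataFrame(Y, columns=TWO_GROUP.index)
        d = estimate_dispersion(c, TWO_GROUP.values)
        res = exact_test(c, [f"L{j}" for j in range(6)], ["L6", "L7"], d)
        called = res["fdr"] <= 0.1
        assert called.values[de].mean() >= 0.8
        false = called.values & ~np.isin(np.arange(G), de)
        assert false.sum() / max(called.sum(), 1) <= 0.15


class TestGLM:
    def test_null_pvalues_uniform(self):
        """LRT p-values are uniform under the null; the chi-square reference
        is asymptotic in the counts, so the check uses well-expressed
        clusters."""
        rng = np.random.default_rng(41)
        G = 2000
        mu = rng.lognormal(5.5, 0.8, G)
        Y = nb_counts(rng, mu, 0.1, 8)
        c = pd.DataFrame(Y, columns=TWO_GROUP.index)
        d = estimate_dispersion(c, TWO_GROUP.values)
        res = glm_lrt(c, TWO_GROUP, "grp", d)
        assert kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_agrees_with_exact_test_ranking(self, null_counts):
        rng = np.random.default_rng(8)
        c = null_counts.copy()
        boost = rng.choice(len(c), 200, replace=False)
        c.iloc[boost, :6] = (c.iloc[boost, :6] * 4).astype(int)
        d = estimate_dispersion(c, TWO_GROUP.values)
        res_g = glm_lrt(c, TWO_GROUP, "grp", d)
        res_e = exact_test(c, [f"L{j}" for j in range(6)], ["L6", "L7"], d)
        assert spearmanr(res_g["pvalue"], res_e["pvalue"]).statistic >= 0.99

    def test_paired_design_recovers_fraction_effect(self):
        rng = np.random.default_rng(9)
        npairs, G = 6, 1200
        pairs = np.repeat(np.arange(npairs), 2)
        frac = np.tile([1.0, 0.0], npairs)
        base = rng.lognormal(4.3, 0.8, G)
        eff = np.zeros(G)
        sel = rng.choice(G, G // 10, replace=False)
        eff[sel] = 1.0  # planted 2x on a subset
        eta = (np.log(base)[:, None]
               + rng.normal(0, 0.3, (G, npairs))[:, pairs] * np.log(2)
               + np.outer(eff, frac) * np.log(2))
        r = 10.0
        Y = rng.negative_binomial(r, r / (r + np.exp(eta)))
        cols = [f"x{j}" for j in range(2 * npairs)]
        counts = pd.DataFrame(Y, columns=cols)
        dd = {"intercept": np.ones(2 * npairs)}
        for k in range(1, npairs):
            dd[f"pair{k}"] = (pairs == k).astype(float)
        dd["fraction"] = frac
        design = pd.DataFrame(dd, index=cols)
        d = estimate_dispersion(counts, design.values)
        res = glm_lrt(counts, design, "fraction", d)
        est = res["logFC"].values[sel]
        se = res["se_logFC"].values[sel]
        cover = ((est - 1.96 * se <= 1.0) & (1.0 <= est + 1.96 * se)).mean()
        assert cover >= 0.9
        assert abs(est.mean() - 1.0) < 0.15

    def test_scale_invariance(self, null_counts):
        d = Dispersion(common=0.1)
        base = glm_lrt(null_counts, TWO_GROUP, "grp", d)
        scaled = null_counts.copy()
        scaled["L0"] = scaled["L0"] * 5
        res = glm_lrt(scaled, TWO_GROUP, "grp", d)
        # the offset absorbs the scaling; residual jitter comes from the
        # recomputed TMM trim on discrete counts
        ok = null_counts.min(axis=1) >= 5
        diff = (res.loc[ok, "logFC"] - base.loc[ok, "logFC"]).abs()
        assert diff.median() < 0.02
        assert diff.quantile(0.99) < 0.1
        assert diff.max() < 0.25

    def test_rank_deficient_design_names_aliased(self, null_counts):
        bad = TWO_GROUP.copy()
        bad["dup"] = bad["grp"]
        with pytest.raises(ValueError, match="dup|grp"):
            glm_lrt(null_counts, bad, "grp", 0.1)


class TestBH:
    def test_constant_ratio_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            assert np.allclose(bh_adjust(p), brute_force_bh(p))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])


class TestEnrichedSet:
    def _table(self):
        return pd.DataFrame(
            {"logFC": [2.0, -1.5, 0.5, 3.0], "logCPM": 10.0,
             "pvalue": [0.001, 0.002, 0.5, 0.01],
             "fdr": [0.004, 0.004, 0.5, 0.02]},
            index=["c1", "c2", "c3", "c4"],
        )

    def test_directions(self):
        t = self._table()
        ann = {"c1": ["A"], "c2": ["B"], "c4": ["A", "C"]}
        up = enriched_set(t, 0.1, "up", ann)
        assert up["clusters"] == ["c1", "c4"] and up["genes"] == ["A", "C"]
        down = enriched_set(t, 0.1, "down", ann)
        assert down["clusters"] == ["c2"] and down["genes"] == ["B"]

    def test_all_high_fdr_empty(self):
        t = self._table()
        t["fdr"] = 0.5
        assert enriched_set(t, 0.1, "up")["clusters"] == []

    def test_threshold_monotonicity(self):
        t = self._table()
        s01 = set(enriched_set(t, 0.1, "up")["clusters"])
        s05 = set(enriched_set(t, 0.5, "up")["clusters"])
        assert s01 <= s05
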