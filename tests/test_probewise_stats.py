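"""Two-group fits, empirical-Bayes prior estimation, moderated t.

The R/Bioconductor limma package (lmFit + eBayes) serves as the independent
oracle for the full moderation path on a small matrix.
"""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clinetile import probewise_stats as ps


def _design(n=5, stage="L2"):
    rows = []
    for end in ("North", "South"):
        for r in range(n):
            rows.append({"array_id": f"{end}{r}", "cline_end": end,
                         "stage": stage, "replicate": r})
    return pd.DataFrame(rows)


def _matrix(values_by_array):
    return pd.DataFrame(values_by_array)


class TestFitProbeModel:
    def test_hand_computed_pooled_variance(self):
        # North = South = {1,2,3}: effect 0, s2 = 1, df = 4
        mat = _matrix({"Na": [1.0], "Nb": [2.0], "Nc": [3.0],
                       "Sa": [1.0], "Sb": [2.0], "Sc": [3.0]})
        design = pd.DataFrame(
            {"array_id": ["Na", "Nb", "Nc", "Sa", "Sb", "Sc"],
             "cline_end": ["North"] * 3 + ["South"] * 3,
             "stage": ["L2"] * 6, "replicate": [0, 1, 2] * 2})
        fit = ps.fit_probe_model(mat, design, "L2")
        assert fit["effect"].iloc[0] == pytest.approx(0.0)
        assert fit["s2"].iloc[0] == pytest.approx(1.0)
        assert fit["df"].iloc[0] == 4

    def test_identical_within_groups(self):
        design = _design(5)
        mat = _matrix({a: [3.0 if a.startswith("N") else 1.0] for a in design["array_id"]})
        fit = ps.fit_probe_model(mat, design, "L2")
        assert fit["s2"].iloc[0] == 0.0
        assert fit["df"].iloc[0] == 8
        assert fit["effect"].iloc[0] == pytest.approx(2.0)

    def test_array_order_exchangeable(self):
        rng = np.random.default_rng(0)
        design = _design(5)
        mat = pd.DataFrame(rng.normal(size=(50, 10)), columns=design["array_id"])
        fit1 = ps.fit_probe_model(mat, design, "L2")
        shuffled = design.sample(frac=1, random_state=1)
        fit2 = ps.fit_probe_model(mat, shuffled, "L2")
        pd.testing.assert_frame_equal(fit1, fit2)

    def test_too_few_arrays_raises(self):
        design = _design(5)
        design = design[design["array_id"] != "North0"]
        design = design[design["array_id"] != "North1"]
        design = design[design["array_id"] != "North2"]
        design = design[design["array_id"] != "North3"]
        mat = _matrix({a: [1.0] for a in design["array_id"]})
        with pytest.raises(ValueError, match=">= 2 arrays"):
            ps.fit_probe_model(mat, design, "L2")


class TestEstimatePrior:
    def test_recovers_scaled_inverse_chisquare(self):
        rng = np.random.default_rng(10)
        d0_true, s0_true, d = 4.0, 1.0, 8.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=20_000)
        s2 = sigma2 * rng.chisquare(d, size=20_000) / d
        prior = ps.estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.05)

    def test_equal_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 2.0)
        prior = ps.estimate_prior(s2, 8.0)
        assert math.isinf(prior.d0)

    def test_huge_spread_gives_small_d0(self):
        rng = np.random.default_rng(11)
        s2 = np.exp(rng.normal(0.0, 4.0, size=20_000))
        prior = ps.estimate_prior(s2, 8.0)
        assert prior.d0 < 1.0
        # downstream moderation then barely moves s2
        sel = s2[s2 > 1.0][:5]
        mod = ps.moderated_t(np.ones(len(sel)), sel, 8.0, prior, 5, 5)
        np.testing.assert_allclose(mod["s2_tilde"], sel, rtol=0.25)

    def test_all_zero_variances_raise(self):
        with pytest.raises(ValueError):
            ps.estimate_prior(np.zeros(100), 8.0)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (1e-5, 0.01, 0.5, 2.0, 1e4):
            x = ps._trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def test_hand_computed_example(self):
        # effect 2, s2 1, s0^2 1, d 8, d0 4, 5v5: s2_tilde 1,
        # t = 2/sqrt(0.4), p two-sided from t with 12 df
        prior = ps.ModerationPrior(d0=4.0, s0_sq=1.0)
        mod = ps.moderated_t(np.array([2.0]), np.array([1.0]), 8.0, prior, 5, 5)
        assert mod["s2_tilde"].iloc[0] == pytest.approx(1.0)
        assert mod["t"].iloc[0] == pytest.approx(2.0 / math.sqrt(0.4), rel=1e-12)
        assert mod["p"].iloc[0] == pytest.approx(2 * sps.t.sf(2 / math.sqrt(0.4), 12),
                                                 rel=1e-12)

    def test_d0_to_zero_limit_is_pooled_t(self):
        rng = np.random.default_rng(12)
        effect = rng.normal(size=1000)
        s2 = rng.chisquare(8, size=1000) / 8
        prior = ps.ModerationPrior(d0=1e-12, s0_sq=1.0)
        mod = ps.moderated_t(effect, s2, 8.0, prior, 5, 5)
        plain_t = effect / np.sqrt(s2 * 0.4)
        plain_p = 2 * sps.t.sf(np.abs(plain_t), 8)
        np.testing.assert_allclose(mod["t"], plain_t, rtol=1e-10)
        np.testing.assert_allclose(mod["p"], plain_p, atol=1e-10)

    def test_d0_infinite_is_z_form(self):
        rng = np.random.default_rng(13)
        effect = rng.normal(size=1000)
        s2 = rng.chisquare(8, size=1000) / 8
        prior = ps.ModerationPrior(d0=math.inf, s0_sq=2.0)
        mod = ps.moderated_t(effect, s2, 8.0, prior, 5, 5)
        z = effect / np.sqrt(2.0 * 0.4)
        np.testing.assert_allclose(mod["t"], z, rtol=1e-12)
        np.testing.assert_allclose(mod["p"], 2 * sps.norm.sf(np.abs(z)), atol=1e-12)

    def test_shrinkage_strictly_between(self):
        prior = ps.ModerationPrior(d0=4.0, s0_sq=1.0)
        s2 = np.array([0.25, 4.0])
        mod = ps.moderated_t(np.ones(2), s2, 8.0, prior, 5, 5)
        assert 0.25 < mod["s2_tilde"].iloc[0] < 1.0
        assert 1.0 < mod["s2_tilde"].iloc[1] < 4.0

    def test_monotone_in_effect(self):
        prior = ps.ModerationPrior(d0=4.0, s0_sq=1.0)
        effects = np.linspace(0, 5, 20)
        mod = ps.moderated_t(effects, np.ones(20), 8.0, prior, 5, 5)
        assert (np.diff(np.abs(mod["t"])) > 0).all()

    def test_degenerate_zero_variance_flagged(self):
        # prior contribution underflows: moderated variance is exactly zero
        prior = ps.ModerationPrior(d0=1e-200, s0_sq=1e-200)
        mod = ps.moderated_t(np.array([1.0]), np.array([0.0]), 8.0, prior, 5, 5)
        assert bool(mod["degenerate"].iloc[0])
        assert mod["p"].iloc[0] == 0.0


class TestNullCalibration:
    def test_moderated_p_uniform_under_null(self):
        # zero-effect simulation with probe-level variance heterogeneity
        rng = np.random.default_rng(99)
        n = 20_000
        sigma = np.sqrt(1.0 * 4 / rng.chisquare(4, size=n))
        design = _design(5)
        mat = pd.DataFrame(sigma[:, None] * rng.standard_normal((n, 10)),
                           columns=design["array_id"])
        stats = ps.probe_statistics(mat, design, "L2")
        ks = sps.kstest(stats["p"], "uniform")
        assert ks.pvalue > 0.01


class TestLimmaOracle:
    def test_matches_limma_ebayes(self, tmp_path):
        rng = np.random.default_rng(42)
        n = 400
        sigma = np.sqrt(4 / rng.chisquare(4, size=n))
        x = sigma[:, None] * rng.standard_normal((n, 10))
        x[:40, :5] += 1.0
        design = _design(5)
        mat = pd.DataFrame(x, columns=design["array_id"],
                           index=[f"p{i}" for i in range(n)])
        mat_path = tmp_path / "mat.tsv"
        out_path = tmp_path / "limma.tsv"
        mat.to_csv(mat_path, sep="\t")
        script = tmp_path / "cmp.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'args <- commandArgs(trailingOnly=TRUE)\n'
            'x <- as.matrix(read.delim(args[1], row.names=1))\n'
            'g <- factor(c(rep("N",5), rep("S",5)), levels=c("S","N"))\n'
            'fit <- eBayes(lmFit(x, model.matrix(~g)))\n'
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n'
            '                  d0=fit$df.prior, s0=fit$s2.prior)\n'
            'write.table(out, args[2], sep="\\t", quote=FALSE)\n')
        subprocess.run(["Rscript", str(script), str(mat_path), str(out_path)],
                       check=True, capture_output=True)
        limma = pd.read_csv(out_path, sep="\t", index_col=0)
        stats = ps.probe_statistics(mat, design, "L2")
        fit = ps.fit_probe_model(mat, design, "L2")
        prior = ps.estimate_prior(fit["s2"].to_numpy(), 8.0)
        assert prior.d0 == pytest.approx(limma["d0"].iloc[0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(limma["s0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(stats["t"], limma["t"], rtol=1e-8)
        np.testing.assert_allclose(stats["p"], limma["p"], rtol=1e-8)
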