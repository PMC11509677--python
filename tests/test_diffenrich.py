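"""Moderated t-test, prior estimation, classification and z-profiles."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavprox import diffenrich, synthdata
from cavprox.diffenrich import (
    D0_INF,
    EstimationError,
    VariancePrior,
    bh_adjust,
    call_enrichment,
    classify_interactome,
    fit_variance_prior,
    moderated_t_test,
    nes_contrasts,
    zscore_profiles,
)
from cavprox.proteomics import InputError, LogMatrix, SampleDesign


def _logmat(values, design=None):
    design = design or SampleDesign.from_layout(n_replicates=3)
    idx = pd.Index([f"P{i}" for i in range(len(values))], name="protein_id")
    return LogMatrix(
        pd.DataFrame(np.asarray(values, float), index=idx, columns=design.sample_ids),
        design,
    )


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self, rng):
        # equal s_g_sq for every protein: no excess spread
        s2 = np.full(200, 0.25)
        prior = fit_variance_prior(s2, 4.0)
        assert prior.d0 == D0_INF
        # with zero spread the marginal-mean correction identifies s0
        # only up to the chi^2 log-bias; the point estimate stays within it
        assert 0.1 < prior.s0_sq < 0.4

    def test_recovery_from_scaled_f_marginal(self, rng):
        """Variances simulated with d0=4, s0²=0.05, d_g=4 are recovered
        within 15%."""
        d0, s0_sq, d_g, n = 4.0, 0.05, 4.0, 5000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d_g, n) / d_g
        prior = fit_variance_prior(s2, d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_too_few_proteins_rejected(self, rng):
        with pytest.raises(EstimationError):
            fit_variance_prior(rng.chisquare(4, 10), 4.0)


class TestModeratedT:
    def _random_logmat(self, rng, n=200):
        return _logmat(25 + rng.standard_normal((n, 12)))

    def test_d0_zero_equals_ordinary_pooled_t(self, rng):
        lm = self._random_logmat(rng, 1000)
        prior = VariancePrior(4.0, 0.05)
        res = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")), prior,
                               d0_override=0.0)
        g1 = lm.values[lm.design.group_samples("Cav1", "NT")].to_numpy()
        g2 = lm.values[lm.design.group_samples("NES", "NT")].to_numpy()
        t_ref, p_ref = stats.ttest_ind(g1, g2, axis=1)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)

    def test_d0_infinite_pins_posterior_variance(self, rng):
        lm = self._random_logmat(rng)
        prior = VariancePrior(D0_INF, 0.7)
        res = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")), prior)
        assert np.allclose(res["s_post_sq"], 0.7)

    def test_posterior_variance_between_prior_and_sample(self, rng):
        lm = self._random_logmat(rng)
        prior = VariancePrior(4.0, 0.5)
        res = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")), prior)
        lo = np.minimum(res["s_g_sq"], prior.s0_sq)
        hi = np.maximum(res["s_g_sq"], prior.s0_sq)
        assert ((res["s_post_sq"] >= lo - 1e-12) & (res["s_post_sq"] <= hi + 1e-12)).all()

    def test_shrinkage_direction(self, rng):
        """Moderation attenuates t when the sample variance is below the
        prior and amplifies it when above."""
        lm = self._random_logmat(rng, 500)
        prior = VariancePrior(4.0, 1.0)
        mod = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")), prior)
        ord_ = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")), prior,
                                d0_override=0.0)
        below = mod["s_g_sq"] < prior.s0_sq
        assert (mod.loc[below, "t_mod"].abs() <= ord_.loc[below, "t_mod"].abs() + 1e-12).all()
        assert (mod.loc[~below, "t_mod"].abs() >= ord_.loc[~below, "t_mod"].abs() - 1e-12).all()

    def test_null_type_i_error_near_nominal(self):
        cfg = synthdata.SynthProteomeConfig(
            n_proteins=2000,
            class_fractions={"background": 1.0},
            detection_limit=-np.inf,
            seed=23,
        )
        table, _ = synthdata.simulate_lfq_experiment(cfg)
        lm = LogMatrix(np.log2(table.intensities), table.design)
        res = nes_contrasts(lm)["NT"]
        rate = float((res["p"] < 0.05).mean())
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_all_missing_group_not_testable(self):
        vals = np.full((40, 12), 25.0)
        vals += np.linspace(0, 1, 40 * 12).reshape(40, 12)  # give variance
        lm = _logmat(vals)
        lm.values.iloc[0, 0:3] = np.nan  # Cav1-NT absent for P0
        res = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")),
                               VariancePrior(4.0, 0.05))
        assert not res.loc["P0", "testable"]
        assert np.isnan(res.loc["P0", "p"])
        assert res["testable"].iloc[1:].all()

    def test_unknown_group_rejected(self, rng):
        lm = self._random_logmat(rng, 50)
        with pytest.raises(InputError):
            moderated_t_test(lm, (("Cav1", "COLD"), ("NES", "NT")),
                             VariancePrior(4.0, 0.05))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestLimmaCrossCheck:
    """Independent oracle: Bioconductor limma on the same matrix."""

    def test_prior_and_moderated_t_match_limma(self, tmp_path, rng):
        n = 300
        design = SampleDesign.from_layout(n_replicates=3)
        vals = 25 + rng.standard_normal((n, 12)) * rng.uniform(0.2, 1.0, (n, 1))
        lm = _logmat(vals)
        cols = (lm.design.group_samples("Cav1", "NT")
                + lm.design.group_samples("NES", "NT"))
        mat = lm.values[cols]
        mat_path = tmp_path / "mat.tsv"
        mat.to_csv(mat_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{mat_path}", row.names=1))
            design <- cbind(Intercept=1, Cav1=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(d0=fit$df.prior, s0=fit$s2.prior,
                              t=fit$t[,"Cav1"], p=fit$p.value[,"Cav1"])
            write.csv(out, "{tmp_path}/limma.csv")
        """)
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "check.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)

        prior = diffenrich.fit_variance_prior_from_logmat(
            lm, (("Cav1", "NT"), ("NES", "NT")))
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        res = moderated_t_test(lm, (("Cav1", "NT"), ("NES", "NT")), prior)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6)


class TestCallsAndClassification:
    def _result(self, index, p, lfc, testable=True):
        return pd.DataFrame(
            {"p": p, "logFC": lfc,
             "testable": testable if np.iterable(testable) else [testable] * len(p)},
            index=index,
        )

    def test_threshold_rules(self):
        idx = pd.Index(["a", "b", "c", "d"])
        res = {
            "NT": self._result(idx, [0.04, 0.04, 0.05, 0.01], [1.2, -0.5, 1.0, 0.0]),
            "HYPO": self._result(idx, [1, 1, 1, 1], [0, 0, 0, 0]),
            "REC": self._result(idx, [1, 1, 1, 1], [0, 0, 0, 0]),
        }
        calls = call_enrichment(res)
        # p<0.05 & logFC>0, strict on both
        assert calls["NT"].tolist() == [True, False, False, False]

    def test_untestable_never_called(self):
        idx = pd.Index(["a"])
        res = {c: self._result(idx, [0.001], [3.0], testable=False)
               for c in ("NT", "HYPO", "REC")}
        calls = call_enrichment(res)
        assert not calls.any().any()

    def test_mismatched_universe_rejected(self):
        res = {
            "NT": self._result(pd.Index(["a"]), [0.5], [0]),
            "HYPO": self._result(pd.Index(["b"]), [0.5], [0]),
            "REC": self._result(pd.Index(["a"]), [0.5], [0]),
        }
        with pytest.raises(InputError):
            call_enrichment(res)

    def test_all_patterns_match_truth_table(self):
        patterns = list(itertools.product([False, True], repeat=3))
        calls = pd.DataFrame(patterns, columns=["NT", "HYPO", "REC"],
                             index=[f"p{i}" for i in range(8)])
        cats, counts = classify_interactome(calls)
        expected = {
            (False, False, False): "none",
            (True, False, False): "NT_only",
            (False, True, False): "HYPO_only",
            (False, False, True): "REC_only",
            (True, True, False): "NT&HYPO",
            (True, False, True): "NT&REC",
            (False, True, True): "HYPO&REC",
            (True, True, True): "NT&HYPO&REC",
        }
        for pat, pid in zip(patterns, calls.index):
            assert cats[pid] == expected[pat]
        assert counts["total_significant"] == 7
        assert counts["co_recovered"] == 2  # NT&REC + triple

    def test_categories_partition_significant_union(self, rng):
        calls = pd.DataFrame(rng.random((300, 3)) < 0.3,
                             columns=["NT", "HYPO", "REC"])
        cats, counts = classify_interactome(calls)
        assert counts["total_significant"] == sum(
            counts[c] for c in diffenrich.CATEGORIES if c != "none"
        )
        assert counts["total_significant"] == int(calls.any(axis=1).sum())

    def test_counts_invariant_to_row_order(self, rng):
        calls = pd.DataFrame(rng.random((100, 3)) < 0.4,
                             columns=["NT", "HYPO", "REC"],
                             index=[f"p{i}" for i in range(100)])
        _, c1 = classify_interactome(calls)
        _, c2 = classify_interactome(calls.sample(frac=1, random_state=0))
        assert c1 == c2

    def test_lower_p_threshold_never_enlarges_categories(self, small_logmat):
        res = nes_contrasts(small_logmat)
        loose = call_enrichment(res, p_thresh=0.05)
        tight = call_enrichment(res, p_thresh=0.01)
        assert ((tight & ~loose).sum().sum()) == 0


class TestZProfiles:
    def test_simple_row(self):
        # condition means (NT, HYPO, REC) = (1, 2, 3) -> z = (-1, 0, 1)
        lm = _logmat([[1.0, 1, 1, 2, 2, 2, 3, 3, 3, 5, 5, 5]])
        z = zscore_profiles(lm, mode="per_condition_mean")
        np.testing.assert_allclose(z.iloc[0][["NT", "HYPO", "REC"]], [-1, 0, 1])

    def test_constant_row_flagged_undefined(self):
        lm = _logmat(np.full((1, 12), 7.0))
        z = zscore_profiles(lm)
        assert z.iloc[0].isna().all()

    def test_core_caveolar_zscore_negative_in_hypo(self):
        """Planted NT&REC interactors show the characteristic z-score
        dip under hypo-osmotic shock in >= 95% of cases."""
        cfg = synthdata.SynthProteomeConfig(n_proteins=800, seed=31)
        table, truth = synthdata.simulate_lfq_experiment(cfg)
        lm = LogMatrix(np.log2(table.intensities), table.design)
        core = truth.index[truth["class"] == "core_caveolar"]
        z = zscore_profiles(lm, core, mode="per_condition_mean")
        frac_neg = (z["HYPO"] < 0).mean()
        assert frac_neg >= 0.95


def _bh_oracle(p):
    """Direct step-up definition, independent of the implementation."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestBH:
    def test_analytic_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0] * 5) == 1.0)

    def test_matches_step_up_oracle(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])
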