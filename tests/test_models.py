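"""Multilevel machinery: design construction, ML fits against OLS and
lme4 oracles, LRT calibration, random-structure pruning, contrasts, and
the robust Yuen-Welch bootstrap."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alphalight.models import (FACTOR_LEVELS, ModelSpec, design_matrix,
                               fit_mixed, lr_test, pairwise_contrasts,
                               prune_random_structure, yuen_welch_boot)


def _rt_frame(rng, n_subj=8, n_trial=60, hf_slope_sd=0.0, light_sd=0.0,
              resid=20.0, hf_effect=5.0):
    rows = []
    for s in range(n_subj):
        b0 = rng.normal(0, 10)
        bh = rng.normal(0, hf_slope_sd)
        bl = rng.normal(0, light_sd, 2)
        hf = rng.integers(0, 2, n_trial)  # 1 = left
        light = rng.integers(0, 3, n_trial)
        y = (500 + b0 + hf * (hf_effect + bh)
             + bl[0] * (light == 1) + bl[1] * (light == 2)
             + rng.normal(0, resid, n_trial))
        rows.append(pd.DataFrame({
            "participant_id": f"S{s:02d}",
            "hemifield": np.where(hf == 1, "left", "right"),
            "light_condition": np.array(["low", "medium", "high"])[light],
            "rt_ms": y,
        }))
    return pd.concat(rows, ignore_index=True)


class TestDesignMatrix:
    def test_factor_coding_uses_reference_levels(self):
        from itertools import product
        cells = list(product(["low", "medium", "high"],
                             ["right", "left"])) * 2
        df = pd.DataFrame(cells, columns=["light_condition", "hemifield"])
        X, cols = design_matrix(
            df, ("light_condition", "hemifield",
                 "light_condition:hemifield"))
        assert "light_condition[medium]" in X.columns
        assert "light_condition[high]" in X.columns
        assert "hemifield[left]" in X.columns
        assert "light_condition[high]:hemifield[left]" in X.columns
        # reference cell (low light, right hemifield) is all zeros
        assert X.iloc[0].drop("Intercept").sum() == 0

    def test_rank_deficiency_names_aliased_columns(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="aliased.*y"):
            design_matrix(df, ("x", "y"))


class TestFitMixed:
    def test_intercept_only_estimates_grand_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"rt_ms": rng.normal(500, 20, 200)})
        fit = fit_mixed(ModelSpec(outcome="rt_ms", fixed=(),
                                  re_terms=()), df)
        assert fit.params["Intercept"] == pytest.approx(
            df.rt_ms.mean(), rel=1e-9)

    def test_zero_variance_random_effects_match_ols(self):
        """Data with no subject-level variance: mixed fixed effects agree
        with the closed-form OLS solution to 1e-6 relative tolerance."""
        rng = np.random.default_rng(1)
        df = _rt_frame(rng, n_subj=6, n_trial=80)
        df["rt_ms"] -= df.groupby("participant_id")["rt_ms"].transform(
            "mean") - df.rt_ms.mean()  # remove subject offsets
        spec = ModelSpec(outcome="rt_ms",
                         fixed=("light_condition", "hemifield"))
        fit = fit_mixed(spec, df)
        X, _ = design_matrix(df, spec.fixed)
        beta = np.linalg.lstsq(X.to_numpy(), df.rt_ms.to_numpy(),
                               rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta, rtol=1e-6,
                           atol=1e-6)

    def test_agrees_with_lme4_oracle(self):
        """Cross-check the ML mixed fit (logLik and fixed effects)
        against lme4 on a small dataset."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(2)
        df = _rt_frame(rng, n_subj=8, n_trial=80, hf_slope_sd=10.0)
        spec = ModelSpec(outcome="rt_ms",
                         fixed=("light_condition", "hemifield"),
                         re_terms=("1", "hemifield"))
        fit = fit_mixed(spec, df)
        with tempfile.TemporaryDirectory() as tmp:
            csv = Path(tmp) / "d.csv"
            df.to_csv(csv, index=False)
            script = Path(tmp) / "fit.R"
            script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$light_condition <- factor(d$light_condition,
                            levels=c("low","medium","high"))
d$hemifield <- factor(d$hemifield, levels=c("right","left"))
m <- lmer(rt_ms ~ light_condition + hemifield +
          (1 + hemifield | participant_id), data=d, REML=FALSE)
cat(logLik(m), fixef(m), sep="\\n")
""")
            out = subprocess.run(["Rscript", str(script)],
                                 capture_output=True, text=True,
                                 check=True)
        vals = [float(v) for v in out.stdout.split()]
        llf_r, coefs_r = vals[0], np.array(vals[1:])
        # small optimiser-level differences between implementations
        assert fit.llf == pytest.approx(llf_r, abs=0.1)
        assert np.allclose(fit.params.to_numpy(), coefs_r, atol=0.1)


class TestLRT:
    def test_identical_fits_give_zero_chi_square(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"rt_ms": rng.normal(0, 1, 100)})
        fit = fit_mixed(ModelSpec(outcome="rt_ms", fixed=(),
                                  re_terms=()), df)
        res = lr_test(fit, fit)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_three_level_factor_costs_two_df(self):
        rng = np.random.default_rng(4)
        df = _rt_frame(rng, n_subj=4, n_trial=50)
        spec = ModelSpec(outcome="rt_ms", fixed=("light_condition",),
                         re_terms=())
        full = fit_mixed(spec, df)
        reduced = fit_mixed(spec.drop_fixed("light_condition"), df)
        assert lr_test(full, reduced).df == 2

    def test_mismatched_n_obs_rejected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"rt_ms": rng.normal(0, 1, 100)})
        f1 = fit_mixed(ModelSpec(outcome="rt_ms", fixed=(),
                                 re_terms=()), df)
        f2 = fit_mixed(ModelSpec(outcome="rt_ms", fixed=(),
                                 re_terms=()), df.iloc[:50])
        with pytest.raises(ValueError):
            lr_test(f1, f2)

    def test_type_i_error_calibrated_under_null(self):
        """Testing a truly absent covariate: rejection rate at alpha=.05
        over 500 simulated datasets stays inside the 99% binomial band."""
        rng = np.random.default_rng(6)
        n, reps, rejections = 120, 500, 0
        for _ in range(reps):
            df = pd.DataFrame({"rt_ms": rng.normal(500, 30, n),
                               "x": rng.normal(0, 1, n)})
            spec = ModelSpec(outcome="rt_ms", fixed=("x",), re_terms=())
            full = fit_mixed(spec, df)
            reduced = fit_mixed(spec.drop_fixed("x"), df)
            if lr_test(full, reduced).p_value < 0.05:
                rejections += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rejections <= hi

    def test_invariant_to_outcome_shift(self):
        rng = np.random.default_rng(7)
        df = _rt_frame(rng, n_subj=5, n_trial=40)
        spec = ModelSpec(outcome="rt_ms", fixed=("hemifield",),
                         re_terms=("1",))
        chi1 = lr_test(fit_mixed(spec, df),
                       fit_mixed(spec.drop_fixed("hemifield"), df))
        df2 = df.assign(rt_ms=df.rt_ms + 1000.0)
        chi2 = lr_test(fit_mixed(spec, df2),
                       fit_mixed(spec.drop_fixed("hemifield"), df2))
        assert chi1.chi_square == pytest.approx(chi2.chi_square, abs=1e-4)


class TestPruneRandomStructure:
    def test_empty_candidate_list_returns_maximal(self):
        rng = np.random.default_rng(8)
        df = _rt_frame(rng, n_subj=5, n_trial=30)
        spec = ModelSpec(outcome="rt_ms", fixed=("hemifield",),
                         re_terms=("1",))
        final, audit = prune_random_structure(spec, df, candidates=())
        assert final.re_terms == ("1",)
        assert audit[0]["step"] == "maximal"

    def test_zero_variance_slopes_pruned_to_intercept(self):
        rng = np.random.default_rng(9)
        df = _rt_frame(rng, n_subj=10, n_trial=60, hf_slope_sd=0.0)
        spec = ModelSpec(outcome="rt_ms",
                         fixed=("light_condition", "hemifield"),
                         re_terms=("1",))
        final, audit = prune_random_structure(
            spec, df, candidates=("hemifield", "light_condition"))
        assert final.re_terms == ("1",)
        steps = [a for a in audit if a["step"] == "candidate"]
        assert {s["term"] for s in steps} == {"hemifield",
                                              "light_condition"}

    def test_recovers_genuine_hemifield_slope_drops_light(self):
        """With a real by-subject hemifield slope and zero-variance light
        slopes, pruning keeps the former and drops the latter in most
        seeded replicates."""
        hits_keep, hits_drop, reps = 0, 0, 12
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            df = _rt_frame(rng, n_subj=12, n_trial=100, hf_slope_sd=12.0,
                           light_sd=0.0)
            spec = ModelSpec(outcome="rt_ms",
                             fixed=("light_condition", "hemifield"),
                             re_terms=("1",))
            final, _ = prune_random_structure(
                spec, df, candidates=("hemifield", "light_condition"))
            if "hemifield" in final.re_terms:
                hits_keep += 1
            if "light_condition" not in final.re_terms:
                hits_drop += 1
        assert hits_keep / reps >= 0.8
        assert hits_drop / reps >= 0.8


class TestContrasts:
    def _fit(self, rng, levels=3):
        df = _rt_frame(rng, n_subj=6, n_trial=60)
        if levels == 2:
            df = df[df.light_condition != "medium"]
        return fit_mixed(ModelSpec(outcome="rt_ms",
                                   fixed=("light_condition",),
                                   re_terms=()), df)

    def test_two_level_contrast_equals_coefficient(self):
        rng = np.random.default_rng(10)
        fit = self._fit(rng, levels=2)
        cons = pairwise_contrasts(fit, "light_condition",
                                  adjustment="max-t")
        assert len(cons) == 1
        assert cons[0].estimate == pytest.approx(
            fit.params["light_condition[high]"])
        assert cons[0].p_adjusted == pytest.approx(cons[0].p_value,
                                                   rel=1e-6)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(11)
        fit = self._fit(rng)
        for method in ("max-t", "holm", "bonferroni"):
            for c in pairwise_contrasts(fit, "light_condition",
                                        adjustment=method):
                assert c.p_adjusted >= c.p_value - 1e-12

    def test_max_t_dominates_bonferroni(self):
        """Single-step max-|t| is uniformly no more conservative than
        Bonferroni over simulated fits."""
        rng = np.random.default_rng(12)
        dominated = total = 0
        for _ in range(20):
            fit = self._fit(rng)
            maxt = pairwise_contrasts(fit, "light_condition",
                                      adjustment="max-t")
            bonf = pairwise_contrasts(fit, "light_condition",
                                      adjustment="bonferroni")
            for a, b in zip(maxt, bonf):
                total += 1
                if a.p_adjusted <= b.p_adjusted + 1e-9:
                    dominated += 1
        assert dominated / total >= 0.99

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(13)
        fit = self._fit(rng)
        cons = {c.name: c.estimate
                for c in pairwise_contrasts(fit, "light_condition",
                                            adjustment="none")}
        hl = cons["high - low"]
        hm = cons["high - medium"]
        ml = cons["medium - low"]
        assert hl == pytest.approx(hm + ml, abs=1e-9)

    def test_unknown_factor_rejected(self):
        rng = np.random.default_rng(14)
        fit = self._fit(rng)
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, "weather")


class TestYuenWelch:
    def test_identical_samples_give_zero_statistic(self):
        x = np.arange(12.0)
        res = yuen_welch_boot(x, x.copy(), seed=0)
        assert res.statistic == 0.0
        assert res.p_value > 0.9

    def test_trimmed_mean_ignores_extreme_inflation(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        res1 = yuen_welch_boot(x, y, seed=1)
        x2 = x.copy()
        x2[np.argmax(x2)] *= 10.0
        res2 = yuen_welch_boot(x2, y, seed=1)
        assert res2.trimmed_diff == pytest.approx(res1.trimmed_diff)

    def test_null_type_i_error_calibrated(self):
        """Two same-distribution samples of 12: rejection rate at
        alpha=.05 across simulations stays in the 99% binomial band."""
        rng = np.random.default_rng(16)
        reps, rejections = 400, 0
        for r in range(reps):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            if yuen_welch_boot(x, y, n_boot=600,
                               seed=r).p_value < 0.05:
                rejections += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rejections <= hi

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            yuen_welch_boot([1, 2, 3], [1, 2, 3, 4, 5], seed=0)
        with pytest.raises(ValueError):
            yuen_welch_boot(np.ones(6), np.ones(6), trim=0.6, seed=0)
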