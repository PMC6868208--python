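"""Mixed-model LRTs, Bonferroni correction and the power computation."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from shoalstress import inference


def gaussian_table(n_groups=23, n_per=10, shift=0.0, group_sd=0.5,
                   resid_sd=1.0, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        for cond, code in (("after_24h", 0), ("immediate", 1)):
            y = rng.normal(u + shift * code, resid_sd, n_per)
            rows.append(pd.DataFrame(
                {"group_id": f"g{g}", "condition": cond, "value": y}
            ))
    return pd.concat(rows, ignore_index=True)


def binary_table(n_groups=23, n_per=180, p0=0.5, p1=None, group_sd=0.5,
                 seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    p1 = p0 if p1 is None else p1
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        for cond, p in (("after_24h", p0), ("immediate", p1)):
            prob = expit(np.log(p / (1 - p)) + u)
            y = rng.binomial(1, prob, n_per)
            rows.append(pd.DataFrame(
                {"group_id": f"g{g}", "condition": cond, "value": y}
            ))
    return pd.concat(rows, ignore_index=True)


class TestGaussianLmm:
    def test_identical_conditions_give_null_result(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in range(10):
            y = rng.normal(g, 1.0, 12)
            for cond in ("immediate", "after_24h"):
                rows.append(pd.DataFrame(
                    {"group_id": f"g{g}", "condition": cond, "value": y}
                ))
        res = inference.fit_lmm_lrt(pd.concat(rows, ignore_index=True))
        assert res.chi_sq == pytest.approx(0.0, abs=1e-5)
        assert res.p_raw > 0.99

    def test_chi_sq_is_twice_loglik_difference(self):
        res = inference.fit_lmm_lrt(gaussian_table(shift=0.7))
        assert res.chi_sq == pytest.approx(
            max(0.0, 2 * (res.llf_full - res.llf_null)), abs=1e-6
        )

    def test_near_zero_random_effect_matches_classical_lrt(self):
        """With no group variance the LMM LRT approaches the OLS one."""
        df = gaussian_table(n_groups=20, n_per=15, shift=0.25, group_sd=0.0, seed=5)
        res = inference.fit_lmm_lrt(df)
        y = df["value"].to_numpy()
        x = df["condition"].map(inference.CONDITION_CODE).to_numpy()

        def ols_llf(resid):
            n = len(resid)
            s2 = np.mean(resid**2)
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1)

        beta = np.polyfit(x, y, 1)
        chi_ols = 2 * (ols_llf(y - np.polyval(beta, x)) - ols_llf(y - y.mean()))
        p_ols = stats.chi2.sf(chi_ols, 1)
        assert res.p_raw == pytest.approx(p_ols, rel=0.10)

    def test_two_sd_shift_detected(self):
        """A 2-residual-SD condition shift is overwhelming at this size."""
        detected = 0
        for seed in range(20):
            res = inference.fit_lmm_lrt(
                gaussian_table(n_groups=23, n_per=5, shift=2.0, seed=seed)
            )
            detected += res.p_raw < 0.001 and res.coef > 0
        assert detected >= 19

    def test_log_transform_bookkeeping_exact(self):
        df = gaussian_table(shift=0.3)
        df["value"] = np.exp(df["value"])
        res_log = inference.fit_lmm_lrt(df, transform="log")
        df2 = df.assign(value=np.log(df["value"]))
        res_manual = inference.fit_lmm_lrt(df2, transform="none")
        assert res_log.chi_sq == pytest.approx(res_manual.chi_sq, abs=1e-8)
        assert res_log.llf_full == pytest.approx(res_manual.llf_full, abs=1e-8)

    def test_log_transform_requires_positive(self):
        df = gaussian_table()
        df.loc[0, "value"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            inference.fit_lmm_lrt(df, transform="log")

    def test_single_group_design_rejected(self):
        df = gaussian_table(n_groups=1)
        with pytest.raises(ValueError, match="at least 2 groups"):
            inference.fit_lmm_lrt(df)


class TestBinomialGlmm:
    def test_matches_lme4_glmer(self, tmp_path):
        """Log-likelihoods, chi-squared and coefficient agree with R lme4."""
        df = binary_table(n_groups=12, n_per=40, p0=0.38, p1=0.66, group_sd=0.8,
                          seed=42)
        res = inference.fit_glmm_binomial_lrt(df)
        data_path = tmp_path / "d.csv"
        df.assign(cond=df["condition"].map(inference.CONDITION_CODE)).to_csv(
            data_path, index=False
        )
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{data_path}')\n"
            "full <- glmer(value ~ cond + (1|group_id), data=d, family=binomial, nAGQ=15)\n"
            "null <- glmer(value ~ 1 + (1|group_id), data=d, family=binomial, nAGQ=15)\n"
            "cat(logLik(full), logLik(null), fixef(full)['cond'], sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        llf_full, llf_null, coef = map(float, out.stdout.strip().split("\n"))
        assert res.llf_full == pytest.approx(llf_full, abs=1e-3)
        assert res.llf_null == pytest.approx(llf_null, abs=1e-3)
        assert res.chi_sq == pytest.approx(2 * (llf_full - llf_null), rel=1e-4)
        assert res.coef == pytest.approx(coef, abs=1e-3)

    def test_strong_effect_full_size_design(self):
        df = binary_table(p0=0.1, p1=0.9, seed=11)
        res = inference.fit_glmm_binomial_lrt(df)
        assert res.p_raw < 1e-6
        assert res.coef > 0
        assert res.converged

    def test_all_zero_response_flagged_not_crashing(self):
        df = binary_table(p0=0.5, seed=1)
        df["value"] = 0
        res = inference.fit_glmm_binomial_lrt(df)
        assert not res.converged
        assert "degenerate" in res.note
        assert res.p_raw == 1.0

    def test_non_binary_rejected(self):
        df = binary_table(n_groups=3, n_per=5)
        df.loc[0, "value"] = 2
        with pytest.raises(ValueError, match="binary"):
            inference.fit_glmm_binomial_lrt(df)


class TestBonferroni:
    def test_examples_and_cap(self):
        assert inference.bonferroni_adjust([0.01], m=5)[0] == pytest.approx(0.05)
        assert inference.bonferroni_adjust([0.3], m=5)[0] == 1.0

    def test_matches_elementwise_oracle(self, rng):
        p = rng.random(50)
        adj = inference.bonferroni_adjust(p, m=7)
        for pi, ai in zip(p, adj):
            assert ai == min(1.0, 7 * pi)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            inference.bonferroni_adjust([1.2])

    def test_adjust_family_defaults_to_family_size(self):
        results = [
            inference.LRTResult(
                response=f"r{i}", family="gaussian_lmm", transform="none",
                chi_sq=1.0, df=1, p_raw=0.02, p_bonferroni=None, coef=1.0,
                llf_full=0.0, llf_null=0.0, n_obs=10, n_groups=2, converged=True,
            )
            for i in range(4)
        ]
        adjusted = inference.adjust_family(results)
        assert all(r.p_bonferroni == pytest.approx(0.08) for r in adjusted)


class TestPairedTSampleSize:
    def test_study_design_value(self):
        """Effect 4 ng/g at the upper-range SD 5.6 and 90% power needs 23 pairs."""
        assert inference.paired_t_sample_size(4.0, 5.6, power=0.90) == 23

    def test_matches_monte_carlo_oracle(self, rng):
        effect, sd = 4.0, 5.6
        n = inference.paired_t_sample_size(effect, sd, power=0.90)

        def mc_power(n, reps=20_000):
            diffs = rng.normal(effect, sd, size=(reps, n))
            t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n))
            crit = stats.t.ppf(0.975, n - 1)
            return np.mean(np.abs(t) > crit)

        assert mc_power(n) >= 0.90 - 0.01
        assert mc_power(n - 1) < 0.90 + 0.01

    def test_doubling_effect_never_needs_more_pairs(self):
        for effect in (1.0, 2.0, 4.0):
            assert inference.paired_t_sample_size(
                2 * effect, 5.6
            ) <= inference.paired_t_sample_size(effect, 5.6)

    def test_extreme_power_finite(self):
        n = inference.paired_t_sample_size(0.1, 5.6, power=0.999999)
        assert np.isfinite(n) and n > 1000

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            inference.paired_t_sample_size(-1.0, 5.6)
        with pytest.raises(ValueError, match="unattainable"):
            inference.paired_t_sample_size(4.0, 5.6, power=1.0)
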