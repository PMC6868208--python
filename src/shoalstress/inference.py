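"""Condition-difference testing with mixed-effects likelihood-ratio tests.

The design is repeated-measures: every group (shoal) is observed in both
conditions (``immediate`` exposure to the stressor vs ``after_24h``), so all
models carry a per-group random intercept. Continuous responses (per-frame
group metrics, per-fish cortisol) use a Gaussian linear mixed model;
clip-level presence/absence behaviours use a binomial (logistic) mixed
model. Both are fitted by maximum likelihood — not REML — so that the full
model (with the condition fixed effect) and the null model (without it) are
comparable by a likelihood-ratio test on 1 df. Families of tests are
Bonferroni-corrected.

The Gaussian model is fitted with :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
The binomial model is fitted here directly: the marginal likelihood of a
random-intercept logistic model is a one-dimensional integral per group,
evaluated by adaptive Gauss–Hermite quadrature (one node reproduces the
Laplace approximation; the default 15 nodes is more accurate) and maximised
with scipy. With a binary condition covariate the per-group likelihood
depends on the data only through success/trial counts per condition, which
makes the fit fast enough for large calibration simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.power import TTestPower

CONDITIONS = ("immediate", "after_24h")
#: condition coding used in all models: effect = immediate minus after_24h
CONDITION_CODE = {"immediate": 1.0, "after_24h": 0.0}


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of the condition effect for one response."""

    response: str
    family: str            # "gaussian_lmm" | "binomial_glmm"
    transform: str         # "none" | "log"
    chi_sq: float          # 2 * (llf_full - llf_null), clipped at 0
    df: int
    p_raw: float
    p_bonferroni: float | None
    coef: float            # condition coefficient (immediate - after_24h scale)
    llf_full: float
    llf_null: float
    n_obs: int
    n_groups: int
    converged: bool
    note: str = ""


def _validate_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    required = {response, "condition", "group_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    if table["group_id"].nunique() < 2:
        raise ValueError(
            "need at least 2 groups: the group random effect is "
            "unidentifiable in a single-group design"
        )
    df = table[[response, "condition", "group_id"]].dropna().copy()
    df["_cond"] = df["condition"].map(CONDITION_CODE)
    return df


def _lrt_from_llfs(llf_full: float, llf_null: float) -> tuple[float, float]:
    chi = 2.0 * (llf_full - llf_null)
    if chi < 0:  # numerical noise from independent optimisations
        chi = 0.0
    return chi, float(stats.chi2.sf(chi, df=1))


def fit_lmm_lrt(
    table: pd.DataFrame,
    response: str = "value",
    transform: str = "none",
) -> LRTResult:
    """Gaussian LMM condition test: response ~ condition + (1 | group).

    Fits full and null models by maximum likelihood and compares them with
    a chi-squared(1) likelihood-ratio test. ``transform="log"`` models the
    natural log of the response and requires strictly positive values.
    """
    df = _validate_table(table, response)
    y = df[response].to_numpy(float)
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive values")
        y = np.log(y)
    elif transform != "none":
        raise ValueError(f"unknown transform: {transform}")
    df = df.assign(_y=y)

    converged = True
    note = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        full = MixedLM.from_formula("_y ~ _cond", groups="group_id", data=df).fit(
            reml=False
        )
        null = MixedLM.from_formula("_y ~ 1", groups="group_id", data=df).fit(
            reml=False
        )
    if not (full.converged and null.converged):
        converged = False
        note = "mixed-model optimiser did not converge"
    singular = [w for w in caught if "singular" in str(w.message).lower()
                or "boundary" in str(w.message).lower()]
    if singular and converged:
        note = "random-effect variance at/near boundary"
    chi, p = _lrt_from_llfs(full.llf, null.llf)
    return LRTResult(
        response=response,
        family="gaussian_lmm",
        transform=transform,
        chi_sq=chi,
        df=1,
        p_raw=p,
        p_bonferroni=None,
        coef=float(full.params["_cond"]),
        llf_full=float(full.llf),
        llf_null=float(null.llf),
        n_obs=len(df),
        n_groups=df["group_id"].nunique(),
        converged=converged,
        note=note,
    )


# ---------------------------------------------------------------------------
# binomial GLMM (random-intercept logistic model, ML via adaptive quadrature)
# ---------------------------------------------------------------------------

def _group_counts(df: pd.DataFrame, response: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-group (k, n) success/trial counts for conditions coded 0 and 1."""
    agg = (
        df.groupby(["group_id", "_cond"])[response]
        .agg(["sum", "count"])
        .unstack("_cond", fill_value=0)
    )
    k = np.column_stack(
        [agg.get(("sum", c), pd.Series(0, index=agg.index)) for c in (0.0, 1.0)]
    ).astype(float)
    n = np.column_stack(
        [agg.get(("count", c), pd.Series(0, index=agg.index)) for c in (0.0, 1.0)]
    ).astype(float)
    return k, n


def _glmm_negll(params: np.ndarray, k: np.ndarray, n: np.ndarray,
                with_effect: bool, nodes: np.ndarray, weights: np.ndarray) -> float:
    """Negative marginal log-likelihood, adaptive Gauss–Hermite per group.

    ``k``/``n`` are (n_groups, 2) success/trial counts for condition codes
    0 and 1; the random intercept is standard-normal scaled by sigma. Each
    group's likelihood L_g = ∫ exp(g(u)) du (g = Bernoulli log-likelihood
    plus the N(0,1) log-density) is evaluated by centring ``nodes`` at the
    mode of g with the Laplace standard deviation:
    L_g ≈ √2·σ̂ · Σ_i w_i · exp(g(μ + √2·σ̂·x_i) + x_i²).
    """
    if with_effect:
        b0, b1, log_s = params
    else:
        (b0, log_s), b1 = params, 0.0
    s = np.exp(log_s)
    eta0 = np.array([b0, b0 + b1])  # linear predictor per condition code

    # per-group mode of the log integrand by Newton iteration
    u_hat = np.zeros(k.shape[0])
    for _ in range(50):
        p = special.expit(eta0[None, :] + s * u_hat[:, None])
        grad = (s * (k - n * p)).sum(axis=1) - u_hat
        hess = -(s**2 * (n * p * (1 - p))).sum(axis=1) - 1.0
        step = grad / hess
        u_hat -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(eta0[None, :] + s * u_hat[:, None])
    curv = (s**2 * (n * p * (1 - p))).sum(axis=1) + 1.0  # -g''(u) at mode
    sd_hat = 1.0 / np.sqrt(curv)

    u = u_hat[:, None] + np.sqrt(2.0) * sd_hat[:, None] * nodes[None, :]  # (G, U)
    lp = eta0[None, :, None] + s * u[:, None, :]                          # (G, 2, U)
    ll = (
        k[:, :, None] * (-np.logaddexp(0.0, -lp))
        + (n - k)[:, :, None] * (-np.logaddexp(0.0, lp))
    ).sum(axis=1)
    log_integrand = ll - 0.5 * u**2 - 0.5 * np.log(2 * np.pi)
    log_lg = (
        special.logsumexp(
            log_integrand + np.log(weights)[None, :] + nodes[None, :] ** 2, axis=1
        )
        + np.log(sd_hat)
        + 0.5 * np.log(2.0)
    )
    return -float(log_lg.sum())


def _glmm_fit(k: np.ndarray, n: np.ndarray, with_effect: bool,
              n_nodes: int = 15) -> tuple[np.ndarray, float, bool]:
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    ktot, ntot = k.sum(), n.sum()
    p_pool = np.clip(ktot / max(ntot, 1.0), 1e-4, 1 - 1e-4)
    b0_start = special.logit(p_pool)
    if with_effect:
        p1 = np.clip(k[:, 1].sum() / max(n[:, 1].sum(), 1.0), 1e-4, 1 - 1e-4)
        p0 = np.clip(k[:, 0].sum() / max(n[:, 0].sum(), 1.0), 1e-4, 1 - 1e-4)
        x0 = np.array([special.logit(p0), special.logit(p1) - special.logit(p0), np.log(0.5)])
        bounds = [(-25, 25), (-25, 25), (-10, 4)]
    else:
        x0 = np.array([b0_start, np.log(0.5)])
        bounds = [(-25, 25), (-10, 4)]

    res = optimize.minimize(
        _glmm_negll, x0, args=(k, n, with_effect, nodes, weights),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success:
        res2 = optimize.minimize(
            _glmm_negll, res.x, args=(k, n, with_effect, nodes, weights),
            method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10,
                                           "maxiter": 4000},
        )
        if res2.fun <= res.fun:
            res = res2
    return res.x, -float(res.fun), bool(res.success)


def fit_glmm_binomial_lrt(
    table: pd.DataFrame,
    response: str = "value",
    n_quad: int = 15,
) -> LRTResult:
    """Binomial GLMM condition test: presence ~ condition + (1 | group).

    The clip-level 0/1 response is modelled with a logistic mixed model
    (group random intercept), fitted by maximum likelihood via adaptive
    Gauss–Hermite quadrature, and the condition effect is tested with a
    chi-squared(1) LRT. Degenerate responses (all 0 or all 1) and apparent
    complete separation are flagged rather than raising.
    """
    df = _validate_table(table, response)
    y = df[response].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("binomial response must be binary (0/1)")
    k, n = _group_counts(df, response)

    note = ""
    if y.sum() == 0 or y.sum() == len(y):
        note = "degenerate response: no variation in presence"
        return LRTResult(
            response=response, family="binomial_glmm", transform="none",
            chi_sq=0.0, df=1, p_raw=1.0, p_bonferroni=None, coef=0.0,
            llf_full=0.0, llf_null=0.0, n_obs=len(df),
            n_groups=k.shape[0], converged=False, note=note,
        )

    params_f, llf_full, ok_f = _glmm_fit(k, n, with_effect=True, n_nodes=n_quad)
    params_n, llf_null, ok_n = _glmm_fit(k, n, with_effect=False, n_nodes=n_quad)
    converged = ok_f and ok_n
    if abs(params_f[1]) >= 20:
        note = "possible complete separation: condition effect at bound"
        converged = False
    chi, p = _lrt_from_llfs(llf_full, llf_null)
    return LRTResult(
        response=response, family="binomial_glmm", transform="none",
        chi_sq=chi, df=1, p_raw=p, p_bonferroni=None,
        coef=float(params_f[1]), llf_full=llf_full, llf_null=llf_null,
        n_obs=len(df), n_groups=k.shape[0], converged=converged, note=note,
    )


# ---------------------------------------------------------------------------
# multiple testing and design
# ---------------------------------------------------------------------------

def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p -> min(1, m * p), default m = len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, m * p)


def adjust_family(results: list[LRTResult], m: int | None = None) -> list[LRTResult]:
    """Bonferroni-adjust a family of LRT results (default m = family size)."""
    if m is None:
        m = len(results)
    adj = bonferroni_adjust([r.p_raw for r in results], m=m)
    return [replace(r, p_bonferroni=float(a)) for r, a in zip(results, adj)]


def paired_t_sample_size(
    effect: float,
    sd: float,
    power: float = 0.90,
    alpha: float = 0.05,
) -> int:
    """Smallest n of pairs giving a two-sided paired t-test the target power.

    ``effect`` is the minimum difference to detect and ``sd`` the standard
    deviation of the paired differences (same units, e.g. ng/g cortisol).
    """
    if effect <= 0 or sd <= 0:
        raise ValueError("effect and sd must be positive")
    if not 0 < power < 1:
        raise ValueError("unattainable power: must be in (0, 1)")
    d = effect / sd
    solver = TTestPower()
    n_float = solver.solve_power(
        effect_size=d, power=power, alpha=alpha, alternative="two-sided"
    )
    n = max(2, int(np.ceil(n_float)) - 1)
    while solver.power(effect_size=d, nobs=n, alpha=alpha,
                       alternative="two-sided") < power:
        n += 1
    return n
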