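"""Crossover linear mixed model and baseline summaries.

The model follows the repeated-measures crossover design: one random
intercept per pig, a fixed categorical stage effect, and — because the
variability of most hemodynamic variables changes markedly between shock,
support and drug stages — stage-specific residual variances by default
(with a pooled-variance fallback when the heterogeneous fit does not
converge).  Estimation is REML; contrasts are reported against a reference
stage with Wald 95% CIs built from pig-level cluster-robust (CR1 sandwich)
standard errors and t quantiles with n_pigs - 1 degrees of freedom — on this
balanced design a stage contrast is a paired mean difference across ten
animals, and both the large-sample normal quantile and the model-based
(diagonal-residual) covariance undercover in that regime.

statsmodels' MixedLM assumes homoscedastic residuals, so the REML fitter
lives here; the homoscedastic special case is cross-checked against
MixedLM in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import InsufficientDataError, ModelFailureError

_LOG_BOUNDS = (-30.0, 15.0)


@dataclass
class EffectEstimate:
    """One cell of the contrast table: stage mean difference vs reference."""

    variable: str
    stage: str
    mean_difference: float
    ci_lo: float
    ci_hi: float
    p_value: float
    reference_stage: str


@dataclass
class LMMFit:
    """Fitted random-intercept model with stage-dependent residual variances."""

    variable: str
    stages: list
    beta: np.ndarray            # stage cell means (+ period slope if used)
    cov_beta: np.ndarray        # model-based (inverse Fisher) covariance
    sigma_b2: float             # pig random-intercept variance
    sigma_e2: dict              # stage -> residual variance
    heteroscedastic: bool
    include_period: bool
    converged: bool
    n_pigs: int
    reml: float
    data: pd.DataFrame = field(repr=False)
    fallback_used: bool = False
    cov_beta_robust: np.ndarray | None = None  # pig-level sandwich (CR1)

    def conditional_residuals(self) -> np.ndarray:
        """y - X beta - Z b_hat with BLUP pig intercepts."""
        res = []
        for _, grp in self.data.groupby("pig_id", sort=True):
            y = grp["__y"].to_numpy()
            X = _design(grp, self.stages, self.include_period)
            r_marg = y - X @ self.beta
            d = np.array([self.sigma_e2[s] for s in grp["stage"]])
            sigma = self.sigma_b2 * np.ones((len(y), len(y))) + np.diag(d)
            b_hat = self.sigma_b2 * np.sum(np.linalg.solve(sigma, r_marg))
            res.append(r_marg - b_hat)
        return np.concatenate(res)


def _design(grp: pd.DataFrame, stages: list, include_period: bool) -> np.ndarray:
    X = np.zeros((len(grp), len(stages) + (1 if include_period else 0)))
    for j, s in enumerate(stages):
        X[(grp["stage"] == s).to_numpy(), j] = 1.0
    if include_period:
        X[:, -1] = grp["period"].to_numpy() - grp["period"].mean()
    return X


def _reml_nll(theta: np.ndarray, blocks: list, stages: list, het: bool,
              p: int) -> float:
    sigma_b2 = np.exp(theta[0])
    if het:
        sig = {s: np.exp(theta[1 + j]) for j, s in enumerate(stages)}
    else:
        sig = {s: np.exp(theta[1]) for s in stages}
    A = np.zeros((p, p))
    u = np.zeros(p)
    q = 0.0
    ld = 0.0
    for X, y, stage_idx in blocks:
        d = np.array([sig[stages[i]] for i in stage_idx])
        n = len(y)
        sigma = sigma_b2 * np.ones((n, n)) + np.diag(d)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        ld += 2.0 * float(np.sum(np.log(np.diag(L))))
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        A += Xi.T @ Xi
        u += Xi.T @ yi
        q += float(yi @ yi)
    sign, ldA = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(A, u)
    nll = 0.5 * (ld + ldA + q - float(u @ beta))
    return nll if np.isfinite(nll) else 1e12


def _solve_beta(theta: np.ndarray, blocks: list, stages: list, het: bool,
                p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, dict]:
    sigma_b2 = float(np.exp(theta[0]))
    if het:
        sig = {s: float(np.exp(theta[1 + j])) for j, s in enumerate(stages)}
    else:
        sig = {s: float(np.exp(theta[1])) for s in stages}
    A = np.zeros((p, p))
    u = np.zeros(p)
    whitened = []
    for X, y, stage_idx in blocks:
        d = np.array([sig[stages[i]] for i in stage_idx])
        sigma = sigma_b2 * np.ones((len(y), len(y))) + np.diag(d)
        L = np.linalg.cholesky(sigma)
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        A += Xi.T @ Xi
        u += Xi.T @ yi
        whitened.append((Xi, yi))
    beta = np.linalg.solve(A, u)
    cov_model = np.linalg.inv(A)
    # pig-level sandwich (CR1): robust to misspecified within-pig covariance,
    # e.g. pig-by-stage interaction correlations the diagonal model misses
    meat = np.zeros((p, p))
    for Xi, yi in whitened:
        g = Xi.T @ (yi - Xi @ beta)
        meat += np.outer(g, g)
    n_c = len(blocks)
    cr1 = n_c / (n_c - 1) if n_c > 1 else 1.0
    cov_robust = cr1 * (cov_model @ meat @ cov_model)
    return beta, cov_model, cov_robust, sigma_b2, sig


def fit_lmm(
    records: pd.DataFrame,
    variable: str,
    *,
    heteroscedastic: bool = True,
    include_period: bool = False,
) -> LMMFit:
    """REML fit of the random-intercept stage model for one variable."""
    need = {"pig_id", "stage", variable}
    if not need.issubset(records.columns):
        raise InsufficientDataError(f"records must contain columns {sorted(need)}")
    df = records[["pig_id", "stage", variable]
                 + (["period"] if include_period else [])].copy()
    df = df.rename(columns={variable: "__y"}).dropna()
    df = df.sort_values(["pig_id", "stage"], kind="mergesort").reset_index(drop=True)
    pigs = df["pig_id"].unique()
    if len(pigs) < 3:
        raise InsufficientDataError(
            f"need >= 3 pigs for the mixed model, got {len(pigs)}"
        )
    stages = list(pd.unique(records["stage"]))
    stages = [s for s in stages if s in set(df["stage"])]
    p = len(stages) + (1 if include_period else 0)

    blocks = []
    for _, grp in df.groupby("pig_id", sort=True):
        X = _design(grp, stages, include_period)
        stage_idx = np.array([stages.index(s) for s in grp["stage"]])
        blocks.append((X, grp["__y"].to_numpy(), stage_idx))

    # moment starting values
    stage_means = df.groupby("stage")["__y"].mean()
    resid = df["__y"] - df["stage"].map(stage_means)
    pig_means = resid.groupby(df["pig_id"]).mean()
    v_within = float(np.var(resid - df["pig_id"].map(pig_means).to_numpy(), ddof=1)) \
        if len(df) > 1 else 1.0
    v_between = max(float(np.var(pig_means, ddof=1)) if len(pig_means) > 1 else 0.0,
                    1e-8)
    v_within = max(v_within, 1e-8)

    def _optimize(het: bool):
        n_var = 1 + (len(stages) if het else 1)
        x0 = np.log(np.r_[v_between, np.full(n_var - 1, v_within)])
        res = optimize.minimize(
            _reml_nll, x0, args=(blocks, stages, het, p),
            method="L-BFGS-B", bounds=[_LOG_BOUNDS] * n_var,
            options={"maxiter": 500},
        )
        return res

    het_used = heteroscedastic
    fallback = False
    res = _optimize(het_used)
    if het_used and (not res.success or not np.isfinite(res.fun)):
        warnings.warn(
            f"heteroscedastic REML did not converge for {variable!r}; "
            "falling back to a pooled residual variance", stacklevel=2,
        )
        het_used, fallback = False, True
        res = _optimize(False)
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise ModelFailureError(f"mixed model failed for variable {variable!r}")

    beta, cov, cov_rob, sigma_b2, sig = _solve_beta(res.x, blocks, stages,
                                                    het_used, p)
    return LMMFit(
        variable=variable, stages=stages, beta=beta, cov_beta=cov,
        sigma_b2=sigma_b2, sigma_e2=sig, heteroscedastic=het_used,
        include_period=include_period, converged=bool(res.success),
        n_pigs=len(pigs), reml=float(res.fun), data=df, fallback_used=fallback,
        cov_beta_robust=cov_rob,
    )


def effects_vs_reference(fit: LMMFit, reference_stage: str) -> list[EffectEstimate]:
    """Wald contrasts (stage minus reference) from a fitted model.

    CIs and p-values use the t distribution with n_pigs - 1 degrees of
    freedom: on this balanced crossover a stage-vs-reference contrast is a
    paired mean difference across pigs, whose exact small-sample reference
    is t with n - 1 df; the large-sample normal quantile undercovers with
    ten animals.
    """
    if reference_stage not in fit.stages:
        raise InsufficientDataError(
            f"reference stage {reference_stage!r} not present in fit"
        )
    df_t = max(fit.n_pigs - 1, 1)
    tq = float(sps.t.ppf(0.975, df=df_t))
    cov = fit.cov_beta_robust if fit.cov_beta_robust is not None else fit.cov_beta
    j_ref = fit.stages.index(reference_stage)
    out = []
    for j, s in enumerate(fit.stages):
        if s == reference_stage:
            out.append(EffectEstimate(fit.variable, s, 0.0, 0.0, 0.0, 1.0,
                                      reference_stage))
            continue
        c = np.zeros(len(fit.beta))
        c[j], c[j_ref] = 1.0, -1.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        tstat = est / se if se > 0 else np.inf * np.sign(est)
        pv = float(min(max(2.0 * sps.t.sf(abs(tstat), df=df_t), 1e-300), 1.0))
        out.append(EffectEstimate(
            fit.variable, s, est, est - tq * se, est + tq * se, pv,
            reference_stage,
        ))
    return out


def fit_stage_lmm(
    records: pd.DataFrame,
    variable: str,
    reference_stage: str = "impella",
    *,
    heteroscedastic: bool = True,
    include_period: bool = False,
) -> list[EffectEstimate]:
    """Contrast table (every stage vs reference) for one variable."""
    fit = fit_lmm(records, variable, heteroscedastic=heteroscedastic,
                  include_period=include_period)
    return effects_vs_reference(fit, reference_stage)


def residual_normality(fit: LMMFit, p_threshold: float = 0.05) -> dict:
    """Shapiro-Wilk on conditional residuals; flags non-normal residuals."""
    r = fit.conditional_residuals()
    if len(r) < 3:
        raise InsufficientDataError("need >= 3 residuals")
    if np.ptp(r) < 1e-12:
        raise InsufficientDataError("residuals are constant; test undefined")
    w, pv = sps.shapiro(r)
    return {"statistic": float(w), "p_value": float(pv),
            "flagged": bool(pv < p_threshold)}


def leave_one_out_sensitivity(
    records: pd.DataFrame,
    variable: str,
    reference_stage: str = "impella",
    **fit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refit excluding each pig once; report effect ranges and sign stability.

    Returns (per-fit frame, per-stage summary frame).
    """
    pigs = list(pd.unique(records["pig_id"]))
    if len(pigs) < 4:
        raise InsufficientDataError("need >= 4 pigs for leave-one-out analysis")
    full = {e.stage: e for e in
            fit_stage_lmm(records, variable, reference_stage, **fit_kwargs)}
    rows = []
    for pig in pigs:
        try:
            effs = fit_stage_lmm(records[records["pig_id"] != pig], variable,
                                 reference_stage, **fit_kwargs)
        except ModelFailureError as err:
            raise ModelFailureError(f"{err} (excluding {pig})") from err
        for e in effs:
            rows.append({"excluded_pig": pig, "stage": e.stage,
                         "mean_difference": e.mean_difference,
                         "ci_lo": e.ci_lo, "ci_hi": e.ci_hi,
                         "p_value": e.p_value})
    per_fit = pd.DataFrame(rows)
    summ = []
    for stage, grp in per_fit.groupby("stage", sort=False):
        if stage == reference_stage:
            continue
        effs = grp["mean_difference"]
        full_sign = np.sign(full[stage].mean_difference)
        summ.append({
            "stage": stage, "full_effect": full[stage].mean_difference,
            "effect_min": float(effs.min()), "effect_max": float(effs.max()),
            "sign_stable": bool((np.sign(effs) == full_sign).all()),
        })
    return per_fit, pd.DataFrame(summ)


def summarize_baseline(records: pd.DataFrame, variable: str,
                       stage: str = "baseline") -> dict:
    """Arithmetic mean and t-based 95% CI of one variable at one stage."""
    vals = records.loc[records["stage"] == stage, variable].dropna().to_numpy() \
        if "stage" in records.columns else records[variable].dropna().to_numpy()
    n = len(vals)
    if n < 2:
        raise InsufficientDataError("need >= 2 values")
    m = float(np.mean(vals))
    se = float(np.std(vals, ddof=1)) / np.sqrt(n)
    tq = float(sps.t.ppf(0.975, df=n - 1))
    return {"mean": m, "ci_lo": m - tq * se, "ci_hi": m + tq * se, "n": n}
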