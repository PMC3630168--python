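"""Multiple imputation by predictive mean matching, and Rubin pooling.

Missing outcome/covariate values are multiply imputed: for each of *m*
imputations the imputation model's parameters are drawn from their
approximate Bayesian posterior (normal draw around the OLS fit with a
scaled-inverse-chi-square variance draw), predicted means are computed
for observed and missing cases, and each missing value is replaced by
the observed value of a donor selected uniformly among the
``donor_pool_size`` cases with nearest predicted means -- so every
imputed value is an actually observed value of that variable.

Per-imputation regression fits are pooled with Rubin's rules (averaged
coefficients; total covariance = within + (1 + 1/m) x between) and an
overall likelihood-ratio chi-square against the intercept-only model,
averaged across imputations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImputationConfig:
    m: int = 10
    donor_pool_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")
        if self.donor_pool_size < 1:
            raise ValueError("donor_pool_size must be >= 1")


@dataclass
class PooledRegressionFit:
    """Rubin-pooled OLS fit over m imputed datasets."""

    params: pd.Series                 # averaged coefficients
    params_per_imp: pd.DataFrame      # m x k per-imputation coefficients
    cov_total: pd.DataFrame           # within + (1 + 1/m) * between
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lr_chisq: float                   # mean of per-imputation 2*(llf - llnull)
    lr_df: int
    lr_pvalue: float
    fvalue: float                     # mean per-imputation overall F
    rsquared: float                   # averaged across imputations
    rsquared_adj: float
    m: int
    n: int
    df_resid: float


def _bayes_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-approximate parameter draw; returns (beta_hat, beta_star)."""
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    beta_hat = xtx_inv @ X.T @ y
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2 * xtx_inv
    # symmetrize for the Cholesky-free multivariate draw
    cov = (cov + cov.T) / 2
    beta_star = rng.multivariate_normal(beta_hat, cov, method="eigh")
    return beta_hat, beta_star


def pmm_impute(
    cohort: pd.DataFrame,
    variables: list[str],
    predictors: list[str],
    config: ImputationConfig | None = None,
) -> list[pd.DataFrame]:
    """Produce *m* completed copies of *cohort* by predictive mean matching.

    Each variable in *variables* is imputed from the *predictors* (other
    analysis variables; their own missing cells are mean-filled within
    the imputation model only).  Observed values are never altered.  A
    variable with no observed values is a fatal error; a donor pool
    larger than the observed sample is shrunk with a warning.
    """
    config = config or ImputationConfig()
    rng = np.random.default_rng(config.seed)
    for var in variables:
        n_obs = cohort[var].notna().sum()
        if n_obs == 0:
            raise ValueError(f"variable {var!r} is entirely missing; cannot impute")
        if n_obs < config.donor_pool_size:
            warnings.warn(
                f"{var!r}: only {n_obs} observed values; donor pool shrunk", stacklevel=2
            )

    pred_cols = [c for c in predictors if c not in variables]
    Xraw = cohort[pred_cols].astype(float)
    Xfill = Xraw.fillna(Xraw.mean())
    X = np.column_stack([np.ones(len(cohort)), Xfill.to_numpy()])

    datasets = []
    for _ in range(config.m):
        completed = cohort.copy()
        for var in variables:
            y = cohort[var].astype(float)
            obs = y.notna().to_numpy()
            mis = ~obs
            if not mis.any():
                continue
            beta_hat, beta_star = _bayes_draw(X[obs], y[obs].to_numpy(), rng)
            yhat_obs = X[obs] @ beta_hat
            yhat_mis = X[mis] @ beta_star
            pool = min(config.donor_pool_size, obs.sum())
            y_obs = y[obs].to_numpy()
            filled = np.empty(mis.sum())
            for i, target in enumerate(yhat_mis):
                d = np.abs(yhat_obs - target)
                donors = np.argsort(d, kind="stable")[:pool]
                filled[i] = y_obs[donors[rng.integers(pool)]]
            col = completed[var]
            if col.dtype.kind in "iu" or str(col.dtype) == "Int64":
                completed.loc[mis, var] = np.round(filled).astype(int)
            else:
                completed.loc[mis, var] = filled
        datasets.append(completed)
    return datasets


def pool_fits(results: list, null_results: list | None = None) -> PooledRegressionFit:
    """Combine per-imputation OLS fits (statsmodels results) by Rubin's rules.

    *null_results* are the matching intercept-only fits used for the
    averaged likelihood-ratio chi-square; without them the LR statistic
    is reported as NaN.
    """
    if not results:
        raise ValueError("no fits to pool")
    names = list(results[0].params.index)
    for r in results[1:]:
        if list(r.params.index) != names:
            raise ValueError(
                f"mismatched coefficient names across imputations: {list(r.params.index)} vs {names}"
            )
    m = len(results)
    P = pd.DataFrame([r.params for r in results]).reset_index(drop=True)
    qbar = P.mean(axis=0)
    ubar = sum(np.asarray(r.cov_params()) for r in results) / m
    if m > 1:
        dev = P.to_numpy() - qbar.to_numpy()
        B = dev.T @ dev / (m - 1)
    else:
        B = np.zeros_like(ubar)
    total = ubar + (1 + 1 / m) * B

    se = np.sqrt(np.diag(total))
    t = qbar.to_numpy() / se
    df_resid = float(results[0].df_resid)
    # Rubin large-sample df; falls back to the residual df when the
    # between-imputation variance vanishes (e.g. no missing data)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_frac = (1 + 1 / m) * np.diag(B) / np.diag(ubar)
        nu = (m - 1) * (1 + 1 / np.maximum(r_frac, 1e-12)) ** 2
    dof = np.where(np.diag(B) <= 1e-300, df_resid, np.minimum(nu, df_resid))
    pvals = 2 * stats.t.sf(np.abs(t), dof)

    k = len(names) - (1 if "const" in names else 0)
    if null_results is not None:
        lr = float(np.mean([2 * (r.llf - r0.llf) for r, r0 in zip(results, null_results)]))
        lr_p = float(stats.chi2.sf(lr, k)) if k > 0 else 1.0
    else:
        lr, lr_p = float("nan"), float("nan")
    fval = float(np.mean([r.fvalue for r in results]))

    return PooledRegressionFit(
        params=qbar,
        params_per_imp=P,
        cov_total=pd.DataFrame(total, index=names, columns=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(pvals, index=names),
        lr_chisq=lr,
        lr_df=k,
        lr_pvalue=lr_p,
        fvalue=fval,
        rsquared=float(np.mean([r.rsquared for r in results])),
        rsquared_adj=float(np.mean([r.rsquared_adj for r in results])),
        m=m,
        n=int(results[0].nobs),
        df_resid=df_resid,
    )
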