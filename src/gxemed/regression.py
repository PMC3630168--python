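"""Outcome transforms, prevalence filtering, and G x E regressions.

Behavioral outcomes are brought to their analysis scales (ln(x+1) for
the positively skewed orienting frequency, square root for instrumental
care duration, identity for the normally distributed vocalizing and
sensitivity measures), rare behaviors are dropped by a 15% prevalence
filter, and full/reduced multivariate regressions with a dominant-coded
genotype, the early-care composite, and their cross-product are fitted
per imputation and pooled.  Model reduction removes non-significant
covariates one at a time by the single-term removal F-test (= t^2 of the
pooled coefficient); the genotype, environment, and interaction terms
are never removable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import BEHAVIOR_COLS
from .genetics import code_dominant
from .impute import PooledRegressionFit, pool_fits

#: Default covariate set for the behavior models (the depression score is
#: dropped from the model predicting depression itself).
DEFAULT_COVARIATES = [
    "age",
    "education",
    "parity",
    "cesd_postnatal",
    "infant_gender",
    "infant_activity",
]


@dataclass
class ModelSpec:
    """One G x E regression: outcome ~ G + E + covariates + G:E."""

    outcome: str
    genotype: str = "rs2740210"
    environment: str = "care_quality"
    interaction: bool = True
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    @property
    def protected_terms(self) -> list[str]:
        terms = ["G", "E"]
        if self.interaction:
            terms.append("GxE")
        return terms

    def __post_init__(self):
        if self.outcome == "cesd_postnatal" and "cesd_postnatal" in self.covariates:
            self.covariates = [c for c in self.covariates if c != "cesd_postnatal"]


@dataclass
class ReductionTrace:
    """Covariates removed during backward elimination, worst p first."""

    removed: list[tuple[str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


def transform_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add analysis-scale outcome columns.

    ``orienting_log`` = ln(orienting frequency + 1) (the +1 accommodates
    zero counts), ``instrumental_sqrt`` = sqrt(duration), and
    ``infant_activity`` = reaching + smiling + crying durations.
    Vocalizing and sensitivity stay on their native scales.  Negative
    inputs are a data error.
    """
    out = cohort.copy()
    for col in ["orienting_away_freq", "instrumental_dur", "reaching_dur", "smiling_dur", "crying_dur"]:
        vals = out[col].astype(float)
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative values in {col}: cannot transform")
    out["orienting_log"] = np.log(out["orienting_away_freq"].astype(float) + 1.0)
    out["instrumental_sqrt"] = np.sqrt(out["instrumental_dur"].astype(float))
    out["infant_activity"] = (
        out["reaching_dur"].astype(float)
        + out["smiling_dur"].astype(float)
        + out["crying_dur"].astype(float)
    )
    return out


def prevalence_filter(cohort: pd.DataFrame, behaviors: list[str] | None = None, threshold: float = 0.15) -> list[str]:
    """Behaviors shown by at least *threshold* of mothers (inclusive).

    Presence = value > 0 among observed entries.
    """
    behaviors = behaviors or [c for c in BEHAVIOR_COLS if c in cohort.columns]
    kept = []
    for col in behaviors:
        vals = cohort[col].dropna().astype(float)
        if len(vals) and (vals > 0).mean() >= threshold:
            kept.append(col)
    return kept


def _design(spec: ModelSpec, data: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    g = data[spec.genotype]
    if g.dtype == object or isinstance(g.dropna().iloc[0] if g.notna().any() else 0, str):
        from .cohort import LOCI, genotype_strings

        g = code_dominant(g, genotype_strings(spec.genotype)[0], spec.genotype)
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["G"] = g.astype(float)
    X["E"] = data[spec.environment].astype(float)
    for cov in covariates:
        X[cov] = data[cov].astype(float)
    if spec.interaction:
        X["GxE"] = X["G"] * X["E"]
    y = data[spec.outcome].astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    return X[keep], y[keep]


def fit_model(spec: ModelSpec, datasets: list[pd.DataFrame], covariates: list[str] | None = None) -> PooledRegressionFit:
    """OLS per completed dataset, pooled across imputations.

    Raises on a rank-deficient design, naming the collinear terms.
    """
    covariates = list(spec.covariates if covariates is None else covariates)
    fits, nulls = [], []
    for data in datasets:
        X, y = _design(spec, data, covariates)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X.to_numpy())
            bad = [X.columns[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
            raise ValueError(f"rank-deficient design; collinear terms: {bad}")
        fits.append(sm.OLS(y, X).fit())
        nulls.append(sm.OLS(y, X[["const"]]).fit())
    return pool_fits(fits, nulls)


def reduce_model(
    spec: ModelSpec,
    datasets: list[pd.DataFrame],
    alpha: float = 0.05,
) -> tuple[PooledRegressionFit, ReductionTrace]:
    """Backward elimination of non-significant covariates.

    At each step the non-protected covariate whose single-term removal
    F-test (equivalently the squared pooled t) has the largest p-value
    above *alpha* is dropped and the model refitted; G, E, and G x E are
    always retained.  Returns the reduced fit and the removal trace.
    """
    covariates = list(spec.covariates)
    trace = ReductionTrace()
    fit = fit_model(spec, datasets, covariates)
    while covariates:
        pvals = fit.pvalues[covariates]
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            break
        trace.removed.append((worst, float(pvals[worst])))
        covariates.remove(worst)
        fit = fit_model(spec, datasets, covariates)
    trace.retained = covariates
    return fit, trace


def anova_main_effect(
    datasets: list[pd.DataFrame], outcome: str, genotype: str
) -> PooledRegressionFit:
    """Genotype main-effect ANOVA as OLS with genotype indicator coding
    (equivalent by construction), pooled over imputations."""
    fits, nulls = [], []
    for data in datasets:
        g = data[genotype]
        if g.dtype == object:
            codes = pd.get_dummies(g.astype("string"), prefix=genotype, drop_first=True)
        else:
            codes = pd.get_dummies(g.astype("Int64"), prefix=genotype, drop_first=True)
        X = pd.concat([pd.Series(1.0, index=data.index, name="const"), codes.astype(float)], axis=1)
        y = data[outcome].astype(float)
        keep = X.notna().all(axis=1) & y.notna()
        fits.append(sm.OLS(y[keep], X[keep]).fit())
        nulls.append(sm.OLS(y[keep], X.loc[keep, ["const"]]).fit())
    return pool_fits(fits, nulls)


def descriptive_correlations(cohort: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho (tie-corrected) and two-sided p-values, pairwise
    deletion; constant columns give NaN entries."""
    rho = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    pval = pd.DataFrame(np.zeros((len(columns), len(columns))), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for j in range(i + 1, len(columns)):
            b = columns[j]
            pair = cohort[[a, b]].dropna().astype(float)
            if len(pair) < 10:
                raise ValueError(f"fewer than 10 paired observations for ({a}, {b})")
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                res = stats.spearmanr(pair[a], pair[b])
                r, p = res.statistic, res.pvalue
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval
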