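"""Composite early-care-quality score.

The nine early-experience questionnaire dimensions are reduced by a
principal component analysis of their correlation matrix; two components
are retained and rotated with the quartimax criterion; per-subject scores
on the first rotated component form the *early care quality* composite,
sign-oriented so that abuse/neglect dimensions load negatively (higher
score = better early care).  Subjects with incomplete questionnaires get
their composite filled in afterwards by stochastic-regression single
imputation on the nine original dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ADVERSITY_DIMS, QUESTIONNAIRE_DIMS


@dataclass
class CareQualityFactor:
    """Loadings, eigenvalues, rotation, and per-subject composite scores."""

    loadings: pd.DataFrame          # 9 x 2 rotated loadings
    unrotated_loadings: pd.DataFrame
    eigenvalues: np.ndarray         # all eigenvalues of the correlation matrix, descending
    rotation: np.ndarray            # 2 x 2 orthogonal rotation applied
    scores: pd.Series               # standardized first-component scores (NaN where unscored)
    imputed_flag: pd.Series         # True where the composite was imputed
    no_structure: bool = False      # True when no eigenvalue clears the null bound


def quartimax_criterion(loadings: np.ndarray) -> float:
    """Sum of fourth powers of the loadings (the quantity quartimax maximizes)."""
    return float((np.asarray(loadings) ** 4).sum())


def quartimax_rotate(loadings: np.ndarray, tol: float = 1e-9, max_sweeps: int = 200):
    """Orthogonal quartimax rotation by pairwise Givens rotations.

    For each column pair the criterion-maximizing angle has the closed
    form theta = (pi - atan2(B, A)) / 4 with u = a^2 - b^2, v = 2ab,
    A = (sum v^2 - sum u^2) / 2 and B = sum(u v); sweeps repeat until the
    criterion improves by less than *tol*.  Returns ``(rotated, T)`` with
    ``rotated = loadings @ T`` and ``T`` orthonormal.  A single-component
    input comes back unchanged with an identity rotation and a warning.
    """
    L = np.array(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be a 2-D array")
    k = L.shape[1]
    T = np.eye(k)
    if k < 2:
        warnings.warn("single component: quartimax rotation is the identity", stacklevel=2)
        return L, T
    crit = quartimax_criterion(L)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = L[:, i], L[:, j]
                u = a**2 - b**2
                v = 2 * a * b
                A = ((v**2).sum() - (u**2).sum()) / 2.0
                B = (u * v).sum()
                theta = (np.pi - np.arctan2(B, A)) / 4.0
                # fold into (-pi/4, pi/4]: rotations differing by pi/2 permute columns
                theta = (theta + np.pi / 4) % (np.pi / 2) - np.pi / 4
                c, s = np.cos(theta), np.sin(theta)
                G = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ G
                T[:, [i, j]] = T[:, [i, j]] @ G
        new_crit = quartimax_criterion(L)
        if new_crit - crit < tol:
            break
        crit = new_crit
    return L, T


def _null_eigenvalue_bound(p: int, n: int) -> float:
    """Rough upper bound on the leading correlation-matrix eigenvalue of
    pure-noise data (Marchenko-Pastur edge (1 + sqrt(p/n))^2 with a small
    finite-sample cushion)."""
    return (1.0 + np.sqrt(p / n)) ** 2 + 3.0 * np.sqrt(p / n)


def extract_care_quality(questionnaire: pd.DataFrame, n_components: int = 2) -> CareQualityFactor:
    """Derive the early-care-quality composite from the nine dimensions.

    Complete-case correlation-matrix PCA, *n_components* retained,
    quartimax rotation, first rotated component scored by the regression
    method and standardized (mean 0, sd 1) over scored subjects.  Rows
    with any missing dimension receive NaN scores (impute them next with
    :func:`stochastic_regression_impute`).
    """
    q = questionnaire[QUESTIONNAIRE_DIMS].astype(float)
    complete = q.dropna()
    if len(complete) < 30:
        raise ValueError(f"need >= 30 complete questionnaire rows, have {len(complete)}")
    for col in q.columns:
        if complete[col].nunique() < 2:
            raise ValueError(f"degenerate (constant) questionnaire column: {col}")

    corr = np.corrcoef(complete.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    unrot = eigvec[:, :n_components] * np.sqrt(np.maximum(eigval[:n_components], 0.0))
    rot, T = quartimax_rotate(unrot)

    # component with the larger sum of squared rotated loadings comes first
    ss = (rot**2).sum(axis=0)
    if ss[0] < ss.max():
        lead = int(np.argmax(ss))
        perm = [lead] + [c for c in range(n_components) if c != lead]
        rot, T = rot[:, perm], T[:, perm]

    # orient: adversity dimensions load negatively on care quality
    adv_idx = [QUESTIONNAIRE_DIMS.index(d) for d in ADVERSITY_DIMS]
    if rot[adv_idx, 0].mean() > 0:
        rot[:, 0] *= -1.0
        T[:, 0] *= -1.0

    # regression-method component scores on standardized data
    mu, sd = complete.mean(), complete.std(ddof=1)
    z = (q - mu) / sd
    weights = np.linalg.solve(corr, rot)
    raw = z.to_numpy() @ weights[:, 0]
    scores = pd.Series(raw, index=q.index)
    scores[q.isna().any(axis=1)] = np.nan
    obs = scores.dropna()
    scores = (scores - obs.mean()) / obs.std(ddof=1)

    no_structure = bool(eigval[0] < _null_eigenvalue_bound(q.shape[1], len(complete)))
    if no_structure:
        warnings.warn("no component exceeds the pure-noise eigenvalue bound", stacklevel=2)

    dims = list(QUESTIONNAIRE_DIMS)
    cols = [f"component_{i + 1}" for i in range(n_components)]
    return CareQualityFactor(
        loadings=pd.DataFrame(rot, index=dims, columns=cols),
        unrotated_loadings=pd.DataFrame(unrot, index=dims, columns=cols),
        eigenvalues=eigval,
        rotation=T,
        scores=scores,
        imputed_flag=pd.Series(False, index=q.index),
        no_structure=no_structure,
    )


def stochastic_regression_impute(
    scores: pd.Series,
    predictors: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    noise_scale: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Fill missing composite scores by stochastic regression imputation.

    Observed scores are regressed on the nine questionnaire dimensions;
    each missing score becomes its fitted value plus Gaussian noise with
    the residual standard deviation (*noise_scale* overrides it; 0 gives
    deterministic regression imputation).  Predictor cells that are
    themselves missing are filled with the observed column mean for
    prediction only.  A subject missing the score and every predictor is
    left missing.  Returns ``(completed_scores, imputed_flag)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = scores.astype(float)
    X = predictors[QUESTIONNAIRE_DIMS].astype(float)
    obs = y.notna()
    if obs.sum() == 0:
        raise ValueError("no observed scores to fit the imputation model")
    Xf = X.fillna(X[obs].mean())
    design = np.column_stack([np.ones(len(Xf)), Xf.to_numpy()])
    beta, *_ = np.linalg.lstsq(design[obs.to_numpy()], y[obs].to_numpy(), rcond=None)
    fitted = design @ beta
    resid = y[obs].to_numpy() - fitted[obs.to_numpy()]
    dof = max(int(obs.sum()) - design.shape[1], 1)
    sd = float(np.sqrt((resid**2).sum() / dof)) if noise_scale is None else float(noise_scale)

    out = y.copy()
    flag = pd.Series(False, index=y.index)
    for pos, idx in enumerate(y.index):
        if obs[idx]:
            continue
        if X.loc[idx].isna().all():
            continue  # nothing to predict from; reported via the flag staying False
        out[idx] = fitted[pos] + (sd * rng.standard_normal() if sd > 0 else 0.0)
        flag[idx] = True
    return out, flag


def kendall_intercorrelations(
    questionnaire: pd.DataFrame, dims: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Kendall tau-b matrix over questionnaire dimensions.

    Pairwise-complete observations; requires >= 10 pairs per cell;
    constant columns give NaN entries.
    """
    dims = list(dims or QUESTIONNAIRE_DIMS)
    out = pd.DataFrame(np.eye(len(dims)), index=dims, columns=dims)
    for i, a in enumerate(dims):
        for j in range(i + 1, len(dims)):
            b = dims[j]
            pair = questionnaire[[a, b]].dropna()
            if len(pair) < 10:
                raise ValueError(f"fewer than 10 paired observations for ({a}, {b})")
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                tau = np.nan
            else:
                tau = stats.kendalltau(pair[a], pair[b]).statistic
            out.loc[a, b] = out.loc[b, a] = tau
    return out
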