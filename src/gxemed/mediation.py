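"""Genotype-moderated mediation path model with bias-corrected bootstrap.

Two regression equations define the path model (X = early care quality,
M = CES-D depression centered at the clinical cut-off of 16, Y = sqrt
instrumental care duration, Z = dominant-coded genotype, 0 for the
reference homozygote and 1 for carriers):

    M = a0 + a1*X + a2*Z + a3*X*Z + e1
    Y = b0 + b1*X + b2*M + b3*Z + b4*X*Z + b5*M*Z + e2

Within each genotype group the simple effects follow from the
coefficients in closed form:

    first stage   a1 + a3*Z        (X -> M)
    second stage  b2 + b5*Z        (M -> Y)
    direct        b1 + b4*Z        (X -> Y holding M)
    indirect      first * second
    total         direct + indirect

and group differences are the carrier-minus-reference contrasts (the
first-stage difference is identically a3, the direct difference b4).
Confidence intervals come from a nonparametric case-resampling bootstrap
with bias-corrected percentile bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import genotype_strings
from .genetics import code_dominant

#: Clinical CES-D cut-off used to center the mediator.
CESD_CENTER = 16.0

EQ1_TERMS = ["a0", "a1", "a2", "a3"]
EQ2_TERMS = ["b0", "b1", "b2", "b3", "b4", "b5"]


@dataclass
class PathCoefficients:
    """Estimated coefficients of the two path equations."""

    a: dict[str, float]
    b: dict[str, float]
    r2_eq1: float = float("nan")
    r2_eq2: float = float("nan")
    n: int = 0
    mediator: str = "postnatal"

    def __post_init__(self):
        missing = [k for k in EQ1_TERMS if k not in self.a] + [k for k in EQ2_TERMS if k not in self.b]
        if missing:
            raise ValueError(f"path coefficients missing terms: {missing}")


@dataclass
class SimpleEffects:
    """Simple effects at one moderator level (or their group difference)."""

    first: float
    second: float
    direct: float
    indirect: float
    total: float
    z: int | None = None


@dataclass
class BootstrapCi:
    estimate: float
    lower: float
    upper: float
    n_boot: int
    z0: float
    ci_level: float
    seed: int | None = None
    n_failed: int = 0


def _prepare(cohort: pd.DataFrame, genotype: str, mediator: str, outcome: str) -> pd.DataFrame:
    med_col = {"postnatal": "cesd_postnatal", "prenatal": "cesd_prenatal"}.get(mediator)
    if med_col is None:
        raise ValueError(f"mediator must be 'postnatal' or 'prenatal', got {mediator!r}")
    g = cohort[genotype]
    if g.dtype == object or (g.notna().any() and isinstance(g.dropna().iloc[0], str)):
        z = code_dominant(g, genotype_strings(genotype)[0], genotype)
    else:
        z = code_dominant(g, 0)
    df = pd.DataFrame({
        "x": cohort["care_quality"].astype(float),
        "m": cohort[med_col].astype(float) - CESD_CENTER,
        "y": cohort[outcome].astype(float),
        "z": z.astype(float),
    })
    return df.dropna()


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, r2


def _designs(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x, m, y, z = (df[c].to_numpy() for c in ["x", "m", "y", "z"])
    X1 = np.column_stack([np.ones_like(x), x, z, x * z])
    X2 = np.column_stack([np.ones_like(x), x, m, z, x * z, m * z])
    return X1, m, X2, y


def fit_path_model(
    cohort: pd.DataFrame,
    genotype: str = "rs2740210",
    mediator: str = "postnatal",
    outcome: str = "instrumental_sqrt",
) -> PathCoefficients:
    """Fit both path equations by OLS on listwise-complete data.

    The mediator column is chosen by *mediator* ('postnatal' for the
    primary model, 'prenatal' for the sensitivity variant) and centered
    at 16.  Genotype groups with fewer than 10 subjects warn; fewer than
    3 is fatal.
    """
    df = _prepare(cohort, genotype, mediator, outcome)
    for level in (0.0, 1.0):
        size = int((df["z"] == level).sum())
        if size < 3:
            raise ValueError(f"genotype group z={int(level)} has only {size} subjects")
        if size < 10:
            warnings.warn(f"genotype group z={int(level)} has only {size} subjects", stacklevel=2)
    X1, m, X2, y = _designs(df)
    a, r2_1 = _ols(X1, m)
    b, r2_2 = _ols(X2, y)
    return PathCoefficients(
        a=dict(zip(EQ1_TERMS, map(float, a))),
        b=dict(zip(EQ2_TERMS, map(float, b))),
        r2_eq1=r2_1,
        r2_eq2=r2_2,
        n=len(df),
        mediator=mediator,
    )


def simple_effects(p: PathCoefficients, z: int) -> SimpleEffects:
    """Closed-form simple effects at moderator level *z* (0 or 1)."""
    if z not in (0, 1):
        raise ValueError("moderator level z must be 0 or 1")
    first = p.a["a1"] + p.a["a3"] * z
    second = p.b["b2"] + p.b["b5"] * z
    direct = p.b["b1"] + p.b["b4"] * z
    indirect = first * second
    return SimpleEffects(first=first, second=second, direct=direct,
                         indirect=indirect, total=direct + indirect, z=z)


def effect_differences(e0: SimpleEffects, e1: SimpleEffects) -> SimpleEffects:
    """Carrier-minus-reference contrast of simple effects (level 1 - level 0).

    The first-stage difference equals the X x Z interaction (a3) and the
    direct difference equals b4 identically.
    """
    return SimpleEffects(
        first=e1.first - e0.first,
        second=e1.second - e0.second,
        direct=e1.direct - e0.direct,
        indirect=e1.indirect - e0.indirect,
        total=e1.total - e0.total,
        z=None,
    )


def simple_effects_table(p: PathCoefficients) -> pd.DataFrame:
    """Per-group simple effects plus the differences row."""
    e0, e1 = simple_effects(p, 0), simple_effects(p, 1)
    diff = effect_differences(e0, e1)
    rows = [
        {"group": "reference (z=0)", **_row(e0)},
        {"group": "carrier (z=1)", **_row(e1)},
        {"group": "difference", **_row(diff)},
    ]
    return pd.DataFrame(rows)


def _row(e: SimpleEffects) -> dict[str, float]:
    return {"first": e.first, "second": e.second, "direct": e.direct,
            "indirect": e.indirect, "total": e.total}


def _batched_fit(
    df: pd.DataFrame, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Refit both equations on each resample (rows of *idx*) at once.

    Returns ``(a_coefs, b_coefs, bad)`` where *bad* flags resamples with
    an ill-conditioned design or a degenerate genotype group.
    """
    X1, m, X2, y = _designs(df)
    X1b, X2b = X1[idx], X2[idx]
    mb, yb = m[idx], y[idx]
    zb = df["z"].to_numpy()[idx]
    n_carrier = zb.sum(axis=1)
    bad = (n_carrier < 3) | (n_carrier > idx.shape[1] - 3)

    def solve(Xb, yb):
        xtx = np.einsum("bni,bnj->bij", Xb, Xb)
        xty = np.einsum("bni,bn->bi", Xb, yb)
        good = np.linalg.cond(xtx) < 1e10
        beta = np.full((Xb.shape[0], Xb.shape[2]), np.nan)
        if good.any():
            beta[good] = np.linalg.solve(xtx[good], xty[good][..., None])[..., 0]
        return beta, ~good

    a_coefs, bad1 = solve(X1b, mb)
    b_coefs, bad2 = solve(X2b, yb)
    return a_coefs, b_coefs, bad | bad1 | bad2


def bootstrap_path_models(
    cohort_or_df: pd.DataFrame,
    genotype: str = "rs2740210",
    mediator: str = "postnatal",
    outcome: str = "instrumental_sqrt",
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
    max_fail_frac: float = 0.10,
) -> tuple[PathCoefficients, np.ndarray, np.ndarray, int]:
    """Case-resampling bootstrap of both path equations.

    Returns ``(point_fit, a_draws, b_draws, n_failed)`` where the draw
    arrays are (n_boot x 4) and (n_boot x 6) coefficient matrices.
    Resamples whose refit fails (degenerate genotype group or singular
    design) are redrawn; more than *max_fail_frac* failures aborts.
    """
    if n_boot < 200:
        raise ValueError("need n_boot >= 200 for stable bias-corrected intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if {"x", "m", "y", "z"} <= set(cohort_or_df.columns):
        df = cohort_or_df[["x", "m", "y", "z"]].dropna()
    else:
        df = _prepare(cohort_or_df, genotype, mediator, outcome)
    point = fit_path_model_from_xmyz(df, mediator=mediator)
    n = len(df)

    a_draws = np.full((n_boot, 4), np.nan)
    b_draws = np.full((n_boot, 6), np.nan)
    pending = np.arange(n_boot)
    n_failed = 0
    while pending.size:
        idx = rng.integers(n, size=(pending.size, n))
        a_c, b_c, bad = _batched_fit(df, idx)
        ok = ~bad
        a_draws[pending[ok]] = a_c[ok]
        b_draws[pending[ok]] = b_c[ok]
        n_failed += int(bad.sum())
        if n_failed > max_fail_frac * n_boot:
            raise RuntimeError(
                f"{n_failed} failed bootstrap resamples (> {max_fail_frac:.0%} of {n_boot}); "
                "genotype groups too small or design degenerate"
            )
        pending = pending[bad]
    return point, a_draws, b_draws, n_failed


def fit_path_model_from_xmyz(df: pd.DataFrame, mediator: str = "postnatal") -> PathCoefficients:
    """Fit the path equations on a prepared (x, m, y, z) frame."""
    X1, m, X2, y = _designs(df)
    a, r2_1 = _ols(X1, m)
    b, r2_2 = _ols(X2, y)
    return PathCoefficients(
        a=dict(zip(EQ1_TERMS, map(float, a))),
        b=dict(zip(EQ2_TERMS, map(float, b))),
        r2_eq1=r2_1, r2_eq2=r2_2, n=len(df), mediator=mediator,
    )


def _bc_interval(boot: np.ndarray, point: float, ci_level: float) -> tuple[float, float, float]:
    """Bias-corrected percentile interval.  z0 is the normal quantile of
    the fraction of bootstrap draws strictly below the point estimate."""
    if np.allclose(boot, point):
        return point, point, 0.0
    frac = float((boot < point).mean())
    frac = min(max(frac, 0.5 / len(boot)), 1 - 0.5 / len(boot))
    z0 = float(stats.norm.ppf(frac))
    alpha = (1 - ci_level) / 2
    z_lo, z_hi = stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)
    p_lo = float(stats.norm.cdf(2 * z0 + z_lo))
    p_hi = float(stats.norm.cdf(2 * z0 + z_hi))
    lo, hi = np.quantile(boot, [p_lo, p_hi])
    return float(lo), float(hi), z0


def bc_bootstrap(
    cohort: pd.DataFrame,
    statistic,
    genotype: str = "rs2740210",
    mediator: str = "postnatal",
    outcome: str = "instrumental_sqrt",
    n_boot: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> BootstrapCi:
    """Bias-corrected bootstrap CI for any scalar path-model statistic.

    *statistic* maps a :class:`PathCoefficients` to a float (e.g.
    ``lambda p: simple_effects(p, 1).indirect``).  Subjects are resampled
    with replacement and both equations refitted per resample.
    """
    point_fit, a_draws, b_draws, n_failed = bootstrap_path_models(
        cohort, genotype=genotype, mediator=mediator, outcome=outcome,
        n_boot=n_boot, seed=seed,
    )
    point = float(statistic(point_fit))
    boot = np.array([
        statistic(PathCoefficients(a=dict(zip(EQ1_TERMS, a)), b=dict(zip(EQ2_TERMS, b))))
        for a, b in zip(a_draws, b_draws)
    ])
    lo, hi, z0 = _bc_interval(boot, point, ci_level)
    return BootstrapCi(estimate=point, lower=lo, upper=hi, n_boot=n_boot,
                       z0=z0, ci_level=ci_level, seed=seed, n_failed=n_failed)


#: Named extractors for every cell of the simple-effects table.
STATISTICS: dict[str, callable] = {}
for _z in (0, 1):
    for _name in ["first", "second", "direct", "indirect", "total"]:
        STATISTICS[f"{_name}_z{_z}"] = (
            lambda p, z=_z, name=_name: getattr(simple_effects(p, z), name)
        )
for _name in ["first", "second", "direct", "indirect", "total"]:
    STATISTICS[f"{_name}_diff"] = (
        lambda p, name=_name: getattr(
            effect_differences(simple_effects(p, 0), simple_effects(p, 1)), name
        )
    )


def bootstrap_effect_table(
    cohort: pd.DataFrame,
    genotype: str = "rs2740210",
    mediator: str = "postnatal",
    outcome: str = "instrumental_sqrt",
    n_boot: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Simple-effects table with BC bootstrap bounds for every cell,
    sharing one set of bootstrap resamples."""
    point_fit, a_draws, b_draws, _ = bootstrap_path_models(
        cohort, genotype=genotype, mediator=mediator, outcome=outcome,
        n_boot=n_boot, seed=seed,
    )
    rows = []
    for key, fn in STATISTICS.items():
        point = float(fn(point_fit))
        boot = np.array([
            fn(PathCoefficients(a=dict(zip(EQ1_TERMS, a)), b=dict(zip(EQ2_TERMS, b))))
            for a, b in zip(a_draws, b_draws)
        ])
        lo, hi, z0 = _bc_interval(boot, point, ci_level)
        rows.append({"statistic": key, "estimate": point, "ci_lower": lo,
                     "ci_upper": hi, "z0": z0})
    return pd.DataFrame(rows)
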