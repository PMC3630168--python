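"""Synthetic cohort generator.

Generates mother-infant cohorts with the statistical structure the
downstream analysis assumes: three biallelic SNPs in Hardy-Weinberg
equilibrium with configurable pairwise LD, a single latent early-care
factor driving six of nine questionnaire dimensions, a planted
genotype-moderated mediation structure (early care -> postnatal
depression -> instrumental care, every path moderated by a dominant-coded
genotype), positively skewed behavioral durations so the analysis-scale
transforms are exercised, correlated prenatal/postnatal mood scores, and
MCAR missingness at configurable per-class rates.

The outcome equations use Gamma-distributed draws whose mean equals the
(floored) linear predictor and whose standard deviation is constant at
``noise_sd``: outcomes are nonnegative and right-skewed, yet the
analysis-scale regression stays exactly linear in expectation, so planted
coefficients are recoverable without censoring bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    ADVERSITY_DIMS,
    GENOTYPE_COLS,
    LD_PAIR,
    LOCI,
    MISSING_CLASSES,
    QUESTIONNAIRE_DIMS,
    SESSION_SECONDS,
    counts_to_genotype,
    genotype_to_counts,
)

#: Coefficient names of the planted mediation / GxE structure.
#: a* : early care -> (centered) postnatal depression (first-stage equation)
#: b* : early care + depression -> sqrt-scale instrumental care (outcome equation)
EFFECT_KEYS = ("a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3", "b4", "b5")

_DEFAULT_EFFECTS = {
    "a0": 0.0, "a1": -7.98, "a2": -0.72, "a3": 5.62,
    "b0": 12.0, "b1": -3.77, "b2": 0.26, "b3": -0.26, "b4": 7.91, "b5": -0.11,
}

# Six of nine dimensions load on the latent care factor (|loading| =
# sqrt(0.6), giving a leading correlation-matrix eigenvalue near 4);
# sexual abuse and the two LHC dimensions default to pure noise.
_L = float(np.sqrt(0.6))
_DEFAULT_LOADINGS = {
    "ctq_physical_abuse": -_L,
    "ctq_emotional_abuse": -_L,
    "ctq_sexual_abuse": 0.0,
    "ctq_physical_neglect": -_L,
    "ctq_emotional_neglect": -_L,
    "pbi_maternal_care": _L,
    "pbi_overprotection": -_L,
    "lhc_caregiver_changes": 0.0,
    "lhc_residence_changes": 0.0,
}

# Display scale (mean, sd) per questionnaire dimension; correlations are
# unaffected, this only makes the TSV look like questionnaire scores.
_DIM_SCALE = {dim: (10.0, 3.0) for dim in QUESTIONNAIRE_DIMS}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reproduce the cohort structure the analysis was designed
    for: n=187 dyads, minor-allele frequencies 0.31/0.50/0.50, D'=0.79
    between the two OXT SNPs, path coefficients at the published
    path-model scale, residual sd 9, prenatal-postnatal depression rank
    correlation 0.60, and missing-data rates 14%/9%/14%/12% for
    behavior/parity/education/CES-D.
    """

    n_subjects: int = 187
    maf: dict[str, float] = field(
        default_factory=lambda: {"rs2740210": 0.31, "rs4813627": 0.50, "rs237885": 0.50}
    )
    ld_dprime: float = 0.79
    ld_pair: tuple[str, str] = LD_PAIR
    factor_loadings: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    noise_sd: float = 9.0
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    activity_effect: float = 2.8  # per-sd effect of infant activity on sqrt instrumental care
    prepost_depression_corr: float = 0.60
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"behavior": 0.14, "parity": 0.09, "education": 0.14, "cesd": 0.12}
    )
    seed: int = 0

    def __post_init__(self):
        for locus, p in self.maf.items():
            if locus not in LOCI:
                raise ValueError(f"unknown locus {locus!r}")
            if not 0.0 < p <= 0.5:
                raise ValueError(f"maf for {locus} must be in (0, 0.5], got {p}")
        if not 0.0 <= self.ld_dprime <= 1.0:
            raise ValueError(f"ld_dprime must be in [0, 1], got {self.ld_dprime}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        missing = [k for k in EFFECT_KEYS if k not in self.effect_sizes]
        if missing:
            raise ValueError(f"effect_sizes missing coefficients: {missing}")
        if not -1.0 <= self.prepost_depression_corr <= 1.0:
            raise ValueError("prepost_depression_corr must be in [-1, 1]")
        for cls, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {cls!r} must be in [0, 1), got {r}")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if len(set(self.factor_loadings) - set(QUESTIONNAIRE_DIMS)) or len(self.factor_loadings) != 9:
            raise ValueError("factor_loadings must give exactly the nine questionnaire dimensions")


def haplotype_frequencies(p1: float, p2: float, dprime: float) -> np.ndarray:
    """Four-haplotype distribution implied by two minor-allele frequencies
    and a (nonnegative-coupling) D'.

    Order: (minor,minor), (minor,major), (major,minor), (major,major).
    """
    d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    d = dprime * d_max
    h = np.array([
        p1 * p2 + d,
        p1 * (1 - p2) - d,
        (1 - p1) * p2 - d,
        (1 - p1) * (1 - p2) + d,
    ])
    if (h < -1e-12).any():
        raise ValueError("inconsistent (maf, ld_dprime) combination")
    return np.clip(h, 0.0, 1.0)


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject genotypes under random mating.

    The LD pair receives two haplotypes per subject from the
    four-haplotype distribution implied by ``(maf, ld_dprime)``; the
    remaining locus is an independent binomial(2, maf) draw.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    l1, l2 = config.ld_pair
    h = haplotype_frequencies(config.maf[l1], config.maf[l2], config.ld_dprime)
    hap_idx = rng.choice(4, size=(n, 2), p=h / h.sum())
    # haplotype index -> minor-allele indicator at each locus
    minor1 = (hap_idx < 2).sum(axis=1)          # haplotypes 0,1 carry minor at locus 1
    minor2 = (hap_idx % 2 == 0).sum(axis=1)     # haplotypes 0,2 carry minor at locus 2
    out = pd.DataFrame(index=pd.RangeIndex(n))
    out[l1] = counts_to_genotype(pd.Series(minor1, index=out.index), l1)
    out[l2] = counts_to_genotype(pd.Series(minor2, index=out.index), l2)
    for locus in GENOTYPE_COLS:
        if locus in (l1, l2):
            continue
        cnt = rng.binomial(2, config.maf[locus], size=n)
        out[locus] = counts_to_genotype(pd.Series(cnt, index=out.index), locus)
    return out[GENOTYPE_COLS]


def _gamma_mean_sd(rng: np.random.Generator, mean: np.ndarray, sd: float, floor: float = 0.5) -> np.ndarray:
    """Gamma draws with E[X] = max(mean, floor) and constant sd."""
    mu = np.maximum(mean, floor)
    shape = (mu / sd) ** 2
    scale = sd**2 / mu
    return rng.gamma(shape, scale)


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the full cohort table (no missingness) from genotypes.

    Returns ``(cohort, truth)`` where *truth* records the latent care
    factor and the realized analysis-scale linear predictors, for use in
    parameter-recovery checks.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(genotypes)
    e = config.effect_sizes

    care = rng.standard_normal(n)  # latent care-quality factor, higher = better care

    q = pd.DataFrame(index=genotypes.index)
    for dim in QUESTIONNAIRE_DIMS:
        lam = config.factor_loadings[dim]
        resid = np.sqrt(max(0.0, 1.0 - lam**2))
        z = lam * care + resid * rng.standard_normal(n)
        m, s = _DIM_SCALE[dim]
        q[dim] = m + s * z

    # dominant-coded moderator at the first LD locus (reference hom-major = 0)
    g = (genotype_to_counts(genotypes[config.ld_pair[0]], config.ld_pair[0]) > 0).astype(float).to_numpy()

    # first-stage equation: centered postnatal CES-D
    mu_m = 16.0 + e["a0"] + e["a1"] * care + e["a2"] * g + e["a3"] * care * g
    cesd_post = np.clip(np.round(_gamma_mean_sd(rng, mu_m, config.noise_sd)), 0, 60).astype(int)

    # prenatal CES-D sharing a latent rank correlation with postnatal
    rho_s = config.prepost_depression_corr
    rho_p = float(np.clip(2.0 * np.sin(np.pi * rho_s / 6.0), -1.0, 1.0))
    z_post = (cesd_post - cesd_post.mean()) / max(cesd_post.std(), 1e-12)
    z_pre = rho_p * z_post + np.sqrt(max(0.0, 1 - rho_p**2)) * rng.standard_normal(n)
    cesd_pre = np.clip(np.round(18.0 + 8.0 * z_pre), 0, 60).astype(int)

    # infant activity components (right-skewed durations, seconds)
    reaching = np.exp(rng.normal(3.0, 0.8, n))
    smiling = np.exp(rng.normal(3.2, 0.8, n))
    crying = np.exp(rng.normal(2.5, 1.0, n))
    total = reaching + smiling + crying
    over = total > SESSION_SECONDS
    if over.any():  # rescale rare over-budget subjects into the session window
        f = (SESSION_SECONDS * 0.99) / total[over]
        reaching[over] *= f
        smiling[over] *= f
        crying[over] *= f
        total = reaching + smiling + crying
    z_act = (total - total.mean()) / max(total.std(), 1e-12)

    # outcome equation: sqrt-scale instrumental care
    m_c = cesd_post - 16.0
    mu_y = (
        e["b0"] + e["b1"] * care + e["b2"] * m_c + e["b3"] * g
        + e["b4"] * care * g + e["b5"] * m_c * g
        + config.activity_effect * z_act
    )
    sqrt_instr = _gamma_mean_sd(rng, mu_y, config.noise_sd)
    instrumental = np.minimum(sqrt_instr**2, SESSION_SECONDS)

    # behaviors with no planted genetic structure
    orienting = np.round(np.exp(rng.normal(2.1, 0.7, n))).astype(int)
    vocalizing = np.clip(rng.normal(420.0, 150.0, n), 1.0, SESSION_SECONDS)
    subscales = np.clip(np.round(rng.normal(6.0, 1.5, (n, 4))), 1, 9)
    sensitivity = subscales.sum(axis=1).astype(int)

    cohort = pd.DataFrame({"subject_id": [f"S{i + 1:04d}" for i in range(n)]}, index=genotypes.index)
    for locus in GENOTYPE_COLS:
        cohort[locus] = genotypes[locus]
    for dim in QUESTIONNAIRE_DIMS:
        cohort[dim] = q[dim].round(3)
    cohort["cesd_prenatal"] = pd.array(cesd_pre, dtype="Int64")
    cohort["cesd_postnatal"] = pd.array(cesd_post, dtype="Int64")
    cohort["age"] = np.clip(rng.normal(31.2, 4.9, n), 18, 45).round(1)
    cohort["education"] = pd.array(np.clip(np.round(rng.normal(4.81, 2.3, n)), 0, 10).astype(int), dtype="Int64")
    cohort["parity"] = pd.array(rng.binomial(1, 0.5, n), dtype="Int64")
    cohort["infant_gender"] = pd.array(rng.binomial(1, 0.5, n), dtype="Int64")
    cohort["orienting_away_freq"] = pd.array(orienting, dtype="Int64")
    cohort["vocalizing_dur"] = np.round(vocalizing, 1)
    cohort["instrumental_dur"] = np.round(instrumental, 1)
    cohort["sensitivity"] = pd.array(sensitivity, dtype="Int64")
    cohort["reaching_dur"] = np.round(reaching, 1)
    cohort["smiling_dur"] = np.round(smiling, 1)
    cohort["crying_dur"] = np.round(crying, 1)

    truth = {
        "care_latent": pd.Series(care, index=cohort.index),
        "genotype_dominant": pd.Series(g, index=cohort.index),
        "mu_mediator_centered": pd.Series(mu_m - 16.0, index=cohort.index),
        "mu_outcome_sqrt": pd.Series(mu_y, index=cohort.index),
        "config": config,
    }
    return cohort, truth


def inject_missingness(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Delete values completely at random at the configured per-class rates.

    Exactly ``ceil(rate * n)`` entries per column are blanked (rows drawn
    independently per column).  Genotype columns are only touched if a
    ``"genotype"`` rate is explicitly configured.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    out = cohort.copy()
    n = len(out)
    classes = dict(MISSING_CLASSES)
    if "genotype" in config.missing_rates:
        classes["genotype"] = GENOTYPE_COLS
    for cls, cols in classes.items():
        rate = config.missing_rates.get(cls, 0.0)
        if rate == 0.0:
            continue
        n_miss = int(np.ceil(rate * n))
        for col in cols:
            rows = rng.choice(n, size=n_miss, replace=False)
            sentinel = np.nan if out[col].dtype.kind == "f" else pd.NA
            out.iloc[rows, out.columns.get_loc(col)] = sentinel
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Full generator: genotypes -> phenotypes -> missingness.

    One seed drives three independent substreams, so the same config and
    seed always yield a byte-identical table.
    """
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_pheno, r_miss = (np.random.default_rng(s) for s in ss.spawn(3))
    genotypes = simulate_genotypes(config, rng=r_geno)
    complete, truth = simulate_phenotypes(config, genotypes, rng=r_pheno)
    observed = inject_missingness(complete, config, rng=r_miss)
    truth["complete_cohort"] = complete
    return observed, truth


def write_metadata(config: SimulationConfig, path) -> None:
    """Echo the generating configuration (including seed) as YAML."""
    cfg = asdict(config)
    cfg["ld_pair"] = list(cfg["ld_pair"])
    with open(path, "w") as fh:
        yaml.safe_dump({"simulation": cfg}, fh, sort_keys=False)
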