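"""End-to-end orchestration: simulate/load -> genotype QC -> care-quality
factor -> multiple imputation -> G x E regressions -> moderated mediation.

One global seed is split deterministically into per-stage substreams, so
e.g. changing the bootstrap replicate count cannot perturb the
imputation results.  Every stage writes a TSV report into the output
directory, plus a machine-readable ``results.json`` and a run log.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import carefactor, genetics, impute, mediation, regression
from .cohort import (
    CESD_COLS,
    LD_PAIR,
    QUESTIONNAIRE_DIMS,
    genotype_to_counts,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from .simulate import SimulationConfig, simulate_cohort, write_metadata

logger = logging.getLogger("gxemed")

#: Substream labels, in a fixed order, spawned from the global seed.
_STAGES = ["simulate", "factor_impute", "multiple_imputation", "bootstrap"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one input mode: either ``simulation`` is used (cohort_path
    None) or an existing cohort TSV is analyzed.
    """

    output_dir: str | Path = "gxemed_out"
    cohort_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    m_imputations: int = 10
    n_boot: int = 1000
    mediator: str = "postnatal"
    genotype: str = "rs2740210"
    outcomes: list[str] = field(default_factory=lambda: ["instrumental_sqrt", "cesd_postnatal"])

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[_STAGES.index(stage)]
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns the results dictionary that is also written to
    ``results.json``.  Any stage failure raises with the stage name.
    """
    if config.cohort_path is not None and config.simulation is not None:
        raise RuntimeError("pipeline failed at stage 'input': exactly one input mode: "
                           "cohort_path or simulation")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {"seed": config.seed}
    t0 = time.time()

    try:
        stage = "input"
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
            logger.info("loaded cohort %s (n=%d)", config.cohort_path, len(cohort))
        else:
            sim = config.simulation or SimulationConfig(seed=config.stage_seed("simulate"))
            cohort, _ = simulate_cohort(sim)
            write_cohort(cohort, out / "cohort.tsv")
            write_metadata(sim, out / "cohort_meta.yaml")
            logger.info("simulated cohort n=%d seed=%d", len(cohort), sim.seed)
        report = validate_cohort(cohort)
        if not report.ok:
            raise ValueError(f"cohort validation failed: {report.violations[:5]}")

        stage = "genotype_qc"
        qc = genetics.qc_report(cohort)
        qc.to_csv(out / "table_qc_genotypes.tsv", sep="\t", index=False)
        g1 = genotype_to_counts(cohort[LD_PAIR[0]], LD_PAIR[0])
        g2 = genotype_to_counts(cohort[LD_PAIR[1]], LD_PAIR[1])
        haps = genetics.em_haplotype_freqs(g1, g2)
        ld = genetics.ld_stats(haps)
        results["qc"] = {
            "loci": qc.to_dict(orient="records"),
            "ld": {"d_prime": ld.d_prime, "r_squared": ld.r_squared,
                   "chi_square": ld.chi_square, "p_value": ld.p_value},
        }
        logger.info("LD %s-%s: D'=%.3f chi2=%.1f", *LD_PAIR, ld.d_prime, ld.chi_square)

        stage = "care_quality_factor"
        rng_factor = np.random.default_rng(config.stage_seed("factor_impute"))
        factor = carefactor.extract_care_quality(cohort[QUESTIONNAIRE_DIMS])
        scores, imputed = carefactor.stochastic_regression_impute(
            factor.scores, cohort[QUESTIONNAIRE_DIMS], rng=rng_factor
        )
        cohort = cohort.copy()
        cohort["care_quality"] = scores
        factor.loadings.to_csv(out / "factor_loadings.tsv", sep="\t")
        pd.DataFrame({
            "subject_id": cohort["subject_id"],
            "care_quality": scores.round(4),
            "imputed": imputed,
        }).to_csv(out / "care_quality_scores.tsv", sep="\t", index=False)
        results["care_factor"] = {
            "leading_eigenvalue": float(factor.eigenvalues[0]),
            "n_imputed_scores": int(imputed.sum()),
        }
        logger.info("care factor eigenvalue=%.2f imputed=%d", factor.eigenvalues[0], imputed.sum())

        stage = "transforms"
        cohort = regression.transform_outcomes(cohort)
        kept = regression.prevalence_filter(cohort)
        results["prevalence_filter"] = kept

        stage = "descriptives"
        rho, pval = regression.descriptive_correlations(
            cohort,
            ["orienting_away_freq", "vocalizing_dur", "instrumental_dur", "sensitivity",
             "age", "education", "cesd_prenatal", "cesd_postnatal", "infant_activity"],
        )
        rho.round(3).to_csv(out / "table_correlations.tsv", sep="\t")

        stage = "multiple_imputation"
        mi_cfg = impute.ImputationConfig(
            m=config.m_imputations, seed=config.stage_seed("multiple_imputation")
        )
        impute_vars = [
            "orienting_log", "instrumental_sqrt", "vocalizing_dur", "sensitivity",
            "infant_activity", "education", "parity", "cesd_postnatal",
        ]
        predictors = ["care_quality", "age"]
        datasets = impute.pmm_impute(cohort, impute_vars, predictors, mi_cfg)
        logger.info("multiple imputation: m=%d", mi_cfg.m)

        stage = "gxe_regression"
        results["gxe"] = {}
        for outcome in config.outcomes:
            spec = regression.ModelSpec(outcome=outcome, genotype=config.genotype)
            full = regression.fit_model(spec, datasets)
            reduced, trace = regression.reduce_model(spec, datasets)
            tab = pd.DataFrame({
                "term": full.params.index,
                "full_beta": full.params.round(3).values,
                "full_t": full.tvalues.round(2).values,
            }).merge(
                pd.DataFrame({
                    "term": reduced.params.index,
                    "reduced_beta": reduced.params.round(3).values,
                    "reduced_t": reduced.tvalues.round(2).values,
                }),
                on="term", how="left",
            )
            tab.to_csv(out / f"table_gxe_{outcome}.tsv", sep="\t", index=False)
            results["gxe"][outcome] = {
                "gxe_beta_full": float(full.params["GxE"]),
                "gxe_beta_reduced": float(reduced.params["GxE"]),
                "gxe_p_reduced": float(reduced.pvalues["GxE"]),
                "lr_chisq_full": full.lr_chisq,
                "r2_adj_full": full.rsquared_adj,
                "removed": [t for t, _ in trace.removed],
            }
            logger.info("GxE %s: beta=%.2f p=%.3g", outcome,
                        reduced.params["GxE"], reduced.pvalues["GxE"])

        stage = "moderated_mediation"
        paths = mediation.fit_path_model(cohort, genotype=config.genotype, mediator=config.mediator)
        table5 = pd.DataFrame([{**paths.a, **paths.b,
                                "r2_eq1": paths.r2_eq1, "r2_eq2": paths.r2_eq2, "n": paths.n}])
        table5.round(3).to_csv(out / "table_path_coefficients.tsv", sep="\t", index=False)
        effects = mediation.simple_effects_table(paths)
        effects.round(3).to_csv(out / "table_simple_effects.tsv", sep="\t", index=False)
        ci_table = mediation.bootstrap_effect_table(
            cohort, genotype=config.genotype, mediator=config.mediator,
            n_boot=config.n_boot, seed=config.stage_seed("bootstrap"),
        )
        ci_table.round(3).to_csv(out / "table_bootstrap_cis.tsv", sep="\t", index=False)
        results["mediation"] = {
            "a": paths.a, "b": paths.b, "n": paths.n,
            "simple_effects": effects.to_dict(orient="records"),
            "bootstrap": ci_table.to_dict(orient="records"),
        }
        logger.info("mediation n=%d indirect(z=1)=%.3f", paths.n,
                    mediation.simple_effects(paths, 1).indirect)
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    results["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results


__all__ = ["RunConfig", "run_pipeline", "validate_cohort"]
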