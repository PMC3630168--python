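"""Cohort table schema, TSV round-trip, and validation.

A cohort is a plain :class:`pandas.DataFrame`, one row per mother-infant
dyad, with SNP genotypes stored as unphased allele-pair strings ("A/C"),
questionnaire dimension scores as reals, mood scores as integers on the
CES-D 0-60 scale, and behavioral outcomes as counts or durations from a
20-minute (1200 s) coded interaction.  Missing values use a single
sentinel ("NA" on disk, pandas NA in memory) -- never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

#: Coding session length in seconds (20-minute free-play window).
SESSION_SECONDS = 1200.0

#: Candidate loci: label -> (major allele, minor allele).  The two OXT
#: promoter/flanking SNPs form the linkage-disequilibrium pair; the OXTR
#: intronic SNP is treated as independent.
LOCI: dict[str, tuple[str, str]] = {
    "rs2740210": ("C", "A"),
    "rs4813627": ("G", "A"),
    "rs237885": ("T", "G"),
}

#: The locus pair modelled (and estimated) as being in LD.
LD_PAIR: tuple[str, str] = ("rs2740210", "rs4813627")

GENOTYPE_COLS = list(LOCI)

#: Nine early-experience questionnaire dimensions (CTQ / PBI / LHC).
QUESTIONNAIRE_DIMS = [
    "ctq_physical_abuse",
    "ctq_emotional_abuse",
    "ctq_sexual_abuse",
    "ctq_physical_neglect",
    "ctq_emotional_neglect",
    "pbi_maternal_care",
    "pbi_overprotection",
    "lhc_caregiver_changes",
    "lhc_residence_changes",
]

#: Dimensions whose high scores indicate adversity; the composite
#: care-quality score is oriented to correlate negatively with these.
ADVERSITY_DIMS = [
    "ctq_physical_abuse",
    "ctq_emotional_abuse",
    "ctq_sexual_abuse",
    "ctq_physical_neglect",
    "ctq_emotional_neglect",
]

CESD_COLS = ["cesd_prenatal", "cesd_postnatal"]

#: Maternal / infant behavioral outcome and covariate columns coded from
#: video (all subject to the 14% behavioral missing-data class).
BEHAVIOR_COLS = [
    "orienting_away_freq",
    "vocalizing_dur",
    "instrumental_dur",
    "sensitivity",
    "reaching_dur",
    "smiling_dur",
    "crying_dur",
]

#: Missing-data classes -> columns; rates configured per class.
MISSING_CLASSES: dict[str, list[str]] = {
    "behavior": BEHAVIOR_COLS,
    "parity": ["parity"],
    "education": ["education"],
    "cesd": CESD_COLS,
}

COVARIATE_COLS = ["age", "education", "parity", "infant_gender"]

INT_COLS = [
    "cesd_prenatal",
    "cesd_postnatal",
    "education",
    "parity",
    "infant_gender",
    "orienting_away_freq",
    "sensitivity",
]

ALL_COLS = (
    ["subject_id"]
    + GENOTYPE_COLS
    + QUESTIONNAIRE_DIMS
    + CESD_COLS
    + ["age"]
    + ["education", "parity", "infant_gender"]
    + BEHAVIOR_COLS
)


def genotype_strings(locus: str) -> tuple[str, str, str]:
    """Return the (hom-major, het, hom-minor) genotype strings for *locus*.

    Alleles within a genotype are written in alphabetical order, matching
    the usual unphased convention ("A/C", "A/G", "G/T").
    """
    major, minor = LOCI[locus]
    het = "/".join(sorted([major, minor]))
    return f"{major}/{major}", het, f"{minor}/{minor}"


def counts_to_genotype(counts: pd.Series, locus: str) -> pd.Series:
    """Map minor-allele counts (0/1/2, NA allowed) to genotype strings."""
    hom_major, het, hom_minor = genotype_strings(locus)
    mapping = {0: hom_major, 1: het, 2: hom_minor}
    return counts.map(lambda c: mapping[int(c)] if pd.notna(c) else pd.NA)


def genotype_to_counts(geno: pd.Series, locus: str) -> pd.Series:
    """Map genotype strings to minor-allele counts (nullable Int64).

    Raises ``ValueError`` naming the offending string if a genotype uses
    an allele symbol foreign to *locus*.
    """
    _, minor = LOCI[locus]
    valid = set(genotype_strings(locus))
    out = []
    for v in geno:
        if pd.isna(v):
            out.append(pd.NA)
            continue
        if v not in valid:
            raise ValueError(f"unknown genotype {v!r} at locus {locus}")
        out.append(v.count(minor))
    return pd.Series(out, index=geno.index, dtype="Int64")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as TSV with ``NA`` missing sentinels."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV (or comma-separated) table written by :func:`write_cohort`."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"], keep_default_na=True)
    for col in INT_COLS:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


@dataclass
class ValidationReport:
    """Per-column diagnostics from :func:`validate_cohort`."""

    n_subjects: int
    violations: list[str] = field(default_factory=list)
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(cohort) -> ValidationReport:
    """Check column presence, value ranges, and sentinel consistency.

    Accepts a DataFrame or a path to a TSV/CSV file.  Range rules: CES-D
    scores in [0, 60]; durations in [0, 1200] s; genotypes drawn from the
    locus allele symbols; sensitivity (four 1-9 subscales summed) in
    [4, 36]; no duplicated subject ids.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = read_cohort(cohort)
    report = ValidationReport(n_subjects=len(cohort))

    for col in ALL_COLS:
        if col not in cohort.columns:
            report.violations.append(f"missing column: {col}")
    if report.violations:
        return report

    if cohort["subject_id"].duplicated().any():
        dupes = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        report.violations.append(f"duplicated subject_id: {dupes}")

    for col in cohort.columns:
        report.missing_counts[col] = int(cohort[col].isna().sum())

    def _check_range(col, lo, hi):
        vals = cohort[col].dropna()
        bad = vals[(vals < lo) | (vals > hi)]
        for idx, v in bad.items():
            report.violations.append(
                f"{col}: value {v} outside [{lo}, {hi}] at row {idx} "
                f"(subject {cohort.at[idx, 'subject_id']})"
            )

    for col in CESD_COLS:
        _check_range(col, 0, 60)
    for col in ["vocalizing_dur", "instrumental_dur", "reaching_dur", "smiling_dur", "crying_dur"]:
        _check_range(col, 0.0, SESSION_SECONDS)
    _check_range("sensitivity", 4, 36)
    _check_range("orienting_away_freq", 0, math.inf)
    _check_range("education", 0, 10)
    for col in ["parity", "infant_gender"]:
        _check_range(col, 0, 1)

    for locus in GENOTYPE_COLS:
        valid = set(genotype_strings(locus))
        vals = cohort[locus].dropna()
        bad = vals[~vals.isin(valid)]
        for idx, v in bad.items():
            report.violations.append(f"{locus}: invalid genotype {v!r} at row {idx}")

    return report
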