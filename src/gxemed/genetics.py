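"""Genotype QC: allele frequencies, Hardy-Weinberg tests, EM haplotype
frequency estimation, linkage-disequilibrium statistics, and dominant
recoding.

All functions operate on minor-allele-count vectors (0/1/2, NaN for a
failed call) or on :class:`SnpGenotypeCounts` summaries; helpers convert
from "A/C"-style genotype strings.  Missing genotypes are removed
pairwise for two-locus statistics, matching per-SNP genotyping rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LOCI, genotype_to_counts


@dataclass
class SnpGenotypeCounts:
    """Genotype counts for one biallelic locus, minor-allele oriented."""

    locus: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int
    call_rate: float = 1.0
    major_allele: str = ""
    minor_allele: str = ""

    @property
    def n(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor


@dataclass
class HweResult:
    chi_square: float
    df: int
    p_value: float
    monomorphic: bool = False


@dataclass
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies.

    ``p_AB`` is the frequency of the minor/minor haplotype, ``p_Ab``
    minor/major, ``p_aB`` major/minor, ``p_ab`` major/major.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    log_likelihood: float
    n_iterations: int
    n_subjects: int
    non_identifiable: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


@dataclass
class LdStats:
    D: float
    d_prime: float
    r_squared: float
    chi_square: float
    p_value: float


def count_genotypes(counts_or_strings: pd.Series, locus: str = "") -> SnpGenotypeCounts:
    """Tabulate a genotype vector into :class:`SnpGenotypeCounts`.

    Accepts minor-allele counts (0/1/2 with missing) or genotype strings
    for a known locus.
    """
    s = pd.Series(counts_or_strings)
    major = minor = ""
    if s.dropna().map(lambda v: isinstance(v, str)).any():
        if locus not in LOCI:
            raise ValueError(f"locus label required to parse genotype strings, got {locus!r}")
        major, minor = LOCI[locus]
        s = genotype_to_counts(s, locus)
    n_total = len(s)
    obs = s.dropna().astype(int)
    if n_total == 0 or len(obs) == 0:
        raise ValueError(f"no genotyped subjects for locus {locus!r}")
    return SnpGenotypeCounts(
        locus=locus,
        n_hom_major=int((obs == 0).sum()),
        n_het=int((obs == 1).sum()),
        n_hom_minor=int((obs == 2).sum()),
        call_rate=len(obs) / n_total,
        major_allele=major,
        minor_allele=minor,
    )


def allele_frequencies(counts: SnpGenotypeCounts) -> tuple[float, str]:
    """Minor-allele frequency and the allele it belongs to.

    The orientation is recomputed from the data: if the nominal minor
    allele turns out to be the more common one, the reported frequency is
    re-oriented (and the returned label says which allele it is).
    """
    if counts.n == 0:
        raise ValueError(f"zero genotyped subjects at locus {counts.locus!r}")
    p_minor = (counts.n_het + 2 * counts.n_hom_minor) / (2 * counts.n)
    label = counts.minor_allele
    if p_minor > 0.5:
        p_minor = 1.0 - p_minor
        label = counts.major_allele
    return p_minor, label


def hwe_test(counts: SnpGenotypeCounts) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected genotype counts use allele frequencies estimated from the
    same sample; no continuity correction.  A monomorphic locus returns
    chi-square 0, p 1, flagged.
    """
    n = counts.n
    if n == 0:
        raise ValueError("zero genotyped subjects")
    p = (counts.n_het + 2 * counts.n_hom_minor) / (2 * n)
    if p in (0.0, 1.0):
        warnings.warn(f"monomorphic locus {counts.locus!r}: HWE test undefined", stacklevel=2)
        return HweResult(chi_square=0.0, df=1, p_value=1.0, monomorphic=True)
    q = 1.0 - p
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array([counts.n_hom_major, counts.n_het, counts.n_hom_minor], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi_square=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1)))


def hwe_exact_test(counts: SnpGenotypeCounts) -> float:
    """Exact HWE p-value (sum of heterozygote-count probabilities no more
    likely than the observed configuration, conditional on allele counts)."""
    n_ab = counts.n_het
    n_a = 2 * counts.n_hom_minor + counts.n_het  # minor allele count
    n = counts.n
    probs = {}
    parity = n_a % 2
    for het in range(parity, min(n_a, 2 * n - n_a) + 1, 2):
        hom_minor = (n_a - het) // 2
        hom_major = n - het - hom_minor
        if hom_major < 0:
            continue
        logp = (
            _lfact(n) - _lfact(hom_major) - _lfact(het) - _lfact(hom_minor)
            + het * np.log(2.0) + _lfact(n_a) + _lfact(2 * n - n_a) - _lfact(2 * n)
        )
        probs[het] = np.exp(logp)
    p_obs = probs[n_ab]
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))))


def _lfact(k: int) -> float:
    from scipy.special import gammaln

    return float(gammaln(k + 1))


def _loglik(h: np.ndarray, counts: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under
    haplotype frequencies ``h`` (AB, Ab, aB, ab) and random mating."""
    hAB, hAb, haB, hab = np.maximum(h, 1e-300)
    # P(genotype pair) for minor-allele counts (g1, g2); rows g1, cols g2
    p = np.empty((3, 3))
    p[2, 2] = hAB**2
    p[2, 1] = 2 * hAB * hAb
    p[2, 0] = hAb**2
    p[1, 2] = 2 * hAB * haB
    p[1, 1] = 2 * (hAB * hab + hAb * haB)
    p[1, 0] = 2 * hAb * hab
    p[0, 2] = haB**2
    p[0, 1] = 2 * haB * hab
    p[0, 0] = hab**2
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(p, 1e-300))
    return float((counts * logp).sum())


def _genotype_table(g1, g2) -> tuple[np.ndarray, int]:
    g1 = pd.Series(g1).astype("Float64")
    g2 = pd.Series(g2).reset_index(drop=True).astype("Float64")
    g1 = g1.reset_index(drop=True)
    keep = g1.notna() & g2.notna()
    a = g1[keep].astype(int).to_numpy()
    b = g2[keep].astype(int).to_numpy()
    table = np.zeros((3, 3))
    for i, j in zip(a, b):
        table[i, j] += 1
    return table, int(keep.sum())


def em_haplotype_freqs(
    g1,
    g2,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """Two-locus haplotype frequencies by EM over unphased genotypes.

    Subjects missing either genotype are excluded pairwise.  Double
    heterozygotes are split between the cis (AB/ab) and trans (Ab/aB)
    phase proportionally to current haplotype frequencies; every other
    genotype configuration contributes unambiguous gametes.  Iteration
    stops when the largest frequency change falls below *tol*.  The
    log-likelihood is non-decreasing across iterations (EM guarantee,
    asserted in tests).

    Starts at linkage equilibrium.  If the start is exactly symmetric and
    non-identifiable (all subjects double-heterozygous), a tiny
    deterministic perturbation (+1e-6 on p_AB) breaks the tie and the
    result is flagged.
    """
    counts, n = _genotype_table(g1, g2)
    if n == 0:
        raise ValueError("no subjects genotyped at both loci")
    p1 = (counts.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)  # minor freq locus 1
    p2 = (counts.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    h = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])

    non_identifiable = False
    if counts.sum() == counts[1, 1]:  # only double heterozygotes: phase tie
        non_identifiable = True
        h = h + np.array([1e-6, 0.0, 0.0, 0.0])
        h /= h.sum()
        warnings.warn("all subjects double-heterozygous: haplotype phase not identifiable", stacklevel=2)

    n_dh = counts[1, 1]
    # unambiguous gamete counts contributed by the eight phase-certain cells
    base = np.array([
        2 * counts[2, 2] + counts[2, 1] + counts[1, 2],
        2 * counts[2, 0] + counts[2, 1] + counts[1, 0],
        2 * counts[0, 2] + counts[0, 1] + counts[1, 2],
        2 * counts[0, 0] + counts[0, 1] + counts[1, 0],
    ], dtype=float)

    ll = _loglik(h, counts)
    it = 0
    for it in range(1, max_iter + 1):
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        gametes = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        h_new = gametes / (2 * n)
        delta = np.abs(h_new - h).max()
        h = h_new
        ll = _loglik(h, counts)
        if delta < tol:
            break
    return HaplotypeFreqs(
        p_AB=float(h[0]), p_Ab=float(h[1]), p_aB=float(h[2]), p_ab=float(h[3]),
        log_likelihood=ll, n_iterations=it, n_subjects=n,
        non_identifiable=non_identifiable,
    )


def ld_stats(h: HaplotypeFreqs, n_subjects: int | None = None) -> LdStats:
    """LD summaries from haplotype frequencies.

    ``D = p_AB - p_A p_B``; ``D' = |D| / D_max`` with the sign-dependent
    bound; ``r^2 = D^2 / (p_A p_a p_B p_b)``; the association chi-square
    is ``2 n r^2`` on 1 df (n = subjects, 2n gametes).
    """
    n = h.n_subjects if n_subjects is None else n_subjects
    p_a1 = h.p_AB + h.p_Ab  # minor-allele freq, locus 1
    p_a2 = h.p_AB + h.p_aB
    if p_a1 in (0.0, 1.0) or p_a2 in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic locus")
    d = h.p_AB - p_a1 * p_a2
    if d >= 0:
        d_max = min(p_a1 * (1 - p_a2), (1 - p_a1) * p_a2)
    else:
        d_max = min(p_a1 * p_a2, (1 - p_a1) * (1 - p_a2))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    denom = p_a1 * (1 - p_a1) * p_a2 * (1 - p_a2)
    r2 = d**2 / denom
    chi2 = 2 * n * r2
    return LdStats(
        D=float(d),
        d_prime=float(min(d_prime, 1.0)),
        r_squared=float(min(r2, 1.0)),
        chi_square=float(chi2),
        p_value=float(stats.chi2.sf(chi2, 1)),
    )


def code_dominant(genotypes: pd.Series, reference: str | int, locus: str = "") -> pd.Series:
    """Dominant recoding: reference homozygote -> 0, any carrier of the
    alternate allele -> 1, missing stays missing.

    *reference* is either a genotype string like ``"C/C"`` (string input)
    or the count 0 (minor-allele-count input).
    """
    s = pd.Series(genotypes)
    out = pd.Series(pd.NA, index=s.index, dtype="Int64")
    if isinstance(reference, str):
        ref_allele = reference.split("/")[0]
        if reference != f"{ref_allele}/{ref_allele}":
            raise ValueError(f"reference genotype must be homozygous, got {reference!r}")
        alleles = set(LOCI[locus]) if locus in LOCI else None
        for idx, v in s.items():
            if pd.isna(v):
                continue
            if not isinstance(v, str) or v.count("/") != 1:
                raise ValueError(f"cannot parse genotype {v!r}")
            a, b = v.split("/")
            if alleles is not None and not {a, b} <= alleles:
                raise ValueError(f"unknown genotype {v!r} at locus {locus}")
            out[idx] = 0 if v == reference else 1
    else:
        if reference != 0:
            raise ValueError("count-coded input uses reference genotype 0")
        for idx, v in s.items():
            if pd.isna(v):
                continue
            if v not in (0, 1, 2):
                raise ValueError(f"cannot parse genotype {v!r}")
            out[idx] = 0 if v == 0 else 1
    return out


def qc_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-locus QC table: call rate, minor-allele frequency (with its
    allele), genotype counts, and the HWE chi-square/p."""
    rows = []
    for locus in LOCI:
        counts = count_genotypes(cohort[locus], locus)
        maf, allele = allele_frequencies(counts)
        hwe = hwe_test(counts)
        rows.append({
            "locus": locus,
            "pct_genotyped": round(100 * counts.call_rate),
            "minor_allele": allele,
            "maf": round(maf, 3),
            "n_hom_major": counts.n_hom_major,
            "n_het": counts.n_het,
            "n_hom_minor": counts.n_hom_minor,
            "hwe_chi2": round(hwe.chi_square, 3),
            "hwe_p": round(hwe.p_value, 4),
        })
    return pd.DataFrame(rows)
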