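"""Marker quality control: missingness, Hardy-Weinberg, MAF and male X-heterozygosity filters.

The pipeline applies filters in a configurable order and attributes each
removed SNP to the first filter that rejects it, so per-filter removal
counts always sum to n_input - n_retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import GenotypeMatrix

DEFAULT_FILTER_ORDER = ("missingness", "hwe", "maf", "x_het_males")


@dataclass
class QCConfig:
    max_missing: float = 0.10       # SNP call-missingness ceiling (strict >)
    hwe_p_threshold: float = 0.001  # exact-test floor (strict <)
    min_maf: float = 0.02           # strict <
    x_het_male_max_fraction: float = 0.0  # any het male removes by default
    max_missing_per_individual: float | None = None  # optional, default off
    filter_order: tuple = DEFAULT_FILTER_ORDER


@dataclass
class QCReport:
    """Ordered per-filter removal counts; invariant n_input - sum = n_retained."""

    n_input: int
    steps: list = field(default_factory=list)  # (filter, threshold, n_removed)

    @property
    def n_removed(self) -> int:
        return sum(s[2] for s in self.steps)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps, columns=["filter", "threshold", "n_removed"])
        return df


def snp_missingness(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of missing calls."""
    return np.isnan(matrix.calls).mean(axis=0)


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """Non-missing (n0, n1, n2) genotype counts of one SNP column."""
    c = column[~np.isnan(column)]
    return int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())


def maf(column: np.ndarray) -> float:
    """Minor allele frequency, folded to <= 0.5; missing calls excluded.

    Raises ValueError on an all-missing column.
    """
    n0, n1, n2 = genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all calls missing; MAF undefined")
    p = (2 * n2 + n1) / (2 * n)
    return min(p, 1.0 - p)


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the number of
    heterozygotes n1 under HWE has the distribution

        P(n1 | n, nA) = C * 2^n1 * n! / (n0! n1! n2!)

    over all n1 with the same parity as the minor-allele count.  The
    two-sided p sums the probabilities of every table whose probability
    does not exceed the observed table's (probability-ordering
    definition).  Computed by full enumeration in log space.
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError("counts must be non-negative with at least one genotype")
    n = n0 + n1 + n2
    # fold so nA is the minor allele count
    n_minor = 2 * n2 + n1
    if n_minor > n:  # more than half the alleles: swap homozygote roles
        n0, n2 = n2, n0
        n_minor = 2 * n2 + n1
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hets = hets[(n_minor - hets) // 2 <= n]  # implied hom-minor feasible
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    ok = hom_major >= 0
    hets, hom_minor, hom_major = hets[ok], hom_minor[ok], hom_major[ok]
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
    )
    logp -= np.logaddexp.reduce(logp)  # normalize
    probs = np.exp(logp)
    observed = probs[hets == n1]
    if observed.size == 0:  # observed table inconsistent with allele parity
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = probs[probs <= observed[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def x_het_male_fraction(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of male calls that are heterozygous (NaN-safe)."""
    males = np.asarray([s == "M" for s in matrix.sexes])
    if males.sum() == 0:
        return np.zeros(matrix.n_snps)
    calls = matrix.calls[males]
    het = (calls == 1).sum(axis=0)
    nonmiss = (~np.isnan(calls)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), 0.0)
    return frac


def _failure_masks(matrix: GenotypeMatrix, cfg: QCConfig) -> dict[str, np.ndarray]:
    """Boolean removal mask per filter (independent of order)."""
    masks: dict[str, np.ndarray] = {}
    miss = snp_missingness(matrix)
    masks["missingness"] = miss > cfg.max_missing

    hwe_p = np.ones(matrix.n_snps)
    mafs = np.zeros(matrix.n_snps)
    all_missing = np.zeros(matrix.n_snps, dtype=bool)
    for j in range(matrix.n_snps):
        n0, n1, n2 = genotype_counts(matrix.calls[:, j])
        if n0 + n1 + n2 == 0:
            all_missing[j] = True
            continue
        hwe_p[j] = hwe_exact_test(n0, n1, n2)
        p = (2 * n2 + n1) / (2 * (n0 + n1 + n2))
        mafs[j] = min(p, 1 - p)
    masks["hwe"] = hwe_p < cfg.hwe_p_threshold
    masks["maf"] = (mafs < cfg.min_maf) | all_missing

    # equine genome: 31 autosomes + X; only an explicit "X" label is a sex chromosome
    is_x = matrix.snp_map["chromosome"].astype(str).str.upper().eq("X").to_numpy()
    masks["x_het_males"] = is_x & (x_het_male_fraction(matrix) > cfg.x_het_male_max_fraction)
    return masks


def qc_pipeline(matrix: GenotypeMatrix, cfg: QCConfig | None = None):
    """Apply the configured marker filters in order.

    Returns (filtered GenotypeMatrix, QCReport).  A SNP failing several
    filters is counted once, under the first filter in
    ``cfg.filter_order`` that removes it.
    """
    cfg = cfg or QCConfig()
    masks = _failure_masks(matrix, cfg)
    thresholds = {
        "missingness": cfg.max_missing,
        "hwe": cfg.hwe_p_threshold,
        "maf": cfg.min_maf,
        "x_het_males": cfg.x_het_male_max_fraction,
    }
    report = QCReport(n_input=matrix.n_snps)
    removed = np.zeros(matrix.n_snps, dtype=bool)
    for name in cfg.filter_order:
        newly = masks[name] & ~removed
        report.steps.append((name, thresholds[name], int(newly.sum())))
        removed |= newly
    filtered = matrix.subset_snps(~removed)
    return filtered, report
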