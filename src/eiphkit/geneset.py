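"""Set-based association: windowed SNP-to-gene assignment and the sum-of-chi-squared test.

A gene set is tested by summing the chi-square(1) statistics of its
SNPs, T = sum_j F^-1(1 - p_j).  Because nearby SNPs are in linkage
disequilibrium the null of T is not chi-square(k) but a weighted sum
sum_i lambda_i chi2(1), with lambda_i the eigenvalues of the SNPs'
genotype correlation (LD) matrix R.  The upper-tail probability of the
quadratic form is evaluated by numerical inversion of its
characteristic function (Imhof's method), with a Satterthwaite
moment-matching approximation as fallback.  The LD reference is the
analysis sample itself.

SNPs are assigned to genes when they fall within the gene span extended
symmetrically by a window of 0, 5,000 or 20,000 bp; a SNP may belong to
several genes, and SNPs shared by genes of one set are counted once per
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .genio import GenotypeMatrix

GENE_COLUMNS = ["gene_id", "symbol", "chromosome", "start", "end", "tags"]
KNOWN_TAGS = ("cell_cell_adhesion", "cytoskeleton", "blood_flow",
              "stroke", "hypertension", "random")


def assign_snps_to_genes(snp_map: pd.DataFrame, genes: pd.DataFrame,
                         window: int = 0) -> dict[str, list[str]]:
    """Map gene symbol -> SNP ids within [start - window, end + window].

    Boundaries are inclusive; chromosome labels must match; strand is
    ignored (windows are symmetric).
    """
    out: dict[str, list[str]] = {}
    by_chrom = dict(tuple(snp_map.groupby(snp_map["chromosome"].astype(str))))
    for _, g in genes.iterrows():
        snps = by_chrom.get(str(g["chromosome"]))
        if snps is None:
            out[g["symbol"]] = []
            continue
        pos = snps["position"].to_numpy()
        inside = (pos >= g["start"] - window) & (pos <= g["end"] + window)
        out[g["symbol"]] = snps.loc[inside, "snp_id"].tolist()
    return out


def build_gene_sets(genes: pd.DataFrame, tags=KNOWN_TAGS) -> dict[str, list[str]]:
    """Tag -> sorted gene symbols; the ``tags`` column is comma-separated."""
    tag_lists = genes["tags"].fillna("").astype(str).str.split(",")
    sets: dict[str, list[str]] = {}
    for tag in tags:
        if tag not in KNOWN_TAGS:
            raise ValueError(f"unknown tag {tag!r}; known: {KNOWN_TAGS}")
        members = genes.loc[tag_lists.apply(lambda ts: tag in [t.strip() for t in ts]),
                            "symbol"]
        sets[tag] = sorted(members)
    return sets


def set_intersections(sets: dict[str, list[str]], orders=(2, 3)) -> pd.DataFrame:
    """Pairwise/triple intersections of gene sets, ordered by name."""
    rows = []
    names = sorted(sets)
    for r in orders:
        for combo in combinations(names, r):
            common = set(sets[combo[0]])
            for nm in combo[1:]:
                common &= set(sets[nm])
            rows.append({"sets": "&".join(combo), "order": r,
                         "n_common": len(common),
                         "genes": ",".join(sorted(common))})
    return pd.DataFrame(rows)


def ld_correlation(matrix: GenotypeMatrix, snp_ids) -> np.ndarray:
    """Pearson genotype correlation matrix for the listed SNPs.

    Pairwise-complete over missing calls; raises on a zero-variance
    column, naming the SNP.
    """
    sub = matrix.subset_snps(list(snp_ids))
    # preserve requested order
    order = {s: i for i, s in enumerate(sub.snp_map["snp_id"])}
    idx = [order[s] for s in snp_ids]
    g = sub.calls[:, idx]
    for j, s in enumerate(snp_ids):
        col = g[:, j]
        if np.nanvar(col) == 0:
            raise ValueError(f"SNP {s} has zero genotype variance")
    df = pd.DataFrame(g)
    r = df.corr(min_periods=2).to_numpy()  # pairwise-complete Pearson
    np.fill_diagonal(r, 1.0)
    return r


def quadform_tail_imhof(x: float, lambdas: np.ndarray) -> float:
    """P(sum_i lambda_i chi2_1 > x) by Imhof's characteristic-function inversion.

    Returns NaN if the numerical integral fails to converge; callers
    fall back to moment matching.
    """
    lam = np.asarray(lambdas, dtype=float)

    def theta(u):
        return 0.5 * np.arctan(lam * u).sum() - 0.5 * x * u

    def rho(u):
        return np.prod((1 + (lam * u) ** 2) ** 0.25)

    def integrand(u):
        return np.sin(theta(u)) / (u * rho(u))

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0, np.inf, limit=500)
    except Exception:
        return np.nan
    if not np.isfinite(val) or err > 1e-4:
        return np.nan
    return float(min(max(0.5 + val / np.pi, 0.0), 1.0))


def quadform_tail_satterthwaite(x: float, lambdas: np.ndarray) -> float:
    """Moment-matching c * chi2_nu approximation to the quadratic-form tail."""
    lam = np.asarray(lambdas, dtype=float)
    s1, s2 = lam.sum(), (lam ** 2).sum()
    if s2 <= 0:
        raise ValueError("all eigenvalues are zero")
    c = s2 / s1
    nu = s1 ** 2 / s2
    return float(stats.chi2.sf(x / c, df=nu))


@dataclass
class SetTestResult:
    """One row of the gene-set analysis table."""

    set_name: str
    n_genes: int
    n_snps: int
    chi_square_observed: float
    p_value: float
    top_snp_p: float
    top_snp_id: str
    method: str = "imhof"

    def to_row(self) -> dict:
        return {
            "Gene Set": self.set_name, "No Genes": self.n_genes,
            "No SNPs": self.n_snps,
            "Chi-Square (Observed)": self.chi_square_observed,
            "p-Value": self.p_value, "Top SNP p-Value": self.top_snp_p,
            "Top SNP": self.top_snp_id,
        }


def set_test(p_values, r: np.ndarray, snp_ids=None, set_name: str = "",
             n_genes: int = 0, eig_floor: float = 1e-8) -> SetTestResult:
    """Sum-of-chi-squared set test against the LD-aware quadratic-form null.

    ``p_values`` are the per-SNP association p-values (same order as the
    rows of the LD correlation matrix ``r``).  T = sum chi2_1-quantiles;
    the null is sum lambda_i chi2_1 over eigenvalues of r (negatives
    clipped to 0, values below ``eig_floor`` dropped).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size != r.shape[0]:
        raise ValueError("p-value vector and LD matrix size mismatch")
    chi2 = stats.chi2.isf(p, df=1)
    t_obs = float(chi2.sum())
    lam = np.linalg.eigvalsh((r + r.T) / 2)
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > eig_floor]
    if lam.size == 0:
        raise ValueError("LD matrix has no usable eigenvalues")
    p_set = quadform_tail_imhof(t_obs, lam)
    method = "imhof"
    if not np.isfinite(p_set):
        p_set = quadform_tail_satterthwaite(t_obs, lam)
        method = "satterthwaite"
    p_set = float(min(max(p_set, np.finfo(float).tiny), 1.0))
    top = int(np.argmin(p))
    return SetTestResult(
        set_name=set_name, n_genes=n_genes, n_snps=int(p.size),
        chi_square_observed=t_obs, p_value=p_set,
        top_snp_p=float(p[top]),
        top_snp_id=(list(snp_ids)[top] if snp_ids is not None else str(top)),
        method=method,
    )


def run_gene_set_analysis(assoc_table: pd.DataFrame, genes: pd.DataFrame,
                          sets: dict[str, list[str]], matrix: GenotypeMatrix,
                          windows=(0, 5000, 20000)) -> dict[int, pd.DataFrame]:
    """Full set analysis at each assignment window.

    ``assoc_table`` must carry snp_id and p_value columns.  For each
    window the SNPs assigned to any gene of a set are pooled
    (deduplicated), tested jointly, and emitted as one row of the
    window's table.  Sets with zero assigned (testable) SNPs produce an
    NA row.
    """
    pmap = assoc_table.set_index("snp_id")["p_value"].dropna()
    snp_map = matrix.snp_map
    out: dict[int, pd.DataFrame] = {}
    for window in windows:
        gene2snps = assign_snps_to_genes(snp_map, genes, window=window)
        rows = []
        for name, members in sets.items():
            snps: list[str] = []
            seen = set()
            for sym in members:
                for s in gene2snps.get(sym, []):
                    if s not in seen and s in pmap.index:
                        seen.add(s)
                        snps.append(s)
            # drop SNPs without genotype variance (cannot enter R)
            usable = [s for s in snps
                      if np.nanvar(matrix.column(s)) > 0]
            if not usable:
                rows.append({"Gene Set": name, "No Genes": len(members),
                             "No SNPs": 0, "Chi-Square (Observed)": np.nan,
                             "p-Value": np.nan, "Top SNP p-Value": np.nan,
                             "Top SNP": ""})
                continue
            r = ld_correlation(matrix, usable)
            res = set_test(pmap.loc[usable].to_numpy(), r, snp_ids=usable,
                           set_name=name, n_genes=len(members))
            rows.append(res.to_row())
        out[window] = pd.DataFrame(rows)
    return out
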