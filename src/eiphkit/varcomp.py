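"""Genomic relationship matrices and REML estimation of SNP heritability.

The model is the standard GREML decomposition

    y = X b + g + e,    g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2)

with G the genomic relationship matrix built from standardized dosages,
Z_ij = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),  G = Z Z' / m.  Variance
components are estimated by EM-REML (monotone in the restricted
likelihood), with standard errors from the expected information matrix
and a likelihood-ratio test of sigma_g^2 = 0 against the boundary
mixture 0.5 chi2_0 + 0.5 chi2_1.  Per-chromosome scans fit one
chromosome's GRM at a time against a residual, which is the well-posed
choice at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix


@dataclass
class GRM:
    """Genomic relationship matrix with the SNP count and ids behind it."""

    values: np.ndarray
    m_snps: int
    individuals: list = field(default_factory=list)


def build_grm(matrix: GenotypeMatrix, snp_ids=None) -> GRM:
    """GRM from observed-frequency-standardized dosages.

    Missing calls are replaced by the per-SNP mean (0 after centring);
    monomorphic SNPs in the subset are excluded with a warning.
    """
    sub = matrix if snp_ids is None else matrix.subset_snps(list(snp_ids))
    g = sub.calls
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic SNPs from GRM")
    g = g[:, poly]
    p = p[poly]
    if g.shape[1] == 0:
        raise ValueError("no polymorphic SNPs for GRM")
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.where(np.isnan(z), 0.0, z)
    m = z.shape[1]
    return GRM(values=(z @ z.T) / m, m_snps=m, individuals=list(sub.individuals))


@dataclass
class VarianceEstimate:
    """REML variance-component estimates and diagnostics."""

    sigma_g2: float
    sigma_e2: float
    se_g2: float
    se_e2: float
    loglik: float
    converged: bool
    identifiable: bool
    n_iter: int
    lrt_p: float = np.nan
    loglik_path: list = field(default_factory=list)

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else np.nan

    def summary(self) -> str:
        lines = [
            "REML variance components (y = Xb + g + e)",
            f"  sigma_g^2: {self.sigma_g2:.6g} (SE {self.se_g2:.3g})",
            f"  sigma_e^2: {self.sigma_e2:.6g} (SE {self.se_e2:.3g})",
            f"  h^2:       {self.h2:.4f}",
            f"  logL_R:    {self.loglik:.4f}  (iterations: {self.n_iter},"
            f" converged: {self.converged})",
        ]
        if np.isfinite(self.lrt_p):
            lines.append(f"  LRT p (sigma_g^2 = 0, boundary mixture): {self.lrt_p:.4g}")
        if not self.identifiable:
            lines.append("  WARNING: components not identifiable (GRM ~ identity)")
        return "\n".join(lines)


class GREMLModel:
    """REML model of a phenotype with one genomic variance component.

    Parameters
    ----------
    phenotype : array-like (n,)
    grm : GRM or ndarray
    covariates : optional fixed-effect design (intercept added automatically).
    """

    def __init__(self, phenotype, grm, covariates=None):
        y = np.asarray(phenotype, dtype=float)
        gmat = grm.values if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
        if gmat.shape[0] != y.size:
            raise ValueError("GRM dimension must match phenotype length")
        if covariates is None:
            x = np.ones((y.size, 1))
        else:
            c = np.asarray(covariates, dtype=float)
            if c.ndim == 1:
                c = c[:, None]
            x = np.column_stack([np.ones(y.size), c])
        keep = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
        self.y = y[keep]
        self.x = x[keep]
        self.gmat = gmat[np.ix_(keep, keep)]
        # rotate into the GRM eigenbasis: the covariance is diagonal there
        s, u = np.linalg.eigh((self.gmat + self.gmat.T) / 2)
        self.s = np.clip(s, 0.0, None)
        self.ystar = u.T @ self.y
        self.xstar = u.T @ self.x
        self.n = self.y.size
        self.identifiable = float(np.ptp(self.s)) > 1e-8

    # -- restricted likelihood machinery (diagonal V in the eigenbasis) --

    def _pieces(self, sg2: float, se2: float):
        v = sg2 * self.s + se2
        vinv = 1.0 / v
        xv = self.xstar * vinv[:, None]          # V^-1 X
        xvx = self.xstar.T @ xv
        b = np.linalg.inv(xvx)
        py = vinv * self.ystar - xv @ (b @ (xv.T @ self.ystar))
        return v, vinv, xv, xvx, b, py

    def reml_loglik(self, sg2: float, se2: float) -> float:
        """Restricted log-likelihood at (sigma_g^2, sigma_e^2), constant dropped."""
        v, vinv, xv, xvx, b, py = self._pieces(sg2, se2)
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        return float(-0.5 * (np.log(v).sum() + logdet_xvx + self.ystar @ py))

    def fit(self, max_iter: int = 200, tol: float = 1e-8,
            start: tuple[float, float] | None = None,
            compute_lrt: bool = True, polish: bool = True) -> VarianceEstimate:
        """EM-REML fit; the restricted likelihood is monotone across iterations.

        Starting values default to half the phenotypic variance for each
        component.  Variances are truncated at a small positive floor
        (boundary constraint).  Non-convergence returns the last
        iterate, flagged.
        """
        var_y = float(np.var(self.y, ddof=1))
        floor = max(var_y, 1e-12) * 1e-8
        sg2, se2 = start if start is not None else (var_y / 2, var_y / 2)
        sg2, se2 = max(sg2, floor), max(se2, floor)
        path = [self.reml_loglik(sg2, se2)]
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            v, vinv, xv, xvx, b, py = self._pieces(sg2, se2)
            # tr(P A) = tr(V^-1 A) - tr(B X'V^-1 A V^-1 X), A diagonal (S or I)
            w = xv  # V^-1 X in eigenbasis
            tr_pg = float(vinv @ self.s) - float(np.einsum("ij,ij->", w @ b, self.s[:, None] * w))
            tr_pe = float(vinv.sum()) - float(np.einsum("ij,ij->", w @ b, w))
            ypgpy = float(py @ (self.s * py))
            ypepy = float(py @ py)
            sg2_new = sg2 + (sg2 ** 2 / self.n) * (ypgpy - tr_pg)
            se2_new = se2 + (se2 ** 2 / self.n) * (ypepy - tr_pe)
            sg2_new, se2_new = max(sg2_new, floor), max(se2_new, floor)
            ll = self.reml_loglik(sg2_new, se2_new)
            path.append(ll)
            delta = max(abs(sg2_new - sg2), abs(se2_new - se2))
            sg2, se2 = sg2_new, se2_new
            if delta < tol * max(var_y, 1e-12):
                converged = True
                break
        if polish:
            # EM is slow near a variance boundary; a deterministic simplex
            # polish on the log scale sharpens the optimum.  Accepted only
            # if it improves the restricted likelihood, so the recorded
            # path stays monotone.
            from scipy import optimize

            def nll(logv):
                return -self.reml_loglik(float(np.exp(logv[0])), float(np.exp(logv[1])))

            res = optimize.minimize(
                nll, np.log([max(sg2, floor), max(se2, floor)]),
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 600})
            if -res.fun > path[-1]:
                sg2, se2 = (float(max(v, floor)) for v in np.exp(res.x))
                path.append(float(-res.fun))
                converged = converged or bool(res.success)
        se_g2, se_e2 = self._information_se(sg2, se2)
        lrt_p = np.nan
        if compute_lrt and self.identifiable:
            ll_full = path[-1]
            ll_null = self._null_loglik()
            lrt = max(0.0, 2 * (ll_full - ll_null))
            lrt_p = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0
        return VarianceEstimate(
            sigma_g2=sg2, sigma_e2=se2, se_g2=se_g2, se_e2=se_e2,
            loglik=path[-1], converged=converged,
            identifiable=self.identifiable, n_iter=n_iter,
            lrt_p=lrt_p, loglik_path=path,
        )

    def _null_loglik(self) -> float:
        """Restricted log-likelihood of the sigma_g^2 = 0 model (closed form in se2)."""
        # profile: with V = se2 I, REML of se2 is RSS/(n - k)
        q, _ = np.linalg.qr(self.xstar)
        resid = self.ystar - q @ (q.T @ self.ystar)
        k = self.xstar.shape[1]
        se2 = float(resid @ resid) / (self.n - k)
        return self.reml_loglik(0.0, se2) if se2 > 0 else -np.inf

    def _information_se(self, sg2: float, se2: float):
        """SEs from the expected (Fisher) information of the variance components."""
        v, vinv, xv, xvx, b, py = self._pieces(sg2, se2)
        # form P explicitly in the eigenbasis (n x n; fine at study scale)
        p = np.diag(vinv) - xv @ b @ xv.T
        ps = p * self.s[None, :]       # P diag(S)
        i_gg = 0.5 * np.einsum("ij,ji->", ps, ps)
        i_ge = 0.5 * np.einsum("ij,ji->", ps, p)
        i_ee = 0.5 * np.einsum("ij,ji->", p, p)
        info = np.array([[i_gg, i_ge], [i_ge, i_ee]])
        try:
            cov = np.linalg.inv(info)
            return float(np.sqrt(max(cov[0, 0], 0))), float(np.sqrt(max(cov[1, 1], 0)))
        except np.linalg.LinAlgError:
            return np.nan, np.nan


def write_grm(grm: GRM, prefix) -> None:
    """Write a GRM as lower-triangle TSV (i, j, m_snps, value) with an id sidecar."""
    n = grm.values.shape[0]
    with open(f"{prefix}.grm.tsv", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t{grm.values[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for ind in grm.individuals:
            fh.write(f"{ind}\n")


def read_grm(prefix) -> GRM:
    tab = pd.read_csv(f"{prefix}.grm.tsv", sep="\t",
                      names=["i", "j", "m_snps", "value"])
    ids = [l.strip() for l in open(f"{prefix}.grm.id") if l.strip()]
    n = len(ids)
    values = np.zeros((n, n))
    values[tab["i"] - 1, tab["j"] - 1] = tab["value"]
    values[tab["j"] - 1, tab["i"] - 1] = tab["value"]
    return GRM(values=values, m_snps=int(tab["m_snps"].iloc[0]), individuals=ids)


def reml_fit(phenotype, grm, covariates=None, max_iter: int = 200,
             tol: float = 1e-8) -> VarianceEstimate:
    """Functional wrapper: fit the one-component GREML model."""
    return GREMLModel(phenotype, grm, covariates).fit(max_iter=max_iter, tol=tol)


def per_chromosome_scan(phenotype, matrix: GenotypeMatrix, covariates=None,
                        min_snps: int = 10) -> pd.DataFrame:
    """One REML fit per chromosome GRM, each against its own residual.

    Chromosomes with fewer than ``min_snps`` SNPs are skipped with a
    warning.  Returns a table (chromosome, m_snps, sigma_g2, se_g2,
    sigma_e2, se_e2, h2, lrt_p) sorted by chromosome.
    """
    rows = []
    for chrom, grp in matrix.snp_map.groupby("chromosome", sort=False):
        if len(grp) < min_snps:
            warnings.warn(f"chromosome {chrom}: only {len(grp)} SNPs, skipped")
            continue
        mask = matrix.snp_map["chromosome"].to_numpy() == chrom
        grm = build_grm(matrix.subset_snps(mask))
        est = reml_fit(phenotype, grm, covariates)
        rows.append({
            "chromosome": chrom, "m_snps": grm.m_snps,
            "sigma_g2": est.sigma_g2, "se_g2": est.se_g2,
            "sigma_e2": est.sigma_e2, "se_e2": est.se_e2,
            "h2": est.h2, "lrt_p": est.lrt_p,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("chromosome", key=lambda s: s.astype(str)).reset_index(drop=True)
    return df
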