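"""Population and family structure: pairwise IBS, classical MDS, permutation test.

Pairwise identity-by-state (IBS) at dosage-coded biallelic SNPs is the
mean over shared non-missing markers of (2 - |g_i - g_j|)/2.  The IBS
matrix is visualised by classical (Torgerson) multidimensional scaling
of the distance D = 1 - IBS, and a label-permutation test asks whether
case/control group membership explains any of the variance in pairwise
IBS — the standard check that a family-structured cohort is not
stratified along the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix


def ibs_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Symmetric n x n matrix of pairwise IBS proportions in [0, 1].

    Pair (i, j) averages (2 - |g_i - g_j|)/2 over SNPs non-missing in
    both individuals; the diagonal is exactly 1.  Raises if some pair
    shares no non-missing SNP.
    """
    g = matrix.calls
    n = g.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    mask = ~np.isnan(g)
    gz = np.where(mask, g, 0.0)
    m = mask.astype(float)
    shared = m @ m.T  # SNPs non-missing in both
    if (shared[~np.eye(n, dtype=bool)] == 0).any():
        raise ValueError("some pair of individuals shares no non-missing SNP")
    # sum |gi - gj| over shared SNPs: expand via the three dosage levels
    abs_sum = np.zeros((n, n))
    levels = (0.0, 1.0, 2.0)
    ind = {v: ((gz == v) & mask).astype(float) for v in levels}
    for a in levels:
        for b in levels:
            d = abs(a - b)
            if d:
                abs_sum += d * (ind[a] @ ind[b].T)
    ibs = 1.0 - abs_sum / (2.0 * shared)
    np.fill_diagonal(ibs, 1.0)
    return ibs


def mds(ibs: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical MDS coordinates from an IBS matrix.

    Double-centres the squared distance D = 1 - IBS and returns the
    top-k eigenvectors scaled by sqrt(eigenvalue).  Axis signs are fixed
    so each axis's largest-magnitude loading is positive, making plots
    reproducible.  If fewer than k eigenvalues are positive, the extra
    axes are dropped.
    """
    d = 1.0 - np.asarray(ibs, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    k_eff = min(k, int(pos.sum()))
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for axis in range(k_eff):
        imax = np.argmax(np.abs(coords[:, axis]))
        if coords[imax, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return coords


@dataclass
class PermutationTestResult:
    statistic: float   # between-group proportion of variance in pairwise IBS
    p_value: float
    n_perm: int


def _between_group_variance_proportion(ibs: np.ndarray, labels: np.ndarray) -> float:
    """Between-group SS / total SS of off-diagonal pairwise IBS values.

    Pairs are classified within-case, within-control or between-group;
    the statistic is the usual one-way ANOVA variance proportion across
    those three pair classes.
    """
    n = ibs.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = ibs[iu]
    li, lj = labels[iu[0]], labels[iu[1]]
    cls = np.where(li == lj, np.where(li, 1, 0), 2)  # 0 ctrl-ctrl, 1 case-case, 2 between
    grand = vals.mean()
    ss_total = ((vals - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for c in (0, 1, 2):
        sel = vals[cls == c]
        if sel.size:
            ss_between += sel.size * (sel.mean() - grand) ** 2
    return float(ss_between / ss_total)


def group_ibs_permutation_test(
    ibs: np.ndarray,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test for between-group differences in pairwise IBS.

    ``labels`` is a boolean case indicator per individual.  The observed
    statistic is the proportion of variance in off-diagonal IBS values
    explained by pair class; the p-value is (1 + #{permuted >= observed})
    / (1 + n_perm) under size-preserving label permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = _between_group_variance_proportion(ibs, labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _between_group_variance_proportion(ibs, perm) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(statistic=observed, p_value=p, n_perm=n_perm)


def cluster_separation(coords: np.ndarray, families) -> float:
    """Ratio of between-family to within-family dispersion in MDS space.

    ``families`` labels each individual with a family id (a background
    cohort may share one id).  Returns the ratio of the mean squared
    distance between family centroids and the grand centroid to the mean
    squared within-family deviation — large values mean families form
    outlying clusters.
    """
    families = np.asarray(families)
    grand = coords.mean(axis=0)
    between, within, k = 0.0, 0.0, 0
    for fam in np.unique(families):
        pts = coords[families == fam]
        cen = pts.mean(axis=0)
        between += ((cen - grand) ** 2).sum()
        within += ((pts - cen) ** 2).sum() / max(len(pts), 1)
        k += 1
    return float(between / max(within / k, 1e-300) / k) if k else 0.0
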